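"""Data containers for multichannel recordings, events, and epochs.

A :class:`Recording` holds a continuous channels x samples array at a fixed
sampling rate together with an event table (stimulus onsets, articulation
onsets, acoustic-edge annotations, ...) and an optional electrode table
(coordinates, region labels, hemisphere/dominance flags, positions along
the mediolateral and anteroposterior axes of the supratemporal plane).

Recordings round-trip losslessly through an HDF5 container::

    /data          float array, channels x samples
    /sample_rate   scalar
    /channel_ids   string array
    /events/...    one dataset per event-table column
    /electrodes/...one dataset per electrode-table column (optional)

Event and electrode tables also round-trip through TSV for interoperability
with annotation tooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "Recording",
    "EpochSet",
    "EVENT_COLUMNS",
    "ELECTRODE_COLUMNS",
    "read_recording",
    "write_recording",
    "read_table_tsv",
    "write_table_tsv",
    "epoch",
]

EVENT_COLUMNS = ["onset_s", "duration_s", "type", "trial_id"]
ELECTRODE_COLUMNS = [
    "id",
    "x",
    "y",
    "z",
    "region",
    "hemisphere",
    "dominant",
    "mediolateral_pos_mm",
    "anteroposterior_pos_mm",
]

#: default baseline window relative to the alignment event, seconds
DEFAULT_BASELINE = (-0.300, -0.050)


class FormatError(ValueError):
    """Raised when a container file is missing required datasets."""


@dataclass
class Recording:
    """Continuous multichannel recording with events and electrode metadata."""

    data: np.ndarray  # channels x samples
    sample_rate_hz: float
    channel_ids: list[str]
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS))
    electrodes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError("channel_ids do not match data rows")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        if self.electrodes is not None:
            known = set(self.electrodes["id"].astype(str))
            if not set(self.channel_ids) <= known:
                raise ValueError("channel_ids missing from electrode table")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def events_of_type(self, event_type: str) -> pd.DataFrame:
        return self.events[self.events["type"] == event_type].reset_index(drop=True)

    def select_channels(self, keep: list[str]) -> "Recording":
        idx = [self.channel_ids.index(c) for c in keep]
        elec = self.electrodes
        if elec is not None:
            elec = elec[elec["id"].astype(str).isin(keep)].reset_index(drop=True)
        return replace(self, data=self.data[idx], channel_ids=list(keep), electrodes=elec)


@dataclass
class EpochSet:
    """Electrodes x trials x time array aligned to an event type.

    ``times`` is relative to the alignment event (seconds, 0 at the event);
    the baseline window defaults to -300..-50 ms.
    """

    data: np.ndarray  # electrodes x trials x time
    sample_rate_hz: float
    times: np.ndarray
    channel_ids: list[str]
    alignment: str = "stimulus_onset"
    baseline_window: tuple[float, float] = DEFAULT_BASELINE
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be electrodes x trials x time")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis mismatch")
        b0, b1 = self.baseline_window
        if b0 < self.times[0] - 1e-9 or b1 > self.times[-1] + 1e-9:
            raise ValueError("baseline window lies outside the epoch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    def baseline_mask(self) -> np.ndarray:
        from ._util import window_slice

        return window_slice(self.times, self.baseline_window)


# ---------------------------------------------------------------------------
# persistence


def _write_frame(group: h5py.Group, frame: pd.DataFrame) -> None:
    for col in frame.columns:
        values = frame[col].to_numpy()
        if values.dtype == object or values.dtype.kind in "U":
            values = np.asarray([str(v) for v in values], dtype="S")
        group.create_dataset(col, data=values)


def _read_frame(group: h5py.Group, columns: list[str]) -> pd.DataFrame:
    out = {}
    for col in columns:
        if col not in group:
            continue
        values = group[col][()]
        if values.dtype.kind == "S":
            values = np.asarray([v.decode() for v in values])
        out[col] = values
    return pd.DataFrame(out)


def write_recording(recording: Recording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
        f.create_dataset("sample_rate", data=float(recording.sample_rate_hz))
        f.create_dataset("channel_ids", data=np.asarray(recording.channel_ids, dtype="S"))
        _write_frame(f.create_group("events"), recording.events)
        if recording.electrodes is not None:
            _write_frame(f.create_group("electrodes"), recording.electrodes)


def read_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        for required in ("data", "sample_rate", "channel_ids"):
            if required not in f:
                raise FormatError(f"missing dataset /{required}")
        data = f["data"][()]
        fs = float(f["sample_rate"][()])
        channel_ids = [c.decode() for c in f["channel_ids"][()]]
        events = _read_frame(f["events"], EVENT_COLUMNS) if "events" in f else None
        electrodes = _read_frame(f["electrodes"], ELECTRODE_COLUMNS) if "electrodes" in f else None
    if events is None or events.empty:
        events = pd.DataFrame(columns=EVENT_COLUMNS)
    else:
        events = events[EVENT_COLUMNS]
        if events["onset_s"].max() > data.shape[1] / fs:
            raise FormatError("event onsets exceed recording duration (sample-rate mismatch?)")
    if electrodes is not None and electrodes.empty:
        electrodes = None
    if electrodes is not None:
        electrodes["dominant"] = electrodes["dominant"].astype(str).isin(("True", "true", "1"))
    return Recording(data, fs, channel_ids, events, electrodes)


def write_table_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_table_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# epoching


def epoch(
    recording: Recording,
    event_type: str,
    window_s: tuple[float, float],
    baseline_window: tuple[float, float] = DEFAULT_BASELINE,
) -> EpochSet:
    """Slice the recording around every event of ``event_type``.

    Trials whose window falls outside the recording are dropped with a
    warning; the count of dropped trials is kept on the result. Windows are
    half-open in samples, ``[start, end)``.
    """
    fs = recording.sample_rate_hz
    w0, w1 = window_s
    n_time = int(round((w1 - w0) * fs))
    if n_time <= 0:
        raise ValueError("empty epoch window")
    times = w0 + np.arange(n_time) / fs
    events = recording.events_of_type(event_type)
    if events.empty:
        raise ValueError(f"no events of type {event_type!r}")

    slices, dropped = [], 0
    for onset in events["onset_s"].to_numpy():
        start = int(round((onset + w0) * fs))
        if start < 0 or start + n_time > recording.n_samples:
            dropped += 1
            continue
        slices.append(recording.data[:, start : start + n_time])
    if dropped:
        warnings.warn(f"dropped {dropped} trial(s) outside recording bounds", stacklevel=2)
    if not slices:
        raise ValueError("all trials fell outside the recording")
    data = np.stack(slices, axis=1)  # electrodes x trials x time
    return EpochSet(
        data,
        fs,
        times,
        list(recording.channel_ids),
        alignment=event_type,
        baseline_window=baseline_window,
        n_dropped=dropped,
    )
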