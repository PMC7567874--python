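#!/usr/bin/env python
"""Envelope and edge encoding of speech-like stimuli.

Speech-like envelopes (planted edge/syllable annotations) drive synthetic
neural series: band amplitudes tracking the envelope at frequency-specific
delays (low 135 ms and beta 95 ms, anti-correlated; high-gamma 45 ms,
positively correlated) and a low-frequency phase reset at acoustic edges.
The analyses recover the lags by lagged Spearman correlation, re-detect the
edges, and contrast post-edge phase organization against syllable onsets.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from audiopred import speech as sp
from audiopred.containers import write_table_tsv
from audiopred.simulate import simulate_reset_phase_series
from audiopred.stimuli import make_speech_like_envelope

OUT = Path("results")
FS = 1000.0


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(4)
    sentences = make_speech_like_envelope(n_sentences=20, seed=3)
    env = np.concatenate([s.envelope for s in sentences])
    mask = sp.trial_boundary_mask([len(s.envelope) for s in sentences], FS)

    # planted frequency-specific lags (sign mirrors the band's relation to
    # the envelope: low/beta anti-correlated, high-gamma positive)
    planted = {"low": (135, -1.0), "beta": (95, -1.0), "high_gamma": (45, +1.0)}
    rows = []
    for band, (lag_ms, sign) in planted.items():
        neural = sign * np.roll(env, int(lag_ms)) + rng.normal(0, 0.5 * env.std(), len(env))
        curve, peak_lag, rho = sp.lagged_spearman(neural, env, FS, max_lag_ms=300, valid_mask=mask)
        write_table_tsv(curve, OUT / f"speech_lag_curve_{band}.tsv")
        rows.append({"band": band, "planted_lag_ms": lag_ms, "recovered_lag_ms": peak_lag, "rho": rho})
    lags = pd.DataFrame(rows)
    write_table_tsv(lags, OUT / "speech_lag_recovery.tsv")
    print("lagged Spearman correlation with the speech envelope:")
    print(lags.to_string(index=False))

    # edge re-detection against the planted annotation
    tp = fp = fn = 0
    for s in sentences:
        ann = sp.detect_edges(sp.EnvelopeTrace(s.times, s.envelope, FS, 10.0))
        matched = np.zeros(len(s.edge_times), bool)
        for t in ann.edge_times:
            d = np.abs(s.edge_times - t)
            if len(d) and d.min() < 0.06 and not matched[d.argmin()]:
                matched[d.argmin()] = True
                tp += 1
            else:
                fp += 1
        fn += int((~matched).sum())
    print(f"\nedge detection: precision {tp / (tp + fp):.3f}, recall {tp / (tp + fn):.3f}")

    # post-edge phase organization, edges vs syllable onsets
    fs_neural = 500.0
    edges, sylls, offset = [], [], 0.5
    for s in sentences:
        edges.extend(offset + s.edge_times)
        sylls.extend(offset + s.syllable_times)
        offset += s.duration_s + 0.5
    phase = simulate_reset_phase_series(12, offset + 0.5, fs_neural, np.array(edges), rng=7)
    table = sp.post_edge_itc(phase, fs_neural, np.array(edges), np.array(sylls))
    p = sp.edge_vs_syllable_test(table)
    write_table_tsv(table, OUT / "speech_post_edge_itc.tsv")
    print(
        f"post-edge ITC {table['edge_itc'].mean():.3f} vs post-syllable {table['syllable_itc'].mean():.3f} "
        f"(Wilcoxon one-sided p = {p:.2g})"
    )


if __name__ == "__main__":
    main()
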