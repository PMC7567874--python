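"""Sustained/transient response classification with two-basis NNMF.

A non-negative feature matrix A (m electrodes x n time points; rectified
trial-mean high-gamma percent-change power, or rectified ITC change) is
factorized as A ~ W H with rank k = 2 by multiplicative (Lee-Seung,
Frobenius) updates, restarted from many random initializations and keeping
the replicate with the smallest residual. The two archetypes (rows of H)
recover a sustained, envelope-locked comb and a transient onset bump; the
row of H is normalized to unit maximum, with the compensating scale folded
into W, so the per-electrode class weights are in the units of the feature
itself. Class bias = sustained weight minus transient weight, response
magnitude = their sum; a binary bias threshold (default 10) yields discrete
classifications, and electrodes whose power- and phase-based biases
disagree in sign (both above threshold) are "mixed".

Archetypes fitted on listening epochs transfer to articulation epochs by
conserving H and recomputing W = A H^+ (Moore-Penrose right pseudo-inverse;
non-negative least squares available as a stricter option), which tests
whether each response class survives self-generated speech.

Also here: the anatomical-gradient statistic (Spearman correlation of class
bias with anteroposterior position over high-magnitude electrodes), peak
electrode selection, and traveling-wave velocity estimation from
high-gamma peak times along the mediolateral axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "rectify",
    "NNMFModel",
    "nnmf_fit",
    "orient_model",
    "classify",
    "classify_joint",
    "transfer_weights",
    "gradient_correlation",
    "select_peak_electrode",
    "WaveFit",
    "traveling_wave_fit",
]

_EPS = 1e-12


def rectify(series: np.ndarray, baseline: float | np.ndarray = 0.0) -> np.ndarray:
    """Half-wave rectification of a baseline-referenced feature:
    ``max(series - baseline, 0)`` — anything at or below baseline is 0."""
    return np.clip(np.asarray(series, dtype=float) - baseline, 0.0, None)


@dataclass
class NNMFModel:
    W: np.ndarray  # m x k class weights
    H: np.ndarray  # k x n class archetypes (rows max-normalized)
    residual: float
    k: int = 2
    seed: int = 0
    n_replicates: int = 1
    converged: bool = True
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    sustained_index: int = 0

    @property
    def class_bias(self) -> np.ndarray:
        """Sustained weight minus transient weight per electrode."""
        transient = 1 - self.sustained_index
        return self.W[:, self.sustained_index] - self.W[:, transient]

    @property
    def response_magnitude(self) -> np.ndarray:
        return np.abs(self.W).sum(axis=1)


def _mu_factorize(A, k, rng, max_iter, tol):
    m, n = A.shape
    scale = np.sqrt(A.mean() / k) + _EPS
    W = rng.uniform(0.1, 1.0, size=(m, k)) * scale
    H = rng.uniform(0.1, 1.0, size=(k, n)) * scale
    history = []
    prev = None
    for _ in range(max_iter):
        H *= (W.T @ A) / (W.T @ W @ H + _EPS)
        W *= (A @ H.T) / (W @ (H @ H.T) + _EPS)
        obj = float(np.linalg.norm(A - W @ H, "fro"))
        history.append(obj)
        if prev is not None and prev - obj <= tol * max(prev, _EPS):
            return W, H, obj, np.asarray(history), True
        prev = obj
    return W, H, history[-1], np.asarray(history), False


def nnmf_fit(
    A: np.ndarray,
    k: int = 2,
    n_replicates: int = 1000,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int = 0,
) -> NNMFModel:
    """Best-of-``n_replicates`` multiplicative-update factorization.

    Each replicate starts from a random non-negative initialization seeded
    deterministically from ``seed`` and a replicate counter; the model with
    the smallest Frobenius residual is returned (ties by first). The
    multiplicative updates make the objective non-increasing within each
    replicate; rows of H are max-normalized afterwards with the scale
    folded into W.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] < k:
        raise ValueError("A must be m x n with m >= k")
    if np.any(A < 0):
        raise ValueError("A must be non-negative")
    if not np.any(A > 0):
        raise ValueError("A is identically zero")

    best = None
    for r in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(r,)))
        W, H, obj, history, converged = _mu_factorize(A, k, rng, max_iter, tol)
        if best is None or obj < best[2]:
            best = (W, H, obj, history, converged)
    W, H, obj, history, converged = best

    norms = H.max(axis=1)
    norms[norms <= 0] = 1.0
    H = H / norms[:, None]
    W = W * norms[None, :]
    return NNMFModel(W, H, obj, k, seed, n_replicates, converged, history)


def orient_model(model: NNMFModel, sustained_template: np.ndarray) -> NNMFModel:
    """Identify which archetype is the sustained one.

    The archetype correlating best with a canonical sustained template (a
    comb at the modulation frequency over the rhythmic period) is labeled
    sustained; ``class_bias`` then has sustained-positive sign.
    """
    if model.k != 2:
        raise ValueError("orientation defined for k = 2")
    corr = [np.corrcoef(h, sustained_template)[0, 1] for h in model.H]
    model.sustained_index = int(np.argmax(corr))
    return model


def classify(bias: np.ndarray, bias_threshold: float = 10.0) -> np.ndarray:
    """Threshold a (sustained-positive) class bias into discrete labels."""
    bias = np.asarray(bias, dtype=float)
    labels = np.full(bias.shape, "unclassified", dtype=object)
    labels[bias > bias_threshold] = "sustained"
    labels[bias < -bias_threshold] = "transient"
    return labels


def classify_joint(
    bias_power: np.ndarray, bias_itc: np.ndarray, bias_threshold: float = 10.0
) -> np.ndarray:
    """Joint classification from power- and phase-based biases.

    Electrodes qualifying (|bias| > threshold) in both measures with
    opposite signs are "mixed"; agreement (or a single qualifying measure)
    gives sustained/transient; neither qualifying gives "unclassified".
    """
    p = classify(bias_power, bias_threshold)
    q = classify(bias_itc, bias_threshold)
    out = np.full(p.shape, "unclassified", dtype=object)
    for i in range(len(out)):
        kinds = {p[i], q[i]} - {"unclassified"}
        if kinds == {"sustained", "transient"}:
            out[i] = "mixed"
        elif len(kinds) == 1:
            out[i] = kinds.pop()
    return out


def transfer_weights(model: NNMFModel, A_new: np.ndarray, method: str = "pinv") -> np.ndarray:
    """Recompute class weights for new epochs with conserved archetypes.

    ``pinv``: W = A H^+ (right pseudo-inverse), negative weights rectified
    to zero. ``nnls``: per-electrode non-negative least squares.
    """
    A_new = np.asarray(A_new, dtype=float)
    H = model.H
    if A_new.shape[1] != H.shape[1]:
        raise ValueError("new feature matrix does not match archetype time axis")
    if np.linalg.matrix_rank(H) < model.k:
        raise ValueError("degenerate archetypes (rank < k)")
    if method == "pinv":
        W = A_new @ np.linalg.pinv(H)
        return np.clip(W, 0.0, None)
    if method == "nnls":
        return np.stack([optimize.nnls(H.T, row)[0] for row in A_new])
    raise ValueError(f"unknown method {method!r}")


def gradient_correlation(
    bias: np.ndarray,
    magnitude: np.ndarray,
    anteroposterior_pos_mm: np.ndarray,
    magnitude_min: float = 10.0,
) -> tuple[float, float, int]:
    """Spearman correlation of class bias with anteroposterior position
    over electrodes with response magnitude above ``magnitude_min``.

    Sign convention: bias is sustained-positive and position increases
    posteriorly, so an anterior-sustained / posterior-transient gradient
    gives a negative correlation; callers wanting "transient-posterior
    positive" can flip the bias sign.
    """
    mask = np.asarray(magnitude) > magnitude_min
    if mask.sum() < 5:
        raise ValueError("fewer than 5 electrodes above the magnitude threshold")
    res = stats.spearmanr(np.asarray(bias)[mask], np.asarray(anteroposterior_pos_mm)[mask])
    return float(res.statistic), float(res.pvalue), int(mask.sum())


def select_peak_electrode(summary: pd.DataFrame, measure: str, by: str = "subject") -> pd.DataFrame:
    """Most active electrode per subject: argmax of ``measure`` with a
    deterministic lexicographic tie-break on electrode id."""
    frames = []
    for _, sub in summary.groupby(by):
        sub = sub.sort_values([measure, "electrode"], ascending=[False, True], kind="mergesort")
        frames.append(sub.iloc[:1])
    return pd.concat(frames, ignore_index=True)


@dataclass
class WaveFit:
    velocity_m_per_s: float | None
    direction: str | None
    per_pulse: pd.DataFrame
    n_valid: int

    @property
    def defined(self) -> bool:
        return self.velocity_m_per_s is not None


def traveling_wave_fit(
    peak_times_ms: np.ndarray,
    mediolateral_pos_mm: np.ndarray,
    r2_min: float = 0.5,
) -> WaveFit:
    """Velocity of a traveling wave from per-pulse peak times.

    For each pulse, peak time is regressed on mediolateral position with a
    robust (Theil-Sen) slope; velocity = 1/slope (mm/ms = m/s). Pulses with
    a poor or non-positive fit (Pearson R^2 < ``r2_min``) are flagged; the
    mean wave averages the valid per-pulse velocities. The fit is undefined
    when fewer than half the pulses are valid.
    """
    peak_times_ms = np.atleast_2d(np.asarray(peak_times_ms, dtype=float))
    pos = np.asarray(mediolateral_pos_mm, dtype=float)
    if peak_times_ms.shape[1] != len(pos) or len(pos) < 4:
        raise ValueError("need peak times for >= 4 electrodes")
    rows = []
    for pulse, t in enumerate(peak_times_ms):
        slope = stats.theilslopes(t, pos).slope
        r = stats.pearsonr(pos, t).statistic
        r2 = float(r**2)
        valid = bool(r2 >= r2_min and slope > 0)
        rows.append(
            {
                "pulse": pulse,
                "slope_ms_per_mm": float(slope),
                "r2": r2,
                "velocity_m_per_s": 1.0 / slope if valid else np.nan,
                "valid": valid,
            }
        )
    per_pulse = pd.DataFrame(rows)
    n_valid = int(per_pulse["valid"].sum())
    if n_valid < max(1, len(per_pulse) // 2):
        return WaveFit(None, None, per_pulse, n_valid)
    velocity = float(per_pulse.loc[per_pulse["valid"], "velocity_m_per_s"].mean())
    return WaveFit(velocity, "medial_to_lateral", per_pulse, n_valid)
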