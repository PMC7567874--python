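"""Small shared helpers (RNG plumbing, window arithmetic)."""

from __future__ import annotations

import numpy as np

__all__ = ["as_rng", "stage_rng", "window_slice"]


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Return a numpy Generator from a seed, an existing Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def stage_rng(master_seed: int, stage: int) -> np.random.Generator:
    """Derive an independent per-stage Generator from a master seed.

    Stages are numbered; each gets a child of ``SeedSequence(master_seed)``
    so they are independently re-runnable and jointly reproducible.
    """
    return np.random.default_rng(np.random.SeedSequence(master_seed).spawn(stage + 1)[stage])


def window_slice(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Boolean mask selecting samples with ``window[0] <= t < window[1]``."""
    t0, t1 = window
    if not t1 > t0:
        raise ValueError(f"empty window {window!r}")
    return (times >= t0) & (times < t1)
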