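"""Detection-task and chronometric-stimulation statistics.

Detection accuracy is summarized per tone level (hit rate on tone-present
trials; overall accuracy including correct rejections is reported
separately) and, within the lowest level, per temporal position; the
position-2 contrast is the behavioral signature of temporal prediction at
the first missing pulse's rising edge. Stimulation outcomes are compared
with a pooled-variance two-proportion z test, one-sided by default (the
direction being that edge-locked stimulation of early auditory cortex
degrades performance).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "accuracy_by_condition",
    "position_effect_test",
    "two_proportion_z",
    "reconstruct_counts",
]


def _binomial_se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1 - p) / n)) if n else np.nan


def accuracy_by_condition(trials: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Hit rates per level, per (level, position), and overall accuracy.

    ``by_level`` / ``by_level_position``: hit rate on tone-present trials
    with binomial standard errors; ``overall``: accuracy over all trials
    (hits + correct rejections). Empty cells appear with NaN rate.
    """
    present = trials[trials["tone_present"]]

    def rates(group_cols) -> pd.DataFrame:
        rows = []
        groups = present.groupby(group_cols) if len(present) else []
        for key, sub in groups:
            key = key if isinstance(key, tuple) else (key,)
            n = len(sub)
            p = float(sub["response"].mean())
            rows.append(dict(zip(group_cols, key), hit_rate=p, n=n, se=_binomial_se(p, n)))
        return pd.DataFrame(rows)

    correct = np.where(trials["tone_present"], trials["response"], ~trials["response"])
    overall = pd.DataFrame(
        {
            "accuracy": [float(np.mean(correct))],
            "n": [len(trials)],
            "se": [_binomial_se(float(np.mean(correct)), len(trials))],
        }
    )
    return {
        "by_level": rates(["level_index"]),
        "by_level_position": rates(["level_index", "position_index"]),
        "overall": overall,
    }


def per_subject_position_rates(trials: pd.DataFrame, level_index: int = 1) -> pd.DataFrame:
    """Subjects x positions hit-rate table at one intensity level."""
    sub = trials[trials["tone_present"] & (trials["level_index"] == level_index)]
    table = sub.groupby(["subject_id", "position_index"])["response"].mean().unstack()
    return table


def position_effect_test(
    position_rates: pd.DataFrame,
    target_position: int = 2,
    correction: str = "holm",
) -> pd.DataFrame:
    """Paired Wilcoxon of the target position against every other position.

    ``position_rates`` is subjects x positions (hit rates at the lowest
    level). One-sided: the target position is hypothesized to be better.
    All-tied contrasts get p = 1 (no evidence of an effect). Holm
    correction by default; ``correction=None`` for raw p-values.
    """
    if len(position_rates) < 6:
        raise ValueError("need at least 6 subjects for the signed-rank test")
    target = position_rates[target_position].to_numpy()
    rows = []
    for other in position_rates.columns:
        if other == target_position:
            continue
        diff = target - position_rates[other].to_numpy()
        ok = np.isfinite(diff)
        if np.allclose(diff[ok], 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(diff[ok], alternative="greater").pvalue)
        rows.append({"contrast": f"{target_position}_vs_{other}", "median_diff": float(np.median(diff[ok])), "p": p})
    out = pd.DataFrame(rows)
    if correction == "holm":
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adjusted = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p"][idx])
            adjusted[idx] = min(1.0, running)
        out["p_adjusted"] = adjusted
    return out


def two_proportion_z(
    successes1: int,
    n1: int,
    successes2: int,
    n2: int,
    sided: str = "one",
) -> tuple[float, float]:
    """Pooled-variance two-proportion z test.

    ``z = (p1 - p2) / SE`` with the pooled standard error. One-sided
    (default) tests whether group 1's proportion is *lower* than group 2's
    (p = Phi(z)); swapping the groups flips the sign of z and maps
    p -> 1 - p. Two-sided gives 2 Phi(-|z|). Zero pooled variance yields
    (0, nan).
    """
    if min(n1, n2) < 5:
        raise ValueError("need at least 5 trials per group")
    p1, p2 = successes1 / n1, successes2 / n2
    pooled = (successes1 + successes2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var <= 0:
        return 0.0, float("nan")
    z = (p1 - p2) / np.sqrt(var)
    if sided == "one":
        p = float(stats.norm.cdf(z))
    elif sided == "two":
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        raise ValueError("sided must be 'one' or 'two'")
    return float(z), p


def reconstruct_counts(percent: float, n: int) -> tuple[int, bool]:
    """Integer success count behind a printed percentage.

    Returns ``(round(percent/100 * n), ambiguous)`` where ``ambiguous``
    flags that a neighboring integer count would print as the same rounded
    percentage.
    """
    if not 0 <= percent <= 100:
        raise ValueError("percent must lie in [0, 100]")
    s = int(round(percent / 100.0 * n))
    printed = round(100.0 * s / n)
    ambiguous = any(
        0 <= s + d <= n and round(100.0 * (s + d) / n) == printed for d in (-1, 1)
    )
    return s, ambiguous
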