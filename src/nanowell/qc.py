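"""Data-point filters and statistical tests for well-level signals.

Filtering happens in a fixed order.  First, structurally missing posts are
flagged: a post lost during fabrication leaves only the negative-control
fluorescence in its well, so its net signal is strongly negative; nets below
−1000 AFU (strict) are excluded.  Second, a one-sided high-tail Grubbs test
at 99.9% confidence removes at most one debris-inflated value per group.
Region comparisons then use Tukey's honest significant difference test, with
the Tukey–Kramer adjustment since region well counts differ, and p-values
are summarized by the usual star tiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QcConfig",
    "flag_missing_posts",
    "grubbs_critical_value",
    "grubbs_filter",
    "tukey_hsd",
    "significance_stars",
    "coefficient_of_variation",
]


@dataclass(frozen=True)
class QcConfig:
    """Thresholds for the well-level filters.

    ``missing_post_threshold_afu`` is on the net (control-subtracted) signal;
    ``grubbs_alpha`` is the one-sided test size per filtering pass;
    ``grubbs_iterative`` repeats the test until no outlier remains (off by
    default: a single pass removes at most one point).
    """

    missing_post_threshold_afu: float = -1000.0
    grubbs_alpha: float = 0.001
    grubbs_iterative: bool = False
    tukey_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.grubbs_alpha < 1:
            raise ValueError("grubbs_alpha must be in (0, 1)")
        if not 0 < self.tukey_alpha < 1:
            raise ValueError("tukey_alpha must be in (0, 1)")
        if self.missing_post_threshold_afu >= 0:
            raise ValueError("missing-post threshold must be negative")


def flag_missing_posts(
    wq: pd.DataFrame, cfg: QcConfig = QcConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split well quantifications into retained rows and missing-post rows.

    Rows with ``net_afu`` strictly below the threshold are flagged
    ``missing_post`` and excluded; the boundary value itself is retained.
    Retained values are returned unaltered.
    """
    net = wq["net_afu"]
    missing = net.notna() & (net < cfg.missing_post_threshold_afu)
    flagged = wq[missing].copy()
    flagged["flags"] = flagged["flags"].apply(
        lambda f: f + (";" if f else "") + "missing_post"
    )
    return wq[~missing].reset_index(drop=True), flagged.reset_index(drop=True)


def grubbs_critical_value(n: int, alpha: float) -> float:
    """One-sided Grubbs critical value.

    ``G_crit = ((n−1)/√n) · √(t² / (n−2+t²))`` with ``t`` the upper ``α/n``
    quantile of Student's t on ``n−2`` degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = stats.t.ppf(1.0 - alpha / n, n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_filter(
    values: Sequence[float], cfg: QcConfig = QcConfig()
) -> tuple[np.ndarray, list[int]]:
    """One-sided (high tail) Grubbs outlier removal.

    Tests ``G = (max − mean) / sd`` against the critical value; by default a
    single pass removes at most one point.  Returns the kept values and the
    indices (into the input) of removed points.  A zero-variance sample has
    no outlier by definition.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 3:
        raise ValueError("need a 1-D sample with n >= 3")
    keep = np.ones(values.size, dtype=bool)
    outliers: list[int] = []
    while keep.sum() >= 3:
        sub = values[keep]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        g = (sub.max() - sub.mean()) / sd
        if g <= grubbs_critical_value(int(keep.sum()), cfg.grubbs_alpha):
            break
        idx = int(np.flatnonzero(keep)[np.argmax(sub)])
        keep[idx] = False
        outliers.append(idx)
        if not cfg.grubbs_iterative:
            break
    return values[keep], outliers


def tukey_hsd(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> pd.DataFrame:
    """All-pairs comparison of group means (Tukey–Kramer).

    p-values come from the studentized-range distribution with pooled
    within-group variance; unequal group sizes use the Kramer adjustment.
    Returns one row per unordered pair with the mean difference, p-value,
    significance at ``alpha`` and the star label.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    for g, a in zip(labels, arrays):
        if a.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            p = float(res.pvalue[i, j])
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_value": p,
                    "significant": p < alpha,
                    "stars": significance_stars(p),
                }
            )
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """Star tier for a p-value: ***, **, * (strict thresholds) or NS."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample coefficient of variation in percent: 100 · sd / mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("CV needs n >= 2")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)
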