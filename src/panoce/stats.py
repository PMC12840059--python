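"""Group-level statistics: Mann-Whitney U comparisons and box summaries.

Implements the nonparametric two-sample comparison used for mean-
stiffness group differences, with an exact null distribution by
enumeration for small samples and a tie-corrected normal approximation
with continuity correction otherwise, plus the 1.5x-IQR box-plot
summary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .exceptions import ValidationError

__all__ = [
    "GroupSummary",
    "mann_whitney_u",
    "box_summary",
    "group_report",
]

#: Largest pooled sample size for which the "auto" method enumerates the
#: exact null distribution.
EXACT_LIMIT = 12


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided U for x: pairs (i, j) with x_i > y_j, ties counted half."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _exact_p(pooled: np.ndarray, n: int, u_low: float) -> float:
    """Two-sided exact p-value by enumeration of all C(n+m, n) splits.

    Uses a subset-sum dynamic program over doubled midranks (integers even
    with ties), counting splits whose U is at most ``u_low`` or at least
    ``nm - u_low``.
    """
    N = pooled.size
    m = N - n
    ranks2 = np.round(2.0 * rankdata(pooled)).astype(np.int64)
    max_sum = int(ranks2.sum())
    # ways[k, s] = number of k-subsets with doubled-rank sum s
    ways = np.zeros((n + 1, max_sum + 1), dtype=np.float64)
    ways[0, 0] = 1.0
    for r in ranks2:
        for k in range(n - 1, -1, -1):
            ways[k + 1, r:] += ways[k, :max_sum + 1 - r]
    total = ways[n].sum()
    # doubled U for doubled rank sum s2:  U2 = s2 - n (n + 1)
    s2 = np.arange(max_sum + 1)
    u2 = s2 - n * (n + 1)
    u_low2 = int(round(2.0 * u_low))
    nm2 = 2 * n * m
    count = ways[n, (u2 <= u_low2) | (u2 >= nm2 - u_low2)].sum()
    return min(1.0, float(count / total))


def mann_whitney_u(x, y, alternative: str = "two-sided",
                   method: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U test for two independent samples.

    Parameters
    ----------
    x, y
        Samples (e.g. per-sample mean stiffness values), each with at
        least two observations.
    method
        ``"auto"`` enumerates the exact null distribution when
        ``len(x) + len(y) <= 12`` and otherwise uses the tie-corrected
        normal approximation with continuity correction; ``"exact"`` and
        ``"asymptotic"`` force one route.

    Returns
    -------
    (U, p)
        ``U`` is the minimum of the two one-sided statistics; ``p`` is
        the two-sided p-value.
    """
    if alternative != "two-sided":
        raise ValidationError("only the two-sided alternative is supported")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise ValidationError("each sample needs n >= 2")
    n, m = x.size, y.size
    ux = _u_statistic(x, y)
    u_low = min(ux, n * m - ux)

    if method == "auto":
        method = "exact" if n + m <= EXACT_LIMIT else "asymptotic"
    if method == "exact":
        p = _exact_p(np.concatenate([x, y]), n, u_low)
    elif method == "asymptotic":
        pooled = np.concatenate([x, y])
        N = n + m
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (N * (N - 1)))
        var_u = n * m / 12.0 * ((N + 1) - tie_term)
        if var_u <= 0:
            p = 1.0
        else:
            z = (u_low - n * m / 2.0 + 0.5) / np.sqrt(var_u)
            p = min(1.0, 2.0 * float(norm.cdf(z)))
    else:
        raise ValidationError(f"unknown method {method!r}")
    return u_low, p


@dataclass
class GroupSummary:
    """Box-plot summary of one group (1.5x-IQR whisker rule)."""

    label: str
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def box_summary(values, label: str = "") -> GroupSummary:
    """Quartiles by linear interpolation between order statistics (the
    common "type 7" convention) and whiskers at the most extreme data
    values within 1.5x IQR of the quartiles."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValidationError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return GroupSummary(label, int(v.size), float(v.mean()), float(med),
                        float(q1), float(q3), float(inside.min()),
                        float(inside.max()),
                        np.sort(v[(v < lo_fence) | (v > hi_fence)]))


def group_report(per_sample: pd.DataFrame, group_col: str = "group",
                 value_col: str = "mean_kpa", bonferroni: bool = False,
                 method: str = "auto") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group box summaries plus all pairwise Mann-Whitney p-values.

    Parameters
    ----------
    per_sample
        Table with one row per sample; needs a group label column and a
        numeric value column (typically per-sample mean stiffness).
    bonferroni
        If True, append a Bonferroni-adjusted p-value column (off by
        default; raw p-values are always reported).

    Returns
    -------
    (summaries, pairwise)
        Two data frames: per-group summaries and the pairwise test table.
    """
    groups = list(dict.fromkeys(per_sample[group_col]))
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    by = {g: per_sample.loc[per_sample[group_col] == g, value_col].to_numpy()
          for g in groups}

    summaries = pd.DataFrame([{
        "group": g, "n": s.n, "mean": s.mean, "median": s.median,
        "q1": s.q1, "q3": s.q3,
        "whisker_low": s.whisker_low, "whisker_high": s.whisker_high,
    } for g, s in ((g, box_summary(v, g)) for g, v in by.items())])

    rows = []
    for ga, gb in itertools.combinations(groups, 2):
        u, p = mann_whitney_u(by[ga], by[gb], method=method)
        rows.append({"group_a": ga, "group_b": gb, "U": u, "p": p})
    pairwise = pd.DataFrame(rows)
    if bonferroni:
        pairwise["p_bonferroni"] = np.minimum(1.0, pairwise["p"] * len(rows))
    return summaries, pairwise


def boxplot_figure(per_sample: pd.DataFrame, path, group_col: str = "group",
                   value_col: str = "mean_kpa") -> None:
    """Save a box-plot figure of per-group mean stiffness."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    groups = list(dict.fromkeys(per_sample[group_col]))
    data = [per_sample.loc[per_sample[group_col] == g, value_col] for g in groups]
    fig, ax = plt.subplots(figsize=(1.6 * len(groups) + 1.5, 4))
    ax.boxplot(data, tick_labels=groups, whis=1.5, showmeans=True)
    ax.set_ylabel("mean stiffness (kPa)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
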