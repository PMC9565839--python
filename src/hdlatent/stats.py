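"""Cohort statistics: Welch's t (raw or from summary statistics),
Welch's heteroscedastic ANOVA with Games-Howell post hoc pairwise
tests, and Pearson chi-square with optional Yates correction.

All tests are two-sided at alpha = 0.05.  The summary-statistics forms
exist so published group means/SDs/sizes can be re-analyzed without the
underlying raw data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "summarize",
    "welch_t",
    "welch_anova",
    "games_howell",
    "chi_square",
]


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def summarize(sample, label: str = "") -> GroupSummary:
    x = np.asarray(sample, dtype=float)
    return GroupSummary(label=label, n=len(x), mean=float(x.mean()),
                        sd=float(x.std(ddof=1)))


def _as_summary(g, i: int) -> GroupSummary:
    if isinstance(g, GroupSummary):
        return g
    return summarize(g, label=f"g{i}")


def welch_t(a: GroupSummary | np.ndarray, b: GroupSummary | np.ndarray):
    """Welch's unequal-variance t-test from summaries or raw samples.

    Returns (t, df, p) with Welch-Satterthwaite degrees of freedom and a
    two-sided p-value.
    """
    a = _as_summary(a, 0)
    b = _as_summary(b, 1)
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    if va + vb == 0:
        if a.mean == b.mean:
            raise ValueError("zero variance and equal means: t undefined")
        return np.inf, float(a.n + b.n - 2), 0.0
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_anova(groups):
    """Welch's heteroscedastic F test for k independent groups
    (summaries or raw samples).  Returns (F, df1, df2, p).

    Weights w_i = n_i / s_i^2; the denominator degrees of freedom are
    Welch-adjusted.
    """
    gs = [_as_summary(g, i) for i, g in enumerate(groups)]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    k = len(gs)
    w = np.array([g.n / g.sd**2 for g in gs])
    m = np.array([g.mean for g in gs])
    n = np.array([g.n for g in gs])
    sw = w.sum()
    grand = (w * m).sum() / sw
    num = ((w * (m - grand) ** 2).sum()) / (k - 1)
    lam = (1.0 - w / sw) ** 2 / (n - 1)
    den = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * lam.sum()
    f = num / den
    df1 = k - 1
    df2 = (k**2 - 1) / (3.0 * lam.sum())
    p = sps.f.sf(f, df1, df2)
    return float(f), float(df1), float(df2), float(p)


def games_howell(groups) -> pd.DataFrame:
    """Games-Howell pairwise comparisons after Welch's ANOVA.

    Per pair: SE = sqrt(s_i^2/n_i + s_j^2/n_j), Welch df, and the
    p-value from the studentized range distribution with k groups
    (q = |diff| * sqrt(2) / SE).
    """
    gs = [_as_summary(g, i) for i, g in enumerate(groups)]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    k = len(gs)
    rows = []
    for a, b in combinations(gs, 2):
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = np.sqrt(va + vb)
        diff = a.mean - b.mean
        if se == 0:
            df = float(a.n + b.n - 2)
            p = 1.0 if diff == 0 else 0.0
            q = 0.0 if diff == 0 else np.inf
        else:
            df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
            q = abs(diff) * np.sqrt(2.0) / se
            p = sps.studentized_range.sf(q, k, df)
        rows.append(
            {
                "group_a": a.label, "group_b": b.label, "diff": diff,
                "se": se, "df": df, "q": q, "p": float(np.clip(p, 0.0, 1.0)),
            }
        )
    return pd.DataFrame(rows)


def chi_square(table: np.ndarray | pd.DataFrame, yates: bool | None = None):
    """Pearson chi-square test of independence.

    ``yates=None`` applies the continuity correction exactly when the
    table is 2x2 (the convention used for the cohort gender table);
    expected counts are returned so cells below 5 can be flagged.
    Returns (chi2, df, p, expected).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    if yates is None:
        yates = obs.shape == (2, 2)
    chi2, p, df, expected = sps.chi2_contingency(obs, correction=yates)
    return float(chi2), int(df), float(p), expected
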