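"""Alpha diversity (observed OTUs, Shannon index in nats) and the cohort's
group-comparison (Welch t) and Shapiro-Wilk normality checks."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .tables import OtuTable, ValidationError

__all__ = ["alpha_diversity", "compare_groups", "normality_check", "diversity_contrasts"]


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Per-sample observed OTU count and Shannon index.

    Shannon is -sum p_i ln p_i over the nonzero proportions of each sample;
    a single-feature sample scores 0, k equally abundant features score ln k.
    """
    vals = table.values
    sums = vals.sum(axis=0)
    if (sums <= 0).any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(sums <= 0)]
        raise ValidationError(f"all-zero samples have undefined diversity: {bad}")
    observed = (vals > 0).sum(axis=0)
    shannon = np.empty(table.n_samples)
    for j in range(table.n_samples):
        p = vals[:, j] / sums[j]
        p = p[p > 0]
        shannon[j] = float(-(p * np.log(p)).sum())
    return pd.DataFrame(
        {"observed_otus": observed, "shannon": shannon}, index=table.sample_ids
    )


def compare_groups(values, groups) -> tuple[float, float, float]:
    """Welch two-sample two-tailed t-test.

    Group 1 is the lexicographically first level; swapping the group labels
    flips the sign of t and leaves P unchanged. Returns (t, Welch df, P).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValidationError("values and groups must have equal length")
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValidationError(f"expected exactly two groups, got {levels}")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValidationError("both groups have zero variance; t-test undefined")
    se2 = va / len(a) + vb / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk W and P; defined for 3 <= n <= 5000 non-constant samples."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if not 3 <= n <= 5000:
        raise ValidationError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {n}")
    if np.ptp(values) == 0:
        raise ValidationError("constant vector; normality test undefined")
    w, p = stats.shapiro(values)
    return float(w), float(p)


def diversity_contrasts(report: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Tidy two-group contrasts of each diversity/trait column in ``report``."""
    levels = sorted(pd.unique(groups))
    rows = []
    for col in report.columns:
        t, df, p = compare_groups(report[col].to_numpy(), groups.to_numpy())
        rows.append({"metric": col, "group1": levels[0], "group2": levels[1],
                     "t": t, "df": df, "P": p})
    return pd.DataFrame(rows)
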