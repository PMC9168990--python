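"""Two-group cohort statistics: pooled-variance Student's t-tests, Pearson
chi-square for 2x2 tables, ANOVA-F feature ranking, and a cohort-wide
comparison over glycopeptides and derived traits.

The t-test is the equal-variance (pooled) form and the chi-square carries no
continuity correction; p-values are reported raw, with Benjamini-Hochberg
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "ttest_two_tailed",
    "chi_square_2x2",
    "f_rank_features",
    "compare_all",
    "benjamini_hochberg",
]


@dataclass
class GroupComparison:
    """One feature's two-group comparison."""

    feature: str
    statistic: float
    p_value: float
    stat_name: str = "t"
    mean_a: float = float("nan")
    sd_a: float = float("nan")
    mean_b: float = float("nan")
    sd_b: float = float("nan")
    n_a: int = 0
    n_b: int = 0
    df: float = float("nan")


def ttest_two_tailed(a, b, feature: str = "") -> GroupComparison:
    """Two-tailed pooled-variance Student's t-test.

    Zero pooled variance with equal means gives t = 0, p = 1; with unequal
    means, t = +/-inf and p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs n >= 2")
    df = na + nb - 2
    var_pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if var_pooled == 0:
        t = 0.0 if diff == 0 else float(np.sign(diff)) * float("inf")
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / np.sqrt(var_pooled * (1.0 / na + 1.0 / nb))
        p = 2.0 * stats.t.sf(abs(t), df)
    return GroupComparison(
        feature=feature,
        statistic=float(t),
        p_value=float(p),
        stat_name="t",
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_a=na,
        n_b=nb,
        df=float(df),
    )


def chi_square_2x2(a: int, b: int, c: int, d: int, feature: str = "") -> GroupComparison:
    """Pearson chi-square (no continuity correction) for the table
    [[a, b], [c, d]], with p from the chi-square distribution at 1 df."""
    counts = (a, b, c, d)
    if any(x < 0 or int(x) != x for x in counts):
        raise ValueError("counts must be nonnegative integers")
    n = a + b + c + d
    if n <= 0:
        raise ValueError("empty table")
    margins = {"row1": a + b, "row2": c + d, "col1": a + c, "col2": b + d}
    for name, m in margins.items():
        if m == 0:
            raise ValueError(f"zero margin {name}: chi-square undefined")
    chi2 = n * (a * d - b * c) ** 2 / (
        margins["row1"] * margins["row2"] * margins["col1"] * margins["col2"]
    )
    p = float(stats.chi2.sf(chi2, df=1))
    return GroupComparison(
        feature=feature,
        statistic=float(chi2),
        p_value=p,
        stat_name="chi2",
        n_a=a + b,
        n_b=c + d,
        df=1.0,
    )


def f_rank_features(X: pd.DataFrame, labels, k: int) -> list[tuple[str, float]]:
    """Rank features by one-way ANOVA F (descending; ties by name) and
    return the top ``k`` as (name, F) pairs."""
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if levels.size != 2:
        raise ValueError(f"expected 2 classes, got {levels.size}")
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds {X.shape[1]} features")
    mask = labels == levels[0]
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each class needs n >= 2")
    scored: list[tuple[str, float]] = []
    for col in X.columns:
        ga = X[col].to_numpy(dtype=float)[mask]
        gb = X[col].to_numpy(dtype=float)[~mask]
        scored.append((str(col), _anova_f(ga, gb)))
    scored.sort(key=lambda item: (-item[1], item[0]))
    return scored[:k]


def _anova_f(a: np.ndarray, b: np.ndarray) -> float:
    grand = np.concatenate([a, b]).mean()
    ss_between = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df_within = a.size + b.size - 2
    if ss_within == 0:
        return float("inf") if ss_between > 0 else 0.0
    return float(ss_between / (ss_within / df_within))


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def compare_all(
    features: pd.DataFrame,
    grouping: pd.Series,
    adjust: bool = False,
) -> pd.DataFrame:
    """Pooled t-test per feature column between the two grouping levels.

    ``grouping`` is aligned on the feature table's index and must have
    exactly two levels with n >= 2 each.  Returns a tidy frame; with
    ``adjust=True`` a Benjamini-Hochberg ``q`` column is appended.
    """
    grouping = grouping.loc[features.index]
    levels = sorted(pd.unique(grouping.dropna()))
    if len(levels) != 2:
        raise ValueError(f"grouping must have exactly 2 levels, got {levels}")
    mask = (grouping == levels[0]).to_numpy()
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each grouping level needs n >= 2")
    rows = []
    for col in features.columns:
        vals = features[col].to_numpy(dtype=float)
        cmp = ttest_two_tailed(vals[mask], vals[~mask], feature=str(col))
        rows.append(
            {
                "feature": cmp.feature,
                "level_a": levels[0],
                "level_b": levels[1],
                "mean_a": cmp.mean_a,
                "sd_a": cmp.sd_a,
                "mean_b": cmp.mean_b,
                "sd_b": cmp.sd_b,
                "n_a": cmp.n_a,
                "n_b": cmp.n_b,
                "t": cmp.statistic,
                "p": cmp.p_value,
            }
        )
    out = pd.DataFrame(rows)
    if adjust:
        out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out
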