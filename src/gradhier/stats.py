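"""Group statistics: normality-gated two-sample tests, chi-square, and
clinical-scale correlations.

The comparison logic follows the classical clinical-reporting convention:
if both groups pass a Shapiro–Wilk normality check (alpha = 0.05) the
variable is compared with an equal-variance two-sample t-test and reported
as mean +/- SD; otherwise with a Mann–Whitney U test (tie-corrected normal
approximation, reported as Z) and median (Q1 ~ Q3) summaries. Categorical
2x2 tables use the Pearson chi-square without continuity correction by
default. All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .atlas import ValidationError

__all__ = [
    "GroupComparisonResult",
    "CorrelationResult",
    "normality_gate",
    "compare_groups",
    "chi_square_2x2",
    "correlate_with_scales",
    "multiplicity_adjust",
    "demographics_table",
]


@dataclass(frozen=True)
class GroupComparisonResult:
    variable: str
    test_used: str  # {"t_test", "mann_whitney_u"}
    statistic: float  # t, or the normal-approximation Z for Mann-Whitney
    p_value: float
    group_summaries: dict[str, str]
    direction: str  # "<group1> lower/higher than <group2>" or "no difference"
    normality: str  # gate outcome, for auditing which branch ran

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p_value outside [0, 1]")


@dataclass(frozen=True)
class CorrelationResult:
    score_variable: str
    clinical_scale: str
    pearson_r: float
    p_value: float
    n: int
    scope: str = "network"

    def __post_init__(self) -> None:
        if abs(self.pearson_r) > 1 + 1e-12:
            raise ValidationError("|r| must be <= 1")
        if self.n < 3:
            raise ValidationError("correlation needs n >= 3")


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    """Median and quartiles by inclusive linear interpolation."""
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def normality_gate(samples: list[np.ndarray], alpha: float = 0.05) -> str:
    """Shapiro–Wilk in each group; "normal" only if every group passes.

    A zero-variance (constant) sample cannot be tested and is classified
    non_normal rather than crashing.
    """
    for x in samples:
        x = np.asarray(x, dtype=float)
        if x.size < 3:
            raise ValidationError("normality_gate needs n >= 3 per group")
        if np.ptp(x) == 0:
            return "non_normal"
        if scipy.stats.shapiro(x).pvalue < alpha:
            return "non_normal"
    return "normal"


def _mann_whitney_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """U statistic of x, tie-corrected normal-approximation Z, two-sided p."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:  # all values tied
        return u1, 0.0, 1.0
    z = (u1 - mu) / np.sqrt(sigma2)
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return float(u1), float(z), float(min(p, 1.0))


def compare_groups(
    values: np.ndarray,
    labels: np.ndarray,
    variable: str = "value",
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Normality-gated two-sample comparison of ``values`` between groups.

    Groups are the sorted unique labels; the direction reports which group
    has the lower central value. The Mann–Whitney branch reports the
    tie-corrected normal-approximation Z as the statistic (U is folded into
    the Z), matching common clinical tables.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, got {groups}")
    x = values[labels == groups[0]]
    y = values[labels == groups[1]]
    if min(len(x), len(y)) < 3:
        raise ValidationError("each group needs n >= 3")

    gate = normality_gate([x, y], alpha=alpha)
    if gate == "normal":
        res = scipy.stats.ttest_ind(x, y, equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
        test = "t_test"
        summaries = {
            g: f"{v.mean():.3f} ± {v.std(ddof=1):.3f}"
            for g, v in ((groups[0], x), (groups[1], y))
        }
        lower_first = x.mean() < y.mean()
        tied = x.mean() == y.mean()
    else:
        _, stat, p = _mann_whitney_z(x, y)
        test = "mann_whitney_u"
        summaries = {}
        for g, v in ((groups[0], x), (groups[1], y)):
            med, q1, q3 = _quartiles(v)
            summaries[g] = f"{med:g}({q1:g} ∼ {q3:g})"
        lower_first = np.median(x) < np.median(y)
        tied = np.median(x) == np.median(y)

    if tied:
        direction = "no difference"
    elif lower_first:
        direction = f"{groups[0]} lower than {groups[1]}"
    else:
        direction = f"{groups[0]} higher than {groups[1]}"
    return GroupComparisonResult(
        variable=variable,
        test_used=test,
        statistic=stat,
        p_value=p,
        group_summaries=summaries,
        direction=direction,
        normality=gate,
    )


def chi_square_2x2(table: np.ndarray, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 contingency table (df = 1).

    No continuity correction unless ``yates`` is set.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got {t.shape}")
    if (t < 0).any():
        raise ValidationError("cell counts must be >= 0")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("both margins must be nonzero")
    stat, p, _, _ = scipy.stats.chi2_contingency(t, correction=yates)
    return float(stat), float(p)


def correlate_with_scales(
    scores: pd.DataFrame,
    cohort: pd.DataFrame,
    score_columns: list[str],
    scales: tuple[str, ...] = ("cesd", "hamd"),
    group: str | None = "case",
    scope: str = "network",
) -> list[CorrelationResult]:
    """Pearson correlations between score variables and clinical scales.

    ``scores`` must carry subject_id plus the score columns; it is merged
    with the cohort table on subject_id, restricted to ``group`` (the
    clinical correlations are computed within the symptomatic group by
    default; pass None to pool).
    """
    merged = scores.merge(cohort, on="subject_id", how="inner")
    if group is not None:
        merged = merged[merged["group"] == group]
    if len(merged) < 3:
        raise ValidationError(f"n = {len(merged)} after merge/restriction; need >= 3")
    results = []
    for col in score_columns:
        for scale in scales:
            r, p = scipy.stats.pearsonr(merged[col], merged[scale])
            results.append(
                CorrelationResult(
                    score_variable=col,
                    clinical_scale=scale,
                    pearson_r=float(r),
                    p_value=float(p),
                    n=len(merged),
                    scope=scope,
                )
            )
    return results


def multiplicity_adjust(p_values: np.ndarray, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini–Hochberg (default) adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def demographics_table(cohort: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Clinical/demographics comparison table for a two-group cohort.

    Continuous variables (age, education, cesd, hamd) go through the
    normality-gated comparison; sex uses the chi-square on its 2x2 table.
    """
    rows = []
    labels = cohort["group"].to_numpy()
    for var in ("age", "education", "cesd", "hamd"):
        res = compare_groups(cohort[var].to_numpy(), labels, variable=var)
        rows.append(
            {
                "variable": var,
                "test": res.test_used,
                "statistic": res.statistic,
                "p_value": res.p_value,
                **{f"summary_{g}": s for g, s in res.group_summaries.items()},
            }
        )
    groups = sorted(set(labels.tolist()))
    table = np.array(
        [
            [
                ((cohort["group"] == g) & (cohort["sex"] == s)).sum()
                for g in groups
            ]
            for s in ("M", "F")
        ]
    )
    stat, p = chi_square_2x2(table)
    rows.append(
        {
            "variable": "sex",
            "test": "chi_square",
            "statistic": stat,
            "p_value": p,
            **{
                f"summary_{g}": f"{table[0, i]}/{table[1, i]} (M/F)"
                for i, g in enumerate(groups)
            },
        }
    )
    return pd.DataFrame(rows)
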