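"""Group statistics for the two-outcome cohort.

Continuous features are screened for normality (Lilliefors in each group)
and homoscedasticity (Levene); groups are compared with Student's t-test
when both hold and with the Mann-Whitney U-test otherwise.  Categorical
variables are compared with Fisher's exact test.  Significance is read at
p < 0.05; no multiple-testing correction is applied, so per-feature
p-values are to be interpreted marginally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sct
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "FeatureComparison",
    "CategoricalComparison",
    "CohortReport",
    "screen_distribution",
    "compare_feature",
    "fisher_exact",
    "cohort_report",
]

ALPHA = 0.05


@dataclass(frozen=True)
class FeatureComparison:
    """One continuous feature compared between the two outcome groups."""

    feature: str
    mean_recur: float
    sd_recur: float
    mean_sr: float
    sd_sr: float
    test_used: str  #: "t" or "mann-whitney"
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class CategoricalComparison:
    """A 2x2 contingency table with its Fisher exact p-value."""

    feature: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class CohortReport:
    """Descriptive and inferential summary of a cohort feature table."""

    features: pd.DataFrame
    categorical: pd.DataFrame
    n_recur: int
    n_sr: int

    @property
    def n_total(self) -> int:
        return self.n_recur + self.n_sr

    @property
    def recurrence_pct(self) -> float:
        """Percentage of patients relapsing to AF."""
        return 100.0 * self.n_recur / self.n_total

    @property
    def sr_pct(self) -> float:
        """Percentage of patients maintaining sinus rhythm."""
        return 100.0 * self.n_sr / self.n_total


def screen_distribution(
    x: np.ndarray, y: np.ndarray
) -> tuple[bool, bool]:
    """Screen two samples for normality and equal variances.

    Returns ``(normal, homoscedastic)``: normal when the Lilliefors test
    retains normality (p >= 0.05) in *both* groups, homoscedastic when
    Levene's test retains equal variances.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 4 or y.size < 4:
        raise ValueError("need at least 4 observations per group to screen")
    normal = True
    for s in (x, y):
        if np.std(s) == 0:
            normal = False
            break
        _, p = lilliefors(s, dist="norm")
        if p < ALPHA:
            normal = False
            break
    _, p_lev = sct.levene(x, y)
    homoscedastic = bool(p_lev >= ALPHA) if np.isfinite(p_lev) else True
    return normal, homoscedastic


def compare_feature(
    feature: str, x_recur: np.ndarray, y_sr: np.ndarray
) -> FeatureComparison:
    """Compare one feature between the recurrence and SR groups.

    Uses the t-test when both screening conditions hold, otherwise the
    Mann-Whitney U-test (including degenerate constant samples).
    """
    x, y = np.asarray(x_recur, float), np.asarray(y_sr, float)
    normal, homo = screen_distribution(x, y)
    if normal and homo:
        test_used = "t"
        _, p = sct.ttest_ind(x, y)
    else:
        test_used = "mann-whitney"
        if np.std(np.concatenate([x, y])) == 0:
            p = 1.0  # all observations identical: no evidence of a shift
        else:
            _, p = sct.mannwhitneyu(x, y, alternative="two-sided")
    return FeatureComparison(
        feature=feature,
        mean_recur=float(np.mean(x)),
        sd_recur=float(np.std(x, ddof=1)),
        mean_sr=float(np.mean(y)),
        sd_sr=float(np.std(y, ddof=1)),
        test_used=test_used,
        p_value=float(p),
    )


def fisher_exact(table, feature: str = "categorical") -> CategoricalComparison:
    """Two-sided Fisher exact test of a 2x2 count table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        p = 1.0  # an empty margin carries no information
    else:
        _, p = sct.fisher_exact(t, alternative="two-sided")
    return CategoricalComparison(
        feature=feature,
        table=((int(t[0, 0]), int(t[0, 1])), (int(t[1, 0]), int(t[1, 1]))),
        p_value=float(p),
    )


def cohort_report(
    cohort: pd.DataFrame,
    clinical: pd.DataFrame | None = None,
    feature_columns: list[str] | None = None,
) -> CohortReport:
    """Per-feature group comparison of a cohort feature table.

    ``cohort`` must carry ``patient_id``, a binary ``label`` column with
    values "recur" / "SR", and one column per continuous feature.
    Optional ``clinical`` columns (binary, indexed like ``cohort``) are
    compared as 2x2 tables with Fisher's exact test.
    """
    labels = cohort["label"].to_numpy()
    groups = set(labels)
    if groups != {"recur", "SR"}:
        raise ValueError(f"need both outcome groups, found {sorted(groups)}")
    recur = cohort[cohort["label"] == "recur"]
    sr = cohort[cohort["label"] == "SR"]
    if len(recur) < 2 or len(sr) < 2:
        raise ValueError("need at least 2 patients per group")

    if feature_columns is None:
        feature_columns = [
            c
            for c in cohort.columns
            if c not in ("patient_id", "label")
            and pd.api.types.is_numeric_dtype(cohort[c])
        ]
    rows = []
    for col in feature_columns:
        cmp = compare_feature(col, recur[col].to_numpy(), sr[col].to_numpy())
        rows.append(
            {
                "feature": cmp.feature,
                "mean_recur": cmp.mean_recur,
                "sd_recur": cmp.sd_recur,
                "mean_sr": cmp.mean_sr,
                "sd_sr": cmp.sd_sr,
                "test_used": cmp.test_used,
                "p_value": cmp.p_value,
                "significant": cmp.significant,
            }
        )
    features = pd.DataFrame(rows)

    cat_rows = []
    if clinical is not None:
        for col in clinical.columns:
            flags = clinical[col].to_numpy().astype(bool)
            in_recur = labels == "recur"
            table = [
                [int(np.sum(flags & in_recur)), int(np.sum(~flags & in_recur))],
                [int(np.sum(flags & ~in_recur)), int(np.sum(~flags & ~in_recur))],
            ]
            cmp = fisher_exact(table, feature=col)
            cat_rows.append(
                {
                    "feature": col,
                    "table": cmp.table,
                    "p_value": cmp.p_value,
                    "significant": cmp.significant,
                }
            )
    categorical = pd.DataFrame(cat_rows)
    return CohortReport(
        features=features,
        categorical=categorical,
        n_recur=len(recur),
        n_sr=len(sr),
    )
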