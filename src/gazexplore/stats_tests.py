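"""Two-sample group comparisons for the per-trial feature table.

Two tests are used side by side: Student's t test (Welch's unequal-variance
form by default, since group variances of gaze features differ; the pooled
form is available) and the Mann-Whitney-Wilcoxon rank test, which needs no
normality assumption and is invariant under any strictly increasing
transformation of the data.  Both are two-sided.

``compare_all_features`` assembles a per-feature report of group means and
both p-values over the seven trajectory quantities (mu_F, sigma_F, mu_S,
sigma_S, p_FS, p_SF, lambda).  Raw p-values are reported, matching common
practice for descriptive group tables; a Bonferroni-adjusted column is
included as clearly-labeled supplementary information.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gaze_io import DataError
from .markov_features import FEATURE_NAMES

__all__ = ["TestMethod", "TTestVariant", "TestResult", "t_test", "mww_test", "compare_all_features"]

REPORT_FEATURES = (*FEATURE_NAMES, "lambda")


class TestMethod(str, enum.Enum):
    T_TEST = "t_test"
    MWW = "mww"


class TTestVariant(str, enum.Enum):
    WELCH = "welch"
    POOLED = "pooled"


@dataclass(frozen=True)
class TestResult:
    method: TestMethod
    statistic: float
    p_value: float
    n1: int
    n2: int
    variant: TTestVariant | None = None
    flagged: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise DataError(f"p-value outside [0, 1]: {self.p_value}")


def t_test(
    group1,
    group2,
    variant: TTestVariant = TTestVariant.WELCH,
) -> TestResult:
    """Two-sided two-sample Student's t test.

    With zero variance in both groups and equal means the statistic is
    undefined; the conventional p = 1 is returned with a flag.
    """
    g1 = np.asarray(group1, float)
    g2 = np.asarray(group2, float)
    if g1.size < 2 or g2.size < 2:
        raise DataError("each group needs at least 2 observations for a t test")

    if np.var(g1) == 0 and np.var(g2) == 0 and np.mean(g1) == np.mean(g2):
        return TestResult(
            method=TestMethod.T_TEST,
            statistic=0.0,
            p_value=1.0,
            n1=g1.size,
            n2=g2.size,
            variant=variant,
            flagged="zero variance in both groups with equal means",
        )

    res = stats.ttest_ind(g1, g2, equal_var=(variant is TTestVariant.POOLED))
    return TestResult(
        method=TestMethod.T_TEST,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=g1.size,
        n2=g2.size,
        variant=variant,
    )


def mww_test(group1, group2) -> TestResult:
    """Two-sided Mann-Whitney-Wilcoxon test.

    Uses the exact null distribution when the combined sample size is at
    most 20 and there are no ties, and the normal approximation with tie
    correction otherwise.  The reported statistic is U of group1.
    """
    g1 = np.asarray(group1, float)
    g2 = np.asarray(group2, float)
    if g1.size < 1 or g2.size < 1:
        raise DataError("each group needs at least 1 observation")

    combined = np.concatenate([g1, g2])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
    return TestResult(
        method=TestMethod.MWW,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=g1.size,
        n2=g2.size,
    )


def compare_all_features(
    table: pd.DataFrame,
    group_col: str = "group",
    *,
    alpha: float = 0.05,
    variant: TTestVariant = TTestVariant.WELCH,
    features: tuple[str, ...] = REPORT_FEATURES,
) -> pd.DataFrame:
    """Group-comparison report over the per-trial feature table.

    One row per feature with the group means, Welch t and MWW p-values, a
    significance flag at ``alpha`` (on the raw t p-value) and a
    supplementary Bonferroni-adjusted t p-value.
    """
    groups = sorted(table[group_col].dropna().unique())
    if len(groups) != 2:
        raise DataError(f"exactly two groups required, found {groups}")
    g1_name, g2_name = groups
    g1 = table[table[group_col] == g1_name]
    g2 = table[table[group_col] == g2_name]

    rows = []
    for feat in features:
        if feat not in table.columns:
            raise DataError(f"feature column {feat!r} missing from table")
        v1 = g1[feat].dropna().to_numpy(float)
        v2 = g2[feat].dropna().to_numpy(float)
        t_res = t_test(v1, v2, variant=variant)
        m_res = mww_test(v1, v2)
        rows.append(
            {
                "feature": feat,
                f"mean_{g1_name}": float(np.mean(v1)),
                f"mean_{g2_name}": float(np.mean(v2)),
                "t_p": t_res.p_value,
                "mww_p": m_res.p_value,
                "significant": bool(t_res.p_value < alpha),
                "t_p_bonferroni": min(1.0, t_res.p_value * len(features)),
            }
        )
    return pd.DataFrame(rows).set_index("feature")
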