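"""Group-difference tests for cohort covariates and covariate-adjusted comparison.

Continuous covariates are compared between the ABE and non-ABE groups with a
two-sample t-test from summary statistics (Welch by default, pooled
optionally), categorical ones (sex) with a 2x2 Pearson chi-squared, and the
normalized intensities with an analysis of covariance: a least-squares
linear model of the feature on an intercept, the group indicator, and the
covariates, with the group term tested by a partial F-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, UndefinedMetricError

POSITIVE = "ABE"


def welch_t(mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int,
            pooled: bool = False) -> tuple[float, float, float]:
    """Two-sample t-test from group summaries; returns (t, df, two-sided p).

    Welch-Satterthwaite degrees of freedom by default; ``pooled=True`` uses
    the equal-variance test.
    """
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be >= 0")
    if n_a <= 1 or n_b <= 1:
        raise ValueError("each group needs n > 1")
    if sd_a == 0 and sd_b == 0 and mean_a == mean_b:
        raise UndefinedMetricError("zero variance in both groups with equal means")
    t, p = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=pooled
    )
    if pooled:
        df = n_a + n_b - 2
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return float(t), float(df), float(p)


def chi2_proportions(count_a: int, n_a: int, count_b: int, n_b: int) -> tuple[float, float]:
    """2x2 Pearson chi-squared (1 df, no continuity correction) on two proportions."""
    for count, n in ((count_a, n_a), (count_b, n_b)):
        if not 0 <= count <= n:
            raise ValueError(f"count {count} outside [0, {n}]")
    table = np.array([[count_a, n_a - count_a], [count_b, n_b - count_b]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise UndefinedMetricError("zero margin in the 2x2 table; test undefined")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def adjusted_group_test(values, groups, covariates=None,
                        positive_label: str = POSITIVE) -> tuple[float, float, float]:
    """Covariate-adjusted group comparison of a feature (ANCOVA).

    Fits ``feature ~ 1 + group + covariates`` by least squares and tests the
    group indicator with a partial F-test (1 numerator df; identical to the
    squared t of the group coefficient).  Returns ``(F, p, adjusted group
    effect)`` where the effect is the group-coefficient estimate: the
    difference positive minus negative at fixed covariates.
    """
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if y.shape != groups.shape or y.ndim != 1:
        raise ValueError("values and groups must be 1D and equal length")
    indicator = (groups == positive_label).astype(float)
    if indicator.min() == indicator.max():
        raise ValueError("both groups must be present")
    cols = {"group": indicator}
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        if len(cov) != len(y):
            raise ValueError("covariate rows must match values")
        for name in cov.columns:
            cols[str(name)] = cov[name].to_numpy(dtype=float)
    X = sm.add_constant(pd.DataFrame(cols, index=range(len(y))))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise CollinearityError("design matrix is rank deficient")
    fit = sm.OLS(y, X).fit()
    ftest = fit.f_test("group = 0")
    return float(ftest.fvalue), float(ftest.pvalue), float(fit.params["group"])


def group_summary(df: pd.DataFrame, covariate_columns: list[str],
                  group_column: str = "group", sex_column: str = "sex",
                  positive_label: str = POSITIVE) -> dict:
    """Per-group n, per-covariate mean +/- SD, male counts, and the test results.

    The shape of the cohort characteristics table: chi-squared p for sex,
    Welch t p for each continuous covariate.
    """
    is_pos = df[group_column] == positive_label
    a, b = df[is_pos], df[~is_pos]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n > 1 for testing")
    out: dict = {"n": {"positive": len(a), "negative": len(b)}, "covariates": {}}
    male_a = int((a[sex_column] == "M").sum())
    male_b = int((b[sex_column] == "M").sum())
    stat, p = chi2_proportions(male_a, len(a), male_b, len(b))
    out["sex"] = {
        "male": {"positive": male_a, "negative": male_b},
        "chi2": stat,
        "p": p,
    }
    for col in covariate_columns:
        ma, sa = float(a[col].mean()), float(a[col].std(ddof=1))
        mb, sb = float(b[col].mean()), float(b[col].std(ddof=1))
        t, dof, p = welch_t(ma, sa, len(a), mb, sb, len(b))
        out["covariates"][col] = {
            "positive": {"mean": ma, "sd": sa},
            "negative": {"mean": mb, "sd": sb},
            "t": t,
            "df": dof,
            "p": p,
        }
    return out
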