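"""Shared statistical procedures: two-sample t, Bonferroni, two-sample
KS, categorical OLS and two-way ANOVA.

These are thin, explicitly-parameterized adapters over scipy and
statsmodels so the analysis modules agree on one convention for each
test (t-test variant, KS p-value mode, ANOVA sum-of-squares type) and
return a uniform result record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: Optional[float] = None


def t_two_sample(a: Sequence[float], b: Sequence[float],
                 variant: str = "welch") -> TestResult:
    """Two-sided two-sample t-test.

    ``variant='welch'`` uses unequal variances with Welch-Satterthwaite
    degrees of freedom; ``variant='pooled'`` is the classical Student
    test with df = n_a + n_b - 2. Two samples with zero variance and
    equal means yield t = 0, p = 1 rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per sample")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 \
            and np.mean(a) == np.mean(b):
        df = len(a) + len(b) - 2
        return TestResult(0.0, 1.0, f"t ({variant})", df)
    equal_var = variant == "pooled"
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(float(res.statistic), float(res.pvalue),
                      f"t ({variant})", float(res.df))


def bonferroni_alpha(m: int, family_alpha: float = 0.05) -> float:
    """Per-comparison alpha controlling the family-wise error at
    ``family_alpha`` over ``m`` comparisons."""
    if m < 1:
        raise ValueError("number of comparisons m must be >= 1")
    return family_alpha / m


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    The statistic is the supremum distance between the two empirical
    CDFs. The p-value is exact for small samples (both n <= 10) and
    asymptotic otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("KS test requires non-empty samples")
    method = "exact" if max(len(a), len(b)) <= 10 else "asymp"
    res = sps.ks_2samp(a, b, method=method)
    return TestResult(float(res.statistic), float(res.pvalue),
                      f"KS two-sample ({method})")


def ols_categorical(rows: pd.DataFrame, response: str,
                    factors: Sequence[str]):
    """OLS of ``response`` on dummy-coded categorical ``factors``.

    Returns the fitted statsmodels results object (coefficients, SEs,
    t, p, R^2, nobs). Raises on a rank-deficient design, naming the
    collinear columns.
    """
    rows = pd.DataFrame(rows)
    if not np.all(np.isfinite(rows[response].to_numpy(dtype=float))):
        raise ValueError(f"non-finite values in response {response!r}")
    formula = f"{response} ~ " + " + ".join(f"C({f})" for f in factors)
    model = smf.ols(formula, data=rows)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("rank-deficient design matrix; collinear columns "
                         f"among {list(model.exog_names)}")
    return model.fit()


def anova_two_way(rows: pd.DataFrame, response: str, factor_a: str,
                  factor_b: str, ss_type: int = 2) -> dict:
    """Two-way ANOVA with interaction; Type II sums of squares by
    default (robust to mild imbalance), Type I/III available.

    Returns a dict mapping term name (factor names and
    ``'<A>:<B>'`` for the interaction) to :class:`TestResult`.
    """
    rows = pd.DataFrame(rows)
    for factor in (factor_a, factor_b):
        if rows[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs >= 2 levels")
    cells = rows.groupby([factor_a, factor_b], observed=True).size()
    n_expected = rows[factor_a].nunique() * rows[factor_b].nunique()
    if len(cells) < n_expected:
        raise ValueError(
            f"empty design cells: {n_expected - len(cells)} of "
            f"{n_expected} (A x B) combinations have no observations")
    # Type III tests are only meaningful under sum-to-zero contrasts;
    # treatment coding is fine for Types I and II
    coding = ", Sum" if ss_type == 3 else ""
    fa, fb = f"C({factor_a}{coding})", f"C({factor_b}{coding})"
    formula = f"{response} ~ {fa} * {fb}"
    fit = smf.ols(formula, data=rows).fit()
    table = anova_lm(fit, typ=ss_type)
    out = {}
    name_map = {fa: factor_a, fb: factor_b,
                f"{fa}:{fb}": f"{factor_a}:{factor_b}"}
    for raw, name in name_map.items():
        row = table.loc[raw]
        out[name] = TestResult(statistic=float(row["F"]),
                               p_value=float(row["PR(>F)"]),
                               df=float(row["df"]),
                               method=f"two-way ANOVA (type {ss_type})")
    return out
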