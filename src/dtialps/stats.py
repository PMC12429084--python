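"""The cohort statistics battery: group comparisons, correlations, models.

Everything is two-sided.  Summary-statistic forms of the t tests are
vectorizable (array inputs give array result fields), which keeps large
null-simulation suites cheap.  Regression fits go through statsmodels with
Wald confidence intervals, matching common clinical-statistics software
conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "StatTestResult",
    "RegressionResult",
    "pooled_t_test",
    "pooled_t_test_data",
    "welch_t_test",
    "welch_t_test_data",
    "mann_whitney_u",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "pearson_r",
    "cohens_d",
    "cohens_d_data",
    "logistic_fit",
    "linear_fit",
    "vif",
]


@dataclass(frozen=True)
class StatTestResult:
    statistic: float
    df: float
    p_value: float
    effect_size: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    method: str = ""


@dataclass
class RegressionResult:
    """Coefficient table of a fitted linear or logistic model.

    All per-coefficient entries are pandas Series/DataFrames indexed by
    predictor name (including ``const``).  ``odds_ratios``/``or_ci`` are only
    set for logistic fits, ``standardized_betas`` only for linear fits.
    """

    coefficients: pd.Series
    standard_errors: pd.Series
    p_values: pd.Series
    conf_int: pd.DataFrame
    converged: bool
    n_iter: int
    model: str
    odds_ratios: pd.Series | None = None
    or_ci: pd.DataFrame | None = None
    standardized_betas: pd.Series | None = None
    n_obs: int = 0


# ---------------------------------------------------------------------------
# two-sample tests from summary statistics (vectorizable)
# ---------------------------------------------------------------------------


def _check_two_sample(sd1, n1, sd2, n2) -> None:
    if np.any(np.asarray(n1) < 2) or np.any(np.asarray(n2) < 2):
        raise ValueError("both groups need n >= 2")
    if np.any(np.asarray(sd1) <= 0) or np.any(np.asarray(sd2) <= 0):
        raise ValueError("standard deviations must be > 0")


def pooled_t_test(mean1, sd1, n1, mean2, sd2, n2, alpha: float = 0.05) -> StatTestResult:
    """Pooled-variance two-sided t test; effect size is the mean difference."""
    _check_two_sample(sd1, n1, sd2, n2)
    mean1, sd1, n1 = np.asarray(mean1, float), np.asarray(sd1, float), np.asarray(n1, float)
    mean2, sd2, n2 = np.asarray(mean2, float), np.asarray(sd2, float), np.asarray(n2, float)
    df = n1 + n2 - 2
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df)
    se = sp * np.sqrt(1.0 / n1 + 1.0 / n2)
    diff = mean1 - mean2
    t = diff / se
    p = 2.0 * sps.t.sf(np.abs(t), df)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return StatTestResult(
        statistic=_maybe_scalar(t),
        df=_maybe_scalar(df),
        p_value=_maybe_scalar(p),
        effect_size=_maybe_scalar(diff),
        ci_low=_maybe_scalar(diff - tcrit * se),
        ci_high=_maybe_scalar(diff + tcrit * se),
        method="pooled t",
    )


def welch_t_test(mean1, sd1, n1, mean2, sd2, n2, alpha: float = 0.05) -> StatTestResult:
    """Welch two-sided t test with Satterthwaite degrees of freedom."""
    _check_two_sample(sd1, n1, sd2, n2)
    mean1, sd1, n1 = np.asarray(mean1, float), np.asarray(sd1, float), np.asarray(n1, float)
    mean2, sd2, n2 = np.asarray(mean2, float), np.asarray(sd2, float), np.asarray(n2, float)
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se = np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    diff = mean1 - mean2
    t = diff / se
    p = 2.0 * sps.t.sf(np.abs(t), df)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return StatTestResult(
        statistic=_maybe_scalar(t),
        df=_maybe_scalar(df),
        p_value=_maybe_scalar(p),
        effect_size=_maybe_scalar(diff),
        ci_low=_maybe_scalar(diff - tcrit * se),
        ci_high=_maybe_scalar(diff + tcrit * se),
        method="welch t",
    )


def _maybe_scalar(x):
    x = np.asarray(x)
    return float(x) if x.ndim == 0 else x


def _summary(x):
    x = np.asarray(x, dtype=float)
    return x.mean(), x.std(ddof=1), x.shape[0]


def pooled_t_test_data(x, y, alpha: float = 0.05) -> StatTestResult:
    return pooled_t_test(*_summary(x), *_summary(y), alpha=alpha)


def welch_t_test_data(x, y, alpha: float = 0.05) -> StatTestResult:
    return welch_t_test(*_summary(x), *_summary(y), alpha=alpha)


def mann_whitney_u(x, y) -> StatTestResult:
    """Two-sided Mann-Whitney U, normal approximation with tie correction."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    n1, n2 = x.shape[0], y.shape[0]
    rank_biserial = 1.0 - 2.0 * res.statistic / (n1 * n2)
    return StatTestResult(
        statistic=float(res.statistic),
        df=np.nan,
        p_value=float(res.pvalue),
        effect_size=float(rank_biserial),
        method="mann-whitney u",
    )


# ---------------------------------------------------------------------------
# 2x2 tables
# ---------------------------------------------------------------------------


def _check_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table entries must be non-negative integers")
    return t.astype(float)


def chi_square_2x2(table, yates: bool = False) -> StatTestResult:
    """Pearson chi-square on a 2x2 table, df = 1, optional continuity correction.

    Effect size is the phi coefficient signed by the cross-product ad - bc.
    """
    t = _check_table(table)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square undefined with a zero margin")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=yates)
    n = t.sum()
    phi = np.sqrt(chi2 / n) * np.sign(t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0])
    return StatTestResult(
        statistic=float(chi2),
        df=float(df),
        p_value=float(p),
        effect_size=float(phi),
        method="chi-square" + (" (yates)" if yates else ""),
    )


def fisher_exact_2x2(table, ci: bool = False, alpha: float = 0.05) -> StatTestResult:
    """Fisher's exact test, two-sided by summing hypergeometric probabilities
    no larger than that of the observed table.  Effect size is the sample
    odds ratio; with ``ci=True`` a conditional-MLE confidence interval is
    attached.
    """
    t = _check_table(table)
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    lo = hi = np.nan
    if ci:
        res = sps.contingency.odds_ratio(t.astype(int), kind="conditional")
        interval = res.confidence_interval(confidence_level=1 - alpha)
        lo, hi = float(interval.low), float(interval.high)
    return StatTestResult(
        statistic=float(odds),
        df=np.nan,
        p_value=float(p),
        effect_size=float(odds),
        ci_low=lo,
        ci_high=hi,
        method="fisher exact",
    )


# ---------------------------------------------------------------------------
# correlation and effect size
# ---------------------------------------------------------------------------


def pearson_r(x, y, alpha: float = 0.05) -> StatTestResult:
    """Pearson correlation; p from t = r sqrt((n-2)/(1-r^2)), Fisher-z CI."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    res = sps.pearsonr(x, y)
    n = x.shape[0]
    r = res.statistic
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    interval = res.confidence_interval(confidence_level=1 - alpha)
    return StatTestResult(
        statistic=float(t),
        df=float(n - 2),
        p_value=float(res.pvalue),
        effect_size=float(r),
        ci_low=float(interval.low),
        ci_high=float(interval.high),
        method="pearson r",
    )


def cohens_d(mean1, sd1, n1, mean2, sd2, n2, alpha: float = 0.05) -> StatTestResult:
    """Cohen's d with pooled SD and a normal-approximation confidence interval."""
    _check_two_sample(sd1, n1, sd2, n2)
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    d = (mean1 - mean2) / sp
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2)))
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    return StatTestResult(
        statistic=float(d),
        df=float(n1 + n2 - 2),
        p_value=np.nan,
        effect_size=float(d),
        ci_low=float(d - z * se),
        ci_high=float(d + z * se),
        method="cohens d",
    )


def cohens_d_data(x, y, alpha: float = 0.05) -> StatTestResult:
    return cohens_d(*_summary(x), *_summary(y), alpha=alpha)


# ---------------------------------------------------------------------------
# regression models
# ---------------------------------------------------------------------------


def _as_design(X, names) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        df = X.copy()
    else:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] == 1 and X.shape[1] > 1 and names is None:
            X = X.T
        cols = names or [f"x{i + 1}" for i in range(X.shape[1])]
        df = pd.DataFrame(X, columns=cols)
    return df.astype(float)


_SEPARATION_BETA = 30.0  # |logit coef| beyond this flags quasi-separation


def logistic_fit(
    y,
    X,
    names=None,
    alpha: float = 0.05,
    per_sd: bool = False,
) -> RegressionResult:
    """Maximum-likelihood logistic regression with Wald confidence intervals.

    ``per_sd=True`` z-scores every non-binary predictor first, so odds ratios
    are per 1 SD of the analysis sample.  Complete or quasi-complete
    separation is reported as ``converged=False`` rather than returning
    silently diverged estimates.
    """
    y = np.asarray(y, float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    df = _as_design(X, names)
    if per_sd:
        for c in df.columns:
            col = df[c]
            if set(col.unique()) - {0.0, 1.0}:
                df[c] = (col - col.mean()) / col.std(ddof=1)
    design = sm.add_constant(df, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("design matrix is rank-deficient")

    converged = True
    n_iter = 0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        n_iter = int(fit.mle_retvals.get("iterations", 0))
        converged = bool(fit.mle_retvals.get("converged", False))
        params = fit.params
        bse = fit.bse
        pvals = fit.pvalues
        cint = fit.conf_int(alpha=alpha)
    except Exception:  # statsmodels raises on perfect separation
        k = design.shape[1]
        idx = design.columns
        nanrow = pd.Series(np.full(k, np.nan), index=idx)
        return RegressionResult(
            coefficients=nanrow,
            standard_errors=nanrow,
            p_values=nanrow,
            conf_int=pd.DataFrame({"low": nanrow, "high": nanrow}),
            converged=False,
            n_iter=0,
            model="logistic",
            n_obs=y.shape[0],
        )
    if np.any(np.abs(params.to_numpy()) > _SEPARATION_BETA) or not np.all(
        np.isfinite(bse.to_numpy())
    ):
        converged = False
    cint.columns = ["low", "high"]
    with np.errstate(over="ignore"):  # diverged separation fits overflow exp
        odds = np.exp(params)
        or_ci = np.exp(cint)
    return RegressionResult(
        coefficients=params,
        standard_errors=bse,
        p_values=pvals,
        conf_int=cint,
        converged=converged,
        n_iter=n_iter,
        model="logistic" + (" (per-SD)" if per_sd else ""),
        odds_ratios=odds,
        or_ci=or_ci,
        n_obs=y.shape[0],
    )


def linear_fit(y, X, names=None, alpha: float = 0.05, standardize: bool = False) -> RegressionResult:
    """OLS linear regression; standardized betas computed from the raw fit.

    With ``standardize=True`` the model is instead fitted on z-scored outcome
    and predictors, so the coefficients themselves are standardized betas.
    """
    y = np.asarray(y, float)
    df = _as_design(X, names)
    sx = df.std(ddof=1)
    sy = y.std(ddof=1)
    if standardize:
        df = (df - df.mean()) / sx
        y = (y - y.mean()) / sy
    design = sm.add_constant(df, has_constant="add")
    fit = sm.OLS(y, design).fit()
    cint = fit.conf_int(alpha=alpha)
    cint.columns = ["low", "high"]
    betas = fit.params.drop("const") * (1.0 if standardize else sx / sy)
    return RegressionResult(
        coefficients=fit.params,
        standard_errors=fit.bse,
        p_values=fit.pvalues,
        conf_int=cint,
        converged=True,
        n_iter=0,
        model="ols" + (" (standardized)" if standardize else ""),
        standardized_betas=betas,
        n_obs=y.shape[0],
    )


def vif(X, names=None) -> pd.Series:
    """Variance inflation factors: 1 / (1 - R^2_j) from auxiliary regressions
    of each predictor on the others (with intercept).  Orthogonal centered
    designs give exactly 1; values below 2 are the acceptability threshold
    used in the replication recipe.
    """
    df = _as_design(X, names)
    if df.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    out = {}
    for col in df.columns:
        others = sm.add_constant(df.drop(columns=col), has_constant="add")
        r2 = sm.OLS(df[col], others).fit().rsquared
        out[col] = 1.0 / (1.0 - r2) if r2 < 1.0 else np.inf
    return pd.Series(out, name="vif")
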