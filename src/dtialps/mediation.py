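"""Simple mediation with bias-corrected bootstrap confidence intervals.

One binary exposure X (ePVS presence), one continuous mediator M (DTI-ALPS),
one continuous outcome Y (processing speed), optional covariates C.  Four
ordinary-least-squares fits give the paths:

    M = i1 + a X + g' C            (path a)
    Y = i2 + c' X + b M + d' C     (paths b and c-prime)
    Y = i3 + c X + e' C            (total effect c)

The indirect effect is a*b, and on any single sample the OLS decomposition
identity c = c' + a*b holds to machine precision.  Inference on a*b uses
case resampling: rows are drawn with replacement, both path models refitted,
and the bias-corrected (BC, no acceleration) percentile interval reported::

    z0 = Phi^-1( #{ab_boot < ab_hat} / B )
    bounds at empirical percentiles Phi(2 z0 -/+ z_{1-alpha/2})

By default the mediator and outcome are z-scored on the analysis sample and
the binary exposure is left 0/1, so path a is in mediator-SD units per
exposure switch and b in outcome-SD per mediator-SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["MediationSpec", "MediationResult", "mediate", "bc_interval"]

_MAX_REDRAW_ROUNDS = 10  # cap on redraws of degenerate bootstrap replicates
_BOOT_CHUNK = 2_000_000  # max elements per batched design chunk


@dataclass(frozen=True)
class MediationSpec:
    exposure: str = "epvs_present"
    mediator: str = "alps"
    outcome: str = "psi"
    covariates: tuple[str, ...] = ("age", "sex", "qrisk3")
    n_boot: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class MediationResult:
    a: float
    b: float
    c_prime: float
    c: float
    indirect: float
    ci_low: float
    ci_high: float
    boot_mean: float
    boot_sd: float
    t_stat: float
    p_a: float
    p_b: float
    p_cprime: float
    n_boot_effective: int
    n_obs: int
    ci_degenerate: bool = False
    boot_indirect: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def bc_interval(boot_values, point_estimate: float, alpha: float = 0.05):
    """Bias-corrected bootstrap interval (type-7 empirical quantiles).

    Returns ``(low, high)``.  A constant bootstrap distribution gives a
    degenerate interval (low == high) with a warning.  The bias fraction is
    clipped away from 0/1 so the correction stays finite.
    """
    boot = np.asarray(boot_values, dtype=float)
    if boot.size == 0:
        raise ValueError("boot_values must be non-empty")
    if np.all(boot == boot[0]):
        warnings.warn("constant bootstrap distribution; degenerate interval")
        return float(boot[0]), float(boot[0])
    frac = np.mean(boot < point_estimate)
    eps = 1.0 / (boot.size + 1.0)
    z0 = sps.norm.ppf(np.clip(frac, eps, 1.0 - eps))
    zc = sps.norm.ppf(1.0 - alpha / 2.0)
    p_lo = sps.norm.cdf(2.0 * z0 - zc)
    p_hi = sps.norm.cdf(2.0 * z0 + zc)
    lo, hi = np.quantile(boot, [p_lo, p_hi], method="linear")
    return float(lo), float(hi)


def _ols_beta(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def _ols_pvalues(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, k = X.shape
    beta = _ols_beta(X, y)
    resid = y - X @ beta
    dof = n - k
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2.0 * sps.t.sf(np.abs(t), dof)
    return beta, p


def _batched_beta(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Solve OLS for a batch of designs A (B, n, k) and targets y (B, n)."""
    G = np.einsum("bni,bnj->bij", A, A)
    h = np.einsum("bni,bn->bi", A, y)
    try:
        return np.linalg.solve(G, h[..., None])[..., 0]
    except np.linalg.LinAlgError:
        # a resample can make a 0/1 covariate constant (collinear with the
        # intercept); minimum-norm OLS keeps the identified coefficients exact
        return np.einsum("bij,bj->bi", np.linalg.pinv(G), h)


def mediate(data: pd.DataFrame, spec: MediationSpec | None = None) -> MediationResult:
    """Fit the mediation model and bootstrap the indirect effect.

    Deterministic given ``spec.seed``.  Bootstrap replicates in which the
    resampled exposure has a single level are redrawn (up to a capped number
    of rounds); any that remain are dropped and ``n_boot_effective`` reduced.
    """
    spec = spec or MediationSpec()
    cols = [spec.exposure, spec.mediator, spec.outcome, *spec.covariates]
    df = data.loc[:, cols].dropna().reset_index(drop=True)
    n = df.shape[0]
    if n < len(spec.covariates) + 3:
        raise ValueError(f"too few complete cases ({n}) for the mediation model")

    x = np.asarray(df[spec.exposure], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("exposure must have both levels in the analysis sample")

    def numeric(col: pd.Series) -> np.ndarray:
        if col.dtype.kind in "OUSb":
            return pd.Categorical(col).codes.astype(float)
        return np.asarray(col, dtype=float)

    m = np.asarray(df[spec.mediator], dtype=float)
    y = np.asarray(df[spec.outcome], dtype=float)
    if spec.standardize:
        m = (m - m.mean()) / m.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)
    C = np.column_stack([numeric(df[c]) for c in spec.covariates]) if spec.covariates else np.empty((n, 0))

    ones = np.ones((n, 1))
    Xm = np.hstack([ones, x[:, None], C])           # mediator model
    Xy = np.hstack([ones, x[:, None], m[:, None], C])  # outcome model
    Xc = Xm                                          # total-effect model
    if np.linalg.matrix_rank(Xy) < Xy.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates?)")

    beta_m, p_m = _ols_pvalues(Xm, m)
    beta_y, p_y = _ols_pvalues(Xy, y)
    beta_c = _ols_beta(Xc, y)
    a = float(beta_m[1])
    c_prime = float(beta_y[1])
    b = float(beta_y[2])
    c = float(beta_c[1])
    indirect = a * b

    rng = np.random.default_rng(spec.seed)
    B = spec.n_boot
    idx = rng.integers(0, n, size=(B, n))
    degen = _degenerate_mask(x, idx)
    rounds = 0
    while np.any(degen) and rounds < _MAX_REDRAW_ROUNDS:
        idx[degen] = rng.integers(0, n, size=(int(degen.sum()), n))
        degen = _degenerate_mask(x, idx)
        rounds += 1
    keep = ~degen
    idx = idx[keep]
    n_eff = int(idx.shape[0])

    boot = np.empty(n_eff)
    chunk = max(1, _BOOT_CHUNK // (n * Xy.shape[1]))
    for start in range(0, n_eff, chunk):
        sl = idx[start : start + chunk]
        Am = Xm[sl]          # (b, n, k1)
        Ay = Xy[sl]
        a_b = _batched_beta(Am, m[sl])[:, 1]
        b_b = _batched_beta(Ay, y[sl])[:, 2]
        boot[start : start + chunk] = a_b * b_b

    lo, hi = np.nan, np.nan
    degenerate_ci = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        lo, hi = bc_interval(boot, indirect, spec.alpha)
        degenerate_ci = any("degenerate" in str(w.message) for w in caught)

    boot_sd = float(boot.std(ddof=1)) if n_eff > 1 else np.nan
    return MediationResult(
        a=a,
        b=b,
        c_prime=c_prime,
        c=c,
        indirect=indirect,
        ci_low=lo,
        ci_high=hi,
        boot_mean=float(boot.mean()),
        boot_sd=boot_sd,
        t_stat=float(indirect / boot_sd) if boot_sd and np.isfinite(boot_sd) and boot_sd > 0 else np.nan,
        p_a=float(p_m[1]),
        p_b=float(p_y[2]),
        p_cprime=float(p_y[1]),
        n_boot_effective=n_eff,
        n_obs=n,
        ci_degenerate=degenerate_ci,
        boot_indirect=boot,
    )


def _degenerate_mask(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    xr = x[idx]
    return np.all(xr == xr[:, :1], axis=1)
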