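"""Synthetic DWI phantoms and cohort tables for the glymphatic-CSVD analysis.

Two generators live here.

``generate_dwi_phantom`` builds a block phantom with three fiber regions —
projection (z-dominant), association (y-dominant) and subcortical
(x-dominant) — embedded in isotropic background.  The x-axis diffusivities of
the projection and association regions are solved analytically so that the
noiseless ALPS pipeline returns a prescribed index exactly; Rician noise at a
configurable b0 SNR degrades the signal on top of that ground truth.

``generate_cohort`` draws a cohort table with a binary ePVS exposure, vascular
risk covariates, and a linear structural mediation model
(ePVS -> ALPS -> processing speed) on standardized scales:

    M* = a*ePVS + gamma' C + eps_m        (mediator, ALPS)
    Y* = b*M* + c'*ePVS + delta' C + eps_y  (outcome, PSI)

The standardized columns (``alps_std``, ``psi_std``) carry the structural
path coefficients; the raw columns (``alps``, ``psi``) are per-group affine
maps of them onto the printed group means/SDs, so both the path-recovery and
group-mean views of the data are reproducible.  The two views cannot share a
single scale because the published group means imply a much larger
standardized group difference than the published path a; see
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alps import ROISpec
from .dwi import DWIVolume, GradientScheme, TensorField, fibonacci_scheme
from .epvs import grade_epvs

__all__ = [
    "GroupStats",
    "CohortParams",
    "PhantomSpec",
    "solve_axis_diffusivities",
    "generate_dwi_phantom",
    "phantom_tensors",
    "default_region_map",
    "phantom_rois",
    "generate_cohort",
    "structural_moments",
    "COHORT_COLUMNS",
]

SMOKING_LEVELS = ("non", "ex", "light", "moderate", "heavy")

COHORT_COLUMNS = [
    "id",
    "age",
    "sex",
    "family_history",
    "hypertension",
    "smoking",
    "sbp",
    "bmi",
    "qrisk3",
    "epvs_present",
    "epvs_count_bg",
    "epvs_count_cso",
    "epvs_grade_bg",
    "epvs_grade_cso",
    "alps",
    "psi",
    "pri",
    "wmi",
    "alps_std",
    "psi_std",
]


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupStats:
    """Location/scale per exposure group (with vs without ePVS)."""

    mean_with: float
    sd_with: float
    mean_without: float
    sd_without: float

    def mean(self, present: bool) -> float:
        return self.mean_with if present else self.mean_without

    def sd(self, present: bool) -> float:
        return self.sd_with if present else self.sd_without


def _default_group_means() -> dict:
    # observed group summaries of the study cohort (with / without ePVS)
    return {
        "sbp": GroupStats(134.3, 15.8, 123.9, 13.5),
        "bmi": GroupStats(26.4, 3.6, 23.2, 4.6),
        "qrisk3": GroupStats(4.5, 5.9, 1.3, 1.7),
        "psi": GroupStats(98.7, 12.7, 105.1, 14.5),
        "pri": GroupStats(101.7, 12.8, 102.7, 12.3),
        "wmi": GroupStats(107.4, 18.5, 108.5, 19.6),
    }


def _default_covariate_effects() -> dict:
    # standardized effects of age / sex(male) / QRISK3 on mediator and outcome
    return {
        "mediator": {"age": -0.20, "sex": 0.0, "qrisk3": -0.05},
        "outcome": {"age": -0.10, "sex": 0.0, "qrisk3": 0.0},
    }


@dataclass(frozen=True)
class CohortParams:
    """Generating conditions of the synthetic cohort.

    Defaults are the replication conditions: n = 60 adults aged 25-65,
    ePVS prevalence 43.3%, group means from the study's demographic table,
    ALPS group means 1.80 +/- 0.15 (no ePVS) vs 1.55 +/- 0.30 (ePVS), and the
    standardized mediation paths a = -0.2813, b = +0.8861, c' = 0.0412.

    ``noise_sd_mediator`` / ``noise_sd_outcome`` are the residual SDs of the
    standardized structural equations; the defaults make the standardized
    mediator and outcome have unit marginal variance under the default paths
    and covariate effects.
    """

    n_subjects: int = 60
    epvs_prevalence: float = 0.433
    age_mean: float = 38.47
    age_sd: float = 8.63
    age_range: tuple[float, float] = (25.0, 65.0)
    male_fraction: float = 19.0 / 60.0
    group_means: dict = field(default_factory=_default_group_means)
    alps_group_means: GroupStats = GroupStats(1.55, 0.30, 1.80, 0.15)
    path_a: float = -0.2813
    path_b: float = 0.8861
    path_cprime: float = 0.0412
    noise_sd_mediator: float = 0.966
    noise_sd_outcome: float = 0.418
    covariate_effects: dict = field(default_factory=_default_covariate_effects)
    family_history_rate: tuple[float, float] = (0.462, 0.088)  # (with, without)
    hypertension_rate: tuple[float, float] = (0.307, 0.029)
    smoking_probs: tuple[float, ...] = (0.866, 0.100, 0.017, 0.017, 0.0)
    epvs_count_mean: dict = field(
        default_factory=lambda: {"bg": 6.0, "cso": 9.0}
    )
    epvs_count_dispersion: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if not 0.0 <= self.epvs_prevalence <= 1.0:
            raise ValueError("epvs_prevalence must be in [0, 1]")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0, 1]")
        lo, hi = self.age_range
        if not (lo >= 25.0 and hi <= 65.0 and lo < hi):
            raise ValueError("age_range must be within [25, 65]")
        for name, val in [
            ("age_sd", self.age_sd),
            ("noise_sd_mediator", self.noise_sd_mediator),
            ("noise_sd_outcome", self.noise_sd_outcome),
            ("epvs_count_dispersion", self.epvs_count_dispersion),
        ]:
            if not (np.isfinite(val) and val > 0):
                raise ValueError(f"{name} must be finite and > 0")
        for coef in (self.path_a, self.path_b, self.path_cprime, self.age_mean):
            if not np.isfinite(coef):
                raise ValueError("non-finite structural parameter")
        for gs in list(self.group_means.values()) + [self.alps_group_means]:
            if gs.sd_with <= 0 or gs.sd_without <= 0:
                raise ValueError("group scale parameters must be > 0")


def _age_dist(params: CohortParams):
    lo, hi = params.age_range
    a = (lo - params.age_mean) / params.age_sd
    b = (hi - params.age_mean) / params.age_sd
    return sps.truncnorm(a, b, loc=params.age_mean, scale=params.age_sd)


def _qrisk_gamma(mean: float, sd: float):
    # gamma matched to mean/SD: positive support, right-skewed like risk scores
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return shape, scale


def structural_moments(params: CohortParams) -> dict:
    """Analytic per-group moments of the standardized mediator and outcome.

    Used for the per-group affine map onto the printed raw scales, and handy
    as an oracle in tests.  Covariate z-scores use the configured age
    moments, an exact Bernoulli standardization for sex, and the analytic
    mixture moments of the two-group gamma QRISK3 distribution.
    """
    p = params.epvs_prevalence
    gm = params.group_means["qrisk3"]
    mix_mean = p * gm.mean_with + (1 - p) * gm.mean_without
    mix_var = (
        p * gm.sd_with**2
        + (1 - p) * gm.sd_without**2
        + p * (1 - p) * (gm.mean_with - gm.mean_without) ** 2
    )
    mix_sd = float(np.sqrt(mix_var))

    age = _age_dist(params)
    age_mean_t, age_var_t = age.stats(moments="mv")
    e_age_z = (float(age_mean_t) - params.age_mean) / params.age_sd
    v_age_z = float(age_var_t) / params.age_sd**2

    gam_m = params.covariate_effects["mediator"]
    gam_y = params.covariate_effects["outcome"]
    a, b, cp = params.path_a, params.path_b, params.path_cprime
    sm2 = params.noise_sd_mediator**2
    sy2 = params.noise_sd_outcome**2

    out = {"qrisk_mix_mean": mix_mean, "qrisk_mix_sd": mix_sd}
    for g in (0, 1):
        present = bool(g)
        e_qz = (gm.mean(present) - mix_mean) / mix_sd
        v_qz = gm.sd(present) ** 2 / mix_var
        cov_var = {"age": v_age_z, "sex": 1.0, "qrisk3": v_qz}
        cov_mean = {"age": e_age_z, "sex": 0.0, "qrisk3": e_qz}

        m_mean = a * g + sum(gam_m[k] * cov_mean[k] for k in cov_mean)
        m_var = sum(gam_m[k] ** 2 * cov_var[k] for k in cov_var) + sm2
        y_mean = b * m_mean + cp * g + sum(gam_y[k] * cov_mean[k] for k in cov_mean)
        y_var = (
            sum((b * gam_m[k] + gam_y[k]) ** 2 * cov_var[k] for k in cov_var)
            + b**2 * sm2
            + sy2
        )
        out[g] = {
            "m_mean": m_mean,
            "m_sd": float(np.sqrt(m_var)),
            "y_mean": y_mean,
            "y_sd": float(np.sqrt(y_var)),
        }
    return out


def generate_cohort(params: CohortParams | None = None) -> pd.DataFrame:
    """Draw a cohort table; identical params (incl. seed) give identical tables."""
    params = params or CohortParams()
    n = params.n_subjects
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in COHORT_COLUMNS})

    rng = np.random.default_rng(params.seed)
    p = params.epvs_prevalence

    age = _age_dist(params).rvs(size=n, random_state=rng)
    male = rng.random(n) < params.male_fraction
    epvs = rng.random(n) < p

    fh_rate = np.where(epvs, *params.family_history_rate)
    htn_rate = np.where(epvs, *params.hypertension_rate)
    family_history = rng.random(n) < fh_rate
    hypertension = rng.random(n) < htn_rate
    smoking = rng.choice(
        len(SMOKING_LEVELS), size=n, p=np.asarray(params.smoking_probs)
    )

    def group_normal(gs: GroupStats) -> np.ndarray:
        mean = np.where(epvs, gs.mean_with, gs.mean_without)
        sd = np.where(epvs, gs.sd_with, gs.sd_without)
        return rng.normal(mean, sd)

    sbp = group_normal(params.group_means["sbp"])
    bmi = group_normal(params.group_means["bmi"])

    gm_q = params.group_means["qrisk3"]
    shape = np.empty(n)
    scale = np.empty(n)
    for present in (True, False):
        sh, sc = _qrisk_gamma(gm_q.mean(present), gm_q.sd(present))
        mask = epvs == present
        shape[mask], scale[mask] = sh, sc
    qrisk3 = rng.gamma(shape, scale)

    # standardized covariates entering the structural equations
    mom = structural_moments(params)
    age_z = (age - params.age_mean) / params.age_sd
    mf = params.male_fraction
    sex_z = (male.astype(float) - mf) / np.sqrt(mf * (1 - mf)) if 0 < mf < 1 else np.zeros(n)
    qrisk_z = (qrisk3 - mom["qrisk_mix_mean"]) / mom["qrisk_mix_sd"]
    covs = {"age": age_z, "sex": sex_z, "qrisk3": qrisk_z}

    gam_m = params.covariate_effects["mediator"]
    gam_y = params.covariate_effects["outcome"]
    x = epvs.astype(float)
    m_std = (
        params.path_a * x
        + sum(gam_m[k] * covs[k] for k in covs)
        + rng.normal(0.0, params.noise_sd_mediator, n)
    )
    y_std = (
        params.path_b * m_std
        + params.path_cprime * x
        + sum(gam_y[k] * covs[k] for k in covs)
        + rng.normal(0.0, params.noise_sd_outcome, n)
    )

    # per-group affine map onto the printed raw scales
    def group_map(std, key_mean, key_sd, gs: GroupStats) -> np.ndarray:
        raw = np.empty(n)
        for g in (0, 1):
            mask = epvs == bool(g)
            mu, sd = mom[g][key_mean], mom[g][key_sd]
            raw[mask] = gs.mean(bool(g)) + gs.sd(bool(g)) * (std[mask] - mu) / sd
        return raw

    alps = group_map(m_std, "m_mean", "m_sd", params.alps_group_means)
    alps = np.maximum(alps, 0.01)  # ALPS is a ratio of diffusivities, > 0
    psi = group_map(y_std, "y_mean", "y_sd", params.group_means["psi"])
    pri = group_normal(params.group_means["pri"])
    wmi = group_normal(params.group_means["wmi"])

    # ePVS counts: positives draw 1 + NB(mean - 1, dispersion); absent -> 0
    counts = {}
    for region, mean_count in params.epvs_count_mean.items():
        k = params.epvs_count_dispersion
        mu = max(mean_count - 1.0, 1e-9)
        nb = rng.negative_binomial(k, k / (k + mu), n)
        counts[region] = np.where(epvs, 1 + nb, 0)

    return pd.DataFrame(
        {
            "id": [f"S{i:04d}" for i in range(1, n + 1)],
            "age": age,
            "sex": np.where(male, "male", "female"),
            "family_history": family_history.astype(int),
            "hypertension": hypertension.astype(int),
            "smoking": np.asarray(SMOKING_LEVELS)[smoking],
            "sbp": sbp,
            "bmi": bmi,
            "qrisk3": qrisk3,
            "epvs_present": epvs.astype(int),
            "epvs_count_bg": counts["bg"],
            "epvs_count_cso": counts["cso"],
            "epvs_grade_bg": grade_epvs(counts["bg"]),
            "epvs_grade_cso": grade_epvs(counts["cso"]),
            "alps": alps,
            "psi": psi,
            "pri": pri,
            "wmi": wmi,
            "alps_std": m_std,
            "psi_std": y_std,
        },
        columns=COHORT_COLUMNS,
    )


# ---------------------------------------------------------------------------
# DWI phantom generator
# ---------------------------------------------------------------------------

BACKGROUND, PROJECTION, ASSOCIATION, SUBCORTICAL = 0, 1, 2, 3


def solve_axis_diffusivities(
    target_alps: float, d_perp_proj: float, d_perp_assoc: float
) -> tuple[float, float]:
    """Invert the ALPS formula for the two x-axis diffusivities (equal split).

    Returns (dx_proj, dx_assoc) with
    mean(dx_proj, dx_assoc) = target_alps * mean(d_perp_proj, d_perp_assoc).
    """
    for name, v in [
        ("target_alps", target_alps),
        ("d_perp_proj", d_perp_proj),
        ("d_perp_assoc", d_perp_assoc),
    ]:
        if not (np.isfinite(v) and v > 0):
            raise ValueError(f"{name} must be finite and > 0")
    dx = target_alps * 0.5 * (d_perp_proj + d_perp_assoc)
    return dx, dx


def default_region_map(grid_shape: tuple[int, int, int] = (16, 16, 12)) -> np.ndarray:
    """Block region map: three 5x5x5 fiber regions in isotropic background."""
    nx, ny, nz = grid_shape
    if nx < 15 or ny < 15 or nz < 9:
        raise ValueError(f"grid {grid_shape} too small for the default regions")
    labels = np.full(grid_shape, BACKGROUND, dtype=np.int8)
    z0 = (nz - 5) // 2
    labels[2:7, 2:7, z0 : z0 + 5] = PROJECTION
    labels[9:14, 2:7, z0 : z0 + 5] = ASSOCIATION
    labels[2:7, 9:14, z0 : z0 + 5] = SUBCORTICAL
    return labels


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, diffusivities and noise of a DWI block phantom.

    The x-axis diffusivities of the projection and association regions are
    derived from ``target_alps`` via :func:`solve_axis_diffusivities`; the
    dominant-fiber axis carries ``d_axial`` and the remaining perpendicular
    axes the ``d_perp_*`` values.  ``snr_b0 = inf`` disables noise.
    """

    target_alps: float = 1.80
    grid_shape: tuple[int, int, int] = (16, 16, 12)
    voxel_size: float = 2.5
    region_map: np.ndarray | None = None
    d_axial: float = 1.4e-3
    d_perp_proj: float = 0.8e-3  # Dy in the projection region
    d_perp_assoc: float = 0.7e-3  # Dz in the association region
    d_background: float = 0.8e-3
    s0: float = 1000.0
    snr_b0: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.target_alps > 0:
            raise ValueError("target_alps must be > 0")
        if not self.snr_b0 > 0:
            raise ValueError("snr_b0 must be > 0 (use inf for noiseless)")
        for name in ("d_axial", "d_perp_proj", "d_perp_assoc", "d_background", "s0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    def regions(self) -> np.ndarray:
        if self.region_map is not None:
            return np.asarray(self.region_map)
        return default_region_map(self.grid_shape)


def phantom_tensors(spec: PhantomSpec) -> TensorField:
    """Noise-free generating tensor field of a phantom (the analytic oracle)."""
    labels = spec.regions()
    for lab, name in [(PROJECTION, "projection"), (ASSOCIATION, "association"), (SUBCORTICAL, "subcortical")]:
        if np.count_nonzero(labels == lab) < 12:
            raise ValueError(f"region map lacks a usable {name} region")
    dx_proj, dx_assoc = solve_axis_diffusivities(
        spec.target_alps, spec.d_perp_proj, spec.d_perp_assoc
    )
    diag = {
        BACKGROUND: (spec.d_background,) * 3,
        # projection fibers run along z; the PVS axis is x
        PROJECTION: (dx_proj, spec.d_perp_proj, spec.d_axial),
        # association fibers run along y
        ASSOCIATION: (dx_assoc, spec.d_axial, spec.d_perp_assoc),
        # subcortical fibers run along x
        SUBCORTICAL: (spec.d_axial, 0.75e-3, 0.75e-3),
    }
    D = np.zeros(labels.shape + (3, 3))
    for lab, d in diag.items():
        mask = labels == lab
        for ax in range(3):
            D[mask, ax, ax] = d[ax]
    return TensorField(
        tensor=D,
        s0=np.full(labels.shape, spec.s0),
        fit_ok=np.ones(labels.shape, dtype=bool),
    )


def phantom_rois(spec: PhantomSpec) -> list[ROISpec]:
    """ROIs at the centroid of each fiber region of the phantom."""
    labels = spec.regions()
    rois = []
    for lab, name in [(PROJECTION, "projection"), (ASSOCIATION, "association"), (SUBCORTICAL, "subcortical")]:
        where = np.argwhere(labels == lab)
        if where.size == 0:
            continue
        center = tuple(int(round(c)) for c in where.mean(axis=0))
        rois.append(ROISpec(label=name, center=center))
    return rois


def generate_dwi_phantom(
    spec: PhantomSpec, scheme: GradientScheme | None = None
) -> DWIVolume:
    """Synthesize the DWI signal of a phantom, optionally Rician-degraded.

    Signal model S = S0 exp(-b g'Dg); Rician noise is the magnitude of the
    complex signal with two independent Gaussian channels of SD S0/snr_b0.
    """
    scheme = scheme or fibonacci_scheme()
    field = phantom_tensors(spec)
    D = field.tensor.reshape(-1, 3, 3)
    g = scheme.bvecs
    b = scheme.bvals
    # quadratic form g'Dg per voxel and volume
    q = np.einsum("vi,nij,vj->nv", g, D, g)
    signal = spec.s0 * np.exp(-q * b[None, :])
    if np.isfinite(spec.snr_b0):
        rng = np.random.default_rng(spec.seed)
        sigma = spec.s0 / spec.snr_b0
        re = signal + rng.normal(0.0, sigma, signal.shape)
        im = rng.normal(0.0, sigma, signal.shape)
        signal = np.hypot(re, im)
    shape = spec.regions().shape
    affine = np.diag([spec.voxel_size] * 3 + [1.0])
    return DWIVolume(
        signal=signal.reshape(shape + (len(scheme),)), affine=affine, scheme=scheme
    )
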