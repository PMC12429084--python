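"""End-to-end orchestration: simulate -> fit -> ALPS -> grade -> stats -> mediation.

A :class:`RunConfig` fully determines a run; a single global seed is fanned
out to per-stage child seeds through ``numpy.random.SeedSequence`` with a
fixed stage order, so any stage can be reproduced in isolation.  The
consolidated :class:`RunReport` holds machine-precision stage outputs plus a
config hash; a rounded human summary mirrors clinical reporting conventions
(2 decimals for p values and indices, 1 for percentages).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alps import compute_subject_alps
from .dwi import read_dwi, write_dwi
from .epvs import cohens_kappa, grade_epvs, qrisk_category
from .mediation import MediationSpec, mediate
from .stats import (
    chi_square_2x2,
    cohens_d_data,
    fisher_exact_2x2,
    linear_fit,
    logistic_fit,
    pearson_r,
    pooled_t_test_data,
    mann_whitney_u,
    vif,
)
from .synthetic import (
    CohortParams,
    PhantomSpec,
    generate_cohort,
    generate_dwi_phantom,
    phantom_rois,
)

__all__ = [
    "RunConfig",
    "RunReport",
    "PipelineStageError",
    "run",
    "replication_recipe",
    "load_config",
    "save_config",
]

_STAGES = ("cohort", "imaging", "epvs", "stats", "mediation")


class PipelineStageError(RuntimeError):
    """An error raised inside a pipeline stage, labelled with the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")


@dataclass(frozen=True)
class RunConfig:
    mode: str = "full-replication"  # simulate | analyze | full-replication
    out_dir: str | None = None
    cohort: CohortParams = field(default_factory=CohortParams)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    mediation: MediationSpec = field(default_factory=MediationSpec)
    # analyze-mode inputs
    cohort_csv: str | None = None
    dwi_dir: str | None = None
    use_t_tests: bool = True  # False switches continuous comparisons to Mann-Whitney
    alpha: float = 0.05
    seed: int = 0
    grade_flip_prob: float = 0.06  # second-rater disagreement for the kappa demo

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        ph = d["phantom"]
        if ph.get("region_map") is not None:
            ph["region_map"] = np.asarray(ph["region_map"]).tolist()
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    mode: str
    seed: int
    config_hash: str
    version: str
    stages: dict

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "version": self.version,
            "stages": self.stages,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def replication_recipe(seed: int = 0) -> RunConfig:
    """The canonical configuration of the replication run.

    n = 60 subjects, ePVS prevalence 0.433, mediation with 10,000
    bias-corrected bootstrap resamples at alpha = 0.05, phantoms at SNR 30.
    The mediation runs on the standardized structural columns, the scale on
    which the published path coefficients live.
    """
    return RunConfig(
        mode="full-replication",
        cohort=CohortParams(),
        phantom=PhantomSpec(),
        mediation=MediationSpec(
            exposure="epvs_present",
            mediator="alps_std",
            outcome="psi_std",
            covariates=("age", "sex", "qrisk3"),
            n_boot=10_000,
            alpha=0.05,
        ),
        seed=seed,
    )


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run(config: RunConfig) -> RunReport:
    """Execute the configured stages in order, failing fast with stage labels."""
    if config.mode not in ("simulate", "analyze", "full-replication"):
        raise ValueError(f"unknown mode {config.mode!r}")
    seeds = dict(zip(_STAGES, _child_seeds(config.seed, len(_STAGES))))
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    stages: dict = {}

    # --- cohort -----------------------------------------------------------
    try:
        if config.mode == "analyze":
            if not config.cohort_csv or not Path(config.cohort_csv).exists():
                raise FileNotFoundError(f"cohort CSV not found: {config.cohort_csv}")
            cohort = pd.read_csv(config.cohort_csv)
        else:
            cohort = generate_cohort(replace(config.cohort, seed=seeds["cohort"]))
        stages["cohort"] = {
            "n_subjects": int(cohort.shape[0]),
            "n_epvs_present": int(cohort["epvs_present"].sum()),
            "epvs_prevalence_pct": 100.0 * float(cohort["epvs_present"].mean()),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("cohort", exc) from exc

    # --- imaging ----------------------------------------------------------
    try:
        if config.mode == "analyze" and config.dwi_dir:
            cohort = _analyze_dwi_dir(cohort, config)
        elif config.mode != "analyze":
            cohort = _simulate_imaging(cohort, config, seeds["imaging"], out_dir)
        if "alps_measured" in cohort:
            grp = cohort.groupby("epvs_present")["alps_measured"].agg(["mean", "std"])
            stages["imaging"] = {
                "alps_mean_no_epvs": float(grp.loc[0, "mean"]),
                "alps_sd_no_epvs": float(grp.loc[0, "std"]),
                "alps_mean_epvs": float(grp.loc[1, "mean"]),
                "alps_sd_epvs": float(grp.loc[1, "std"]),
                "snr_b0": float(config.phantom.snr_b0),
            }
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("imaging", exc) from exc

    # --- ePVS grading / agreement ----------------------------------------
    try:
        stages["epvs"] = _epvs_stage(cohort, config, seeds["epvs"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("epvs", exc) from exc

    # --- statistics battery ----------------------------------------------
    try:
        stages["stats"] = _stats_stage(cohort, config)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("stats", exc) from exc

    # --- mediation --------------------------------------------------------
    try:
        med_spec = replace(config.mediation, seed=seeds["mediation"])
        med = mediate(cohort, med_spec)
        stages["mediation"] = {
            "a": med.a,
            "b": med.b,
            "c_prime": med.c_prime,
            "c": med.c,
            "indirect": med.indirect,
            "ci_low": med.ci_low,
            "ci_high": med.ci_high,
            "boot_sd": med.boot_sd,
            "t_stat": med.t_stat,
            "p_a": med.p_a,
            "p_b": med.p_b,
            "p_cprime": med.p_cprime,
            "n_boot_effective": med.n_boot_effective,
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("mediation", exc) from exc

    report = RunReport(
        mode=config.mode,
        seed=config.seed,
        config_hash=config.hash(),
        version=__version__,
        stages=stages,
    )
    if out_dir:
        cohort.to_csv(out_dir / "cohort.csv", index=False)
        report.to_json(out_dir / "report.json")
        (out_dir / "summary.txt").write_text(render_summary(report))
    return report


def _simulate_imaging(cohort, config: RunConfig, seed: int, out_dir) -> pd.DataFrame:
    """One phantom per subject with the subject's ALPS as ground truth."""
    measured = np.empty(cohort.shape[0])
    phantom_dir = out_dir / "phantoms" if out_dir else None
    if phantom_dir:
        phantom_dir.mkdir(exist_ok=True)
    child = _child_seeds(seed, max(cohort.shape[0], 1))
    for i, (_, row) in enumerate(cohort.iterrows()):
        spec = replace(config.phantom, target_alps=float(row["alps"]), seed=child[i])
        dwi = generate_dwi_phantom(spec)
        if phantom_dir:
            sid = row["id"]
            write_dwi(
                dwi,
                phantom_dir / f"{sid}.nii.gz",
                phantom_dir / f"{sid}.bval",
                phantom_dir / f"{sid}.bvec",
            )
        measured[i] = compute_subject_alps(dwi, phantom_rois(spec)).alps
    out = cohort.copy()
    out["alps_measured"] = measured
    return out


def _analyze_dwi_dir(cohort, config: RunConfig) -> pd.DataFrame:
    """Compute ALPS from on-disk NIfTI + bval/bvec bundles named by subject id."""
    dwi_dir = Path(config.dwi_dir)
    rois = phantom_rois(config.phantom)
    measured = []
    for sid in cohort["id"]:
        nii = dwi_dir / f"{sid}.nii.gz"
        bval = dwi_dir / f"{sid}.bval"
        bvec = dwi_dir / f"{sid}.bvec"
        for p in (nii, bval, bvec):
            if not p.exists():
                raise FileNotFoundError(f"missing DWI input for {sid}: {p}")
        dwi = read_dwi(nii, bval, bvec)
        measured.append(compute_subject_alps(dwi, rois).alps)
    out = cohort.copy()
    out["alps_measured"] = measured
    return out


def _epvs_stage(cohort, config: RunConfig, seed: int) -> dict:
    grades = grade_epvs(cohort["epvs_count_bg"].to_numpy(dtype=int))
    rng = np.random.default_rng(seed)
    # second synthetic rater: occasional +/-1-grade disagreement
    flip = rng.random(grades.shape[0]) < config.grade_flip_prob
    step = rng.choice([-1, 1], size=grades.shape[0])
    rater_b = np.clip(grades + flip * step, 0, 4)
    agreement = cohens_kappa(grades, rater_b)
    qcat = pd.Series([qrisk_category(s) for s in cohort["qrisk3"]])
    return {
        "grade_counts_bg": {int(g): int(c) for g, c in zip(*np.unique(grades, return_counts=True))},
        "kappa": agreement.kappa,
        "kappa_ci": [agreement.ci_low, agreement.ci_high],
        "qrisk_categories": qcat.value_counts().to_dict(),
    }


def _stats_stage(cohort, config: RunConfig) -> dict:
    present = cohort["epvs_present"] == 1
    out: dict = {"group_comparisons": {}, "categorical": {}, "correlations": {}}

    compare = pooled_t_test_data if config.use_t_tests else mann_whitney_u
    for var in ("age", "sbp", "bmi", "qrisk3", "psi", "pri", "wmi"):
        if var not in cohort:
            continue
        res = compare(cohort.loc[present, var], cohort.loc[~present, var])
        out["group_comparisons"][var] = {
            "statistic": res.statistic,
            "p": res.p_value,
            "effect": res.effect_size,
        }
    if "psi" in cohort and present.any() and (~present).any():
        d = cohens_d_data(cohort.loc[present, "psi"], cohort.loc[~present, "psi"])
        out["group_comparisons"]["psi_cohens_d"] = {
            "d": d.effect_size,
            "ci": [d.ci_low, d.ci_high],
        }

    for var in ("family_history", "hypertension"):
        if var not in cohort:
            continue
        tab = pd.crosstab(cohort[var], cohort["epvs_present"]).reindex(
            index=[0, 1], columns=[0, 1], fill_value=0
        ).to_numpy()
        entry = {}
        if np.all(tab.sum(axis=0) > 0) and np.all(tab.sum(axis=1) > 0):
            entry["chi2_p"] = chi_square_2x2(tab).p_value
        entry["fisher_p"] = fisher_exact_2x2(tab).p_value
        out["categorical"][var] = entry

    for xv, yv in (("alps", "psi"), ("alps", "age"), ("qrisk3", "age")):
        if xv in cohort and yv in cohort:
            r = pearson_r(cohort[xv], cohort[yv])
            out["correlations"][f"{xv}~{yv}"] = {"r": r.effect_size, "p": r.p_value}

    predictors = [v for v in ("age", "sbp", "bmi", "qrisk3", "psi") if v in cohort]
    X = cohort[predictors].copy()
    X["sex_male"] = (cohort["sex"] == "male").astype(float) if cohort["sex"].dtype == object else cohort["sex"]
    logit = logistic_fit(cohort["epvs_present"].to_numpy(float), X)
    out["logistic"] = {
        "converged": logit.converged,
        "odds_ratios": logit.odds_ratios.to_dict() if logit.odds_ratios is not None else None,
        "p": logit.p_values.to_dict(),
    }
    out["vif"] = vif(X).to_dict()

    # adjusted group comparison of ALPS (general linear model + Bonferroni)
    target = "alps_measured" if "alps_measured" in cohort else "alps"
    adj = cohort[["age", "hypertension"]].copy()
    adj["sex_male"] = X["sex_male"]
    adj["epvs_present"] = cohort["epvs_present"].astype(float)
    lm = linear_fit(cohort[target].to_numpy(float), adj)
    n_pairwise = 1  # two groups -> one pairwise contrast
    out["adjusted_alps_comparison"] = {
        "coef_epvs": float(lm.coefficients["epvs_present"]),
        "p_bonferroni": min(1.0, float(lm.p_values["epvs_present"]) * n_pairwise),
    }
    return out


_ROUND_P = 2


def render_summary(report: RunReport) -> str:
    """Human-readable rounded summary of a run report."""
    s = report.stages
    lines = [
        f"dtialps v{report.version}  mode={report.mode}  seed={report.seed}  config={report.config_hash}",
    ]
    if "cohort" in s:
        c = s["cohort"]
        lines.append(
            f"cohort: n={c['n_subjects']}, ePVS present n={c['n_epvs_present']} "
            f"({c['epvs_prevalence_pct']:.1f}%)"
        )
    if "imaging" in s:
        im = s["imaging"]
        lines.append(
            f"ALPS (pipeline): no ePVS {im['alps_mean_no_epvs']:.2f} ± {im['alps_sd_no_epvs']:.2f}"
            f" | ePVS {im['alps_mean_epvs']:.2f} ± {im['alps_sd_epvs']:.2f}"
        )
    if "epvs" in s:
        lines.append(f"inter-rater kappa (synthetic 2nd rater): {s['epvs']['kappa']:.2f}")
    if "stats" in s and "psi" in s["stats"]["group_comparisons"]:
        g = s["stats"]["group_comparisons"]["psi"]
        lines.append(f"PSI group difference: {g['effect']:.1f} points (p={g['p']:.2f})")
    if "mediation" in s:
        m = s["mediation"]
        lines.append(
            f"mediation: a={m['a']:.2f} b={m['b']:.2f} c'={m['c_prime']:.2f} "
            f"indirect={m['indirect']:.2f} [{m['ci_low']:.2f}, {m['ci_high']:.2f}]"
        )
    return "\n".join(lines) + "\n"


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML; nested sections rebuild the dataclasses."""
    raw = yaml.safe_load(Path(path).read_text())
    cohort_raw = raw.pop("cohort", {})
    gm = cohort_raw.pop("group_means", None)
    alps_gm = cohort_raw.pop("alps_group_means", None)
    from .synthetic import GroupStats  # local import to avoid cycle at module load

    if gm is not None:
        cohort_raw["group_means"] = {k: GroupStats(**v) for k, v in gm.items()}
    if alps_gm is not None:
        cohort_raw["alps_group_means"] = GroupStats(**alps_gm)
    if "age_range" in cohort_raw:
        cohort_raw["age_range"] = tuple(cohort_raw["age_range"])
    for tup in ("family_history_rate", "hypertension_rate", "smoking_probs"):
        if tup in cohort_raw:
            cohort_raw[tup] = tuple(cohort_raw[tup])
    phantom_raw = raw.pop("phantom", {})
    if phantom_raw.get("region_map") is not None:
        phantom_raw["region_map"] = np.asarray(phantom_raw["region_map"])
    if "grid_shape" in phantom_raw:
        phantom_raw["grid_shape"] = tuple(phantom_raw["grid_shape"])
    med_raw = raw.pop("mediation", {})
    if "covariates" in med_raw:
        med_raw["covariates"] = tuple(med_raw["covariates"])
    return RunConfig(
        cohort=CohortParams(**cohort_raw),
        phantom=PhantomSpec(**phantom_raw),
        mediation=MediationSpec(**med_raw),
        **raw,
    )
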