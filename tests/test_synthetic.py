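"""Cohort and phantom generators: determinism, invariants, calibration."""

import numpy as np
import pytest
from scipy import stats as sps

from dtialps.alps import compute_subject_alps
from dtialps.epvs import GRADE_BINS, grade_epvs
from dtialps.mediation import MediationSpec, mediate
from dtialps.synthetic import (
    COHORT_COLUMNS,
    CohortParams,
    PhantomSpec,
    generate_cohort,
    generate_dwi_phantom,
    phantom_rois,
    phantom_tensors,
    solve_axis_diffusivities,
    structural_moments,
)


class TestSolveAxisDiffusivities:
    @pytest.mark.parametrize(
        "target, dp, da, expected",
        [
            (1.0, 0.75e-3, 0.75e-3, 0.75e-3),
            (1.80, 0.8e-3, 0.7e-3, 1.35e-3),
            (2.0, 1e-3, 1e-3, 2e-3),
        ],
    )
    def test_equal_split_inverts_formula(self, target, dp, da, expected):
        dx_proj, dx_assoc = solve_axis_diffusivities(target, dp, da)
        assert dx_proj == pytest.approx(expected)
        assert dx_assoc == pytest.approx(expected)
        assert 0.5 * (dx_proj + dx_assoc) == pytest.approx(target * 0.5 * (dp + da))

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            solve_axis_diffusivities(-1.0, 1e-3, 1e-3)
        with pytest.raises(ValueError):
            solve_axis_diffusivities(1.5, 0.0, 1e-3)


class TestPhantom:
    @pytest.mark.parametrize("target", [1.0, 1.3, 1.55, 1.80, 2.2, 2.5])
    def test_noiseless_pipeline_roundtrip(self, target):
        spec = PhantomSpec(target_alps=target, snr_b0=np.inf)
        res = compute_subject_alps(generate_dwi_phantom(spec), phantom_rois(spec))
        assert res.alps == pytest.approx(target, abs=1e-6)

    def test_same_seed_bit_identical(self):
        a = generate_dwi_phantom(PhantomSpec(seed=42))
        b = generate_dwi_phantom(PhantomSpec(seed=42))
        assert np.array_equal(a.signal, b.signal)

    def test_different_seed_differs(self):
        a = generate_dwi_phantom(PhantomSpec(seed=1))
        b = generate_dwi_phantom(PhantomSpec(seed=2))
        assert not np.array_equal(a.signal, b.signal)

    def test_generating_tensors_match_pipeline_oracle(self):
        spec = PhantomSpec(target_alps=1.7, snr_b0=np.inf)
        truth = phantom_tensors(spec)
        fitted = compute_subject_alps(generate_dwi_phantom(spec), phantom_rois(spec))
        # projection ROI mean Dxx equals the generating x diffusivity
        dx_proj, _ = solve_axis_diffusivities(1.7, spec.d_perp_proj, spec.d_perp_assoc)
        assert fitted.dx_proj == pytest.approx(dx_proj, abs=1e-9)
        assert truth.tensor[3, 3, 5, 0, 0] == pytest.approx(dx_proj)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(target_alps=-1.0)
        with pytest.raises(ValueError):
            PhantomSpec(snr_b0=0.0)
        with pytest.raises(ValueError):
            generate_dwi_phantom(PhantomSpec(region_map=np.zeros((6, 6, 6), np.int8)))


class TestCohortBasics:
    def test_empty_cohort_has_full_column_set(self):
        t = generate_cohort(CohortParams(n_subjects=0))
        assert list(t.columns) == COHORT_COLUMNS
        assert t.shape[0] == 0

    def test_same_seed_identical_table(self):
        p = CohortParams(n_subjects=40, seed=9)
        assert generate_cohort(p).equals(generate_cohort(p))

    def test_invariants_hold(self, small_cohort):
        t = small_cohort
        assert (t["alps"] > 0).all()
        assert t["age"].between(25, 65).all()
        np.testing.assert_array_equal(
            t["epvs_grade_bg"], grade_epvs(t["epvs_count_bg"].to_numpy())
        )
        np.testing.assert_array_equal(
            t["epvs_grade_cso"], grade_epvs(t["epvs_count_cso"].to_numpy())
        )
        absent = t["epvs_present"] == 0
        assert (t.loc[absent, "epvs_count_bg"] == 0).all()
        assert (t.loc[~absent, "epvs_count_bg"] >= 1).all()

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            CohortParams(epvs_prevalence=1.5)
        with pytest.raises(ValueError):
            CohortParams(n_subjects=-1)
        with pytest.raises(ValueError):
            CohortParams(age_range=(20.0, 65.0))
        with pytest.raises(ValueError):
            CohortParams(noise_sd_mediator=0.0)

    def test_expected_positive_count_is_26_of_60(self):
        counts = [
            generate_cohort(CohortParams(n_subjects=60, seed=s))["epvs_present"].sum()
            for s in range(300)
        ]
        assert np.mean(counts) == pytest.approx(26, abs=1.0)


class TestCohortCalibration:
    def test_marginals_converge_to_configured_values(self, large_cohort):
        t = large_cohort
        p = CohortParams()
        assert t["epvs_present"].mean() == pytest.approx(p.epvs_prevalence, rel=0.02)
        assert (t["sex"] == "male").mean() == pytest.approx(p.male_fraction, rel=0.05)

        # age follows the truncated normal; compare to its analytic mean
        a = (25 - p.age_mean) / p.age_sd
        b = (65 - p.age_mean) / p.age_sd
        age_mean = sps.truncnorm(a, b, loc=p.age_mean, scale=p.age_sd).mean()
        assert t["age"].mean() == pytest.approx(age_mean, rel=0.02)

        for var in ("sbp", "bmi", "qrisk3"):
            gs = p.group_means[var]
            grp = t.groupby("epvs_present")[var].mean()
            assert grp[1] == pytest.approx(gs.mean_with, rel=0.02)
            assert grp[0] == pytest.approx(gs.mean_without, rel=0.02)

    def test_group_alps_and_psi_scales(self, large_cohort):
        t = large_cohort
        grp = t.groupby("epvs_present")["alps"].agg(["mean", "std"])
        assert grp.loc[0, "mean"] == pytest.approx(1.80, abs=0.01)
        assert grp.loc[1, "mean"] == pytest.approx(1.55, abs=0.01)
        assert grp.loc[0, "std"] == pytest.approx(0.15, abs=0.01)
        assert grp.loc[1, "std"] == pytest.approx(0.30, abs=0.01)
        psi = t.groupby("epvs_present")["psi"].mean()
        assert psi[0] == pytest.approx(105.1, abs=0.5)
        assert psi[1] == pytest.approx(98.7, abs=0.5)

    def test_standardized_columns_have_unit_scale(self, large_cohort):
        assert large_cohort["alps_std"].std() == pytest.approx(1.0, abs=0.02)
        assert large_cohort["psi_std"].std() == pytest.approx(1.0, abs=0.02)

    def test_structural_paths_recovered_at_large_n(self, large_cohort):
        """OLS on the generating model recovers each path within +/-0.02."""
        res = mediate(
            large_cohort,
            MediationSpec(mediator="alps_std", outcome="psi_std", n_boot=1, seed=0),
        )
        p = CohortParams()
        assert res.a == pytest.approx(p.path_a, abs=0.02)
        assert res.b == pytest.approx(p.path_b, abs=0.02)
        assert res.c_prime == pytest.approx(p.path_cprime, abs=0.02)

    def test_structural_moment_oracle_matches_samples(self, large_cohort):
        mom = structural_moments(CohortParams())
        grp = large_cohort.groupby("epvs_present")["alps_std"].agg(["mean", "std"])
        for g in (0, 1):
            assert grp.loc[g, "mean"] == pytest.approx(mom[g]["m_mean"], abs=0.02)
            assert grp.loc[g, "std"] == pytest.approx(mom[g]["m_sd"], abs=0.02)


class TestNoisyPhantomRecovery:
    def test_snr30_group_mean_recovers_target(self):
        """Monte-Carlo check against the noiseless oracle at SNR(b0) = 30."""
        target = 1.80
        vals = []
        for s in range(20):
            spec = PhantomSpec(target_alps=target, snr_b0=30.0, seed=1000 + s)
            vals.append(
                compute_subject_alps(generate_dwi_phantom(spec), phantom_rois(spec)).alps
            )
        assert np.mean(vals) == pytest.approx(target, abs=0.05)
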