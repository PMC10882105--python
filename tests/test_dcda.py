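"""Dose-space CDA: Hill fits, dose equivalence, model limits, pipeline, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cdaction import (
    DoseMatrix,
    HillParams,
    SynthSpec,
    ValidationError,
    dcda_viability,
    eob_validity,
    eocda,
    equivalent_dose,
    fit_dcda,
    fit_dcda_pipeline,
    fit_hill,
    flag_outliers,
    gen_combination_matrix,
    gof_paired_t,
    hill_viability,
    local_dcda_flags,
)
from cdaction.dcda import HillFitError

doses_st = st.floats(min_value=0.0, max_value=50.0)


class TestHill:
    def test_viability_values(self):
        h = HillParams(k=1.0, n=1.0)
        assert hill_viability(h, 0.0) == 1.0
        assert hill_viability(h, 1.0) == 0.5
        assert hill_viability(h, 3.0) == pytest.approx(0.25, abs=1e-12)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            hill_viability(HillParams(1, 1), -0.5)

    def test_linear_data_line_fit_k(self):
        # viability% = 90 - 10*D crosses 50% at D = 4
        d = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        v = (90.0 - 10.0 * d) / 100.0
        h = fit_hill(d, v, refine=False)
        assert h.k == pytest.approx(4.0, rel=1e-6)

    def test_recovers_generating_parameters(self):
        true = HillParams(k=2.0, n=1.5)
        d = 2.0 * np.geomspace(0.25, 4.0, 6)
        h = fit_hill(d, hill_viability(true, d))
        assert h.k == pytest.approx(2.0, abs=0.05)
        assert h.n == pytest.approx(1.5, abs=0.05)

    def test_flat_viability_rejected(self):
        d = np.array([1.0, 2.0, 3.0])
        with pytest.raises(HillFitError):
            fit_hill(d, np.full(3, 0.8))

    def test_increasing_viability_rejected(self):
        d = np.array([1.0, 2.0, 3.0])
        with pytest.raises(HillFitError):
            fit_hill(d, np.array([0.3, 0.5, 0.8]))


class TestEquivalentDose:
    def test_sham_identity(self):
        h = HillParams(k=2.0, n=1.3)
        assert equivalent_dose(h, h, 3.0) == pytest.approx(3.0, abs=1e-12)

    def test_hand_value(self):
        # to_k * (D / from_k)^(from_n / to_n) = 2 * 2^2 = 8
        a = HillParams(k=1.0, n=2.0)
        b = HillParams(k=2.0, n=1.0)
        assert equivalent_dose(a, b, 2.0) == pytest.approx(8.0, abs=1e-12)

    def test_ec50_maps_to_ec50(self, hill_a, hill_b):
        assert equivalent_dose(hill_a, hill_b, hill_a.k) == pytest.approx(hill_b.k)

    @settings(max_examples=50, deadline=None)
    @given(d=doses_st)
    def test_equal_effect(self, d):
        hill_a, hill_b = HillParams(5, 1.5), HillParams(8, 2.0)
        v_from = hill_viability(hill_a, d)
        v_to = hill_viability(hill_b, equivalent_dose(hill_a, hill_b, d))
        assert v_to == pytest.approx(v_from, abs=1e-10)


class TestDcdaViability:
    unit = HillParams(k=1.0, n=1.0)

    @pytest.mark.parametrize(
        "rho, expected",
        [
            (0.0, 0.25),  # Bliss: 0.5 * 0.5
            (1.0, 1.0 / 3.0),  # sham: V(1 + 1)
            (0.5, 0.5 * 0.25 + 0.5 / 3.0),  # mixture of the two
        ],
    )
    def test_hand_values(self, rho, expected):
        assert dcda_viability(self.unit, self.unit, 1.0, 1.0, rho) == pytest.approx(
            expected, abs=1e-10
        )

    def test_frechet_bound_at_minus_one(self):
        # VA = 0.5, VB = 0.4: max(0, 0.9 - 1) = 0
        a = HillParams(k=1.0, n=1.0)
        b = HillParams(k=1.0, n=1.0)
        d_b = 1.5  # V(1.5) = 0.4
        assert dcda_viability(a, b, 1.0, d_b, -1.0) == pytest.approx(0.0, abs=1e-12)

    def test_sham_compliance_exact(self, hill_a):
        da, db = 3.0, 7.0
        v = dcda_viability(hill_a, hill_a, da, db, 1.0)
        assert v == pytest.approx(hill_viability(hill_a, da + db), abs=1e-12)

    def test_rho_out_of_range(self, hill_a, hill_b):
        with pytest.raises(ValueError):
            dcda_viability(hill_a, hill_b, 1.0, 1.0, 1.2)

    @settings(max_examples=60, deadline=None)
    @given(
        da=doses_st,
        db=doses_st,
        rho=st.floats(min_value=-1.0, max_value=1.0),
    )
    def test_below_single_agent_envelope(self, da, db, rho):
        a, b = HillParams(5, 1.5), HillParams(8, 2.0)
        v = dcda_viability(a, b, da, db, rho)
        env = min(hill_viability(a, da), hill_viability(b, db))
        assert v <= env + 1e-12

    def test_monotone_in_dose_and_continuous_at_zero(self, hill_a, hill_b):
        d = np.linspace(0, 30, 40)
        for rho in (-0.7, -0.2, 0.0, 0.4, 1.0):
            v = dcda_viability(hill_a, hill_b, d[:, None], d[None, :], rho)
            assert np.all(np.diff(v, axis=0) <= 1e-12)
            assert np.all(np.diff(v, axis=1) <= 1e-12)
        below = dcda_viability(hill_a, hill_b, 4.0, 6.0, -1e-9)
        above = dcda_viability(hill_a, hill_b, 4.0, 6.0, +1e-9)
        assert below == pytest.approx(above, abs=1e-6)


def _exact_matrix(hill_a, hill_b, rho, n_doses=6):
    da = hill_a.k * np.geomspace(0.25, 4, n_doses)
    db = hill_b.k * np.geomspace(0.25, 4, n_doses)
    v = dcda_viability(hill_a, hill_b, da[:, None], db[None, :], rho)
    return DoseMatrix(
        doses_A=da,
        doses_B=db,
        viability=v,
        mono_A=hill_viability(hill_a, da),
        mono_B=hill_viability(hill_b, db),
    )


class TestFitDcda:
    def test_self_consistency(self, hill_a, hill_b):
        m = _exact_matrix(hill_a, hill_b, 0.3)
        rho, rmse, _ = fit_dcda(m)
        assert rho == pytest.approx(0.3, abs=2.0 / 199)
        assert rmse < 0.01

    def test_recovery_from_simulation(self, hill_a, hill_b):
        spec = SynthSpec(
            hill_A=hill_a, hill_B=hill_b, rho_true=0.3, n_units=10_000,
            noise_sd=0.02, seed=4,
        )
        fit = fit_dcda_pipeline(gen_combination_matrix(spec))
        assert fit.rho_hat == pytest.approx(0.3, abs=0.1)


class TestFlagOutliers:
    def test_no_outliers_when_exact(self, hill_a, hill_b):
        m = _exact_matrix(hill_a, hill_b, 0.2)
        assert flag_outliers(m.viability, m.viability) == frozenset()

    def test_single_corrupted_cell_flagged(self, hill_a, hill_b):
        rng = np.random.default_rng(1)
        m = _exact_matrix(hill_a, hill_b, 0.2)
        sigma = 0.01
        obs = m.viability + rng.normal(0, sigma, m.shape)
        obs[2, 3] += 10 * sigma
        flagged = flag_outliers(obs.ravel(), m.viability.ravel())
        assert 2 * m.shape[1] + 3 in flagged

    def test_matches_statsmodels_cutoff(self):
        """Cross-check the studentized residuals against the oracle directly."""
        import statsmodels.api as sm
        from statsmodels.stats.outliers_influence import OLSInfluence

        rng = np.random.default_rng(2)
        pred = np.linspace(0.1, 0.9, 36)
        obs = pred + rng.normal(0, 0.02, 36)
        obs[10] += 0.2
        res = OLSInfluence(
            sm.OLS(obs, sm.add_constant(pred)).fit()
        ).resid_studentized_external
        cutoff = stats.t.ppf(1 - 0.05 / 72, df=33)
        expected = frozenset(np.flatnonzero(np.abs(res) > cutoff).tolist())
        assert flag_outliers(obs, pred) == expected

    def test_constant_predictions_rejected(self):
        with pytest.raises(ValidationError):
            flag_outliers(np.linspace(0, 1, 10), np.full(10, 0.5))


class TestPipeline:
    def test_clean_matrix_keeps_initial_rho(self, hill_a, hill_b):
        spec = SynthSpec(
            hill_A=hill_a, hill_B=hill_b, rho_true=0.0, n_units=20_000,
            noise_sd=0.01, seed=6,
        )
        fit = fit_dcda_pipeline(gen_combination_matrix(spec))
        if not fit.outliers:
            assert fit.rho_hat == fit.rho_hat_initial

    def test_corrupted_cell_recovered(self, hill_a, hill_b):
        spec = SynthSpec(
            hill_A=hill_a, hill_B=hill_b, rho_true=0.3, n_units=50_000,
            noise_sd=0.01, seed=8,
        )
        m = gen_combination_matrix(spec)
        v = m.viability.copy()
        v[4, 4] = min(v[4, 4] + 0.3, 1.2)
        corrupted = DoseMatrix(
            doses_A=m.doses_A, doses_B=m.doses_B, viability=v,
            mono_A=m.mono_A, mono_B=m.mono_B,
        )
        fit = fit_dcda_pipeline(corrupted)
        assert (4, 4) in fit.outliers
        assert fit.rho_hat == pytest.approx(0.3, abs=0.1)

    def test_eocda_field_consistent(self, hill_a, hill_b):
        m = _exact_matrix(hill_a, hill_b, 0.4)
        fit = fit_dcda_pipeline(m)
        np.testing.assert_allclose(fit.eocda, fit.predicted - m.viability)


class TestPairedTTest:
    def test_identical_is_one(self):
        assert gof_paired_t(np.linspace(0, 1, 10), np.linspace(0, 1, 10)) == 1.0

    def test_offset_with_noise_rejected(self):
        rng = np.random.default_rng(3)
        pred = np.linspace(0.2, 0.8, 36)
        obs = pred - 0.1 + rng.normal(0, 0.01, 36)
        assert gof_paired_t(pred, obs) < 1e-6

    def test_constant_nonzero_offset_degenerate(self):
        with pytest.raises(ValidationError):
            gof_paired_t(np.linspace(0, 1, 10), np.linspace(0, 1, 10) + 0.1)

    def test_matches_scipy(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 1, 20)
        b = a + rng.normal(0, 0.05, 20)
        assert gof_paired_t(a, b) == pytest.approx(stats.ttest_rel(a, b).pvalue)


class TestEOBAndEOCDA:
    def test_eob_exact_bliss_is_one(self, hill_a, hill_b):
        m = _exact_matrix(hill_a, hill_b, 0.0)
        assert eob_validity(m, hills=(hill_a, hill_b)) == 1.0

    def test_eob_less_valid_as_correlation_grows(self, hill_a, hill_b):
        ps = []
        for rho in (0.0, 0.8):
            spec = SynthSpec(
                hill_A=hill_a, hill_B=hill_b, rho_true=rho, n_units=20_000,
                noise_sd=0.02, seed=9,
            )
            ps.append(eob_validity(gen_combination_matrix(spec)))
        assert ps[1] < ps[0]

    def test_eob_invalid_for_strongly_correlated_matrix(self, hill_a, hill_b):
        spec = SynthSpec(
            hill_A=hill_a, hill_B=hill_b, rho_true=0.8, n_units=20_000,
            noise_sd=0.02, seed=10,
        )
        assert eob_validity(gen_combination_matrix(spec)) < 0.01

    def test_eocda_sign_and_antisymmetry(self):
        p = np.array([[0.5]])
        o = np.array([[0.3]])
        assert eocda(p, o)[0, 0] == pytest.approx(0.2)
        np.testing.assert_allclose(eocda(p, o), -eocda(o, p))

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            eocda(np.zeros((2, 2)), np.zeros((3, 2)))


class TestLocalFlags:
    def test_exact_matrix_all_consistent(self, hill_a, hill_b):
        # a correlation on the candidate grid makes the fit residuals all zero
        rho_on_grid = float(np.linspace(-1, 1, 200)[129])
        m = _exact_matrix(hill_a, hill_b, rho_on_grid)
        fit = fit_dcda_pipeline(m)
        assert fit.local_flags is not None
        assert all(f.status == "consistent" for f in fit.local_flags)

    def test_synergistic_cell_flagged(self, hill_a, hill_b):
        spec = SynthSpec(
            hill_A=hill_a, hill_B=hill_b, rho_true=0.2, n_units=100_000,
            noise_sd=0.01, seed=12,
        )
        m = gen_combination_matrix(spec)
        v = m.viability.copy()
        # kills moderately more cells than predicted: below the Bonferroni
        # outlier cutoff but beyond the local z threshold
        v[5, 5] = max(v[5, 5] - 0.025, 0.0)
        bumped = DoseMatrix(
            doses_A=m.doses_A, doses_B=m.doses_B, viability=v,
            mono_A=m.mono_A, mono_B=m.mono_B,
        )
        fit = fit_dcda_pipeline(bumped)
        assert (5, 5) not in fit.outliers
        flags = {tuple(map(int, f.index)): f for f in local_dcda_flags(bumped, fit)}
        f = flags[(5, 5)]
        assert f.status == "non_dCDA"
        assert f.direction == "synergistic"
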