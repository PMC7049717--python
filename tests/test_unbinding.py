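import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from smtkinetics.unbinding import (
    BiphasicParams,
    BiphasicUnbindingModel,
    alpha_from_km,
    km_relation,
    rate_apparent,
    rate_eq_occupancy,
    rate_minimum,
)

# literature-style parameter sets used as fixtures
NONREPRESSOR = dict(k_o_off=22.0, k_r=12.0, k_f=0.018, K_m=12.0)
REPRESSOR_MIX = dict(k_o_off=25.0, k_r=16.0, k_f=0.012, K_m=14.0)
SALT_BRIDGE_MUTANT = dict(k_o_off=22.0, k_r=21.0, k_f=0.021, K_m=38.6)


class TestOccupancyRate:
    def test_zero_occupancy_zero_concentration_is_spontaneous_rate(self):
        p = BiphasicParams(k_o=10.0, k_r=12.0, k_f=0.018, K_m=12.0, alpha=0.5)
        assert rate_eq_occupancy(p, 0, 0.0) == pytest.approx(p.k_o_off)

    def test_arithmetic(self):
        p = BiphasicParams(k_o=10.0, k_r=12.0, k_f=0.018, K_m=12.0, alpha=0.5)
        assert rate_eq_occupancy(p, 2, 100.0) == pytest.approx(10 + 3 + 1.8)

    def test_alpha_near_one_removes_occupancy_dependence(self):
        p = BiphasicParams(k_o=10.0, k_r=12.0, k_f=0.018, K_m=12.0, alpha=1 - 1e-9)
        vals = [rate_eq_occupancy(p, n, 50.0) for n in range(6)]
        np.testing.assert_allclose(vals, vals[0], rtol=1e-6)

    def test_occupancy_above_maximum_rejected(self):
        p = BiphasicParams(k_o=10.0, k_r=12.0, k_f=0.018, K_m=12.0, alpha=0.5, n_o=5)
        with pytest.raises(ValueError):
            rate_eq_occupancy(p, 6, 0.0)


class TestApparentRate:
    def test_zero_concentration_limit(self):
        p = BiphasicParams(**NONREPRESSOR)
        assert rate_apparent(p, 0.0) == pytest.approx(p.k_o_off)

    def test_nonrepressor_value_at_100nM(self):
        assert rate_apparent(BiphasicParams(**NONREPRESSOR), 100.0) == pytest.approx(
            11.80, abs=0.01
        )

    def test_no_oligomer_reduces_to_linear_facilitated_law(self):
        p = BiphasicParams(k_o_off=5.0, k_r=0.0, k_f=0.02, K_m=10.0)
        P = np.array([0.0, 50.0, 500.0])
        np.testing.assert_allclose(rate_apparent(p, P), 5.0 + 0.02 * P)

    def test_large_concentration_slope_is_k_f(self):
        p = BiphasicParams(**REPRESSOR_MIX)
        slope = (rate_apparent(p, 2e5) - rate_apparent(p, 1e5)) / 1e5
        assert slope == pytest.approx(p.k_f, rel=1e-9)


class TestKmRelation:
    def test_value(self):
        assert km_relation(22.0, 0.77, 0.5) == pytest.approx(22 / (0.77 * 0.5))

    def test_alpha_to_zero_gives_kd1(self):
        assert km_relation(22.0, 0.77, 1e-12) == pytest.approx(22 / 0.77, rel=1e-9)

    def test_doubling_k1_halves_km(self):
        assert km_relation(22.0, 1.54, 0.3) == pytest.approx(
            km_relation(22.0, 0.77, 0.3) / 2
        )

    def test_rounded_literature_values_flag_infeasible_alpha(self):
        # k_o_off = 22, k_1 = 0.77, K_m = 12 implies alpha < 0: the
        # inversion reports the tension instead of hiding it
        alpha, feasible = alpha_from_km(22.0, 0.77, 12.0)
        assert alpha < 0 and not feasible

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            km_relation(22.0, 0.77, 1.0)


class TestRateMinimum:
    def test_repressor_mix_parameters(self):
        p = BiphasicParams(**REPRESSOR_MIX)
        assert rate_minimum(p) == pytest.approx(63.8, abs=0.1)

    def test_no_impeded_term_no_minimum(self):
        assert rate_minimum(BiphasicParams(k_o_off=5, k_r=0, k_f=0.01, K_m=10)) is None

    def test_boundary_case(self):
        p = BiphasicParams(k_o_off=10, k_r=0.1, k_f=0.01, K_m=10)  # k_r = k_f K_m
        assert rate_minimum(p) == pytest.approx(0.0, abs=1e-12)

    @given(
        k_o_off=st.floats(5.0, 50.0),
        k_r_frac=st.floats(0.01, 0.99),
        k_f=st.floats(1e-3, 0.05),
        K_m=st.floats(1.0, 100.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_numerical_minimizer(self, k_o_off, k_r_frac, k_f, K_m):
        p = BiphasicParams(k_o_off=k_o_off, k_r=k_r_frac * k_o_off, k_f=k_f, K_m=K_m)
        pm = rate_minimum(p)
        res = optimize.minimize_scalar(
            lambda x: rate_apparent(p, x), bounds=(0.0, 1e5), method="bounded"
        )
        if pm is None:
            # monotone increasing: numerical minimum sits at the origin
            assert res.x < 1e-2 or rate_apparent(p, 0.0) <= res.fun + 1e-9
        else:
            assert res.x == pytest.approx(pm, rel=1e-3, abs=1e-2)

    def test_biphasic_signature_decreasing_then_increasing(self):
        p = BiphasicParams(**NONREPRESSOR)
        pm = rate_minimum(p)
        lo = np.linspace(0.1, pm * 0.95, 20)
        hi = np.linspace(pm * 1.05, pm * 20, 20)
        assert (np.diff(rate_apparent(p, lo)) < 0).all()
        assert (np.diff(rate_apparent(p, hi)) > 0).all()


class TestFit:
    P8 = np.geomspace(10, 1000, 8)

    def test_noiseless_self_consistency(self):
        truth = BiphasicParams(**REPRESSOR_MIX)
        k = rate_apparent(truth, self.P8)
        fit = BiphasicUnbindingModel(self.P8, k).fit(n_boot=0)
        assert fit.params.k_o_off == pytest.approx(truth.k_o_off, rel=1e-4)
        assert fit.params.K_m == pytest.approx(truth.K_m, rel=1e-3)
        assert fit.chi2 < 1e-8

    def test_linear_data_prefers_linear_model(self, rng):
        k = 5.0 + 0.02 * self.P8 + rng.normal(0, 0.1, len(self.P8))
        fit = BiphasicUnbindingModel(self.P8, k, np.full(8, 0.1)).fit(n_boot=0)
        assert not fit.prefers_biphasic

    def test_biphasic_data_prefers_biphasic_model(self, rng):
        truth = BiphasicParams(**NONREPRESSOR)
        k = rate_apparent(truth, self.P8) * (1 + 0.03 * rng.standard_normal(8))
        fit = BiphasicUnbindingModel(self.P8, k, 0.03 * k).fit(n_boot=0)
        assert fit.prefers_biphasic

    def test_noisy_km_recovery(self):
        truth = BiphasicParams(**SALT_BRIDGE_MUTANT)
        g = np.random.default_rng(5)
        k = rate_apparent(truth, self.P8) * (1 + 0.1 * g.standard_normal(8))
        fit = BiphasicUnbindingModel(self.P8, k, 0.1 * np.abs(k)).fit(
            n_boot=200, seed=5
        )
        assert abs(fit.params.K_m - truth.K_m) < 3 * fit.sd["K_m"]

    def test_refit_of_fitted_curve_is_idempotent(self):
        truth = BiphasicParams(**NONREPRESSOR)
        g = np.random.default_rng(6)
        k = rate_apparent(truth, self.P8) * (1 + 0.05 * g.standard_normal(8))
        fit1 = BiphasicUnbindingModel(self.P8, k, 0.05 * k).fit(n_boot=0)
        k_clean = rate_apparent(fit1.params, self.P8)
        fit2 = BiphasicUnbindingModel(self.P8, k_clean, 0.05 * k).fit(n_boot=0)
        assert fit2.params.K_m == pytest.approx(fit1.params.K_m, rel=1e-3)
        assert fit2.params.k_o_off == pytest.approx(fit1.params.k_o_off, rel=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            BiphasicUnbindingModel([10, 100, 1000], [5, 4, 6])

    def test_narrow_range_warns(self):
        with pytest.warns(UserWarning, match="decade"):
            BiphasicUnbindingModel([10, 20, 30, 40], [5, 4, 4.5, 5])

    def test_params_enforce_internal_consistency(self):
        with pytest.raises(ValueError):
            BiphasicParams(k_o=5.0, k_o_off=20.0, k_r=12.0, k_f=0.01, K_m=10.0)
        p = BiphasicParams(k_o_off=22.0, k_r=12.0, k_f=0.018, K_m=12.0)
        assert p.k_o == pytest.approx(10.0)
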