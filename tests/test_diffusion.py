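import numpy as np
import pandas as pd
import pytest

from conftest import MIX_D, MIX_F, T_LAPSE
from smtkinetics.diffusion import (
    DisplacementMixtureModel,
    DisplacementSet,
    bootstrap_sd,
    brownian_cdf,
    displacements,
)


def _tracks(rows):
    return pd.DataFrame(rows, columns=["cell_id", "track_id", "frame", "x_um", "y_um"])


class TestDisplacements:
    def test_three_four_five_triangle(self):
        t = _tracks([(0, 0, 0, 0.0, 0.0), (0, 0, 1, 0.3, 0.4)])
        np.testing.assert_allclose(displacements(t, 0.04).r, [0.5])

    def test_single_localization_yields_none(self):
        t = _tracks([(0, 0, 0, 0.1, 0.1)])
        assert len(displacements(t, 0.04).r) == 0

    def test_five_frame_track_gives_four(self):
        t = _tracks([(0, 0, f, 0.01 * f, 0.0) for f in range(5)])
        assert len(displacements(t, 0.04).r) == 4

    def test_gaps_and_track_breaks_excluded(self):
        t = _tracks(
            [(0, 0, 0, 0.0, 0.0), (0, 0, 2, 1.0, 0.0),  # frame gap
             (0, 1, 0, 0.0, 0.0), (0, 1, 1, 0.1, 0.0)]  # new track
        )
        np.testing.assert_allclose(displacements(t, 0.04).r, [0.1])

    def test_empty_input(self):
        assert len(displacements(_tracks([]), 0.04).r) == 0


class TestBrownianCdf:
    def test_threshold_captures_tb_state(self):
        # r0 = 0.2 um captures > 99.5% of displacements at the
        # tight-binding D of 0.033 um^2/s
        val = brownian_cdf(0.2, 0.033, 0.04, 0.0)
        assert val == pytest.approx(0.99949, abs=5e-5)
        assert val >= 0.995

    def test_zero_displacement(self):
        assert brownian_cdf(0.0, 0.82, 0.04) == 0.0

    def test_nb_state_value(self):
        assert brownian_cdf(0.2, 0.82, 0.04, 0.0) == pytest.approx(0.263, abs=5e-4)

    def test_degenerate_zero_motion_zero_noise(self):
        assert brownian_cdf(0.2, 0.0, 0.04, 0.0) == 1.0
        assert brownian_cdf(0.0, 0.0, 0.04, 0.0) == 0.0


class TestMixtureFit:
    def test_single_state_data_flags_duplicates(self, rng):
        r = np.sqrt(rng.exponential(4 * 1.0 * T_LAPSE, size=20_000))
        fit = DisplacementMixtureModel(
            DisplacementSet(r, T_LAPSE), n_states=3, sigma_loc=0.0
        ).fit()
        assert fit.fractions["all"].max() > 0.95 or fit.duplicate_components

    def test_three_state_recovery(self, mixture_displacements):
        fit = DisplacementMixtureModel(
            DisplacementSet(mixture_displacements, T_LAPSE), n_states=3, sigma_loc=0.0
        ).fit()
        np.testing.assert_allclose(fit.D, MIX_D, rtol=0.08)
        np.testing.assert_allclose(fit.fractions["all"], MIX_F, atol=0.015)
        assert fit.converged

    def test_fractions_sum_to_one(self, mixture_displacements):
        fit = DisplacementMixtureModel(
            DisplacementSet(mixture_displacements, T_LAPSE), n_states=3, sigma_loc=0.0
        ).fit()
        assert fit.fractions["all"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_shared_D_per_group_fractions(self, rng):
        f_a, f_b = np.array([0.6, 0.3, 0.1]), np.array([0.2, 0.3, 0.5])
        sets = []
        for label, f in (("lo", f_a), ("hi", f_b)):
            comp = rng.choice(3, size=25_000, p=f)
            r = np.sqrt(rng.exponential(4 * MIX_D[comp] * T_LAPSE))
            sets.append(DisplacementSet(r, T_LAPSE, group=label))
        fit = DisplacementMixtureModel(sets, n_states=3, sigma_loc=0.0).fit()
        assert set(fit.fractions) == {"lo", "hi"}  # D shared by construction
        np.testing.assert_allclose(fit.fractions["lo"], f_a, atol=0.03)
        np.testing.assert_allclose(fit.fractions["hi"], f_b, atol=0.03)

    def test_three_state_loglike_dominates_two_state(self, mixture_displacements):
        dset = DisplacementSet(mixture_displacements, T_LAPSE)
        ll3 = DisplacementMixtureModel(dset, n_states=3, sigma_loc=0.0).fit().loglike
        ll2 = DisplacementMixtureModel(dset, n_states=2, sigma_loc=0.0).fit().loglike
        assert ll3 >= ll2 - 1e-6

    def test_single_state_fit_unbiased_against_moment_oracle(self, rng):
        D = 0.5
        r2 = rng.exponential(4 * D * T_LAPSE, size=30_000)
        fit = DisplacementMixtureModel(
            DisplacementSet(np.sqrt(r2), T_LAPSE), n_states=1, sigma_loc=0.0
        ).fit()
        oracle = r2.mean() / (4 * T_LAPSE)  # moment estimator of D
        assert fit.D[0] == pytest.approx(oracle, rel=1e-6)

    def test_cdf_mode_agrees_with_mle(self, mixture_displacements):
        model = DisplacementMixtureModel(
            DisplacementSet(mixture_displacements, T_LAPSE), n_states=3, sigma_loc=0.0
        )
        em = model.fit()
        cdf = model.fit_cdf()
        np.testing.assert_allclose(cdf.D, em.D, rtol=0.15)
        np.testing.assert_allclose(
            cdf.fractions["all"], em.fractions["all"], atol=0.04
        )

    def test_n_states_below_one_rejected(self):
        with pytest.raises(ValueError):
            DisplacementMixtureModel(
                DisplacementSet(np.ones(600), T_LAPSE), n_states=0
            )

    def test_few_displacements_warn(self):
        with pytest.warns(UserWarning, match="displacements"):
            DisplacementMixtureModel(DisplacementSet(np.ones(10), T_LAPSE))


class TestBootstrap:
    def test_zero_replicates_rejected(self, rng):
        r = np.sqrt(rng.exponential(4 * 0.5 * T_LAPSE, size=1000))
        model = DisplacementMixtureModel(
            DisplacementSet(r, T_LAPSE), n_states=1, sigma_loc=0.0
        )
        with pytest.raises(ValueError):
            bootstrap_sd(model, 0, seed=1)

    def test_identical_cells_give_zero_sd(self, rng):
        # every cell contributes the same displacements, so every
        # resample is the same dataset and the spread collapses
        r_cell = np.sqrt(rng.exponential(4 * 0.5 * T_LAPSE, size=200))
        r = np.tile(r_cell, 4)
        cells = np.repeat(np.arange(4), 200)
        model = DisplacementMixtureModel(
            DisplacementSet(r, T_LAPSE, cell_ids=cells), n_states=1, sigma_loc=0.0
        )
        with pytest.warns(UserWarning):
            fit = bootstrap_sd(model, 20, seed=2)
        assert fit.D_sd[0] == pytest.approx(0.0, abs=1e-12)

    def test_bootstrap_sd_matches_sampling_spread(self, rng):
        """68% normal-interval coverage: the bootstrap s.d. should match
        the true sampling spread of the fraction estimate."""
        D, f = MIX_D, MIX_F
        estimates, sds = [], []
        import warnings

        for i in range(30):
            g = np.random.default_rng(500 + i)
            comp = g.choice(3, size=4000, p=f)
            r = np.sqrt(g.exponential(4 * D[comp] * T_LAPSE))
            model = DisplacementMixtureModel(
                DisplacementSet(r, T_LAPSE), n_states=3, sigma_loc=0.0
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = bootstrap_sd(model, 40, seed=i, fit=model.fit())
            estimates.append(fit.fractions["all"][2])
            sds.append(fit.fractions_sd["all"][2])
        covered = np.mean(
            np.abs(np.array(estimates) - f[2]) <= np.array(sds)
        )
        assert 0.5 <= covered <= 0.95  # ~68% +- binomial noise at n=30
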