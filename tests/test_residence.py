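import numpy as np
import pandas as pd
import pytest

from conftest import MIX_D, MIX_F, T_LAPSE, draw_dwell_times
from smtkinetics.diffusion import brownian_cdf
from smtkinetics.residence import (
    DwellTimeModel,
    ResidenceTimeSet,
    extract_tau,
    fit_on_times,
    tau_from_displacements,
)

R0 = 0.2


def _track_from_displacements(r_seq, cell=0, track=0):
    """Build a straight-line track whose successive displacement
    lengths are r_seq."""
    x = np.concatenate([[0.0], np.cumsum(r_seq)])
    return pd.DataFrame(
        {
            "cell_id": cell,
            "track_id": track,
            "frame": np.arange(len(x)),
            "x_um": x,
            "y_um": 0.0,
        }
    )


class TestExtractTau:
    def test_interior_run(self):
        ts = extract_tau(
            _track_from_displacements([0.5, 0.1, 0.1, 0.1, 0.6]), R0, T_LAPSE
        )
        np.testing.assert_allclose(ts.tau, [3 * T_LAPSE])
        assert not ts.censored[0]

    def test_all_above_threshold(self):
        ts = extract_tau(_track_from_displacements([0.5, 0.5, 0.5]), R0, T_LAPSE)
        assert len(ts.tau) == 0

    def test_trailing_run_censored(self):
        ts = extract_tau(_track_from_displacements([0.5, 0.1, 0.1]), R0, T_LAPSE)
        np.testing.assert_allclose(ts.tau, [2 * T_LAPSE])
        assert ts.censored[0]

    def test_two_runs_in_one_track(self):
        ts = extract_tau(
            _track_from_displacements([0.1, 0.5, 0.1, 0.1, 0.5]), R0, T_LAPSE
        )
        np.testing.assert_allclose(sorted(ts.tau), [T_LAPSE, 2 * T_LAPSE])
        assert not ts.censored.any()

    def test_displacement_sequence_helper_agrees(self):
        r = np.array([0.5, 0.1, 0.1, 0.1, 0.6, 0.1])
        a = tau_from_displacements(r, R0, T_LAPSE)
        b = extract_tau(_track_from_displacements(r), R0, T_LAPSE)
        np.testing.assert_allclose(sorted(a.tau), sorted(b.tau))
        assert a.censored.sum() == b.censored.sum() == 1


class TestFitOnTimes:
    def test_geometric_lengths_recover_rate(self, rng):
        # mean 10 frames -> k_bleach ~ 1/(10 * 0.04) = 2.5 1/s
        lengths = rng.geometric(0.1, size=5000)
        k, sd = fit_on_times(lengths, T_LAPSE, seed=1)
        assert abs(k - 2.5) < 3 * max(sd, 0.01)

    def test_insufficient_tracks_rejected(self):
        with pytest.raises(ValueError):
            fit_on_times(np.array([7.0]), T_LAPSE)

    def test_degenerate_identical_lengths_rejected(self):
        with pytest.raises(ValueError):
            fit_on_times(np.full(200, 12.0), T_LAPSE)

    def test_scale_equivariance(self, rng):
        lengths = rng.geometric(0.2, size=1000)
        k1, _ = fit_on_times(lengths, T_LAPSE, seed=2)
        k2, _ = fit_on_times(2 * lengths, T_LAPSE, seed=2)
        assert k2 == pytest.approx(k1 / 2)


def _dwell_fixture(rng, k_minus1, k_bleach, n=4000, weights=None, sigma=0.02):
    """Dwell times drawn from the generative discrete mixture."""
    p = np.array([brownian_cdf(R0, D, T_LAPSE, sigma) for D in MIX_D])
    a = np.exp(-k_bleach * T_LAPSE)
    c = p.copy()
    c[2] *= np.exp(-k_minus1 * T_LAPSE)
    if weights is None:
        weights = MIX_F * p
        weights = weights / weights.sum()
    taus, cens = draw_dwell_times(rng, weights, a * c, a * (1 - c), n, T_LAPSE)
    return ResidenceTimeSet(taus, cens, R0, T_LAPSE)


def _pure_tb_fit(reference_diffusion_fit):
    """Diffusion fit matching a pure tight-binding population."""
    import copy

    f = copy.copy(reference_diffusion_fit)
    f.fractions = {"all": np.array([1e-9, 1e-9, 1.0])}
    return f


class TestDwellFit:
    def test_pure_tb_no_bleach(self, rng, reference_diffusion_fit):
        k_true = 5.0
        ts = _dwell_fixture(rng, k_true, 0.0, weights=np.array([0, 0, 1.0]))
        assert ts.tau[~ts.censored].mean() == pytest.approx(0.2, rel=0.1)
        fit = DwellTimeModel(ts, _pure_tb_fit(reference_diffusion_fit), 0.0).fit(
            n_boot=40, seed=1
        )
        assert abs(fit.k_minus1 - k_true) < 3 * fit.k_minus1_sd

    def test_bleach_correction(self, rng, reference_diffusion_fit):
        """With k_bleach = 2, the naive inverse-mean rate of pure-TB
        dwells sits near 7 while the corrected estimate returns ~5."""
        k_true, kb = 5.0, 2.0
        ts = _dwell_fixture(rng, k_true, kb, weights=np.array([0, 0, 1.0]))
        fit = DwellTimeModel(ts, _pure_tb_fit(reference_diffusion_fit), kb).fit(
            n_boot=40, seed=2
        )
        assert fit.naive_rate > k_true + kb - 1.5
        assert abs(fit.k_minus1 - k_true) < 3 * fit.k_minus1_sd
        assert fit.k_minus1 <= fit.naive_rate

    def test_three_state_mixture_recovery(self, rng, reference_diffusion_fit):
        k_true, kb = 5.0, 2.0
        ts = _dwell_fixture(rng, k_true, kb, n=6000)
        fit = DwellTimeModel(ts, reference_diffusion_fit, kb).fit(n_boot=40, seed=3)
        assert abs(fit.k_minus1 - k_true) < 3 * fit.k_minus1_sd

    def test_float_weight_mode(self, rng, reference_diffusion_fit):
        ts = _dwell_fixture(rng, 5.0, 2.0, n=6000)
        fit = DwellTimeModel(
            ts, reference_diffusion_fit, 2.0, tie_weights=False
        ).fit()
        assert 2.0 < fit.k_minus1 < 9.0

    def test_discrete_model_converges_to_continuous(self, rng, reference_diffusion_fit):
        """At a lapse much shorter than the dwell, the geometric
        likelihood recovers the continuous exponential rate."""
        k_true = 5.0
        t_small = 0.002
        dwells = rng.exponential(1 / k_true, size=8000)
        tau = np.maximum(np.round(dwells / t_small), 1) * t_small
        ref = _pure_tb_fit(reference_diffusion_fit)
        ref.t_lapse = t_small
        ts = ResidenceTimeSet(tau, np.zeros(len(tau), dtype=bool), R0, t_small)
        fit = DwellTimeModel(ts, ref, 0.0).fit()
        # oracle: discrete-geometric MLE has mean-of-tau form
        assert fit.k_minus1 == pytest.approx(k_true, rel=0.08)

    def test_threshold_robustness(self, rng, reference_diffusion_fit):
        """k_minus1 is stable for r0 in 0.15-0.25 um: the TB state is
        essentially fully captured across that range."""
        k_true, kb = 5.0, 1.0
        fits = []
        for r0 in (0.15, 0.2, 0.25):
            p = np.array([brownian_cdf(r0, D, T_LAPSE, 0.02) for D in MIX_D])
            a = np.exp(-kb * T_LAPSE)
            c = p.copy()
            c[2] *= np.exp(-k_true * T_LAPSE)
            w = MIX_F * p
            w = w / w.sum()
            taus, cens = draw_dwell_times(rng, w, a * c, a * (1 - c), 5000, T_LAPSE)
            ts = ResidenceTimeSet(taus, cens, r0, T_LAPSE)
            fits.append(DwellTimeModel(ts, reference_diffusion_fit, kb).fit())
        ks = [f.k_minus1 for f in fits]
        assert max(ks) - min(ks) < 0.15 * k_true
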