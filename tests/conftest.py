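import numpy as np
import pytest

from smtkinetics.diffusion import DiffusionStateFit

# three-state displacement mixture used throughout: resolved diffusion
# constants (um^2/s) and fractional populations at ~290 nM
MIX_D = np.array([6.7, 0.82, 0.033])
MIX_F = np.array([0.181, 0.472, 0.347])
T_LAPSE = 0.040


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mixture_displacements():
    """50k per-lapse displacement lengths drawn from the three-state
    Brownian mixture (no localization error)."""
    g = np.random.default_rng(7)
    comp = g.choice(3, size=50_000, p=MIX_F)
    return np.sqrt(g.exponential(4.0 * MIX_D[comp] * T_LAPSE))


@pytest.fixture
def reference_diffusion_fit():
    """A DiffusionStateFit holding the known mixture truth, for stages
    downstream of the mixture fit."""
    return DiffusionStateFit(
        D=MIX_D.copy(),
        fractions={"all": MIX_F.copy()},
        t_lapse=T_LAPSE,
        sigma_loc=0.020,
        loglike=0.0,
        n_obs=50_000,
        converged=True,
        n_iter=0,
    )


def draw_dwell_times(rng, weights, continuation, exit_prob, n, t_lapse):
    """Sample thresholded dwell runs from the discrete mixture model.

    Per run: pick a component by ``weights``; each frame continues with
    probability ``continuation[i]``, ends observed (uncensored) with
    ``exit_prob[i]`` and is otherwise censored (track terminated).
    Returns (tau, censored).
    """
    comp = rng.choice(len(weights), size=n, p=weights)
    taus = np.empty(n)
    cens = np.empty(n, dtype=bool)
    for i, ci in enumerate(comp):
        j = 1
        while True:
            u = rng.random()
            if u < continuation[ci]:
                j += 1
            else:
                taus[i] = j * t_lapse
                cens[i] = u >= continuation[ci] + exit_prob[ci]
                break
    return taus, cens
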