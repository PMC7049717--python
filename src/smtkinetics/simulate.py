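"""Synthetic single-molecule tracking data.

Simulates a tagged DNA-binding protein switching between three diffusion
states — freely diffusing (FD), nonspecifically bound and sliding on the
chromosome (NB), and tightly bound (TB) — inside a spherocylindrical
cell, observed under stroboscopic time-lapse imaging (short excitation
pulses separated by a longer lapse) with Gaussian localization error and
exponential photobleaching/blinking.

State switching is a continuous-time Markov chain over {FD, NB, TB};
binding steps are treated as pseudo-first-order so each molecule evolves
independently.  Motion is Brownian in 3D with the diffusion constant of
the current state and specular reflection at the membrane; the camera
records the (x, y) position at each frame midpoint plus isotropic noise.
Motion blur within the short excitation pulse is neglected (at the
relevant diffusion constants it is below the localization error).
Blinking is pooled with photobleaching into a single track-termination
rate, and tracks are never gap-closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import CellGeometry, reflect_into, sample_points

__all__ = [
    "KineticScheme",
    "ImagingModel",
    "STATE_NAMES",
    "simulate_tracks",
    "stationary_distribution",
]

#: index -> label for the hidden diffusion state
STATE_NAMES = ("FD", "NB", "TB")


@dataclass(frozen=True)
class KineticScheme:
    """Per-molecule three-state kinetic scheme.

    Diffusion constants in um^2/s with ``D_FD > D_NB > D_TB >= 0``.
    Rates in 1/s; binding rates are effective pseudo-first-order rates
    (site concentrations folded in).  ``k_minus1`` is the apparent
    unbinding rate constant from a tight-binding site, the quantity the
    residence-time analysis recovers; its concentration dependence can
    be injected by the caller via the biphasic rate law.

    Transitions: FD <-> TB (k1_on / k_minus1), FD <-> NB (k2_on /
    k_minus2), NB <-> TB (k3 / k_minus3, default off).
    """

    D_FD: float = 6.7
    D_NB: float = 0.82
    D_TB: float = 0.033
    k1_on: float = 0.0
    k_minus1: float = 0.0
    k2_on: float = 0.0
    k_minus2: float = 0.0
    k3: float = 0.0
    k_minus3: float = 0.0

    def __post_init__(self) -> None:
        rates = (self.k1_on, self.k_minus1, self.k2_on, self.k_minus2, self.k3, self.k_minus3)
        if any(k < 0 for k in rates):
            raise ValueError("all rate constants must be >= 0")
        if not (self.D_FD > self.D_NB > self.D_TB >= 0):
            raise ValueError("diffusion constants must satisfy D_FD > D_NB > D_TB >= 0")

    @property
    def diffusion_constants(self) -> np.ndarray:
        return np.array([self.D_FD, self.D_NB, self.D_TB])

    @property
    def generator(self) -> np.ndarray:
        """3x3 CTMC generator matrix Q (rows: from-state FD, NB, TB)."""
        q = np.array(
            [
                [0.0, self.k2_on, self.k1_on],
                [self.k_minus2, 0.0, self.k3],
                [self.k_minus1, self.k_minus3, 0.0],
            ]
        )
        np.fill_diagonal(q, -q.sum(axis=1))
        return q


@dataclass(frozen=True)
class ImagingModel:
    """Stroboscopic time-lapse observation model.

    t_lapse : frame-to-frame interval (s), default 40 ms.
    t_exposure : excitation pulse length (s), default 4 ms.
    sigma_loc : localization precision (um), default 20 nm.
    k_bleach : effective photobleach + blink track-termination rate
        (1/s of elapsed time); per-frame survival exp(-k_bleach*t_lapse).
    frames_per_cycle : frames per photoconversion/imaging cycle; caps
        observable track length.
    """

    t_lapse: float = 0.040
    t_exposure: float = 0.004
    sigma_loc: float = 0.020
    k_bleach: float = 2.0
    frames_per_cycle: int = 30

    def __post_init__(self) -> None:
        if not (0 < self.t_exposure <= self.t_lapse):
            raise ValueError("need 0 < t_exposure <= t_lapse")
        if self.sigma_loc < 0 or self.k_bleach < 0:
            raise ValueError("sigma_loc and k_bleach must be >= 0")
        if self.frames_per_cycle < 1:
            raise ValueError("frames_per_cycle must be >= 1")


def stationary_distribution(scheme: KineticScheme) -> np.ndarray:
    """Stationary distribution of the three-state chain.

    Null left-eigenvector of the generator, normalized to sum 1.  For a
    reducible chain (some rates zero) returns a valid stationary vector
    supported on the reachable closed classes.
    """
    q = scheme.generator
    # solve pi Q = 0, sum(pi) = 1 by least squares on the augmented system
    a = np.vstack([q.T, np.ones(3)])
    b = np.zeros(4)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _sample_track_lengths(
    rng: np.random.Generator, n: int, imaging: ImagingModel
) -> np.ndarray:
    """Number of observed frames per molecule: geometric bleaching capped
    at frames_per_cycle."""
    cap = imaging.frames_per_cycle
    p_bleach = -np.expm1(-imaging.k_bleach * imaging.t_lapse)
    if p_bleach <= 0:
        return np.full(n, cap, dtype=int)
    # geometric on {1, 2, ...}: frames observed before the bleach event
    lengths = rng.geometric(p_bleach, size=n)
    return np.minimum(lengths, cap)


def simulate_tracks(
    geom: CellGeometry,
    scheme: KineticScheme,
    imaging: ImagingModel,
    n_molecules: int,
    seed: int | np.random.Generator,
    cell_id: str | int = 0,
    dt: float = 0.001,
    initial_state: int | None = None,
    track_id_start: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ``n_molecules`` stroboscopically observed trajectories.

    Propagation uses a fixed integration step ``dt`` (default 1 ms): at
    each step the molecule may switch state (probability
    ``1 - exp(-q_i dt)``, destination by branching ratios — exact for at
    most one transition per step, a safe approximation for dt much
    smaller than all waiting times) and takes a Brownian step with the
    current state's D, reflected at the membrane.  Frames are recorded
    every ``t_lapse``.

    Returns
    -------
    tracks : DataFrame with columns cell_id, track_id, frame, x_um, y_um
    states : DataFrame with matching rows and a ``state`` column holding
        the hidden state label at each frame (simulation ground truth,
        for test oracles only).
    """
    if n_molecules < 0:
        raise ValueError("n_molecules must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    q = scheme.generator
    exit_rates = -np.diag(q)
    # per-step switch probability and destination distribution per state
    p_switch = -np.expm1(-exit_rates * dt)
    branch = np.zeros((3, 3))
    for i in range(3):
        if exit_rates[i] > 0:
            branch[i] = q[i] / exit_rates[i]
            branch[i, i] = 0.0
    branch_cdf = np.cumsum(branch, axis=1)

    n_frames = _sample_track_lengths(rng, n_molecules, imaging)
    steps_per_frame = max(int(round(imaging.t_lapse / dt)), 1)
    sigma_step = np.sqrt(2.0 * scheme.diffusion_constants * dt)

    pos = sample_points(geom, n_molecules, rng)
    if initial_state is None:
        pi = stationary_distribution(scheme)
        states = rng.choice(3, size=n_molecules, p=pi)
    else:
        states = np.full(n_molecules, int(initial_state))

    max_frames = int(n_frames.max()) if n_molecules else 0
    obs_x = np.full((n_molecules, max_frames), np.nan)
    obs_y = np.full((n_molecules, max_frames), np.nan)
    obs_state = np.full((n_molecules, max_frames), -1, dtype=int)

    alive = np.arange(n_molecules)
    for frame in range(max_frames):
        alive = np.flatnonzero(n_frames > frame)
        if alive.size == 0:
            break
        # record at frame midpoint (position at start of frame's exposure;
        # blur within the 4 ms pulse neglected)
        noise = rng.normal(0.0, imaging.sigma_loc, size=(alive.size, 2))
        obs_x[alive, frame] = pos[alive, 0] + noise[:, 0]
        obs_y[alive, frame] = pos[alive, 1] + noise[:, 1]
        obs_state[alive, frame] = states[alive]
        # propagate to the next frame
        for _ in range(steps_per_frame):
            u = rng.random(alive.size)
            switching = u < p_switch[states[alive]]
            if switching.any():
                sw = alive[switching]
                v = rng.random(sw.size)
                new = (v[:, None] < branch_cdf[states[sw]]).argmax(axis=1)
                states[sw] = new
            step = rng.normal(size=(alive.size, 3)) * sigma_step[states[alive]][:, None]
            pos[alive] = reflect_into(geom, pos[alive] + step)

    rows = []
    for m in range(n_molecules):
        nf = n_frames[m]
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": cell_id,
                    "track_id": track_id_start + m,
                    "frame": np.arange(nf),
                    "x_um": obs_x[m, :nf],
                    "y_um": obs_y[m, :nf],
                }
            )
        )
    if rows:
        tracks = pd.concat(rows, ignore_index=True)
        states_df = tracks[["cell_id", "track_id", "frame"]].copy()
        states_df["state"] = [
            STATE_NAMES[obs_state[m, f]]
            for m in range(n_molecules)
            for f in range(n_frames[m])
        ]
    else:
        tracks = pd.DataFrame(columns=["cell_id", "track_id", "frame", "x_um", "y_um"])
        states_df = pd.DataFrame(columns=["cell_id", "track_id", "frame", "state"])
    return tracks, states_df
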