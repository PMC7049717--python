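"""Residence-time (dwell-time) analysis with photobleaching correction.

A molecule tightly bound to the chromosome produces a run of
consecutive small per-lapse displacements.  Thresholding the r-vs-time
trajectory at ``r0`` (chosen so that essentially all tight-binding
displacements fall below it) converts each trajectory into a set of
residence times ``tau``.  Their distribution is a mixture:

* the tightly bound (TB) component survives each frame with probability
  ``exp(-(k_minus1 + k_bleach) * t_lapse) * p_TB``, where ``k_minus1``
  is the apparent unbinding rate constant — the free parameter — and
  ``p_TB`` the sub-threshold probability of a TB displacement;
* freely diffusing (FD) and nonspecifically bound (NB) molecules also
  produce short sub-threshold runs by chance; their per-frame
  continuation probabilities ``p_i`` follow from the fitted diffusion
  constants, attenuated by the same bleaching survival.

Component weights are tied to the diffusion-state fit (proportional to
``f_i * p_i``, the rate at which state i produces sub-threshold
displacements); a float mode lets them be refit.  Runs cut off by the
end of a track are censored and enter the likelihood through survival
terms — dropping them would bias the unbinding rate upward.  Times are
quantized to whole lapses, so the likelihood uses the discrete
(geometric) form rather than a binned exponential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .diffusion import DiffusionStateFit, brownian_cdf

__all__ = [
    "ResidenceTimeSet",
    "extract_tau",
    "fit_on_times",
    "DwellTimeModel",
    "DwellFit",
]


@dataclass
class ResidenceTimeSet:
    """Thresholded sub-``r0`` dwell times with censoring flags.

    ``tau`` in seconds (multiples of ``t_lapse``); ``censored[i]`` is
    True when run i was terminated by the end of its track rather than
    by an above-threshold displacement.  ``cell_ids`` enable cell-level
    bootstrap.
    """

    tau: np.ndarray
    censored: np.ndarray
    r0: float
    t_lapse: float
    group: str = "all"
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.r0 <= 0 or self.t_lapse <= 0:
            raise ValueError("r0 and t_lapse must be > 0")
        if self.tau.shape != self.censored.shape:
            raise ValueError("tau and censored must match in length")
        if len(self.tau) and self.tau.min() < self.t_lapse - 1e-12:
            raise ValueError("tau values must be >= t_lapse")

    @property
    def n_uncensored(self) -> int:
        return int((~self.censored).sum())


def _runs_below(r: np.ndarray, r0: float) -> list[tuple[int, bool]]:
    """Maximal runs of consecutive displacements with r < r0.

    Returns (run length, censored) pairs; a run reaching the last
    displacement of the track is censored (no above-threshold exit was
    observed).
    """
    below = np.asarray(r) < r0
    out: list[tuple[int, bool]] = []
    count = 0
    for i, b in enumerate(below):
        if b:
            count += 1
        elif count:
            out.append((count, False))
            count = 0
    if count:
        out.append((count, True))
    return out


def extract_tau(
    tracks: pd.DataFrame,
    r0: float,
    t_lapse: float,
    group: str = "all",
) -> ResidenceTimeSet:
    """Residence times from a track table.

    Each residence time starts when the per-lapse displacement length
    drops below ``r0`` and ends when it jumps back above, giving
    ``tau = (run length) * t_lapse``; a run still open at the track's
    last displacement is flagged censored.
    """
    if r0 <= 0:
        raise ValueError("r0 must be > 0")
    taus: list[float] = []
    cens: list[bool] = []
    cells: list = []
    if len(tracks):
        t = tracks.sort_values(["cell_id", "track_id", "frame"], kind="stable")
        for (cid, _tid), sub in t.groupby(["cell_id", "track_id"], sort=False):
            if len(sub) < 2:
                continue
            ok = np.diff(sub["frame"].values) == 1
            r = np.hypot(np.diff(sub["x_um"].values), np.diff(sub["y_um"].values))
            # a frame gap breaks the run like an above-threshold jump,
            # but censored (no exit observed)
            for seg in np.split(r, np.flatnonzero(~ok) + 1) if not ok.all() else [r]:
                for length, c in _runs_below(seg, r0):
                    taus.append(length * t_lapse)
                    cens.append(c)
                    cells.append(cid)
    return ResidenceTimeSet(
        np.asarray(taus), np.asarray(cens, dtype=bool), r0, t_lapse, group,
        np.asarray(cells) if cells else np.empty(0, dtype=object),
    )


def tau_from_displacements(
    r: np.ndarray, r0: float, t_lapse: float, group: str = "all"
) -> ResidenceTimeSet:
    """Residence times from a single displacement-length sequence."""
    runs = _runs_below(np.asarray(r, dtype=float), r0)
    taus = np.array([l * t_lapse for l, _ in runs])
    cens = np.array([c for _, c in runs], dtype=bool)
    return ResidenceTimeSet(taus, cens, r0, t_lapse, group)


def fit_on_times(
    track_lengths: np.ndarray,
    t_lapse: float,
    n_boot: int = 200,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Effective photobleach/blink rate from fluorescence on-times.

    On-time of a track = frames * t_lapse; the termination process is
    exponential on the elapsed-time axis, so the maximum-likelihood rate
    is 1/mean(on-time).  Returns ``(k_bleach, sd)`` with the s.d. from a
    track-level bootstrap.
    """
    lengths = np.asarray(track_lengths, dtype=float)
    if len(lengths) < 100:
        raise ValueError(f"need >= 100 tracks to estimate k_bleach, got {len(lengths)}")
    on = lengths * t_lapse
    if np.allclose(on, on[0]):
        raise ValueError("all tracks have the same length; on-time distribution degenerate")
    k = 1.0 / on.mean()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reps = [
        1.0 / on[rng.integers(0, len(on), size=len(on))].mean() for _ in range(n_boot)
    ]
    return float(k), float(np.std(reps, ddof=1))


@dataclass
class DwellFit:
    """Fitted apparent unbinding rate constant and diagnostics."""

    k_minus1: float
    k_minus1_sd: float | None
    k_bleach: float
    weights: np.ndarray  # FD/NB/TB mixture weights used
    loglike: float
    n_tau: int
    n_uncensored: int
    non_identifiable: bool
    naive_rate: float  # inverse mean tau, uncorrected

    def summary(self) -> str:
        sd = f" +- {self.k_minus1_sd:.3g}" if self.k_minus1_sd is not None else ""
        lines = [
            "Residence-time fit (three-state + photobleaching model)",
            f"  k_minus1 = {self.k_minus1:.4g}{sd} 1/s  (naive 1/<tau> = {self.naive_rate:.4g})",
            f"  k_bleach (fixed) = {self.k_bleach:.4g} 1/s",
            f"  component weights FD/NB/TB = "
            + "/".join(f"{w:.3f}" for w in self.weights),
            f"  n_tau = {self.n_tau} ({self.n_uncensored} uncensored), logL = {self.loglike:.1f}",
        ]
        if self.non_identifiable:
            lines.append("  warning: estimate pinned at a bound; not identifiable")
        return "\n".join(lines)


class DwellTimeModel:
    """Three-state + photobleaching model for residence times.

    Parameters
    ----------
    taus : ResidenceTimeSet
        Thresholded dwell times with censoring flags.
    diffusion_fit : DiffusionStateFit
        Global mixture fit supplying D_FD/D_NB/D_TB, the per-group
        fractions and sigma_loc; component weights and the FD/NB
        continuation probabilities are derived from it.
    k_bleach : float
        Photobleach/blink termination rate (1/s elapsed time), measured
        from on-times; held fixed.
    tie_weights : bool
        If True (default), mixture weights are tied to ``f_i * p_i``
        from the diffusion fit; if False they are refit from the dwell
        data (more parameters, used as a robustness check).

    ``fit()`` returns a :class:`DwellFit`; a cell-level bootstrap
    supplies the standard deviation.
    """

    K_MAX_FACTOR = 10.0  # upper bound for k_minus1, in units of 1/t_lapse

    def __init__(
        self,
        taus: ResidenceTimeSet,
        diffusion_fit: DiffusionStateFit,
        k_bleach: float,
        tie_weights: bool = True,
    ):
        if diffusion_fit.n_states != 3:
            raise ValueError("dwell model expects a three-state diffusion fit")
        if k_bleach < 0:
            raise ValueError("k_bleach must be >= 0")
        if taus.n_uncensored < 100:
            import warnings

            warnings.warn(
                f"only {taus.n_uncensored} uncensored dwell times; "
                "k_minus1 will be poorly constrained",
                stacklevel=2,
            )
        self.taus = taus
        self.diffusion_fit = diffusion_fit
        self.k_bleach = float(k_bleach)
        self.tie_weights = tie_weights
        f = diffusion_fit.fractions.get(
            taus.group, next(iter(diffusion_fit.fractions.values()))
        )
        self.f_states = np.asarray(f, dtype=float)
        # sub-threshold probability per state from the resolved D's
        self.p_below = np.array(
            [
                brownian_cdf(taus.r0, D, taus.t_lapse, diffusion_fit.sigma_loc)
                for D in diffusion_fit.D
            ]
        )

    # -- likelihood ------------------------------------------------------

    def _log_likelihood(self, k_minus1: float, weights: np.ndarray) -> float:
        t = self.taus.t_lapse
        j = np.round(self.taus.tau / t).astype(int)  # run length in frames
        cens = self.taus.censored
        a = np.exp(-self.k_bleach * t)  # per-frame bleach survival
        # per-frame sub-threshold continuation for FD/NB/TB; TB also
        # requires staying bound
        c = self.p_below.copy()
        c[2] *= np.exp(-k_minus1 * t)
        q = np.clip(a * c, 1e-300, 1 - 1e-12)
        # run of j displacements: j-1 observed continuations (survive
        # bleach AND stay sub-threshold, prob a*c each), then either an
        # observed above-threshold exit (uncensored, prob a*(1-c)) or
        # track termination (censored; its probability does not depend
        # on the kinetics, so it enters as a pure survival term)
        log_q = np.log(q)
        log_exit = np.log(np.clip(a * (1 - c), 1e-300, None))
        ll_comp = (j[:, None] - 1) * log_q[None, :]
        ll_comp = ll_comp + np.where(cens[:, None], 0.0, log_exit[None, :])
        log_w = np.log(np.maximum(weights, 1e-300))
        m = (ll_comp + log_w[None, :]).max(axis=1, keepdims=True)
        return float(
            (m[:, 0] + np.log(np.exp(ll_comp + log_w[None, :] - m).sum(axis=1))).sum()
        )

    def _tied_weights(self, k_minus1: float) -> np.ndarray:
        # entry rate into a sub-threshold run ~ occupancy x chance the
        # state's displacement falls below threshold
        w = self.f_states * self.p_below
        return w / w.sum()

    def fit(self, n_boot: int = 0, seed: int | np.random.Generator = 0) -> DwellFit:
        t = self.taus.t_lapse
        k_hi = self.K_MAX_FACTOR / t
        uncens = self.taus.tau[~self.taus.censored]
        naive = 1.0 / uncens.mean() if len(uncens) else np.nan

        if self.tie_weights:
            def nll(k):
                return -self._log_likelihood(k, self._tied_weights(k))

            res = optimize.minimize_scalar(nll, bounds=(1e-6, k_hi), method="bounded")
            k_hat = float(res.x)
            weights = self._tied_weights(k_hat)
            ll = -float(res.fun)
        else:
            def nll_vec(theta):
                k = np.exp(theta[0])
                e = np.concatenate([np.exp(theta[1:]), [1.0]])
                return -self._log_likelihood(k, e / e.sum())

            x0 = np.array([np.log(max(naive, 1e-3)), 0.0, 0.0])
            res = optimize.minimize(nll_vec, x0, method="Nelder-Mead")
            k_hat = float(np.exp(res.x[0]))
            e = np.concatenate([np.exp(res.x[1:]), [1.0]])
            weights = e / e.sum()
            ll = -float(res.fun)

        pinned = k_hat < 1e-4 or k_hat > 0.99 * k_hi
        sd = None
        if n_boot:
            rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
            sd = self._bootstrap_sd(n_boot, rng)
        return DwellFit(
            k_minus1=k_hat,
            k_minus1_sd=sd,
            k_bleach=self.k_bleach,
            weights=weights,
            loglike=ll,
            n_tau=len(self.taus.tau),
            n_uncensored=self.taus.n_uncensored,
            non_identifiable=pinned,
            naive_rate=float(naive),
        )

    def _bootstrap_sd(self, n_boot: int, rng: np.random.Generator) -> float:
        ts = self.taus
        reps = []
        cells = (
            np.unique(ts.cell_ids)
            if ts.cell_ids is not None and len(ts.cell_ids) == len(ts.tau)
            else None
        )
        use_cells = cells is not None and len(cells) >= 2
        import warnings

        for _ in range(n_boot):
            if use_cells:
                pick = rng.choice(cells, size=len(cells), replace=True)
                idx = np.concatenate([np.flatnonzero(ts.cell_ids == c) for c in pick])
            else:
                idx = rng.integers(0, len(ts.tau), size=len(ts.tau))
            rep_set = ResidenceTimeSet(
                ts.tau[idx], ts.censored[idx], ts.r0, ts.t_lapse, ts.group,
                None if ts.cell_ids is None or not use_cells else ts.cell_ids[idx],
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = DwellTimeModel(
                    rep_set, self.diffusion_fit, self.k_bleach, self.tie_weights
                ).fit()
            reps.append(rep.k_minus1)
        return float(np.std(reps, ddof=1))
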