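"""Diffusion-state deconvolution from displacement statistics.

Under stroboscopic time-lapse imaging, the per-lapse displacement length
``r`` of a molecule in a single Brownian state with diffusion constant
``D`` follows a 2D Rayleigh law; equivalently ``r^2`` is exponential
with mean ``4 D t_lapse + 4 sigma_loc^2`` (static localization error
broadens the apparent variance).  A molecule population occupying
several states yields a mixture of such exponentials, and fitting the
mixture — with the diffusion constants shared globally across cell
groups of different protein concentration but the fractional
populations free per group — resolves the freely-diffusing (FD),
nonspecifically bound (NB) and tightly bound (TB) states and their
occupancies.

The maximum-likelihood fit is solved by expectation-maximization on the
exponential mixture (monotone in likelihood, no constraints needed); an
empirical-CDF least-squares mode is provided as a cross-check.
Uncertainties come from a cell-level bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "DisplacementSet",
    "displacements",
    "brownian_cdf",
    "DisplacementMixtureModel",
    "DiffusionStateFit",
    "bootstrap_sd",
]


@dataclass
class DisplacementSet:
    """Per-lapse displacement lengths for one concentration group.

    ``r`` in um; ``cell_ids`` (same length) enable cell-level
    resampling; ``group`` is the concentration-bin label.
    """

    r: np.ndarray
    t_lapse: float
    group: str = "all"
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if (self.r < 0).any():
            raise ValueError("displacement lengths must be >= 0")
        if self.t_lapse <= 0:
            raise ValueError("t_lapse must be > 0")
        if self.cell_ids is not None:
            self.cell_ids = np.asarray(self.cell_ids)
            if self.cell_ids.shape != self.r.shape:
                raise ValueError("cell_ids must match r in length")


def displacements(tracks: pd.DataFrame, t_lapse: float, group: str = "all") -> DisplacementSet:
    """Per-lapse displacement lengths from a track table.

    One ``r`` per adjacent-frame localization pair within a track; pairs
    spanning a frame gap or a track boundary are excluded.  Expects
    columns cell_id, track_id, frame, x_um, y_um.
    """
    if len(tracks) == 0:
        return DisplacementSet(np.empty(0), t_lapse, group, np.empty(0, dtype=object))
    t = tracks.sort_values(["cell_id", "track_id", "frame"], kind="stable")
    same = (
        (t["cell_id"].values[1:] == t["cell_id"].values[:-1])
        & (t["track_id"].values[1:] == t["track_id"].values[:-1])
        & (np.diff(t["frame"].values) == 1)
    )
    dx = np.diff(t["x_um"].values)[same]
    dy = np.diff(t["y_um"].values)[same]
    return DisplacementSet(
        np.hypot(dx, dy), t_lapse, group, t["cell_id"].values[1:][same]
    )


def brownian_cdf(r0: float, D: float, t_lapse: float, sigma_loc: float = 0.0):
    """CDF of the 2D Brownian per-lapse displacement length at ``r0``.

    ``P(r <= r0) = 1 - exp(-r0^2 / (4 D t_lapse + 4 sigma_loc^2))``,
    the Rayleigh CDF with the apparent variance inflated by the static
    localization error.  Returns 1.0 for r0 > 0 when both D and
    sigma_loc are zero (all displacements are exactly zero).
    """
    r0 = np.asarray(r0, dtype=float)
    if np.any(r0 < 0) or D < 0:
        raise ValueError("r0 and D must be >= 0")
    scale = 4.0 * D * t_lapse + 4.0 * sigma_loc**2
    if scale == 0:
        return np.where(r0 > 0, 1.0, 0.0)[()] if r0.ndim == 0 else np.where(r0 > 0, 1.0, 0.0)
    return -np.expm1(-(r0**2) / scale)


@dataclass
class DiffusionStateFit:
    """Result of the global displacement-mixture fit.

    Diffusion constants are sorted descending (FD, NB, TB, ...); they
    are shared across groups while fractions are per group.  Standard
    deviations are filled in by :func:`bootstrap_sd` (None until then).
    """

    D: np.ndarray  # (n_states,) um^2/s, descending
    fractions: dict[str, np.ndarray]  # group -> (n_states,)
    t_lapse: float
    sigma_loc: float
    loglike: float
    n_obs: int
    converged: bool
    n_iter: int
    D_sd: np.ndarray | None = None
    fractions_sd: dict[str, np.ndarray] | None = None
    duplicate_components: bool = field(default=False)

    @property
    def n_states(self) -> int:
        return len(self.D)

    def summary(self) -> str:
        lines = [
            "Displacement mixture fit "
            f"({self.n_states} states, {self.n_obs} displacements, "
            f"logL = {self.loglike:.1f}, "
            f"{'converged' if self.converged else 'NOT converged'})",
            f"{'state':>6} {'D (um^2/s)':>12} {'sd':>9}",
        ]
        labels = _state_labels(self.n_states)
        for i, lab in enumerate(labels):
            sd = f"{self.D_sd[i]:.3g}" if self.D_sd is not None else "-"
            lines.append(f"{lab:>6} {self.D[i]:>12.4g} {sd:>9}")
        lines.append("fractions per group:")
        for g, f in self.fractions.items():
            fs = ", ".join(
                f"{lab}={fi:.3f}" + (
                    f"+-{self.fractions_sd[g][i]:.3f}" if self.fractions_sd else ""
                )
                for i, (lab, fi) in enumerate(zip(labels, f))
            )
            lines.append(f"  {g}: {fs}")
        if self.duplicate_components:
            lines.append("warning: near-duplicate diffusion components detected")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "D": self.D.tolist(),
            "D_sd": None if self.D_sd is None else self.D_sd.tolist(),
            "fractions": {g: f.tolist() for g, f in self.fractions.items()},
            "fractions_sd": None
            if self.fractions_sd is None
            else {g: f.tolist() for g, f in self.fractions_sd.items()},
            "t_lapse": self.t_lapse,
            "sigma_loc": self.sigma_loc,
            "loglike": self.loglike,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }

    def plot_cdf(self, displacement_set: "DisplacementSet", ax=None):
        """Empirical CDF of r with the fitted mixture CDF overlaid.

        Requires matplotlib; uses the fractions of the set's group.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        r = np.sort(displacement_set.r)
        ax.step(r, np.arange(1, len(r) + 1) / len(r), where="post", label="empirical")
        f = self.fractions[displacement_set.group]
        grid = np.linspace(0, r[-1], 400)
        model = sum(
            fi * brownian_cdf(grid, Di, self.t_lapse, self.sigma_loc)
            for fi, Di in zip(f, self.D)
        )
        ax.plot(grid, model, label="mixture fit")
        for lab, fi, Di in zip(_state_labels(self.n_states), f, self.D):
            ax.plot(
                grid,
                fi * brownian_cdf(grid, Di, self.t_lapse, self.sigma_loc),
                ls="--", lw=0.8, label=f"{lab} (D={Di:.3g})",
            )
        ax.set_xlabel("displacement length r (um)")
        ax.set_ylabel("CDF")
        ax.legend()
        return ax


def _state_labels(n: int) -> list[str]:
    if n == 3:
        return ["FD", "NB", "TB"]
    return [f"S{i}" for i in range(n)]


class DisplacementMixtureModel:
    """Global exponential-mixture model for squared displacements.

    Parameters
    ----------
    groups : sequence of DisplacementSet
        One per concentration group; all must share ``t_lapse``.
    n_states : int
        Number of Brownian states to resolve (default 3).
    sigma_loc : float
        Localization precision (um), fixed — it is measured upstream,
        and floating it trades off against the slowest D.

    ``fit()`` returns a :class:`DiffusionStateFit`.
    """

    def __init__(
        self,
        groups: list[DisplacementSet] | DisplacementSet,
        n_states: int = 3,
        sigma_loc: float = 0.020,
    ):
        if isinstance(groups, DisplacementSet):
            groups = [groups]
        if n_states < 1:
            raise ValueError("n_states must be >= 1")
        if not groups:
            raise ValueError("need at least one displacement set")
        t0 = groups[0].t_lapse
        if any(abs(g.t_lapse - t0) > 1e-12 for g in groups):
            raise ValueError("all groups must share t_lapse")
        for g in groups:
            if len(g.r) < 500:
                warnings.warn(
                    f"group {g.group!r} has only {len(g.r)} displacements; "
                    "the mixture fit may be unreliable",
                    stacklevel=2,
                )
        self.groups = list(groups)
        self.n_states = n_states
        self.sigma_loc = float(sigma_loc)
        self.t_lapse = t0

    @classmethod
    def from_tracks(
        cls,
        tracks: pd.DataFrame,
        t_lapse: float,
        group_col: str | None = None,
        **kwargs,
    ) -> "DisplacementMixtureModel":
        """Build directly from a track table, optionally split by a
        group column (e.g. a concentration bin)."""
        if group_col is None:
            return cls(displacements(tracks, t_lapse), **kwargs)
        sets = [
            displacements(sub, t_lapse, group=str(g))
            for g, sub in tracks.groupby(group_col, sort=True)
        ]
        return cls(sets, **kwargs)

    # -- EM fit ----------------------------------------------------------

    def _init_means(self, rng: np.random.Generator | None = None) -> np.ndarray:
        """Spread initial component means over log-quantiles of r^2."""
        r2 = np.concatenate([g.r**2 for g in self.groups])
        r2 = r2[r2 > 0]
        if r2.size == 0:
            return np.geomspace(1e-6, 1e-3, self.n_states)
        qs = np.linspace(0.15, 0.9, self.n_states)
        means = np.quantile(r2, qs)
        return np.maximum.accumulate(np.maximum(means, 1e-12))

    def fit(
        self,
        max_iter: int = 2000,
        tol: float = 1e-10,
        means_init: np.ndarray | None = None,
    ) -> DiffusionStateFit:
        """Maximum-likelihood fit by EM on r^2.

        Component scales (hence D's) are shared across groups; mixture
        weights are free per group.  Convergence on relative change of
        the total log-likelihood.
        """
        k = self.n_states
        r2s = [g.r**2 for g in self.groups]
        n_total = sum(len(r2) for r2 in r2s)
        if n_total == 0:
            raise ValueError("no displacements to fit")
        means = np.sort(np.asarray(means_init, dtype=float)) if means_init is not None else self._init_means()
        weights = [np.full(k, 1.0 / k) for _ in r2s]

        floor = 4.0 * self.sigma_loc**2 + 1e-12  # a state cannot be narrower than pure noise
        means = np.maximum(means, floor)
        old_ll = -np.inf
        converged = False
        for it in range(1, max_iter + 1):
            num = np.zeros(k)
            den = np.zeros(k)
            ll = 0.0
            new_weights = []
            for r2, w in zip(r2s, weights):
                # E-step: responsibilities under exponential densities
                log_dens = -np.log(means)[None, :] - r2[:, None] / means[None, :]
                log_w = np.log(np.maximum(w, 1e-300))
                logp = log_dens + log_w[None, :]
                m = logp.max(axis=1, keepdims=True)
                p = np.exp(logp - m)
                s = p.sum(axis=1, keepdims=True)
                resp = p / s
                ll += float((np.log(s[:, 0]) + m[:, 0]).sum())
                # M-step accumulators (scales pooled across groups)
                num += resp.T @ r2
                den += resp.sum(axis=0)
                new_weights.append(resp.mean(axis=0))
            weights = new_weights
            means = np.maximum(num / np.maximum(den, 1e-300), floor)
            if np.isfinite(old_ll) and abs(ll - old_ll) <= tol * (abs(old_ll) + 1.0):
                converged = True
                break
            old_ll = ll

        # sort states by D descending: FD, NB, TB
        order = np.argsort(means)[::-1]
        means = means[order]
        weights = [w[order] for w in weights]
        D = (means - 4.0 * self.sigma_loc**2) / (4.0 * self.t_lapse)
        D = np.maximum(D, 0.0)
        dup = bool(
            np.any(np.abs(np.diff(means)) < 0.05 * means[:-1])
        )
        fractions = {
            g.group: w / w.sum() for g, w in zip(self.groups, weights)
        }
        return DiffusionStateFit(
            D=D,
            fractions=fractions,
            t_lapse=self.t_lapse,
            sigma_loc=self.sigma_loc,
            loglike=ll,
            n_obs=n_total,
            converged=converged,
            n_iter=it,
            duplicate_components=dup,
        )

    # -- empirical-CDF least squares cross-check -------------------------

    def fit_cdf(self, n_grid: int = 200) -> DiffusionStateFit:
        """Least-squares fit of the model CDF to the empirical CDF of r.

        Cross-check mode for the likelihood fit: minimizes the summed
        squared CDF residuals over a quantile grid, single group only
        stacked across groups with shared D.
        """
        k = self.n_states
        t = self.t_lapse

        def unpack(theta):
            D = np.exp(theta[:k])
            fr = []
            for gi in range(len(self.groups)):
                a = theta[k + gi * (k - 1) : k + (gi + 1) * (k - 1)]
                e = np.concatenate([np.exp(a), [1.0]])
                fr.append(e / e.sum())
            return D, fr

        grids, ecdfs = [], []
        for g in self.groups:
            r = np.sort(g.r)
            qs = np.linspace(0.005, 0.995, n_grid)
            grid = np.quantile(r, qs)
            ecdf = np.searchsorted(r, grid, side="right") / len(r)
            grids.append(grid)
            ecdfs.append(ecdf)

        def resid(theta):
            D, fr = unpack(theta)
            out = []
            for grid, ecdf, f in zip(grids, ecdfs, fr):
                model = sum(
                    fi * brownian_cdf(grid, Di, t, self.sigma_loc)
                    for fi, Di in zip(f, D)
                )
                out.append(model - ecdf)
            return np.concatenate(out)

        em = self.fit()
        d0 = np.log(np.maximum(em.D, 1e-6))
        f0 = []
        for g in self.groups:
            f = em.fractions[g.group]
            f0.extend(np.log(np.maximum(f[:-1], 1e-6) / max(f[-1], 1e-6)))
        theta0 = np.concatenate([d0, f0])
        sol = optimize.least_squares(resid, theta0, method="lm", max_nfev=20000)
        D, fr = unpack(sol.x)
        order = np.argsort(D)[::-1]
        return DiffusionStateFit(
            D=D[order],
            fractions={g.group: f[order] for g, f in zip(self.groups, fr)},
            t_lapse=t,
            sigma_loc=self.sigma_loc,
            loglike=float(-0.5 * sol.cost),
            n_obs=em.n_obs,
            converged=bool(sol.success),
            n_iter=int(sol.nfev),
        )


def bootstrap_sd(
    model: DisplacementMixtureModel,
    n_boot: int,
    seed: int | np.random.Generator,
    fit: DiffusionStateFit | None = None,
) -> DiffusionStateFit:
    """Cell-level bootstrap standard deviations for a mixture fit.

    Cells are resampled with replacement within each group (falling back
    to displacement-level resampling when no cell ids are attached);
    the fit is repeated on each replicate, warm-started at the point
    estimate, and per-parameter standard deviations across replicates
    are attached to (a copy of) the fit.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if n_boot < 50:
        warnings.warn(f"n_boot={n_boot} is small; s.d. estimates will be noisy", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if fit is None:
        fit = model.fit()
    means0 = 4.0 * fit.D * model.t_lapse + 4.0 * model.sigma_loc**2

    D_reps = []
    f_reps: dict[str, list[np.ndarray]] = {g.group: [] for g in model.groups}
    for _ in range(n_boot):
        sets = []
        for g in model.groups:
            if g.cell_ids is not None and len(np.unique(g.cell_ids)) >= 2:
                cells = np.unique(g.cell_ids)
                pick = rng.choice(cells, size=len(cells), replace=True)
                idx = np.concatenate([np.flatnonzero(g.cell_ids == c) for c in pick])
            else:
                idx = rng.integers(0, len(g.r), size=len(g.r))
            sets.append(
                DisplacementSet(
                    g.r[idx], g.t_lapse, g.group,
                    None if g.cell_ids is None else g.cell_ids[idx],
                )
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep_model = DisplacementMixtureModel(sets, model.n_states, model.sigma_loc)
            rep = rep_model.fit(means_init=means0)
        D_reps.append(rep.D)
        for g in model.groups:
            f_reps[g.group].append(rep.fractions[g.group])

    fit.D_sd = np.std(np.array(D_reps), axis=0, ddof=1)
    fit.fractions_sd = {
        g: np.std(np.array(v), axis=0, ddof=1) for g, v in f_reps.items()
    }
    return fit
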