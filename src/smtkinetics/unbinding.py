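"""Biphasic (impeded-then-facilitated) unbinding rate law.

A DNA-bound protein dimer inside an oligomer of ``n`` dimers unbinds
with microscopic rate constant

    k(n) = k_o + k_r * alpha**n + k_f * [P]_FD

where ``k_o`` is the intrinsic unbinding rate constant, the
``k_r * alpha**n`` term captures impeded unbinding from oligomer
stabilization (0 < alpha < 1, n up to the oligomerization number n_o)
and ``k_f * [P]_FD`` captures facilitated unbinding via a ternary
protein2-DNA intermediate (assisted dissociation / direct substitution),
linear in the free diffusing-dimer concentration.

Averaging over the oligomer occupancy in the weak-oligomerization,
low-concentration limit gives the apparent unbinding rate constant

    k_app([P]) = k_o_off + k_r * (exp(-[P]_FD / K_m) - 1) + k_f * [P]_FD

with ``k_o_off = k_o + k_r`` (the spontaneous rate at zero free-protein
concentration) and ``K_m = k_o_off / (k_1 (1 - alpha))`` the effective
dissociation constant of the oligomer on the chromosome.  When
``k_r > k_f * K_m`` the curve first decreases, reaches a minimum at
``P_min = K_m * ln(k_r / (k_f K_m))``, and then increases — the
biphasic signature; otherwise it is monotone increasing
(facilitated-only behavior).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "BiphasicParams",
    "rate_eq_occupancy",
    "rate_apparent",
    "km_relation",
    "alpha_from_km",
    "rate_minimum",
    "BiphasicUnbindingModel",
    "BiphasicFit",
]


@dataclass
class BiphasicParams:
    """Parameters of the biphasic unbinding rate law.

    Rates in 1/s, ``k_f`` in 1/(nM s), concentrations in nM of free
    dimers.  ``k_o_off = k_o + k_r`` is enforced; construct either from
    (k_o, k_r) or from (k_o_off, k_r).
    """

    k_r: float
    k_f: float
    K_m: float
    k_o: float | None = None
    k_o_off: float | None = None
    alpha: float | None = None
    n_o: int = 5

    def __post_init__(self) -> None:
        if self.k_o is None and self.k_o_off is None:
            raise ValueError("provide k_o or k_o_off")
        if self.k_o is None:
            self.k_o = self.k_o_off - self.k_r
        if self.k_o_off is None:
            self.k_o_off = self.k_o + self.k_r
        if abs(self.k_o_off - (self.k_o + self.k_r)) > 1e-9 * max(1.0, self.k_o_off):
            raise ValueError("inconsistent parameters: k_o_off must equal k_o + k_r")
        if self.k_r < 0 or self.k_f < 0 or self.k_o < -1e-12:
            raise ValueError("rate constants must be >= 0")
        if self.K_m <= 0:
            raise ValueError("K_m must be > 0")
        if self.alpha is not None and not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_o < 1:
            raise ValueError("n_o must be >= 1")


def rate_eq_occupancy(params: BiphasicParams, n: int, P_FD: float) -> float:
    """Microscopic unbinding rate constant at oligomer occupancy ``n``.

    ``k(n) = k_o + k_r alpha**n + k_f [P]_FD``; requires ``alpha`` set
    and ``0 <= n <= n_o``.
    """
    if params.alpha is None:
        raise ValueError("occupancy-resolved rate requires alpha")
    if not (0 <= n <= params.n_o):
        raise ValueError(f"occupancy n={n} outside [0, n_o={params.n_o}]")
    return params.k_o + params.k_r * params.alpha**n + params.k_f * P_FD


def rate_apparent(params: BiphasicParams, P_FD):
    """Apparent (occupancy-averaged) unbinding rate constant.

    ``k_app = k_o_off + k_r (exp(-P_FD/K_m) - 1) + k_f P_FD`` for free
    dimer concentration(s) ``P_FD`` in nM.
    """
    p = np.asarray(P_FD, dtype=float)
    out = params.k_o_off + params.k_r * np.expm1(-p / params.K_m) + params.k_f * p
    return float(out) if out.ndim == 0 else out


def km_relation(k_o_off: float, k_1: float, alpha: float) -> float:
    """Oligomer dissociation constant from the rate constants:
    ``K_m = k_o_off / (k_1 (1 - alpha))`` (nM)."""
    if k_1 <= 0:
        raise ValueError("k_1 must be > 0")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    return k_o_off / (k_1 * (1.0 - alpha))


def alpha_from_km(k_o_off: float, k_1: float, K_m: float) -> tuple[float, bool]:
    """Invert the K_m relation: ``alpha = 1 - k_o_off / (k_1 K_m)``.

    Returns ``(alpha, feasible)``.  With rounded literature values the
    implied alpha can fall outside (0, 1); the flag marks that
    internal-consistency tension — the value is reported as a
    diagnostic, never silently clipped.
    """
    if k_1 <= 0 or K_m <= 0:
        raise ValueError("k_1 and K_m must be > 0")
    alpha = 1.0 - k_o_off / (k_1 * K_m)
    return alpha, bool(0 < alpha < 1)


def rate_minimum(params: BiphasicParams) -> float | None:
    """Free concentration (nM) minimizing the apparent rate, if any.

    Setting the derivative of the apparent rate law to zero gives
    ``P_min = K_m ln(k_r / (k_f K_m))`` when ``k_r > k_f K_m``; when
    ``k_r <= k_f K_m`` the curve is monotone increasing and there is no
    interior minimum (returns None; the boundary case k_r = k_f K_m
    gives P_min = 0).
    """
    if params.k_f <= 0:
        return None if params.k_r == 0 else np.inf
    ratio = params.k_r / (params.k_f * params.K_m)
    if ratio < 1:
        return None
    return params.K_m * np.log(ratio)


@dataclass
class BiphasicFit:
    """Weighted nonlinear least-squares fit of the apparent rate law."""

    params: BiphasicParams
    sd: dict[str, float]
    chi2: float
    aic: float
    aic_linear: float
    linear_params: tuple[float, float]  # (k_o_off, k_f) of the k_r=0 fit
    prefers_biphasic: bool
    km_pinned: bool
    P_min: float | None
    n_points: int

    def summary(self) -> str:
        p = self.params
        lines = [
            "Biphasic unbinding fit (apparent rate law, weighted NLS)",
            f"  k_o_off = {p.k_o_off:.4g} +- {self.sd.get('k_o_off', float('nan')):.3g} 1/s",
            f"  k_r     = {p.k_r:.4g} +- {self.sd.get('k_r', float('nan')):.3g} 1/s",
            f"  k_f     = {p.k_f:.4g} +- {self.sd.get('k_f', float('nan')):.3g} 1/(nM s)",
            f"  K_m     = {p.K_m:.4g} +- {self.sd.get('K_m', float('nan')):.3g} nM",
            f"  chi2 = {self.chi2:.3g} (n = {self.n_points}), "
            f"AIC = {self.aic:.1f} vs linear {self.aic_linear:.1f} "
            f"-> {'biphasic' if self.prefers_biphasic else 'linear (facilitated-only)'}",
        ]
        if self.P_min is not None and np.isfinite(self.P_min):
            lines.append(f"  rate minimum at P_FD = {self.P_min:.4g} nM")
        else:
            lines.append("  monotone increasing (no interior rate minimum)")
        if self.km_pinned:
            lines.append("  warning: K_m pinned at a bound; poorly identified")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        p = self.params
        return {
            "k_o_off": p.k_o_off,
            "k_r": p.k_r,
            "k_f": p.k_f,
            "K_m": p.K_m,
            "sd": dict(self.sd),
            "chi2": self.chi2,
            "aic": self.aic,
            "aic_linear": self.aic_linear,
            "prefers_biphasic": self.prefers_biphasic,
            "P_min": None if self.P_min is None else float(self.P_min),
            "n_points": self.n_points,
        }

    def plot(self, P=None, k=None, sd=None, ax=None):
        """Fitted apparent rate law, optionally with the data points.

        Log concentration axis, as the curve spans decades.  Requires
        matplotlib.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if P is not None:
            ax.errorbar(P, k, yerr=sd, fmt="o", capsize=3, label="data")
            grid = np.geomspace(min(P) / 3, max(P) * 2, 200)
        else:
            grid = np.geomspace(self.params.K_m / 10, self.params.K_m * 100, 200)
        ax.plot(grid, rate_apparent(self.params, grid), label="biphasic fit")
        if self.P_min is not None and np.isfinite(self.P_min) and self.P_min > 0:
            ax.axvline(self.P_min, ls="--", lw=0.8, color="gray")
        ax.set_xscale("log")
        ax.set_xlabel("free dimer concentration $[P]_{FD}$ (nM)")
        ax.set_ylabel("apparent unbinding rate $k_{-1}$ (1/s)")
        ax.legend()
        return ax


class BiphasicUnbindingModel:
    """Fit the apparent unbinding rate law to (P_FD, k_minus1, sd) data.

    Parameters
    ----------
    P_FD : array
        Free diffusing-dimer concentrations (nM).
    k : array
        Apparent unbinding rate constants (1/s) per concentration group.
    sd : array, optional
        Standard deviations of ``k``; weights are 1/sd^2.  If omitted,
        unit weights.
    n_o : int
        Oligomerization number carried through to the parameter set
        (default 5; it does not enter the apparent law directly).
    """

    K_M_BOUNDS = (1e-3, 1e5)

    def __init__(self, P_FD, k, sd=None, n_o: int = 5):
        self.P = np.asarray(P_FD, dtype=float)
        self.k = np.asarray(k, dtype=float)
        if self.P.shape != self.k.shape or self.P.ndim != 1:
            raise ValueError("P_FD and k must be 1D arrays of equal length")
        if len(self.P) < 4:
            raise ValueError("need >= 4 (P, k) points to fit the rate law")
        span = self.P.max() / max(self.P.min(), 1e-12)
        if span < 10:
            import warnings

            warnings.warn(
                "concentration range spans less than a decade; "
                "K_m will be poorly constrained",
                stacklevel=2,
            )
        self.sd = np.ones_like(self.k) if sd is None else np.asarray(sd, dtype=float)
        if (self.sd <= 0).any():
            raise ValueError("sd values must be > 0")
        self.n_o = n_o

    @classmethod
    def from_dataframe(cls, df, p_col="P_FD", k_col="k_minus1", sd_col="sd", **kw):
        sd = df[sd_col].values if sd_col in df else None
        return cls(df[p_col].values, df[k_col].values, sd, **kw)

    # ---------------------------------------------------------------

    def _fit_point(self):
        """Weighted NLS point estimate; returns (theta, chi2).

        theta = (k_o, k_r, k_f, K_m), all bounded below by 0 — the
        intrinsic-rate parameterization keeps the fitted law
        non-negative everywhere (k_o_off = k_o + k_r).
        """

        def model(P, k_o, k_r, k_f, K_m):
            return k_o + k_r * np.exp(-P / K_m) + k_f * P

        k_hi = self.k.max()
        slope = max((self.k[-1] - self.k[len(self.k) // 2]) / (self.P[-1] - self.P[len(self.P) // 2] + 1e-12), 1e-6)
        p0_list = [
            (self.k.min(), max(self.k[0] - self.k.min(), 0.1 * k_hi), slope, np.median(self.P)),
            (0.5 * k_hi, 0.5 * k_hi, slope, 0.3 * np.median(self.P)),
            (self.k[0], 1e-3 * k_hi, slope, np.median(self.P)),
        ]
        lo = (0.0, 0.0, 0.0, self.K_M_BOUNDS[0])
        hi = (np.inf, np.inf, np.inf, self.K_M_BOUNDS[1])
        best = None
        for p0 in p0_list:
            try:
                popt, _ = optimize.curve_fit(
                    model, self.P, self.k, p0=np.clip(p0, lo, hi),
                    sigma=self.sd, absolute_sigma=True,
                    bounds=(lo, hi), maxfev=20000,
                )
            except RuntimeError:
                continue
            chi2 = float(np.sum(((self.k - model(self.P, *popt)) / self.sd) ** 2))
            if best is None or chi2 < best[1]:
                best = (popt, chi2)
        if best is None:
            raise RuntimeError("biphasic rate-law fit failed to converge from all starts")
        return best

    def _fit_linear(self):
        """Nested facilitated-only model: k = k_o_off + k_f P (k_r = 0)."""
        w = 1.0 / self.sd**2
        X = np.column_stack([np.ones_like(self.P), self.P])
        wx = X * w[:, None]
        beta = np.linalg.solve(X.T @ wx, wx.T @ self.k)
        beta = np.maximum(beta, 0.0)
        chi2 = float(np.sum(w * (self.k - X @ beta) ** 2))
        return beta, chi2

    def fit(self, n_boot: int = 200, seed: int | np.random.Generator = 0) -> BiphasicFit:
        """Point fit plus parametric bootstrap s.d. and the nested
        linear-model comparison by AIC."""
        popt, chi2 = self._fit_point()
        beta_lin, chi2_lin = self._fit_linear()
        n = len(self.P)
        aic = chi2 + 2 * 4
        aic_lin = chi2_lin + 2 * 2

        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        names = ("k_o", "k_r", "k_f", "K_m")
        sd: dict[str, float] = {}
        if n_boot:
            reps = []
            k_fit = popt[0] + popt[1] * np.exp(-self.P / popt[3]) + popt[2] * self.P
            for _ in range(n_boot):
                k_rep = k_fit + rng.normal(0.0, self.sd)
                try:
                    rep = BiphasicUnbindingModel(self.P, k_rep, self.sd, self.n_o)
                    reps.append(rep._fit_point()[0])
                except RuntimeError:
                    continue
            if len(reps) >= 2:
                reps = np.array(reps)
                sds = np.std(reps, axis=0, ddof=1)
                sd = dict(zip(names, map(float, sds)))
                sd["k_o_off"] = float(np.std(reps[:, 0] + reps[:, 1], ddof=1))

        # pinned at a bound, or below the sampled concentration range
        # (the impeded phase was then never observed and K_m is not
        # really constrained by the data)
        km_pinned = (
            not (self.K_M_BOUNDS[0] * 1.01 < popt[3] < self.K_M_BOUNDS[1] * 0.99)
            or popt[3] < 0.5 * self.P.min()
        )
        params = BiphasicParams(
            k_o=float(popt[0]), k_r=float(popt[1]), k_f=float(popt[2]),
            K_m=float(popt[3]), n_o=self.n_o,
        )
        return BiphasicFit(
            params=params,
            sd=sd,
            chi2=chi2,
            aic=aic,
            aic_linear=aic_lin,
            linear_params=(float(beta_lin[0]), float(beta_lin[1])),
            prefers_biphasic=aic < aic_lin,
            km_pinned=km_pinned,
            P_min=rate_minimum(params),
            n_points=n,
        )
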