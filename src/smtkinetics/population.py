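"""Equilibrium site-binding model for the state populations.

The fractional occupancies of the freely diffusing (FD),
nonspecifically bound (NB) and tightly bound (TB) states across cells
of different total protein concentration carry thermodynamic
information: with a finite concentration of chromosomal binding sites,
raising the total protein concentration saturates the sites, so the FD
fraction rises and the TB fraction falls.

The model is mass-action competitive binding with site depletion.  For
free dimer concentration ``P`` (nM),

    bound_TB = C_TB * P / (K_d1 + P)      (tight-binding sites,
                                           capacity C_TB = [D0]_TB * n_o)
    bound_NB = C_NB * P / (K_d2 + P)      (nonspecific sites, C_NB = [D0]_NB)

and conservation ``P_total = P + bound_NB + bound_TB`` fixes P by
monotone root finding.  ``K_d1 = k_o_off / k_1`` ties this module to
the unbinding kinetics; ``K_d3 = k_minus3 / k_3`` (the NB<->TB
partition) is carried as a derived diagnostic ratio, not a free
parameter of the default isotherm.  The same solve supplies the
free-concentration mapping ``P_FD = f_FD * P_total`` used when fitting
the concentration dependence of the unbinding rate constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "EquilibriumModel",
    "solve_equilibrium",
    "EquilibriumPopulationModel",
    "EquilibriumFit",
]


@dataclass(frozen=True)
class EquilibriumModel:
    """Site-binding parameters: dissociation constants (nM) and site
    capacities (nM).  ``D0_TB_no`` is the tight-site capacity including
    oligomer slots ([D0]_TB * n_o); ``K_d3`` is the optional NB<->TB
    partition ratio diagnostic (dimensionless)."""

    K_d1: float
    K_d2: float
    D0_NB: float
    D0_TB_no: float
    K_d3: float | None = None

    def __post_init__(self) -> None:
        if self.K_d1 <= 0 or self.K_d2 <= 0:
            raise ValueError("dissociation constants must be > 0")
        if self.D0_NB < 0 or self.D0_TB_no < 0:
            raise ValueError("site capacities must be >= 0")


def solve_equilibrium(P_total: float, model: EquilibriumModel):
    """Free concentration and state fractions at one total concentration.

    Solves ``P + C_TB P/(K_d1+P) + C_NB P/(K_d2+P) = P_total`` for the
    free dimer concentration P by bisection (the left side is strictly
    increasing in P, and the root is bracketed by (0, P_total]).

    Returns ``(P_FD, f_FD, f_NB, f_TB)`` with the fractions summing to
    one exactly at the solution.
    """
    if P_total <= 0:
        raise ValueError("P_total must be > 0")

    def excess(p):
        return (
            p
            + model.D0_TB_no * p / (model.K_d1 + p)
            + model.D0_NB * p / (model.K_d2 + p)
            - P_total
        )

    try:
        p = optimize.brentq(excess, 1e-12 * P_total, P_total, xtol=1e-12, rtol=1e-14)
    except ValueError as err:  # pragma: no cover - bracket is guaranteed
        raise RuntimeError(f"equilibrium solve failed at P_total={P_total}") from err
    b_tb = model.D0_TB_no * p / (model.K_d1 + p)
    b_nb = model.D0_NB * p / (model.K_d2 + p)
    return p, p / P_total, b_nb / P_total, b_tb / P_total


def predict_fractions(P_total: np.ndarray, model: EquilibriumModel) -> np.ndarray:
    """(n, 3) array of (f_FD, f_NB, f_TB) over total concentrations."""
    return np.array([solve_equilibrium(p, model)[1:] for p in np.asarray(P_total, dtype=float)])


@dataclass
class EquilibriumFit:
    """Fitted site-binding model with bootstrap uncertainties."""

    model: EquilibriumModel
    sd: dict[str, float]
    chi2: float
    n_groups: int
    degenerate: bool

    def summary(self) -> str:
        m = self.model
        g = lambda k: f"{self.sd.get(k, float('nan')):.3g}"
        lines = [
            "Equilibrium population fit (competitive site binding)",
            f"  K_d1      = {m.K_d1:.4g} +- {g('K_d1')} nM",
            f"  K_d2      = {m.K_d2:.4g} +- {g('K_d2')} nM",
            f"  [D0]_NB   = {m.D0_NB:.4g} +- {g('D0_NB')} nM",
            f"  [D0]_TB*n_o = {m.D0_TB_no:.4g} +- {g('D0_TB_no')} nM",
            f"  chi2 = {self.chi2:.3g} over {self.n_groups} groups",
        ]
        if self.degenerate:
            lines.append(
                "  warning: capacity/K_d poorly separated over this "
                "concentration range"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        m = self.model
        return {
            "K_d1": m.K_d1,
            "K_d2": m.K_d2,
            "D0_NB": m.D0_NB,
            "D0_TB_no": m.D0_TB_no,
            "sd": dict(self.sd),
            "chi2": self.chi2,
            "n_groups": self.n_groups,
        }


class EquilibriumPopulationModel:
    """Fit the site-binding model to per-group fractions.

    Parameters
    ----------
    P_total : array (n_groups,)
        Mean total dimer concentration per group (nM).
    fractions : array (n_groups, 3)
        Observed (f_FD, f_NB, f_TB) per group.
    sd : array, optional
        Standard deviations of the fractions (same shape); weights are
        1/sd^2 where available.
    """

    def __init__(self, P_total, fractions, sd=None):
        self.P = np.asarray(P_total, dtype=float)
        self.f = np.asarray(fractions, dtype=float)
        if self.f.shape != (len(self.P), 3):
            raise ValueError("fractions must be (n_groups, 3)")
        if len(self.P) < 4:
            raise ValueError("need >= 4 concentration groups")
        self.sd = None if sd is None else np.asarray(sd, dtype=float)
        if self.sd is not None and (self.sd <= 0).any():
            raise ValueError("sd values must be > 0")

    @classmethod
    def from_dataframe(cls, df, p_col="P_total_nM",
                       f_cols=("f_FD", "f_NB", "f_TB"), sd_cols=None):
        sd = df[list(sd_cols)].values if sd_cols else None
        return cls(df[p_col].values, df[list(f_cols)].values, sd)

    def _resid(self, theta: np.ndarray) -> np.ndarray:
        model = EquilibriumModel(*np.exp(theta))
        pred = predict_fractions(self.P, model)
        res = pred - self.f
        if self.sd is not None:
            res = res / self.sd
        return res.ravel()

    def _fit_point(self, theta0: np.ndarray | None = None) -> tuple[np.ndarray, float]:
        if theta0 is None:
            theta0 = np.log(
                [np.median(self.P) * 0.1, np.median(self.P) * 3.0,
                 np.median(self.P) * 5.0, np.median(self.P) * 0.5]
            )
        sol = optimize.least_squares(self._resid, theta0, method="lm", max_nfev=40000)
        return sol.x, float(np.sum(sol.fun**2))

    def fit(self, n_boot: int = 100, seed: int | np.random.Generator = 0) -> EquilibriumFit:
        """Weighted least squares (log-parameterized, so all parameters
        stay positive) plus parametric bootstrap s.d."""
        theta, chi2 = self._fit_point()
        names = ("K_d1", "K_d2", "D0_NB", "D0_TB_no")
        sd: dict[str, float] = {}
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        if n_boot:
            model0 = EquilibriumModel(*np.exp(theta))
            pred0 = predict_fractions(self.P, model0)
            noise_sd = self.sd if self.sd is not None else np.full_like(self.f, 0.02)
            reps = []
            for _ in range(n_boot):
                f_rep = np.clip(pred0 + rng.normal(0.0, noise_sd), 1e-4, 1.0)
                try:
                    rep = EquilibriumPopulationModel(self.P, f_rep, self.sd)
                    reps.append(np.exp(rep._fit_point(theta)[0]))
                except Exception:
                    continue
            if len(reps) >= 2:
                sds = np.std(np.array(reps), axis=0, ddof=1)
                sd = dict(zip(names, map(float, sds)))
        params = np.exp(theta)
        span = self.P.max() / self.P.min()
        degenerate = span < 10 or any(
            sd.get(k, 0.0) > 2 * v for k, v in zip(names, params)
        )
        return EquilibriumFit(
            model=EquilibriumModel(*params),
            sd=sd,
            chi2=chi2,
            n_groups=len(self.P),
            degenerate=degenerate,
        )
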