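"""End-to-end driver: simulate -> quantify -> group -> fit -> report.

Chains the synthetic experiment (or user-supplied track/cell tables)
through single-cell protein quantification, concentration grouping,
global diffusion-state deconvolution, per-group residence-time fits,
the biphasic unbinding rate-law fit, the equilibrium population fit
and the residence-site clustering analysis, writing a machine-readable
summary (JSON) plus per-stage tables (TSV).  Every stochastic stage is
seeded from the single run seed, so identical configurations produce
identical reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .diffusion import DisplacementMixtureModel, bootstrap_sd, displacements
from .geometry import CellGeometry
from .population import EquilibriumModel, EquilibriumPopulationModel, solve_equilibrium
from .residence import DwellTimeModel, extract_tau, fit_on_times
from .scqpc import append_concentrations, group_cells, group_summary
from .simulate import ImagingModel, KineticScheme, simulate_tracks
from .spatial import random_reference, ratio_curve, residence_sites
from .unbinding import BiphasicParams, BiphasicUnbindingModel, rate_apparent

__all__ = ["simulate_experiment", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def simulate_experiment(config: RunConfig, seed: int | None = None):
    """Synthetic multi-cell tracking experiment with known truth.

    Per cell: a spherocylinder geometry, a lognormal total dimer
    concentration, state fractions from the equilibrium isotherm, an
    unbinding rate constant from the biphasic apparent rate law at the
    cell's free concentration, and effective on-rates chosen so the
    three-state chain is stationary at those fractions.  Returns
    ``(tracks, cells, states)`` DataFrames; ``cells`` carries the
    SCQPC inputs plus ``true_concentration_nM`` columns for oracles.
    """
    t = config.truth
    rng = np.random.default_rng(config.seed if seed is None else seed)
    imaging = ImagingModel(
        t_lapse=config.t_lapse,
        t_exposure=config.t_exposure,
        sigma_loc=config.sigma_loc,
        k_bleach=config.k_bleach,
        frames_per_cycle=config.frames_per_cycle,
    )
    eq_truth = EquilibriumModel(t.K_d1, t.K_d2, t.D0_NB, t.D0_TB_no)
    bi_truth = BiphasicParams(k_o_off=t.k_o_off, k_r=t.k_r, k_f=t.k_f, K_m=t.K_m)

    all_tracks, all_states, cell_rows = [], [], []
    for ci in range(t.n_cells):
        length = max(
            rng.normal(t.cell_length_mean, t.cell_length_sd), 2.2 * t.cell_radius
        )
        geom = CellGeometry(length, t.cell_radius)
        conc = t.conc_median * np.exp(rng.normal(0.0, t.conc_sigma))
        p_fd, f_fd, f_nb, f_tb = solve_equilibrium(conc, eq_truth)
        k_minus1 = rate_apparent(bi_truth, p_fd)
        # detailed-balance on-rates pinning the chain at the isotherm fractions
        scheme = KineticScheme(
            D_FD=t.D_FD, D_NB=t.D_NB, D_TB=t.D_TB,
            k1_on=k_minus1 * f_tb / f_fd,
            k_minus1=k_minus1,
            k2_on=t.k_minus2 * f_nb / f_fd,
            k_minus2=t.k_minus2,
        )
        tracks, states = simulate_tracks(
            geom, scheme, imaging, t.molecules_per_cell, rng, cell_id=ci
        )
        all_tracks.append(tracks)
        all_states.append(states)
        # SCQPC bookkeeping: total dimers from the true concentration;
        # untracked monomers appear as residual fluorescence
        from .geometry import cell_volume
        from .scqpc import NM_PER_MOLECULE_FL

        n_dimers = max(
            int(round(conc * cell_volume(geom) / NM_PER_MOLECULE_FL)),
            t.molecules_per_cell,
        )
        cell_rows.append(
            {
                "cell_id": ci,
                "length_um": length,
                "radius_um": t.cell_radius,
                "n_tracked": t.molecules_per_cell,
                "residual_fluorescence": 2 * n_dimers * config.eta_pc
                - t.molecules_per_cell,
                "true_concentration_nM": conc,
                "true_P_FD_nM": p_fd,
                "true_k_minus1": k_minus1,
                "true_f_FD": f_fd,
                "true_f_NB": f_nb,
                "true_f_TB": f_tb,
            }
        )
    tracks = pd.concat(all_tracks, ignore_index=True)
    states = pd.concat(all_states, ignore_index=True)
    cells = pd.DataFrame(cell_rows)
    return tracks, cells, states


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path | None = None,
    tracks: pd.DataFrame | None = None,
    cells: pd.DataFrame | None = None,
) -> dict:
    """Run every analysis stage and return the report bundle.

    When ``tracks``/``cells`` are not supplied, a synthetic experiment
    is generated from the config truth.  Writes summary.json and the
    per-stage TSVs into ``out_dir`` if given.
    """
    report: dict = {"config_seed": config.seed}

    # -- stage: data --------------------------------------------------
    if tracks is None or cells is None:
        try:
            tracks, cells, _states = simulate_experiment(config)
        except Exception as err:
            raise PipelineError("simulate", str(err)) from err
        report["data"] = "simulated"
    else:
        report["data"] = "supplied"

    # -- stage: scqpc + grouping --------------------------------------
    try:
        cells = append_concentrations(cells, eta_pc=config.eta_pc)
        cells = group_cells(cells, config.n_groups)
        groups = group_summary(cells)
    except Exception as err:
        raise PipelineError("scqpc", str(err)) from err
    report["groups"] = groups.to_dict("records")

    cell_to_group = dict(zip(cells["cell_id"], cells["group"]))
    tracks = tracks.copy()
    tracks["group"] = tracks["cell_id"].map(cell_to_group)

    # -- stage: diffusion ---------------------------------------------
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            disp_sets = [
                displacements(sub, config.t_lapse, group=str(g))
                for g, sub in tracks.groupby("group", sort=True)
            ]
            mix = DisplacementMixtureModel(
                disp_sets, n_states=config.n_states, sigma_loc=config.sigma_loc
            )
            dfit = mix.fit()
            dfit = bootstrap_sd(mix, config.n_boot, np.random.default_rng(config.seed + 1), dfit)
    except Exception as err:
        raise PipelineError("fit-diffusion", str(err)) from err
    report["diffusion"] = dfit.to_dict()

    # -- stage: photobleaching ----------------------------------------
    try:
        lengths = tracks.groupby(["cell_id", "track_id"]).size().values
        k_bleach, k_bleach_sd = fit_on_times(
            lengths, config.t_lapse, seed=np.random.default_rng(config.seed + 2)
        )
    except Exception as err:
        raise PipelineError("fit-bleach", str(err)) from err
    report["k_bleach"] = {"value": k_bleach, "sd": k_bleach_sd}

    # -- stage: residence times per group -----------------------------
    k_rows = []
    try:
        import warnings

        conc_by_group = dict(zip(groups["group"], groups["mean_nM"]))
        for g, sub in tracks.groupby("group", sort=True):
            taus = extract_tau(sub, config.r0, config.t_lapse, group=str(g))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dwell = DwellTimeModel(taus, dfit, k_bleach).fit(
                    n_boot=config.n_boot,
                    seed=np.random.default_rng(config.seed + 10 + int(g)),
                )
            f_fd = dfit.fractions[str(g)][0]
            p_cell = conc_by_group[g]
            k_rows.append(
                {
                    "group": int(g),
                    "P_cell_nM": float(p_cell),
                    "P_FD_nM": float(f_fd * p_cell),
                    "k_minus1": dwell.k_minus1,
                    "sd": dwell.k_minus1_sd,
                    "n_tau": dwell.n_tau,
                }
            )
    except Exception as err:
        raise PipelineError("fit-residence", str(err)) from err
    k_table = pd.DataFrame(k_rows)
    report["k_minus1_table"] = k_table.to_dict("records")

    # -- stage: biphasic rate law -------------------------------------
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bi_model = BiphasicUnbindingModel(
                k_table["P_FD_nM"].values,
                k_table["k_minus1"].values,
                k_table["sd"].values,
                n_o=config.n_o,
            )
            bi = bi_model.fit(n_boot=config.n_boot, seed=np.random.default_rng(config.seed + 3))
    except Exception as err:
        raise PipelineError("fit-unbinding", str(err)) from err
    report["unbinding"] = bi.to_dict()

    # -- stage: equilibrium populations -------------------------------
    try:
        f_obs = np.array([dfit.fractions[str(g)] for g in sorted(k_table["group"])])
        f_sd = (
            np.array([dfit.fractions_sd[str(g)] for g in sorted(k_table["group"])])
            if dfit.fractions_sd
            else None
        )
        if f_sd is not None:
            f_sd = np.clip(f_sd, 1e-3, None)
        eq_model = EquilibriumPopulationModel(
            k_table["P_cell_nM"].values, f_obs, f_sd
        )
        eq = eq_model.fit(n_boot=min(config.n_boot, 50),
                          seed=np.random.default_rng(config.seed + 4))
    except Exception as err:
        raise PipelineError("fit-population", str(err)) from err
    report["population"] = eq.to_dict()

    # -- stage: spatial clustering ------------------------------------
    try:
        geoms = {
            row.cell_id: CellGeometry(row.length_um, row.radius_um)
            for row in cells.itertuples(index=False)
        }
        obs_sets, ref_sets = [], []
        for g, sub in tracks.groupby("group", sort=True):
            obs = residence_sites(sub, config.r0, group=str(g))
            if obs.n_sites < 2:
                continue
            ref = random_reference(
                geoms, obs.counts(), np.random.default_rng(config.seed + 100 + int(g))
            )
            obs_sets.append(obs)
            ref_sets.append(ref)
        grid = np.array([0.07, 0.1, 0.15, 0.2, 0.3, 0.5])
        ratios = ratio_curve(obs_sets, ref_sets, grid)
    except Exception as err:
        raise PipelineError("spatial", str(err)) from err
    report["spatial_ratio_curve"] = ratios.to_dict("records")

    # -- Table-1-style condensed summary ------------------------------
    k1 = bi.params.k_o_off / eq.model.K_d1 if eq.model.K_d1 > 0 else None
    report["parameter_table"] = {
        "k_1_per_nM_s": k1,
        "k_o_off_per_s": bi.params.k_o_off,
        "k_r_per_s": bi.params.k_r,
        "k_f_per_nM_s": bi.params.k_f,
        "K_m_nM": bi.params.K_m,
        "K_d1_nM": eq.model.K_d1,
        "K_d2_nM": eq.model.K_d2,
        "D0_NB_nM": eq.model.D0_NB,
        "D0_TB_no_nM": eq.model.D0_TB_no,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=_json_default)
        )
        k_table.to_csv(out / "k_minus1_table.tsv", sep="\t", index=False)
        groups.to_csv(out / "groups.tsv", sep="\t", index=False)
        ratios.to_csv(out / "spatial_ratio_curve.tsv", sep="\t", index=False)
        frac_rows = []
        for g in sorted(dfit.fractions):
            row = {"group": g}
            for lab, f in zip(("FD", "NB", "TB"), dfit.fractions[g]):
                row[f"f_{lab}"] = f
            frac_rows.append(row)
        pd.DataFrame(frac_rows).to_csv(out / "fractions.tsv", sep="\t", index=False)
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
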