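"""Residence-site clustering statistics.

If a DNA-binding protein oligomerizes around its binding sites, the
locations where molecules reside in the tight-binding state should pile
up at molecular (tens of nanometres) scales.  This module tests that
against a spatial null: for each cell, the same number of sites is
thrown uniformly into a spherocylinder of the same size and projected
to the imaging plane.  Comparisons use the normalized pair-wise
distance distribution (PWDD), the fraction of pair distances within a
radius threshold R, and the observed/reference ratio of that fraction
as a function of R — clustering shows up as a ratio above 1 that grows
as R shrinks.  Pair distances are always formed within a cell and
pooled across cells, never across cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .geometry import CellGeometry, sample_points

__all__ = [
    "SiteSet",
    "residence_sites",
    "random_reference",
    "pwdd",
    "fraction_within",
    "ratio_curve",
]


@dataclass
class SiteSet:
    """Residence-site coordinates, one entry per cell.

    ``sites[cell_id]`` is an (n_i, 2) array of (x, y) positions in um;
    one site per residence event (maximal sub-threshold run), placed at
    the mean localization of the run.
    """

    sites: dict = field(default_factory=dict)
    group: str = "all"

    @property
    def n_sites(self) -> int:
        return sum(len(v) for v in self.sites.values())

    def counts(self) -> dict:
        return {c: len(v) for c, v in self.sites.items()}


def residence_sites(tracks: pd.DataFrame, r0: float, group: str = "all") -> SiteSet:
    """One site per maximal sub-``r0`` displacement run, at the run's
    mean localization.  Same thresholding convention as the
    residence-time extraction."""
    if r0 <= 0:
        raise ValueError("r0 must be > 0")
    per_cell: dict = {}
    if len(tracks):
        t = tracks.sort_values(["cell_id", "track_id", "frame"], kind="stable")
        for (cid, _tid), sub in t.groupby(["cell_id", "track_id"], sort=False):
            if len(sub) < 2:
                continue
            x = sub["x_um"].values
            y = sub["y_um"].values
            ok = np.diff(sub["frame"].values) == 1
            r = np.hypot(np.diff(x), np.diff(y))
            below = (r < r0) & ok
            # localizations i..i+len(run) belong to a run of
            # displacements starting at i
            start = None
            for i, b in enumerate(np.append(below, False)):
                if b and start is None:
                    start = i
                elif not b and start is not None:
                    pts = np.column_stack([x[start : i + 1], y[start : i + 1]])
                    per_cell.setdefault(cid, []).append(pts.mean(axis=0))
                    start = None
    return SiteSet(
        {c: np.array(v) for c, v in per_cell.items()}, group=group
    )


def random_reference(
    geometries: dict,
    counts: dict,
    seed: int | np.random.Generator,
    mode: str = "3d_projected",
) -> SiteSet:
    """Uniform random sites matched per cell in count and geometry.

    ``geometries[cell_id]`` is a :class:`CellGeometry`; ``counts`` the
    observed per-cell site numbers.  Default draws uniformly in the 3D
    spherocylinder and projects to (x, y), matching how imaging sees
    chromosome-free uniform sites; ``mode='2d'`` instead draws in the
    2D footprint (the projection of the spherocylinder outline).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict = {}
    for cid, n in counts.items():
        geom = geometries[cid]
        if mode == "3d_projected":
            pts = sample_points(geom, n, rng)[:, :2]
        elif mode == "2d":
            # rejection-sample the 2D footprint: stadium shape
            pts = np.empty((n, 2))
            filled = 0
            half = geom.total_length / 2.0
            r = geom.radius
            hc = geom.cylinder_length / 2.0
            while filled < n:
                cand = rng.uniform((-half, -r), (half, r), size=(max(2 * (n - filled), 32), 2))
                ax = np.clip(cand[:, 0], -hc, hc)
                good = cand[(cand[:, 0] - ax) ** 2 + cand[:, 1] ** 2 <= r * r]
                take = min(n - filled, len(good))
                pts[filled : filled + take] = good[:take]
                filled += take
        else:
            raise ValueError(f"unknown reference mode {mode!r}")
        out[cid] = pts
    return SiteSet(out, group="reference")


def _pair_distances(sites: SiteSet) -> np.ndarray:
    """All within-cell pairwise distances, pooled across cells.

    Cells with fewer than two sites contribute nothing.
    """
    ds = [pdist(v) for v in sites.sites.values() if len(v) >= 2]
    return np.concatenate(ds) if ds else np.empty(0)


def pwdd(sites: SiteSet, bin_width: float = 0.05, r_max: float | None = None):
    """Normalized pair-wise distance distribution.

    Returns ``(bin_centers, density)`` with the histogram normalized to
    unit sum.  Requires at least one cell with >= 2 sites.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    d = _pair_distances(sites)
    if len(d) == 0:
        raise ValueError("need at least 2 sites in some cell for a PWDD")
    if r_max is None:
        r_max = d.max() + bin_width
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist, edges = np.histogram(d, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, hist / hist.sum()


def fraction_within(sites: SiteSet, R: float, method: str = "pairs") -> float:
    """Fraction of residence sites "within" radius R of one another.

    ``method='pairs'`` (default): fraction of within-cell pair
    distances <= R, pooled over cells.  ``method='nn'``: fraction of
    sites whose nearest neighbour in the same cell lies <= R.  Both
    are non-decreasing in R and carry the same clustering signature.
    """
    if R <= 0:
        raise ValueError("R must be > 0")
    if method == "pairs":
        d = _pair_distances(sites)
        if len(d) == 0:
            return np.nan
        return float(np.mean(d <= R))
    if method == "nn":
        flags = []
        for v in sites.sites.values():
            if len(v) < 2:
                continue
            from scipy.spatial.distance import squareform

            dm = squareform(pdist(v))
            np.fill_diagonal(dm, np.inf)
            flags.append(dm.min(axis=1) <= R)
        if not flags:
            return np.nan
        return float(np.mean(np.concatenate(flags)))
    raise ValueError(f"unknown method {method!r}")


def ratio_curve(
    observed: list[SiteSet] | SiteSet,
    reference: list[SiteSet] | SiteSet,
    R_grid: np.ndarray,
) -> pd.DataFrame:
    """Average observed/reference fraction-within-R ratio across groups.

    ``observed`` and ``reference`` are parallel per-group site sets.
    Where the reference fraction is zero (no pairs that close) the
    ratio is undefined and reported as NaN for that group/R.  Returns a
    DataFrame with columns R, ratio (mean over groups), sd, n_groups.
    """
    if isinstance(observed, SiteSet):
        observed = [observed]
    if isinstance(reference, SiteSet):
        reference = [reference]
    if len(observed) != len(reference):
        raise ValueError("observed and reference group lists must be parallel")
    rows = []
    for R in np.asarray(R_grid, dtype=float):
        ratios = []
        for obs, ref in zip(observed, reference):
            fo = fraction_within(obs, R)
            fr = fraction_within(ref, R)
            if not np.isfinite(fo) or not np.isfinite(fr) or fr == 0:
                continue
            ratios.append(fo / fr)
        if ratios:
            rows.append(
                {
                    "R": R,
                    "ratio": float(np.mean(ratios)),
                    "sd": float(np.std(ratios, ddof=1)) if len(ratios) > 1 else np.nan,
                    "n_groups": len(ratios),
                }
            )
        else:
            rows.append({"R": R, "ratio": np.nan, "sd": np.nan, "n_groups": 0})
    return pd.DataFrame(rows)


def pwdd_difference_ci(
    observed: SiteSet,
    reference: SiteSet,
    bin_width: float = 0.05,
    r_max: float = 3.0,
    n_boot: int = 200,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Observed-minus-reference PWDD with 95% cell-bootstrap bounds.

    Resamples cells with replacement in both sets; returns a DataFrame
    with bin centers, the two normalized PWDDs, their difference, and
    the 2.5/97.5 percentile bounds of the difference.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def hist_of(ss: SiteSet, keys=None) -> np.ndarray:
        keys = list(ss.sites) if keys is None else keys
        ds = [pdist(ss.sites[k]) for k in keys if len(ss.sites[k]) >= 2]
        d = np.concatenate(ds) if ds else np.empty(0)
        h, _ = np.histogram(d, bins=edges)
        return h / h.sum() if h.sum() else np.zeros(len(centers))

    obs_h = hist_of(observed)
    ref_h = hist_of(reference)
    diffs = []
    obs_keys = list(observed.sites)
    ref_keys = list(reference.sites)
    for _ in range(n_boot):
        ok = [obs_keys[i] for i in rng.integers(0, len(obs_keys), len(obs_keys))]
        rk = [ref_keys[i] for i in rng.integers(0, len(ref_keys), len(ref_keys))]
        diffs.append(hist_of(observed, ok) - hist_of(reference, rk))
    lo, hi = np.percentile(np.array(diffs), [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "r_um": centers,
            "observed": obs_h,
            "reference": ref_h,
            "difference": obs_h - ref_h,
            "ci_lo": lo,
            "ci_hi": hi,
        }
    )
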