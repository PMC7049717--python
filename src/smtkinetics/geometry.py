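"""Spherocylinder cell geometry.

Rod-shaped bacteria such as *E. coli* are well approximated by a
spherocylinder: a cylinder of radius ``r`` capped by two hemispheres.
This module provides the analytic cell volume used for per-cell protein
quantification and uniform point sampling inside the cell used both by
the trajectory simulator and by the random-site spatial null.

Coordinate convention: the cell long axis is x, the origin is the cell
center, so the cell spans ``[-L/2, L/2]`` in x.  Imaging projects onto
the (x, y) plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CellGeometry", "cell_volume", "sample_points", "contains", "reflect_into"]


@dataclass(frozen=True)
class CellGeometry:
    """Spherocylinder: pole-to-pole length and radius, both in micrometres.

    Parameters
    ----------
    total_length : float
        Pole-to-pole cell length L (um).  Must satisfy ``L >= 2 r``.
    radius : float
        Cap/cylinder radius r (um), strictly positive.
    """

    total_length: float
    radius: float

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if self.total_length < 2 * self.radius:
            raise ValueError(
                f"total_length ({self.total_length}) must be >= 2*radius "
                f"({2 * self.radius}): a spherocylinder cannot be shorter "
                "than its two caps"
            )

    @property
    def cylinder_length(self) -> float:
        """Length of the cylindrical midsection, L - 2r (um)."""
        return self.total_length - 2 * self.radius

    @property
    def volume(self) -> float:
        """Cell volume in fL (= um^3)."""
        return cell_volume(self)


def cell_volume(geom: CellGeometry) -> float:
    """Volume of a spherocylinder in fL (um^3).

    V = pi r^2 (L - 2r) + (4/3) pi r^3 — a cylinder plus two
    hemispherical caps.  Degenerates to a sphere at L = 2r.
    """
    r = geom.radius
    return np.pi * r * r * geom.cylinder_length + (4.0 / 3.0) * np.pi * r**3


def contains(geom: CellGeometry, points: np.ndarray, tol: float = 0.0) -> np.ndarray:
    """Boolean mask of which 3D points lie inside the spherocylinder.

    Parameters
    ----------
    points : (n, 3) array
        Coordinates in the cell frame (um).
    tol : float
        Dilation of the surface (um); positive values accept points up
        to ``tol`` outside, e.g. to allow for localization error.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    half = geom.cylinder_length / 2.0
    # distance from the cylinder axis segment [-half, half] x {(0,0)}
    ax = np.clip(pts[:, 0], -half, half)
    d2 = (pts[:, 0] - ax) ** 2 + pts[:, 1] ** 2 + pts[:, 2] ** 2
    return d2 <= (geom.radius + tol) ** 2


def sample_points(geom: CellGeometry, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Sample ``n`` points uniformly inside the spherocylinder.

    Rejection sampling from the bounding box — exactly uniform, and
    deterministic given ``seed``.

    Returns an (n, 3) array of (x, y, z) in um, cell frame.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty((n, 3), dtype=float)
    filled = 0
    half_l = geom.total_length / 2.0
    r = geom.radius
    while filled < n:
        m = max(2 * (n - filled), 64)
        cand = rng.uniform(
            low=(-half_l, -r, -r), high=(half_l, r, r), size=(m, 3)
        )
        good = cand[contains(geom, cand)]
        take = min(n - filled, good.shape[0])
        out[filled : filled + take] = good[:take]
        filled += take
    return out


def reflect_into(geom: CellGeometry, points: np.ndarray, max_iter: int = 8) -> np.ndarray:
    """Mirror-reflect points that fell outside the membrane back inside.

    Points outside the spherocylinder are reflected across the nearest
    surface point (specular reflection off the membrane).  A handful of
    iterations suffices when step lengths are small compared with the
    radius; any stragglers are projected just inside the surface.
    """
    pts = np.array(np.atleast_2d(points), dtype=float)
    half = geom.cylinder_length / 2.0
    r = geom.radius
    for _ in range(max_iter):
        ax = np.clip(pts[:, 0], -half, half)
        rel = pts - np.column_stack([ax, np.zeros(len(pts)), np.zeros(len(pts))])
        d = np.linalg.norm(rel, axis=1)
        outside = d > r
        if not outside.any():
            return pts
        # reflect radially about the surface: d -> 2r - d
        scale = (2 * r - d[outside]) / d[outside]
        pts[outside] = (
            np.column_stack([ax[outside], np.zeros(outside.sum()), np.zeros(outside.sum())])
            + rel[outside] * scale[:, None]
        )
    # numerical fallback: clamp leftovers just inside
    ax = np.clip(pts[:, 0], -half, half)
    rel = pts - np.column_stack([ax, np.zeros(len(pts)), np.zeros(len(pts))])
    d = np.linalg.norm(rel, axis=1)
    outside = d > r
    if outside.any():
        pts[outside] = (
            np.column_stack([ax[outside], np.zeros(outside.sum()), np.zeros(outside.sum())])
            + rel[outside] * (0.999 * r / d[outside])[:, None]
        )
    return pts
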