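"""Bidimensional empirical mode decomposition (BEMD) of a real 2-D matrix.

BEMD adaptively splits an image into bidimensional intrinsic mode functions
(BIMFs) plus a residue.  Each BIMF is obtained by *sifting*: locate the strict
local maxima and minima over 8-neighbourhoods, fit smooth envelope surfaces
through each set, subtract the envelope mean, and repeat until the normalised
squared change between consecutive sifts

    SD = sum( (h_{p-1} - h_p)^2 / h_{p-1}^2 )

falls below a threshold (0.25 by default).  Subtracting each accepted BIMF
from the running residue makes the decomposition complete by construction:
sum(BIMFs) + residue == input exactly.  BIMFs are ordered from the highest to
the lowest local spatial frequency; the residue carries the overall trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import (CloughTocher2DInterpolator,
                               LinearNDInterpolator, NearestNDInterpolator)
from scipy.spatial import QhullError

# Denominator guard for the SD stopping criterion: cells where the previous
# sift is this close to zero are excluded from the sum (the criterion divides
# by h^2, which is undefined there).
_SD_EPS = 1e-12


class MonotoneResidue(Exception):
    """Signals that a matrix has no interior extrema left to sift."""


@dataclass(frozen=True)
class BemdConfig:
    """BEMD parameters: 5 BIMFs, SD threshold 0.25, at most 10 sifts each."""

    n_bimfs: int = 5
    sd_threshold: float = 0.25
    max_sift_iters: int = 10
    neighborhood: str = "8-connected"
    boundary: str = "mirror"

    def __post_init__(self) -> None:
        if self.n_bimfs < 1:
            raise ValueError("n_bimfs must be >= 1")
        if not self.sd_threshold > 0:
            raise ValueError("sd_threshold must be positive")
        if self.max_sift_iters < 1:
            raise ValueError("max_sift_iters must be >= 1")
        if self.neighborhood != "8-connected":
            raise ValueError("only 8-connected neighbourhoods are supported")
        if self.boundary != "mirror":
            raise ValueError("only mirror boundary handling is supported")


@dataclass
class BIMFSet:
    """Ordered BIMFs plus residue; ``sum(bimfs) + residue == input``."""

    bimfs: list[np.ndarray]
    residue: np.ndarray
    sift_counts: list[int] = field(default_factory=list)

    @property
    def n_bimfs(self) -> int:
        return len(self.bimfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for b in self.bimfs:
            out += b
        return out


def find_extrema(matrix: np.ndarray,
                 neighborhood: str = "8-connected"
                 ) -> tuple[tuple[np.ndarray, np.ndarray],
                            tuple[np.ndarray, np.ndarray]]:
    """Strict local maxima and minima over mirror-extended 8-neighbourhoods.

    Returns ``((max_points, max_values), (min_points, min_values))`` where the
    point arrays have shape (n, 2) in (row, col) order.  A pixel qualifies
    only if strictly greater (resp. smaller) than all 8 neighbours, so
    plateaus yield no extrema.
    """
    if neighborhood != "8-connected":
        raise ValueError("only 8-connected neighbourhoods are supported")
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or min(m.shape) < 3:
        raise ValueError("matrix must be 2-D and at least 3x3")
    fp = np.ones((3, 3), dtype=bool)
    fp[1, 1] = False
    neigh_max = ndimage.maximum_filter(m, footprint=fp, mode="mirror")
    neigh_min = ndimage.minimum_filter(m, footprint=fp, mode="mirror")
    maxima = np.argwhere(m > neigh_max)
    minima = np.argwhere(m < neigh_min)
    return ((maxima, m[tuple(maxima.T)] if maxima.size else np.empty(0)),
            (minima, m[tuple(minima.T)] if minima.size else np.empty(0)))


def _mirror_points(points: np.ndarray, values: np.ndarray,
                   shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Half-sample mirror of a scattered point set across all four borders.

    A point at row r is reflected to -1-r and 2*nrows-1-r (likewise columns),
    the reflections carrying the original value.  This keeps envelope fits
    from diving at the image borders, where the extrema hull ends.
    """
    nr, nc = shape
    rows, cols, vals = [points[:, 0]], [points[:, 1]], [values]
    reflections_r = (lambda r: -1 - r, lambda r: 2 * nr - 1 - r)
    reflections_c = (lambda c: -1 - c, lambda c: 2 * nc - 1 - c)
    base_r, base_c = points[:, 0], points[:, 1]
    for fr in (None, *reflections_r):
        for fc in (None, *reflections_c):
            if fr is None and fc is None:
                continue
            rows.append(fr(base_r) if fr else base_r)
            cols.append(fc(base_c) if fc else base_c)
            vals.append(values)
    pts = np.column_stack([np.concatenate(rows), np.concatenate(cols)])
    return pts, np.concatenate(vals)


def envelope_surface(points: np.ndarray, values: np.ndarray,
                     shape: tuple[int, int]) -> np.ndarray:
    """Smooth surface over the full grid interpolating scattered support points.

    With >= 16 support points the set is mirror-padded across the borders and
    fitted with a C1 piecewise-cubic scattered interpolant; with fewer points,
    or when the configuration is degenerate (collinear), the fit falls back to
    linear interpolation with nearest-neighbour extrapolation.  Exactly
    interpolates the support values in every branch.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    values = np.asarray(values, dtype=float).ravel()
    if points.size == 0:
        raise MonotoneResidue("no extrema: cannot fit an envelope")
    grid_r, grid_c = np.mgrid[0:shape[0], 0:shape[1]]
    grid = np.column_stack([grid_r.ravel(), grid_c.ravel()])

    if len(points) == 1 or np.ptp(values) == 0:
        # single support point or flat values: constant surface
        if len(points) == 1:
            return np.full(shape, values[0])
        return np.full(shape, values[0])

    def _fallback() -> np.ndarray:
        try:
            lin = LinearNDInterpolator(points, values)
            out = lin(grid)
        except QhullError:
            out = np.full(len(grid), np.nan)
        nan = np.isnan(out)
        if nan.any():
            near = NearestNDInterpolator(points, values)
            out[nan] = near(grid[nan])
        return out.reshape(shape)

    if len(points) < 16:
        return _fallback()
    pts, vals = _mirror_points(points, values, shape)
    try:
        ct = CloughTocher2DInterpolator(pts, vals)
        out = ct(grid)
    except QhullError:
        return _fallback()
    nan = np.isnan(out)
    if nan.any():
        near = NearestNDInterpolator(pts, vals)
        out[nan] = near(grid[nan])
    return out.reshape(shape)


def sift_once(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One sifting step: ``h = matrix - (e_max + e_min) / 2``.

    Raises :class:`MonotoneResidue` when the matrix has no strict maxima or
    no strict minima (nothing left to sift).
    """
    m = np.asarray(matrix, dtype=float)
    (max_pts, max_vals), (min_pts, min_vals) = find_extrema(m)
    if len(max_pts) == 0 or len(min_pts) == 0:
        raise MonotoneResidue("matrix has no interior extrema")
    e_max = envelope_surface(max_pts, max_vals, m.shape)
    e_min = envelope_surface(min_pts, min_vals, m.shape)
    env_mean = 0.5 * (e_max + e_min)
    return m - env_mean, env_mean


def _sd(prev: np.ndarray, cur: np.ndarray) -> float:
    """Normalised squared change between consecutive sifts (zero-guarded)."""
    mask = np.abs(prev) >= _SD_EPS
    if not mask.any():
        return 0.0
    d = prev[mask] - cur[mask]
    return float(np.sum(d * d / (prev[mask] * prev[mask])))


def extract_bimf(matrix: np.ndarray, sd_threshold: float = 0.25,
                 max_iters: int = 10) -> tuple[np.ndarray, int]:
    """Sift one BIMF out of ``matrix``.

    Iterates :func:`sift_once` until the SD criterion drops below
    ``sd_threshold`` or ``max_iters`` sifts have run; the envelope mean is
    recomputed from the current iterate at every step.  Returns the final
    sift result and the number of sifts used.
    """
    h_prev = np.asarray(matrix, dtype=float)
    h, _ = sift_once(h_prev)  # first sift: propagate MonotoneResidue
    n_iters = 1
    while _sd(h_prev, h) >= sd_threshold and n_iters < max_iters:
        h_prev = h
        try:
            h, _ = sift_once(h_prev)
        except MonotoneResidue:
            break
        n_iters += 1
    return h, n_iters


def decompose(matrix: np.ndarray,
              config: BemdConfig = BemdConfig()) -> BIMFSet:
    """Full BEMD: repeatedly extract BIMFs from the running residue.

    Stops after ``config.n_bimfs`` modes or as soon as the residue has no
    extrema left.  Completeness holds exactly because each BIMF is literally
    subtracted from the residue.
    """
    m = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("input matrix contains non-finite values")
    residue = m.copy()
    bimfs: list[np.ndarray] = []
    counts: list[int] = []
    for _ in range(config.n_bimfs):
        try:
            bimf, n = extract_bimf(residue, config.sd_threshold,
                                   config.max_sift_iters)
        except MonotoneResidue:
            break
        bimfs.append(bimf)
        counts.append(n)
        residue = residue - bimf
    return BIMFSet(bimfs=bimfs, residue=residue, sift_counts=counts)
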