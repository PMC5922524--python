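"""Spatial statistics on geographic site networks and grids.

All distances are great-circle (haversine) kilometres on WGS84.  The
module provides inverse-distance-weighted interpolation of site values
onto a grid, Moran's I with permutation tests, distance-class
correlograms, Moran's Eigenvector Maps (MEMs) for spatial filtering, and
RGB composition of three compositional axes into a single raster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from sklearn.metrics.pairwise import haversine_distances

from .data import SiteRegistry
from .grids import GridGeometry, GridSurface

__all__ = ["SpatialWeights", "Correlogram", "MemBasis", "haversine_km",
           "idw_interpolate", "morans_i", "correlogram", "mem_basis",
           "rgb_compose"]

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Pairwise great-circle distances (km) between two coordinate sets."""
    a = np.radians(np.column_stack([np.atleast_1d(lat1), np.atleast_1d(lon1)]))
    b = np.radians(np.column_stack([np.atleast_1d(lat2), np.atleast_1d(lon2)]))
    return haversine_distances(a, b) * EARTH_RADIUS_KM


def _site_distances(registry: SiteRegistry) -> np.ndarray:
    return haversine_km(registry.lon, registry.lat, registry.lon, registry.lat)


@dataclass
class SpatialWeights:
    """Symmetric non-negative site-pair weights with zero diagonal.

    ``strict`` additionally demands a positive weight for every site;
    distance-class weights relax this because a site can be isolated in
    a single class.
    """

    w: np.ndarray
    strict: bool = True

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < 0):
            raise ValueError("weights must be non-negative")
        if not np.allclose(self.w, self.w.T):
            raise ValueError("weights must be symmetric")
        np.fill_diagonal(self.w, 0.0)
        if self.strict and np.any(self.w.sum(axis=1) == 0):
            raise ValueError("every site needs at least one positive weight")


@dataclass
class Correlogram:
    """Moran's I per geographic distance class."""

    bounds: np.ndarray           # class edges, length n_classes + 1
    morans_i: np.ndarray         # NaN where a class holds no pairs
    p_values: np.ndarray         # Holm-adjusted permutation p's
    n_pairs: np.ndarray

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return (self.p_values < alpha) & ~np.isnan(self.morans_i)


@dataclass
class MemBasis:
    """Moran's Eigenvector Map basis for a site network."""

    vectors: np.ndarray          # site x m, orthonormal
    eigenvalues: np.ndarray      # descending
    morans_i: np.ndarray
    p_values: np.ndarray
    selected: np.ndarray         # indices of positive, significant MEMs

    def selected_vectors(self) -> np.ndarray:
        return self.vectors[:, self.selected]


def idw_interpolate(registry: SiteRegistry, values, geometry: GridGeometry,
                    power: float = 2.0, n_neighbors: int | None = None,
                    mask: np.ndarray | None = None,
                    exact_tol_km: float = 1e-6) -> GridSurface:
    """Inverse-distance-weighted interpolation of site values onto a grid.

    Cell value = sum(w_i * v_i) / sum(w_i) with w_i = d_i**(-power) over
    the ``n_neighbors`` nearest sites (all sites by default).  A cell
    whose center coincides with a site takes the site value exactly.
    The output is a convex combination, hence bounded by the site-value
    range.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(registry):
        raise ValueError("one value per site required")
    if len(registry) == 0:
        raise ValueError("empty site registry")
    lon, lat = geometry.cell_centers()
    cells = np.column_stack([lon.ravel(), lat.ravel()])
    dist = haversine_km(cells[:, 0], cells[:, 1], registry.lon, registry.lat)

    if n_neighbors is not None and n_neighbors < len(registry):
        k = n_neighbors
        part = np.argpartition(dist, k - 1, axis=1)[:, :k]
        sel = np.take_along_axis(dist, part, axis=1)
        vals = values[part]
    else:
        sel, vals = dist, np.broadcast_to(values, dist.shape)

    out = np.empty(cells.shape[0])
    exact = sel.min(axis=1) < exact_tol_km
    with np.errstate(divide="ignore"):
        w = sel ** (-power)
    w = np.where(np.isfinite(w), w, 0.0)
    sw = w.sum(axis=1)
    ok = sw > 0
    out[ok] = (w[ok] * vals[ok]).sum(axis=1) / sw[ok]
    if np.any(exact):
        nearest = sel.argmin(axis=1)
        out[exact] = vals[exact, nearest[exact]]
    if np.any(~ok & ~exact):
        raise ValueError("cell with empty interpolation neighborhood")
    grid = out.reshape(geometry.n_rows, geometry.n_cols)
    return GridSurface(geometry, grid, mask)


def _moran_stat(z: np.ndarray, w: np.ndarray, z2sum: float, w_sum: float) -> float:
    n = z.size
    return float(n / w_sum * (z @ w @ z) / z2sum)


def morans_i(values, weights: SpatialWeights, n_perm: int = 999,
             seed: int = 0) -> tuple[float, float, float]:
    """Global Moran's I with a two-sided permutation test.

    Returns ``(I, expected, p)`` where ``expected = -1/(n-1)`` and the
    p-value counts permutations at least as far from the expectation as
    the observed statistic.
    """
    x = np.asarray(values, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("Moran's I undefined for constant values")
    z = x - x.mean()
    w = weights.w
    w_sum = w.sum()
    z2 = float(z @ z)
    i_obs = _moran_stat(z, w, z2, w_sum)
    expected = -1.0 / (len(x) - 1)
    if n_perm <= 0:
        return i_obs, expected, np.nan
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        zp = rng.permutation(z)
        if abs(_moran_stat(zp, w, z2, w_sum) - expected) >= abs(i_obs - expected) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return i_obs, expected, p


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment, NaN-aware."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    idx = np.where(~np.isnan(p))[0]
    if idx.size == 0:
        return out
    m = idx.size
    order = idx[np.argsort(p[idx])]
    running = 0.0
    for rank, i in enumerate(order):
        adj = min(1.0, (m - rank) * p[i])
        running = max(running, adj)
        out[i] = running
    return out


def correlogram(values, registry: SiteRegistry, n_classes: int = 14,
                n_perm: int = 199, seed: int = 0) -> Correlogram:
    """Moran's I spatial correlogram over equal-width distance classes.

    Distance classes partition [0, max pair distance]; each class uses
    binary membership weights.  Per-class permutation p-values are
    Holm-adjusted across classes.  Empty classes are flagged with NaN
    rather than treated as errors.
    """
    x = np.asarray(values, dtype=float)
    dist = _site_distances(registry)
    d_max = dist.max()
    if d_max == 0:
        raise ValueError("all sites at one location")
    bounds = np.linspace(0.0, d_max, n_classes + 1)
    iu = np.triu_indices(len(x), k=1)
    eps = 1e-9
    i_vals = np.full(n_classes, np.nan)
    p_raw = np.full(n_classes, np.nan)
    n_pairs = np.zeros(n_classes, dtype=int)
    for k in range(n_classes):
        lo, hi = bounds[k], bounds[k + 1]
        if k == n_classes - 1:
            hi += eps
        inclass = (dist[iu] >= lo) & (dist[iu] < hi)
        n_pairs[k] = int(inclass.sum())
        if n_pairs[k] == 0:
            continue
        w = np.zeros_like(dist)
        w[iu[0][inclass], iu[1][inclass]] = 1.0
        w = w + w.T
        weights = SpatialWeights(w, strict=False)
        i_vals[k], _, p_raw[k] = morans_i(x, weights, n_perm=n_perm,
                                          seed=seed + k)
    return Correlogram(bounds, i_vals, _holm(p_raw), n_pairs)


def _gabriel_edges(dist: np.ndarray) -> np.ndarray:
    """Adjacency of the Gabriel graph from a pairwise distance matrix.

    Edge (i, j) survives iff no third point k satisfies
    d_ik^2 + d_jk^2 < d_ij^2 (k inside the circle with diameter ij).
    """
    n = dist.shape[0]
    d2 = dist**2
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if not np.any(d2[i] + d2[j] < d2[i, j] - 1e-12):
                adj[i, j] = adj[j, i] = True
    return adj


def mem_basis(registry: SiteRegistry, alpha: float = 0.05, n_perm: int = 199,
              seed: int = 0) -> MemBasis:
    """Moran's Eigenvector Maps for a site network.

    Connectivity is the Gabriel graph union the minimum spanning tree
    (the MST guarantees a connected network); edge weights are
    ``1 - (d_ij/d_max)**2`` with ``d_max`` the longest retained edge.
    Eigenvectors of the doubly-centered weight matrix give orthogonal
    spatial patterns ordered from broad (positive Moran's I) to fine
    (negative).  MEMs with positive eigenvalue and permutation-
    significant positive Moran's I are flagged as ``selected`` for use
    as spatial covariates.
    """
    n = len(registry)
    if n < 4:
        raise ValueError("need at least 4 sites for a MEM basis")
    dist = _site_distances(registry)
    adj = _gabriel_edges(dist)
    mst = minimum_spanning_tree(dist).toarray()
    adj |= (mst > 0) | (mst.T > 0)
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp != 1:
        raise ValueError("site connectivity graph is disconnected")
    d_max = dist[adj].max()
    w = np.where(adj, 1.0 - (dist / d_max) ** 2, 0.0)
    np.fill_diagonal(w, 0.0)
    return mem_from_weights(SpatialWeights(w), alpha=alpha, n_perm=n_perm,
                            seed=seed)


def mem_from_weights(weights: SpatialWeights, alpha: float = 0.05,
                     n_perm: int = 199, seed: int = 0) -> MemBasis:
    """MEM basis from an arbitrary spatial weight matrix."""
    w = weights.w
    n = w.shape[0]
    h = np.eye(n) - np.ones((n, n)) / n
    centered = h @ w @ h
    eigval, eigvec = np.linalg.eigh(centered)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # drop near-zero eigenvalues (the centered constant direction)
    keep = np.abs(eigval) > 1e-9 * max(1.0, np.abs(eigval).max())
    eigval, eigvec = eigval[keep], eigvec[:, keep]

    m = eigvec.shape[1]
    ivals = np.empty(m)
    pvals = np.empty(m)
    for k in range(m):
        i_k, _, _ = morans_i(eigvec[:, k], weights, n_perm=0)
        ivals[k] = i_k
        # one-sided (positive autocorrelation) permutation test
        rng = np.random.default_rng(seed + k)
        z = eigvec[:, k] - eigvec[:, k].mean()
        z2 = float(z @ z)
        w_sum = w.sum()
        count = sum(_moran_stat(rng.permutation(z), w, z2, w_sum) >= i_k - 1e-12
                    for _ in range(n_perm))
        pvals[k] = (count + 1) / (n_perm + 1)
    selected = np.where((eigval > 1e-9) & (pvals < alpha) & (ivals > 0))[0]
    return MemBasis(eigvec, eigval, ivals, pvals, selected)


def rgb_compose(axis1: GridSurface, axis2: GridSurface, axis3: GridSurface
                ) -> np.ndarray:
    """Compose three axes into an RGB image (uint8, masked cells 0-alpha).

    All three channels share one scaling span (the largest axis range),
    so the intensity spread of each channel is proportional to the
    spread of its axis.  A constant axis maps to mid-intensity 128.
    Returns an (n_rows, n_cols, 4) RGBA array.
    """
    surfaces = (axis1, axis2, axis3)
    if not (axis1.same_geometry(axis2) and axis1.same_geometry(axis3)):
        raise ValueError("axes must share grid geometry")
    mask = axis1.mask & axis2.mask & axis3.mask
    spans = [np.ptp(s.values[mask]) if mask.any() else 0.0 for s in surfaces]
    span = max(spans)
    geom = axis1.geometry
    out = np.zeros((geom.n_rows, geom.n_cols, 4), dtype=np.uint8)
    for ch, s in enumerate(surfaces):
        if span == 0 or np.ptp(s.values[mask]) == 0:
            channel = np.full(mask.sum(), 128.0)
        else:
            v = s.values[mask]
            channel = (v - v.min()) / span * 255.0
        out[..., ch][mask] = np.round(channel).astype(np.uint8)
    out[..., 3][mask] = 255
    return out
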