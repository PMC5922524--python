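"""Cluster-number estimation and K-means regionalization.

The number of floristic groups is estimated on the Cailliez-corrected
principal-coordinate scores with the L-method: the within-group sum of
squares (WGSS) is plotted against the number of clusters k, two
regression lines are fitted around every candidate knee, and the knee
minimizing the length-weighted residual standard error wins.  Because
the answer depends on the largest k included in the curve, the L-method
is repeated for every maximum k from 4 to n_sites - 1 and the modal
optimum across runs is taken as the consensus.  The final partition is a
K-means clustering of the three interpolated ordination axes over all
grid cells, deliberately blind to cell coordinates, so any spatial
cohesion in the result is carried by the data.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage


from .grids import GridGeometry, GridSurface

__all__ = ["KCurve", "KConsensus", "RegionPartition", "kmeans_partition",
           "wgss_curve", "lmethod_knee", "consensus_k", "regionalize"]

logger = logging.getLogger(__name__)


@dataclass
class KCurve:
    """Within-group sum of squares per number of clusters."""

    k: np.ndarray
    wgss: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=int)
        self.wgss = np.asarray(self.wgss, dtype=float)
        if self.k.size != self.wgss.size:
            raise ValueError("k and wgss must align")
        if np.any(np.diff(self.k) <= 0):
            raise ValueError("k must be strictly increasing")

    def truncated(self, k_max: int) -> "KCurve":
        keep = self.k <= k_max
        return KCurve(self.k[keep], self.wgss[keep])


@dataclass
class KConsensus:
    """Optimal k per maximum-k run and the modal consensus."""

    max_k_values: np.ndarray
    optimal_k: np.ndarray
    modal_k: int

    def frequency_table(self) -> pd.DataFrame:
        counts = Counter(self.optimal_k.tolist())
        return pd.DataFrame(sorted(counts.items()),
                            columns=["optimal_k", "n_runs"])


@dataclass
class RegionPartition:
    """Integer sub-region label per unmasked grid cell."""

    geometry: GridGeometry
    labels: np.ndarray           # 0 on masked cells, 1..k elsewhere
    mask: np.ndarray
    k: int

    def __post_init__(self) -> None:
        lab = self.labels[self.mask]
        if lab.size and (lab.min() < 1 or lab.max() > self.k):
            raise ValueError("labels must lie in 1..k on unmasked cells")

    def region_sizes(self) -> np.ndarray:
        return np.array([(self.labels[self.mask] == r).sum()
                         for r in range(1, self.k + 1)])

    def cohesion(self) -> np.ndarray:
        """Largest-connected-component fraction per region (rook adjacency)."""
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        out = np.empty(self.k)
        for r in range(1, self.k + 1):
            member = (self.labels == r) & self.mask
            total = member.sum()
            if total == 0:
                out[r - 1] = np.nan
                continue
            comp, n_comp = ndimage.label(member, structure=structure)
            sizes = ndimage.sum_labels(member, comp, index=np.arange(1, n_comp + 1))
            out[r - 1] = sizes.max() / total
        return out

    def site_labels(self, lons, lats) -> np.ndarray:
        """Region label at each site's grid cell."""
        out = np.empty(len(lons), dtype=int)
        for i, (lo, la) in enumerate(zip(lons, lats)):
            r, c = self.geometry.cell_of(lo, la)
            out[i] = self.labels[r, c]
        return out


def kmeans_partition(x: np.ndarray, k: int, n_starts: int = 50,
                     max_iter: int = 100, seed: int = 0
                     ) -> tuple[np.ndarray, float]:
    """Best-of-restarts Lloyd K-means; returns (labels, WGSS).

    All restarts run simultaneously as one batched Lloyd iteration with
    random-observation (Forgy) initialization per restart — the classic
    random-start scheme — which keeps the hundreds of small clusterings
    behind the consensus procedure cheap.  Empty clusters are re-seeded
    on the observation farthest from its center.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, d = x.shape
    if k > n:
        raise ValueError("k cannot exceed the number of observations")
    if k == n:
        return np.arange(k), 0.0
    if k == 1:
        mu = x.mean(axis=0)
        return np.zeros(n, dtype=int), float(np.sum((x - mu) ** 2))
    rng = np.random.default_rng(seed)
    init_idx = np.argsort(rng.random((n_starts, n)), axis=1)[:, :k]
    centers = x[init_idx]
    x2 = np.einsum("nd,nd->n", x, x)
    labels = np.full((n_starts, n), -1, dtype=np.int64)
    active = np.arange(n_starts)
    for _ in range(max_iter):
        c = centers[active]
        # squared distances via the expansion |x|^2 - 2 x.c + |c|^2
        dist2 = (x2[None, :, None] - 2.0 * np.einsum("nd,skd->snk", x, c)
                 + np.einsum("skd,skd->sk", c, c)[:, None, :])
        new_labels = dist2.argmin(axis=2)
        moved = (new_labels != labels[active]).any(axis=1)
        labels[active] = new_labels
        active = active[moved]
        if active.size == 0:
            break
        sub = labels[active]
        m = active.size
        flat = (sub + (np.arange(m) * k)[:, None]).ravel()
        counts = np.bincount(flat, minlength=m * k).reshape(m, k)
        sums = np.empty((m, k, d))
        for j in range(d):
            sums[:, :, j] = np.bincount(
                flat, weights=np.broadcast_to(x[:, j], (m, n)).ravel(),
                minlength=m * k).reshape(m, k)
        empty_s, empty_k = np.where(counts == 0)
        if empty_s.size:
            logger.debug("re-seeding %d empty clusters", empty_s.size)
            d2m = dist2[moved]
            point_d2 = np.take_along_axis(d2m, sub[:, :, None], axis=2)[:, :, 0]
            for s, ck in zip(empty_s, empty_k):
                far = int(point_d2[s].argmax())
                sums[s, ck] = x[far]
                counts[s, ck] = 1
                point_d2[s, far] = 0.0
        centers[active] = sums / counts[:, :, None]
    dist2 = (x2[None, :, None] - 2.0 * np.einsum("nd,skd->snk", x, centers)
             + np.einsum("skd,skd->sk", centers, centers)[:, None, :])
    labels = dist2.argmin(axis=2)
    inertia = np.take_along_axis(dist2, labels[:, :, None], axis=2)[:, :, 0].sum(axis=1)
    best = int(inertia.argmin())
    return labels[best].astype(int), float(max(inertia[best], 0.0))


def wgss_curve(x: np.ndarray, k_max: int, n_starts: int = 50,
               max_iter: int = 100, seed: int = 0, k_min: int = 1) -> KCurve:
    """WGSS for k = k_min..k_max, each the best of ``n_starts`` restarts.

    The curve starts at k = 1 (the total sum of squares).  On strongly
    blob-clustered data the steep convex drop from k = 1 can drag the
    left regression segment of the knee search and bias the knee low;
    ``k_min=2`` excludes that point.  On gradient-structured community
    data the k = 1 point anchors the left segment and sharpens the knee.
    """
    if k_max < 4:
        raise ValueError("k_max must be at least 4 for knee detection")
    ks = np.arange(k_min, k_max + 1)
    wgss = np.empty(ks.size)
    for i, k in enumerate(ks):
        _, wgss[i] = kmeans_partition(x, int(k), n_starts=n_starts,
                                      max_iter=max_iter, seed=seed)
    for i in range(1, wgss.size):  # guard against rare restart failures
        if wgss[i] > wgss[i - 1]:
            logger.warning("WGSS increased at k=%d; clamping (restart failure)",
                           ks[i])
            wgss[i] = wgss[i - 1]
    return KCurve(ks, wgss)


def _rse(xs: np.ndarray, ys: np.ndarray) -> float:
    """Residual standard error of a straight-line fit, sqrt(SSE/(n-2))."""
    n = xs.size
    coeff, res, *_ = np.polyfit(xs, ys, 1, full=True)
    sse = float(res[0]) if res.size else float(
        np.sum((ys - np.polyval(coeff, xs)) ** 2))
    return np.sqrt(max(sse, 0.0) / (n - 2))


def lmethod_knee(curve: KCurve) -> int:
    """L-method knee of an evaluation-metric-vs-k curve.

    Every candidate knee c (the 3rd through the antepenultimate point)
    splits the curve into a left segment [first..c] and right segment
    [c..last], sharing the knee point.  Each segment gets a straight
    least-squares line; the combined score is the segment-length-
    weighted residual standard error and the knee with the smallest
    score wins, ties going to the smallest k.
    """
    n = curve.k.size
    if n < 5:
        raise ValueError("need at least 5 curve points for a knee")
    xs, ys = curve.k.astype(float), curve.wgss
    cand_k, scores = [], []
    for c in range(2, n - 2):            # 0-based index of the knee point
        n_l, n_r = c + 1, n - c
        rse_l = _rse(xs[: c + 1], ys[: c + 1])
        rse_r = _rse(xs[c:], ys[c:])
        scores.append((n_l * rse_l + n_r * rse_r) / (n_l + n_r))
        cand_k.append(int(curve.k[c]))
    scores = np.asarray(scores)
    # ties (within fp noise of the curve scale) go to the smallest k
    tol = 1e-9 * max(1.0, float(np.abs(ys).max()))
    best = scores.min()
    return cand_k[int(np.argmax(scores <= best + tol))]


def consensus_k(scores: np.ndarray, n_starts: int = 50, max_iter: int = 100,
                seed: int = 0, max_k_cap: int | None = None,
                k_min: int = 1) -> KConsensus:
    """Modal L-method optimum over all maximum-k choices.

    One WGSS curve is computed up to the largest needed k (with
    ``n_starts`` restarts per k, which makes the curve effectively
    deterministic) and truncated to each maximum k in 4..n_sites-1; the
    modal knee across truncations is the consensus, ties to the
    smallest k.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if n < 6:
        raise ValueError("need at least 6 observations")
    hi = n - 1 if max_k_cap is None else min(n - 1, max_k_cap)
    full = wgss_curve(scores, hi, n_starts=n_starts, max_iter=max_iter,
                      seed=seed, k_min=k_min)
    max_ks, opts = [], []
    for mk in range(4, hi + 1):
        sub = full.truncated(mk)
        if sub.k.size < 5:
            continue
        max_ks.append(mk)
        opts.append(lmethod_knee(sub))
    opts = np.asarray(opts, dtype=int)
    counts = Counter(opts.tolist())
    top = max(counts.values())
    modal = min(k for k, c in counts.items() if c == top)
    return KConsensus(np.asarray(max_ks), opts, int(modal))


def regionalize(axes: list[GridSurface], k: int, n_starts: int = 50,
                max_iter: int = 100, seed: int = 0) -> RegionPartition:
    """K-means partition of grid cells on their interpolated axis values.

    Only the compositional coordinates enter the clustering — no lon/lat
    features — and labels are renumbered by descending region size.
    """
    geom = axes[0].geometry
    if any(not a.same_geometry(axes[0]) for a in axes[1:]):
        raise ValueError("axes must share geometry")
    mask = np.logical_and.reduce([a.mask for a in axes])
    x = np.column_stack([a.values[mask] for a in axes])
    if k > x.shape[0]:
        raise ValueError("k exceeds the number of unmasked cells")
    labels, _ = kmeans_partition(x, k, n_starts=n_starts, max_iter=max_iter,
                                 seed=seed)
    order = np.argsort(-np.bincount(labels, minlength=k), kind="stable")
    renum = np.empty(k, dtype=int)
    renum[order] = np.arange(1, k + 1)
    grid = np.zeros((geom.n_rows, geom.n_cols), dtype=int)
    grid[mask] = renum[labels]
    return RegionPartition(geom, grid, mask, k)
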