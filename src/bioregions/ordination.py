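"""Ordination of dissimilarity matrices.

Two complementary embeddings of the Simpson turnover matrix are used
downstream:

* non-metric multidimensional scaling (NMDS) in three dimensions, whose
  axes are interpolated and mapped — NMDS preserves only the rank order
  of dissimilarities and is assessed with Kruskal's stress-1;
* principal coordinates (PCoA) with the Cailliez correction, which adds
  the smallest constant to all off-diagonal dissimilarities that makes
  the matrix exactly Euclidean, so the full-dimensional scores reproduce
  the (corrected) observed distances — the representation required by
  the Euclidean K-means machinery that estimates the number of groups.

Stress is reported as a fraction in [0, 1]; multiply by 100 for the
percentage convention some software prints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .betadiv import DissimilarityMatrix

__all__ = ["OrdinationResult", "ShepardFit", "PcoaResult",
           "nmds", "shepard_fit", "pcoa_cailliez"]


@dataclass
class OrdinationResult:
    """An NMDS configuration with its Kruskal stress-1."""

    labels: list[str]
    scores: np.ndarray
    stress: float
    n_starts: int
    converged: bool
    seed: int


@dataclass
class ShepardFit:
    """Goodness-of-fit summaries from the Shepard diagram."""

    stress: float
    nonmetric_r2: float
    linear_r2: float


@dataclass
class PcoaResult:
    labels: list[str]
    scores: np.ndarray
    eigenvalues: np.ndarray
    cailliez_constant: float


def _kruskal_stress(delta: np.ndarray, dist: np.ndarray) -> tuple[float, np.ndarray]:
    """Stress-1 and monotone-fitted distances for condensed vectors."""
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    order = np.argsort(delta, kind="stable")
    fitted = np.empty_like(dist)
    fitted[order] = iso.fit_transform(delta[order], dist[order])
    denom = float(np.sum(dist**2))
    if denom == 0:
        return 0.0, fitted
    stress = float(np.sqrt(np.sum((dist - fitted) ** 2) / denom))
    return stress, fitted


def _principal_rotation(scores: np.ndarray) -> np.ndarray:
    """Center, rotate to principal axes, and fix axis signs."""
    x = scores - scores.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    for j in range(x.shape[1]):
        i = int(np.argmax(np.abs(x[:, j])))
        if x[i, j] < 0:
            x[:, j] = -x[:, j]
    return x


def nmds(d: DissimilarityMatrix, n_axes: int = 3, n_starts: int = 20,
         max_iter: int = 200, seed: int = 0, eps: float = 1e-6
         ) -> OrdinationResult:
    """Best-of-starts non-metric MDS of a dissimilarity matrix.

    ``n_starts`` random initializations plus one metric start (the
    classical-scaling configuration) are run through SMACOF with
    monotone regression; the configuration with the lowest Kruskal
    stress-1 wins and is rotated to its principal axes.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    dm = np.ascontiguousarray(d.d)
    rng = np.random.default_rng(seed)
    delta = d.condensed()

    candidates: list[tuple[float, np.ndarray, bool]] = []

    def _run(init, rs):
        pos, _, n_iter = smacof(
            dm, metric=False, n_components=n_axes, init=init, n_init=1,
            max_iter=max_iter, eps=eps, random_state=rs,
            normalized_stress=True, return_n_iter=True)
        dist = pdist(pos)
        stress, _ = _kruskal_stress(delta, dist)
        candidates.append((stress, pos, n_iter < max_iter))

    # metric start from classical scaling of the (uncorrected) matrix
    metric_init = _classical_scaling(dm, n_axes)
    _run(metric_init, None)
    for _ in range(n_starts):
        _run(None, int(rng.integers(0, 2**31 - 1)))

    candidates.sort(key=lambda t: t[0])
    stress, pos, conv = candidates[0]
    scores = _principal_rotation(pos)
    return OrdinationResult(list(d.labels), scores, stress, n_starts, conv, seed)


def shepard_fit(d: DissimilarityMatrix, result: OrdinationResult) -> ShepardFit:
    """Shepard-diagram fit statistics for an NMDS result.

    ``nonmetric_r2 = 1 - stress**2`` by definition of stress-1;
    ``linear_r2`` is the squared Pearson correlation between the
    monotone-fitted and the configuration distances.
    """
    delta = d.condensed()
    dist = pdist(result.scores)
    stress, fitted = _kruskal_stress(delta, dist)
    nonmetric_r2 = 1.0 - stress**2
    if np.std(fitted) == 0 or np.std(dist) == 0:
        linear_r2 = 0.0
    else:
        linear_r2 = float(np.corrcoef(fitted, dist)[0, 1] ** 2)
    return ShepardFit(stress=stress, nonmetric_r2=nonmetric_r2, linear_r2=linear_r2)


def _gower_center(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _classical_scaling(dm: np.ndarray, n_axes: int) -> np.ndarray:
    b = _gower_center(-0.5 * dm**2)
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:n_axes]
    w = np.clip(w[idx], 0.0, None)
    return v[:, idx] * np.sqrt(w)


def cailliez_constant(dm: np.ndarray) -> float:
    """Smallest additive constant making a distance matrix Euclidean.

    The constant is the largest real eigenvalue of the 2n x 2n block
    matrix [[0, 2*D1], [-I, -4*D2]] where D1 and D2 are the Gower
    double-centerings of -D^2/2 and -D/2.
    """
    n = dm.shape[0]
    d1 = _gower_center(-0.5 * dm**2)
    d2 = _gower_center(-0.5 * dm)
    block = np.block([[np.zeros((n, n)), 2.0 * d1],
                      [-np.eye(n), -4.0 * d2]])
    eig = np.linalg.eigvals(block)
    real = eig.real[np.abs(eig.imag) < 1e-8]
    c = float(real.max()) if real.size else 0.0
    return max(c, 0.0)


def pcoa_cailliez(d: DissimilarityMatrix, tol: float = 1e-8) -> PcoaResult:
    """Principal coordinates with the Cailliez negative-eigenvalue fix.

    If the input matrix is already Euclidean the constant is 0 and this
    is plain PCoA.  Otherwise the constant ``c`` is added to every
    off-diagonal dissimilarity before the eigen-decomposition, and the
    pairwise Euclidean distances among the full-space scores equal
    ``d_ij + c`` exactly (to numerical tolerance).
    """
    dm = d.d.copy()
    b = _gower_center(-0.5 * dm**2)
    w = np.linalg.eigvalsh(b)
    c = 0.0
    if w.min() < -tol:
        c = cailliez_constant(dm)
        off = ~np.eye(dm.shape[0], dtype=bool)
        dm[off] += c
        b = _gower_center(-0.5 * dm**2)
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    if w.min() < -1e-6 * max(1.0, w.max()):
        raise ValueError("matrix remains non-Euclidean after Cailliez correction")
    keep = w > tol * max(1.0, w.max())
    scores = v[:, keep] * np.sqrt(np.clip(w[keep], 0.0, None))
    return PcoaResult(list(d.labels), scores, w, c)
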