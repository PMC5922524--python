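"""Derived environmental variables and the site-level predictor table.

Variables follow the standard water–energy framing for semi-arid floras:

* Köppen aridity index ``AI = MAP / (MAT + 33)`` (mm·°C⁻¹), a joint
  water-availability/productivity proxy — low values are arid;
* historical aridity change ``HAI = AI_current − AI_LGM``, averaged over
  general circulation models (GCMs) of the last glacial maximum;
* hydric and thermal envelope change: per-cell Euclidean distance to the
  origin of a PCA of the standardized Δ-bioclimatic variables
  (current − LGM differences), computed separately for the temperature
  group (Bio1–Bio11) and the precipitation group (Bio12–Bio19), and
  averaged over GCMs.

Site-level values aggregate grid cells inside a 10-km radius buffer
around each site, and the table is screened for collinearity before
modelling.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import SiteRegistry
from .grids import GridSurface
from .spatial import haversine_km

__all__ = ["aridity_index", "historical_ai", "envelope_distance",
           "buffer_aggregate", "collinearity_screen", "vif"]

logger = logging.getLogger(__name__)


def aridity_index(map_surface: GridSurface, mat_surface: GridSurface
                  ) -> GridSurface:
    """Köppen aridity index AI = MAP / (MAT + 33) per cell."""
    if not map_surface.same_geometry(mat_surface):
        raise ValueError("MAP and MAT grids must share geometry")
    mask = map_surface.mask & mat_surface.mask
    mat = mat_surface.values
    if np.any(mat[mask] <= -33.0):
        raise ValueError("MAT <= -33 °C makes the aridity index singular")
    vals = np.zeros_like(mat)
    vals[mask] = map_surface.values[mask] / (mat[mask] + 33.0)
    return GridSurface(map_surface.geometry, vals, mask)


def historical_ai(current_ai: GridSurface,
                  lgm_ai_per_gcm: list[GridSurface]) -> GridSurface:
    """Consensus current-minus-LGM aridity change, averaged over GCMs."""
    if not lgm_ai_per_gcm:
        raise ValueError("need at least one LGM aridity layer")
    for g in lgm_ai_per_gcm:
        if not g.same_geometry(current_ai):
            raise ValueError("LGM layer geometry mismatch")
    mask = current_ai.mask.copy()
    for g in lgm_ai_per_gcm:
        mask &= g.mask
    stack = np.stack([current_ai.values - g.values for g in lgm_ai_per_gcm])
    vals = stack.mean(axis=0)
    vals[~mask] = 0.0
    return GridSurface(current_ai.geometry, vals, mask)


def envelope_distance(delta_layers: list[GridSurface]) -> GridSurface:
    """Multivariate change distance from a stack of Δ-bioclim layers.

    Cells are rows, Δ variables columns; columns are centered and scaled
    to unit variance, all principal-component axes are retained, and
    each cell's distance to the ordination origin is the Euclidean norm
    of its score vector.  With every axis kept this equals the norm of
    the standardized row — the PCA rotation cannot change it — which is
    asserted as a numerical invariant in the tests.
    """
    if len(delta_layers) < 2:
        raise ValueError("need at least two Δ layers")
    geom = delta_layers[0].geometry
    mask = delta_layers[0].mask.copy()
    for g in delta_layers[1:]:
        if not g.same_geometry(delta_layers[0]):
            raise ValueError("Δ layer geometry mismatch")
        mask &= g.mask
    x = np.column_stack([g.values[mask] for g in delta_layers])
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not np.all(keep):
        logger.warning("dropping %d zero-variance Δ variables", (~keep).sum())
    x = x[:, keep]
    if x.shape[1] == 0:
        raise ValueError("no Δ variable with variance")
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    # full-rank PCA scores: rotation by the right singular vectors
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    scores = z @ vt.T
    dist = np.linalg.norm(scores, axis=1)
    vals = np.zeros((geom.n_rows, geom.n_cols))
    vals[mask] = dist
    return GridSurface(geom, vals, mask)


def buffer_aggregate(surface: GridSurface, registry: SiteRegistry,
                     radius_km: float = 10.0, stat: str = "mean"
                     ) -> np.ndarray:
    """Per-site statistic over grid cells within a haversine buffer.

    ``stat`` is one of ``mean``, ``range``, ``cv`` (sd/|mean|).  A site
    with no unmasked cell center inside the radius is an error — the
    grid does not cover it.
    """
    if stat not in {"mean", "range", "cv"}:
        raise ValueError(f"unknown statistic '{stat}'")
    lon, lat = surface.geometry.cell_centers()
    cl, cm = lon[surface.mask], lat[surface.mask]
    vals = surface.values[surface.mask]
    dist = haversine_km(registry.lon, registry.lat, cl, cm)
    out = np.empty(len(registry))
    for i, sid in enumerate(registry.site_ids):
        sel = dist[i] <= radius_km
        if not np.any(sel):
            raise ValueError(f"site '{sid}' has no grid cells within "
                             f"{radius_km} km")
        v = vals[sel]
        if stat == "mean":
            out[i] = v.mean()
        elif stat == "range":
            out[i] = np.ptp(v)
        else:
            m = v.mean()
            out[i] = 0.0 if v.size == 1 else (v.std(ddof=1) / abs(m)
                                              if m != 0 else np.inf)
    return out


def collinearity_screen(table: pd.DataFrame, r_threshold: float = 0.75,
                        priority: list[str] | None = None
                        ) -> tuple[pd.DataFrame, list[dict]]:
    """Drop one variable from every highly correlated pair.

    Pairs are visited by descending |r|; the lower-priority member is
    dropped (priority = position in ``priority``, column order by
    default) and correlations recomputed until no pair exceeds the
    threshold.  Returns the screened table and a report of dropped
    pairs.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least two variables")
    cols = list(table.columns)
    prio = {c: i for i, c in enumerate(priority or cols)}
    rank = {c: prio.get(c, len(prio) + i) for i, c in enumerate(cols)}
    kept = list(cols)
    report: list[dict] = []
    while len(kept) >= 2:
        corr = table[kept].corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        r = corr[i, j]
        if abs(r) <= r_threshold:
            break
        a, b = kept[i], kept[j]
        drop = b if rank[a] <= rank[b] else a
        keep = a if drop == b else b
        report.append({"kept": keep, "dropped": drop, "r": float(r)})
        kept.remove(drop)
    return table[kept], report


def vif(table: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per variable, VIF_j = 1/(1 - R²_j)."""
    x = table.to_numpy(dtype=float)
    n, p = x.shape
    if p < 2:
        raise ValueError("need at least two variables")
    out = {}
    for j, col in enumerate(table.columns):
        y = x[:, j]
        others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        if r2 > 1.0 - 1e-12:
            raise ValueError(f"exact collinearity involving '{col}'")
        out[col] = 1.0 / (1.0 - r2)
    return pd.Series(out)
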