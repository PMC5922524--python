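"""Seeded synthetic landscapes with planted floristic sub-regions.

The generator emulates the situation the pipeline is built for: a
semi-arid domain whose woody flora turns over along a west–east aridity
gradient.  Annual precipitation (bio12) is a smooth longitudinal
gradient plus a Gaussian random field; mean annual temperature (bio1) is
anti-correlated with a smooth elevation field; the remaining bioclim
layers are noisy affine functions of whichever of those two governs
them.  Last-glacial-maximum (LGM) counterparts add per-GCM smooth
offsets.  Soil (sand, cation exchange capacity) and human-footprint
layers are independent random fields, deliberately uncorrelated with the
planted structure, so any model preferring them over aridity is wrong.

Planted truth: the Köppen aridity surface is sliced into ``planted_k``
quantile bands, and each species receives a Gaussian aridity niche
centered in a home band plus a circular geographic range.  Site
incidence is Bernoulli in the product of niche affinity, range
membership, and a detection ceiling ``p_max``:

    P(s at i) = p_max · exp(-(AI_i - μ_s)² / (2σ_s²)) · 1[d(i, c_s) ≤ r_s]

Aridity therefore drives both the community turnover and the region
labels, by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .data import OccurrenceTable, SiteRegistry, filter_localities
from .grids import GridGeometry, GridSurface
from .predictors import aridity_index
from .spatial import haversine_km

__all__ = ["LandscapeConfig", "EnvStack", "SyntheticTruth",
           "generate_landscape", "generate_community"]

THERMAL_BIOS = list(range(1, 12))      # bio1..bio11
HYDRIC_BIOS = list(range(12, 20))      # bio12..bio19


@dataclass
class LandscapeConfig:
    """Knobs of the synthetic landscape.

    Defaults give a 60×60 grid at 2.5 arc-min (~2.5°, the scale of a
    compact semi-arid domain), five planted sub-regions, a ~350–1600
    mm/yr precipitation gradient and moderate random-field noise.
    """

    n_rows: int = 60
    n_cols: int = 60
    cell_size_arcmin: float = 2.5
    origin_lon: float = -42.0
    origin_lat: float = -8.0
    planted_k: int = 5
    map_range: tuple[float, float] = (350.0, 1600.0)
    noise_scale: float = 0.06          # GRF sd as fraction of gradient span
    smooth_sigma: float = 6.0          # cells
    n_gcms: int = 3
    lgm_temp_offset: tuple[float, float] = (-5.0, -2.0)   # °C range over GCMs
    lgm_precip_factor: tuple[float, float] = (0.75, 0.9)  # MAP multiplier


@dataclass
class EnvStack:
    """Named environmental layers on one shared grid."""

    geometry: GridGeometry
    layers: dict[str, GridSurface]

    def __post_init__(self) -> None:
        for name, surf in self.layers.items():
            if surf.geometry != self.geometry:
                raise ValueError(f"layer '{name}' has mismatched geometry")
        masks = [s.mask for s in self.layers.values()]
        if masks and not all(np.array_equal(m, masks[0]) for m in masks[1:]):
            raise ValueError("layer masks are inconsistent")

    def __getitem__(self, name: str) -> GridSurface:
        return self.layers[name]

    def bio(self, j: int, gcm: int | None = None) -> GridSurface:
        """Current (gcm=None) or per-GCM LGM bioclim layer j."""
        return self[f"bio{j}" if gcm is None else f"lgm{gcm}_bio{j}"]

    def aridity(self, gcm: int | None = None) -> GridSurface:
        return aridity_index(self.bio(12, gcm), self.bio(1, gcm))


@dataclass
class SyntheticTruth:
    """Ground truth planted into a synthetic landscape."""

    planted_k: int
    region_of_cell: np.ndarray
    seed: int
    band_edges: np.ndarray
    niche_mu: np.ndarray | None = None
    niche_sigma: np.ndarray | None = None
    range_center: np.ndarray | None = None      # (n_species, 2) lon/lat
    range_radius: np.ndarray | None = None      # km
    site_cells: np.ndarray = field(default=None)

    def region_at(self, geometry: GridGeometry, lons, lats) -> np.ndarray:
        out = np.empty(len(lons), dtype=int)
        for i, (lo, la) in enumerate(zip(lons, lats)):
            r, c = geometry.cell_of(lo, la)
            out[i] = self.region_of_cell[r, c]
        return out


def _grf(rng: np.random.Generator, shape: tuple[int, int],
         sigma: float) -> np.ndarray:
    """Smooth Gaussian random field with unit variance."""
    noise = rng.standard_normal(shape)
    sm = gaussian_filter(noise, sigma, mode="reflect")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def generate_landscape(config: LandscapeConfig | None = None, seed: int = 0
                       ) -> tuple[EnvStack, SyntheticTruth]:
    """Build the environmental stack and the planted region truth."""
    cfg = config or LandscapeConfig()
    if cfg.planted_k < 2:
        raise ValueError("planted_k must be at least 2")
    geom = GridGeometry(cfg.origin_lon, cfg.origin_lat, cfg.cell_size_arcmin,
                        cfg.n_rows, cfg.n_cols)
    rng = np.random.default_rng(seed)
    shape = (cfg.n_rows, cfg.n_cols)
    u = np.tile(np.linspace(0.0, 1.0, cfg.n_cols), (cfg.n_rows, 1))
    lo, hi = cfg.map_range
    span = hi - lo

    def surf(vals):
        return GridSurface(geom, vals)

    layers: dict[str, GridSurface] = {}
    bio12 = lo + span * u + cfg.noise_scale * span * _grf(rng, shape,
                                                         cfg.smooth_sigma)
    bio12 = np.clip(bio12, 10.0, None)
    elevation = np.clip(450.0 + 350.0 * _grf(rng, shape, cfg.smooth_sigma),
                        20.0, None)
    bio1 = 27.0 - 0.0055 * elevation + 0.4 * _grf(rng, shape, cfg.smooth_sigma)
    layers["bio1"] = surf(bio1)
    layers["bio12"] = surf(bio12)
    layers["elevation"] = surf(elevation)

    t_z = (bio1 - bio1.mean()) / max(bio1.std(), 1e-9)
    h_z = (bio12 - bio12.mean()) / max(bio12.std(), 1e-9)
    for j in THERMAL_BIOS[1:]:
        base = 5.0 + 1.5 * j
        layers[f"bio{j}"] = surf(base + 2.0 * t_z
                                 + 0.8 * _grf(rng, shape, cfg.smooth_sigma))
    for j in HYDRIC_BIOS[1:]:
        base = 20.0 + 8.0 * j
        layers[f"bio{j}"] = surf(base + 25.0 * h_z
                                 + 10.0 * _grf(rng, shape, cfg.smooth_sigma))

    # LGM stacks: current + per-GCM smooth offsets + noise
    t_lo, t_hi = cfg.lgm_temp_offset
    p_lo, p_hi = cfg.lgm_precip_factor
    for g in range(1, cfg.n_gcms + 1):
        dt = rng.uniform(t_lo, t_hi)
        fp = rng.uniform(p_lo, p_hi)
        t_field = dt + 0.6 * _grf(rng, shape, cfg.smooth_sigma)
        p_field = fp + 0.04 * _grf(rng, shape, cfg.smooth_sigma)
        for j in THERMAL_BIOS:
            cur = layers[f"bio{j}"].values
            layers[f"lgm{g}_bio{j}"] = surf(
                cur + t_field + 0.3 * _grf(rng, shape, cfg.smooth_sigma))
        for j in HYDRIC_BIOS:
            cur = layers[f"bio{j}"].values
            layers[f"lgm{g}_bio{j}"] = surf(
                np.clip(cur * p_field
                        + 5.0 * _grf(rng, shape, cfg.smooth_sigma), 0.0, None))

    # nuisance layers, independent of the aridity construction
    layers["sand"] = surf(65.0 + 12.0 * _grf(rng, shape, cfg.smooth_sigma))
    layers["cec"] = surf(np.clip(15.0 + 6.0 * _grf(rng, shape,
                                                   cfg.smooth_sigma), 0.5, None))
    layers["footprint"] = surf(np.clip(20.0 + 10.0 * _grf(rng, shape,
                                                          cfg.smooth_sigma),
                                       0.0, None))

    stack = EnvStack(geom, layers)
    ai = stack.aridity().values
    edges = np.quantile(ai, np.linspace(0.0, 1.0, cfg.planted_k + 1))
    if np.unique(edges).size != edges.size:
        raise ValueError("planted_k exceeds the number of distinguishable "
                         "aridity bands")
    region = np.clip(np.searchsorted(edges, ai, side="right"), 1,
                     cfg.planted_k)
    truth = SyntheticTruth(cfg.planted_k, region.astype(int), seed, edges)
    return stack, truth


def generate_community(stack: EnvStack, truth: SyntheticTruth,
                       n_sites: int = 150, n_species: int = 600,
                       seed: int = 0, p_max: float = 0.6,
                       niche_width_frac: float = 0.35,
                       generalist_frac: float = 0.1,
                       range_radius_frac: tuple[float, float] = (0.3, 0.8),
                       min_species: int = 5
                       ) -> tuple[OccurrenceTable, SiteRegistry]:
    """Sample sites and draw a niche-structured incidence table.

    Sites are grid cells sampled without replacement; each species gets
    a home aridity band, a Gaussian niche of width ``niche_width_frac``
    times its band's width (a ``generalist_frac`` fraction get niches
    four times wider), and a circular geographic range.  Sites are
    re-filtered to at least ``min_species`` species, mirroring the
    treatment of real compilations.
    """
    geom = stack.geometry
    rng = np.random.default_rng(seed)
    mask = next(iter(stack.layers.values())).mask
    valid = np.flatnonzero(mask.ravel())
    if n_sites > valid.size:
        raise ValueError("more sites than unmasked cells")
    cells = np.sort(rng.choice(valid, size=n_sites, replace=False))
    rows, cols = np.unravel_index(cells, mask.shape)
    lon_g, lat_g = geom.cell_centers()
    site_lon = lon_g[rows, cols]
    site_lat = lat_g[rows, cols]
    site_ids = [f"S{i:04d}" for i in range(n_sites)]

    ai = stack.aridity().values
    site_ai = ai[rows, cols]
    k = truth.planted_k
    edges = truth.band_edges
    band_width = np.diff(edges)
    band_center = 0.5 * (edges[:-1] + edges[1:])

    home = rng.integers(0, k, size=n_species)
    mu = band_center[home] + rng.normal(0.0, 0.15, n_species) * band_width[home]
    sigma = niche_width_frac * band_width[home]
    generalist = rng.random(n_species) < generalist_frac
    sigma = np.where(generalist, 4.0 * sigma, sigma)

    lon_min, lon_max = lon_g.min(), lon_g.max()
    lat_min, lat_max = lat_g.min(), lat_g.max()
    center_lon = rng.uniform(lon_min, lon_max, n_species)
    center_lat = rng.uniform(lat_min, lat_max, n_species)
    half_diag = 0.5 * haversine_km(np.array([lon_min]), np.array([lat_min]),
                                   np.array([lon_max]),
                                   np.array([lat_max]))[0, 0]
    r_lo, r_hi = range_radius_frac
    radius = rng.uniform(r_lo, r_hi, n_species) * 2.0 * half_diag

    dist = haversine_km(site_lon, site_lat, center_lon, center_lat)
    affinity = np.exp(-((site_ai[:, None] - mu[None, :]) ** 2)
                      / (2.0 * sigma[None, :] ** 2))
    prob = p_max * affinity * (dist <= radius[None, :])
    inc = (rng.random(prob.shape) < prob).astype(np.uint8)

    present = inc.sum(axis=0) > 0
    species = [f"sp{j:04d}" for j in range(n_species)]
    table = OccurrenceTable(site_ids, [s for s, p in zip(species, present) if p],
                            inc[:, present])
    table = filter_localities(table, min_species=min_species)
    if table.n_sites < 2:
        raise ValueError("degenerate configuration: fewer than 2 sites survive")
    keep = [site_ids.index(s) for s in table.sites]
    registry = SiteRegistry(list(table.sites), site_lon[keep], site_lat[keep])

    truth.niche_mu = mu
    truth.niche_sigma = sigma
    truth.range_center = np.column_stack([center_lon, center_lat])
    truth.range_radius = radius
    truth.site_cells = cells[keep]
    return table, registry
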