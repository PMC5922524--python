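"""Configuration-driven orchestration of the full analysis.

Stages: input (synthetic landscape + community, or files) → Simpson
matrix → NMDS (+ Shepard fit) → IDW interpolation of the three axes →
RGB map → PCoA + consensus number of groups → K-means regionalization →
predictor table (buffers, collinearity screen, VIF) → MEM spatial
filters → multinomial candidate ranking (AICc) → deviance partition →
residual correlogram → group dendrogram + turnover network → PERMANOVA
comparison of classification schemes.  Every artifact lands in the
output directory and is checksummed into a JSON manifest.

Each stochastic stage receives a sub-seed derived from the run seed by a
fixed offset, so stages can be re-run in isolation and reruns are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .betadiv import (DissimilarityMatrix, pooled_incidence,
                      shared_species_counts, simpson_dissimilarity)
from .data import (OccurrenceTable, SiteRegistry, filter_localities,
                   read_occurrences, read_registry)
from .drivers import (DEFAULT_SETS, build_candidates, partition_deviance,
                      permanova_2way, rank_candidates, residual_diagnostics)
from .grids import GridSurface, write_ascii_grid
from .groups import bootstrap_support
from .ordination import nmds, pcoa_cailliez, shepard_fit
from .predictors import (aridity_index, buffer_aggregate, collinearity_screen,
                         envelope_distance, historical_ai, vif)
from .regionalization import consensus_k, regionalize
from .spatial import idw_interpolate, mem_basis, rgb_compose
from .synthetic import (THERMAL_BIOS, HYDRIC_BIOS, EnvStack, LandscapeConfig,
                        generate_community, generate_landscape)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "compare_classifications",
           "build_predictor_table"]

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets (documented contract: stages re-runnable alone)
STAGE_SEEDS = {"landscape": 0, "community": 1, "nmds": 2, "consensus": 3,
               "regionalize": 4, "mem": 5, "permanova": 6, "bootstrap": 7,
               "correlogram": 8}


@dataclass
class RunConfig:
    """All pipeline settings; YAML/JSON round-trip."""

    seed: int = 0
    output_dir: str = "bioregions_run"
    # synthetic input (used when no file paths are given)
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    n_sites: int = 150
    n_species: int = 600
    # file input (optional)
    occurrences_path: str | None = None
    registry_path: str | None = None
    min_species: int = 5
    # ordination / interpolation
    nmds_axes: int = 3
    nmds_starts: int = 20
    nmds_max_iter: int = 200
    idw_power: float = 2.0
    idw_neighbors: int | None = None
    # clustering
    kmeans_starts: int = 50
    kmeans_max_iter: int = 100
    consensus_max_k: int | None = None
    fixed_k: int | None = None
    # predictors
    buffer_radius_km: float = 10.0
    r_threshold: float = 0.75
    predictor_priority: tuple = ("AI", "HAI", "hydric_change",
                                 "thermal_change", "elevation",
                                 "elevation_cv", "sand", "cec", "footprint")
    # models / spatial filters
    mem_alpha: float = 0.05
    mem_permutations: int = 199
    max_mems: int = 8            # broadest selected MEMs used as covariates
    ridge: float = 1e-8
    # comparisons
    permanova_permutations: int = 1000
    n_physiognomy_classes: int = 3
    # group structure
    bootstrap_replicates: int = 1000

    def sub_seed(self, stage: str) -> int:
        return (self.seed * 16 + STAGE_SEEDS[stage]) % (2**31 - 1)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        land = raw.pop("landscape", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(land, dict):
            cfg.landscape = LandscapeConfig(**land)
        return cfg

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


@dataclass
class RunResult:
    """In-memory summary of a pipeline run."""

    config: RunConfig
    table: OccurrenceTable
    registry: SiteRegistry
    stack: EnvStack | None
    truth: object | None
    dissimilarity: DissimilarityMatrix
    stress: float
    nonmetric_r2: float
    linear_r2: float
    modal_k: int
    partition: object
    site_region: np.ndarray
    predictor_table: pd.DataFrame
    model_table: pd.DataFrame
    best_model: str
    deviance_partition: object
    comparison: pd.DataFrame | None
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def build_predictor_table(stack: EnvStack, registry: SiteRegistry,
                          radius_km: float = 10.0) -> pd.DataFrame:
    """Site-level predictor table from an environmental stack.

    Current aridity, consensus historical-aridity change, hydric and
    thermal envelope-change distances (per-GCM PCA distances averaged),
    elevation mean and CV, soil and footprint means — each aggregated
    over a buffer around the site.
    """
    n_gcms = len({k.split("_")[0] for k in stack.layers if k.startswith("lgm")})
    ai = stack.aridity()
    hai = historical_ai(ai, [stack.aridity(g) for g in range(1, n_gcms + 1)])

    def consensus_envelope(bios: list[int]) -> GridSurface:
        per_gcm = []
        for g in range(1, n_gcms + 1):
            deltas = [stack.bio(j).copy_with(stack.bio(j).values
                                             - stack.bio(j, g).values)
                      for j in bios]
            per_gcm.append(envelope_distance(deltas))
        mean_vals = np.mean([s.values for s in per_gcm], axis=0)
        return per_gcm[0].copy_with(mean_vals)

    thermal = consensus_envelope(THERMAL_BIOS)
    hydric = consensus_envelope(HYDRIC_BIOS)

    cols = {
        "AI": (ai, "mean"),
        "HAI": (hai, "mean"),
        "hydric_change": (hydric, "mean"),
        "thermal_change": (thermal, "mean"),
        "elevation": (stack["elevation"], "mean"),
        "elevation_cv": (stack["elevation"], "cv"),
        "sand": (stack["sand"], "mean"),
        "cec": (stack["cec"], "mean"),
        "footprint": (stack["footprint"], "mean"),
    }
    data = {name: buffer_aggregate(surface, registry, radius_km, stat)
            for name, (surface, stat) in cols.items()}
    return pd.DataFrame(data, index=registry.site_ids)


def compare_classifications(d: DissimilarityMatrix, schemes: dict[str, np.ndarray],
                            physiognomy: np.ndarray, n_perm: int = 1000,
                            seed: int = 0) -> pd.DataFrame:
    """Two-way PERMANOVA of each classification scheme against the flora.

    For every scheme a PERMANOVA with physiognomy entered first and the
    scheme second partitions the Simpson matrix; the scheme's sequential
    R² values are tabulated side by side.
    """
    rows = []
    for i, (name, labels) in enumerate(schemes.items()):
        labels = np.asarray(labels)
        if np.unique(labels).size < 2:
            raise ValueError(f"scheme '{name}' has fewer than two levels")
        tab = permanova_2way(d, physiognomy, labels, n_perm=n_perm,
                             seed=seed + i)
        by_term = tab.set_index("term")
        rows.append({
            "scheme": name,
            "n_groups": int(np.unique(labels).size),
            "R2_physiognomy": by_term.loc["A", "R2"],
            "R2_scheme": by_term.loc["B", "R2"],
            "R2_interaction": by_term.loc["AxB", "R2"],
            "p_scheme": by_term.loc["B", "p"],
            "pseudo_F_scheme": by_term.loc["B", "pseudo_F"],
        })
    return pd.DataFrame(rows)


def _region_polygons(partition) -> dict:
    """Dissolved GeoJSON feature collection of the region partition."""
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    geom = partition.geometry
    step = geom.cell_size_deg
    features = []
    for r in range(1, partition.k + 1):
        rows, cols = np.where((partition.labels == r) & partition.mask)
        boxes = [box(geom.origin_lon + c * step - step / 2,
                     geom.origin_lat - rr * step - step / 2,
                     geom.origin_lon + c * step + step / 2,
                     geom.origin_lat - rr * step + step / 2)
                 for rr, c in zip(rows, cols)]
        if not boxes:
            continue
        merged = unary_union(boxes)
        features.append({"type": "Feature",
                         "properties": {"region": int(r),
                                        "n_cells": int(len(boxes))},
                         "geometry": mapping(merged)})
    return {"type": "FeatureCollection", "features": features}


def run_pipeline(config: RunConfig | None = None) -> RunResult:
    """Execute the full analysis and write all artifacts."""
    cfg = config or RunConfig()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def save_df(df: pd.DataFrame, name: str, **kw):
        p = out / name
        df.to_csv(p, **kw)
        artifacts.append(p)

    def save_json(obj, name: str):
        p = out / name
        p.write_text(json.dumps(obj, indent=2, default=float))
        artifacts.append(p)

    # ---- stage: input -------------------------------------------------
    stack = truth = None
    if cfg.occurrences_path and cfg.registry_path:
        table = filter_localities(read_occurrences(cfg.occurrences_path),
                                  cfg.min_species)
        registry = read_registry(cfg.registry_path).subset(table.sites)
        logger.info("loaded %d sites, %d species", table.n_sites,
                    table.n_species)
    else:
        stack, truth = generate_landscape(cfg.landscape,
                                          seed=cfg.sub_seed("landscape"))
        table, registry = generate_community(
            stack, truth, n_sites=cfg.n_sites, n_species=cfg.n_species,
            seed=cfg.sub_seed("community"), min_species=cfg.min_species)
        logger.info("synthetic community: %d sites, %d species",
                    table.n_sites, table.n_species)
    pairs = table.to_frame().stack()
    pairs = pairs[pairs > 0].reset_index()[["level_0", "level_1"]]
    pairs.columns = ["site_id", "species"]
    save_df(pairs, "occurrences.csv", index=False)
    save_df(registry.to_frame(), "registry.csv", index=False)

    # ---- stage: turnover + ordination --------------------------------
    d = simpson_dissimilarity(table)
    p = out / "simpson.csv"
    d.to_csv(p)
    artifacts.append(p)
    ord_res = nmds(d, n_axes=cfg.nmds_axes, n_starts=cfg.nmds_starts,
                   max_iter=cfg.nmds_max_iter, seed=cfg.sub_seed("nmds"))
    fit = shepard_fit(d, ord_res)
    scores_df = pd.DataFrame(ord_res.scores, index=table.sites,
                             columns=[f"axis{j+1}"
                                      for j in range(cfg.nmds_axes)])
    save_df(scores_df, "nmds_scores.csv", index_label="site_id")
    save_json({"stress": fit.stress, "stress_pct": 100 * fit.stress,
               "nonmetric_r2": fit.nonmetric_r2, "linear_r2": fit.linear_r2,
               "converged": ord_res.converged, "n_starts": cfg.nmds_starts},
              "nmds_report.json")

    # ---- stage: interpolation + RGB ----------------------------------
    geometry = stack.geometry if stack is not None else _bounding_geometry(registry)
    mask = (next(iter(stack.layers.values())).mask if stack is not None
            else None)
    axes = [idw_interpolate(registry, ord_res.scores[:, j], geometry,
                            power=cfg.idw_power,
                            n_neighbors=cfg.idw_neighbors, mask=mask)
            for j in range(min(cfg.nmds_axes, 3))]
    for j, surf in enumerate(axes):
        pth = out / f"nmds_axis{j+1}.asc"
        write_ascii_grid(surf, pth)
        artifacts.append(pth)
    rgba = rgb_compose(*axes[:3]) if len(axes) >= 3 else None
    if rgba is not None:
        from PIL import Image
        pth = out / "beta_diversity_rgb.png"
        Image.fromarray(rgba, mode="RGBA").save(pth)
        artifacts.append(pth)

    # ---- stage: number of groups + regionalization -------------------
    pcoa = pcoa_cailliez(d)
    if cfg.fixed_k is not None:
        modal_k = cfg.fixed_k
        consensus_df = pd.DataFrame({"optimal_k": [modal_k], "n_runs": [0]})
    else:
        cons = consensus_k(pcoa.scores, n_starts=cfg.kmeans_starts,
                           max_iter=cfg.kmeans_max_iter,
                           seed=cfg.sub_seed("consensus"),
                           max_k_cap=cfg.consensus_max_k)
        modal_k = cons.modal_k
        consensus_df = cons.frequency_table()
    save_df(consensus_df, "consensus_k.csv", index=False)
    partition = regionalize(axes, modal_k, n_starts=cfg.kmeans_starts,
                            max_iter=cfg.kmeans_max_iter,
                            seed=cfg.sub_seed("regionalize"))
    pth = out / "regions.asc"
    write_ascii_grid(GridSurface(partition.geometry,
                                 partition.labels.astype(float),
                                 partition.mask), pth)
    artifacts.append(pth)
    save_json(_region_polygons(partition), "regions.geojson")
    site_region = partition.site_labels(registry.lon, registry.lat)

    # ---- stage: predictors -------------------------------------------
    if stack is not None:
        pred = build_predictor_table(stack, registry, cfg.buffer_radius_km)
        screened, screen_report = collinearity_screen(
            pred, cfg.r_threshold, list(cfg.predictor_priority))
        vifs = vif(screened)
        save_df(pred, "predictors.csv", index_label="site_id")
        save_json({"dropped": screen_report,
                   "kept": list(screened.columns),
                   "vif": vifs.to_dict()}, "collinearity_report.json")

        # ---- stage: driver models ------------------------------------
        mems = mem_basis(registry, alpha=cfg.mem_alpha,
                         n_perm=cfg.mem_permutations,
                         seed=cfg.sub_seed("mem"))
        mem_vectors = mems.selected_vectors()[:, :cfg.max_mems]
        sets = {name: [v for v in cols if v in screened.columns]
                for name, cols in DEFAULT_SETS.items()}
        sets = {k: v for k, v in sets.items() if v}
        candidates = build_candidates(
            sets,
            current=[s for s in ("current_climate",) if s in sets],
            historical=[s for s in ("historical_climate",) if s in sets])
        model_table = rank_candidates(site_region, screened, candidates,
                                      mem_vectors, ridge=cfg.ridge)
        save_df(model_table.table, "model_table.csv", index=False)
        best = model_table.best()
        best_fit = model_table.fits[best]
        dev_part = partition_deviance(site_region,
                                      screened[candidates[best]],
                                      mem_vectors, ridge=cfg.ridge)
        env_share, mem_share = dev_part.shares_of_explained()
        save_json({"best_model": best,
                   "total_explained": dev_part.total_explained,
                   "unique_env": dev_part.unique_env,
                   "unique_spatial": dev_part.unique_spatial,
                   "shared": dev_part.shared,
                   "unexplained": dev_part.unexplained,
                   "share_of_explained_env": env_share,
                   "share_of_explained_spatial": mem_share,
                   "n_mems_selected": int(mems.selected.size),
                   "n_mems_used": int(mem_vectors.shape[1])},
                  "deviance_partition.json")
        resid_cg = residual_diagnostics(best_fit, registry,
                                        seed=cfg.sub_seed("correlogram"))
        save_df(pd.DataFrame({"lo_km": resid_cg.bounds[:-1],
                              "hi_km": resid_cg.bounds[1:],
                              "morans_i": resid_cg.morans_i,
                              "p_holm": resid_cg.p_values,
                              "n_pairs": resid_cg.n_pairs}),
                "residual_correlogram.csv", index=False)
    else:
        pred = screened = model_table = dev_part = None
        best = ""

    # ---- stage: group structure --------------------------------------
    region_of_site = {s: int(r) for s, r in zip(table.sites, site_region)}
    network = shared_species_counts(table, region_of_site)
    save_df(network.to_frame(), "turnover_network.csv")
    if np.unique(site_region).size >= 3:
        grp_inc = pooled_incidence(table, region_of_site)
        tree = bootstrap_support(grp_inc, n_boot=cfg.bootstrap_replicates,
                                 seed=cfg.sub_seed("bootstrap"))
        pth = out / "dendrogram.nwk"
        pth.write_text(tree.to_newick() + "\n")
        artifacts.append(pth)

    # ---- stage: classification comparison ----------------------------
    comparison = None
    if stack is not None and truth is not None:
        truth_at_sites = truth.region_at(stack.geometry, registry.lon,
                                         registry.lat)
        rng = np.random.default_rng(cfg.sub_seed("permanova"))
        schemes = {
            "kmeans_regionalization": site_region,
            "planted_truth": truth_at_sites,
            "random_labels": rng.permutation(truth_at_sites),
        }
        site_ai = pred["AI"].to_numpy()
        phys = np.digitize(site_ai, np.quantile(
            site_ai, np.linspace(0, 1, cfg.n_physiognomy_classes + 1))[1:-1])
        comparison = compare_classifications(
            d, schemes, phys, n_perm=cfg.permanova_permutations,
            seed=cfg.sub_seed("permanova"))
        save_df(comparison, "classification_comparison.csv", index=False)

    # ---- manifest -----------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": {k: cfg.sub_seed(k) for k in STAGE_SEEDS},
        "config": cfg.to_dict(),
        "n_sites": table.n_sites,
        "n_species": table.n_species,
        "modal_k": int(modal_k),
        "stress": fit.stress,
        "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
    }
    save_json(manifest, "manifest.json")
    return RunResult(
        config=cfg, table=table, registry=registry, stack=stack, truth=truth,
        dissimilarity=d, stress=fit.stress, nonmetric_r2=fit.nonmetric_r2,
        linear_r2=fit.linear_r2, modal_k=int(modal_k), partition=partition,
        site_region=site_region, predictor_table=pred,
        model_table=None if model_table is None else model_table.table,
        best_model=best, deviance_partition=dev_part, comparison=comparison,
        manifest=manifest)


def _bounding_geometry(registry: SiteRegistry, cell_arcmin: float = 2.5,
                       pad_cells: int = 2):
    """Grid geometry covering a site registry (file-input mode)."""
    from .grids import GridGeometry
    step = cell_arcmin / 60.0
    lon0 = registry.lon.min() - pad_cells * step
    lat1 = registry.lat.max() + pad_cells * step
    n_cols = int(np.ceil((registry.lon.max() - lon0) / step)) + 1 + pad_cells
    n_rows = int(np.ceil((lat1 - registry.lat.min()) / step)) + 1 + pad_cells
    return GridGeometry(lon0, lat1, cell_arcmin, n_rows, n_cols)
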