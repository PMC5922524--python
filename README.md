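# bioregions

Quantitative floristic bioregionalization and environmental driver
inference from presence/absence data.

Biogeographers compiling site-by-species incidence tables for a region
face two linked questions: *how many floristic sub-regions are there,
and where are they?* and *which environmental factors — current
climate, climate history, soil, topography, human pressure — explain
the division?*  Expert-drawn regionalizations answer neither
reproducibly.  `bioregions` implements a fully quantitative pipeline
for both questions, aimed at plant community ecologists working with
compiled floristic surveys and gridded environmental layers.

## Method

1. **Turnover.** Pairwise Simpson dissimilarity between sites,
   βsim = min(b, c)/(min(b, c) + a), which isolates species turnover
   from richness differences.
2. **Ordination & mapping.** Three-dimensional NMDS of the βsim matrix
   (Kruskal stress-1, best of many starts); inverse-distance-weighted
   interpolation of the three axis scores onto a 2.5 arc-min grid; RGB
   composition so similar colors mean similar floras.
3. **Number of groups.** PCoA with the Cailliez correction embeds βsim
   exactly in Euclidean space; K-means (50 starts × 100 iterations)
   yields a WGSS-vs-k curve; the L-method (two regression lines, RSE
   minimized) finds the knee for every maximum k from 4 to n−1 and the
   modal knee is the consensus k.
4. **Regionalization.** K-means partition of the grid cells on their
   interpolated axis values only — no coordinates — then cohesion
   statistics, group dendrogram (UPGMA + species bootstrap) and a
   shared/exclusive species network.
5. **Drivers.** Multinomial logistic regression of sub-region
   membership on predictor sets (Köppen aridity AI = MAP/(MAT+33),
   historical aridity change, hydric/thermal envelope change, soil,
   topography, footprint) with Moran's Eigenvector Maps as spatial
   filters; AICc/wAICc ranking; deviance partition into unique
   environmental, unique spatial, and shared components; residual
   correlograms; and two-way PERMANOVA comparison against alternative
   classification schemes.

A seeded synthetic-landscape generator (aridity gradient, 19 current +
3×19 LGM bioclim layers, niche-structured communities with planted
sub-regions, nuisance soil/footprint layers) provides ground truth for
every recovery claim.  See `docs/methods.md` for models, defaults, and
numerical decisions.

## Worked example

```python
from bioregions import RunConfig, run_pipeline

cfg = RunConfig(seed=1, output_dir="demo_run", nmds_starts=10)
res = run_pipeline(cfg)
print("sites:", res.table.n_sites, "species:", res.table.n_species)
print(f"stress: {100*res.stress:.1f}  (nonmetric R2 {res.nonmetric_r2:.3f},"
      f" linear R2 {res.linear_r2:.3f})")
print("consensus k:", res.modal_k)
print("best driver model:", res.best_model)
```

On the default synthetic landscape (60×60 grid, 150 sites, 600 species,
5 planted aridity-band regions) this prints:

```
sites: 150 species: 574
stress: 11.3  (nonmetric R2 0.987, linear R2 0.920)
consensus k: 5
best driver model: AI
```

Reading the numbers: a stress of 11.3 (0.113 as a fraction) means the
3-D NMDS preserves the rank order of the turnover matrix well
(nonmetric R² = 1 − stress² = 0.987).  The consensus over 144 L-method
runs picks k = 5 (139 of 144 runs; the planted number), and the
partition of the interpolated surface matches the planted regions at a
cell-level adjusted Rand index of 0.76.  Among thirteen candidate
driver models the aridity-only model is AICc-best with essentially all
the Akaike weight (wAICc ≈ 0.996) — the correct answer, since the
planted regions are aridity bands and soil/footprint layers are noise.
In the PERMANOVA comparison the K-means regionalization explains 17.8%
of the floristic variation where a random relabeling explains 1.9%.

The same run from the shell:

```bash
bioregions all --seed 1 --out demo_run
```

writes `regions.asc` / `regions.geojson` (the sub-region map),
`beta_diversity_rgb.png`, `nmds_scores.csv`, `consensus_k.csv`,
`model_table.csv`, `deviance_partition.json`,
`classification_comparison.csv`, `dendrogram.nwk`,
`turnover_network.csv` and a checksummed `manifest.json`.  `simulate`,
`regionalize`, `drivers` and `compare` run the corresponding subsets;
`--config run.yaml` overrides any setting.

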