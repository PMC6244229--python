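# forestscape

Multi-scale landscape structure and forest-bird diversity analysis.

`forestscape` is a tested, reusable implementation of a common workflow in
landscape ecology: quantify the composition and configuration of the
landscape surrounding avian point-count locations at many spatial scales,
classify species into habitat guilds from their empirical occurrence
patterns, compute guild diversity measures, fit standardized linear models
with AIC-based scale-of-effect selection, and rank the relative importance
of **habitat amount**, **habitat configuration**, and **matrix quality** for
bird diversity. A synthetic-data module generates land-cover mosaics and
Poisson point counts with known ground truth, so every stage is validated
end to end without any external downloads.

It is aimed at landscape ecologists and spatial biostatisticians who work
with categorical land-cover rasters (NLCD-like class codes) and point-count
survey tables.

## The method

**Landscapes and metrics.** A landscape is a circular area of radius *r*
(default radii 0.2–16 km) centred on a count location. Per landscape the
package computes forest amount (FA, cell fraction of the forest classes),
forest patch density (FPD, 8-connected patches per km²), the forest
clumpiness index, agriculture amount (AG), the four developed-class
proportions, forest–developed edge density, Shannon cover diversity, and
statistics of co-registered elevation / population / housing surfaces. The
clumpiness index is built from rook adjacencies of the focal class,

```
G_i = g_ii / Σ_k g_ik
CLUMPY = (G_i − P_i)/P_i        if G_i < P_i and P_i < 0.5
       = (G_i − P_i)/(1 − P_i)  otherwise
```

with `P_i` the class proportion; it spans −1 (checkerboard dispersion)
through 0 (random) to +1 (one solid patch) and is undefined when
`P_i ∈ {0, 1}`.

**Composite indices.** Urbanization (URB) and high-intensity urbanization
(URBHI) are principal components of six standardized inputs (four
developed-class proportions, population density, housing density), retained
by the Kaiser–Guttman criterion (λ > 1) and sign-anchored to total developed
cover and high-intensity cover respectively. Two landscape-heterogeneity
components (H1, H2) come from a PCA of elevation mean/range, Shannon cover
diversity, and forest–developed edge density.

**Guilds.** Each species' cumulative share of individuals across locations
ranked by forest amount is compared to the cumulative share of forest
amount itself with a Kolmogorov–Smirnov statistic; significance comes from
a permutation test that shuffles the count vector over locations. Species
whose individuals significantly lag forest accumulation (concentrated in
the most-forested landscapes) are *forest-area sensitive*; those that run
significantly ahead of it are *edge/open*; the rest are *forest
generalists*.

**Diversity and models.** Per location and guild (area-sensitive,
generalist, and their union), the package computes relative abundance,
Chao1 estimated richness `S_obs + F1²/(2F2)` (bias-corrected fallback at
F2 = 0), and Pielou evenness `H′/ln S_obs`. For each of the nine responses,
one Gaussian linear model per radius (all landscape predictors at that
radius plus covariates, all standardized to mean 0 / sd 1) is fit; the
radius with the lowest AIC is the scale of effect. Effects whose 95% Wald
CI excludes zero are *meaningful*; per response, the components amount
(FA), configuration (FPD, FCI), and matrix quality (URB, URBHI, AG) are
placed first/second/third by their largest meaningful |β|, and placements
are tallied across responses into an overall importance ordering.

## Worked example

Ranking landscape-structure components from a published statewide
coefficient table shipped with the package:

```python
from forestscape import load_example_effects, tally_and_order
from forestscape.ranking import EXAMPLE_MEASURES

tally = tally_and_order(load_example_effects(), EXAMPLE_MEASURES)
print(tally.counts)
print("Overall order:", " > ".join(tally.order))
```

```
                first  second  third
amount              3       1      1
matrix quality      3       3      1
configuration       1       1      3
Overall order: amount > matrix quality > configuration
```

Forest amount carries the largest meaningful effect on three of nine
diversity measures and heads the overall ordering; matrix quality is the
most frequent runner-up, and configuration most often places third.

Computing multi-scale metrics on a simulated landscape:

```python
from forestscape import (LandscapeSimConfig, generate_landcover,
                         sample_locations, compute_metric_set)

cfg = LandscapeSimConfig(nrows=200, ncols=200, cell_size=0.03,
                         aggregation=0.6, seed=42)
raster = generate_landcover(cfg)
locs = sample_locations(raster, n=5, max_radius=1.0, seed=42)
metrics = compute_metric_set(raster, locs, radii=(0.2, 0.5, 1.0))
print(metrics[["location_id", "radius", "FA", "FPD", "FCI", "AG"]]
      .head(3).round(3).to_string(index=False))
```

```
 location_id  radius    FA    FPD   FCI    AG
           0     0.2 0.577 24.331 0.631 0.168
           0     0.5 0.567  5.068 0.630 0.149
           0     1.0 0.498  5.389 0.616 0.201
```

Each row is one location × radius: around location 0, 58% of the 0.2 km
landscape is forest, split into ~24 patches/km² with strong spatial
aggregation (FCI 0.63), and 17% is agriculture.

The full pipeline (simulate → metrics → indices → guilds → diversity →
models → ranking) runs from the command line:

```bash
forestscape all --seed 1 --outdir run/
```

writing plain CSV/JSON stage files plus `ranking.txt` and a `manifest.json`
that records the configuration hash and seed for exact replay.

## Layout

```
src/forestscape/
  raster.py       land-cover container, ASCII-grid + legend I/O
  simulate.py     neutral landscapes, surfaces, Poisson point counts
  metrics.py      circular landscapes and class-level metrics
  indices.py      urbanization / heterogeneity PCA (sklearn transformers)
  guilds.py       KS permutation guild classifier
  diversity.py    relative abundance, Chao1, Pielou per guild
  models.py       standardized OLS per scale, AIC selection, VIFs
  ranking.py      meaningful-effect placement counting
  experiments.py  seeded validation studies
  pipeline.py     stage orchestration with plain-file handoff
  cli.py          `forestscape` command-line interface
```

See `docs/methods.md` for modelling assumptions, parameter defaults, and
known limitations.
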