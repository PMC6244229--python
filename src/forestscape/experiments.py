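"""Seeded validation experiments exercising the pipeline end to end.

Each function runs a self-contained simulation study against ground truth:
brute-force agreement for the configuration metrics, standardized-effect and
scale-of-effect recovery, guild-label recovery, and full-pipeline
determinism.  They are used by the test suite and by the acceptance script;
problem sizes are chosen so each study runs in seconds to a few minutes on a
single core while leaving comfortable statistical margins.
"""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd

from .guilds import AREA_SENSITIVE, EDGE_OPEN, GENERALIST, KSGuildClassifier
from .metrics import (
    DiscMask,
    adjacency_tally,
    clumpiness,
    compute_metric_set,
    edge_density_forest_developed,
    patch_density,
)
from .models import FitResult, ModelSpec, ScaleSelectingLinearModel, fit_glm
from .pipeline import RunConfig, run_pipeline
from .raster import ClassDef, LandCoverRaster
from .simulate import (
    BirdSimConfig,
    LandscapeSimConfig,
    SpeciesSpec,
    generate_landcover,
    generate_point_counts,
    sample_locations,
)

_ORACLE_LEGEND = {
    41: ClassDef(41, "forest-deciduous", "forest"),
    22: ClassDef(22, "developed-low", "developed"),
    82: ClassDef(82, "cultivated", "agriculture"),
    52: ClassDef(52, "other", "other"),
}


# -- brute-force oracles (independent of the vectorized implementations) ------


def _flood_fill_count(focal: np.ndarray) -> int:
    seen = np.zeros_like(focal, dtype=bool)
    nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    n = 0
    nr, nc = focal.shape
    for i in range(nr):
        for j in range(nc):
            if focal[i, j] and not seen[i, j]:
                n += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    r, c = stack.pop()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < nr and 0 <= cc < nc and focal[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
    return n


def _pair_scan(grid: np.ndarray):
    """(like, total, fd_edges) by explicit neighbor scan on a full grid."""
    forest = grid == 41
    dev = grid == 22
    like = total = edges = 0
    nr, nc = grid.shape
    for i in range(nr):
        for j in range(nc):
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                r, c = i + dr, j + dc
                if not (0 <= r < nr and 0 <= c < nc):
                    continue
                if forest[i, j]:
                    total += 1
                    like += forest[r, c]
                if (dr, dc) in ((1, 0), (0, 1)):
                    if (forest[i, j] and dev[r, c]) or (dev[i, j] and forest[r, c]):
                        edges += 1
    return like, total, edges


def metric_oracle_agreement(seed: int, n_rasters: int = 100, shape=(20, 20)) -> float:
    """Fraction of random rasters where patch count, adjacency tally, edge
    density, and clumpiness all agree exactly with brute-force scans."""
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_rasters):
        grid = rng.choice([41, 22, 82, 52], p=[0.4, 0.2, 0.2, 0.2], size=shape)
        raster = LandCoverRaster(grid.astype(np.int64), dict(_ORACLE_LEGEND), 1.0)
        mask = DiscMask(0, shape[0], 0, shape[1], np.ones(shape, dtype=bool))
        area = shape[0] * shape[1]

        n_oracle = _flood_fill_count(grid == 41)
        like, total, edges = _pair_scan(grid)
        tally = adjacency_tally(mask, raster)

        p = (grid == 41).mean()
        if p in (0.0, 1.0):
            fci_oracle = float("nan")
        else:
            g = like / total if total else 0.0
            fci_oracle = (g - p) / p if (g < p and p < 0.5) else (g - p) / (1 - p)
        fci = clumpiness(tally)

        agree = (
            patch_density(mask, raster) == n_oracle / area
            and (tally.g_like, tally.g_total) == (like, total)
            and edge_density_forest_developed(mask, raster) == edges / area
            and (
                (np.isnan(fci) and np.isnan(fci_oracle))
                or fci == fci_oracle
            )
        )
        ok += agree
    return ok / n_rasters


# -- parameter recovery --------------------------------------------------------

TRUE_BETA_FA = 0.34
TRUE_BETA_AG = -0.22


def _effect_data(rng, n, sigma=1.0, rho=0.3):
    cov = np.array([[1.0, rho], [rho, 1.0]])
    X = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    fa = (X[:, 0] - X[:, 0].mean()) / X[:, 0].std(ddof=1)
    ag = (X[:, 1] - X[:, 1].mean()) / X[:, 1].std(ddof=1)
    y = TRUE_BETA_FA * fa + TRUE_BETA_AG * ag + sigma * rng.standard_normal(n)
    return pd.DataFrame({"FA": fa, "AG": ag, "y": y})


def beta_recovery(seed: int, n: int = 5000) -> FitResult:
    """One standardized OLS fit on synthetic data with known effects."""
    rng = np.random.default_rng(seed)
    spec = ModelSpec(response="y", scale=1.0, landscape_predictors=("FA", "AG"))
    return fit_glm(spec, _effect_data(rng, n))


def ci_coverage(seed: int, n_reps: int = 200, n: int = 1000) -> float:
    """Fraction of 95% CIs (both effects pooled) containing the truth."""
    rng = np.random.default_rng(seed)
    spec = ModelSpec(response="y", scale=1.0, landscape_predictors=("FA", "AG"))
    hits = trials = 0
    for _ in range(n_reps):
        res = fit_glm(spec, _effect_data(rng, n))
        for name, truth in (("FA", TRUE_BETA_FA), ("AG", TRUE_BETA_AG)):
            e = res.effect(name)
            hits += e["lo"] <= truth <= e["hi"]
            trials += 1
    return hits / trials


# -- scale-of-effect recovery --------------------------------------------------


def scale_recovery(
    seed: int,
    n_reps: int = 100,
    radii=(0.5, 1.0, 2.0),
    true_scale: float = 1.0,
    n_locations: int = 250,
) -> float:
    """Fraction of replicates where AIC selects the generating radius.

    One simulated landscape supplies forest and agriculture amounts at each
    radius; every replicate draws a fresh response from the predictors at the
    true scale (standardized effects 0.5 FA, −0.3 AG, unit noise).
    """
    lc = LandscapeSimConfig(nrows=200, ncols=200, cell_size=0.1, seed=seed)
    raster = generate_landcover(lc)
    locs = sample_locations(raster, n_locations, max(radii), seed)
    metrics = compute_metric_set(raster, locs, radii)
    X = metrics[["location_id", "radius", "FA", "AG"]]
    true = X[X["radius"] == true_scale].set_index("location_id")
    z = {}
    for c in ("FA", "AG"):
        v = true[c].to_numpy()
        z[c] = (v - v.mean()) / v.std(ddof=1)

    rng = np.random.default_rng(seed)
    wins = 0
    for _ in range(n_reps):
        y = pd.Series(
            0.5 * z["FA"] - 0.3 * z["AG"] + rng.standard_normal(len(true)),
            index=true.index, name="y",
        )
        model = ScaleSelectingLinearModel(landscape_predictors=("FA", "AG"))
        model.fit(X, y)
        wins += model.best_scale_ == true_scale
    return wins / n_reps


# -- guild recovery ------------------------------------------------------------


def guild_recovery(
    seed: int,
    n_species: int = 60,
    n_locations: int = 2000,
    n_permutations: int = 999,
    alpha: float = 0.05,
    radii=(0.25, 0.5, 1.0),
) -> float:
    """Fraction of synthetic species whose guild label is recovered.

    Species with strong positive (negative) forest-amount effects concentrate
    their individuals in the most (least) forested landscapes; species with
    no landscape effect are forest generalists under the permutation null.
    """
    lc = LandscapeSimConfig(nrows=300, ncols=300, cell_size=0.05, seed=seed)
    raster = generate_landcover(lc)
    locs = sample_locations(raster, n_locations, max(radii), seed)
    metrics = compute_metric_set(raster, locs, radii)

    kinds = [
        (AREA_SENSITIVE, {"FA": 1.2}),
        (EDGE_OPEN, {"FA": -1.2}),
        (GENERALIST, {}),
    ]
    species = []
    for i in range(n_species):
        guild, effects = kinds[i % 3]
        species.append(
            SpeciesSpec(f"sp{i:03d}", guild, dict(effects), radii[i % len(radii)])
        )
    bird = BirdSimConfig(species=species, intercept=float(np.log(2.0)), seed=seed)
    sim = generate_point_counts(metrics, bird, locs, seed)

    clf = KSGuildClassifier(alpha, n_permutations, seed)
    clf.fit(sim.counts, metrics[["location_id", "radius", "FA"]])
    correct = sum(
        clf.labels_.get(sp.name) == sp.guild for sp in species
    )
    return correct / n_species


# -- end-to-end determinism ----------------------------------------------------


def pipeline_determinism(seed: int, workdir: str | Path) -> bool:
    """Run a tiny full pipeline twice; True iff all outputs are byte-identical."""
    workdir = Path(workdir)
    cfg = dict(
        radii=(0.2, 0.5, 1.0), nrows=120, ncols=120, n_locations=150,
        n_species=9, n_permutations=99, seed=seed,
    )
    out1 = run_pipeline(RunConfig(**cfg), workdir / "run1")
    out2 = run_pipeline(RunConfig(**cfg), workdir / "run2")
    names = sorted(p.name for p in out1.iterdir())
    if names != sorted(p.name for p in out2.iterdir()):
        return False
    _, mismatch, errors = filecmp.cmpfiles(out1, out2, names, shallow=False)
    return not mismatch and not errors
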