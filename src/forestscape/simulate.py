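"""Synthetic landscapes, auxiliary surfaces, and point-count tables.

This module is the test bed for the whole pipeline: it produces a multi-class
land-cover mosaic with controllable class proportions and spatial aggregation
(a modified-random-clusters neutral landscape), correlated elevation /
population / housing surfaces, and Poisson point counts whose log-means depend
on known standardized landscape effects at a known scale.  Because the ground
truth (true effects, true scale of effect, true habitat association) is
recorded alongside the data, every downstream stage — metric extraction, PCA
indices, guild classification, scale-selecting models — can be validated
without any external data.

All randomness flows from a single top-level seed through named substreams
(``landcover`` / ``surfaces`` / ``locations`` / ``counts``), so identical
configurations reproduce bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import ClassDef, LandCoverRaster

__all__ = [
    "DEFAULT_PROPORTIONS",
    "LandscapeSimConfig",
    "SpeciesSpec",
    "BirdSimConfig",
    "PointCountSim",
    "generate_landcover",
    "generate_surfaces",
    "sample_locations",
    "generate_point_counts",
]

# NLCD-like legend: code, name, cover group
CLASS_DEFS = {
    "forest-deciduous": ClassDef(41, "forest-deciduous", "forest"),
    "forest-evergreen": ClassDef(42, "forest-evergreen", "forest"),
    "forest-mixed": ClassDef(43, "forest-mixed", "forest"),
    "developed-open": ClassDef(21, "developed-open", "developed"),
    "developed-low": ClassDef(22, "developed-low", "developed"),
    "developed-med": ClassDef(23, "developed-med", "developed"),
    "developed-high": ClassDef(24, "developed-high", "developed"),
    "cultivated": ClassDef(82, "cultivated", "agriculture"),
    "pasture": ClassDef(81, "pasture", "agriculture"),
    "other": ClassDef(52, "other", "other"),
}

#: Default class proportions: a forest-dominated mosaic with an
#: agricultural fringe and a modest development gradient, loosely patterned
#: on mid-Atlantic US land cover.
DEFAULT_PROPORTIONS = {
    "forest-deciduous": 0.35,
    "forest-evergreen": 0.05,
    "forest-mixed": 0.12,
    "developed-open": 0.06,
    "developed-low": 0.04,
    "developed-med": 0.02,
    "developed-high": 0.01,
    "cultivated": 0.12,
    "pasture": 0.11,
    "other": 0.12,
}

# Site-percolation threshold for 4-neighbor lattices; the aggregation knob
# scales the marking probability toward (but never past) this point.
_PERCOLATION_LIMIT = 0.5927

_STREAMS = {"landcover": 0, "surfaces": 1, "locations": 2, "counts": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class LandscapeSimConfig:
    """Configuration of the neutral-landscape generator.

    ``aggregation`` in [0, 1] controls spatial clumping: 0 gives an i.i.d.
    random mosaic, values near 1 grow large single-class clusters.
    """

    nrows: int = 200
    ncols: int = 200
    cell_size: float = 0.03  # km; NLCD-like 30 m cells
    proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    aggregation: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.nrows < 8 or self.ncols < 8:
            raise ConfigError("grid must be at least 8x8")
        if not 0.0 <= self.aggregation <= 1.0:
            raise ConfigError("aggregation must lie in [0, 1]")
        unknown = set(self.proportions) - set(CLASS_DEFS)
        if unknown:
            raise ConfigError(f"unknown land-cover classes: {sorted(unknown)}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class proportions sum to {total!r}, expected 1")
        if any(p < 0 for p in self.proportions.values()):
            raise ConfigError("class proportions must be nonnegative")


def generate_landcover(config: LandscapeSimConfig) -> LandCoverRaster:
    """Generate a categorical mosaic by the modified-random-clusters method.

    Cells are first marked i.i.d. with probability proportional to the
    aggregation parameter and grouped into 4-connected clusters; unmarked
    cells join their nearest cluster.  Patches are then assigned to classes
    greedily against the configured area quotas, which keeps realized class
    fractions close to the targets at any aggregation level.
    """
    config.validate()
    rng = _rng(config.seed, "landcover")
    shape = (config.nrows, config.ncols)
    n_cells = shape[0] * shape[1]

    p_mark = _PERCOLATION_LIMIT * config.aggregation
    if p_mark > 0:
        marked = rng.random(shape) < p_mark
    else:
        marked = np.zeros(shape, dtype=bool)

    if marked.any():
        labels, n_lab = ndimage.label(marked)  # 4-connectivity default
        if not marked.all():
            # every unmarked cell adopts the label of its nearest marked cell
            idx = ndimage.distance_transform_edt(
                ~marked, return_distances=False, return_indices=True
            )
            labels = labels[tuple(idx)]
        patch_ids = labels.ravel() - 1
        n_patches = n_lab
    else:
        patch_ids = np.arange(n_cells)
        n_patches = n_cells

    patch_sizes = np.bincount(patch_ids, minlength=n_patches)

    names = sorted(config.proportions)
    targets = np.array([config.proportions[n] for n in names]) * n_cells
    deficits = targets.astype(float)
    assigned = np.empty(n_patches, dtype=np.int64)
    order = rng.permutation(n_patches)
    for pid in order:
        k = int(np.argmax(deficits))
        assigned[pid] = k
        deficits[k] -= patch_sizes[pid]

    codes = np.array([CLASS_DEFS[n].code for n in names])
    grid = codes[assigned[patch_ids]].reshape(shape)
    legend = {c.code: c for c in CLASS_DEFS.values()}
    return LandCoverRaster(grid, legend, config.cell_size)


# -- auxiliary surfaces --------------------------------------------------------

#: Relative development intensity by class, used to shape the population and
#: housing density surfaces.
_DEV_INTENSITY = {21: 0.25, 22: 0.5, 23: 0.75, 24: 1.0}

_BACKGROUND_POP = 2.0  # people / km^2 away from development
_PEAK_POP = 2500.0  # people / km^2 under solid high-intensity development
_PERSONS_PER_HOUSEHOLD = 2.4


def generate_surfaces(
    raster: LandCoverRaster, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Elevation, population density, and housing density surfaces.

    Elevation is a smooth Gaussian random field (m a.s.l.).  Population and
    housing densities increase with smoothed local development intensity plus
    multiplicative lognormal noise, so an undeveloped raster yields a flat
    background and developed blocks stand out.  Deterministic given the seed.
    """
    rng = _rng(seed, "surfaces")
    shape = raster.shape

    sigma_elev = max(shape) / 16
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_elev)
    sd = field_.std()
    if sd > 0:
        field_ = field_ / sd
    elevation = 450.0 + 150.0 * field_

    intensity = np.zeros(shape)
    for code, w in _DEV_INTENSITY.items():
        intensity[raster.grid == code] = w
    smooth = ndimage.gaussian_filter(intensity, sigma=2.0)
    noise_pop = np.exp(rng.normal(0.0, 0.3, shape))
    population = _BACKGROUND_POP + _PEAK_POP * smooth * noise_pop
    noise_house = np.exp(rng.normal(0.0, 0.1, shape))
    housing = (
        _BACKGROUND_POP / _PERSONS_PER_HOUSEHOLD
        + (_PEAK_POP / _PERSONS_PER_HOUSEHOLD) * smooth * noise_pop * noise_house
    )
    return elevation, population, housing


# -- point counts --------------------------------------------------------------

HABITAT_POOL = ("forest", "edge", "open", "wetland")
SEASON_WINDOW = (145, 185)  # Julian days: late May through early July
YEAR_POOL = (2004, 2005, 2006, 2007, 2008, 2009)


@dataclass
class SpeciesSpec:
    """One simulated species: guild label, true effects, true scale."""

    name: str
    guild: str  # "area-sensitive" | "generalist" | "edge-open"
    effects: dict[str, float]  # predictor -> true standardized beta
    scale: float  # radius (map units) at which the effects act


@dataclass
class BirdSimConfig:
    """Generative model for point counts.

    Counts are Poisson with log-mean = intercept + sum of true standardized
    landscape effects at each species' true scale + small additive survey
    terms (observer, start time, date, year, habitat, land-use change).
    """

    species: list[SpeciesSpec] = field(default_factory=list)
    intercept: float = math.log(2.0)
    observer_pool: int = 20
    observer_sd: float = 0.1
    time_effect: float = -0.05
    date_effect: float = -0.05
    year_effect: float = 0.0
    landuse_change_effect: float = -0.1
    habitat_effects: dict[str, float] = field(
        default_factory=lambda: {"forest": 0.1, "edge": 0.0, "open": -0.1, "wetland": 0.0}
    )
    seed: int = 0

    def validate(self, radii: list[float] | None = None) -> None:
        for sp in self.species:
            for beta in sp.effects.values():
                if not math.isfinite(beta):
                    raise ConfigError(f"non-finite effect for species {sp.name!r}")
            if radii is not None and not any(
                math.isclose(sp.scale, r) for r in radii
            ):
                raise ConfigError(
                    f"species {sp.name!r} true scale {sp.scale} is not among "
                    f"the configured radii {radii}"
                )


@dataclass
class PointCountSim:
    """Simulated survey: long count table, location table, and ground truth."""

    counts: pd.DataFrame  # location_id, species, count (count > 0 rows only)
    locations: pd.DataFrame  # location_id, x, y + survey covariates
    truth: dict  # species -> {guild, scale, effects}


def sample_locations(
    raster: LandCoverRaster, n: int, max_radius: float, seed: int
) -> pd.DataFrame:
    """Sample ``n`` distinct cell-center locations ≥ ``max_radius`` from the edge.

    Mirrors a border-exclusion rule: every sampled point is surrounded by a
    complete landscape at the largest configured radius.
    """
    margin = int(math.ceil(max_radius / raster.cell_size)) + 1
    nrow, ncol = raster.shape
    if nrow - 2 * margin <= 0 or ncol - 2 * margin <= 0:
        raise ConfigError(
            f"raster too small for margin of {margin} cells at radius {max_radius}"
        )
    rows = np.arange(margin, nrow - margin)
    cols = np.arange(margin, ncol - margin)
    n_avail = len(rows) * len(cols)
    if n > n_avail:
        raise ConfigError(f"requested {n} locations but only {n_avail} interior cells")
    rng = _rng(seed, "locations")
    flat = rng.choice(n_avail, size=n, replace=False)
    rr = rows[flat // len(cols)]
    cc = cols[flat % len(cols)]
    x, y = raster.rowcol_to_xy(rr, cc)
    return pd.DataFrame(
        {"location_id": np.arange(n), "x": x, "y": y, "row": rr, "col": cc}
    )


def _survey_covariates(n: int, config: BirdSimConfig, rng: np.random.Generator):
    obs = rng.integers(0, config.observer_pool, n)
    start = rng.uniform(0.0, 300.0, n)  # minutes after 05:00
    date = rng.integers(SEASON_WINDOW[0], SEASON_WINDOW[1] + 1, n)
    year = rng.choice(YEAR_POOL, n)
    habitat = rng.choice(HABITAT_POOL, n)
    luc = (rng.random(n) < 0.1).astype(int)
    return pd.DataFrame(
        {
            "observer": [f"obs{i:02d}" for i in obs],
            "start_time": start,
            "julian_date": date,
            "year": year,
            "dominant_habitat": habitat,
            "landuse_change": luc,
        }
    )


def _zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=1) if len(v) > 1 else 0.0
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def generate_point_counts(
    metrics: pd.DataFrame,
    config: BirdSimConfig,
    locations: pd.DataFrame,
    seed: int,
) -> PointCountSim:
    """Draw Poisson counts for every species at every location.

    ``metrics`` is the tidy per-location × radius table from
    :func:`forestscape.metrics.compute_metric_set`; each species reads its
    predictors at its own true scale, standardized across locations.
    """
    radii = sorted(metrics["radius"].unique()) if len(metrics) else []
    config.validate(radii if radii else None)
    rng = _rng(seed, "counts")
    n = len(locations)

    schema_counts = pd.DataFrame(
        {"location_id": pd.Series(dtype=np.int64), "species": pd.Series(dtype=str),
         "count": pd.Series(dtype=np.int64)}
    )
    if n == 0:
        loc_out = locations.copy()
        for c in ("observer", "start_time", "julian_date", "year",
                  "dominant_habitat", "landuse_change"):
            loc_out[c] = pd.Series(dtype=object)
        truth = {sp.name: {"guild": sp.guild, "scale": sp.scale,
                           "effects": dict(sp.effects)} for sp in config.species}
        return PointCountSim(schema_counts, loc_out, truth)

    survey = _survey_covariates(n, config, rng)
    loc_out = pd.concat([locations.reset_index(drop=True), survey], axis=1)

    observer_effects = rng.normal(0.0, config.observer_sd, config.observer_pool)
    obs_idx = survey["observer"].str.slice(3).astype(int).to_numpy()
    eta_survey = (
        observer_effects[obs_idx]
        + config.time_effect * _zscore(survey["start_time"].to_numpy())
        + config.date_effect * _zscore(survey["julian_date"].to_numpy())
        + config.year_effect * _zscore(survey["year"].to_numpy())
        + config.landuse_change_effect * survey["landuse_change"].to_numpy()
        + survey["dominant_habitat"].map(config.habitat_effects).to_numpy(dtype=float)
    )

    # standardized predictors per scale, aligned to the location order
    z_by_scale: dict[float, pd.DataFrame] = {}
    for r in radii:
        sub = metrics[metrics["radius"] == r].set_index("location_id")
        sub = sub.loc[loc_out["location_id"].to_numpy()]
        z_by_scale[r] = sub.apply(
            lambda col: _zscore(col.to_numpy()) if col.dtype.kind == "f" else col
        )

    rows = []
    truth = {}
    for sp in config.species:
        eta = np.full(n, config.intercept) + eta_survey
        if sp.effects:
            r = next(rr for rr in radii if math.isclose(rr, sp.scale))
            z = z_by_scale[r]
            for pred, beta in sp.effects.items():
                if pred not in z.columns:
                    raise ConfigError(
                        f"predictor {pred!r} for species {sp.name!r} absent from metrics"
                    )
                eta = eta + beta * z[pred].to_numpy(dtype=float)
        counts = rng.poisson(np.exp(eta))
        nz = counts > 0
        if nz.any():
            rows.append(pd.DataFrame({
                "location_id": loc_out["location_id"].to_numpy()[nz],
                "species": sp.name,
                "count": counts[nz],
            }))
        truth[sp.name] = {"guild": sp.guild, "scale": sp.scale,
                          "effects": dict(sp.effects)}

    counts_df = (
        pd.concat(rows, ignore_index=True) if rows else schema_counts
    )
    return PointCountSim(counts_df, loc_out, truth)
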