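"""End-to-end orchestration with plain-file handoff between stages.

Every stage reads and writes ordinary files (ASCII grids, CSV, JSON), so
each is individually re-runnable and testable; a manifest records the
configuration hash, seed, and package version needed to replay a run.
Identical configuration and seed produce byte-identical outputs.

Stages, in order:

``simulate``  land-cover raster + surfaces + locations + point counts
``metrics``   per-location × radius landscape metrics (long CSV)
``indices``   per-scale PCA scores: URB, URBHI (when retained), H1, H2
``guilds``    KS guild classification of species (full location set)
``diversity`` nine diversity measures per location
``fit``       standardized models per response with AIC scale selection
``rank``      component placements and overall importance ordering
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import ALL_FOREST, diversity_table
from .guilds import AREA_SENSITIVE, GENERALIST, KSGuildClassifier, filter_species
from .indices import HeterogeneityIndex, UrbanizationIndex
from .metrics import compute_metric_set
from .models import ScaleSelectingLinearModel, select_locations
from .ranking import tally_and_order
from .raster import read_ascii_grid, write_ascii_grid
from .simulate import (
    BirdSimConfig,
    ConfigError,
    LandscapeSimConfig,
    SpeciesSpec,
    generate_landcover,
    generate_point_counts,
    generate_surfaces,
    sample_locations,
)

log = logging.getLogger("forestscape")

GUILD_ABBR = {ALL_FOREST: "AF", AREA_SENSITIVE: "AS", GENERALIST: "FG"}

#: Responses modelled with the negative-inverse transform (right-skewed
#: counts/richness); all others use the identity.
NEGATIVE_INVERSE_RESPONSES = ("AS_RA", "AS_SR", "FG_SR")


class DataError(ValueError):
    """A stage input failed validation."""


@dataclass
class RunConfig:
    """Full pipeline configuration (simulate mode)."""

    radii: tuple[float, ...] = (0.2, 0.5, 1.0)
    seed: int = 0
    nrows: int = 200
    ncols: int = 200
    cell_size: float = 0.03
    aggregation: float = 0.6
    proportions: dict | None = None
    n_locations: int = 300
    n_species: int = 8
    intercept: float = float(np.log(2.0))
    species: list[dict] = field(default_factory=list)
    alpha: float = 0.05
    n_permutations: int = 999
    min_locations: int = 30
    min_forest: float = 0.5
    connectivity: int = 8
    strict_inverse: bool = False
    covariates_per_scale: tuple[str, ...] = ("H1", "H2")
    covariates_continuous: tuple[str, ...] = (
        "start_time", "julian_date", "year",
    )
    covariates_categorical: tuple[str, ...] = (
        "observer", "dominant_habitat", "landuse_change",
    )

    def __post_init__(self) -> None:
        self.radii = tuple(float(r) for r in self.radii)
        if list(self.radii) != sorted(set(self.radii)):
            raise ConfigError("radii must be strictly increasing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _default_species(config: RunConfig) -> list[SpeciesSpec]:
    """A mixed community: area-sensitive, edge/open, and generalist species.

    Strong positive (negative) forest-amount effects make individuals
    concentrate in the most (least) forested landscapes; generalists carry
    no landscape effect.  True scales rotate through the configured radii.
    """
    specs = []
    kinds = [
        (AREA_SENSITIVE, {"FA": 1.0}),
        ("edge-open", {"FA": -1.0}),
        (GENERALIST, {}),
    ]
    for i in range(config.n_species):
        guild, effects = kinds[i % 3]
        scale = config.radii[i % len(config.radii)]
        specs.append(SpeciesSpec(f"sp{i:03d}", guild, dict(effects), scale))
    return specs


def _species_from_config(config: RunConfig) -> list[SpeciesSpec]:
    if not config.species:
        return _default_species(config)
    return [
        SpeciesSpec(s["name"], s["guild"], dict(s.get("effects", {})),
                    float(s["scale"]))
        for s in config.species
    ]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


class Pipeline:
    """Run stages into an output directory with plain-file handoff."""

    def __init__(self, config: RunConfig, outdir: str | Path):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)

    # -- stages ----------------------------------------------------------------

    def simulate(self) -> None:
        c = self.config
        lc = LandscapeSimConfig(
            nrows=c.nrows, ncols=c.ncols, cell_size=c.cell_size,
            aggregation=c.aggregation, seed=c.seed,
            **({"proportions": dict(c.proportions)} if c.proportions else {}),
        )
        raster = generate_landcover(lc)
        write_ascii_grid(self.outdir / "landcover.asc", raster.grid,
                         raster.cell_size, raster.origin, raster.legend)
        elev, pop, house = generate_surfaces(raster, c.seed)
        for name, surf in (("elevation", elev), ("population", pop),
                           ("housing", house)):
            write_ascii_grid(self.outdir / f"{name}.asc", surf,
                             raster.cell_size, raster.origin)
        locations = sample_locations(raster, c.n_locations, max(c.radii), c.seed)
        metrics = compute_metric_set(
            raster, locations, c.radii,
            {"elevation": elev, "population": pop, "housing": house},
            c.connectivity,
        )
        bird = BirdSimConfig(species=_species_from_config(c),
                             intercept=c.intercept, seed=c.seed)
        sim = generate_point_counts(metrics, bird, locations, c.seed)
        _write_csv(sim.locations, self.outdir / "locations.csv")
        _write_csv(sim.counts, self.outdir / "counts.csv")
        (self.outdir / "truth.json").write_text(
            json.dumps(sim.truth, indent=2, sort_keys=True)
        )
        # cache the wide metric table for downstream stages
        _write_csv(metrics, self.outdir / "metrics_wide.csv")

    def metrics(self) -> None:
        """Long-form metric CSV (location, radius, metric, value)."""
        wide = self._read("metrics_wide.csv")
        long = wide.melt(
            id_vars=["location_id", "radius"], var_name="metric",
            value_name="value",
        )
        _write_csv(long, self.outdir / "metrics.csv")

    def indices(self) -> None:
        wide = self._read("metrics_wide.csv")
        frames = []
        report = {}
        for r in self.config.radii:
            sub = wide[wide["radius"] == r].reset_index(drop=True)
            urb = UrbanizationIndex().fit(sub)
            het = HeterogeneityIndex().fit(sub)
            scores = pd.concat(
                [sub[["location_id", "radius"]],
                 urb.score_frame(sub), het.score_frame(sub)], axis=1,
            )
            frames.append(scores)
            report[str(r)] = {
                "urbanization": {
                    "eigenvalues": urb.eigenvalues_.tolist(),
                    "variance_fractions": urb.variance_fractions_.tolist(),
                    "loadings": urb.loadings_.tolist(),
                    "n_retained": urb.n_retained_,
                },
                "heterogeneity": {
                    "eigenvalues": het.eigenvalues_.tolist(),
                    "loadings": het.loadings_.tolist(),
                },
            }
        out = pd.concat(frames, ignore_index=True)
        if "URBHI" not in out.columns:
            out["URBHI"] = np.nan
        _write_csv(out, self.outdir / "indices.csv")
        (self.outdir / "pca_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )

    def guilds(self) -> None:
        c = self.config
        counts = self._read("counts.csv")
        wide = self._read("metrics_wide.csv")
        retained = filter_species(counts, c.min_locations)
        if not retained:
            raise DataError("no species pass the occurrence filter")
        clf = KSGuildClassifier(c.alpha, c.n_permutations, c.seed)
        clf.fit(counts[counts["species"].isin(retained)],
                wide[["location_id", "radius", "FA"]])
        ev = clf.evidence_.copy()
        ev["final_label"] = ev["species"].map(clf.labels_)
        _write_csv(ev, self.outdir / "guilds.csv")

    def diversity(self) -> None:
        counts = self._read("counts.csv")
        guilds = self._read("guilds.csv")
        locations = self._read("locations.csv")
        guild_of = (
            guilds.drop_duplicates("species").set_index("species")["final_label"]
            .to_dict()
        )
        div = diversity_table(
            counts[counts["species"].isin(guild_of)], guild_of,
            locations["location_id"].to_numpy(),
        )
        _write_csv(div, self.outdir / "diversity.csv")

    def fit(self) -> None:
        c = self.config
        wide = self._read("metrics_wide.csv")
        idx = self._read("indices.csv")
        locations = self._read("locations.csv")
        div = self._read("diversity.csv")

        X = wide.merge(idx, on=["location_id", "radius"], how="left")
        fa_small = (
            wide[wide["radius"] == min(c.radii)]
            .set_index("location_id")["FA"]
        )
        raster = read_ascii_grid(self.outdir / "landcover.asc")
        selected = select_locations(
            locations, fa_small, raster.bounds(), max(c.radii), c.min_forest
        )
        if len(selected) < 30:
            raise DataError(
                f"only {len(selected)} locations pass the landscape filter"
            )
        sel_ids = selected["location_id"].to_numpy()
        Xs = X[X["location_id"].isin(sel_ids)]
        cov = selected.set_index("location_id")

        all_fits = []
        aic_report = {}
        for guild, abbr in GUILD_ABBR.items():
            sub = div[div["guild"] == guild].set_index("location_id")
            for measure in ("RA", "SR", "J"):
                name = f"{abbr}_{measure}"
                y = sub[measure].reindex(sel_ids)
                y.name = name
                transform = (
                    "negative-inverse" if name in NEGATIVE_INVERSE_RESPONSES
                    else "identity"
                )
                model = ScaleSelectingLinearModel(
                    covariates_per_scale=c.covariates_per_scale,
                    covariates_continuous=c.covariates_continuous,
                    covariates_categorical=c.covariates_categorical,
                    response_transform=transform,
                    strict_inverse=c.strict_inverse,
                )
                try:
                    model.fit(Xs, y, cov.reset_index())
                except ValueError as exc:
                    # a response can be unfittable on sparse communities
                    # (e.g. evenness undefined when a guild has one species)
                    log.warning("skipping response %s: %s", name, exc)
                    aic_report[name] = {"skipped": str(exc)}
                    continue
                for r, res in model.results_.items():
                    eff = res.effects.copy()
                    eff.insert(0, "measure", name)
                    eff.insert(1, "radius", r)
                    eff["aic"] = res.aic
                    eff["n"] = res.n
                    eff["best"] = r == model.best_scale_
                    eff["vif"] = eff["predictor"].map(res.vif)
                    all_fits.append(eff)
                aic_report[name] = {
                    "best_scale": model.best_scale_,
                    "aic": {str(k): v.aic for k, v in model.results_.items()},
                    "n": model.n_used_,
                }
        if not all_fits:
            raise DataError("no diversity response could be modelled")
        fits = pd.concat(all_fits, ignore_index=True)
        _write_csv(fits, self.outdir / "fits.csv")
        (self.outdir / "model_report.json").write_text(
            json.dumps(aic_report, indent=2, sort_keys=True)
        )

    def rank(self) -> None:
        fits = self._read("fits.csv")
        best = fits[fits["best"]]
        table = best.loc[
            best["predictor"].isin(("FA", "FPD", "FCI", "URB", "URBHI", "AG")),
            ["measure", "predictor", "beta", "lo", "hi"],
        ]
        measures = sorted(fits["measure"].unique())
        tally = tally_and_order(table, measures)
        counts = tally.counts.reset_index(names="component")
        _write_csv(counts, self.outdir / "placements.csv")
        lines = ["Relative importance of landscape-structure components", ""]
        for i, comp in enumerate(tally.order, 1):
            row = tally.counts.loc[comp]
            lines.append(
                f"{i}. {comp}: {row['first']} first, {row['second']} second, "
                f"{row['third']} third placements"
            )
        (self.outdir / "ranking.txt").write_text("\n".join(lines) + "\n")
        (self.outdir / "ranking.json").write_text(
            json.dumps({"order": list(tally.order),
                        "per_measure": tally.per_measure}, indent=2)
        )

    # -- orchestration ---------------------------------------------------------

    STAGES = ("simulate", "metrics", "indices", "guilds", "diversity", "fit", "rank")

    def run_all(self) -> Path:
        for stage in self.STAGES:
            t0 = time.perf_counter()
            try:
                getattr(self, stage)()
            except Exception as exc:
                raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)
        manifest = {
            "config": asdict(self.config),
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "version": __version__,
            "stages": list(self.STAGES),
        }
        (self.outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str)
        )
        return self.outdir

    def _read(self, name: str) -> pd.DataFrame:
        path = self.outdir / name
        if not path.exists():
            raise DataError(f"missing stage input {name}; run earlier stages first")
        return pd.read_csv(path)


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Run every stage into ``outdir`` and return it."""
    return Pipeline(config, outdir).run_all()


def validate_inputs(
    raster_path: str | Path,
    locations_path: str | Path,
    counts_path: str | Path,
) -> dict:
    """Check ingested inputs; returns a report of per-file pass/fail messages."""
    report: dict[str, list[str]] = {"pass": [], "fail": []}
    try:
        raster = read_ascii_grid(raster_path, categorical=True)
        report["pass"].append(f"{raster_path}: raster and legend OK")
    except Exception as exc:
        report["fail"].append(f"{raster_path}: {exc}")
        report["ok"] = False
        return report
    try:
        loc = pd.read_csv(locations_path)
        missing = {"location_id", "x", "y"} - set(loc.columns)
        if missing:
            report["fail"].append(f"{locations_path}: missing columns {sorted(missing)}")
        else:
            xmin, ymin, xmax, ymax = raster.bounds()
            bad = loc[
                (loc["x"] < xmin) | (loc["x"] > xmax)
                | (loc["y"] < ymin) | (loc["y"] > ymax)
            ]
            if len(bad):
                for lid in bad["location_id"]:
                    report["fail"].append(
                        f"{locations_path}: location {lid} outside raster extent"
                    )
            else:
                report["pass"].append(f"{locations_path}: schema and containment OK")
    except Exception as exc:
        report["fail"].append(f"{locations_path}: {exc}")
    try:
        counts = pd.read_csv(counts_path)
        missing = {"location_id", "species", "count"} - set(counts.columns)
        if missing:
            report["fail"].append(f"{counts_path}: missing columns {sorted(missing)}")
        else:
            report["pass"].append(f"{counts_path}: schema OK")
    except Exception as exc:
        report["fail"].append(f"{counts_path}: {exc}")
    report["ok"] = not report["fail"]
    return report
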