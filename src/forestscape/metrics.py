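"""Class-level landscape metrics inside circular landscapes.

Landscapes are discs centered on survey points.  A cell belongs to a disc
when its *center* lies within the radius.  Composition metrics (forest
amount, agriculture amount, developed-class proportions, Shannon cover
diversity) are cell fractions; configuration metrics follow the standard
class-level raster definitions: patch density from 8-connected components,
and the clumpiness index from 4-neighbor (rook) adjacency tallies,

    G_i = g_ii / sum_k g_ik
    CLUMPY = (G_i - P_i) / P_i        if G_i < P_i and P_i < 0.5
           = (G_i - P_i) / (1 - P_i)  otherwise,

undefined (NaN) when the focal class covers none or all of the landscape.
Adjacencies are tallied from each focal cell to its rook neighbors inside
the disc (ordered pairs), without the double-count boundary correction some
implementations apply at extreme proportions; a brute-force oracle in the
test suite pins the contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .raster import LandCoverRaster

__all__ = [
    "DEFAULT_RADII_KM",
    "BoundaryError",
    "DiscMask",
    "ClassAdjacencyTally",
    "extract_landscape",
    "forest_amount",
    "agriculture_amount",
    "group_proportion",
    "class_proportions",
    "patch_density",
    "adjacency_tally",
    "clumpiness",
    "edge_density_forest_developed",
    "shannon_cover_diversity",
    "surface_stats",
    "compute_metric_set",
]

#: The ten analysis radii (km), spanning territory to dispersal scales.
DEFAULT_RADII_KM = (0.2, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 16.0)

#: Developed-class metric columns, from the NLCD-like legend.
DEVELOPED_COLUMNS = {
    "dev_open": 21,
    "dev_low": 22,
    "dev_med": 23,
    "dev_high": 24,
}


class BoundaryError(ValueError):
    """A requested disc crosses the raster boundary."""


class RegistrationError(ValueError):
    """A surface does not share the raster's grid."""


@dataclass
class DiscMask:
    """A circular landscape as a window into the raster grid.

    ``local`` is a boolean array over the window ``[row0:row1, col0:col1]``
    marking cells whose centers fall inside the disc.
    """

    row0: int
    row1: int
    col0: int
    col1: int
    local: np.ndarray

    @property
    def n_cells(self) -> int:
        return int(self.local.sum())

    def window(self, grid: np.ndarray) -> np.ndarray:
        return grid[self.row0 : self.row1, self.col0 : self.col1]

    def extract(self, grid: np.ndarray) -> np.ndarray:
        """Values of the grid at disc cells (1-D)."""
        return self.window(grid)[self.local]


def extract_landscape(
    raster: LandCoverRaster, center: tuple[float, float], radius: float
) -> DiscMask:
    """Cells whose centers lie within ``radius`` of ``center`` (map units).

    Raises :class:`BoundaryError` when the disc extends past the raster
    extent — callers pre-filter locations so that landscapes are complete.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    x, y = center
    xmin, ymin, xmax, ymax = raster.bounds()
    if x - radius < xmin or x + radius > xmax or y - radius < ymin or y + radius > ymax:
        raise BoundaryError(
            f"disc at ({x}, {y}) with radius {radius} crosses the raster boundary"
        )
    rc, cc = raster.xy_to_rowcol(x, y)
    r_cells = radius / raster.cell_size
    row0 = max(int(np.floor(rc - r_cells)), 0)
    row1 = min(int(np.ceil(rc + r_cells)) + 1, raster.shape[0])
    col0 = max(int(np.floor(cc - r_cells)), 0)
    col1 = min(int(np.ceil(cc + r_cells)) + 1, raster.shape[1])
    rows = np.arange(row0, row1)
    cols = np.arange(col0, col1)
    dr = (rows - rc)[:, None]
    dc = (cols - cc)[None, :]
    local = dr * dr + dc * dc <= r_cells * r_cells
    if not local.any():
        # a disc smaller than half a cell still contains its own cell center
        raise BoundaryError("disc contains no cell centers")
    return DiscMask(row0, row1, col0, col1, local)


# -- composition ---------------------------------------------------------------


def group_proportion(mask: DiscMask, raster: LandCoverRaster, group: str) -> float:
    """Fraction of disc cells in a cover group."""
    codes = raster.codes_in_group(group)
    if not codes:
        return 0.0
    vals = mask.extract(raster.grid)
    return float(np.isin(vals, list(codes)).mean())


def forest_amount(mask: DiscMask, raster: LandCoverRaster) -> float:
    """Proportional forest area of the landscape."""
    return group_proportion(mask, raster, "forest")


def agriculture_amount(mask: DiscMask, raster: LandCoverRaster) -> float:
    """Proportional agricultural area (cultivated + pasture) of the landscape."""
    return group_proportion(mask, raster, "agriculture")


def class_proportions(mask: DiscMask, raster: LandCoverRaster) -> dict[int, float]:
    """Fraction of disc cells per class code (codes present only)."""
    vals = mask.extract(raster.grid)
    codes, counts = np.unique(vals, return_counts=True)
    n = vals.size
    return {int(c): float(k) / n for c, k in zip(codes, counts)}


def shannon_cover_diversity(mask: DiscMask, raster: LandCoverRaster) -> float:
    """Shannon diversity (nats) of land-cover classes within the disc."""
    p = np.array(list(class_proportions(mask, raster).values()))
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


# -- configuration -------------------------------------------------------------


def patch_density(
    mask: DiscMask, raster: LandCoverRaster, connectivity: int = 8, group: str = "forest"
) -> float:
    """Patches of a cover group per unit landscape area (per km² in km units).

    Patches are connected components (8-neighbor by default) of group cells
    restricted to the disc.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    focal = mask.window(raster.group_mask(group)) & mask.local
    n_patches = measure.label(
        focal, connectivity=1 if connectivity == 4 else 2, return_num=True
    )[1]
    area = mask.n_cells * raster.cell_area
    return n_patches / area


@dataclass(frozen=True)
class ClassAdjacencyTally:
    """Rook-adjacency tally for a focal class within a landscape.

    ``g_like`` counts focal→focal neighbor relations and ``g_total`` all
    focal→any relations, each counted once per ordered (focal, neighbor)
    pair with both cells inside the disc.
    """

    proportion: float  # P_i, focal-class fraction of disc cells
    g_like: int  # g_ii
    g_total: int  # sum_k g_ik

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError(f"class proportion {self.proportion} outside [0, 1]")
        if not 0 <= self.g_like <= self.g_total:
            raise ValueError("adjacency counts must satisfy 0 <= g_like <= g_total")


def adjacency_tally(
    mask: DiscMask, raster: LandCoverRaster, group: str = "forest"
) -> ClassAdjacencyTally:
    """Tally rook adjacencies of a cover group inside the disc."""
    inside = mask.local
    focal = mask.window(raster.group_mask(group)) & inside
    g_like = 0
    g_total = 0
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb_in = _shift(inside, dr, dc)
        nb_focal = _shift(focal, dr, dc)
        g_total += int((focal & nb_in).sum())
        g_like += int((focal & nb_focal).sum())
    p = focal.sum() / inside.sum()
    return ClassAdjacencyTally(float(p), g_like, g_total)


def _shift(a: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Boolean array shifted by (dr, dc) with False fill (no wraparound)."""
    out = np.zeros_like(a)
    src_r = slice(max(-dr, 0), a.shape[0] - max(dr, 0))
    src_c = slice(max(-dc, 0), a.shape[1] - max(dc, 0))
    dst_r = slice(max(dr, 0), a.shape[0] - max(-dr, 0))
    dst_c = slice(max(dc, 0), a.shape[1] - max(-dc, 0))
    out[dst_r, dst_c] = a[src_r, src_c]
    return out


def clumpiness(tally: ClassAdjacencyTally) -> float:
    """Clumpiness index in [-1, 1]; NaN when the class covers 0% or 100%.

    -1 is maximal dispersion (checkerboard), 0 a random mosaic, +1 a single
    solid patch.
    """
    p = tally.proportion
    if p == 0.0 or p == 1.0:
        return float("nan")
    g = tally.g_like / tally.g_total if tally.g_total > 0 else 0.0
    if g < p and p < 0.5:
        return (g - p) / p
    return (g - p) / (1.0 - p)


def edge_density_forest_developed(mask: DiscMask, raster: LandCoverRaster) -> float:
    """Forest–developed shared edge length per unit landscape area.

    Shared rook edges between forest and developed cells (both inside the
    disc) have length ``cell_size`` each; density is length / disc area.
    """
    inside = mask.local
    forest = mask.window(raster.group_mask("forest")) & inside
    dev = mask.window(raster.group_mask("developed")) & inside
    n_edges = 0
    for dr, dc in ((1, 0), (0, 1)):  # unordered pairs: two directions suffice
        n_edges += int((forest & _shift(dev, dr, dc)).sum())
        n_edges += int((dev & _shift(forest, dr, dc)).sum())
    area = mask.n_cells * raster.cell_area
    return n_edges * raster.cell_size / area


# -- continuous surfaces -------------------------------------------------------


def surface_stats(mask: DiscMask, surface: np.ndarray) -> tuple[float, float]:
    """(mean, max − min) of a co-registered surface over disc cells."""
    surface = np.asarray(surface)
    if surface.shape[0] < mask.row1 or surface.shape[1] < mask.col1:
        raise RegistrationError(
            f"surface shape {surface.shape} does not cover the disc window"
        )
    vals = mask.extract(surface)
    return float(vals.mean()), float(vals.max() - vals.min())


# -- the per-location × scale metric table ------------------------------------


def compute_metric_set(
    raster: LandCoverRaster,
    locations: pd.DataFrame,
    radii: tuple[float, ...] | list[float] = DEFAULT_RADII_KM,
    surfaces: dict[str, np.ndarray] | None = None,
    connectivity: int = 8,
) -> pd.DataFrame:
    """Compute all landscape metrics per location and radius.

    ``locations`` needs ``location_id``, ``x``, ``y`` columns.  ``surfaces``
    may provide ``elevation``, ``population`` and ``housing`` grids
    co-registered with the raster.  Returns a tidy frame with one row per
    location × radius.
    """
    surfaces = surfaces or {}
    records = []
    for loc in locations.itertuples(index=False):
        for r in radii:
            mask = extract_landscape(raster, (loc.x, loc.y), r)
            tally = adjacency_tally(mask, raster)
            props = class_proportions(mask, raster)
            rec = {
                "location_id": loc.location_id,
                "radius": float(r),
                "FA": forest_amount(mask, raster),
                "FPD": patch_density(mask, raster, connectivity),
                "FCI": clumpiness(tally),
                "AG": agriculture_amount(mask, raster),
                "ED": edge_density_forest_developed(mask, raster),
                "SHDI": shannon_cover_diversity(mask, raster),
            }
            for col, code in DEVELOPED_COLUMNS.items():
                rec[col] = props.get(code, 0.0)
            if "elevation" in surfaces:
                m, rg = surface_stats(mask, surfaces["elevation"])
                rec["elev_mean"], rec["elev_range"] = m, rg
            if "population" in surfaces:
                rec["pop_density"] = surface_stats(mask, surfaces["population"])[0]
            if "housing" in surfaces:
                rec["housing_density"] = surface_stats(mask, surfaces["housing"])[0]
            records.append(rec)
    return pd.DataFrame.from_records(records)
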