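"""Categorical land-cover raster container and plain-text I/O.

The raster is a single-band integer grid with a legend mapping class codes to
class names and cover groups (forest / developed / agriculture / other).
Coordinates follow the usual GIS convention: ``(x, y)`` map units with *y*
increasing northward, so row 0 is the northernmost row.  I/O uses the ESRI
ASCII grid format with a JSON legend sidecar, so every artifact on disk is
human-readable text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ClassDef", "LandCoverRaster", "read_ascii_grid", "write_ascii_grid"]

#: Cover groups every legend entry must belong to.
COVER_GROUPS = ("forest", "developed", "agriculture", "other")


@dataclass(frozen=True)
class ClassDef:
    """One land-cover class: integer code, name, and cover group."""

    code: int
    name: str
    group: str

    def __post_init__(self) -> None:
        if self.group not in COVER_GROUPS:
            raise ValueError(
                f"unknown cover group {self.group!r} for class {self.name!r}; "
                f"expected one of {COVER_GROUPS}"
            )


@dataclass
class LandCoverRaster:
    """Categorical grid plus legend, cell size and origin.

    Parameters
    ----------
    grid
        2-D integer array of class codes; row 0 is the northern edge.
    legend
        Mapping ``code -> ClassDef`` covering every code present in the grid.
    cell_size
        Cell edge length in map units (> 0).  Map units are kilometres
        throughout this package unless stated otherwise.
    origin
        ``(x, y)`` map coordinates of the *center* of cell ``(0, 0)``.
    """

    grid: np.ndarray
    legend: dict[int, ClassDef]
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("grid must hold integer class codes")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        present = set(np.unique(self.grid).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"grid codes missing from legend: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def codes_in_group(self, group: str) -> frozenset[int]:
        """All legend codes belonging to a cover group."""
        if group not in COVER_GROUPS:
            raise ValueError(f"unknown cover group {group!r}")
        return frozenset(c.code for c in self.legend.values() if c.group == group)

    def group_mask(self, group: str) -> np.ndarray:
        """Boolean grid marking cells of a cover group."""
        codes = self.codes_in_group(group)
        if not codes:
            return np.zeros(self.grid.shape, dtype=bool)
        return np.isin(self.grid, list(codes))

    # -- coordinate transforms -------------------------------------------------

    def rowcol_to_xy(self, row: np.ndarray, col: np.ndarray):
        """Map coordinates of cell centers (y decreases with row index)."""
        x0, y0 = self.origin
        return x0 + np.asarray(col) * self.cell_size, y0 - np.asarray(row) * self.cell_size

    def xy_to_rowcol(self, x: float, y: float) -> tuple[float, float]:
        """Fractional (row, col) of a map coordinate."""
        x0, y0 = self.origin
        return (y0 - y) / self.cell_size, (x - x0) / self.cell_size

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster extent (cell edges)."""
        nrow, ncol = self.grid.shape
        x0, y0 = self.origin
        half = self.cell_size / 2
        return (
            x0 - half,
            y0 - (nrow - 1) * self.cell_size - half,
            x0 + (ncol - 1) * self.cell_size + half,
            y0 + half,
        )


def write_ascii_grid(
    path: str | Path,
    grid: np.ndarray,
    cell_size: float,
    origin: tuple[float, float] = (0.0, 0.0),
    legend: dict[int, ClassDef] | None = None,
    nodata: float = -9999,
) -> None:
    """Write a grid as an ESRI ASCII raster; legend goes to a JSON sidecar."""
    path = Path(path)
    grid = np.asarray(grid)
    nrow, ncol = grid.shape
    half = cell_size / 2
    xll = origin[0] - half
    yll = origin[1] - (nrow - 1) * cell_size - half
    integer = np.issubdtype(grid.dtype, np.integer)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncol}\n")
        fh.write(f"nrows {nrow}\n")
        fh.write(f"xllcorner {xll!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {cell_size!r}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in grid:
            if integer:
                fh.write(" ".join(str(int(v)) for v in row))
            else:
                fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")
    if legend is not None:
        sidecar = path.with_suffix(path.suffix + ".legend.json")
        payload = {
            str(c.code): {"name": c.name, "group": c.group} for c in legend.values()
        }
        sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_ascii_grid(path: str | Path, categorical: bool | None = None):
    """Read an ESRI ASCII grid.

    Returns a :class:`LandCoverRaster` when a ``.legend.json`` sidecar exists
    (or ``categorical=True``), otherwise the tuple ``(array, cell_size,
    origin)`` for continuous surfaces.
    """
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    cell = header["cellsize"]
    nrow = int(header["nrows"])
    origin = (
        header["xllcorner"] + cell / 2,
        header["yllcorner"] + (nrow - 1) * cell + cell / 2,
    )
    arr = np.array(rows)
    sidecar = path.with_suffix(path.suffix + ".legend.json")
    if categorical is None:
        categorical = sidecar.exists()
    if not categorical:
        return arr, cell, origin
    if not sidecar.exists():
        raise FileNotFoundError(f"legend sidecar not found: {sidecar}")
    raw = json.loads(sidecar.read_text())
    legend = {
        int(code): ClassDef(int(code), spec["name"], spec["group"])
        for code, spec in raw.items()
    }
    return LandCoverRaster(arr.astype(np.int64), legend, cell, origin)
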