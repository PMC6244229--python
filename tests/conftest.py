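"""Shared fixtures: tiny rasters, full-rectangle landscape masks, and
brute-force oracles (flood fill, pair scans) that pin the metric contracts."""

from __future__ import annotations

import numpy as np
import pytest

from forestscape.metrics import DiscMask
from forestscape.raster import ClassDef, LandCoverRaster

# single representative code per cover group, for compact test rasters
CODE = {"F": 41, "D": 22, "A": 82, "O": 52}
TEST_LEGEND = {
    41: ClassDef(41, "forest-deciduous", "forest"),
    42: ClassDef(42, "forest-evergreen", "forest"),
    43: ClassDef(43, "forest-mixed", "forest"),
    21: ClassDef(21, "developed-open", "developed"),
    22: ClassDef(22, "developed-low", "developed"),
    23: ClassDef(23, "developed-med", "developed"),
    24: ClassDef(24, "developed-high", "developed"),
    82: ClassDef(82, "cultivated", "agriculture"),
    81: ClassDef(81, "pasture", "agriculture"),
    52: ClassDef(52, "other", "other"),
}


def raster_from_rows(rows: list[str], cell_size: float = 1.0) -> LandCoverRaster:
    """Build a raster from strings of F/D/A/O group letters."""
    grid = np.array([[CODE[ch] for ch in row] for row in rows], dtype=np.int64)
    return LandCoverRaster(grid, dict(TEST_LEGEND), cell_size)


def full_mask(shape: tuple[int, int]) -> DiscMask:
    """A rectangular landscape covering the whole grid."""
    return DiscMask(0, shape[0], 0, shape[1], np.ones(shape, dtype=bool))


def random_raster(rng: np.random.Generator, shape=(20, 20), cell_size=1.0,
                  p_forest=0.4, p_dev=0.2, p_ag=0.2) -> LandCoverRaster:
    codes = rng.choice(
        [41, 22, 82, 52],
        p=[p_forest, p_dev, p_ag, 1 - p_forest - p_dev - p_ag],
        size=shape,
    )
    return LandCoverRaster(codes.astype(np.int64), dict(TEST_LEGEND), cell_size)


# -- brute-force oracles -------------------------------------------------------


def oracle_patch_count(focal: np.ndarray, connectivity: int = 8) -> int:
    """Flood-fill component count, independent of the labeling library."""
    focal = np.asarray(focal, dtype=bool)
    seen = np.zeros_like(focal)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    n = 0
    for i in range(focal.shape[0]):
        for j in range(focal.shape[1]):
            if focal[i, j] and not seen[i, j]:
                n += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    r, c = stack.pop()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < focal.shape[0]
                            and 0 <= cc < focal.shape[1]
                            and focal[rr, cc]
                            and not seen[rr, cc]
                        ):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
    return n


def oracle_adjacency(focal: np.ndarray, inside: np.ndarray) -> tuple[int, int]:
    """(like, total) ordered rook adjacencies from focal cells, pair scan."""
    like = total = 0
    nr, nc = focal.shape
    for i in range(nr):
        for j in range(nc):
            if not (focal[i, j] and inside[i, j]):
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                r, c = i + dr, j + dc
                if 0 <= r < nr and 0 <= c < nc and inside[r, c]:
                    total += 1
                    if focal[r, c]:
                        like += 1
    return like, total


def oracle_edge_pairs(a: np.ndarray, b: np.ndarray, inside: np.ndarray) -> int:
    """Unordered rook pairs with one cell in a, the other in b (pair scan)."""
    n = 0
    nr, nc = a.shape
    for i in range(nr):
        for j in range(nc):
            if not inside[i, j]:
                continue
            for dr, dc in ((1, 0), (0, 1)):
                r, c = i + dr, j + dc
                if 0 <= r < nr and 0 <= c < nc and inside[r, c]:
                    if (a[i, j] and b[r, c]) or (b[i, j] and a[r, c]):
                        n += 1
    return n


def oracle_disc_cells(shape, center_rc, r_cells) -> np.ndarray:
    """Boolean grid of cells whose centers lie within r_cells of center."""
    out = np.zeros(shape, dtype=bool)
    for i in range(shape[0]):
        for j in range(shape[1]):
            if (i - center_rc[0]) ** 2 + (j - center_rc[1]) ** 2 <= r_cells**2:
                out[i, j] = True
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
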