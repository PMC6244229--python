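"""Landscape-metric contracts against hand counts and brute-force oracles."""

import numpy as np
import pytest

from forestscape.metrics import (
    BoundaryError,
    ClassAdjacencyTally,
    adjacency_tally,
    agriculture_amount,
    clumpiness,
    edge_density_forest_developed,
    extract_landscape,
    forest_amount,
    patch_density,
    shannon_cover_diversity,
    surface_stats,
)

from conftest import (
    full_mask,
    oracle_adjacency,
    oracle_disc_cells,
    oracle_edge_pairs,
    oracle_patch_count,
    random_raster,
    raster_from_rows,
)


class TestDiscExtraction:
    def test_subcell_radius_contains_exactly_one_cell(self):
        r = raster_from_rows(["FFFF"] * 4)
        x, y = r.rowcol_to_xy(np.array([2]), np.array([2]))
        mask = extract_landscape(r, (float(x[0]), float(y[0])), 0.4)
        assert mask.n_cells == 1

    @pytest.mark.parametrize("radius", [1.5, 3.0, 4.2])
    def test_matches_brute_force_distance_scan(self, radius):
        r = raster_from_rows(["F" * 15] * 15)
        x, y = r.rowcol_to_xy(np.array([7]), np.array([7]))
        mask = extract_landscape(r, (float(x[0]), float(y[0])), radius)
        expected = oracle_disc_cells((15, 15), (7, 7), radius)
        got = np.zeros((15, 15), dtype=bool)
        got[mask.row0 : mask.row1, mask.col0 : mask.col1] = mask.local
        assert np.array_equal(got, expected)

    def test_disc_overlapping_edge_raises(self):
        r = raster_from_rows(["F" * 10] * 10)
        x, y = r.rowcol_to_xy(np.array([1]), np.array([5]))
        with pytest.raises(BoundaryError):
            extract_landscape(r, (float(x[0]), float(y[0])), 3.0)


class TestComposition:
    def test_all_forest_is_one(self):
        r = raster_from_rows(["FFFF"] * 4)
        assert forest_amount(full_mask((4, 4)), r) == 1.0

    def test_direct_ratio(self):
        rows = ["FFDDD", "FFDDD", "DDDDD", "DDDDD", "DDDDD"]
        r = raster_from_rows(rows)
        assert forest_amount(full_mask((5, 5)), r) == pytest.approx(4 / 25)

    def test_agriculture_half(self):
        r = raster_from_rows(["AAFF"] * 4)
        m = full_mask((4, 4))
        assert agriculture_amount(m, r) == 0.5
        assert forest_amount(m, r) == 0.5

    def test_no_agriculture_is_zero(self):
        r = raster_from_rows(["FFDD"] * 4)
        assert agriculture_amount(full_mask((4, 4)), r) == 0.0

    def test_random_raster_matches_recount(self, rng):
        for _ in range(20):
            r = random_raster(rng)
            m = full_mask(r.shape)
            assert forest_amount(m, r) == pytest.approx((r.grid == 41).mean())
            assert agriculture_amount(m, r) == pytest.approx((r.grid == 82).mean())

    def test_group_proportions_sum_to_one(self, rng):
        from forestscape.metrics import group_proportion

        for _ in range(20):
            r = random_raster(rng)
            m = full_mask(r.shape)
            total = sum(
                group_proportion(m, r, g)
                for g in ("forest", "developed", "agriculture", "other")
            )
            assert total == pytest.approx(1.0, abs=1e-9)


class TestShannonDiversity:
    def test_single_class_zero(self):
        r = raster_from_rows(["FFFF"] * 4)
        assert shannon_cover_diversity(full_mask((4, 4)), r) == 0.0

    def test_two_equal_classes_ln2(self):
        r = raster_from_rows(["FFDD"] * 4)
        assert shannon_cover_diversity(full_mask((4, 4)), r) == pytest.approx(
            np.log(2)
        )

    def test_four_equal_classes_ln4(self):
        r = raster_from_rows(["FDAO"] * 4)
        assert shannon_cover_diversity(full_mask((4, 4)), r) == pytest.approx(
            np.log(4)
        )


class TestPatchDensity:
    def test_single_cell_patch(self):
        rows = ["DDDDD", "DDDDD", "DDFDD", "DDDDD", "DDDDD"]
        r = raster_from_rows(rows)
        assert patch_density(full_mask((5, 5)), r) == pytest.approx(1 / 25)

    def test_opposite_corners_two_patches(self):
        rows = ["FDDD", "DDDD", "DDDD", "DDDF"]
        r = raster_from_rows(rows)
        assert patch_density(full_mask((4, 4)), r) == pytest.approx(2 / 16)

    def test_no_forest_zero(self):
        r = raster_from_rows(["DDDD"] * 4)
        assert patch_density(full_mask((4, 4)), r) == 0.0

    def test_diagonal_joined_under_8_but_not_4_connectivity(self):
        rows = ["FDD", "DFD", "DDF"]
        r = raster_from_rows(rows)
        m = full_mask((3, 3))
        assert patch_density(m, r, connectivity=8) == pytest.approx(1 / 9)
        assert patch_density(m, r, connectivity=4) == pytest.approx(3 / 9)


class TestClumpiness:
    def test_checkerboard_is_minus_one(self):
        rows = ["FDFD", "DFDF", "FDFD", "DFDF"]
        r = raster_from_rows(rows)
        t = adjacency_tally(full_mask((4, 4)), r)
        assert t.proportion == 0.5
        assert t.g_like == 0
        assert clumpiness(t) == pytest.approx(-1.0)

    def test_solid_block_hand_count(self):
        rows = ["DDDD", "DFFD", "DFFD", "DDDD"]
        r = raster_from_rows(rows)
        t = adjacency_tally(full_mask((4, 4)), r)
        assert (t.proportion, t.g_like, t.g_total) == (0.25, 8, 16)
        assert clumpiness(t) == pytest.approx((0.5 - 0.25) / 0.75)

    def test_undefined_at_full_coverage(self):
        r = raster_from_rows(["FFFF"] * 4)
        assert np.isnan(clumpiness(adjacency_tally(full_mask((4, 4)), r)))

    def test_undefined_at_zero_coverage(self):
        r = raster_from_rows(["DDDD"] * 4)
        assert np.isnan(clumpiness(adjacency_tally(full_mask((4, 4)), r)))

    def test_invalid_tally_rejected(self):
        with pytest.raises(ValueError):
            ClassAdjacencyTally(1.2, 0, 0)
        with pytest.raises(ValueError):
            ClassAdjacencyTally(0.5, 5, 4)

    def test_bounded_when_defined(self, rng):
        for _ in range(50):
            r = random_raster(rng, shape=(12, 12))
            v = clumpiness(adjacency_tally(full_mask((12, 12)), r))
            if not np.isnan(v):
                assert -1.0 <= v <= 1.0

    def test_solid_block_reaches_one_only_with_all_like_adjacencies(self):
        rows = ["OOOO", "OFFO", "OFFO", "OOOO"]
        r = raster_from_rows(rows)
        # forest cells also touch non-forest: g_like < g_total, FCI < 1
        t = adjacency_tally(full_mask((4, 4)), r)
        assert clumpiness(t) < 1.0
        # full-like tally at partial coverage would give exactly 1
        assert clumpiness(ClassAdjacencyTally(0.5, 10, 10)) == pytest.approx(1.0)


class TestEdgeDensity:
    def test_no_developed_zero(self):
        r = raster_from_rows(["FFAA"] * 4)
        assert edge_density_forest_developed(full_mask((4, 4)), r) == 0.0

    def test_surrounded_cell_hand_count(self):
        rows = ["DDD", "DFD", "DDD"]
        r = raster_from_rows(rows)
        assert edge_density_forest_developed(full_mask((3, 3)), r) == pytest.approx(
            4 / 9
        )


class TestSurfaceStats:
    def test_constant_surface(self):
        r = raster_from_rows(["FFFF"] * 4)
        m = full_mask(r.shape)
        mean, rng_ = surface_stats(m, np.full(r.shape, 7.5))
        assert (mean, rng_) == (7.5, 0.0)

    def test_linear_field_range(self):
        m = full_mask((3, 4))
        surface = np.repeat(np.arange(3.0)[:, None], 4, axis=1)
        assert surface_stats(m, surface) == (1.0, 2.0)

    def test_matches_recomputation(self, rng):
        m = full_mask((10, 10))
        s = rng.normal(size=(10, 10))
        mean, range_ = surface_stats(m, s)
        assert mean == pytest.approx(s.mean())
        assert range_ == pytest.approx(s.max() - s.min())

    def test_shape_mismatch_raises(self):
        from forestscape.metrics import RegistrationError

        with pytest.raises(RegistrationError):
            surface_stats(full_mask((10, 10)), np.zeros((5, 5)))


class TestOracles:
    """The labeling/adjacency/edge routines equal brute-force scans."""

    def test_random_rasters_match_all_oracles(self, rng):
        for _ in range(100):
            r = random_raster(rng, shape=(20, 20))
            m = full_mask((20, 20))
            forest = r.grid == 41
            dev = r.grid == 22
            inside = m.local

            n_oracle = oracle_patch_count(forest, 8)
            assert patch_density(m, r) == pytest.approx(n_oracle / 400)

            like, total = oracle_adjacency(forest, inside)
            t = adjacency_tally(m, r)
            assert (t.g_like, t.g_total) == (like, total)

            edges = oracle_edge_pairs(forest, dev, inside)
            assert edge_density_forest_developed(m, r) == pytest.approx(edges / 400)

    def test_metrics_invariant_to_rotation(self, rng):
        from forestscape.raster import LandCoverRaster
        from conftest import TEST_LEGEND

        for _ in range(10):
            r = random_raster(rng, shape=(14, 14))
            rot = LandCoverRaster(
                np.ascontiguousarray(np.rot90(r.grid)), dict(TEST_LEGEND), 1.0
            )
            m = full_mask((14, 14))
            assert forest_amount(m, r) == forest_amount(m, rot)
            assert patch_density(m, r) == patch_density(m, rot)
            t1, t2 = adjacency_tally(m, r), adjacency_tally(m, rot)
            assert (t1.g_like, t1.g_total) == (t2.g_like, t2.g_total)
            assert edge_density_forest_developed(
                m, r
            ) == edge_density_forest_developed(m, rot)
            assert shannon_cover_diversity(m, r) == pytest.approx(
                shannon_cover_diversity(m, rot)
            )

    def test_metrics_invariant_to_translation(self, rng):
        """The same disc contents give the same metrics wherever they sit."""
        base = random_raster(rng, shape=(9, 9))
        big = np.full((21, 21), 52, dtype=np.int64)
        from forestscape.raster import LandCoverRaster
        from conftest import TEST_LEGEND

        vals = {}
        for off in (0, 6, 12):
            grid = big.copy()
            grid[off : off + 9, off : off + 9] = base.grid
            r = LandCoverRaster(grid, dict(TEST_LEGEND), 1.0)
            x, y = r.rowcol_to_xy(np.array([off + 4]), np.array([off + 4]))
            mask = extract_landscape(r, (float(x[0]), float(y[0])), 4.0)
            vals[off] = (
                forest_amount(mask, r),
                patch_density(mask, r),
                clumpiness(adjacency_tally(mask, r)),
            )
        assert vals[0] == vals[6] == vals[12]
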