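"""Garden polygon product: polygonize, filters, areas, density."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from mulchmap import synthetic_scene as sc
from mulchmap.geo_io import GridTransform, LabelRaster
from mulchmap.gardens import (GardenPolygon, GardenPolygonSet,
                              apply_exclusion_mask, filter_min_area,
                              kernel_density, polygonize, total_area)

PX = 3.7
CELL = PX * PX  # 13.69 m^2


def label_raster(mask, class_names=("other", "mulch"), pixel_size=PX):
    labels = np.where(np.asarray(mask, bool), 1, 0).astype(np.int16)
    tf = GridTransform(pixel_size, 0.0, labels.shape[0] * pixel_size)
    return LabelRaster(labels, list(class_names), tf)


def flood_fill_components(mask):
    """Brute-force 4-connected component enumeration (oracle)."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if mask[r0, c0] and not seen[r0, c0]:
                stack, cells = [(r0, c0)], []
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    cells.append((r, c))
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < mask.shape[0]
                                and 0 <= cc < mask.shape[1]
                                and mask[rr, cc] and not seen[rr, cc]):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
                comps.append(cells)
    return comps


class TestPolygonize:
    def test_block_area(self):
        mask = np.zeros((4, 4), bool)
        mask[1:3, 1:3] = True
        ps = polygonize(label_raster(mask))
        assert len(ps) == 1
        assert ps.polygons[0].area_m2 == pytest.approx(4 * CELL)  # 54.76
        assert ps.polygons[0].geometry.area == pytest.approx(4 * CELL)

    def test_diagonal_cells_are_separate_components(self):
        mask = np.eye(2, dtype=bool)
        ps = polygonize(label_raster(mask))
        assert len(ps) == 2
        ps8 = polygonize(label_raster(mask), connectivity=8)
        assert len(ps8) == 1

    def test_no_target_cells_gives_empty_set(self):
        ps = polygonize(label_raster(np.zeros((3, 3), bool)))
        assert len(ps) == 0
        assert total_area(ps)["m2"] == 0.0

    def test_matches_flood_fill_oracle(self, rng):
        mask = rng.random((20, 20)) < 0.35
        ps = polygonize(label_raster(mask))
        oracle = flood_fill_components(mask)
        assert len(ps) == len(oracle)
        assert sorted(p.cell_count for p in ps.polygons) == \
            sorted(len(c) for c in oracle)
        assert sorted(p.area_m2 for p in ps.polygons) == pytest.approx(
            sorted(len(c) * CELL for c in oracle))


class TestFilters:
    def test_min_area_strict_less_than(self):
        ps = GardenPolygonSet([
            GardenPolygon(1, 1, 5.0, (1, 1), box(0, 0, 1, 5)),
            GardenPolygon(2, 1, 13.69, (3, 3), box(2, 0, 3, 13.69)),
            GardenPolygon(3, 1, 10.0, (5, 5), box(4, 0, 5, 10)),
        ], PX)
        kept = filter_min_area(ps, 10.0)
        assert sorted(p.area_m2 for p in kept.polygons) == [10.0, 13.69]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0.1, 100.0), min_size=1, max_size=60),
           st.floats(1.0, 50.0))
    def test_min_area_matches_enumeration(self, areas, threshold):
        ps = GardenPolygonSet(
            [GardenPolygon(i, 1, a, (i, 0), box(i, 0, i + 0.5, a))
             for i, a in enumerate(areas)], PX)
        kept = filter_min_area(ps, threshold)
        assert len(kept) == sum(a >= threshold for a in areas)

    def test_filter_idempotent(self, rng):
        areas = rng.uniform(1, 40, size=30)
        ps = GardenPolygonSet(
            [GardenPolygon(i, 1, a, (i, 0), box(i, 0, i + 0.5, a))
             for i, a in enumerate(areas)], PX)
        once = filter_min_area(ps, 10.0)
        twice = filter_min_area(once, 10.0)
        assert [p.component_id for p in once.polygons] == \
            [p.component_id for p in twice.polygons]

    def test_mask_covering_everything_empties_set(self):
        ps = GardenPolygonSet(
            [GardenPolygon(1, 1, CELL, (5, 5), box(4, 4, 6, 6))], PX)
        kept, report = apply_exclusion_mask(ps, [box(-100, -100, 100, 100)])
        assert len(kept) == 0
        assert report.dropped_count == 1
        assert report.dropped_area_m2 == pytest.approx(CELL)

    def test_empty_mask_is_identity(self):
        ps = GardenPolygonSet(
            [GardenPolygon(1, 1, CELL, (5, 5), box(4, 4, 6, 6))], PX)
        kept, report = apply_exclusion_mask(ps, [])
        assert len(kept) == 1 and report.dropped_count == 0

    def test_half_plane_mask_matches_centroid_oracle(self, rng):
        polys = []
        for i in range(50):
            x, y = rng.uniform(0, 100, size=2)
            polys.append(GardenPolygon(i, 1, 20.0, (x, y),
                                       box(x - 1, y - 1, x + 1, y + 1)))
        ps = GardenPolygonSet(polys, PX)
        half = box(0, 0, 50, 100)
        kept, report = apply_exclusion_mask(ps, [half])
        expected_drop = [p for p in polys if p.centroid[0] <= 50]
        assert report.dropped_count == len(expected_drop)
        assert all(p.centroid[0] > 50 for p in kept.polygons)


class TestAreasAndDensity:
    def test_unit_conversions(self):
        ps = GardenPolygonSet(
            [GardenPolygon(i, 1, CELL, (i, 0), box(i, 0, i + 1, 1))
             for i in range(100)], PX)
        areas = total_area(ps)
        assert areas["m2"] == pytest.approx(1369.0)
        assert areas["ha"] == pytest.approx(0.1369)
        assert areas["km2"] == pytest.approx(0.001369)

    def test_polygonize_conserves_cell_area(self, small_scene):
        """Polygonized mulch area equals mulch cell count x pixel area."""
        _, _, _, truth = small_scene
        ps = polygonize(truth, target="mulch")
        n_cells = int((truth.labels ==
                       truth.class_names.index("mulch")).sum())
        assert total_area(ps)["m2"] == pytest.approx(n_cells * CELL)

    def test_cellsum_single_polygon_single_cell(self):
        ps = GardenPolygonSet(
            [GardenPolygon(1, 2, 2 * CELL, (620.0, 380.0),
                           box(619, 379, 621, 381))], PX,
            extent=(0.0, 0.0, 1000.0, 1000.0))
        surf = kernel_density(ps, cell=500.0)
        assert (surf.values > 0).sum() == 1
        # centroid (620, 380) falls in column 1, row 1 of the 2x2 lattice
        assert surf.values[1, 1] == pytest.approx(2 * CELL)

    def test_cellsum_conserves_total_area(self, small_scene):
        _, _, _, truth = small_scene
        ps = polygonize(truth, target="mulch")
        surf = kernel_density(ps, cell=100.0)
        assert surf.values.sum() == pytest.approx(total_area(ps)["m2"])

    def test_quartic_zero_outside_bandwidth(self):
        ps = GardenPolygonSet(
            [GardenPolygon(1, 1, CELL, (100.0, 100.0),
                           box(99, 99, 101, 101))], PX,
            extent=(0.0, 0.0, 2000.0, 2000.0))
        surf = kernel_density(ps, cell=100.0, bandwidth=500.0,
                              mode="quartic")
        rr, cc = np.mgrid[0:surf.values.shape[0], 0:surf.values.shape[1]]
        gx, gy = surf.transform.cell_center(rr, cc)
        d = np.hypot(gx - 100.0, gy - 100.0)
        assert np.all(surf.values[d >= 500.0] == 0.0)
        assert np.all(surf.values[d < 500.0] > 0.0)

    def test_bad_parameters_rejected(self):
        ps = GardenPolygonSet([], PX, extent=(0, 0, 10, 10))
        with pytest.raises(ValueError):
            kernel_density(ps, cell=0.0)
        with pytest.raises(ValueError):
            kernel_density(ps, mode="gaussian")

    def test_coastal_bias_shows_in_density(self, library):
        """Mulch density mass concentrates in the biased (coastal) half of
        default scenes."""
        lower = []
        for seed in range(5):
            cfg = sc.SceneConfig(height=96, width=96, seed=seed)
            _, _, truth = sc.generate_scene(cfg, library)
            ps = polygonize(truth, target="mulch")
            surf = kernel_density(ps, cell=100.0)
            half = surf.values.shape[0] // 2
            lower.append(surf.values[half:].sum()
                         > surf.values[:half].sum())
        assert sum(lower) >= 4


class TestPipelineOrderProperties:
    def test_mask_then_filter_equals_filter_then_mask(self, small_scene):
        _, _, _, truth = small_scene
        ps = polygonize(truth, target="mulch")
        mask = [box(0.0, 0.0, 120.0, 120.0)]
        a = filter_min_area(apply_exclusion_mask(ps, mask)[0], 10.0)
        b = apply_exclusion_mask(filter_min_area(ps, 10.0), mask)[0]
        assert [p.component_id for p in a.polygons] == \
            [p.component_id for p in b.polygons]

    def test_polygonize_recovers_patch_structure(self, small_scene):
        """Polygonize of the truth map yields plausibly many mulch
        components covering the truth's mulch fraction."""
        _, _, _, truth = small_scene
        ps = polygonize(truth, target="mulch")
        assert len(ps) >= 1
        frac = total_area(ps)["m2"] / (truth.labels.size * CELL)
        assert frac == pytest.approx(truth.class_fraction("mulch"))
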