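"""Urban-extent delineation: centre filtering, contiguity, hulls, clipping."""

from collections import deque

import numpy as np
import pytest
from shapely.geometry import LineString, Point, Polygon, box
from shapely.ops import unary_union

from sdindex.errors import InputError
from sdindex.raster import Raster
from sdindex.urban_extents import (
    UrbanCentre,
    buffer_and_hull,
    clip_extents,
    component_polygon,
    contiguous_urban_components,
    merge_overlapping_hulls,
    reclassify_urban,
    select_centres,
)


def centre(qa, name="c", poly=None):
    poly = poly if poly is not None else box(0, 0, 1, 1)
    return UrbanCentre(poly.centroid, poly, qa, name, "SYN")


def flood_fill_components(mask):
    """Oracle: BFS flood fill with queen (8-neighbour) connectivity."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    components = []
    for r0, c0 in zip(*np.nonzero(mask)):
        if seen[r0, c0]:
            continue
        cells = set()
        queue = deque([(r0, c0)])
        seen[r0, c0] = True
        while queue:
            r, c = queue.popleft()
            cells.add((r, c))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < mask.shape[0]
                        and 0 <= cc < mask.shape[1]
                        and mask[rr, cc]
                        and not seen[rr, cc]
                    ):
                        seen[rr, cc] = True
                        queue.append((rr, cc))
        components.append(frozenset(cells))
    return set(components)


def grid_raster(values, cell=1000.0):
    values = np.asarray(values)
    h = values.shape[0]
    return Raster(values, (cell, 0.0, 0.0, 0.0, -cell, h * cell), "metric", None)


class TestSelectCentres:
    def test_keeps_only_quality_flag_one(self):
        kept = select_centres([centre(1, "a"), centre(0, "b"), centre(1, "c")])
        assert [c.name for c in kept] == ["a", "c"]

    def test_empty_and_identity_cases(self):
        assert select_centres([]) == []
        all_good = [centre(1, "a"), centre(1, "b")]
        assert select_centres(all_good) == all_good

    def test_missing_flag_is_an_error(self):
        with pytest.raises(InputError):
            select_centres([centre(None)])


class TestReclassify:
    def test_urban_class_window(self):
        grid = grid_raster([[10, 11, 13], [21, 23, 30], [12, 22, 20]])
        out = reclassify_urban(grid)
        assert out.tolist() == [[0, 0, 0], [1, 1, 1], [0, 1, 0]]

    def test_nodata_becomes_not_urban(self):
        grid = Raster(
            np.array([[30, -1], [21, 30]]),
            (1000.0, 0, 0, 0, -1000.0, 2000.0),
            "metric",
            nodata=-1,
        )
        assert reclassify_urban(grid).tolist() == [[1, 0], [1, 1]]


class TestContiguity:
    def test_component_with_centre_kept_blob_without_dropped(self):
        values = np.zeros((6, 6), dtype=int)
        values[0:2, 0:2] = 30  # blob touching the centre
        values[4:6, 4:6] = 21  # far blob, no centre
        grid = grid_raster(values)
        c = centre(1, poly=box(0, 4000, 2000, 6000))  # over the class-30 blob
        comps = contiguous_urban_components(reclassify_urban(grid), grid, [c])
        assert len(comps) == 1
        mask, touching = comps[0]
        assert mask[0:2, 0:2].all() and mask.sum() == 4
        assert touching == [c]

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_flood_fill_oracle_on_random_grids(self, trial):
        rng = np.random.default_rng(1000 + trial)
        mask = rng.random((10, 10)) < 0.45
        grid = grid_raster(np.where(mask, 30, 11))
        everywhere = centre(1, poly=box(0, 0, 10_000, 10_000))
        comps = contiguous_urban_components(mask.astype(np.uint8), grid, [everywhere])
        got = {frozenset(zip(*np.nonzero(m))) for m, _ in comps}
        assert got == flood_fill_components(mask)


class TestBufferAndHull:
    def test_hull_contains_buffered_cell(self):
        cell = box(0, 0, 1000, 1000)
        hull = buffer_and_hull(cell, "metric", 3000.0)
        assert hull.contains(cell)
        assert hull.area >= (7000.0 * 7000.0) * 0.75  # rounded-corner square

    def test_zero_buffer_is_hull_of_component(self):
        cell = box(0, 0, 1000, 1000)
        hull = buffer_and_hull(cell, "metric", 0.0)
        assert hull.symmetric_difference(cell).area < 1e-6

    def test_geometric_monotonicity(self):
        comp = unary_union([box(0, 0, 1000, 1000), box(1000, 1000, 2000, 2000)])
        buffered = comp.buffer(500.0)
        hull = buffer_and_hull(comp, "metric", 500.0)
        assert hull.area >= buffered.area >= comp.area

    def test_negative_buffer_rejected(self):
        with pytest.raises(ValueError):
            buffer_and_hull(box(0, 0, 1, 1), "metric", -1.0)


def naive_overlap_merge(hulls):
    """Oracle: repeatedly replace any overlapping pair by the hull of its union."""
    polys = list(hulls)
    changed = True
    while changed:
        changed = False
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                if polys[i].intersection(polys[j]).area > 0:
                    merged = unary_union([polys[i], polys[j]]).convex_hull
                    polys = [p for k, p in enumerate(polys) if k not in (i, j)]
                    polys.append(merged)
                    changed = True
                    break
            if changed:
                break
    return polys


class TestMergeHulls:
    def test_disjoint_unchanged(self):
        a, b = box(0, 0, 1, 1), box(5, 5, 6, 6)
        assert len(merge_overlapping_hulls([a, b])) == 2

    def test_overlapping_pair_merges_to_covering_hull(self):
        a, b = box(0, 0, 2, 2), box(1, 1, 3, 3)
        (merged,) = merge_overlapping_hulls([a, b])
        assert merged.contains(a) and merged.contains(b)

    def test_transitive_chain_collapses(self):
        a, b, c = box(0, 0, 2, 1), box(1.5, 0, 3.5, 1), box(3, 0, 5, 1)
        assert a.intersection(c).area == 0  # only chained via b
        assert len(merge_overlapping_hulls([a, b, c])) == 1

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_pairwise_merge_oracle(self, trial):
        rng = np.random.default_rng(2000 + trial)
        hulls = []
        for _ in range(8):
            x, y = rng.uniform(0, 10, 2)
            w, h = rng.uniform(0.5, 3, 2)
            hulls.append(box(x, y, x + w, y + h))
        got = merge_overlapping_hulls(hulls)
        expected = naive_overlap_merge(hulls)
        assert len(got) == len(expected)
        assert unary_union(got).symmetric_difference(unary_union(expected)).area < 1e-9
        for i in range(len(got)):
            for j in range(i + 1, len(got)):
                assert got[i].intersection(got[j]).area < 1e-12

    def test_outputs_pairwise_interior_disjoint_after_growth(self):
        # merging two hulls grows a hull that newly overlaps a third
        a, b = box(0, 0, 4, 1), box(0, 2, 4, 3)
        bridge = box(3.5, 0, 4.5, 3)
        c = box(0.5, 1.2, 1.5, 1.8)  # inside hull(a ∪ b ∪ bridge) only
        out = merge_overlapping_hulls([a, b, bridge, c])
        assert len(out) == 1


class TestClipExtents:
    def test_inland_extent_unchanged_offshore_dropped(self):
        admin = box(0, 0, 10, 10)
        inland = box(2, 2, 4, 4)
        offshore = box(20, 20, 22, 22)
        out = clip_extents([inland, offshore], admin)
        assert len(out) == 1
        assert out[0].equals(inland)

    def test_straddling_extent_clipped_to_oracle_intersection(self):
        admin = box(0, 0, 10, 10)
        straddle = box(8, 2, 14, 5)
        (clipped,) = clip_extents([straddle], admin)
        assert clipped.area == pytest.approx(straddle.intersection(admin).area, rel=1e-12)

    def test_water_mask_subtracted(self):
        admin = box(0, 0, 10, 10)
        water = box(0, 0, 10, 2)  # coastal strip
        coastal = box(1, 1, 3, 4)
        (clipped,) = clip_extents([coastal], admin, water=water)
        assert clipped.equals(box(1, 2, 3, 4))


def test_pipeline_extents_each_contain_a_selected_centre(city_bundle, city_run):
    bundle_out, _ = city_run
    selected = select_centres(city_bundle.centres)
    for extent in bundle_out.extents:
        assert any(extent.geometry.intersects(c.polygon) for c in selected)


def test_extent_delineation_is_deterministic(city_bundle):
    from sdindex.urban_extents import delineate_urban_extents

    runs = [
        delineate_urban_extents(
            city_bundle.settlement_grid,
            city_bundle.centres,
            city_bundle.admin_boundary,
            water=city_bundle.water,
            iso3="SYN",
        )
        for _ in range(2)
    ]
    assert [e.uext_ID for e in runs[0]] == [e.uext_ID for e in runs[1]]
    for e1, e2 in zip(*runs):
        assert e1.geometry.equals_exact(e2.geometry, 0)
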