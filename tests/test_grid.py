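"""Grid surfaces, L1 hotspot extraction and protected-area overlap."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from edgegrid.assessment import combine
from edgegrid.categories import ThreatCategory
from edgegrid.grid import (HotspotSet, build_surfaces, cell_polygon,
                           l1_hotspots, pa_overlap, rasterize_taxa)
from edgegrid.phylo import EdgeScore

from oracles import hotspot_oracle, pa_point_sampling_oracle

C = ThreatCategory
KM = 1000.0


def surface_from(values: dict) -> pd.DataFrame:
    """Surface with one eligible cell per (i, j) -> mean_edge value."""
    return pd.DataFrame(
        [{"cell_i": i, "cell_j": j, "n_endemic": 1, "n_threatened": 0,
          "n_cr": 0, "n_edge_scored": 1, "mean_edge": v}
         for (i, j), v in values.items()]
    )


class TestRasterize:
    def test_multiple_points_one_cell(self, spec):
        pts = {"a": np.array([[KM, KM], [2 * KM, 2 * KM], [4 * KM, 4 * KM]])}
        cellmap = rasterize_taxa(pts, spec)
        assert cellmap == {(0, 0): {"a"}}

    def test_shared_cell_richness(self, spec):
        pts = {"a": np.array([[KM, KM]]), "b": np.array([[2 * KM, 3 * KM]])}
        cellmap = rasterize_taxa(pts, spec)
        assert cellmap[(0, 0)] == {"a", "b"}

    def test_counts_match_nested_loop_oracle(self, spec, rng):
        pts = {
            f"t{k}": rng.uniform(-100 * KM, 100 * KM, size=(rng.integers(1, 30), 2))
            for k in range(20)
        }
        cellmap = rasterize_taxa(pts, spec)
        want: dict = {}
        for tid, arr in pts.items():
            for x, y in arr:
                cell = (math.floor(x / 5000.0), math.floor(y / 5000.0))
                want.setdefault(cell, set()).add(tid)
        assert cellmap == want


class TestSurfaces:
    def test_counts_per_category(self, spec):
        cellmap = {(0, 0): {"a", "b", "c"}}
        assessments = [combine("a", C.CR, C.CR), combine("b", C.VU, C.LC),
                       combine("c", C.LC, C.LC)]
        surf = build_surfaces(cellmap, assessments)
        row = surf.iloc[0]
        assert (row.n_endemic, row.n_threatened, row.n_cr) == (3, 2, 1)

    def test_mean_edge(self):
        cellmap = {(1, 1): {"a", "b"}, (2, 2): {"c"}}
        scores = {"a": EdgeScore("a", 1, 1, 2.0), "b": EdgeScore("b", 1, 1, 4.0)}
        surf = build_surfaces(cellmap, [], scores).set_index(["cell_i", "cell_j"])
        assert surf.loc[(1, 1), "mean_edge"] == pytest.approx(3.0)
        assert math.isnan(surf.loc[(2, 2), "mean_edge"])

    def test_richness_ordering_invariant_holds(self, spec, rng):
        cats = [C.CR, C.EN, C.VU, C.NT, C.LC]
        taxa = {f"t{k}": cats[k % 5] for k in range(50)}
        pts = {t: rng.uniform(0, 50 * KM, size=(5, 2)) for t in taxa}
        assessments = [combine(t, c, c) for t, c in taxa.items()]
        surf = build_surfaces(rasterize_taxa(pts, spec), assessments)
        assert (surf.n_cr <= surf.n_threatened).all()
        assert (surf.n_threatened <= surf.n_endemic).all()

    def test_order_invariance(self, spec, rng):
        pts = {f"t{k}": rng.uniform(0, 30 * KM, size=(4, 2)) for k in range(10)}
        a = [combine(t, C.VU, C.LC) for t in pts]
        s1 = build_surfaces(rasterize_taxa(pts, spec), a)
        rev = dict(reversed(list(pts.items())))
        s2 = build_surfaces(rasterize_taxa(rev, spec), list(reversed(a)))
        pd.testing.assert_frame_equal(s1, s2)


class TestHotspots:
    def test_one_percent_of_200_distinct_cells(self):
        values = {(i, 0): float(i) for i in range(200)}
        hs = l1_hotspots(surface_from(values), "mean_edge")
        assert hs.cells == {(198, 0), (199, 0)}
        assert len(hs.cells) == math.ceil(0.01 * 200)

    def test_ties_at_top_value_all_selected(self):
        values = {(i, 0): float(i) for i in range(97)}
        values.update({(100, 0): 999.0, (101, 0): 999.0, (102, 0): 999.0})
        hs = l1_hotspots(surface_from(values), "mean_edge")
        assert hs.cells == {(100, 0), (101, 0), (102, 0)}

    def test_random_surfaces_match_sort_and_slice_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 400))
            # duplicate-heavy values exercise the tie rule
            values = {(i, 0): float(rng.integers(0, 20)) for i in range(n)}
            hs = l1_hotspots(surface_from(values), "mean_edge")
            assert hs.cells == hotspot_oracle(values)
            assert len(hs.cells) >= math.ceil(0.01 * n)

    def test_all_distinct_count_is_exactly_ceil(self, rng):
        for n in (1, 37, 100, 101, 250):
            vals = rng.permutation(n).astype(float)
            values = {(i, 0): float(vals[i]) for i in range(n)}
            hs = l1_hotspots(surface_from(values), "mean_edge")
            assert len(hs.cells) == math.ceil(0.01 * n)

    def test_all_equal_metric_degenerates_to_all_cells(self):
        values = {(i, 0): 5.0 for i in range(50)}
        hs = l1_hotspots(surface_from(values), "mean_edge")
        assert len(hs.cells) == 50 and hs.degenerate

    def test_zero_endemic_cells_excluded_from_quantile(self):
        surf = surface_from({(i, 0): float(i) for i in range(100)})
        surf.loc[surf.cell_i < 50, "n_endemic"] = 0
        hs = l1_hotspots(surf, "mean_edge")
        assert hs.n_eligible == 50
        assert hs.cells == {(99, 0)}

    def test_no_eligible_cells_rejected(self):
        surf = surface_from({(0, 0): 1.0})
        surf["n_endemic"] = 0
        with pytest.raises(ValueError):
            l1_hotspots(surf, "mean_edge")


def hotset(cells):
    return HotspotSet(metric="mean_edge", cells=frozenset(cells), threshold=0.0, n_eligible=len(cells))


class TestPaOverlap:
    def test_cell_fully_inside_pa(self, spec):
        rep = pa_overlap(hotset({(0, 0)}), [box(-KM, -KM, 10 * KM, 10 * KM)], spec)
        assert rep.n_inside == 1 and rep.pct_outside == 0.0

    def test_constructed_27_5_percent_outside(self, spec):
        """40 hotspot cells, 11 outside every PA -> 27.5% outside."""
        cells = {(i, 0) for i in range(40)}
        pa = [box(0, 0, 144 * KM, 5 * KM)]  # reaches into cell 28, not 29
        rep = pa_overlap(hotset(cells), pa, spec)
        assert rep.n_outside == 11
        assert rep.pct_outside == pytest.approx(27.5)
        assert rep.pct_inside + rep.pct_outside == pytest.approx(100.0)

    def test_empty_pa_set_all_outside(self, spec):
        rep = pa_overlap(hotset({(0, 0), (5, 5)}), [], spec)
        assert rep.pct_outside == 100.0

    def test_random_rectangles_match_point_sampling_oracle(self, spec, rng):
        cells = {(int(i), int(j)) for i, j in rng.integers(0, 20, size=(30, 2))}
        rects = []
        for _ in range(5):
            # snap to 500 m so every overlap strip contains sample points
            x0, y0 = np.round(rng.uniform(0, 90 * KM, 2) / 500) * 500
            w, h = np.round(rng.uniform(5 * KM, 20 * KM, 2) / 500) * 500
            rects.append((x0, y0, x0 + w, y0 + h))
        pas = [box(*r) for r in rects]
        rep = pa_overlap(hotset(cells), pas, spec)
        for cell in cells:
            want = pa_point_sampling_oracle(
                spec.cell_bounds(*cell, spec.map_cell_m), rects, step=100.0
            )
            assert (cell in rep.inside_cells) == want

    def test_centroid_mode(self, spec):
        # PA touches the cell edge but not its centroid
        pa = [box(0, 0, KM, 5 * KM)]
        assert pa_overlap(hotset({(0, 0)}), pa, spec, mode="intersect").n_inside == 1
        assert pa_overlap(hotset({(0, 0)}), pa, spec, mode="centroid").n_inside == 0

    def test_unknown_mode_rejected(self, spec):
        with pytest.raises(ValueError):
            pa_overlap(hotset({(0, 0)}), [], spec, mode="bogus")
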