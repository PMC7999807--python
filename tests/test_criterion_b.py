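"""Range geometry (EOO/AOO/locations) and the Criterion B decision rule."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgegrid.categories import ThreatCategory
from edgegrid.criterion_b import (CriterionBThresholds, RangeMetrics,
                                  assess_criterion_b, compute_aoo,
                                  compute_eoo, compute_range_metrics,
                                  count_locations)

from oracles import binning_oracle, criterion_b_oracle, hull_area_oracle

KM = 1000.0


def metrics(eoo, aoo, nloc):
    return RangeMetrics(eoo_km2=eoo, aoo_km2=aoo, n_locations=nloc, n_points=1)


class TestGeometry:
    def test_square_eoo(self):
        pts = np.array([[0, 0], [10 * KM, 0], [10 * KM, 10 * KM], [0, 10 * KM]])
        area, degenerate = compute_eoo(pts)
        assert area == pytest.approx(100.0)
        assert not degenerate

    def test_collinear_points_are_degenerate(self):
        pts = np.array([[0, 0], [KM, KM], [2 * KM, 2 * KM]])
        area, degenerate = compute_eoo(pts)
        assert area == 0.0 and degenerate

    def test_empty_input_rejected(self, spec):
        with pytest.raises(ValueError):
            compute_eoo(np.empty((0, 2)))
        with pytest.raises(ValueError):
            compute_aoo(np.empty((0, 2)), spec)
        with pytest.raises(ValueError):
            count_locations(np.empty((0, 2)), spec)

    def test_eoo_matches_hull_oracle_on_random_sets(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 51))
            pts = rng.uniform(-200 * KM, 200 * KM, size=(n, 2))
            area, _ = compute_eoo(pts)
            want = hull_area_oracle(pts) / 1e6
            assert area == pytest.approx(want, rel=1e-6)

    def test_aoo_single_cell(self, spec):
        pts = np.array([[100.0, 100.0], [500.0, 900.0], [1500.0, 1999.0]])
        aoo, cells = compute_aoo(pts, spec)
        assert aoo == 4.0 and len(cells) == 1

    def test_aoo_half_open_grid(self, spec):
        pts = np.array([[1 * KM, 1 * KM], [3 * KM, 1 * KM]])
        aoo, cells = compute_aoo(pts, spec)
        assert aoo == 8.0 and cells == {(0, 0), (1, 0)}

    def test_aoo_and_locations_match_binning_oracle(self, spec, rng):
        for _ in range(100):
            n = int(rng.integers(1, 201))
            pts = rng.uniform(-300 * KM, 300 * KM, size=(n, 2))
            aoo, cells = compute_aoo(pts, spec)
            want_cells = binning_oracle(pts, spec.origin, spec.aoo_cell_m)
            assert cells == want_cells
            assert aoo == len(want_cells) * 4.0
            assert count_locations(pts, spec) == len(
                binning_oracle(pts, spec.origin, spec.location_cell_m)
            )

    def test_locations_examples(self, spec):
        one_cell = np.array([[KM, KM], [9 * KM, 9 * KM]])
        assert count_locations(one_cell, spec) == 1
        three = np.array([[KM, KM], [15 * KM, KM], [45 * KM, KM]])
        assert count_locations(three, spec) == 3

    def test_aoo_invariant_under_permutation_and_duplication(self, spec, rng):
        pts = rng.uniform(0, 100 * KM, size=(50, 2))
        aoo, _ = compute_aoo(pts, spec)
        shuffled = pts[rng.permutation(len(pts))]
        doubled = np.vstack([pts, pts])
        assert compute_aoo(shuffled, spec)[0] == aoo
        assert compute_aoo(doubled, spec)[0] == aoo


class TestDecisionRule:
    @pytest.mark.parametrize(
        "eoo,aoo,nloc,want,subs",
        [
            (50.0, 8.0, 1, "CR", {"B1", "B2"}),
            (15000.0, 1800.0, 8, "VU", {"B1", "B2"}),
            (1e6, 1e5, 500, "LC", set()),
        ],
    )
    def test_threshold_examples(self, eoo, aoo, nloc, want, subs):
        res = assess_criterion_b(metrics(eoo, aoo, nloc))
        assert res.category.value == want
        assert set(res.triggered_subcriteria) == subs

    def test_nonpositive_locations_rejected(self):
        with pytest.raises(ValueError):
            assess_criterion_b(metrics(10.0, 4.0, 0))

    def test_exhaustive_lattice_matches_decision_table_oracle(self):
        """Boundary-spanning sweep over (EOO, AOO, locations)."""
        eoos = [0, 50, 99.99, 100, 4999, 5000, 19999, 20000, 29999, 30000, 1e6]
        aoos = [0, 4, 9.99, 10, 499, 500, 1999, 2000, 2999, 3000, 1e5]
        locs = [1, 2, 5, 6, 10, 11, 15, 16, 100]
        for nt_buffer in (True, False):
            t = CriterionBThresholds(nt_buffer=nt_buffer)
            for eoo, aoo, nloc in itertools.product(eoos, aoos, locs):
                got = assess_criterion_b(metrics(eoo, aoo, nloc), t).category.value
                want = criterion_b_oracle(eoo, aoo, nloc, nt_buffer=nt_buffer)
                assert got == want, (eoo, aoo, nloc, nt_buffer)

    def test_eoo_floor_rule(self):
        # raw EOO below AOO (degenerate hull): the floor drives B1
        res = assess_criterion_b(metrics(0.0, 4000.0, 3))
        assert res.metrics.effective_eoo_km2 == 4000.0
        assert res.category == ThreatCategory.EN  # B1: 4000 < 5000, loc<=5

    def test_threatened_implies_triggered_subcriterion(self):
        for eoo in (50, 500, 5000, 50000):
            for aoo in (4, 40, 400, 4000):
                for nloc in (1, 3, 7, 20):
                    res = assess_criterion_b(metrics(eoo, aoo, nloc))
                    if res.category.is_threatened:
                        assert res.triggered_subcriteria

    @given(
        eoo=st.floats(0, 1e6), aoo=st.floats(0, 1e5), nloc=st.integers(1, 1000),
        d_eoo=st.floats(0, 1e5), d_aoo=st.floats(0, 1e4), d_loc=st.integers(0, 50),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_severity_monotone_nonincreasing_in_each_metric(
        self, eoo, aoo, nloc, d_eoo, d_aoo, d_loc
    ):
        """Growing any of EOO/AOO/locations never raises severity."""
        base = assess_criterion_b(metrics(eoo, aoo, nloc)).category.severity_rank
        assert assess_criterion_b(metrics(eoo + d_eoo, aoo, nloc)).category.severity_rank <= base
        # AOO feeds the EOO floor, so hold the floor fixed when growing AOO
        if aoo + d_aoo <= max(eoo, aoo):
            assert assess_criterion_b(metrics(eoo, aoo + d_aoo, nloc)).category.severity_rank <= base
        assert assess_criterion_b(metrics(eoo, aoo, nloc + d_loc)).category.severity_rank <= base


def test_adding_a_point_never_shrinks_metrics(spec, rng):
    pts = rng.uniform(0, 50 * KM, size=(20, 2))
    m0 = compute_range_metrics(pts, spec)
    for _ in range(20):
        extra = rng.uniform(-100 * KM, 150 * KM, size=(1, 2))
        m1 = compute_range_metrics(np.vstack([pts, extra]), spec)
        assert m1.eoo_km2 >= m0.eoo_km2 - 1e-9
        assert m1.aoo_km2 >= m0.aoo_km2
        assert m1.n_locations >= m0.n_locations
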