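"""Preliminary IUCN Criterion B assessment from occurrence geometry.

Computes the standard range metrics — Extent of Occurrence (EOO, convex
hull area), Area of Occupancy (AOO, occupied 2-km cells x 4 km2) and the
number of locations (occupied 10-km cells) — and assigns a category from
the IUCN Criterion B1/B2 threshold tables. The continuing-decline condition
(b) of Criterion B is assumed satisfied, as in automated ConR-style
assessments: results are preliminary categorizations, not full Red List
assessments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPoint

from .categories import ThreatCategory
from .projection import ProjectionSpec, occupied_cells

M2_PER_KM2 = 1e6


@dataclass(frozen=True)
class RangeMetrics:
    """Per-taxon geographic range measures (areas in km2)."""

    eoo_km2: float
    aoo_km2: float
    n_locations: int
    n_points: int
    eoo_degenerate: bool = False

    @property
    def effective_eoo_km2(self) -> float:
        """EOO floored at AOO (IUCN rule: EOO may not be smaller than AOO)."""
        return max(self.eoo_km2, self.aoo_km2)


@dataclass(frozen=True)
class CriterionBThresholds:
    """IUCN Criterion B threshold table (km2 areas, location counts).

    The defaults are the standard IUCN values: B1 (EOO) 100/5000/20000 km2
    and B2 (AOO) 10/500/2000 km2 for CR/EN/VU, with location conditions
    1/<=5/<=10. The NT buffer assigns NT when the VU thresholds are missed
    by at most 50% (EOO < 30000 or AOO < 3000, locations <= 15); it is
    configurable and can be disabled, collapsing NT into LC.
    """

    eoo_cr: float = 100.0
    eoo_en: float = 5000.0
    eoo_vu: float = 20000.0
    aoo_cr: float = 10.0
    aoo_en: float = 500.0
    aoo_vu: float = 2000.0
    loc_cr: int = 1
    loc_en: int = 5
    loc_vu: int = 10
    nt_buffer: bool = True
    nt_buffer_factor: float = 1.5
    loc_nt: int = 15


@dataclass(frozen=True)
class CriterionBResult:
    metrics: RangeMetrics
    category: ThreatCategory
    triggered_subcriteria: frozenset[str] = field(default_factory=frozenset)


def compute_eoo(points_xy: np.ndarray) -> tuple[float, bool]:
    """Convex-hull area of projected points in km2.

    Returns (area, degenerate): fewer than 3 non-collinear points give area
    0 with the degenerate flag set. The EOO-floor (EOO := max(EOO, AOO)) is
    applied at assessment time, not here.
    """
    if len(points_xy) == 0:
        raise ValueError("EOO requires at least one point")
    hull = MultiPoint(points_xy).convex_hull
    area_km2 = hull.area / M2_PER_KM2
    return area_km2, area_km2 == 0.0


def compute_aoo(
    points_xy: np.ndarray, spec: ProjectionSpec
) -> tuple[float, set[tuple[int, int]]]:
    """AOO in km2 plus the set of occupied AOO grid cells.

    AOO = (number of distinct occupied cells) x (cell area); default 2-km
    cells give 4 km2 per cell.
    """
    if len(points_xy) == 0:
        raise ValueError("AOO requires at least one point")
    cells = occupied_cells(points_xy, spec, spec.aoo_cell_m)
    cell_area_km2 = (spec.aoo_cell_m / 1000.0) ** 2
    return len(cells) * cell_area_km2, cells


def count_locations(points_xy: np.ndarray, spec: ProjectionSpec) -> int:
    """Number of IUCN "locations", approximated by occupied 10-km cells."""
    if len(points_xy) == 0:
        raise ValueError("locations require at least one point")
    return len(occupied_cells(points_xy, spec, spec.location_cell_m))


def compute_range_metrics(points_xy: np.ndarray, spec: ProjectionSpec) -> RangeMetrics:
    eoo, degenerate = compute_eoo(points_xy)
    aoo, _cells = compute_aoo(points_xy, spec)
    nloc = count_locations(points_xy, spec)
    return RangeMetrics(
        eoo_km2=eoo,
        aoo_km2=aoo,
        n_locations=nloc,
        n_points=len(points_xy),
        eoo_degenerate=degenerate,
    )


def assess_criterion_b(
    metrics: RangeMetrics, thresholds: CriterionBThresholds | None = None
) -> CriterionBResult:
    """Assign a preliminary Criterion B category from range metrics.

    B1 ranks on effective EOO (floored at AOO), B2 on AOO, both gated by
    the location-count conditions; the final category is the more severe of
    the two ranks. If neither subcriterion triggers, the NT buffer rule may
    assign NT; otherwise LC.
    """
    t = thresholds or CriterionBThresholds()
    if metrics.n_locations <= 0:
        raise ValueError("number of locations must be positive")
    eoo = metrics.effective_eoo_km2
    aoo = metrics.aoo_km2
    nloc = metrics.n_locations

    def rank(value: float, cr: float, en: float, vu: float) -> ThreatCategory:
        if value < cr and nloc <= t.loc_cr:
            return ThreatCategory.CR
        if value < en and nloc <= t.loc_en:
            return ThreatCategory.EN
        if value < vu and nloc <= t.loc_vu:
            return ThreatCategory.VU
        return ThreatCategory.LC

    rank_b1 = rank(eoo, t.eoo_cr, t.eoo_en, t.eoo_vu)
    rank_b2 = rank(aoo, t.aoo_cr, t.aoo_en, t.aoo_vu)

    triggered = set()
    if rank_b1.is_threatened:
        triggered.add("B1")
    if rank_b2.is_threatened:
        triggered.add("B2")
    category = rank_b1 if rank_b1.severity_rank >= rank_b2.severity_rank else rank_b2

    if not category.is_threatened:
        near_b1 = eoo < t.eoo_vu * t.nt_buffer_factor
        near_b2 = aoo < t.aoo_vu * t.nt_buffer_factor
        if t.nt_buffer and (near_b1 or near_b2) and nloc <= t.loc_nt:
            category = ThreatCategory.NT
        else:
            category = ThreatCategory.LC
    return CriterionBResult(
        metrics=metrics, category=category, triggered_subcriteria=frozenset(triggered)
    )
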