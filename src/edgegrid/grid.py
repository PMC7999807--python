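"""5-km grid surfaces, L1 hotspot extraction, protected-area overlap.

Per-cell surfaces carry endemic richness, threatened and CR richness, and
mean EDGE over the scored taxa present. L1 hotspots for a metric are the
top 1% of eligible cells (cells holding at least one endemic taxon);
the threshold is the k-th largest metric value with k = ceil(q * n), and
ties at the threshold are included, so hotspot sets may slightly exceed
1%. PA overlap intersects the full square cell polygon with the protected
areas (centroid-membership mode available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box
from shapely.strtree import STRtree

from .assessment import CombinedAssessment
from .phylo import EdgeScore
from .projection import ProjectionSpec

HOTSPOT_METRICS = ("n_endemic", "n_cr", "mean_edge")


def rasterize_taxa(
    points_by_taxon: dict[str, np.ndarray], spec: ProjectionSpec
) -> dict[tuple[int, int], set[str]]:
    """Presence map: cell -> set of taxa with >=1 point in that 5-km cell."""
    cellmap: dict[tuple[int, int], set[str]] = {}
    for tid, pts in points_by_taxon.items():
        if len(pts) == 0:
            continue
        i, j = spec.cell_index(pts[:, 0], pts[:, 1], spec.map_cell_m)
        for cell in set(zip(i.tolist(), j.tolist())):
            cellmap.setdefault(cell, set()).add(tid)
    return cellmap


def build_surfaces(
    cellmap: dict[tuple[int, int], set[str]],
    assessments: list[CombinedAssessment],
    edge_scores: dict[str, EdgeScore] | None = None,
) -> pd.DataFrame:
    """Per-cell richness/threat/EDGE surface, one row per occupied cell.

    Taxa without an assessment count toward endemic richness only; mean
    EDGE is NaN in cells with no scored taxon.
    """
    cat_by_taxon = {a.taxon_id: a for a in assessments}
    edge_scores = edge_scores or {}
    rows = []
    for (i, j) in sorted(cellmap):
        taxa = cellmap[(i, j)]
        n_threat = n_cr = 0
        edges = []
        for tid in taxa:
            a = cat_by_taxon.get(tid)
            if a is not None:
                n_threat += a.is_threatened
                n_cr += a.category_combined.value == "CR"
            s = edge_scores.get(tid)
            if s is not None:
                edges.append(s.edge)
        rows.append(
            {"cell_i": i, "cell_j": j,
             "n_endemic": len(taxa), "n_threatened": n_threat, "n_cr": n_cr,
             "n_edge_scored": len(edges),
             "mean_edge": float(np.mean(edges)) if edges else float("nan")}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class HotspotSet:
    metric: str
    cells: frozenset[tuple[int, int]]
    threshold: float
    n_eligible: int
    degenerate: bool = False


def l1_hotspots(
    surface: pd.DataFrame, metric: str, quantile: float = 0.01
) -> HotspotSet:
    """Top-``quantile`` cells for a metric among eligible cells.

    Eligible cells hold >=1 endemic taxon; for mean_edge they must also
    hold >=1 scored taxon. Threshold = k-th largest value with
    k = ceil(quantile * n_eligible); members = cells with value >=
    threshold (ties included). All-equal metrics degenerate to every
    eligible cell being a hotspot.
    """
    elig = surface[surface["n_endemic"] > 0]
    values = elig[metric].to_numpy(dtype=float)
    keep = ~np.isnan(values)
    elig, values = elig[keep], values[keep]
    n = len(values)
    if n == 0:
        raise ValueError("no eligible cells for hotspot extraction")
    k = max(1, math.ceil(quantile * n))
    threshold = float(np.sort(values)[::-1][k - 1])
    mask = values >= threshold
    cells = frozenset(
        zip(elig["cell_i"].to_numpy()[mask].tolist(), elig["cell_j"].to_numpy()[mask].tolist())
    )
    return HotspotSet(
        metric=metric,
        cells=cells,
        threshold=threshold,
        n_eligible=n,
        degenerate=bool(mask.all() and n > k),
    )


@dataclass(frozen=True)
class PaOverlapReport:
    metric: str
    n_hotspots: int
    n_inside: int
    n_outside: int
    pct_inside: float
    pct_outside: float
    inside_cells: frozenset[tuple[int, int]] = field(default_factory=frozenset)


def cell_polygon(i: int, j: int, spec: ProjectionSpec) -> Polygon:
    xmin, ymin, xmax, ymax = spec.cell_bounds(i, j, spec.map_cell_m)
    return box(xmin, ymin, xmax, ymax)


def pa_overlap(
    hotspots: HotspotSet,
    pas: list[Polygon],
    spec: ProjectionSpec,
    mode: str = "intersect",
) -> PaOverlapReport:
    """Protected-area gap report for a hotspot set.

    A hotspot cell is "inside" iff its full square polygon intersects any
    PA polygon (mode="intersect", default) or its centroid falls in a PA
    (mode="centroid"). An empty PA set puts every hotspot outside.
    """
    if mode not in ("intersect", "centroid"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    inside = set()
    if pas:
        tree = STRtree(pas)
        for (i, j) in hotspots.cells:
            poly = cell_polygon(i, j, spec)
            probe = poly.centroid if mode == "centroid" else poly
            for idx in tree.query(probe):
                if pas[idx].intersects(probe):
                    inside.add((i, j))
                    break
    n = len(hotspots.cells)
    n_in = len(inside)
    return PaOverlapReport(
        metric=hotspots.metric,
        n_hotspots=n,
        n_inside=n_in,
        n_outside=n - n_in,
        pct_inside=100.0 * n_in / n if n else float("nan"),
        pct_outside=100.0 * (n - n_in) / n if n else float("nan"),
        inside_cells=frozenset(inside),
    )
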