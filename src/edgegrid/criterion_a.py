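"""Preliminary IUCN Criterion A assessment from a land-cover threat overlay.

Population reduction is proxied by the fraction of a taxon's occupied AOO
cells whose land cover falls in human-influence ("threat") classes: the
potential decline in habitat quality stands in for a decline in AOO, hence
in population. The proxy is a static habitat-quality snapshot; no temporal
window (10 years / 3 generations) is modelled.

Raster layers use a majority-class rule per cell; polygon layers use the
class at the cell centroid. An occurrence-level mode (each record a voting
unit instead of each occupied cell) is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .categories import ThreatCategory
from .landcover import NODATA, LandCoverPolygons, LandCoverRaster
from .projection import ProjectionSpec

LandCoverLayer = LandCoverRaster | LandCoverPolygons


@dataclass(frozen=True)
class CriterionAThresholds:
    """Population-reduction thresholds in percent (IUCN A2 defaults).

    CR >= 80, EN >= 50, VU >= 30; the NT buffer (>= 20) is configurable.
    """

    cr_pct: float = 80.0
    en_pct: float = 50.0
    vu_pct: float = 30.0
    nt_pct: float = 20.0
    nt_buffer: bool = True


@dataclass(frozen=True)
class CriterionAResult:
    threatened_cell_fraction: float  # over cells with known land cover
    inferred_reduction_pct: float
    category: ThreatCategory
    n_cells: int = 0
    n_threatened: int = 0
    n_unknown: int = 0


def classify_cells(
    cells: set[tuple[int, int]], lc: LandCoverLayer, spec: ProjectionSpec
) -> dict[tuple[int, int], bool | None]:
    """Flag each occupied AOO cell as threatened / natural / unknown (None).

    Raster mode: threatened iff the majority class within the cell is a
    threat class. Polygon mode: threatened iff the class at the cell
    centroid is a threat class.
    """
    if lc is None:
        raise ValueError("land-cover layer is required")
    flags: dict[tuple[int, int], bool | None] = {}
    for (i, j) in cells:
        xmin, ymin, xmax, ymax = spec.cell_bounds(i, j, spec.aoo_cell_m)
        if isinstance(lc, LandCoverRaster):
            code = lc.majority_class_in(xmin, ymin, xmax, ymax)
        else:
            code = lc.class_at((xmin + xmax) / 2.0, (ymin + ymax) / 2.0)
        flags[(i, j)] = None if code == NODATA else code in lc.threat_classes
    return flags


def classify_points(
    points_xy: np.ndarray, lc: LandCoverLayer
) -> list[bool | None]:
    """Occurrence-level threat flags (sensitivity-analysis mode)."""
    out: list[bool | None] = []
    for x, y in points_xy:
        code = lc.class_at(float(x), float(y))
        out.append(None if code == NODATA else code in lc.threat_classes)
    return out


def assess_criterion_a(
    flags, thresholds: CriterionAThresholds | None = None
) -> CriterionAResult:
    """Category from the threatened fraction of known-class cells.

    ``flags`` is any iterable of True/False/None (None = unknown land
    cover, excluded from the denominator). All-unknown yields DD.
    """
    t = thresholds or CriterionAThresholds()
    values = list(flags.values()) if isinstance(flags, dict) else list(flags)
    if not values:
        raise ValueError("at least one occupied cell is required")
    n_unknown = sum(1 for v in values if v is None)
    known = [v for v in values if v is not None]
    n_threat = sum(known)
    if not known:
        return CriterionAResult(
            threatened_cell_fraction=float("nan"),
            inferred_reduction_pct=float("nan"),
            category=ThreatCategory.DD,
            n_cells=len(values),
            n_threatened=0,
            n_unknown=n_unknown,
        )
    frac = n_threat / len(known)
    pct = 100.0 * frac
    if pct >= t.cr_pct:
        cat = ThreatCategory.CR
    elif pct >= t.en_pct:
        cat = ThreatCategory.EN
    elif pct >= t.vu_pct:
        cat = ThreatCategory.VU
    elif t.nt_buffer and pct >= t.nt_pct:
        cat = ThreatCategory.NT
    else:
        cat = ThreatCategory.LC
    return CriterionAResult(
        threatened_cell_fraction=frac,
        inferred_reduction_pct=pct,
        category=cat,
        n_cells=len(values),
        n_threatened=n_threat,
        n_unknown=n_unknown,
    )
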