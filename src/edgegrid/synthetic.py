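"""Seeded synthetic scenarios: occurrences, land cover, tree, PAs, reference.

Stands in for a national endemic-flora occurrence database plus its
ancillary layers so the whole pipeline is testable offline. Per-taxon
point clouds are clustered (isotropic bivariate normal around cluster
centres, truncated to a small radius) and *designed* to land in a target
IUCN Criterion B category by construction: cluster centres are snapped to
centres of distinct 10-km location cells, so the number of locations is
exact, and the spatial extent of the cluster box bounds EOO below the
relevant threshold. Land cover is a categorical raster with an exact-count
threat fraction plus an excluded (olive-grove analogue) class; protected
areas are non-overlapping rectangles hitting a target coverage; the
phylogeny is an ultrametric pure-birth (Yule) tree rescaled to a fixed
root age.

A single integer seed drives everything through numpy SeedSequence
spawning (streams: occurrences, landcover, pas, tree), so a scenario is
shareable as a (config, seed) pair and byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from .categories import ThreatCategory
from .io import OccurrenceRecord, write_occurrences, write_polygons
from .landcover import LandCoverRaster
from .projection import LambertAzimuthalEqualArea, ProjectionSpec

#: Land-cover class codes used by the generator.
CODE_ARTIFICIAL = 112   # threat (urban analogue)
CODE_AGRICULTURE = 211  # threat (arable analogue)
CODE_OLIVE = 223        # agricultural but excluded from the threat set
CODE_NATURAL = 311      # forest/natural analogue
THREAT_CODES = frozenset({CODE_ARTIFICIAL, CODE_AGRICULTURE})

#: Per-category range designs: number of 10-km location cells occupied and
#: the side (km) of the box the cells are drawn from. Location counts alone
#: pin the category for VU/NT/LC (they exceed the next-severer location
#: gate while AOO stays tiny); CR additionally needs its single-cell hull
#: under 100 km2, EN its two-cell hull under 5000 km2 — both guaranteed by
#: the box sides and the 2.5-km truncation radius.
CATEGORY_DESIGNS: dict[ThreatCategory, tuple[int, float]] = {
    ThreatCategory.CR: (1, 10.0),
    ThreatCategory.EN: (2, 60.0),
    ThreatCategory.VU: (7, 100.0),
    ThreatCategory.NT: (12, 160.0),
    ThreatCategory.LC: (18, 340.0),
}

#: Designed category mix over the taxon set.
CATEGORY_WEIGHTS: dict[ThreatCategory, float] = {
    ThreatCategory.CR: 0.30,
    ThreatCategory.EN: 0.20,
    ThreatCategory.VU: 0.20,
    ThreatCategory.NT: 0.15,
    ThreatCategory.LC: 0.15,
}

CLUSTER_SIGMA_M = 1000.0
CLUSTER_TRUNC_M = 2500.0
POINTS_PER_CLUSTER = 6


@dataclass(frozen=True)
class SyntheticScenario:
    """Scenario configuration; all defaults emulate the study setting.

    The domain is a Greece-sized rectangle in the equal-area plane,
    centred on the projection origin; ``pa_cover`` defaults to 0.28
    (protected-area network covering 28% of the territory) and
    ``tree_root_age_myr`` to 100 Myr.
    """

    n_taxa: int = 200
    domain_km: tuple[float, float] = (500.0, 400.0)
    center_lonlat: tuple[float, float] = (22.0, 38.5)
    threat_fraction: float = 0.30
    excluded_fraction: float = 0.05
    pa_cover: float = 0.28
    pa_block_km: float = 25.0
    landcover_pixel_km: float = 1.0
    tree_root_age_myr: float = 100.0
    seed: int = 0

    def projection_spec(self) -> ProjectionSpec:
        proj = LambertAzimuthalEqualArea(lon0=self.center_lonlat[0], lat0=self.center_lonlat[1])
        return ProjectionSpec(projection=proj)

    def domain_bounds_m(self) -> tuple[float, float, float, float]:
        w, h = self.domain_km[0] * 1000.0, self.domain_km[1] * 1000.0
        return (-w / 2.0, -h / 2.0, w / 2.0, h / 2.0)

    def _streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("occurrences", "landcover", "pas", "tree")
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def designed_categories(n_taxa: int) -> list[ThreatCategory]:
    """Deterministic category assignment matching CATEGORY_WEIGHTS."""
    counts = {c: int(round(w * n_taxa)) for c, w in CATEGORY_WEIGHTS.items()}
    drift = n_taxa - sum(counts.values())
    counts[ThreatCategory.CR] += drift
    out: list[ThreatCategory] = []
    for cat in CATEGORY_DESIGNS:
        out.extend([cat] * counts[cat])
    return out[:n_taxa]


def _truncated_cluster(rng: np.random.Generator, cx: float, cy: float, n: int) -> np.ndarray:
    """Isotropic normal points around (cx, cy), resampled into the
    truncation radius so location membership is guaranteed."""
    pts = np.empty((n, 2))
    k = 0
    while k < n:
        p = rng.normal(0.0, CLUSTER_SIGMA_M, size=2)
        if np.hypot(*p) <= CLUSTER_TRUNC_M:
            pts[k] = (cx + p[0], cy + p[1])
            k += 1
    return pts


def generate_occurrences(
    scenario: SyntheticScenario, rng: np.random.Generator | None = None
) -> tuple[list[OccurrenceRecord], pd.DataFrame]:
    """Occurrence records (lon/lat) plus the designed ground-truth table."""
    rng = rng or scenario._streams()["occurrences"]
    spec = scenario.projection_spec()
    xmin, ymin, xmax, ymax = scenario.domain_bounds_m()
    cell = spec.location_cell_m
    taxa = designed_categories(scenario.n_taxa)

    records: list[OccurrenceRecord] = []
    truth_rows = []
    for idx, cat in enumerate(taxa):
        tid = f"taxon_{idx:04d}"
        n_cells, box_km = CATEGORY_DESIGNS[cat]
        side = box_km * 1000.0
        n_side = max(1, int(side // cell))
        if n_side * n_side < n_cells:
            raise ValueError(f"infeasible design for {cat}: box too small for {n_cells} cells")
        # place the design box on the 10-km lattice, fully inside the domain
        max_i = int((xmax - xmin) // cell) - n_side
        max_j = int((ymax - ymin) // cell) - n_side
        bi = int(rng.integers(0, max_i + 1))
        bj = int(rng.integers(0, max_j + 1))
        flat = rng.choice(n_side * n_side, size=n_cells, replace=False)
        pts_all = []
        for f in np.sort(flat):
            ci, cj = bi + int(f) % n_side, bj + int(f) // n_side
            cx = xmin + (ci + 0.5) * cell
            cy = ymin + (cj + 0.5) * cell
            pts_all.append(_truncated_cluster(rng, cx, cy, POINTS_PER_CLUSTER))
        pts = np.vstack(pts_all)
        lon, lat = spec.projection.inverse(pts[:, 0], pts[:, 1])
        for lo, la in zip(lon, lat):
            records.append(OccurrenceRecord(tid, float(lo), float(la)))
        truth_rows.append({"taxon_id": tid, "category": cat.value, "n_locations_designed": n_cells})
    truth = pd.DataFrame(truth_rows)
    return records, truth


def generate_landcover(
    scenario: SyntheticScenario, rng: np.random.Generator | None = None
) -> LandCoverRaster:
    """Categorical raster with an exact-count realized threat fraction."""
    if not 0.0 <= scenario.threat_fraction <= 1.0:
        raise ValueError("threat_fraction must be in [0, 1]")
    rng = rng or scenario._streams()["landcover"]
    xmin, ymin, xmax, ymax = scenario.domain_bounds_m()
    px = scenario.landcover_pixel_km * 1000.0
    ncols = int(round((xmax - xmin) / px))
    nrows = int(round((ymax - ymin) / px))
    n = nrows * ncols
    n_threat = int(round(scenario.threat_fraction * n))
    n_excl = min(int(round(scenario.excluded_fraction * n)), n - n_threat)
    codes = np.full(n, CODE_NATURAL, dtype=int)
    codes[:n_threat // 2] = CODE_ARTIFICIAL
    codes[n_threat // 2:n_threat] = CODE_AGRICULTURE
    codes[n_threat:n_threat + n_excl] = CODE_OLIVE
    rng.shuffle(codes)
    return LandCoverRaster(
        codes=codes.reshape(nrows, ncols),
        x_min=xmin, y_min=ymin, pixel_m=px,
        threat_classes=THREAT_CODES,
    )


def generate_pas(scenario: SyntheticScenario, rng: np.random.Generator | None = None):
    """Non-overlapping PA rectangles totalling pa_cover x domain area.

    Rectangles are whole blocks of a coarse partition, plus one shrunken
    block so the realized coverage matches the target exactly (up to
    block-count granularity).
    """
    if not 0.0 <= scenario.pa_cover <= 1.0:
        raise ValueError("pa_cover must be in [0, 1]")
    rng = rng or scenario._streams()["pas"]
    if scenario.pa_cover == 0.0:
        return []
    xmin, ymin, xmax, ymax = scenario.domain_bounds_m()
    blk = scenario.pa_block_km * 1000.0
    nx = int((xmax - xmin) // blk)
    ny = int((ymax - ymin) // blk)
    target_area = scenario.pa_cover * (xmax - xmin) * (ymax - ymin)
    block_area = blk * blk
    order = rng.permutation(nx * ny)
    polys = []
    remaining = target_area
    for f in order:
        if remaining <= 0:
            break
        i, j = int(f) % nx, int(f) // nx
        bx, by = xmin + i * blk, ymin + j * blk
        if remaining >= block_area:
            polys.append(box(bx, by, bx + blk, by + blk))
            remaining -= block_area
        else:
            polys.append(box(bx, by, bx + blk * (remaining / block_area), by + blk))
            remaining = 0.0
    return polys


def generate_tree(
    taxon_ids: list[str],
    root_age: float = 100.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> str:
    """Ultrametric pure-birth (Yule) tree over the taxa, as a Newick string.

    Split times follow the Yule process (waiting time to the next split is
    exponential with rate proportional to the number of extant lineages),
    then the whole tree is rescaled so the root-to-tip depth equals
    ``root_age``. Tip labels are a random permutation of ``taxon_ids``.
    """
    n = len(taxon_ids)
    if n < 2:
        raise ValueError("need at least two taxa")
    rng = rng or np.random.default_rng(seed)

    split_times = [0.0]
    t = 0.0
    for k in range(2, n):
        t += rng.exponential(1.0 / k)
        split_times.append(t)
    depth = t + rng.exponential(1.0 / n)
    scale = root_age / depth

    class _Node:
        __slots__ = ("t0", "t1", "children", "label")

        def __init__(self, t0):
            self.t0, self.t1, self.children, self.label = t0, None, [], None

    root = _Node(0.0)
    root.t1 = 0.0
    active: list[_Node] = []
    for _ in range(2):
        c = _Node(0.0)
        root.children.append(c)
        active.append(c)
    for st in split_times[1:]:
        k = int(rng.integers(0, len(active)))
        parent = active.pop(k)
        parent.t1 = st
        for _ in range(2):
            c = _Node(st)
            parent.children.append(c)
            active.append(c)
    labels = [taxon_ids[i] for i in rng.permutation(n)]
    for leaf, lab in zip(active, labels):
        leaf.t1 = depth
        leaf.label = lab

    def newick(node: _Node, parent_t: float) -> str:
        length = (node.t1 - parent_t) * scale
        if node.children:
            inner = ",".join(newick(c, node.t1) for c in node.children)
            return f"({inner}):{length:.10g}"
        return f"{node.label}:{length:.10g}"

    return newick(root, 0.0) + ";"


def write_scenario(scenario: SyntheticScenario, out_dir: str | Path) -> dict[str, Path]:
    """Materialize all scenario inputs as the files the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    streams = scenario._streams()
    records, truth = generate_occurrences(scenario, streams["occurrences"])
    lc = generate_landcover(scenario, streams["landcover"])
    pas = generate_pas(scenario, streams["pas"])
    tree_newick = generate_tree(
        sorted(truth["taxon_id"]), root_age=scenario.tree_root_age_myr, rng=streams["tree"]
    )
    paths = {
        "occurrences": out / "occurrences.csv",
        "landcover": out / "landcover.csv",
        "pas": out / "pas.geojson",
        "tree": out / "tree.nwk",
        "reference": out / "reference.csv",
        "scenario": out / "scenario.json",
    }
    write_occurrences(records, paths["occurrences"])
    lc.to_csv(paths["landcover"])
    write_polygons(pas, paths["pas"])
    paths["tree"].write_text(tree_newick + "\n")
    truth.to_csv(paths["reference"], index=False)
    with open(paths["scenario"], "w") as fh:
        json.dump(asdict(scenario), fh, indent=1, sort_keys=True)
    return paths
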