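"""End-to-end orchestration: stages communicating via files in a run dir.

Stage layout inside a run directory:

    inputs/            occurrences.csv, landcover.csv, tree.nwk,
                       pas.geojson, reference.csv (either synthesized by
                       the simulate stage or copied/pointed-to by config)
    projection.json    the resolved projection + grid convention
    assessments.csv    per-taxon A/B/combined categories + range metrics
    edge_scores.csv    per-taxon ED / GE / EDGE
    surfaces.csv       per-5km-cell richness / threat / mean-EDGE surface
    hotspots_<metric>.geojson
    pa_overlap.json    gap analysis per hotspot metric
    validation.json    confusion-matrix scores (when a reference exists)
    manifest.json      config, seed, versions, sha256 checksums

Each stage is a pure function of (files, config), so any stage can be
rerun in isolation; rerunning with the same seed reproduces every output
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assessment import (CombinedAssessment, assessments_to_frame, combine,
                         validate)
from .categories import ThreatCategory
from .criterion_a import (CriterionAThresholds, assess_criterion_a,
                          classify_cells, classify_points)
from .criterion_b import (CriterionBThresholds, assess_criterion_b,
                          compute_aoo, compute_range_metrics)
from .grid import HOTSPOT_METRICS, cell_polygon, l1_hotspots, pa_overlap, rasterize_taxa, build_surfaces
from .io import (read_occurrences, read_protected_areas, read_tree,
                 write_polygons, write_surface_csv)
from .landcover import LandCoverRaster
from .phylo import EdgeScore, edge_scores_for
from .projection import LambertAzimuthalEqualArea, ProjectionSpec
from .synthetic import SyntheticScenario, write_scenario

log = logging.getLogger("edgegrid")

#: Display names for the hotspot metrics (richness, CR richness, mean EDGE).
METRIC_LABELS = {"n_endemic": "GR", "n_cr": "CR_END", "mean_edge": "EDGE"}


@dataclass
class RunConfig:
    """Everything a run needs; every defaulted decision is serialized into
    the manifest so a run is reproducible from (config, seed)."""

    scenario: SyntheticScenario | None = None
    occurrences: str | None = None
    landcover: str | None = None
    tree: str | None = None
    pas: str | None = None
    reference: str | None = None
    thresholds_a: CriterionAThresholds = field(default_factory=CriterionAThresholds)
    thresholds_b: CriterionBThresholds = field(default_factory=CriterionBThresholds)
    hotspot_quantile: float = 0.01
    criterion_a_mode: str = "cell"        # "cell" | "occurrence"
    pa_overlap_mode: str = "intersect"    # "intersect" | "centroid"
    aoo_cell_m: float = 2000.0
    location_cell_m: float = 10000.0
    map_cell_m: float = 5000.0

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, allow_nan=False)


def _nan_to_none(x: float) -> float | None:
    return None if x is None or (isinstance(x, float) and math.isnan(x)) else x


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_projection(run_dir: Path) -> ProjectionSpec:
    with open(run_dir / "projection.json") as fh:
        p = json.load(fh)
    return ProjectionSpec(
        projection=LambertAzimuthalEqualArea(p["lon0"], p["lat0"]),
        origin=tuple(p["origin"]),
        aoo_cell_m=p["aoo_cell_m"],
        location_cell_m=p["location_cell_m"],
        map_cell_m=p["map_cell_m"],
    )


def stage_simulate(config: RunConfig, run_dir: Path) -> dict[str, Path]:
    """Materialize synthetic inputs under <run_dir>/inputs."""
    assert config.scenario is not None
    paths = write_scenario(config.scenario, run_dir / "inputs")
    log.info("simulate: wrote %d input files", len(paths))
    return paths


def _resolve_inputs(config: RunConfig, run_dir: Path) -> dict[str, Path | None]:
    inputs = run_dir / "inputs"
    def pick(key: str, fname: str) -> Path | None:
        explicit = getattr(config, key)
        if explicit:
            return Path(explicit)
        cand = inputs / fname
        return cand if cand.exists() else None
    return {
        "occurrences": pick("occurrences", "occurrences.csv"),
        "landcover": pick("landcover", "landcover.csv"),
        "tree": pick("tree", "tree.nwk"),
        "pas": pick("pas", "pas.geojson"),
        "reference": pick("reference", "reference.csv"),
    }


def _resolve_projection(config: RunConfig, run_dir: Path, records) -> ProjectionSpec:
    if config.scenario is not None:
        spec = config.scenario.projection_spec()
        spec = dataclasses.replace(
            spec, aoo_cell_m=config.aoo_cell_m,
            location_cell_m=config.location_cell_m, map_cell_m=config.map_cell_m,
        )
    else:
        lons = [r.lon for r in records]
        lats = [r.lat for r in records]
        spec = ProjectionSpec(
            projection=LambertAzimuthalEqualArea(float(np.mean(lons)), float(np.mean(lats))),
            aoo_cell_m=config.aoo_cell_m,
            location_cell_m=config.location_cell_m,
            map_cell_m=config.map_cell_m,
        )
    _write_json(
        {"lon0": spec.projection.lon0, "lat0": spec.projection.lat0,
         "origin": list(spec.origin), "aoo_cell_m": spec.aoo_cell_m,
         "location_cell_m": spec.location_cell_m, "map_cell_m": spec.map_cell_m},
        run_dir / "projection.json",
    )
    return spec


def stage_assess(config: RunConfig, run_dir: Path) -> pd.DataFrame:
    """Criterion A + B per taxon, combined; writes assessments.csv."""
    from .io import project_points

    paths = _resolve_inputs(config, run_dir)
    if paths["occurrences"] is None:
        raise FileNotFoundError("assess stage: no occurrence file")
    records, report = read_occurrences(paths["occurrences"])
    spec = _resolve_projection(config, run_dir, records)
    points = project_points(records, spec)

    lc = None
    if paths["landcover"] is not None:
        lc = LandCoverRaster.from_csv(paths["landcover"])
    else:
        log.warning("assess: no land-cover layer; Criterion A will be DD")

    rows = []
    for tid in sorted(points):
        pts = points[tid]
        try:
            metrics = compute_range_metrics(pts, spec)
            res_b = assess_criterion_b(metrics, config.thresholds_b)
        except ValueError as exc:
            raise RuntimeError(f"criterion_b stage failed for taxon {tid}: {exc}") from exc
        if lc is None:
            cat_a, red_pct, n_threat, n_cells, n_unknown = ThreatCategory.DD, float("nan"), 0, 0, 0
        else:
            try:
                if config.criterion_a_mode == "occurrence":
                    flags = classify_points(pts, lc)
                else:
                    _, cells = compute_aoo(pts, spec)
                    flags = classify_cells(cells, lc, spec)
                res_a = assess_criterion_a(flags, config.thresholds_a)
            except ValueError as exc:
                raise RuntimeError(f"criterion_a stage failed for taxon {tid}: {exc}") from exc
            cat_a, red_pct = res_a.category, res_a.inferred_reduction_pct
            n_threat, n_cells, n_unknown = res_a.n_threatened, res_a.n_cells, res_a.n_unknown
        comb = combine(tid, cat_a, res_b.category)
        rows.append({
            "taxon_id": tid,
            "n_points": metrics.n_points,
            "eoo_km2": metrics.eoo_km2,
            "effective_eoo_km2": metrics.effective_eoo_km2,
            "aoo_km2": metrics.aoo_km2,
            "n_locations": metrics.n_locations,
            "eoo_degenerate": metrics.eoo_degenerate,
            "subcriteria_B": "+".join(sorted(res_b.triggered_subcriteria)),
            "n_cells_A": n_cells, "n_threatened_A": n_threat, "n_unknown_A": n_unknown,
            "reduction_pct_A": red_pct,
            "category_A": comb.category_a.value,
            "category_B": comb.category_b.value,
            "category_combined": comb.category_combined.value,
            "is_threatened": comb.is_threatened,
        })
    df = pd.DataFrame(rows).sort_values("taxon_id", ignore_index=True)
    df.to_csv(run_dir / "assessments.csv", index=False, float_format="%.10g")
    log.info("assess: %d taxa (%d rejected occurrence rows)", len(df), report.n_rejected)
    return df


def load_assessments(run_dir: Path) -> list[CombinedAssessment]:
    df = pd.read_csv(run_dir / "assessments.csv")
    return [
        combine(str(r.taxon_id), ThreatCategory(r.category_A), ThreatCategory(r.category_B))
        for r in df.itertuples(index=False)
    ]


def stage_edge(config: RunConfig, run_dir: Path) -> dict[str, EdgeScore] | None:
    """EDGE scores from the tree + combined categories; writes edge_scores.csv.

    Skipped with a warning when no tree is available.
    """
    paths = _resolve_inputs(config, run_dir)
    if paths["tree"] is None:
        log.warning("edge: no tree available; stage skipped")
        return None
    tree = read_tree(paths["tree"])
    cats = {a.taxon_id: a.category_combined for a in load_assessments(run_dir)}
    scores, skipped = edge_scores_for(tree, cats)
    df = pd.DataFrame(
        {"taxon_id": list(scores),
         "ed": [s.ed for s in scores.values()],
         "ge": [s.ge for s in scores.values()],
         "edge": [s.edge for s in scores.values()]}
    ).sort_values("taxon_id", ignore_index=True)
    df.to_csv(run_dir / "edge_scores.csv", index=False, float_format="%.10g")
    if skipped:
        log.warning("edge: %d taxa skipped (absent from tree or DD)", len(skipped))
    return scores


def stage_grid(config: RunConfig, run_dir: Path) -> pd.DataFrame:
    """Surfaces + L1 hotspot GeoJSONs from assessments and EDGE scores."""
    from .io import project_points

    paths = _resolve_inputs(config, run_dir)
    records, _ = read_occurrences(paths["occurrences"])
    spec = _load_projection(run_dir)
    points = project_points(records, spec)
    assessments = load_assessments(run_dir)
    scores: dict[str, EdgeScore] = {}
    edge_path = run_dir / "edge_scores.csv"
    if edge_path.exists():
        for r in pd.read_csv(edge_path).itertuples(index=False):
            scores[str(r.taxon_id)] = EdgeScore(str(r.taxon_id), float(r.ed), int(r.ge), float(r.edge))

    cellmap = rasterize_taxa(points, spec)
    surface = build_surfaces(cellmap, assessments, scores)
    write_surface_csv(surface, run_dir / "surfaces.csv")

    for metric in HOTSPOT_METRICS:
        if metric == "mean_edge" and not scores:
            continue
        hs = l1_hotspots(surface, metric, config.hotspot_quantile)
        cells = sorted(hs.cells)
        write_polygons(
            [cell_polygon(i, j, spec) for i, j in cells],
            run_dir / f"hotspots_{METRIC_LABELS[metric]}.geojson",
            properties=[
                {"cell_i": i, "cell_j": j, "metric": METRIC_LABELS[metric],
                 "threshold": hs.threshold} for i, j in cells
            ],
        )
    return surface


def stage_overlap(config: RunConfig, run_dir: Path) -> dict:
    """PA gap analysis for every hotspot metric; writes pa_overlap.json."""
    paths = _resolve_inputs(config, run_dir)
    spec = _load_projection(run_dir)
    pas = read_protected_areas(paths["pas"]) if paths["pas"] is not None else []
    if not pas:
        log.warning("overlap: empty PA set; all hotspots fall outside")
    surface = pd.read_csv(run_dir / "surfaces.csv")
    out = {}
    for metric in HOTSPOT_METRICS:
        label = METRIC_LABELS[metric]
        if not (run_dir / f"hotspots_{label}.geojson").exists():
            continue
        hs = l1_hotspots(surface, metric, config.hotspot_quantile)
        rep = pa_overlap(hs, pas, spec, mode=config.pa_overlap_mode)
        out[label] = {
            "n_hotspots": rep.n_hotspots, "n_inside": rep.n_inside,
            "n_outside": rep.n_outside,
            "pct_inside": _nan_to_none(rep.pct_inside),
            "pct_outside": _nan_to_none(rep.pct_outside),
            "mode": config.pa_overlap_mode,
        }
    _write_json(out, run_dir / "pa_overlap.json")
    return out


def stage_validate(config: RunConfig, run_dir: Path) -> dict | None:
    """Confusion-matrix validation against the reference table, if present."""
    paths = _resolve_inputs(config, run_dir)
    if paths["reference"] is None:
        log.warning("validate: no reference table; stage skipped")
        return None
    ref_df = pd.read_csv(paths["reference"])
    reference = {
        str(r.taxon_id): ThreatCategory(r.category) for r in ref_df.itertuples(index=False)
    }
    report = validate(load_assessments(run_dir), reference)
    out = {
        "TP": report.tp, "FP": report.fp, "TN": report.tn, "FN": report.fn,
        "n_reference": report.n_reference, "n_unmatched": report.n_unmatched,
        "accuracy": _nan_to_none(report.accuracy),
        "sensitivity": _nan_to_none(report.sensitivity),
        "specificity": _nan_to_none(report.specificity),
        "balanced_accuracy": _nan_to_none(report.balanced_accuracy),
    }
    _write_json(out, run_dir / "validation.json")
    return out


def run_pipeline(config: RunConfig, run_dir: str | Path) -> Path:
    """Run every stage end to end and write the run manifest."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    if config.scenario is not None:
        stage_simulate(config, run_dir)
    stage_assess(config, run_dir)
    stage_edge(config, run_dir)
    stage_grid(config, run_dir)
    stage_overlap(config, run_dir)
    stage_validate(config, run_dir)

    outputs = sorted(
        p for p in run_dir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package": "edgegrid",
        "version": __version__,
        "seed": config.scenario.seed if config.scenario else None,
        "config": config.to_jsonable(),
        "checksums": {str(p.relative_to(run_dir)): _sha256(p) for p in outputs},
    }
    _write_json(manifest, run_dir / "manifest.json")
    return run_dir
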