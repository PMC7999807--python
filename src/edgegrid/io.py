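"""Readers and writers for the pipeline's external formats.

Occurrences come in as delimited text (configurable column names), the
phylogeny as Newick, protected areas and hotspot exports as GeoJSON
polygons, grid surfaces and assessments as CSV. Everything written here is
plain text and round-trips through the matching reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape

from .projection import ProjectionSpec


@dataclass(frozen=True)
class OccurrenceRecord:
    """One georeferenced observation of a taxon (WGS84 decimal degrees)."""

    taxon_id: str
    lon: float
    lat: float

    def __post_init__(self):
        if not self.taxon_id:
            raise ValueError("taxon_id must be non-empty")
        if not (-180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0):
            raise ValueError(f"coordinates out of range: ({self.lon}, {self.lat})")


@dataclass
class ReadReport:
    """Counts from a validated read: kept rows and rejected rows."""

    n_read: int = 0
    n_valid: int = 0
    n_rejected: int = 0
    rejections: list[str] = field(default_factory=list)


def read_occurrences(
    path: str | Path,
    taxon_col: str = "taxon_id",
    lon_col: str = "lon",
    lat_col: str = "lat",
    sep: str = ",",
) -> tuple[list[OccurrenceRecord], ReadReport]:
    """Read a delimited occurrence table into validated records.

    Rows with unparsable or out-of-range coordinates are dropped and counted
    in the report; the reader does not deduplicate (dedup happens at
    projection time, on occupied space not record counts).

    Raises ``KeyError`` if a mapped column is missing and ``ValueError`` if
    the file yields zero valid rows.
    """
    df = pd.read_csv(path, sep=sep)
    for col in (taxon_col, lon_col, lat_col):
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in {path}")
    report = ReadReport(n_read=len(df))
    records: list[OccurrenceRecord] = []
    for row in df.itertuples(index=False):
        tid = str(getattr(row, taxon_col))
        try:
            rec = OccurrenceRecord(tid, float(getattr(row, lon_col)), float(getattr(row, lat_col)))
        except (ValueError, TypeError) as exc:
            report.n_rejected += 1
            report.rejections.append(f"{tid}: {exc}")
            continue
        records.append(rec)
    report.n_valid = len(records)
    if not records:
        raise ValueError(f"no valid occurrence rows in {path}")
    return records, report


def write_occurrences(records: list[OccurrenceRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {"taxon_id": [r.taxon_id for r in records],
         "lon": [r.lon for r in records],
         "lat": [r.lat for r in records]}
    )
    df.to_csv(path, index=False, float_format="%.10g")


def project_points(
    records: list[OccurrenceRecord], spec: ProjectionSpec
) -> dict[str, np.ndarray]:
    """Per-taxon arrays of unique projected points, shape (n, 2), metres.

    Exact duplicate lon/lat rows collapse to one point; near-duplicates are
    kept. The equal-area projection makes downstream km2 areas meaningful.
    """
    by_taxon: dict[str, set[tuple[float, float]]] = {}
    for rec in records:
        by_taxon.setdefault(rec.taxon_id, set()).add((rec.lon, rec.lat))
    out: dict[str, np.ndarray] = {}
    for tid, pts in by_taxon.items():
        arr = np.array(sorted(pts), dtype=float)
        x, y = spec.projection.forward(arr[:, 0], arr[:, 1])
        out[tid] = np.column_stack([x, y])
    return out


def read_tree(path: str | Path) -> dendropy.Tree:
    """Parse a rooted Newick tree with branch lengths; validate tip labels.

    Raises ``ValueError`` on duplicate tip labels or missing branch lengths
    (the root edge may be absent or zero).
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels in tree")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise ValueError("tree has edges without branch lengths")
        if node.edge.length < 0:
            raise ValueError("negative branch length in tree")
    return tree


def read_protected_areas(path: str | Path) -> list[Polygon]:
    """Read PA polygons from a GeoJSON FeatureCollection (analysis plane).

    Invalid polygons are repaired with a zero-width buffer.
    """
    with open(path) as fh:
        gj = json.load(fh)
    polys: list[Polygon] = []
    for feat in gj.get("features", []):
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            geom = geom.buffer(0)
        if geom.geom_type == "Polygon":
            polys.append(geom)
        elif geom.geom_type == "MultiPolygon":
            polys.extend(geom.geoms)
    return polys


def write_polygons(polys: list[Polygon], path: str | Path, properties: list[dict] | None = None) -> None:
    feats = []
    for k, poly in enumerate(polys):
        props = properties[k] if properties else {}
        feats.append({"type": "Feature", "properties": props, "geometry": mapping(poly)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1, sort_keys=True)


def write_surface_csv(surface: pd.DataFrame, path: str | Path) -> None:
    """Write a grid surface (one row per cell, indexed by cell_i/cell_j)."""
    surface.sort_values(["cell_i", "cell_j"]).to_csv(path, index=False, float_format="%.10g")


def read_surface_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
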