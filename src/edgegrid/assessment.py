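"""Criterion combination, validation against a reference set, summaries.

The combined category is the maximum-severity join of the Criterion A and
Criterion B categories (a taxon is CR overall if either criterion rates it
CR). Validation aggregates categories into threatened (CR, EN, VU) vs not
threatened (LC, NT) and scores the binary classifier with a confusion
matrix; DD rows on either side are excluded, as reference sets exclude
data-deficient taxa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .categories import ASSESSABLE, ThreatCategory, max_severity


@dataclass(frozen=True)
class CombinedAssessment:
    taxon_id: str
    category_a: ThreatCategory
    category_b: ThreatCategory
    category_combined: ThreatCategory
    is_threatened: bool


@dataclass(frozen=True)
class ValidationReport:
    """Binary confusion matrix with "threatened" as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int
    n_reference: int
    n_unmatched: int
    accuracy: float
    sensitivity: float  # NaN when the reference has no threatened taxa
    specificity: float
    balanced_accuracy: float


def combine(
    taxon_id: str, category_a: ThreatCategory, category_b: ThreatCategory
) -> CombinedAssessment:
    """Maximum-severity combination; DD on one side defers to the other."""
    combined = max_severity(category_a, category_b)
    return CombinedAssessment(
        taxon_id=taxon_id,
        category_a=category_a,
        category_b=category_b,
        category_combined=combined,
        is_threatened=combined.is_threatened,
    )


def validate(
    predicted: list[CombinedAssessment],
    reference: dict[str, ThreatCategory],
) -> ValidationReport:
    """Score predictions against a reference assessment table.

    Taxa missing from either side, and DD taxa on either side, are excluded
    and counted as unmatched. Raises ``ValueError`` if no taxa match.
    """
    pred_by_id = {a.taxon_id: a for a in predicted}
    tp = fp = tn = fn = 0
    n_unmatched = 0
    for tid, ref_cat in reference.items():
        pred = pred_by_id.get(tid)
        if pred is None or ref_cat is ThreatCategory.DD or pred.category_combined is ThreatCategory.DD:
            n_unmatched += 1
            continue
        ref_pos = ref_cat.is_threatened
        pred_pos = pred.is_threatened
        if pred_pos and ref_pos:
            tp += 1
        elif pred_pos and not ref_pos:
            fp += 1
        elif not pred_pos and not ref_pos:
            tn += 1
        else:
            fn += 1
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("no taxa shared between predictions and reference")
    sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    bal = (sens + spec) / 2.0 if not (math.isnan(sens) or math.isnan(spec)) else float("nan")
    return ValidationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        n_reference=n,
        n_unmatched=n_unmatched,
        accuracy=(tp + tn) / n,
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=bal,
    )


def assessments_to_frame(assessments: list[CombinedAssessment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon_id": [a.taxon_id for a in assessments],
            "category_A": [a.category_a.value for a in assessments],
            "category_B": [a.category_b.value for a in assessments],
            "category_combined": [a.category_combined.value for a in assessments],
            "is_threatened": [a.is_threatened for a in assessments],
        }
    ).sort_values("taxon_id", ignore_index=True)


def category_summaries(
    assessments: list[CombinedAssessment],
    taxonomy: pd.DataFrame | None = None,
    min_group_size: int = 10,
) -> dict[str, pd.DataFrame]:
    """Per-category proportion tables: overall, per criterion, per group.

    ``taxonomy`` may map taxon_id to family and/or genus columns; groups
    with fewer than ``min_group_size`` taxa are excluded from ranked group
    tables. Proportions are in percent and sum to 100 per table row-set.
    """
    df = assessments_to_frame(assessments)
    cats = [c.value for c in ASSESSABLE] + [ThreatCategory.DD.value]

    def table(series: pd.Series) -> pd.DataFrame:
        counts = series.value_counts().reindex(cats, fill_value=0)
        out = pd.DataFrame({"category": cats, "n": counts.values})
        out["pct"] = 100.0 * out["n"] / max(out["n"].sum(), 1)
        return out

    result = {
        "combined": table(df["category_combined"]),
        "criterion_A": table(df["category_A"]),
        "criterion_B": table(df["category_B"]),
    }
    if taxonomy is not None:
        merged = df.merge(taxonomy, on="taxon_id", how="left")
        for level in ("family", "genus"):
            if level not in merged.columns:
                continue
            rows = []
            for name, grp in merged.groupby(level):
                if len(grp) < min_group_size:
                    continue
                n_threat = int(grp["is_threatened"].sum())
                n_cr = int((grp["category_combined"] == "CR").sum())
                rows.append(
                    {level: name, "n_taxa": len(grp), "n_threatened": n_threat,
                     "n_cr": n_cr, "pct_cr": 100.0 * n_cr / len(grp)}
                )
            if rows:
                result[level] = (
                    pd.DataFrame(rows).sort_values(["n_cr", level], ascending=[False, True], ignore_index=True)
                )
    return result
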