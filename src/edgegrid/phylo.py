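"""Fair-proportion evolutionary distinctiveness (ED) and EDGE scores.

ED apportions each branch of the time-calibrated tree equally among the
tips descending from it: ED(tip) = sum over root-to-tip edges of
(edge length / number of descendant tips). Summed over all tips this
returns exactly the tree's total branch length (its phylogenetic
diversity) — the defining property of the fair-proportion measure.

The EDGE score combines ED with the threat weight GE (LC=0, NT=1, VU=2,
EN=3, CR=4):

    EDGE = ln(1 + ED) + GE * ln 2

so each one-category increase in threat adds exactly ln 2, encoding a
two-fold increase in extinction risk per Red List step. Natural logarithms
throughout. Polytomies are allowed; descendant counts are taken on the
tree as given.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy

from .categories import ThreatCategory

LN2 = math.log(2.0)


@dataclass(frozen=True)
class EdgeScore:
    taxon_id: str
    ed: float
    ge: int
    edge: float


def fair_proportion_ed(tree: dendropy.Tree) -> dict[str, float]:
    """Fair-proportion ED per tip label, in the tree's length units (Myr).

    A tree whose branch lengths are all zero yields ED = 0 for every tip.
    """
    n_leaves: dict[int, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            n_leaves[id(node)] = 1
        else:
            n_leaves[id(node)] = sum(n_leaves[id(c)] for c in node.child_nodes())

    acc: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length or 0.0
        acc[id(node)] = acc[id(node.parent_node)] + length / n_leaves[id(node)]
    return {leaf.taxon.label: acc[id(leaf)] for leaf in tree.leaf_node_iter()}


def edge_score(taxon_id: str, ed: float, category: ThreatCategory) -> EdgeScore:
    """EDGE = ln(1+ED) + GE*ln2; DD taxa have no defined score."""
    if ed < 0:
        raise ValueError("ED must be non-negative")
    if category is ThreatCategory.DD:
        raise ValueError("EDGE is undefined for DD taxa")
    ge = category.ge_weight
    return EdgeScore(taxon_id=taxon_id, ed=ed, ge=ge, edge=math.log1p(ed) + ge * LN2)


def edge_scores_for(
    tree: dendropy.Tree, categories: dict[str, ThreatCategory]
) -> tuple[dict[str, EdgeScore], list[str]]:
    """Score every tree tip with a non-DD category.

    Returns (scores, skipped): taxa absent from the tree or rated DD get no
    score and are listed in ``skipped`` for the run report.
    """
    eds = fair_proportion_ed(tree)
    scores: dict[str, EdgeScore] = {}
    skipped: list[str] = []
    for tid, cat in sorted(categories.items()):
        if tid not in eds or cat is ThreatCategory.DD:
            skipped.append(tid)
            continue
        scores[tid] = edge_score(tid, eds[tid], cat)
    return scores, skipped
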