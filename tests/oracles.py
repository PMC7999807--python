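"""Independent brute-force oracles used by the test suite.

Each oracle is coded from first principles, sharing no geometry, binning
or traversal code with the package, so an agreement test is a genuine
dual-route check.
"""

from __future__ import annotations

import math


# ---------------------------------------------------------------- geometry

def hull_area_oracle(points) -> float:
    """Convex-hull area via Jarvis march (gift wrapping), O(n^2)-O(n^3).

    Returns 0.0 for fewer than 3 non-collinear points. ``points`` is a
    sequence of (x, y) pairs.
    """
    pts = sorted(set((float(x), float(y)) for x, y in points))
    if len(pts) < 3:
        return 0.0
    start = min(pts)
    hull = [start]
    current = start
    while True:
        candidate = None
        for p in pts:
            if p == current:
                continue
            if candidate is None:
                candidate = p
                continue
            cross = ((candidate[0] - current[0]) * (p[1] - current[1])
                     - (candidate[1] - current[1]) * (p[0] - current[0]))
            if cross < 0:
                candidate = p
            elif cross == 0:  # collinear: keep the farther point
                d_c = (candidate[0] - current[0]) ** 2 + (candidate[1] - current[1]) ** 2
                d_p = (p[0] - current[0]) ** 2 + (p[1] - current[1]) ** 2
                if d_p > d_c:
                    candidate = p
        if candidate == start or candidate is None:
            break
        hull.append(candidate)
        current = candidate
        if len(hull) > len(pts):  # safety for degenerate inputs
            break
    if len(hull) < 3:
        return 0.0
    area2 = 0.0
    for k in range(len(hull)):
        x1, y1 = hull[k]
        x2, y2 = hull[(k + 1) % len(hull)]
        area2 += x1 * y2 - x2 * y1
    return abs(area2) / 2.0


def binning_oracle(points, origin, cell) -> set[tuple[int, int]]:
    """Occupied half-open grid cells by plain floor division."""
    x0, y0 = origin
    return {
        (math.floor((x - x0) / cell), math.floor((y - y0) / cell))
        for x, y in points
    }


# --------------------------------------------------------- decision tables

def criterion_b_oracle(eoo, aoo, nloc, nt_buffer=True) -> str:
    """Independent Criterion B decision table (IUCN B1/B2 thresholds)."""
    eff = max(eoo, aoo)

    def b1():
        if eff < 100 and nloc <= 1:
            return 5
        if eff < 5000 and nloc <= 5:
            return 4
        if eff < 20000 and nloc <= 10:
            return 3
        return 1

    def b2():
        if aoo < 10 and nloc <= 1:
            return 5
        if aoo < 500 and nloc <= 5:
            return 4
        if aoo < 2000 and nloc <= 10:
            return 3
        return 1

    rank = max(b1(), b2())
    if rank == 1 and nt_buffer and (eff < 30000 or aoo < 3000) and nloc <= 15:
        rank = 2
    return {5: "CR", 4: "EN", 3: "VU", 2: "NT", 1: "LC"}[rank]


def criterion_a_oracle(pct, nt_buffer=True) -> str:
    """Independent Criterion A decision table (A2 percent thresholds)."""
    if pct >= 80:
        return "CR"
    if pct >= 50:
        return "EN"
    if pct >= 30:
        return "VU"
    if nt_buffer and pct >= 20:
        return "NT"
    return "LC"


SEVERITY = {"CR": 5, "EN": 4, "VU": 3, "NT": 2, "LC": 1}


def pairwise_max_oracle(cat_a: str, cat_b: str) -> str:
    """Severity join of two non-DD categories."""
    return cat_a if SEVERITY[cat_a] >= SEVERITY[cat_b] else cat_b


def tally_oracle(pred_threat: dict[str, bool], ref_threat: dict[str, bool]):
    """Hand-rolled 2x2 confusion tally over the shared taxa."""
    tp = fp = tn = fn = 0
    for tid, ref in ref_threat.items():
        if tid not in pred_threat:
            continue
        pred = pred_threat[tid]
        if pred and ref:
            tp += 1
        elif pred and not ref:
            fp += 1
        elif not pred and not ref:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


# ----------------------------------------------------------------- phylo

def ed_path_walk_oracle(tree) -> dict[str, float]:
    """Fair-proportion ED by walking each tip's path to the root and
    counting descendants of every edge by full subtree enumeration.

    ``tree`` is a dendropy Tree.
    """

    def n_tips_below(node) -> int:
        return sum(1 for _ in node.leaf_iter())

    out = {}
    for leaf in tree.leaf_node_iter():
        total = 0.0
        node = leaf
        while node.parent_node is not None:
            length = node.edge.length or 0.0
            total += length / n_tips_below(node)
            node = node.parent_node
        out[leaf.taxon.label] = total
    return out


def total_branch_length(tree) -> float:
    return sum(
        (n.edge.length or 0.0)
        for n in tree.preorder_node_iter()
        if n.parent_node is not None
    )


# --------------------------------------------------------------- hotspots

def hotspot_oracle(values: dict, quantile: float = 0.01) -> set:
    """Sort-and-slice top-quantile selection with tie expansion.

    ``values`` maps cell id -> metric value; returns the member cell ids.
    """
    items = sorted(values.items(), key=lambda kv: -kv[1])
    n = len(items)
    k = max(1, math.ceil(quantile * n))
    threshold = items[k - 1][1]
    return {cid for cid, v in items if v >= threshold}


def pa_point_sampling_oracle(cell_bounds, pa_rects, step=100.0) -> bool:
    """True iff the cell intersects any axis-aligned PA rectangle, decided
    by dense point sampling at ``step`` metres (plus interval logic for
    exactness on rectangles)."""
    xmin, ymin, xmax, ymax = cell_bounds
    for (rx0, ry0, rx1, ry1) in pa_rects:
        x = xmin
        while x <= xmax:
            y = ymin
            while y <= ymax:
                if rx0 <= x <= rx1 and ry0 <= y <= ry1:
                    return True
                y += step
            x += step
    return False
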