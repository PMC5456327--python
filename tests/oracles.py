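"""Independent brute-force reference implementations used as oracles.

These deliberately avoid the code paths they check: plain loops and
first-principles formulas only.
"""

from __future__ import annotations

import numpy as np


def holm_stepdown(pvalues):
    """Holm adjusted p-values straight from the step-down definition."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        candidate = min(1.0, (m - rank) * p[idx])
        running = max(running, candidate)
        adjusted[idx] = running
    return adjusted


def kappa_2x2(a, b, universe):
    """Cohen's kappa from an explicitly tabulated 2x2 agreement table."""
    both = neither = only_a = only_b = 0
    for g in universe:
        in_a, in_b = g in a, g in b
        if in_a and in_b:
            both += 1
        elif in_a:
            only_a += 1
        elif in_b:
            only_b += 1
        else:
            neither += 1
    n = both + neither + only_a + only_b
    po = (both + neither) / n
    marg_a = (both + only_a) / n
    marg_b = (both + only_b) / n
    pe = marg_a * marg_b + (1 - marg_a) * (1 - marg_b)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def consistency_by_enumeration(features, group, studies):
    """Per-cluster direction multiset enumeration for the consensus merge.

    Returns (consensus: dict cluster -> (mean_ratio, n_studies),
    removed: set of clusters).
    """
    group_of = dict(zip(studies["study_id"], studies["group"]))
    per_cluster: dict[str, list[float]] = {}
    for row in features.itertuples(index=False):
        if group_of[row.study_id] == group:
            per_cluster.setdefault(row.cluster_id, []).append(row.ratio)
    consensus, removed = {}, set()
    for cluster, ratios in per_cluster.items():
        directions = {"up" if r > 1 else "down" for r in ratios}
        if len(directions) > 1:
            removed.add(cluster)
        else:
            consensus[cluster] = (sum(ratios) / len(ratios), len(ratios))
    return consensus, removed


def average_linkage_cophenetic(D):
    """O(n^3) UPGMA agglomeration from a square distance matrix.

    Returns (cophenetic matrix, merge heights in order). Inter-cluster
    distance is the mean of all pairwise original distances.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    members = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    heights = []
    while len(members) > 1:
        keys = sorted(members)
        best = None
        for ai, i in enumerate(keys):
            for j in keys[ai + 1:]:
                d = float(np.mean([D[a, b] for a in members[i]
                                   for b in members[j]]))
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        for a in members[i]:
            for b in members[j]:
                coph[a, b] = coph[b, a] = d
        members[min(i, j)] = members.pop(i) + members.pop(j)
    return coph, heights
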