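"""Independent brute-force oracles used only by the test suite.

Each function re-derives a quantity by a different route than the package
(explicit path walks, pairwise enumeration, naive agglomeration) so that
agreement is a genuine cross-check rather than a re-run of the same code.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import gammaln


def _node_tipset(node):
    tips = {t.name for t in node.tips()}
    return tips if tips else {node.name}


def unweighted_unifrac_oracle(tree, present_a, present_b) -> float:
    """UniFrac via explicit root-to-tip path edge sets."""

    def edge_set(present):
        edges = set()
        for name in present:
            node = tree.find(name)
            while node.parent is not None:
                edges.add(id(node))
                node = node.parent
        return edges

    lengths = {id(n): (n.length or 0.0) for n in tree.traverse(include_self=False)}
    ea, eb = edge_set(present_a), edge_set(present_b)
    union = sum(lengths[e] for e in ea | eb)
    unique = sum(lengths[e] for e in ea ^ eb)
    return unique / union if union > 0 else 0.0


def weighted_unifrac_oracle(tree, counts_a, counts_b, normalized=True) -> float:
    """Weighted UniFrac by per-branch summation over explicit tip sets.

    ``counts_x`` map tip name -> count.
    """
    ta = sum(counts_a.values())
    tb = sum(counts_b.values())
    num = den = 0.0
    for node in tree.traverse(include_self=False):
        tips = _node_tipset(node)
        pa = sum(counts_a.get(t, 0) for t in tips) / ta
        pb = sum(counts_b.get(t, 0) for t in tips) / tb
        length = node.length or 0.0
        num += length * abs(pa - pb)
        den += length * (pa + pb)
    if not normalized:
        return num
    return num / den if den > 0 else 0.0


def faith_pd_oracle(tree, present) -> float:
    """Faith's PD as the union of root-to-tip edge sets of the present tips."""
    edges = set()
    for name in present:
        node = tree.find(name)
        while node.parent is not None:
            edges.add(node)
            node = node.parent
    return sum(e.length or 0.0 for e in edges)


def expected_rarefied_richness(counts, depth) -> float:
    """Closed-form E[S] under subsampling without replacement.

    E[S] = sum_i (1 - C(N - N_i, d) / C(N, d)).
    """

    def log_comb(n, k):
        if k > n:
            return -np.inf
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    counts = np.asarray(counts)
    total = counts.sum()
    out = 0.0
    for ni in counts[counts > 0]:
        out += 1.0 - np.exp(log_comb(total - ni, depth) - log_comb(total, depth))
    return out


def vcv_oracle(tree) -> dict:
    """MRCA depths via explicit root-to-tip node paths for every tip pair."""

    def path(node):
        nodes = []
        while node is not None:
            nodes.append(node)
            node = node.parent
        return nodes[::-1]  # root first

    def depth_to(node):
        d = 0.0
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        return d

    tips = list(tree.tips())
    out = {}
    for a, b in itertools.combinations_with_replacement(tips, 2):
        if a is b:
            out[(a.name, b.name)] = depth_to(a)
            continue
        pa, pb = path(a), path(b)
        mrca = None
        for na, nb in zip(pa, pb):
            if na is nb:
                mrca = na
            else:
                break
        out[(a.name, b.name)] = out[(b.name, a.name)] = depth_to(mrca)
    return out


def permanova_ss_oracle(d, labels):
    """Pseudo-F and R^2 by direct pairwise enumeration of the SS partition."""
    d = np.asarray(d, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    groups, counts = np.unique(labels, return_counts=True)
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g, ng in zip(groups, counts):
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(
            d[i, j] ** 2 for i, j in itertools.combinations(idx, 2)
        ) / ng
    ss_between = ss_total - ss_within
    a = len(groups)
    f = (ss_between / (a - 1)) / (ss_within / (n - a)) if ss_within > 0 else np.inf
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def average_linkage_heights_oracle(d, ids) -> list[float]:
    """Merge heights of naive O(n^3) average-linkage agglomeration.

    Cluster distance is the mean of the original pairwise distances across
    the two clusters (UPGMA on the full matrix).
    """
    d = np.asarray(d, dtype=float)
    index = {name: i for i, name in enumerate(ids)}
    clusters = [frozenset([name]) for name in ids]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            dist = np.mean(
                [
                    d[index[x], index[y]]
                    for x in clusters[a]
                    for y in clusters[b]
                ]
            )
            key = (dist, tuple(sorted(clusters[a] | clusters[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        (dist, _), a, b = best
        heights.append(dist)
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return heights


def bipartitions_oracle(tree) -> set[frozenset]:
    """Non-trivial splits by walking every internal edge explicitly."""
    all_tips = frozenset(t.name for t in tree.tips())
    n = len(all_tips)
    ref = min(all_tips)
    splits = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > n - 2:
            continue
        splits.add(side if ref not in side else all_tips - side)
    return splits
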