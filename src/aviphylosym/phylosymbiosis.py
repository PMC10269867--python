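"""Phylosymbiosis: congruence between the host phylogeny and a dendrogram of
microbial community similarity.

A per-species UniFrac matrix is clustered into a dendrogram; topological
congruence with the host tree is the normalized Robinson-Foulds distance
nRF = |splits(T1) symmetric-difference splits(T2)| / (|splits(T1)| + |splits(T2)|)
over non-trivial unrooted bipartitions, so nRF = 0 means identical topologies
and nRF = 1 means no shared split. Significance comes from shuffling the tip
labels on the fixed dendrogram topology and recomputing nRF; the p-value is
the fraction of shuffles at least as congruent (nRF_perm <= nRF_obs) as
observed, out of (by default) 1,000 shuffles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from skbio import DistanceMatrix, TreeNode

from . import rarefaction_alpha
from .beta_diversity import distance_matrix

LINKAGES = ("complete", "average", "single", "ward")


def species_mean_distance(dm: DistanceMatrix, meta: pd.DataFrame) -> DistanceMatrix:
    """Collapse a sample-level distance matrix to species level.

    The entry for a species pair is the mean of all between-sample distances
    across the two species; the diagonal is zero.
    """
    species = meta.loc[list(dm.ids), "species"]
    groups = {sp: np.flatnonzero(species.to_numpy() == sp)
              for sp in pd.unique(species)}
    ids = sorted(groups)
    out = np.zeros((len(ids), len(ids)))
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            b = ids[j]
            block = dm.data[np.ix_(groups[a], groups[b])]
            out[i, j] = out[j, i] = float(block.mean())
    return DistanceMatrix(out, ids=ids)


def hierarchical_cluster(dm: DistanceMatrix, linkage: str = "complete") -> TreeNode:
    """Agglomerative clustering of a distance matrix into a rooted,
    ultrametric, binary dendrogram.

    Ids are sorted lexicographically before clustering so that equal-height
    merge candidates resolve toward the smallest member id, making the
    dendrogram deterministic.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    if len(dm.ids) < 2:
        raise ValueError("clustering needs at least two ids")
    if np.isnan(dm.data).any():
        raise ValueError("distance matrix contains NaN")
    ids = sorted(dm.ids)
    d = dm.filter(ids)
    condensed = d.condensed_form()
    z = hierarchy.linkage(condensed, method=linkage)
    root_cluster = hierarchy.to_tree(z)

    def build(cluster, parent_height):
        height = cluster.dist / 2.0  # ultrametric node height
        if cluster.is_leaf():
            node = TreeNode(name=ids[cluster.id])
            node.length = parent_height
            return node
        node = TreeNode(
            children=[build(cluster.left, height), build(cluster.right, height)]
        )
        node.length = parent_height - height
        return node

    tree = build(root_cluster, root_cluster.dist / 2.0)
    tree.length = None
    return tree


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial unrooted bipartitions of a tree's tip set.

    Each split is represented canonically by the side not containing the
    lexicographically smallest tip. Pendant edges and the root's trivial
    edge are excluded; trees with fewer than four tips have no non-trivial
    split.
    """
    tips = sorted(t.name for t in tree.tips())
    n = len(tips)
    if n < 4:
        return set()
    ref = tips[0]
    all_tips = frozenset(tips)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= n - 2:
            splits.add(side if ref not in side else all_tips - side)
    return splits


def normalized_rf(tree_a: TreeNode, tree_b: TreeNode) -> tuple[float, int]:
    """Normalized Robinson-Foulds distance and the shared-split count.

    The two trees must carry identical tip sets (prune the host tree first).
    nRF is the symmetric-difference count over the total number of
    non-trivial splits in the two trees (2(n-3) for two binary trees); a
    pair of trees with no non-trivial splits has nRF 0 by convention.
    """
    tips_a = {t.name for t in tree_a.tips()}
    tips_b = {t.name for t in tree_b.tips()}
    if tips_a != tips_b:
        raise ValueError(
            f"tip sets differ: only in first {sorted(tips_a - tips_b)[:10]}, "
            f"only in second {sorted(tips_b - tips_a)[:10]}"
        )
    s_a, s_b = bipartitions(tree_a), bipartitions(tree_b)
    denom = len(s_a) + len(s_b)
    rf = len(s_a ^ s_b)
    nrf = rf / denom if denom > 0 else 0.0
    return nrf, len(s_a & s_b)


@dataclass
class PhylosymbiosisResult:
    n: int
    nRF: float
    congruent_splits: int
    p: float
    p_plus_one: float  # (count+1)/(n_perm+1) never-zero variant
    n_perm: int
    seed: int
    body_site: str | None = None
    metric: str | None = None
    linkage: str | None = None
    status: str = "ok"
    null_mean_nRF: float = field(default=float("nan"))


def permutation_test(
    host_tree: TreeNode, dendrogram: TreeNode, n_perm: int = 1000, seed: int = 0
) -> PhylosymbiosisResult:
    """Tip-shuffle permutation test of host-tree/dendrogram congruence.

    Tip labels are shuffled uniformly at random on the fixed dendrogram
    topology; p is the fraction of shuffles whose nRF is less than or equal
    to the observed nRF (more congruent or equivalent).
    """
    labels = sorted(t.name for t in dendrogram.tips())
    n = len(labels)
    if n < 5:
        raise ValueError("permutation test needs at least 5 shared tips")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-value resolution is coarse")
    nrf_obs, congruent = normalized_rf(host_tree, dendrogram)
    host_splits = bipartitions(host_tree)
    n_host = len(host_splits)
    # dendrogram splits as index sets over the sorted label vector
    index_of = {name: i for i, name in enumerate(labels)}
    dendro_index_splits = [
        np.fromiter((index_of[t] for t in side), dtype=int)
        for side in bipartitions(dendrogram)
    ]
    n_dendro = len(dendro_index_splits)
    denom = n_host + n_dendro
    all_tips = frozenset(labels)
    ref = min(labels)
    rng = np.random.default_rng(seed)
    label_arr = np.array(labels)
    hits = 0
    null_sum = 0.0
    for _ in range(n_perm):
        perm = rng.permutation(label_arr)
        shared = 0
        for idx in dendro_index_splits:
            side = frozenset(perm[idx])
            if ref in side:
                side = all_tips - side
            if side in host_splits:
                shared += 1
        nrf_perm = (denom - 2 * shared) / denom if denom > 0 else 0.0
        null_sum += nrf_perm
        if nrf_perm <= nrf_obs:
            hits += 1
    return PhylosymbiosisResult(
        n=n, nRF=nrf_obs, congruent_splits=congruent,
        p=hits / n_perm, p_plus_one=(hits + 1) / (n_perm + 1),
        n_perm=n_perm, seed=seed, null_mean_nRF=null_sum / max(n_perm, 1),
    )


def run_phylosymbiosis(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    asv_tree: TreeNode,
    host_tree: TreeNode,
    body_site: str,
    metric: str = "weighted_unifrac",
    linkage: str = "complete",
    n_perm: int = 1000,
    seed: int = 0,
    depth: int | None = None,
    min_samples_per_species: int = 3,
) -> PhylosymbiosisResult:
    """End-to-end phylosymbiosis test for one body site.

    Restricts to species with more than two sampled individuals at the site,
    rarefies, computes the UniFrac matrix, averages it to species level,
    clusters, and runs the tip-shuffle permutation test against the pruned
    host phylogeny. Returns a result row flagged ``insufficient n`` when
    fewer than five eligible species remain.
    """
    site_meta = meta[meta["body_site"] == body_site]
    site_samples = [s for s in table.index if s in site_meta.index]
    if not site_samples:
        raise ValueError(f"no samples for body site {body_site!r}")
    counts = site_meta.loc[site_samples].groupby("species")["sample_id"].nunique()
    eligible = set(counts.index[counts >= min_samples_per_species])
    keep = [s for s in site_samples if site_meta.loc[s, "species"] in eligible]

    def insufficient(n_found):
        return PhylosymbiosisResult(
            n=n_found, nRF=float("nan"), congruent_splits=0, p=float("nan"),
            p_plus_one=float("nan"), n_perm=n_perm, seed=seed,
            body_site=body_site, metric=metric, linkage=linkage,
            status="insufficient n",
        )

    if len(eligible) < 5:
        return insufficient(len(eligible))
    sub = table.loc[keep]
    if depth is not None:
        sub = rarefaction_alpha.rarefy(sub, depth, seed=seed)
        species_left = set(site_meta.loc[list(sub.index), "species"])
        if len(species_left) < 5:
            return insufficient(len(species_left))
    dm = distance_matrix(sub, asv_tree, metric=metric)
    sp_dm = species_mean_distance(dm, site_meta)
    dendrogram = hierarchical_cluster(sp_dm, linkage=linkage)
    pruned_host = host_tree.shear(list(sp_dm.ids))
    result = permutation_test(pruned_host, dendrogram, n_perm=n_perm, seed=seed)
    result.body_site = body_site
    result.metric = metric
    result.linkage = linkage
    return result
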