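"""Rarefaction and alpha diversity: observed richness, Shannon, Simpson and
Faith's PD, with per-species aggregation and pairwise body-site tests.

Conventions: Shannon uses the natural log; Simpson is reported as the
Gini-Simpson index 1 - sum(p_i^2) (the classic probability-of-interspecific-
encounter form, bounded in [0, 1]); Faith's PD includes the path to the root
of the ASV tree by default. Rarefaction is subsampling without replacement,
so rarefied counts are multivariate-hypergeometric draws.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .beta_diversity import branch_matrix

ALPHA_METRICS = ("observed", "shannon", "simpson", "faith_pd")

#: Rarefaction depths used by the pipeline: one global depth and one per
#: body site (reads per sample after subsampling).
DEFAULT_DEPTH = 4000
DEFAULT_SITE_DEPTHS = {
    "blood": 4030,
    "buccal": 10961,
    "cloaca": 10329,
    "intestine": 9094,
    "gizzard": 22306,
}

SIGNIFICANCE_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star annotation ('ns' above 0.05)."""
    for threshold, stars in SIGNIFICANCE_LEVELS:
        if p < threshold:
            return stars
    return "ns"


def rarefy(table: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose library size falls below ``depth`` are removed. ASV columns
    whose rarefied total is zero are retained (callers may drop them via the
    returned table's ``attrs['empty_asvs']``). Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be a positive integer")
    totals = table.sum(axis=1)
    keep = totals[totals >= depth].index
    if len(keep) == 0:
        raise ValueError(f"all samples fall below rarefaction depth {depth}")
    rng = np.random.default_rng(seed)
    counts = table.loc[keep].to_numpy(dtype=np.int64)
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    rarefied = pd.DataFrame(out, index=keep, columns=table.columns)
    rarefied.index.name = table.index.name
    rarefied.attrs["empty_asvs"] = list(table.columns[rarefied.sum(axis=0) == 0])
    rarefied.attrs["excluded_samples"] = sorted(set(table.index) - set(keep))
    return rarefied


def rarefaction_curve(
    table: pd.DataFrame, depths: list[int], reps: int, seed: int
) -> pd.DataFrame:
    """Mean observed richness per sample at each subsampling depth.

    Returns a long-format frame (sample_id, depth, mean_richness) covering,
    for each sample, the requested depths not exceeding its library size.
    """
    if sorted(depths) != list(depths):
        raise ValueError("depths must be ascending")
    rng = np.random.default_rng(seed)
    rows = []
    for sample_id, counts in table.iterrows():
        vec = counts.to_numpy(dtype=np.int64)
        total = int(vec.sum())
        for depth in depths:
            if depth > total:
                continue
            richness = [
                int(np.count_nonzero(rng.multivariate_hypergeometric(vec, depth)))
                for _ in range(reps)
            ]
            rows.append((sample_id, depth, float(np.mean(richness))))
    return pd.DataFrame(rows, columns=["sample_id", "depth", "mean_richness"])


def _check_counts(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("sample has no positive counts")
    if np.any(counts < 0):
        raise ValueError("negative counts")
    return counts


def observed_richness(counts) -> int:
    """Number of ASVs with a positive count."""
    counts = _check_counts(counts)
    return int(np.count_nonzero(counts))


def shannon(counts) -> float:
    """Shannon entropy -sum(p_i ln p_i) of the relative abundances."""
    counts = _check_counts(counts)
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


def simpson(counts, gini: bool = True) -> float:
    """Gini-Simpson index 1 - sum(p_i^2); ``gini=False`` returns sum(p_i^2)."""
    counts = _check_counts(counts)
    p = counts / counts.sum()
    d = float(np.sum(p**2))
    return 1.0 - d if gini else d


def faith_pd(
    presence_ids, asv_tree: TreeNode, include_root: bool = True
) -> float:
    """Faith's phylogenetic diversity of the ASVs present in a sample.

    Sum of branch lengths of the minimal subtree spanning the present tips
    and (by default) the root. With ``include_root=False`` the path from the
    tips' most recent common ancestor up to the root is excluded.
    """
    present = list(dict.fromkeys(presence_ids))
    if not present:
        raise ValueError("sample has no ASVs present")
    lengths, incidence = branch_matrix(asv_tree, present)
    pd_value = float(lengths[incidence.any(axis=1)].sum())
    if not include_root and len(present) >= 1:
        mrca = asv_tree.lca(present) if len(present) > 1 else next(
            t for t in asv_tree.tips() if t.name == present[0]
        )
        node, drop = mrca, 0.0
        while node.parent is not None:
            drop += node.length or 0.0
            node = node.parent
        pd_value -= drop
    return pd_value


def alpha_diversity(
    table: pd.DataFrame, asv_tree: TreeNode | None = None
) -> pd.DataFrame:
    """Long-format table of the four alpha metrics for every sample.

    ``faith_pd`` rows are produced only when an ASV tree is supplied.
    """
    rows = []
    for sample_id, counts in table.iterrows():
        vec = counts.to_numpy(dtype=np.int64)
        rows.append((sample_id, "observed", float(observed_richness(vec))))
        rows.append((sample_id, "shannon", shannon(vec)))
        rows.append((sample_id, "simpson", simpson(vec)))
        if asv_tree is not None:
            present = list(table.columns[vec > 0])
            rows.append((sample_id, "faith_pd", faith_pd(present, asv_tree)))
    return pd.DataFrame(rows, columns=["sample_id", "metric", "value"])


def aggregate_by_species(
    alpha: pd.DataFrame, meta: pd.DataFrame
) -> pd.DataFrame:
    """Average per-sample alpha values within species.

    Returns a frame indexed by species with one column per metric plus an
    ``n`` column (number of samples contributing per species).
    """
    merged = alpha.merge(
        meta[["species"]], left_on="sample_id", right_index=True, how="left"
    )
    if merged["species"].isna().any():
        bad = merged.loc[merged["species"].isna(), "sample_id"].unique()
        raise ValueError(f"samples without species metadata: {list(bad[:10])}")
    wide = merged.pivot_table(
        index="species", columns="metric", values="value", aggfunc="mean"
    )
    n = merged.groupby("species")["sample_id"].nunique()
    wide["n"] = n
    return wide


def pairwise_alpha_tests(
    alpha: pd.DataFrame,
    meta: pd.DataFrame,
    grouping: str = "body_site",
    equal_var: bool = False,
    bonferroni_m: int | None = None,
) -> pd.DataFrame:
    """Welch two-sample t tests between all group pairs, per metric.

    Pairs where either group has fewer than two samples are flagged as
    skipped. ``bonferroni_m`` adds a ``p_adj`` column (defaults to the number
    of tests performed).
    """
    merged = alpha.merge(
        meta[[grouping]], left_on="sample_id", right_index=True, how="inner"
    )
    rows = []
    for metric, sub in merged.groupby("metric", sort=True):
        groups = {g: s["value"].to_numpy() for g, s in sub.groupby(grouping)}
        for g1, g2 in itertools.combinations(sorted(groups), 2):
            a, b = groups[g1], groups[g2]
            if len(a) < 2 or len(b) < 2:
                rows.append((g1, g2, metric, np.nan, np.nan, "skipped"))
                continue
            if np.array_equal(np.sort(a), np.sort(b)) and np.var(a) == 0:
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(a, b, equal_var=equal_var)
                if np.isnan(p):  # both groups constant and equal
                    t, p = 0.0, 1.0
            rows.append((g1, g2, metric, float(t), float(p), significance_stars(p)))
    out = pd.DataFrame(
        rows, columns=["group1", "group2", "metric", "t", "p", "stars"]
    )
    m = bonferroni_m if bonferroni_m is not None else int(out["p"].notna().sum())
    out["p_adj"] = np.minimum(1.0, out["p"] * max(m, 1))
    return out
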