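"""Phylogeny-aware beta diversity and permutation tests on distance matrices.

UniFrac is computed from a branch incidence matrix: for every branch b of the
ASV tree, p_X(b) is the fraction of sample X's reads descending from b.
Unweighted UniFrac is the branch length unique to either sample's spanned
edge set over the length of the union; weighted UniFrac is
sum_b len(b) * |p_A(b) - p_B(b)|, optionally normalised by its maximum
attainable value sum_b len(b) * (p_A(b) + p_B(b)) so it lies in [0, 1].

PERMANOVA follows the one-way distance-based sum-of-squares partition:
SS_total = sum_{i<j} d_ij^2 / N, SS_within summed over within-group pairs
(each group's pair sum divided by its size), SS_between the difference,
pseudo-F = (SS_between/(a-1)) / (SS_within/(N-a)), with a permutation p-value
of (#{F_perm >= F_obs} + 1)/(n_perm + 1). Beta-dispersion embeds the matrix
by principal coordinates, using the corrected squared-distance-to-centroid
rule under negative eigenvalues (real-part contribution minus imaginary-part
contribution), then applies a one-way F with a permutation p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode


def branch_matrix(asv_tree: TreeNode, asv_ids) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and tip incidence of every non-root edge.

    Returns ``(lengths, incidence)`` where ``incidence[b, j]`` is 1 when ASV
    ``asv_ids[j]`` descends from branch ``b``. Raises if an ASV is not a tip.
    """
    tip_index = {}
    for i, name in enumerate(asv_ids):
        tip_index[name] = i
    tree_tips = {t.name for t in asv_tree.tips()}
    missing = sorted(set(asv_ids) - tree_tips)
    if missing:
        raise ValueError(f"ASVs absent from the ASV tree: {missing[:10]}")
    lengths, rows = [], []
    # postorder so each node's tip set is the union of its children's
    below: dict[int, np.ndarray] = {}
    for node in asv_tree.postorder(include_self=True):
        if node.is_tip():
            vec = np.zeros(len(asv_ids), dtype=bool)
            if node.name in tip_index:
                vec[tip_index[node.name]] = True
        else:
            vec = np.zeros(len(asv_ids), dtype=bool)
            for child in node.children:
                vec |= below[id(child)]
        below[id(node)] = vec
        if node.parent is not None:
            lengths.append(node.length or 0.0)
            rows.append(vec)
    return np.asarray(lengths, dtype=float), np.asarray(rows)


def _branch_proportions(counts: np.ndarray, incidence: np.ndarray) -> np.ndarray:
    total = counts.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("empty sample (no reads)")
    return (incidence.astype(float) @ (counts / total).T).T


def unweighted_unifrac(a_counts, b_counts, asv_ids, asv_tree: TreeNode) -> float:
    """Unweighted UniFrac between two samples (presence/absence of lineages)."""
    lengths, inc = branch_matrix(asv_tree, list(asv_ids))
    a = np.asarray(a_counts, dtype=float) > 0
    b = np.asarray(b_counts, dtype=float) > 0
    if not a.any() or not b.any():
        raise ValueError("empty sample (no ASVs present)")
    in_a = inc @ a > 0
    in_b = inc @ b > 0
    union = float(lengths[in_a | in_b].sum())
    unique = float(lengths[in_a ^ in_b].sum())
    return unique / union if union > 0 else 0.0


def weighted_unifrac(
    a_counts, b_counts, asv_ids, asv_tree: TreeNode, normalized: bool = True
) -> float:
    """Weighted UniFrac between two samples; normalised to [0, 1] by default."""
    lengths, inc = branch_matrix(asv_tree, list(asv_ids))
    counts = np.vstack([a_counts, b_counts]).astype(float)
    p = _branch_proportions(counts, inc)
    num = float(lengths @ np.abs(p[0] - p[1]))
    if not normalized:
        return num
    den = float(lengths @ (p[0] + p[1]))
    return num / den if den > 0 else 0.0


def distance_matrix(
    table: pd.DataFrame,
    asv_tree: TreeNode,
    metric: str = "weighted_unifrac",
    normalized: bool = True,
) -> DistanceMatrix:
    """All-pairs UniFrac distance matrix for a feature table.

    ``metric`` is ``"weighted_unifrac"`` or ``"unweighted_unifrac"``. The
    computation shares one branch incidence matrix across all pairs.
    """
    lengths, inc = branch_matrix(asv_tree, list(table.columns))
    counts = table.to_numpy(dtype=float)
    if np.any(counts.sum(axis=1) <= 0):
        empty = list(table.index[counts.sum(axis=1) <= 0])
        raise ValueError(f"empty samples: {empty[:10]}")
    n = counts.shape[0]
    out = np.zeros((n, n))
    if metric == "weighted_unifrac":
        p = _branch_proportions(counts, inc)  # samples x branches
        for i in range(n):
            diff = np.abs(p[i + 1 :] - p[i]) @ lengths
            if normalized:
                den = (p[i + 1 :] + p[i]) @ lengths
                diff = np.divide(diff, den, out=np.zeros_like(diff), where=den > 0)
            out[i, i + 1 :] = diff
    elif metric == "unweighted_unifrac":
        present = (inc.astype(float) @ (counts > 0).T).T > 0  # samples x branches
        for i in range(n):
            union = (present[i + 1 :] | present[i]) @ lengths
            unique = (present[i + 1 :] ^ present[i]) @ lengths
            out[i, i + 1 :] = np.divide(
                unique, union, out=np.zeros_like(unique), where=union > 0
            )
    else:
        raise ValueError(f"unknown metric {metric!r}")
    out = out + out.T
    return DistanceMatrix(out, ids=[str(s) for s in table.index])


@dataclass
class PermanovaResult:
    variable: str
    pseudo_F: float
    R2: float
    p: float
    n_perm: int
    n_samples: int
    n_groups: int
    dispersion_F: float | None = None
    dispersion_p: float | None = None


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int = 0,
    variable: str = "group",
) -> PermanovaResult:
    """One-way PERMANOVA of a categorical factor on a distance matrix."""
    labels = np.asarray(labels)
    uniq, codes = np.unique(labels, return_inverse=True)
    a, n = len(uniq), len(labels)
    if n != dm.shape[0]:
        raise ValueError("labels length does not match distance matrix")
    if a < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    d2 = dm.data**2

    def f_stat(c):
        ss_total, ss_within = _permanova_ss(d2, c, a)
        ss_between = ss_total - ss_within
        if ss_within <= 0:
            return np.inf, ss_between / ss_total if ss_total > 0 else 0.0
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
        r2 = ss_between / ss_total if ss_total > 0 else 0.0
        return f, r2

    f_obs, r2 = f_stat(codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_perm, _ = f_stat(rng.permutation(codes))
        if f_perm >= f_obs:  # ties counted: conservative
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return PermanovaResult(
        variable=variable,
        pseudo_F=float(f_obs),
        R2=float(r2),
        p=float(p),
        n_perm=n_perm,
        n_samples=n,
        n_groups=a,
    )


def _pcoa_parts(dm: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate axes split into real- and imaginary-part blocks."""
    d2 = dm.data**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh((g + g.T) / 2)
    tol = 1e-10 * max(1.0, np.abs(w).max())
    pos = w > tol
    neg = w < -tol
    x_real = v[:, pos] * np.sqrt(w[pos])
    x_imag = v[:, neg] * np.sqrt(-w[neg])
    return x_real, x_imag


def centroid_distances(dm: DistanceMatrix, labels) -> np.ndarray:
    """Per-sample distance to its group centroid in principal-coordinate space.

    Squared distances use the corrected rule under negative eigenvalues:
    real-part contribution minus imaginary-part contribution, clipped at zero.
    """
    labels = np.asarray(labels)
    uniq, codes = np.unique(labels, return_inverse=True)
    x_real, x_imag = _pcoa_parts(dm)
    z = np.empty(len(labels))
    for g in range(len(uniq)):
        idx = np.flatnonzero(codes == g)
        d2 = np.zeros(len(idx))
        if x_real.size:
            c = x_real[idx].mean(axis=0)
            d2 += ((x_real[idx] - c) ** 2).sum(axis=1)
        if x_imag.size:
            c = x_imag[idx].mean(axis=0)
            d2 -= ((x_imag[idx] - c) ** 2).sum(axis=1)
        z[idx] = np.sqrt(np.clip(d2, 0.0, None))
    return z


def beta_dispersion(
    dm: DistanceMatrix, labels, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Homogeneity-of-dispersion test (distance to group centroid).

    Groups of size one are excluded with a warning. Returns ``(F, p)``; if
    all points coincide, F is 0 and p is 1.
    """
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    singletons = counts[counts < 2].index
    if len(singletons) > 0:
        warnings.warn(f"excluding size-1 groups: {sorted(singletons)}")
        keep = ~np.isin(labels, singletons)
        dm = dm.filter(np.asarray(dm.ids)[keep])
        labels = labels[keep]
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("beta dispersion needs at least two groups of size >= 2")
    z = centroid_distances(dm, labels)
    if np.allclose(z, 0.0):
        return 0.0, 1.0

    def anova_f(c):
        grand = z.mean()
        ss_b = ss_w = 0.0
        for g in range(len(uniq)):
            zg = z[c == g]
            ss_b += len(zg) * (zg.mean() - grand) ** 2
            ss_w += ((zg - zg.mean()) ** 2).sum()
        df_b, df_w = len(uniq) - 1, len(z) - len(uniq)
        return np.inf if ss_w <= 0 else (ss_b / df_b) / (ss_w / df_w)

    f_obs = anova_f(codes)
    rng = np.random.default_rng(seed)
    hits = sum(anova_f(rng.permutation(codes)) >= f_obs for _ in range(n_perm))
    return float(f_obs), float((hits + 1) / (n_perm + 1))


def permanova_report(
    dm: DistanceMatrix,
    meta: pd.DataFrame,
    variables: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-factor PERMANOVA + dispersion test for each metadata variable.

    Each variable is tested on its own (one-variable-at-a-time effect sizes);
    samples with missing values for a variable are dropped for that row.
    """
    rows = []
    meta = meta.loc[list(dm.ids)]
    for var in variables:
        values = meta[var]
        ok = values.notna()
        sub_dm = dm.filter(np.asarray(dm.ids)[ok.to_numpy()]) if not ok.all() else dm
        labels = values[ok].to_numpy()
        if len(pd.unique(labels)) < 2:
            rows.append((var, np.nan, np.nan, np.nan, np.nan, np.nan, int(ok.sum())))
            continue
        res = permanova(sub_dm, labels, n_perm=n_perm, seed=seed, variable=var)
        try:
            disp_f, disp_p = beta_dispersion(sub_dm, labels, n_perm=n_perm, seed=seed)
        except ValueError:
            disp_f, disp_p = np.nan, np.nan
        rows.append(
            (var, res.pseudo_F, res.R2, res.p, disp_f, disp_p, res.n_samples)
        )
    return pd.DataFrame(
        rows,
        columns=["variable", "pseudo_F", "R2", "p", "dispersion_F", "dispersion_p", "n"],
    )
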