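"""Phylogenetic signal and host-size ~ diversity regressions.

The phylogenetic covariance C has C_ij equal to the shared root-to-tip path
length of species i and j (the depth of their most recent common ancestor)
and C_ii equal to species i's root-to-tip depth. Pagel's lambda multiplies
the off-diagonal of C: lambda = 0 is a star phylogeny (no signal), lambda = 1
is plain Brownian motion. The lambda fit maximises the multivariate-normal
likelihood of the trait with covariance sigma2 * C_lambda, profiling the mean
and sigma2 analytically by GLS at each lambda and searching lambda on [0, 1];
significance of the signal is a likelihood-ratio test against lambda = 0 on
one degree of freedom. PGLS estimates beta = (X' V^-1 X)^-1 X' V^-1 y with
V = C (Brownian) or C_lambda at the ML lambda of the residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from skbio import TreeNode

LAMBDA_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)
_FLAT_TOL = 1e-8


def prune_tree(host_tree: TreeNode, species) -> TreeNode:
    """Prune the host tree to a species subset, preserving path lengths."""
    species = list(species)
    tips = {t.name for t in host_tree.tips()}
    missing = sorted(set(species) - tips)
    if missing:
        raise ValueError(f"species absent from host tree: {missing[:10]}")
    return host_tree.shear(species)


def vcv_from_tree(host_tree: TreeNode, species=None) -> pd.DataFrame:
    """Phylogenetic variance-covariance matrix (MRCA depths) of the tips."""
    tree = prune_tree(host_tree, species) if species is not None else host_tree
    tip_dm = tree.tip_tip_distances()
    ids = list(tip_dm.ids)
    # pruning can leave a stem edge on the new root; it is shared ancestry of
    # every remaining species, so it enters all depths (path lengths are
    # measured from the original root)
    stem = tree.length or 0.0
    depths = {}
    for tip in tree.tips():
        node, d = tip, stem
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        depths[tip.name] = d
    depth = np.array([depths[i] for i in ids])
    # shared path = (depth_i + depth_j - d_ij) / 2
    c = (depth[:, None] + depth[None, :] - tip_dm.data) / 2.0
    np.fill_diagonal(c, depth)
    return pd.DataFrame(c, index=ids, columns=ids)


def lambda_transform(c: pd.DataFrame | np.ndarray, lam: float):
    """Scale the off-diagonal of a phylogenetic covariance by lambda."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    values = c.to_numpy() if isinstance(c, pd.DataFrame) else np.asarray(c)
    out = values * lam
    np.fill_diagonal(out, np.diag(values))
    if isinstance(c, pd.DataFrame):
        return pd.DataFrame(out, index=c.index, columns=c.columns)
    return out


def _mvn_profile_loglik(y: np.ndarray, x: np.ndarray, v: np.ndarray):
    """Profiled Gaussian log-likelihood of y ~ N(X beta, sigma2 V).

    Returns (logL, beta, sigma2_ml, xtvix) with sigma2 at its ML value.
    """
    n = len(y)
    cho = np.linalg.cholesky(v)
    logdet = 2.0 * np.sum(np.log(np.diag(cho)))
    xs = np.linalg.solve(cho, x)
    ys = np.linalg.solve(cho, y)
    xtvix = xs.T @ xs
    beta = np.linalg.solve(xtvix, xs.T @ ys)
    resid = ys - xs @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    loglik = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2) + logdet + n)
    return loglik, beta, sigma2, xtvix


def _maximise_lambda(loglik) -> tuple[float, float]:
    """Maximise a scalar log-likelihood over lambda in [0, 1].

    Grid evaluation at {0, .25, .5, .75, 1} seeds bounded local searches;
    a likelihood flat across the grid (star phylogeny) returns the boundary 0
    with a warning.
    """
    grid_ll = [loglik(l) for l in LAMBDA_GRID]
    if max(grid_ll) - min(grid_ll) < _FLAT_TOL:
        warnings.warn("likelihood is flat in lambda (star-like tree); returning 0")
        return 0.0, grid_ll[0]
    best_lam, best_ll = max(zip(LAMBDA_GRID, grid_ll), key=lambda t: t[1])
    i = LAMBDA_GRID.index(best_lam)
    lo = LAMBDA_GRID[max(i - 1, 0)]
    hi = LAMBDA_GRID[min(i + 1, len(LAMBDA_GRID) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda l: -loglik(l), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        if -res.fun > best_ll:
            best_lam, best_ll = float(res.x), float(-res.fun)
    return best_lam, best_ll


@dataclass
class LambdaFit:
    lam: float
    sigma2: float
    mu: float
    loglik: float
    loglik0: float
    p: float
    p_adj: float | None = None
    flat: bool = False


def fit_pagel_lambda(trait: pd.Series, host_tree: TreeNode) -> LambdaFit:
    """ML estimate of Pagel's lambda for one species-level trait.

    ``trait`` is indexed by species names matching host-tree tips; the tree
    is pruned to the trait's species. Requires at least 4 species and a
    non-constant trait.
    """
    trait = trait.dropna()
    if len(trait) < 4:
        raise ValueError("Pagel's lambda needs at least 4 species")
    if float(np.var(trait.to_numpy())) == 0.0:
        raise ValueError("trait is constant; lambda is undefined")
    c = vcv_from_tree(host_tree, list(trait.index))
    y = trait.loc[c.index].to_numpy(dtype=float)
    cv = c.to_numpy()
    x = np.ones((len(y), 1))

    def loglik(lam):
        return _mvn_profile_loglik(y, x, lambda_transform(cv, lam))[0]

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        lam_hat, ll_hat = _maximise_lambda(loglik)
        flat = any("flat in lambda" in str(w.message) for w in caught)
    for w in caught:
        warnings.warn_explicit(w.message, w.category, w.filename, w.lineno)
    ll0 = loglik(0.0)
    ll_hat = max(ll_hat, ll0)
    _, beta, sigma2, _ = _mvn_profile_loglik(
        y, x, lambda_transform(cv, lam_hat)
    )
    lrt = 2.0 * (ll_hat - ll0)
    p = float(stats.chi2.sf(max(lrt, 0.0), df=1))
    return LambdaFit(
        lam=float(lam_hat), sigma2=float(sigma2), mu=float(beta[0]),
        loglik=float(ll_hat), loglik0=float(ll0), p=p, flat=flat,
    )


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    value: float  # Pearson r for the ordinary fit; the GLS slope for PGLS
    p: float
    n_species: int
    method: str
    se: float | None = None
    p_adj: float | None = None
    lam: float | None = None


def pearson_regression(x: pd.Series, y: pd.Series) -> RegressionFit:
    """Ordinary least squares with Pearson's r and its two-sided p-value."""
    common = x.dropna().index.intersection(y.dropna().index)
    if len(common) < 3:
        raise ValueError("Pearson regression needs at least 3 species")
    xv = x.loc[common].to_numpy(dtype=float)
    yv = y.loc[common].to_numpy(dtype=float)
    if np.var(xv) == 0 or np.var(yv) == 0:
        raise ValueError("zero-variance input to Pearson regression")
    res = stats.linregress(xv, yv)
    return RegressionFit(
        slope=float(res.slope), intercept=float(res.intercept),
        value=float(res.rvalue), p=float(res.pvalue), n_species=len(common),
        method="pearson", se=float(res.stderr),
    )


def pgls_fit(
    x: pd.Series, y: pd.Series, host_tree: TreeNode, correlation: str = "bm"
) -> RegressionFit:
    """Phylogenetic generalized least squares of y on x.

    ``correlation='bm'`` uses V = C (Brownian motion); ``'lambda_ml'``
    jointly maximises the regression likelihood over Pagel's lambda of the
    residual covariance. Slope inference is a t test on n - 2 degrees of
    freedom with the unbiased GLS residual variance.
    """
    common = x.dropna().index.intersection(y.dropna().index)
    if len(common) < 4:
        raise ValueError("PGLS needs at least 4 species")
    c = vcv_from_tree(host_tree, list(common))
    ids = list(c.index)
    xv = x.loc[ids].to_numpy(dtype=float)
    yv = y.loc[ids].to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(ids)), xv])
    cv = c.to_numpy()
    lam_hat = None
    if correlation == "bm":
        v = cv
    elif correlation == "lambda_ml":
        def loglik(lam):
            return _mvn_profile_loglik(yv, design, lambda_transform(cv, lam))[0]

        lam_hat, _ = _maximise_lambda(loglik)
        v = lambda_transform(cv, lam_hat)
    else:
        raise ValueError(f"unknown correlation structure {correlation!r}")
    try:
        _, beta, _, xtvix = _mvn_profile_loglik(yv, design, v)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular phylogenetic covariance; consider a lambda floor"
        ) from exc
    n, p_par = len(ids), 2
    cho = np.linalg.cholesky(v)
    resid = np.linalg.solve(cho, yv - design @ beta)
    s2 = float(resid @ resid) / (n - p_par)
    se = np.sqrt(np.diag(np.linalg.inv(xtvix)) * s2)
    tval = beta[1] / se[1]
    pval = float(2.0 * stats.t.sf(abs(tval), df=n - p_par))
    return RegressionFit(
        slope=float(beta[1]), intercept=float(beta[0]), value=float(beta[1]),
        p=pval, n_species=n, method=f"pgls_{correlation}", se=float(se[1]),
        lam=lam_hat,
    )


def subset_species(
    meta: pd.DataFrame,
    host_tree: TreeNode,
    mode: str = "full",
    order_column: str = "order",
) -> tuple[list[str], TreeNode]:
    """Select the species subset for one analysis block and prune the tree.

    ``full`` keeps every species present in the metadata; ``passeriformes``
    keeps species of the largest bird order; ``n_gt_2`` keeps species with
    at least three samples in the supplied metadata (pass per-body-site
    metadata to get per-site counts).
    """
    counts = meta.groupby("species")["sample_id"].nunique()
    if mode == "full":
        species = list(counts.index)
    elif mode == "passeriformes":
        if order_column not in meta.columns:
            raise ValueError(f"metadata lacks the {order_column!r} column")
        keep = meta.loc[meta[order_column] == "Passeriformes", "species"]
        species = sorted(set(keep))
    elif mode == "n_gt_2":
        species = list(counts.index[counts >= 3])
    else:
        raise ValueError(f"unknown subset mode {mode!r}")
    tips = {t.name for t in host_tree.tips()}
    species = sorted(set(species) & tips)
    if not species:
        raise ValueError(f"subset {mode!r} selects no species present in the tree")
    return species, prune_tree(host_tree, species)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment p_adj = min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = int(np.sum(~np.isnan(p)))
    if m < 1:
        raise ValueError("m must be at least 1")
    return np.minimum(1.0, p * m)


def species_mass(meta: pd.DataFrame) -> pd.Series:
    """Per-species mass: arithmetic mean of sampled individuals' masses (g)."""
    return meta.groupby("species")["mass_g"].mean()


def comparative_report(
    species_alpha: dict[str, pd.DataFrame],
    meta: pd.DataFrame,
    host_tree: TreeNode,
    subsets=("full", "passeriformes", "n_gt_2"),
    mass_scales=("raw", "log"),
    metrics=("observed", "shannon", "simpson", "faith_pd"),
    pgls_correlation: str = "bm",
) -> pd.DataFrame:
    """Regression + PGLS + lambda table over body sites, metrics and subsets.

    ``species_alpha`` maps body site -> species-level alpha table (the output
    of :func:`aviphylosym.rarefaction_alpha.aggregate_by_species` on that
    site's rarefied samples). Bonferroni multiplicity is the number of
    testable rows sharing (subset, statistic family, mass scale), i.e. the
    site x metric block, and is recorded in the ``m`` column.
    """
    mass_all = species_mass(meta)
    rows = []
    for site, sp_alpha in species_alpha.items():
        site_meta = meta[meta["body_site"] == site]
        site_meta = site_meta[site_meta["species"].isin(sp_alpha.index)]
        for subset in subsets:
            try:
                species, pruned = subset_species(site_meta, host_tree, subset)
            except ValueError as exc:
                rows.append(
                    dict(body_site=site, subset=subset, status=f"empty: {exc}")
                )
                continue
            for metric in metrics:
                if metric not in sp_alpha.columns:
                    continue
                div = sp_alpha.loc[sp_alpha.index.intersection(species), metric]
                mass = mass_all.loc[div.index]
                row = dict(
                    body_site=site, subset=subset, metric=metric,
                    n_species=len(div), status="ok",
                )
                if len(div) < 4 or np.var(div.to_numpy()) == 0 or np.var(
                    mass.to_numpy()
                ) == 0:
                    row["status"] = "untestable"
                    rows.append(row)
                    continue
                lam_fit = fit_pagel_lambda(div, pruned)
                row.update(
                    lambda_=lam_fit.lam, lambda_p=lam_fit.p,
                    lambda_flat=lam_fit.flat,
                )
                for scale in mass_scales:
                    xv = np.log(mass) if scale == "log" else mass
                    ols = pearson_regression(xv, div)
                    pgls = pgls_fit(xv, div, pruned, correlation=pgls_correlation)
                    row[f"r_{scale}"] = ols.value
                    row[f"r_p_{scale}"] = ols.p
                    row[f"pgls_value_{scale}"] = pgls.value
                    row[f"pgls_se_{scale}"] = pgls.se
                    row[f"pgls_p_{scale}"] = pgls.p
                rows.append(row)
    report = pd.DataFrame(rows)
    if report.empty or "status" not in report.columns:
        return report
    testable = report["status"] == "ok"
    for subset in subsets:
        block = testable & (report["subset"] == subset)
        m = int(block.sum())
        if m == 0:
            continue
        report.loc[block, "m"] = m
        p_cols = [c for c in report.columns
                  if c == "lambda_p" or c.startswith(("r_p_", "pgls_p_"))]
        for col in p_cols:
            report.loc[block, f"{col}_adj"] = bonferroni(report.loc[block, col], m)
    return report
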