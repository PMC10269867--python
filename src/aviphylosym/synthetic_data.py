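"""Synthetic multi-species, multi-body-site microbiota with known structure.

The generator provides ground truth for every pipeline stage: a Yule host
phylogeny; species traits drawn under the Pagel-lambda Brownian model;
and count tables built from logistic-normal compositions in which a single
dial ``s`` mixes host-tree Brownian structure into per-ASV log-abundances
(s = 1: fully tree-structured communities, s = 0: no phylosymbiosis).

Mass and diversity are linked at the composition level: each species gets a
target Shannon diversity h = h0 + slope_true * log(mass) + lambda-BM noise,
realised by tempering its composition (Shannon of softmax(logits / T) is
monotone in T, so T is solved by bisection). Sequencing is multinomial at a
log-normal library size whose median (20,000 reads) leaves a realistic
minority of libraries below the 4,000-read rarefaction threshold.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from skbio import TreeNode

from .core_io import parse_newick, to_newick, write_feature_table, write_metadata
from .phylo_comparative import lambda_transform, vcv_from_tree

DIETS = ("animal", "plant", "omnivore")
NEST_TYPES = ("open_cup", "closed_cup", "cavity")
NEST_LOCATIONS = ("understory", "ground", "canopy")
NEST_HABITS = ("solitary", "colonial")
SOCIAL = ("solitary_pairs", "single_species_flock", "mixed_species_flock")


def simulate_host_tree(n_species: int, seed: int, prefix: str = "sp") -> TreeNode:
    """Pure-birth (Yule) ultrametric tree rescaled to unit depth."""
    if n_species < 4:
        raise ValueError("need at least 4 species")
    taxa = dendropy.TaxonNamespace(
        [f"{prefix}{i + 1:04d}" for i in range(n_species)]
    )
    dtree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        taxon_namespace=taxa,
        rng=random.Random(seed),
    )
    tree = parse_newick(dtree.as_string(schema="newick").replace("[&R] ", ""))
    # the simulator stops at the n-th speciation, leaving zero-length pendant
    # branches; extend every tip by the Exp(n * birth_rate) waiting time to
    # the (unobserved) next event, the standard Yule conditioning
    extra = random.Random(seed ^ 0x5EED).expovariate(n_species)
    for tip in tree.tips():
        tip.length = (tip.length or 0.0) + extra
    tree.length = None  # drop the simulator's origin-to-crown stem edge
    # rescale to unit depth and square up float jitter so depths are exact
    scale = max(t.accumulate_to_ancestor(tree) for t in tree.tips())
    for node in tree.traverse(include_self=False):
        if node.length is not None:
            node.length /= scale
    for tip in tree.tips():
        tip.length += 1.0 - tip.accumulate_to_ancestor(tree)
    return tree


def _bm_cholesky(tree: TreeNode, lam: float) -> tuple[list[str], np.ndarray]:
    c = vcv_from_tree(tree)
    v = lambda_transform(c.to_numpy(), lam)
    v = v + 1e-10 * np.eye(v.shape[0])
    return list(c.index), np.linalg.cholesky(v)


def simulate_trait_lambda(
    tree: TreeNode, lambda_true: float, mu: float, sigma2: float, seed: int
) -> pd.Series:
    """One draw from MVN(mu, sigma2 * C_lambda) over the tree's tips."""
    if not 0.0 <= lambda_true <= 1.0:
        raise ValueError("lambda_true must lie in [0, 1]")
    ids, chol = _bm_cholesky(tree, lambda_true)
    rng = np.random.default_rng(seed)
    values = mu + np.sqrt(sigma2) * (chol @ rng.standard_normal(len(ids)))
    return pd.Series(values, index=ids, name="trait")


def simulate_mass_and_diversity(
    tree: TreeNode,
    slope_true: float,
    lambda_true: float,
    noise: float,
    seed: int,
    log_mass_mu: float = 4.0,
    log_mass_sigma2: float = 1.0,
    mass_lambda: float = 1.0,
    diversity_mu: float = 3.0,
) -> tuple[pd.Series, pd.Series]:
    """Species mass (grams) and a diversity trait with a known regression.

    log-mass evolves under near-Brownian motion (strong phylogenetic signal,
    as body size shows empirically); diversity = slope_true * log(mass) +
    lambda-BM noise with standard deviation ``noise``.
    """
    rng = np.random.default_rng(seed)
    log_mass = simulate_trait_lambda(
        tree, mass_lambda, log_mass_mu, log_mass_sigma2,
        seed=int(rng.integers(2**31)),
    )
    ids, chol = _bm_cholesky(tree, lambda_true)
    eps = noise * (chol @ rng.standard_normal(len(ids)))
    diversity = diversity_mu + slope_true * log_mass.loc[ids] + eps
    mass = np.exp(log_mass.loc[ids]).rename("mass_g")
    return mass, diversity.rename("diversity")


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic community generator.

    Defaults describe a modest multi-species survey: 40 host species, three
    individuals each, four body sites, a 300-ASV pool, log-normal library
    sizes with median 20,000 reads, strong phylogenetic signal in body size,
    a weak negative size-diversity slope, and intermediate phylosymbiosis.
    """

    n_species: int = 40
    samples_per_species: int = 3
    n_asvs: int = 300
    body_sites: tuple[str, ...] = ("blood", "buccal", "cloaca", "intestine")
    depth_median: float = 20000.0
    depth_sigma: float = 1.0
    lambda_true: float = 0.5  # signal of the diversity trait's BM noise
    slope_true: float = -0.05  # effect of log mass on Shannon diversity
    phylosymbiosis_signal: float = 0.5  # s dial, 0 = none, 1 = fully clade-structured
    comp_scale: float = 2.0  # sd of per-ASV species effects on the log scale
    site_effect_sd: float = 2.0
    site_effect_frac: float = 0.3
    shannon_mu_frac: float = 0.6  # baseline Shannon as a fraction of ln(n_asvs)
    shannon_noise: float = 0.25
    mass_jitter_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.phylosymbiosis_signal <= 1.0:
            raise ValueError("phylosymbiosis_signal must lie in [0, 1]")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must lie in [0, 1]")
        if self.n_asvs < 2:
            raise ValueError("need at least 2 ASVs")


def _shannon_of_logits(logits: np.ndarray, temp: float) -> float:
    z = logits / temp
    z = z - z.max()
    p = np.exp(z)
    p /= p.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def _temper(logits: np.ndarray, target_h: float) -> np.ndarray:
    """Find p = softmax(logits / T) whose Shannon entropy matches target_h."""
    lo, hi = 0.05, 50.0
    target_h = float(np.clip(target_h, 1e-3, np.log(len(logits)) - 1e-6))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _shannon_of_logits(logits, mid) < target_h:
            lo = mid
        else:
            hi = mid
    z = logits / (0.5 * (lo + hi))
    z = z - z.max()
    p = np.exp(z)
    return p / p.sum()


def _assign_taxonomy(tree: TreeNode, species: list[str]) -> pd.DataFrame:
    """Label the larger root clade as Passeriformes; group genera/families
    by position along the sorted species list (synthetic taxonomy)."""
    children = tree.children
    clades = sorted(
        ({t.name for t in ch.tips()} for ch in children), key=len, reverse=True
    )
    passerine = clades[0] if clades else set(species)
    rows = []
    for i, sp in enumerate(species):
        rows.append(
            dict(
                species=sp,
                order="Passeriformes" if sp in passerine else "OtherOrder",
                family=f"fam{i // 9 + 1:02d}",
                genus=f"gen{i // 3 + 1:02d}",
            )
        )
    return pd.DataFrame(rows).set_index("species")


def simulate_feature_table(
    host_tree: TreeNode, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, TreeNode]:
    """Simulate (feature table, metadata, ASV tree) for a host phylogeny.

    Per-species expected ASV log-abundances mix Brownian structure on the
    host tree (weight s) with iid noise (weight 1 - s), plus per-body-site
    offsets on a random subset of ASVs; compositions are tempered to hit
    each species' target Shannon diversity, and reads are multinomial.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    asv_tree = simulate_host_tree(
        config.n_asvs, seed=int(rng.integers(2**31)), prefix="asv"
    )
    species_ids, chol = _bm_cholesky(host_tree, 1.0)
    n_sp, n_asv = len(species_ids), config.n_asvs
    s = config.phylosymbiosis_signal

    base = rng.normal(0.0, 1.5, size=n_asv)  # rank-abundance skeleton
    tree_part = chol @ rng.standard_normal((n_sp, n_asv))
    iid_part = rng.standard_normal((n_sp, n_asv))
    species_part = config.comp_scale * (s * tree_part + (1.0 - s) * iid_part)

    site_offsets = {}
    for site in config.body_sites:
        mask = rng.random(n_asv) < config.site_effect_frac
        off = np.zeros(n_asv)
        off[mask] = rng.normal(0.0, config.site_effect_sd, size=int(mask.sum()))
        site_offsets[site] = off

    mass, _ = simulate_mass_and_diversity(
        host_tree, config.slope_true, config.lambda_true, config.shannon_noise,
        seed=int(rng.integers(2**31)),
    )
    log_mass = np.log(mass.loc[species_ids])
    h_mu = config.shannon_mu_frac * np.log(n_asv)
    ids2, chol2 = _bm_cholesky(host_tree, config.lambda_true)
    h_noise = pd.Series(
        config.shannon_noise * (chol2 @ rng.standard_normal(n_sp)), index=ids2
    )
    target_h = (
        h_mu
        + config.slope_true * (log_mass - float(log_mass.mean()))
        + h_noise.loc[species_ids]
    )

    taxonomy = _assign_taxonomy(host_tree, species_ids)
    asv_ids = sorted(t.name for t in asv_tree.tips())
    records, count_rows, sample_ids = [], [], []
    k = 0
    for si, sp in enumerate(species_ids):
        for _ in range(config.samples_per_species):
            individual_mass = float(
                mass.loc[sp] * np.exp(rng.normal(0.0, config.mass_jitter_sd))
            )
            sex = "male" if rng.random() < 0.5 else "female"
            for site in config.body_sites:
                logits = base + species_part[si] + site_offsets[site]
                p = _temper(logits, float(target_h.loc[sp]))
                depth = int(
                    np.maximum(
                        1,
                        np.round(
                            np.exp(
                                rng.normal(
                                    np.log(config.depth_median), config.depth_sigma
                                )
                            )
                        ),
                    )
                )
                counts = rng.multinomial(depth, p)
                k += 1
                sid = f"s{k:05d}"
                sample_ids.append(sid)
                count_rows.append(counts)
                records.append(
                    dict(
                        sample_id=sid,
                        species=sp,
                        body_site=site,
                        mass_g=individual_mass,
                        sex=sex,
                        order=taxonomy.loc[sp, "order"],
                        family=taxonomy.loc[sp, "family"],
                        genus=taxonomy.loc[sp, "genus"],
                        diet=DIETS[int(rng.integers(len(DIETS)))],
                        nest_type=NEST_TYPES[int(rng.integers(len(NEST_TYPES)))],
                        nest_location=NEST_LOCATIONS[
                            int(rng.integers(len(NEST_LOCATIONS)))
                        ],
                        nesting_habit=NEST_HABITS[int(rng.integers(len(NEST_HABITS)))],
                        social_system=SOCIAL[int(rng.integers(len(SOCIAL)))],
                        extraction_plate=f"plate{k % 4 + 1}",
                    )
                )
    table = pd.DataFrame(
        np.asarray(count_rows, dtype=np.int64),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=asv_ids,
    )
    meta = pd.DataFrame(records).set_index("sample_id", drop=False)
    return table, meta, asv_tree


def write_simulation(
    out_dir, host_tree: TreeNode, table: pd.DataFrame, meta: pd.DataFrame,
    asv_tree: TreeNode, config: SimulationConfig,
) -> None:
    """Write feature_table.tsv, metadata.tsv, host.nwk, asv.nwk, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_feature_table(table, out / "feature_table.tsv")
    write_metadata(meta, out / "metadata.tsv")
    (out / "host.nwk").write_text(to_newick(host_tree))
    (out / "asv.nwk").write_text(to_newick(asv_tree))
    truth = dataclasses.asdict(config)
    truth["body_sites"] = list(config.body_sites)
    (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
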