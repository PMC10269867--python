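"""End-to-end orchestration: rarefaction, alpha tests, PERMANOVA report,
comparative (regression/PGLS/lambda) table and phylosymbiosis table.

Each stage writes one TSV under the output directory with a provenance
header (config hash, seed, stage seed); a stage whose output file already
exists is skipped, so deleting one report and re-running recomputes only
that stage. All randomness derives from the run seed plus a stable per-stage
offset, making reruns byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import beta_diversity, core_io, phylo_comparative, phylosymbiosis, rarefaction_alpha

COMPARATIVE_EXCLUDED_SITES = ("liver", "spleen")


@dataclass
class RunConfig:
    table_path: str
    meta_path: str
    host_tree_path: str
    asv_tree_path: str
    out_dir: str
    depth: int = rarefaction_alpha.DEFAULT_DEPTH
    site_depths: dict = field(default_factory=dict)  # body_site -> depth
    beta_variables: tuple[str, ...] = ("sex", "diet", "order", "extraction_plate")
    metrics: tuple[str, ...] = ("weighted_unifrac", "unweighted_unifrac")
    subsets: tuple[str, ...] = ("full", "passeriformes", "n_gt_2")
    linkage: str = "complete"
    n_perm: int = 999
    phylosymbiosis_n_perm: int = 1000
    seed: int = 0
    alpha_level: float = 0.05
    pgls_correlation: str = "bm"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("beta_variables", "metrics", "subsets"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def site_depth(self, site: str) -> int:
        return int(self.site_depths.get(site, self.depth))

    def config_hash(self) -> str:
        """Hash of the analysis parameters (filesystem locations excluded, so
        identical analyses in different directories hash identically)."""
        params = dataclasses.asdict(self)
        for key in ("table_path", "meta_path", "host_tree_path",
                    "asv_tree_path", "out_dir"):
            params.pop(key)
        payload = json.dumps(params, sort_keys=True, default=str)
        return hashlib.md5(payload.encode()).hexdigest()[:12]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed: base seed plus a stable hash of the name."""
    return int((seed + zlib.crc32(stage.encode())) % (2**31))


def _write_report(df: pd.DataFrame, path: Path, config: RunConfig, stage: str) -> None:
    header = (
        f"# stage={stage} config_hash={config.config_hash()} "
        f"seed={config.seed} stage_seed={stage_seed(config.seed, stage)}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _comparative_sites(meta: pd.DataFrame) -> list[str]:
    sites = sorted(set(meta["body_site"]) - set(COMPARATIVE_EXCLUDED_SITES))
    return sites


def run_all(config: RunConfig, log=print) -> dict[str, Path]:
    """Run every analysis stage; returns the mapping stage -> report path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = core_io.read_feature_table(config.table_path)
    meta = core_io.read_metadata(config.meta_path)
    host_tree = core_io.read_newick(config.host_tree_path)
    asv_tree = core_io.read_newick(config.asv_tree_path)
    core_io.validate_inputs(table, meta, host_tree, asv_tree, strict=True)
    meta = meta.loc[[s for s in table.index if s in meta.index]]
    sites = _comparative_sites(meta)
    paths = {
        "alpha": out / "alpha.tsv",
        "alpha_tests": out / "alpha_tests.tsv",
        "beta": out / "beta_report.tsv",
        "comparative": out / "comparative.tsv",
        "phylosymbiosis": out / "phylosymbiosis.tsv",
    }
    log_lines = []

    def _log(msg):
        log_lines.append(msg)
        log(msg)

    def _rarefied_site(site: str, stage: str) -> pd.DataFrame:
        site_samples = meta.index[meta["body_site"] == site]
        sub = table.loc[[s for s in table.index if s in set(site_samples)]]
        return rarefaction_alpha.rarefy(
            sub, config.site_depth(site), seed=stage_seed(config.seed, stage)
        )

    # ---- alpha: global rarefaction, per-sample metrics --------------------
    if paths["alpha"].exists() and paths["alpha_tests"].exists():
        _log("alpha: outputs exist, skipping")
        alpha = pd.read_csv(paths["alpha"], sep="\t", comment="#")
    else:
        rarefied = rarefaction_alpha.rarefy(
            table, config.depth, seed=stage_seed(config.seed, "alpha")
        )
        _log(
            f"alpha: rarefied to {config.depth}, kept {rarefied.shape[0]} samples, "
            f"excluded {len(rarefied.attrs['excluded_samples'])}"
        )
        alpha = rarefaction_alpha.alpha_diversity(rarefied, asv_tree)
        _write_report(alpha, paths["alpha"], config, "alpha")
        tests = rarefaction_alpha.pairwise_alpha_tests(alpha, meta)
        _write_report(tests, paths["alpha_tests"], config, "alpha_tests")

    # ---- beta: per-site UniFrac + PERMANOVA over metadata variables -------
    if paths["beta"].exists():
        _log("beta: output exists, skipping")
    else:
        rows = []
        # body site tested on the globally rarefied table
        global_rarefied = rarefaction_alpha.rarefy(
            table, config.depth, seed=stage_seed(config.seed, "beta_global")
        )
        for metric in config.metrics:
            dm = beta_diversity.distance_matrix(global_rarefied, asv_tree, metric)
            rep = beta_diversity.permanova_report(
                dm, meta.loc[list(dm.ids)], ["body_site"],
                n_perm=config.n_perm, seed=stage_seed(config.seed, "beta_global"),
            )
            rep.insert(0, "metric", metric)
            rep.insert(0, "body_site", "all")
            rows.append(rep)
        for site in sites:
            site_rarefied = _rarefied_site(site, "beta")
            site_meta = meta.loc[list(site_rarefied.index)]
            for metric in config.metrics:
                dm = beta_diversity.distance_matrix(site_rarefied, asv_tree, metric)
                rep = beta_diversity.permanova_report(
                    dm, site_meta, list(config.beta_variables),
                    n_perm=config.n_perm, seed=stage_seed(config.seed, f"beta_{site}"),
                )
                rep.insert(0, "metric", metric)
                rep.insert(0, "body_site", site)
                rows.append(rep)
        beta_report = pd.concat(rows, ignore_index=True)
        _write_report(beta_report, paths["beta"], config, "beta")
        _log(f"beta: {len(beta_report)} PERMANOVA rows")

    # ---- comparative: regression + PGLS + lambda per site/metric/subset ---
    if paths["comparative"].exists():
        _log("comparative: output exists, skipping")
    else:
        species_alpha = {}
        for site in sites:
            site_rarefied = _rarefied_site(site, "comparative")
            site_alpha = rarefaction_alpha.alpha_diversity(site_rarefied, asv_tree)
            species_alpha[site] = rarefaction_alpha.aggregate_by_species(
                site_alpha, meta
            )
        report = phylo_comparative.comparative_report(
            species_alpha, meta, host_tree, subsets=config.subsets,
            pgls_correlation=config.pgls_correlation,
        )
        _write_report(report, paths["comparative"], config, "comparative")
        _log(f"comparative: {len(report)} rows")

    # ---- phylosymbiosis: nRF + permutation test per site/metric -----------
    if paths["phylosymbiosis"].exists():
        _log("phylosymbiosis: output exists, skipping")
    else:
        rows = []
        for site in sites:
            for metric in config.metrics:
                res = phylosymbiosis.run_phylosymbiosis(
                    table, meta, asv_tree, host_tree, body_site=site,
                    metric=metric, linkage=config.linkage,
                    n_perm=config.phylosymbiosis_n_perm,
                    seed=stage_seed(config.seed, f"phylosym_{site}_{metric}"),
                    depth=config.site_depth(site),
                )
                rows.append(dataclasses.asdict(res))
        report = pd.DataFrame(rows)[
            ["body_site", "metric", "n", "nRF", "congruent_splits", "p",
             "p_plus_one", "n_perm", "linkage", "status", "seed"]
        ]
        _write_report(report, paths["phylosymbiosis"], config, "phylosymbiosis")
        _log(f"phylosymbiosis: {len(report)} rows")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return paths
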