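"""Simulate the survey analysed by the rest of the scripts.

Generates a 60-species host phylogeny, a 200-ASV pool, and three body-site
count tables (blood, cloaca, intestine; three individuals per species) with
strong community phylogenetic structure (s = 0.8), strong phylogenetic
signal in body size, and a weak negative size-diversity slope (-0.05 on the
log scale). Everything is written under results/sim/ with the generating
parameters in truth.json.

Run from the repository root: python analysis/01_simulate.py
"""

from pathlib import Path

from aviphylosym import synthetic_data as sd

OUT = Path("results/sim")
SEED = 42

CONFIG = sd.SimulationConfig(
    n_species=60,
    samples_per_species=3,
    n_asvs=200,
    body_sites=("blood", "cloaca", "intestine"),
    phylosymbiosis_signal=0.8,
    slope_true=-0.05,
    seed=SEED,
)


def main() -> None:
    host = sd.simulate_host_tree(CONFIG.n_species, seed=SEED)
    table, meta, asv_tree = sd.simulate_feature_table(host, CONFIG)
    sd.write_simulation(OUT, host, table, meta, asv_tree, CONFIG)
    depths = table.sum(axis=1)
    print(f"wrote {OUT}/: {table.shape[0]} samples x {table.shape[1]} ASVs")
    print(f"library sizes: median {int(depths.median())}, "
          f"{int((depths < 4000).sum())} below the 4,000-read threshold")
    print(f"phylosymbiosis signal s={CONFIG.phylosymbiosis_signal}, "
          f"size-diversity slope {CONFIG.slope_true}")


if __name__ == "__main__":
    main()
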