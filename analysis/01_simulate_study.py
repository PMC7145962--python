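"""Generate the synthetic two-platform study and all companion inputs.

Writes probe-level expression for both platforms, sample metadata,
probe-to-gene maps, gene-set collections (GMT), a scale-free PPI edge
list, miRNA/TF interaction tables, the companion miRNA expression set,
curated-style disease gene lists, and the planted ground truth.

Run from the repository root:  python analysis/01_simulate_study.py
"""

import json
from pathlib import Path

import pandas as pd

from bridgefinder import simulate

OUT = Path("results/analysis")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = simulate.SimConfig(seed=1)
    sim = simulate.generate_expression(config)
    reg = simulate.generate_regulator_tables(sim.truth, config)
    lists = simulate.generate_disease_gene_lists(sim.truth, config.seed + 2)
    functions = simulate.generate_gene_sets(sim.truth, 40, config.seed + 3, "function")
    pathways = simulate.generate_gene_sets(sim.truth, 20, config.seed + 4, "pathway")
    ppi = simulate.generate_ppi(sim.truth, 400, 2, config.seed + 5)

    simulate.write_expression_tsv(sim.platform_a, OUT / "expr_platform_a.tsv", "probe")
    simulate.write_expression_tsv(sim.platform_b, OUT / "expr_platform_b.tsv", "probe")
    sim.probe_to_gene_a.to_csv(OUT / "probe_map_a.tsv", sep="\t")
    sim.probe_to_gene_b.to_csv(OUT / "probe_map_b.tsv", sep="\t")
    simulate.write_metadata_tsv(sim.metadata, OUT / "metadata.tsv")
    simulate.write_gmt(functions, OUT / "functions.gmt")
    simulate.write_gmt(pathways, OUT / "pathways.gmt")
    simulate.write_ppi_tsv(ppi, OUT / "ppi.tsv")
    simulate.write_interactions_tsv(
        pd.concat([reg.mirna_targets, reg.tf_targets]), OUT / "interactions.tsv"
    )
    simulate.write_expression_tsv(reg.mirna_expression, OUT / "mirna_expression.tsv")
    simulate.write_metadata_tsv(reg.mirna_metadata, OUT / "mirna_metadata.tsv")
    for disease, genes in lists.items():
        (OUT / f"disease_genes_{disease}.txt").write_text("\n".join(genes) + "\n")
    simulate.write_truth_json(sim.truth, OUT / "ground_truth.json")
    with open(OUT / "sim_config.json", "w") as fh:
        json.dump({"seed": config.seed, "n_genes": config.n_genes}, fh)

    meta = sim.metadata
    print(f"platform A: {int((meta.platform == 'A').sum())} samples")
    print(f"platform B: {int((meta.platform == 'B').sum())} samples")
    print(meta.groupby(['platform', 'diagnosis']).size().to_string())
    print(f"\nwrote study inputs to {OUT}/")


if __name__ == "__main__":
    main()
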