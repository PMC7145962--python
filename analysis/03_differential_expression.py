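"""Screen differentially expressed genes and miRNAs.

Runs the three moderated-t comparisons (MCI vs CTL, AD vs CTL, MCI vs
AD) under the fold-change rule FC > 1.2 or FC < 5/6 at p < 0.05, screens
the companion miRNA panel the same way, and assembles each disease's
candidate gene set (DEGs united with the curated-style disease lists).

Requires 02_preprocess_integration.py to have been run.
"""

from pathlib import Path

import pandas as pd

from bridgefinder import diffexpr

OUT = Path("results/analysis")


def _samples(meta: pd.DataFrame, group: str) -> list[str]:
    return list(meta.loc[meta["diagnosis"] == group, "sample_id"])


def main() -> None:
    expr = pd.read_csv(OUT / "expression_adjusted.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(OUT / "metadata_retained.tsv", sep="\t")

    comparisons = {
        "DEG1_MCI_vs_CTL": ("MCI", "CTL"),
        "DEG2_AD_vs_CTL": ("AD", "CTL"),
        "DEG3_MCI_vs_AD": ("MCI", "AD"),
    }
    screened = {}
    for name, (a, b) in comparisons.items():
        table = diffexpr.moderated_t_table(expr, _samples(meta, a), _samples(meta, b))
        table.to_csv(OUT / f"{name}.tsv", sep="\t")
        up, down = diffexpr.screen_degs(table)
        screened[name] = (up, down)
        print(f"{name}: {len(up)} up, {len(down)} down "
              f"(prior df d0 = {table.attrs['d0']:.1f})")

    mirna = pd.read_csv(OUT / "mirna_expression.tsv", sep="\t", index_col=0)
    mirna_meta = pd.read_csv(OUT / "mirna_metadata.tsv", sep="\t")
    for disease in ("MCI", "AD"):
        table = diffexpr.moderated_t_table(
            mirna, _samples(mirna_meta, disease), _samples(mirna_meta, "CTL")
        )
        up, down = diffexpr.screen_degs(table)
        de = sorted(up | down)
        (OUT / f"de_mirnas_{disease}.txt").write_text("\n".join(de) + "\n")
        print(f"DE miRNAs {disease} vs CTL: {len(de)}")

    universe = list(expr.index)
    for disease, own in (("MCI", "DEG1_MCI_vs_CTL"), ("AD", "DEG2_AD_vs_CTL")):
        up1, down1 = screened[own]
        up3, down3 = screened["DEG3_MCI_vs_AD"]
        db = (OUT / f"disease_genes_{disease}.txt").read_text().split()
        candidates, venn = diffexpr.assemble_candidate_genes(
            [up1 | down1, up3 | down3], [db], universe
        )
        (OUT / f"candidates_{disease}.txt").write_text("\n".join(candidates) + "\n")
        print(f"potential {disease} genes: {venn['n_candidates']} "
              f"(union {venn['n_union_raw']}, dropped {venn['n_dropped_not_in_matrix']})")


if __name__ == "__main__":
    main()
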