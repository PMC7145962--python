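"""Run the complete bridge-molecule analysis and summarize the report.

Executes every stage from simulation through bridge regulators under one
config (seed 1) and narrates the findings: trait-associated modules per
disease, bridge functions/pathways, overlapping/crosstalk/bridge genes,
major pathogenic genes with shared and bridge flags, and bridge
regulators with their differential-expression status.
"""

from pathlib import Path

import pandas as pd

from bridgefinder import pipeline, simulate

OUT = Path("results/analysis/pipeline")


def main() -> None:
    config = pipeline.PipelineConfig(
        sim=simulate.SimConfig(seed=1), outdir=str(OUT)
    )
    report = pipeline.run_all(config)

    counts = report["metadata"]["sample_counts"]
    print(f"samples retained: {counts['total']} "
          f"({counts['MCI']} MCI, {counts['AD']} AD, {counts['CTL']} CTL)")
    for name, c in report["deg_counts"].items():
        print(f"{name}: {c['up']} up / {c['down']} down")
    for disease in ("MCI", "AD"):
        mod = report["modules"][disease]
        sig = {
            t["module"]: (round(t["r"], 3), f"{t['p']:.2e}")
            for t in mod["trait"] if t["significant"]
        }
        print(f"{disease}: {len(mod['sizes']) - ('grey' in mod['sizes'])} modules, "
              f"trait-associated: {sig}")
    print(f"bridge functions: {report['bridge_functions']}")
    print(f"bridge pathways: {report['bridge_pathways']}")
    print(f"overlapping genes: {len(report['overlapping_genes'])}, "
          f"crosstalk genes: {len(report['crosstalk_genes'])}, "
          f"bridge genes: {len(report['bridge_genes'])}")
    major = pd.DataFrame(report["major_pathogenic_genes"])
    for disease in ("MCI", "AD"):
        sub = major[major["disease"] == disease]
        bridge_also = sub.loc[sub["is_bridge_gene"], "gene"].tolist()
        print(f"major pathogenic genes {disease}: {sub['gene'].tolist()}")
        print(f"  of which bridge genes: {bridge_also}")
    print(f"shared major pathogenic genes: {report['shared_major_genes']}")
    for r in report["bridge_regulators"]:
        flags = []
        if r["de_in_mci"]:
            flags.append("DE in MCI")
        if r["de_in_ad"]:
            flags.append("DE in AD")
        print(f"bridge regulator: {r['regulator']} ({r['type']}"
              f"{', ' + ', '.join(flags) if flags else ''})")
    print(f"\nfull report: {OUT}/bridge_report.json")


if __name__ == "__main__":
    main()
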