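"""End-to-end orchestration: simulate -> preprocess -> differential
expression -> candidate assembly -> co-expression modules -> enrichment ->
PPI / bridge genes -> pivot regulators -> bridge report.

Every stage writes its tables under the output directory before the next
stage starts, so intermediate results can be inspected and individual
stages re-run. Identical config + seed gives a byte-identical report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from bridgefinder import coexpression, diffexpr, enrichment, networks, regulators, simulate
from bridgefinder import preprocess as pp

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_all"]


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    screen: diffexpr.ScreenParams = field(default_factory=diffexpr.ScreenParams)
    keep_groups: tuple[str, ...] = ("CTL", "MCI", "AD")
    shrink_batch: bool = True
    # co-expression knobs
    r2_target: float = 0.8
    min_module_size: int = 30
    cut_height: float = 0.99
    merge_diss: float = 0.25
    trait_alpha: float = 0.05
    # enrichment
    n_function_terms: int = 40
    n_pathway_terms: int = 20
    enrich_alpha: float = 0.05
    # networks
    ppi_nodes: int = 400
    ppi_attach: int = 2
    #: crosstalk thresholds are quantiles of each module's intramodular
    #: TOM weights (the absolute-scale analogs of a fixed cut like 0.3 or
    #: 0.6, which only make sense relative to the data's TOM scale)
    crosstalk_quantile: float = 0.6
    crosstalk_top_k: int = 40
    secondary_quantile: float = 0.9
    top_n_major: int = 10
    # regulators
    pivot_alpha: float = 0.05
    pivot_min_targets: int = 2
    outdir: str = "results/pipeline"

    @property
    def seed(self) -> int:
        return self.sim.seed

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        sim = simulate.SimConfig(**payload.pop("sim", {}))
        screen = diffexpr.ScreenParams(**payload.pop("screen", {}))
        payload["keep_groups"] = tuple(payload.get("keep_groups", ("CTL", "MCI", "AD")))
        return cls(sim=sim, screen=screen, **payload)


def _samples_of(meta: pd.DataFrame, group: str) -> list[str]:
    return list(meta.loc[meta["diagnosis"] == group, "sample_id"])


def _disease_wgcna(
    config: PipelineConfig,
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    candidates: list[str],
    disease: str,
    outdir: Path,
) -> tuple[coexpression.ModuleSet, pd.DataFrame, list[str]]:
    """Co-expression modules on the candidate genes over disease + CTL
    samples; returns the module set, the TOM, and the selected
    (significantly trait-correlated) module labels."""
    if not candidates:
        raise PipelineError("coexpression", f"empty candidate gene set for {disease}")
    samples = _samples_of(meta, disease) + _samples_of(meta, "CTL")
    sub = expr.loc[candidates, samples]
    report = coexpression.pick_soft_threshold(sub, r2_target=config.r2_target)
    adj = coexpression.adjacency(sub, report.chosen)
    tom = coexpression.tom_similarity(adj)
    modules = coexpression.detect_modules(
        tom,
        sub,
        min_size=config.min_module_size,
        cut_height=config.cut_height,
        merge_diss=config.merge_diss,
    )
    trait = pd.DataFrame(
        {
            disease: [
                1.0 if d == disease else 0.0
                for d in meta.set_index("sample_id").loc[samples, "diagnosis"]
            ]
        },
        index=samples,
    )
    coexpression.attach_trait_correlations(modules, trait, alpha=config.trait_alpha)
    selected = sorted(
        modules.trait_stats.loc[modules.trait_stats["significant"], "module"]
    )
    report.table.to_csv(outdir / f"soft_threshold_{disease}.tsv", sep="\t", index=False)
    modules.labels.rename("module").to_csv(
        outdir / f"modules_{disease}.tsv", sep="\t", index_label="gene"
    )
    modules.trait_stats.to_csv(
        outdir / f"module_trait_{disease}.tsv", sep="\t", index=False
    )
    logger.info(
        "%s: power=%d, %d modules, selected=%s",
        disease,
        report.chosen,
        modules.eigengenes.shape[1],
        selected,
    )
    return modules, tom, selected


def run_all(config: PipelineConfig) -> dict:
    """Run the full bridge-molecule analysis on a simulated study.

    Returns the bridge report (also written as ``bridge_report.json``)
    holding bridge genes with provenance, bridge functions / pathways,
    per-disease major pathogenic genes with bridge and shared flags,
    pivot pairs, bridge regulators with DE flags, and run metadata.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- simulate --------------------------------------------------------
    sim = simulate.generate_expression(config.sim)
    truth = sim.truth
    reg_data = simulate.generate_regulator_tables(truth, config.sim)
    disease_lists = simulate.generate_disease_gene_lists(truth, config.sim.seed + 2)
    functions = simulate.generate_gene_sets(
        truth, config.n_function_terms, config.sim.seed + 3, category="function"
    )
    pathways = simulate.generate_gene_sets(
        truth, config.n_pathway_terms, config.sim.seed + 4, category="pathway"
    )
    ppi = simulate.generate_ppi(
        truth, config.ppi_nodes, config.ppi_attach, config.sim.seed + 5
    )
    simulate.write_expression_tsv(sim.platform_a, outdir / "expr_platform_a.tsv")
    simulate.write_expression_tsv(sim.platform_b, outdir / "expr_platform_b.tsv")
    simulate.write_metadata_tsv(sim.metadata, outdir / "metadata.tsv")
    simulate.write_gmt(functions, outdir / "functions.gmt")
    simulate.write_gmt(pathways, outdir / "pathways.gmt")
    simulate.write_ppi_tsv(ppi, outdir / "ppi.tsv")
    simulate.write_interactions_tsv(
        pd.concat([reg_data.mirna_targets, reg_data.tf_targets]),
        outdir / "interactions.tsv",
    )
    simulate.write_truth_json(truth, outdir / "ground_truth.json")

    # --- preprocess ------------------------------------------------------
    try:
        gene_a = pp.collapse_probes(sim.platform_a, sim.probe_to_gene_a)
        gene_b = pp.collapse_probes(sim.platform_b, sim.probe_to_gene_b)
        merged = pp.merge_platforms(gene_a, gene_b)
        merged, meta, counts = pp.filter_samples(
            merged, sim.metadata, keep=config.keep_groups
        )
        meta_idx = meta.set_index("sample_id")
        adjusted = pp.adjust_batch(
            merged,
            batch=meta_idx.loc[merged.columns, "platform"],
            covariates=meta_idx.loc[merged.columns, "diagnosis"],
            shrink=config.shrink_batch,
        )
    except (ValueError, KeyError) as err:
        raise PipelineError("preprocess", str(err)) from err
    simulate.write_expression_tsv(adjusted, outdir / "expression_adjusted.tsv")
    sample_counts = {"total": int(merged.shape[1]), **counts}

    # --- differential expression ----------------------------------------
    groups = {g: _samples_of(meta, g) for g in ("MCI", "AD", "CTL")}
    try:
        deg1 = diffexpr.moderated_t_table(
            adjusted, groups["MCI"], groups["CTL"], config.screen
        )
        deg2 = diffexpr.moderated_t_table(
            adjusted, groups["AD"], groups["CTL"], config.screen
        )
        deg3 = diffexpr.moderated_t_table(
            adjusted, groups["MCI"], groups["AD"], config.screen
        )
    except ValueError as err:
        raise PipelineError("diffexpr", str(err)) from err
    for name, table in (("DEG1_MCI_vs_CTL", deg1), ("DEG2_AD_vs_CTL", deg2), ("DEG3_MCI_vs_AD", deg3)):
        table.to_csv(outdir / f"{name}.tsv", sep="\t")
    up1, down1 = diffexpr.screen_degs(deg1, config.screen)
    up2, down2 = diffexpr.screen_degs(deg2, config.screen)
    up3, down3 = diffexpr.screen_degs(deg3, config.screen)
    deg_counts = {
        "DEG1_MCI_vs_CTL": {"up": len(up1), "down": len(down1)},
        "DEG2_AD_vs_CTL": {"up": len(up2), "down": len(down2)},
        "DEG3_MCI_vs_AD": {"up": len(up3), "down": len(down3)},
    }

    # --- candidate assembly ---------------------------------------------
    universe = list(adjusted.index)
    cand_mci, venn_mci = diffexpr.assemble_candidate_genes(
        [up1 | down1, up3 | down3], [disease_lists["MCI"]], universe
    )
    cand_ad, venn_ad = diffexpr.assemble_candidate_genes(
        [up2 | down2, up3 | down3], [disease_lists["AD"]], universe
    )

    # --- co-expression per disease --------------------------------------
    modules_mci, tom_mci, sel_mci = _disease_wgcna(
        config, adjusted, meta, cand_mci, "MCI", outdir
    )
    modules_ad, tom_ad, sel_ad = _disease_wgcna(
        config, adjusted, meta, cand_ad, "AD", outdir
    )
    if not sel_mci or not sel_ad:
        raise PipelineError(
            "coexpression",
            f"no trait-significant module (MCI: {sel_mci}, AD: {sel_ad})",
        )
    genes_mci = sorted(
        set().union(*(modules_mci.module_genes(m) for m in sel_mci))
    )
    genes_ad = sorted(set().union(*(modules_ad.module_genes(m) for m in sel_ad)))

    # --- enrichment + bridge terms --------------------------------------
    collection = pd.concat([functions, pathways], ignore_index=True)
    collection_genes = set().union(*collection["genes"])
    background = sorted(set(universe) & collection_genes)
    enr_mci = enrichment.enrich_module(genes_mci, collection, background)
    enr_ad = enrichment.enrich_module(genes_ad, collection, background)
    enr_mci.to_csv(outdir / "enrichment_MCI.tsv", sep="\t", index=False)
    enr_ad.to_csv(outdir / "enrichment_AD.tsv", sep="\t", index=False)
    bridge_term_sets = enrichment.bridge_terms(
        enrichment.significant_terms(enr_mci, config.enrich_alpha),
        enrichment.significant_terms(enr_ad, config.enrich_alpha),
    )

    # --- PPI connectivity + bridge genes --------------------------------
    try:
        _, conn_mci = networks.induce_ppi_network(genes_mci, ppi)
        _, conn_ad = networks.induce_ppi_network(genes_ad, ppi)
    except ValueError as err:
        raise PipelineError("networks", str(err)) from err
    major_mci = networks.major_pathogenic_genes(conn_mci, config.top_n_major)
    major_ad = networks.major_pathogenic_genes(conn_ad, config.top_n_major)
    shared_major = sorted(set(major_mci) & set(major_ad))

    overlap = networks.overlapping_genes(genes_mci, genes_ad)
    # primary modules get the top-k rule; any further selected AD module
    # gets the stricter max-degree rule (the turquoise-style screen)
    edges_mci = coexpression.export_module_network(tom_mci, modules_mci, 0.0)
    edges_ad = coexpression.export_module_network(tom_ad, modules_ad, 0.0)

    def _module_threshold(edges: pd.DataFrame, module: str, q: float) -> float:
        w = edges.loc[edges["module"] == module, "weight"]
        return float(w.quantile(q)) if len(w) else 1.0

    rules_mci = {
        m: networks.CrosstalkRule(
            _module_threshold(edges_mci.edges, m, config.crosstalk_quantile),
            "top_k",
            config.crosstalk_top_k,
        )
        for m in sel_mci
    }
    rules_ad = {}
    for i, m in enumerate(sel_ad):
        if i == 0:
            rules_ad[m] = networks.CrosstalkRule(
                _module_threshold(edges_ad.edges, m, config.crosstalk_quantile),
                "top_k",
                config.crosstalk_top_k,
            )
        else:
            rules_ad[m] = networks.CrosstalkRule(
                _module_threshold(edges_ad.edges, m, config.secondary_quantile),
                "max_degree",
            )
    crosstalk = pd.concat(
        [
            networks.crosstalk_genes(edges_mci, rules_mci),
            networks.crosstalk_genes(edges_ad, rules_ad),
        ],
        ignore_index=True,
    )
    bridge = networks.bridge_genes(overlap, set(crosstalk["gene"]))
    bridge.to_csv(outdir / "bridge_genes.tsv", sep="\t", index=False)

    major_rows = []
    for disease, major in (("MCI", major_mci), ("AD", major_ad)):
        for g in major:
            major_rows.append(
                (
                    disease,
                    g,
                    bool(g in set(bridge["gene"])),
                    g in shared_major,
                )
            )
    major_table = pd.DataFrame(
        major_rows, columns=["disease", "gene", "is_bridge_gene", "is_shared"]
    )
    major_table.to_csv(outdir / "major_pathogenic_genes.tsv", sep="\t", index=False)

    # --- pivot regulators -----------------------------------------------
    interactions = pd.concat(
        [reg_data.mirna_targets, reg_data.tf_targets], ignore_index=True
    )
    module_map_mci = {m: modules_mci.module_genes(m) for m in sel_mci}
    module_map_ad = {m: modules_ad.module_genes(m) for m in sel_ad}
    try:
        pivots_mci = regulators.pivot_analysis(
            module_map_mci, interactions, universe,
            alpha=config.pivot_alpha, min_targets=config.pivot_min_targets,
        )
        pivots_ad = regulators.pivot_analysis(
            module_map_ad, interactions, universe,
            alpha=config.pivot_alpha, min_targets=config.pivot_min_targets,
        )
    except ValueError as err:
        raise PipelineError("regulators", str(err)) from err
    pivots_mci.to_csv(outdir / "pivots_MCI.tsv", sep="\t", index=False)
    pivots_ad.to_csv(outdir / "pivots_AD.tsv", sep="\t", index=False)
    bridge_regs = regulators.bridge_regulators(pivots_mci, pivots_ad)

    mir_meta = reg_data.mirna_metadata
    mir_groups = {g: _samples_of(mir_meta, g) for g in ("MCI", "AD", "CTL")}
    de_mir_mci = diffexpr.moderated_t_table(
        reg_data.mirna_expression, mir_groups["MCI"], mir_groups["CTL"], config.screen
    )
    de_mir_ad = diffexpr.moderated_t_table(
        reg_data.mirna_expression, mir_groups["AD"], mir_groups["CTL"], config.screen
    )
    up_m, down_m = diffexpr.screen_degs(de_mir_mci, config.screen)
    up_a, down_a = diffexpr.screen_degs(de_mir_ad, config.screen)
    bridge_regs = regulators.flag_de_bridge_regulators(
        bridge_regs, up_m | down_m, up_a | down_a
    )
    bridge_regs.to_csv(outdir / "bridge_regulators.tsv", sep="\t", index=False)

    # --- report ----------------------------------------------------------
    report = {
        "metadata": {
            "seed": config.seed,
            "package_version": "0.1.0",
            "screen": asdict(config.screen),
            "sample_counts": sample_counts,
        },
        "deg_counts": deg_counts,
        "candidates": {
            "MCI": {"n": len(cand_mci), "venn": venn_mci},
            "AD": {"n": len(cand_ad), "venn": venn_ad},
        },
        "modules": {
            "MCI": {
                "selected": sel_mci,
                "sizes": {k: int(v) for k, v in modules_mci.sizes().items()},
                "trait": modules_mci.trait_stats.to_dict("records"),
            },
            "AD": {
                "selected": sel_ad,
                "sizes": {k: int(v) for k, v in modules_ad.sizes().items()},
                "trait": modules_ad.trait_stats.to_dict("records"),
            },
        },
        "bridge_functions": bridge_term_sets.get("function", []),
        "bridge_pathways": bridge_term_sets.get("pathway", []),
        "overlapping_genes": sorted(overlap),
        "crosstalk_genes": sorted(set(crosstalk["gene"])),
        "bridge_genes": bridge.to_dict("records"),
        "major_pathogenic_genes": major_table.to_dict("records"),
        "shared_major_genes": shared_major,
        "pivot_pairs": {
            "MCI": pivots_mci.to_dict("records"),
            "AD": pivots_ad.to_dict("records"),
        },
        "bridge_regulators": bridge_regs.to_dict("records"),
    }
    with open(outdir / "bridge_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
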