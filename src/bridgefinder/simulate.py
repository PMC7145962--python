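"""Synthetic two-platform expression data with planted co-expression modules,
trait effects, batch distortion, regulator tables and interaction networks.

Every generator is deterministic under a fixed seed and carries its ground
truth alongside, so downstream recovery (module detection, differential
expression, pivot scoring) can be tested against known structure.

The expression model is a single-factor-per-module latent model: gene ``g``
in module ``m`` has

    x_gs = mu_g + lambda * f_m(s) + eps_gs,

with ``f_m ~ N(shift_m(group(s)), 1)`` per sample and
``lambda = noise_sd * sqrt(rho / (1 - rho))`` so that every same-module gene
pair has population correlation ``rho`` (the ``within_module_cor`` knob).
Disease effects act on the module factor, not per gene, so the module
eigengene-trait correlation is the natural recovered signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimulatedExpression",
    "RegulatorData",
    "generate_expression",
    "generate_gene_sets",
    "generate_disease_gene_lists",
    "generate_ppi",
    "generate_regulator_tables",
    "write_expression_tsv",
    "write_metadata_tsv",
    "write_gmt",
    "write_ppi_tsv",
    "write_interactions_tsv",
    "write_truth_json",
]

#: diagnosis labels retained by the analysis
CORE_GROUPS = ("CTL", "MCI", "AD")
#: rare bookkeeping categories that appear only on platform B and are
#: removed during preprocessing
EXTRANEOUS_GROUPS = ("borderline-MCI", "CTL-to-AD", "MCI-to-CTL", "other")

# platform compositions of the two-platform blood mRNA study the generator
# emulates: platform A (GPL6947-like) has 329 samples, platform B
# (GPL10558-like) has 388 including the four extraneous categories
DEFAULT_GROUP_COUNTS: dict[str, dict[str, int]] = {
    "A": {"MCI": 80, "AD": 145, "CTL": 104},
    "B": {
        "MCI": 109,
        "AD": 139,
        "CTL": 134,
        "borderline-MCI": 3,
        "CTL-to-AD": 1,
        "MCI-to-CTL": 1,
        "other": 1,
    },
}


def _default_trait_effects() -> dict[int, dict[str, float]]:
    # module 0 is the shared disease module (down in both diseases,
    # mirroring a blue-module-style negative association); module 1 is
    # MCI-specific, module 2 AD-specific, module 3 a null control.
    return {
        0: {"MCI": -1.0, "AD": -1.0},
        1: {"MCI": -1.0},
        2: {"AD": 1.0},
        3: {},
    }


@dataclass
class SimConfig:
    """Knobs of the synthetic study.

    Defaults mirror the emulated study design: the printed platform
    compositions, four planted 60-gene modules on a background of
    unstructured genes, within-module correlation 0.7, a one-standard-
    deviation latent trait shift for affected modules, and a visible
    platform batch effect.
    """

    seed: int = 0
    n_genes: int = 800
    probes_per_gene: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1}
    )
    module_sizes: Sequence[int] = (60, 60, 60, 60)
    within_module_cor: float = 0.7
    #: per-module, per-group mean shift of the latent factor (std units)
    trait_effect: Mapping[int, Mapping[str, float]] = field(
        default_factory=_default_trait_effects
    )
    #: sd of the per-gene location offset applied to platform B
    #: (twice the residual noise sd, a clearly visible platform effect)
    batch_offsets: float = 2.0
    #: variance multiplier applied to platform B deviations
    batch_scale: float = 1.5
    group_counts: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GROUP_COUNTS.items()}
    )
    noise_sd: float = 1.0
    probe_noise_sd: float = 0.15
    #: loading multiplier for the designated hub genes of each module, so
    #: hubs carry the highest intramodular connectivity (hub ~ high kME)
    hub_loading_boost: float = 1.4
    n_hubs_per_module: int = 3
    #: fraction of *background* genes also measured on platform B
    #: (module genes are always on both platforms)
    platform_b_coverage: float = 0.9
    n_unmapped_probes: int = 5
    n_regulators: int = 30
    targets_per_regulator: int = 10
    regulator_module_enrichment: float = 0.8
    #: samples per group in the companion miRNA expression set
    mirna_group_counts: Mapping[str, int] = field(
        default_factory=lambda: {"CTL": 50, "MCI": 50, "AD": 50}
    )
    mirna_de_shift: float = 1.0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)} "
                f"but only {self.n_genes} genes are available"
            )
        if not 0.0 <= self.within_module_cor <= 1.0:
            raise ValueError("within_module_cor must lie in [0, 1]")
        if any(s < 0 for s in self.module_sizes):
            raise ValueError("module sizes must be non-negative")
        if self.noise_sd < 0 or self.probe_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        for platform, counts in self.group_counts.items():
            if any(c < 0 for c in counts.values()):
                raise ValueError(f"negative sample count on platform {platform}")


@dataclass
class GroundTruth:
    """Planted structure carried alongside the generated data."""

    gene_module: dict[str, int]
    #: per-module dict of group -> latent-factor shift
    trait_effects: dict[int, dict[str, float]]
    hub_genes: dict[int, list[str]]
    #: regulator id -> (type, module index)
    pivot_regulators: dict[str, tuple[str, int]]
    #: per-disease genes whose module carries a shift for that disease
    de_genes: dict[str, list[str]]
    genes: list[str]

    def module_genes(self, module: int) -> list[str]:
        return [g for g, m in self.gene_module.items() if m == module]

    def modules_for_disease(self, disease: str) -> list[int]:
        return sorted(
            m for m, eff in self.trait_effects.items() if eff.get(disease, 0.0) != 0.0
        )


@dataclass
class SimulatedExpression:
    """Probe-level matrices for both platforms plus metadata and truth."""

    platform_a: pd.DataFrame
    platform_b: pd.DataFrame
    probe_to_gene_a: pd.Series
    probe_to_gene_b: pd.Series
    metadata: pd.DataFrame
    truth: GroundTruth


@dataclass
class RegulatorData:
    mirna_targets: pd.DataFrame
    tf_targets: pd.DataFrame
    mirna_expression: pd.DataFrame
    mirna_metadata: pd.DataFrame


def _sample_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for platform in sorted(config.group_counts):
        counts = config.group_counts[platform]
        i = 0
        for group in list(CORE_GROUPS) + list(EXTRANEOUS_GROUPS):
            for _ in range(int(counts.get(group, 0))):
                i += 1
                rows.append((f"S{platform}_{i:04d}", platform, group))
    return pd.DataFrame(rows, columns=["sample_id", "platform", "diagnosis"])


def _gene_values(
    config: SimConfig, meta: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, GroundTruth]:
    """Gene-level (pre-probe) expression for every sample on both platforms."""
    genes = [f"GENE{i:04d}" for i in range(config.n_genes)]
    gene_module: dict[str, int] = {}
    pos = 0
    for m, size in enumerate(config.module_sizes):
        for g in genes[pos : pos + size]:
            gene_module[g] = m
        pos += size

    n_samples = len(meta)
    rho = config.within_module_cor
    if config.noise_sd == 0 or rho >= 1.0:
        lam = 1.0
    else:
        lam = config.noise_sd * np.sqrt(rho / (1.0 - rho))

    mu = rng.normal(7.0, 1.0, size=config.n_genes)
    values = np.empty((config.n_genes, n_samples))
    groups = meta["diagnosis"].to_numpy()

    # latent module factors, shifted per diagnosis group
    factors = np.zeros((config.n_modules, n_samples))
    effects = {int(m): dict(v) for m, v in config.trait_effect.items()}
    for m in range(config.n_modules):
        shift = np.array([effects.get(m, {}).get(g, 0.0) for g in groups])
        factors[m] = rng.normal(0.0, 1.0, n_samples) + shift

    hub_genes = {
        m: sorted(g for g, mm in gene_module.items() if mm == m)[
            : config.n_hubs_per_module
        ]
        for m in range(config.n_modules)
    }
    hubs = {h for hs in hub_genes.values() for h in hs}

    eps = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    for i, g in enumerate(genes):
        m = gene_module.get(g)
        if m is None:
            values[i] = mu[i] + eps[i]
        else:
            lam_g = lam * (config.hub_loading_boost if g in hubs else 1.0)
            values[i] = mu[i] + lam_g * factors[m] + eps[i]

    de_genes = {
        disease: sorted(
            g
            for g, m in gene_module.items()
            if effects.get(m, {}).get(disease, 0.0) != 0.0
        )
        for disease in ("MCI", "AD")
    }
    truth = GroundTruth(
        gene_module=gene_module,
        trait_effects=effects,
        hub_genes=hub_genes,
        pivot_regulators={},  # filled by generate_regulator_tables
        de_genes=de_genes,
        genes=genes,
    )
    expr = pd.DataFrame(values, index=genes, columns=meta["sample_id"].to_numpy())
    return expr, truth


def _probe_matrix(
    gene_expr: pd.DataFrame,
    gene_subset: Sequence[str],
    platform: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series]:
    """Expand gene values into probe rows (replicates + probe noise)."""
    counts = sorted(config.probes_per_gene)
    probs = np.array([config.probes_per_gene[c] for c in counts], dtype=float)
    probs = probs / probs.sum()
    rows, probe_ids, mapping = [], [], []
    for g in gene_subset:
        n_probes = int(rng.choice(counts, p=probs))
        base = gene_expr.loc[g].to_numpy()
        for j in range(n_probes):
            offset = rng.normal(0.0, config.probe_noise_sd)
            noise = rng.normal(0.0, config.probe_noise_sd, size=base.shape)
            rows.append(base + offset + noise)
            pid = f"PRB{platform}_{g}_{j}"
            probe_ids.append(pid)
            mapping.append((pid, g))
    # a handful of unannotated probes, dropped at probe collapse
    for u in range(config.n_unmapped_probes):
        rows.append(rng.normal(7.0, 1.0, size=gene_expr.shape[1]))
        probe_ids.append(f"PRB{platform}_UNMAPPED_{u}")
    matrix = pd.DataFrame(rows, index=probe_ids, columns=gene_expr.columns)
    probe_map = pd.Series(dict(mapping), name="gene")
    probe_map.index.name = "probe"
    return matrix, probe_map


def generate_expression(
    config: SimConfig,
) -> SimulatedExpression:
    """Generate probe-level two-platform expression with planted structure.

    Platform B receives a per-gene location offset (sd ``batch_offsets``)
    and a variance inflation (``batch_scale``) on top of the shared
    gene-level signal, emulating a cross-platform batch effect. The
    extraneous diagnosis categories occur only on platform B.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta = _sample_table(config)
    gene_expr, truth = _gene_values(config, meta, rng)

    a_samples = meta.loc[meta["platform"] == "A", "sample_id"]
    b_samples = meta.loc[meta["platform"] == "B", "sample_id"]

    # platform B: location/scale distortion around each gene's own mean
    b_expr = gene_expr[b_samples].copy()
    gene_means = gene_expr.mean(axis=1).to_numpy()[:, None]
    offsets = rng.normal(0.0, config.batch_offsets, size=(len(gene_expr), 1))
    b_expr = pd.DataFrame(
        gene_means
        + offsets
        + np.sqrt(config.batch_scale) * (b_expr.to_numpy() - gene_means),
        index=b_expr.index,
        columns=b_expr.columns,
    )

    module_genes = [g for g in truth.genes if g in truth.gene_module]
    background = [g for g in truth.genes if g not in truth.gene_module]
    n_keep = int(round(config.platform_b_coverage * len(background)))
    kept_background = sorted(
        rng.choice(background, size=n_keep, replace=False)
    ) if background else []
    b_genes = module_genes + kept_background

    expr_a, map_a = _probe_matrix(gene_expr[a_samples], truth.genes, "A", config, rng)
    expr_b, map_b = _probe_matrix(b_expr, b_genes, "B", config, rng)
    return SimulatedExpression(
        platform_a=expr_a,
        platform_b=expr_b,
        probe_to_gene_a=map_a,
        probe_to_gene_b=map_b,
        metadata=meta,
        truth=truth,
    )


def generate_gene_sets(
    truth: GroundTruth,
    n_terms: int,
    seed: int,
    category: str = "function",
    random_size: tuple[int, int] = (10, 50),
) -> pd.DataFrame:
    """GMT-style collection: one positive-control term per planted module
    followed by random decoy terms drawn from the gene universe.

    Returns a frame with columns term_id, term_name, category, genes
    (frozenset).
    """
    if n_terms < 0:
        raise ValueError("n_terms must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    modules = sorted({m for m in truth.gene_module.values()})
    for m in modules:
        if len(rows) >= n_terms:
            break
        rows.append(
            (
                f"{category.upper()}_MODULE_{m}",
                f"planted module {m} ({category})",
                category,
                frozenset(truth.module_genes(m)),
            )
        )
    i = 0
    while len(rows) < n_terms:
        size = int(rng.integers(random_size[0], random_size[1] + 1))
        members = rng.choice(truth.genes, size=min(size, len(truth.genes)), replace=False)
        rows.append(
            (
                f"{category.upper()}_RANDOM_{i:03d}",
                f"decoy term {i} ({category})",
                category,
                frozenset(members),
            )
        )
        i += 1
    return pd.DataFrame(rows, columns=["term_id", "term_name", "category", "genes"])


def generate_disease_gene_lists(
    truth: GroundTruth, seed: int, n_extra: int = 50
) -> dict[str, list[str]]:
    """Curated-database-style disease gene lists: each disease's planted
    module genes diluted with random background genes."""
    rng = np.random.default_rng(seed)
    lists: dict[str, list[str]] = {}
    for disease in ("MCI", "AD"):
        core: set[str] = set()
        for m in truth.modules_for_disease(disease):
            core.update(truth.module_genes(m))
        extras = rng.choice(truth.genes, size=min(n_extra, len(truth.genes)), replace=False)
        lists[disease] = sorted(core | set(extras))
    return lists


def generate_ppi(
    truth: GroundTruth, n_nodes: int, m_attach: int, seed: int
) -> nx.Graph:
    """Scale-free (preferential-attachment) PPI over gene symbols.

    The planted hub genes are assigned to the highest-degree nodes of the
    generated topology, so they carry the extra edges that preferential
    attachment concentrates on early nodes.
    """
    if not n_nodes > m_attach >= 1:
        raise ValueError("need n_nodes > m_attach >= 1")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n_nodes, m_attach, seed=int(rng.integers(2**31)))

    hubs = sorted({h for hs in truth.hub_genes.values() for h in hs})
    others = [x for x in truth.genes if x not in set(hubs)]
    if n_nodes > len(truth.genes):
        raise ValueError("n_nodes exceeds number of simulated genes")
    # highest-degree topology nodes -> planted hubs, rest -> random genes
    by_degree = sorted(g.nodes, key=lambda v: (-g.degree(v), v))
    label: dict[int, str] = {}
    for node, hub in zip(by_degree, hubs):
        label[node] = hub
    remaining_nodes = [v for v in by_degree if v not in label]
    chosen = rng.choice(others, size=len(remaining_nodes), replace=False)
    for node, gene in zip(remaining_nodes, chosen):
        label[node] = gene
    relabeled = nx.relabel_nodes(g, label)
    relabeled.remove_edges_from(nx.selfloop_edges(relabeled))
    return relabeled


def generate_regulator_tables(
    truth: GroundTruth, config: SimConfig
) -> RegulatorData:
    """Regulator-target tables plus a companion miRNA expression matrix.

    Half the regulators are miRNAs, half transcription factors. One miRNA
    pivot is planted per trait-affected module -- the pivot of the shared
    module is therefore a bridge-regulator positive control -- plus one TF
    pivot on the shared module. Pivot target draws are enriched for the
    assigned module at rate ``regulator_module_enrichment``; all other
    regulators draw targets uniformly. Pivot miRNAs additionally receive a
    mean expression shift in the diagnosis groups their module affects,
    making them differentially expressed in the companion miRNA data.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_mirna = config.n_regulators // 2
    n_tf = config.n_regulators - n_mirna
    mirnas = [f"hsa-miR-sim-{i:03d}" for i in range(n_mirna)]
    tfs = [f"TF{i:03d}" for i in range(n_tf)]

    affected = sorted(
        m for m, eff in truth.trait_effects.items() if any(v != 0.0 for v in eff.values())
    )
    shared = [
        m
        for m in affected
        if truth.trait_effects[m].get("MCI", 0.0) != 0.0
        and truth.trait_effects[m].get("AD", 0.0) != 0.0
    ]
    pivots: dict[str, tuple[str, int]] = {}
    for i, m in enumerate(affected):
        if i < len(mirnas):
            pivots[mirnas[i]] = ("miRNA", m)
    if shared and tfs:
        pivots[tfs[0]] = ("TF", shared[0])
    truth.pivot_regulators = pivots

    universe = np.array(truth.genes)
    t = config.targets_per_regulator

    def draw_targets(reg: str) -> list[str]:
        if reg in pivots:
            _, m = pivots[reg]
            module = np.array(truth.module_genes(m))
            n_in = int(round(config.regulator_module_enrichment * t))
            n_in = min(n_in, len(module))
            inside = rng.choice(module, size=n_in, replace=False)
            pool = np.setdiff1d(universe, inside)
            outside = rng.choice(pool, size=t - n_in, replace=False)
            return sorted(set(inside) | set(outside))
        return sorted(rng.choice(universe, size=t, replace=False))

    mirna_rows = [
        (reg, "miRNA", target) for reg in mirnas for target in draw_targets(reg)
    ]
    tf_rows = [(reg, "TF", target) for reg in tfs for target in draw_targets(reg)]
    cols = ["regulator", "type", "target"]
    mirna_targets = pd.DataFrame(mirna_rows, columns=cols)
    tf_targets = pd.DataFrame(tf_rows, columns=cols)

    # companion miRNA expression: pivot miRNAs shift in affected diagnoses
    rows = []
    for grp in sorted(config.mirna_group_counts):
        for i in range(int(config.mirna_group_counts[grp])):
            rows.append((f"SM_{grp}_{i:03d}", "miRNA-panel", grp))
    mirna_meta = pd.DataFrame(rows, columns=["sample_id", "platform", "diagnosis"])
    groups = mirna_meta["diagnosis"].to_numpy()
    base = rng.normal(6.0, 1.0, size=len(mirnas))
    values = rng.normal(0.0, 1.0, size=(len(mirnas), len(mirna_meta))) + base[:, None]
    for i, reg in enumerate(mirnas):
        if reg in pivots:
            _, m = pivots[reg]
            for disease, eff in truth.trait_effects[m].items():
                if eff != 0.0:
                    mask = groups == disease
                    values[i, mask] += np.sign(eff) * config.mirna_de_shift
    mirna_expr = pd.DataFrame(
        values, index=mirnas, columns=mirna_meta["sample_id"].to_numpy()
    )
    return RegulatorData(
        mirna_targets=mirna_targets,
        tf_targets=tf_targets,
        mirna_expression=mirna_expr,
        mirna_metadata=mirna_meta,
    )


# ---------------------------------------------------------------------------
# plain-text writers

def write_expression_tsv(matrix: pd.DataFrame, path: str | Path, id_name: str = "feature_id") -> None:
    out = matrix.copy()
    out.index.name = id_name
    out.to_csv(path, sep="\t", float_format="%.6g")


def write_metadata_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def write_gmt(collection: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for _, row in collection.iterrows():
            genes = "\t".join(sorted(row["genes"]))
            fh.write(f"{row['term_id']}\t{row['term_name']}\t{genes}\n")


def write_ppi_tsv(graph: nx.Graph, path: str | Path) -> None:
    edges = sorted(tuple(sorted(e)) for e in graph.edges)
    pd.DataFrame(edges, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def write_interactions_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "gene_module": truth.gene_module,
        "trait_effects": {str(k): v for k, v in truth.trait_effects.items()},
        "hub_genes": {str(k): v for k, v in truth.hub_genes.items()},
        "pivot_regulators": {
            k: list(v) for k, v in truth.pivot_regulators.items()
        },
        "de_genes": truth.de_genes,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
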