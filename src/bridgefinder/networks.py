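"""PPI connectivity ranking and bridge-gene identification.

Module genes are embedded in the protein-interaction graph together with
their direct neighbors; connectivity (degree in that induced network)
ranks module genes, the top of the ranking being the "major pathogenic
genes". Bridge genes are the union of overlapping genes (intersection of
the two diseases' module gene sets) and crosstalk genes (high-degree
genes of the thresholded intramodular TOM networks), with per-gene
provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from bridgefinder.coexpression import ModuleEdgeList

logger = logging.getLogger(__name__)

__all__ = [
    "CrosstalkRule",
    "read_ppi",
    "induce_ppi_network",
    "major_pathogenic_genes",
    "overlapping_genes",
    "crosstalk_genes",
    "bridge_genes",
]


@dataclass(frozen=True)
class CrosstalkRule:
    """Per-module crosstalk selection: threshold intramodular edges by
    weight, rank genes by degree, then keep either the top k
    (``selection='top_k'``) or every gene tied at the maximum degree
    (``selection='max_degree'``)."""

    weight_threshold: float = 0.3
    selection: str = "top_k"
    k: int = 40

    def __post_init__(self) -> None:
        if self.selection not in {"top_k", "max_degree"}:
            raise ValueError("selection must be 'top_k' or 'max_degree'")


def read_ppi(path: str | Path) -> nx.Graph:
    table = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    g.add_edges_from(
        (a, b) for a, b in table.iloc[:, :2].itertuples(index=False) if a != b
    )
    return g


def induce_ppi_network(
    module_genes: Iterable[str], ppi: nx.Graph
) -> tuple[nx.Graph, pd.DataFrame]:
    """Induced network over module genes plus their direct PPI neighbors.

    Returns the network and a connectivity table restricted to module
    genes (genes absent from the PPI keep degree 0); ranks are dense with
    lexicographic tie-break.
    """
    module_genes = sorted(set(module_genes))
    if not module_genes:
        raise ValueError("empty module gene set")
    present = [g for g in module_genes if g in ppi]
    if not present:
        logger.warning("no module gene present in the PPI graph")
        network = nx.Graph()
    else:
        nodes = set(present)
        for g in present:
            nodes.update(ppi.neighbors(g))
        network = ppi.subgraph(nodes).copy()
    rows = []
    for g in module_genes:
        deg = network.degree(g) if g in network else 0
        rows.append((g, int(deg), True))
    table = pd.DataFrame(rows, columns=["gene", "degree", "is_module_gene"])
    table = table.sort_values(
        ["degree", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = table["degree"].rank(method="dense", ascending=False).astype(int)
    return network, table


def major_pathogenic_genes(table: pd.DataFrame, top_n: int = 10) -> list[str]:
    """Top module genes by induced-network degree (lexicographic ties)."""
    if table.empty:
        raise ValueError("empty connectivity table")
    ordered = table.sort_values(
        ["degree", "gene"], ascending=[False, True], kind="mergesort"
    )
    return list(ordered["gene"].head(top_n))


def overlapping_genes(
    mci_module_genes: Iterable[str], ad_module_genes: Iterable[str]
) -> set[str]:
    return set(mci_module_genes) & set(ad_module_genes)


def crosstalk_genes(
    module_edges: ModuleEdgeList | pd.DataFrame,
    rules: Mapping[str, CrosstalkRule],
) -> pd.DataFrame:
    """Apply per-module crosstalk rules to an intramodular edge list.

    Returns a frame (gene, module, degree) with one row per selected gene
    per module.
    """
    edges = module_edges.edges if isinstance(module_edges, ModuleEdgeList) else module_edges
    rows = []
    for module, rule in sorted(rules.items()):
        if rule.weight_threshold >= 1.0:
            logger.warning("module %s: threshold >= 1 selects nothing", module)
            continue
        sub = edges[
            (edges["module"] == module) & (edges["weight"] > rule.weight_threshold)
        ]
        if sub.empty:
            continue
        degree: dict[str, int] = {}
        for a, b in zip(sub["gene_a"], sub["gene_b"]):
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        ranked = sorted(degree.items(), key=lambda kv: (-kv[1], kv[0]))
        if rule.selection == "top_k":
            chosen = ranked[: rule.k]
        else:
            top = ranked[0][1]
            chosen = [kv for kv in ranked if kv[1] == top]
        rows.extend((g, module, d) for g, d in chosen)
    return pd.DataFrame(rows, columns=["gene", "module", "degree"])


def bridge_genes(
    overlapping: Iterable[str], crosstalk: Iterable[str]
) -> pd.DataFrame:
    """Union of overlapping and crosstalk genes with provenance flags."""
    overlapping, crosstalk = set(overlapping), set(crosstalk)
    rows = []
    for g in sorted(overlapping | crosstalk):
        in_o, in_c = g in overlapping, g in crosstalk
        provenance = "both" if in_o and in_c else ("overlapping" if in_o else "crosstalk")
        rows.append((g, in_o, in_c, provenance))
    return pd.DataFrame(
        rows, columns=["gene", "is_overlapping", "is_crosstalk", "provenance"]
    )
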