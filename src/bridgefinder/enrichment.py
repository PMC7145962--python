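"""Hypergeometric over-representation analysis (ORA) and bridge terms.

One hypergeometric kernel serves both module enrichment against gene-set
collections and the pivot-regulator scoring: the upper-tail probability
of drawing at least ``k`` annotated genes when ``n`` genes are sampled
without replacement from a background of ``N`` genes of which ``K`` carry
the annotation. Benjamini-Hochberg adjustment is applied within each
(module, category) block; bridge functions / pathways are the
cross-disease intersections of the significant term sets.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "hypergeom_upper",
    "read_gmt",
    "enrich_module",
    "significant_terms",
    "bridge_terms",
]


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), evaluated stably.

    ``k = 0`` returns exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric bounds N={N}, K={K}, n={n}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def read_gmt(path: str | Path, category: str) -> pd.DataFrame:
    """Read a GMT file into the collection frame used by enrich_module."""
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            rows.append((parts[0], parts[1], category, frozenset(parts[2:])))
    return pd.DataFrame(rows, columns=["term_id", "term_name", "category", "genes"])


def enrich_module(
    query: Iterable[str],
    collection: pd.DataFrame,
    background: Iterable[str],
) -> pd.DataFrame:
    """ORA of a gene set against a collection.

    Rows are emitted only for terms overlapping the query (k >= 1),
    BH-adjusted within category, sorted by (p, term_id) for deterministic
    ties. Columns: term_id, term_name, category, N, K, n, k, p, p_adj.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background universe")
    query = set(query) & background
    N, n = len(background), len(query)
    rows = []
    for _, term in collection.iterrows():
        term_genes = set(term["genes"]) & background
        K = len(term_genes)
        k = len(term_genes & query)
        if k < 1 or K < 1:
            continue
        rows.append(
            (
                term["term_id"],
                term["term_name"],
                term["category"],
                N,
                K,
                n,
                k,
                hypergeom_upper(N, K, n, k),
            )
        )
    result = pd.DataFrame(
        rows, columns=["term_id", "term_name", "category", "N", "K", "n", "k", "p"]
    )
    if result.empty:
        result["p_adj"] = pd.Series(dtype=float)
        return result
    result["p_adj"] = 1.0
    for cat, idx in result.groupby("category").groups.items():
        result.loc[idx, "p_adj"] = multipletests(
            result.loc[idx, "p"], method="fdr_bh"
        )[1]
    return result.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)


def significant_terms(
    result: pd.DataFrame, alpha: float = 0.05, use_adjusted: bool = False
) -> dict[str, set[str]]:
    """Per-category sets of significant term ids (raw p by default)."""
    col = "p_adj" if use_adjusted else "p"
    out: dict[str, set[str]] = {}
    for cat, sub in result.groupby("category"):
        out[str(cat)] = set(sub.loc[sub[col] < alpha, "term_id"])
    return out


def bridge_terms(
    mci_terms: Mapping[str, set[str]], ad_terms: Mapping[str, set[str]]
) -> dict[str, list[str]]:
    """Per-category intersection of the two diseases' significant terms."""
    out = {}
    for cat in sorted(set(mci_terms) | set(ad_terms)):
        out[cat] = sorted(mci_terms.get(cat, set()) & ad_terms.get(cat, set()))
    return out
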