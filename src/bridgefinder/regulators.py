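"""Pivot-regulator analysis.

A regulator (miRNA or transcription factor) is a *pivot* of a module when
at least ``min_targets`` of its targets fall inside the module and the
hypergeometric upper-tail probability of that overlap against the
interaction background is below ``alpha``. The background universe is
the set of genes that appear both in the module-analysis expression
profile and as a target of at least one regulator. Bridge regulators are
pivots of both diseases' modules; miRNA bridge regulators are further
flagged when they are themselves differentially expressed.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from statsmodels.stats.multitest import multipletests

from bridgefinder.enrichment import hypergeom_upper

__all__ = ["pivot_analysis", "bridge_regulators", "flag_de_bridge_regulators"]


def pivot_analysis(
    module_genes: Mapping[str, Iterable[str]],
    interactions: pd.DataFrame,
    expression_genes: Iterable[str],
    alpha: float = 0.05,
    min_targets: int = 2,
) -> pd.DataFrame:
    """Score every (regulator, module) pair by hypergeometric overlap.

    ``interactions`` has columns (regulator, type, target). Reported rows
    satisfy k >= min_targets and raw p < alpha; BH-adjusted p over all
    tested pairs is reported alongside but not used for the cut.
    Columns: regulator, type, module, k, K, n, N, p, p_adj.
    """
    if interactions.empty:
        raise ValueError("empty interaction table")
    background = set(expression_genes) & set(interactions["target"])
    if not background:
        raise ValueError("no expression gene appears as a regulator target")
    N = len(background)

    reg_targets = {
        reg: set(sub["target"]) & background
        for reg, sub in interactions.groupby("regulator")
    }
    reg_type = dict(
        interactions.drop_duplicates("regulator")[["regulator", "type"]].to_numpy()
    )
    rows = []
    for module, genes in sorted(module_genes.items()):
        mod = set(genes) & background
        n = len(mod)
        if n == 0:
            continue
        for reg in sorted(reg_targets):
            targets = reg_targets[reg]
            K = len(targets)
            k = len(targets & mod)
            if k < min_targets:
                continue
            p = hypergeom_upper(N, K, n, k)
            rows.append((reg, reg_type[reg], module, k, K, n, N, p))
    table = pd.DataFrame(
        rows, columns=["regulator", "type", "module", "k", "K", "n", "N", "p"]
    )
    if table.empty:
        table["p_adj"] = pd.Series(dtype=float)
        return table
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    table = table[table["p"] < alpha]
    return table.sort_values(["p", "regulator", "module"], kind="mergesort").reset_index(
        drop=True
    )


def bridge_regulators(
    mci_pivots: pd.DataFrame, ad_pivots: pd.DataFrame
) -> pd.DataFrame:
    """Regulators that are pivots of at least one module in both diseases,
    annotated with each disease's best p."""
    if mci_pivots.empty or ad_pivots.empty:
        return pd.DataFrame(columns=["regulator", "type", "best_p_mci", "best_p_ad"])
    shared = sorted(set(mci_pivots["regulator"]) & set(ad_pivots["regulator"]))
    rows = []
    for reg in shared:
        sub_m = mci_pivots[mci_pivots["regulator"] == reg]
        sub_a = ad_pivots[ad_pivots["regulator"] == reg]
        rows.append(
            (
                reg,
                sub_m["type"].iloc[0],
                float(sub_m["p"].min()),
                float(sub_a["p"].min()),
            )
        )
    return pd.DataFrame(rows, columns=["regulator", "type", "best_p_mci", "best_p_ad"])


def flag_de_bridge_regulators(
    bridge: pd.DataFrame,
    de_mirnas_mci: Iterable[str],
    de_mirnas_ad: Iterable[str],
) -> pd.DataFrame:
    """Flag each bridge regulator for differential-expression membership;
    transcription factors are never flagged (the DE screen covers miRNAs
    only)."""
    de_mci, de_ad = set(de_mirnas_mci), set(de_mirnas_ad)
    out = bridge.copy()
    if out.empty:
        out["de_in_mci"] = pd.Series(dtype=bool)
        out["de_in_ad"] = pd.Series(dtype=bool)
        return out
    is_mirna = out["type"] == "miRNA"
    out["de_in_mci"] = is_mirna & out["regulator"].isin(de_mci)
    out["de_in_ad"] = is_mirna & out["regulator"].isin(de_ad)
    return out
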