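"""Moderated-t differential expression and the fold-change / p screen.

The variance moderation is the classic empirical-Bayes scheme for
microarrays: per-gene pooled variances s_g^2 (d_g residual df) are assumed
to follow s0^2 * F(d_g, d0) under the prior; the hyperparameters (d0,
s0^2) are fitted by moment matching on log s_g^2, the posterior variance
is the precision-weighted blend

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and the moderated t uses d0 + d_g degrees of freedom. Screening follows
the fold-change rule FC > 1.2 or FC < 5/6 at p < 0.05 (strict
inequalities), with fold change taken as 2^(difference of log2 group
means).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenParams",
    "fit_variance_prior",
    "moderated_t_table",
    "screen_degs",
    "assemble_candidate_genes",
]

D0_CAP = 1e9  # stands in for an infinite prior df


@dataclass(frozen=True)
class ScreenParams:
    """Fold-change / p thresholds; 5/6 = 1/1.2 makes the rule symmetric
    on the ratio scale."""

    fc_up: float = 1.2
    fc_down: float = 5.0 / 6.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.fc_down < 1.0 < self.fc_up):
            raise ValueError("need 0 < fc_down < 1 < fc_up")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x by Newton iteration on 1/y (monotone)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < tol:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) of the scaled-F variance prior on log s^2.

    Returns d0 capped at 1e9 (representing infinity when the observed
    log-variance spread is no wider than sampling noise alone).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return D0_CAP, float(np.median(s2[ok])) if ok.any() else 1.0
    e = np.log(s2[ok]) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_var = float(np.var(e, ddof=1))
    target = e_var - float(special.polygamma(1, df / 2.0))
    if target <= 0:
        d0 = D0_CAP
        s0_sq = float(np.exp(np.mean(e)))
    else:
        d0 = min(2.0 * _trigamma_inverse(target), D0_CAP)
        s0_sq = float(
            np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    return d0, s0_sq


def moderated_t_table(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    params: ScreenParams = ScreenParams(),
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-feature moderated-t comparison of group A against group B.

    Group A is the disease (first-listed) group, so direction "down" means
    lower in disease. ``prior_df`` overrides the fitted d0 (0 recovers the
    ordinary pooled-variance two-sample t exactly).
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")

    xa = matrix[group_a].to_numpy(dtype=float)
    xb = matrix[group_b].to_numpy(dtype=float)
    na, nb = xa.shape[1], xb.shape[1]
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    var_a, var_b = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    df_resid = na + nb - 2
    s2 = ((na - 1) * var_a + (nb - 1) * var_b) / df_resid

    if prior_df is None:
        d0, s0_sq = fit_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        _, s0_sq = fit_variance_prior(s2, df_resid) if d0 > 0 else (None, float("nan"))

    if d0 > 0:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = min(d0 + df_resid, D0_CAP)
    else:
        s2_post = s2
        df_total = float(df_resid)

    log2fc = mean_a - mean_b
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log2fc / se
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    dead = s2_post <= 0
    if dead.any():
        logger.warning(
            "%d features with zero variance in both groups: p set to 1",
            int(dead.sum()),
        )
        t_mod = np.where(dead, 0.0, t_mod)
        p = np.where(dead, 1.0, p)

    p_adj = multipletests(p, method="fdr_bh")[1]
    fc = 2.0**log2fc
    direction = np.where(
        (fc > params.fc_up) & (p < params.alpha),
        "up",
        np.where((fc < params.fc_down) & (p < params.alpha), "down", "ns"),
    )
    table = pd.DataFrame(
        {
            "feature_id": matrix.index,
            "mean_A": mean_a,
            "mean_B": mean_b,
            "log2FC": log2fc,
            "FC": fc,
            "t_mod": t_mod,
            "p": p,
            "p_adj_BH": p_adj,
            "direction": direction,
        }
    ).set_index("feature_id")
    table.attrs["d0"] = d0
    table.attrs["s0_sq"] = s0_sq
    table.attrs["df_residual"] = df_resid
    return table


def screen_degs(
    table: pd.DataFrame, params: ScreenParams = ScreenParams()
) -> tuple[set[str], set[str]]:
    """Apply the fold-change / p rule with strict inequalities."""
    up = set(table.index[(table["FC"] > params.fc_up) & (table["p"] < params.alpha)])
    down = set(table.index[(table["FC"] < params.fc_down) & (table["p"] < params.alpha)])
    return up, down


def assemble_candidate_genes(
    deg_sets: Iterable[Iterable[str]],
    database_lists: Iterable[Iterable[str]],
    universe: Iterable[str],
) -> tuple[list[str], dict[str, int]]:
    """Union of DEG sets and curated disease lists, restricted to genes in
    the expression matrix; returns the candidate list plus Venn-style
    bookkeeping counts."""
    universe = set(universe)
    deg_sets = [set(s) for s in deg_sets]
    database_lists = [set(s) for s in database_lists]
    union: set[str] = set()
    for s in deg_sets + database_lists:
        union |= s
    candidates = sorted(union & universe)
    counts = {
        "n_candidates": len(candidates),
        "n_union_raw": len(union),
        "n_dropped_not_in_matrix": len(union - universe),
    }
    for i, s in enumerate(deg_sets):
        counts[f"deg_set_{i}"] = len(s)
    for i, s in enumerate(database_lists):
        counts[f"database_list_{i}"] = len(s)
    return candidates, counts
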