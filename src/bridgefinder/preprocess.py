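"""Cross-platform expression preprocessing.

Probe-to-gene collapse (mean over probes), common-gene platform merge,
diagnosis-based sample filtering, and a parametric empirical-Bayes
location/scale batch adjustment (the ComBat procedure) with biological
covariates protected so group differences survive correction.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger(__name__)

__all__ = ["collapse_probes", "merge_platforms", "filter_samples", "adjust_batch"]

KEEP_DEFAULT = frozenset({"CTL", "MCI", "AD"})


def collapse_probes(
    probe_matrix: pd.DataFrame, probe_to_gene: Mapping[str, str] | pd.Series | pd.DataFrame
) -> pd.DataFrame:
    """Collapse probe rows to gene rows by the per-sample arithmetic mean.

    Probes without a mapping are dropped (counted in the log); a probe
    mapped to more than one gene is an error.
    """
    if isinstance(probe_to_gene, pd.DataFrame):
        if probe_to_gene.shape[1] != 2:
            raise ValueError("probe map frame must have two columns (probe, gene)")
        dup = probe_to_gene.iloc[:, 0][
            probe_to_gene.drop_duplicates().iloc[:, 0].duplicated()
        ]
        if len(dup):
            raise ValueError(f"probe mapped to multiple genes: {sorted(set(dup))}")
        mapping = pd.Series(
            probe_to_gene.iloc[:, 1].to_numpy(), index=probe_to_gene.iloc[:, 0]
        )
    else:
        mapping = pd.Series(dict(probe_to_gene)) if not isinstance(
            probe_to_gene, pd.Series
        ) else probe_to_gene
    if mapping.empty:
        raise ValueError("empty probe-to-gene mapping")

    genes = probe_matrix.index.to_series().map(mapping)
    n_dropped = int(genes.isna().sum())
    if n_dropped:
        logger.info("dropping %d probes without a gene annotation", n_dropped)
    kept = probe_matrix.loc[genes.notna()]
    collapsed = kept.groupby(genes.dropna()).mean()
    collapsed.index.name = "gene"
    return collapsed.sort_index()


def merge_platforms(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Row-intersect two gene-level matrices and concatenate their samples.

    Gene order in the result is lexicographic for reproducibility.
    """
    common = sorted(set(a.index) & set(b.index))
    if not common:
        raise ValueError("no genes shared between the two platforms")
    overlap = set(a.columns) & set(b.columns)
    if overlap:
        raise ValueError(f"duplicate sample ids across platforms: {sorted(overlap)[:5]}")
    merged = pd.concat([a.loc[common], b.loc[common]], axis=1)
    logger.info(
        "merged platforms: %d common genes, %d samples", len(common), merged.shape[1]
    )
    return merged


def filter_samples(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    keep: Iterable[str] = KEEP_DEFAULT,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Retain only samples whose diagnosis is in ``keep``.

    Column order is preserved. Returns the filtered matrix, the filtered
    metadata and the per-class retained counts.
    """
    keep = set(keep)
    meta_idx = meta.set_index("sample_id")
    missing = [s for s in matrix.columns if s not in meta_idx.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    diagnosis = meta_idx.loc[matrix.columns, "diagnosis"]
    retained = [s for s in matrix.columns if diagnosis[s] in keep]
    out_matrix = matrix[retained]
    out_meta = meta[meta["sample_id"].isin(retained)].reset_index(drop=True)
    counts = out_meta["diagnosis"].value_counts().to_dict()
    counts = {k: int(v) for k, v in counts.items()}
    logger.info("retained %d samples: %s", len(retained), counts)
    return out_matrix, out_meta, counts


def _design_matrix(labels: Sequence[str], drop_first: bool) -> np.ndarray:
    levels = sorted(set(labels))
    if drop_first:
        levels = levels[1:]
    arr = np.zeros((len(labels), len(levels)))
    for j, lev in enumerate(levels):
        arr[:, j] = [1.0 if x == lev else 0.0 for x in labels]
    return arr


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = float(np.mean(delta_hat)), float(np.var(delta_hat, ddof=1))
    return (2.0 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = float(np.mean(delta_hat)), float(np.var(delta_hat, ddof=1))
    return (m * s2 + m**3) / s2


def _it_sol(
    z_batch: np.ndarray,
    g_hat: np.ndarray,
    d_hat: np.ndarray,
    g_bar: float,
    t2: float,
    a: float,
    b: float,
    conv: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-point iteration for the EB posterior location/scale per gene."""
    n = z_batch.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def adjust_batch(
    matrix: pd.DataFrame,
    batch: Sequence[str] | pd.Series,
    covariates: Sequence[str] | pd.Series | None = None,
    shrink: bool = True,
) -> pd.DataFrame:
    """Location/scale batch adjustment with optional empirical-Bayes
    shrinkage (parametric ComBat).

    Each gene is standardized by its covariate-adjusted grand mean and
    pooled variance; per-batch per-gene location (gamma) and scale
    (delta^2) are estimated and, if ``shrink``, shrunk toward a normal /
    inverse-gamma prior whose hyperparameters are moment-matched across
    genes, then removed. ``covariates`` (e.g. diagnosis) are protected:
    their fitted effects are part of the standardization mean and are
    restored untouched.
    """
    batch = np.asarray(batch)
    if batch.shape[0] != matrix.shape[1]:
        raise ValueError("batch labels must align with matrix columns")
    batches = sorted(set(batch))
    if len(batches) < 2:
        raise ValueError("need at least two batches")
    sizes = {b: int((batch == b).sum()) for b in batches}
    small = [b for b, n in sizes.items() if n < 2]
    if small:
        raise ValueError(f"batches with fewer than 2 samples: {small}")

    y = matrix.to_numpy(dtype=float)
    n_genes, n_samples = y.shape

    batch_design = _design_matrix(batch, drop_first=False)
    if covariates is not None:
        cov = np.asarray(covariates)
        cov_design = _design_matrix(cov, drop_first=True)
        design = np.hstack([batch_design, cov_design])
    else:
        cov_design = np.zeros((n_samples, 0))
        design = batch_design
    n_batch = len(batches)

    b_hat, *_ = linalg.lstsq(design, y.T)
    sample_frac = np.array([sizes[b] / n_samples for b in batches])
    grand_mean = sample_frac @ b_hat[:n_batch]  # per gene
    resid = y - (design @ b_hat).T
    var_pooled = (resid**2).mean(axis=1)

    degenerate = var_pooled <= 1e-12
    if degenerate.any():
        logger.warning(
            "%d genes have (near-)zero pooled variance; location-only "
            "adjustment applied",
            int(degenerate.sum()),
        )
    scale = np.sqrt(np.where(degenerate, 1.0, var_pooled))

    stand_mean = grand_mean[:, None] + (cov_design @ b_hat[n_batch:]).T
    z = (y - stand_mean) / scale[:, None]

    adjusted = z.copy()
    for bi, b in enumerate(batches):
        idx = np.where(batch == b)[0]
        zb = z[:, idx]
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        zero_var = d_hat <= 1e-12
        if zero_var.any():
            logger.warning(
                "batch %s: %d genes with zero within-batch variance; "
                "location-only adjustment for these",
                b,
                int(zero_var.sum()),
            )
        if shrink and n_genes >= 2 and np.var(d_hat[~zero_var] if (~zero_var).any() else d_hat, ddof=1 if n_genes > 1 else 0) > 0:
            g_bar, t2 = float(np.mean(g_hat)), float(np.var(g_hat, ddof=1))
            pos = d_hat[~zero_var] if (~zero_var).any() else d_hat
            a, bp = _aprior(pos), _bprior(pos)
            if t2 <= 0 or not np.isfinite(a) or not np.isfinite(bp):
                g_star, d_star = g_hat, d_hat
            else:
                g_star, d_star = _it_sol(zb, g_hat, d_hat, g_bar, t2, a, bp)
        else:
            g_star, d_star = g_hat, d_hat
        d_star = np.where(d_star <= 1e-12, 1.0, d_star)
        adjusted[:, idx] = (zb - g_star[:, None]) / np.sqrt(d_star[:, None])

    out = adjusted * scale[:, None] + stand_mean
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
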