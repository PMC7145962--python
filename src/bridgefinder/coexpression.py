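"""Self-contained weighted co-expression network core.

Implements the canonical WGCNA sequence: soft-threshold selection by the
scale-free topology fit index, unsigned adjacency a_ij = |cor|^beta,
topological overlap similarity

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

average-linkage hierarchical module detection on 1 - TOM with a static
height cut, eigengene computation (first principal component of the
standardized module submatrix), eigengene-based module merging, Pearson
eigengene-trait correlation, and thresholded intramodular edge export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "SoftThresholdReport",
    "ModuleSet",
    "ModuleEdgeList",
    "pick_soft_threshold",
    "adjacency",
    "tom_similarity",
    "module_eigengene",
    "detect_modules",
    "module_trait_correlation",
    "attach_trait_correlations",
    "export_module_network",
]

#: module label sequence, assigned by decreasing module size
COLOR_SEQUENCE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)
GREY = "grey"


@dataclass
class SoftThresholdReport:
    table: pd.DataFrame  # columns: power, r2_signed, mean_connectivity
    chosen: int
    r2_target: float


@dataclass
class ModuleSet:
    """Gene-to-module labels plus eigengenes and trait statistics."""

    labels: pd.Series  # gene -> color label
    eigengenes: pd.DataFrame  # samples x modules
    trait_stats: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["module", "trait", "r", "p", "significant"]
        )
    )

    def module_genes(self, label: str) -> list[str]:
        return sorted(self.labels.index[self.labels == label])

    @property
    def module_labels(self) -> list[str]:
        return [l for l in self.eigengenes.columns]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()


@dataclass
class ModuleEdgeList:
    edges: pd.DataFrame  # module, gene_a, gene_b, weight
    degrees: pd.DataFrame  # module, gene, degree
    weight_threshold: float


def _abs_correlation(matrix: pd.DataFrame) -> np.ndarray:
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.all():
        raise ValueError("all genes are constant")
    if constant.any():
        logger.warning(
            "%d constant genes: correlations set to 0", int(constant.sum())
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        cor = np.corrcoef(x)
    cor = np.nan_to_num(cor, nan=0.0)
    np.fill_diagonal(cor, 1.0)
    return np.abs(np.clip(cor, -1.0, 1.0))


def _scale_free_r2(k: np.ndarray, n_bins: int) -> float:
    """Signed scale-free topology fit index of a connectivity vector."""
    k = k[k > 0]
    if len(k) < 2 or np.allclose(k, k[0]):
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k = np.array([k[which == b].mean() if (which == b).any() else 0.0 for b in range(n_bins)])
    freq = np.array([(which == b).sum() for b in range(n_bins)]) / len(k)
    ok = (mean_k > 0) & (freq > 0)
    if ok.sum() < 2:
        return 0.0
    lx, ly = np.log10(mean_k[ok]), np.log10(freq[ok])
    if np.allclose(lx, lx[0]):
        return 0.0
    slope, _, r, *_ = stats.linregress(lx, ly)
    # positive when frequency decays with connectivity (scale-free law)
    return float(-np.sign(slope) * r**2)


def pick_soft_threshold(
    matrix: pd.DataFrame,
    powers: range | list[int] = range(1, 21),
    r2_target: float = 0.8,
    n_bins: int = 10,
    min_mean_connectivity: float = 2.0,
) -> SoftThresholdReport:
    """Choose the soft-threshold power beta.

    The chosen beta is the smallest candidate whose scale-free fit index
    reaches ``r2_target``; if none does, the argmax of the index. Powers
    that drive the mean connectivity below ``min_mean_connectivity`` are
    excluded from selection (a nearly-empty network fits a power law
    trivially and clusters poorly); if every power falls below the floor
    the constraint is dropped.
    """
    if matrix.shape[0] < 3 or matrix.shape[1] < 4:
        raise ValueError("need at least 3 genes and 4 samples")
    abscor = _abs_correlation(matrix)
    rows = []
    for beta in powers:
        a = abscor**beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=0)
        rows.append((int(beta), _scale_free_r2(k, n_bins), float(k.mean())))
    table = pd.DataFrame(rows, columns=["power", "r2_signed", "mean_connectivity"])
    eligible = table[table["mean_connectivity"] >= min_mean_connectivity]
    if eligible.empty:
        eligible = table
    reaching = eligible[eligible["r2_signed"] >= r2_target]
    if len(reaching):
        chosen = int(reaching["power"].iloc[0])
    else:
        chosen = int(eligible.loc[eligible["r2_signed"].idxmax(), "power"])
    return SoftThresholdReport(table=table, chosen=chosen, r2_target=r2_target)


def adjacency(matrix: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned adjacency |Pearson cor|^beta (diagonal stored as 1)."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    a = _abs_correlation(matrix) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=matrix.index, columns=matrix.index)


def tom_similarity(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap similarity of an adjacency in [0, 1].

    The diagonal of ``adj`` is ignored (connectivity excludes self);
    isolated gene pairs with a zero denominator get TOM 0; the diagonal of
    the result is 1.
    """
    is_frame = isinstance(adj, pd.DataFrame)
    a = adj.to_numpy(dtype=float).copy() if is_frame else np.array(adj, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1.0 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    shared = a @ a  # (i,j): sum_u a_iu a_uj, diagonal of a is zero
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(denom > 0, numer / denom, 0.0)
    tom = np.clip(tom, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    if is_frame:
        return pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return tom


def module_eigengene(matrix: pd.DataFrame, member_genes: list[str]) -> pd.Series:
    """First principal component of the gene-standardized module submatrix,
    scaled to unit variance and oriented so the average correlation with
    member genes is non-negative."""
    if len(member_genes) < 2:
        raise ValueError("need at least 2 member genes")
    x = matrix.loc[list(member_genes)].to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all member genes are constant")
    x = x[keep]
    z = (x - x.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    e_sd = e.std(ddof=1)
    if e_sd == 0:
        raise ValueError("degenerate eigengene")
    e = e / e_sd
    mean_cor = np.mean([np.corrcoef(e, row)[0, 1] for row in z])
    if mean_cor < 0:
        e = -e
    return pd.Series(e, index=matrix.columns)


def _relabel_by_size(assignments: dict[str, int]) -> pd.Series:
    series = pd.Series(assignments)
    sizes = series[series >= 0].value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    rename = {
        m: (COLOR_SEQUENCE[i] if i < len(COLOR_SEQUENCE) else f"module{i + 1}")
        for i, m in enumerate(order)
    }
    return series.map(lambda m: GREY if m < 0 else rename[m])


def detect_modules(
    tom: pd.DataFrame,
    matrix: pd.DataFrame,
    min_size: int = 30,
    cut_height: float = 0.99,
    merge_diss: float = 0.25,
) -> ModuleSet:
    """Average-linkage hierarchical module detection on 1 - TOM.

    A static cut at ``cut_height`` defines initial clusters; clusters
    below ``min_size`` go to grey; module pairs whose eigengene
    dissimilarity (1 - cor) falls below ``merge_diss`` are merged
    iteratively; final labels follow the color sequence by decreasing
    size.
    """
    genes = list(tom.index)
    if len(genes) < min_size:
        logger.warning("fewer genes (%d) than min_size; all grey", len(genes))
        return ModuleSet(
            labels=pd.Series(GREY, index=genes),
            eigengenes=pd.DataFrame(index=matrix.columns),
        )
    diss = 1.0 - tom.to_numpy(dtype=float)
    diss = (diss + diss.T) / 2.0
    np.fill_diagonal(diss, 0.0)
    link = hierarchy.linkage(squareform(diss, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")

    members: dict[int, list[str]] = {}
    for g, c in zip(genes, raw):
        members.setdefault(int(c), []).append(g)
    modules = {c: gl for c, gl in members.items() if len(gl) >= min_size}
    if not modules:
        logger.warning("no cluster reached min_size=%d; all grey", min_size)
        return ModuleSet(
            labels=pd.Series(GREY, index=genes),
            eigengenes=pd.DataFrame(index=matrix.columns),
        )

    # iterative eigengene merging
    module_lists = {i: sorted(gl) for i, (c, gl) in enumerate(sorted(modules.items()))}
    while len(module_lists) > 1:
        keys = sorted(module_lists)
        me = {k: module_eigengene(matrix, module_lists[k]) for k in keys}
        best: tuple[float, int, int] | None = None
        for i, ki in enumerate(keys):
            for kj in keys[i + 1 :]:
                d = 1.0 - float(np.corrcoef(me[ki], me[kj])[0, 1])
                if best is None or d < best[0]:
                    best = (d, ki, kj)
        assert best is not None
        if best[0] >= merge_diss:
            break
        _, ki, kj = best
        module_lists[ki] = sorted(set(module_lists[ki]) | set(module_lists[kj]))
        del module_lists[kj]

    assignments = {g: -1 for g in genes}
    for k, gl in module_lists.items():
        for g in gl:
            assignments[g] = k
    labels = _relabel_by_size(assignments).reindex(genes)

    eigengenes = {}
    for lab in sorted(set(labels) - {GREY}):
        eigengenes[lab] = module_eigengene(matrix, sorted(labels.index[labels == lab]))
    eg = pd.DataFrame(eigengenes, index=matrix.columns)
    # column order: by decreasing size then name
    sizes = labels.value_counts()
    eg = eg[sorted(eg.columns, key=lambda c: (-sizes[c], c))]
    return ModuleSet(labels=labels, eigengenes=eg)


def module_trait_correlation(
    eigengene: pd.Series, trait: pd.Series | np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of a module eigengene with a 0/1 trait; p from
    the two-sided t test with n - 2 df."""
    t = np.asarray(trait, dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("trait must have both classes present")
    e = np.asarray(eigengene, dtype=float)
    if np.std(e) == 0:
        raise ValueError("constant eigengene")
    r, p = stats.pearsonr(e, t)
    return float(r), float(p)


def attach_trait_correlations(
    modules: ModuleSet,
    traits: pd.DataFrame,
    alpha: float = 0.05,
) -> ModuleSet:
    """Fill ``trait_stats`` for every (module, trait-column) pair; traits
    are 0/1 indicator columns aligned to the eigengene samples."""
    rows = []
    for lab in modules.eigengenes.columns:
        for trait_name in traits.columns:
            r, p = module_trait_correlation(
                modules.eigengenes[lab], traits[trait_name]
            )
            rows.append((lab, trait_name, r, p, p < alpha))
    modules.trait_stats = pd.DataFrame(
        rows, columns=["module", "trait", "r", "p", "significant"]
    )
    return modules


def export_module_network(
    tom: pd.DataFrame, modules: ModuleSet, weight_threshold: float = 0.0
) -> ModuleEdgeList:
    """Intramodular edges with TOM weight strictly above the threshold,
    plus per-gene degree on the thresholded network."""
    if not 0.0 <= weight_threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    edge_rows, degree_rows = [], []
    for lab in modules.eigengenes.columns:
        genes = modules.module_genes(lab)
        degree = {g: 0 for g in genes}
        sub = tom.loc[genes, genes].to_numpy()
        for i, gi in enumerate(genes):
            for j in range(i + 1, len(genes)):
                w = float(sub[i, j])
                if w > weight_threshold:
                    gj = genes[j]
                    edge_rows.append((lab, gi, gj, w))
                    degree[gi] += 1
                    degree[gj] += 1
        for g in genes:
            degree_rows.append((lab, g, degree[g]))
    return ModuleEdgeList(
        edges=pd.DataFrame(edge_rows, columns=["module", "gene_a", "gene_b", "weight"]),
        degrees=pd.DataFrame(degree_rows, columns=["module", "gene", "degree"]),
        weight_threshold=weight_threshold,
    )
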