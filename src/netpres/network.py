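"""Weighted coexpression network construction and module detection.

Pipeline within the reference species: robust correlation (biweight
midcorrelation) -> soft-threshold power selection against scale-free
topology -> adjacency -> topological overlap -> average-linkage clustering
-> dynamic hybrid tree cut -> eigengene-based module merging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from netpres.treecut import cut_tree_hybrid
from netpres.types import ExpressionMatrix, ModuleAssignment, ModuleSummary


@dataclass
class CorrelationMatrix:
    values: pd.DataFrame  # genes x genes, symmetric, unit diagonal
    method: str = "bicor"

    @property
    def genes(self) -> pd.Index:
        return self.values.index


@dataclass
class AdjacencyMatrix:
    values: pd.DataFrame
    power: float

    @property
    def genes(self) -> pd.Index:
        return self.values.index


@dataclass
class TOMatrix:
    values: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def dissimilarity(self) -> pd.DataFrame:
        return 1.0 - self.values


def bicor_transform(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise biweight transform used by the midcorrelation.

    For each row: u = (x - median) / (9 * MAD), w = (1 - u^2)^2 on |u| < 1,
    xt = (x - median) * w. Rows with MAD 0 fall back to mean-centering
    (Pearson); fully constant rows come back as all-zero with a flag.

    Returns (transformed rows, fallback mask). The transform is per-row, so
    any correlation between rows is the normalized dot product of the
    transformed vectors — this is what makes large bicor matrices cheap.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x, axis=1, keepdims=True)
    dev = x - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    fallback = (mad[:, 0] == 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        u = dev / (9.0 * mad)
    # fallback rows are overwritten below; keep their weights finite meanwhile
    u = np.nan_to_num(u, nan=1.0, posinf=1.0, neginf=-1.0)
    w = np.square(1.0 - np.square(u)) * (np.abs(u) < 1)
    xt = dev * w

    if fallback.any():
        # MAD 0: Pearson-style centering; constant rows end up all zero.
        c = x[fallback] - x[fallback].mean(axis=1, keepdims=True)
        xt[fallback] = c
    return xt, fallback


def _normalize_rows(xt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.sqrt(np.sum(np.square(xt), axis=1))
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    return xt / safe[:, None], zero


def bicor_vectors(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two 1-D vectors."""
    xt, _ = bicor_transform(np.vstack([x, y]))
    n, zero = _normalize_rows(xt)
    if zero.any():
        return 0.0
    return float(np.clip(n[0] @ n[1], -1.0, 1.0))


def correlation_core(x: np.ndarray, method: str = "bicor") -> np.ndarray:
    """Gene x gene correlation matrix (rows of ``x`` are genes)."""
    if method == "bicor":
        xt, fallback = bicor_transform(x)
        if fallback.any():
            warnings.warn(
                f"{int(fallback.sum())} gene(s) with zero MAD; Pearson fallback used"
            )
    elif method == "pearson":
        xt = x - x.mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown correlation method: {method}")
    n, zero = _normalize_rows(xt)
    c = n @ n.T
    np.clip(c, -1.0, 1.0, out=c)
    np.fill_diagonal(c, 1.0)
    if zero.any():
        # constant even after fallback: correlation undefined, set to 0
        c[zero, :] = 0.0
        c[:, zero] = 0.0
        c[np.ix_(zero, zero)] = 0.0
        np.fill_diagonal(c, 1.0)
    return c


def cross_correlation(x: np.ndarray, y: np.ndarray, method: str = "bicor") -> np.ndarray:
    """Correlation between rows of ``x`` and rows of ``y`` (shared columns)."""
    if method == "bicor":
        xt, _ = bicor_transform(x)
        yt, _ = bicor_transform(y)
    elif method == "pearson":
        xt = x - x.mean(axis=1, keepdims=True)
        yt = y - y.mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown correlation method: {method}")
    nx, zx = _normalize_rows(xt)
    ny, zy = _normalize_rows(yt)
    c = nx @ ny.T
    np.clip(c, -1.0, 1.0, out=c)
    c[zx, :] = 0.0
    c[:, zy] = 0.0
    return c


def bicor_matrix(em: ExpressionMatrix, method: str = "bicor") -> CorrelationMatrix:
    """All-pairs correlation of genes across samples."""
    if em.n_samples < 4:
        raise ValueError("need at least 4 samples for a correlation network")
    c = correlation_core(em.values.values, method=method)
    return CorrelationMatrix(
        pd.DataFrame(c, index=em.genes, columns=em.genes), method=method
    )


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit: signed R^2 of log10(freq) ~ log10(k).

    Degrees are binned into ``n_bins`` equal-occupancy bins; the fit index is
    R^2 multiplied by the sign of minus the slope, so topologies where
    frequency decays with connectivity score positively.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size == 0:
        raise ValueError("all connectivities are zero")
    order = np.argsort(k)
    bins = np.array_split(order, n_bins)
    mean_k, freq = [], []
    for b in bins:
        if len(b) == 0:
            continue
        mean_k.append(k[b].mean())
        freq.append(len(b) / k.size)
    mean_k = np.asarray(mean_k)
    freq = np.asarray(freq)
    # equal-occupancy bins can duplicate k values; merge degenerate bins
    ok = mean_k > 0
    lx, ly = np.log10(mean_k[ok]), np.log10(freq[ok])
    if len(lx) < 3 or np.allclose(lx, lx[0]):
        return 0.0, 0.0
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = np.sum((ly - pred) ** 2)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(r2 * np.sign(-slope)), float(slope)


def soft_threshold_table(
    cm: CorrelationMatrix, powers: list[float] | None = None
) -> pd.DataFrame:
    """Diagnostics (fit index, slope, mean/median/max connectivity) per power."""
    if powers is None:
        powers = list(range(1, 13))
    a = np.abs(cm.values.values)
    rows = []
    for beta in powers:
        adj = a**beta
        k = adj.sum(axis=1) - 1.0  # exclude self
        fit, slope = scale_free_fit(k)
        rows.append(
            {
                "power": beta,
                "fit": fit,
                "slope": slope,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    return pd.DataFrame(rows)


def pick_soft_threshold(
    cm: CorrelationMatrix,
    powers: list[float] | None = None,
    r2_target: float = 0.8,
) -> tuple[float, pd.DataFrame]:
    """Smallest power whose scale-free fit reaches ``r2_target``, else argmax fit."""
    if powers is not None and sorted(powers) != list(powers):
        raise ValueError("powers must be sorted ascending")
    table = soft_threshold_table(cm, powers)
    above = table[table["fit"] >= r2_target]
    if len(above):
        beta = float(above.iloc[0]["power"])
    else:
        beta = float(table.loc[table["fit"].idxmax(), "power"])
    return beta, table


def adjacency(cm: CorrelationMatrix, power: float = 5.0) -> AdjacencyMatrix:
    """Unsigned adjacency a_ij = |cor_ij|^power, unit diagonal."""
    a = np.abs(cm.values.values) ** power
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(
        pd.DataFrame(a, index=cm.genes, columns=cm.genes), power=power
    )


def tom_similarity(am: AdjacencyMatrix) -> TOMatrix:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    l_ij excludes i and j from the shared-neighbour sum and k_i excludes the
    diagonal; the diagonal of the result is 1.
    """
    a = np.asarray(am.values.values, dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)  # work with the off-diagonal part
    k = a.sum(axis=1)
    shared = a @ a  # sum over all u of a_iu a_uj; u = i,j contribute 0 off-diagonal
    num = shared + a
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    np.clip(tom, 0.0, 1.0, out=tom)
    return TOMatrix(pd.DataFrame(tom, index=am.genes, columns=am.genes))


def cut_modules(
    dissimilarity: pd.DataFrame,
    min_module_size: int = 50,
    deep_split: int = 3,
    cut_height: float | None = None,
    pam_stage: bool = False,
) -> ModuleAssignment:
    """Average-linkage clustering + dynamic hybrid tree cut on a distance matrix.

    Clusters smaller than ``min_module_size`` are left unassigned (label 0);
    labels are renumbered by decreasing size. ``pam_stage`` optionally
    re-assigns leftover genes to the cluster with the highest mean similarity,
    off by default.
    """
    genes = dissimilarity.index
    n = len(genes)
    if n < min_module_size:
        warnings.warn("fewer genes than min_module_size: everything unassigned")
        return ModuleAssignment(pd.Series(0, index=genes, dtype=int))
    d = np.asarray(dissimilarity.values, dtype=float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    link = average(squareform(d, checks=False))
    labels = cut_tree_hybrid(
        link,
        min_cluster_size=min_module_size,
        deep_split=deep_split,
        cut_height=cut_height,
    )
    if pam_stage:
        labels = _pam_assign(labels, d)
    ma = ModuleAssignment(pd.Series(labels, index=genes, dtype=int))
    return ma.relabeled_by_size()


def _pam_assign(labels: np.ndarray, dissim: np.ndarray) -> np.ndarray:
    """Assign each leftover gene to the cluster with smallest mean distance."""
    labels = labels.copy()
    mods = sorted(set(labels) - {0})
    if not mods:
        return labels
    unassigned = np.where(labels == 0)[0]
    for g in unassigned:
        means = [dissim[g, labels == m].mean() for m in mods]
        labels[g] = mods[int(np.argmin(means))]
    return labels


def merge_similar_modules(
    ms: ModuleSummary,
    ma: ModuleAssignment,
    cut_height: float = 0.15,
) -> ModuleAssignment:
    """Merge modules whose eigengenes cluster below ``cut_height`` on 1 - cor."""
    mods = list(ms.eigengenes.columns)
    if cut_height <= 0 or len(mods) < 2:
        return ma
    me = ms.eigengenes.values  # samples x modules, unit-norm columns
    c = np.corrcoef(me.T)
    d = np.clip(1.0 - c, 0.0, None)
    np.fill_diagonal(d, 0.0)
    link = average(squareform((d + d.T) / 2.0, checks=False))
    groups = fcluster(link, t=cut_height, criterion="distance")
    mapping = {0: 0}
    for mod, grp in zip(mods, groups):
        mapping[int(mod)] = int(grp)
    merged = ModuleAssignment(ma.labels.map(mapping).astype(int))
    return merged.relabeled_by_size()
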