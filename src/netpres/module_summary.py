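"""Module eigengenes, variance explained, and kME (module membership)."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from netpres.network import cross_correlation
from netpres.types import ExpressionMatrix, ModuleAssignment, ModuleSummary


def _standardize(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} constant gene(s) dropped from module")
    x = (x[keep] - mean[keep]) / sd[keep]
    return x


def eigengene(em: ExpressionMatrix, genes) -> tuple[np.ndarray, float]:
    """First principal component of a module's standardized expression.

    Returns the unit-norm sample-space score vector and the fraction of
    variance it explains. The sign is fixed so the eigengene correlates
    positively with the mean standardized expression of the module.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("module needs at least 2 genes")
    if em.n_samples < 3:
        raise ValueError("need at least 3 samples")
    x = _standardize(em.values.loc[genes].values)
    if x.shape[0] < 2:
        raise ValueError("module collapsed to <2 non-constant genes")
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    me = vt[0]
    total = float(np.sum(s**2))
    var_explained = float(s[0] ** 2 / total) if total > 0 else 0.0
    if np.corrcoef(me, x.mean(axis=0))[0, 1] < 0:
        me = -me
    return me, var_explained


def module_eigengenes(
    em: ExpressionMatrix, ma: ModuleAssignment
) -> tuple[pd.DataFrame, pd.Series]:
    """Eigengene matrix (samples x modules) and variance-explained per module."""
    mes, ves = {}, {}
    for mod in ma.module_ids:
        members = [g for g in ma.members(mod) if g in em.genes]
        if len(members) < 2:
            raise ValueError(f"module {mod} has <2 genes present in the data")
        me, ve = eigengene(em, members)
        mes[mod] = me
        ves[mod] = ve
    eig = pd.DataFrame(mes, index=em.samples)
    return eig, pd.Series(ves, name="variance_explained")


def kme(
    em: ExpressionMatrix, eigengenes: pd.DataFrame, method: str = "bicor"
) -> pd.DataFrame:
    """Gene x module matrix of correlations between genes and eigengenes.

    Uses the same correlation estimator as the network stage by default so
    kME is comparable to the network's edge weights. Constant genes get 0.
    """
    x = em.values.values
    y = eigengenes.values.T  # modules x samples
    c = cross_correlation(x, y, method=method)
    return pd.DataFrame(c, index=em.genes, columns=eigengenes.columns)


def summarize_modules(
    em: ExpressionMatrix,
    ma: ModuleAssignment,
    method: str = "bicor",
) -> ModuleSummary:
    """ModuleSummary = eigengenes + variance explained + full kME matrix."""
    eig, ve = module_eigengenes(em, ma)
    k = kme(em, eig, method=method)
    return ModuleSummary(
        eigengenes=eig, variance_explained=ve, kme=k, species=em.species
    )


def summary_table(ms: ModuleSummary, ma: ModuleAssignment) -> pd.DataFrame:
    """Per-module report: size and variance-explained fraction."""
    sizes = ma.sizes()
    rows = []
    for mod in ms.eigengenes.columns:
        rows.append(
            {
                "module": int(mod),
                "size": int(sizes.get(mod, 0)),
                "variance_explained": float(ms.variance_explained[mod]),
            }
        )
    return pd.DataFrame(rows).sort_values("module").reset_index(drop=True)
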