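"""Cross-species module preservation.

The primary statistic is the fraction of module genes whose kME (correlation
with the module eigengene) has the same sign in both species, with a
permutation null: gene labels are jointly permuted over the harmonized
universe, modules of the original sizes are re-drawn, and the p-value is the
proportion of permutations in which a random module beats the observed
consistency fraction (strict >). Composite density/connectivity Z statistics
are provided as a secondary summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from netpres.module_summary import summarize_modules
from netpres.network import bicor_transform, _normalize_rows
from netpres.types import ExpressionMatrix, ModuleAssignment, ModuleSummary


@dataclass
class PreservationResult:
    table: pd.DataFrame  # module, n_genes, n_consistent, fraction, p, p_lt_min
    n_permutations: int


def align_test_to_ref(test_em: ExpressionMatrix, pairs: pd.DataFrame) -> ExpressionMatrix:
    """Re-index a harmonized test-species matrix onto reference gene IDs."""
    mapping = dict(zip(pairs["test_gene"], pairs["ref_gene"]))
    values = test_em.values.rename(index=mapping)
    return ExpressionMatrix(values, species=test_em.species)


def project_assignment(
    test_em: ExpressionMatrix,
    ref_assignment: ModuleAssignment,
    method: str = "bicor",
) -> ModuleSummary:
    """Eigengenes + kME in the test species using the reference memberships.

    ``test_em`` must share the reference gene universe (see
    :func:`align_test_to_ref`).
    """
    common = ref_assignment.genes.intersection(test_em.genes)
    if len(common) == 0:
        raise ValueError("no shared genes between assignment and test data")
    em = test_em.subset_genes(common)
    ma = ModuleAssignment(ref_assignment.labels.loc[common])
    for mod in ma.module_ids:
        if len(ma.members(mod)) < 2:
            raise ValueError(f"module {mod} has <2 genes in the test data")
    return summarize_modules(em, ma, method=method)


def consistency_fraction(
    kme_ref: pd.Series, kme_test: pd.Series, genes
) -> tuple[int, float]:
    """Genes with concordant, nonzero kME sign in both species.

    Exact zeros count as inconsistent (measure-zero on real data).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    r = np.sign(kme_ref.loc[genes].values)
    t = np.sign(kme_test.loc[genes].values)
    consistent = (r == t) & (r != 0) & (t != 0)
    n = int(consistent.sum())
    return n, n / len(genes)


def concordance_indicator(kme_ref: pd.Series, kme_test: pd.Series) -> pd.Series:
    """Per-gene sign-concordance indicator over the full universe."""
    r = np.sign(kme_ref.values)
    t = np.sign(kme_test.loc[kme_ref.index].values)
    ind = (r == t) & (r != 0) & (t != 0)
    return pd.Series(ind, index=kme_ref.index, name="concordant")


def permutation_pvalue(
    kme_sign_ref: pd.Series,
    kme_sign_test: pd.Series,
    assignment: ModuleAssignment,
    n_perm: int = 10000,
    seed: int | None = None,
    smoothed: bool = False,
) -> PreservationResult:
    """Permutation p-value for the consistency fraction of every module.

    One joint permutation per iteration re-partitions the universe into
    modules of the original sizes, so the across-module correlation of the
    null is preserved. ``smoothed`` switches to the add-one estimator
    (1 + b) / (1 + N); off by default (strict proportion, with a
    ``p_lt_min`` flag when no permutation beats the observed value).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value")
    rng = np.random.default_rng(seed)
    ind = concordance_indicator(kme_sign_ref, kme_sign_test).values.astype(np.int64)
    n_universe = ind.size

    modules = assignment.module_ids
    sizes = [len(assignment.members(m)) for m in modules]
    observed = []
    for m in modules:
        genes = [g for g in assignment.members(m)]
        n_c, frac = consistency_fraction(kme_sign_ref, kme_sign_test, genes)
        observed.append((n_c, frac))

    offsets = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
    exceed = np.zeros(len(modules), dtype=np.int64)
    obs_frac = np.array([f for _, f in observed])
    sizes_arr = np.asarray(sizes, dtype=float)
    for _ in range(n_perm):
        perm = rng.permutation(ind)
        cs = np.concatenate([[0], np.cumsum(perm)])
        counts = cs[offsets[1:]] - cs[offsets[:-1]]
        exceed += (counts / sizes_arr) > obs_frac

    if smoothed:
        p = (1.0 + exceed) / (1.0 + n_perm)
        p_lt_min = np.zeros(len(modules), dtype=bool)
    else:
        p = exceed / n_perm
        p_lt_min = exceed == 0

    table = pd.DataFrame(
        {
            "module": modules,
            "n_genes": sizes,
            "n_consistent": [c for c, _ in observed],
            "fraction": obs_frac,
            "p": p,
            "p_lt_min": p_lt_min,
        }
    )
    # guard against modules not covering the universe (offsets assume a
    # permutation partition over all genes; leftover genes are simply unused)
    if offsets[-1] > n_universe:
        raise ValueError("module sizes exceed the gene universe")
    return PreservationResult(table=table, n_permutations=n_perm)


def gene_level_kme(
    ref_summary: ModuleSummary,
    test_summary: ModuleSummary,
    assignment: ModuleAssignment,
) -> tuple[pd.Series, pd.Series]:
    """Collapse the gene x module kME matrices to one value per gene.

    Assigned genes take their own module's column; unassigned genes take the
    column where their reference |kME| is largest, so every gene in the
    universe carries a well-defined sign-concordance indicator for the
    permutation null.
    """
    common = ref_summary.kme.index.intersection(test_summary.kme.index)
    kr_mat = ref_summary.kme.loc[common]
    kt_mat = test_summary.kme.loc[common, kr_mat.columns]
    labels = assignment.labels.loc[common]

    col_pos = {m: i for i, m in enumerate(kr_mat.columns)}
    best = np.abs(kr_mat.values).argmax(axis=1)
    pos = np.array(
        [col_pos.get(lab, best[i]) for i, lab in enumerate(labels.values)]
    )
    rows = np.arange(len(common))
    kr = pd.Series(kr_mat.values[rows, pos], index=common)
    kt = pd.Series(kt_mat.values[rows, pos], index=common)
    return kr, kt


def preservation_report(
    ref_summary: ModuleSummary,
    test_summary: ModuleSummary,
    assignment: ModuleAssignment,
    n_perm: int = 10000,
    seed: int | None = None,
    p_cut: float = 1e-4,
) -> PreservationResult:
    """Full preservation table: one joint permutation null for all modules."""
    kr, kt = gene_level_kme(ref_summary, test_summary, assignment)
    sub = ModuleAssignment(assignment.labels.loc[kr.index])
    res = permutation_pvalue(kr, kt, sub, n_perm=n_perm, seed=seed)
    table = res.table
    table["preserved"] = (table["p"] < p_cut) | (
        table["p_lt_min"] & (1.0 / n_perm <= p_cut)
    )
    return PreservationResult(table=table, n_permutations=n_perm)


def _module_stats(
    members: np.ndarray,
    ref_norm: np.ndarray,
    test_norm: np.ndarray,
    ref_std: np.ndarray,
    test_std: np.ndarray,
    power: float,
) -> np.ndarray:
    """(meanCor, meanAdj, cor_kME, cor_cor) for one member set."""
    cr = ref_norm[members] @ ref_norm[members].T
    ct = test_norm[members] @ test_norm[members].T
    iu = np.triu_indices(len(members), k=1)
    mean_cor = float(np.abs(ct[iu]).mean())
    mean_adj = float((np.abs(ct[iu]) ** power).mean())
    cor_cor = _pearson(cr[iu], ct[iu])
    kr = _kme_of(ref_std[members])
    kt = _kme_of(test_std[members])
    cor_kme = _pearson(kr, kt)
    return np.array([mean_cor, mean_adj, cor_kme, cor_cor])


def _kme_of(x_std: np.ndarray) -> np.ndarray:
    """Pearson kME of member genes with their own first principal component."""
    _, s, vt = np.linalg.svd(x_std, full_matrices=False)
    me = vt[0]
    if np.corrcoef(me, x_std.mean(axis=0))[0, 1] < 0:
        me = -me
    me_c = me - me.mean()
    me_c /= np.linalg.norm(me_c)
    xc = x_std - x_std.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    norms[norms == 0] = 1.0
    return (xc @ me_c) / norms


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def composite_preservation(
    ref_em: ExpressionMatrix,
    test_em: ExpressionMatrix,
    assignment: ModuleAssignment,
    power: float = 5.0,
    n_perm: int = 200,
    seed: int | None = None,
    method: str = "bicor",
) -> pd.DataFrame:
    """Density/connectivity composite Z statistics and median ranks.

    Test-species statistics per module: mean intramodule |cor|, mean
    intramodule adjacency at ``power``, correlation of ref vs test kME over
    members, and correlation of the vectorized intramodule correlation
    matrices. Each is standardized against random same-size modules to a Z
    score; z_summary averages the density and connectivity families.
    """
    rng = np.random.default_rng(seed)
    common = assignment.genes.intersection(ref_em.genes).intersection(test_em.genes)
    ref = ref_em.subset_genes(common)
    test = test_em.subset_genes(common)
    labels = assignment.labels.loc[common]

    if method == "bicor":
        rt, _ = bicor_transform(ref.values.values)
        tt, _ = bicor_transform(test.values.values)
    else:
        rt = ref.values.values - ref.values.values.mean(axis=1, keepdims=True)
        tt = test.values.values - test.values.values.mean(axis=1, keepdims=True)
    ref_norm, _ = _normalize_rows(rt)
    test_norm, _ = _normalize_rows(tt)

    def _std(x: np.ndarray) -> np.ndarray:
        m = x.mean(axis=1, keepdims=True)
        s = x.std(axis=1, keepdims=True)
        s[s == 0] = 1.0
        return (x - m) / s

    ref_std = _std(ref.values.values)
    test_std = _std(test.values.values)

    modules = sorted(set(labels.values) - {0})
    n = len(common)
    observed = {}
    for m in modules:
        members = np.where(labels.values == m)[0]
        observed[m] = _module_stats(members, ref_norm, test_norm, ref_std, test_std, power)

    perm_stats = {m: np.empty((n_perm, 4)) for m in modules}
    sizes = {m: int((labels.values == m).sum()) for m in modules}
    for it in range(n_perm):
        perm = rng.permutation(n)
        offset = 0
        for m in modules:
            members = perm[offset : offset + sizes[m]]
            offset += sizes[m]
            perm_stats[m][it] = _module_stats(
                members, ref_norm, test_norm, ref_std, test_std, power
            )

    rows = []
    for m in modules:
        mu = perm_stats[m].mean(axis=0)
        sd = perm_stats[m].std(axis=0, ddof=1)
        flagged = bool((sd == 0).any())
        sd = np.where(sd == 0, np.nan, sd)
        z = (observed[m] - mu) / sd
        z_density = np.nanmean(z[:2])
        z_connectivity = np.nanmean(z[2:])
        rows.append(
            {
                "module": m,
                "size": sizes[m],
                "z_mean_cor": z[0],
                "z_mean_adj": z[1],
                "z_cor_kme": z[2],
                "z_cor_cor": z[3],
                "z_density": z_density,
                "z_connectivity": z_connectivity,
                "z_summary": (z_density + z_connectivity) / 2.0,
                "sd_zero_flag": flagged,
            }
        )
    out = pd.DataFrame(rows)

    # median rank over the four statistics (1 = best, i.e. largest observed)
    obs_mat = np.vstack([observed[m] for m in modules])
    ranks = np.empty_like(obs_mat)
    for j in range(4):
        order = (-obs_mat[:, j]).argsort()
        ranks[order, j] = np.arange(1, len(modules) + 1)
    out["median_rank"] = np.median(ranks, axis=1)
    return out
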