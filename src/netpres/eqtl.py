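"""Dosage-based eQTL scanning: QC, OLS with covariates, cis/trans, enrichment.

The association model is ordinary least squares of expression on allele
dosage plus covariates plus an intercept; the reported beta/SE/p are for the
dosage coefficient (two-sided t-test). The scan is vectorized by
residualizing both sides on the covariates (Frisch-Waugh), which gives the
exact OLS coefficient and the correct residual degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from netpres.types import DosageMatrix, ExpressionMatrix, GenePosition, SnpInfo

GENOMEWIDE_P = 5e-8
CIS_WINDOW = 1_000_000


@dataclass
class QcReport:
    kept: DosageMatrix
    fails: pd.DataFrame  # snp, reason


def hwe_chisq(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """1-df goodness-of-fit test of Hardy-Weinberg equilibrium."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotype counts")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    ok = expected > 0
    stat = float(np.sum((observed[ok] - expected[ok]) ** 2 / expected[ok]))
    return stat, float(stats.chi2.sf(stat, df=1))


def snp_qc(
    dm: DosageMatrix,
    genotype_counts: pd.DataFrame | None = None,
    maf_min: float = 0.01,
    call_min: float = 0.99,
    hwe_p_min: float = 1e-5,
    r2_min: float = 0.3,
) -> QcReport:
    """Remove SNPs failing MAF / call-rate / HWE / imputation-quality rules.

    HWE is tested only when hard genotype counts (columns n_aa, n_ab, n_bb,
    indexed by SNP) are supplied. Call rate is the fraction of non-missing
    dosages.
    """
    fails = []
    keep = []
    call_rate = 1.0 - dm.values.isna().mean(axis=1)
    for snp in dm.snps:
        reasons = []
        if dm.maf[snp] < maf_min:
            reasons.append("maf")
        if call_rate[snp] < call_min:
            reasons.append("call_rate")
        if dm.r2[snp] < r2_min:
            reasons.append("imputation_r2")
        if genotype_counts is not None and snp in genotype_counts.index:
            row = genotype_counts.loc[snp]
            _, p = hwe_chisq(int(row["n_aa"]), int(row["n_ab"]), int(row["n_bb"]))
            if p < hwe_p_min:
                reasons.append("hwe")
        if reasons:
            fails.append({"snp": snp, "reason": ";".join(reasons)})
        else:
            keep.append(snp)
    if not keep:
        warnings.warn("all SNPs removed by QC")
    kept = DosageMatrix(
        dm.values.loc[keep], maf=dm.maf.loc[keep], r2=dm.r2.loc[keep]
    )
    return QcReport(kept=kept, fails=pd.DataFrame(fails, columns=["snp", "reason"]))


def _residualize(y: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Residuals of the rows of y against an orthonormal column basis q."""
    return y - (y @ q) @ q.T


def _covariate_basis(n: int, covariates: pd.DataFrame | None, samples) -> tuple[np.ndarray, int]:
    if covariates is None:
        c = np.ones((n, 1))
    else:
        cov = covariates.loc[list(samples)].values.astype(float)
        c = np.column_stack([np.ones(n), cov])
    q, r = np.linalg.qr(c)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(abs(r[0, 0]), 1.0)))
    if rank < c.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    return q, c.shape[1]


def fit_eqtl(
    dm: DosageMatrix,
    em: ExpressionMatrix,
    covariates: pd.DataFrame | None = None,
    snp_positions: pd.DataFrame | None = None,
    gene_positions: pd.DataFrame | None = None,
    window: int = CIS_WINDOW,
    min_samples: int = 30,
) -> pd.DataFrame:
    """OLS scan of every SNP against every gene.

    Returns one record per (snp, gene) with beta, se, p, and (when positions
    are provided) a cis/trans class plus a genome-wide significance flag.
    """
    samples = dm.samples.intersection(em.samples)
    if len(samples) < min_samples:
        raise ValueError(f"only {len(samples)} shared samples (< {min_samples})")
    n = len(samples)
    q, n_cov_cols = _covariate_basis(n, covariates, samples)

    expr = _residualize(em.values[samples].values, q)  # genes x n
    dosg = _residualize(dm.values[samples].values, q)  # snps x n
    df_resid = n - 1 - n_cov_cols  # dosage + intercept + covariates

    snp_class = None
    if snp_positions is not None and gene_positions is not None:
        snp_class = _cis_lookup(dm.snps, em.genes, snp_positions, gene_positions, window)

    records = []
    gene_ids = list(em.genes)
    ss_expr = np.sum(expr**2, axis=1)
    for i, snp in enumerate(dm.snps):
        d = dosg[i]
        ss_d = float(d @ d)
        if ss_d <= 1e-12:
            warnings.warn(f"{snp}: zero dosage variance after residualization; skipped")
            continue
        beta = (expr @ d) / ss_d
        rss = ss_expr - beta**2 * ss_d
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / df_resid / ss_d)
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        pval = 2.0 * stats.t.sf(np.abs(tval), df=df_resid)
        pval = np.clip(pval, np.finfo(float).tiny, 1.0)
        for j, gene in enumerate(gene_ids):
            cls = snp_class[(snp, gene)] if snp_class is not None else "unclassified"
            records.append(
                {
                    "snp": snp,
                    "gene": gene,
                    "beta": float(beta[j]),
                    "se": float(se[j]),
                    "p": float(pval[j]),
                    "class": cls,
                    "genomewide": bool(pval[j] < GENOMEWIDE_P),
                }
            )
    return pd.DataFrame(records)


def classify_cis_trans(
    snp: SnpInfo, gene: GenePosition, window: int = CIS_WINDOW
) -> str:
    """cis iff same chromosome and within ``window`` bp of the probe interval.

    Bounds are inclusive: a SNP exactly ``window`` bp from either probe edge
    is cis. Missing coordinates yield "unclassified".
    """
    if snp.chrom is None or gene.chrom is None or snp.pos is None:
        return "unclassified"
    if str(snp.chrom) != str(gene.chrom):
        return "trans"
    if gene.start - window <= snp.pos <= gene.end + window:
        return "cis"
    return "trans"


def _cis_lookup(snps, genes, snp_positions, gene_positions, window):
    spos = snp_positions.set_index("id")
    gpos = gene_positions.set_index("id")
    out = {}
    for snp in snps:
        if snp not in spos.index:
            for gene in genes:
                out[(snp, gene)] = "unclassified"
            continue
        srow = spos.loc[snp]
        si = SnpInfo(snp, str(srow["chrom"]), int(srow["pos"]))
        for gene in genes:
            if gene not in gpos.index:
                out[(snp, gene)] = "unclassified"
                continue
            grow = gpos.loc[gene]
            gp = GenePosition(gene, str(grow["chrom"]), int(grow["start"]), int(grow["end"]))
            out[(snp, gene)] = classify_cis_trans(si, gp, window)
    return out


def conditional_scan(
    dm: DosageMatrix,
    em: ExpressionMatrix,
    covariates: pd.DataFrame | None,
    lead_snp: str,
    conditioning_snp: str,
    **kwargs,
) -> pd.DataFrame:
    """Re-fit the lead SNP with the conditioning SNP's dosage as a covariate."""
    for snp in (lead_snp, conditioning_snp):
        if snp not in dm.snps:
            raise ValueError(f"SNP {snp} not in dosage matrix")
    samples = dm.samples.intersection(em.samples)
    lead = dm.values.loc[lead_snp, samples].values.astype(float)
    cond = dm.values.loc[conditioning_snp, samples].values.astype(float)
    r = np.corrcoef(lead, cond)[0, 1]
    if abs(r) > 1 - 1e-10:
        out = pd.DataFrame(
            {
                "snp": [lead_snp],
                "gene": [None],
                "beta": [np.nan],
                "se": [np.inf],
                "p": [np.nan],
                "class": ["unclassified"],
                "genomewide": [False],
            }
        )
        out["collinear_flag"] = True
        warnings.warn("lead and conditioning dosages are collinear (r^2 = 1)")
        return out
    cond_col = pd.DataFrame(
        {"_conditioning_dosage": dm.values.loc[conditioning_snp]}, index=dm.samples
    )
    cov = cond_col if covariates is None else covariates.join(cond_col, how="inner")
    lead_dm = DosageMatrix(
        dm.values.loc[[lead_snp]],
        maf=dm.maf.loc[[lead_snp]],
        r2=dm.r2.loc[[lead_snp]],
    )
    out = fit_eqtl(lead_dm, em, covariates=cov, **kwargs)
    out["collinear_flag"] = False
    return out


def trans_set_enrichment(
    records: pd.DataFrame,
    target_genes: set[str],
    p_cut: float = 0.01,
    method: str = "fisher",
) -> dict:
    """2x2 enrichment of sub-threshold associations in a target gene set.

    ``records`` must carry one row per gene (e.g. one SNP against all genes).
    Returns the table, the per-group proportions, the odds ratio, and a
    two-sided exact p (hypergeometric-sum Fisher test; chi-square by flag).
    """
    if not target_genes:
        raise ValueError("empty target gene set")
    rec = records.drop_duplicates("gene")
    is_target = rec["gene"].isin(target_genes).values
    is_hit = (rec["p"] < p_cut).values
    a = int((is_target & is_hit).sum())  # target, hit
    b = int((is_target & ~is_hit).sum())
    c = int((~is_target & is_hit).sum())
    d = int((~is_target & ~is_hit).sum())
    table = np.array([[a, b], [c, d]])
    if method == "fisher":
        odds, p = stats.fisher_exact(table, alternative="two-sided")
    elif method == "chi2":
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
    else:
        raise ValueError(f"unknown method: {method}")
    return {
        "table": table,
        "n_target": a + b,
        "n_background": c + d,
        "prop_target": a / (a + b) if a + b else np.nan,
        "prop_background": c / (c + d) if c + d else np.nan,
        "odds_ratio": float(odds),
        "p": float(p),
    }
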