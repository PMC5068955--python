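"""Hypergeometric gene-set over-representation with BH FDR."""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def hypergeom_enrichment(
    query: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    ease: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric p for each set, with fold and BH FDR.

    p = P[X >= overlap] with X ~ Hypergeom(N=|universe|, K=|set|, n=|query|);
    fold = observed / expected overlap. ``ease`` subtracts one from the
    overlap before testing (the DAVID-style conservative variant).
    """
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    n_u, n_q = len(universe), len(query)
    rows = []
    for name, genes in gene_sets.items():
        members = set(genes) & universe
        overlap = query & members
        k = len(overlap)
        k_test = max(k - 1, 0) if ease else k
        # sf(k-1) = P[X >= k]
        p = float(stats.hypergeom.sf(k_test - 1, n_u, len(members), n_q))
        expected = len(members) * n_q / n_u
        fold = k / expected if expected > 0 else float("nan")
        rows.append(
            {
                "set": name,
                "set_size": len(members),
                "overlap": k,
                "expected": expected,
                "fold": fold,
                "p": min(p, 1.0),
                "genes": ",".join(sorted(overlap)),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["p"].values, method="fdr_bh")[1]
    else:
        out["fdr"] = []
    return out.sort_values("p").reset_index(drop=True)
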