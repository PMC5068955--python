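"""Probe collapse, ortholog harmonization, and outlier-sample detection."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from netpres.types import ExpressionMatrix, OrthologMap, ProbeMatrix


def collapse_probes(pm: ProbeMatrix) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """One row per gene: keep the probe with maximum across-sample mean.

    Ties are broken by the lexicographically smallest probe ID. Returns the
    gene-level matrix plus a report of every probe with its mean intensity
    and whether it was chosen.
    """
    pm.validate()
    mapped = pm.probe_to_gene.dropna()
    if mapped.empty:
        raise ValueError("no probe has a gene assignment")
    means = pm.values.loc[mapped.index].mean(axis=1)
    report = pd.DataFrame(
        {"probe": mapped.index, "gene": mapped.values, "mean": means.values}
    ).sort_values(["gene", "mean", "probe"], ascending=[True, False, True])
    # stable sort above: first row per gene is the winner (max mean, min ID on ties)
    chosen = report.drop_duplicates("gene", keep="first")
    report["chosen"] = report["probe"].isin(set(chosen["probe"]))

    values = pm.values.loc[chosen["probe"].values]
    values.index = chosen["gene"].values
    em = ExpressionMatrix(values.sort_index(), species=pm.species)
    em.validate()
    return em, report.reset_index(drop=True)


def harmonize_orthologs(
    ref: ExpressionMatrix, test: ExpressionMatrix, om: OrthologMap
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """Restrict both matrices to ortholog pairs present in both, rows aligned.

    Many-to-many pairs are resolved greedily: pairs are ranked by combined
    mean expression and accepted only if neither gene is already used, so the
    surviving map is one-to-one. Returns (ref, test, resolved pair table).
    """
    om.validate()
    pairs = om.pairs[["ref_gene", "test_gene"]].drop_duplicates()
    present = pairs[
        pairs["ref_gene"].isin(ref.genes) & pairs["test_gene"].isin(test.genes)
    ].copy()
    dropped = len(pairs) - len(present)
    if dropped:
        warnings.warn(f"{dropped} ortholog pair(s) dropped: gene missing in a matrix")
    if present.empty:
        raise ValueError("no ortholog pair present in both matrices")

    present["score"] = (
        ref.values.loc[present["ref_gene"]].mean(axis=1).values
        + test.values.loc[present["test_gene"]].mean(axis=1).values
    )
    present = present.sort_values(
        ["score", "ref_gene", "test_gene"], ascending=[False, True, True]
    )
    used_ref: set = set()
    used_test: set = set()
    keep_rows = []
    for row in present.itertuples(index=False):
        if row.ref_gene in used_ref or row.test_gene in used_test:
            continue
        used_ref.add(row.ref_gene)
        used_test.add(row.test_gene)
        keep_rows.append((row.ref_gene, row.test_gene))
    resolved = pd.DataFrame(keep_rows, columns=["ref_gene", "test_gene"])
    resolved = resolved.sort_values("ref_gene").reset_index(drop=True)
    if len(resolved) < len(present):
        warnings.warn(
            f"{len(present) - len(resolved)} many-to-many ortholog pair(s) resolved "
            "by combined mean expression"
        )

    ref_out = ExpressionMatrix(
        ref.values.loc[resolved["ref_gene"].values], species=ref.species
    )
    test_out = ExpressionMatrix(
        test.values.loc[resolved["test_gene"].values], species=test.species
    )
    return ref_out, test_out, resolved


def outlier_report(em: ExpressionMatrix, z_cut: float = 3.0) -> pd.DataFrame:
    """Mean Euclidean distance of each sample to all others, with flags."""
    flagged = detect_outlier_samples(em, z_cut=z_cut)
    d = squareform(pdist(em.values.values.T, metric="euclidean"))
    n = d.shape[0]
    mean_d = d.sum(axis=1) / (n - 1)
    return pd.DataFrame(
        {
            "sample": em.samples,
            "mean_distance": mean_d,
            "flagged": [s in set(flagged) for s in em.samples],
        }
    )


def detect_outlier_samples(em: ExpressionMatrix, z_cut: float = 3.0) -> list[str]:
    """Samples whose mean Euclidean distance to the rest is > mean + z_cut * SD.

    The rule is applied once more after removing the first round's flags, so
    an extreme outlier cannot mask a second one. Requires >= 10 samples.
    """
    if em.n_samples < 10:
        raise ValueError("need at least 10 samples for outlier detection")
    samples = list(em.samples)
    x = em.values.values.T  # samples x genes
    flagged: list[str] = []
    active = np.arange(len(samples))
    for _ in range(2):  # initial pass + one iteration
        if len(active) < 3:
            break
        d = squareform(pdist(x[active], metric="euclidean"))
        mean_d = d.sum(axis=1) / (len(active) - 1)
        sd = mean_d.std()
        if sd == 0:
            break
        cut = mean_d.mean() + z_cut * sd
        bad = mean_d > cut
        if not bad.any():
            break
        flagged.extend(samples[i] for i in active[bad])
        active = active[~bad]
    return sorted(flagged, key=samples.index)
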