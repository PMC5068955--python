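"""Shared container types passed between pipeline stages.

All matrices are thin wrappers around pandas objects so every stage can be
used interactively; invariants that later stages rely on are checked in
``validate`` methods rather than on every access.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ProbeMatrix:
    """Probe-level intensities plus the probe -> gene assignment.

    ``values`` is probes x samples; ``probe_to_gene`` maps each probe ID to
    at most one gene ID (probes without a gene are dropped at collapse time).
    """

    values: pd.DataFrame
    probe_to_gene: pd.Series
    species: str = ""

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probe IDs")
        unknown = self.probe_to_gene.index.difference(self.values.index)
        if len(unknown):
            raise ValueError(f"probe map refers to unknown probes: {list(unknown)[:5]}")

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class ExpressionMatrix:
    """Gene-level expression, genes x samples, with a species tag."""

    values: pd.DataFrame
    species: str = ""

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene IDs")
        if self.values.isna().any().any():
            raise ValueError("missing values in expression matrix")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], species=self.species)

    def drop_samples(self, samples) -> "ExpressionMatrix":
        keep = self.values.columns.difference(pd.Index(samples), sort=False)
        return ExpressionMatrix(self.values[keep], species=self.species)


@dataclass
class OrthologMap:
    """One row per (ref_gene, test_gene) ortholog pair."""

    pairs: pd.DataFrame  # columns: ref_gene, test_gene

    def validate(self) -> None:
        missing = {"ref_gene", "test_gene"} - set(self.pairs.columns)
        if missing:
            raise ValueError(f"ortholog map missing columns: {missing}")


@dataclass
class ModuleAssignment:
    """Gene -> integer module label; 0 is reserved for unassigned genes.

    Labels are ordered by decreasing module size (1 = largest).
    """

    labels: pd.Series  # index: gene IDs, values: non-negative ints

    @property
    def genes(self) -> pd.Index:
        return self.labels.index

    @property
    def module_ids(self) -> list[int]:
        ids = sorted(set(self.labels.values) - {0})
        return ids

    def members(self, module: int) -> pd.Index:
        return self.labels.index[self.labels.values == module]

    def sizes(self) -> pd.Series:
        counts = self.labels[self.labels > 0].value_counts().sort_index()
        counts.name = "size"
        return counts

    @property
    def n_unassigned(self) -> int:
        return int((self.labels == 0).sum())

    def relabeled_by_size(self) -> "ModuleAssignment":
        """Renumber labels so 1 is the largest module (ties broken by old label)."""
        counts = self.labels[self.labels > 0].value_counts()
        order = sorted(counts.index, key=lambda m: (-counts[m], m))
        mapping = {old: new for new, old in enumerate(order, start=1)}
        mapping[0] = 0
        return ModuleAssignment(self.labels.map(mapping))


@dataclass
class ModuleSummary:
    """Per-module eigengene, variance explained, and the gene x module kME matrix."""

    eigengenes: pd.DataFrame  # samples x modules (unit-norm columns)
    variance_explained: pd.Series  # module -> fraction in [0, 1]
    kme: pd.DataFrame  # genes x modules, correlations in [-1, 1]
    species: str = ""

    def validate(self) -> None:
        ve = self.variance_explained
        if ((ve < -1e-12) | (ve > 1 + 1e-12)).any():
            raise ValueError("variance explained outside [0, 1]")


@dataclass
class SnpInfo:
    """1-based inclusive SNP coordinate."""

    id: str
    chrom: str
    pos: int


@dataclass
class GenePosition:
    """1-based inclusive probe/gene interval."""

    id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.id}: start > end")


@dataclass
class DosageMatrix:
    """Imputed allele dosages in [0, 2], SNPs x samples, with per-SNP metadata."""

    values: pd.DataFrame  # snps x samples
    maf: pd.Series = field(default=None)  # type: ignore[assignment]
    r2: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.maf is None:
            freq = self.values.mean(axis=1) / 2.0
            self.maf = np.minimum(freq, 1 - freq)
        if self.r2 is None:
            self.r2 = pd.Series(1.0, index=self.values.index)

    def validate(self) -> None:
        v = self.values.values
        if np.nanmin(v) < -1e-9 or np.nanmax(v) > 2 + 1e-9:
            raise ValueError("dosages outside [0, 2]")

    @property
    def snps(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns
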