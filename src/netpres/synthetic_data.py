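"""Paired two-species synthetic studies with known module and eQTL structure.

Expression follows a latent-factor model: each module m has a latent signal
e_m per sample, and a member gene g with loading lam_g is generated as
lam_g * e_m + sqrt(1 - lam_g^2) * noise. Preserved modules reuse the same
loadings (and signs) in the test species with fresh latent signals;
non-preserved modules degrade to pure noise there. Dosage effects enter
either at the module level (trans: beta * dosage added to e_m) or at the
single-gene level (cis). Probe-level redundancy, outlier samples and
covariates make the preprocessing stages non-trivial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from netpres.types import DosageMatrix, ExpressionMatrix, OrthologMap, ProbeMatrix

_PROBE_OFFSET_SD = 0.5
_PROBE_NOISE_SD = 0.25


@dataclass(frozen=True)
class TransEffect:
    """Module-level dosage effect: beta * dosage added to the latent signal."""

    snp_index: int
    module_index: int  # 1-based module label
    beta: float


@dataclass(frozen=True)
class CisEffect:
    """Single-gene dosage effect: beta * dosage added to one gene."""

    snp_index: int
    gene_index: int  # 0-based gene index
    beta: float


@dataclass
class SimConfig:
    n_genes: int = 2000
    n_samples_ref: int = 300
    n_samples_test: int = 80
    module_sizes: tuple[int, ...] = (150, 120, 100, 80, 70, 60)
    preserved_flags: tuple[bool, ...] = (True, True, True, False, False, False)
    loading_range: tuple[float, float] = (0.3, 0.9)
    noise_sd: float = 1.0
    n_probes_per_gene: tuple[int, int] = (1, 3)
    n_outlier_samples: int = 0
    outlier_offset: float = 8.0  # in units of noise_sd
    n_snps: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    trans_effect: TransEffect | None = None
    cis_effects: tuple[CisEffect, ...] = ()
    n_covariates: int = 2
    covariate_effect_sd: float = 0.05
    sign_flip_fraction: float = 0.0  # partial-preservation knob (test species)
    dosage_blur: bool = False
    seed: int = 0

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum(module_sizes) exceeds n_genes")
        if len(self.preserved_flags) != len(self.module_sizes):
            raise ValueError("preserved_flags must match module_sizes in length")
        lo, hi = self.loading_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("loading_range must lie in (0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if self.trans_effect is not None:
            te = self.trans_effect
            if not (1 <= te.module_index <= len(self.module_sizes)):
                raise ValueError("trans_effect module index out of range")
            if not (0 <= te.snp_index < self.n_snps):
                raise ValueError("trans_effect snp index out of range")
        for ce in self.cis_effects:
            if not (0 <= ce.gene_index < self.n_genes):
                raise ValueError("cis_effect gene index out of range")
            if not (0 <= ce.snp_index < self.n_snps):
                raise ValueError("cis_effect snp index out of range")


@dataclass
class TruthLabels:
    module_labels: pd.Series  # ref gene -> module (0 = background)
    preserved: dict[int, bool]
    loadings: pd.Series  # ref gene -> loading (0 for background)
    eqtls: list[dict] = field(default_factory=list)
    outlier_samples: list[str] = field(default_factory=list)


@dataclass
class SimStudy:
    ref_probes: ProbeMatrix
    test_probes: ProbeMatrix
    ortholog_map: OrthologMap
    dosages: DosageMatrix
    snp_positions: pd.DataFrame  # id, chrom, pos
    gene_positions: pd.DataFrame  # id, chrom, start, end (ref genes)
    covariates: pd.DataFrame  # ref samples x covariates
    truth: TruthLabels

    def ref_expression(self) -> ExpressionMatrix:
        """Noise-free collapse shortcut for tests: gene-level ref matrix."""
        from netpres.preprocess import collapse_probes

        return collapse_probes(self.ref_probes)[0]


def _gene_positions(gene_ids: list[str]) -> pd.DataFrame:
    genes_per_chrom = 500
    rows = []
    for i, g in enumerate(gene_ids):
        start = 1_000_000 + (i % genes_per_chrom) * 2_000_000
        rows.append(
            {
                "id": g,
                "chrom": str(1 + i // genes_per_chrom),
                "start": start,
                "end": start + 49,
            }
        )
    return pd.DataFrame(rows)


def _probe_layer(
    gene_values: np.ndarray,
    gene_ids: list[str],
    samples: list[str],
    probe_counts: np.ndarray,
    rng: np.random.Generator,
    prefix: str,
) -> ProbeMatrix:
    rows, probe_ids, probe_genes = [], [], []
    for i, g in enumerate(gene_ids):
        for j in range(probe_counts[i]):
            offset = rng.normal(0.0, _PROBE_OFFSET_SD)
            noise = rng.normal(0.0, _PROBE_NOISE_SD, size=gene_values.shape[1])
            rows.append(gene_values[i] + offset + noise)
            probe_ids.append(f"{g}_P{j + 1}")
            probe_genes.append(g)
    values = pd.DataFrame(np.vstack(rows), index=probe_ids, columns=samples)
    return ProbeMatrix(
        values=values,
        probe_to_gene=pd.Series(probe_genes, index=probe_ids, name="gene"),
        species=prefix,
    )


def generate_paired_study(config: SimConfig) -> SimStudy:
    """Deterministic (given seed) paired-species study with known truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ng, nr, nt = config.n_genes, config.n_samples_ref, config.n_samples_test

    ref_genes = [f"HG{i + 1:05d}" for i in range(ng)]
    test_genes = [f"MG{i + 1:05d}" for i in range(ng)]
    ref_samples = [f"R{i + 1:04d}" for i in range(nr)]
    test_samples = [f"T{i + 1:04d}" for i in range(nt)]

    # truth bookkeeping: modules occupy the leading genes, in blocks
    labels = np.zeros(ng, dtype=int)
    loadings = np.zeros(ng)
    start = 0
    for m, size in enumerate(config.module_sizes, start=1):
        labels[start : start + size] = m
        loadings[start : start + size] = rng.uniform(*config.loading_range, size=size)
        start += size

    # dosages
    mafs = rng.uniform(*config.maf_range, size=config.n_snps)
    dos = rng.binomial(2, mafs[:, None], size=(config.n_snps, nr)).astype(float)
    if config.dosage_blur:
        dos = np.clip(dos + rng.uniform(-0.2, 0.2, size=dos.shape), 0.0, 2.0)
    snp_ids = [f"SNP{i + 1:04d}" for i in range(config.n_snps)]

    # latent module signals (reference), with optional trans dosage effect
    latents_ref = rng.normal(size=(len(config.module_sizes), nr))
    eqtl_truth: list[dict] = []
    if config.trans_effect is not None:
        te = config.trans_effect
        latents_ref[te.module_index - 1] += te.beta * dos[te.snp_index]
        targets = [ref_genes[i] for i in np.where(labels == te.module_index)[0]]
        eqtl_truth.append(
            {
                "kind": "trans",
                "snp": snp_ids[te.snp_index],
                "module": te.module_index,
                "genes": targets,
                "beta": te.beta,
            }
        )

    noise = rng.normal(0.0, config.noise_sd, size=(ng, nr))
    expr_ref = noise.copy()
    for m in range(1, len(config.module_sizes) + 1):
        idx = labels == m
        lam = loadings[idx][:, None]
        expr_ref[idx] = lam * latents_ref[m - 1] + np.sqrt(1 - lam**2) * noise[idx]

    for ce in config.cis_effects:
        expr_ref[ce.gene_index] += ce.beta * dos[ce.snp_index]
        eqtl_truth.append(
            {
                "kind": "cis",
                "snp": snp_ids[ce.snp_index],
                "genes": [ref_genes[ce.gene_index]],
                "beta": ce.beta,
            }
        )

    # covariates added linearly to all reference genes
    cov = rng.normal(size=(config.n_covariates, nr))
    if config.n_covariates:
        coeffs = rng.normal(0.0, config.covariate_effect_sd, size=(ng, config.n_covariates))
        expr_ref += coeffs @ cov

    # outlier samples: constant offset on every gene
    outlier_samples: list[str] = []
    if config.n_outlier_samples:
        which = rng.choice(nr, size=config.n_outlier_samples, replace=False)
        expr_ref[:, which] += config.outlier_offset * config.noise_sd
        outlier_samples = [ref_samples[i] for i in sorted(which)]

    # test species
    latents_test = rng.normal(size=(len(config.module_sizes), nt))
    noise_t = rng.normal(0.0, config.noise_sd, size=(ng, nt))
    expr_test = noise_t.copy()
    preserved: dict[int, bool] = {}
    for m, flag in enumerate(config.preserved_flags, start=1):
        preserved[m] = bool(flag)
        if not flag:
            continue
        idx = labels == m
        lam = loadings[idx].copy()
        if config.sign_flip_fraction > 0:
            flip = rng.random(lam.size) < config.sign_flip_fraction
            lam[flip] *= -1.0
        lam = lam[:, None]
        expr_test[idx] = lam * latents_test[m - 1] + np.sqrt(1 - lam**2) * noise_t[idx]

    # probe layers (collapse is non-trivial: offsets + probe noise)
    lo, hi = config.n_probes_per_gene
    counts_ref = rng.integers(lo, hi + 1, size=ng)
    counts_test = rng.integers(lo, hi + 1, size=ng)
    ref_probes = _probe_layer(expr_ref, ref_genes, ref_samples, counts_ref, rng, "ref")
    test_probes = _probe_layer(expr_test, test_genes, test_samples, counts_test, rng, "test")

    gene_pos = _gene_positions(ref_genes)
    snp_pos = _snp_positions(snp_ids, gene_pos, config, rng)

    truth = TruthLabels(
        module_labels=pd.Series(labels, index=ref_genes, name="module"),
        preserved=preserved,
        loadings=pd.Series(loadings, index=ref_genes, name="loading"),
        eqtls=eqtl_truth,
        outlier_samples=outlier_samples,
    )
    return SimStudy(
        ref_probes=ref_probes,
        test_probes=test_probes,
        ortholog_map=OrthologMap(
            pd.DataFrame({"ref_gene": ref_genes, "test_gene": test_genes})
        ),
        dosages=DosageMatrix(
            pd.DataFrame(dos, index=snp_ids, columns=ref_samples),
            maf=pd.Series(np.minimum(mafs, 1 - mafs), index=snp_ids),
        ),
        snp_positions=snp_pos,
        gene_positions=gene_pos,
        covariates=pd.DataFrame(
            cov.T,
            index=ref_samples,
            columns=[f"COV{i + 1}" for i in range(config.n_covariates)],
        ),
        truth=truth,
    )


def _snp_positions(
    snp_ids: list[str],
    gene_pos: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """cis SNPs sit inside their target gene's window; others are placed far away."""
    gp = gene_pos.set_index("id")
    max_chrom = max(int(c) for c in gene_pos["chrom"])
    chrom = np.full(len(snp_ids), str(max_chrom + 1), dtype=object)
    pos = rng.integers(1, 500_000_000, size=len(snp_ids)).astype(np.int64)
    for ce in config.cis_effects:
        g = gp.iloc[ce.gene_index]
        chrom[ce.snp_index] = g["chrom"]
        pos[ce.snp_index] = int(g["start"]) + 10
    return pd.DataFrame({"id": snp_ids, "chrom": chrom, "pos": pos})


def write_study(study: SimStudy, outdir: str | Path, vcf: bool = False) -> dict[str, Path]:
    """Write the standard pipeline input files (all plain text TSV/JSON)."""
    from netpres import io as npio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    for tag, pm in (("ref", study.ref_probes), ("test", study.test_probes)):
        paths[f"{tag}_expression"] = npio.write_probe_matrix(
            pm, outdir / f"{tag}_probes.tsv", outdir / f"{tag}_probe_map.tsv"
        )[0]

    paths["orthologs"] = outdir / "orthologs.tsv"
    study.ortholog_map.pairs.to_csv(paths["orthologs"], sep="\t", index=False)

    paths["dosages"] = outdir / "dosages.tsv"
    npio.write_dosage_tsv(study.dosages, paths["dosages"])
    if vcf:
        paths["vcf"] = outdir / "dosages.vcf"
        npio.write_dosage_vcf(study.dosages, study.snp_positions, paths["vcf"])

    paths["snp_positions"] = outdir / "snp_positions.tsv"
    study.snp_positions.to_csv(paths["snp_positions"], sep="\t", index=False)
    paths["gene_positions"] = outdir / "gene_positions.tsv"
    study.gene_positions.to_csv(paths["gene_positions"], sep="\t", index=False)
    paths["covariates"] = outdir / "covariates.tsv"
    study.covariates.to_csv(paths["covariates"], sep="\t")

    truth = {
        "module_labels": study.truth.module_labels.to_dict(),
        "preserved": {str(k): v for k, v in study.truth.preserved.items()},
        "loadings": study.truth.loadings.to_dict(),
        "eqtls": study.truth.eqtls,
        "outlier_samples": study.truth.outlier_samples,
    }
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
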