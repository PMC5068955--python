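"""Plain-text readers/writers for the pipeline's standard formats.

Expression/probe/dosage matrices are TSV with the row ID in the first column
and sample IDs in the header. Positions are 1-based inclusive. Gene sets use
the GMT convention (name, description, genes...). VCF dosage input expects a
per-genotype DS FORMAT field and is parsed with pysam when available.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from netpres.types import DosageMatrix, ExpressionMatrix, OrthologMap, ProbeMatrix


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_expression_tsv(path: str | Path, species: str = "") -> ExpressionMatrix:
    em = ExpressionMatrix(read_matrix_tsv(path), species=species)
    em.validate()
    return em


def write_expression_tsv(em: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    em.values.to_csv(path, sep="\t", index_label="gene")
    return path


def read_probe_matrix(
    values_path: str | Path, map_path: str | Path, species: str = ""
) -> ProbeMatrix:
    values = read_matrix_tsv(values_path)
    pmap = pd.read_csv(map_path, sep="\t", dtype=str)
    pm = ProbeMatrix(
        values=values,
        probe_to_gene=pd.Series(
            pmap["gene"].values, index=pmap["probe"].values, name="gene"
        ),
        species=species,
    )
    pm.validate()
    return pm


def write_probe_matrix(
    pm: ProbeMatrix, values_path: str | Path, map_path: str | Path
) -> tuple[Path, Path]:
    values_path, map_path = Path(values_path), Path(map_path)
    pm.values.to_csv(values_path, sep="\t", index_label="probe")
    pd.DataFrame(
        {"probe": pm.probe_to_gene.index, "gene": pm.probe_to_gene.values}
    ).to_csv(map_path, sep="\t", index=False)
    return values_path, map_path


def read_ortholog_tsv(path: str | Path) -> OrthologMap:
    om = OrthologMap(pd.read_csv(path, sep="\t", dtype=str))
    om.validate()
    return om


def read_positions_tsv(path: str | Path) -> pd.DataFrame:
    """SNP (id, chrom, pos) or gene (id, chrom, start, end) position table."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    return df


def read_covariates_tsv(path: str | Path) -> pd.DataFrame:
    """Samples x covariates table (sample IDs in the first column)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_dosage_tsv(path: str | Path) -> DosageMatrix:
    dm = DosageMatrix(read_matrix_tsv(path))
    dm.validate()
    return dm


def write_dosage_tsv(dm: DosageMatrix, path: str | Path) -> Path:
    path = Path(path)
    dm.values.to_csv(path, sep="\t", index_label="snp")
    return path


def write_dosage_vcf(
    dm: DosageMatrix, snp_positions: pd.DataFrame, path: str | Path
) -> Path:
    """Minimal VCF 4.2 with a DS (dosage) FORMAT field, uncompressed text."""
    path = Path(path)
    pos = snp_positions.set_index("id")
    samples = list(dm.samples)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        chroms = pd.unique(pos["chrom"].astype(str))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for snp in dm.snps:
            row = pos.loc[snp]
            ds = "\t".join(f"{v:.3f}" for v in dm.values.loc[snp].values)
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{snp}\tA\tG\t.\tPASS\t.\tDS\t{ds}\n")
    return path


def read_dosage_vcf(path: str | Path) -> tuple[DosageMatrix, pd.DataFrame]:
    """Dosage matrix + positions from a VCF with a DS FORMAT field."""
    try:
        import pysam
    except ImportError:  # pragma: no cover - pysam is in the standard stack
        return _read_dosage_vcf_plain(path)
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    snp_ids, chroms, positions, rows = [], [], [], []
    for rec in vf:
        snp_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
        chroms.append(str(rec.chrom))
        positions.append(int(rec.pos))
        rows.append([float(rec.samples[s]["DS"]) for s in samples])
    values = pd.DataFrame(rows, index=snp_ids, columns=samples)
    dm = DosageMatrix(values)
    dm.validate()
    pos = pd.DataFrame({"id": snp_ids, "chrom": chroms, "pos": positions})
    return dm, pos


def _read_dosage_vcf_plain(path: str | Path) -> tuple[DosageMatrix, pd.DataFrame]:
    samples: list[str] = []
    snp_ids, chroms, positions, rows = [], [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            fmt = fields[8].split(":")
            ds_idx = fmt.index("DS")
            snp_ids.append(fields[2])
            chroms.append(fields[0])
            positions.append(int(fields[1]))
            rows.append([float(v.split(":")[ds_idx]) for v in fields[9:]])
    dm = DosageMatrix(pd.DataFrame(rows, index=snp_ids, columns=samples))
    dm.validate()
    return dm, pd.DataFrame({"id": snp_ids, "chrom": chroms, "pos": positions})


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")
    return path
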