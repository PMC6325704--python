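"""Reading and writing the pipeline's on-disk formats.

Genotypes travel as VCF (homozygous diploid GT, ``./.`` for missing) or as a
samples x SNPs TSV coded {0, 2, NA}; climate series, coverage summaries and
trait tables as plain TSV.  VCF handling is delegated to pysam.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import pysam

from .core import MISSING, GenotypeMatrix

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_climate_tsv",
    "read_climate_tsv",
    "read_gff_genes",
]

_GT_TO_CODE = {(0, 0): 0, (1, 1): 2, (0, 1): 1, (1, 0): 1}


def write_vcf(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a :class:`GenotypeMatrix` as an uncompressed VCF."""
    header = pysam.VariantHeader()
    header.add_meta("source", "brachykit")
    header.formats.add("GT", 1, "String", "Genotype")
    chrom_max: dict[str, int] = {}
    for c, p in zip(matrix.chrom, matrix.pos):
        chrom_max[c] = max(chrom_max.get(c, 0), int(p))
    for c, length in chrom_max.items():
        header.contigs.add(c, length=length + 1)
    for s in matrix.samples:
        header.add_sample(s)

    ref = matrix.ref if matrix.ref is not None else np.full(matrix.n_snps, "A")
    alt = matrix.alt if matrix.alt is not None else np.full(matrix.n_snps, "T")
    qual = matrix.qual

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in range(matrix.n_snps):
            rec = out.new_record(
                contig=str(matrix.chrom[j]),
                start=int(matrix.pos[j]) - 1,
                stop=int(matrix.pos[j]),
                alleles=(str(ref[j]), str(alt[j])),
            )
            if qual is not None:
                rec.qual = float(qual[j])
            for i, s in enumerate(matrix.samples):
                g = matrix.calls[i, j]
                if g == MISSING:
                    rec.samples[s]["GT"] = (None, None)
                elif g == 0:
                    rec.samples[s]["GT"] = (0, 0)
                elif g == 2:
                    rec.samples[s]["GT"] = (1, 1)
                else:
                    rec.samples[s]["GT"] = (0, 1)
            out.write(rec)


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a :class:`GenotypeMatrix`."""
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        chrom, pos, ref, alt, qual, rows = [], [], [], [], [], []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"non-biallelic record at {rec.chrom}:{rec.pos}")
            chrom.append(rec.chrom)
            pos.append(rec.pos)
            ref.append(rec.ref)
            alt.append(rec.alts[0])
            qual.append(np.nan if rec.qual is None else rec.qual)
            row = np.full(len(samples), MISSING, dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                if gt is not None and None not in gt:
                    row[i] = _GT_TO_CODE.get(tuple(gt), MISSING)
            rows.append(row)
    calls = np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0), np.int8)
    return GenotypeMatrix(
        samples=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos),
        calls=calls,
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        qual=np.array(qual, dtype=float),
    )


def write_genotype_tsv(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Samples x SNPs TSV with {0, 2, NA}; columns named chrom:pos."""
    cols = [f"{c}:{p}" for c, p in zip(matrix.chrom, matrix.pos)]
    df = pd.DataFrame(
        np.where(matrix.calls == MISSING, np.nan, matrix.calls),
        index=pd.Index(matrix.samples, name="sample"),
        columns=cols,
    )
    df.to_csv(path, sep="\t", na_rep="NA")


def read_genotype_tsv(path: str | os.PathLike) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    chrom, pos = zip(*(c.rsplit(":", 1) for c in df.columns))
    calls = df.to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    return GenotypeMatrix(
        samples=[str(s) for s in df.index],
        chrom=np.array(chrom, dtype=object),
        pos=np.array([int(p) for p in pos]),
        calls=calls,
    )


def write_climate_tsv(series: pd.DataFrame, path: str | os.PathLike) -> None:
    """Climate series TSV: ISO timestamp, temp_C, par (plus day column)."""
    series.to_csv(path, sep="\t", index=False)


def read_climate_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "timestamp" in df.columns:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def read_gff_genes(path: str | os.PathLike) -> pd.DataFrame:
    """Extract gene records (chrom, start, end, gene_id) from a GFF3 file.

    Malformed rows (wrong column count, non-numeric coordinates) are skipped.
    Coordinates stay 1-based inclusive as in the file.
    """
    names = [
        "seqid", "source", "type", "start", "end",
        "score", "strand", "phase", "attributes",
    ]
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=names,
        dtype=str, on_bad_lines="skip",
    )
    df = df[df["type"] == "gene"].copy()
    df["start"] = pd.to_numeric(df["start"], errors="coerce")
    df["end"] = pd.to_numeric(df["end"], errors="coerce")
    df = df.dropna(subset=["start", "end"])

    def _gene_id(attrs: str) -> str:
        for part in str(attrs).split(";"):
            if part.startswith("ID="):
                return part[3:]
        return str(attrs)

    return pd.DataFrame(
        {
            "chrom": df["seqid"].to_numpy(),
            "start": df["start"].astype(int).to_numpy(),
            "end": df["end"].astype(int).to_numpy(),
            "gene_id": df["attributes"].map(_gene_id).to_numpy(),
        }
    )
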