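"""Readers and writers for the formats the pipeline touches.

FASTA alignments go through Biopython, VCF through pysam (restricted to
biallelic SNP records; anything else is skipped and counted), metadata and
genotype matrices are plain TSV.  All writers emit text formats that their
paired reader round-trips exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AlignedSequenceSet,
    GenotypeMatrix,
    Sex,
    SiteCountTable,
    SpecimenRecord,
)

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("specimen_id", "taxon_label", "sex", "locality")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, gene: str = "other") -> AlignedSequenceSet:
    """Read an aligned multi-FASTA; the specimen id is the first
    whitespace-delimited token of each header."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty FASTA file: {path}")
    sequences: dict[str, str] = {}
    for rec in records:
        sid = rec.id.split()[0]
        if sid in sequences:
            raise ValueError(f"duplicate specimen id in FASTA: {sid!r}")
        sequences[sid] = str(rec.seq)
    return AlignedSequenceSet(gene, sequences)


def write_fasta(aln: AlignedSequenceSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Specimen metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> list[SpecimenRecord]:
    """Read a specimen metadata TSV with header
    specimen_id / taxon_label / sex / locality (+ optional notes)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file missing required columns: {missing}")
    if df["specimen_id"].duplicated().any():
        dupes = sorted(df.loc[df["specimen_id"].duplicated(), "specimen_id"])
        raise ValueError(f"duplicate specimen ids in metadata: {dupes}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SpecimenRecord(
                specimen_id=row.specimen_id,
                taxon_label=row.taxon_label,
                sex=Sex.parse(row.sex),
                locality=row.locality,
                notes=getattr(row, "notes", ""),
            )
        )
    return records


def write_metadata(records: Sequence[SpecimenRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in records],
            "taxon_label": [r.taxon_label for r in records],
            "sex": [r.sex.value for r in records],
            "locality": [r.locality for r in records],
            "notes": [r.notes for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype matrices (TSV + VCF)
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str = "auto") -> GenotypeMatrix:
    """Read a genotype matrix from a VCF (biallelic SNPs only) or a dosage
    TSV (rows = specimens, columns = loci, codes 0/1/2/NA)."""
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.suffix in (".vcf", ".bcf", ".gz") else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_genotype_tsv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    loci: list[str] = []
    ref: list[str] = []
    alt: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        locus = rec.id or f"{rec.chrom}:{rec.pos}"
        dosages = np.full(len(samples), np.nan)
        for i, sample in enumerate(samples):
            gt = rec.samples[sample].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            if any(a not in (0, 1) for a in gt):
                raise ValueError(
                    f"non-biallelic GT {gt} at {locus} sample {sample}"
                )
            dosages[i] = sum(1 for a in gt if a == 1)
        loci.append(locus)
        ref.append(rec.ref)
        alt.append(alts[0])
        rows.append(dosages)
    vf.close()
    if n_skipped:
        logger.info("skipped %d non-biallelic/non-SNP VCF records", n_skipped)
    calls = pd.DataFrame(
        np.array(rows).T if rows else np.empty((len(samples), 0)),
        index=samples,
        columns=loci,
    )
    return GenotypeMatrix(
        calls,
        pd.Series(ref, index=loci, dtype=object),
        pd.Series(alt, index=loci, dtype=object),
    )


def _read_genotype_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = np.full(df.shape, np.nan)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = df.iat[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            cell = str(cell).strip()
            if cell in ("", "NA", "nan", "."):
                continue
            if cell not in ("0", "1", "2"):
                # +2: header line plus 1-based numbering
                raise ValueError(
                    f"malformed genotype {cell!r} at line {i + 2} "
                    f"(specimen {df.index[i]!r}, locus {df.columns[j]!r})"
                )
            values[i, j] = float(cell)
    calls = pd.DataFrame(values, index=df.index, columns=df.columns)
    return GenotypeMatrix(calls)


def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    out = gm.calls.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.index.name = "specimen_id"
    out.to_csv(path, sep="\t")


def write_vcf(gm: GenotypeMatrix, path: str | Path, chrom: str = "synthetic") -> None:
    """Write the matrix as an uncompressed biallelic-SNP VCF; loci without
    known alleles are written as A/T placeholders with the locus id in ID."""
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={chrom},length={max(gm.n_loci, 1)}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in gm.specimens:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for pos, locus in enumerate(gm.loci, start=1):
            ref = gm.ref_allele[locus]
            alt = gm.alt_allele[locus]
            if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
                ref, alt = "A", "T"
            rec = out.new_record(
                contig=chrom, start=pos - 1, stop=pos,
                alleles=(ref, alt), id=locus,
            )
            for s in gm.specimens:
                d = gm.calls.at[s, locus]
                if np.isnan(d):
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(d)]
            out.write(rec)


# ---------------------------------------------------------------------------
# Site count tables
# ---------------------------------------------------------------------------

def read_site_counts(path: str | Path) -> SiteCountTable:
    df = pd.read_csv(path, sep="\t", dtype={"specimen_id": str, "site_id": str})
    return SiteCountTable(df)


def write_site_counts(table: SiteCountTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t", index=False)
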