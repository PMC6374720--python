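"""Shared data model: specimens, alignments, genotype matrices, partitions.

Genotypes are stored as alternate-allele dosage (0, 1, 2) with an explicit
missing sentinel (NaN) — never conflated with dosage 0.  Hemizygous males at
X-linked loci arrive coded as homozygous (0 or 2), because reduced-
representation genotyping cannot distinguish hemizygosity from homozygosity.

Alignment coordinates are 0-based internally; every user-facing report is
1-based.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Nucleotide alphabet accepted in alignments: bases, IUPAC ambiguity, gap.
ALIGNMENT_ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

#: Expansion of every IUPAC nucleotide code into its compatible bases.
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
    "-": frozenset(),
}


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, value: object) -> "Sex":
        """Parse a free-form sex field, case-insensitively; blank → unknown."""
        if value is None:
            return cls.UNKNOWN
        text = str(value).strip().lower()
        if text in ("", "na", "nan", "none", "?"):
            return cls.UNKNOWN
        if text in ("m", "male"):
            return cls.MALE
        if text in ("f", "female"):
            return cls.FEMALE
        if text == "unknown":
            return cls.UNKNOWN
        raise ValueError(f"unparseable sex value: {value!r}")


@dataclass(frozen=True)
class SpecimenRecord:
    """One voucher specimen with its phenotypic identification."""

    specimen_id: str
    taxon_label: str
    sex: Sex = Sex.UNKNOWN
    locality: str = ""
    notes: str = ""


class AlignedSequenceSet:
    """An equal-length nucleotide alignment keyed by specimen id.

    Sequences are upper-cased and RNA ``U`` is mapped to ``T`` on
    construction.  Construction fails on ragged alignments (naming the
    offending record) and on characters outside the IUPAC+gap alphabet.
    """

    def __init__(self, gene: str, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("alignment is empty")
        self.gene = gene
        normalized: dict[str, str] = {}
        length: int | None = None
        for sid, seq in sequences.items():
            seq = str(seq).upper().replace("U", "T")
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise ValueError(
                    f"ragged alignment: record {sid!r} has length "
                    f"{len(seq)}, expected {length}"
                )
            bad = set(seq) - ALIGNMENT_ALPHABET
            if bad:
                raise ValueError(
                    f"record {sid!r} contains non-IUPAC characters: "
                    f"{sorted(bad)}"
                )
            normalized[sid] = seq
        if length == 0:
            raise ValueError("alignment has zero columns")
        self.sequences = normalized
        self._length = int(length)  # type: ignore[arg-type]

    @property
    def length(self) -> int:
        return self._length

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, specimen_id: str) -> str:
        return self.sequences[specimen_id]

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.sequences.items())

    def subset(self, specimen_ids: Sequence[str]) -> "AlignedSequenceSet":
        return AlignedSequenceSet(
            self.gene, {s: self.sequences[s] for s in specimen_ids}
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlignedSequenceSet):
            return NotImplemented
        return self.gene == other.gene and self.sequences == other.sequences


class GenotypeMatrix:
    """Specimens x biallelic loci, entries = alternate-allele dosage.

    Backed by a float DataFrame (index = specimen ids, columns = locus ids)
    with values in {0, 1, 2} and NaN for missing calls.  ``ref_allele`` /
    ``alt_allele`` are optional per-locus nucleotide Series ("N" when the
    source format carries no allele identity, e.g. a bare dosage TSV).
    """

    def __init__(
        self,
        calls: pd.DataFrame,
        ref_allele: pd.Series | None = None,
        alt_allele: pd.Series | None = None,
    ):
        calls = calls.astype(float)
        values = calls.to_numpy()
        valid = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise ValueError(
                f"invalid genotype code {values[i, j]!r} for specimen "
                f"{calls.index[i]!r} at locus {calls.columns[j]!r}"
            )
        if calls.index.has_duplicates or calls.columns.has_duplicates:
            raise ValueError("duplicate specimen or locus identifiers")
        self.calls = calls
        n = pd.Series("N", index=calls.columns)
        self.ref_allele = n if ref_allele is None else ref_allele.reindex(calls.columns)
        self.alt_allele = n.copy() if alt_allele is None else alt_allele.reindex(calls.columns)

    @property
    def specimens(self) -> list[str]:
        return list(self.calls.index)

    @property
    def loci(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_specimens(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.calls.to_numpy()

    def call_rate(self) -> pd.Series:
        """Per-locus fraction of specimens with a non-missing call."""
        return self.calls.notna().mean(axis=0)

    def subset(
        self,
        specimens: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        calls = self.calls
        if specimens is not None:
            missing = set(specimens) - set(calls.index)
            if missing:
                raise KeyError(f"unknown specimens: {sorted(missing)}")
            calls = calls.loc[list(specimens)]
        if loci is not None:
            calls = calls[list(loci)]
        return GenotypeMatrix(
            calls,
            self.ref_allele.reindex(calls.columns),
            self.alt_allele.reindex(calls.columns),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        if list(self.calls.index) != list(other.calls.index):
            return False
        if list(self.calls.columns) != list(other.calls.columns):
            return False
        a, b = self.values, other.values
        return bool(((a == b) | (np.isnan(a) & np.isnan(b))).all())


@dataclass
class SiteCountTable:
    """Per specimen x site read counts for each base (quality-filtered
    upstream; read-level trimming and mapping filters are assumed to have
    been applied before this table was produced)."""

    counts: pd.DataFrame  # columns: specimen_id, site_id, A, C, G, T

    REQUIRED = ("specimen_id", "site_id", "A", "C", "G", "T")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.counts.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        base_cols = self.counts[list("ACGT")]
        arr = base_cols.to_numpy()
        if np.isnan(arr).any() or (arr < 0).any() or (arr != arr.astype(int)).any():
            raise ValueError("read counts must be non-negative integers")
        self.counts = self.counts.copy()
        self.counts[list("ACGT")] = arr.astype(int)

    @property
    def sites(self) -> list[str]:
        return list(pd.unique(self.counts["site_id"]))

    @property
    def specimens(self) -> list[str]:
        return list(pd.unique(self.counts["specimen_id"]))


@dataclass
class TaxonPartition:
    """Specimen → analysis taxon map, treated as a revisable hypothesis.

    Starts from phenotypic identifications; reassignments (e.g. a female
    re-identified from its molecular genotype) are logged with a reason and
    flip the provenance flag to ``revised``.
    """

    assignments: dict[str, str]
    provenance: str = "phenotype"
    revisions: list[dict[str, str]] = field(default_factory=list)

    @classmethod
    def from_records(cls, records: Sequence[SpecimenRecord]) -> "TaxonPartition":
        return cls({r.specimen_id: r.taxon_label for r in records})

    @property
    def taxa(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.assignments.values():
            seen.setdefault(t, None)
        return list(seen)

    def members(self, taxon: str) -> list[str]:
        return [s for s, t in self.assignments.items() if t == taxon]

    def __getitem__(self, specimen_id: str) -> str:
        return self.assignments[specimen_id]

    def __contains__(self, specimen_id: str) -> bool:
        return specimen_id in self.assignments

    def reassign(self, specimen_id: str, new_taxon: str, reason: str) -> None:
        if specimen_id not in self.assignments:
            raise KeyError(f"unknown specimen: {specimen_id!r}")
        if not reason:
            raise ValueError("a reassignment requires a reason")
        self.revisions.append(
            {
                "specimen_id": specimen_id,
                "old_taxon": self.assignments[specimen_id],
                "new_taxon": new_taxon,
                "reason": reason,
            }
        )
        self.assignments[specimen_id] = new_taxon
        self.provenance = "revised"
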