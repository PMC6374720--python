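"""Sequence-level diagnostics for species delimitation.

Implements the barcoding-style toolkit: collapsing aligned sequences into
haplotypes, uncorrected p-distances within and between taxa, pure diagnostic
nucleotide characters (a state carried by every focal haplotype and by no
other haplotype), simple indel coding of alignment gaps, and a translation
sanity check for protein-coding mitochondrial alignments.

Uncorrected p-distances use pairwise deletion: an alignment column is
compared for a pair only when both sequences carry an unambiguous base
there.  Distances are reported in percent, rounded half-even to 2 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .model import AlignedSequenceSet, IUPAC_EXPANSION, TaxonPartition

UNAMBIGUOUS = frozenset("ACGT")


# ---------------------------------------------------------------------------
# Haplotype collapsing
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeTable:
    """Distinct haplotypes and the specimen → haplotype membership map."""

    haplotypes: list[tuple[str, str]]
    membership: dict[str, str]
    gene: str = "other"

    def sequence_of(self, haplotype_id: str) -> str:
        for hid, seq in self.haplotypes:
            if hid == haplotype_id:
                return seq
        raise KeyError(haplotype_id)

    def members_of(self, haplotype_id: str) -> list[str]:
        return [s for s, h in self.membership.items() if h == haplotype_id]

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def multiplicity(self) -> dict[str, int]:
        counts: dict[str, int] = {hid: 0 for hid, _ in self.haplotypes}
        for h in self.membership.values():
            counts[h] += 1
        return counts


def _compatible(a: str, b: str) -> bool:
    """True when two sequences agree at every column where both carry an
    unambiguous, ungapped base."""
    return all(
        ca == cb
        for ca, cb in zip(a, b)
        if ca in UNAMBIGUOUS and cb in UNAMBIGUOUS
    )


def collapse_haplotypes(
    aln: AlignedSequenceSet, mode: str = "strict"
) -> HaplotypeTable:
    """Collapse an alignment into distinct haplotypes.

    ``strict`` (default): two specimens share a haplotype iff their aligned
    sequences are identical strings (ambiguity codes included).  ``lenient``:
    a specimen joins the first existing haplotype whose sequence agrees with
    it at every column where both are unambiguous and ungapped.  Haplotypes
    are numbered H1, H2, ... in first-occurrence order.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError("mode must be 'strict' or 'lenient'")
    haplotypes: list[tuple[str, str]] = []
    membership: dict[str, str] = {}
    index: dict[str, str] = {}  # sequence -> haplotype id (strict mode)
    for sid, seq in aln:
        hid = None
        if mode == "strict":
            hid = index.get(seq)
        else:
            for existing_id, existing_seq in haplotypes:
                if _compatible(seq, existing_seq):
                    hid = existing_id
                    break
        if hid is None:
            hid = f"H{len(haplotypes) + 1}"
            haplotypes.append((hid, seq))
            index[seq] = hid
        membership[sid] = hid
    return HaplotypeTable(haplotypes, membership, gene=aln.gene)


# ---------------------------------------------------------------------------
# Uncorrected p-distance
# ---------------------------------------------------------------------------

def p_distance(a: str, b: str) -> float:
    """Proportion of compared columns at which two aligned sequences differ.

    Columns with a gap or IUPAC ambiguity in either sequence are excluded
    (pairwise deletion).  Returns NaN when no column is comparable.
    """
    if len(a) != len(b):
        raise ValueError(
            f"sequences have unequal length: {len(a)} vs {len(b)}"
        )
    a = a.upper()
    b = b.upper()
    compared = 0
    diff = 0
    for ca, cb in zip(a, b):
        if ca in UNAMBIGUOUS and cb in UNAMBIGUOUS:
            compared += 1
            if ca != cb:
                diff += 1
    if compared == 0:
        return float("nan")
    return diff / compared


@dataclass
class DistanceTable:
    """Mean pairwise p-distances (%) within and between groups."""

    groups: list[str]
    within: dict[str, float]        # percent; NaN for single-haplotype groups
    between: pd.DataFrame           # symmetric, percent
    gene: str = "other"

    def to_frame(self, na_as_zero: bool = False) -> pd.DataFrame:
        """Lower-triangle layout: within-group values on the diagonal,
        between-group means below it, rounded half-even to 2 decimals.

        ``na_as_zero`` renders undefined single-haplotype diagonals as 0.00,
        the convention used by published distance tables; the package keeps
        NaN internally so the two cases stay distinguishable.
        """
        n = len(self.groups)
        out = pd.DataFrame("", index=self.groups, columns=self.groups)
        for i, gi in enumerate(self.groups):
            w = self.within[gi]
            if np.isnan(w):
                out.iat[i, i] = "0.00" if na_as_zero else "NA"
            else:
                out.iat[i, i] = f"{round(w, 2):.2f}"
            for j in range(i):
                gj = self.groups[j]
                out.iat[i, j] = f"{round(self.between.at[gi, gj], 2):.2f}"
        return out

    def to_tsv(self, path, na_as_zero: bool = True) -> None:
        frame = self.to_frame(na_as_zero=na_as_zero)
        with open(path, "w") as fh:
            fh.write(f"# gene: {self.gene}\n")
            if na_as_zero and any(np.isnan(v) for v in self.within.values()):
                fh.write(
                    "# note: single-haplotype groups have no within-group "
                    "pairs; their diagonal is printed as 0.00 by convention\n"
                )
            frame.to_csv(fh, sep="\t")


def group_distance_table(
    hap: HaplotypeTable, part: TaxonPartition, groups: Sequence[str] | None = None
) -> DistanceTable:
    """Mean pairwise p-distance among unique haplotypes, within and between
    taxa.

    Each haplotype enters a group's set once regardless of how many
    specimens carry it; a haplotype shared between two taxa belongs to both
    sets (so a cross-group pair of the same haplotype contributes distance
    zero — exactly the signal of haplotype sharing).
    """
    if groups is None:
        groups = part.taxa
    groups = list(groups)
    if not groups:
        raise ValueError("at least one group is required")
    hap_sets: dict[str, list[str]] = {}
    for g in groups:
        seen: dict[str, None] = {}
        for sid in part.members(g):
            h = hap.membership.get(sid)
            if h is not None:
                seen.setdefault(h, None)
        if not seen:
            raise ValueError(f"group {g!r} has no haplotypes")
        hap_sets[g] = list(seen)
    seq = dict(hap.haplotypes)
    cache: dict[tuple[str, str], float] = {}

    def dist(h1: str, h2: str) -> float:
        key = (h1, h2) if h1 <= h2 else (h2, h1)
        if key not in cache:
            cache[key] = p_distance(seq[key[0]], seq[key[1]])
        return cache[key]

    within: dict[str, float] = {}
    for g in groups:
        hs = hap_sets[g]
        if len(hs) < 2:
            within[g] = float("nan")
        else:
            vals = [
                dist(hs[i], hs[j])
                for i in range(len(hs))
                for j in range(i + 1, len(hs))
            ]
            within[g] = float(np.nanmean(vals)) * 100.0
    between = pd.DataFrame(0.0, index=groups, columns=groups)
    for i, gi in enumerate(groups):
        for j in range(i + 1, len(groups)):
            gj = groups[j]
            vals = [dist(h1, h2) for h1 in hap_sets[gi] for h2 in hap_sets[gj]]
            m = float(np.nanmean(vals)) * 100.0
            between.at[gi, gj] = m
            between.at[gj, gi] = m
    return DistanceTable(groups, within, between, gene=hap.gene)


# ---------------------------------------------------------------------------
# Diagnostic nucleotide characters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiagnosticCharacter:
    """A nucleotide-position combination found in all focal haplotypes and
    in no non-focal haplotype.  ``position`` is a 1-based alignment column."""

    position: int
    state: str
    focal_group: str


def find_diagnostic_characters(
    aln: AlignedSequenceSet,
    part: TaxonPartition,
    focal_group: str,
    mode: str = "strict",
) -> list[DiagnosticCharacter]:
    """Exhaustive column scan for pure diagnostic characters.

    The scan runs over haplotypes, not specimens, so a haplotype shared
    between the focal taxon and another taxon defeats diagnosis naturally.
    ``strict`` skips columns where any focal haplotype is ambiguous or
    gapped; ``lenient`` resolves focal ambiguity codes against their IUPAC
    expansion.  Non-focal states are always IUPAC-expanded, so an ambiguity
    code compatible with the candidate state blocks it.
    """
    hap = collapse_haplotypes(aln, mode="strict")
    focal_specimens = [s for s in aln.specimen_ids
                      if part.assignments.get(s) == focal_group]
    if not focal_specimens:
        raise ValueError(f"focal group {focal_group!r} has no specimens")
    focal_haps = {hap.membership[s] for s in focal_specimens}
    other_haps = {
        hap.membership[s]
        for s in aln.specimen_ids
        if s in part and part[s] != focal_group
    }
    seq = dict(hap.haplotypes)
    found: list[DiagnosticCharacter] = []
    for col in range(aln.length):
        focal_chars = {seq[h][col] for h in focal_haps}
        other_chars = {seq[h][col] for h in other_haps}
        other_bases: set[str] = set()
        for c in other_chars:
            other_bases |= IUPAC_EXPANSION[c]
        if mode == "strict":
            if not focal_chars <= UNAMBIGUOUS or len(focal_chars) != 1:
                continue
            (state,) = focal_chars
            candidates = [state]
        else:
            shared = set("ACGT")
            for c in focal_chars:
                shared &= IUPAC_EXPANSION[c]
            candidates = sorted(shared)
        for state in candidates:
            if state not in other_bases:
                found.append(DiagnosticCharacter(col + 1, state, focal_group))
    return found


# ---------------------------------------------------------------------------
# Simple indel coding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GapCharacter:
    """One coded indel character: a distinct maximal gap extent
    (1-based inclusive columns) with a per-sequence score of
    1 (gap present), 0 (absent) or '-' (inapplicable)."""

    start: int
    end: int
    states: tuple[tuple[str, str], ...]  # (specimen_id, score)

    def score(self, specimen_id: str) -> str:
        return dict(self.states)[specimen_id]


@dataclass
class GapCharacterBlock:
    characters: list[GapCharacter] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = {
            f"{c.start}-{c.end}": dict(c.states) for c in self.characters
        }
        return pd.DataFrame(cols)


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal runs of '-' as 1-based inclusive (start, end) extents."""
    runs = []
    start = None
    for i, c in enumerate(seq):
        if c == "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start + 1, i))
            start = None
    if start is not None:
        runs.append((start + 1, len(seq)))
    return runs


def code_gaps(aln: AlignedSequenceSet) -> GapCharacterBlock:
    """Simple indel coding: each distinct maximal gap extent becomes one
    binary character; a sequence scores 1 when it bears exactly that extent,
    inapplicable ('-') when its own gap strictly contains the extent, and 0
    otherwise.  Characters are ordered by (start, end)."""
    runs_by_seq = {sid: _gap_runs(seq) for sid, seq in aln}
    extents = sorted({r for runs in runs_by_seq.values() for r in runs})
    characters = []
    for (a, b) in extents:
        states = []
        for sid in aln.specimen_ids:
            runs = runs_by_seq[sid]
            if (a, b) in runs:
                score = "1"
            elif any(x <= a and b <= y and (x, y) != (a, b) for x, y in runs):
                score = "-"
            else:
                score = "0"
            states.append((sid, score))
        characters.append(GapCharacter(a, b, tuple(states)))
    return GapCharacterBlock(characters)


# ---------------------------------------------------------------------------
# Translation sanity check
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranslationReport:
    specimen_id: str
    protein: str
    internal_stops: tuple[int, ...]      # 1-based amino-acid positions
    ambiguous_residues: tuple[int, ...]  # 1-based amino-acid positions

    @property
    def ok(self) -> bool:
        return not self.internal_stops and not self.ambiguous_residues


def translation_check(
    aln: AlignedSequenceSet, genetic_code: int = 5, frame: int = 1
) -> list[TranslationReport]:
    """Translate each (degapped) sequence and flag internal stop codons and
    ambiguous amino acids.  Default genetic code 5 (invertebrate
    mitochondrial); ``frame`` in {1, 2, 3}."""
    if frame not in (1, 2, 3):
        raise ValueError(f"frame must be 1, 2 or 3, got {frame}")
    reports = []
    for sid, seq in aln:
        nt = seq.replace("-", "")[frame - 1:]
        nt = nt[: len(nt) - len(nt) % 3]
        protein = str(Seq(nt).translate(table=genetic_code))
        stops = tuple(
            i + 1 for i, aa in enumerate(protein) if aa == "*" and i < len(protein) - 1
        )
        ambiguous = tuple(
            i + 1 for i, aa in enumerate(protein) if aa in "XBZJ"
        )
        reports.append(TranslationReport(sid, protein, stops, ambiguous))
    return reports
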