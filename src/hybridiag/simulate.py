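"""Synthetic data with the exact statistical structure the pipeline assumes.

Two generators:

* :func:`simulate_sequences` plants haplotype clusters with known mutational
  distances, for testing haplotype collapsing, distances and parsimony
  networks.
* :func:`simulate_cross_dataset` simulates a heterospecific cross between
  two parental taxa: autosomal and X-linked loci fixed for alternate
  alleles, loci with allele-frequency (not fixed) differences, F1 / BC1 /
  F2 offspring by Mendelian gamete draws, X0 sex chromosomes (females XX,
  males X0 with the single X from the mother and hemizygous genotypes coded
  homozygous), maternally inherited mitochondrial haplotypes, and optional
  genotyping error and missingness.

Loci are independent (no linkage), matching the one-SNP-per-locus
subsetting the downstream analyses assume.  Every generator is
deterministic given its seed, and each returns a truth table sufficient to
score the downstream stages without re-deriving expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    AlignedSequenceSet,
    GenotypeMatrix,
    Sex,
    SiteCountTable,
    SpecimenRecord,
    TaxonPartition,
)

BASES = np.array(list("ACGT"))

CLASS_LABELS = ("parental_A", "parental_B", "F1", "BC1A", "BC1B", "F2")


# ---------------------------------------------------------------------------
# Sequence clusters
# ---------------------------------------------------------------------------

def _mutate(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return out


def simulate_sequences(
    n_haplotypes: int,
    length: int,
    intra_steps: int,
    inter_steps: int,
    n_groups: int,
    seed: int = 0,
) -> tuple[AlignedSequenceSet, pd.DataFrame]:
    """Plant ``n_groups`` haplotype clusters in one alignment.

    Group ancestors radiate from a common root, each separated from it by
    exactly ``inter_steps`` substitutions at private positions (so two
    non-root ancestors are ``2 * inter_steps`` apart).  Every other
    haplotype sits 1..``intra_steps`` substitutions from its group ancestor,
    again at fresh positions, so all planted pairwise distances are exact
    sums of step counts.  Returns the alignment and a truth table
    (haplotype id, group, steps from the group ancestor).
    """
    if n_haplotypes < n_groups or n_groups < 1:
        raise ValueError("need at least one haplotype per group")
    counts = [
        n_haplotypes // n_groups + (1 if g < n_haplotypes % n_groups else 0)
        for g in range(n_groups)
    ]
    if intra_steps == 0 and max(counts) > 1:
        raise ValueError(
            "intra_steps=0 cannot produce distinct within-group haplotypes"
        )
    rng = np.random.default_rng(seed)
    budget = (n_groups - 1) * inter_steps + (n_haplotypes - n_groups) * intra_steps
    if budget > length:
        raise ValueError(
            f"length {length} too short for the requested steps ({budget})"
        )
    free = list(rng.permutation(length))

    def take(k: int) -> np.ndarray:
        got = free[:k]
        del free[:k]
        return np.asarray(got, dtype=int)

    root = BASES[rng.integers(4, size=length)]
    sequences: dict[str, str] = {}
    rows = []
    for g in range(n_groups):
        ancestor = root if g == 0 else _mutate(root, take(inter_steps), rng)
        for h in range(counts[g]):
            if h == 0:
                seq, steps = ancestor, 0
            else:
                steps = int(rng.integers(1, intra_steps + 1))
                seq = _mutate(ancestor, take(steps), rng)
            hid = f"G{g + 1}_H{h + 1}"
            sequences[hid] = "".join(seq)
            rows.append({"haplotype_id": hid, "group": g + 1,
                         "steps_from_ancestor": steps})
    truth = pd.DataFrame(rows)
    return AlignedSequenceSet("other", sequences), truth


# ---------------------------------------------------------------------------
# Cross design
# ---------------------------------------------------------------------------

@dataclass
class CrossDesign:
    """Parameters of a synthetic heterospecific cross.

    Defaults mirror the empirical study system this generator emulates:
    36 + 20 parental specimens, 14 F1 hybrids, and a candidate panel of
    60 autosomal diagnostic, 51 X-linked diagnostic and 34 nondiagnostic
    loci, with taxon A as the maternal parent.  Nondiagnostic allele
    frequencies default to strongly divergent but unfixed values
    (parent-A allele at frequency U(0.8, 1) in A and U(0, 0.2) in B), which
    reproduces the observed ~86% F1 heterozygosity at such loci.
    """

    n_parent_a: int = 36
    n_parent_b: int = 20
    n_f1: int = 14
    n_bc1a: int = 0
    n_bc1b: int = 0
    n_f2: int = 0
    n_auto_diag: int = 60
    n_xlinked_diag: int = 51
    n_nondiag: int = 34
    nondiag_freqs: Sequence[tuple[float, float]] | None = None
    error_rate: float = 0.0
    missing_rate: float = 0.0
    maternal_taxon: str = "taxonA"
    taxon_a: str = "taxonA"
    taxon_b: str = "taxonB"
    hybrid_label: str = "hybrid"
    n_f1_males: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_parent_a", "n_parent_b", "n_f1", "n_bc1a", "n_bc1b",
                     "n_f2", "n_auto_diag", "n_xlinked_diag", "n_nondiag"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("error_rate", "missing_rate"):
            if not 0.0 <= getattr(self, name) <= 0.5:
                raise ValueError(f"{name} must be in [0, 0.5]")
        if self.maternal_taxon not in (self.taxon_a, self.taxon_b):
            raise ValueError("maternal_taxon must be one of the parent taxa")
        if self.nondiag_freqs is not None and len(self.nondiag_freqs) != self.n_nondiag:
            raise ValueError("nondiag_freqs must list one (pA, pB) per locus")
        if self.n_f1_males is not None and not 0 <= self.n_f1_males <= self.n_f1:
            raise ValueError("n_f1_males out of range")


@dataclass
class CrossResult:
    """Everything a downstream stage needs, plus planted truth."""

    genotypes: GenotypeMatrix
    records: list[SpecimenRecord]
    partition: TaxonPartition
    specimen_truth: pd.DataFrame   # specimen_id, true_class, sex, mito_taxon
    locus_truth: pd.DataFrame      # locus_id, category, a_is_alt, p_a, p_b
    mito_assignments: dict[str, str]
    mito: AlignedSequenceSet
    design: CrossDesign = field(repr=False, default=None)  # type: ignore[assignment]

    def truth_class(self, specimen_id: str) -> str:
        row = self.specimen_truth.loc[
            self.specimen_truth["specimen_id"] == specimen_id
        ]
        return row["true_class"].iloc[0]


class _Individual:
    """Allele-level representation: 1 = parent-A-associated allele."""

    __slots__ = ("auto_mat", "auto_pat", "x", "sex", "mito")

    def __init__(self, auto_mat, auto_pat, x, sex, mito):
        self.auto_mat = auto_mat    # (n_auto,) 0/1
        self.auto_pat = auto_pat
        self.x = x                  # (2, n_x) for females, (1, n_x) for males
        self.sex = sex
        self.mito = mito


def _make_parental(taxon_is_a: bool, sex: Sex, p_auto_a: np.ndarray,
                   p_x_a: np.ndarray, mito: str,
                   rng: np.random.Generator) -> _Individual:
    p_auto = p_auto_a if taxon_is_a else 1.0 - p_auto_a
    p_x = p_x_a if taxon_is_a else 1.0 - p_x_a
    auto_mat = (rng.random(p_auto.size) < p_auto).astype(np.int8)
    auto_pat = (rng.random(p_auto.size) < p_auto).astype(np.int8)
    n_chrom = 2 if sex == Sex.FEMALE else 1
    x = (rng.random((n_chrom, p_x.size)) < p_x).astype(np.int8)
    return _Individual(auto_mat, auto_pat, x, sex, mito)


def _cross(mother: _Individual, father: _Individual, sex: Sex,
           rng: np.random.Generator) -> _Individual:
    n_auto = mother.auto_mat.size
    pick_m = rng.integers(2, size=n_auto)
    auto_mat = np.where(pick_m == 0, mother.auto_mat, mother.auto_pat)
    pick_p = rng.integers(2, size=n_auto)
    auto_pat = np.where(pick_p == 0, father.auto_mat, father.auto_pat)
    n_x = mother.x.shape[1]
    pick_x = rng.integers(mother.x.shape[0], size=n_x)
    x_from_mother = mother.x[pick_x, np.arange(n_x)]
    if sex == Sex.MALE:
        x = x_from_mother[None, :]
    else:
        x = np.vstack([x_from_mother, father.x[0]])
    return _Individual(auto_mat.astype(np.int8), auto_pat.astype(np.int8),
                       x.astype(np.int8), sex, mother.mito)


def _a_dosage(ind: _Individual) -> np.ndarray:
    auto = ind.auto_mat + ind.auto_pat
    if ind.sex == Sex.MALE:
        x = 2 * ind.x[0]          # hemizygous, coded homozygous
    else:
        x = ind.x[0] + ind.x[1]
    return np.concatenate([auto, x]).astype(float)


def simulate_cross_dataset(design: CrossDesign) -> CrossResult:
    """Simulate genotypes, metadata, mitochondrial haplotypes and truth
    tables for a two-taxon cross (see module docstring)."""
    rng = np.random.default_rng(design.seed)
    maternal_is_a = design.maternal_taxon == design.taxon_a

    # --- locus layout: [auto diag, nondiag] autosomal + [x diag] X ---
    auto_ids = [f"AD{i + 1:04d}" for i in range(design.n_auto_diag)]
    nd_ids = [f"ND{i + 1:04d}" for i in range(design.n_nondiag)]
    x_ids = [f"XD{i + 1:04d}" for i in range(design.n_xlinked_diag)]
    loci = auto_ids + nd_ids + x_ids
    if design.nondiag_freqs is not None:
        nd_pa = np.array([p for p, _ in design.nondiag_freqs])
        nd_pb = np.array([q for _, q in design.nondiag_freqs])
    else:
        nd_pa = rng.uniform(0.8, 1.0, size=design.n_nondiag)
        nd_pb = rng.uniform(0.0, 0.2, size=design.n_nondiag)
    # frequency of the parent-A-associated allele, per autosomal locus
    p_auto_a = np.concatenate([np.ones(design.n_auto_diag), nd_pa])
    p_auto_b_carries_a = np.concatenate([np.zeros(design.n_auto_diag), nd_pb])
    p_x_a = np.ones(design.n_xlinked_diag)

    def freq_for(taxon_is_a: bool) -> tuple[np.ndarray, np.ndarray]:
        if taxon_is_a:
            return p_auto_a, p_x_a
        return p_auto_b_carries_a, np.zeros(design.n_xlinked_diag)

    def parental(taxon_is_a: bool, sex: Sex) -> _Individual:
        pa, px = freq_for(taxon_is_a)
        mito = design.taxon_a if taxon_is_a else design.taxon_b
        return _make_parental(True, sex, pa, px, mito, rng)

    def f1(sex: Sex) -> _Individual:
        mother = parental(maternal_is_a, Sex.FEMALE)
        father = parental(not maternal_is_a, Sex.MALE)
        return _cross(mother, father, sex, rng)

    def offspring(cls: str, sex: Sex) -> _Individual:
        if cls == "F1":
            return f1(sex)
        if cls == "BC1A":
            return _cross(f1(Sex.FEMALE), parental(True, Sex.MALE), sex, rng)
        if cls == "BC1B":
            return _cross(f1(Sex.FEMALE), parental(False, Sex.MALE), sex, rng)
        if cls == "F2":
            return _cross(f1(Sex.FEMALE), f1(Sex.MALE), sex, rng)
        raise ValueError(cls)

    # --- specimens ---
    groups = [
        ("parental_A", "A", design.n_parent_a),
        ("parental_B", "B", design.n_parent_b),
        ("F1", "F1", design.n_f1),
        ("BC1A", "BC1A", design.n_bc1a),
        ("BC1B", "BC1B", design.n_bc1b),
        ("F2", "F2", design.n_f2),
    ]
    dosage_rows: list[np.ndarray] = []
    specimen_ids: list[str] = []
    records: list[SpecimenRecord] = []
    truth_rows = []
    for cls, prefix, n in groups:
        for i in range(n):
            if cls == "F1" and design.n_f1_males is not None:
                sex = Sex.MALE if i < design.n_f1_males else Sex.FEMALE
            else:
                sex = Sex.MALE if i % 2 == 0 else Sex.FEMALE
            if cls == "parental_A":
                ind = parental(True, sex)
                label = design.taxon_a
            elif cls == "parental_B":
                ind = parental(False, sex)
                label = design.taxon_b
            else:
                ind = offspring(cls, sex)
                label = design.hybrid_label
            sid = f"{prefix}{i + 1:05d}"
            specimen_ids.append(sid)
            dosage_rows.append(_a_dosage(ind))
            records.append(
                SpecimenRecord(sid, label, sex, locality="synthetic")
            )
            truth_rows.append(
                {"specimen_id": sid, "true_class": cls, "sex": sex.value,
                 "mito_taxon": ind.mito, "taxon_label": label}
            )

    # --- orientation + allele identities ---
    a_is_alt = rng.random(len(loci)) < 0.5
    ref_alt_idx = np.array(
        [rng.choice(4, size=2, replace=False) for _ in loci]
    )
    ref = pd.Series(BASES[ref_alt_idx[:, 0]], index=loci, dtype=object)
    alt = pd.Series(BASES[ref_alt_idx[:, 1]], index=loci, dtype=object)
    dos_a = np.vstack(dosage_rows) if dosage_rows else np.empty((0, len(loci)))
    dos_alt = np.where(a_is_alt[None, :], dos_a, 2.0 - dos_a)
    calls = pd.DataFrame(dos_alt, index=specimen_ids, columns=loci)
    gm = GenotypeMatrix(calls, ref, alt)
    if design.error_rate > 0 or design.missing_rate > 0:
        noise_seed = int(rng.integers(2**31))
        gm = add_genotyping_noise(
            gm, design.error_rate, design.missing_rate, noise_seed
        )

    category = (
        ["autosomal_diagnostic"] * design.n_auto_diag
        + ["nondiagnostic"] * design.n_nondiag
        + ["x_linked_diagnostic"] * design.n_xlinked_diag
    )
    locus_truth = pd.DataFrame(
        {
            "locus_id": loci,
            "category": category,
            "a_is_alt": a_is_alt,
            "ref": ref.to_numpy(),
            "alt": alt.to_numpy(),
            "p_a": np.concatenate([p_auto_a, p_x_a]),
            "p_b": np.concatenate(
                [p_auto_b_carries_a, np.zeros(design.n_xlinked_diag)]
            ),
        }
    )
    specimen_truth = pd.DataFrame(truth_rows)

    # --- mitochondrial haplotypes (maternal inheritance) ---
    mito_assignments = dict(
        zip(specimen_truth["specimen_id"], specimen_truth["mito_taxon"])
    )
    mito = _mito_alignment(specimen_truth, design, rng)

    partition = TaxonPartition.from_records(records)
    return CrossResult(
        genotypes=gm,
        records=records,
        partition=partition,
        specimen_truth=specimen_truth,
        locus_truth=locus_truth,
        mito_assignments=mito_assignments,
        mito=mito,
        design=design,
    )


def _mito_alignment(specimen_truth: pd.DataFrame, design: CrossDesign,
                    rng: np.random.Generator,
                    length: int = 300, divergence_steps: int = 15) -> AlignedSequenceSet:
    """Two mitochondrial haplotypes, one per parental lineage, copied down
    the maternal line of every specimen."""
    root = BASES[rng.integers(4, size=length)]
    positions = rng.choice(length, size=divergence_steps, replace=False)
    other = _mutate(root, positions, rng)
    hap = {design.taxon_a: "".join(root), design.taxon_b: "".join(other)}
    sequences = {
        row.specimen_id: hap[row.mito_taxon]
        for row in specimen_truth.itertuples(index=False)
    }
    return AlignedSequenceSet("COI", sequences)


# ---------------------------------------------------------------------------
# Noise + read-count simulation
# ---------------------------------------------------------------------------

def add_genotyping_noise(
    gm: GenotypeMatrix, error_rate: float, missing_rate: float, seed: int = 0
) -> GenotypeMatrix:
    """Perturb each called genotype to an adjacent dosage with probability
    ``error_rate`` (heterozygotes move up or down with equal probability)
    and set it missing with probability ``missing_rate``."""
    for name, value in (("error_rate", error_rate), ("missing_rate", missing_rate)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    values = gm.values.copy()
    called = ~np.isnan(values)
    flip = called & (rng.random(values.shape) < error_rate)
    direction = rng.integers(2, size=values.shape)  # for heterozygotes
    perturbed = np.where(
        values == 0, 1.0,
        np.where(values == 2, 1.0, np.where(direction == 0, 0.0, 2.0)),
    )
    values = np.where(flip, perturbed, values)
    drop = called & (rng.random(values.shape) < missing_rate)
    values = np.where(drop, np.nan, values)
    calls = pd.DataFrame(values, index=gm.specimens, columns=gm.loci)
    return GenotypeMatrix(calls, gm.ref_allele, gm.alt_allele)


def simulate_site_counts(
    gm_true: GenotypeMatrix,
    depth_mean: float,
    error_rate: float,
    seed: int = 0,
) -> SiteCountTable:
    """Simulate per-site read counts from true genotypes.

    Depth is Poisson(``depth_mean``) per specimen x site; reads draw from
    the genotype's allele mix (50/50 for heterozygotes) and each read
    miscalls to a uniformly chosen other base with probability
    ``error_rate``.  Missing genotypes yield zero coverage."""
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    rng = np.random.default_rng(seed)
    base_index = {b: i for i, b in enumerate("ACGT")}
    rows = []
    for sid in gm_true.specimens:
        for locus in gm_true.loci:
            counts = np.zeros(4, dtype=int)
            d = gm_true.calls.at[sid, locus]
            if not np.isnan(d):
                ref = gm_true.ref_allele[locus]
                alt = gm_true.alt_allele[locus]
                depth = rng.poisson(depth_mean)
                if depth > 0:
                    n_alt = (
                        depth if d == 2 else 0 if d == 0
                        else rng.binomial(depth, 0.5)
                    )
                    for base, n in ((alt, n_alt), (ref, depth - n_alt)):
                        if n == 0:
                            continue
                        n_err = rng.binomial(n, error_rate) if error_rate > 0 else 0
                        counts[base_index[base]] += n - n_err
                        for _ in range(n_err):
                            wrong = [b for b in "ACGT" if b != base]
                            counts[base_index[wrong[rng.integers(3)]]] += 1
            rows.append(
                {"specimen_id": sid, "site_id": locus,
                 "A": counts[0], "C": counts[1],
                 "G": counts[2], "T": counts[3]}
            )
    return SiteCountTable(pd.DataFrame(rows))
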