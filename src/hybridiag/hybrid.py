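"""Hybrid-origin diagnosis from genome-wide SNP genotypes.

The pipeline: count SNPs shared between a focal taxon and candidate
parents; place specimens by principal-coordinate analysis of genotypic
distances; build a diagnostic panel of loci fixed for alternate alleles in
the two parental taxa; summarise each putative hybrid by its hybrid index
(fraction of panel alleles from parent A) and interspecific heterozygosity;
classify specimens as parental, F1, backcross, or later-generation hybrids;
flag sex-linked panel loci under X0 sex determination (males hemizygous,
X maternally inherited); and infer the maternal parent from mitochondrial
haplotype assignments.

Expected error-free signatures at autosomal panel loci:

====================  ===========  ==============
class                 hybrid index heterozygosity
====================  ===========  ==============
parental A            1.0          0.0
parental B            0.0          0.0
F1                    0.5          1.0
BC1 (to A)            E = 0.75     E = 0.5
F2                    E = 0.5      E = 0.5
====================  ===========  ==============

A first-generation backcross additionally carries *no* homozygote for the
non-recurrent parent's allele, which is what separates it from an F2; the
classifier uses that signature alongside the 75% index rule.  The
later-generation rung keeps the conventional 25%-heterozygosity ceiling
even though the Mendelian F2 expectation is 50%; see docs/methods.md.

The sklearn-style estimators :class:`HybridClassifier` (fit = panel
construction on parental genotypes, predict = classification ladder) and
:class:`GenotypePCoA` are the core; the module-level functions wrap them
over the domain containers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa
from sklearn.base import BaseEstimator

from .config import Config
from .model import GenotypeMatrix, Sex, SpecimenRecord, TaxonPartition

logger = logging.getLogger(__name__)

HYBRID_CLASSES = (
    "parental_A", "parental_B", "F1", "backcross_A", "backcross_B",
    "later_generation", "unresolved",
)


# ---------------------------------------------------------------------------
# Shared-SNP counts
# ---------------------------------------------------------------------------

def shared_snp_counts(
    gm: GenotypeMatrix,
    part: TaxonPartition,
    focal_taxon: str,
    other_taxa: Sequence[str],
    cfg: Config | None = None,
) -> dict[str, int]:
    """Number of sites carrying a non-reference allele in both the focal
    taxon and each comparison taxon, over sites passing the minimum call
    rate.  Parental candidates are expected to share the most."""
    cfg = cfg or Config()
    for taxon in (focal_taxon, *other_taxa):
        if not part.members(taxon):
            raise ValueError(f"unknown or empty taxon: {taxon!r}")
    rate = gm.call_rate()
    loci = [l for l in gm.loci if rate[l] >= cfg.min_call_rate]
    sub = gm.subset(loci=loci)

    def snp_mask(taxon: str) -> np.ndarray:
        members = [s for s in part.members(taxon) if s in sub.calls.index]
        block = sub.calls.loc[members].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nansum(block > 0, axis=0) > 0

    focal = snp_mask(focal_taxon)
    return {t: int((focal & snp_mask(t)).sum()) for t in other_taxa}


# ---------------------------------------------------------------------------
# Principal-coordinate analysis
# ---------------------------------------------------------------------------

def genotypic_distance_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise genotypic distance: root mean squared allele-count
    difference over co-called loci."""
    n = values.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(values[i]) & ~np.isnan(values[j])
            if not both.any():
                raise ValueError(
                    f"specimens {i} and {j} share no called loci; "
                    "subset to a higher call rate first"
                )
            diff = values[i, both] - values[j, both]
            d[i, j] = d[j, i] = np.sqrt(np.mean(diff**2))
    return d


class GenotypePCoA(BaseEstimator):
    """Classical principal-coordinate analysis of genotypic distances.

    Transformer-shaped: ``fit_transform(X)`` takes a specimen x locus dosage
    array (NaN = missing) and returns coordinates on the leading axes.
    Axes are ordered by eigenvalue and each axis's sign is fixed so its
    largest-magnitude coordinate is positive.

    Attributes (after fit): ``coordinates_``, ``eigenvalues_``,
    ``proportion_explained_``.
    """

    def __init__(self, n_axes: int = 2):
        self.n_axes = n_axes

    def fit(self, X, y=None) -> "GenotypePCoA":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 3:
            raise ValueError("PCoA requires at least 3 specimens")
        dist = genotypic_distance_matrix(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = _skbio_pcoa(DistanceMatrix(dist), number_of_dimensions=0)
        coords = result.samples.to_numpy()[:, : self.n_axes]
        # pad in the degenerate case of fewer axes than requested
        if coords.shape[1] < self.n_axes:
            pad = np.zeros((coords.shape[0], self.n_axes - coords.shape[1]))
            coords = np.hstack([coords, pad])
        for k in range(coords.shape[1]):
            col = coords[:, k]
            if col[np.argmax(np.abs(col))] < 0:
                coords[:, k] = -col
        self.coordinates_ = coords
        eig = result.eigvals.to_numpy()
        self.eigenvalues_ = eig[: self.n_axes]
        total = eig[eig > 0].sum()
        self.proportion_explained_ = (
            np.clip(self.eigenvalues_, 0, None) / total if total > 0
            else np.zeros(self.n_axes)
        )
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).coordinates_


def pcoa_coordinates(
    gm: GenotypeMatrix,
    specimens: Sequence[str] | None = None,
    n_axes: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCoA coordinates and eigenvalues for the given specimens."""
    sub = gm.subset(specimens=list(specimens) if specimens is not None else None)
    est = GenotypePCoA(n_axes=n_axes).fit(sub.values)
    coords = pd.DataFrame(
        est.coordinates_,
        index=sub.specimens,
        columns=[f"axis{k + 1}" for k in range(n_axes)],
    )
    return coords, est.eigenvalues_


# ---------------------------------------------------------------------------
# Diagnostic panel + hybrid metrics
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticPanel:
    """Loci fixed for alternate alleles in the two parental taxa.

    ``a_is_alt`` records the orientation: True when the alternate allele is
    the parent-A allele at that locus.  ``a_allele`` gives the nucleotide
    when the source format carried allele identities."""

    loci: list[str]
    a_is_alt: dict[str, bool]
    parent_a: str
    parent_b: str
    call_rate_requirement: float
    a_allele: dict[str, str] = field(default_factory=dict)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset(self, loci: Sequence[str]) -> "DiagnosticPanel":
        """Restrict the panel to the given loci (e.g. after removing
        sex-linked candidates, whose hemizygous male genotypes would bias
        autosomal hybrid metrics)."""
        keep = [l for l in self.loci if l in set(loci)]
        return DiagnosticPanel(
            loci=keep,
            a_is_alt={l: self.a_is_alt[l] for l in keep},
            parent_a=self.parent_a,
            parent_b=self.parent_b,
            call_rate_requirement=self.call_rate_requirement,
            a_allele={l: v for l, v in self.a_allele.items() if l in set(keep)},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": self.loci,
                "parentA_allele_is_alt": [self.a_is_alt[l] for l in self.loci],
                "parentA_allele": [self.a_allele.get(l, "N") for l in self.loci],
            }
        )


@dataclass
class HybridMetrics:
    """Per-specimen hybrid diagnosis at a diagnostic panel."""

    specimen_id: str
    n_loci_called: int
    index_a: float      # fraction of panel alleles from parent A
    het_frac: float     # fraction of called panel loci heterozygous
    hom_a_frac: float   # fraction homozygous for the parent-A allele
    hom_b_frac: float   # fraction homozygous for the parent-B allele
    hybrid_class: str | None = None


class HybridClassifier(BaseEstimator):
    """Fixed-difference panel construction and hybrid-class assignment,
    sklearn-style.

    ``fit(X, y)`` takes parental reference genotypes (dosage array with NaN
    missing; ``y`` holds exactly two parental labels) and learns the panel:
    loci whose call rate meets ``panel_call_rate`` and where every called
    parent-A genotype is homozygous for one allele and every called
    parent-B genotype homozygous for the other.  ``predict(X)`` computes
    per-specimen hybrid index and heterozygosity over the panel and walks
    the classification ladder parental → F1 → backcross →
    later-generation → unresolved.

    Attributes (after fit): ``panel_mask_``, ``a_is_alt_``, ``classes_``,
    ``parent_a_``, ``parent_b_``, ``n_features_in_``.
    """

    def __init__(
        self,
        parent_a: str | None = None,
        parent_b: str | None = None,
        panel_call_rate: float = 1.0,
        parental_index_min: float = 0.95,
        f1_het_min: float = 0.95,
        backcross_index: float = 0.75,
        backcross_hom_tol: float = 0.05,
        latergen_het: float = 0.25,
    ):
        self.parent_a = parent_a
        self.parent_b = parent_b
        self.panel_call_rate = panel_call_rate
        self.parental_index_min = parental_index_min
        self.f1_het_min = f1_het_min
        self.backcross_index = backcross_index
        self.backcross_hom_tol = backcross_hom_tol
        self.latergen_het = latergen_het

    @classmethod
    def from_config(cls, cfg: Config, parent_a=None, parent_b=None):
        return cls(
            parent_a=parent_a,
            parent_b=parent_b,
            panel_call_rate=cfg.panel_call_rate,
            parental_index_min=cfg.parental_index_min,
            f1_het_min=cfg.f1_het_min,
            backcross_index=cfg.backcross_index,
            backcross_hom_tol=cfg.backcross_hom_tol,
            latergen_het=cfg.latergen_het,
        )

    # -- fitting ------------------------------------------------------

    def fit(self, X, y) -> "HybridClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        labels = list(dict.fromkeys(y))
        parent_a = self.parent_a if self.parent_a is not None else labels[0]
        parent_b = self.parent_b if self.parent_b is not None else (
            labels[1] if len(labels) > 1 else None
        )
        if parent_a not in labels or parent_b not in labels:
            raise ValueError(
                f"parental labels {parent_a!r}/{parent_b!r} not both present"
            )
        mask_a = y == parent_a
        mask_b = y == parent_b
        if mask_a.sum() == 0 or mask_b.sum() == 0:
            raise ValueError("both parental taxa need at least one specimen")
        if mask_a.sum() < 2 or mask_b.sum() < 2:
            warnings.warn(
                "fewer than 2 specimens in a parental taxon; fixed "
                "differences may be sampling artifacts", stacklevel=2,
            )
        A, B = X[mask_a], X[mask_b]
        call_rate = 1.0 - np.isnan(X).mean(axis=0)
        rate_ok = call_rate >= self.panel_call_rate - 1e-12

        def fixed_for(block: np.ndarray, value: float) -> np.ndarray:
            called = ~np.isnan(block)
            return (called.sum(axis=0) > 0) & np.all(
                np.isnan(block) | (block == value), axis=0
            )

        a_ref, a_alt = fixed_for(A, 0.0), fixed_for(A, 2.0)
        b_ref, b_alt = fixed_for(B, 0.0), fixed_for(B, 2.0)
        a_is_alt = a_alt & b_ref
        a_is_ref = a_ref & b_alt
        self.panel_mask_ = rate_ok & (a_is_alt | a_is_ref)
        self.a_is_alt_ = a_is_alt[self.panel_mask_]
        self.parent_a_ = parent_a
        self.parent_b_ = parent_b
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.asarray(HYBRID_CLASSES)
        return self

    # -- prediction ---------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "panel_mask_"):
            raise RuntimeError("estimator is not fitted")

    def metrics(self, X) -> pd.DataFrame:
        """Hybrid index, heterozygosity and homozygote fractions per row."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of loci than fit data")
        panel = X[:, self.panel_mask_]
        # re-orient to parent-A allele dosage
        dos_a = np.where(self.a_is_alt_, panel, 2.0 - panel)
        called = ~np.isnan(dos_a)
        n_called = called.sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            index_a = np.nansum(dos_a, axis=1) / (2.0 * n_called)
            het = np.nansum(dos_a == 1.0, axis=1) / n_called
            hom_a = np.nansum(dos_a == 2.0, axis=1) / n_called
            hom_b = np.nansum(dos_a == 0.0, axis=1) / n_called
        return pd.DataFrame(
            {
                "n_loci_called": n_called,
                "index_a": index_a,
                "het_frac": het,
                "hom_a_frac": hom_a,
                "hom_b_frac": hom_b,
            }
        )

    def _classify_row(self, n_called, index_a, het, hom_a, hom_b) -> str:
        if n_called == 0:
            return "unresolved"
        par_tol = 1.0 - self.parental_index_min
        if het <= par_tol:
            if index_a >= self.parental_index_min:
                return "parental_A"
            if index_a <= par_tol:
                return "parental_B"
        if het >= self.f1_het_min:
            return "F1"
        if index_a > 0.5 and (
            index_a >= self.backcross_index or hom_b <= self.backcross_hom_tol
        ):
            return "backcross_A"
        if index_a < 0.5 and (
            index_a <= 1.0 - self.backcross_index
            or hom_a <= self.backcross_hom_tol
        ):
            return "backcross_B"
        if het <= self.latergen_het:
            return "later_generation"
        return "unresolved"

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        m = self.metrics(X)
        out = [
            self._classify_row(
                row.n_loci_called, row.index_a, row.het_frac,
                row.hom_a_frac, row.hom_b_frac,
            )
            for row in m.itertuples(index=False)
        ]
        return np.asarray(out, dtype=object)


# ---------------------------------------------------------------------------
# Function wrappers over the domain containers
# ---------------------------------------------------------------------------

def build_fixed_panel(
    gm: GenotypeMatrix,
    part: TaxonPartition,
    parent_a: str,
    parent_b: str,
    cfg: Config | None = None,
) -> DiagnosticPanel:
    """Build the fixed-difference diagnostic panel from parental specimens.

    The call-rate requirement (default 100%) is evaluated over *all*
    specimens in the matrix, matching the idea that a diagnostic panel must
    be scoreable in every individual."""
    cfg = cfg or Config()
    members_a = [s for s in part.members(parent_a) if s in gm.calls.index]
    members_b = [s for s in part.members(parent_b) if s in gm.calls.index]
    if not members_a or not members_b:
        raise ValueError(
            f"empty parental taxon among {parent_a!r}, {parent_b!r}"
        )
    est = HybridClassifier.from_config(cfg, parent_a=parent_a, parent_b=parent_b)
    parents = members_a + members_b
    y = [parent_a] * len(members_a) + [parent_b] * len(members_b)
    # call-rate requirement uses the full matrix, not just parents
    full_rate = gm.call_rate().to_numpy()
    est.fit(gm.subset(specimens=parents).values, y)
    est.panel_mask_ &= full_rate >= cfg.panel_call_rate - 1e-12
    # recompute orientation subset after the extra masking
    X = gm.subset(specimens=parents).values
    a_block = X[: len(members_a)]
    a_alt_fixed = np.all(np.isnan(a_block) | (a_block == 2.0), axis=0)
    est.a_is_alt_ = a_alt_fixed[est.panel_mask_]
    loci = [l for l, keep in zip(gm.loci, est.panel_mask_) if keep]
    a_is_alt = {l: bool(v) for l, v in zip(loci, est.a_is_alt_)}
    a_allele = {
        l: (gm.alt_allele[l] if a_is_alt[l] else gm.ref_allele[l])
        for l in loci
    }
    return DiagnosticPanel(
        loci=loci,
        a_is_alt=a_is_alt,
        parent_a=parent_a,
        parent_b=parent_b,
        call_rate_requirement=cfg.panel_call_rate,
        a_allele=a_allele,
    )


def _panel_estimator(panel: DiagnosticPanel, gm: GenotypeMatrix,
                     cfg: Config) -> HybridClassifier:
    """Wrap an existing panel in a fitted estimator over gm's locus order."""
    est = HybridClassifier.from_config(
        cfg, parent_a=panel.parent_a, parent_b=panel.parent_b
    )
    mask = np.asarray([l in set(panel.loci) for l in gm.loci])
    est.panel_mask_ = mask
    est.a_is_alt_ = np.asarray(
        [panel.a_is_alt[l] for l in gm.loci if l in set(panel.loci)]
    )
    est.parent_a_ = panel.parent_a
    est.parent_b_ = panel.parent_b
    est.n_features_in_ = gm.n_loci
    est.classes_ = np.asarray(HYBRID_CLASSES)
    return est


def hybrid_metrics(
    gm: GenotypeMatrix,
    panel: DiagnosticPanel,
    specimen: str,
    cfg: Config | None = None,
) -> HybridMetrics:
    """Hybrid index and heterozygosity of one specimen at the panel loci."""
    cfg = cfg or Config()
    est = _panel_estimator(panel, gm, cfg)
    row = est.metrics(gm.subset(specimens=[specimen]).values).iloc[0]
    if row.n_loci_called == 0:
        warnings.warn(
            f"specimen {specimen!r} has no called panel loci; unresolved",
            stacklevel=2,
        )
    return HybridMetrics(
        specimen_id=specimen,
        n_loci_called=int(row.n_loci_called),
        index_a=float(row.index_a),
        het_frac=float(row.het_frac),
        hom_a_frac=float(row.hom_a_frac),
        hom_b_frac=float(row.hom_b_frac),
    )


def classify_specimen(m: HybridMetrics, cfg: Config | None = None) -> str:
    """Assign a hybrid class from metrics via the classification ladder.

    The ladder is total and ordered — exactly one class per specimen:
    parental (index beyond ``parental_index_min`` with matching near-zero
    heterozygosity), F1 (heterozygosity >= ``f1_het_min``), backcross
    (index on one side of 0.5 and either beyond ``backcross_index`` or
    carrying no more than ``backcross_hom_tol`` opposite-parent
    homozygotes), later-generation (heterozygosity <= ``latergen_het``),
    else unresolved."""
    cfg = cfg or Config()
    est = HybridClassifier.from_config(cfg)
    label = est._classify_row(
        m.n_loci_called, m.index_a, m.het_frac, m.hom_a_frac, m.hom_b_frac
    )
    m.hybrid_class = label
    return label


def hybrid_report(
    gm: GenotypeMatrix,
    panel: DiagnosticPanel,
    specimens: Sequence[str] | None = None,
    cfg: Config | None = None,
) -> pd.DataFrame:
    """Metrics + class for many specimens as a tidy DataFrame."""
    cfg = cfg or Config()
    specimens = list(specimens) if specimens is not None else gm.specimens
    est = _panel_estimator(panel, gm, cfg)
    X = gm.subset(specimens=specimens).values
    table = est.metrics(X)
    table.insert(0, "specimen_id", specimens)
    table["hybrid_class"] = est.predict(X)
    return table


# ---------------------------------------------------------------------------
# Sex linkage (X0)
# ---------------------------------------------------------------------------

@dataclass
class SexLinkageReport:
    """Per-locus sex-linkage status with per-sex genotype tallies.

    Under X0 sex determination a male's single X comes from his mother, so
    at an X-linked panel locus every hybrid male types homozygous for the
    maternal parent's allele while every hybrid female is heterozygous."""

    table: pd.DataFrame  # index = locus, columns = status + tallies
    maternal_parent: str

    def loci_with_status(self, status: str) -> list[str]:
        return list(self.table.index[self.table["status"] == status])

    def summary(self) -> dict[str, int]:
        counts = self.table["status"].value_counts().to_dict()
        return {
            s: int(counts.get(s, 0))
            for s in ("autosomal_diagnostic", "sex_linked", "nondiagnostic")
        }


def detect_sex_linked_loci(
    gm: GenotypeMatrix,
    panel: DiagnosticPanel,
    records: Sequence[SpecimenRecord] | Mapping[str, Sex],
    hybrids: Sequence[str],
    maternal_parent: str,
    cfg: Config | None = None,
    candidate_loci: Sequence[str] | None = None,
) -> SexLinkageReport:
    """Partition panel-candidate loci by the genotype pattern they show in
    sexed hybrid specimens.

    ``autosomal_diagnostic``: every called hybrid is heterozygous.
    ``sex_linked``: every called hybrid male is homozygous for the
    maternal parent's allele and every called hybrid female heterozygous
    (up to ``sexlink_max_mismatches`` exceptions per locus).
    ``nondiagnostic``: anything else.
    """
    cfg = cfg or Config()
    if maternal_parent not in (panel.parent_a, panel.parent_b):
        raise ValueError(
            f"maternal parent {maternal_parent!r} is not a panel parent"
        )
    if isinstance(records, Mapping):
        sex_of = dict(records)
    else:
        sex_of = {r.specimen_id: r.sex for r in records}
    males = [s for s in hybrids if sex_of.get(s) == Sex.MALE]
    females = [s for s in hybrids if sex_of.get(s) == Sex.FEMALE]
    if not males and not females:
        raise ValueError("no sexed hybrid specimens")
    loci = list(candidate_loci) if candidate_loci is not None else panel.loci
    maternal_is_a = maternal_parent == panel.parent_a
    tol = cfg.sexlink_max_mismatches
    rows = []
    for locus in loci:
        a_is_alt = panel.a_is_alt[locus]
        maternal_hom = (2.0 if a_is_alt else 0.0) if maternal_is_a else (
            0.0 if a_is_alt else 2.0
        )
        male_calls = gm.calls.loc[males, locus].dropna()
        female_calls = gm.calls.loc[females, locus].dropna()
        all_calls = gm.calls.loc[list(hybrids), locus].dropna()
        m_hom_mat = int((male_calls == maternal_hom).sum())
        m_het = int((male_calls == 1.0).sum())
        m_other = len(male_calls) - m_hom_mat - m_het
        f_het = int((female_calls == 1.0).sum())
        f_other = len(female_calls) - f_het
        n_het_all = int((all_calls == 1.0).sum())
        if len(all_calls) - n_het_all <= tol and len(all_calls) > 0:
            status = "autosomal_diagnostic"
        elif (
            len(male_calls) > 0
            and (len(male_calls) - m_hom_mat) <= tol
            and f_other <= tol
        ):
            status = "sex_linked"
        else:
            status = "nondiagnostic"
        rows.append(
            {
                "locus": locus, "status": status,
                "males_hom_maternal": m_hom_mat, "males_het": m_het,
                "males_other": m_other, "females_het": f_het,
                "females_other": f_other,
                "n_males_called": len(male_calls),
                "n_females_called": len(female_calls),
            }
        )
    table = pd.DataFrame(rows).set_index("locus")
    return SexLinkageReport(table, maternal_parent)


# ---------------------------------------------------------------------------
# Maternal-parent inference
# ---------------------------------------------------------------------------

@dataclass
class MaternalInference:
    """Which parental taxon mothered the hybrids, from mitochondrial
    haplotype cluster assignments (mtDNA is maternally inherited)."""

    maternal_parent: str         # taxon label, or "bidirectional"
    counts: dict[str, int]       # hybrids per parental mito cluster
    excluded: list[str]          # hybrids lacking a mito assignment

    @property
    def direction(self) -> str:
        if self.maternal_parent == "bidirectional":
            return "hybrids arise from crosses in both directions"
        return (
            f"hybrids are progeny of female {self.maternal_parent} "
            "(mothers) crossed with males of the other parental taxon"
        )


def infer_maternal_parent(
    mito_assignments: Mapping[str, str],
    panel: DiagnosticPanel,
    hybrids: Sequence[str],
) -> MaternalInference:
    """Infer the maternal parent as the parental taxon whose mitochondrial
    cluster contains the hybrids' haplotypes; a split implies bidirectional
    crossing.  Hybrids without an assignment are excluded and logged."""
    counts = {panel.parent_a: 0, panel.parent_b: 0}
    excluded = []
    for h in hybrids:
        taxon = mito_assignments.get(h)
        if taxon is None:
            excluded.append(h)
        elif taxon in counts:
            counts[taxon] += 1
        else:
            raise ValueError(
                f"hybrid {h!r} assigned to non-parental cluster {taxon!r}"
            )
    if excluded:
        logger.info("hybrids without mito assignment excluded: %s", excluded)
    assigned = [t for t, c in counts.items() if c > 0]
    if not assigned:
        raise ValueError("no hybrid has a mitochondrial assignment")
    maternal = assigned[0] if len(assigned) == 1 else "bidirectional"
    return MaternalInference(maternal, counts, excluded)
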