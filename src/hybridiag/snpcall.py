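"""Genotype calling from per-site read counts and population-level site
filtering.

Calling rule, applied per specimen x site (reads are assumed base-quality
filtered upstream):

* homozygote — the most common allele carries at least ``allele_support_frac``
  (default 80%) of the reads and at least ``min_unique_reads`` (default 5)
  unique reads;
* heterozygote — otherwise, the two most common alleles jointly carry at
  least the support fraction, the most common allele meets the unique-read
  floor, and the second allele was observed;
* missing — otherwise.

Site filters, applied to the called genotype matrix: minimum minor-allele
frequency (1%), a heterozygosity rate constrained to at most twice the
product of the two allele frequencies, and a minimum call rate (20%).
Because the observed heterozygote fraction fluctuates around 2pq even at
Hardy–Weinberg equilibrium, the 2pq ceiling is enforced as a one-sided
exact binomial test at ``het_excess_alpha`` (default 0.01) rather than as a
knife-edge inequality; collapsed-paralog artifacts (every specimen
heterozygous) fail it at any realistic sample size, while genuine HWE sites
almost never do.  Setting ``het_excess_alpha`` to 1.0 restores the literal
bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .config import Config
from .model import GenotypeMatrix, SiteCountTable

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SiteCall:
    """A genotype call at one specimen x site: the allele pair (hom calls
    repeat the allele) or None for missing."""

    alleles: tuple[str, str] | None

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]

    def dosage(self, ref: str, alt: str) -> float:
        """Alternate-allele dosage relative to (ref, alt); NaN when the call
        is missing or involves an out-of-model allele."""
        if self.alleles is None:
            return float("nan")
        if not set(self.alleles) <= {ref, alt}:
            return float("nan")
        return float(sum(1 for a in self.alleles if a == alt))


def call_genotype_at_site(counts: Mapping[str, int], cfg: Config) -> SiteCall:
    """Call one genotype from base read counts (see module docstring)."""
    tallies = []
    for base in BASES:
        n = int(counts.get(base, 0))
        if n < 0:
            raise ValueError(f"negative read count for {base}: {n}")
        tallies.append((n, base))
    extra = set(counts) - set(BASES)
    if extra:
        raise ValueError(f"counts must be over A/C/G/T, got {sorted(extra)}")
    # sort by count desc, then alphabetically for determinism
    tallies.sort(key=lambda t: (-t[0], t[1]))
    total = sum(n for n, _ in tallies)
    if total == 0:
        return SiteCall(None)
    (n1, a1), (n2, a2) = tallies[0], tallies[1]
    if n1 / total >= cfg.allele_support_frac and n1 >= cfg.min_unique_reads:
        return SiteCall((a1, a1))
    if cfg.het_support_rule == "union":
        support_ok = (n1 + n2) / total >= cfg.allele_support_frac
    else:  # "each": each allele carries half of the required fraction
        frac = cfg.allele_support_frac / 2.0
        support_ok = n1 / total >= frac and n2 / total >= frac
    reads_ok = n1 >= cfg.min_unique_reads and n2 >= 1
    if cfg.het_min_reads_each:
        reads_ok = n1 >= cfg.min_unique_reads and n2 >= cfg.min_unique_reads
    if support_ok and reads_ok:
        return SiteCall(tuple(sorted((a1, a2))))  # type: ignore[arg-type]
    return SiteCall(None)


def call_matrix(
    table: SiteCountTable,
    cfg: Config,
    ref_alt: Mapping[str, tuple[str, str]] | None = None,
) -> GenotypeMatrix:
    """Call every specimen x site in a count table into a dosage matrix.

    When ``ref_alt`` is not supplied, the reference allele at a site is the
    majority allele among all calls there and the alternate is the other
    observed allele; calls carrying a third allele become missing.
    """
    specimens = table.specimens
    sites = table.sites
    calls: dict[tuple[str, str], SiteCall] = {}
    for row in table.counts.itertuples(index=False):
        counts = {b: getattr(row, b) for b in BASES}
        calls[(row.specimen_id, row.site_id)] = call_genotype_at_site(counts, cfg)
    ref_list, alt_list = [], []
    values = np.full((len(specimens), len(sites)), np.nan)
    for j, site in enumerate(sites):
        if ref_alt is not None and site in ref_alt:
            ref, alt = ref_alt[site]
        else:
            allele_counts: dict[str, int] = {}
            for s in specimens:
                call = calls.get((s, site))
                if call is not None and call.alleles is not None:
                    for a in call.alleles:
                        allele_counts[a] = allele_counts.get(a, 0) + 1
            ranked = sorted(allele_counts, key=lambda a: (-allele_counts[a], a))
            ref = ranked[0] if ranked else "N"
            alt = ranked[1] if len(ranked) > 1 else "N"
        ref_list.append(ref)
        alt_list.append(alt)
        for i, s in enumerate(specimens):
            call = calls.get((s, site))
            if call is not None:
                values[i, j] = call.dosage(ref, alt)
    frame = pd.DataFrame(values, index=specimens, columns=sites)
    return GenotypeMatrix(
        frame,
        pd.Series(ref_list, index=sites, dtype=object),
        pd.Series(alt_list, index=sites, dtype=object),
    )


# ---------------------------------------------------------------------------
# Site filtering
# ---------------------------------------------------------------------------

STATUSES = ("retained", "fail_call_rate", "monomorphic", "fail_maf",
            "fail_het_constraint")


@dataclass
class SiteFilterReport:
    """Per-site filter outcome; every input site gets exactly one status."""

    status: pd.Series  # index = locus ids, values in STATUSES

    def summary(self) -> dict[str, int]:
        counts = self.status.value_counts().to_dict()
        return {s: int(counts.get(s, 0)) for s in STATUSES}

    def to_tsv(self, path) -> None:
        out = self.status.rename("status").to_frame()
        out.index.name = "locus"
        out.to_csv(path, sep="\t")


def _het_excess(n_het: int, n_called: int, two_pq: float, alpha: float) -> bool:
    """Heterozygote fraction significantly above the 2pq ceiling."""
    if n_called == 0 or n_het / n_called <= two_pq:
        return False
    if alpha >= 1.0:
        return True
    p = binomtest(n_het, n_called, min(two_pq, 1.0), alternative="greater").pvalue
    return p <= alpha


def filter_sites(
    gm: GenotypeMatrix, cfg: Config
) -> tuple[GenotypeMatrix, SiteFilterReport]:
    """Apply the population-level site filters (see module docstring).

    Checks run in order call rate → monomorphic → minor-allele frequency →
    heterozygosity ceiling; the first failure determines the status.
    Filtering is idempotent: retained sites pass all checks again.
    """
    statuses: dict[str, str] = {}
    keep: list[str] = []
    values = gm.values
    for j, locus in enumerate(gm.loci):
        col = values[:, j]
        called = col[~np.isnan(col)]
        n = gm.n_specimens
        n_called = called.size
        if n == 0 or n_called / n < cfg.min_call_rate:
            statuses[locus] = "fail_call_rate"
            continue
        p_alt = called.sum() / (2 * n_called)
        if p_alt in (0.0, 1.0):
            statuses[locus] = "monomorphic"
            continue
        maf = min(p_alt, 1 - p_alt)
        if maf < cfg.min_maf:
            statuses[locus] = "fail_maf"
            continue
        n_het = int((called == 1).sum())
        two_pq = 2 * p_alt * (1 - p_alt)
        if _het_excess(n_het, n_called, two_pq, cfg.het_excess_alpha):
            statuses[locus] = "fail_het_constraint"
            continue
        statuses[locus] = "retained"
        keep.append(locus)
    report = SiteFilterReport(pd.Series(statuses).reindex(gm.loci))
    return gm.subset(loci=keep), report
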