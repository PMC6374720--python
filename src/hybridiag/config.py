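"""Analysis configuration: every threshold in the pipeline, with defaults.

Defaults follow the genotyping-by-sequencing retention rules and hybrid
classification cut-offs the pipeline implements: 80% read support, >=5 unique
reads, base quality >=20, 1% minimum allele frequency, 20% minimum call rate,
100% call rate for diagnostic panels, 95% network confidence, backcross index
0.75 and later-generation heterozygosity 0.25.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class Config:
    # --- genotype calling (read-count level) ---
    allele_support_frac: float = 0.80   # top allele(s) must carry this read fraction
    min_unique_reads: int = 5           # unique reads backing the most common allele
    min_base_qual: int = 20             # PHRED floor; applied upstream of the count table
    het_support_rule: str = "union"     # "union": top-two reads jointly >=80%; "each": each >=40%
    het_min_reads_each: bool = False    # stricter option: both het alleles need min_unique_reads

    # --- site filtering ---
    min_maf: float = 0.01               # minimum minor-allele frequency
    min_call_rate: float = 0.20         # fraction of specimens genotyped
    het_excess_alpha: float = 0.01      # one-sided binomial alpha for het > 2pq; 1.0 = literal bound

    # --- sequence analyses ---
    network_confidence: float = 0.95    # statistical-parsimony confidence
    haplotype_collapse: str = "strict"  # "strict" identity or "lenient" ambiguity-tolerant
    diagnostic_mode: str = "strict"     # focal ambiguity handling in diagnostic-character scan

    # --- hybrid diagnosis ---
    panel_call_rate: float = 1.00       # call-rate requirement for panel loci
    pcoa_min_call_rate: float = 0.90    # call-rate subset used for ordination
    parental_index_min: float = 0.95    # hybrid index at/above which a specimen is parental
    f1_het_min: float = 0.95            # panel heterozygosity at/above which a specimen is F1
    backcross_index: float = 0.75       # >=75% of diagnostic alleles from one parent
    backcross_hom_tol: float = 0.05     # tolerated opposite-parent homozygote fraction in a backcross
    latergen_het: float = 0.25          # heterozygosity at/below which a hybrid is later-generation
    sexlink_max_mismatches: int = 0     # per-locus genotype exceptions tolerated in sex-linkage calls

    # --- reproducibility ---
    rng_seed: int = 0

    _FRACTIONS = (
        "allele_support_frac", "min_maf", "min_call_rate", "het_excess_alpha",
        "network_confidence", "panel_call_rate", "pcoa_min_call_rate",
        "parental_index_min", "f1_het_min", "backcross_index",
        "backcross_hom_tol", "latergen_het",
    )

    def __post_init__(self) -> None:
        for name in self._FRACTIONS:
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.min_unique_reads < 0 or self.sexlink_max_mismatches < 0:
            raise ValueError("count thresholds must be non-negative")
        if self.het_support_rule not in ("union", "each"):
            raise ValueError("het_support_rule must be 'union' or 'each'")
        if self.haplotype_collapse not in ("strict", "lenient"):
            raise ValueError("haplotype_collapse must be 'strict' or 'lenient'")
        if self.diagnostic_mode not in ("strict", "lenient"):
            raise ValueError("diagnostic_mode must be 'strict' or 'lenient'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "Config":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
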