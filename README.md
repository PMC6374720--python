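# hybridiag

Diagnosing interspecific hybrids that masquerade as species.

Rare insect "species" are sometimes nothing of the sort: a morphologically
distinctive form can turn out to be a cohort of first-generation hybrids
between two common, co-occurring species. `hybridiag` implements the
genetic toolkit for testing that hypothesis end to end, from classical
DNA-barcoding diagnostics through genome-wide SNP analysis, together with a
Mendelian cross simulator that makes every stage testable with planted
truth. It was built around the stonefly case in which a putative species
proved to be nonintrogressive F1 hybrids of two capniid species under X0
sex determination, but the machinery is general.

## What it computes

**Sequence diagnostics** (per-gene alignments, e.g. COI / cyt *b* / ITS1):

- haplotype collapsing and per-taxon haplotype sharing;
- uncorrected p-distances with pairwise deletion,
  `p = (# differing compared columns) / (# compared columns)`, reported as
  within/between-taxon mean percentages;
- pure diagnostic nucleotide characters: states present in every focal
  haplotype and absent from all others;
- simple indel coding of gaps (one binary character per distinct gap
  extent, nested gaps scored inapplicable);
- translation checks for stop codons / ambiguous residues
  (invertebrate mitochondrial code);
- statistical-parsimony (95%) haplotype networks: haplotypes are linked
  when their substitution count is within the parsimony connection limit —
  the largest *j* for which *P*(no superimposed substitutions among *j*
  hits over *m* sites) = ∏ᵢ₌₀^(j−1) (m−i)/m still meets the confidence.
  Separate networks are the classical operational criterion for separate
  species.

**SNP-based hybrid diagnosis** (biallelic genotype matrices, VCF/TSV, or
per-site read counts):

- genotype calling (≥80% read support, ≥5 unique reads) and site filters
  (MAF ≥ 1%, call rate ≥ 20%, heterozygosity ≤ 2·p·q);
- shared-SNP counts between a focal taxon and candidate parents;
- principal-coordinate placement of specimens from genotypic distances;
- fixed-difference diagnostic panels: loci homozygous for one allele in
  every specimen of parent A and the alternate allele in parent B;
- per-specimen hybrid index *h* (fraction of panel alleles from parent A)
  and interspecific heterozygosity *H* (fraction of panel loci
  heterozygous), and a classification ladder: parental (*h* ≈ 0 or 1),
  F1 (*H* ≈ 1), backcross (*h* on one side of ½ with no opposite-parent
  homozygotes, expectation *h* = 0.75), later-generation (*H* ≤ 0.25),
  else unresolved;
- X0 sex-linkage detection: loci where every hybrid male is homozygous
  for the maternal parent's allele (a male's single X is maternal) while
  every hybrid female is heterozygous;
- maternal-parent inference from mitochondrial haplotype clusters.

The panel/classifier layer is exposed both as functions over the domain
containers and as sklearn-style estimators (`HybridClassifier`,
`GenotypePCoA`) that compose with scikit-learn tooling.

## Worked example

Simulate the default study design — 36 + 20 parental specimens, 14 F1
hybrids (13 male, 1 female), 60 autosomal diagnostic, 51 X-linked
diagnostic and 34 nondiagnostic loci, taxon A maternal — then diagnose the
hybrids from the written VCF:

```bash
hybridiag simulate --out-dir demo --seed 1
hybridiag hybriddx --genotypes demo/genotypes.vcf \
    --metadata demo/specimens.tsv \
    --parent-a taxonA --parent-b taxonB --focal hybrid \
    --maternal taxonA --out-dir demo/dx
```

which prints

```
panel_size: 111
class_counts:
  F1: 14
```

111 candidate loci are fixed for alternate alleles in the two parents (the
60 autosomal + 51 X-linked planted ones; none of the 34
frequency-divergent loci slipped in), and all 14 putative hybrids classify
as F1. `demo/dx/hybrid_metrics.tsv` holds the per-specimen evidence:

```
specimen_id  n_loci_called  index_a  het_frac  hom_a_frac  hom_b_frac  hybrid_class
F100001      60             0.5      1.0       0.0         0.0         F1
F100002      60             0.5      1.0       0.0         0.0         F1
...
```

each specimen drew exactly half its panel alleles from each parent and is
heterozygous at every autosomal panel locus — the F1 signature. The
sex-linkage report partitions the 111 candidates into 60 autosomal
diagnostic and 51 sex-linked loci (`sex_linkage.tsv`), the latter showing
the male-homozygous / female-heterozygous X0 pattern. A single YAML config
runs the whole pipeline (sequences + genotypes) with a digest-stamped
manifest: `hybridiag run-all --config config.yaml --out-dir out`.

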