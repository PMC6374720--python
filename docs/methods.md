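# Methods

This note documents the models, rules and numerical choices behind
`hybridiag`, in the order the pipeline runs them, and states what the
synthetic-data generator does and does not emulate.

## Data model

Genotypes are alternate-allele dosages in {0, 1, 2} with NaN as the
explicit missing sentinel; missing is never conflated with dosage 0.
Hemizygous genotypes cannot be distinguished from homozygous ones by
reduced-representation sequencing, so male X-linked genotypes are *coded*
homozygous (0 or 2) throughout — the sex-linkage detector exploits this
coding rather than fighting it. Alignment columns are 0-based internally
and 1-based in every report. Taxon assignments (`TaxonPartition`) are a
revisable hypothesis: reassignments (e.g. a female whose molecular
genotype contradicts her phenotypic identification) are logged with a
reason and flip the provenance flag.

## Genotype calling and site filters

A genotype is called homozygous when the most common allele carries at
least `allele_support_frac` (0.80) of the reads and at least
`min_unique_reads` (5) unique reads; otherwise heterozygous when the two
most common alleles jointly reach the support fraction, the most common
allele meets the unique-read floor and the second allele was observed;
otherwise missing. The protocol wording is ambiguous about whether the
80% applies to the union of the top two alleles or to each; the default is
the union, with `het_support_rule="each"` (each allele ≥ 40%) and
`het_min_reads_each` as stricter options. Read-level handling (base
quality ≥ 20, end-of-read trimming, unique mapping) belongs upstream of
the count table and is assumed done.

Site filters run in a fixed order (call rate → monomorphic → MAF →
heterozygosity), so each site gets exactly one failure status. The
heterozygosity rule bounds the observed heterozygote fraction by 2·p·q
(p, q the frequencies of the two most common alleles, estimated from the
called genotypes). Applied as a knife-edge inequality this rejects about
half of all genuinely Hardy–Weinberg sites, because the observed fraction
fluctuates symmetrically around 2·p̂·q̂; the filter's purpose is to remove
collapsed-paralog artifacts in which essentially *every* specimen is
heterozygous. The bound is therefore enforced as a one-sided exact
binomial test: a site fails only when its heterozygote count significantly
exceeds 2·p̂·q̂ at `het_excess_alpha` (0.01). All-heterozygote artifact
sites fail at any realistic sample size (p-value 0.5ⁿ); HWE sites fail at
the nominal 1% rate. `het_excess_alpha = 1.0` restores the literal bound.

## Sequence diagnostics

*Haplotype collapsing* defaults to strict string identity (ambiguity codes
distinguish); a lenient mode merges a sequence into the first haplotype
it is compatible with at every mutually unambiguous, ungapped column
(first-match greedy, so the merge is order-dependent — the reason it is
not the default). Numbering follows first occurrence.

*p-distances* use pairwise deletion: columns with a gap or IUPAC ambiguity
in either sequence are excluded; the distance is NaN when nothing is
comparable. Group tables average over *unique haplotypes*, each counted
once regardless of multiplicity, and a haplotype shared by two taxa sits
in both taxon sets, so haplotype sharing drags the between-taxon mean
toward zero — exactly the signal of interest. A single-haplotype group
has no within-group pairs; the value is NaN internally, printed as 0.00
(with a footnote) by the table writer to match the convention of published
distance tables. Percentages are rounded half-even to 2 decimals.

*Diagnostic characters* are found by exhaustive column scan over
haplotypes. Strict mode (default) skips columns where any focal haplotype
is ambiguous or gapped; lenient mode intersects the focal IUPAC
expansions. Non-focal states are always IUPAC-expanded, so an ambiguity
code compatible with the candidate state blocks it — a conservative
choice that avoids claiming diagnosis on the back of an N.

*Gap coding* follows simple indel coding: each distinct maximal gap extent
is one binary character; a sequence scores present only for exactly that
extent, inapplicable when its own gap strictly contains the extent, absent
otherwise. Characters are ordered by (start, end).

*Translation checks* use the invertebrate mitochondrial code (table 5) by
default, degap, trim to frame, and flag internal stops and ambiguous
residues.

## Statistical-parsimony networks

The connection limit is the largest step count *j* whose parsimony
probability still meets the confidence (default 0.95). The probability
model: *j* substitutions placed uniformly over *m* sites are all
parsimoniously interpretable iff no two hit the same site, so

P(j, m) = ∏ᵢ₌₀^(j−1) (m − i)/m,

evaluated by its recursion P(j) = P(j−1)·(m−j+1)/m. This is the
no-superimposed-substitution core of the statistical-parsimony criterion;
it is deliberately free of a substitution-rate prior, depends only on
alignment length and confidence, and has the required limiting behaviour
(limit → 1 as confidence → 1; non-decreasing in *m*). At 95% the limits
are 3, 7, 8 and 10 steps for lengths 100, 428, 563 and 918. Tests verify
the recursion against an independent exact-rational direct evaluation.

Network construction simplifies full cladogram estimation to what the
downstream analyses consume. Haplotypes with ambiguity codes are dropped
first (logged); columns gapped in any retained haplotype are excluded
from Hamming distances (mitochondrial barcoding alignments typically have
none). Pairs are processed in increasing (distance, id, id) order —
deterministic tie-break — all distance-1 edges are kept (so loops are
retained, not broken), and a longer pair within the limit is joined
through a chain of unobserved intermediate nodes only when not already
connected. Network membership therefore equals the connected components
of the distance-thresholded graph, which tests verify against a
brute-force oracle; edge sets inside a component may differ from other
implementations whose tie-breaking is undocumented, but membership,
step counts and haplotype sharing — the reported quantities — do not.

## Hybrid diagnosis

*PCoA.* The genotypic distance between two specimens is the root mean
squared dosage difference over co-called loci (pairwise-complete). The
eigen-step is classical PCoA (double-centering); axis signs are fixed by
making each axis's largest-magnitude coordinate positive. The metric of
the original desktop tool is not restated in its documentation, so this
choice is documented and swappable; tests verify the implementation
against an independent double-centering + `scipy.linalg.eigh` route.

*Panel.* A locus enters the diagnostic panel when its call rate over all
specimens meets `panel_call_rate` (1.0) and every called parent-A
genotype is homozygous for one allele while every called parent-B
genotype is homozygous for the other. Panel construction uses parents
only; the post-hoc partition of panel candidates by hybrid genotype
patterns (diagnostic / sex-linked / nondiagnostic) is kept separate, to
avoid the circularity of validating a panel with the specimens it is
meant to diagnose. With small parental samples a strongly
frequency-divergent locus can look fixed by sampling accident; no filter
can distinguish that from a true fixed difference, which is why the panel
guarantee in the tests is stated for interior allele frequencies and
parental n ≥ 10.

*Metrics.* For specimen *i* over called panel loci, the hybrid index is
hᵢ = Σ (parent-A allele dosage) / (2 · n_called) and interspecific
heterozygosity Hᵢ is the heterozygous fraction; the homozygote fractions
for each parental allele are carried alongside (hom_A = h − H/2,
hom_B = 1 − H/2 − h).

*Classification ladder*, total and ordered (first match wins):

1. parental_A: h ≥ 0.95 and H ≤ 0.05 (parental_B mirrored);
2. F1: H ≥ 0.95;
3. backcross_A: h > 0.5 and (h ≥ 0.75 **or** hom_B ≤ 0.05)
   (backcross_B mirrored);
4. later_generation: H ≤ 0.25;
5. unresolved.

The 0.75 index rule is the conventional backcross expectation — a BC1
carries on average 75% recurrent-parent alleles — but an individual BC1's
index is (L + Binomial(L, ½))/2L over L loci, and nearly half of true
BC1s fall below 0.75. What separates a first-generation backcross from an
F2 exactly is that it carries *no* homozygote for the non-recurrent
parent's allele; the hom ≤ 0.05 gate encodes that Mendelian signature and
makes error-free BC1 cohorts classify correctly, while the 0.75 rule is
retained for robustness under noise. The later-generation ceiling of 25%
heterozygosity is kept verbatim as the conventional screening rule even
though the Mendelian F2 expectation at diagnostic loci is 50%; an
error-free F2 therefore typically lands in `unresolved` rather than
`later_generation`, and the simulator's truth tables document the
expectation. The residual class overlaps are irreducible: with 20 loci a
BC1 that happens to be heterozygous at ≥ 19 of them is indistinguishable
from an F1 (probability ≈ 2 × 10⁻⁵ per specimen).

Thresholds 0.95/0.05 are tolerances the source rules do not state;
genotyping error makes exact-pattern rules brittle, and all of them are
`Config` fields.

*Sex linkage.* Candidate loci (panel candidates) are partitioned by the
pattern in sexed hybrids: `autosomal_diagnostic` when every called hybrid
is heterozygous; `sex_linked` when every called hybrid male is homozygous
for the maternal parent's allele and every called female heterozygous
(up to `sexlink_max_mismatches`, default 0); `nondiagnostic` otherwise.
The sex model is fixed to X0 (males X, no Y; the male X is maternal);
ZW/XY systems are out of scope. In the full pipeline, sex-linked loci are
removed from the panel *before* hybrid metrics are computed, because
hemizygous male genotypes at X loci would otherwise depress H and bias h
toward the maternal parent — the failure mode is visible in the simulator
if the exclusion is disabled.

*Maternal parent* is the parental taxon whose mitochondrial haplotype
cluster (network component containing that taxon's specimens) contains
the hybrids' haplotypes; a split is reported as bidirectional crossing.

## The synthetic cross generator

`CrossDesign` defaults are the emulated study conditions: 36 + 20
parental specimens, 14 F1 (13 male, 1 female via `n_f1_males`), panel of
60 autosomal diagnostic + 51 X-linked diagnostic + 34 nondiagnostic loci,
taxon A maternal. Diagnostic loci are fixed (frequency 1 vs 0 of the
A-associated allele); nondiagnostic loci default to strongly divergent
but unfixed frequencies (U(0.8, 1) in A vs U(0, 0.2) in B), which
reproduces the observed ~86% F1 heterozygosity at such loci; any per-locus
(pA, pB) list can be supplied instead. Parental genotypes are binomial
draws from the taxon frequency; offspring are built by explicit gamete
draws from freshly sampled (grand)parents — F1 = female(maternal taxon) ×
male(other), BC1 = F1 female × parental male, F2 = F1 × F1 — so all
Mendelian marginals are exact by construction and are verified by
chi-square tests across seeds. X chromosomes follow X0 rules per locus:
sons receive one of the mother's X alleles (coded homozygous), daughters
one maternal draw plus the father's single X. Mitochondrial haplotypes
copy down the maternal line, and a two-haplotype mitochondrial alignment
is emitted so the sequence stage can recover the cross direction.
Orientation (whether the A-parent allele is REF or ALT) is randomized per
locus and recorded in the truth table.

Noise is a symmetric dosage perturbation (a called genotype moves to an
adjacent dosage with probability ε, heterozygotes up/down with equal
probability) plus independent missingness μ. Depth-dependent error —
the real error structure of genotyping-by-sequencing — is covered
separately by `simulate_site_counts` (Poisson depth, 50/50 allele
sampling in heterozygotes, per-read miscalls to a uniform other base)
feeding the genotype caller.

Deliberately **not** emulated: linkage disequilibrium (the analyses
subset to one SNP per locus, so loci are independent), population
structure within parental taxa, selection, recombination maps,
alignment/mapping error, and reference bias. Passing tests on this
generator therefore demonstrate correctness of the inference rules under
their own assumptions, not robustness to those real-data complications.

## Problem sizes and determinism

Every generator and every pipeline run is deterministic given the config
seed; reruns produce byte-identical TSV/JSON outputs, which the manifest's
SHA-256 digests make checkable. The test suite uses cohorts of 50
specimens per class (20-locus panels) for classification guarantees,
10,000 BC1 individuals at 60 loci for the Mendelian mean (Monte-Carlo SE
≈ 0.03%), 1,000 nondiagnostic loci × 10 seeds for panel specificity, and
≤ 50-haplotype instances for the network oracle — sizes chosen so the
whole suite runs in well under a minute while keeping Monte-Carlo
tolerances tight.

## Known limitations

- The parsimony probability model omits a substitution-model prior;
  absolute connection limits can differ by a few steps from tools that
  embed one, though component structure on well-separated clusters does
  not.
- Lenient haplotype collapsing is order-dependent (documented above).
- The later-generation rule contradicts the F2 Mendelian expectation (kept
  deliberately; see the ladder discussion).
- The caller assumes biallelic sites after upstream read processing;
  paralog collapse is only addressed statistically, via the 2·p·q filter.
- Distance-table reproduction against archived sequence data requires
  those alignments on disk; nothing is downloaded at run time.
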