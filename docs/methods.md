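# Methods

## The co-detection model

A single sequencing library mixes two kinds of molecules derived from each
double-stranded DNA fragment. Before enzymatic conversion, a copy of each
strand is synthesized with a deamination-resistant cytosine analog
(5-propynyl-dCTP-like). Conversion then deaminates unmodified cytosines to
uracil (read as T), so:

* **original strands** keep their methylation signal (methylated CpGs read
  as C, unmethylated as T) but lose their fixed-pool UMI cytosines to
  conversion — the UMI reads as its C→T collapse on mate 1 and, because
  mate 2 sequences the reverse complement, as its G→A collapse on mate 2;
* **protected copy strands** keep their sequence (and hence mutations)
  intact, including the UMI.

Demultiplexing inverts this: a read pair whose two UMIs exactly match the
pool goes to the genetic stream (MM-genet); a pair whose UMIs match a C→T
or G→A collapsed pool entry goes to the methylation stream (MM-meth);
everything else is unassigned. Matching is exact string lookup — the
"perfect match" requirement — so the pool must be collision-free across all
exact and collapsed forms. The package ships a generated 32-member pool with
that property (the assay's actual 32 sequences are not public) and validates
any user pool by brute-force pairwise comparison of all 96 forms. Both mates
must agree on the stream; discordant pairs are counted as unassigned rather
than risking stream contamination in variant calling. Either collapse mode
is accepted per mate, since which mate shows C→T versus G→A depends on the
strand of origin.

## Simulator

`mmseq.simulate` generates truth-labelled libraries at the level the
pipeline consumes. Per duplex molecule: a span on a reference contig,
per-CpG methylation states (dyad-symmetric), optional planted variants and
allele-linked methylation, and a UMI at each end drawn from the pool. Per
original strand, `2**c − 1` protected copies are synthesized — the
exponential-doubling reading of `c` pre-amplification cycles (one cycle is
the genomic-DNA condition, three the cell-free-DNA condition); the true
per-cycle efficiency of the protective pre-amplification is unknown, so the
doubling formula is this package's model, not a measured quantity.
Conversion is per-cytosine Bernoulli:

| event | probability | default |
|---|---|---|
| unmethylated C converts (original strand) | `conversion_sensitivity` | 0.9989 |
| methylated C converts (original strand) | `1 − conversion_specificity` | 1 − 0.9743 |
| analog C converts (protected strand) | `1 − analog_resistance` | 0.05 |
| strand survives conversion | `strand_survival` | 0.8 |
| extra PCR copies per strand | Poisson, rate `d/(1−d)` | d = 0.1 |

UMI cytosines are unmodified by design and convert like unmethylated
genomic cytosines. Sensitivity/specificity defaults are the conversion
operating point of the enzymatic chemistry; survival 0.8 and duplicate rate
0.1 are chosen as realistic conversion-loss/duplication levels for a
converted library. Fragment lengths are uniform in [60, 90] bp (≤ read
span, so each mate fully covers the molecule); spike-in contigs emulate
fully unmethylated lambda DNA, and pUC19 dilutions in which a molecule is
fully CpG-methylated with probability equal to the dilution level
(5/2/1/0.5/0.2/0%).

What the simulator does **not** model: sequencing error beyond conversion
events, indels, real cfDNA fragment-size distributions, M-bias, mappability.
Passing recovery tests therefore demonstrates correctness of the pipeline's
logic under the stated noise model, not robustness to alignment artifacts
in real data.

## Stream processing

**Deduplication / consensus.** Duplicates are fragments with the same
orientation (flag pair) whose start and end coordinates agree within a
tolerance and, in UMI-aware mode, whose per-mate UMIs are within Hamming
distance 1. Methylation-stream dedup uses exact coordinates
(MarkDuplicates-equivalent); QC duplicate-rate estimation and genetic-stream
consensus use tolerance 5 with UMI awareness. Requiring an identical flag
pair keeps the Watson and Crick strands of one molecule separate — without
it, dyad merging and duplex pairing would be destroyed. One representative
(first in coordinate sort order) is kept per cluster, making the result
order-independent; consensus takes the per-position majority base and masks
positions below 70% agreement to N.

**Methylation calling.** On original-top fragments a plus-strand reference
C read as C/T is methylated/unmethylated; on original-bottom fragments the
informative base is the plus-strand G (read G/A). CpG dyads are merged into
one site keyed by the plus-strand C, matching CX-report conventions; a
cytosine whose dyad partner falls outside the fragment is skipped rather
than miscounted. CHG/CHH contexts are called per strand. Conversion QC:
sensitivity = converted cytosines / all cytosines on the lambda analog,
specificity = unconverted CpG cytosines / all CpG cytosines on the fully
methylated pUC19 analog (its non-CpG cytosines are unmethylated and are
excluded), plus the C→T/G→A substitution rate of the genetic stream over a
user-supplied QC region.

**Variants and CNV.** Germline SNPs come from a molecule-level pileup of
consensus fragments filtered at ≥10× coverage, ≥2 supporting molecules and
VAF ≥ 0.15; no genotype model. The somatic filter is the pure predicate:
≥5 supporting reads, VAF ≥ 0.1%, not C>T/G>A (retained in the DNA-seq
comparison mode), not present in the paired white-blood-cell sample (CHIP),
and not synonymous/intronic/UTR — annotations are consumed as an input
column rather than computed from a gene model. CNV: 10 kb bins, bins <1×
dropped, copy ratio = coverage / genome median, LOWESS of ratio vs GC
(falling back to a constant fit when GC is near-constant), re-centered so
the median corrected ratio is 1, and copy number = 2 × corrected ratio
(diploid scaling — the thresholds 3.5/0.5 read most naturally on a
copy-number scale, and are configurable). Segmentation is threshold
run-length with ≥3 consecutive bins; no change-point model is attempted.

## Duplex phasing and ASM

Genetic and methylation fragments from the same molecule are joined on
identical coordinates, conversion-consistent UMI pairs (each meth UMI equals
a collapse of the corresponding genet UMI) and strand-class-consistent flags
(Watson: 99/147 with 67/131; Crick: 83/163 with 115/179). Matching is
greedy one-to-one in deterministic sort order; with a 32×32 UMI pair space
ambiguous joins are rare and resolve by that order. Allele-specific
methylation allocates each pair to an allele by the genet base at the SNP
and accumulates methylated/unmethylated CpG counts within ±200 bp (the
window is a package default; configurable), tested with the two-sided
Fisher exact test (minimum-likelihood two-sidedness; any zero margin leaves
p undefined rather than fabricating 1.0).

## Clinical layers

* **ctDNA**: marker fragments covering ≥5 CpGs are eligible; a fragment with
  every covered CpG methylated counts as tumor-derived. Positive iff any
  kept somatic mutation, or fraction > 0.1% with ≥3 ctDNA fragments and
  ≥3000 eligible fragments. All boundaries are strict exactly as stated.
* **Immune cfDNA**: per marker, the proportion of fully covering fragments
  with the requisite number of unmethylated CpGs (default: all — symmetric
  with the fully-methylated ctDNA rule; per-marker override available);
  cell-type fraction = mean over its markers; calibration = per-type OLS
  against complete-blood-count training pairs, clipped at 0 and renormalized
  to sum exactly to 1. NLR = neutrophil / (all lymphocyte-group) fractions.
  Flow-cytometry normalization rescales the lymphocyte group and the
  neutrophil/eosinophil/monocyte group to their CBC totals.
* **Promoter CpG selection**: methylation–expression Pearson r < −0.15,
  position within −1000/+750 bp of the TSS (strand-aware; the convention is
  applied to the annotated strand), and >5 CpGs within 75 bp. Candidates
  merge when 100 bp flanks overlap; isolated candidates get a 75 bp flank.
  A gene is hypermethylated when the cluster's mean beta exceeds 0.07
  (strict).
* **LOH**: grid search over integer allele copy numbers M ≥ N ≥ 0, M ≤ 8,
  maximizing a Gaussian likelihood with expected BAF
  `(M·p + (1−p)) / ((M+N)·p + 2(1−p))` and expected normalized depth
  `((M+N)·p + 2(1−p)) / (ψ·p + 2(1−p))` at tumor purity p and ploidy ψ,
  uniform prior (the published description gives no more detail, so the
  simplest identifiable error model is used; σ_BAF = 0.05, σ_depth = 0.1
  are configurable and only matter for ties). Expected BAF at M+N = 0 with
  p = 1 is undefined and treated as 0.5 so depth decides. LOH = (N = 0,
  M ≥ 1); biallelic loss = homozygous deletion, LOH+methylation,
  LOH+deleterious mutation, or two deleterious mutations.
* **Panel design**: greedy addition of the exon maximizing the minimum
  coverage gain across cohorts (the multi-cohort objective is not published;
  maximizing the minimum guarantees every cohort progresses), ties broken by
  total gain then exon order, until every cohort strictly exceeds the 85%
  target or no exon adds coverage anywhere (returned with a warning flag).
* **qPCR**: mutation positive iff Ct < 26; methylation positive iff
  marker-A ΔCt < 10 or marker-B ΔCt < 10.5; missing values are negative.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` exercise: 50 000 read pairs for
demultiplexing accuracy; ~10 000+ spike-in cytosine observations per
conversion metric; a 200 kb genome at ~25× deduplicated methylation
coverage (60 000 molecules) for beta recovery; a 10 Mb genome in 10 kb bins
with a planted 100 kb four-copy gain; ~200 duplex pairs for ASM; 20
simulated seven-type immune mixtures at 2000 fragments/marker; and
exhaustive or enumeration-oracle checks for the pure rules (somatic filter,
ctDNA status, Fisher test to n ≤ 30, LOH grid to M ≤ 4, panel greedy to 6
exons). These sizes were chosen so each property is measured with
comfortable statistical margin.

## Known limitations

Cohort-scale headline numbers from the original clinical study (detection
rates, perfect-UMI percentages, pairing rates) depend on restricted-access
patient sequencing data and are not reproduced here; the package instead
verifies every computational rule on synthetic data with known truth.
The aligner, base recalibration, and the statistical internals of external
variant callers are out of scope: the pipeline starts from aligned
fragments (or the simulator's equivalent) and implements the printed
filtering rules atop a simple pileup.
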