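# Methods

## Overview

`ase-scan` implements a chip-anchored allele-specific-expression (ASE)
scan. Its stages mirror how such scans are run in practice:

1. **Cohort simulation** (`synth`) — reference autosomes, a biallelic SNP
   panel with population allele frequencies, phased HWE genotypes, and
   RNA-seq-like reads over heterozygous sites with a planted allelic
   ratio per site.
2. **Genotype QC** (`genoqc`) — per-sample and per-SNP call-rate filters,
   minor-allele-frequency filter, exact conditional Hardy–Weinberg test,
   autosome restriction.
3. **Diploid construction and counting** (`diploid`) — two personalized
   haplotype sequences per individual; allele counts at heterozygous SNPs
   by a strict perfect-match, unique-locus assignment rule; a ≥ 20-read
   coverage filter.
4. **Imbalance calling** (`asecall`) — exact two-sided binomial test per
   (individual, SNP) against Binomial(n, ½), Benjamini–Hochberg FDR
   across all tests, monoallelic flagging. Exposed as the
   `AllelicImbalance` model / `ASEResults` results pair.
5. **Profiling** (`profiles`) — per-SNP consistency, ASE/biallelic
   partition, monoallelic proportions, allele-direction analysis,
   occurrence histogram, chromosome distribution, per-individual
   regression.
6. **Annotation** (`annotate`) — consequence classification against
   explicit gene models and intersection with external interval/ID lists.

## Model and assumptions

The sampling model for an informative read at a heterozygous SNP is a
Bernoulli choice between the two haplotypes with probability θ for
haplotype A. Balanced expression is θ = ½; cis-regulatory imbalance is
½ < θ < 1; monoallelic expression is θ = 1. The binomial test assumes
reads are independent given θ and that the perfect-match filter removes
rather than biases miscounted reads (an error in a read makes it match
neither haplotype, except for the rare error that lands exactly on the
SNP and converts one allele into the other — see *Limitations*).

The test is two-sided by the minimum-likelihood rule: p = Σ P(j) over all
j with P(j) ≤ P(k). For the symmetric p = ½ null this coincides exactly
with the doubled smaller tail min(1, 2·P(X ≤ min(k, n−k))), which is the
closed form used in the implementation; the equivalence is enforced by an
enumeration oracle in the tests. BH adjustment is applied jointly across
all (individual, SNP) tests of a run by default; per-individual scoping
is available via `CallConfig(scope="per_individual")`. Significance uses
the strict inequality q < α.

The Hardy–Weinberg filter uses the exact conditional test: conditioned on
the observed allele counts, the probability of every heterozygote count
whose conditional probability does not exceed the observed one is summed.
A chi-square variant is available (`QCConfig(hwe_method="chisq")`) but
the exact test is the default because it is well defined for any counts
and is oracle-checkable by full enumeration. The exact test is
conservative at small minor-allele counts, so the realized rejection rate
under HWE-true data sits below the nominal threshold.

## Perfect-match assignment

"Perfect match" is operationalized as: the read, or its reverse
complement, occurs as an exact full-length substring of a haplotype
sequence. A read is allele-informative iff its occurrences across both
haplotypes collapse to **one genomic locus in one haplotype** and that
locus covers the SNP. Reads occurring in both haplotypes (they span no
heterozygous site) or at several loci are ambiguous and discarded; reads
occurring nowhere (sequencing errors) are unassigned. A read spanning two
heterozygous sites with conflicting haplotype support matches neither
haplotype and is therefore unassigned automatically — no per-site
base-peeking exists in this rule.

Two equivalent search routes implement the rule: a k-mer hash of both
haplotype genomes when all reads share one length (the generated-data
case), and substring scanning otherwise; tests verify both against an
independent regex-based brute-force re-scan. The ≥ 20-read coverage
threshold counts only allele-informative reads; ambiguous reads do not
contribute. Coordinates are 0-based half-open internally and converted to
1-based only at the VCF/GFF boundary.

## Synthetic cohort: what it emulates, and what it does not

Defaults (all in `SimulationConfig`): 2 autosomes × 50 kb, 200 SNPs, 20
individuals, minor-allele frequency uniform on [0.05, 0.5], 100 bp
single-end reads, mean informative coverage 30× per heterozygous site
(Poisson), base error 10⁻³ (uniform substitution), θ classes
(0.5 : 60%, 0.8 : 25%, 1.0 : 15%), no missing genotypes. The θ-class
mixture is a design choice for a population in which imbalance is common
but balanced sites dominate; it is not an estimate from any dataset. The
class is drawn per SNP and expressed by every heterozygous carrier,
so site-level consistency statistics have a planted truth; the favored
haplotype is hapA by convention (configurable to ref/alt/major for
direction-analysis scenarios, in which case the recorded hapA fraction
for a carrier phased the other way is 1 − θ).

SNP positions keep ≥ read-length spacing and a read-length margin from
chromosome ends, so every read covers at most one SNP, is never clipped,
and per-site counts recover the planted θ without contamination from
neighbouring sites. Calibration studies that need no per-base realism
(null FDR replicates, power at fixed coverage) use the counts-level
generator `simulate_counts`, which draws Binomial(n, θ) allele counts
directly; it is distributionally identical to error-free read simulation
followed by perfect-match counting.

Not emulated: splicing and isoforms, indels, paired-end reads, quality
scores, GC/coverage bias, reference/mapping bias, overdispersion beyond
Poisson coverage, linkage disequilibrium between SNPs, and relatedness
among individuals. Passing tests therefore demonstrate correctness of the
statistical machinery and the assignment rule, not robustness to those
real-data phenomena.

## Numerical and design choices

- **Problem sizes.** Default runs use 200 SNPs × 20 individuals
  (~45,000 reads); the assignment-correctness check uses 2 × 10 kb
  chromosomes, 50 SNPs, 10 individuals. These sizes give stable
  Monte-Carlo estimates for every reported quantity while keeping a full
  run in seconds.
- **Percent rounding** is decimal half-up to 2 places (43/46 → 93.48),
  not banker's rounding.
- **Direction analysis** requires ≥ 5 significant individuals per SNP;
  the major allele is the more frequent allele in the QC-passed cohort
  (alt iff alt frequency > 0.5, ties to ref). Ties in read counts cannot
  be significant under the binomial test, so every significant record has
  a strict majority allele and no tie-break is needed.
- **Consequence severity** when several classes apply (across transcripts
  or within one): missense > synonymous > splice region > 5′UTR > 3′UTR >
  intron > non-coding transcript; intergenic only when no gene overlaps.
  The splice-region window is 8 intronic / 3 exonic bases around internal
  exon boundaries. There are no upstream/downstream classes: only
  transcribed positions are classified.
- **Top-site ranking** orders by number of significant individuals, then
  consistency percentage, then site id.
- **Determinism.** All stages draw from generators spawned from one
  `SeedSequence`; FASTQ gzip members are written with fixed mtime and
  empty embedded filename so identical configurations produce
  byte-identical artifacts.
- **Degenerate inputs.** Empty count tables yield empty, correctly typed
  call tables; a coverage threshold no record reaches produces a valid
  all-zero report; monomorphic sites have HWE p = 1; an all-missing site
  is a call-rate failure, not an HWE evaluation.

## Known limitations

- A sequencing error exactly at the SNP position can convert a read from
  one allele into a perfect match for the other, leaving a single stray
  minor-count read; at error rate 10⁻³ this makes a small fraction of
  planted θ = 1 observations fail the strict monoallelic flag. This is a
  property of the perfect-match contract itself, not of the simulator.
- The binomial model ignores extra-binomial variation (e.g. PCR
  duplicates, bursty transcription); a beta-binomial extension is out of
  scope.
- Significance-based selection inflates the apparent effect size among
  significant calls (winner's curse); k/n among significant records
  overestimates θ near the detection boundary.
- The consequence classifier covers the SNP-in-transcript vocabulary
  only; regulatory consequences, indels and canonical-transcript logic of
  full annotators are out of scope.
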