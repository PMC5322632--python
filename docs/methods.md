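# Methods

## Setting and data model

The package compares the spectrum of single-nucleotide variation in a
resequenced case cohort against two kinds of background: a genotype- or
count-level control population of comparable size, and a very large
aggregate reference available only as per-site allele counts (AC/AN).
All analyses operate on biallelic SNVs; indel records are dropped at
ingestion and counted, never modelled, because the panel-sequencing
platforms this targets have unreliable indel calls. Multiallelic VCF
records are split into biallelic site records, conserving alternate-allele
copies.

Coordinates are 1-based inclusive throughout. A gene panel carries, per
gene, the chromosome, X-linkage, and promoter/coding intervals; promoters
are defined strand-aware as 500 bp upstream through 50 bp downstream of the
first base of exon 1. Cohort chromosome counts are 2(F + M) for autosomal
loci and 2F + M for X-linked loci (males hemizygous; a heterozygous male
call at an X-linked site is a validation error). Missing genotypes reduce
the per-site called-chromosome count rather than being imputed, matching
the count-based model of pooled sequencing.

## Spectrum statistics

Three integer statistics summarize a gene scope (or the panel-wide sum —
all three are additive over disjoint scopes):

1. **Rare count**: sites *present* (≥ 1 alternate copy) with folded
   MAF = min(f, 1 − f) ≤ t, default t = 0.01 inclusive. The comparison is
   done in exact integer arithmetic (q·min(a, n − a) ≤ p·n for t = p/q), so
   boundary cases like 6/576 vs 6/600 are deterministic. Presence is
   required: an unobserved allele has MAF 0 but is not a detected variant,
   which keeps rare counts subsets of detected totals.
2. **Case-specific count**: case alternate count ≥ 1 and control count 0,
   over a shared site universe (absent means count 0).
3. **Damaging count**: present sites called damaging by both SIFT and
   PolyPhen-2. The published tables report concordant categorical calls, so
   the concordant *count* is the default; a `score_sum` mode (0–2 damaging
   calls per present site) is available as the dosage-style alternative.
   Sites with a missing call on either predictor cannot be concordant and
   are effectively excluded.

The rare statistic is tested on the case side by default; a case-minus-
control contrast (`rare_count_contrast`) is exposed for the alternative
reading.

## Permutation test

Null hypothesis: case and control chromosomes are exchangeable at every
variable site. Each replicate redraws, independently per site, the case
alternate count from the hypergeometric distribution of dealing the pooled
case_n + ctrl_n chromosomes (of which case_alt + ctrl_alt carry the
alternate) into sets of the original sizes; per-site totals are conserved
exactly. The statistic is recomputed on every permuted case cohort with
rarity/specificity judged from the permuted counts — the same code path
scores observed and permuted data. Sites are permuted independently: the
test deliberately ignores linkage disequilibrium between sites, which is a
documented property of the procedure, not an approximation we correct.

Tie handling, which published resequencing analyses rarely specify, is
exposed explicitly:

* `strict` (default): P = #{replicates with statistic > observed} / n_perm,
  matching the classical "randomized value higher than observed" phrasing.
  This proportion can be exactly 0 and is anti-conservative near the
  boundary.
* `ge`: add-one correction P = (#{≥ observed} + 1) / (n_perm + 1); never
  zero, conservative, and the mode used for all calibration claims.

Both replicate counts are stored in every result. Default n_perm is
100,000; the calibration and power studies below use 400 replicates per
panel since only the α = 0.05 decision is needed there.

Degenerate scopes — empty, or with no site that can vary under permutation
(every pooled count 0 or saturated) — have a point-mass null distribution;
the test is uninformative and the result is flagged `degenerate` with P = 1
in both modes. The reference-simulation test (below) instead reports the
plain proportion in such cases (a monomorphic reference genuinely cannot
exceed a nonzero observed count, and P = 0 is the informative answer
there); the two conventions are intentional.

Randomness: each scope's replicates come from a `SeedSequence` derived from
the master seed and a CRC-32 of the scope label, so per-gene results do not
depend on analysis order, and the panel-wide test permutes all sites
jointly under its own ("ALL") substream. P-values are bit-reproducible
given (seed, n_perm).

## Reference simulation test

The aggregate reference has no individual-level data, so exchangeability
cannot be permuted. Instead each replicate simulates a case-sized cohort:
per site, alternate count ~ Binomial(n_chrom, AC/AN) (default), or
hypergeometric sampling without replacement from the finite reference pool
(the two agree when AN ≫ n_chrom; the binomial is the default because an
exome aggregate is effectively infinite relative to a few hundred cases).
n_chrom is the case cohort's sex-adjusted chromosome count — 576 autosomal
/ 428 X-linked for 288 cases of 140 F + 148 M. The observed statistic is
the case rare count; each simulated cohort is scored identically, with
rarity judged within the simulated cohort (default, symmetric with the
observed side) or by reference MAF (`rarity="reference"`).

Case-carried sites absent from the reference enter with frequency 0 and can
never appear in simulated cohorts; their observed presence is precisely the
excess the test is designed to detect. Reference sites the case cohort
missed still contribute simulated rare sites, which is what keeps the test
calibrated when the case cohort is drawn from the reference population
(verified empirically below).

## Single-SNP layer

Sites with MAF ≥ 0.05 (inclusive, folded, in either cohort) are tested
individually with the pooled two-proportion z-test, two-sided — the study
design reports frequency differences in both directions. No continuity
correction by default (a corrected variant is a flag). A pooled proportion
of exactly 0 or 1 is flagged degenerate with P = 1.

Hardy-Weinberg screening uses the 1-df chi-square against p², 2pq, q²
expectations with allele frequencies estimated from the genotypes; at
n ≈ 288 and MAF ≥ 5% the approximation is adequate (its P-values are
empirically uniform under HWE — see below), and a Levene-Haldane exact
conditional test is available by flag for small counts. X-linked sites use
female (diploid) genotypes only.

## Synthetic data generator

The generator encodes the study-like conditions used throughout the tests:
ten genes with the panel's coding lengths (2358–2433 bp, mean ≈ 2670),
TLR7/TLR8 X-linked, 288 cases (140 F / 148 M), 379 controls, and a 33,000-
individual reference. Sites arise per gene at a configurable density
(default 0.0045 candidates/bp ≈ 12 per gene, matching the observed
per-gene site counts) in two pools:

* a **common pool** (fraction 0.6 of site mass) with frequencies from a
  neutral-like SFS — allele-count classes i = 1..K, K = 757 ≈ the control
  chromosome count, with P(i) ∝ 1/i — or a Beta(a, b) alternative;
* a **rare pool** (the remainder) with the same SFS truncated to the
  ≤ 1% band.

Every baseline site's frequency is drawn once and sampled *binomially into
both cohorts* (sex-correct chromosome counts on X); sites undetected in
both are dropped. Population-specific variants therefore emerge from
sampling, and at enrichment ρ = 1 case and control chromosomes are
exchangeable draws from the same frequency model — the permutation null
holds by construction. This exchangeable baseline is deliberate: injecting
sites conditioned to be present in one cohort would build a specificity
excess into the "null" and no permutation test could be calibrated against
it.

Enrichment (ρ > 1) adds, in designated genes, case-private rare variants at
rate (ρ − 1) × the rare-pool rate, each guaranteed present in the cases
(1 + binomial extra copies) and absent from the controls and the reference —
the risk-variant alternative. Annotations are drawn per class
probabilities (missense 0.58, nonsense 0.025, remainder synonymous,
matching the observed coding-class proportions 69/3/47 of 119; concordant-
damaging probability 0.30 given missense ≈ 21/69); dbSNP membership is
likelier for common-pool sites (0.95 vs 0.15). Genotype-level output
places alt copies uniformly on chromosomes, giving HWE-consistent genotype
counts for the promoter-style workflow.

`generate_case_reference_pair` produces the matched case + aggregate
reference for the simulation test: candidate sites are drawn once, the case
samples each binomially and the reference samples the same frequency with
66,000 chromosomes, so the reference catalogues essentially every candidate
the way a deep exome aggregate dwarfs one study. The site universe is the
union of detections.

What the generator does **not** emulate: linkage disequilibrium (the
permutation test ignores it by design), sequencing/genotyping error and
platform differences between cohorts, population stratification, and
coverage-driven call-rate variation beyond optional uniform AN jitter.
Passing calibration on these fixtures therefore shows the procedures are
correct under their own assumptions; it cannot show robustness to
differential error between case and control platforms, which in real data
must be addressed upstream.

## Numerical and design choices

* Frequency thresholds are parsed as exact decimals (0.01 → 1/100) and
  compared in integer arithmetic; no floating-point boundary ambiguity.
* P-values from counting are exact fractions of replicate counts; the
  add-one mode bounds them away from 0.
* The per-gene total correlation is Pearson's r (the unqualified
  "correlation coefficient" of summary tables); it errors on fewer than 3
  genes or zero variance rather than returning NaN.
* Bonferroni adjustment is min(1, m·p) with a caller-supplied m, since the
  effective number of tests is a judgement call when statistics overlap.
* Problem sizes for the empirical studies: 1000 synthetic panels for each
  null-calibration estimate and 220 panels per enrichment level for the
  power curve, each with 400 permutation/simulation replicates (only the
  α = 0.05 decision is consumed); 5000 replicates for the z-test size and
  HWE-uniformity checks. These sizes put ~3 Monte-Carlo standard errors at
  about 2 percentage points on a rejection rate near 0.05.

## Empirical properties (recomputed by the test suite and acceptance script)

* Permutation P-values match exhaustive enumeration over all hypergeometric
  outcomes on panels of ≤ 3 sites and ≤ 12 pooled chromosomes within 3
  Monte-Carlo standard errors at n_perm = 1e5.
* At ρ = 1 both one-sided tests (add-one mode) reject at ≤ 0.06 for
  α = 0.05 across 1000 panels; power is monotone over ρ ∈ {1, 2, 4, 8}.
* The z-test's empirical size lies in [0.04, 0.06] under an equal-frequency
  null at study sample sizes, and HWE chi-square P-values are uniform
  (KS distance < 0.05) under simulated equilibrium at n = 288, MAF 0.3.

## Known limitations

* Ignoring LD means gene-level P-values treat sites as independent; for
  tightly linked promoter variants the effective number of independent
  sites is smaller than the site count.
* The strict tie mode can report P = 0; use the add-one mode when the
  replicate budget is small.
* The reference simulation test inherits any differential detection between
  the case platform and the reference's exome capture; it assumes the
  reference catalogues the population completely.
* The two-proportion test assumes allele-level independence (HWE within
  cohorts); it is an allele-count test, not a genotype association model.
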