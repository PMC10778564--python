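# Methods

## Scope and model

panelkit implements the analysis layer of an ultra-deep, molecular-tagged
amplicon cfDNA assay: from UMI-tagged reads (or a simulator standing in for
them) to somatic variant calls, copy-number gain calls and cohort statistics.
Wet-lab steps, alignment and vendor software are outside scope; their outputs
(tagged-read tables, per-amplicon coverage tables) are the package's inputs.

### Panel

The built-in replica panel has 273 amplicons over 46 prostate-cancer genes with
amplicon lengths drawn deterministically from 75–140 bp. Real designs are
proprietary, so coordinates are invented: genes are tiled on synthetic
per-gene blocks, AR receives 8 amplicons (the copy-number target needs a
multi-amplicon block) and the remaining 265 are spread round-robin over the
other 45 genes. Each amplicon carries exactly one interrogated locus (its
midpoint) with a deterministic reference base; all downstream rules operate on
allele/strand/UMI counts at these loci, so base-level sequence is never
synthesized.

### Synthetic-data generator

The generator emulates, with known truth:

1. **Spike-in AF standards** — three cell-line DNAs mixed into wild-type
   background so that four mutations (AR p.T878A, RB1 p.K715\*, TP53 p.R248W,
   TP53 p.V274F, each homozygous in its line) sit at 10%, 1%, 0.5% or 0.1%
   allele fraction; 22 ng input per standard. The VCaP-like line carries the
   AR amplification.
2. **Plasma samples** — a stated tumor fraction, per-gene somatic variants at
   stated AFs, optional AR gain, and metadata (PSA, cfDNA amount, therapy,
   CHAARTED volume inputs).
3. **Negative references** — wild-type DNA and a healthy male donor (no
   somatic variants, tumor fraction 0).
4. **Matched cohorts** — deterministic tumor/plasma variant-list structures
   for concordance analysis, and seeded cohorts with a stated PSA–ctDNA
   positivity effect for parameter-recovery checks.

Generative model per sample: mass → haploid genome equivalents
(GE = ⌊ng·1000/3.3⌋; 3.3 pg per haploid genome); per amplicon,
molecules ~ Binomial(GE, conversion efficiency); a molecule at a variant locus
is alternate with probability equal to the variant's target AF; reads per
molecule = 1 + Poisson(mean − 1), inheriting UMI and strand; each read's allele
flips to a random wrong base with the per-base error rate. Per-amplicon
coverage totals are negative binomial around the target depth. AR amplicons
are scaled by the diploid copy mixture factor f = ((1 − tf)·2 + tf·c)/2 for
tumor fraction tf at c copies, and the alternate-allele probability at AR loci
is divided by f (gained copies carry the reference allele, so molecule count
inflation and AF dilution cancel in expected mutant-molecule counts).

Key defaults, with units and rationale:

| parameter | default | why |
|---|---|---|
| pg per haploid genome | 3.3 pg | standard human genome mass |
| conversion efficiency | 0.5 | fraction of input molecules yielding a sequenced family; chosen so a 0.1% standard at 22 ng yields ~3 mutant families per variant, putting it at the stochastic detection edge where partial recovery is the expected outcome |
| reads per family | 1 + Poisson(8) | median family size 9, comfortably above the QC floor of 7 while keeping the ≥ 8 mean-family-size validity rule satisfiable |
| per-base error rate | 1e-3 | typical raw amplicon sequencing error; family consensus must suppress it |
| coverage depth target | 50,000× | the assay's stated minimum depth per amplicon |
| coverage dispersion | NB size 400 (CV ≈ 5%) | modest inter-amplicon variability so the ratio statistic's sampling noise is realistic but the calibration worked example is stable |
| spike AR copies | 25 | derived from the measured 10%-standard coverage ratio 119,842.8/55,644 ≈ 2.154 via f: c = (2·2.154 − 1.8)/0.1 ≈ 25. A disclosed calibration, not cell-line biology; it places the expected 10%-standard ratio at 2.15, safely above the threshold of 2, whereas a value putting the expectation exactly at 2.0 would make both calibration and detection coin flips under sampling noise |
| tumor AR copies (plasma scenarios) | 2 | no amplification unless requested |

**What the generator does not emulate** — and hence what passing tests do not
establish about real data: base-level sequence context and quality scores, PCR
chimeras and UMI collisions, fragment-length biology, systematic per-amplicon
efficiency differences (real molecular coverage ranges over orders of
magnitude; here uniformity is near 1 by construction), multi-locus amplicons,
indels, and contamination. Results on real libraries depend on upstream
alignment and tag integrity that the simulator assumes perfect.

## Consensus calling

Families are keyed by (amplicon, UMI); reads of a family must share a strand
(one tag marks one molecule; a conflict is a contract violation, not data).
Consensus is the majority allele; ties break toward the reference
(conservative). A "functional molecule" is any family with ≥ 1 read; the QC
median is over all families. Molecular uniformity is the fraction of panel
amplicons whose molecular coverage is ≥ 20% of the mean molecular coverage —
the common vendor definition, adopted because the term is otherwise undefined.

The validity rule — only amplicons with mean family size ≥ 8 are callable — is
one reading of an ambiguous requirement ("an average of 8 reads per amplicon
for each input DNA molecule"); the per-amplicon-mean reading is implemented
deliberately and exposed as `min_mean_reads` rather than guessed silently.

The support rule counts raw reads (≥ 3, both strands represented) while the
reported AF is family-based. The two spaces are intentionally mixed: read
counts are what the minimum-support sentence regulates, while molecular
families are the assay's unit of quantification.

The theoretical LOD uses m = 6 detectable mutant molecules; m is
reverse-engineered so that 20 ng and 50,000× give exactly 0.1%, and is
documented as such.

## Somatic filter cascade

Five conjunctive rules (a–e, see README). Design choices: the three public
germline databases collapse to a single `in_common_db` flag (the logic, not the
lookup, is the subject here); the accepted consequence set is the complement of
the stated exclusions within a minimal vocabulary {missense, nonsense,
frameshift, splice, synonymous, intronic, utr3, utr5}; an *unannotated*
consequence fails rule (d) — conservative, preventing unannotated noise from
passing; missing population MAF means "never observed" and is treated as 0.
The audit trail records the first failed rule in a→e order; the verdict itself
is order-independent (a pure conjunction), and both properties are tested.
The CHIP flag (AF < 1% and absent from matched tumor; indeterminate without
tumor) is advisory metadata for buffy-coat confirmation, never a filter.

## Copy-number ratio

The statistic is median (and mean) of raw per-amplicon total reads for the
target gene versus all other amplicons. No GC or length normalization: the
calibrated threshold is defined on raw ratios and normalization would move it.
Calibration takes the smallest amplification-positive ratio, floors it to one
significant digit, and requires it to strictly exceed every negative-reference
ratio (the 10% standard's measured 2.154 → threshold 2.0). The amplification
boundary is inclusive (ratio ≥ threshold): the defining positive sits at the
rounded threshold, which forces ≥ rather than >. Median is primary; the
mean-based call is computed alongside and any disagreement is surfaced on the
call object. Gene losses are not called — the panel is too small to resolve
them.

## Cohort statistics

Concordance is patient-level and requires ≥ 1 shared variant, matched on
(chrom, pos, ref, alt) — protein annotation is display-only. Patients whose
tumor has no panel-covered mutation are "no target mutation" and excluded from
the corrected rate; patients under 2 ng cfDNA are excluded as library
failures. Both the raw and corrected denominators are reported. CHAARTED
volume: high iff (≥ 4 bone metastases with ≥ 1 outside pelvis/spine) and/or
visceral metastases. The PSA contingency cutoff is 4 ng/mL with the boundary
going to the high group ("normal" is strictly < 4).

Fisher's exact test (two-sided, hypergeometric with fixed margins), Pearson
correlation (t-transform p, n − 2 df), Wilcoxon–Mann–Whitney (exact null when
n₁·n₂ ≤ 10,000 and tie-free, else normal approximation with continuity
correction and average ranks) and the t-test are delegated to scipy.stats
behind this module's interface; the t-test is Welch (the safer default when
equal variances are unverifiable, disclosed since the choice is not forced).
Constant samples with equal means return p = 1 by convention. Missing clinical
values are excluded pairwise per analysis and every result carries its
effective n. No multiple-testing correction is applied; p-values are raw.

## Numerical and engineering choices

- Determinism: every stochastic step takes an explicit seed; one generator
  family (numpy PCG64), with fixed sub-streams for molecule, read and coverage
  stages so outputs are byte-identical under a repeated seed.
- BED is 0-based half-open, VCF 1-based; conversions live only in the I/O
  module. VCF INFO floats are renormalized to 6 significant digits on read so
  written values round-trip exactly through htslib's float32 storage.
- LOD and threshold rounding use a 1e-9 relative guard against float noise at
  digit boundaries.
- Family grouping is vectorized (run-length on sorted keys, falling back to a
  stable sort for arbitrary input order), so full-scale samples (~8M reads,
  ~0.9M families) group in seconds.
- Degenerate inputs: empty read tables yield empty family tables; empty family
  tables fail QC with an explicit reason; zero background coverage raises
  rather than returning an infinite ratio; a calibration whose negatives reach
  the positives raises rather than emitting a threshold.

## Problem sizes used in tests

Unit and property tests run on a 6-amplicon panel or sub-nanogram masses where
the property under test does not depend on scale. The end-to-end sensitivity
checks use the full 273-amplicon panel at the 22 ng study condition: 20
replicates of the 0.5% standard (expecting 4/4 recovery in each) and 20 of the
0.1% standard (expecting partial recovery with mean strictly between 0 and 4 —
at ~1.7 expected mutant families per strand, single-strand-only support is a
common dropout mode). The copy-number null/detection checks use 100-plus
simulated coverage profiles per condition. The acceptance script reports
sensitivity over 20 seeded replicates of the 0.5% standard (80 recovery
opportunities).

## Known limitations

- Single-nucleotide events at one locus per amplicon; no indels, phasing, or
  multi-allelic handling.
- The annotation universe is synthetic; rule (b–e) behavior on real gnomAD /
  ClinVar idiosyncrasies (multi-allelic sites, conflicting submissions) is
  untested.
- The copy-number statistic detects strong gains at tumor fractions around
  10%; at 1% the expected ratio (~1.1) is indistinguishable from noise, which
  is a property of the assay, not a defect of the implementation.
- Tumor fraction itself is not estimated (panel too small for genome-wide
  copy profiles), and gene losses are out of scope.
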