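# Methods

## The genome-wide z-score

The copy-number route to cfDNA tumor fraction rests on one observation:
at tumor fraction θ, a segment present at tumor copy number c instead of
the diploid 2 changes its expected share of sequenced reads by the factor
((1−θ)·2 + θ·c)/2. Aggregating such deviations across the genome yields a
scalar instability score whose null distribution can be learned from
healthy donors.

The statistic is computed in three deterministic steps:

1. **GC correction.** Each bin's count rate (count/total) is divided by
   the median rate of its GC decile. Deciles are quantile bins of the
   genome's GC values — a property of the grid, not of the sample — so
   the correction is reproducible and scale-invariant. A decile with
   fewer than 5 bins falls back to the global median with a warning.
   Decile-median correction was chosen over LOESS because it is
   tolerance-free: two runs can be compared bit for bit.
2. **Per-segment standardization.** Segment ratio r_i is the mean of its
   bins' corrected ratios; z_i = (r_i − μ_i)/σ_i with μ_i, σ_i the mean
   and SD (ddof = 1) of the segment ratios across the healthy panel.
   Segmentation comes from the fixed genome definition (chromosome arms
   on a real genome; 20 toy segments by default) rather than data-driven
   changepoint detection, again for determinism.
3. **Genome-wide score.** S = Σ z_i² sums squared deviations over
   segments; Z = (S − μ_S)/σ_S, where μ_S and σ_S are the mean and SD of
   S computed leave-one-out within the panel (each donor scored against
   the other n−1). Z is unbounded and can be negative — a sample even
   more panel-like than a typical panel member.

Z ≥ 5 labels a sample high tumor fraction and Z in [2.5, 5) is annotated
as roughly 5–10% tumor fraction. These cutpoints are carried as fixed
workflow constants; on the toy genome the simulated Z–θ response is
steeper than that empirical calibration (Z crosses 5 near θ ≈ 0.04 under
default noise), which affects none of the monotonicity or null-calibration
properties but means the band annotations should not be read as estimates
of the toy cohort's θ.

Leave-one-out panel calibration requires at least 4 donors (3 remaining
per fold) and errors out on zero segment SD or zero S variance rather
than guessing. Whether the published statistic aggregates per-bin or
per-arm deviations, and whether S sums squares or absolute values, is not
recoverable from the sources available; the standardized sum-of-squares
construction above is this package's defining contract, and the
properties tested against it (null calibration, monotonicity in θ,
scale invariance, copy-number-neutral blindness) are the ones any
reasonable variant would share.

## Fragment-size features

Short fragments are 1–150 bp and long fragments 151–500 bp, both bounds
closed; a fragment of length 150 is short and 151 is long. The
short/long ratio uses raw counts with no pseudocount — an empty long
range is an error, not a zero. Window fractions are evaluated
independently on closed intervals and may overlap. Lengths outside
[1, 500] are excluded at ingest and counted. Fragment lengths arrive as
(length, count) tables; parsing them from alignment template lengths is
left to a thin adapter (absolute template length, proper pairs only) so
the core stays dependency-light. No capture-bias correction is applied to
targeted-assay fragment sizes; this is a recorded simplification.

## Tumor-fraction classifier

The label is mVAF ≥ 10%. Features are standardized on training folds
only, inside a pipeline, and fit by maximum-likelihood logistic
regression (no penalty). Quasi-complete separation is detected via
non-convergence and handled by refitting with a fixed small ridge penalty
(C = 1000), logged. Folds are stratified and seeded; out-of-fold
predicted probabilities are pooled into a single ROC curve (pooling was
chosen over averaging per-fold AUCs to give one comparable curve; with
~20 positives per cohort, per-fold ROC curves would rest on 3–4
positives each). Feature sets are compared on an identical fold
assignment, so AUC differences are paired. AUC is the rank statistic
(ties count 1/2), which equals the trapezoidal area under the empirical
ROC; the suite verifies the equivalence numerically.

## Detection limits

Detection is deliberately threshold-based — the workflow's question is
"what would the assay report", not "what is statistically present":

| mode | limit | applies to |
| --- | --- | --- |
| genotyping | 1% VAF | loci known from the patient's tumor |
| de novo | 2% / 5% VAF | hotspot / non-hotspot loci |
| ultra-deep | 0.1% VAF | loci in the small (129-gene analog) panel |

plus a read-support floor of 3 variant reads for the targeted modes and
2 for the ultra-deep mode. The published limits are pure VAF thresholds;
the floor is this package's guard against single-read artifacts and is
configurable. In genotyping mode, loci not on the known list fall back to
the de novo thresholds, mirroring how a combined genotyping + de novo
assay behaves. Loci outside a mode's panel are dropped with a log
message, as a capture assay simply does not see them.

mVAF is the median VAF of detected mutations (a config switch allows the
mean for sensitivity analysis; the median is the primary definition).
Zero detections leave mVAF absent, never zero. TMB divides the
non-synonymous detection count by 1,016,478 bp of panel territory;
≥ 10 mutations/Mb is TMB-high. CCF ≥ 0.75 defines clonal, CCF < 0.75
subclonal, absent CCF unknown. MSI scores are accepted as a pass-through
column and not interpreted.

## Concordance statistics

Fisher's exact test conditions on both margins and uses the two-sided
minimum-likelihood rule: sum the probabilities of all tables with the
same margins whose probability does not exceed the observed table's.
Probabilities are evaluated in log space (gammaln), so tables with N in
the hundreds remain exact to double precision; a relative tie tolerance
of 2e-12 is wide enough to absorb float error in genuine ties and narrow
enough never to swallow a distinct hypergeometric probability at the
table sizes enumerated in the tests. The minimum-likelihood rule (rather
than the doubling rule) is the dominant convention and the one that
reproduces the published p-values. The Mann-Whitney U test enumerates all
rank configurations exactly when min(n_x, n_y) ≤ 8 without ties, else
uses the normal approximation with tie and continuity corrections. The
Yates χ² is N·(max(0, |ad−bc| − N/2))²/((a+b)(c+d)(a+c)(b+d)) on 1 df,
with zero margins rejected. TMB concordance reports Pearson r, the
least-squares slope of plasma on tumor, and the correlation t-test
p-value per tumor-fraction stratum; degenerate variance yields an absent
(NaN) entry. Strata are single pre-specified comparisons; no
multiple-testing correction is applied.

## Triage

Detection short-circuits everything: a sample with any stage-1 detection
is reported. Otherwise Z < 5 routes to the ultra-deep assay and Z ≥ 5 to
exome-scale profiling. An optional `material_available` flag converts a
reflex decision into `reflex_unavailable` for honest accounting of
insufficient-material dropout. A reflex assay that also finds nothing is
reported as a final non-detection without further routing. Branch counts
always sum to the cohort size, and stage-2 profiles are only accepted for
samples that were actually reflexed.

## The synthetic cohort

The generator emulates the data-generating process the analysis assumes,
at the study's assay scales: ~10M sWGS reads, 644× tumor depth, 631×
plasma targeted depth, 12,000× collapsed ultra-deep depth, a 10-donor
healthy panel and 118 patients.

* **Coverage.** Expected bin weight = bin length × GC factor
  (1 + 0.5·(gc − 0.40)) × copy-number mixture ((1−θ)·2 + θ·c)/2 ×
  a per-sample, per-segment lognormal biological factor (σ = 0.008,
  representing inter-individual coverage variability the panel must
  absorb). Counts are negative-binomial with variance = 2 × mean.
* **Fragments.** Discretized normals on [1, 500] bp: normal cfDNA mode
  166 bp, tumor mode 145 bp, both SD 25 bp; a per-sample mode jitter
  (SD 6 bp) represents biological and library-preparation variability.
  The tumor-component weight is the genome-averaged molecule fraction
  θ·c/(θ·c + (1−θ)·2). The jitter value was calibrated so the size
  ratio is informative but noisier than the copy-number score, placing
  the size-only AUC near 0.8 on default cohorts — the qualitative
  regime reported for real cohorts.
* **Mutations.** Expected plasma VAF = θ·CCF·m/(θ·c + (1−θ)·2)
  (multiplicity m, default 1; tumor purity 1). Observed alt counts are
  binomial at assay depth with a substitution-error floor (2e-4
  targeted, 1e-5 post-collapse ultra-deep). Tumor allele counts use
  CCF/c directly. Per patient: 1 + Poisson(4) mutations, 60% clonal
  (CCF ~ U(0.75, 1)), hotspot probability 0.25, ultra-deep panel
  membership 0.4; 8% of patients are panel-negative (all drivers outside
  both panels — the case the exome reflex exists for); 64% have matched
  tumor sequencing, enabling genotyping mode and concordance analysis.
* **Cohort θ.** No empirical θ distribution is available to this
  package, so the default is log-uniform on [0.004, 0.6]: most
  metastatic patients shed little tumor DNA, a minority shed a lot, and
  ~19% of patients land above the mVAF ≥ 10% boundary (θ ≈ 0.2 for
  clonal diploid tumors), matching the reported high/low split. The
  floor sits below the 1% targeted detection limit (θ ≈ 0.02) but above
  the ultra-deep limit (θ ≈ 0.002), so the reflex stage has real work
  to do.
* **Copy-number-quiet tumors.** 15% of patients have their CNA
  deviations scaled by U(0.2, 0.6), emulating tumors whose fraction
  cannot be read from coverage alone — the known blind spot of the
  copy-number route and the reason the size features exist.
* **Seeding.** One master seed; per-sample streams derive from
  SeedSequence(master, crc32(sample_id)), so any sample regenerates
  independently and runs are bit-identical.

What passing tests on this cohort do **not** show: performance on real
plasma, where GC bias is not a smooth linear factor, fragment-length
laws are not normals, CHIP variants contaminate plasma-only calls, tumor
purity is below 1, and the θ distribution is whatever the clinic sends.
The generator contains no read-level artifacts (FASTQ/BAM), no indels or
SVs, and no tumor-purity modeling.

## Problem sizes and numerics

The toy genome is 20 segments × 50 bins of 1 Mb. Default test and
acceptance runs use the full 118-patient cohort at the study's read and
depth scales (a cohort simulates in ~1 s); unit tests use scaled-down
cohorts (≤ 24 patients, ≤ 1M reads) where only contracts, not power, are
at stake. Degenerate inputs fail loudly by policy: all-zero coverage,
zero panel SDs, empty long-fragment ranges, one-class ROC labels and
zero-margin contingency tables all raise typed errors rather than
returning sentinel values.
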