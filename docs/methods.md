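# Methods

## The in-vivo error-rate statistic

A transcription error in mature RNA shows up in RNA-seq as a mismatch
between an aligned read and the reference genome. Two other processes
produce exactly the same signal: base-calling errors (whose probability is
encoded per base in the Phred score, p = 10^(−Q/10)) and fixed single-base
differences between the sequenced strain and the reference (SNVs). The
statistic is designed so both contaminants are suppressed *before* rates are
computed:

* **Quality thresholding.** A base call participates only if Phred ≥ `qmin`
  (default 30, i.e. a residual base-calling error probability ≤ 10⁻³, of
  which one third lands on any particular wrong base). Sub-threshold calls
  are excluded from the numerator *and* the denominator, keeping E(p) a
  frequency over a well-defined set of bases. The alternative convention —
  thresholding only the numerator — deflates rates by inflating the
  denominator with bases that were never allowed to contribute a mismatch;
  it is available as `threshold_numerator_only=True` for comparison.
* **Variant masking.** A reference position is excluded when ≥ `alt_fraction`
  (default 0.8) of its quality-passing coverage (≥ `min_coverage`, default
  10) agrees on one non-reference base. A heterozygous-like tie between two
  alternative bases is masked when their combined fraction clears the
  threshold — conservative exclusion protects the error statistic, which is
  the consumer of the mask. Transcription errors themselves (~10⁻³ per base)
  cannot reach an 0.8 consensus at any realistic coverage, which is why the
  caller has essentially zero false-mask rate in the recovery tests.
* **Alignment policy.** Reads must be uniquely placed with ≤ 3 mismatches,
  and only single-match-run (substitution-only) alignments are accepted;
  anything else is skipped with a warning. This mirrors an ungapped
  short-read alignment model and bounds the damage a misplaced read can do.
* **Coordinates and strand.** Reference positions are 0-based internally and
  1-based only at the SAM/VCF boundary. Read positions are 1-based in
  sequencing direction; reverse-strand alignments are reverse-complemented
  into read orientation on load, so position 7 means the 7th sequenced base
  and substitution types are reported on the RNA-level strand (a C→U
  transcription error reads as C>T).

Rates are percentages. `N(p) = 0` yields NaN (undefined), deliberately
distinct from an observed 0%. The per-position counts decompose exactly:
Σ_s M(p, s) = M(p), asserted on every construction of the table.

Between-sample comparison (`compare_samples`) returns 100·E_a/E_b with a
binomial standard error, se/ratio = sqrt((1−p_a)/M_a + (1−p_b)/M_b),
treating the two mismatch counts as independent binomials. At desk-scale
read counts this sampling error is the dominant uncertainty: the counts at a
single read position are small, and any comparison should be read against
the propagated s.e. the function reports.

## The synthetic-data generator

The generator emulates the statistical structure the statistic assumes —
nothing more:

* a uniform-composition genome with a configurable GC fraction, and a
  "sample genome" differing at exactly `round(L·snv_fraction)` uniformly
  placed SNV positions;
* strand-specific reads with uniform starts on the sense strand of the
  sample genome (a `include_reverse` flag adds reverse-strand reads;
  default off, matching a strand-specific library);
* three independent per-base event channels applied in causal order:
  SNV (carried by the sample genome), then a transcription error drawn from
  a 4×4 off-diagonal substitution matrix over the template base, then a
  sequencing error with probability 10^(−Q/10) for the base's sampled Phred
  Q, replacing the current base with one of the three alternatives uniformly.
  When several events hit one site, all are recorded in the truth table with
  before/after bases, so chains resolve unambiguously to the emitted base.

The default quality profile declines linearly from mean Phred 38 (position 1)
to 28 (last position) with s.d. 3, truncated to [2, 41] — a realistic mixture
of bases above and below the Q30 threshold, so the threshold actually does
work in tests. Determinism is strict: one integer seed, fanned out through
`numpy.random.SeedSequence` per stage, gives byte-identical FASTA/ FASTQ/
SAM/VCF/TSV outputs.

What the generator does *not* model — and therefore what passing recovery
tests do not show about real libraries: PCR duplicates, indels, paired-end
structure, expression-level (coverage) heterogeneity, reverse-transcription
errors as a separate channel (folded into the sequencing channel), and
context-dependent base-calling error. Uniform coverage is intentional: the
estimator is coverage-weighted by construction, so uniformity isolates the
statistic under test.

Kinetic series are drawn from the named model at its true parameters plus
Gaussian noise on the model's natural response scale: additive on fractions
and velocities (exponential, Michaelis–Menten), on ln k for Arrhenius and
the pH titration, and on log₁₀ k for the log-linear pH model. Rate-valued
responses get log-scale (≈ proportional) noise because measured rates are
strictly positive and their replicate scatter is proportional to the value
(experimental point-wise s.d. in this kind of assay is ~10–15% of the
value); additive noise on a titration curve spanning decades would go
negative at the low-pH end.

## Fitting

* **Exponential and Michaelis–Menten**: bounded nonlinear least squares
  (scipy `curve_fit`, trust-region reflective) with deterministic,
  derivative-free starts — k₀ from the initial slope over the amplitude;
  (k_cat, K_M)₀ from a Lineweaver–Burk linearization. Bounds keep rates
  non-negative and the exponential amplitude in (0, 1.1] (fractions may
  overshoot 1 through noise). Degenerate inputs (all-zero response;
  monotone-linear MM data with K_M escaping past 50× the largest
  concentration) return a *flagged* result rather than raising, so batch
  fitting proceeds. A fitted K_M outside the sampled concentration range
  triggers a warning that the design misses the half-saturation point.
* **Arrhenius and log-linear pH**: closed-form OLS (these models are linear
  in their transformed coordinates); E_a = −slope·R reported in kJ·mol⁻¹
  with the slope s.e. propagated. Temperatures are accepted in °C or K via
  an explicit unit flag; everything is Kelvin internally. Non-positive rates
  are rejected (their logarithm is undefined) rather than silently dropped.
* **pH titration**: fitted on the log₁₀ k scale (matching the error
  structure above), pK_a starting at the pH of half-maximal rate, Hill-like
  slope n bounded to [0.3, 3].
* **Model selection** between the two non-nested pH shapes uses AICc on the
  common log₁₀ k response; a score difference < 2 is flagged ambiguous, and
  an essentially flat profile (log₁₀ k range < 0.05) is flagged degenerate
  because neither shape is identified.
* **Weighting**: unweighted least squares throughout — the assays provide no
  per-point variance model.
* **Fold changes** use the delta method: se(a/b) = (a/b)·sqrt((se_a/a)² +
  (se_b/b)²), valid when the relative errors are small; the test suite
  checks it against Monte-Carlo resampling.

Parameter uncertainty comes from the Jacobian-based covariance of the
least-squares fit. The calibration sweep (200 replicates per model at the
default noise levels) keeps the primary parameter's median absolute relative
error within 5% and 1-s.e. coverage near the Gaussian 68%, so the reported
standard errors can be taken at face value under the generator's noise
model.

## Problem sizes

All validation runs on synthetic data at sizes chosen to make the binomial
or regression sampling error small relative to the tolerances being checked:
the main error-statistic run uses a 50 kb genome with 40 000 × 50 bp reads
(≈ 1.6×10⁶ quality-passing included bases, ~30× quality-passing coverage for
the variant caller); the between-sample ratio comparison uses 4×10⁶ × 25 bp
reads per sample, processed in 250 000-read chunks to keep memory flat,
giving a ratio s.e. of ≈ 5 percentage points; kinetics recovery uses the
assay-like designs listed in the tests (10 time points, 6–7 concentrations,
10 temperatures over 0–45 °C, 9 pH points over 1.5+ units).

## Known limitations

* The statistic estimates per-position rates at the read level; it does not
  aggregate to transcript-level error rates or model expression structure.
* The variant caller is a frequency-consensus rule intended to build an
  exclusion list from deep, clean coverage; it is not a general-purpose
  genotyper and will miss variants in low-coverage regions (those positions
  then leak SNV mismatches into the error rate, which is why coverage ≥ 20
  is the regime the recovery guarantees refer to).
* The sequencing-error channel trusts the reported Phred scores; systematic
  miscalibration of qualities in a real instrument run would bias the
  residual contamination estimate.
* Fold-change propagation assumes independent, approximately Gaussian
  parameter estimates; for ratios of poorly determined parameters the
  Monte-Carlo route is the safer check.
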