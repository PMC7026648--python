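# transfidelity

Tools for two questions about transcription fidelity in bacteria and
cyanobacteria:

1. **How often does RNA polymerase put the wrong base into mRNA in vivo?**
   Estimated from RNA-seq alignments as a position-wise, substitution-specific
   mismatch statistic with Phred-quality thresholding and genomic-variant
   exclusion, so that sequencing errors and strain SNVs are not mistaken for
   transcription errors.
2. **How efficient is the polymerase's intrinsic proofreading (transcript
   cleavage)?** Characterised by fitting enzyme-kinetics models to in-vitro
   assay series: single-exponential time courses, Michaelis–Menten Mg²⁺
   titrations, Arrhenius temperature series, and pH–rate profiles.

The package is aimed at people analysing transcription fidelity experiments —
RNA-seq mismatch spectra on one side, gel-quantified cleavage kinetics on the
other — and ships a synthetic-data module that generates both kinds of input
with known ground truth, so every stage of the analysis can be validated by
parameter recovery.

## The error-rate statistic

For read position *p* (1-based, in sequencing direction) and substitution type
*s* (one of the 12 ref→obs changes, reported on the RNA-level strand):

```
E(p)    = 100 · M(p) / N(p)        (percent)
E(p, s) = 100 · M(p, s) / N(p)
```

where `N(p)` counts reads whose base at *p* passes the inclusion predicates —
neither read nor reference base is `N`, Phred ≥ 30 (quality < 30 excluded),
and the reference position is not a masked single-base variant — and `M(p)`,
`M(p, s)` count the included bases that mismatch the reference (by type).
Note the denominator is *all* included bases at *p*, not only those whose
reference base matches the left side of *s*: with ~25% C content, a C→U
transcription-error rate of 2×10⁻³ per C appears as E(p, C>T) ≈ 0.05%.

Upstream filters mirror an ungapped, substitution-only alignment policy
(unique placements, at most 3 mismatches). Genomic variants are masked by a
transparent frequency-consensus rule: a position is excluded when ≥ 80% of
its quality-passing coverage (≥ 10×) agrees on one non-reference base.

## Kinetic models

| model | form | reported parameters |
|---|---|---|
| exponential | y(t) = A·(1 − e^(−kt)) | rate k (s⁻¹), amplitude A |
| michaelis_menten | v(c) = k_cat·c / (K_M + c) | k_cat, K_M (mM Mg²⁺) |
| arrhenius | ln k = ln A − E_a/(R·T), R = 8.314 J·mol⁻¹·K⁻¹ | E_a (kJ·mol⁻¹), ln A |
| ph_loglinear | log₁₀ k = c₀ + g·pH | gradient g |
| ph_titration | k = k_max / (1 + 10^(n·(pK_a − pH))) | k_max, apparent pK_a, slope n |

`analyze_ph_profile` fits the last two (non-nested) models on the common
log₁₀ k scale and selects by small-sample-corrected AIC: a log-linear profile
with g ≈ 1 indicates rate tracking hydroxide concentration, while a
plateauing titration curve with an apparent pK_a indicates a general base
participating in catalysis. `fold_change` compares any fitted parameter
between two enzymes with delta-method error propagation.

## Worked example

The demo simulates a transcriptome (20 kb genome, 20 000 × 50 bp reads,
C→U transcription errors at 2×10⁻³, 0.5% SNVs, realistic declining quality
profile), masks variants, computes the error table, fits all four kinetic
model families to noisy synthetic series, and checks every recovered value
against its generator truth:

```bash
transfidelity demo --out demo_out --seed 5
```

`demo_out/report.md` from that exact command:

```
Error statistic: E(7, C>T) = 0.0507% over 19726 included bases (configured
transcription rate 2.00e-03).
```

0.0507% is the per-included-base rate at read position 7: with this genome's
~25% C content the configured per-C rate of 2×10⁻³ predicts
100·(0.25·2×10⁻³ + sequencing residual) ≈ 0.05%. The report also records a
variant-mask recall of 1.0 (100/100 true SNVs masked), a fitted exponential
rate of 0.0160 s⁻¹ (truth 0.016), k_cat = 1.98 and K_M = 4.97 (truth 2 and
5), E_a = 60.3 kJ·mol⁻¹ (truth 60), and a pH titration selected with
pK_a = 6.74 (truth 6.8) — every check marked `yes`.

The same pieces are available as a library:

```python
import transfidelity as tf

cfg = tf.SimConfig(genome_length=50_000, n_reads=40_000, read_length=50,
                   transcription_error_matrix=tf.substitution_matrix(**{"C>T": 2e-3}),
                   snv_fraction=0.005, seed=101)
genome = tf.simulate_genome(cfg)
reads  = tf.filter_alignments(tf.simulate_reads(cfg, genome).to_aligned_reads(genome))
mask   = tf.call_variant_mask(reads, genome.reference)
table  = tf.compute_error_table(reads, genome.reference, mask, qmin=30)
print(tf.specific_error_rate(table, read_pos=7, substitution="C>T"))
```

Real data enter the same way through `tf.read_alignments("sample.sam",
"reference.fa")`, or via `transfidelity errors --sam sample.sam --ref
reference.fa --out results/`.

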