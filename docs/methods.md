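# Methods

## Statistical model of the discovery stage

The discovery analysis treats log2 LFQ intensities as approximately normal
(protein-wise), with each patient contributing a *paired* observation. For
protein *p* and patient *i* the per-patient fold change is

    FC_pi = log2 I(p, followup_i) − log2 I(p, baseline_i),

computed only where both intensities are present (pairwise-complete; nothing
is imputed, and the per-protein share of incomplete pairs is reported as
"% blanks"). The direction convention is follow-up minus baseline, so a
protein suppressed by treatment carries a negative fold change. The median
of the available FCs summarizes the protein; the concordance percentage is
the share of available FCs whose sign matches the median's (exact zeros
count toward neither sign; if the median is exactly zero the larger sign
fraction is reported).

Significance is a two-sided paired t-test on the differences, BH-corrected
across all testable proteins at FDR < 0.01. A protein is testable when it
has at least `min_pairs` (default 2) complete pairs and nonzero variance of
differences; otherwise its p-value is undefined, it is flagged, and it does
not enter the BH denominator. BH itself is the standard step-up procedure
with monotonicity enforcement (statsmodels `fdr_bh`); the test suite checks
it against a hand-rolled step-up oracle.

### Immunoglobulin handling and the fold-change cutoff

Proteins whose keyword set contains UniProt keyword KW-1280 /
"Immunoglobulin" form a distinct distributional class: they shift coherently
downward under immunomodulatory treatment and would otherwise distort the
fold-change distribution. The z-score fold-change cutoff therefore estimates
its reference mean and sample SD over **non-immunoglobulin** proteins only;
every protein (including immunoglobulins) then receives a two-sided normal
tail probability relative to that reference, and `high_fc` requires a strict
tail < 0.05. Verification candidates are the conjunction FDR < 0.01,
z-tail < 0.05, concordance > 80% (strict inequalities), with a config list
for force-included proteins of special interest.

### Degenerate inputs

Zero or negative intensities that are not encoded as missing raise an error
(LFQ zero means "not quantified" and is parsed to missing at I/O time).
A zero-variance protein has an undefined t-test p-value by construction. For
the concordance categorization only, a zero-variance protein with a nonzero
median fold change is classed as changed: in the zero-noise limit identical
nonzero differences across all patients are maximal, not absent, evidence.
This keeps the categorizer's behavior continuous in the noise level.

## Concordance categories

The treatment state (increased / decreased / unchanged by FDR < 0.01 plus
fold-change sign) is crossed with the reference state (increased / decreased
/ unchanged / absent) into six mutually exclusive, exhaustive categories.
Reference entries never quantified in the treatment data are reported
separately rather than silently dropped, since accession-matching failures
occur in both directions in cross-study comparisons.

## Over-representation test

For each term with at least one annotated background protein the upper-tail
hypergeometric probability P[X ≥ k] is computed with N the background size,
K the term's background count, n the subset size and k the subset hits;
BH correction runs across tested terms only. Annotations are restricted to
the background before counting, and annotations with excluded evidence
codes (default IEA) are removed first. No ontology-graph propagation is
performed — annotations are taken as given flat sets, which is a stated
limitation: terms whose signal lives only in descendant terms will be
missed.

## PRM verification

**Peak QC.** Fragments with |mass error| > 10 ppm are dropped; a measurement
survives with ≥ 3 remaining fragments and ≥ 8 points across the
chromatographic peak. When one trypsinated replicate's peak is truncated
and its sibling's is not, the clean replicate alone represents the sample;
if both are truncated, both are kept (no better information exists). The
per-measurement ratio is the quotient of summed surviving light and heavy
fragment areas — summing before dividing is robust to single-fragment
dropout (per-fragment ratio averaging is selectable via the orientation
config). QC precedes quantification throughout.

**Calibration.** The reverse curve varies the heavy standard (8×, 4×, 2×,
1×, 0.5×, 0.25×, 0.125×, 0.06×, 0.03× of the nominal 1:1 level — a 2.4
orders-of-magnitude span) against a constant pool, in trypsinated
duplicates. The fit is weighted least squares of ratio on theoretical
concentration (fmol/µl injected) with weights 1/concentration, reflecting
the larger absolute variability at high concentration under multiplicative
noise. Fits require ≥ 3 points and by default a span of ≥ 1 order of
magnitude.

**Linear range.** Manual inspection of the low-concentration region is
replaced by an automated surrogate: starting from the full series, the
lowest level is trimmed until a refit on the retained levels back-calculates
every retained level's mean concentration within a relative bias tolerance
(default 20%, a common targeted-proteomics acceptance band). The retained
bottom level is the lower limit of quantification; tightening the tolerance
can only shrink the range (verified as a property test). If no trim
succeeds the curve has no linear range and quantification refuses to run.

**Quantification.** Concentration = (ratio − intercept)/slope on the
calibration scale; values below the linear range are censored as < LOQ
*before* any transformation; survivors are rescaled by the sample's heavy
spike level relative to the calibration's nominal spike (the reported
concentration is proportional to the assumed spike level — doubling the
spike doubles every reported concentration exactly), converted to fmol/µl
sample, log2-transformed and averaged over replicates; a single valid
replicate is representative on its own. Verification statistics reuse the
discovery machinery (median log2 FC, concordance %, paired t, BH) at
FDR < 0.05, plus a seeded percentile bootstrap (default 2000 draws) for a
95% CI of the median fold change — the bootstrap is a pragmatic, explicitly
non-canonical CI choice for a median of paired differences.

## The synthetic-data generator

`simulate_cohort` draws, on the log2 scale,

    x(p, i, t) = μ_p + b_i + δ_p·1[t = followup] + ε_pit,

with protein baselines μ_p ~ N(25, 2²) (an LFQ-like scale), patient
intercepts b_i ~ N(0, 0.5²) shared by each pair, residual noise
ε ~ N(0, noise_sd²), and shifts δ_p that are 0 for unchanged proteins,
± effect_size for a `frac_changed` subset (default 25%, ±0.5), and a
coherent −0.8 for the immunoglobulin class (default 5% of proteins, which
also carries the KW-1280 keyword and extra missingness). Missingness is
missing-not-at-random: logistic in the true log2 abundance with a base rate
(default 10% at the cohort's center abundance) and slope 0.8 per log2 unit,
so low-abundance proteins drop out more — the dominant mechanism in
label-free data. Defaults mirror a 56-patient, ~1200-protein CSF discovery
cohort; tests and examples use smaller sizes, stated per test. Generation is
a pure function of the config (fixed seed ⇒ byte-identical tables).

`simulate_calibration` produces ratio = slope·conc + intercept under
multiplicative log-normal noise with a given CV (unit mean), optionally with
a low-end **response floor**: below a threshold concentration the mean
response stops tracking the dilution, emulating interference/
detection-limit plateaus. A floor is used rather than a saturation-style
multiplier because the multiplier c/(c+h) is nearly affine over a dilution
series and is absorbed by the fitted intercept, never producing the > 20%
back-calculated bias that defines a trimmable nonlinear region. With the
floor at 0.1 and the nine-point design, the two lowest levels exceed the
bias tolerance and the linear range starts at the third level (0.125×).

`simulate_prm_export` writes Skyline-style transition rows: per-peptide
patient concentrations are log-normal around the 1:1 spike with a paired
log2 effect, the measured ratio responds linearly to concentration, total
heavy signal is spread over fragments with small per-fragment noise, and
low-point-count, high-ppm and truncated records are injected at small rates
to exercise every QC rule.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: peptide-to-protein inference, between-protein
correlation (co-regulation), retention-time or batch drift, interference
that biases rather than censors, non-normal heavy-tailed noise, and real
annotation structure (GO terms are flat synthetic sets). Statistical
guarantees (FDR control, recovery rates) are therefore statements about the
generator's assumptions, not about any particular instrument or cohort.

## Verification scale and determinism choices

The acceptance checks run at the sizes the properties are stated for:
hundreds of null cohorts of 200 proteins × 30 patients for FDR control, 100
seeds of 56-patient cohorts for shift recovery, 200 seeded duplicate curves
for slope recovery — sizes chosen so each property's Monte-Carlo error is
small against its acceptance band. Slope recovery at 5% measurement CV has a
mean per-curve relative error near 1.7% with a small tail beyond 5%, so the
5% figure is asserted on the mean (with a secondary ≥ 90%-of-curves check),
not on every single draw. One global seed fans out to per-stage seeds by
hashing the stage name, so stages are individually reproducible and a full
`run-all` is byte-identical across runs; all derived seeds stay below 2^31.

## Known limitations

- Protein groups with multiple accessions are joined on the accession string
  as given; no protein-inference or isoform handling.
- The reference list is a single consolidated direction per protein; no
  multi-study vote rules.
- The linear-range rule is an automated stand-in for expert inspection and
  can differ from a human call near the tolerance boundary.
- The z-score cutoff assumes the non-immunoglobulin median-FC distribution
  is adequately normal; heavy tails would inflate the flagged set.
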