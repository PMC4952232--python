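# Methods

This note documents the statistical model behind `remsig`, the conventions
chosen where the procedure admits more than one reasonable reading, and
what the synthetic cohorts do and do not establish about real data.

## Study setting and outcome model

The pipeline targets a three-arm observational design: rheumatoid-arthritis
patients starting one of three biologics, with whole-blood expression
profiled at baseline and the therapeutic outcome read off the Clinical
Disease Activity Index (CDAI) at month 6. Remission (REM) is CDAI ≤ 2.8;
the boundary value itself is remission. A patient who discontinues before
month 6 has no month-6 CDAI; the last observed CDAI is carried forward
(LOCF) and the label follows from the imputed value. Labeling is therefore
deterministic and idempotent given the visit series, and a patient with no
CDAI observation at all is rejected rather than silently labeled.

## Preprocessing

Quantile normalization equalizes the full intensity distribution across
samples: each sample's values are replaced by the across-sample mean of
order statistics at matching ranks. Within-sample ties receive the mean of
the reference values at the tied rank positions (the limma-style
convention; with continuous intensities ties are measure-zero, so the
sorted vectors of all samples are bit-identical after normalization).
Detection filtering keeps probes "present" in strictly more than
`min_present` samples (default 50, counted over the pooled cohort) and,
when an annotation map is supplied, drops unannotated probes. Where a
dataset carries no scanner detection calls, `detection_calls` provides an
explicit substitute rule — present iff the value lies above a configurable
quantile of its sample column (default 0.10) — recorded in provenance.
Multi-probe genes collapse to the probe with the highest mean intensity
across all samples, kept verbatim (no averaging); "highest signal
intensity" is interpreted as highest mean because the mean is
order-invariant and the conventional collapse summary. Normalization
precedes filtering.

## Enrichment analysis

Genes are ranked by the signal-to-noise ratio between outcome classes,
s = (μ_A − μ_B)/(σ_A + σ_B), with the class order fixed as
(A, B) = (NON-REM, REM), so positive s means NON-REM-upregulated and a
positive enrichment score reads "NON-REM > REM". Each class SD is floored
at max(0.2·|class mean|, 0.2) — the convention of the reference desktop
implementation — so near-constant genes cannot dominate the ranking. The
metric is computed on log2(intensity + 1) by default (configurable to the
linear scale); ranking ties break lexicographically by gene id so results
are reproducible to the bit.

For a set with N_H members among N ranked genes, the running statistic
rises by |s_i|^p / Σ_hits |s_j|^p at a member and falls by 1/(N − N_H)
otherwise; the ES is the signed maximum deviation from zero, and the
weight exponent defaults to p = 1 (the classic "weighted" statistic; p = 0
recovers the ordinary two-sample KS deviation, which is how the
implementation is cross-checked against an independent ECDF oracle). If
every member's metric is exactly zero at p > 0, the walk degrades
gracefully to equal weights. Core (leading-edge) genes are the members at
or before the peak (ES > 0) or at or after the trough (ES < 0).

The null is phenotype permutation: labels are shuffled preserving class
sizes, the metric and every ES are recomputed (default 1000 permutations,
shared across sets). Nominal p is one-sided among same-sign null scores
and floored at 1/(same-sign count); when no null score is as extreme the
value is flagged as an upper bound ("< 1/n_perm"). NES divides the ES by
the mean magnitude of the set's same-sign null scores. The FDR q compares
the same-sign tail fraction of the pooled null NES with the same-sign tail
fraction of the observed NES, clipped to [0, 1] and made monotone within
each sign. Significance combines nominal p < 0.05 with q < 0.1; set sizes
outside [15, 500] after intersection with the dataset are excluded.

## Signature scores

Every core gene is standardized across the pooled cohort (all arms — the
z-transform population is deliberately the full cohort even though each
signature is evaluated within one arm), using the sample SD (n − 1);
zero-variance genes are dropped with a warning. A patient's signature
score is the plain mean of core-gene z-scores, which makes the score
invariant to gene-wise affine rescaling of the raw matrix and makes the
score of a union of disjoint cores the size-weighted mean of the component
scores — both identities are tested exactly. Signatures whose score
vectors correlate at r ≥ 0.95 are consolidated to one representative
(caller-supplied priority, e.g. blood-cell sets over pathway sets); the
default threshold keeps 0.96/0.99-level duplicates merged while leaving
0.77–0.91-level relatives separate.

## Association and prediction

Firth's penalized likelihood ℓ*(β) = ℓ(β) + ½ log det I(β) (Jeffreys-prior
penalty) is maximized by Newton iteration on the hat-diagonal-modified
score with component-wise step capping and step-halving; convergence is
max |score| < 1e−6 within 100 iterations, and non-convergence is flagged
on the result rather than raised. Estimates are finite even under complete
separation, the regime where ordinary ML diverges. Per-predictor p values
are penalized likelihood-ratio tests (the constrained fit keeps the full
penalty, maximized over the free coefficients). Confidence intervals are
profile penalized-likelihood intervals — bisection to 1e−6 on the
coefficient scale against the χ²₁ quantile, reported on the OR scale; a
bound that cannot be bracketed within ±20 on the coefficient scale is
reported open and flagged. Profile intervals were chosen over Wald because
near-separation makes the likelihood surface strongly asymmetric, which is
exactly when Wald intervals mislead. No multiple-testing adjustment is
applied, and this is stated in output.

ROC analysis treats NON-REM as positive. Thresholds sweep the unique score
values with the strict-inequality call "positive iff score > t"; the AUC
uses the Mann–Whitney rank convention (ties count half), which equals the
trapezoidal area of the stored curve. A REM-upregulated signature
(negative ES) enters the ROC negated so that high oriented score always
predicts NON-REM; the recorded cutoff carries its orientation. The
operating point maximizes Youden's J = sensitivity + specificity − 1, ties
broken toward higher specificity; PPV = TP/(TP + FP) and NPV = TN/(TN + FN)
at that cutoff. Youden's index is the package's definition of "optimal
cutoff" and is recorded in provenance. A bootstrap percentile CI for the
AUC is available as an extension.

## Stratification

Each patient gets one binary call per signature — strictly above vs at-or-
below the oriented cutoff (a score exactly at the threshold is "below") —
and the three ordered calls map to a group id 1 + 4c₁ + 2c₂ + c₃ ∈ {1..8}.
The encoding is an arbitrary but documented bijection (emitted with
results); group composition and per-group non-remission rates, not the
numbering, are the meaningful output. Rates are reported to one decimal
percent; empty groups appear with n = 0 and an undefined rate.

## Synthetic cohorts

The generator draws per-gene baselines b_g ~ N(8, 2²) on the log2 scale,
adds within-group Gaussian noise (SD 1.0 by default), exponentiates to the
linear scale, and shifts planted-set members by δ·noise_sd (log2 scale) in
one arm-by-outcome stratum. Defaults reproduce the emulated design: arms
of 140/38/31, remission rates 0.300/0.211/0.226 with REM counts rounded to
the nearest integer (42/8/7, pooling to 27.3 %), ~15k genes, baseline CDAI
drawn to match a median of 21.7 with IQR 14.9–28.9, and 1/4/1 early
discontinuers per arm whose month-6 CDAI is missing and whose last
observation exceeds 2.8. Planted sets occupy disjoint gene blocks (a
design requesting more planted genes than exist is an error); decoy sets
are drawn from the non-planted pool and never share genes with planted
sets. All randomness flows from one integer seed through NumPy's PCG64
generator, echoed into the design provenance.

The log-normal intensity model and independent-gene noise are harness
choices, not claims about any real microarray cohort: real data carry
gene–gene correlation, batch effects, and heavier tails. Passing tests
demonstrate that the algorithms are implemented correctly and calibrated
under the generative model (planted 30-gene sets at δ = 0.8 in a
140-patient arm are recovered at the stated significance rule in ≥ 90 % of
seeded simulations while decoys stay at the nominal false-positive rate);
they do not certify effect sizes or predictive performance on clinical
data, where the real-data analysis remains subject to the usual
overfitting caveat when ROC cutoffs are derived on the discovery cohort.

## Problem sizes and numerical choices

Tests and the acceptance script run the enrichment engine at 2000 genes
rather than the full ~15k: the engine's cost is linear in gene count and
the calibration properties under study (permutation p uniformity, planted
recovery, FDR behavior) do not depend on the population size, so the
smaller population is the package's chosen default for simulation studies.
Other fixed numerics: enrichment running-statistic ties resolve to the
first extremum; Firth step cap 5 per component with up to 30 halvings;
profile-CI bracketing limit ±20 on the coefficient scale; quantile-
normalization tie groups averaged exactly, not interpolated.

## Known limitations

- Gene-set permutation mode, preranked enrichment, and metrics other than
  signal-to-noise are out of scope.
- The per-gene z-transform ignores the sign of a core gene's own
  regulation; a set with mixed up/down members dilutes its score (the
  plain-average definition is deliberate).
- The multivariate Firth mode relies on the caller to supply a sensible
  adjustment set; the tool refuses strongly correlated covariate pairs but
  performs no variable selection.
- DeLong CIs for AUC are not provided (bootstrap only).
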