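# Methods

This note documents the models, defaults and numerical choices behind
`autoreact`, and what the synthetic studies do and do not demonstrate.

## Generative model of the synthetic cohort

The bead-array generator treats the natural-log MFI of analyte *j* in
well *i* as

    ln MFI_ij ~ N( mu_j + b_{block(j)} + 1{case, j in T} * delta_j * ln 2 , sigma_j^2 )

with per-analyte baselines mu_j ~ N(baseline_log_mfi_mean,
baseline_log_mfi_sd²), plate/block offsets b ~ N(0, block_offset_sd²),
and per-analyte variances drawn from a scaled inverse chi-square family,
sigma²_j = scale²·d₀/χ²_{d₀} with d₀ = `analyte_sd_shape` and scale =
`analyte_sd_scale`.  The inverse-chi-square choice is deliberate: it is
exactly the exchangeable-variance prior the downstream empirical-Bayes
moderation assumes, so the variance-shrinkage engine is well-specified
on its own test-bed and its parameter recovery can be checked.  Case
effects delta_j (log2 units) are drawn uniformly from
`effect_log2fc_range` for the `n_differential` truth analytes; effects
are multiplicative on MFI so "fold change" keeps its usual meaning.
Each technical replicate adds independent N(0, replicate_noise_sd²)
noise on the log scale.  Empty and buffer wells draw from a low
log-normal background (ln MFI ≈ 3.4 ± 0.3); a `sticky_analyte_fraction`
of analytes has its empty-well mean inflated by +2.5 log units, giving
the empty-well outlier rule genuine structure to find.  Plasma control
wells replicate one fixed pseudo-sample.  All randomness flows from one
root seed through independent seed-sequence substreams (latent signal,
replicate 1, replicate 2), making datasets bit-reproducible.

Key defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_cases / n_controls | 30 / 30 | the study's cohort size |
| n_analytes / n_differential | 256 / 7 | the study's post-exclusion panel and discovery count |
| effect_log2fc_range | (0.3, 1.2) | spans the published log2FC magnitudes (0.36–1.11) |
| baseline_log_mfi_mean / sd | 6.2 / 1.0 | raw MFI centred near 500 with a realistic dynamic range |
| analyte_sd_shape / scale | 8.0 / 0.30 | moderate variance heterogeneity; ~30% CV on the raw scale, typical for serum bead assays |
| replicate_noise_sd | 0.10 | ~10% technical CV between replicate plates |
| n_empty / n_plasma / n_buffer | 6 / 3 / 3 | the assay layout's control wells |
| n_blocks | 3 | beads coupled in three plates |
| sticky_analyte_fraction | 0.05 | a few percent of beads bind non-specifically |

The variance family needs both a shape (`analyte_sd_shape`, the spread
of per-analyte variances) and a scale (`analyte_sd_scale`); the scale
was fixed once at 0.30 as above.

The planar-screen generator produces log-normal intensities with
per-(block, sample) backgrounds, a few percent of small (<30 px) or
image-flagged spots, random and concentrated missingness, ~1% of
antigens printed in two array batches with distinct printing-control
signal, and `n_differential` antigens spiked ×200 in three sera each —
enough workload for every filtering rule and far beyond the 70-MAD call
threshold.

What the generator does *not* emulate: bead counts, pixel-level image
artefacts, covariates (age/sex — the analysis uses analytes only),
analyte–analyte correlation beyond block offsets, and plate-position
effects.  Passing tests therefore show the *procedures* are correct and
calibrated under the stated model, not that real serum data meet that
model.

## Preliminary screen

Intensities are scored per (block, sample) stratum as
(x − median)/MAD with the **unscaled** MAD (no 1.4826 factor): the
screen counts literal "MADs above the median".  Zero-MAD or <2-value
strata are flagged and scored NA rather than infinite, keeping
downstream counts defined.  Reactivity is one-sided (score > cutoff,
default 70) and an antigen is shortlisted when reactive in ≥3 sera.
The MAD stratum is per block *and* sample; the alternative reading (per
block across samples) would not adjust sample-specific background,
which the transform exists to remove.

## Bead-array preprocessing

Order is fixed: empty-well outlier detection → per-replicate noise
thresholds and below-noise exclusion → replicate validation/averaging →
background subtraction → weighted Box-Cox → robust spline
normalization.  Conventions: every threshold comparison is strict
(`>`); the empty-well outlier rule is one-sided over the across-analyte
distribution of empty-well means; exclusion requires an analyte to be
below noise in **both** replicates (configurable to either); discordant
replicate pairs (|d − median(d)| > 3 × 1.4826·MAD of the paired
differences) are flagged as provenance but still averaged — the rule
identifies, it does not censor.

**Weighted Box-Cox.** Per analyte, values are shifted by
max(0, ε − min) with ε = 10⁻⁶ of the analyte range (background
subtraction can produce non-positives), then the exponent λ maximises
the weight-multiplied profile log-likelihood on a grid over [−2, 2]
(step 0.01) with golden-section refinement; |λ| < 10⁻³ uses the log
branch.  Weights default to 1 — the weighted form is kept for fidelity
to the assay literature but no weighting scheme is imposed.  Constant
analytes get λ := 1 and a flag.

**Robust spline normalization (RSN).** The reference distribution is
the per-rank median of the sorted well profiles.  Each well is mapped
onto it by a monotone PCHIP spline through 11 quantile anchors (deciles
plus both ends), each anchor estimated as the median of the values
whose empirical CDF falls within ±0.05 of the anchor probability —
including the extreme anchors, because raw sample extremes are too
noisy to anchor a mapping and measurably distort downstream p-value
calibration.  Anchors are forced non-decreasing, tied input anchors are
collapsed, and beyond the anchor span the mapping continues linearly
with the boundary slope (floored at 0), so within-well ranks are
preserved.  With fewer analytes than anchors the mapping falls back to
a two-anchor linear stretch.

## Differential testing

The moderated t is the package's own implementation of the standard
empirical-Bayes linear-model closed forms: prior (d₀, s₀²) by method of
moments on ln s², with trigamma(d₀/2) = Var(e) − trigamma(d/2) inverted
by Newton iteration and d₀ := ∞ when the excess dispersion is
non-positive; posterior variances are the precision-weighted blend; the
reference distribution is t with d₀ + d df (normal when d₀ = ∞).  The
d₀ → 0 limit reproduces the classical pooled t exactly and is tested.
The estimator uses all analytes, with no robust down-weighting and no
intensity trend.  BH adjustment is the step-up rule with an explicit
q ≥ p clamp (mathematically implied; guards 1-ulp rounding).  Fold
changes divide group means on the background-subtracted scale, floored
at ε = 10⁻⁶ of the analyte range.  Cohort-table statistics are Pearson
chi-square without continuity correction and the unpaired t (Welch by
default; pooled optional).

## Classification

IRLS maximum likelihood with intercept, tolerance 10⁻⁸ on the
coefficient step, 100 iterations max; singular systems retry with a
10⁻⁸ ridge jitter.  Separation is *flagged* (standardized coefficient
magnitude > 50, or non-convergence at near-zero deviance), never
penalized: near-separable serology panels legitimately produce huge
coefficients.  Backward elimination drops, at each step, the term whose
removal most lowers the AIC, stopping when no removal improves it; ties
break by term order; the intercept stays.  LOOCV refits coefficients
per fold with the term set held fixed — selection happens once on the
full data, so selection bias is inherited by design and the in-sample
and held-out AUCs are both reported to make the gap visible.  Accuracy
thresholds held-out probabilities at 0.5.  A caveat documented in the
tests: with balanced classes and uninformative features, LOOCV accuracy
at threshold 0.5 is biased *below* chance (leaving out a case tilts the
training prior toward controls), so "≈0.5 under the null" is not the
correct expectation for this estimator.  ROC curves sweep all unique
thresholds; ties move both coordinates at once, making the trapezoid
area exactly the Mann–Whitney U/(n₁n₂).

## Enrichment

One-sided hypergeometric over-representation.  The gene universe
defaults to the genes represented on the analyte panel (the analysis
asks "which sets are over-represented among my hits, given what the
panel could have shown"); a collection-wide universe is a caller
choice.  The query takes genes of analytes with **raw** p < 0.05 — ORA
needs ~20+ genes to be meaningful, so the query is deliberately broader
than the corrected discovery list (an adjusted-p mode exists).  Query
genes outside the universe are dropped with a warning count; K = 0 sets
are skipped; results sort by k/K then p.

## Visual summaries

PCA is SVD on column-centered (not scaled, by default) data; variance
fractions are σ²ᵢ/Σσ².  Heatmap ordering standardizes columns to mean
0 / SD 1 and clusters rows and columns by complete linkage on Euclidean
distances (scipy linkage; deterministic tie handling), checked against
a brute-force agglomerative oracle.  95% concentration ellipses come
from the 2-D score covariance scaled by the χ²₂ 0.95 quantile, emitted
as parameters rather than graphics.  Figure rendering is intentionally
out of scope; every plotted quantity exists as a tested table.

## Study sizes and calibration checks

The simulation studies (also run by `scripts/acceptance.py`) use: 2000
analytes for null p-value calibration (KS); 100 pipeline runs of 256
analytes for BH FDR under the global null and under spiking (7 analytes
at log2FC 0.6–1.2); 20 seeds at the full design point for recovery and
classifier AUC; 50 seeds × 2000 variances for (d₀, s₀²) recovery.
These sizes give stable estimates while keeping the full suite around
two to three minutes.  Residual null miscalibration is mild and traces
to per-analyte Box-Cox exponent noise at n = 60 wells — an inherent
property of fitting a power transform per analyte at this sample size,
visible only at the resolution of a 2000-analyte KS test.

## Known limitations

- Real cohort quantities (the published seven discoveries, AUC
  0.864/0.829, LOOCV 0.85/0.75, PC1 44.89%) require the deposited
  cohort data and a version-pinned gene-set collection; they are design
  anchors for the synthetic studies, not reproduction targets.
- The RSN reference is defined from the data at hand; normalizing a
  single new well against a stored reference is not implemented.
- No covariate adjustment in testing or classification (the analysis
  design is two-group, analytes only).
- Bead-count QC and weighting schemes for the weighted Box-Cox are
  intentionally unmodelled.
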