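# Methods

`mirnascreen` implements a two-phase circulating-miRNA biomarker analysis
for predicting spontaneous preterm birth (PTB, delivery < 34 weeks) and
mid-pregnancy cervical shortening (cervical length < 25 mm at gestational
time point B or C after a normal measurement at A) from plasma sampled at
three windows: A (12–14⁺⁶), B (15–17⁺⁶) and C (18–21⁺⁶) weeks. Because the
underlying patient data are not publicly deposited, the package pairs the
analysis with a synthetic-cohort generator that reproduces the statistical
structure the analysis assumes; every stage is exercised end to end on
generated data.

## Discovery phase (digital counts)

Input is a samples × probes matrix of molecule counts from a
hybridization-counting assay with endogenous and negative-control probes.

1. **Haemolysis QC.** Red-cell miRNAs (hsa-miR-16-5p, hsa-miR-25-3p,
   hsa-miR-93-5p) flag blood-cell contamination of plasma. Per marker, a
   robust z-score is computed across samples on log2(count + 1):
   z = (x − median) / (1.4826 · MAD). A sample is excluded when any marker
   exceeds z > 3 (the cut-off is configurable; the source convention states
   only "very high expression"). When the MAD is zero, any deviation from
   the median is flagged.
2. **Background subtraction.** The background is the mean of the
   negative-control counts plus two sample standard deviations (n − 1
   denominator), computed per sample from that sample's own negative
   controls (controls ship per lane on the platform; a pooled-cohort
   threshold is available as an option). The threshold is subtracted from
   the endogenous counts and the result floored at zero, so zero means
   "not above background".
3. **Top-100 normalization.** The reference set is the 100 endogenous
   probes with the highest mean count across samples, chosen globally (a
   per-sample set would make the normalizer discontinuous in the data).
   Each sample is scaled by (grand mean of the reference counts) / (the
   sample's reference mean), equalizing reference-set means across samples.
   Note this normalizer is compositional: it is exactly invariant to a
   per-sample depth factor only up to a cohort-wide constant, and a probe
   set whose mass is concentrated in a few probes makes the factor noisy
   (see *Synthetic data* below).
4. **Prevalence filter.** A marker is retained iff, in at least one
   clinical group, strictly more than half of the samples are above
   background (value > 0). Expression in exactly half the samples of every
   group does not qualify. The grouping is the outcome partition by
   default; any partition (e.g. control samples by time point) can be
   supplied.
5. **Differential expression.** At each time point, PRETERM vs TERM and
   SHORT vs TERM are compared per retained marker with the Welch
   unequal-variance t-test on log2(count + 1) — the log-geometric-mean
   comparison conventional for count screens. (The normality-gated
   Student-t / Mann-Whitney comparison used in the validation phase is
   available as an option.) The +1 offset keeps background-subtracted
   zeros finite and is configurable.
6. **Candidate selection (marker-level FDR).** The discovery claim is
   about markers, not individual tests, so the default rule aggregates
   each marker's six phase tests (3 time points × 2 comparisons) into one
   p-value by Bonferroni-corrected minimum p, then applies
   Benjamini–Hochberg across markers; candidates have marker-level
   q < 0.05. Rationale: with a marker truly differential in all six
   tests, test-level BH at 0.05 admits E[null test rejections] ≈
   0.05 · R · π₀ ≈ 2–3 because the many true rejections relax the step-up
   threshold, and those null rejections land on distinct markers — the
   discovered *marker set*'s FDR is then far above the nominal level.
   Marker-level BH keeps it at ≈ 0.05 (measured: ≈ 0.42 expected false
   markers per cohort with nine strong true markers, the step-up floor).
   Test-level pooled BH and per-(comparison × time point) BH remain
   config options, and per-test q-values are always reported.

## Longitudinal tests

Serial profiles (subjects × 3 time points) are tested for a
gestational-age effect. When every time point passes the
D'Agostino–Pearson omnibus normality test (possible only for n ≥ 8),
repeated-measures ANOVA is used with the Greenhouse–Geisser correction —
ε = (Σλ)² / ((k−1)Σλ²) over the eigenvalues of the double-centred
covariance, clipped to [1/(k−1), 1] — followed by a linear-trend contrast
(−1, 0, +1) tested per subject against zero. Otherwise the Friedman rank
test is used, followed by Dunn's pairwise z-tests on mean within-subject
ranks with Bonferroni adjustment over the three pairs. The Friedman null
distribution is computed exactly (dynamic programming over per-subject
rank permutations) for tie-free designs with ≤ 15 subjects — at those
sizes the χ² approximation is off by an order of magnitude in the tail —
and by the χ² approximation beyond.

## Validation phase (RT-qPCR)

Input is a long-format Ct table with duplicate technical replicates, an
inter-plate calibrator assay on every plate, and two spike-in controls
(cel-254 added before extraction, UniSp6 before reverse transcription)
measured for every sample.

1. **Replicate collapse.** Cells are averaged over detected replicates;
   cells whose replicate CV (sd/mean) is ≥ 2% are flagged but retained;
   a cell is undetected only when all replicates are.
2. **Median normalization.** Step 1 removes plate effects: each plate's
   offset is its calibrator Ct minus the median calibrator Ct over plates.
   Step 2 removes per-sample technical loss: for each spike-in, a sample's
   deviation from the cross-sample median is computed (on plate-corrected
   Cts); the per-sample offset is the median over the spike-ins — the
   midpoint with two, the stated controls. Both offsets are subtracted.
   The chain inverts injected plate/sample offsets exactly in the
   noiseless limit, up to the unidentifiable global constant (the median
   of the injected offsets).
3. **Quantification.** Fold change between groups is 2^(−ΔG) with
   ΔG = mean Ct(experimental) − mean Ct(control). Per-sample relative
   expression is r = 2^(−(Ct − mean control Ct)) rescaled so the control
   mean is exactly 1; reported group means are arithmetic (table
   convention), so the group-mean ratio matches the fold change through
   geometric, not arithmetic, means. Undetected cells are excluded with a
   warning rather than imputed at a ceiling Ct, which would bias fold
   changes toward the ceiling.
4. **Screening.** Per-marker ROC curves are built on relative expression
   (orientation automatic, AUC ≥ 0.5); the AUC equals the Mann-Whitney
   concordance with ties counted ½, and its p-value against 0.5 comes from
   the Mann-Whitney test. The screening operating point is the threshold
   capturing **every** case (100% detection rate): for an up-in-cases
   marker, the minimum case score, with a control exactly at the threshold
   counted screen-positive (conservative). Specificity is the fraction of
   controls strictly on the negative side, with an exact Clopper–Pearson
   95% interval from beta quantiles. Multi-marker panels are combined by a
   maximum-likelihood logistic model on per-marker log2 relative
   expression, fitted and evaluated in-sample (the published convention);
   under perfect separation the MLE diverges and an L2-ridge fit (C = 1)
   is substituted with a warning. A rank-mean combination is available.

## Multivariate profiles

PCA and PLS-DA are computed by NIPALS after unit-variance (UV) scaling
(centre, divide by the variable's standard deviation S_k; constant
variables dropped with a warning; the source's "dividing by 1/S_k" is read
as division by S_k, the stated intent being unit variance). PLS-DA is PLS1
against a 0/1 class response; R²Y = 1 − RSS/TSS cumulatively over
components. Q²Y = 1 − PRESS/TSS is estimated by seven-round internal
cross-validation with samples assigned round-robin after a seed-fixed
shuffle (a deterministic venetian-blind assignment is available). Q²Y is
computed on the 0/1 response, so even perfectly separated classes cap
below 1 by the linear-regression residual.

## Synthetic data

The generator emulates the study design: serial samples at A/B/C for
16 TERM / 13 PRETERM / 24 SHORT patients (discovery) and an independent
validation layout (defaults 84/17/28 in the analysis scripts).

* **Counts.** Negative binomial around per-probe baselines
  (variance = μ + αμ², α = 0.1 by default), multiplied by the group ×
  time-point fold effect for true markers and by a log-normal per-patient
  random effect (sd 1.0 log2 units by default) shared across the
  patient's three samples — making patient identity, not gestational age,
  the dominant variance component, as PCA of the generated profiles
  confirms.
* **Fold effects.** Defaults for the nine marker miRNAs follow the
  published mean-relative-expression scale, rising over time points
  (≈ 4–24×), for both case groups.
* **Abundance profile.** ~55 of 800 probes are consistently expressed.
  Expressed null probes span a broad 2^8–2^13-count band with the
  red-cell miRNAs at its top (2^12–2^14) and the nine signal markers at
  low abundance (2^4–2^6.5, tens of counts, consistent with the low
  digital counts reported for them). This was a deliberate design point:
  the top-100-mean normalizer inherits the sampling noise of whatever
  probes carry its mass. Concentrating the mass in two or three dominant
  probes makes the per-sample factor track those probes' random effects
  (group-level artifacts up to ~0.4 log2 units), while a broad band keeps
  the factor stable and the signal markers' fold effects contribute ≪ 1%
  of reference mass, so normalization bias is negligible.
* **Noise floor.** Negative controls at mean 4 counts; non-expressed
  probes below that; the per-sample background threshold then removes
  them, and the prevalence filter recovers essentially the expressed set.
* **Haemolysis.** A configurable fraction of samples (default 2%) has the
  three red-cell markers multiplied by 20 — "very high expression" made
  detectable by construction.
* **qPCR.** Ct = assay baseline − log2(true relative expression) + plate
  offset + per-sample offset + N(0, 0.2 cycles) replicate noise, duplicate
  replicates; the calibrator carries only its plate's offset, the
  spike-ins carry plate + sample offsets, so the normalization chain can
  remove both nuisance terms.
* **Reproducibility.** All randomness flows from `SimConfig.seed` through
  named `numpy.random.SeedSequence` child streams (structure, patients,
  counts, haemolysis, clinical; a separate parent for qPCR layout,
  offsets and noise), so identical seeds give byte-identical outputs.

What the generator does **not** emulate: haemolysis as a graded continuum
(it is a fixed 20× spike), probe-specific hybridization efficiencies,
qPCR amplification-efficiency differences between assays, batch/lot
effects, and any correlation between marker expression and cervical
length beyond group membership. Passing tests therefore demonstrate that
the pipeline recovers the structure it assumes, not that the assumed
structure matches any particular clinical cohort.

## Problem sizes and numerics

The simulation-based tests use cohorts of 800 probes × ~160 samples with
100 Monte-Carlo seeds for the recovery and false-discovery checks, 2000
replicates for test-calibration checks, and 200 for the cross-validation
null; these sizes give Monte-Carlo standard errors comfortably inside the
asserted bands. NIPALS runs to a 1e−12 relative score change (hard error
after 2000 iterations) and matches full SVD to 1e−8 in tests. Mann-Whitney
p-values are exact for tie-free samples when the smaller group has n < 8,
normal-approximated with tie correction otherwise. The outcome-derivation
rule uses strict inequalities; a cervical length of exactly 25 mm triggers
neither side of the rule and raises a warning, since the convention for
the boundary is not documented.

## Known limitations

* The discovery phase tests each time point cross-sectionally; the
  longitudinal tests are exposed for profile analysis but candidate
  selection does not use them (matching the published marker definition).
* Marker-level FDR uses Bonferroni min-p aggregation, conservative under
  the positive dependence between a marker's six tests.
* In-sample logistic combination overstates panel performance by
  construction (no held-out evaluation), as in the source analysis.
* Native binary instrument exports (RCC) are out of scope; counts are
  read from delimited text as exported by instrument software.
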