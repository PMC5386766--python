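# Methods

## The problem and the model

After radiotherapy for high-grade glioma, a newly enhancing lesion more
than six months past complete response is either tumor recurrence or
radionecrosis. Both enhance because the blood–brain barrier is broken; they
differ in microvasculature (recurrence builds new vessels, necrosis does
not) and in blood products (radiation vasculopathy bleeds, in larger foci).
The package quantifies both axes:

* **perfusion**: normalized cerebral blood volume (nCBV) from dynamic
  susceptibility contrast (DSC) MRI, summarised over the enhancing-lesion
  volume of interest by cumulative-histogram percentile points;
* **hemorrhage**: the proportion of susceptibility-weighted (SWI) lesion
  voxels darker than a ventricular reference median (proSWMRI);

and combines them in a conjunction rule — recurrence iff
nCBV90 > c₁ **and** proSWMRI ≤ c₂ — whose purpose is specificity: a
hemorrhagic necrosis can mimic high perfusion signal, but it cannot mimic a
low dark-voxel fraction.

## Perfusion quantification

Signal is converted per voxel as ΔR2\*(t) = −ln(S(t)/S₀)/TE with S₀ the
mean of the first `n_baseline` (default 4, configurable 2–10) pre-bolus
samples. Leakage from contrast extravasation is removed against the mean
curve of a non-enhancing reference region by ordinary least squares on
voxel(t) ≈ k₁·ref(t) − k₂·∫₀ᵗ ref (trapezoid cumulative integral);
corrected(t) = voxel(t) + k₂·∫₀ᵗ ref. k₂ = 0 reproduces the input exactly,
and on data built from the linear model the coefficients are recovered to
machine precision.

The first pass is modelled by the gamma-variate k·(t−t₀)^α·e^(−(t−t₀)/β)
(peak at t₀ + α·β), least-squares fitted on the window from bolus arrival
to the first post-peak local minimum or the 30%-of-peak crossing, whichever
is earlier — the window is what excludes recirculation. For a single curve
the fit is free in all four parameters: t₀ initialised at the last sample
below baseline mean + 3 SD, α at 3 with β moment-matched from the peak
position, bounds α ∈ (0.1, 10], β ∈ (0.1, 30] s.

**Hierarchical constraint in map computation.** Voxelwise free 4-parameter
fits are badly conditioned at realistic single-voxel SNR: t₀/α/β trade off
along a flat valley, producing gross outliers that corrupt both the lesion
histogram and the white-matter normalizer, and per-voxel bolus *detection*
selection-biases low-amplitude regions (only upward noise excursions cross
the threshold). `compute_cbv_map` therefore fits the averaged
reference-region curve once, freely, and anchors every voxel fit to it: the
bolus shape (α, β) and the first-pass window come from the reference, the
voxel keeps a free amplitude and an arrival time within ±2 samples. Within
one acquisition the first-pass shape is set by the injection profile, so
the constraint trades a small bias (observed ≈ −1% at SNR 50, −4% at
SNR 20 on lesion-level recovery) for an order-of-magnitude variance
reduction. Voxels whose fit still fails are excluded from maps and counted
in the QC table rather than interpolated.

rCBV is the trapezoidal integral of the fitted curve, sampled on the
acquisition grid refined 16-fold from t₀ out to where the gamma-variate
tail mass falls below 10⁻⁶ (at least t₀ + 10·β). Coarser/shorter grids are
not used because the composite-trapezoid endpoint error at the raw 1.5 s
spacing reaches ~19% at α = 1 and the 10·β truncation alone discards 6.7%
of the mass at α = 5; with both refinements the quadrature agrees with the
closed form k·β^(α+1)·Γ(α+1) to 0.07% worst-case over α ∈ [1,5],
β ∈ [1,6]. nCBV divides by the mean rCBV over the contralateral
normal-appearing white matter mask. Processing order is
correct-then-fit-then-integrate by default (the leakage model is defined on
raw dynamic curves); a fit-then-correct order is available behind a flag.

## Histogram features and proSWMRI

Lesion nCBV values (union of the ROI across slices, fit-valid voxels only)
are binned from 0 at width 0.1 and cumulated to percent; the Xth percentile
point is the value with X% of voxels to its left. Reported percentiles use
linear interpolation between order statistics — this removes
bin-quantization error and agrees with reading the binned curve within one
bin by construction (verified against a full-sort oracle). Features are the
mean and the 70/90/95/99 points; ordering ncbv70 ≤ ncbv90 ≤ ncbv95 ≤ ncbv99
is enforced at the type level.

proSWMRI = 100 × #(lesion voxels strictly below the ventricular median) /
#(lesion voxels). "Below" is strict — ties count as not-dark (measure-zero
in real magnitude data) — and the ventricular reference is one pooled 3-D
median, not per-slice. The statistic is invariant under any strictly
monotone rescaling applied jointly to image and reference.

## Classification statistics

Recurrence is the positive class throughout; nCBV90 discriminates in the
greater-is-positive direction, proSWMRI lesser-is-positive. ROC curves are
tabulated at cutoff candidates placed at midpoints between adjacent
distinct scores (plus the two degenerate extremes). Youden's J is identical
to an observed-value scan, but a midpoint cutoff leaves a symmetric margin
— with cutoffs at training extrema, a held-out boundary subject in LOOCV is
always misclassified even on separable data. Ties in J break toward higher
specificity (the rule's purpose), then toward the more conservative
threshold. Boundary conventions follow the rule as printed: strict > for
nCBV90, ≤ for proSWMRI.

AUC uses the trapezoidal/Mann–Whitney identity (scikit-learn), with 95% CI
and paired AUC comparison from the DeLong structural-component covariance
(implemented here; variance validated against a 2000-resample bootstrap).
The combined AUC is computed on the stepwise logistic model's linear
predictor, while the combined sensitivity/specificity come from the
conjunction rule — the two summarise different objects and only this split
makes both reportable at once. Stepwise selection is forward entry by
likelihood-ratio test at p < 0.05 with backward removal at p > 0.10
(statsmodels likelihoods); perfect separation is flagged, not hidden.
LOOCV re-derives both Youden cutoffs on every n−1 fold by default (the
honest variant); a fixed-rule variant exists since either reading of the
original procedure is defensible. Group comparisons: unpaired Student's
t-test, and Mann–Whitney exact for combined n ≤ 25 without ties (normal
approximation with tie correction otherwise). Rater agreement is ICC(2,1)
(two-way random, absolute agreement, single measures; pingouin, validated
against the explicit ANOVA decomposition) plus a within-subject CoV: mean
over subjects of pair SD / pair mean × 100, excluding zero-mean pairs with
a warning.

## Survival

Kaplan–Meier product-limit curves per conjunction-rule stratum (lifelines;
validated against the hand product-limit), median OS with the
log–log-transform 95% CI (the original interval method is unstated; this
is the standard choice), survival rates at 6/12/24 months with
month = 30.44 days, and the one-degree-of-freedom log-rank test with
hypergeometric tie handling. The survival clock starts at the first
appearance of measurable enhancement on follow-up MRI; the synthetic
generator emits times on that clock.

## Histopathology

Per patient, hemorrhagic foci are size-classed by longest diameter
(≤ 5 mm / > 5 mm) as percentages of the focus count. The group summary is
the unweighted mean of per-patient percentages — deliberately not the
pooled-count proportion, which differs (pooled recurrence ≤ 5 mm is
249/283 ≈ 88% vs the per-patient average 94). Printed percentages and raw
counts are stored as independent columns in the packaged table because
they are not exactly consistent with each other in the source material.
Groups are compared by exact Mann–Whitney on the per-patient percentages.

## Synthetic data: what it emulates and what it does not

The DSC phantom builds ΔR2\*(t) per voxel from a gamma-variate first pass
(arrival 9 s, α = 3, β = 2 s on a 60 × 1.5 s time axis, TE 35 ms), a
20%-amplitude recirculation bump delayed 15 s, a −k₂·∫ref leakage term in
lesion voxels (k₂ = 0.02), and Gaussian signal noise at a configured SNR
(σ = S₀/SNR). The NAWM peak ΔR2\* of 4 s⁻¹ corresponds to a ~13% signal
drop — physiologic for white matter at a standard 0.1 mmol/kg dose. Lesion
voxels carry CBV ratio 3. The SWI phantom plants exactly
round(f·n_lesion) lesion voxels below the ventricular plateau with no
ties, so proSWMRI recovers 100·f exactly whenever f·n_lesion is integral.

Feature-level cohorts (32 recurrence / 19 radionecrosis by default) draw
mean nCBV, nCBV90 and proSWMRI from zero-truncated normals at the
published group means/SDs (truncation by resampling, because several SDs
exceed their means; proSWMRI clipped at 100); the minor percentile points
are fixed multiples of nCBV90 so the ordering invariant holds by
construction. Note that zero-truncation shifts the realised means above
the nominal ones (e.g. recurrence proSWMRI 9.3 ± 9.79 realises ≈ 12.3);
tests therefore compare against the analytic truncated-normal mean.
Survival is exponential with hazard by conjunction-rule stratum
(ln 2/365 d⁻¹ if rule-positive, ln 2/940 d⁻¹ otherwise — the published
stratum medians), administratively censored at 1825 days. Within-group
correlation between nCBV90 and proSWMRI defaults to 0 (configurable).

Not emulated: anatomy, partial volume, motion, scanner artifacts,
arterial-input-function variability, inter-sequence registration error, and
any real covariance structure between perfusion and susceptibility
features. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated noise model, not clinical performance on real
images; the published cohort-level AUCs and cutoffs derive from patient
data that is not distributed, so they serve as generator defaults and
sanity envelopes, not as reproduction targets.

## Problem sizes and numerical choices

Unit and acceptance suites run phantoms at 16×16×2 (tests) and 32×32×4
(acceptance script) with 60 time points — sizes chosen so the whole suite
stays desk-scale while every voxel path is exercised; replicate suites use
100 seeded feature-level cohorts. Fit tolerances: curve_fit xtol/ftol
1e-12, max 20k evaluations. Degenerate inputs (flat curves, empty masks,
single-class labels, all-censored survival, zero-mean rater pairs) raise
typed validation errors or are flagged, never silently imputed. All
randomness flows through numpy Generators seeded from explicit integers;
identical configuration yields byte-identical pipeline reports (no
timestamps in any artifact).

## Known limitations

* The shape-anchored voxel fit assumes a spatially constant bolus shape;
  strong dispersion/delay heterogeneity in real data would bias voxel
  amplitudes (the free 4-parameter fit remains available per curve).
* No arterial-input-function deconvolution — rCBV is a relative,
  non-deconvolved integral, as in the modelled workflow; CBF/MTT are out
  of scope.
* proSWMRI cannot distinguish calcification from hemorrhage, and mixing
  SWI/SWAN-like contrasts changes its scale; the reference-median design
  only removes monotone global rescalings.
* The conjunction rule's cutoffs are cohort-derived; the package reports
  LOOCV as an internal check but provides no external-validation
  machinery.
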