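# radrec

Quantitative MRI analysis for a hard neuro-oncology question: when a new
enhancing lesion appears months after radiotherapy for high-grade glioma, is
it **tumor recurrence** or **radionecrosis**? The two look alike on
conventional contrast-enhanced MRI but are treated very differently.

`radrec` implements the two-sequence quantitative pipeline that separates
them, plus the statistics and survival analysis used to evaluate it:

1. **DSC perfusion → nCBV.** A dynamic susceptibility contrast series is
   converted voxelwise to ΔR2\*(t) = −ln(S(t)/S₀)/TE, leakage-corrected with
   the two-coefficient linear model
   voxel(t) ≈ k₁·ref(t) − k₂·∫₀ᵗ ref, fitted with a gamma-variate
   k·(t−t₀)^α·e^(−(t−t₀)/β) over the first-pass window, and integrated to
   rCBV. Division by the mean rCBV of contralateral normal-appearing white
   matter gives nCBV. Recurrent tumor is hyperperfused; necrosis is not.
2. **Cumulative histogram features.** Over the whole enhancing-lesion VOI
   the nCBV distribution is summarised (bin width 0.1) by its mean and the
   70th/90th/95th/99th percentile points; **nCBV90** is the working
   discriminator.
3. **proSWMRI.** On a susceptibility-weighted image, the percentage of
   lesion voxels darker than the ventricular median signal. Radionecrosis is
   hemorrhage-rich and dark; recurrence mostly is not.
4. **Conjunction classifier.** Predict recurrence iff
   `nCBV90 > c₁ AND proSWMRI ≤ c₂`, with Youden-optimal cutoffs from ROC
   analysis (published operating point: c₁ = 2.07, c₂ = 15.76%). The AND
   removes the classic false positive — hemorrhagic necrosis with high
   apparent perfusion. Evaluation: AUCs with DeLong CIs and paired DeLong
   comparison, stepwise logistic regression, Fisher's exact comparison of
   specificities, leave-one-out cross-validation, Kaplan–Meier/log-rank
   survival by rule stratum, ICC(2,1)/CoV rater agreement, and
   hemorrhagic-foci histopathology statistics.

No patient images ship with the package; a synthetic module generates DSC
phantoms (bolus + recirculation + leakage + noise), SWI phantoms with a
planted dark-voxel fraction, and feature-level cohorts with the published
group means/SDs and rule-stratified exponential survival — all with known
ground truth, so every stage is tested against what was planted.

## Worked example

```bash
radrec run-all --seed 3 --out run/
```

runs simulate → perfusion → features → classify → survive → histo and writes
`run/report.json`. On the seeded 12×12×2 phantom with planted CBV ratio 3
and a 51-patient synthetic cohort this prints (abridged from
`run/report.json`):

```
phantom_features:  mean_ncbv 2.975  ncbv90 3.222  pro_swmri 16.667
histology avr:     radionecrosis small 56.86  recurrence small 93.67
```

The phantom lesion's nCBV comes back at the planted ratio 3 (percentiles
spread by acquisition noise), proSWMRI equals the planted dark fraction
(nearest representable on a 9-voxel lesion), and averaging the packaged
per-patient hemorrhagic-foci table reproduces the published group averages
(57/94 after display rounding). The classification section reports each
variable's AUC and Youden cutoff, the conjunction rule's confusion counts,
the DeLong and Fisher p-values, and LOOCV accuracy; the survival section
reports per-stratum median OS with 95% CI, 6/12/24-month rates and the
log-rank test.

Library use mirrors scikit-learn:

```python
from radrec import ConjunctionRuleClassifier
clf = ConjunctionRuleClassifier().fit(X, y)   # X columns: (nCBV90, proSWMRI)
clf.rule_                                     # derived Youden cutoff pair
clf.predict(X)                                # "recurrence"/"radionecrosis"
```

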