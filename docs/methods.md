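# Methods

## Pipeline overview

The analysis chain is: (1) spectra on a common wavenumber grid with an
attached laser-line reference intensity; (2) crop to 377–1720 cm⁻¹,
normalize to the reference, subtract a global linear background; (3)
integrate seven band windows, each with its own local linear baseline;
(4) form four biomarker ratios; (5) score each spectrum with a linear
classifier under 10-fold cross-validation; (6) feed the resulting
sensitivity/specificity into the exact binomial majority-vote analysis.

## Preprocessing and band integration

**Baseline.** "Linear background subtraction" is underdetermined; the
implementation anchors the line at the mean `(wavenumber, intensity)` of the
first and last `edge_points = 5` grid samples of the region — deterministic
and robust to single-pixel noise. A least-squares line through all points in
the region is available via `method="lsq"`.

**Windows.** Endpoints snap to the nearest grid point and are inclusive.
Two windows are implemented exactly as the acquisition protocol prints them
even though they look anomalous: the second phenylalanine window is
[1543, 1574] cm⁻¹ (printed in descending order, and *not* containing the
1609 cm⁻¹ band center), and the 1005 cm⁻¹ phenylalanine window [970, 1040]
overlaps the ν₁PO₄ window [907, 990]. Each window gets an independent local
baseline, so overlap is permitted. Neither anomaly is "fixed" silently;
both are configurable.

**Integration.** Trapezoid rule on the native grid (Simpson optional). For
a Gaussian band of height `A` and width `fwhm` fully inside a window the
integral matches the closed form `A·fwhm·√(π/ln 16)` to better than 1% at
4 cm⁻¹ spacing; halving the step changes it by < 0.5%. When a window is
narrow relative to the band (the amide I window [1625, 1725] around a wide
1660 cm⁻¹ band), the edge-anchored baseline sits on the band's shoulders
and the area is systematically underestimated; this bias is consistent
across spectra and cancels in ratio comparisons.

**Negative areas.** Noise can push a baseline-subtracted area negative.
Areas are clamped at zero by default for ratio stability; clamping can be
disabled (`clamp=False`), which restores exact linearity
`area(αS) = α·area(S)`.

## Biomarkers

`mineral_to_matrix = ν₁PO₄/amide I`, `carbonate_to_matrix = ν₁CO₃/amide I`,
`calcium = ν₂PO₄/amide III`, `phenylalanine = (phe1005 + phe1609)/amide III`.
Two phenylalanine bands are measured but the content is defined against a
single denominator; the default numerator sums both band areas (all measured
signal), with a `"1005"`-only switch since either convention is defensible.
Records whose amide denominator falls below `epsilon = 1e-12` are flagged
invalid and excluded (and counted), never propagated as infinities. All four
ratios are exactly invariant under scaling of the whole spectrum.

## Classification

"LDA with logit scoring" is implemented as a linear discriminant whose
posterior probability (logistic in the discriminant value) is converted to
odds `P(ROD)/(1−P(ROD))`; the decision threshold is odds = 1, with exact
ties called normal (conservative, measure-zero). The full-spectrum route
projects preprocessed spectra onto 20 principal components and scores with a
linear SVM whose decision values are Platt-calibrated (1-D logistic
regression) on the training fold, landing on the same odds scale. PCA and
the calibration are fitted within training folds only.

Cross-validation is stratified by class and shuffled by seed, i.e.
spectrum-wise. This mirrors the original evaluation but leaks patient
identity across folds (all seven samples appear in every training split); a
`grouped=True` mode keeps each sample's spectra in one fold for a
leakage-free, much more pessimistic estimate. ROD is the positive class
everywhere. Diagnostic metrics follow the definitional identities; a metric
with an empty denominator is reported as NaN, not zero.

## Majority-vote aggregation

The sample-level error for N odd spectra is the exact binomial lower tail
`Σ_{k<N/2} C(N,k)(1−p)^{N−k} p^k` — no normal approximation. Even N is
rejected (the majority rule leaves ties undefined). `minimal_odd_n` uses the
strict inequality `Q(N) < α` and requires `p > 1/2`, with a search cap at
N = 10,001. Coefficients use exact integer arithmetic up to N = 60 and
log-gamma accumulation beyond, avoiding overflow. A Monte-Carlo estimator
(`monte_carlo_majority`) serves as an internal verification oracle.

At the reference single-spectrum operating point (`p₁ = 0.837`,
`p₂ = 0.783`) the tails give 5 and 7 spectra respectively for error < 5%.
Note the asymmetry: the *specificity* side (Type I, normal called ROD)
needs 5 and the *sensitivity* side (Type II) needs 7; summaries that pair
"7" with Type I implicitly swap the labels relative to these equations. The
package reports both `n_star` values keyed to their p inputs.

A note on the reference operating point: in the reference single-spectrum
confusion table the counts imply specificity 83.4% while the printed cell
reads 83.7% (the printed FPR 16.6% matches the counts); the printed
precision, NPV and FNR cells are likewise inconsistent with the counts. The
package computes all metrics from counts by the identities and uses the
conventional printed `p₁ = 0.837` for the replicate analysis.

## Synthetic cohort generator

Each spectrum is `power · [baseline + Σ_b m_b f_b A_b g_b(ν)] + ε(ν)` on a
336-point grid (377…1717 cm⁻¹ step 4): a linear baseline, seven Gaussian
bands (`g_b` unit height; Lorentzian optional), additive Gaussian noise
`ε ~ N(0, 0.01²)`, and a log-normal laser-power factor (CV 5%) that scales
the signal and the attached reference intensity — so reference
normalization removes it exactly, as on the instrument. `m_b` is a
per-sample log-normal multiplier (between-patient heterogeneity), `f_b` a
per-spectrum one (within-section spatial heterogeneity); both have mean 1.

Class differences enter through the mean amplitudes: ROD multiplies the two
phenylalanine bands by 2.8 and the three mineral bands (ν₁PO₄, ν₂PO₄,
ν₁CO₃) by 0.72, with amide bands unchanged. These effect sizes, with sample
CVs of 0.025–0.04 and spectrum CVs of 0.275–0.385, were calibrated once so
that the default cohort reproduces the realistic single-spectrum regime:
10-fold-CV LDA accuracy 0.80 ± 0.01 across seeds at 2,000 spectra/class.
No quantitative effect sizes exist to copy — only the directions and the
resulting classification accuracy are constrained — so the preset targets
that regime rather than any raw-spectrum shape.

What the generator does **not** emulate: PMMA-embedding signal, fluorescence
curvature (the background is exactly linear), cosmic rays, detector
etaloning, polarization effects, or spatial correlation between neighboring
map pixels (a smoothed multiplicative field is available but off by
default, since real-map texture is qualitative here). Passing tests on this
cohort therefore demonstrate the correctness and calibration of the
*analysis*, not performance on real patient spectra, which are not publicly
available.

Determinism: one cohort seed fans out through independent child streams per
sample; identical configs give bit-identical cohorts, and the pipeline's
classifier fold seed is fanned out separately so changing it never perturbs
the simulated spectra.

## Problem sizes

Tests and the demonstration pipeline use scaled-down cohorts — 1 × n strips
of 150–2,000 spectra per class instead of full 150 × 150 maps — chosen so
the statistical assertions (direction of mean biomarker differences,
accuracy interval, 3-SE Monte-Carlo agreement) are well-powered while the
suite stays fast. Full-size maps (22,500 spectra each, 157,500 per cohort)
are supported through the same API and file formats.

## Known limitations

* Spectrum-wise cross-validation overstates accuracy relative to a
  patient-held-out evaluation; use `grouped=True` for the honest-but-coarse
  variant (with 7 samples it yields only 7 folds).
* The binomial aggregation assumes the N spectra are independent and
  identically distributed draws from the sample; spatially adjacent map
  pixels violate independence, which is why the method contemplates spectra
  from *different locations*.
* The odds scores are calibrated per training fold; only their position
  relative to 1 is used downstream, not their absolute scale.
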