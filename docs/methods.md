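# Methods

`drusenkit` is a simulation-and-analysis package for method-comparison
studies of OCT drusen volumetry in age-related macular degeneration.
This note documents the model, the defaults and why they were chosen,
the numerical choices, and what the synthetic experiments do and do not
demonstrate about real data.

## Eye model

An eye is a 2-D en-face scene in micrometres with the fovea at the
origin:

* **Bruch's membrane (BM)** — a gentle low-order polynomial
  `c00 + c10·x' + c01·y' + c20·x'² + c02·y'²` on coordinates scaled by
  3000 µm, with coefficients drawn per eye (constant 50–150 µm, linear
  ±20 µm, quadratic −25…+10 µm).  Only smooth physiologic curvature is
  modeled; no axial artifacts or pathology of BM itself.
* **Healthy RPE** — BM plus a per-eye physiologic offset drawn uniformly
  in 30–40 µm.
* **Drusen** — spherical caps lifting the RPE.  A cap with base radius
  *a* and peak height *h* has the closed-form volume
  V = (π·h/6)·(3a² + h²), which provides an analytic ground truth for
  every volumetric claim.  Cap geometry bounds h ≤ a.  Overlapping caps
  add their heights, so the analytic total is an exact sum; real soft
  drusen coalesce rather than add, which matters only for densely packed
  configurations and not for the agreement statistics studied here.
* **Reticular pseudodrusen (RPD)** — cap-shaped deposits sitting *above*
  the RPE.  Individual RPD lesions are ~100 µm across but coalesce into
  confluent ribbons; a lesion object here represents such a confluent
  patch (diameter 600–1400 µm, 3 + Poisson(5) patches per RPD eye).
  Patch heights are rescaled per eye so that the total RPD volume is
  1.2× the eye's drusen volume — RPD burden tracks disease severity —
  and RPD-positive eyes carry a 0.6× reduced soft-drusen rate, matching
  the observation that RPD eyes have slightly lower measured drusen
  volumes than RPD-free intermediate AMD.

### Staging

Beckmann staging by maximal drusen base diameter: no AMD ≤ 63 µm, early
AMD (eAMD) 63–125 µm, intermediate AMD (iAMD) > 125 µm.  Stage models
enforce the class invariant by construction:

| stage  | small (30–63 µm) | medium (63–125 µm) | large (150–700 µm) |
|--------|------------------|--------------------|---------------------|
| no AMD | 1 + Pois(1.5), only in 30 % of eyes | — | — |
| eAMD   | Pois(2) | 1 + Pois(3) | — |
| iAMD   | — | Pois(4) | 1 + Pois(7·G), G ~ Gamma(1.3, 1/1.3) |

Heights are a uniform fraction of the diameter (0.20–0.35).  The
gamma-mixed (negative-binomial-like) large-drusen count gives iAMD the
strongly right-skewed, overdispersed volume distribution seen clinically
(mean ≈ 0.13 mm³, SD ≈ 0.12 mm³ on the dense raster at defaults, range
to ≈ 0.9 mm³).  No published per-stage drusen count/size distributions
exist; these defaults were chosen once to reproduce the clinical group
summaries in order of magnitude and were then frozen.  Bump centers are
uniform on a 2400 µm-radius disc about the fovea so that lesions lie
inside every scan pattern and essentially inside the 5-mm grading
circle.

## Device profiles

A profile fixes the scan pattern and the measurement distortion.
Defaults (fields in µm; ~290 µm/deg):

| profile | B-scans | spacing | A-scan pitch | field | bias slope | RPD capture |
|---|---|---|---|---|---|---|
| spectralis_dense  | 241 | 30.2  | 29 | 8700×7248 | 1.0 | 0.6 |
| spectralis_sparse | 25  | 241.7 | 29 | 5800×5801 | 1.0 | 0.6 |
| cirrus            | 200 | 30.15 | 30.15 | 6000×6000 | 0.5 | 0.35 |

Axial pitch is 3.9 µm everywhere, so the 5-pixel filter threshold is the
canonical 19.5 µm.  Surface noise is i.i.d. Gaussian, SD 2 µm per node on
each surface.

The simulated RPE is
`BM + offset + bias_slope·h + bias_intercept (where h > 0) + noise`,
with *h* the drusen height **plus captured RPD height**: a device's
systematic error applies to everything its algorithm segments as an RPE
elevation, not only to true sub-RPE drusen.  The Cirrus-style slope of
0.5 mirrors the observed ≈ 2× inter-device volume ratio and makes the
fitted Deming conversion land near the published 0.473 / 2.112 slopes.

RPD capture is Bernoulli per lesion per scan, *shared within a device
family* (the same algorithm treats a patch identically on its dense and
sparse raster) and independent across families.  This is what produces
the package's RPD stratification effect: in RPD eyes the two devices
disagree about which confluent patches contribute volume at all, which
lowers the inter-device ICC (≈ 0.77 → ≈ 0.66–0.71 at defaults) while
leaving the inter-scan ICC essentially untouched — the clinically
observed pattern.  The different capture probabilities (0.6 vs 0.35)
additionally make the Cirrus-style measurement *relatively* smaller in
RPD eyes.

## Segmentation

Both algorithms reduce to "RPE minus a reconstructed drusen-free floor,
clipped at zero":

* **BM-offset floor** — the per-eye offset is the mode of the histogram
  of RPE−BM with bin width equal to the axial pitch (ties broken toward
  the smaller offset; the returned value is the median gap inside the
  modal bin, which is exact for a constant gap and robust to drusen
  covering a minority of the field).  An RPE below BM over more than half
  the scan raises `ImplausibleSegmentationError`.
* **Expected-RPE floor** — per B-scan, a degree-3 polynomial is fit to
  the segmented RPE and iteratively refit (5 iterations) on the support
  `RPE ≤ fit + 5 µm`, excluding drusen from the support.  All rows share
  one design matrix, so each iteration is a single batched weighted
  normal-equations solve; rows whose support would become underdetermined
  keep their previous fit.  With 0 iterations this degrades to a plain
  least-squares fit that cuts through drusen (tested as such).

**False-positive filter.**  8-connected components of the positive
en-face height mask whose *peak* height is strictly below
5 px × axial pitch (19.5 µm) are zeroed; a component reaching exactly
the threshold is kept.  The filter is idempotent and can only remove
volume.  Connectivity is not specified by device vendors; 8-connectivity
is standard image-analysis practice.  One consequence of per-node
Gaussian noise worth knowing: about half of all drusen-free nodes have
slightly positive height, and at that density the positive mask
percolates, so the noise sheet connected to a genuine druse survives the
filter and adds a small (~0.01–0.02 mm³) offset to eyes with detected
drusen on *both* devices, while drusen-free eyes are cleanly zeroed.
This inflates the early-AMD group mean relative to clinical tables but
does not affect detection, ordering, or agreement conclusions.

## Volumetry

Drusen volume inside a fovea-centered circle sums
`height × row spacing × A-scan pitch` over nodes whose centers fall in
the circle (no partial-pixel weighting; the scheme converges as spacing
shrinks and is within 2 % of the closed form at 10 µm spacing, 5 % at
30 µm for a 500/60 µm cap).  The 3-mm volume never exceeds the 5-mm
volume.  For sparse rasters the *filtered* height map is linearly
interpolated along the slow axis to the target spacing (default: the
finest configured device spacing) before summation.  Interpolating the
filtered map, not the raw surfaces, is deliberate: a sparse raster
cannot re-detect a druse that fell between its B-scans, which is exactly
the mechanism that costs medium-drusen sensitivity in eAMD (detection
≈ 0.98 dense vs ≈ 0.55 sparse at defaults) while leaving large-drusen
iAMD volumes in near-complete agreement (inter-scan ICC ≈ 0.98–0.99).
The interpolation error is alignment-dependent: it is worst (≈ −15 % for
a 500 µm cap) when a B-scan passes exactly through the cap center, and
within a few percent for generic positions.  Vendor interpolation
schemes are proprietary; linear interpolation is an assumption.

## Agreement statistics

All statistics operate on paired per-eye volumes and are implemented
from their definitions (libraries serve only as cross-check oracles in
the tests):

* **Two-way single-measurement ICC.**  From the two-way ANOVA mean
  squares (MSR rows/eyes, MSC columns/methods, MSE residual; k = 2):
  consistency = (MSR−MSE)/(MSR+MSE); agreement =
  (MSR−MSE)/(MSR+MSE+(k/n)·max(MSC−MSE, 0)).  A constant between-method
  offset leaves consistency unchanged and strictly lowers agreement;
  agreement ≤ consistency always (the truncation of the negative column
  component preserves this).  95 % CIs: the exact F construction for
  consistency, the Satterthwaite-df F approximation for agreement.  Zero
  between-eye variance returns an `undefined_low_variance` status rather
  than a number — low-variance groups (no AMD, eAMD) produce
  uninterpretable ICCs by design.
* **Bland–Altman** — differences oriented as (denser/reference method) −
  (other); limits of agreement at mean ± 1.96 SD; the standardized mean
  difference divides by the mean of the per-eye averages and is flagged
  undefined when that mean is zero.
* **Wilcoxon signed rank** — zeros dropped (Wilcoxon's original
  treatment); exact null distribution by the shift recursion for ≤ 25
  nonzero differences (midranks doubled to integers), tie-corrected
  normal approximation with 0.5 continuity correction beyond; all-zero
  input returns p = 1 with a degenerate flag.
* **Jonckheere–Terpstra** — J counts, over ordered group pairs, pairs
  with the later-group value larger (ties ½).  Exact permutation p by
  full enumeration for pooled n ≤ 10, tie-corrected normal approximation
  with continuity correction otherwise.  For fully tied input the exact
  p is 1 (every arrangement attains the observed J); the approximation
  returns 0.5 when the tie-corrected variance vanishes.
* **High-risk κ** — per-method cut-offs applied as ≥ (boundary inclusive);
  Cohen's κ and percent agreement on the 2×2 table; a single-cell table
  is flagged `undefined_degenerate`.
* **ROC** — candidate thresholds at the unique observed values plus +∞,
  positive iff value ≥ threshold; AUC by the Mann–Whitney rank statistic
  with ties ½ (identical to trapezoidal integration of the staircase);
  the operating threshold minimizes (1−se)² + (1−sp)² — the
  closest-to-corner rule as printed, *not* Youden's J — with ties broken
  toward the smaller threshold.

## Conversion

Deming regression with λ = 1 (orthogonal): slope =
(s_yy − λ·s_xx + √((s_yy − λ·s_xx)² + 4λ·s_xy²)) / (2·s_xy).  λ = 1 is
the only choice under which the two fit directions are exact algebraic
inverses, consistent with the published conversion pair being
near-reciprocal (2.112 ≈ 1/0.473).  The workflow restricts iAMD pairs to
an optimal subset (drop eyes whose Cirrus-style value exceeds the
Spectralis-style value and eyes with per-eye mean > 0.2 mm³; a pair
exactly at the cap is kept), splits round(0.8·n)/rest with a seeded
permutation (unstratified — the original split method is unstated), fits
on the training part, and reports mean error and RMSE of converted vs
observed values on the held-out part.  The published coefficients
(0.473/−0.0091 and 2.112/+0.0193) ship as named constants for the
worked-example cut-off conversion (0.03 → 0.083 mm³) and are kept
distinct from freshly fitted values.  A sklearn-style estimator
(`DemingRegression`) wraps the same closed form for pipeline use.

## Problem sizes and determinism

Everything is a pure function of (config, seed).  The test suite uses
200 eyes per stage for the detection-asymmetry and inter-scan-agreement
properties, 10 seeds × 100 iAMD eyes for the RPD stratification
property, and n = 200 for Deming parameter recovery; the acceptance
script runs the full three-modality study at the clinical composition
49/25/126.  These sizes put Monte-Carlo error well inside the asserted
margins while keeping the default suite in the low minutes on one CPU.

## Limitations

* Surfaces are simulated directly; there is no B-scan intensity
  rendering, speckle, optics or curvature model, and no deep-learning
  layer regression — layer surfaces are inputs.
* The generator's drusen/RPD distributions are plausibility-calibrated,
  not fitted to data; passing property tests demonstrates internal
  consistency of the measurement-and-statistics chain, not clinical
  accuracy of any particular number.
* Two eyes per subject are not modeled (each synthetic eye is an
  independent subject); the clinical analysis likewise used both eyes of
  most subjects without intra-subject clustering adjustment, so the
  statistics replicate that practice and CIs should be read accordingly.
* The inter-scan mean difference at defaults is slightly *negative*
  (sparse ≥ dense by ~0.005 mm³, from convexity loss in slow-axis linear
  interpolation), whereas the clinical comparison found the dense scan
  slightly larger; magnitude and near-perfect inter-scan agreement match,
  the sign of this small term does not.
* Drusen area, lesion counts, and 3-mm-circle endpoints beyond the
  reported volume are out of scope.
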