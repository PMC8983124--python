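# Methods

This note documents the models, generators, numerical choices, and known
limitations behind each pipeline stage. Problem sizes quoted for tests
and scripts are the defaults the package ships with.

## CT phantom and %LAA

**Generating model.** The phantom is a soft-tissue elliptic-cylinder
body inside exterior air (−1000 HU, touching the lateral and caudal grid
borders), containing an ellipsoidal lung and a walled, symmetric
bifurcating airway tree (default 3 levels, lumen radius 1.25 mm, wall
1 mm of soft tissue) that opens at the cranial face. Tissue HU are drawn
per compartment: normal parenchyma N(−700, 60), emphysema N(−930, 30),
soft tissue N(+40, 20), airway lumen N(−1000, 5) truncated at ±2 SD (the
lumen is homogeneous air; truncation keeps every lumen voxel at or below
−990 HU, which downstream airway tests rely on). These defaults are
engineering choices — no ferret-lung HU histograms are available to
calibrate against a clinical reconstruction kernel — placed so the %LAA
thresholds (−950…−870 HU) fall between the two parenchymal modes, where
threshold behaviour is informative.

Emphysema is voxelwise Bernoulli(f) within the lung by default, which
makes the expected %LAA exactly computable: at threshold T,

    %LAA(T) = 100 · [ f·Φ((T+930)/30) + (1−f)·Φ((T+700)/60) ]

e.g. ≈ 24.6% at −870 HU for f = 0.25. A blob mode (union of random
spheres) is available for spatial-coherence experiments; its realised
fraction overshoots the target by at most one blob.

**Pipeline.** Lung segmentation thresholds at −320 HU (separates
parenchyma from soft tissue in this mixture and in common mammalian CT
practice), removes every low-attenuation component connected to the grid
border (exterior air, and the airway opening), and keeps the largest two
remaining components (left/right lungs may or may not fuse at the
carina; configurable). Airway extraction grows a 26-connected region
from a trachea seed (auto mode: the darkest candidate component that
opens at the top face without touching a lateral face, seeded at the
top-slice centroid) starting at −950 HU, relaxing in +10 HU steps up to
−500 HU; a step that multiplies the region volume by more than the leak
factor (default 2.0) indicates a breach into parenchyma and the pre-leak
region is returned. Mask refinement subtracts the airway, closes with a
2 mm ball (realised by Euclidean-distance-transform dilation/erosion
with anisotropic spacing, which makes the closing exactly idempotent),
fills holes in 3D, and re-subtracts the airway so the result is
guaranteed disjoint from it. %LAA uses inclusive comparison (≤), so
voxels exactly at a threshold count.

On the default 96³ phantom (0.5 mm voxels, ~97,000 lung voxels) the
pipeline %LAA sits within ~0.5 points of the truth-mask count; the small
deficit comes from airway-wall voxels recaptured by closing, which
dilute the denominator. The acceptance-scale check uses a 160³ phantom.

## Spirometry

Traces are generated as multi-compartment washouts: cumulative exhaled
volume V(t) = FVC·Σ aᵢ(1−e^{−(t−t₀)/τᵢ}) after onset, zero before.
Noise is added to the flow channel only; the volume channel stays the
analytic truth so FEV_x truth is exact. Default sampling is 1 kHz.

Onset is back-extrapolated: a line through the rising-limb samples
between 25% and 75% of peak flow, t₀ at its zero crossing — the standard
spirometry convention, needed because the generating model's onset is a
free parameter and real maneuvers have no marked zero. When the rise is
effectively instantaneous (pure exponential decay) the fallback is the
first sample above the noise floor (2% of peak), accurate to one sample.
FEV_x is linearly interpolated cumulative volume at t₀+x; FVC is the
end-of-trace cumulative volume, and an end-of-test criterion (flow below
1% of peak sustained 50 ms) only decides whether the maneuver is flagged
truncated. For noiseless analytic traces sampled at 1 kHz this keeps
FEV_x and the ratio within 0.1% of closed form provided the trace runs
to its plateau (≈ 7 slow time constants).

Calibration of the timed volume scans a grid (default 0.1–1.0 s, step
0.1) for the smallest x at which a summary of control FEV_x:FVC ratios
is strictly above the floor (default 0.7). The default summary is the
minimum — all controls must clear the floor — because the alternative
(sex-dimorphic animals dragging the minimum down) is exactly the
ambiguity the data show; the quantile is configurable and logged in the
result. Five τ = 0.2 s controls cross 0.7 at x = 0.2408 s analytically,
so the grid returns 0.3 s.

Multistroke IC sums the 3→15 and 15→30 cmH₂O delivered volumes; for any
monotone PV relationship this equals the single full stroke because
volume is a state function. The generator's recruitment offset δ
inflates the second stroke so the summed maneuver overreads the true IC
by the factor (1+δ); the analysis-side correction IC = (v1+v2)/(1+δ)
inverts that exactly. δ defaults to zero: the empirical ~5% overestimate
is an observation about a particular apparatus, not a physical constant.

## PV compliance

The deflation limb is fitted with V(P) = A − B·e^{−KP} by
Levenberg–Marquardt (bounds B ≥ 0, 10⁻⁶ ≤ K ≤ 10); quasistatic
compliance is the derivative at the reference pressure,
Cst = B·K·e^{−K·P_ref}, default P_ref = 5 cmH₂O (a physiologic
tidal-range operating point). Fits with R² ≤ 0.9 are flagged
`accepted=False` and should be excluded from averages, mirroring
standard practice for model-based mechanics. If K collapses below 10⁻³
cmH₂O⁻¹ the exponential is unidentifiable from a straight line over the
3–30 cmH₂O window and a linear fit supplies Cst (= slope) with a
fallback flag. Noise-free loops recover (A, B, K) to 10⁻⁶ relative.

## Morphometry

Airspaces are the bright (low-stain) side of an Otsu split for grayscale
input, or the foreground of binary input; labelling is 8-connected.
Regions overlapping the exclusion mask by any pixel are removed entirely
(the mask stands in for the investigator excluding conducting airways;
any-overlap is the conservative deterministic rule). Border-touching
regions are excluded by default since their missing parts bias SA/P
upward; regions under 10 px are noise. Area is pixel count × (pixel
size)²; perimeter is the length of the marching-squares contour after
Douglas–Peucker simplification at 0.8 px tolerance. The simplification
matters: the raw contour is accurate for axis-aligned edges but
overestimates smooth boundaries by ~5% through staircase excursions,
while classical isotropically-calibrated estimators (Crofton-type)
underestimate axis-aligned rectangles by ~5%; the simplified contour
keeps both squares (−0.5%) and disks of radius ≥ 20 px (≤ 1%) within
the tolerances the tests assert. SA/P is the per-airspace ratio;
lobe summaries are means of per-airspace ratios (the pooled
total-area/total-perimeter alternative is reported alongside), and the
animal mean is the unweighted mean of lobe means.

## Longitudinal mixed model

The model for repeated IC/Ln measures is

    value_ij = α_sex(i) + β_genotype(i)·age_ij + u_i + e_ij,
    u_i ~ N(0, σ_u²),  e_ij ~ N(0, σ²)

fitted by REML (statsmodels MixedLM). Genotype slopes use a cell-means
interaction coding with no main age term, so each genotype's slope is a
directly reported fixed effect; slope contrasts are Wald tests on the
fitted covariance (normal approximation — Satterthwaite-type small-sample
degrees of freedom are not available in this estimator, a known
limitation at very small n). No random slope is included: at 6–19
animals per genotype a random slope is weakly identified, and the
fixed-effect slope is the estimand. Noise-free cohorts make the REML
likelihood degenerate, so an exactly-interpolating per-animal OLS is
detected (residual ≈ 0) and its exact slopes returned instead.

The synthetic cohorts mirror the study design: PiMM 19 animals × 6
visits over ages 100–1000 d (generating slope 0.000093 mL/cm/day), PiZZ
6 × 6 over 100–700 d (0.00043), AAT-KO 13 × 7 over 100–1100 d
(0.00036). Sex alternates within each cohort; sex intercepts are 0.75
(F) and 1.05 (M) mL/cm, random-intercept SD 0.08, residual SD 0.05
mL/cm — chosen once from typical ferret scale (IC ≈ 30–45 mL, body
length ≈ 38–44 cm, strong sexual dimorphism). Recovery runs use 200
Monte-Carlo cohorts per preset, which puts the Monte-Carlo SE of the
mean slope at ≈ 1–3 × 10⁻⁶, about 1% of the generating values.

## Paired ratios and inhibition AUC

Case/control ratios are tested on the log scale with a one-sample t-test
against zero (repeated measures collapsed to per-animal means first; a
mixed-model variant on the raw repeats is a straightforward extension
but the per-animal collapse is the default because it is exact under the
balanced designs generated here). Inhibition capacity is the trapezoidal
AUC of residual protease activity over sample volume — trapezoid rather
than Simpson because assay volumes are unevenly spaced — with activity
normalised to 1 at zero volume; lower AUC means more antiprotease. The
AUC is bounded by [0, max volume] whenever activity lies in [0, 1].

## What the synthetic data do and do not show

The generators share the real data's structure (HU mixtures with a
threshold-spanning emphysema mode, exponential emptying, Salazar–Knowles
PV shape, balanced longitudinal designs with sex dimorphism) but none of
its nuisance processes: no reconstruction-kernel texture or beam
hardening, no anatomically faithful lobar geometry, no cardiogenic or
breathing-motion artifacts, no effort-dependent flow plateaus, no
operator variability in airway exclusion, and Gaussian rather than
heavy-tailed measurement noise. Passing tests therefore demonstrate that
the estimators are correct and unbiased under their stated models at the
study's sample sizes — not that the models capture every property of
ferret data. Degenerate inputs (no lung candidate, all-zero flow,
single-visit cohorts, identical regression abscissae) raise typed errors
rather than returning numbers.
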