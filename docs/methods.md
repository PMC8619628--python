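# Methods

`stromaquant` quantifies tumor-associated stromal collagen from label-free
two-channel multiphoton images and screens the resulting per-patient
features for association with time-to-event outcomes. This note records
the models, the defaults and why they were chosen, what the synthetic data
does and does not emulate, and the numerical decisions that shape results.

## Imaging model and conventions

A multiphoton acquisition is modeled as two coregistered 8-bit channels on
a common pixel grid: `R`, second-harmonic generation (SHG), bright only
over fibrillar collagen; and `G`, two-photon autofluorescence (2PAF),
bright over all tissue (cellular stroma and glandular epithelium).
Conventions used everywhere:

- coordinates are `(row, col)`, 0-based, pixel centers at integer
  positions; intensities live on the 0–255 scale;
- physical distances are micrometres, with a default pixel pitch of
  0.497 µm/pixel and a default region-of-interest size of 500 µm
  (1006 px at that pitch, rounded to the nearest pixel);
- fiber orientations are axial quantities on [0°, 180°); all angular
  differences are taken modulo 180° and folded to [0°, 90°].

## Collagen features

Seven quantifiers summarize an ROI (the same seven enter the survival
screen, in this fixed reporting order): collagen area fraction `af`, mean
SHG-foreground intensity `i_r`, normalized stromal intensity ratio
`i_r/(i_r+i_g)`, mean fiber length, mean fiber width, mean fiber angle to
the tumor-gland boundary, and orientation coherence. `i_g`, the mean 2PAF
intensity over tissue, and fiber straightness are carried as auxiliary
fields.

**Thresholds.** The tissue mask is an Otsu threshold of `G` followed by
morphological closing (disk r = 3 px) and removal of components under
50 px; the SHG foreground is an Otsu threshold of `R` computed within the
analysis region. Both accept a fixed-value override for cohort-wide
thresholds. Thresholding is per image; with per-image Otsu, collagen-poor
images acquire a threshold inside the noise distribution and their area
fraction is overestimated — a known limitation of automatic per-image
thresholds that the RS/NS contrast tests tolerate because it affects both
groups. If no SHG pixel survives thresholding the degenerate values
`af = 0, i_r = 0, norm_intensity = 0` are returned (the collagen-free
limit), not an error.

**Gland/stroma segmentation.** Glands are autofluorescent tissue that is
locally SHG-free. The implementation subtracts the cleaned SHG foreground
from the tissue mask and morphologically opens the remaining void with a
disk (default radius 12 px ≈ 6 µm at the default pitch): stromal
inter-fiber gaps vanish, gland-caliber voids survive with borders that
track the surrounding fibers. Hole filling and an area filter
(default 2000 px) follow; contours of the mask are the tumor-gland
boundaries. A windowed-density formulation was tried first and abandoned:
the averaging window erodes the detected gland by its own radius and
sparse stromal patches alias as glands, which capped the phantom Dice
score near 0.8. The disk radius is the knob that matters: it must exceed
the stroma's fiber-free gaps but stay below the gland caliber, so very
fiber-sparse stroma will misclassify (documented failure mode: an image
with no SHG at all classifies essentially all tissue as gland, with a
warning).

**Fiber tracing.** The tracer substitutes a transparent
smooth–threshold–skeletonize–link pipeline for curvelet-based tools:
Gaussian ridge smoothing (σ = 2 px), Otsu threshold within the mask,
skeletonization, splitting at branch points, pruning of segments under
15 px, then greedy linking of end pairs closer than 8 px whose end
orientations differ by less than 20°, best angle first (ties broken by
gap), each endpoint used once. Defaults were set on phantom recoveries
(exact count up to 50 disjoint fibers; lengths within 10%).

**Fiber width.** Per-point widths start from the Euclidean distance
transform of the raw image thresholded at the tracing threshold, then are
rescaled to a full-width-at-half-maximum under a Gaussian cross-section
model: the EDT radius is the ridge half-width *at the threshold*, so the
reported width would otherwise grow as the threshold drops. With peak
intensity `p` at the skeleton point and threshold `t`, width =
2·EDT·sqrt(ln 2 / ln(p/t)), with the upscaling capped at 2× for points
barely above threshold. Endpoints are excluded from the per-fiber mean
(they bias widths low). Phantom recovery is within ~15% for widths of
2–6 px; sub-pixel aliasing dominates the residual error for the narrowest
fibers.

**Coherence.** The structure tensor (Gaussian-averaged gradient outer
product, σ = 2 px) is summed over the mask — an average weighted by
gradient energy — and the coherence of the summed tensor,
(λ₁ − λ₂)/(λ₁ + λ₂), is reported. Parallel stripes score ≥ 0.95,
isotropic noise ≤ 0.01, and the score is rotation-invariant to within
0.05. Note that the coherence of *k* discrete isotropically oriented
fibers is upward-biased by roughly 1/√k; ROIs with only a handful of
fibers therefore read as spuriously aligned.

**Boundary angle.** For each fiber, the boundary point nearest the fiber
midpoint is found over all gland contours; the boundary tangent is a
central difference over a ±5-point window (wrapping on closed contours);
the feature is the acute axial difference between the fiber's
principal-axis orientation and that tangent. With no gland in the ROI the
feature is missing (NaN) and is excluded from aggregation.

## Synthetic phantoms

Phantoms exist so every stage can be validated against exact ground
truth. A phantom is: a tissue footprint (an inscribed ellipse by default,
emulating a round tissue core on dark glass — necessary for
autofluorescence-based tissue masking to be meaningful; a full-frame
option exists for tracer tests); zero or more SHG-free, brighter-green
elliptical glands; and fibers rendered into `R` as Gaussian-profile
ridges whose FWHM equals the nominal fiber width, summed, clipped and
quantized last (fixed seeds reproduce images bit-for-bit).

Fiber centerlines are unit-step random walks: the axis is drawn from a
von Mises distribution on the doubled angle (κ = 0 isotropic; the walk
direction along the axis is randomized), per-step drift is bounded by the
curviness parameter, lengths and widths are truncated normals. Seed
midpoints are uniform over the frame *expanded by half a fiber length*,
and rendering clips fibers to the stroma — the physical analogue of
sectioning — because seeding strictly inside the region depletes coverage
within half a fiber length of every edge, which masquerades as SHG-free
gland. `true_af` counts the noiseless half-maximum footprint of the
rendered fibers over tissue; recovering it by thresholding requires a
threshold at half the fiber peak (the acceptance phantom uses
equal-brightness fibers for exactly this reason — with a threshold of 0,
the ≥1-count footprint of a Gaussian ridge is about three times wider
than its half-maximum footprint).

What the phantoms do **not** emulate: optical point-spread functions and
shot noise (additive Gaussian noise only), nuclei and cellular texture in
the 2PAF channel, fiber crimp/waviness beyond bounded angular drift,
spatially varying background, and 3-D structure. Passing phantom tests
therefore demonstrates correctness of the measurement pipeline, not
robustness to every property of real tissue.

The reactive-stroma archetype used in contrast tests is dense, bright,
thick and aligned (110 fibers, peak 140, width 3.5 µm, κ = 3); the
normal-stroma archetype is dim, thin and isotropic (45 fibers, peak 55,
width 2.0 µm, κ = 0). The normal archetype deliberately has enough fibers
that ROI-level isotropy is expressed (see the 1/√k bias above).

## Cohort simulation

Each patient has a latent feature vector drawn from a population
distribution (defaults chosen as plausible values on each feature's
scale: af 0.25 ± 0.08, i_r 80 ± 20, width 3.0 ± 0.8 µm, ...); cores
scatter around it with a smaller within-patient SD; features are mutually
independent across patients unless an effect is imposed. Recurrence times
are exponential with rate `h0 · exp(Σ β_f (x̄_f − μ_f))` where `x̄` is the
patient's across-core mean and `μ` the population mean — centering keeps
`h0` (default 0.02/month) the event rate of a typical patient — with
administrative censoring at the end of follow-up (default 36 months, the
three-year biochemical-recurrence window). Within-patient correlation
across cores is a simulator knob, not an inference target. Simulated
times verifiably satisfy proportional hazards: coefficient recovery
within 2 SE in ≈95% of replicate cohorts.

## Survival screen

Per-patient features are the field-wise means of core-level features
(missing values excluded; a field missing in all cores stays missing).
Cox models use the Efron tie correction (Newton–Raphson, precision 1e-9)
via lifelines; a monotone partial likelihood (perfect separation,
detected as a diverging standardized coefficient after a convergence
warning) raises an error naming the covariate. The univariable screen
fits one model per feature on that feature's complete cases, reports HR,
95% Wald CI and the raw two-sided p in a fixed order, and flags features
with p < 0.05. Fraction-valued features (area fraction, normalized
intensity ratio) enter the models per percentage point (×100), the scale
on which such quantities are conventionally tabulated; p-values, flags
and KM splits are invariant to this scaling. **No multiple-testing correction is applied** — the screen
reports raw p-values as a hypothesis generator, so about one false flag
per twenty null features is expected at the 0.05 level. Flagged features
are partitioned by a Spearman collinearity screen (|ρ| > 0.7 cannot share
a model), yielding one multivariable candidate model per group; models
are compared by AIC and by likelihood-ratio tests against their nested
base. Kaplan–Meier curves split each flagged feature at its mean (ties at
the mean go to "Low"), with the two-group log-rank test. The
proportional-hazards check correlates scaled Schoenfeld residuals with
the event-time rank (Pearson, two-sided p) per covariate.

## Numerical and testing choices

- Quantization to 8 bits is always the final rendering step; all
  stochastic stages take explicit integer seeds, so outputs are
  bit-reproducible across platforms.
- Registration maximizes normalized cross-correlation over 6 affine
  parameters (Powell, parameters scaled so a step of 1 ≈ 1 px of
  translation), initialized by phase correlation when no initial
  transform is given; failure returns the initial transform with a flag
  and warning.
- Monte-Carlo test sizes were chosen so that binomial noise cannot
  plausibly cross the asserted bounds at the package's true operating
  characteristics (e.g. 500 replicate cohorts for CI-coverage bounds,
  5000 null replicates for type-I error rates); smaller internal checks
  state correspondingly wider bands.
- The end-to-end demo simulates 60 patients × 3 cores as 200×200 px
  phantom cores with patient-level brightness and width levels driving a
  proportional-hazards recurrence model (log-HR 0.05 per intensity unit
  and 1.2 per µm of width — the latter close to the hazard ratios
  reported for fiber width in prostate-cancer cohorts). Because wider
  fibers also cover more area, the extracted area fraction genuinely
  correlates with width and is usually flagged alongside it; the
  collinearity partition then assigns them to separate models, which is
  the intended behavior, not a defect.

## Known limitations

- Per-image Otsu thresholds inflate `af` in collagen-poor images.
- The tracer merges touching parallel fibers closer than about one
  smoothing width; counts are exact only for separated fibers.
- Width estimates assume a Gaussian ridge cross-section; flat-topped or
  hollow fibers would be misestimated.
- The gland rule requires fibrous stroma; fiber-sparse benign tissue will
  over-segment as gland.
- The screen is a screen: raw p-values, no prediction model, no
  competing risks, no time-varying covariates.
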