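# Methods

This note documents the models, parameter choices and numerical conventions
behind `alphaqar`, and what the synthetic-data validation does and does not
demonstrate about real data.

## Quantification model

A list-mode alpha camera records one event per detected scintillation:
centroid position (µm) and timestamp (s). With `N₀` parent atoms at reference
time 0 and decay constant `λ = ln2 / T½`, the expected counts in an
acquisition window `[t₁, t₂)` are `f·N₀(e^(−λt₁) − e^(−λt₂))`, where the
sensitivity factor `f` is the camera's single global quantification constant
(detected events per primary decay; it can exceed 1 for chains emitting
several alphas per parent decay). Summing over the windows of an acquisition
schedule and inverting gives activity at the reference time:

    A₀ = (λ/f) · Counts_total / Σᵢ (e^(−λ·tᵢ₁) − e^(−λ·tᵢ₂)).

This is exact for spliced, interrupted or week-long recordings. The module
also quantifies the error of the naive alternative (assume the average of the
start and end activities): with `x = λT` the relative error is
`(x/2)·coth(x/2) − 1`, i.e. ~0.25% for a 60-hour Ac-225 acquisition but
~2% at one week and ~7.9% at two weeks. The formula is the ratio of the
trapezoid-of-endpoints average to the exact exponential time-average; the
test suite and the acceptance script both re-derive it by numerical
quadrature at run time.

**Calibration.** `f` is fitted from a dilution series by least squares through
the origin (zero activity cannot yield counts), weighted by 1/counts under
the Poisson variance model, with an unweighted fallback when any sample has
zero counts. Per-sample primary decays use the same schedule-exact decay
weights — no constant-activity shortcut. Detector efficiency is
`f / (0.5 · alphas_per_primary)`: the scintillator covers the sample from one
side, so only half of all isotropically emitted alphas can ever reach it.
The built-in Ac-225 chain uses T½ = 9.920 d and 4 alphas per primary decay.

## Event binning

Half-open square bins `[edge, edge + Δ)` with 0-based indexing; events on the
top/right outer edge, or outside the grid, are dropped and counted. Default
pitch 26.5 µm (the camera's native pixel). Binning is translation-consistent
and conserves events by construction.

## Warp correction

The camera's residual distortion is estimated from lattice phantoms (circles,
squares or dots). The ideal lattice is generated digitally; element centroids
of the measured and ideal images are extracted as intensity-weighted
connected-component centroids and paired by nearest neighbour. Two stages
compose the corrected→raw mapping:

* a global least-squares rigid alignment (closed form, SVD);
* a free-form residual: a thin-plate smoothing spline through the
  per-element residual displacements, rendered densely on the corrected grid.

The global isotropic scale (the circles phantom's role) is estimated
separately as the median ratio of paired inter-centroid distances, which is
rotation/translation-invariant and insensitive to centroid discretization.

Design notes:

* Phantom elements are rendered with a one-pixel anti-aliased coverage ramp
  rather than hard 0/1 values: the phantom exists to provide subpixel
  centroid references, and binary rasterization would quantize centroids at
  the ~0.25 px level for few-pixel elements.
* The free-form stage is fitted on centroid correspondences rather than by
  intensity-based B-spline optimization: for blob-lattice phantoms the
  correspondences are exact, the fit is deterministic and fast, and recovery
  accuracy at the centroids (< 0.5 px RMS for a barrel field; < 0.25 px for
  identical images) is asserted in the tests.
* The Jacobian determinant of the total mapping is computed by central
  differences (one-sided at borders). Corrected images are bilinear
  resamplings multiplied per-pixel by the Jacobian, which conserves total
  counts to < 0.5% for smooth fields with content away from the frame edge.
  Fields with a non-positive Jacobian anywhere (folding) are flagged.
* The synthetic distortion model for validation is an isotropic scale plus a
  radial polynomial `r' = r(1 + k₁r²)` (barrel-like, maximal in the corners)
  plus optional smooth local bumps; the generator emits the analytic truth
  field.

Warp correction is always applied before any cross-modality registration;
the pipeline records stage order in its manifest and tests assert it.

## Coregistration and stacking

The same physical sections are imaged on both modalities, so a true rigid
1:1 mapping exists. Three sections per microscope slide are registered as a
single rigid body: landmark initialization (≥ 3 paired points, closed-form
least-squares rigid fit via the cross-covariance SVD, no scale) followed by
an intensity-driven rigid Euler refinement under Mattes mutual information
(32 histogram bins, intensity-normalized images, multi-resolution pyramid).
No scaling degree of freedom exists anywhere in this step, because the warp
correction has already calibrated the autoradiography grid physically.

Section stacking registers each section to its neighbour toward the middle
(reference) section and composes transforms:

* *activity_only*: rigid Euler then similarity stages fitted on the activity
  maps; the resulting transforms are applied to the anatomy images for
  evaluation.
* *anatomy_guided*: the same stages fitted on the anatomy images plus a
  free-form B-spline refinement with a coarse control grid and
  coarse-to-fine scale schedule; the identical transforms move the activity.

Registration uses SimpleITK. A bending-energy penalty is not available in
its registration framework, so free-form regularization comes from the
coarse control-point spacing (default ¼ of the section extent), the
multi-resolution schedule, and an explicit fold check: the dense Jacobian of
the composed field must be positive everywhere or the fit is rejected.
Optimizer budgets default to a few hundred iterations per stage with
early-stop criteria; the plateau of the metric over the trailing 10% of
iterations is the convergence check reported to callers. Masks are
resampled nearest-neighbour, images bilinear.

Evaluation follows the Dice similarity coefficient of adjacent anatomical
masks (Otsu + largest component + hole fill) after registration, compared
between strategies with a two-sided paired t-test; `2|A∩B|/(|A|+|B|)`, with
the empty∩empty case defined as 1.0 and flagged. On synthetic tumor stacks
with sparse hot-spot activity and smooth inter-section warps, the
anatomy-guided strategy consistently attains equal or higher Dice — sparse
activity constrains a rigid/similarity fit poorly, while anatomy carries
boundary structure everywhere.

## Kidney compartment analysis

Stain-like anatomy images (bright F-actin tissue, dark lumina) are segmented
by: global Otsu (256-bin) → hole fill → minimum-area filter (default
0.05 mm²) for tissue; then an inner Otsu pass restricted to tissue extracts
dark lumina, classified by shape statistics. Defaults: glomeruli =
equivalent diameter 50–150 µm, circularity `4πA/P² ≥ 0.7`, bbox aspect < 3;
vessels = equivalent diameter > 150 µm or aspect ≥ 3; lumina under 400 µm²
discarded. These bands reflect murine renal microanatomy and are
configurable; vessels are deliberately limited to large vessels (the blood
pool compartment). A separation guard (class means at least 3 pooled SDs
apart) keeps Otsu from hallucinating tissue on empty images.

Uptake profiling applies an exact Euclidean distance transform to a
reference mask (tissue edge, vessels, or glomeruli) and bins activity by
distance (default 5 µm bins on the anatomy grid), normalized to the
section-mean activity concentration, so the pixel-count-weighted profile
mean is exactly 1 when the profile covers the full tissue. Empty bins are
reported missing, not zero. When profiling distance-from-vessels, vessel
interiors are excluded and the distance-0 band reported separately.

Replicates are aggregated with equal section weights; per-bin 95% CIs are
`mean ± t₀.₉₇₅,(n−1)·SEM` (a seeded percentile bootstrap is available). The
per-bin significance rule is CI exceedance, unadjusted for multiple
comparisons, and deliberately so — outputs are labelled accordingly. Two
variants are computed: per-condition exceedance flags (the other condition's
mean exits this condition's CI) and the reported between-condition call,
which requires *mutual* exceedance. The one-sided variant has an intrinsic
per-bin false-positive rate near 16–20% under i.i.d. replicates; the mutual
criterion measures ~3% (n = 3) to ~9% (n = 9) on flat phantoms over 100
seeded noise draws, keeping the rule at or below its nominal level.

## Microdosimetry

The dose-voxel kernel (DVK) is the mean absorbed dose per voxel per primary
decay for decays uniformly distributed in the central voxel. It is generated
by a purpose-built Monte Carlo under the continuous slowing-down
approximation: each chain alpha is emitted isotropically and travels in a
straight line; the Bragg–Kleeman relation `R(E) = k·E^1.75` in liquid water
(k calibrated so R(8.375 MeV) = 85 µm, giving R(5.83 MeV) ≈ 45 µm,
consistent with tabulated CSDA ranges) determines the energy lost per step
(default step: min(voxel-min-dim/4, 1 µm)), deposited at the step midpoint's
voxel. Energy straggling, delta rays, angular scattering, recoil nuclei and
beta/gamma dose are neglected; alpha tracks in water are nearly straight and
these omissions are small at the 26.5 µm voxel scale. The Ac-225 chain is
modeled as exactly 4 alphas at {5.830, 6.341, 7.067, 8.375} MeV (the 2.1%
Bi-213 alpha branch folded into the Po-213 line); energies are configurable.
Water density 1.0 g/cm³ throughout.

Each generated kernel is checked for: non-negativity, total energy per
primary within 1% of ΣE_α (conservation), the central voxel being the
maximum, and axis mirror-symmetry within Monte Carlo noise. Default voxels
are 26.5 µm in-plane; the z voxel defaults to the 28 µm section spacing
(each measured section taken as representative of its slab), with 14 µm
(the cut thickness) available via configuration.

Dose-rate maps are the 3D FFT convolution of decays-per-hour
(activity × 3600) with the Gy-per-decay kernel — linear in activity and
translation-equivariant by construction; an interior voxel of a uniform
activity block reproduces the charged-particle-equilibrium closed form
`a·3600·ΣE_α/m_voxel` to well under 1%. When the kernel's z-extent exceeds
the measured stack's z-extent, dose from unmeasured planes is missing near
the stack faces; this truncation is disclosed with a warning rather than
silently accepted. Cumulative DVHs report the masked volume fraction at or
above each threshold on a uniform grid from 0 to the masked maximum
(starting at 1.0, monotone non-increasing, ending at 0). No time-integrated
dose is computed — outputs are dose *rates* at the activity reference time.

## Synthetic data: what it shows and what it does not

All generators are pure functions of (spec, seed) on numpy's PCG64;
substreams are derived from CRC32-hashed names so adding a consumer never
perturbs existing draws, and every truth artifact (fields, transforms,
masks, enrichment geometry) is emitted alongside the data.

* *List-mode*: per pixel and window, counts are Poisson with the forward
  model's mean; positions uniform within the pixel; timestamps follow the
  truncated exponential. This validates the quantification chain exactly but
  says nothing about detector dead time, spatially varying sensitivity, or
  centroiding artifacts of real cameras.
* *Kidney phantom*: elliptical tissue, a cortical band holding 20
  non-overlapping glomeruli (60–120 µm), a few large elongated vessels, and
  a triangular annular enrichment (default 2× at 50–100 µm around
  glomeruli). Real phalloidin images have texture, partial-volume edges and
  segmentation ambiguity that the phantom does not reproduce, so passing
  tests demonstrate correctness of the measurement chain, not segmentation
  robustness on real stains.
* *Tumor stacks*: a lobed 3D shape sliced at 28 µm spacing; anatomy carries
  boundary and internal texture, activity a few 3D Gaussian hot-spots
  (sparse, as typical for antibody-delivered alpha emitters); non-reference
  sections receive known rigid perturbations (default ≤ 6°, ≤ 120 µm) and an
  optional smooth warp (40 µm amplitude in validation). Real sectioning
  artifacts (tears, folds) are out of scope.
* Test and validation problem sizes (96–256 px sections, 3-section stacks,
  20-stack comparisons, 10⁴–10⁵ kernel primaries) are chosen so the full
  suite runs interactively; all sizes scale up via the same APIs, and the
  CLI default for kernel generation is 10⁶ primaries.

## Known limitations

* No vendor binary list-mode parsing (the layout is unpublished); a CSV
  dialect (`x_um,y_um,t_s` + JSON schedule sidecar) stands in. Dropped-frame
  handling is represented only as session merging.
* The scalar sensitivity factor ignores spatially varying (flat-field)
  response; no optical PSF deconvolution.
* The three phantom corrections are implemented as one composed fit per
  phantom (scale from circles-type, free-form from squares/dots-type); how a
  vendor pipeline would merge three separate corrections is not specified
  anywhere and is left to the caller.
* The CSDA kernel is a documented surrogate for full radiation transport:
  adequate for water-equivalent soft tissue at >10 µm voxels, not for bone,
  interfaces, or sub-micron microdosimetry.
* Landmark selection is manual by design; no automatic landmark detection.
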