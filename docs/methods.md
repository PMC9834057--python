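# Methods

`svatlas` constructs surface–volume consistent spatiotemporal brain atlases
for early development, where rapidly changing tissue contrast (including the
T1w isointense phase around 3–6 months and the T2w phase around 9–12 months)
makes intensity-driven registration unreliable. Registration is therefore
driven by tissue probability maps and explicitly constrained by cortical
surface correspondences, so that the volumetric atlas's WM–GM and GM–CSF
interfaces coincide with the averaged cortical surfaces. This note documents
the model, the numerical choices, the synthetic data used for validation,
and the limits of what the desk-scale experiments demonstrate.

## Conventions

All grids are axis-aligned RAS lattices; the world coordinate of voxel `v`
is `origin + v * spacing` (mm). A displacement field `φ` lives on the fixed
grid in millimetres and induces the deformation `Φ(x) = x + φ(x)`.
Resampling uses the pull-back convention — the warped value at `x` is the
input sampled trilinearly at `x + φ(x)`, with zero extension outside the
domain — so point sets (surface vertices) transform with the *inverse* of a
volume-resampling field. Composition `compose(outer, inner)` realizes
`Φ_outer ∘ Φ_inner` (rightmost map applied first); inversion uses the
fixed-point iteration `ψ ← −φ(x + ψ)` (default tolerance 1e-3 mm, 50
iterations). No diffeomorphism is enforced; where an assembled field folds
far from the anatomy, a damped pseudo-inverse is used and its residual is
verified at the surface vertices that actually consume it (rejected above
half a voxel).

## Surface-constrained dynamic elasticity registration (SC-DEM)

The displacement between a moving and a fixed tissue map is evolved by a
damped wave equation in artificial time,

    ∂²φ/∂t² = α (∇²φ + ∇(∇·φ)) + β f_vol + γ f_surf,

integrated by damped leapfrog with Neumann (replicate) boundaries and
second-order central differences. The volumetric mismatch force is

    f_vol(x) = Σ_c [I_mov,c(x+φ) − I_ref,c(x)] · ∇I_mov,c(x+φ),

summed over the (WM, GM, CSF) probability channels, with gradients by
central differences on the warped map. As written this is the *ascent*
direction of the squared mismatch under the pull-back convention, so the
integrator applies it with a negative sign; the implementation of the force
itself is literal and oracle-tested at 1e-12.

The surface force encodes predetermined surface correspondences: at each
constraint point with target displacement Δψ, the residual Δψ − φ(point) is
splatted onto the grid with a Gaussian kernel (default width 2×max voxel
spacing), truncated at 3σ, and normalized by the splatted weight sum
*saturated at the single-vertex peak weight*. Full normalization would hold
the force at full strength throughout the truncation support, which in
practice drives unbounded drift of far voxels whenever a vertex residual
persists; the saturated form decays with the Gaussian at sparse support and
reduces to the weighted mean where vertices are dense. Constraint points
are anchored at the predicted fixed-frame correspondence locations with
displacements pointing back to the moving surface, so the converged
pull-back field resamples moving tissue onto the fixed surfaces.

Parameters (all exposed in the `[scdem]` config block): α = 0.15 (elastic
smoothness), β = 8 (volumetric force weight), γ = 1 (surface force weight),
damping 0.25 per step, 150 steps by default, halting early when the mean
combined force magnitude falls below `force_tol` (1e-4). These were
calibrated on phantoms: stiff settings (α ≈ 1 with weak forces) leave the
elastic term balancing the mismatch far from alignment, a visible shrinkage
bias. The integration step is chosen automatically as the smaller of half
the elastic stability limit `dt² α · 2Σ 1/h_i² < 1` and a force-stiffness
cap `0.7/√(β·max|∇I|²)`; either bound alone admits divergence. For
known-deformation recovery experiments a short continuation schedule is
used (registering 2-voxel- and 1-voxel-smoothed maps before the raw maps,
then a low-α polish), which widens attraction basins without any grid
pyramid.

Affine pre-alignment (9 dof: translation, rotation, anisotropic scale) is
initialized from foreground centroids and second moments of the summed
tissue probability and refined by Powell minimization of the channelwise
SSD on a stride-2 lattice. It replaces external tooling and is deterministic.

## Cortical surface processing

Inflation applies umbrella smoothing with the displacement normalized by
the local mean squared edge length — this normalization makes a round
sphere a fixed point of the flow, so irregular-valence vertices accrue no
spurious convexity — followed by a global rescaling restoring total area
(within 0.1%). Average convexity is the negated accumulated outward-normal
displacement (mm), with the area-weighted mean removed each step so the
attribute integrates to ~0: sulcal fundi end negative, gyral crowns
positive. Mean curvature uses the cotangent Laplace–Beltrami operator with
barycentric vertex areas, signed positive where the Laplacian points inward
(a unit sphere has H = +1). Cortical thickness is the distance between
index-corresponded white and pial vertices. The T1w/T2w ribbon ratio
averages the intensity ratio at 5 equally spaced depths along the
white→pial segment, excluding samples with |T2w| < 1e-6.

Spherical mapping projects the inflated surface radially and then relaxes
vertices tangentially to reduce the summed squared difference between
spherical edge lengths and the (scale-normalized) source edge lengths;
steps that would fold a spherical triangle are halved and, failing that,
reverted. Spherical registration is a deliberately minimal demons scheme:
per-vertex tangential steps along the fixed attribute gradient scaled by
the attribute difference, graph-Gaussian smoothing of the update field,
reprojection, fold rejection, and a monotone acceptance rule on the mean
squared attribute difference. Three coarse-to-fine levels are realized by
decreasing attribute-smoothing scales on the full mesh (convexity drives
the coarse levels, curvature joins at the finest), rather than by mesh
decimation, because input maps need not be nested icospheres. Precomputed
correspondences (e.g. from an external tool, or exact generator
correspondences) can be supplied instead.

## Reference atlas construction

Scans within ±1.5 months of the reference age (12 months) are selected; the
temporal kernel is Gaussian, `w(τ₁,τ₂) = exp(−(τ₁−τ₂)²/2σ²)/(σ√2π)` with
σ = 0.7 months. The reference scan is the one minimizing mean channelwise
SSD to all others after centroid alignment (ties to the smallest subject
id). Groupwise registration registers every scan to the reference map,
fuses the warped maps into a new reference, and repeats; each fused
reference is additionally *de-biased* by resampling with the inverse of the
mean total (affine + nonlinear) map, the affine factor inverted
analytically. Without de-biasing the atlas provably stays anchored at the
initial reference subject's shape.

The surface atlas is the temporally weighted average of registered vertex
coordinates on shared spherical indexing. Each subject's corrective
volumetric displacement is computed per voxel from the closest atlas-surface
triangle (point-to-triangle distance over the pooled white+pial surfaces of
both hemispheres, k-nearest-centroid candidates with a provably complete
fallback to exhaustive search): if the voxel is within δ = 6 mm of all
three vertices, the correction is the Gaussian-weighted (σ_g = 3 mm) mean
of the vertex residuals, else exactly zero. The total field is the vector
sum `φ + Δφ`. Tissue labels are fused by weighted majority voting over
per-subject argmax classes (background participates; ties resolve
WM > GM > CSF > background, preserving thin WM structures); intensities
and probabilities by the weighted mean.

## Longitudinal atlases

Intra-subject growth fields `φ_(τ′→τ)` (affine + SC-DEM) are transported to
atlas space by conjugation, `Φ∥ = Φ_A⁻¹ ∘ Φ_L ∘ Φ_A`, evaluated pointwise
with the affine factors applied analytically so the maps extend as pure
affines beyond the grid (zero-extension of a linearly growing combined
field corrupts the chain at the corners, and its fixed-point inversion
cannot converge there). Age-specific fields are kernel regressions of the
transported fields with weights `w(τ′,τ₀)·w(τ,12)`, pairs outside either
±1.5-month window excluded. The reference atlas is propagated by
resampling volumes with the regressed field and moving surface vertices
with its inverse, which keeps the white surface on the warped WM/GM
interface by construction. Month-specific T1w/T2w atlases pull each τ′
intensity image through `Φ_L ∘ Φ_A ∘ Φ∥` (rightmost first) and average.
Note the direction conventions here are fixed by the constant-translation
test case (volumes and surfaces must shift consistently); writing the same
chain with every factor typed as a point map in one consistent convention
is the only way all identity limits hold.

## Developmental trajectories

Population features are modeled as `f_i(t) = s(t) + γ_i` with `s` a
penalized cubic spline and `γ_i` a subject random intercept (GAMM); atlas
features drop the intercept (GAM). The spline is fitted through its
mixed-model representation: a cubic B-spline basis (k = 8 functions by
default) with second-difference penalty is split into unpenalized fixed
effects (intercept + linear trend) and an iid random-coefficient block, and
variances — hence the smoothing parameter — are REML estimates (statsmodels
MixedLM; degenerate noiseless data falls back to a near-unpenalized fit).
k = 8 rather than a smaller basis because logistic-shaped growth over
0.5–24 months is visibly biased at k = 6; mgcv's default (k = 10) is larger
still, and one test cross-checks the fitted curve against mgcv via Rscript.
Growth rates are percentage changes (first-year baseline 0.5 months, the
2-week atlas); velocities are central differences of the fitted curve on a
0.1-month grid with the peak age at the argmax (ties to the earliest age);
laterality uses LI = (L−R)/(L+R) with a one-sample two-tailed t-test at
α = 0.01; ROI summaries are vertex-area-weighted means.

## Synthetic cohort

Phantoms are star-shaped two-hemisphere "brains": the white surface is a
spherical-harmonic-folded ellipsoid (fixed ℓ = 3–5 pattern shared by all
subjects so folds correspond across the cohort), the pial surface a radial
offset of it, and WM/GM/CSF probabilities are rasterized exactly from the
same radius functions (1-voxel-σ smoothing as partial volume), so surfaces
and tissue interfaces agree by construction. Tissue volumes follow
four-parameter logistic curves shaped to give roughly +95% first-year and
+13% second-year whole-brain growth; the cortical thickness and white
radius are solved from the prescribed volumes at each age. T1w/T2w means
per tissue follow smooth contrast curves crossing zero at 4.5 and 10.5
months (the centres of the isointense windows); Gaussian noise sd defaults
to 3 intensity units. Per-subject variability is a seeded low-order
harmonic radial perturbation plus a small rigid+scale jitter (the scale
cubed multiplies all prescribed volumes and is recorded as ground truth).
Cohorts follow the staggered-enrolment design: first visits at 2 weeks
(encoded 0.5 months), 1, 2, 9, 10 and 11 months, then every 3 months to 12
months and once at 24 months. Everything is deterministic under the seed.

Default desk scale: 48³ voxels at 2 mm, icosphere subdivision 3 (642
vertices) per hemisphere surface. A separate *blob* phantom — random
smooth two-tissue texture inside a ball — serves the solver-recovery and
atlas-sharpness experiments: its dense, isotropically oriented interfaces
make a warping field fully observable. On brain-like phantoms, smooth
interfaces cannot constrain motion tangential to themselves (the aperture
problem; measured ~0.14 voxels normal vs ~0.93 voxels tangential residual),
so no tissue-driven method can pass a sub-half-voxel recovery bar there,
and the registered groupwise atlas cannot out-sharpen a majority vote.
These are statements about observability, not about the solver.

What the phantoms do not emulate: bias fields, motion artefacts, partial
volume beyond isotropic smoothing, topology differences between subjects,
or realistic fold variability. Passing tests therefore demonstrate the
correctness and internal consistency of the machinery at desk scale, not
performance on clinical data, and the printed growth percentages of real
cohorts are out of scope.

## Validation experiments and problem sizes

The experiments in `svatlas.experiments` (shared by the test suite and
`scripts/acceptance.py`) use: 48³ grids for recovery/sharpness/end-to-end
runs, 16³ grids with ~160-vertex surfaces for the corrective-displacement
and transport oracles, subdivision-4 icospheres (2562 vertices) for
geometry and spherical registration, 40 subjects × 6 visits for trajectory
recovery, and 12 subjects on the staggered schedule for the end-to-end
spatiotemporal run (reference atlas + propagation to months 1–24, scored
against the generator's prescribed GM curve and the white-to-interface
distance). Fitted-curve accuracy is assessed at the design's observed ages;
the 12.5–24-month observation gap is a property of the visit schedule, not
of the estimator. In the surface-constraint experiment the predetermined
surface displacements use the phantoms' exact shared-index correspondences,
isolating the force mechanism from spherical-registration accuracy (which
is scored separately); at 642 vertices the internal spherical registration
has a ~2 mm correspondence floor, comparable to the inter-subject anatomy
differences themselves.

## Known limitations

- Single-resolution solver (no grid pyramid); large deformations rely on
  the map-smoothing continuation and the affine pre-step.
- The demons-style spherical registration is a minimal stand-in: no
  velocity fields or spherical-harmonic regularization, and its accuracy
  floor scales with mesh resolution.
- Fixed-point inversion assumes a contractive field; assembled fields may
  fold far from the anatomy, where only a pseudo-inverse (with verified
  surface residuals) is available.
- Random intercepts only in the GAMM (no random slopes); REML variance
  estimation can sit at boundary values for degenerate inputs.
- Oblique acquisition grids, DICOM, and real-cohort reproduction are out
  of scope.
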