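# Methods

`liverdir` evaluates how accurately intensity-based deformable image
registration (DIR) recovers respiratory motion of the liver and a liver
tumor in a 4DCT series, using implanted fiducial markers as the gold
standard. Because patient 4DCT cannot be redistributed, the package
ships a synthetic breathing phantom with analytically known motion;
every downstream quantity (marker positions, displacement fields, organ
masks, volumes) therefore has an exact reference value.

## The breathing phantom

A 4DCT series is emulated as `n_phases` (default 10) snapshots of one
breathing cycle. The reference configuration is the 50% phase
(end-expiration); every other phase is produced by the analytic
diffeomorphism

    T_t(x) = x + a(t) · (A ⊙ w(x)),      a(t) = (1 + cos 2πt)/2,

with `A` the peak displacement vector in mm (default (1.5, 2.0, 7.6) for
(LR, AP, SI) — SI-dominant, ‖A‖ ≈ 8 mm, matching the motion range of
liver SBRT patients) and `w` a separable Tukey (tapered-cosine) window:
1 on a central plateau covering tumor and markers, rolling smoothly to 0
at the volume boundary. `a` is 1 at 0% (peak inhale) and exactly 0 at
50%, so the reference phase carries zero displacement and marker
trajectories are periodic. The taper fraction (default 0.3 per axis)
bounds the displacement gradient well below 1, which guarantees
invertibility; each generated field is additionally audited numerically
(min Jacobian determinant > 0) and the generator rejects amplitudes that
fail, naming the offending phase.

The anatomy is a liver-like ellipsoid (80 HU) in a −100 HU background,
a tumor sphere (40 HU) and three spherical fiducial blobs (1200 HU,
radius 1.5 mm) inside the liver, on a 96×96×80 grid at 1×1×2 mm — the
in-plane/slice anisotropy of clinical 4DCT at desk scale. Two features
matter for registrability:

* **Intra-liver texture.** A Gaussian-correlated random intensity field
  (σ = 25 HU, 5 mm correlation length) is blended into the liver and
  fixed in material coordinates, i.e. advected with the motion, like the
  vessel/parenchyma contrast of a contrast-enhanced CT. Without it the
  liver interior is homogeneous and its motion is *unobservable in
  principle* to any intensity-driven method (the aperture problem): a
  registration can reach near-perfect image similarity while recovering
  under a third of the true interior displacement. A textureless phantom
  would therefore test nothing that transfers to patient data.
* **Exact marker ground truth.** Phase images are rendered by resampling
  the reference tissue through the numerically inverted analytic map
  (fixed-point iteration; linear interpolation), but the marker blobs
  are re-stamped sharply at the analytically advected centers with
  sub-voxel partial-volume coverage (4³ sub-sampling per voxel). Marker
  truth is thus exact rather than interpolation-limited, and thresholded
  centroids track the true centers to ≲ 0.35 mm.

Per-phase scanner noise is additive Gaussian (default σ = 10 HU),
independent between phases, from a seeded generator. True organ volumes
are computed as ∫ det ∇T over the reference shape with anti-aliased
coverage weights — the exact volume of the warped shape, immune to the
~1% voxel-count jitter of binary masks — so the true GTV volume is
constant across phases whenever the tumor sits on the envelope plateau.

What the phantom does **not** emulate: hysteresis and cycle-to-cycle
breathing irregularity, 4D reconstruction/binning artifacts, CT physics
(beam hardening, streaks around metal), sliding interfaces (liver vs.
chest wall), and marker-shape irregularity. Consequences of the last
point are discussed under *Limitations*.

## Marker localization

Fiducials are segmented by a strict > 500 HU threshold, 26-connected
components, discarding components under 3 voxels (noise spikes). The
measured position is the unweighted centroid of each component's voxel
centers in world mm. Identities across phases are assigned by
minimum-total-distance (Hungarian) matching against the reference
phase — exact for three markers and safe because inter-marker distances
(≈ 10–60 mm) far exceed breathing displacements (≤ 13 mm). The markers'
center of mass (COM) is the arithmetic mean of the three centroids; its
RMS error never exceeds the worst single marker's, which is why it is
the preferred tumor surrogate.

## Pairwise registration

`register_pair` is a greedy, multiresolution discretization of
symmetric diffeomorphic normalization:

* **Similarity**: windowed squared normalized cross-correlation,
  `CC(x) = ⟨ā,b̄⟩²/(⟨ā,ā⟩⟨b̄,b̄⟩)` over a (2r+1)³ window (r = 3 voxels),
  computed with box-filter sums; partial windows at the image border use
  in-bounds counts. Locally constant patches (variance below a
  scale-aware floor) contribute 0 to both metric and gradient. CC is
  invariant to affine intensity rescaling of either image — verified to
  4·10⁻¹⁰ voxels on the resulting fields.
* **Symmetry**: two half-fields (mid-space → A, mid-space → B) receive
  opposite half-updates each iteration and are composed (not added), so
  forward and inverse maps come out of one optimization; the reported
  inverse-consistency residual is max ‖φ_BA∘φ_AB − id‖ (typically
  0.4–0.7 mm ≈ ⅓ voxel on phantoms).
* **Update rule**: per-voxel step along the unit CC-gradient direction,
  scaled by the local misalignment (1 − CC), by a saturation
  `‖g‖/(‖g‖+s)` with `s` the 75th percentile of gradient magnitudes at
  the level, and by the step cap (0.4 voxel). The per-voxel
  normalization is essential: the marker and organ-boundary gradients
  are ~100× the parenchyma-texture gradients, so a globally normalized
  step freezes the liver interior; the saturation in turn stops static
  image noise from deforming featureless regions at full speed.
* **Regularization**: each update is smoothed with σ = 1.0 voxel
  (fluid-like), the running half-fields with σ = 0.5 voxel (elastic).
  Sigmas are in voxels of the current pyramid level so the invertibility
  bound max‖∇step‖ ≈ cap/σ_update < 1 holds uniformly across levels;
  expressing them in mm violated that bound at coarse levels and folded
  the field (min Jacobian < 0).
* **Greedy accept/reject**: an update that worsens the metric is rolled
  back and retried at half step; after four consecutive rejections the
  level terminates (plateau). The accepted metric trace is therefore
  monotone by construction.
* **Pyramid**: shrink factors 4/2/1 with 4/2/0 mm pre-smoothing,
  iteration caps 200/150/80, convergence when the relative metric drop
  over 10 iterations falls below 10⁻⁵.
* **Audits**: Jacobian positivity of both output maps at interior voxels
  (violation raises an error naming the level) and the
  inverse-consistency residual.

Out-of-bounds behavior: clamp-to-edge for displacement-field lookups;
image samples outside the volume take a per-level, per-image background
(the median border intensity — a plain minimum picks noise outliers
whose artificial edges dominate the capped updates, and a value pooled
across both images breaks CC's affine invariance).

On the default phantom (96×96×80, ‖A‖ ≈ 8 mm), registering the 50%↔0%
pair recovers the true marker mapping to a mean error of ~0.8 mm (min
Jacobian ≈ 0.3), in the sub-slice-thickness regime expected of liver
4DCT DIR. One pair takes ~2–3 minutes on one CPU core.

## Strategies, propagation, metrics

*Reference* registers every phase directly to the 50% phase.
*Sequential* registers cyclically adjacent phases (wrap-around 90%→0%
by default; a flag disables it) and composes transforms along the
shortest cyclic path, ties broken toward increasing phase index; the
composition count per phase is reported as the drift diagnostic.
Pairwise results are cached by (pair, parameter hash) in memory and
optionally on disk, so the two strategies share adjacent-pair fields —
which is also mathematically faithful: at a phase adjacent to the
reference the two strategies *are* the same registration problem.

The mid-ventilation phase is the one whose markers-COM lies nearest the
time-averaged markers-COM (ties to the lower index). Liver and GTV
masks are pulled from mid-ventilation onto each phase through the
composed target→mid point map (linear interpolation, 0.5 threshold) and
summarized by COM, volume (voxel count × voxel volume, cm³) and the
coefficient of variation 100·sd/mean with the sample (n−1) standard
deviation.

The registration error is `r_error = ‖x_{f,j} − φ_j(x_{f,ref})‖` with
measured centroids on both sides and φ_j the reference→phase-j point
map of the strategy under test; transforming marker points through the
composed field and hopping them link-by-link agree to machine precision.
The relative distance variation `d = ‖x₂,j − x₁,j‖ − ‖x₂,ref − x₁,ref‖`
is evaluated for marker–marker, GTV COM–marker, GTV COM–markers-COM and
GTV COM–liver-COM pairs. Distributions are compared with the two-sample
Kolmogorov–Smirnov test (asymptotic p, two-sided), both pooled across
phases/markers (headline) and per phase. Report cells round half away
from zero at one decimal.

The marker-inpainting control deletes all > 500 HU voxels plus a 2 mm
physical-radius halo and refills them in fast-marching order: the
anisotropic Eikonal distance from the mask boundary is solved with
first-order upwind updates, and each voxel becomes a normalized
weighted average of already-known neighbours within 3 mm, with
direction/distance/level-set weights (ε = 10⁻⁶ guards). Being a convex
combination, the fill stays within the range of the boundary values;
outside the mask the volume is bit-identical. The registration is then
repeated (reference strategy) on the inpainted images with the original
measured markers still serving as ground truth.

## What passing tests show — and what they do not

Phantom results demonstrate that the implementation recovers known
smooth, periodic, SI-dominant motion to sub-slice accuracy under
realistic contrast and noise, that sequential composition adds less
than a voxel diagonal of drift, and that inpainting leaves everything
outside its mask untouched. They do not certify accuracy on patient
data with sliding interfaces, irregular breathing, binning artifacts or
non-smooth deformation.

Two statistical checks deserve explicit caution. With exact, rigidly
co-moving markers the three per-phase errors are nearly identical
(within-phase sd ≈ 0.05–0.15 mm), so pooled KS comparisons between
strategies operate on n = 15 samples with ~0.2 mm scatter and declare
*any* consistent shift above ~0.3 mm — far below voxel size —
statistically significant. The phantom studies indeed yield p ≈ 0.003
for reference-vs-sequential (composition adds ~0.33 mm per hop) and for
original-vs-inpainted (texture-only driving is ~0.6 mm worse at the
largest displacements), even though all three arms stay well inside the
sub-2 mm accuracy regime. Statistical indistinguishability of this kind
is only observed when measurement scatter (irregular marker rendering,
reconstruction artifacts, patient heterogeneity) dominates systematic
algorithmic differences; a noise-free gold standard makes the KS test
*more* severe, not less. The package reports the honest p-values.

## Numerical choices

* Axis order (x=LR, y=AP, z=SI), 0-based voxel indices,
  `world = origin + index ⊙ spacing`, axis-aligned grids only.
* Field inversion by fixed-point iteration `v ← −u(x+v)` to 0.01 mm
  (≤ 50 iterations), valid for the positive-Jacobian fields produced
  here; Jacobians by central differences in mm.
* Mask warping: linear interpolation then 0.5 threshold; the volume bias
  this convention introduces is tested against ground truth (< 5%).
* NIfTI I/O through nibabel with diagonal affines; displacement fields
  as 4D NIfTI plus a JSON sidecar with direction tags.
* Reduced problem sizes for multi-phase studies: the strategy and
  inpainting studies run on a 6-phase 64×64×48 phantom with iteration
  caps 150/100/60, the package's standard reduced configuration; the
  single-pair accuracy check runs at the full default size.

## Limitations

* The per-registration error floor (~0.3 mm on phantoms) is set by the
  noise-vs-texture equilibrium, and accumulates linearly along composed
  sequential chains.
* The reduced study's tumor (0.9 cm³, ~65 voxels at 2 mm slices) is
  smaller than typical liver GTVs, so its voxel-count volume metrics are
  quantization-dominated: composed-field noise erodes the small convex
  mask through the interpolate-then-threshold convention by up to ~8%
  at the most-composed phase, and the propagated GTV CV (3.0%) mostly
  measures that discretization, not tissue compressibility. The
  convention itself preserves grid-resolved structures (the liver) to
  well under 5% under exact motion fields.
* Fiducial blobs are rendered identically in every phase; real markers
  produce phase-varying streaks, which adds measured-centroid scatter
  the phantom lacks (see the KS discussion above).
* Total-field smoothing below ~0.5 voxel destabilizes the diffeomorphism
  audit on noisy phantoms; accuracy gains from weaker regularization are
  deliberately not pursued.
* The CLI loads phantom-generated NIfTI series; arbitrary clinical DICOM
  series are out of scope (convert to NIfTI first).
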