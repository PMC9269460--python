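# liverdir

Evaluation of intensity-based deformable image registration (DIR) for
respiratory tumor motion in liver 4DCT.

In liver stereotactic body radiotherapy, the tumor is usually invisible
on non-contrast CT, so implanted gold fiducial markers serve as its
surrogate. Respiratory-correlated 4DCT captures the breathing cycle in
ten phase bins, and DIR between phases promises automatic tumor and
organ tracking — *if* its accuracy can be trusted. `liverdir`
quantifies that accuracy the way a fiducial-validation study does: the
measured marker centroid in phase *j* is compared with the
reference-phase marker carried into phase *j* by the registration
point map φ_j,

    r_error = ‖ x_{f,j} − φ_j ∘ x_{f,ref} ‖ ,

together with relative-distance variations
`d = ‖x₂,j − x₁,j‖ − ‖x₂,ref − x₁,ref‖` between markers, tumor COM and
liver COM, Kolmogorov–Smirnov comparisons between registration
strategies, and DIR-based contour propagation with per-phase volumes
and their coefficient of variation (CV).

The package provides:

* a **synthetic breathing phantom** (`liverdir.phantom`) — liver,
  tumor, three >500 HU fiducials, SI-dominant cyclic motion with an
  analytically invertible displacement field, textured parenchyma,
  seeded noise, and exact ground truth for every marker, field, mask
  and volume;
* **marker localization** (`liverdir.markers`) — 500 HU threshold,
  connected components, sub-voxel centroids, Hungarian identity
  tracking, markers' center of mass;
* **symmetric diffeomorphic registration** (`liverdir.registration`) —
  multiresolution greedy optimization of a local cross-correlation
  metric with fluid/elastic regularization, returning forward and
  inverse point maps with Jacobian and inverse-consistency audits;
* **field algebra** (`liverdir.fields`) — warping, point transforms,
  composition, fixed-point inversion, Jacobian determinants;
* **strategies** (`liverdir.strategies`) — all-phases-to-reference vs
  sequential adjacent registration with minimal-composition cyclic
  paths and caching;
* **marker inpainting** (`liverdir.inpaint`) — fast-marching (Telea
  style) removal of the high-intensity marker artifacts, for the
  control experiment showing registration is tissue-driven;
* **contour propagation and metrics** (`liverdir.propagation`,
  `liverdir.metrics`, `liverdir.pipeline`) — mid-ventilation selection,
  label warping, COM/volume/CV tables, KS tests, and an end-to-end
  pipeline with CSV/JSON reports, plus a `liverdir` CLI
  (`simulate`, `register`, `inpaint`, `evaluate`, `report`).

## Worked example

```python
import numpy as np
from liverdir import (PhantomSpec, generate_series, register_pair,
                      transform_points, RegistrationParams)

spec = PhantomSpec(seed=1)              # 96×96×80 @ 1×1×2 mm, 10 phases
series, truth = generate_series(spec)   # phases + exact ground truth

ref = series.reference_index            # 50% phase (end-expiration)
res = register_pair(series.volumes[ref], series.volumes[0],
                    RegistrationParams(), tag_a=ref, tag_b=0)

est = transform_points(truth.marker_trajectories_mm[ref], res.phi_ab)
err = np.linalg.norm(est - truth.marker_trajectories_mm[0], axis=1)
print(f"true displacement : {np.linalg.norm(truth.marker_trajectories_mm[0] - truth.marker_trajectories_mm[ref], axis=1).mean():.1f} mm")
print(f"mean marker error : {err.mean():.2f} mm")
print(f"min Jacobian      : {res.min_jacobian_ab:.2f}")
print(f"inverse consistency: {res.inverse_consistency_mm:.2f} mm")
```

Output (one CPU core, a few minutes):

```
true displacement : 8.0 mm
mean marker error : 0.82 mm
min Jacobian      : 0.30
inverse consistency: 0.63 mm
```

The markers moved 8 mm peak-to-peak (SI-dominant breathing); after
registration the predicted marker positions land within ~0.8 mm of the
measured ones — well inside the 2 mm slice thickness, the accuracy
regime required for radiotherapy use. A positive minimum Jacobian
certifies the map is a diffeomorphism.

The full study — both strategies, the inpainted control arm, contour
propagation and KS comparisons — runs from the command line:

```bash
liverdir evaluate --seed 1 --out results/
liverdir report --results results/
```

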