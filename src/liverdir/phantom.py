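"""Synthetic 4DCT breathing phantom with analytically known motion.

The phantom emulates a respiratory-correlated CT of the upper abdomen:
a low-contrast liver-like ellipsoid, an embedded tumor sphere, and three
implanted radio-opaque fiducial blobs (>500 HU), sampled over one
breathing cycle in ``n_phases`` phase bins.  Motion is a separable,
analytically invertible displacement

    u(x, t) = a(t) * (A ⊙ w(x)),   a(t) = (1 + cos 2πt) / 2,

where ``A`` is the peak amplitude vector (mm, SI-dominant by default)
and ``w`` a smooth raised-cosine (Tukey) spatial envelope that equals 1
on a central plateau and falls to 0 at the volume boundary.  The 50%
phase (t = 0.5) carries zero displacement and serves as the reference
configuration; 0% (t = 0) is peak inhale.

Because the map is analytic, every downstream consumer gets exact
ground truth: per-phase displacement fields, marker trajectories, organ
masks and volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .fields import jacobian_determinant
from .grid import DisplacementField, ImageVolume, index_grid_mm, sample_at_points, save_volume


class PhantomError(ValueError):
    pass


@dataclass
class PhantomSpec:
    """Parameters of the synthetic breathing phantom (world mm, HU)."""

    grid_shape: tuple[int, int, int] = (96, 96, 80)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 2.0)  # LR, AP, SI
    liver_center_mm: tuple[float, float, float] = (48.0, 48.0, 80.0)
    liver_axes_mm: tuple[float, float, float] = (36.0, 32.0, 54.0)
    liver_hu: float = 80.0
    tumor_center_mm: tuple[float, float, float] = (52.0, 48.0, 88.0)
    tumor_radius_mm: float = 8.0
    tumor_hu: float = 40.0
    marker_positions_mm: tuple[tuple[float, float, float], ...] = (
        (44.0, 42.0, 80.0),
        (60.0, 54.0, 84.0),
        (50.0, 56.0, 100.0),
    )
    marker_hu: float = 1200.0
    marker_radius_mm: float = 1.5
    background_hu: float = -100.0
    # intra-liver parenchyma/vessel texture: a smooth random intensity
    # field fixed in material coordinates (advected with the motion), as
    # in contrast-enhanced CT; without it interior motion would be
    # unobservable to any intensity-based registration
    texture_sigma_hu: float = 25.0
    texture_corr_mm: float = 5.0
    amplitude_mm: tuple[float, float, float] = (1.5, 2.0, 7.6)  # (LR, AP, SI)
    n_phases: int = 10
    noise_sigma_hu: float = 10.0
    envelope_taper: float = 0.3  # per-axis taper fraction of the Tukey window
    enforce_si_dominant: bool = True
    seed: int = 0

    # -- derived geometry ------------------------------------------------
    @property
    def spacing(self) -> np.ndarray:
        return np.asarray(self.spacing_mm, dtype=float)

    @property
    def origin(self) -> np.ndarray:
        return np.zeros(3)

    @property
    def amplitude(self) -> np.ndarray:
        return np.asarray(self.amplitude_mm, dtype=float)

    @property
    def phase_fractions(self) -> np.ndarray:
        return np.arange(self.n_phases) / self.n_phases

    @property
    def reference_index(self) -> int:
        """Index of the phase nearest t = 0.5 (end-expiration)."""
        return int(np.argmin(np.abs(self.phase_fractions - 0.5)))

    def phase_percent(self, k: int) -> int:
        return int(round(100.0 * k / self.n_phases))

    def validate(self) -> None:
        if self.n_phases < 2:
            raise PhantomError(f"n_phases must be >= 2, got {self.n_phases}")
        if self.marker_hu <= 500:
            raise PhantomError(
                f"marker HU must exceed the 500 HU detection threshold, got {self.marker_hu}"
            )
        c = np.asarray(self.liver_center_mm)
        ax = np.asarray(self.liver_axes_mm)
        for i, m in enumerate(self.marker_positions_mm):
            r2 = np.sum(((np.asarray(m) - c) / ax) ** 2)
            if r2 >= 1.0:
                raise PhantomError(
                    f"marker {i} at {m} mm lies outside the liver ellipsoid "
                    f"(normalized radius {np.sqrt(r2):.2f})"
                )
        a = self.amplitude
        if self.enforce_si_dominant and (a[2] < a[0] or a[2] < a[1]):
            raise PhantomError(
                f"SI amplitude {a[2]} mm must dominate LR/AP {a[:2]} "
                "(set enforce_si_dominant=False to override)"
            )

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        kwargs = {}
        for k, v in d.items():
            if isinstance(v, list):
                v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
            kwargs[k] = v
        return cls(**kwargs)

    def save_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def reduced_spec(**overrides) -> PhantomSpec:
    """A reduced breathing phantom (6 phases, 64×64×48 voxels) with the
    default motion amplitudes, sized for multi-phase strategy studies."""
    kwargs = dict(
        grid_shape=(64, 64, 48),
        spacing_mm=(1.0, 1.0, 2.0),
        liver_center_mm=(32.0, 32.0, 48.0),
        liver_axes_mm=(24.0, 22.0, 34.0),
        tumor_center_mm=(34.0, 32.0, 50.0),
        tumor_radius_mm=6.0,
        marker_positions_mm=(
            (28.0, 28.0, 44.0),
            (38.0, 36.0, 48.0),
            (33.0, 37.0, 56.0),
        ),
        n_phases=6,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@dataclass
class Series4D:
    """Ordered phase volumes of one breathing cycle."""

    volumes: list[ImageVolume]
    phase_fractions: np.ndarray
    reference_index: int

    @property
    def n_phases(self) -> int:
        return len(self.volumes)

    def phase_percent(self, k: int) -> int:
        return int(round(100.0 * self.phase_fractions[k]))


@dataclass
class GroundTruth4D:
    """Exact per-phase truth exported by the generator.

    ``fields_ref_to_phase[p]`` is the analytic point map from reference
    phase coordinates to phase-p coordinates, sampled on the reference
    grid (the map at the reference phase itself is identity).
    """

    fields_ref_to_phase: list[DisplacementField]
    marker_trajectories_mm: np.ndarray  # (n_phases, n_markers, 3)
    liver_masks: list[np.ndarray]
    gtv_masks: list[np.ndarray]
    liver_volumes_cm3: np.ndarray
    gtv_volumes_cm3: np.ndarray
    min_jacobian: np.ndarray  # per phase

    @property
    def n_phases(self) -> int:
        return len(self.fields_ref_to_phase)


# ---------------------------------------------------------------------------
# Motion model
# ---------------------------------------------------------------------------


def temporal_amplitude(t) -> np.ndarray:
    """Cyclic breathing amplitude a(t) = (1 + cos 2πt)/2; 1 at inhale (t=0),
    0 at exhale (t=0.5)."""
    return 0.5 * (1.0 + np.cos(2.0 * np.pi * np.asarray(t, dtype=float)))


def spatial_envelope(spec: PhantomSpec, points_mm: np.ndarray) -> np.ndarray:
    """Separable Tukey (tapered-cosine) envelope in [0, 1].

    Equals 1 on the central plateau, rolls off as a raised cosine over
    the outer ``envelope_taper`` fraction of each axis, and is exactly 0
    at (and beyond) the boundary voxel centers.
    """
    pts = np.asarray(points_mm, dtype=float)
    extent = (np.asarray(spec.grid_shape) - 1) * spec.spacing
    s = (pts - spec.origin) / extent
    alpha = spec.envelope_taper
    w = np.ones(pts.shape[:-1])
    for ax in range(3):
        sa = np.clip(s[..., ax], 0.0, 1.0)
        edge = np.minimum(sa, 1.0 - sa)  # distance to nearer boundary, in [0, 0.5]
        ramp = np.where(
            edge >= alpha, 1.0, 0.5 * (1.0 - np.cos(np.pi * edge / alpha))
        )
        w = w * ramp
    return w


def breathing_displacement(spec: PhantomSpec, t: float, points_mm: np.ndarray) -> np.ndarray:
    """Analytic displacement u(x, t) in mm for points in reference coordinates."""
    w = spatial_envelope(spec, points_mm)
    return temporal_amplitude(t) * w[..., None] * spec.amplitude


def inverse_breathing_displacement(
    spec: PhantomSpec, t: float, points_mm: np.ndarray, n_iter: int = 25
) -> np.ndarray:
    """Fixed-point inverse of the analytic map: v with y + v(y) = T_t^{-1}(y).

    Converges because the displacement gradient is bounded below 1 for
    any amplitude that passes the Jacobian positivity check.
    """
    pts = np.asarray(points_mm, dtype=float)
    v = np.zeros_like(pts)
    for _ in range(n_iter):
        v = -breathing_displacement(spec, t, pts + v)
    return v


# ---------------------------------------------------------------------------
# Anatomy rendering
# ---------------------------------------------------------------------------


def _liver_mask_at(spec: PhantomSpec, points_mm: np.ndarray) -> np.ndarray:
    c = np.asarray(spec.liver_center_mm)
    ax = np.asarray(spec.liver_axes_mm)
    return np.sum(((points_mm - c) / ax) ** 2, axis=-1) <= 1.0


def _gtv_mask_at(spec: PhantomSpec, points_mm: np.ndarray) -> np.ndarray:
    c = np.asarray(spec.tumor_center_mm)
    return np.sum((points_mm - c) ** 2, axis=-1) <= spec.tumor_radius_mm**2


def _soft_coverage_sphere(spec: PhantomSpec, points_mm: np.ndarray) -> np.ndarray:
    """Per-voxel coverage fraction of the tumor sphere via a linear ramp
    of the signed distance over one voxel width (anti-aliased volume
    estimate, free of the voxel-count quantization of binary masks)."""
    c = np.asarray(spec.tumor_center_mm)
    d = np.linalg.norm(points_mm - c, axis=-1) - spec.tumor_radius_mm
    h = float(np.mean(spec.spacing))
    return np.clip(0.5 - d / h, 0.0, 1.0)


def _soft_coverage_ellipsoid(spec: PhantomSpec, points_mm: np.ndarray) -> np.ndarray:
    c = np.asarray(spec.liver_center_mm)
    ax = np.asarray(spec.liver_axes_mm)
    q = (points_mm - c) / ax
    f = np.linalg.norm(q, axis=-1)
    grad = np.linalg.norm(q / ax, axis=-1) / np.maximum(f, 1e-9)
    d = (f - 1.0) / np.maximum(grad, 1e-9)  # first-order signed distance
    h = float(np.mean(spec.spacing))
    return np.clip(0.5 - d / h, 0.0, 1.0)


def _add_liver_texture(
    data: np.ndarray, liver_mask: np.ndarray, spec: PhantomSpec, rng
) -> None:
    """Blend a smooth random texture into the liver (material-fixed)."""
    if spec.texture_sigma_hu <= 0:
        return
    tex = ndimage.gaussian_filter(
        rng.standard_normal(spec.grid_shape), sigma=spec.texture_corr_mm / spec.spacing
    )
    tex /= max(float(tex.std()), 1e-12)
    data[liver_mask] += spec.texture_sigma_hu * tex[liver_mask]


def _stamp_markers(
    data: np.ndarray, spec: PhantomSpec, centers_mm: np.ndarray, subsamples: int = 4
) -> None:
    """Blend spherical marker blobs into ``data`` with sub-voxel coverage.

    Coverage is estimated by regular sub-sampling of each candidate
    voxel, so the >500 HU footprint (and hence the detected centroid)
    tracks the analytic center at sub-voxel precision.
    """
    spacing = spec.spacing
    r = spec.marker_radius_mm
    # sub-voxel offsets (cell centers of an s^3 subdivision)
    off1d = [(np.arange(subsamples) + 0.5) / subsamples - 0.5 for _ in range(3)]
    ox, oy, oz = np.meshgrid(*off1d, indexing="ij")
    sub = np.stack([ox, oy, oz], axis=-1).reshape(-1, 3) * spacing
    halo = np.ceil((r + 0.5 * spacing.max()) / spacing).astype(int)
    for c in np.atleast_2d(centers_mm):
        ci = np.round((c - spec.origin) / spacing).astype(int)
        lo = np.maximum(ci - halo, 0)
        hi = np.minimum(ci + halo + 1, np.asarray(spec.grid_shape))
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        pts = index_grid_mm(
            tuple(h - l for l, h in zip(lo, hi)), spacing, spec.origin + lo * spacing
        )
        d2 = np.sum((pts[..., None, :] + sub - c) ** 2, axis=-1)
        cov = np.mean(d2 <= r * r, axis=-1)
        data[sl] = (1.0 - cov) * data[sl] + cov * spec.marker_hu


def build_anatomy(
    spec: PhantomSpec, noise: bool = True
) -> tuple[ImageVolume, np.ndarray, np.ndarray, np.ndarray]:
    """Render the reference-phase anatomy.

    Returns (volume, liver mask, GTV mask, marker centers mm).  The
    volume is background/liver/tumor HU with markers stamped on top and,
    if requested, additive Gaussian noise (seeded).
    """
    spec.validate()
    pts = index_grid_mm(spec.grid_shape, spec.spacing, spec.origin)
    liver = _liver_mask_at(spec, pts)
    gtv = _gtv_mask_at(spec, pts)
    data = np.full(spec.grid_shape, spec.background_hu, dtype=float)
    data[liver] = spec.liver_hu
    data[gtv] = spec.tumor_hu
    rng = np.random.default_rng(spec.seed)
    _add_liver_texture(data, liver, spec, rng)
    markers = np.asarray(spec.marker_positions_mm, dtype=float)
    _stamp_markers(data, spec, markers)
    if noise and spec.noise_sigma_hu > 0:
        data = data + rng.normal(0.0, spec.noise_sigma_hu, size=data.shape)
    vol = ImageVolume(data, spec.spacing, spec.origin)
    return vol, liver, gtv, markers


# ---------------------------------------------------------------------------
# Series generation
# ---------------------------------------------------------------------------


def generate_series(spec: PhantomSpec) -> tuple[Series4D, GroundTruth4D]:
    """Generate the phase volumes and the exact ground truth.

    Tissue is rendered by resampling the reference anatomy through the
    inverse analytic map (linear interpolation); marker blobs are then
    re-stamped sharply at the analytically advected centers so marker
    ground truth is exact rather than interpolation-limited.  Each
    phase receives an independent, seeded noise realization.
    """
    spec.validate()
    pts = index_grid_mm(spec.grid_shape, spec.spacing, spec.origin)
    # noise-free reference tissue (no markers: they are stamped per phase)
    liver_ref = _liver_mask_at(spec, pts)
    gtv_ref = _gtv_mask_at(spec, pts)
    tissue = np.full(spec.grid_shape, spec.background_hu, dtype=float)
    tissue[liver_ref] = spec.liver_hu
    tissue[gtv_ref] = spec.tumor_hu
    rng = np.random.default_rng(spec.seed)
    _add_liver_texture(tissue, liver_ref, spec, rng)
    tissue_vol = ImageVolume(tissue, spec.spacing, spec.origin)

    markers_ref = np.asarray(spec.marker_positions_mm, dtype=float)
    voxel_cm3 = float(np.prod(spec.spacing)) / 1000.0
    cov_liver_ref = _soft_coverage_ellipsoid(spec, pts)
    cov_gtv_ref = _soft_coverage_sphere(spec, pts)

    volumes: list[ImageVolume] = []
    fields: list[DisplacementField] = []
    traj = np.empty((spec.n_phases, len(markers_ref), 3))
    liver_masks, gtv_masks = [], []
    liver_vol = np.empty(spec.n_phases)
    gtv_vol = np.empty(spec.n_phases)
    min_jac = np.empty(spec.n_phases)

    for k, t in enumerate(spec.phase_fractions):
        u = breathing_displacement(spec, t, pts)
        fld = DisplacementField(
            u, spec.spacing, spec.origin,
            from_phase=spec.reference_index, to_phase=k,
        )
        jac = jacobian_determinant(fld)
        min_jac[k] = float(jac.min())
        if min_jac[k] <= 0.0:
            raise PhantomError(
                f"amplitude {spec.amplitude_mm} mm makes the true map of phase "
                f"{k} ({spec.phase_percent(k)}%) non-invertible "
                f"(min Jacobian determinant {min_jac[k]:.3f} <= 0)"
            )
        fields.append(fld)

        v = inverse_breathing_displacement(spec, t, pts)
        data = sample_at_points(
            tissue_vol, pts + v, order=1, background=spec.background_hu
        )
        centers = markers_ref + breathing_displacement(spec, t, markers_ref)
        traj[k] = centers
        _stamp_markers(data, spec, centers)
        if spec.noise_sigma_hu > 0:
            data = data + rng.normal(0.0, spec.noise_sigma_hu, size=data.shape)
        volumes.append(ImageVolume(data, spec.spacing, spec.origin))

        lm = _liver_mask_at(spec, pts + v)
        gm = _gtv_mask_at(spec, pts + v)
        liver_masks.append(lm)
        gtv_masks.append(gm)
        # exact warped-shape volumes: vol(T(Ω)) = ∫_Ω det ∇T dx, with the
        # reference shape integrated by anti-aliased coverage (the same
        # quadrature every phase, so no voxelization jitter across phases)
        liver_vol[k] = float((cov_liver_ref * jac).sum()) * voxel_cm3
        gtv_vol[k] = float((cov_gtv_ref * jac).sum()) * voxel_cm3

    series = Series4D(volumes, spec.phase_fractions, spec.reference_index)
    truth = GroundTruth4D(
        fields, traj, liver_masks, gtv_masks, liver_vol, gtv_vol, min_jac
    )
    return series, truth


def true_marker_map(
    spec: PhantomSpec, ref_positions_mm: np.ndarray, phase_fraction: float
) -> np.ndarray:
    """Exact positions at a phase of markers given in reference coordinates."""
    p = np.asarray(ref_positions_mm, dtype=float)
    return p + breathing_displacement(spec, phase_fraction, p)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def write_series(
    spec: PhantomSpec, series: Series4D, truth: GroundTruth4D, out_dir
) -> Path:
    """Write phase volumes, true masks, marker trajectories and volumes.

    Phases are named by their percent label (phase_00 ... phase_90 for a
    10-phase series).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec.save_yaml(out / "phantom_spec.yaml")
    rows = []
    for k, vol in enumerate(series.volumes):
        pct = series.phase_percent(k)
        save_volume(vol, out / f"phase_{pct:02d}.nii.gz")
        save_volume(
            ImageVolume(truth.liver_masks[k].astype(float), vol.spacing, vol.origin),
            out / f"liver_mask_{pct:02d}.nii.gz",
        )
        save_volume(
            ImageVolume(truth.gtv_masks[k].astype(float), vol.spacing, vol.origin),
            out / f"gtv_mask_{pct:02d}.nii.gz",
        )
        for m, pos in enumerate(truth.marker_trajectories_mm[k]):
            rows.append(
                {
                    "phase_index": k,
                    "phase_percent": pct,
                    "marker_id": m,
                    "x_mm": pos[0],
                    "y_mm": pos[1],
                    "z_mm": pos[2],
                }
            )
    pd.DataFrame(rows).to_csv(out / "true_markers.csv", index=False)
    pd.DataFrame(
        {
            "phase_index": np.arange(series.n_phases),
            "phase_percent": [series.phase_percent(k) for k in range(series.n_phases)],
            "liver_cm3": truth.liver_volumes_cm3,
            "gtv_cm3": truth.gtv_volumes_cm3,
            "min_jacobian": truth.min_jacobian,
        }
    ).to_csv(out / "true_volumes.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {
                "n_phases": series.n_phases,
                "reference_index": series.reference_index,
                "phase_percents": [
                    series.phase_percent(k) for k in range(series.n_phases)
                ],
            },
            fh,
            indent=2,
        )
    return out


def load_series(series_dir) -> Series4D:
    """Load a phase series previously written by :func:`write_series`."""
    from .grid import load_volume

    d = Path(series_dir)
    with open(d / "manifest.json") as fh:
        man = json.load(fh)
    vols = [
        load_volume(d / f"phase_{pct:02d}.nii.gz") for pct in man["phase_percents"]
    ]
    fractions = np.asarray(man["phase_percents"], dtype=float) / 100.0
    return Series4D(vols, fractions, man["reference_index"])
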