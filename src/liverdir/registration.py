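"""Symmetric diffeomorphic intensity-based registration of a phase pair.

The algorithm is a greedy, multiresolution discretization of symmetric
normalization: two half-transforms (one from each image toward a common
mid-space) are updated along the gradient of a windowed normalized
cross-correlation (CC) similarity, with fluid-like smoothing of each
update (velocity regularization) and light elastic smoothing of the
running fields.  On convergence the half-fields are composed into full
forward and inverse point maps, audited for Jacobian positivity and
inverse consistency.

CC is invariant to affine intensity changes, which makes it suitable
for CT phases with contrast and noise variations; its local window also
keeps the similarity meaningful inside the low-contrast liver.
"""

from __future__ import annotations

from dataclasses import dataclass
from hashlib import sha1

import numpy as np
from scipy import ndimage

from .fields import compose_fields, invert_field, jacobian_determinant
from .grid import DisplacementField, GridMismatchError, ImageVolume


class RegistrationError(RuntimeError):
    pass


@dataclass
class RegistrationParams:
    """Tunables of the pair registration (distances in mm unless noted)."""

    cc_radius: int = 3  # window half-width, voxels
    shrink_factors: tuple[int, ...] = (4, 2, 1)  # coarse -> fine
    smoothing_sigmas_mm: tuple[float, ...] = (4.0, 2.0, 0.0)
    iterations: tuple[int, ...] = (200, 150, 80)
    step_cap_voxels: float = 0.4  # max update per iteration, voxel units
    # smoothing sigmas are in voxels of the current level, so the bound
    # max|grad(step)| ~ step_cap / update_sigma < 1 that keeps every
    # composed step invertible holds uniformly across levels
    update_sigma_vox: float = 1.0  # fluid-like smoothing of each update
    total_sigma_vox: float = 0.5  # elastic smoothing of the running fields
    convergence_tol: float = 1e-5  # relative metric change over the window
    convergence_window: int = 10
    background_hu: float | None = None  # None: per-level median border intensity
    inverse_tol_mm: float = 0.01
    require_diffeomorphic: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.step_cap_voxels <= 0.5):
            raise ValueError(
                f"step cap must be in (0, 0.5] voxels, got {self.step_cap_voxels}"
            )
        if self.update_sigma_vox < 0 or self.total_sigma_vox < 0:
            raise ValueError("smoothing sigmas must be >= 0")
        if not (
            len(self.shrink_factors)
            == len(self.smoothing_sigmas_mm)
            == len(self.iterations)
        ):
            raise ValueError("per-level settings must have equal length")

    def cache_key(self) -> str:
        payload = repr(sorted(self.__dict__.items())).encode()
        return sha1(payload).hexdigest()[:12]


@dataclass
class RegistrationResult:
    """Forward/inverse point maps of one registered pair plus diagnostics."""

    phi_ab: DisplacementField  # maps A coordinates to B coordinates
    phi_ba: DisplacementField
    metric_trace: list[float]
    level_trace_sizes: list[int]
    converged: bool
    inverse_consistency_mm: float
    min_jacobian_ab: float
    min_jacobian_ba: float


# ---------------------------------------------------------------------------
# Local cross-correlation
# ---------------------------------------------------------------------------


def _window_sums(x: np.ndarray, size: int) -> np.ndarray:
    # constant-0 padding so partial windows at the boundary sum in-bounds
    # voxels only; pairs with the in-bounds count from an all-ones filter
    return ndimage.uniform_filter(x, size=size, mode="constant", cval=0.0) * size**3


def local_cc(
    a: np.ndarray, b: np.ndarray, radius: int = 3, want_gradient: bool = True,
    spacing: np.ndarray | None = None,
):
    """Windowed squared normalized cross-correlation and its gradient.

    ``CC(x) = <ā, b̄>² / (<ā, ā> <b̄, b̄>)`` over a ``(2r+1)³``
    neighbourhood with local means removed.  Returns the mean CC over
    valid voxels (local variance above a scale-aware floor in both
    images; constant patches contribute 0) and, optionally, the
    per-voxel analytic gradient of CC with respect to a displacement of
    ``b``, as a ``(*shape, 3)`` array (mm⁻¹ if spacing is given).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise GridMismatchError(f"shape mismatch {a.shape} vs {b.shape}")
    size = 2 * int(radius) + 1
    n = _window_sums(np.ones_like(a), size)
    sa = _window_sums(a, size)
    sb = _window_sums(b, size)
    saa = _window_sums(a * a, size) - sa * sa / n
    sbb = _window_sums(b * b, size) - sb * sb / n
    sab = _window_sums(a * b, size) - sa * sb / n
    # variance floor: absorbs accumulation rounding on flat patches
    tol_a = 1e-9 * size**3 * max(float(a.var()), 1e-300)
    tol_b = 1e-9 * size**3 * max(float(b.var()), 1e-300)
    valid = (saa > tol_a) & (sbb > tol_b)
    cc = np.zeros_like(a)
    np.divide(sab * sab, saa * sbb, out=cc, where=valid)
    np.clip(cc, 0.0, 1.0, out=cc)
    mean_cc = float(cc[valid].mean()) if np.any(valid) else 0.0
    if not want_gradient:
        return mean_cc, cc, None
    a_bar = a - sa / n
    b_bar = b - sb / n
    coef = np.zeros_like(a)
    np.divide(2.0 * sab, saa * sbb, out=coef, where=valid)
    ratio = np.zeros_like(a)
    np.divide(sab, sbb, out=ratio, where=valid)
    scal = coef * (a_bar - ratio * b_bar)
    if spacing is None:
        gb = np.gradient(b)
    else:
        gb = np.gradient(b, *(float(s) for s in spacing))
    grad = np.stack([scal * g for g in gb], axis=-1)
    return mean_cc, cc, grad


# ---------------------------------------------------------------------------
# Multiresolution greedy symmetric optimization
# ---------------------------------------------------------------------------


def _border(data: np.ndarray) -> np.ndarray:
    faces = [data[0], data[-1], data[:, 0], data[:, -1], data[:, :, 0], data[:, :, -1]]
    return np.concatenate([f.ravel() for f in faces])


def _shrink(data: np.ndarray, spacing: np.ndarray, factor: int, sigma_mm: float):
    if sigma_mm > 0:
        data = ndimage.gaussian_filter(data, sigma=sigma_mm / spacing)
    if factor > 1:
        data = data[::factor, ::factor, ::factor]
    return np.ascontiguousarray(data), spacing * factor


def _sample_field(u: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Interpolate a (*shape, 3) field at voxel coords (3, N), clamped."""
    out = np.empty((coords.shape[1], 3))
    for c in range(3):
        out[:, c] = ndimage.map_coordinates(
            u[..., c], coords, order=1, mode="nearest"
        )
    return out


def _upsample(u: np.ndarray, old_spacing, new_shape, new_spacing) -> np.ndarray:
    scale = np.asarray(new_spacing) / np.asarray(old_spacing)
    idx = np.indices(new_shape, dtype=np.float64)
    coords = (idx * scale[:, None, None, None]).reshape(3, -1)
    return _sample_field(u, coords).reshape(*new_shape, 3)


def _smooth_field(u: np.ndarray, sigma_vox: float) -> np.ndarray:
    if sigma_vox <= 0:
        return u
    out = np.empty_like(u)
    for c in range(3):
        out[..., c] = ndimage.gaussian_filter(u[..., c], sigma=sigma_vox)
    return out


def register_pair(
    vol_a: ImageVolume,
    vol_b: ImageVolume,
    params: RegistrationParams | None = None,
    tag_a: int | str = "A",
    tag_b: int | str = "B",
) -> RegistrationResult:
    """Register two phase volumes symmetrically; return both point maps.

    ``phi_ab`` maps A coordinates to B coordinates (and pulls the B
    image back onto A's grid); ``phi_ba`` is its counterpart.  The two
    are built from the converged half-fields, so they are inverse to
    each other up to the reported consistency residual.
    """
    params = params or RegistrationParams()
    if not vol_a.same_grid(vol_b):
        raise GridMismatchError("registration requires a common voxel grid")

    u_a: np.ndarray | None = None  # half-field mid -> A, mm
    u_b: np.ndarray | None = None
    prev_spacing = None
    trace: list[float] = []
    level_sizes: list[int] = []
    converged = False
    n_levels = len(params.shrink_factors)

    for lev in range(n_levels):
        factor = params.shrink_factors[lev]
        sigma = params.smoothing_sigmas_mm[lev]
        a_l, sp = _shrink(vol_a.data, vol_a.spacing, factor, sigma)
        b_l, _ = _shrink(vol_b.data, vol_b.spacing, factor, sigma)
        if params.background_hu is not None:
            bg_a = bg_b = params.background_hu
        else:
            # robust per-level, per-image background for out-of-bounds
            # samples: the median border intensity (a plain min would pick
            # noise outliers whose artificial edges then dominate the
            # capped updates; a pooled value would break the invariance
            # of CC to affine intensity changes of one image)
            bg_a = float(np.median(_border(a_l)))
            bg_b = float(np.median(_border(b_l)))
        shape = a_l.shape
        idx = np.indices(shape, dtype=np.float64)
        if u_a is None:
            u_a = np.zeros((*shape, 3))
            u_b = np.zeros((*shape, 3))
        else:
            u_a = _upsample(u_a, prev_spacing, shape, sp)
            u_b = _upsample(u_b, prev_spacing, shape, sp)
        prev_spacing = sp

        sp_col = sp[:, None]
        level_trace: list[float] = []
        grad_scale: float | None = None  # robust scale, fixed per level
        n_rejected = 0
        pending: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

        def _apply(delta: np.ndarray) -> None:
            # compose each half-field with half the (already smoothed)
            # update, then apply the light elastic smoothing
            nonlocal u_a, u_b
            half = 0.5 * delta
            for sign, u in ((1.0, u_b), (-1.0, u_a)):
                d = sign * half
                coords = idx.reshape(3, -1) + (d.reshape(-1, 3).T / sp_col)
                u[...] = d + _sample_field(u, coords).reshape(*shape, 3)
            u_a = _smooth_field(u_a, params.total_sigma_vox)
            u_b = _smooth_field(u_b, params.total_sigma_vox)

        for _ in range(params.iterations[lev]):
            coords_a = idx.reshape(3, -1) + (u_a.reshape(-1, 3).T / sp_col)
            coords_b = idx.reshape(3, -1) + (u_b.reshape(-1, 3).T / sp_col)
            a_w = ndimage.map_coordinates(
                a_l, coords_a, order=1, mode="constant", cval=bg_a
            ).reshape(shape)
            b_w = ndimage.map_coordinates(
                b_l, coords_b, order=1, mode="constant", cval=bg_b
            ).reshape(shape)
            mean_cc, cc, grad = local_cc(
                a_w, b_w, radius=params.cc_radius, spacing=sp
            )
            metric = 1.0 - mean_cc

            # greedy accept/reject: an update that worsened the metric
            # is rolled back and retried at half the step; the next
            # fresh update returns to the full cap
            if pending is not None and level_trace and metric > level_trace[-1]:
                ua_prev, ub_prev, last_delta = pending
                u_a = ua_prev.copy()
                u_b = ub_prev.copy()
                n_rejected += 1
                retry = 0.5 * last_delta
                if (
                    n_rejected >= 4
                    or float(np.abs(retry / sp).max()) < 1e-4
                ):
                    # plateau: halved retries stopped helping
                    converged = converged or lev == n_levels - 1
                    break
                _apply(retry)
                pending = (ua_prev, ub_prev, retry)
                continue
            level_trace.append(metric)
            n_rejected = 0

            # demons-style per-voxel step: unit CC-gradient direction,
            # scaled by the local misalignment (1 − CC), a saturation on
            # the gradient magnitude, and the step cap.  A global
            # gradient normalization would let the huge marker and
            # organ-boundary gradients freeze the low-contrast
            # parenchyma, whose texture carries the interior motion;
            # conversely an unconditional unit step would let static
            # image noise deform featureless regions, so weak gradients
            # (relative to a robust per-level scale) are damped.
            gn = np.linalg.norm(grad, axis=-1, keepdims=True)
            if float(gn.max()) < 1e-30:
                converged = True
                break
            if grad_scale is None:
                nz = gn[gn > 0]
                grad_scale = float(np.percentile(nz, 75.0)) if nz.size else 1.0
            sat = gn / (gn + max(grad_scale, 1e-30))
            delta = (
                params.step_cap_voxels
                * (1.0 - cc)[..., None]
                * sat
                * (grad / np.maximum(gn, 1e-30))
                * sp
            )
            delta[gn[..., 0] < 1e-30] = 0.0
            delta = _smooth_field(delta, params.update_sigma_vox)
            pending = (u_a.copy(), u_b.copy(), delta)
            _apply(delta)

            w = params.convergence_window
            if len(level_trace) > w:
                drop = level_trace[-w - 1] - level_trace[-1]
                scale = max(abs(level_trace[-w - 1]), 1e-12)
                if drop / scale < params.convergence_tol:
                    converged = lev == n_levels - 1
                    break
        trace.extend(level_trace)
        level_sizes.append(len(level_trace))

    sp = prev_spacing
    fa = DisplacementField(u_a, sp, vol_a.origin, from_phase="mid", to_phase=tag_a)
    fb = DisplacementField(u_b, sp, vol_a.origin, from_phase="mid", to_phase=tag_b)
    inv_a, ok_a = invert_field(fa, tol_mm=params.inverse_tol_mm)
    inv_b, ok_b = invert_field(fb, tol_mm=params.inverse_tol_mm)
    phi_ab = compose_fields(inv_a, fb, check_tags=False)
    phi_ba = compose_fields(inv_b, fa, check_tags=False)
    phi_ab.from_phase, phi_ab.to_phase = tag_a, tag_b
    phi_ba.from_phase, phi_ba.to_phase = tag_b, tag_a

    interior = (slice(1, -1),) * 3
    min_jac_ab = float(jacobian_determinant(phi_ab)[interior].min())
    min_jac_ba = float(jacobian_determinant(phi_ba)[interior].min())
    if params.require_diffeomorphic and (min_jac_ab <= 0 or min_jac_ba <= 0):
        raise RegistrationError(
            f"Jacobian positivity failed at the finest level "
            f"(shrink {params.shrink_factors[-1]}): "
            f"min det {min(min_jac_ab, min_jac_ba):.4f} <= 0"
        )

    comp = compose_fields(phi_ab, phi_ba, check_tags=False)
    residual = float(np.max(np.linalg.norm(comp.data, axis=-1)))
    return RegistrationResult(
        phi_ab=phi_ab,
        phi_ba=phi_ba,
        metric_trace=trace,
        level_trace_sizes=level_sizes,
        converged=converged and ok_a and ok_b,
        inverse_consistency_mm=residual,
        min_jacobian_ab=min_jac_ab,
        min_jacobian_ba=min_jac_ba,
    )


def identity_result(
    vol: ImageVolume, tag: int | str = "ref"
) -> RegistrationResult:
    """Trivial result mapping a phase to itself (used for the reference)."""
    zero = DisplacementField.zeros_like(vol, from_phase=tag, to_phase=tag)
    return RegistrationResult(
        phi_ab=zero,
        phi_ba=DisplacementField.zeros_like(vol, from_phase=tag, to_phase=tag),
        metric_trace=[],
        level_trace_sizes=[],
        converged=True,
        inverse_consistency_mm=0.0,
        min_jacobian_ab=1.0,
        min_jacobian_ba=1.0,
    )
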