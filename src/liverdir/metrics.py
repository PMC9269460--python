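"""Registration-accuracy metrics and statistical comparison.

Two distance metrics drive the evaluation:

* the registration error ``r_error = ‖x_{f,j} − φ_j(x_{f,ref})‖`` —
  the Euclidean distance between the marker measured in phase j and
  the reference-phase marker carried into phase j by the registration
  point map φ_j;
* the relative distance variation
  ``d = ‖x₂,j − x₁,j‖ − ‖x₂,ref − x₁,ref‖`` — the signed change of a
  pairwise distance across phases, zero under rigid motion.

Distributions of r_error are compared between registration strategies
(and between original and inpainted images) with the two-sample
Kolmogorov–Smirnov test.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .fields import transform_points
from .grid import DisplacementField


def registration_error(
    measured_mm: np.ndarray,
    reference_mm: np.ndarray,
    phi: DisplacementField,
) -> np.ndarray:
    """Euclidean distance between measured and transform-predicted markers.

    ``phi`` must map reference-phase coordinates to the measured
    phase's coordinates.  Accepts single points or (n, 3) arrays.
    """
    est = transform_points(reference_mm, phi)
    err = np.linalg.norm(
        np.atleast_2d(measured_mm) - np.atleast_2d(est), axis=-1
    )
    return err if np.ndim(measured_mm) > 1 else float(err[0])


def relative_distance(
    p1_j: np.ndarray, p2_j: np.ndarray, p1_ref: np.ndarray, p2_ref: np.ndarray
) -> float:
    """Signed change of the pairwise distance relative to the reference."""
    d_j = np.linalg.norm(np.asarray(p2_j, float) - np.asarray(p1_j, float))
    d_ref = np.linalg.norm(np.asarray(p2_ref, float) - np.asarray(p1_ref, float))
    return float(d_j - d_ref)


def displacement_3d(lr_mm: float, ap_mm: float, si_mm: float) -> float:
    """Euclidean norm of per-axis peak-to-peak excursions."""
    return float(np.linalg.norm([lr_mm, ap_mm, si_mm]))


def peak_to_peak_displacement(com_trajectory_mm: np.ndarray) -> dict[str, float]:
    """Per-axis (max − min over phases) excursion of a COM trajectory and
    its 3D norm — the tumor-motion summary with markers COM as surrogate."""
    traj = np.asarray(com_trajectory_mm, dtype=float)
    ptp = traj.max(axis=0) - traj.min(axis=0)
    return {
        "LR": float(ptp[0]),
        "AP": float(ptp[1]),
        "SI": float(ptp[2]),
        "3D": displacement_3d(*ptp),
    }


def extreme_phase_displacement(
    com_trajectory_mm: np.ndarray, phase_a: int, phase_b: int
) -> dict[str, float]:
    """Alternative displacement convention: between two named phases
    (typically 0% inhale vs 50% exhale) instead of the cycle extremes."""
    traj = np.asarray(com_trajectory_mm, dtype=float)
    diff = np.abs(traj[phase_a] - traj[phase_b])
    return {
        "LR": float(diff[0]),
        "AP": float(diff[1]),
        "SI": float(diff[2]),
        "3D": displacement_3d(*diff),
    }


def ks_two_sample(sample_x, sample_y) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test.

    D = sup |ECDF_x − ECDF_y|; the p-value comes from the asymptotic
    Kolmogorov distribution with effective size nm/(n+m).
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero (report-cell convention)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def error_table(rows: list[dict]) -> pd.DataFrame:
    """Row-level r_error table: one row per (strategy, phase, marker)."""
    df = pd.DataFrame(rows)
    expected = {"strategy", "phase_index", "marker_id", "r_error_mm"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (df["r_error_mm"] < 0).any():
        raise ValueError("r_error must be non-negative")
    return df


def summarize_errors(df: pd.DataFrame) -> pd.DataFrame:
    """Per-(strategy, phase) mean/median/sd/max summary of r_error."""
    g = df.groupby(["strategy", "phase_index"])["r_error_mm"]
    out = g.agg(mean="mean", median="median", sd="std", max="max").reset_index()
    return out


def summarize_relative_distances(df: pd.DataFrame) -> pd.DataFrame:
    g = df.groupby(["pair_label", "phase_index"])["d_mm"]
    return g.agg(mean="mean", max=lambda s: s.abs().max()).reset_index()
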