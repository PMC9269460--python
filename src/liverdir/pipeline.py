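"""End-to-end evaluation pipeline on a synthetic breathing series.

Stages: generate (or load) the 4D series → localize and track fiducial
markers → register with the reference and sequential strategies
(optionally repeated on marker-inpainted images) → propagate contours
from mid-ventilation → compute registration-error and relative-distance
tables and the Kolmogorov–Smirnov strategy comparisons.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import markers as mk
from .grid import ImageVolume
from .inpaint import inpaint_markers
from .metrics import (
    error_table,
    extreme_phase_displacement,
    ks_two_sample,
    peak_to_peak_displacement,
    registration_error,
    relative_distance,
    round_half_away,
    summarize_errors,
)
from .phantom import PhantomSpec, Series4D, generate_series
from .propagation import (
    StructureTrajectory,
    propagate_structures,
    select_mid_ventilation,
    volume_cv,
)
from .registration import RegistrationParams
from .strategies import (
    link_fields,
    make_cache,
    reference_registration,
    sequential_registration,
)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    phantom: PhantomSpec = dc_field(default_factory=PhantomSpec)
    registration: RegistrationParams = dc_field(default_factory=RegistrationParams)
    run_reference: bool = True
    run_sequential: bool = True
    run_inpainted: bool = True
    inpaint_dilation_mm: float = 2.0
    inpaint_slicewise: bool = False
    # False: per-axis max-min over all phases; True: 0% vs reference
    # (end-inspiration vs end-expiration) only
    displacement_between_extremes: bool = False
    cyclic: bool = True
    cache_dir: str | None = None
    out_dir: str | None = None
    seed: int | None = None  # overrides the phantom seed when given


@dataclass
class PipelineReport:
    errors: pd.DataFrame  # (strategy, phase, marker, r_error)
    error_summary: pd.DataFrame
    relative_distances: pd.DataFrame
    motion_summary: pd.DataFrame  # Table-1-style per-structure rows
    structures: StructureTrajectory | None
    ks_tests: dict[str, dict[str, float]]
    mid_ventilation: int
    reference_index: int
    composition_counts: dict[int, int]
    manifest: dict


def _measure_markers(series: Series4D) -> mk.MarkerSet:
    return mk.detect_and_track(series.volumes, series.reference_index)


def _strategy_errors(
    strategy: str,
    fields_by_phase: dict,
    measured: mk.MarkerSet,
    ref: int,
) -> list[dict]:
    rows = []
    ref_pts = measured.centroids_mm[ref]
    for j, phi in fields_by_phase.items():
        if j == ref:
            continue
        errs = registration_error(measured.centroids_mm[j], ref_pts, phi)
        for f, e in enumerate(np.atleast_1d(errs)):
            rows.append(
                {
                    "strategy": strategy,
                    "phase_index": j,
                    "marker_id": f,
                    "r_error_mm": float(e),
                }
            )
    return rows


def run_pipeline(config: PipelineConfig | None = None) -> PipelineReport:
    cfg = config or PipelineConfig()
    spec = cfg.phantom
    if cfg.seed is not None:
        spec = PhantomSpec.from_dict({**spec.to_dict(), "seed": cfg.seed})
    t0 = time.time()

    try:
        series, truth = generate_series(spec)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("generate", e) from e
    ref = series.reference_index

    try:
        measured = _measure_markers(series)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("markers", e) from e

    params = cfg.registration
    cache = make_cache(params, cfg.cache_dir)
    rows: list[dict] = []
    pair_fields = None
    comp_counts: dict[int, int] = {}

    if cfg.run_reference:
        try:
            ref_results = reference_registration(series, params, ref, cache=cache)
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("reference_registration", e) from e
        rows += _strategy_errors(
            "reference", {j: r.phi_ab for j, r in ref_results.items()}, measured, ref
        )

    if cfg.run_sequential:
        try:
            pair_results, composed, comp_counts = sequential_registration(
                series, params, ref, cyclic=cfg.cyclic, cache=cache
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("sequential_registration", e) from e
        pair_fields = link_fields(pair_results)
        rows += _strategy_errors("sequential", composed, measured, ref)

    if cfg.run_inpainted:
        try:
            inpainted = Series4D(
                [
                    inpaint_markers(
                        v,
                        dilation_radius_mm=cfg.inpaint_dilation_mm,
                        slicewise=cfg.inpaint_slicewise,
                    )[0]
                    for v in series.volumes
                ],
                series.phase_fractions,
                ref,
            )
            inp_results = reference_registration(inpainted, params, ref)
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("inpainted_registration", e) from e
        # measured marker coordinates from the original images are still
        # the gold standard for the inpainted registrations
        rows += _strategy_errors(
            "inpainted_reference",
            {j: r.phi_ab for j, r in inp_results.items()},
            measured,
            ref,
        )

    errors = error_table(rows) if rows else pd.DataFrame(
        columns=["strategy", "phase_index", "marker_id", "r_error_mm"]
    )
    summary = summarize_errors(errors) if len(errors) else errors

    # --- contour propagation (sequential links, mid-ventilation source) ---
    mid_vent = select_mid_ventilation(measured)
    structures = None
    if pair_fields is not None:
        try:
            liver_mv = ImageVolume(
                truth.liver_masks[mid_vent].astype(float), spec.spacing, spec.origin
            )
            gtv_mv = ImageVolume(
                truth.gtv_masks[mid_vent].astype(float), spec.spacing, spec.origin
            )
            structures = propagate_structures(
                liver_mv, gtv_mv, pair_fields, mid_vent, series.n_phases, cfg.cyclic
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("propagation", e) from e

    # --- relative distance variations -----------------------------------
    rel_rows: list[dict] = []
    cents = measured.centroids_mm
    nm = measured.n_markers
    for j in range(series.n_phases):
        for f1 in range(nm):
            for f2 in range(f1 + 1, nm):
                rel_rows.append(
                    {
                        "phase_index": j,
                        "pair_label": f"marker{f1 + 1}-marker{f2 + 1}",
                        "d_mm": relative_distance(
                            cents[j, f1], cents[j, f2], cents[ref, f1], cents[ref, f2]
                        ),
                    }
                )
        if structures is not None:
            g_j, g_r = structures.gtv_com_mm[j], structures.gtv_com_mm[ref]
            l_j, l_r = structures.liver_com_mm[j], structures.liver_com_mm[ref]
            for f in range(nm):
                rel_rows.append(
                    {
                        "phase_index": j,
                        "pair_label": f"gtvcom-marker{f + 1}",
                        "d_mm": relative_distance(
                            g_j, cents[j, f], g_r, cents[ref, f]
                        ),
                    }
                )
            com_j, com_r = measured.com(j), measured.com(ref)
            rel_rows.append(
                {
                    "phase_index": j,
                    "pair_label": "gtvcom-markerscom",
                    "d_mm": relative_distance(g_j, com_j, g_r, com_r),
                }
            )
            rel_rows.append(
                {
                    "phase_index": j,
                    "pair_label": "gtvcom-livercom",
                    "d_mm": relative_distance(g_j, l_j, g_r, l_r),
                }
            )
    rel = pd.DataFrame(rel_rows)

    # --- motion / volume summary (cohort-table style) --------------------
    if cfg.displacement_between_extremes:
        disp = extreme_phase_displacement(measured.com_trajectory(), 0, ref)
    else:
        disp = peak_to_peak_displacement(measured.com_trajectory())
    motion_rows = [
        {"quantity": f"tumor_displacement_{k}_mm", "value": round_half_away(v)}
        for k, v in disp.items()
    ]
    for f in range(nm):
        for g in range(f + 1, nm):
            d = float(
                np.linalg.norm(cents[mid_vent, f] - cents[mid_vent, g])
            )
            motion_rows.append(
                {
                    "quantity": f"distance_marker{f + 1}_marker{g + 1}_mm",
                    "value": round_half_away(d),
                }
            )
    if structures is not None:
        gcv = volume_cv(structures.gtv_volume_cm3)
        lcv = volume_cv(structures.liver_volume_cm3)
        motion_rows += [
            {
                "quantity": "gtv_midvent_cm3",
                "value": round_half_away(structures.gtv_volume_cm3[mid_vent]),
            },
            {
                "quantity": "gtv_mean_cm3",
                "value": round_half_away(float(structures.gtv_volume_cm3.mean())),
            },
            {"quantity": "gtv_cv_percent", "value": round_half_away(gcv)},
            {
                "quantity": "liver_midvent_cm3",
                "value": round_half_away(structures.liver_volume_cm3[mid_vent]),
            },
            {
                "quantity": "liver_mean_cm3",
                "value": round_half_away(float(structures.liver_volume_cm3.mean())),
            },
            {"quantity": "liver_cv_percent", "value": round_half_away(lcv)},
        ]
    motion = pd.DataFrame(motion_rows)

    # --- KS comparisons ---------------------------------------------------
    ks: dict[str, dict[str, float]] = {}

    def _pool(name: str) -> np.ndarray:
        return errors.loc[errors.strategy == name, "r_error_mm"].to_numpy()

    def _ks_entry(key: str, a: str, b: str) -> None:
        xa, xb = _pool(a), _pool(b)
        if xa.size and xb.size:
            d, p = ks_two_sample(xa, xb)
            entry = {"D": d, "p": p}
            for j in sorted(errors.phase_index.unique()):
                pa = errors.query("strategy == @a and phase_index == @j")[
                    "r_error_mm"
                ].to_numpy()
                pb = errors.query("strategy == @b and phase_index == @j")[
                    "r_error_mm"
                ].to_numpy()
                if pa.size and pb.size:
                    dj, pj = ks_two_sample(pa, pb)
                    entry[f"p_phase_{j}"] = pj
            ks[key] = entry

    if cfg.run_reference and cfg.run_sequential:
        _ks_entry("reference_vs_sequential", "reference", "sequential")
    if cfg.run_reference and cfg.run_inpainted:
        _ks_entry("original_vs_inpainted", "reference", "inpainted_reference")

    manifest = {
        "phantom": spec.to_dict(),
        "registration": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in params.__dict__.items()
        },
        "params_hash": params.cache_key(),
        "reference_index": ref,
        "mid_ventilation": mid_vent,
        "n_phases": series.n_phases,
        "runtime_s": round(time.time() - t0, 1),
    }

    report = PipelineReport(
        errors=errors,
        error_summary=summary,
        relative_distances=rel,
        motion_summary=motion,
        structures=structures,
        ks_tests=ks,
        mid_ventilation=mid_vent,
        reference_index=ref,
        composition_counts=comp_counts,
        manifest=manifest,
    )
    if cfg.out_dir:
        write_report(report, cfg.out_dir)
    return report


def write_report(report: PipelineReport, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.errors.to_csv(out / "registration_errors.csv", index=False)
    report.error_summary.to_csv(out / "error_summary.csv", index=False)
    report.relative_distances.to_csv(out / "relative_distances.csv", index=False)
    report.motion_summary.to_csv(out / "motion_summary.csv", index=False)
    if report.structures is not None:
        report.structures.to_frame().to_csv(out / "structures.csv", index=False)
    with open(out / "ks_tests.json", "w") as fh:
        json.dump(report.ks_tests, fh, indent=2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2)
    return out
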