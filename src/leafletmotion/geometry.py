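"""Leaflet vector geometry and the eight PLAX motion metrics.

From the five landmarks of each phase, four base-anchored vectors are
formed (B→M, B→T, B→A, B→OB) plus a "global" leaflet vector — the mean of
the mid- and tip-point vectors. Comparing systolic (open) and diastolic
(closed) configurations yields, per patient:

===============  ==============================================================
``ld_mid``       linear displacement of the mid-leaflet vector, mm
``ld_tip``       linear displacement of the tip vector, mm
``ld_global``    linear displacement of the global vector, mm
``ad_mid``       angular displacement of the mid vector w.r.t. the B→A axis, °
``ad_tip``       angular displacement of the tip vector, °
``ad_global``    mean of ``ad_mid`` and ``ad_tip``, °
``linearity``    diastolic internal leaflet angle (apex at M), °; 180° = straight
``flexibility``  |systolic − diastolic internal angle|, °
===============  ==============================================================

All geometry is computed in millimetre space: pixel coordinates are scaled
per axis by the study calibration before any distance or angle, so
anisotropic calibrations do not distort angles.

Angular displacement supports an optional cardiac-rotation correction: the
signed phase-to-phase rotation of the B→OB axis (opposing hinge point,
tracking whole-heart rotation) is subtracted from the leaflet vector's
signed absolute-frame rotation. Without correction, angles are measured
against each phase's own B→A axis, which already cancels any rigid rotation
applied to a whole frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .annotations import (
    Calibration,
    DegeneracyError,
    PhaseAnnotation,
    StudyAnnotation,
)

Vec = tuple[float, float]

#: column order of the metrics table written by the CLI
METRIC_NAMES = ("ld_mid", "ld_tip", "ld_global", "ad_mid", "ad_tip",
                "ad_global", "linearity", "flexibility")


@dataclass(frozen=True)
class LeafletVectorSet:
    """Base-anchored leaflet vectors of one phase, in mm (image y-down)."""

    v_M: Vec
    v_T: Vec
    v_A: Vec
    v_OB: Vec
    v_G: Vec
    phase: str


@dataclass(frozen=True)
class MotionMetrics:
    """The eight derived leaflet motion features of one study."""

    ld_mid: float
    ld_tip: float
    ld_global: float
    ad_mid: float
    ad_tip: float
    ad_global: float
    linearity: float
    flexibility: float
    rotation_corrected: bool = False

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _norm(v: Vec) -> float:
    return math.hypot(v[0], v[1])


def _sub(a: Vec, b: Vec) -> Vec:
    return (a[0] - b[0], a[1] - b[1])


def _signed_angle_deg(v: Vec) -> float:
    # atan2 in image coordinates (y down); sign flipped so that
    # counterclockwise in anatomical (y-up) orientation is positive.
    return -math.degrees(math.atan2(v[1], v[0]))


def _wrap180(deg: float) -> float:
    return (deg + 180.0) % 360.0 - 180.0


def leaflet_vectors(phase_annotation: PhaseAnnotation,
                    calibration: Calibration) -> LeafletVectorSet:
    """Build the base-anchored vector set of one phase, in mm."""
    sx, sy = calibration.mm_per_px_x, calibration.mm_per_px_y
    b = phase_annotation["B"]

    def vec_to(name: str) -> Vec:
        p = phase_annotation[name]
        return ((p.x - b.x) * sx, (p.y - b.y) * sy)

    v_M, v_T, v_A, v_OB = (vec_to(n) for n in ("M", "T", "A", "OB"))
    for name, v in (("M", v_M), ("T", v_T), ("A", v_A)):
        if _norm(v) == 0.0:
            raise DegeneracyError(
                f"phase {phase_annotation.phase}: B coincides with {name}")
    v_G = ((v_M[0] + v_T[0]) / 2.0, (v_M[1] + v_T[1]) / 2.0)
    return LeafletVectorSet(v_M=v_M, v_T=v_T, v_A=v_A, v_OB=v_OB, v_G=v_G,
                            phase=phase_annotation.phase)


def linear_displacement(v_phase1: Vec, v_phase2: Vec) -> float:
    """Euclidean distance, mm, between the same base-anchored vector in two phases."""
    return _norm(_sub(v_phase1, v_phase2))


def vector_angle_to_reference(v: Vec, v_ref: Vec) -> float:
    """Unsigned angle between ``v`` and ``v_ref`` in degrees, in [0, 180].

    Computed as the arccosine of the normalized dot product, clamped to
    [-1, 1] before inversion to absorb rounding.
    """
    nv, nr = _norm(v), _norm(v_ref)
    if nv == 0.0 or nr == 0.0:
        raise DegeneracyError("zero-length vector has no direction")
    c = (v[0] * v_ref[0] + v[1] * v_ref[1]) / (nv * nr)
    c = max(-1.0, min(1.0, c))
    return math.degrees(math.acos(c))


def angular_displacement(vec_sys: LeafletVectorSet, vec_dia: LeafletVectorSet,
                         landmark: str, correct_rotation: bool = False) -> float:
    """Phase-to-phase rotation of the ``M`` or ``T`` vector, degrees in [0, 180].

    Uncorrected: absolute difference of each phase's unsigned angle to its
    own B→A axis. Corrected: the leaflet vector's signed absolute-frame
    rotation minus the signed rotation of the B→OB axis (whole-heart
    rotation), wrapped and returned as an absolute value.
    """
    if landmark not in ("M", "T"):
        raise ValueError(f"angular displacement is defined at M or T, got {landmark!r}")
    v_sys = vec_sys.v_M if landmark == "M" else vec_sys.v_T
    v_dia = vec_dia.v_M if landmark == "M" else vec_dia.v_T
    if not correct_rotation:
        theta_sys = vector_angle_to_reference(v_sys, vec_sys.v_A)
        theta_dia = vector_angle_to_reference(v_dia, vec_dia.v_A)
        return abs(theta_sys - theta_dia)
    for v in (v_sys, v_dia, vec_sys.v_OB, vec_dia.v_OB):
        if _norm(v) == 0.0:
            raise DegeneracyError("zero-length vector in rotation correction")
    leaflet_rot = _wrap180(_signed_angle_deg(v_sys) - _signed_angle_deg(v_dia))
    heart_rot = _wrap180(_signed_angle_deg(vec_sys.v_OB)
                         - _signed_angle_deg(vec_dia.v_OB))
    return abs(_wrap180(leaflet_rot - heart_rot))


def internal_angle(phase_annotation: PhaseAnnotation,
                   calibration: Calibration) -> float:
    """Internal leaflet angle at apex M, between M→B and M→T, degrees in [0, 180]."""
    sx, sy = calibration.mm_per_px_x, calibration.mm_per_px_y
    m = phase_annotation["M"]
    b = phase_annotation["B"]
    t = phase_annotation["T"]
    mb = ((b.x - m.x) * sx, (b.y - m.y) * sy)
    mt = ((t.x - m.x) * sx, (t.y - m.y) * sy)
    if _norm(mb) == 0.0 or _norm(mt) == 0.0:
        raise DegeneracyError(
            f"phase {phase_annotation.phase}: degenerate leaflet segment at M")
    return vector_angle_to_reference(mb, mt)


def compute_motion_metrics(study: StudyAnnotation,
                           correct_rotation: bool = False,
                           global_ld_convention: str = "vector_mean",
                           global_ad_convention: str = "scalar_mean",
                           ) -> MotionMetrics:
    """Derive the eight motion metrics of one study.

    ``global_ld_convention``: ``"vector_mean"`` (default) takes the global
    linear displacement as the displacement of the averaged vector v_G;
    ``"scalar_mean"`` averages ld_mid and ld_tip instead.
    ``global_ad_convention``: ``"scalar_mean"`` (default) averages ad_mid
    and ad_tip; ``"vector"`` measures the angular displacement of v_G itself.
    """
    if global_ld_convention not in ("vector_mean", "scalar_mean"):
        raise ValueError(f"unknown global_ld_convention {global_ld_convention!r}")
    if global_ad_convention not in ("scalar_mean", "vector"):
        raise ValueError(f"unknown global_ad_convention {global_ad_convention!r}")
    try:
        vec_sys = leaflet_vectors(study.systole, study.calibration)
        vec_dia = leaflet_vectors(study.diastole, study.calibration)
        ld_mid = linear_displacement(vec_sys.v_M, vec_dia.v_M)
        ld_tip = linear_displacement(vec_sys.v_T, vec_dia.v_T)
        if global_ld_convention == "vector_mean":
            ld_global = linear_displacement(vec_sys.v_G, vec_dia.v_G)
        else:
            ld_global = (ld_mid + ld_tip) / 2.0
        ad_mid = angular_displacement(vec_sys, vec_dia, "M", correct_rotation)
        ad_tip = angular_displacement(vec_sys, vec_dia, "T", correct_rotation)
        if global_ad_convention == "scalar_mean":
            ad_global = (ad_mid + ad_tip) / 2.0
        else:
            if not correct_rotation:
                t_s = vector_angle_to_reference(vec_sys.v_G, vec_sys.v_A)
                t_d = vector_angle_to_reference(vec_dia.v_G, vec_dia.v_A)
                ad_global = abs(t_s - t_d)
            else:
                lr = _wrap180(_signed_angle_deg(vec_sys.v_G)
                              - _signed_angle_deg(vec_dia.v_G))
                hr = _wrap180(_signed_angle_deg(vec_sys.v_OB)
                              - _signed_angle_deg(vec_dia.v_OB))
                ad_global = abs(_wrap180(lr - hr))
        lin = internal_angle(study.diastole, study.calibration)
        flex = abs(internal_angle(study.systole, study.calibration) - lin)
    except DegeneracyError as err:
        raise DegeneracyError(f"patient {study.patient_id}: {err}") from err
    return MotionMetrics(
        ld_mid=ld_mid, ld_tip=ld_tip, ld_global=ld_global,
        ad_mid=ad_mid, ad_tip=ad_tip, ad_global=ad_global,
        linearity=lin, flexibility=flex,
        rotation_corrected=correct_rotation,
    )


def metrics_table(studies, correct_rotation: bool = False):
    """Compute metrics for many studies; returns a pandas DataFrame.

    Columns: patient_id, rater_id, replicate, the eight metrics, and the
    rotation_corrected flag.
    """
    import pandas as pd

    rows = []
    for study in studies:
        m = compute_motion_metrics(study, correct_rotation=correct_rotation)
        row = {"patient_id": study.patient_id, "rater_id": study.rater_id,
               "replicate": study.replicate}
        row.update(m.as_dict())
        row["rotation_corrected"] = m.rotation_corrected
        rows.append(row)
    return pd.DataFrame(rows)
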