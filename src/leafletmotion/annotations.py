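"""Landmark annotation data model, validation, file I/O and DICOM calibration.

A study annotation holds the five named PLAX landmarks of the anterior
(right coronary) aortic leaflet analysis in two cardiac phases:

* ``B``  — leaflet base / hinge point (origin of all leaflet vectors)
* ``M``  — mid segment of the right coronary leaflet
* ``T``  — right coronary leaflet tip
* ``A``  — aortic wall at the level of the sinotubular junction
* ``OB`` — opposing leaflet hinge point (cardiac-motion reference)

Coordinates are 0-based continuous pixel positions with y increasing
downward (image convention). A per-study calibration converts pixels to
millimetres per axis; all geometry downstream works in mm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

LANDMARK_NAMES = ("B", "M", "T", "A", "OB")
PHASES = ("systole", "diastole")
CALIBRATION_SOURCES = ("dicom_us_region", "dicom_pixel_spacing", "manual")

#: exact CSV header of the long-form annotation table
CSV_COLUMNS = [
    "patient_id", "rater_id", "replicate", "phase", "frame_index",
    "landmark", "x_px", "y_px", "mm_per_px_x", "mm_per_px_y",
]

_COINCIDENCE_TOL = 1e-9  # px; below this two landmarks count as coincident


class AnnotationError(ValueError):
    """Base class for annotation data errors."""


class SchemaError(AnnotationError):
    """File or object does not conform to the annotation schema."""


class CalibrationError(AnnotationError):
    """Pixel-to-mm calibration missing, non-positive, or implausible."""


class DegeneracyError(AnnotationError):
    """Coincident landmarks make a required vector or angle undefined."""


@dataclass(frozen=True)
class Landmark:
    """A named point in continuous pixel coordinates.

    Construction checks the name only; coordinate invariants (finite,
    non-negative) are reported by :func:`validate_study` and enforced at
    file-reading time, so invalid data can be represented and inspected.
    """

    name: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.name not in LANDMARK_NAMES:
            raise SchemaError(f"unknown landmark name {self.name!r}")


@dataclass(frozen=True)
class Calibration:
    """Millimetres per pixel along each image axis.

    ``source`` records provenance: extracted from a DICOM ultrasound-region
    sequence, from a pixel-spacing attribute, or supplied manually.
    """

    mm_per_px_x: float
    mm_per_px_y: float
    source: str = "manual"

    def __post_init__(self) -> None:
        for label, v in (("mm_per_px_x", self.mm_per_px_x),
                         ("mm_per_px_y", self.mm_per_px_y)):
            if not math.isfinite(v) or v <= 0:
                raise CalibrationError(f"{label} must be positive and finite, got {v}")
        ratio = self.mm_per_px_x / self.mm_per_px_y
        if not 0.2 <= ratio <= 5.0:
            raise CalibrationError(
                f"implausible calibration anisotropy {ratio:.3g} (allowed 0.2–5)"
            )
        if self.source not in CALIBRATION_SOURCES:
            raise CalibrationError(f"unknown calibration source {self.source!r}")


@dataclass(frozen=True)
class PhaseAnnotation:
    """All five landmarks of one cardiac phase (systole = open, diastole = closed)."""

    phase: str
    frame_index: int
    landmarks: dict[str, Landmark] = field(compare=False)

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise SchemaError(f"unknown phase {self.phase!r}")
        if self.frame_index < 0:
            raise SchemaError(f"frame_index must be >= 0, got {self.frame_index}")
        missing = [n for n in LANDMARK_NAMES if n not in self.landmarks]
        if missing:
            raise SchemaError(f"phase {self.phase}: missing landmark(s) {missing}")
        extra = [n for n in self.landmarks if n not in LANDMARK_NAMES]
        if extra:
            raise SchemaError(f"phase {self.phase}: unknown landmark(s) {extra}")

    def __getitem__(self, name: str) -> Landmark:
        return self.landmarks[name]


def _degenerate_pairs(phase: PhaseAnnotation) -> list[tuple[str, str]]:
    out = []
    pairs = [("B", "A", "degenerate reference axis (B coincides with A)"),
             ("B", "M", "degenerate leaflet segment (B coincides with M)"),
             ("M", "T", "degenerate leaflet segment (M coincides with T)")]
    for a, b, msg in pairs:
        if a in phase.landmarks and b in phase.landmarks:
            pa, pb = phase.landmarks[a], phase.landmarks[b]
            if math.hypot(pa.x - pb.x, pa.y - pb.y) <= _COINCIDENCE_TOL:
                out.append((f"{a}/{b}", msg))
    return out


@dataclass(frozen=True)
class StudyAnnotation:
    """One annotated PLAX clip: both phases, calibration, rater and replicate."""

    patient_id: str
    systole: PhaseAnnotation
    diastole: PhaseAnnotation
    calibration: Calibration
    rater_id: str = "R1"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.systole.phase != "systole":
            raise SchemaError(f"study {self.patient_id}: systole slot holds "
                              f"phase {self.systole.phase!r}")
        if self.diastole.phase != "diastole":
            raise SchemaError(f"study {self.patient_id}: diastole slot holds "
                              f"phase {self.diastole.phase!r}")
        if self.replicate < 1:
            raise SchemaError(f"study {self.patient_id}: replicate must be >= 1")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.patient_id, self.rater_id, self.replicate)

    def phase(self, name: str) -> PhaseAnnotation:
        if name == "systole":
            return self.systole
        if name == "diastole":
            return self.diastole
        raise SchemaError(f"unknown phase {name!r}")


def validate_study(study: StudyAnnotation) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid).

    Unlike the constructors, which raise, this re-checks every invariant and
    reports all violations as data. It is pure: same input, same list.
    """
    violations: list[str] = []
    for phase in (study.systole, study.diastole):
        for lm in phase.landmarks.values():
            if not (math.isfinite(lm.x) and math.isfinite(lm.y)):
                violations.append(
                    f"{phase.phase}.{lm.name}: non-finite coordinates")
            elif lm.x < 0 or lm.y < 0:
                violations.append(
                    f"{phase.phase}.{lm.name}: negative pixel coordinate")
        for name in LANDMARK_NAMES:
            if name not in phase.landmarks:
                violations.append(f"{phase.phase}: missing landmark {name}")
        for _, msg in _degenerate_pairs(phase):
            violations.append(f"{phase.phase}: {msg}")
    cal = study.calibration
    for label, v in (("mm_per_px_x", cal.mm_per_px_x),
                     ("mm_per_px_y", cal.mm_per_px_y)):
        if not math.isfinite(v) or v <= 0:
            violations.append(f"calibration.{label}: non-positive scale")
    return violations


# ---------------------------------------------------------------------------
# file I/O


def _study_to_rows(study: StudyAnnotation) -> list[dict]:
    rows = []
    for phase in (study.systole, study.diastole):
        for name in LANDMARK_NAMES:
            lm = phase.landmarks[name]
            rows.append({
                "patient_id": study.patient_id,
                "rater_id": study.rater_id,
                "replicate": study.replicate,
                "phase": phase.phase,
                "frame_index": phase.frame_index,
                "landmark": name,
                "x_px": lm.x,
                "y_px": lm.y,
                "mm_per_px_x": study.calibration.mm_per_px_x,
                "mm_per_px_y": study.calibration.mm_per_px_y,
            })
    return rows


def _study_from_group(key: tuple, rows: pd.DataFrame) -> StudyAnnotation:
    patient_id, rater_id, replicate = key
    label = f"study ({patient_id}, {rater_id}, {replicate})"
    cal_x = rows["mm_per_px_x"].unique()
    cal_y = rows["mm_per_px_y"].unique()
    if len(cal_x) != 1 or len(cal_y) != 1:
        raise SchemaError(f"{label}: calibration differs between rows")
    calibration = Calibration(float(cal_x[0]), float(cal_y[0]))
    phases = {}
    for phase_name, sub in rows.groupby("phase", sort=False):
        if phase_name not in PHASES:
            raise SchemaError(f"{label}: unknown phase {phase_name!r}")
        dup = sub["landmark"][sub["landmark"].duplicated()].tolist()
        if dup:
            raise SchemaError(f"{label}: duplicate landmark row(s) {dup} "
                              f"in phase {phase_name}")
        frames = sub["frame_index"].unique()
        if len(frames) != 1:
            raise SchemaError(f"{label}: inconsistent frame_index in "
                              f"phase {phase_name}")
        landmarks = {}
        for _, r in sub.iterrows():
            landmarks[r["landmark"]] = Landmark(
                r["landmark"], float(r["x_px"]), float(r["y_px"]))
        missing = [n for n in LANDMARK_NAMES if n not in landmarks]
        if missing:
            raise SchemaError(
                f"{label}: landmark {missing[0]!r} absent in phase {phase_name}")
        phases[phase_name] = PhaseAnnotation(
            phase_name, int(frames[0]), landmarks)
    for phase_name in PHASES:
        if phase_name not in phases:
            raise SchemaError(f"{label}: phase {phase_name} absent")
    study = StudyAnnotation(
        patient_id=str(patient_id),
        systole=phases["systole"],
        diastole=phases["diastole"],
        calibration=calibration,
        rater_id=str(rater_id),
        replicate=int(replicate),
    )
    _raise_on_violations(study, label)
    return study


def _raise_on_violations(study: StudyAnnotation, label: str) -> None:
    violations = validate_study(study)
    if not violations:
        return
    msg = f"{label}: " + "; ".join(violations)
    if any("coincides" in v for v in violations):
        raise DegeneracyError(msg)
    if any("calibration" in v for v in violations):
        raise CalibrationError(msg)
    raise SchemaError(msg)


def read_annotations(path: str | Path, format: str | None = None
                     ) -> list[StudyAnnotation]:
    """Read study annotations from a long-form CSV or a JSON file.

    The format is inferred from the extension when not given. Study order
    follows row/object order; duplicate (patient_id, rater_id, replicate)
    keys are rejected.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        df = pd.read_csv(path, dtype={"patient_id": str, "rater_id": str})
        if list(df.columns) != CSV_COLUMNS:
            raise SchemaError(
                f"{path}: expected columns {CSV_COLUMNS}, got {list(df.columns)}")
        studies = []
        seen: set[tuple] = set()
        for key, rows in df.groupby(
                ["patient_id", "rater_id", "replicate"], sort=False):
            if key in seen:
                raise SchemaError(f"duplicate study key {key}")
            seen.add(key)
            studies.append(_study_from_group(key, rows))
        return studies
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        studies = [study_from_dict(obj) for obj in payload]
        keys = [s.key for s in studies]
        if len(set(keys)) != len(keys):
            dup = [k for k in keys if keys.count(k) > 1][0]
            raise SchemaError(f"duplicate study key {dup}")
        for s in studies:
            _raise_on_violations(s, f"study {s.key}")
        return studies
    raise ValueError(f"unknown format {format!r}")


def write_annotations(studies: Iterable[StudyAnnotation], path: str | Path,
                      format: str | None = None) -> None:
    """Write studies to CSV (long form, fixed header) or JSON."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    studies = list(studies)
    if format == "csv":
        rows = [r for s in studies for r in _study_to_rows(s)]
        df = pd.DataFrame(rows, columns=CSV_COLUMNS)
        df.to_csv(path, index=False)
        return
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump([study_to_dict(s) for s in studies], fh, indent=1)
        return
    raise ValueError(f"unknown format {format!r}")


def study_to_dict(study: StudyAnnotation) -> dict:
    def phase_dict(p: PhaseAnnotation) -> dict:
        return {
            "phase": p.phase,
            "frame_index": p.frame_index,
            "landmarks": {n: {"x": p[n].x, "y": p[n].y} for n in LANDMARK_NAMES},
        }
    return {
        "patient_id": study.patient_id,
        "rater_id": study.rater_id,
        "replicate": study.replicate,
        "systole": phase_dict(study.systole),
        "diastole": phase_dict(study.diastole),
        "calibration": {
            "mm_per_px_x": study.calibration.mm_per_px_x,
            "mm_per_px_y": study.calibration.mm_per_px_y,
            "source": study.calibration.source,
        },
    }


def study_from_dict(obj: dict) -> StudyAnnotation:
    def phase_obj(d: dict) -> PhaseAnnotation:
        landmarks = {
            name: Landmark(name, float(pt["x"]), float(pt["y"]))
            for name, pt in d["landmarks"].items()
        }
        return PhaseAnnotation(d["phase"], int(d["frame_index"]), landmarks)
    cal = obj["calibration"]
    return StudyAnnotation(
        patient_id=str(obj["patient_id"]),
        systole=phase_obj(obj["systole"]),
        diastole=phase_obj(obj["diastole"]),
        calibration=Calibration(float(cal["mm_per_px_x"]),
                                float(cal["mm_per_px_y"]),
                                cal.get("source", "manual")),
        rater_id=str(obj.get("rater_id", "R1")),
        replicate=int(obj.get("replicate", 1)),
    )


# ---------------------------------------------------------------------------
# DICOM calibration


def extract_dicom_calibration(dicom_path: str | Path) -> Calibration:
    """Extract mm-per-pixel calibration from DICOM metadata (no pixel decode).

    Precedence: an ultrasound-region sequence entry carrying physical deltas
    in cm (PhysicalUnits code 3) wins over a plain PixelSpacing attribute,
    which is stated in mm with row\\column ordering.
    """
    import pydicom

    ds = pydicom.dcmread(str(dicom_path), stop_before_pixels=True, force=True)

    regions = getattr(ds, "SequenceOfUltrasoundRegions", None)
    if regions:
        for region in regions:
            dx = getattr(region, "PhysicalDeltaX", None)
            dy = getattr(region, "PhysicalDeltaY", None)
            if dx is None or dy is None:
                continue
            units_x = getattr(region, "PhysicalUnitsXDirection", 3)
            units_y = getattr(region, "PhysicalUnitsYDirection", 3)
            if units_x != 3 or units_y != 3:  # 3 = cm
                continue
            if float(dx) == 0 or float(dy) == 0:
                raise CalibrationError(
                    f"{dicom_path}: zero physical delta in ultrasound region")
            return Calibration(abs(float(dx)) * 10.0, abs(float(dy)) * 10.0,
                               source="dicom_us_region")

    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is not None:
        row_mm, col_mm = float(spacing[0]), float(spacing[1])
        if row_mm <= 0 or col_mm <= 0:
            raise CalibrationError(f"{dicom_path}: non-positive pixel spacing")
        return Calibration(mm_per_px_x=col_mm, mm_per_px_y=row_mm,
                           source="dicom_pixel_spacing")

    raise CalibrationError(f"{dicom_path}: uncalibrated study — no ultrasound "
                           "region deltas and no pixel spacing")
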