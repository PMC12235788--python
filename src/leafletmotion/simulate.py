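"""Synthetic cohort generation for leaflet-motion analysis.

The study's echocardiograms are not publicly deposited, so every
downstream stage is exercised on synthetic data with a known generative
model, at three levels:

1. **Feature-level cohorts** (`simulate_feature_cohort`): per severity
   class (control / moderate AS / severe AS), the eight motion metrics and
   the clinical covariates are drawn from marginals moment-matched to the
   published per-class mean ± SD, coupled through a single-latent-factor
   Gaussian copula (a per-patient "disease severity" factor) so that
   features co-vary realistically within class.

2. **Landmark-level studies** (`simulate_landmark_study`): a two-segment
   rigid leaflet articulated in a fixed PLAX scene, with class-conditional
   opening rotation and internal-angle change, optional whole-heart rigid
   motion between phases, pixel quantization scale and annotation jitter —
   returning the exact analytic motion metrics as ground truth.

3. **Rater replicates** (`simulate_rater_replicates`): second-rater and
   same-rater repeat annotations with controlled landmark jitter, for
   intraclass-correlation reliability analysis on a 10% subsample.

Marginals
---------
Non-negative features (displacements, angular displacements, flexibility,
AVA, gradients, velocity, dimensionless index, wall thicknesses) use a
lognormal whose parameters are solved in closed form so the configured
mean and SD are reproduced *exactly* (`moment_match_lognormal`). Linearity
and LVEF use normals truncated to (0, 180] and (0, 100]; age is normal,
floored at 18 years outside the control class. Truncation shifts moments
slightly for classes whose mean sits near a bound (severe linearity); the
shift is deterministic and documented rather than re-calibrated away.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .annotations import Calibration, Landmark, PhaseAnnotation, StudyAnnotation
from .geometry import MotionMetrics

logger = logging.getLogger(__name__)

SEVERITIES = ("control", "moderate", "severe")

#: feature draw order (fixed for reproducibility)
FEATURES = (
    "ld_mid", "ld_tip", "ld_global", "ad_mid", "ad_tip", "ad_global",
    "flexibility", "linearity", "lvef", "ava", "mean_gradient",
    "peak_velocity", "dimensionless_index", "age", "ivsd", "pwd",
)

_LOGNORMAL = {"ld_mid", "ld_tip", "ld_global", "ad_mid", "ad_tip",
              "ad_global", "flexibility", "ava", "mean_gradient",
              "peak_velocity", "dimensionless_index", "ivsd", "pwd"}
_TRUNCNORM_BOUNDS = {"linearity": (0.0, 180.0), "lvef": (0.0, 100.0)}

#: sign of each feature's loading on the shared latent factor. The factor is
#: oriented toward health: mobile leaflets, large valve area, preserved LVEF
#: load positively; gradients, velocity, wall thickness, leaflet stiffness
#: (linearity) and age load negatively.
_DIRECTION = {
    "ld_mid": +1, "ld_tip": +1, "ld_global": +1,
    "ad_mid": +1, "ad_tip": +1, "ad_global": +1,
    "flexibility": +1, "ava": +1, "dimensionless_index": +1, "lvef": +1,
    "mean_gradient": -1, "peak_velocity": -1, "ivsd": -1, "pwd": -1,
    "linearity": -1, "age": -1,
}


@dataclass(frozen=True)
class ClassParams:
    """Per-class sample size and (mean, sd) of every simulated feature."""

    severity: str
    n: int
    params: dict[str, tuple[float, float]]
    sex_fraction_female: float

    def __post_init__(self) -> None:
        if self.severity not in SEVERITIES:
            raise ValueError(f"unknown severity {self.severity!r}")
        if self.n < 2:
            raise ValueError("class size must be >= 2")
        if not 0.0 <= self.sex_fraction_female <= 1.0:
            raise ValueError("sex_fraction_female must be in [0, 1]")
        missing = [f for f in FEATURES if f not in self.params]
        if missing:
            raise ValueError(f"class {self.severity}: missing params {missing}")
        for name, (m, s) in self.params.items():
            if s <= 0:
                raise ValueError(f"class {self.severity}: sd of {name} must be > 0")


def default_class_params() -> dict[str, ClassParams]:
    """Default per-class generative parameters.

    Motion metrics and clinical covariates carry the published per-class
    mean ± SD; interventricular septal (ivsd) and posterior wall (pwd)
    diameters are not published per class and use a plausible hypertrophy
    gradient chosen for this artifact.
    """
    control = {
        "ld_mid": (8.7, 3.1), "ld_tip": (9.5, 3.7), "ld_global": (9.2, 2.9),
        "ad_mid": (56, 14), "ad_tip": (37, 13), "ad_global": (47, 14),
        "flexibility": (52, 18), "linearity": (117, 20),
        "lvef": (65, 5), "ava": (2.89, 0.68), "mean_gradient": (4, 1),
        "peak_velocity": (1.30, 0.27), "dimensionless_index": (0.80, 0.10),
        "age": (39, 18), "ivsd": (9, 1.5), "pwd": (9, 1.5),
    }
    moderate = {
        "ld_mid": (3.1, 2.7), "ld_tip": (4.2, 3.9), "ld_global": (3.6, 3.1),
        "ad_mid": (21, 21), "ad_tip": (17, 16), "ad_global": (18, 18),
        "flexibility": (10, 17), "linearity": (148, 26),
        "lvef": (62, 11), "ava": (1.20, 0.36), "mean_gradient": (23, 6),
        "peak_velocity": (3.06, 0.39), "dimensionless_index": (0.33, 0.11),
        "age": (74, 9), "ivsd": (11, 1.8), "pwd": (11, 1.8),
    }
    severe = {
        "ld_mid": (1.7, 1.6), "ld_tip": (2.4, 2.1), "ld_global": (2.1, 1.8),
        "ad_mid": (11, 12), "ad_tip": (11, 10), "ad_global": (11, 11),
        "flexibility": (5, 11), "linearity": (159, 21),
        "lvef": (57, 14), "ava": (0.87, 0.27), "mean_gradient": (39, 11),
        "peak_velocity": (3.97, 0.56), "dimensionless_index": (0.24, 0.07),
        "age": (80, 13), "ivsd": (12, 2.0), "pwd": (12, 2.0),
    }
    return {
        "control": ClassParams("control", 60, control, 29 / 60),
        "moderate": ClassParams("moderate", 70, moderate, 27 / 70),
        "severe": ClassParams("severe", 70, severe, 30 / 70),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs; the seed fully determines output."""

    class_params: dict[str, ClassParams] = field(default_factory=default_class_params)
    factor_loading: float = 0.8
    seed: int = 0
    landmark_mode: bool = False
    pixel_noise_sd: float = 0.5        # px, annotation jitter
    mm_per_px: float = 0.3             # isotropic calibration of simulated clips
    leaflet_segment_lengths: tuple[float, float] = (7.0, 7.0)  # B–M, M–T, mm
    rater_noise_sd: float = 1.0        # px, second-rater jitter
    intra_rater_noise_sd: float = 0.7  # px, same-rater repeat jitter

    def __post_init__(self) -> None:
        if not 0.0 <= self.factor_loading < 1.0:
            raise ValueError("factor_loading must be in [0, 1)")
        for sev in SEVERITIES:
            if sev not in self.class_params:
                raise ValueError(f"class_params missing severity {sev!r}")


@dataclass(frozen=True)
class PatientRecord:
    """One row of the analysis table: covariates, labels and motion metrics."""

    patient_id: str
    severity: str
    hemodynamic_class: str
    age: float
    sex: str
    ava: float
    mean_gradient: float
    peak_velocity: float
    dimensionless_index: float
    lvef: float
    ivsd: float
    pwd: float
    metrics: MotionMetrics

    @property
    def significant_as(self) -> bool:
        """Significant AS = moderate-or-worse stenosis (binary outcome)."""
        return self.severity in ("moderate", "severe")

    def as_dict(self) -> dict:
        row = {
            "patient_id": self.patient_id, "severity": self.severity,
            "hemodynamic_class": self.hemodynamic_class, "age": self.age,
            "sex": self.sex, "ava": self.ava,
            "mean_gradient": self.mean_gradient,
            "peak_velocity": self.peak_velocity,
            "dimensionless_index": self.dimensionless_index,
            "lvef": self.lvef, "ivsd": self.ivsd, "pwd": self.pwd,
        }
        row.update(self.metrics.as_dict())
        return row


def moment_match_lognormal(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of the lognormal with the given mean and SD.

    sigma^2 = ln(1 + sd^2/mean^2), mu = ln(mean) - sigma^2/2; exact for any
    positive mean and SD.
    """
    if not (mean > 0 and sd > 0) or not (math.isfinite(mean) and math.isfinite(sd)):
        raise ValueError(f"mean and sd must be positive and finite, got {mean}, {sd}")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _marginal_transform(feature: str, scores: np.ndarray,
                        mean: float, sd: float, severity: str) -> np.ndarray:
    """Map standard-normal copula scores through the feature's marginal."""
    if feature in _LOGNORMAL:
        mu, sigma = moment_match_lognormal(mean, sd)
        return np.exp(mu + sigma * scores)
    if feature in _TRUNCNORM_BOUNDS:
        lo, hi = _TRUNCNORM_BOUNDS[feature]
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return sps.truncnorm.ppf(sps.norm.cdf(scores), a, b, loc=mean, scale=sd)
    if feature == "age":
        values = mean + sd * scores
        if severity != "control":
            values = np.maximum(values, 18.0)
        return values
    raise ValueError(f"no marginal defined for feature {feature!r}")


def simulate_feature_cohort(config: SimulationConfig) -> list[PatientRecord]:
    """Draw a full class-labelled cohort at the feature level.

    Within each class every feature's normal copula score is
    ``direction * loading * z + sqrt(1 - loading^2) * eps`` with a shared
    per-patient latent factor z, then mapped through the feature's marginal.
    Severe patients are additionally labelled high- vs low-gradient by the
    40 mmHg mean-gradient convention (a label only, no separate model).
    """
    rng = np.random.default_rng(config.seed)
    lam = config.factor_loading
    resid = math.sqrt(1.0 - lam * lam)
    records: list[PatientRecord] = []
    pid = 0
    for sev in SEVERITIES:
        cp = config.class_params[sev]
        z = rng.standard_normal(cp.n)
        values: dict[str, np.ndarray] = {}
        for feature in FEATURES:
            eps = rng.standard_normal(cp.n)
            score = _DIRECTION[feature] * lam * z + resid * eps
            m, s = cp.params[feature]
            values[feature] = _marginal_transform(feature, score, m, s, sev)
        female = rng.random(cp.n) < cp.sex_fraction_female
        for i in range(cp.n):
            pid += 1
            gradient = float(values["mean_gradient"][i])
            if sev == "severe":
                hemo = ("high_gradient_severe" if gradient >= 40.0
                        else "low_gradient_severe")
            else:
                hemo = sev
            metrics = MotionMetrics(
                ld_mid=float(values["ld_mid"][i]),
                ld_tip=float(values["ld_tip"][i]),
                ld_global=float(values["ld_global"][i]),
                ad_mid=float(values["ad_mid"][i]),
                ad_tip=float(values["ad_tip"][i]),
                ad_global=float(values["ad_global"][i]),
                linearity=float(values["linearity"][i]),
                flexibility=float(values["flexibility"][i]),
                rotation_corrected=False,
            )
            records.append(PatientRecord(
                patient_id=f"P{pid:04d}", severity=sev, hemodynamic_class=hemo,
                age=float(values["age"][i]), sex="F" if female[i] else "M",
                ava=float(values["ava"][i]), mean_gradient=gradient,
                peak_velocity=float(values["peak_velocity"][i]),
                dimensionless_index=float(values["dimensionless_index"][i]),
                lvef=float(values["lvef"][i]), ivsd=float(values["ivsd"][i]),
                pwd=float(values["pwd"][i]), metrics=metrics,
            ))
    return records


def cohort_to_frame(records: Sequence[PatientRecord]):
    """Patient records as a pandas DataFrame (one row per patient)."""
    import pandas as pd

    return pd.DataFrame([r.as_dict() for r in records])


# ---------------------------------------------------------------------------
# landmark-level simulation

_WALL_ANGLE_DEG = -15.0    # screen-space direction of the B->A aortic wall axis
_OB_ANGLE_OFFSET_DEG = 80.0
_B_MM = (12.0, 15.0)       # leaflet hinge position, mm
_BA_LENGTH_MM = 22.0       # hinge to sinotubular-junction wall landmark
_BOB_LENGTH_MM = 20.0      # hinge to opposing hinge, across the lumen
_BASE_ANGLE_MEAN_DEG = 80.0  # diastolic leaflet-to-wall angle
_BASE_ANGLE_SD_DEG = 4.0
_RIGID_ROT_MAX_DEG = 8.0   # whole-heart rotation between phases
_RIGID_TRANS_MAX_MM = 3.0
_RIGID_CENTER_MM = (25.0, 25.0)
_DIA_FRAME, _SYS_FRAME = 0, 12


def _dir(angle_deg: float) -> np.ndarray:
    r = math.radians(angle_deg)
    return np.array([math.cos(r), math.sin(r)])


def _unsigned_angle(v: np.ndarray, ref: np.ndarray) -> float:
    c = float(np.dot(v, ref) / (np.linalg.norm(v) * np.linalg.norm(ref)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _signed_angle_to_wall(v: np.ndarray, ref: np.ndarray) -> float:
    # positive on the lumen side of the wall axis (screen orientation)
    return math.degrees(math.atan2(ref[0] * v[1] - ref[1] * v[0],
                                   ref[0] * v[0] + ref[1] * v[1]))


def simulate_landmark_study(severity: str, config: SimulationConfig,
                            seed: int, patient_id: str | None = None,
                            cardiac_motion: bool = True,
                            ) -> tuple[StudyAnnotation, MotionMetrics]:
    """Simulate one annotated study with exact analytic ground truth.

    The leaflet is two rigid segments hinged at B and articulated at M. Its
    diastolic configuration (base angle to the wall, internal angle drawn
    from the class linearity marginal) opens in systole by a base rotation
    equal to a class ad_mid draw and an internal-angle increase equal to a
    class flexibility draw. A random whole-heart rigid motion (rotation
    within ±8°, translation within ±3 mm) is optionally applied to the
    systolic frame, then coordinates are converted to pixels and jittered.

    Returns the noisy annotation and the noiseless analytic metrics
    (computed before rigid motion and pixel jitter).
    """
    if severity not in SEVERITIES:
        raise ValueError(f"unknown severity {severity!r}")
    rng = np.random.default_rng(seed)
    cp = config.class_params[severity]
    l1, l2 = config.leaflet_segment_lengths
    alpha = _WALL_ANGLE_DEG

    mu_ad, sig_ad = moment_match_lognormal(*cp.params["ad_mid"])
    mu_fx, sig_fx = moment_match_lognormal(*cp.params["flexibility"])
    m_lin, s_lin = cp.params["linearity"]
    a_lin, b_lin = (0.0 - m_lin) / s_lin, (180.0 - m_lin) / s_lin

    resamples = 0
    while True:
        d_beta = float(np.exp(mu_ad + sig_ad * rng.standard_normal()))
        d_phi = float(np.exp(mu_fx + sig_fx * rng.standard_normal()))
        phi_dia = float(sps.truncnorm.rvs(a_lin, b_lin, loc=m_lin, scale=s_lin,
                                          random_state=rng))
        beta_dia = float(rng.normal(_BASE_ANGLE_MEAN_DEG, _BASE_ANGLE_SD_DEG))
        beta_sys = beta_dia - d_beta
        phi_sys = phi_dia + d_phi

        ok = (2.0 < beta_sys < 178.0 and 5.0 < phi_dia < 178.0
              and phi_sys < 178.0)
        if ok:
            frames = {}
            tip_angles = {}
            wall = _dir(alpha)
            b = np.array(_B_MM)
            for phase, beta, phi in (("diastole", beta_dia, phi_dia),
                                     ("systole", beta_sys, phi_sys)):
                m_pt = b + l1 * _dir(alpha + beta)
                t_pt = m_pt + l2 * _dir(alpha + beta + phi - 180.0)
                frames[phase] = {
                    "B": b.copy(),
                    "M": m_pt,
                    "T": t_pt,
                    "A": b + _BA_LENGTH_MM * wall,
                    "OB": b + _BOB_LENGTH_MM * _dir(alpha + _OB_ANGLE_OFFSET_DEG),
                }
                tip_angles[phase] = _signed_angle_to_wall(t_pt - b, wall)
            # keep the tip vector strictly on the lumen side of the wall axis
            # in both phases so unsigned and signed rotations coincide
            if all(0.5 < tip_angles[p] < 179.5 for p in ("diastole", "systole")):
                break
        resamples += 1
        if resamples > 1000:
            raise RuntimeError(
                f"landmark simulation for {severity} failed to find a valid "
                "configuration in 1000 resamples")
    if resamples:
        logger.debug("simulate_landmark_study(%s, seed=%s): %d resample(s)",
                     severity, seed, resamples)

    dia, sys_ = frames["diastole"], frames["systole"]
    v = {ph: {k: frames[ph][k] - frames[ph]["B"] for k in ("M", "T")}
         for ph in frames}
    v_g = {ph: (v[ph]["M"] + v[ph]["T"]) / 2.0 for ph in frames}
    ad_tip = abs(tip_angles["systole"] - tip_angles["diastole"])
    truth = MotionMetrics(
        ld_mid=float(np.linalg.norm(v["systole"]["M"] - v["diastole"]["M"])),
        ld_tip=float(np.linalg.norm(v["systole"]["T"] - v["diastole"]["T"])),
        ld_global=float(np.linalg.norm(v_g["systole"] - v_g["diastole"])),
        ad_mid=d_beta,
        ad_tip=ad_tip,
        ad_global=(d_beta + ad_tip) / 2.0,
        linearity=phi_dia,
        flexibility=d_phi,
        rotation_corrected=False,
    )

    if cardiac_motion:
        gamma = math.radians(rng.uniform(-_RIGID_ROT_MAX_DEG, _RIGID_ROT_MAX_DEG))
        trans = rng.uniform(-_RIGID_TRANS_MAX_MM, _RIGID_TRANS_MAX_MM, size=2)
        c = np.array(_RIGID_CENTER_MM)
        rot = np.array([[math.cos(gamma), -math.sin(gamma)],
                        [math.sin(gamma), math.cos(gamma)]])
        sys_ = {k: c + rot @ (p - c) + trans for k, p in sys_.items()}

    def to_phase(points: dict, phase: str, frame_index: int) -> PhaseAnnotation:
        landmarks = {}
        for name, p in points.items():
            px = p / config.mm_per_px
            if config.pixel_noise_sd > 0:
                px = px + rng.normal(0.0, config.pixel_noise_sd, size=2)
            landmarks[name] = Landmark(name, float(px[0]), float(px[1]))
        return PhaseAnnotation(phase, frame_index, landmarks)

    study = StudyAnnotation(
        patient_id=patient_id or f"SIM-{severity}-{seed}",
        systole=to_phase(sys_, "systole", _SYS_FRAME),
        diastole=to_phase(dia, "diastole", _DIA_FRAME),
        calibration=Calibration(config.mm_per_px, config.mm_per_px,
                                source="manual"),
    )
    return study, truth


def simulate_landmark_cohort(config: SimulationConfig,
                             cardiac_motion: bool = True,
                             ) -> tuple[list[StudyAnnotation], list[MotionMetrics]]:
    """A full cohort of landmark-level studies, class sizes from class_params."""
    rng = np.random.default_rng(config.seed)
    studies, truths = [], []
    pid = 0
    for sev in SEVERITIES:
        cp = config.class_params[sev]
        for _ in range(cp.n):
            pid += 1
            sub_seed = int(rng.integers(0, 2**31 - 1))
            study, truth = simulate_landmark_study(
                sev, config, sub_seed, patient_id=f"P{pid:04d}",
                cardiac_motion=cardiac_motion)
            studies.append(study)
            truths.append(truth)
    return studies, truths


def simulate_rater_replicates(studies: Sequence[StudyAnnotation],
                              config: SimulationConfig,
                              fraction: float = 0.10,
                              ) -> list[StudyAnnotation]:
    """Re-measurement annotations for reliability analysis.

    Selects ``ceil(fraction * n)`` patients at random (seeded) and emits,
    per selected patient, a second-rater annotation (landmark jitter
    ``rater_noise_sd``) and a same-rater repeat (jitter
    ``intra_rater_noise_sd``), with rater_id / replicate set accordingly.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    n_sel = math.ceil(fraction * len(studies))
    idx = rng.choice(len(studies), size=n_sel, replace=False)
    out: list[StudyAnnotation] = []
    for i in sorted(int(j) for j in idx):
        base = studies[i]
        out.append(_jitter_study(base, config.rater_noise_sd, rng,
                                 rater_id="R2", replicate=1))
        out.append(_jitter_study(base, config.intra_rater_noise_sd, rng,
                                 rater_id=base.rater_id, replicate=base.replicate + 1))
    return out


def _jitter_study(study: StudyAnnotation, noise_sd: float,
                  rng: np.random.Generator, rater_id: str,
                  replicate: int) -> StudyAnnotation:
    def jitter_phase(phase: PhaseAnnotation) -> PhaseAnnotation:
        landmarks = {}
        for name, lm in phase.landmarks.items():
            dx, dy = (rng.normal(0.0, noise_sd, size=2) if noise_sd > 0
                      else (0.0, 0.0))
            landmarks[name] = Landmark(name, max(0.0, lm.x + dx),
                                       max(0.0, lm.y + dy))
        return PhaseAnnotation(phase.phase, phase.frame_index, landmarks)

    return StudyAnnotation(
        patient_id=study.patient_id,
        systole=jitter_phase(study.systole),
        diastole=jitter_phase(study.diastole),
        calibration=study.calibration,
        rater_id=rater_id,
        replicate=replicate,
    )
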