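import numpy as np
import pytest

from leafletmotion.annotations import (
    Calibration,
    Landmark,
    PhaseAnnotation,
    StudyAnnotation,
)
from leafletmotion.simulate import SimulationConfig


def make_phase(phase, coords, frame_index=0):
    """Build a PhaseAnnotation from a {name: (x, y)} dict."""
    landmarks = {n: Landmark(n, float(x), float(y)) for n, (x, y) in coords.items()}
    return PhaseAnnotation(phase, frame_index, landmarks)


def make_study(sys_coords, dia_coords, cal=(0.3, 0.3), patient_id="P1",
               rater_id="R1", replicate=1):
    return StudyAnnotation(
        patient_id=patient_id,
        systole=make_phase("systole", sys_coords, 12),
        diastole=make_phase("diastole", dia_coords, 0),
        calibration=Calibration(cal[0], cal[1]),
        rater_id=rater_id,
        replicate=replicate,
    )


#: a simple non-degenerate reference layout (pixel coordinates)
BASE_COORDS = {
    "B": (40.0, 50.0),
    "M": (60.0, 65.0),
    "T": (80.0, 72.0),
    "A": (110.0, 30.0),
    "OB": (50.0, 110.0),
}


@pytest.fixture
def base_coords():
    return dict(BASE_COORDS)


@pytest.fixture
def simple_study(base_coords):
    """Diastole at the base layout; systole with the leaflet moved."""
    sys_coords = dict(base_coords)
    sys_coords["M"] = (70.0, 45.0)
    sys_coords["T"] = (95.0, 42.0)
    return make_study(sys_coords, base_coords)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def default_cohort_df():
    """One default synthetic cohort as a DataFrame (session-cached)."""
    from leafletmotion.simulate import simulate_feature_cohort, cohort_to_frame

    return cohort_to_frame(simulate_feature_cohort(SimulationConfig(seed=0)))


def random_valid_study(rng):
    """A random annotation with non-coincident landmarks."""
    while True:
        pts = {n: tuple(rng.uniform(0, 200, size=2)) for n in
               ("B", "M", "T", "A", "OB")}
        d = {k: np.hypot(pts["B"][0] - v[0], pts["B"][1] - v[1])
             for k, v in pts.items() if k != "B"}
        mt = np.hypot(pts["M"][0] - pts["T"][0], pts["M"][1] - pts["T"][1])
        if min(d.values()) > 1e-3 and mt > 1e-3:
            break
    sys_pts = {n: (v[0] + rng.uniform(-20, 20), v[1] + rng.uniform(-20, 20))
               for n, v in pts.items()}
    sys_pts = {n: (abs(x), abs(y)) for n, (x, y) in sys_pts.items()}
    try:
        return make_study(sys_pts, pts, cal=(rng.uniform(0.1, 0.5),
                                             rng.uniform(0.1, 0.5)))
    except Exception:
        return random_valid_study(rng)
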