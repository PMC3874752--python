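import numpy as np
import pytest

from laphase.curves import TimeVolumeCurve
from laphase.synthetic import (
    CohortConfig,
    GroundTruthPatient,
    build_curve,
    landmark_frames,
    sample_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """41-patient cohort with default parameters, fixed seed."""
    return sample_cohort(CohortConfig(n_patients=41, seed=1))


@pytest.fixture(scope="session")
def cohort_500():
    return sample_cohort(CohortConfig(n_patients=500, seed=5))


@pytest.fixture
def patient():
    """One hand-built patient with a round-number triple."""
    return GroundTruthPatient(
        patient_id="PX",
        group="normal",
        bsa=2.0,
        lvedp=9.0,
        heart_rate=72.0,
        true_lav_max=60.0,
        true_lav_ac=48.0,
        true_lav_min=30.0,
        n_frames=25,
        event_frames=landmark_frames(25),
    )


@pytest.fixture
def curve(patient):
    return build_curve(patient)


def constant_curve(value=40.0, n=25, pid="PCONST"):
    times = np.arange(n) * 33.0
    return TimeVolumeCurve(
        patient_id=pid,
        times=times,
        volumes=np.full(n, value),
        rr_interval=n * 33.0,
        event_frames=landmark_frames(n),
    )


def single_peak_curve(v_min=30.0, v_max=60.0, n=25, pid="PPEAK"):
    """Rising-then-falling curve with no atrial kick."""
    frames = np.arange(n)
    peak = n // 2
    v = np.where(
        frames <= peak,
        v_min + (v_max - v_min) * 0.5 * (1 - np.cos(np.pi * frames / peak)),
        v_min + (v_max - v_min) * 0.5
        * (1 + np.cos(np.pi * (frames - peak) / (n - 1 - peak))),
    )
    times = np.arange(n) * 33.0
    return TimeVolumeCurve(
        patient_id=pid, times=times, volumes=v, rr_interval=n * 33.0,
        event_frames=None,
    )
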