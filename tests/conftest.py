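import numpy as np
import pytest

from trunkrun import AccelTrace, SignalParams, simulate_run_signal
from trunkrun.preprocessing import RunningStage, estimate_tilt, tilt_correct
from trunkrun.preprocessing import AccelTrace as _AccelTrace


@pytest.fixture(scope="session")
def clean_run_params():
    """Noiseless, level, symmetric 60-s run at 2.8 steps/s."""
    return SignalParams(
        duration_s=60.0, fs=100.0, cadence_hz=2.8, noise_sd_g=0.0,
        tilt_ap_deg=0.0, tilt_ml_deg=0.0, drift_deg=0.0, asymmetry=0.0, seed=0,
    )


@pytest.fixture(scope="session")
def clean_run(clean_run_params):
    return simulate_run_signal(clean_run_params)


@pytest.fixture(scope="session")
def full_run_corrected():
    """A 720-s run at 100 Hz, whole-series tilt-corrected (for stage detection)."""
    p = SignalParams(duration_s=720.0, fs=100.0, seed=7, tilt_ap_deg=5.0, drift_deg=2.0)
    trace = simulate_run_signal(p)
    full = RunningStage(0, len(trace))
    vt, ml, ap = tilt_correct(trace, full, estimate_tilt(trace, full))
    return _AccelTrace(subject_id=trace.subject_id, fs=trace.fs, vt=vt, ml=ml, ap=ap)


def make_trace(vt, ml=None, ap=None, fs=100.0, subject_id="t"):
    vt = np.asarray(vt, float)
    z = np.zeros_like(vt)
    return AccelTrace(
        subject_id=subject_id, fs=fs,
        vt=vt, ml=z if ml is None else np.asarray(ml, float),
        ap=z if ap is None else np.asarray(ap, float),
    )
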