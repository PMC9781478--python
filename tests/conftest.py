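import numpy as np
import pytest

from pulsebp import fiducials as fd
from pulsebp import preprocess as pp
from pulsebp import synthetic_data as sd


@pytest.fixture(scope="session")
def subject():
    return sd.generate_subject(3)


@pytest.fixture(scope="session")
def rest_record(subject):
    """Artifact-free resting session with ~125 beats at 1000 Hz."""
    return sd.generate_session(subject, sd.SessionSpec(state="rest", duration=95.0, seed=11))


@pytest.fixture(scope="session")
def detected(rest_record):
    """Shared end-to-end detection products for the resting session."""
    rec = rest_record
    fs = rec.fs
    ecg_f = pp.bandpass_filter(rec.ecg, fs, pp.ECG_FILTER)
    ppg_f = pp.bandpass_filter(rec.ppg, fs, pp.PPG_FILTER)
    ppg_f = pp.moving_average(ppg_f, pp.smooth_window_samples(fs))
    ppg_f = pp.zscore_normalize(ppg_f)
    r_times = fd.detect_r_peaks(ecg_f, fs)
    fids = fd.detect_ppg_fiducials(ppg_f, fs, r_times)
    abp_beats = fd.detect_abp_landmarks(rec.abp, fs, r_times)
    return {
        "ecg_f": ecg_f,
        "ppg_f": ppg_f,
        "r_times": np.asarray(r_times),
        "fids": fids,
        "abp_beats": abp_beats,
    }


def match_truth_beat(record, r_time, tol=0.01):
    """Index of the truth beat whose R time matches, or None."""
    truth_r = record.truth_beats["r_time"].to_numpy()
    i = int(np.argmin(np.abs(truth_r - r_time)))
    return i if abs(truth_r[i] - r_time) <= tol else None
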