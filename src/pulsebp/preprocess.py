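"""Filtering and normalization applied to raw channels before landmark detection.

ECG is band-limited to 0.5-30 Hz and PPG to 0.5-15 Hz before fiducial
detection; both filters are zero-phase so that pulse-arrival timings are not
biased.  Amplitudes are put on a common scale by z-scoring each recording
segment.  All functions are pure array-in/array-out.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import DegenerateSignalError, InvalidParameterError

#: Default passbands (Hz) per channel.
DEFAULT_ECG_BAND = (0.5, 30.0)
DEFAULT_PPG_BAND = (0.5, 15.0)
#: Default moving-average smoothing window for the PPG, in milliseconds.
#: Chosen well below the narrowest pulse feature (crest time ~90 ms) so that
#: smoothing does not displace the pulse foot by more than ~1 ms.
DEFAULT_SMOOTH_WINDOW_MS = 15.0

_FILTER_ORDER = 4


@dataclass(frozen=True)
class FilterSpec:
    """Bandpass specification for one channel.

    Parameters
    ----------
    low_cut, high_cut
        Passband edges in Hz; must satisfy ``0 < low_cut < high_cut < fs/2``.
    kind
        Only ``"bandpass"`` is supported.
    channel
        Informational label (``"ecg"`` or ``"ppg"``).
    """

    low_cut: float
    high_cut: float
    kind: str = "bandpass"
    channel: str = "ppg"

    def validate(self, fs: float) -> None:
        if self.kind != "bandpass":
            raise InvalidParameterError(f"unsupported filter kind: {self.kind!r}")
        if not (0.0 < self.low_cut < self.high_cut):
            raise InvalidParameterError(
                f"need 0 < low_cut < high_cut, got ({self.low_cut}, {self.high_cut})"
            )
        if self.high_cut >= fs / 2.0:
            raise InvalidParameterError(
                f"high_cut {self.high_cut} Hz is at or above Nyquist ({fs / 2.0} Hz)"
            )


ECG_FILTER = FilterSpec(*DEFAULT_ECG_BAND, channel="ecg")
PPG_FILTER = FilterSpec(*DEFAULT_PPG_BAND, channel="ppg")


def bandpass_filter(signal: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase Butterworth bandpass.

    A 4th-order Butterworth is applied forward and backward (``sosfiltfilt``),
    which doubles the effective attenuation and cancels phase delay so that
    landmark times are preserved.
    """
    spec.validate(fs)
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise InvalidParameterError("expected a 1-D sample array")
    if signal.size <= 3 * 2 * _FILTER_ORDER:
        raise InvalidParameterError(
            f"signal of length {signal.size} too short for order-{_FILTER_ORDER} bandpass"
        )
    sos = butter(
        _FILTER_ORDER, [spec.low_cut, spec.high_cut], btype="bandpass", fs=fs, output="sos"
    )
    return sosfiltfilt(sos, signal)


def zscore_normalize(signal: np.ndarray) -> np.ndarray:
    """Standardize a signal to zero mean and unit (population) SD.

    Raises
    ------
    DegenerateSignalError
        If the signal is constant (zero variance).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size < 2:
        raise InvalidParameterError("need at least two samples to normalize")
    sd = float(np.std(signal))  # population SD (ddof=0)
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateSignalError("signal has zero variance; z-score undefined")
    return (signal - float(np.mean(signal))) / sd


def moving_average(signal: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with a shrinking window at the edges.

    ``window`` must be odd so the kernel is symmetric (no time shift).  At the
    array edges the mean is taken over the available samples only, so the
    output has the same length as the input.
    """
    if not isinstance(window, (int, np.integer)) or window < 1 or window % 2 == 0:
        raise InvalidParameterError(f"window must be a positive odd integer, got {window!r}")
    signal = np.asarray(signal, dtype=float)
    if window > signal.size:
        raise InvalidParameterError(
            f"window {window} exceeds signal length {signal.size}"
        )
    if window == 1:
        return signal.copy()
    kernel = np.ones(window)
    sums = np.convolve(signal, kernel, mode="same")
    counts = np.convolve(np.ones_like(signal), kernel, mode="same")
    return sums / counts


def smooth_window_samples(fs: float, window_ms: float = DEFAULT_SMOOTH_WINDOW_MS) -> int:
    """Convert a smoothing window in milliseconds to an odd sample count."""
    n = max(1, int(round(window_ms * fs / 1000.0)))
    if n % 2 == 0:
        n += 1
    return n
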