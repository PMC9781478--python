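"""Per-beat landmark detection on ECG, PPG (and derivatives) and ABP.

The ECG R peak anchors each cardiac cycle; within every R-R window the PPG
pulse foot (onset), maximum-upslope point, systolic peak, dicrotic notch and
diastolic peak are located, together with the a-e waves of the second
derivative and the p1/p2 components of the third derivative.  The ABP wave
foot and peak give per-beat DBP and SBP directly (the ABP channel is used
unfiltered, since filtering would bias pressure values).

Beats whose landmarks cannot be resolved are emitted with absent fields and
flagged rather than silently dropped; they become NaN rows downstream and
are removed by the table-cleaning step.  Flat-line and flat-peak artifact
spans are detected separately and turned into exclusion intervals.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .preprocess import moving_average, smooth_window_samples

R_REFRACTORY_S = 0.2  # minimum separation between accepted R peaks
_MIN_BEAT_WINDOW_S = 0.25

_LANDMARK_FIELDS = (
    "ppg_onset",
    "max_slope",
    "ppg_sys_peak",
    "dicrotic",
    "dia_peak",
    "a_wave",
    "b_wave",
    "c_wave",
    "d_wave",
    "e_wave",
    "p1",
    "p2",
)


@dataclass
class BeatFiducials:
    """Landmark times (s) and amplitudes (normalized units) for one beat.

    Missing landmarks are ``None`` (never 0).  ``rr_prev`` is the R-R
    interval preceding this beat's R peak; ``rr`` the interval to the next R.
    """

    beat: int
    r_time: float
    rr: float
    rr_prev: Optional[float] = None
    ppg_onset: Optional[float] = None
    max_slope: Optional[float] = None
    ppg_sys_peak: Optional[float] = None
    dicrotic: Optional[float] = None
    dia_peak: Optional[float] = None
    a_wave: Optional[float] = None
    b_wave: Optional[float] = None
    c_wave: Optional[float] = None
    d_wave: Optional[float] = None
    e_wave: Optional[float] = None
    p1: Optional[float] = None
    p2: Optional[float] = None
    onset_amp: Optional[float] = None
    sys_amp: Optional[float] = None
    dia_amp: Optional[float] = None
    flags: list[str] = field(default_factory=list)

    def enforce_ordering(self) -> None:
        """Drop landmarks that violate the within-beat ordering invariant."""
        order = ("r_time", "ppg_onset", "max_slope", "ppg_sys_peak", "dicrotic", "dia_peak")
        last = self.r_time
        for name in order[1:]:
            v = getattr(self, name)
            if v is None:
                continue
            ok = v >= last if name == "dia_peak" else v > last
            if not ok:
                setattr(self, name, None)
                if "ordering_violation" not in self.flags:
                    self.flags.append("ordering_violation")
            else:
                last = v


@dataclass
class ExclusionMask:
    """Merged artifact intervals with a reason label per interval."""

    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def merged(self) -> "ExclusionMask":
        ivs = sorted(self.intervals)
        out: list[list] = []
        for s, e, reason in ivs:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
                if reason not in out[-1][2]:
                    out[-1][2] = out[-1][2] + "+" + reason
            else:
                out.append([s, e, reason])
        return ExclusionMask([(s, e, r) for s, e, r in out])

    def overlaps(self, start: float, end: float) -> bool:
        return any(s < end and start < e for s, e, _ in self.intervals)

    def to_frame(self, channel: str = "all") -> pd.DataFrame:
        return pd.DataFrame(
            [(channel, s, e, r) for s, e, r in self.intervals],
            columns=["channel", "start_s", "end_s", "reason"],
        )


# ---------------------------------------------------------------------------
# ECG R peaks
# ---------------------------------------------------------------------------


def detect_r_peaks(ecg: np.ndarray, fs: float) -> list[float]:
    """R-peak times via a Shannon-energy envelope of the differentiated ECG.

    The bandpassed ECG is differentiated, amplitude-normalized, converted to
    a Shannon energy envelope and smoothed; envelope peaks separated by at
    least the 200 ms refractory period mark candidate beats, and each R time
    is refined to the local ECG maximum.  Returns strictly increasing times
    (empty list if the signal carries no QRS energy).
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size < 3:
        return []
    d = np.diff(ecg)
    dmax = float(np.max(np.abs(d)))
    if dmax == 0.0:
        return []
    d = d / dmax
    energy = d**2
    shannon = -energy * np.log(energy + 1e-12)
    env = moving_average(shannon, smooth_window_samples(fs, 50.0))
    height = 0.1 * float(np.max(env))
    peaks, _ = find_peaks(env, height=height, distance=max(1, int(R_REFRACTORY_S * fs)))
    refine = max(1, int(0.05 * fs))
    r_idx = []
    for p in peaks:
        lo, hi = max(0, p - refine), min(ecg.size, p + refine + 1)
        r_idx.append(lo + int(np.argmax(ecg[lo:hi])))
    # refinement can collapse neighbours; re-enforce refractory keeping the larger
    r_idx = sorted(set(r_idx))
    kept: list[int] = []
    for idx in r_idx:
        if kept and (idx - kept[-1]) / fs < R_REFRACTORY_S:
            if ecg[idx] > ecg[kept[-1]]:
                kept[-1] = idx
        else:
            kept.append(idx)
    return [i / fs for i in kept]


# ---------------------------------------------------------------------------
# PPG fiducials
# ---------------------------------------------------------------------------


def _smooth_derivative(x: np.ndarray, fs: float, window: int) -> np.ndarray:
    """Central-difference derivative followed by re-smoothing."""
    return moving_average(np.gradient(x) * fs, window)


def _local_extrema(x: np.ndarray, mode: str) -> np.ndarray:
    d = np.diff(x)
    if mode == "max":
        return np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1
    return np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0)) + 1


def detect_ppg_fiducials(
    ppg: np.ndarray,
    fs: float,
    r_times: Sequence[float],
    deriv_smooth_ms: float = 11.0,
) -> list[BeatFiducials]:
    """Locate pulse landmarks in each R-R window of a filtered, normalized PPG.

    Within each window: the maximum of the (smoothed) first derivative gives
    the max-upslope point; the onset is the signal minimum preceding it; the
    systolic peak is the first signal maximum after it; the dicrotic notch is
    the next local minimum and the diastolic peak the local maximum that
    follows.  The a-e waves are the alternating extrema of the second
    derivative over the systolic phase, and p1/p2 are the zero-crossing
    delimited maxima of the third derivative.  Unresolvable landmarks are
    left absent and the beat flagged.
    """
    ppg = np.asarray(ppg, dtype=float)
    n = ppg.size
    win = smooth_window_samples(fs, deriv_smooth_ms)
    d1 = _smooth_derivative(ppg, fs, win)
    d2 = _smooth_derivative(d1, fs, win)
    d3 = _smooth_derivative(d2, fs, win)

    out: list[BeatFiducials] = []
    r_times = list(r_times)
    for b in range(len(r_times) - 1):
        r0, r1 = r_times[b], r_times[b + 1]
        rr = r1 - r0
        rr_prev = r_times[b] - r_times[b - 1] if b > 0 else None
        fid = BeatFiducials(beat=b, r_time=r0, rr=rr, rr_prev=rr_prev)
        lo, hi = int(round(r0 * fs)), min(n, int(round(r1 * fs)))
        if rr < _MIN_BEAT_WINDOW_S or hi - lo < int(_MIN_BEAT_WINDOW_S * fs):
            fid.flags.append("missing_landmark")
            out.append(fid)
            continue

        seg = ppg[lo:hi]
        seg_d1 = d1[lo:hi]
        ms_i = int(np.argmax(seg_d1))
        if ms_i <= 1:
            fid.flags.append("missing_landmark")
            out.append(fid)
            continue
        onset_i = int(np.argmin(seg[: ms_i + 1]))
        # systolic peak: first local max after the upslope
        maxima = _local_extrema(seg, "max")
        after_ms = maxima[maxima > ms_i]
        if after_ms.size == 0:
            fid.flags.append("missing_landmark")
            fid.ppg_onset = (lo + onset_i) / fs
            fid.onset_amp = float(seg[onset_i])
            fid.max_slope = (lo + ms_i) / fs
            fid.enforce_ordering()
            out.append(fid)
            continue
        sys_i = int(after_ms[0])

        fid.ppg_onset = (lo + onset_i) / fs
        fid.max_slope = (lo + ms_i) / fs
        fid.ppg_sys_peak = (lo + sys_i) / fs
        fid.onset_amp = float(seg[onset_i])
        fid.sys_amp = float(seg[sys_i])

        # dicrotic notch: local minimum after the systolic peak; among
        # candidates prefer the one closest to the e wave of the 2nd
        # derivative (standard notch / e-wave coupling).  A genuine notch
        # must be followed by a diastolic rebound of at least 2% of the
        # pulse amplitude, which rejects noise wiggles on a monotone decay.
        amp = seg[sys_i] - seg[onset_i]
        minima = _local_extrema(seg, "min")
        dic_candidates = minima[(minima > sys_i) & (minima < min(hi - lo - 2, sys_i + int(0.30 * fs)))]
        dic_i = dia_i = None
        if dic_candidates.size:
            seg_d2 = d2[lo:hi]
            e_region = seg_d2[sys_i : min(hi - lo, sys_i + int(0.30 * fs))]
            if e_region.size:
                e_i = sys_i + int(np.argmax(e_region))
                order = dic_candidates[np.argsort(np.abs(dic_candidates - e_i), kind="stable")]
            else:
                order = dic_candidates
            for cand in order:
                cand = int(cand)
                if seg[cand] >= seg[sys_i]:
                    continue
                rebound = maxima[maxima > cand]
                if rebound.size and seg[int(rebound[0])] - seg[cand] >= 0.02 * amp:
                    dic_i, dia_i = cand, int(rebound[0])
                    break
        if dic_i is None:
            fid.flags.append("missing_landmark")
        else:
            fid.dicrotic = (lo + dic_i) / fs
            fid.dia_peak = (lo + dia_i) / fs
            fid.dia_amp = float(seg[dia_i])

        # a-e waves: alternating extrema of the 2nd derivative over the
        # systolic phase (onset .. notch, falling back to onset + 0.3 rr).
        sys_end = dic_i if dic_i is not None else min(hi - lo - 1, onset_i + int(0.3 * rr * fs))
        seg_d2 = d2[lo:hi]
        _assign_abcde(fid, seg_d2, onset_i, sys_end, lo, fs)
        _assign_p1p2(fid, d3[lo:hi], onset_i, sys_i, lo, fs)

        fid.enforce_ordering()
        out.append(fid)
    return out


def _assign_abcde(
    fid: BeatFiducials, d2seg: np.ndarray, start: int, stop: int, offset: int, fs: float
) -> None:
    if stop - start < 5:
        return
    window = d2seg[start:stop]
    maxima = _local_extrema(window, "max")
    minima = _local_extrema(window, "min")
    if maxima.size == 0:
        return
    a_i = int(maxima[np.argmax(window[maxima])])
    fid.a_wave = (offset + start + a_i) / fs
    seq = [("b_wave", minima), ("c_wave", maxima), ("d_wave", minima), ("e_wave", maxima)]
    last = a_i
    for name, pool in seq:
        nxt = pool[pool > last]
        if nxt.size == 0:
            return
        last = int(nxt[0])
        setattr(fid, name, (offset + start + last) / fs)


def _assign_p1p2(
    fid: BeatFiducials, d3seg: np.ndarray, start: int, sys_i: int, offset: int, fs: float
) -> None:
    stop = min(d3seg.size, sys_i + int(0.10 * fs))
    window = d3seg[start:stop]
    if window.size < 5:
        return
    signs = np.sign(window)
    crossings = np.flatnonzero(np.diff(signs) != 0)
    bounds = np.concatenate([[0], crossings + 1, [window.size]])
    peaks = []
    for i in range(len(bounds) - 1):
        seg = window[bounds[i] : bounds[i + 1]]
        if seg.size and np.all(seg >= 0) and seg.max() > 0:
            peaks.append(bounds[i] + int(np.argmax(seg)))
    if peaks:
        fid.p1 = (offset + start + peaks[0]) / fs
    if len(peaks) > 1:
        fid.p2 = (offset + start + peaks[1]) / fs


# ---------------------------------------------------------------------------
# ABP landmarks
# ---------------------------------------------------------------------------


def detect_abp_landmarks(
    abp: np.ndarray,
    fs: float,
    r_times: Sequence[float],
    exclusions: ExclusionMask | None = None,
) -> pd.DataFrame:
    """Per-beat ABP wave foot (DBP) and peak (SBP) within each R-R window.

    The ABP channel is used raw (unfiltered).  The foot is the pre-upstroke
    minimum over the first part of the window; the peak is the maximum that
    follows it.  Beats overlapping an exclusion interval are skipped.
    Returns a frame with columns ``beat, foot_time, DBP, peak_time, SBP``.
    """
    abp = np.asarray(abp, dtype=float)
    n = abp.size
    rows = []
    for b in range(len(r_times) - 1):
        r0, r1 = r_times[b], r_times[b + 1]
        if exclusions is not None and exclusions.overlaps(r0, r1):
            continue
        lo, hi = int(round(r0 * fs)), min(n, int(round(r1 * fs)))
        if hi - lo < int(_MIN_BEAT_WINDOW_S * fs):
            continue
        seg = abp[lo:hi]
        # pre-upstroke minimum: locate the systolic upstroke (max slope
        # before the wave peak), then take the minimum just before it
        peak0 = int(np.argmax(seg))
        slope = moving_average(np.diff(seg), smooth_window_samples(fs, 11.0))
        ms_i = int(np.argmax(slope[: max(1, peak0)])) if peak0 > 1 else 0
        back = max(0, ms_i - int(0.15 * fs))
        foot_i = back + int(np.argmin(seg[back : ms_i + 1])) if ms_i > back else ms_i
        peak_i = foot_i + int(np.argmax(seg[foot_i:]))
        if seg[peak_i] <= seg[foot_i]:
            continue
        rows.append(
            {
                "beat": b,
                "foot_time": (lo + foot_i) / fs,
                "DBP": float(seg[foot_i]),
                "peak_time": (lo + peak_i) / fs,
                "SBP": float(seg[peak_i]),
            }
        )
    return pd.DataFrame(rows, columns=["beat", "foot_time", "DBP", "peak_time", "SBP"])


# ---------------------------------------------------------------------------
# Flat-artifact detection
# ---------------------------------------------------------------------------


def detect_flat_artifacts(
    signal: np.ndarray,
    fs: float,
    min_run: float = 0.2,
    clip_quantile: float = 0.5,
) -> ExclusionMask:
    """Detect flat-line and flat-peak spans in one channel.

    A *flat* run is a stretch of at least ``min_run`` seconds with zero
    first difference.  A run is classified as a clipped ``flat_peak`` when
    it forms a local plateau maximum — its level exceeds the signal
    immediately on both sides and sits at or above the ``clip_quantile``
    quantile of its +/-0.5 s neighbourhood; any other run is a
    ``flat_line``.  (The label is best-effort for runs frozen at arbitrary
    waveform phases; the interval itself is always reported.)
    """
    if min_run <= 0:
        raise ValueError("min_run must be positive")
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    if n < 2:
        return ExclusionMask()
    scale = float(np.max(np.abs(signal))) or 1.0
    flat = np.abs(np.diff(signal)) <= 1e-10 * scale
    min_samples = max(2, int(round(min_run * fs)))
    side = max(1, int(0.03 * fs))
    intervals: list[tuple[float, float, str]] = []
    idx = np.flatnonzero(flat)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        ends = np.concatenate([idx[breaks], [idx[-1]]])
        # merge equal-level runs separated by short gaps (a clipped signal
        # hovering at the ceiling dips below it for a few ms at a time)
        gap = int(0.05 * fs)
        merged: list[list[int]] = []
        for s, e in zip(starts, ends):
            if (
                merged
                and s - merged[-1][1] <= gap
                and abs(signal[int(s)] - signal[int(merged[-1][0])]) <= 1e-10 * scale
            ):
                merged[-1][1] = int(e)
            else:
                merged.append([int(s), int(e)])
        for s, e in merged:
            run_len = e - s + 2  # diff run of k covers k+1 samples
            if run_len < min_samples:
                continue
            lo, hi = int(s), int(e + 2)
            value = signal[lo]
            neigh = signal[max(0, lo - int(0.5 * fs)) : min(n, hi + int(0.5 * fs))]
            margin = 1e-3 * float(np.ptp(neigh) or scale)
            before = signal[max(0, lo - side) : lo]
            after = signal[hi : hi + side]
            is_plateau_max = (
                (before.size == 0 or value > float(np.mean(before)) + margin)
                and (after.size == 0 or value > float(np.mean(after)) + margin)
                and value >= float(np.quantile(neigh, clip_quantile)) - margin
            )
            intervals.append((lo / fs, hi / fs, "flat_peak" if is_plateau_max else "flat_line"))
    return ExclusionMask(intervals).merged()


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------


def fiducials_to_frame(fiducials: Sequence[BeatFiducials]) -> pd.DataFrame:
    """Beat-annotation table: one row per beat, one column per landmark."""
    rows = []
    for f in fiducials:
        row = {
            "beat": f.beat,
            "r_time": f.r_time,
            "rr": f.rr,
            "rr_prev": f.rr_prev,
            "onset_amp": f.onset_amp,
            "sys_amp": f.sys_amp,
            "dia_amp": f.dia_amp,
            "flags": ";".join(f.flags),
        }
        for name in _LANDMARK_FIELDS:
            row[name] = getattr(f, name)
        rows.append(row)
    return pd.DataFrame(rows)


def write_exclusion_mask(mask: ExclusionMask, path: str | Path, channel: str = "all") -> Path:
    """Write a BED-like interval file (``channel,start_s,end_s,reason``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mask.to_frame(channel).to_csv(path, index=False)
    return path
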