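"""Synthetic paired ECG/PPG/ABP sessions with known annotations and BP law.

The study this pipeline emulates recorded adolescents (13-18 y) at 1000 Hz in
two-minute segments, at rest and during an isometric weight-bearing test
(WBT) that raises blood pressure.  No recordings were deposited, so this
module generates physiologically plausible stand-ins with complete ground
truth:

* beat-periodic ECG with a dominant R spike (plus small P/T waves),
* PPG pulses delayed by a controllable pulse arrival time (PAT), with a
  systolic peak, dicrotic notch and diastolic peak, and a well-defined foot,
* ABP waves whose per-beat foot/peak equal the ground-truth DBP/SBP,
* a known feature->BP generative law with a nonlinearity (1/PAT) and one
  threshold interaction term, so the rule-ensemble stage has structure to
  recover,
* rest-vs-WBT level shifts and optional flat-line / flat-peak artifacts.

Every downstream stage is testable against the returned truth annotations.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptySessionError, InvalidParameterError

# ---------------------------------------------------------------------------
# Generative BP law
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LawCoefficients:
    """Coefficients of the per-beat generative BP law.

    ``BP = intercept + slope_inv_pat/PAT + slope_am*AM + slope_rr*RR
          + interaction * 1{PAT < pat_threshold} * AM + noise``

    Units: mmHg throughout; PAT and RR in seconds, AM in normalized
    amplitude units.  The 1/PAT term encodes the usual inverse relation
    between arrival time and pressure; the threshold interaction makes the
    law non-additive in (PAT, AM).
    """

    intercept: float
    slope_inv_pat: float
    slope_am: float
    slope_rr: float
    interaction: float
    pat_threshold: float
    noise_sd: float

    def mean(self, pat: np.ndarray, am: np.ndarray, rr: np.ndarray) -> np.ndarray:
        pat = np.asarray(pat, dtype=float)
        am = np.asarray(am, dtype=float)
        rr = np.asarray(rr, dtype=float)
        return (
            self.intercept
            + self.slope_inv_pat / pat
            + self.slope_am * am
            + self.slope_rr * rr
            + self.interaction * (pat < self.pat_threshold) * am
        )

    def sample(
        self, pat: np.ndarray, am: np.ndarray, rr: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        mu = self.mean(pat, am, rr)
        if self.noise_sd == 0.0:
            return mu
        return mu + rng.normal(0.0, self.noise_sd, size=np.shape(mu))


# Reference operating point used to anchor the law intercept to a subject's
# baseline pressures (rest state): PAT 0.25 s, AM 2.8, RR 0.75 s, and the
# interaction active for half of the beats.
_REF_PAT = 0.25
_REF_AM = 2.8
_REF_RR = 0.75
_REF_INTERACTION_RATE = 0.5

DEFAULT_SBP_SLOPES = dict(slope_inv_pat=6.0, slope_am=5.0, slope_rr=-10.0, interaction=2.0)
DEFAULT_DBP_SLOPES = dict(slope_inv_pat=3.0, slope_am=2.0, slope_rr=-5.0, interaction=0.8)
DEFAULT_SBP_NOISE_SD = 2.0
DEFAULT_DBP_NOISE_SD = 1.5
DEFAULT_PAT_THRESHOLD = 0.25

#: Per-state offsets applied by :func:`generate_session`.  The WBT values are
#: tuned so the mean state effect (through the intercept, the PAT drop and
#: the RR drop combined) is ~+11 mmHg SBP and ~+6 mmHg DBP, the pressor
#: response reported for the isometric weight test.
DEFAULT_STATE_SHIFT: dict[str, dict[str, float]] = {
    "rest": {"sbp": 0.0, "dbp": 0.0, "pat": 0.0, "rr": 0.0},
    "wbt": {"sbp": 8.1, "dbp": 4.7, "pat": -0.02, "rr": -0.10},
}

STATES = ("rest", "wbt")


def _default_coupling(baseline_sbp: float, baseline_dbp: float) -> dict[str, LawCoefficients]:
    def anchor(baseline: float, slopes: dict, noise_sd: float) -> LawCoefficients:
        drift = (
            slopes["slope_inv_pat"] / _REF_PAT
            + slopes["slope_am"] * _REF_AM
            + slopes["slope_rr"] * _REF_RR
            + slopes["interaction"] * _REF_INTERACTION_RATE * _REF_AM
        )
        return LawCoefficients(
            intercept=baseline - drift,
            pat_threshold=DEFAULT_PAT_THRESHOLD,
            noise_sd=noise_sd,
            **slopes,
        )

    return {
        "sbp": anchor(baseline_sbp, DEFAULT_SBP_SLOPES, DEFAULT_SBP_NOISE_SD),
        "dbp": anchor(baseline_dbp, DEFAULT_DBP_SLOPES, DEFAULT_DBP_NOISE_SD),
    }


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectProfile:
    """Static description of one synthetic subject.

    ``bmi`` is derived (weight/height**2) and exposed as a property so the
    consistency invariant cannot be violated.  ``arterial_path_length``
    defaults to half the height, a common heart-to-finger approximation.
    """

    subject_id: str
    age: float  # years
    height: float  # m
    weight: float  # kg
    arterial_path_length: float  # m
    baseline_dbp: float  # mmHg
    baseline_sbp: float  # mmHg
    coupling: Mapping[str, LawCoefficients]
    state_shift: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_STATE_SHIFT.items()}
    )

    def __post_init__(self) -> None:
        if self.height <= 0 or self.weight <= 0:
            raise InvalidParameterError("height and weight must be positive")
        if self.arterial_path_length <= 0:
            raise InvalidParameterError("arterial_path_length must be positive")
        if not self.baseline_sbp > self.baseline_dbp:
            raise InvalidParameterError("baseline_sbp must exceed baseline_dbp")
        for key in ("sbp", "dbp"):
            if key not in self.coupling:
                raise InvalidParameterError(f"coupling must define the {key!r} law")

    @property
    def bmi(self) -> float:
        """Body-mass index in kg/m^2, derived from weight and height."""
        return self.weight / self.height**2


@dataclass(frozen=True)
class ArtifactSpec:
    """One artifact to inject: a flat line or a clipped (flat) peak."""

    kind: str  # {"flat_line", "flat_peak"}
    start: float  # s
    length: float  # s
    clip_quantile: float = 0.5  # flat_peak: clip above this window quantile
    channel: str = "all"  # {"ecg", "ppg", "abp", "all"}

    def __post_init__(self) -> None:
        if self.kind not in ("flat_line", "flat_peak"):
            raise InvalidParameterError(f"unknown artifact kind {self.kind!r}")
        if self.length <= 0:
            raise InvalidParameterError("artifact length must be positive")
        if not 0.0 <= self.clip_quantile < 1.0:
            raise InvalidParameterError("clip_quantile must be in [0, 1)")


@dataclass(frozen=True)
class SessionSpec:
    """Recording-session parameters.

    ``mean_rr`` is the resting reference RR interval; state-dependent shifts
    from the subject profile are applied on top of it, so rest/WBT sessions
    built from the same spec differ only through the state label.
    """

    state: str = "rest"
    duration: float = 120.0  # s
    fs: float = 1000.0  # Hz
    mean_rr: float = 0.75  # s
    rr_sd: float = 0.03  # s (stationary SD of the AR(1) RR process)
    seed: int = 0
    artifact_spec: tuple[ArtifactSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise InvalidParameterError(f"state must be one of {STATES}, got {self.state!r}")
        if self.fs <= 0 or self.duration <= 0:
            raise InvalidParameterError("fs and duration must be positive")
        if not 0.0 < self.mean_rr < self.duration:
            raise InvalidParameterError("need 0 < mean_rr < duration")
        if self.rr_sd < 0:
            raise InvalidParameterError("rr_sd must be non-negative")
        object.__setattr__(self, "artifact_spec", tuple(self.artifact_spec))


@dataclass
class GeneratedRecord:
    """Time-aligned channels plus complete per-beat ground truth."""

    t: np.ndarray
    ecg: np.ndarray
    ppg: np.ndarray
    abp: np.ndarray
    truth_beats: pd.DataFrame
    excluded_intervals: list[tuple[float, float]]
    law: dict[str, LawCoefficients]
    profile: SubjectProfile
    spec: SessionSpec

    @property
    def fs(self) -> float:
        return self.spec.fs

    @property
    def n_beats(self) -> int:
        return len(self.truth_beats)


# ---------------------------------------------------------------------------
# Subject generation
# ---------------------------------------------------------------------------


def generate_subject(
    seed: int, state_shift: Mapping[str, Mapping[str, float]] | None = None
) -> SubjectProfile:
    """Draw a subject profile within the study's demographic ranges.

    Deterministic for a fixed seed.  Age is uniform on [13, 18] years;
    height, BMI and baseline pressures are drawn from adolescent-typical
    normal distributions (clipped to plausible ranges).
    """
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise InvalidParameterError("seed must be a non-negative integer")
    rng = np.random.default_rng(int(seed))
    age = float(rng.uniform(13.0, 18.0))
    height = float(np.clip(rng.normal(1.68, 0.09), 1.45, 1.95))
    bmi = float(np.clip(rng.normal(21.0, 2.2), 16.0, 30.0))
    weight = bmi * height**2
    baseline_dbp = float(np.clip(rng.normal(74.0, 4.0), 60.0, 90.0))
    pulse_pressure = float(np.clip(rng.normal(48.0, 7.0), 30.0, 70.0))
    baseline_sbp = baseline_dbp + pulse_pressure
    shifts = (
        {k: dict(v) for k, v in DEFAULT_STATE_SHIFT.items()}
        if state_shift is None
        else {k: dict(v) for k, v in state_shift.items()}
    )
    return SubjectProfile(
        subject_id=f"S{seed:04d}",
        age=age,
        height=height,
        weight=weight,
        arterial_path_length=0.5 * height,
        baseline_dbp=baseline_dbp,
        baseline_sbp=baseline_sbp,
        coupling=_default_coupling(baseline_sbp, baseline_dbp),
        state_shift=shifts,
    )


# ---------------------------------------------------------------------------
# Waveform templates
# ---------------------------------------------------------------------------

# PPG pulse morphology (seconds relative to the pulse foot/onset).  A
# systolic lobe, a reflected (diastolic) lobe producing the dicrotic notch
# and diastolic peak, and a narrow negative "foot dip" centred on the onset
# so the pulse foot is a sharply curved, well-localized minimum.
_PPG_SYS_T, _PPG_SYS_SIGMA = 0.09, 0.035
_PPG_DIA_T, _PPG_DIA_SIGMA, _PPG_DIA_FRAC = 0.30, 0.09, 0.45
_PPG_DIP_SIGMA, _PPG_DIP_FRAC = 0.025, 0.28

# ABP pulse morphology (relative to the wave foot): half-cosine systolic
# rise to the peak, exponential diastolic runoff with a small dicrotic bump.
# The wave starts exactly at DBP at the foot and tops out exactly at SBP.
_ABP_PEAK_T = 0.12
_ABP_DECAY_TAU = 0.35
_ABP_BUMP_T, _ABP_BUMP_SIGMA, _ABP_BUMP_AMP = 0.33, 0.05, 0.10

# ECG waves: (time offset from R in s, sigma in s, amplitude).
_ECG_WAVES = ((0.0, 0.008, 1.0), (-0.16, 0.025, 0.08), (0.22, 0.05, 0.15))

_ECG_NOISE_SD = 0.01
_PPG_NOISE_SD = 0.01
_ABP_NOISE_SD = 0.08  # mmHg


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _add_lobes(
    out: np.ndarray, t: np.ndarray, t0: float, lobes: Iterable[tuple[float, float, float]]
) -> None:
    """Add Gaussian lobes centred at t0+offset, computed on a local slice."""
    fs = 1.0 / (t[1] - t[0])
    for offset, sigma, amp in lobes:
        lo = max(0, int((t0 + offset - 6 * sigma) * fs))
        hi = min(len(t), int((t0 + offset + 6 * sigma) * fs) + 1)
        if lo < hi:
            out[lo:hi] += amp * _gauss(t[lo:hi], t0 + offset, sigma)


def _ppg_pulse_lobes(am: float, dia_frac: float = _PPG_DIA_FRAC):
    return (
        (_PPG_SYS_T, _PPG_SYS_SIGMA, am),
        (_PPG_DIA_T, _PPG_DIA_SIGMA, dia_frac * am),
        (0.0, _PPG_DIP_SIGMA, -_PPG_DIP_FRAC * am),
    )


def _refine_extremum(x: np.ndarray, idx_lo: int, idx_hi: int, mode: str) -> int:
    seg = x[idx_lo:idx_hi]
    if seg.size == 0:
        return idx_lo
    return idx_lo + (int(np.argmin(seg)) if mode == "min" else int(np.argmax(seg)))


def generate_session(
    profile: SubjectProfile, spec: SessionSpec, dia_frac: float = _PPG_DIA_FRAC
) -> GeneratedRecord:
    """Render one synthetic session.

    Per beat, RR intervals follow an AR(1) process (coefficient 0.8) around
    the state-adjusted mean; PAT, pulse amplitude and a pure-noise
    ``distractor`` covariate are drawn i.i.d.; SBP/DBP follow the subject's
    generative law plus the state's pressor offset.  The clean (noise-free)
    waveforms are rendered first and the truth landmark times are read off
    them numerically, then measurement noise is added.

    ``dia_frac`` scales the reflected (diastolic) lobe of the PPG pulse;
    setting it to 0 produces pulses without a dicrotic notch.
    """
    shift = dict(profile.state_shift.get(spec.state, {"sbp": 0, "dbp": 0, "pat": 0, "rr": 0}))
    mean_rr = spec.mean_rr + shift.get("rr", 0.0)
    mean_pat = _REF_PAT + shift.get("pat", 0.0)
    if mean_rr <= 0.2:
        raise InvalidParameterError("state-adjusted mean RR is implausibly short")

    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs

    # --- beat-parameter draws -------------------------------------------
    t_first = 0.3
    tail = 0.45  # room after the last R so the full PPG/ABP pulse fits
    max_beats = int(np.ceil(spec.duration / max(mean_rr - 4 * spec.rr_sd, 0.3))) + 2
    phi = 0.8  # AR(1) coefficient of the RR process
    innov_sd = spec.rr_sd * np.sqrt(1.0 - phi**2)
    rr_dev = np.empty(max_beats)
    rr_dev[0] = rng.normal(0.0, spec.rr_sd)
    for i in range(1, max_beats):
        rr_dev[i] = phi * rr_dev[i - 1] + rng.normal(0.0, innov_sd)
    rr_all = np.clip(mean_rr + rr_dev, 0.35, 2.0)

    r_times: list[float] = []
    rr_list: list[float] = []
    t_r = t_first
    for i in range(max_beats):
        if t_r + rr_all[i] + tail > spec.duration:
            break
        r_times.append(t_r)
        rr_list.append(rr_all[i])
        t_r += rr_all[i]
    if not r_times:
        raise EmptySessionError(
            f"duration {spec.duration}s too short for one beat (mean RR {mean_rr}s)"
        )
    r = np.asarray(r_times)
    rr = np.asarray(rr_list)
    n_beats = len(r)

    pat = np.clip(rng.normal(mean_pat, 0.02, n_beats), 0.12, 0.45)
    am = np.clip(rng.normal(_REF_AM, 0.2, n_beats), 0.5, None)
    distractor = rng.normal(0.0, 1.0, n_beats)

    sbp = profile.coupling["sbp"].sample(pat, am, rr, rng) + shift.get("sbp", 0.0)
    dbp = profile.coupling["dbp"].sample(pat, am, rr, rng) + shift.get("dbp", 0.0)
    sbp = np.maximum(sbp, dbp + 10.0)  # physiological pulse-pressure floor

    # --- clean waveforms -------------------------------------------------
    ecg = np.zeros(n)
    ppg = np.zeros(n)
    for i in range(n_beats):
        _add_lobes(ecg, t, r[i], _ECG_WAVES)
        _add_lobes(ppg, t, r[i] + pat[i], _ppg_pulse_lobes(am[i], dia_frac))

    feet = r + pat  # ABP foot arrives with the pulse
    abp = np.empty(n)
    foot_idx = np.clip(np.round(feet * fs).astype(int), 0, n - 1)
    bounds = np.concatenate([foot_idx, [n]])
    for i in range(n_beats):
        lo, hi = bounds[i], bounds[i + 1]
        tau = t[lo:hi] - feet[i]
        seg_len = max((hi - lo) / fs, _ABP_PEAK_T + 0.05)
        dbp_next = dbp[i + 1] if i + 1 < n_beats else dbp[i]
        # systolic rise dbp_i -> sbp_i, then a normalized-exponential
        # diastolic runoff landing exactly on the next beat's DBP, so the
        # waveform is continuous and every foot is a genuine local minimum
        rise = dbp[i] + (sbp[i] - dbp[i]) * 0.5 * (
            1.0 - np.cos(np.pi * np.abs(tau) / _ABP_PEAK_T)
        )
        e_end = np.exp(-(seg_len - _ABP_PEAK_T) / _ABP_DECAY_TAU)
        w = (np.exp(-(tau - _ABP_PEAK_T) / _ABP_DECAY_TAU) - e_end) / (1.0 - e_end)
        decay = dbp_next + (sbp[i] - dbp_next) * w
        u_bump = (sbp[i] - dbp[i]) * _ABP_BUMP_AMP * _gauss(tau, _ABP_BUMP_T, _ABP_BUMP_SIGMA)
        abp[lo:hi] = np.where(tau < _ABP_PEAK_T, rise, decay) + u_bump
    abp[: bounds[0]] = dbp[0]  # pre-first-foot run-in at the first DBP

    # --- truth landmarks from the clean PPG ------------------------------
    onset_t = np.empty(n_beats)
    syspk_t = np.empty(n_beats)
    dic_t = np.full(n_beats, np.nan)
    diapk_t = np.full(n_beats, np.nan)
    for i in range(n_beats):
        on_nom = int(round((r[i] + pat[i]) * fs))
        w = int(0.04 * fs)
        onset_idx = _refine_extremum(ppg, max(0, on_nom - w), min(n, on_nom + w), "min")
        sys_lo = onset_idx + int(0.03 * fs)
        sys_hi = min(n, onset_idx + int(0.18 * fs))
        sys_idx = _refine_extremum(ppg, sys_lo, sys_hi, "max")
        onset_t[i] = onset_idx / fs
        syspk_t[i] = sys_idx / fs
        if dia_frac > 0:
            dic_lo = sys_idx + int(0.02 * fs)
            dic_hi = min(n, onset_idx + int((_PPG_DIA_T - 0.02) * fs))
            if dic_hi > dic_lo:
                dic_idx = _refine_extremum(ppg, dic_lo, dic_hi, "min")
                dia_hi = min(n, onset_idx + int((_PPG_DIA_T + 0.12) * fs))
                dia_idx = _refine_extremum(ppg, dic_idx, dia_hi, "max")
                dic_t[i] = dic_idx / fs
                diapk_t[i] = dia_idx / fs

    truth = pd.DataFrame(
        {
            "beat": np.arange(n_beats),
            "r_time": r,
            "ppg_onset_time": onset_t,
            "ppg_peak_time": syspk_t,
            "dicrotic_time": dic_t,
            "diastolic_peak_time": diapk_t,
            "true_pat": pat,
            "true_sbp": sbp,
            "true_dbp": dbp,
            "rr": rr,
            "amplitude": am,
            "distractor": distractor,
        }
    )

    # --- measurement noise ------------------------------------------------
    ecg = ecg + rng.normal(0.0, _ECG_NOISE_SD, n)
    ppg = ppg + rng.normal(0.0, _PPG_NOISE_SD, n)
    abp = abp + rng.normal(0.0, _ABP_NOISE_SD, n)

    record = GeneratedRecord(
        t=t,
        ecg=ecg,
        ppg=ppg,
        abp=abp,
        truth_beats=truth,
        excluded_intervals=[],
        law={k: profile.coupling[k] for k in ("sbp", "dbp")},
        profile=profile,
        spec=spec,
    )
    if spec.artifact_spec:
        record = inject_artifacts(record, spec.artifact_spec)
    return record


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------


def _channels(record: GeneratedRecord, which: str) -> list[np.ndarray]:
    if which == "all":
        return [record.ecg, record.ppg, record.abp]
    return [getattr(record, which)]


def inject_artifacts(
    record: GeneratedRecord, spec: Sequence[ArtifactSpec]
) -> GeneratedRecord:
    """Inject flat-line / flat-peak artifacts; truth beats are unchanged.

    ``flat_line`` freezes the channel at its value at the interval start;
    ``flat_peak`` clips samples above the window's ``clip_quantile`` to that
    quantile (sensor-saturation look).  The intervals actually corrupted are
    appended to ``excluded_intervals`` — for flat peaks this is the span of
    clipped samples, which is what a downstream detector can recover.
    """
    record = GeneratedRecord(
        t=record.t,
        ecg=record.ecg.copy(),
        ppg=record.ppg.copy(),
        abp=record.abp.copy(),
        truth_beats=record.truth_beats.copy(),
        excluded_intervals=list(record.excluded_intervals),
        law=dict(record.law),
        profile=record.profile,
        spec=record.spec,
    )
    fs = record.fs
    n = record.t.size
    for art in spec:
        lo = int(round(art.start * fs))
        hi = int(round((art.start + art.length) * fs))
        lo_c, hi_c = max(0, lo), min(n, hi)
        if hi_c - lo_c < 2:
            warnings.warn(
                f"artifact {art.kind} at [{art.start}, {art.start + art.length}] s "
                "overlaps no samples; ignored",
                stacklevel=2,
            )
            continue
        if art.kind == "flat_line":
            for x in _channels(record, art.channel):
                x[lo_c:hi_c] = x[lo_c]
            record.excluded_intervals.append((lo_c / fs, hi_c / fs))
        else:  # flat_peak
            spans: list[tuple[int, int]] = []
            for x in _channels(record, art.channel):
                window = x[lo_c:hi_c]
                thresh = float(np.quantile(window, art.clip_quantile))
                clipped = window > thresh
                window[clipped] = thresh
                x[lo_c:hi_c] = window
                idx = np.flatnonzero(clipped)
                if idx.size:
                    gap = int(0.05 * fs)
                    breaks = np.flatnonzero(np.diff(idx) > gap)
                    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
                    ends = np.concatenate([idx[breaks], [idx[-1]]])
                    # record substantive plateaus only (short-gap fragments
                    # merged); samples clipped for a few ms around the
                    # threshold crossing are noise-scale nicks
                    min_span = int(0.05 * fs)
                    spans.extend(
                        (lo_c + s, lo_c + e + 1)
                        for s, e in zip(starts, ends)
                        if e - s + 1 >= min_span
                    )
            for s, e in _merge_spans(spans):
                record.excluded_intervals.append((s / fs, e / fs))
    record.excluded_intervals = _merge_float_intervals(record.excluded_intervals)
    return record


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not spans:
        return []
    spans = sorted(spans)
    out = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _merge_float_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


# ---------------------------------------------------------------------------
# Ground-truth beat table
# ---------------------------------------------------------------------------


def ground_truth_beat_table(record: GeneratedRecord) -> pd.DataFrame:
    """One row per beat from the truth annotations, bypassing detection.

    Serves as the oracle table for parameter-recovery tests: the SBP/DBP
    columns were generated by the record's law from exactly the ``true_pat``,
    ``amplitude`` and ``rr`` columns returned here.
    """
    tb = record.truth_beats
    if len(tb) == 0:
        raise EmptySessionError("record contains no beats")
    out = pd.DataFrame(
        {
            "subject_id": record.profile.subject_id,
            "state": record.spec.state,
            "true_pat": tb["true_pat"].to_numpy(),
            "amplitude": tb["amplitude"].to_numpy(),
            "rr": tb["rr"].to_numpy(),
            "distractor": tb["distractor"].to_numpy(),
            "SBP": tb["true_sbp"].to_numpy(),
            "DBP": tb["true_dbp"].to_numpy(),
        }
    )
    out["MBP"] = (out["SBP"] + 2.0 * out["DBP"]) / 3.0
    return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def write_record(record: GeneratedRecord, prefix: str | Path) -> tuple[Path, Path]:
    """Write channels as ``time,ecg,ppg,abp`` CSV plus a JSON truth sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    channels_path = prefix.with_name(prefix.name + "_channels.csv")
    truth_path = prefix.with_name(prefix.name + "_truth.json")
    pd.DataFrame(
        {"time": record.t, "ecg": record.ecg, "ppg": record.ppg, "abp": record.abp}
    ).to_csv(channels_path, index=False, float_format="%.6f")
    sidecar = {
        "profile": {
            **{
                k: getattr(record.profile, k)
                for k in (
                    "subject_id",
                    "age",
                    "height",
                    "weight",
                    "arterial_path_length",
                    "baseline_dbp",
                    "baseline_sbp",
                )
            },
            "state_shift": {k: dict(v) for k, v in record.profile.state_shift.items()},
            "coupling": {k: dataclasses.asdict(v) for k, v in record.profile.coupling.items()},
        },
        "spec": {
            **{
                k: getattr(record.spec, k)
                for k in ("state", "duration", "fs", "mean_rr", "rr_sd", "seed")
            },
            "artifact_spec": [dataclasses.asdict(a) for a in record.spec.artifact_spec],
        },
        "excluded_intervals": [list(iv) for iv in record.excluded_intervals],
        "truth_beats": record.truth_beats.to_dict(orient="list"),
    }
    truth_path.write_text(json.dumps(sidecar, indent=1))
    return channels_path, truth_path


def read_record(prefix: str | Path) -> GeneratedRecord:
    """Read a record written by :func:`write_record`."""
    prefix = Path(prefix)
    channels_path = prefix.with_name(prefix.name + "_channels.csv")
    truth_path = prefix.with_name(prefix.name + "_truth.json")
    df = pd.read_csv(channels_path)
    sidecar = json.loads(truth_path.read_text())
    pr = sidecar["profile"]
    profile = SubjectProfile(
        subject_id=pr["subject_id"],
        age=pr["age"],
        height=pr["height"],
        weight=pr["weight"],
        arterial_path_length=pr["arterial_path_length"],
        baseline_dbp=pr["baseline_dbp"],
        baseline_sbp=pr["baseline_sbp"],
        coupling={k: LawCoefficients(**v) for k, v in pr["coupling"].items()},
        state_shift=pr["state_shift"],
    )
    sp = sidecar["spec"]
    spec = SessionSpec(
        state=sp["state"],
        duration=sp["duration"],
        fs=sp["fs"],
        mean_rr=sp["mean_rr"],
        rr_sd=sp["rr_sd"],
        seed=sp["seed"],
        artifact_spec=tuple(ArtifactSpec(**a) for a in sp["artifact_spec"]),
    )
    return GeneratedRecord(
        t=df["time"].to_numpy(),
        ecg=df["ecg"].to_numpy(),
        ppg=df["ppg"].to_numpy(),
        abp=df["abp"].to_numpy(),
        truth_beats=pd.DataFrame(sidecar["truth_beats"]),
        excluded_intervals=[tuple(iv) for iv in sidecar["excluded_intervals"]],
        law=dict(profile.coupling),
        profile=profile,
        spec=spec,
    )
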