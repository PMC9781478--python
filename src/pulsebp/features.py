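"""Per-beat hemodynamic feature/target table and the cleaning rules.

Each row is one cardiac cycle.  Predictors are pulse-timing intervals
(PAT variants measured from the R peak to PPG landmarks), their RR-relative
versions, pulse wave velocities (arterial path length / PAT), amplitude and
contour descriptors, and subject demographics.  Targets are the per-beat
SBP/DBP read off the ABP wave and the derived mean pressure
MBP = (SBP + 2*DBP)/3.

Cleaning mirrors a two-step protocol: rows with any missing value are
dropped first, then rows with any per-column |z| > 3 (sample SD) are
removed in a single pass.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidBeatError, InvalidParameterError
from .fiducials import BeatFiducials, ExclusionMask
from .synthetic_data import SubjectProfile

#: Demographic columns carried on every row.
DEMOGRAPHIC_COLUMNS = ("age", "height", "weight", "bmi")
#: Target columns.
TARGET_COLUMNS = ("SBP", "DBP", "MBP")
#: Identifier columns excluded from numeric cleaning.
ID_COLUMNS = ("subject_id", "state", "beat")


def mean_bp(sbp: float, dbp: float) -> float:
    """Mean blood pressure, (SBP + 2*DBP)/3 in mmHg.

    Raises a domain error unless ``sbp > dbp > 0``.
    """
    if not (sbp > dbp > 0):
        raise InvalidBeatError(f"need SBP > DBP > 0, got SBP={sbp}, DBP={dbp}")
    return (sbp + 2.0 * dbp) / 3.0


def _interval(later: Optional[float], earlier: float) -> float:
    return later - earlier if later is not None else np.nan


def _pwv(path_length: float, pat: float) -> float:
    return path_length / pat if np.isfinite(pat) and pat > 0 else np.nan


def compute_beat_features(
    fid: BeatFiducials,
    abp_beat: tuple[float, float],
    profile: SubjectProfile,
    ppg: np.ndarray | None = None,
    fs: float | None = None,
    state: str = "rest",
    next_fid: BeatFiducials | None = None,
) -> dict:
    """Build one feature row from a beat's fiducials and its ABP (DBP, SBP).

    Fields whose landmarks are absent come out as NaN.  ``ppg``/``fs`` are
    needed only for the contour descriptors (pulse width at 25% amplitude);
    ``next_fid``, when given, supplies the onset-to-onset (dO) and
    peak-to-peak (dP) wave intervals.
    """
    if fid.rr is None or fid.rr <= 0:
        raise InvalidBeatError(f"beat {fid.beat}: non-positive RR interval")
    dbp, sbp = abp_beat
    r = fid.r_time
    rr = fid.rr
    path = profile.arterial_path_length

    o_pat = _interval(fid.ppg_onset, r)
    p_pat = _interval(fid.ppg_sys_peak, r)
    dia_pat = _interval(fid.dia_peak, r)
    ms_pat = _interval(fid.max_slope, r)

    am = np.nan
    da = np.nan
    if fid.sys_amp is not None and fid.onset_amp is not None:
        am = fid.sys_amp - fid.onset_amp
        if fid.dia_amp is not None and am > 0:
            da = (fid.dia_amp - fid.onset_amp) / am

    row = {
        "subject_id": profile.subject_id,
        "state": state,
        "beat": fid.beat,
        "AM": am,
        "oPAT": o_pat,
        "pPAT": p_pat,
        "diaPAT": dia_pat,
        "msPAT": ms_pat,
        "RoPAT": o_pat / rr,
        "RpPAT": p_pat / rr,
        "oPWV": _pwv(path, o_pat),
        "pPWV": _pwv(path, p_pat),
        "diaPWV": _pwv(path, dia_pat),
        "cT": _interval(fid.ppg_sys_peak, fid.ppg_onset) if fid.ppg_onset is not None else np.nan,
        "rr": rr,
        "DA": da,
        "AM25": _pulse_width_at(fid, ppg, fs, 0.25),
        "slope_BC": _slope_bc(fid, ppg, fs),
        "age": profile.age,
        "height": profile.height,
        "weight": profile.weight,
        "bmi": profile.bmi,
        "SBP": sbp,
        "DBP": dbp,
        "MBP": mean_bp(sbp, dbp) if sbp > dbp > 0 else np.nan,
    }
    row["dO"] = (
        next_fid.ppg_onset - fid.ppg_onset
        if next_fid is not None and next_fid.ppg_onset is not None and fid.ppg_onset is not None
        else np.nan
    )
    row["dP"] = (
        next_fid.ppg_sys_peak - fid.ppg_sys_peak
        if next_fid is not None
        and next_fid.ppg_sys_peak is not None
        and fid.ppg_sys_peak is not None
        else np.nan
    )
    return row


def _pulse_width_at(
    fid: BeatFiducials, ppg: np.ndarray | None, fs: float | None, frac: float
) -> float:
    """Width (s) of the pulse at ``frac`` of its systolic amplitude.

    Provisional contour descriptor: the time between the upstroke and
    downstroke crossings of onset_amp + frac*AM, isolated here so the
    definition can be swapped without touching the table builder.
    """
    if (
        ppg is None
        or fs is None
        or fid.ppg_onset is None
        or fid.ppg_sys_peak is None
        or fid.onset_amp is None
        or fid.sys_amp is None
    ):
        return np.nan
    level = fid.onset_amp + frac * (fid.sys_amp - fid.onset_amp)
    lo = int(round(fid.ppg_onset * fs))
    peak = int(round(fid.ppg_sys_peak * fs))
    hi = min(len(ppg), lo + int(round(fid.rr * fs)))
    if peak <= lo or hi <= peak:
        return np.nan
    up = np.flatnonzero(ppg[lo:peak] >= level)
    down = np.flatnonzero(ppg[peak:hi] <= level)
    if up.size == 0 or down.size == 0:
        return np.nan
    return ((peak + down[0]) - (lo + up[0])) / fs


def _slope_bc(fid: BeatFiducials, ppg: np.ndarray | None, fs: float | None) -> float:
    """Mean second-derivative slope between the b and c waves (provisional)."""
    if ppg is None or fs is None or fid.b_wave is None or fid.c_wave is None:
        return np.nan
    if fid.c_wave <= fid.b_wave:
        return np.nan
    from .preprocess import smooth_window_samples
    from .fiducials import _smooth_derivative

    win = smooth_window_samples(fs, 11.0)
    d2 = _smooth_derivative(_smooth_derivative(np.asarray(ppg, float), fs, win), fs, win)
    bi, ci = int(round(fid.b_wave * fs)), int(round(fid.c_wave * fs))
    if not (0 <= bi < len(d2) and 0 <= ci < len(d2)):
        return np.nan
    return (d2[ci] - d2[bi]) / (fid.c_wave - fid.b_wave)


@dataclass
class BeatFeatureTable:
    """Rectangular per-beat table with cleaning provenance."""

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)


def assemble_beat_table(
    rows: Sequence[Mapping], mask: ExclusionMask | None = None
) -> BeatFeatureTable:
    """Stack per-beat rows, removing beats that intersect the exclusion mask.

    A beat intersects the mask when its cycle window ``[r_time, r_time+rr]``
    overlaps any masked interval; ``r_time``/``rr`` are taken from row keys
    ``_r_time``/``rr`` when present (underscore keys are dropped from the
    output).  Provenance counts are recorded.
    """
    df = pd.DataFrame(list(rows))
    n_before = len(df)
    n_excluded = 0
    if mask is not None and mask.intervals and n_before and "_r_time" in df.columns:
        starts = df["_r_time"].to_numpy(dtype=float)
        ends = starts + df["rr"].to_numpy(dtype=float)
        drop = np.zeros(n_before, dtype=bool)
        for s, e, _ in mask.intervals:
            drop |= (starts < e) & (s < ends)
        n_excluded = int(drop.sum())
        df = df.loc[~drop].reset_index(drop=True)
    df = df.drop(columns=[c for c in df.columns if c.startswith("_")], errors="ignore")
    table = BeatFeatureTable(
        df,
        provenance={
            "n_before": n_before,
            "n_excluded_by_mask": n_excluded,
            "n_after": len(df),
        },
    )
    if len(df) == 0:
        import warnings

        warnings.warn("assembled beat table is empty", stacklevel=2)
    return table


def clean_table(
    table: BeatFeatureTable,
    z_thresh: float = 3.0,
    group_by: Sequence[str] | None = ("subject_id", "state"),
) -> BeatFeatureTable:
    """Apply the two-step cleaning protocol.

    Step 1 drops every row containing at least one missing value.  Step 2
    computes, per numeric column (within each ``group_by`` group, by default
    per subject and state), z-scores with the sample SD of the post-step-1
    table, and drops rows where any |z| exceeds ``z_thresh``.  Constant
    columns cannot produce outliers and are skipped.  Both steps are logged
    in the provenance.
    """
    if z_thresh <= 0:
        raise InvalidParameterError("z_thresh must be positive")
    df = table.data
    n0 = len(df)
    df1 = df.dropna().reset_index(drop=True)
    n1 = len(df1)

    numeric = [
        c
        for c in df1.columns
        if c not in ID_COLUMNS and pd.api.types.is_numeric_dtype(df1[c])
    ]
    group_cols = [c for c in (group_by or []) if c in df1.columns]

    def outlier_mask(sub: pd.DataFrame) -> pd.Series:
        bad = pd.Series(False, index=sub.index)
        for c in numeric:
            x = sub[c].to_numpy(dtype=float)
            sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
            if sd == 0.0 or not np.isfinite(sd):
                continue  # constant column: no outliers possible
            z = (x - float(np.mean(x))) / sd
            bad |= pd.Series(np.abs(z) > z_thresh, index=sub.index)
        return bad

    if group_cols:
        drop = df1.groupby(group_cols, group_keys=False, sort=False).apply(
            outlier_mask, include_groups=False
        )
        drop = drop.reindex(df1.index, fill_value=False)
    else:
        drop = outlier_mask(df1)
    df2 = df1.loc[~drop].reset_index(drop=True)

    provenance = dict(table.provenance)
    provenance.update(
        {
            "n_before_clean": n0,
            "n_after_dropna": n1,
            "n_dropped_nan": n0 - n1,
            "n_dropped_outlier": n1 - len(df2),
            "n_after_clean": len(df2),
            "z_thresh": z_thresh,
            "group_by": list(group_cols),
        }
    )
    return BeatFeatureTable(df2, provenance=provenance)


def build_session_rows(
    fiducials: Sequence[BeatFiducials],
    abp_beats: pd.DataFrame,
    profile: SubjectProfile,
    ppg: np.ndarray | None = None,
    fs: float | None = None,
    state: str = "rest",
) -> list[dict]:
    """Join PPG fiducials with ABP beats on the beat index and build rows.

    Beats missing from the ABP frame (e.g. excluded windows) get NaN
    targets so the dropna step removes them later.  Each row carries a
    private ``_r_time`` key used by :func:`assemble_beat_table` for mask
    intersection.
    """
    abp_by_beat = {int(r.beat): (float(r.DBP), float(r.SBP)) for r in abp_beats.itertuples()}
    rows = []
    for i, fid in enumerate(fiducials):
        dbp, sbp = abp_by_beat.get(fid.beat, (np.nan, np.nan))
        nxt = fiducials[i + 1] if i + 1 < len(fiducials) else None
        row = compute_beat_features(
            fid, (dbp, sbp), profile, ppg=ppg, fs=fs, state=state, next_fid=nxt
        )
        row["_r_time"] = fid.r_time
        rows.append(row)
    return rows
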