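"""Velocity-threshold detection of fixational saccades from binocular gaze.

The pipeline follows the standard median-based adaptive velocity-threshold
approach: blink masking with a 200 ms safety buffer, a five-sample smoothed
derivative, per-component thresholds at six times a median-based estimate of
the velocity SD, an elliptical supra-threshold criterion, duration (>= 6 ms)
and amplitude (3-60 arcmin) filters, merging of events closer than 50 ms,
and a binocular temporal-overlap requirement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import linregress

from .config import (
    DT_S,
    DegenerateInputError,
    InputError,
    MERGE_GAP_MS,
    SAMPLE_RATE,
)

__all__ = [
    "GazeRecording",
    "BlinkMask",
    "build_blink_mask",
    "compute_velocity",
    "estimate_threshold",
    "detect_monocular",
    "filter_saccades",
    "merge_close",
    "binocular_combine",
    "main_sequence_fit",
    "detect_saccades",
]

EVENT_COLUMNS = ["eye", "onset_s", "offset_s", "duration_ms",
                 "amplitude_arcmin", "peak_velocity_deg_s"]


@dataclass
class GazeRecording:
    """Binocular gaze positions (deg) and pupil size, sampled at 500 Hz."""

    time: np.ndarray
    xl: np.ndarray
    yl: np.ndarray
    pl: np.ndarray
    xr: np.ndarray
    yr: np.ndarray
    pr: np.ndarray

    def __post_init__(self):
        n = len(self.time)
        for name in ("xl", "yl", "pl", "xr", "yr", "pr"):
            if len(getattr(self, name)) != n:
                raise InputError("gaze channels must have equal length")

    def __len__(self):
        return len(self.time)

    def eye(self, eye: str):
        if eye == "left":
            return self.xl, self.yl, self.pl
        if eye == "right":
            return self.xr, self.yr, self.pr
        raise InputError(f"unknown eye {eye!r}")


@dataclass
class BlinkMask:
    """Boolean per-sample exclusion mask (True = excluded)."""

    samples: np.ndarray

    def __len__(self):
        return len(self.samples)

    @property
    def intervals(self) -> list[tuple[int, int]]:
        """Sorted, non-overlapping half-open index intervals."""
        m = np.flatnonzero(self.samples)
        if len(m) == 0:
            return []
        breaks = np.flatnonzero(np.diff(m) > 1)
        starts = np.r_[m[0], m[breaks + 1]]
        ends = np.r_[m[breaks] + 1, m[-1] + 1]
        return list(zip(starts.tolist(), ends.tolist()))

    def overlap_ms(self, i0: int, i1: int) -> float:
        """Masked time (ms) within the half-open sample range [i0, i1)."""
        i0 = max(i0, 0)
        i1 = min(i1, len(self.samples))
        if i1 <= i0:
            return 0.0
        return float(self.samples[i0:i1].sum()) * DT_S * 1000.0


def build_blink_mask(rec: GazeRecording, pupil_velocity_limit: float = 50.0,
                     pad_ms: float = 200.0) -> BlinkMask:
    """Mask blink (pupil = 0) and semi-blink (fast pupil change) samples.

    Semi-blinks are samples where the pupil signal changes by more than
    ``pupil_velocity_limit`` tracker units per sample.  Each flagged sample
    is padded by ``pad_ms`` on both sides; the union over both eyes is
    returned.
    """
    bad = np.zeros(len(rec), dtype=bool)
    for pupil in (rec.pl, rec.pr):
        bad |= pupil == 0
        dp = np.abs(np.diff(pupil))
        fast = dp > pupil_velocity_limit
        bad[:-1] |= fast
        bad[1:] |= fast
    pad = int(round(pad_ms / 1000.0 * SAMPLE_RATE))
    if bad.any() and pad > 0:
        bad = ndimage.binary_dilation(bad, np.ones(2 * pad + 1, dtype=bool))
    return BlinkMask(samples=bad)


def compute_velocity(rec: GazeRecording, eye: str,
                     mask: BlinkMask | None = None):
    """Two-dimensional eye velocity (deg/s) from a 5-sample moving window.

    v[n] = (x[n+2] + x[n+1] - x[n-1] - x[n-2]) / (6 dt), the smoothed
    derivative of the classical adaptive-threshold algorithm.  Masked and
    edge samples propagate as NaN.
    """
    x, y, _ = rec.eye(eye)
    if len(x) < 5:
        raise InputError("recording shorter than the 5-sample window")
    x = np.asarray(x, dtype=float).copy()
    y = np.asarray(y, dtype=float).copy()
    if mask is not None:
        x[mask.samples] = np.nan
        y[mask.samples] = np.nan

    def deriv(u):
        v = np.full(len(u), np.nan)
        v[2:-2] = (u[4:] + u[3:-1] - u[1:-3] - u[:-4]) / (6.0 * DT_S)
        return v

    return deriv(x), deriv(y)


def estimate_threshold(vx: np.ndarray, vy: np.ndarray,
                       multiplier: float = 6.0,
                       min_samples: int = 100):
    """Per-component detection thresholds from a median-based velocity SD.

    sigma_k = sqrt(median(v_k^2) - median(v_k)^2) over finite samples and
    eta_k = multiplier * sigma_k.  The median-based estimator is robust to
    the saccades themselves inflating the spread.
    """
    out = []
    for v in (vx, vy):
        v = v[np.isfinite(v)]
        if len(v) < min_samples:
            raise DegenerateInputError(
                f"fewer than {min_samples} unmasked velocity samples")
        med = np.median(v)
        var = np.median(v**2) - med**2
        if var <= 0:
            raise DegenerateInputError("degenerate (constant) velocity trace")
        out.append(multiplier * float(np.sqrt(var)))
    return tuple(out)


def _max_displacement_arcmin(x: np.ndarray, y: np.ndarray) -> float:
    """Maximum pairwise displacement of eye position, in arcmin."""
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    return float(np.sqrt(dx**2 + dy**2).max()) * 60.0


def detect_monocular(time: np.ndarray, x: np.ndarray, y: np.ndarray,
                     vx: np.ndarray, vy: np.ndarray,
                     eta: tuple[float, float], eye: str = "left",
                     min_samples: int = 3) -> pd.DataFrame:
    """Candidate saccades: runs of supra-threshold velocity samples.

    A sample is supra-threshold when (vx/eta_x)^2 + (vy/eta_y)^2 > 1
    (elliptical combination of the two components); maximal runs of at
    least ``min_samples`` consecutive unmasked samples become events.
    Offsets are half-open (one sample past the last supra sample).
    """
    ex, ey = eta
    if ex <= 0 or ey <= 0:
        raise InputError("thresholds must be positive")
    with np.errstate(invalid="ignore"):
        crit = (vx / ex) ** 2 + (vy / ey) ** 2 > 1.0
    crit &= np.isfinite(vx) & np.isfinite(vy)

    rows = []
    padded = np.r_[False, crit, False]
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    for i0, i1 in zip(starts, ends):
        if i1 - i0 < min_samples:
            continue
        speed = np.sqrt(vx[i0:i1] ** 2 + vy[i0:i1] ** 2)
        rows.append({
            "eye": eye,
            "onset_s": float(time[i0]),
            "offset_s": float(time[i1 - 1] + DT_S),
            "duration_ms": (i1 - i0) * DT_S * 1000.0,
            "amplitude_arcmin": _max_displacement_arcmin(x[i0:i1], y[i0:i1]),
            "peak_velocity_deg_s": float(np.max(speed)),
        })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def filter_saccades(events: pd.DataFrame, min_duration_ms: float = 6.0,
                    amplitude_bounds: tuple = (3.0, 60.0)) -> pd.DataFrame:
    """Discard events with duration < 6 ms or amplitude outside 3-60 arcmin."""
    lo, hi = amplitude_bounds
    keep = ((events["duration_ms"] >= min_duration_ms)
            & (events["amplitude_arcmin"] >= lo)
            & (events["amplitude_arcmin"] <= hi))
    return events.loc[keep].reset_index(drop=True)


def merge_close(events: pd.DataFrame, gap_ms: float = MERGE_GAP_MS,
                time=None, x=None, y=None, vx=None, vy=None) -> pd.DataFrame:
    """Merge events separated by less than ``gap_ms`` (overshoot correction).

    Merging is applied transitively until no gap is below the window.  When
    the position/velocity traces are supplied, amplitude and peak velocity
    are recomputed over the merged span; otherwise the maxima of the merged
    events are kept.
    """
    if len(events) == 0:
        return events.copy()
    ev = events.sort_values("onset_s").reset_index(drop=True)
    recs = ev.to_dict("records")
    merged = [recs[0]]
    for nxt in recs[1:]:
        prev = merged[-1]
        if (nxt["onset_s"] - prev["offset_s"]) * 1000.0 < gap_ms:
            prev["offset_s"] = max(prev["offset_s"], nxt["offset_s"])
            prev["duration_ms"] = (prev["offset_s"] - prev["onset_s"]) * 1000.0
            if time is not None:
                t0 = float(time[0])
                i0 = int(round((prev["onset_s"] - t0) / DT_S))
                i1 = int(round((prev["offset_s"] - t0) / DT_S))
                prev["amplitude_arcmin"] = _max_displacement_arcmin(
                    x[i0:i1], y[i0:i1])
                speed = np.sqrt(vx[i0:i1] ** 2 + vy[i0:i1] ** 2)
                prev["peak_velocity_deg_s"] = float(np.nanmax(speed))
            else:
                prev["amplitude_arcmin"] = max(prev["amplitude_arcmin"],
                                               nxt["amplitude_arcmin"])
                prev["peak_velocity_deg_s"] = max(prev["peak_velocity_deg_s"],
                                                  nxt["peak_velocity_deg_s"])
        else:
            merged.append(nxt)
    return pd.DataFrame(merged, columns=EVENT_COLUMNS)


def binocular_combine(left: pd.DataFrame, right: pd.DataFrame) -> pd.DataFrame:
    """Keep saccades that overlap in time across both eyes.

    Events are matched greedily by earliest overlap, each monocular event
    used at most once.  Intervals are half-open, so events that merely touch
    do not overlap.  Binocular parameters are the means across the two eyes.
    """
    li = ri = 0
    rows = []
    l = left.sort_values("onset_s").reset_index(drop=True)
    r = right.sort_values("onset_s").reset_index(drop=True)
    while li < len(l) and ri < len(r):
        a, b = l.iloc[li], r.iloc[ri]
        if a["onset_s"] < b["offset_s"] and b["onset_s"] < a["offset_s"]:
            onset = (a["onset_s"] + b["onset_s"]) / 2.0
            offset = (a["offset_s"] + b["offset_s"]) / 2.0
            rows.append({
                "eye": "binocular",
                "onset_s": onset,
                "offset_s": offset,
                "duration_ms": (offset - onset) * 1000.0,
                "amplitude_arcmin": (a["amplitude_arcmin"]
                                     + b["amplitude_arcmin"]) / 2.0,
                "peak_velocity_deg_s": (a["peak_velocity_deg_s"]
                                        + b["peak_velocity_deg_s"]) / 2.0,
            })
            li += 1
            ri += 1
        elif a["offset_s"] <= b["offset_s"]:
            li += 1
        else:
            ri += 1
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


class MainSequenceFit(NamedTuple):
    slope: float
    intercept: float
    r_squared: float
    n: int


def main_sequence_fit(events: pd.DataFrame, min_events: int = 10) -> MainSequenceFit:
    """OLS of log10 peak velocity on log10 amplitude across saccades."""
    if len(events) < min_events:
        raise InputError(f"need at least {min_events} events")
    la = np.log10(events["amplitude_arcmin"].to_numpy())
    lv = np.log10(events["peak_velocity_deg_s"].to_numpy())
    fit = linregress(la, lv)
    return MainSequenceFit(slope=float(fit.slope), intercept=float(fit.intercept),
                           r_squared=float(fit.rvalue**2), n=len(events))


def detect_saccades(rec: GazeRecording, multiplier: float = 6.0,
                    min_duration_ms: float = 6.0,
                    amplitude_bounds: tuple = (3.0, 60.0),
                    merge_gap_ms: float = MERGE_GAP_MS,
                    pupil_velocity_limit: float = 50.0,
                    pad_ms: float = 200.0):
    """Full detection pass: returns (binocular events, diagnostics dict).

    Thresholds are estimated once per recording over unmasked samples.
    Per-eye pipeline: detect -> duration/amplitude filter -> merge (with
    amplitude recomputation) -> re-filter; then binocular combination.
    """
    mask = build_blink_mask(rec, pupil_velocity_limit, pad_ms)
    per_eye = {}
    diag = {"mask": mask, "thresholds": {}}
    for eye in ("left", "right"):
        vx, vy = compute_velocity(rec, eye, mask)
        eta = estimate_threshold(vx, vy, multiplier)
        diag["thresholds"][eye] = eta
        x, y, _ = rec.eye(eye)
        ev = detect_monocular(rec.time, x, y, vx, vy, eta, eye=eye)
        ev = filter_saccades(ev, min_duration_ms, amplitude_bounds)
        ev = merge_close(ev, merge_gap_ms, time=rec.time, x=x, y=y,
                         vx=vx, vy=vy)
        ev = filter_saccades(ev, min_duration_ms, amplitude_bounds)
        per_eye[eye] = ev
    events = binocular_combine(per_eye["left"], per_eye["right"])
    diag["monocular"] = per_eye
    return events, diag
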