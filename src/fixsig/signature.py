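"""Peri-stimulus saccade-rate and amplitude signatures.

Saccade onsets are epoched into a fixed [-100, 1100) ms window around
stimulus onset, binned at 2 ms, converted to saccades per second, smoothed
with a Savitzky-Golay filter (102 ms window, order 2), normalized by the
individual's baseline rate, and given non-parametric bootstrap confidence
bands (resampling trials with replacement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .config import (
    BIN_MS,
    DT_S,
    EPOCH_END_MS,
    EPOCH_START_MS,
    InputError,
    N_BINS,
    SAMPLE_RATE,
)
from .detection import BlinkMask

__all__ = [
    "EpochedEvents",
    "RateSignature",
    "epoch_trials",
    "epoch_by_condition",
    "compute_signature",
    "smooth_signature",
    "bootstrap_signature",
    "normalize_signature",
    "baseline_rate_of",
]

#: Window and polynomial order of the Savitzky-Golay smoother.
SG_WINDOW_MS = 102.0
SG_ORDER = 2

#: A trial is discarded when blinks mask at least this much of its epoch.
MAX_BLINK_OVERLAP_MS = 100.0

BIN_CENTERS_MS = EPOCH_START_MS + BIN_MS * (np.arange(N_BINS) + 0.5)


@dataclass
class EpochedEvents:
    """Stimulus-locked event times (ms) and amplitudes (arcmin), per trial."""

    times: list          # one array of onset times per valid trial
    amps: list           # matching amplitude arrays (may be empty arrays)
    trial_ids: np.ndarray
    n_invalid: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.times)

    def counts_matrix(self, bin_ms: float = BIN_MS) -> np.ndarray:
        """(n_trials, n_bins) matrix of event counts per time bin."""
        n_bins = int(round((EPOCH_END_MS - EPOCH_START_MS) / bin_ms))
        edges = EPOCH_START_MS + bin_ms * np.arange(n_bins + 1)
        out = np.zeros((self.n_trials, n_bins))
        for i, t in enumerate(self.times):
            if len(t):
                out[i], _ = np.histogram(t, bins=edges)
        return out


@dataclass
class RateSignature:
    """Binned saccade rate (and mean amplitude) around stimulus onset."""

    bins_ms: np.ndarray          # bin centers
    rate: np.ndarray             # saccades/s (dimensionless if normalized)
    amplitude: np.ndarray        # arcmin, NaN where no events fell in a bin
    n_trials: int
    variant: str = "raw"         # raw | smoothed | normalized
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None
    baseline_rate: float | None = None


def _epoch_sample_bounds(onset_s: float) -> tuple[int, int]:
    i0 = int(round((onset_s + EPOCH_START_MS / 1000.0) * SAMPLE_RATE))
    i1 = int(round((onset_s + EPOCH_END_MS / 1000.0) * SAMPLE_RATE))
    return i0, i1


def epoch_trials(event_onsets_s, trial_onsets_s, event_amps=None,
                 mask: BlinkMask | None = None,
                 recording_end_s: float | None = None,
                 trial_ids=None) -> EpochedEvents:
    """Assign detected events to stimulus-locked epochs by onset time.

    Each event is assigned by its onset only, so it is counted exactly once
    even if it straddles the stimulus.  Trials whose epoch extends past the
    recording end, or overlaps a blink mask for at least 100 ms, are dropped.
    """
    event_onsets_s = np.asarray(event_onsets_s, dtype=float)
    order = np.argsort(event_onsets_s)
    event_onsets_s = event_onsets_s[order]
    if event_amps is None:
        event_amps = np.full(len(event_onsets_s), np.nan)
    else:
        event_amps = np.asarray(event_amps, dtype=float)[order]
    trial_onsets_s = np.asarray(trial_onsets_s, dtype=float)
    if trial_ids is None:
        trial_ids = np.arange(len(trial_onsets_s))

    times, amps, kept, n_invalid = [], [], [], 0
    for tid, onset in zip(trial_ids, trial_onsets_s):
        lo = onset + EPOCH_START_MS / 1000.0
        hi = onset + EPOCH_END_MS / 1000.0
        if recording_end_s is not None and hi > recording_end_s:
            n_invalid += 1
            continue
        if mask is not None:
            i0, i1 = _epoch_sample_bounds(onset)
            if mask.overlap_ms(i0, i1) >= MAX_BLINK_OVERLAP_MS:
                n_invalid += 1
                continue
        a = np.searchsorted(event_onsets_s, lo, side="left")
        b = np.searchsorted(event_onsets_s, hi, side="left")
        times.append((event_onsets_s[a:b] - onset) * 1000.0)
        amps.append(event_amps[a:b])
        kept.append(tid)
    return EpochedEvents(times=times, amps=amps,
                         trial_ids=np.asarray(kept), n_invalid=n_invalid)


def epoch_by_condition(events: pd.DataFrame, trials: pd.DataFrame,
                       mask: BlinkMask | None = None,
                       recording_end_s: float | None = None,
                       condition: str = "passive") -> dict:
    """Epoched events per contrast for one trial condition."""
    out = {}
    sel = trials[trials["condition"] == condition]
    for contrast, grp in sel.groupby("contrast"):
        out[float(contrast)] = epoch_trials(
            events["onset_s"].to_numpy(),
            grp["onset_time"].to_numpy(),
            event_amps=events["amplitude_arcmin"].to_numpy(),
            mask=mask, recording_end_s=recording_end_s,
            trial_ids=grp["trial_id"].to_numpy())
    return out


def compute_signature(epoched: EpochedEvents) -> RateSignature:
    """Raw rate signature: mean per-bin count times the sample rate.

    With 2 ms bins the factor 500 converts the mean count per bin into
    saccades per second.  Mean amplitude pools events over trials per bin;
    bins with no events carry NaN.
    """
    if epoched.n_trials < 1:
        raise InputError("no valid trials")
    counts = epoched.counts_matrix()
    rate = counts.mean(axis=0) * SAMPLE_RATE

    edges = EPOCH_START_MS + BIN_MS * np.arange(N_BINS + 1)
    amp_sum = np.zeros(N_BINS)
    amp_n = np.zeros(N_BINS)
    for t, a in zip(epoched.times, epoched.amps):
        if len(t) == 0:
            continue
        idx = np.clip(np.digitize(t, edges) - 1, 0, N_BINS - 1)
        np.add.at(amp_sum, idx, a)
        np.add.at(amp_n, idx, 1)
    with np.errstate(invalid="ignore"):
        amplitude = np.where(amp_n > 0, amp_sum / np.maximum(amp_n, 1), np.nan)
    return RateSignature(bins_ms=BIN_CENTERS_MS.copy(), rate=rate,
                         amplitude=amplitude, n_trials=epoched.n_trials)


def _sg_window_bins() -> int:
    w = int(round(SG_WINDOW_MS / BIN_MS))
    return w + 1 if w % 2 == 0 else w


def _smooth(arr: np.ndarray) -> np.ndarray:
    return savgol_filter(arr, _sg_window_bins(), SG_ORDER, mode="mirror")


def _interp_nan(arr: np.ndarray) -> np.ndarray:
    out = arr.copy()
    bad = ~np.isfinite(out)
    if bad.all() or not bad.any():
        return out
    idx = np.arange(len(out))
    out[bad] = np.interp(idx[bad], idx[~bad], out[~bad])
    return out


def smooth_signature(sig: RateSignature) -> RateSignature:
    """Savitzky-Golay smoothing (102 ms window, order 2, mirrored edges).

    Negative smoothed rates are clipped to zero.  The amplitude trace is
    linearly interpolated across empty bins before smoothing.
    """
    rate = np.clip(_smooth(sig.rate), 0.0, None)
    amp = sig.amplitude
    if np.isfinite(amp).any():
        amp = _smooth(_interp_nan(amp))
    return dc_replace(sig, rate=rate, amplitude=amp, variant="smoothed")


def bootstrap_signature(epoched: EpochedEvents, B: int = 10_000,
                        seed=None, rng=None, smooth: bool = True) -> RateSignature:
    """Smoothed signature with 95% bootstrap confidence bands.

    Trials are resampled with replacement B times; each resampled mean rate
    is smoothed (so the band is consistent with the displayed smoothed
    mean) and the 2.5/97.5 percentiles are taken per bin.
    """
    if epoched.n_trials < 2:
        raise InputError("bootstrap needs at least 2 valid trials")
    if B < 100:
        warnings.warn("fewer than 100 bootstrap repeats; CIs will be crude")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = epoched.counts_matrix()
    n = epoched.n_trials
    weights = rng.multinomial(n, np.full(n, 1.0 / n), size=B)
    rates = (weights @ counts) * (SAMPLE_RATE / n)
    sig = compute_signature(epoched)
    if smooth:
        rates = savgol_filter(rates, _sg_window_bins(), SG_ORDER,
                              mode="mirror", axis=1)
        rates = np.clip(rates, 0.0, None)
        sig = smooth_signature(sig)
    lo, hi = np.percentile(rates, [2.5, 97.5], axis=0)
    return dc_replace(sig, ci_lo=lo, ci_hi=hi)


def normalize_signature(sig: RateSignature, baseline_rate: float) -> RateSignature:
    """Express the rate (and CIs) in units of the individual baseline rate."""
    if baseline_rate <= 0:
        raise InputError("baseline_rate must be positive")
    return dc_replace(
        sig,
        rate=sig.rate / baseline_rate,
        ci_lo=None if sig.ci_lo is None else sig.ci_lo / baseline_rate,
        ci_hi=None if sig.ci_hi is None else sig.ci_hi / baseline_rate,
        variant="normalized",
        baseline_rate=baseline_rate,
    )


def baseline_rate_of(sig: RateSignature) -> float:
    """Individual baseline rate: epoch-mean smoothed rate of the 0% condition."""
    if sig.variant == "raw":
        sig = smooth_signature(sig)
    return float(sig.rate.mean())


def signature_frame(sig: RateSignature) -> pd.DataFrame:
    """Tabular form (bin_ms, rate, ci_lo, ci_hi, amplitude)."""
    return pd.DataFrame({
        "bin_ms": sig.bins_ms,
        "rate": sig.rate,
        "ci_lo": np.nan if sig.ci_lo is None else sig.ci_lo,
        "ci_hi": np.nan if sig.ci_hi is None else sig.ci_hi,
        "amplitude": sig.amplitude,
    })
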