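"""Synthetic binocular gaze sessions with a contrast-dependent rate signature.

The generator produces the statistical structure the downstream analysis
assumes: fixational saccades as an inhomogeneous point process whose rate is
modulated biphasically after stimulus onset (inhibition then rebound, both
growing with log contrast through a shared logistic link), main-sequence
amplitude/velocity coupling, an amplitude dip during inhibition, slow ocular
drift, tracker noise, blinks, and 2AFC responses governed by a psychometric
function that shares the oculomotor sensitivity parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit

from .config import (
    DEAD_TIME_MS,
    DT_S,
    EPOCH_END_MS,
    EPOCH_START_MS,
    InputError,
    SAMPLE_RATE,
    SimulationConfig,
)

__all__ = [
    "modulation_profile",
    "contrast_drive",
    "sample_event_times",
    "sample_epoched_trials",
    "synthesize_recording",
    "simulate_responses",
    "GroundTruth",
]


# ---------------------------------------------------------------------------
# Rate modulation
# ---------------------------------------------------------------------------

def contrast_drive(config: SimulationConfig, contrast: float) -> float:
    """Logistic drive L(c) in [0, 1) shared by inhibition, rebound and 2AFC.

    L is a logistic in log10 contrast with the configured midpoint and
    slope; L(0) = 0 by continuity (no stimulus, no modulation).
    """
    if contrast < 0:
        raise InputError("contrast must be non-negative")
    if contrast == 0:
        return 0.0
    x = (np.log10(contrast) - config.sensitivity_midpoint)
    return float(expit(x / config.sensitivity_slope))


def _bump(t_ms: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - mu) / sd) ** 2)


def _anchored_coeffs(config: SimulationConfig, drive: float):
    """Coefficients of the two-bump mixture, calibrated so that the profile
    equals exactly 1 - depth at the inhibition latency and 1 + gain at the
    rebound latency despite the overlap of the two Gaussian bumps."""
    d = config.inhibition_depth_max * drive
    g = config.rebound_gain_max * drive
    gap = config.rebound_latency - config.inhibition_latency
    e1 = np.exp(-0.5 * (gap / config.rebound_width) ** 2)
    e2 = np.exp(-0.5 * (gap / config.inhibition_width) ** 2)
    b = (g + d * e2) / (1.0 - e1 * e2)
    a = d + b * e1
    return a, b


def modulation_profile(config: SimulationConfig, contrast: float,
                       t_ms: np.ndarray) -> np.ndarray:
    """Dimensionless rate multiplier m(t; c) on the peri-stimulus time grid.

    m(t) = 1 - a * G(t; mu_inh, sd_inh) + b * G(t; mu_reb, sd_reb), with unit
    peak Gaussian bumps and (a, b) solved so that m(mu_inh) = 1 - depth(c)
    and m(mu_reb) = 1 + gain(c).  m(t) = 1 identically at zero contrast and
    the profile is clipped at zero (a rate multiplier cannot be negative).
    """
    t_ms = np.asarray(t_ms, dtype=float)
    drive = contrast_drive(config, contrast)
    if drive == 0.0:
        return np.ones_like(t_ms)
    a, b = _anchored_coeffs(config, drive)
    shift = config.latency_shift_max * drive
    mu_i = config.inhibition_latency - shift
    mu_r = config.rebound_latency - shift
    m = (1.0
         - a * _bump(t_ms, mu_i, config.inhibition_width)
         + b * _bump(t_ms, mu_r, config.rebound_width))
    return np.clip(m, 0.0, None)


# ---------------------------------------------------------------------------
# Event-time sampling
# ---------------------------------------------------------------------------

def _hazard(rate_per_ms: np.ndarray | float):
    """Dead-time-compensated hazard so the observed rate matches the target.

    A renewal process with absolute dead time tau and post-dead-time hazard
    h has mean rate h / (1 + h tau); inverting gives h = r / (1 - r tau).
    """
    tau = DEAD_TIME_MS
    return rate_per_ms / (1.0 - rate_per_ms * tau)


def sample_event_times(config: SimulationConfig, contrast: float,
                       rng=None, t_start_ms: float = EPOCH_START_MS,
                       t_end_ms: float = EPOCH_END_MS,
                       seed=None) -> np.ndarray:
    """Saccade onset times (ms, stimulus-locked) for one trial epoch.

    Events are drawn by thinning an inhomogeneous process with rate
    baseline_rate * m(t; c) and a 50 ms absolute dead time matching the
    detection-side merge window, so generated events are never closer than
    50 ms.  The hazard is dead-time compensated and the sampler starts in
    the stationary state of the baseline renewal process, so the observed
    baseline rate equals ``config.baseline_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if config.baseline_rate == 0:
        return np.asarray([], dtype=float)

    # 1 ms lookup grid of the dead-time-compensated hazard.
    grid = np.arange(t_start_ms, t_end_ms + 1.0, 1.0)
    rate = config.baseline_rate / 1000.0 * modulation_profile(
        config, contrast, grid)
    hz = _hazard(rate)
    hmax = float(hz.max())
    if hmax <= 0:
        return np.asarray([], dtype=float)

    # Stationary initialization: with probability r*tau the process is
    # inside a dead time at epoch start (residual uniform on [0, tau)).
    t = t_start_ms
    if rng.random() < rate[0] * DEAD_TIME_MS:
        t += rng.random() * DEAD_TIME_MS

    out = []
    while True:
        t += rng.exponential(1.0 / hmax)
        if t >= t_end_ms:
            break
        idx = int(t - t_start_ms)
        if rng.random() * hmax < hz[idx]:
            out.append(t)
            t += DEAD_TIME_MS
    return np.asarray(out, dtype=float)


def _draw_amplitudes(config: SimulationConfig, contrast: float,
                     times_ms: np.ndarray, rng) -> np.ndarray:
    """Amplitudes (arcmin) around the configured mean, dipped for events
    inside the inhibition window, redrawn into the detectable 3-60 band."""
    drive = contrast_drive(config, contrast)
    mu = np.full(times_ms.shape, config.amplitude_mean, dtype=float)
    in_dip = np.abs(times_ms - config.inhibition_latency) <= config.inhibition_width
    mu[in_dip] -= config.amplitude_dip * drive
    amps = rng.normal(mu, config.amplitude_sd)
    bad = (amps < 3.0) | (amps > 60.0)
    while np.any(bad):
        amps[bad] = rng.normal(mu[bad], config.amplitude_sd)
        bad = (amps < 3.0) | (amps > 60.0)
    return amps


def sample_epoched_trials(config: SimulationConfig, contrast: float,
                          n_trials: int, rng=None, seed=None):
    """Event-level simulation of ``n_trials`` stimulus-locked epochs.

    Returns (times, amps): two lists of per-trial arrays, onset times in ms
    relative to stimulus onset and amplitudes in arcmin.  This is the
    generator output one obtains after a lossless detection pass, and is
    what the signature / classifier stages consume.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    times, amps = [], []
    for _ in range(n_trials):
        t = sample_event_times(config, contrast, rng=rng)
        times.append(t)
        amps.append(_draw_amplitudes(config, contrast, t, rng))
    return times, amps


# ---------------------------------------------------------------------------
# Full recording synthesis
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Injected events and blink intervals of a synthetic recording."""

    events: pd.DataFrame           # time_s, amplitude_arcmin, peak_velocity_deg_s
    blink_intervals: list = field(default_factory=list)  # (start_s, end_s)


def _make_trial_table(config: SimulationConfig, rng,
                      n_passive=None, n_response=None) -> pd.DataFrame:
    n_passive = config.n_passive if n_passive is None else n_passive
    n_response = config.n_response if n_response is None else n_response
    rows = []
    for c in config.contrasts:
        rows += [(float(c), "passive")] * n_passive
        if c > 0:
            rows += [(float(c), "response")] * n_response
    rng.shuffle(rows)
    onset = 1.0
    onsets, itis = [], rng.uniform(*config.iti_range, size=len(rows))
    for i in range(len(rows)):
        onsets.append(onset)
        onset += (EPOCH_END_MS / 1000.0) + itis[i]
    df = pd.DataFrame({
        "trial_id": np.arange(len(rows)),
        "onset_time": onsets,
        "contrast": [r[0] for r in rows],
        "condition": [r[1] for r in rows],
    })
    ori = rng.choice([-45.0, 45.0], size=len(df))
    ori[df["contrast"] == 0.0] = np.nan
    df["orientation"] = ori
    df["response_correct"] = pd.array([pd.NA] * len(df), dtype="boolean")
    return df


def _session_rate(config: SimulationConfig, trials: pd.DataFrame,
                  n_samples: int) -> np.ndarray:
    """Per-sample target event rate (events/s) over the whole session."""
    rate = np.full(n_samples, config.baseline_rate, dtype=float)
    epoch_len = int(round((EPOCH_END_MS - EPOCH_START_MS) / 1000.0 * SAMPLE_RATE))
    rel_ms = (np.arange(epoch_len) * DT_S * 1000.0) + EPOCH_START_MS
    for onset, contrast in zip(trials["onset_time"], trials["contrast"]):
        if contrast <= 0:
            continue
        i0 = int(round((onset + EPOCH_START_MS / 1000.0) * SAMPLE_RATE))
        i1 = min(i0 + epoch_len, n_samples)
        m = modulation_profile(config, contrast, rel_ms[: i1 - i0])
        rate[i0:i1] = config.baseline_rate * m
    return rate


def _sample_session_events(rate: np.ndarray, rng) -> np.ndarray:
    """Event times (s) over a session given a per-sample rate, with the
    50 ms dead time and dead-time-compensated hazard."""
    hz = _hazard(rate / 1000.0) * 1000.0   # events/s hazard
    hmax = float(hz.max())
    if hmax <= 0:
        return np.asarray([], dtype=float)
    t_end = len(rate) * DT_S
    t = 0.0
    if rng.random() < rate[0] * (DEAD_TIME_MS / 1000.0):
        t += rng.random() * DEAD_TIME_MS / 1000.0
    out = []
    while True:
        t += rng.exponential(1.0 / hmax)
        if t >= t_end:
            break
        if rng.random() * hmax < hz[int(t * SAMPLE_RATE)]:
            out.append(t)
            t += DEAD_TIME_MS / 1000.0
    return np.asarray(out)


def _render_saccades(n_samples: int, times_s: np.ndarray,
                     dx_deg: np.ndarray, dy_deg: np.ndarray,
                     tau_s: np.ndarray, rng, jitter_sd_ms: float):
    """Sum of smooth sigmoidal displacement waveforms on the sample grid.

    Each saccade moves the eye by (dx, dy) along a logistic time course with
    scale tau; the waveform is rendered locally and the full displacement is
    carried forward as a step.  Returns (x, y) in degrees.
    """
    x_local = np.zeros(n_samples)
    y_local = np.zeros(n_samples)
    x_step = np.zeros(n_samples + 1)
    y_step = np.zeros(n_samples + 1)
    jit = rng.normal(0.0, jitter_sd_ms / 1000.0, size=len(times_s))
    for t0, dx, dy, tau, j in zip(times_s, dx_deg, dy_deg, tau_s, jit):
        tc = t0 + 3.0 * tau + j   # waveform midpoint; onset ~ t0
        half = max(8.0 * tau, 5 * DT_S)
        i0 = max(int((tc - half) * SAMPLE_RATE), 0)
        i1 = min(int((tc + half) * SAMPLE_RATE) + 1, n_samples)
        if i1 <= i0:
            continue
        tt = np.arange(i0, i1) * DT_S
        w = expit((tt - tc) / tau)
        x_local[i0:i1] += dx * w
        y_local[i0:i1] += dy * w
        x_step[i1] += dx
        y_step[i1] += dy
    x = x_local + np.cumsum(x_step)[:n_samples]
    y = y_local + np.cumsum(y_step)[:n_samples]
    return x, y


def _ou_drift(n_samples: int, sd_deg: float, timescale_s: float, rng):
    """Mean-reverting (Ornstein-Uhlenbeck) drift, stationary from sample 0."""
    if sd_deg == 0:
        return np.zeros(n_samples)
    rho = np.exp(-DT_S / timescale_s)
    w = rng.normal(0.0, sd_deg * np.sqrt(1.0 - rho**2), size=n_samples)
    w[0] = rng.normal(0.0, sd_deg)
    return lfilter([1.0], [1.0, -rho], w)


def synthesize_recording(config: SimulationConfig, seed=None,
                         n_passive=None, n_response=None):
    """Render a full binocular gaze recording for one synthetic session.

    Returns ``(recording, trials, truth)`` where ``recording`` is a
    :class:`fixsig.detection.GazeRecording`, ``trials`` the trial table
    (responses not yet filled; see :func:`simulate_responses`) and ``truth``
    a :class:`GroundTruth` with the injected events.

    Identical (config, seed) pairs give bit-identical outputs.
    """
    from .detection import GazeRecording

    rng = np.random.default_rng(config.seed if seed is None else seed)
    trials = _make_trial_table(config, rng, n_passive, n_response)
    duration = float(trials["onset_time"].iloc[-1]) + EPOCH_END_MS / 1000.0 + 0.5
    n = int(round(duration * SAMPLE_RATE))

    rate = _session_rate(config, trials, n)
    ev_times = _sample_session_events(rate, rng)

    # Amplitude: dipped inside the inhibition window of the governing trial.
    onsets = trials["onset_time"].to_numpy()
    contrasts = trials["contrast"].to_numpy()
    idx = np.clip(np.searchsorted(onsets, ev_times) - 1, 0, len(onsets) - 1)
    rel_ms = (ev_times - onsets[idx]) * 1000.0
    in_epoch = (rel_ms >= EPOCH_START_MS) & (rel_ms < EPOCH_END_MS)
    amps = np.empty(len(ev_times))
    for k, (t_rel, tri, ok) in enumerate(zip(rel_ms, idx, in_epoch)):
        c = contrasts[tri] if ok else 0.0
        amps[k] = _draw_amplitudes(config, c, np.asarray([t_rel]), rng)[0]

    amp_deg = amps / 60.0
    log_pv = (config.main_sequence_intercept
              + config.main_sequence_slope * np.log10(amp_deg)
              + rng.normal(0.0, config.main_sequence_scatter, size=len(amps)))
    peak_vel = 10.0 ** log_pv                      # deg/s
    tau = amp_deg / (4.0 * peak_vel)               # logistic time scale, s

    # Directions: weakly re-centering so gaze stays near fixation.
    fx = fy = 0.0
    dx = np.empty(len(amps))
    dy = np.empty(len(amps))
    for k in range(len(amps)):
        theta = np.arctan2(-fy, -fx) if (fx or fy) else rng.uniform(0, 2 * np.pi)
        theta += rng.normal(0.0, 0.7)
        dx[k] = amp_deg[k] * np.cos(theta)
        dy[k] = amp_deg[k] * np.sin(theta)
        fx += dx[k]
        fy += dy[k]

    sd_deg = config.drift_sd / 60.0
    noise_deg = config.noise_sd / 60.0
    eyes = {}
    for eye in ("L", "R"):
        sx, sy = _render_saccades(n, ev_times, dx, dy, tau, rng,
                                  config.binocular_jitter_sd)
        ex = sx + _ou_drift(n, sd_deg, config.drift_timescale, rng) \
            + rng.normal(0.0, noise_deg, size=n)
        ey = sy + _ou_drift(n, sd_deg, config.drift_timescale, rng) \
            + rng.normal(0.0, noise_deg, size=n)
        eyes[eye] = (ex, ey)

    # Blinks: pupil drops to exactly 0, position is corrupted.
    pupil_l = np.full(n, 1000.0)
    pupil_r = np.full(n, 1000.0)
    n_blinks = rng.poisson(config.blink_rate * duration / 60.0)
    blink_intervals = []
    for t0 in np.sort(rng.uniform(0.0, duration, size=n_blinks)):
        dur = rng.uniform(*config.blink_duration_range) / 1000.0
        i0 = int(t0 * SAMPLE_RATE)
        i1 = min(int((t0 + dur) * SAMPLE_RATE), n)
        if i1 <= i0:
            continue
        blink_intervals.append((i0 * DT_S, i1 * DT_S))
        pupil_l[i0:i1] = 0.0
        pupil_r[i0:i1] = 0.0
        for eye in ("L", "R"):
            eyes[eye][0][i0:i1] += 2.0
            eyes[eye][1][i0:i1] -= 2.0

    time = np.arange(n) * DT_S
    rec = GazeRecording(time=time,
                        xl=eyes["L"][0], yl=eyes["L"][1], pl=pupil_l,
                        xr=eyes["R"][0], yr=eyes["R"][1], pr=pupil_r)
    truth = GroundTruth(
        events=pd.DataFrame({
            "time_s": ev_times,
            "amplitude_arcmin": amps,
            "peak_velocity_deg_s": peak_vel,
        }),
        blink_intervals=blink_intervals,
    )
    return rec, trials, truth


# ---------------------------------------------------------------------------
# Behavioural responses
# ---------------------------------------------------------------------------

def simulate_responses(config: SimulationConfig, trials: pd.DataFrame,
                       rng=None, seed=None) -> pd.DataFrame:
    """Fill 2AFC correctness for response trials.

    P(correct | c) = 0.5 + 0.5 * L(c), with L the same logistic drive that
    scales the rate signature, so the behavioural threshold (75% correct)
    coincides with the oculomotor sensitivity midpoint by construction.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    trials = trials.copy()
    resp = trials["condition"] == "response"
    p = np.asarray([0.5 + 0.5 * contrast_drive(config, c)
                    for c in trials.loc[resp, "contrast"]])
    draws = rng.random(int(resp.sum())) < p
    col = pd.array([pd.NA] * len(trials), dtype="boolean")
    col[np.flatnonzero(resp.to_numpy())] = draws
    trials["response_correct"] = col
    return trials
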