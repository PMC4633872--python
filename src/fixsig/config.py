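"""Simulation configuration and shared constants.

All epoch-relative times are in milliseconds, absolute recording times in
seconds, gaze positions in degrees of visual angle, saccade amplitudes in
arcmin, rates in events per second (blink rate per minute).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

#: Tracker sampling rate (Hz).  The analysis assumes 500 Hz throughout.
SAMPLE_RATE = 500
DT_S = 1.0 / SAMPLE_RATE

#: Peri-stimulus epoch bounds (ms) and fine binning of the rate signature.
EPOCH_START_MS = -100.0
EPOCH_END_MS = 1100.0
BIN_MS = 2.0
N_BINS = int((EPOCH_END_MS - EPOCH_START_MS) / BIN_MS)  # 600

#: Post-detection merge window and the matching generator dead time (ms).
MERGE_GAP_MS = 50.0
DEAD_TIME_MS = 50.0


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class InputError(ValueError):
    """Invalid argument to an analysis operation."""


class DegenerateInputError(InputError):
    """Input is formally valid but carries no usable signal."""


def default_contrasts() -> list[float]:
    """Twelve log-spaced contrasts spanning 0.7-4% plus a 0% blank."""
    levels = np.geomspace(0.7, 4.0, 12)
    return [0.0] + [float(round(c, 4)) for c in levels]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic fixational-saccade session.

    The defaults describe an average observer: a baseline fixational
    saccade rate of 1.5 per second, a stimulus-locked inhibition dropping
    the normalized rate to 0.5 at 180 ms, a rebound peaking at 2.0 times
    baseline at 420 ms, and a logistic contrast dependence of both phases
    with midpoint at 2% contrast.  Saccade kinematics follow a unit-slope
    log-log main sequence (80 deg/s at 1 degree amplitude).
    """

    # Rate signature
    baseline_rate: float = 1.5          # saccades / s with no stimulus
    inhibition_depth_max: float = 0.5   # normalized rate drop at saturation
    inhibition_latency: float = 180.0   # ms
    inhibition_width: float = 80.0      # ms (Gaussian SD of the trough)
    rebound_gain_max: float = 1.0       # normalized rate rise at saturation
    rebound_latency: float = 420.0      # ms
    rebound_width: float = 120.0        # ms
    # Contrast sensitivity (shared by oculomotor and behavioural links)
    sensitivity_midpoint: float = math.log10(2.0)  # log10(% contrast)
    sensitivity_slope: float = 0.1      # log10-contrast units
    # Saccade kinematics
    amplitude_mean: float = 21.0        # arcmin
    amplitude_sd: float = 8.0           # arcmin
    amplitude_dip: float = 4.0          # arcmin, reduction inside inhibition
    main_sequence_slope: float = 1.0    # log10(deg/s) per log10(deg)
    main_sequence_intercept: float = math.log10(80.0)  # log10(deg/s) at 1 deg
    main_sequence_scatter: float = 0.04  # SD of log10 peak velocity residual
    # Fixation instability and measurement noise
    drift_sd: float = 3.0               # arcmin, stationary SD of slow drift
    drift_timescale: float = 4.0        # s, mean-reversion time of the drift
    noise_sd: float = 0.3               # arcmin, white tracker noise per axis
    binocular_jitter_sd: float = 1.0    # ms, onset offset between the eyes
    blink_rate: float = 1.0             # blinks / minute
    blink_duration_range: tuple = (200.0, 400.0)  # ms
    # Optional latency shortening with contrast (ms at saturation); the
    # threshold estimators do not use latencies, so this is off by default.
    latency_shift_max: float = 0.0
    # Session design
    sample_rate: int = SAMPLE_RATE
    contrasts: list = field(default_factory=default_contrasts)  # % values
    n_passive: int = 900
    n_response: int = 250
    iti_range: tuple = (1.0, 1.4)       # s, uniform inter-trial interval
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.inhibition_depth_max <= 1.0:
            raise ConfigError("inhibition_depth_max must be in [0, 1]")
        if self.rebound_gain_max < 0:
            raise ConfigError("rebound_gain_max must be >= 0")
        for name in ("inhibition_latency", "inhibition_width",
                     "rebound_latency", "rebound_width"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.sample_rate != SAMPLE_RATE:
            raise ConfigError(f"sample_rate is fixed at {SAMPLE_RATE} Hz")
        contrasts = np.asarray(self.contrasts, dtype=float)
        if np.any(contrasts < 0):
            raise ConfigError("contrasts must be non-negative")
        if int(np.sum(contrasts == 0.0)) > 1:
            raise ConfigError("at most one 0% baseline contrast is allowed")
        lo, hi = self.iti_range
        if not lo <= hi:
            raise ConfigError("iti_range bounds must be ordered")
        if self.baseline_rate < 0:
            raise ConfigError("baseline_rate must be >= 0")
        # The thinning sampler compensates for the 50 ms dead time; the
        # correction requires the instantaneous rate to stay below 1/dead.
        peak = self.baseline_rate * (1.0 + self.rebound_gain_max)
        if peak * (DEAD_TIME_MS / 1000.0) >= 0.95:
            raise ConfigError(
                "peak rate too high for the 50 ms generator dead time")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["contrasts"] = list(map(float, d["contrasts"]))
        d["iti_range"] = list(d["iti_range"])
        d["blink_duration_range"] = list(d["blink_duration_range"])
        return d

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("iti_range", "blink_duration_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from a master seed."""
    import hashlib

    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
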