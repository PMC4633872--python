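"""Delimited-text readers/writers, run manifests and the pipeline driver.

All tables are comma-separated UTF-8 with a header row and '.' decimals.
Gaze files carry absolute time in seconds and positions in degrees; epoch
tables carry milliseconds.  Parsers validate rather than coerce: a missing
column, a non-numeric cell or a sampling gap raises a typed error naming
the offending row.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .config import DT_S, SimulationConfig, stage_seed
from .detection import EVENT_COLUMNS, GazeRecording

__all__ = [
    "ParseError",
    "SamplingError",
    "read_gaze",
    "write_gaze",
    "read_trials",
    "write_trials",
    "read_events",
    "write_events",
    "RunManifest",
    "run_pipeline",
]

GAZE_COLUMNS = ["time_s", "xL_deg", "yL_deg", "pupilL",
                "xR_deg", "yR_deg", "pupilR"]
TRIAL_COLUMNS = ["trial_id", "onset_time", "contrast", "condition",
                 "orientation", "response_correct"]

#: Allowed deviation of the sample interval from 2 ms (seconds).
SAMPLING_TOL_S = 1e-6


class ParseError(ValueError):
    """Malformed table content."""


class SamplingError(ParseError):
    """Gaze samples are not uniform at 500 Hz."""


def _numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value in column {col!r} at row {row}")
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ParseError(f"{path}: missing value in {col!r} at row {row}")
        df[col] = coerced.astype(float)
    return df


def write_gaze(rec: GazeRecording, path) -> None:
    pd.DataFrame({
        "time_s": rec.time, "xL_deg": rec.xl, "yL_deg": rec.yl,
        "pupilL": rec.pl, "xR_deg": rec.xr, "yR_deg": rec.yr,
        "pupilR": rec.pr,
    }).to_csv(path, index=False, float_format="%.6f")


def read_gaze(path) -> GazeRecording:
    """Read and validate a gaze table (uniform 500 Hz, numeric cells)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df = _numeric(df, GAZE_COLUMNS, path)
    t = df["time_s"].to_numpy()
    if len(t) >= 2:
        dt = np.diff(t)
        bad = np.abs(dt - DT_S) > SAMPLING_TOL_S
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise SamplingError(
                f"{path}: non-uniform sampling at row {row} "
                f"(interval {dt[row - 1]:.6f} s, expected {DT_S:.6f} s)")
    return GazeRecording(time=t,
                         xl=df["xL_deg"].to_numpy(), yl=df["yL_deg"].to_numpy(),
                         pl=df["pupilL"].to_numpy(),
                         xr=df["xR_deg"].to_numpy(), yr=df["yR_deg"].to_numpy(),
                         pr=df["pupilR"].to_numpy())


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    onsets = df["onset_time"].to_numpy()
    if np.any(np.diff(onsets) <= 0):
        row = int(np.flatnonzero(np.diff(onsets) <= 0)[0]) + 1
        raise ParseError(f"{path}: trial onsets not increasing at row {row}")
    df["response_correct"] = df["response_correct"].astype("boolean")
    return df


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False, float_format="%.6f")


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: config, seeds and output digests."""

    config: dict
    master_seed: int
    stage_seeds: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)
    stages_completed: list = field(default_factory=list)
    version: str = __version__

    def add_file(self, path) -> None:
        self.files[os.path.basename(str(path))] = _sha256(path)

    def write(self, path) -> None:
        tmp = f"{path}.tmp"
        with open(tmp, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
        os.replace(tmp, path)


def run_pipeline(config: SimulationConfig, out_dir, seed: int,
                 stages=("simulate", "detect", "signature", "features",
                         "classify"),
                 n_per_sample: int = 30, boot: int = 100) -> RunManifest:
    """Single-subject pipeline: simulate -> detect -> signature -> thresholds.

    Each stochastic stage draws from a seed derived deterministically from
    the master seed and the stage name; rerunning with the same config and
    seed reproduces every output bit for bit.
    """
    from . import classifier as clf
    from . import detection, features, signature, simulate

    os.makedirs(out_dir, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), master_seed=seed)

    def p(name):
        return os.path.join(out_dir, name)

    rec = trials = events = mask = None
    try:
        if "simulate" in stages:
            s = stage_seed(seed, "simulate")
            manifest.stage_seeds["simulate"] = s
            rec, trials, _ = simulate.synthesize_recording(config, seed=s)
            trials = simulate.simulate_responses(
                config, trials, seed=stage_seed(seed, "responses"))
            write_gaze(rec, p("gaze.csv"))
            write_trials(trials, p("trials.csv"))
            manifest.add_file(p("gaze.csv"))
            manifest.add_file(p("trials.csv"))
            manifest.stages_completed.append("simulate")

        if "detect" in stages:
            if rec is None:
                rec = read_gaze(p("gaze.csv"))
                trials = read_trials(p("trials.csv"))
            events, diag = detection.detect_saccades(rec)
            mask = diag["mask"]
            write_events(events, p("events.csv"))
            manifest.add_file(p("events.csv"))
            manifest.stages_completed.append("detect")

        epoched = norm_sigs = baseline = None
        if "signature" in stages:
            end_s = float(rec.time[-1]) + DT_S
            epoched = signature.epoch_by_condition(events, trials, mask, end_s)
            blank = epoched.get(0.0)
            if blank is None:
                raise ParseError("no 0% baseline condition in trials")
            base_sig = signature.smooth_signature(
                signature.compute_signature(blank))
            baseline = signature.baseline_rate_of(base_sig)
            norm_sigs = {}
            for c, ep in epoched.items():
                sig = signature.bootstrap_signature(
                    ep, B=boot, seed=stage_seed(seed, f"boot{c}"))
                norm_sigs[c] = signature.normalize_signature(sig, baseline)
                frame = signature.signature_frame(norm_sigs[c])
                frame.to_csv(p(f"signature_{c:g}.csv"), index=False)
                manifest.add_file(p(f"signature_{c:g}.csv"))
            manifest.stages_completed.append("signature")

        if "features" in stages and norm_sigs is not None:
            rows = []
            for c in sorted(norm_sigs):
                if c == 0:
                    continue
                f = features.extract_features(norm_sigs[c])
                rows.append({"contrast": c, **f.__dict__})
            feat = pd.DataFrame(rows)
            feat.to_csv(p("features.csv"), index=False)
            manifest.add_file(p("features.csv"))
            if len(feat) >= 5:   # logistic fit needs enough contrast levels
                fit = features.fit_feature_logistic(
                    feat["contrast"], feat["inhibition_magnitude"],
                    value_bounds=(0.0, 1.5))
                with open(p("feature_fit.json"), "w", encoding="utf-8") as fh:
                    json.dump(fit.__dict__, fh, indent=2)
                manifest.add_file(p("feature_fit.json"))
            manifest.stages_completed.append("features")

        if "classify" in stages and epoched is not None:
            curve = clf.classifier_curve(
                {c: ep for c, ep in epoched.items() if c > 0}, epoched[0.0],
                baseline_rate=baseline, n_per_sample=n_per_sample, B=1,
                seed=stage_seed(seed, "classify"))
            pd.DataFrame({"contrast": curve.contrasts,
                          "percent_correct": curve.percent_correct}
                         ).to_csv(p("classifier_curve.csv"), index=False)
            manifest.add_file(p("classifier_curve.csv"))
            manifest.stages_completed.append("classify")
    finally:
        manifest.write(p("manifest.json"))
    return manifest
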