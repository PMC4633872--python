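"""Threshold comparison metrics and generalization experiments.

Predicted thresholds (from signature features or classifier performance) are
compared with behavioural thresholds on the log10-contrast scale via bias,
root variance and RMSE.  Three experiments probe robustness of the
classifier estimator: leave-subject-out training, training on one contrast
and testing on all, and varying the number of trials per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .config import InputError, SimulationConfig
from .classifier import (
    SVM_COST,
    COARSE_BIN_MS,
    fit_classifier_logistic,
    make_samples,
    paired_loocv,
    train_linear_svm,
)
from .features import fit_psychometric
from .signature import EpochedEvents
from .simulate import contrast_drive, sample_epoched_trials

__all__ = [
    "ThresholdComparison",
    "summarize_errors",
    "simulate_cohort",
    "leave_subject_out",
    "cross_contrast",
    "trial_count_sweep",
    "spearman_correlation",
]


# ---------------------------------------------------------------------------
# Error summary
# ---------------------------------------------------------------------------

@dataclass
class ThresholdComparison:
    """Prediction errors (log10-contrast units) across subjects.

    With the population (1/n) variance convention the identity
    rmse^2 = bias^2 + root_variance^2 holds exactly.
    """

    errors: np.ndarray
    bias: float
    root_variance: float
    rmse: float
    n_excluded: int = 0


def summarize_errors(predicted_pct, behavioural_pct,
                     excluded=None) -> ThresholdComparison:
    """Bias / root variance / RMSE of predicted - behavioural thresholds.

    Thresholds are given in % contrast; errors are computed on the log10
    scale.  Subjects flagged in ``excluded`` (rejected fits, missing
    thresholds) are dropped and counted.
    """
    predicted = np.asarray(predicted_pct, dtype=float)
    behavioural = np.asarray(behavioural_pct, dtype=float)
    drop = ~(np.isfinite(predicted) & np.isfinite(behavioural)
             & (predicted > 0) & (behavioural > 0))
    if excluded is not None:
        drop |= np.asarray(excluded, dtype=bool)
    if (~drop).sum() < 2:
        raise InputError("need at least 2 subjects with valid thresholds")
    errors = np.log10(predicted[~drop]) - np.log10(behavioural[~drop])
    bias = float(errors.mean())
    root_var = float(errors.std(ddof=0))
    rmse = float(np.sqrt(np.mean(errors**2)))
    return ThresholdComparison(errors=errors, bias=bias,
                               root_variance=root_var, rmse=rmse,
                               n_excluded=int(drop.sum()))


def spearman_correlation(x, y) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise InputError("need at least 3 pairs")
    return float(spearmanr(x, y).statistic)


# ---------------------------------------------------------------------------
# Synthetic cohorts (event level)
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    """Event-level data for one synthetic observer."""

    config: SimulationConfig
    epoched: dict                  # contrast (>0) -> EpochedEvents
    blank: EpochedEvents
    baseline_rate: float           # measured from the blank condition
    behavioural_threshold: float   # % contrast from the 2AFC psychometric fit
    true_threshold: float          # generator midpoint, % contrast


def _epoched_from_lists(times, amps) -> EpochedEvents:
    return EpochedEvents(times=times, amps=amps,
                         trial_ids=np.arange(len(times)))


def simulate_subject(config: SimulationConfig, n_trials: int, rng,
                     n_response: int = 250) -> SubjectData:
    """One observer's stimulus-locked events plus a behavioural threshold.

    Events are generated directly at the epoch level (the lossless-detection
    limit); the behavioural threshold comes from simulated 2AFC responses
    fitted with the binomial psychometric model.
    """
    epoched = {}
    blank = None
    for c in config.contrasts:
        t, a = sample_epoched_trials(config, c, n_trials, rng=rng)
        ep = _epoched_from_lists(t, a)
        if c == 0:
            blank = ep
        else:
            epoched[float(c)] = ep
    if blank is None:
        raise InputError("config.contrasts must include the 0% baseline")
    total = sum(len(t) for t in blank.times)
    baseline_rate = total / (blank.n_trials * 1.2)

    pos = sorted(epoched)
    n_corr = [int(rng.binomial(n_response, 0.5 + 0.5 * contrast_drive(config, c)))
              for c in pos]
    psy = fit_psychometric(pos, n_corr, [n_response] * len(pos))
    return SubjectData(config=config, epoched=epoched, blank=blank,
                       baseline_rate=baseline_rate,
                       behavioural_threshold=psy.threshold,
                       true_threshold=10.0 ** config.sensitivity_midpoint)


def simulate_cohort(base_config: SimulationConfig, midpoints_pct,
                    n_trials: int, seed=None, rng=None,
                    n_response: int = 250) -> dict:
    """Synthetic observers differing only in sensitivity midpoint."""
    if rng is None:
        rng = np.random.default_rng(seed)
    cohort = {}
    for i, mp in enumerate(midpoints_pct):
        cfg = base_config.replace(sensitivity_midpoint=float(np.log10(mp)))
        cohort[i] = simulate_subject(cfg, n_trials, rng, n_response)
    return cohort


def _subject_samples(sub: SubjectData, n_per_sample: int, rng,
                     bin_ms: float = COARSE_BIN_MS) -> dict:
    stim = {c: make_samples(ep, n_per_sample, rng=rng, bin_ms=bin_ms,
                            baseline_rate=sub.baseline_rate)
            for c, ep in sub.epoched.items()}
    blank = make_samples(sub.blank, n_per_sample, rng=rng, bin_ms=bin_ms,
                         baseline_rate=sub.baseline_rate)
    return {"stim": stim, "blank": blank}


def _threshold_from_accuracies(contrasts, accuracies):
    try:
        fit, threshold = fit_classifier_logistic(contrasts, accuracies)
    except InputError:
        return None, None
    if fit.rejected:
        return None, fit
    return threshold, fit


# ---------------------------------------------------------------------------
# Experiment 1: leave-subject-out
# ---------------------------------------------------------------------------

@dataclass
class LeaveSubjectOutResult:
    subjects: list
    errors: np.ndarray          # (left-out, tested) log10 prediction errors
    row_rmse: np.ndarray        # per left-out subject
    col_rmse: np.ndarray        # per tested subject
    diagonal: np.ndarray


def leave_subject_out(cohort: dict, n_per_sample: int = 30,
                      C: float = SVM_COST, seed=None) -> LeaveSubjectOutResult:
    """Prediction error for every (subject omitted, subject tested) pair.

    For each omitted subject s, training pools samples from all other
    subjects.  Tested subjects in the training pool are evaluated by
    leave-one-pair-out over their own pairs; the omitted subject's samples
    are never seen in training (the matrix diagonal).
    """
    if len(cohort) < 3:
        raise InputError("need at least 3 subjects")
    rng = np.random.default_rng(seed)
    subjects = sorted(cohort)
    samples = {s: _subject_samples(cohort[s], n_per_sample, rng)
               for s in subjects}
    contrasts = sorted({c for s in subjects for c in samples[s]["stim"]})

    errors = np.full((len(subjects), len(subjects)), np.nan)
    for i, s_omit in enumerate(subjects):
        train_subj = [s for s in subjects if s != s_omit]
        for j, s_test in enumerate(subjects):
            accs = []
            for c in contrasts:
                stim_tr = [samples[s]["stim"][c] for s in train_subj]
                blank_tr = [samples[s]["blank"] for s in train_subj]
                xt_stim = samples[s_test]["stim"][c]
                xt_blank = samples[s_test]["blank"]
                npair = min(len(xt_stim), len(xt_blank))
                correct = 0
                if s_test == s_omit:
                    w, b, model = train_linear_svm(
                        np.vstack(stim_tr), np.vstack(blank_tr), C=C)
                    if model is None:
                        continue
                    correct = int(np.sum(xt_stim[:npair] @ w + b > 0)) + \
                        int(np.sum(xt_blank[:npair] @ w + b <= 0))
                else:
                    for p in range(npair):
                        stim_pool = [x for s in train_subj
                                     for q, x in enumerate(samples[s]["stim"][c])
                                     if not (s == s_test and q == p)]
                        blank_pool = [x for s in train_subj
                                      for q, x in enumerate(samples[s]["blank"])
                                      if not (s == s_test and q == p)]
                        w, b, model = train_linear_svm(
                            np.asarray(stim_pool), np.asarray(blank_pool), C=C)
                        if model is None:
                            continue
                        correct += int(xt_stim[p] @ w + b > 0)
                        correct += int(xt_blank[p] @ w + b <= 0)
                accs.append(100.0 * correct / (2 * npair))
            threshold, _ = _threshold_from_accuracies(contrasts, accs)
            if threshold is not None:
                errors[i, j] = (np.log10(threshold)
                                - np.log10(cohort[s_test].behavioural_threshold))

    def _rmse(v):
        v = v[np.isfinite(v)]
        return np.sqrt(np.mean(v**2)) if len(v) else np.nan

    return LeaveSubjectOutResult(
        subjects=subjects, errors=errors,
        row_rmse=np.asarray([_rmse(errors[i]) for i in range(len(subjects))]),
        col_rmse=np.asarray([_rmse(errors[:, j]) for j in range(len(subjects))]),
        diagonal=np.diag(errors).copy(),
    )


# ---------------------------------------------------------------------------
# Experiment 2: train on one contrast, test on all
# ---------------------------------------------------------------------------

@dataclass
class CrossContrastResult:
    train_contrast: float
    test_contrasts: np.ndarray
    percent_correct: np.ndarray
    threshold: float | None
    rejected: bool


def cross_contrast(subject: SubjectData, train_contrast: float,
                   n_per_sample: int = 30, C: float = SVM_COST,
                   seed=None) -> CrossContrastResult:
    """Train at one contrast (vs blank), test the fixed model everywhere.

    Blank samples are split in half: one half trains, the other half serves
    as the blank side of every test, so test blanks are never seen in
    training.  The same-contrast cell instead uses paired LOOCV, matching
    the standard pipeline.
    """
    rng = np.random.default_rng(seed)
    samples = _subject_samples(subject, n_per_sample, rng)
    blank = samples["blank"]
    if len(blank) < 4:
        raise InputError("need at least 4 blank samples to split")
    half = len(blank) // 2
    blank_train, blank_test = blank[:half], blank[half:]
    if train_contrast not in samples["stim"]:
        raise InputError(f"no samples at train contrast {train_contrast}")

    w, b, model = train_linear_svm(samples["stim"][train_contrast],
                                   blank_train, C=C)
    test_contrasts = sorted(samples["stim"])
    accs = []
    for c in test_contrasts:
        if c == train_contrast:
            xs = samples["stim"][c]
            npair = min(len(xs), len(blank))
            accs.append(paired_loocv(xs[:npair], blank[:npair], C=C)
                        .percent_correct)
            continue
        xs = samples["stim"][c]
        n = min(len(xs), len(blank_test))
        correct = int(np.sum(xs[:n] @ w + b > 0)) + \
            int(np.sum(blank_test[:n] @ w + b <= 0))
        accs.append(100.0 * correct / (2 * n))

    fit, threshold = fit_classifier_logistic(test_contrasts, accs)
    return CrossContrastResult(train_contrast=train_contrast,
                               test_contrasts=np.asarray(test_contrasts),
                               percent_correct=np.asarray(accs),
                               threshold=threshold,
                               rejected=fit.rejected or threshold is None)


# ---------------------------------------------------------------------------
# Experiment 3: trials per sample
# ---------------------------------------------------------------------------

def trial_count_sweep(cohort: dict, n_trials_grid, n_samples: int = 10,
                      C: float = SVM_COST, seed=None) -> pd.DataFrame:
    """RMSE/bias of classifier thresholds as trials-per-sample varies.

    For each grid value, samples are rebuilt (at most ``n_samples`` per
    subject), the per-contrast paired LOOCV rerun, thresholds refit and
    compared with behavioural thresholds.  Missing thresholds are clamped
    to the tested contrast range so that an uninformative classifier scores
    the error of a range-edge guess rather than dropping out.  Infeasible
    grid values are skipped.
    """
    rng = np.random.default_rng(seed)
    subjects = sorted(cohort)
    rows = []
    for n_per in n_trials_grid:
        preds, behavs = [], []
        feasible = True
        for s in subjects:
            sub = cohort[s]
            n_avail = min(min(ep.n_trials for ep in sub.epoched.values()),
                          sub.blank.n_trials)
            if n_avail // n_per < 2:
                feasible = False
                break
            contrasts = sorted(sub.epoched)
            accs = []
            for c in contrasts:
                k = min(sub.epoched[c].n_trials // n_per, n_samples,
                        sub.blank.n_trials // n_per)
                xs = make_samples(sub.epoched[c], n_per, rng=rng,
                                  baseline_rate=sub.baseline_rate)[:k]
                xb = make_samples(sub.blank, n_per, rng=rng,
                                  baseline_rate=sub.baseline_rate)[:k]
                accs.append(paired_loocv(xs, xb, C=C).percent_correct)
            threshold, _ = _threshold_from_accuracies(contrasts, accs)
            if threshold is None:
                threshold = contrasts[-1]
            threshold = float(np.clip(threshold, contrasts[0], contrasts[-1]))
            preds.append(threshold)
            behavs.append(sub.behavioural_threshold)
        if not feasible:
            continue
        cmp_ = summarize_errors(preds, behavs)
        rows.append({"n_trials_per_sample": n_per, "rmse": cmp_.rmse,
                     "bias": cmp_.bias, "root_variance": cmp_.root_variance,
                     "n_subjects": len(preds)})
    return pd.DataFrame(rows)
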