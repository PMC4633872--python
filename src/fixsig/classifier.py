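"""Linear support-vector classification of stimulus versus blank trials.

Because single trials carry only a couple of saccades, trials are
down-sampled: disjoint groups of trials are pooled into "samples" whose
feature vector is the baseline-normalized saccade rate in coarse (100 ms)
time bins across the peri-stimulus epoch.  A linear SVM (cost 1e6,
effectively hard margin) separates stimulus samples from blank samples;
accuracy is measured by leave-one-out cross-validation over paired samples,
and a logistic fit of percent correct against log10 contrast yields the
oculomotor threshold at the 75%-correct point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit, logit

from .config import InputError
from .features import LogisticFit, R2_REJECTION
from .signature import EpochedEvents

__all__ = [
    "COARSE_BIN_MS",
    "SVM_COST",
    "make_samples",
    "train_linear_svm",
    "paired_loocv",
    "classifier_curve",
    "per_subject_performance",
    "fit_classifier_logistic",
    "ClassifierCurve",
]

COARSE_BIN_MS = 100.0
SVM_COST = 1e6
SVM_MAX_ITER = 10_000


def make_samples(epoched: EpochedEvents, n_per_sample: int, rng=None,
                 bin_ms: float = COARSE_BIN_MS, baseline_rate: float = 1.0,
                 seed=None) -> np.ndarray:
    """Down-sample trials into pooled feature vectors.

    Valid trials are randomly partitioned without replacement into
    floor(N/n) disjoint samples of n trials; events are pooled per coarse
    bin, converted to a rate (events per trial-second) and divided by the
    subject's baseline rate.  Returns an (n_samples, n_bins) array.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n_trials = epoched.n_trials
    k = n_trials // n_per_sample
    if k < 2:
        raise InputError(
            f"{n_trials} trials cannot form 2 samples of {n_per_sample}")
    counts = epoched.counts_matrix(bin_ms=bin_ms)
    perm = rng.permutation(n_trials)[: k * n_per_sample]
    groups = perm.reshape(k, n_per_sample)
    pooled = counts[groups].sum(axis=1)
    rate = pooled / (n_per_sample * bin_ms / 1000.0)
    return rate / baseline_rate


def _svc(C: float):
    from sklearn.svm import LinearSVC

    # At cost 1e6 the hinge-loss problem is effectively hard margin;
    # liblinear's dual coordinate descent converges on it where libsvm's
    # SMO grinds.  A large intercept_scaling keeps the (regularized)
    # liblinear intercept equivalent to libsvm's free offset.
    return LinearSVC(C=C, loss="hinge", tol=1e-8, max_iter=SVM_MAX_ITER,
                     intercept_scaling=100.0, random_state=0)


def train_linear_svm(samples_a: np.ndarray, samples_b: np.ndarray,
                     C: float = SVM_COST):
    """Fit the linear soft-margin separator; returns (w, b, model).

    Class a is labelled +1 and class b -1, so the decision function
    w.x + b is positive for class a.  The problem is convex, so the fit is
    deterministic given the inputs.
    """
    if len(samples_a) < 1 or len(samples_b) < 1:
        raise InputError("need at least one sample per class")
    X = np.vstack([samples_a, samples_b])
    y = np.r_[np.ones(len(samples_a)), -np.ones(len(samples_b))]
    if np.allclose(samples_a.mean(axis=0), samples_b.mean(axis=0)) and \
            np.allclose(X.var(axis=0), 0):
        warnings.warn("identical degenerate classes; zero-margin model")
        return np.zeros(X.shape[1]), 0.0, None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # iteration-cap notice on chance data
        model = _svc(C).fit(X, y)
    return model.coef_.ravel().copy(), float(model.intercept_[0]), model


@dataclass
class PairedLOOCV:
    percent_correct: float
    decisions: np.ndarray     # (n_pairs, 2) booleans: stim side, blank side


def paired_loocv(samples_stim: np.ndarray, samples_blank: np.ndarray,
                 C: float = SVM_COST, rng=None, seed=None) -> PairedLOOCV:
    """Leave-one-out cross-validation on paired stimulus/blank samples.

    Samples are paired by index after an optional shuffle; for each pair
    the classifier is trained on all remaining pairs and both left-out
    samples are tested.  Percent correct counts both decisions of each pair.
    """
    ns, nb = len(samples_stim), len(samples_blank)
    if ns != nb:
        raise InputError("equal sample counts per group are required")
    if ns < 3:
        raise InputError("need at least 3 pairs")
    if rng is None and seed is not None:
        rng = np.random.default_rng(seed)
    stim = np.asarray(samples_stim, dtype=float)
    blank = np.asarray(samples_blank, dtype=float)
    if rng is not None:
        stim = stim[rng.permutation(ns)]
        blank = blank[rng.permutation(nb)]

    decisions = np.zeros((ns, 2), dtype=bool)
    idx = np.arange(ns)
    for i in range(ns):
        keep = idx != i
        w, b, model = train_linear_svm(stim[keep], blank[keep], C=C)
        if model is None:
            continue   # degenerate: both decisions count as wrong
        decisions[i, 0] = (stim[i] @ w + b) > 0
        decisions[i, 1] = (blank[i] @ w + b) <= 0
    pct = 100.0 * decisions.sum() / (2 * ns)
    return PairedLOOCV(percent_correct=pct, decisions=decisions)


def _classifier_logistic(x, ceiling, mid, slope):
    return 50.0 + (ceiling - 50.0) * expit((x - mid) / slope)


def fit_classifier_logistic(contrasts, percent_correct) -> tuple[LogisticFit, float | None]:
    """Fit percent correct vs log10 contrast (floor 50%, free ceiling <= 100).

    Returns the fit and the 75%-correct threshold in % contrast (None when
    the fitted curve never reaches 75%).
    """
    contrasts = np.asarray(contrasts, dtype=float)
    pc = np.asarray(percent_correct, dtype=float)
    ok = (contrasts > 0) & np.isfinite(pc)
    if ok.sum() < 3:
        raise InputError("need at least 3 contrast levels")
    x, y = np.log10(contrasts[ok]), pc[ok]
    span = max(x.max() - x.min(), 0.3)
    bounds = ([50.0 + 1e-6, x.min() - 1.0, 1e-3], [100.0, x.max() + 1.0, 10.0])
    best, best_ss = None, np.inf
    for m0 in np.linspace(x.min(), x.max(), 5):
        p0 = (min(max(y.max(), 55.0), 100.0), float(m0), span / 6.0)
        try:
            popt, _ = curve_fit(_classifier_logistic, x, y, p0=p0,
                                bounds=bounds, maxfev=20_000)
        except RuntimeError:
            continue
        ss = float(np.sum((y - _classifier_logistic(x, *popt)) ** 2))
        if ss < best_ss:
            best, best_ss = popt, ss
    if best is None:
        fit = LogisticFit(50.0, np.nan, np.nan, np.nan, np.nan, 0.0,
                          rejected=True, converged=False)
        return fit, None
    ceiling, mid, slope = map(float, best)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - best_ss / ss_tot if ss_tot > 0 else 0.0
    threshold = None
    if ceiling > 75.0:
        x75 = mid + slope * float(logit(25.0 / (ceiling - 50.0)))
        threshold = 10.0 ** x75
    fit = LogisticFit(floor=50.0, ceiling=ceiling, midpoint=mid, slope=slope,
                      threshold=np.nan if threshold is None else threshold,
                      r_squared=r2, rejected=r2 < R2_REJECTION)
    return fit, threshold


@dataclass
class ClassifierCurve:
    contrasts: np.ndarray
    percent_correct: np.ndarray          # mean over bootstrap repeats
    bootstrap: dict = field(default_factory=dict)  # contrast -> B accuracies
    n_pairs: int = 0
    fit: LogisticFit | None = None
    threshold: float | None = None       # % contrast at 75% correct


def classifier_curve(epoched_by_contrast: dict, epoched_blank: EpochedEvents,
                     baseline_rate: float, n_per_sample: int = 30,
                     bin_ms: float = COARSE_BIN_MS, B: int = 1000,
                     C: float = SVM_COST, seed=None, rng=None) -> ClassifierCurve:
    """Per-contrast paired-LOOCV accuracy with bootstrap over partitions.

    For each contrast, trials are partitioned into disjoint samples and a
    linear SVM is cross-validated against blank samples; the partition is
    re-randomized B times and accuracies averaged.  A logistic fit of mean
    percent correct over log10 contrast yields the 75%-correct threshold.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    contrasts = sorted(c for c in epoched_by_contrast if c > 0)
    boot: dict[float, np.ndarray] = {}
    mean_pc = []
    n_pairs = 0
    for c in contrasts:
        ep = epoched_by_contrast[c]
        accs = []
        for _ in range(B):
            try:
                xs = make_samples(ep, n_per_sample, rng=rng, bin_ms=bin_ms,
                                  baseline_rate=baseline_rate)
                xb = make_samples(epoched_blank, n_per_sample, rng=rng,
                                  bin_ms=bin_ms, baseline_rate=baseline_rate)
            except InputError:
                accs = []
                break
            npair = min(len(xs), len(xb))
            n_pairs = max(n_pairs, npair)
            res = paired_loocv(xs[:npair], xb[:npair], C=C)
            accs.append(res.percent_correct)
        if not accs:
            continue
        boot[c] = np.asarray(accs)
        mean_pc.append((c, float(np.mean(accs))))

    cs = np.asarray([c for c, _ in mean_pc])
    pc = np.asarray([p for _, p in mean_pc])
    fit, threshold = fit_classifier_logistic(cs, pc)
    return ClassifierCurve(contrasts=cs, percent_correct=pc, bootstrap=boot,
                           n_pairs=n_pairs, fit=fit, threshold=threshold)


def per_subject_performance(samples_by_subject: dict, C: float = SVM_COST) -> dict:
    """Pooled training, per-subject test accuracy.

    ``samples_by_subject`` maps subject -> dict with keys "stim" (contrast ->
    samples) and "blank" (samples).  Pairs are formed within subject; the
    SVM trains on all remaining pairs pooled across subjects, and each
    subject's accuracy aggregates only the pairs whose left-out samples
    belong to that subject.  Returns subject -> (contrasts, percent_correct).
    """
    subjects = list(samples_by_subject)
    contrasts = sorted({c for s in subjects
                        for c in samples_by_subject[s]["stim"]})
    out = {s: {} for s in subjects}
    for c in contrasts:
        pairs = []   # (subject, stim sample, blank sample)
        for s in subjects:
            stim = samples_by_subject[s]["stim"].get(c)
            blank = samples_by_subject[s]["blank"]
            if stim is None:
                continue
            npair = min(len(stim), len(blank))
            pairs += [(s, stim[i], blank[i]) for i in range(npair)]
        if len(pairs) < 3:
            continue
        stim_all = np.asarray([p[1] for p in pairs])
        blank_all = np.asarray([p[2] for p in pairs])
        correct = {s: [] for s in subjects}
        idx = np.arange(len(pairs))
        for i in range(len(pairs)):
            keep = idx != i
            w, b, model = train_linear_svm(stim_all[keep], blank_all[keep], C=C)
            if model is None:
                continue
            s = pairs[i][0]
            correct[s].append((stim_all[i] @ w + b) > 0)
            correct[s].append((blank_all[i] @ w + b) <= 0)
        for s in subjects:
            if correct[s]:
                out[s][c] = 100.0 * np.mean(correct[s])
    missing = [s for s in subjects if not out[s]]
    if missing:
        raise InputError(f"no test pairs for subjects {missing}")
    return {s: (np.asarray(sorted(d)), np.asarray([d[c] for c in sorted(d)]))
            for s, d in out.items()}
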