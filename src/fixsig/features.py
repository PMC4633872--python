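"""Rate-signature features and logistic threshold estimation.

Features (inhibition magnitude/latency, rebound magnitude/latency, minimum
saccade amplitude) are read off the smoothed, baseline-normalized signature.
Thresholds come from logistic fits over log10 contrast: a four-parameter
least-squares logistic for signature features, and a fixed-asymptote
(0.5-1.0) binomial maximum-likelihood logistic for 2AFC psychophysics with
the 75%-correct point as the threshold.  Fits with R^2 below 0.3 are
rejected rather than silently reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, minimize
from scipy.special import expit

from .config import InputError
from .signature import RateSignature

__all__ = [
    "SignatureFeatures",
    "LogisticFit",
    "extract_features",
    "fit_feature_logistic",
    "fit_psychometric",
    "R2_REJECTION",
]

#: Fits with a coefficient of determination below this are rejected.
R2_REJECTION = 0.3

#: Feature search windows (ms post-stimulus).
INHIBITION_WINDOW = (0.0, 400.0)
REBOUND_END = 800.0


@dataclass
class SignatureFeatures:
    inhibition_magnitude: float   # normalized-rate minimum in 0-400 ms
    inhibition_latency: float     # ms
    rebound_magnitude: float      # normalized-rate maximum in (t_inh, 800]
    rebound_latency: float        # ms
    total_magnitude: float        # rebound - inhibition magnitude
    min_amplitude: float          # arcmin, NaN if no amplitude data
    low_signature: bool = False   # no rebound above baseline found


@dataclass
class LogisticFit:
    floor: float
    ceiling: float
    midpoint: float               # log10(% contrast)
    slope: float                  # log10-contrast units
    threshold: float              # % contrast (10**midpoint)
    r_squared: float
    rejected: bool
    converged: bool = True
    out_of_range: bool = False


def extract_features(norm_sig: RateSignature,
                     amp_sig: RateSignature | None = None) -> SignatureFeatures:
    """Read inhibition/rebound/amplitude features off a smoothed signature.

    The inhibition is the minimum of the normalized rate in 0-400 ms, the
    rebound the maximum between the inhibition latency (exclusive) and
    800 ms; ties break to the earliest bin.  A rebound that never exceeds
    baseline is still reported, flagged ``low_signature``.
    """
    bins = norm_sig.bins_ms
    rate = norm_sig.rate
    w_inh = (bins >= INHIBITION_WINDOW[0]) & (bins <= INHIBITION_WINDOW[1])
    i_inh = np.flatnonzero(w_inh)[int(np.argmin(rate[w_inh]))]
    inh_mag = float(rate[i_inh])
    inh_lat = float(bins[i_inh])

    w_reb = (bins > inh_lat) & (bins <= REBOUND_END)
    i_reb = np.flatnonzero(w_reb)[int(np.argmax(rate[w_reb]))]
    reb_mag = float(rate[i_reb])
    reb_lat = float(bins[i_reb])

    min_amp = np.nan
    src = amp_sig if amp_sig is not None else norm_sig
    amp = src.amplitude
    if amp is not None and np.isfinite(amp[w_inh]).any():
        min_amp = float(np.nanmin(amp[w_inh]))

    return SignatureFeatures(
        inhibition_magnitude=inh_mag,
        inhibition_latency=inh_lat,
        rebound_magnitude=reb_mag,
        rebound_latency=reb_lat,
        total_magnitude=reb_mag - inh_mag,
        min_amplitude=min_amp,
        low_signature=reb_mag <= 1.0,
    )


def _logistic4(x, floor, ceiling, mid, slope):
    return floor + (ceiling - floor) * expit((x - mid) / slope)


def fit_feature_logistic(contrasts, values, max_slope: float | None = None,
                         value_bounds: tuple | None = None) -> LogisticFit:
    """Four-parameter logistic least squares over log10 contrast.

    The threshold is the fitted midpoint mapped back to % contrast (the
    half-way criterion between the fitted floor and ceiling).  Five
    deterministic multi-starts span the contrast range; the best
    least-squares solution is kept.

    Unless overridden, the slope is bounded above by (range of log10
    contrast)/2.5: a logistic shallower than that cannot resolve both
    asymptotes inside the tested range, leaving the midpoint unidentified
    and free to run away.  ``value_bounds`` optionally constrains the
    asymptotes to the physically admissible range of the feature (e.g.
    normalized rates are non-negative).
    """
    contrasts = np.asarray(contrasts, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values) & (contrasts > 0)
    if ok.sum() < 5:
        raise InputError("need at least 5 contrast levels with finite values")
    x = np.log10(contrasts[ok])
    y = values[ok]

    span = x.max() - x.min()
    if max_slope is None:
        max_slope = max(span / 2.5, 0.01)
    lo_v, hi_v = (-np.inf, np.inf) if value_bounds is None else value_bounds
    starts = x.min() + span * np.asarray([0.2, 0.35, 0.5, 0.65, 0.8])
    bounds = ([lo_v, lo_v, x.min() - 1.0, 1e-3],
              [hi_v, hi_v, x.max() + 1.0, max_slope])
    best, best_ss = None, np.inf
    for m0 in starts:
        p0 = (float(np.clip(y[np.argmin(x)], lo_v, hi_v)),
              float(np.clip(y[np.argmax(x)], lo_v, hi_v)), float(m0),
              min(max(span / 6.0, 0.05), 0.9 * max_slope))
        try:
            popt, _ = curve_fit(_logistic4, x, y, p0=p0, bounds=bounds,
                                maxfev=20_000)
        except RuntimeError:
            continue
        ss = float(np.sum((y - _logistic4(x, *popt)) ** 2))
        if ss < best_ss:
            best, best_ss = popt, ss

    if best is None:
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                           r_squared=0.0, rejected=True, converged=False)
    floor, ceiling, mid, slope = map(float, best)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - best_ss / ss_tot if ss_tot > 0 else 0.0
    return LogisticFit(floor=floor, ceiling=ceiling, midpoint=mid,
                       slope=slope, threshold=10.0**mid, r_squared=r2,
                       rejected=r2 < R2_REJECTION,
                       out_of_range=not (x.min() <= mid <= x.max()))


def _psychometric(x, mid, slope):
    return 0.5 + 0.5 * expit((x - mid) / slope)


def fit_psychometric(contrasts, n_correct, n_trials) -> LogisticFit:
    """Binomial ML fit of P(correct) = 0.5 + 0.5 * logistic(log10 c).

    Under this fixed-asymptote form the 75%-correct threshold equals the
    fitted midpoint.  All-correct or all-chance data yield a fit flagged
    ``out_of_range`` instead of a silently extrapolated threshold.
    """
    contrasts = np.asarray(contrasts, dtype=float)
    k = np.asarray(n_correct, dtype=float)
    n = np.asarray(n_trials, dtype=float)
    ok = (contrasts > 0) & (n >= 1)
    if ok.sum() < 2:
        raise InputError("need at least 2 positive-contrast levels")
    x, k, n = np.log10(contrasts[ok]), k[ok], n[ok]

    def nll(params):
        mid, log_slope = params
        p = np.clip(_psychometric(x, mid, np.exp(log_slope)), 1e-9, 1 - 1e-9)
        return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))

    span = max(x.max() - x.min(), 0.3)
    best, best_val = None, np.inf
    for m0 in np.linspace(x.min(), x.max(), 5):
        res = minimize(nll, x0=[m0, np.log(span / 6.0)], method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 4000})
        if res.fun < best_val:
            best, best_val = res, res.fun
    mid, slope = float(best.x[0]), float(np.exp(best.x[1]))

    prop = k / n
    fitted = _psychometric(x, mid, slope)
    ss_tot = float(np.sum((prop - prop.mean()) ** 2))
    ss_res = float(np.sum((prop - fitted) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    out_of_range = not (x.min() <= mid <= x.max())
    return LogisticFit(floor=0.5, ceiling=1.0, midpoint=mid, slope=slope,
                       threshold=10.0**mid, r_squared=r2,
                       rejected=r2 < R2_REJECTION, converged=bool(best.success),
                       out_of_range=out_of_range)
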