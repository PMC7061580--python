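"""Per-cycle feature extraction: 9 morphological descriptors + 3 logistic-fit
parameters.

Feature map (all computed on one cycle, baseline removed where noted):

====  =====================================================================
f1    peak relative amplitude, (max - baseline) / baseline
f2    time of the peak from cycle start, s
f3    trapezoidal area under the baseline-subtracted cycle, intensity*s
f4    maximum of the first derivative (fastest rise), intensity/s
f5    minimum of the first derivative (fastest decay, signed), intensity/s
f6    time of the maximum first derivative, s
f7    maximum of the second derivative, intensity/s^2
f8    recovery residual, last sample - baseline, intensity
f9    rise/decay ratio, f4 / |f5| (|f5| floored at EPS)
f10   logistic amplitude A
f11   logistic growth rate k, 1/s
f12   logistic midpoint t0, s
====  =====================================================================

Ties in argmax/argmin resolve to the earliest index.  The logistic
g(t) = A / (1 + exp(-k (t - t0))) is fitted by least squares to the
baseline-subtracted exposure segment only; non-convergence yields a flagged
fallback (the initialization values), never an exception.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .preprocessing import CycleWindow
from .synthetic import AssaySchedule

__all__ = [
    "FeatureVector",
    "LogisticFitResult",
    "FEATURE_NAMES",
    "first_derivative",
    "morphological_features",
    "fit_logistic",
    "extract_features",
]

logger = logging.getLogger(__name__)

#: Division guard for f1 (zero baseline) and f9 (zero decay rate).
EPS = 1e-12

FEATURE_NAMES: tuple[str, ...] = (
    "f1_peak_rel_amplitude",
    "f2_time_to_peak",
    "f3_auc",
    "f4_max_rise_rate",
    "f5_max_decay_rate",
    "f6_time_of_max_rise",
    "f7_max_curvature",
    "f8_recovery_residual",
    "f9_rise_decay_ratio",
    "f10_logistic_A",
    "f11_logistic_k",
    "f12_logistic_t0",
)


@dataclass(frozen=True)
class FeatureVector:
    f1_peak_rel_amplitude: float
    f2_time_to_peak: float
    f3_auc: float
    f4_max_rise_rate: float
    f5_max_decay_rate: float
    f6_time_of_max_rise: float
    f7_max_curvature: float
    f8_recovery_residual: float
    f9_rise_decay_ratio: float
    f10_logistic_A: float
    f11_logistic_k: float
    f12_logistic_t0: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])

    def __len__(self) -> int:
        return len(FEATURE_NAMES)


@dataclass(frozen=True)
class LogisticFitResult:
    A: float
    k: float
    t0: float
    rss: float
    converged: bool


def first_derivative(values: np.ndarray, dt: float) -> np.ndarray:
    """Finite-difference derivative: central interior, one-sided ends."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 samples for a derivative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return np.gradient(values, dt)


def _logistic(t: np.ndarray, A: float, k: float, t0: float) -> np.ndarray:
    return A / (1.0 + np.exp(-k * (t - t0)))


def morphological_features(cycle: CycleWindow, schedule: AssaySchedule) -> tuple[float, ...]:
    """The nine morphological entries (f1..f9) of the feature vector."""
    y = cycle.values
    if y.size != schedule.cycle_samples:
        raise ValueError(
            f"cycle has {y.size} samples, schedule prescribes {schedule.cycle_samples}"
        )
    dt = 1.0 / schedule.sampling_hz
    t = schedule.cycle_times()
    baseline = cycle.baseline
    sub = y - baseline

    if abs(baseline) < EPS:
        logger.warning("cycle %d: baseline ~ 0, f1 guarded by epsilon", cycle.cycle_index)
        baseline_div = EPS
    else:
        baseline_div = baseline
    peak_idx = int(np.argmax(sub))  # earliest index on ties
    f1 = float(sub[peak_idx] / baseline_div)
    f2 = float(t[peak_idx])
    f3 = float(np.trapezoid(sub, dx=dt))

    d1 = first_derivative(y, dt)
    rise_idx = int(np.argmax(d1))
    f4 = float(d1[rise_idx])
    f5 = float(d1.min())
    f6 = float(t[rise_idx])
    d2 = first_derivative(d1, dt)
    f7 = float(d2.max())
    f8 = float(sub[-1])
    f9 = float(f4 / max(abs(f5), EPS))
    return (f1, f2, f3, f4, f5, f6, f7, f8, f9)


def fit_logistic(cycle: CycleWindow, schedule: AssaySchedule, maxfev: int = 2000) -> LogisticFitResult:
    """Least-squares logistic fit on the baseline-subtracted exposure segment.

    Initialization: A0 = max - baseline, t0_0 = time of half-max,
    k0 = 4 / exposure duration.  On failure (or a fitted k <= 0) the result
    carries the initialization values with ``converged=False``.
    """
    t_all = schedule.cycle_times()
    exposure = t_all < schedule.exposure_s
    t = t_all[exposure]
    y = cycle.values[exposure] - cycle.baseline

    a0 = float(y.max())
    k0 = 4.0 / schedule.exposure_s
    if a0 <= EPS:
        # flat (or negative) segment: degenerate, signalled not raised
        return LogisticFitResult(A=0.0, k=k0, t0=schedule.exposure_s / 2, rss=float(np.sum(y**2)), converged=False)
    half_idx = int(np.argmax(y >= a0 / 2.0))
    t0_0 = float(t[half_idx])
    p0 = (a0, k0, t0_0)

    try:
        popt, _ = curve_fit(_logistic, t, y, p0=p0, method="lm", maxfev=maxfev)
        A, k, t0 = (float(v) for v in popt)
        converged = bool(np.isfinite([A, k, t0]).all() and k > 0)
    except RuntimeError:
        A, k, t0 = p0
        converged = False
    rss = float(np.sum((y - _logistic(t, A, k, t0)) ** 2))
    if not converged:
        logger.warning("cycle %d: logistic fit did not converge", cycle.cycle_index)
    return LogisticFitResult(A=A, k=k, t0=t0, rss=rss, converged=converged)


def extract_features(cycle: CycleWindow, schedule: AssaySchedule) -> FeatureVector:
    """The full 12-entry per-cycle feature vector; always finite."""
    morph = morphological_features(cycle, schedule)
    fit = fit_logistic(cycle, schedule)
    return FeatureVector(*morph, fit.A, fit.k, fit.t0)
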