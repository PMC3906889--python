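"""Logistic growth-curve fitting for spot-culture time series.

Each arrayed spot culture yields a background-subtracted pixel-density time
series.  Density is modelled with a logistic growth curve

    G(t) = baseline + K / (1 + exp(-r * (t - L)))

where ``K`` is the carrying capacity above background (intensity units),
``r`` the maximum specific rate (1/h) and ``L`` the time at which the
culture reaches half its carrying capacity (h).  ``L`` is inversely
proportional to fitness and is the parameter used downstream to score
gene interactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import curve_fit


class InvalidSeriesError(ValueError):
    """Raised when a time series violates its invariants."""


class DegenerateGroupError(ValueError):
    """Raised when the untreated group cannot define a z-scale."""


@dataclass(frozen=True)
class TimeSeries:
    """One culture's density-vs-time observations.

    times are hours, strictly increasing; intensities are background
    subtracted and may contain small noise-driven negatives.
    """

    culture_id: str
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise InvalidSeriesError(
                f"{self.culture_id}: times and intensities must be equal-length 1-D"
            )
        if t.size < 4:
            raise InvalidSeriesError(
                f"{self.culture_id}: need >= 4 observations, got {t.size}"
            )
        if np.any(np.diff(t) <= 0):
            raise InvalidSeriesError(f"{self.culture_id}: times must strictly increase")
        if np.any(t < 0):
            raise InvalidSeriesError(f"{self.culture_id}: times must be non-negative")


@dataclass(frozen=True)
class FitConfig:
    """Fitting and no-growth-detection settings.

    k_min: carrying-capacity cut below which a culture is called non-grown
        (intensity units; pipelines typically set this to 5% of the
        plate-wide median K).
    r2_min: minimum coefficient of determination for a growth call.
    tol: optimizer termination tolerance (xtol/ftol/gtol).
    max_iter: maximum objective evaluations for the optimizer.
    fit_baseline: fit the additive offset; when False the baseline is fixed
        at the first observed intensity.
    """

    k_min: float = 5.0
    r2_min: float = 0.7
    tol: float = 1e-12
    max_iter: int = 20000
    fit_baseline: bool = True

    def __post_init__(self) -> None:
        if self.k_min <= 0 or self.r2_min <= 0:
            raise ValueError("no-growth thresholds must be positive")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")


@dataclass(frozen=True)
class GrowthCurveFit:
    """Fitted logistic parameters and diagnostics for one culture.

    When ``grew`` is False the parameters K, r, L (and auc) are NaN
    ("not applicable"); ``converged`` records whether the optimizer
    terminated normally.
    """

    culture_id: str
    K: float
    r: float
    L: float
    baseline: float
    auc: float
    r_squared: float
    ci_lower: Mapping[str, float] = field(default_factory=dict)
    ci_upper: Mapping[str, float] = field(default_factory=dict)
    grew: bool = True
    converged: bool = True


def logistic(t: np.ndarray, baseline: float, K: float, r: float, L: float) -> np.ndarray:
    """Evaluate G(t) = baseline + K / (1 + exp(-r (t - L)))."""
    # expit-style stable form
    z = np.clip(r * (np.asarray(t, dtype=float) - L), -700, 700)
    return baseline + K / (1.0 + np.exp(-z))


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Deterministic starting point: range-based K, half-range crossing L,
    slope-matched r."""
    b0 = float(np.min(y))
    k0 = float(np.max(y) - np.min(y))
    half = b0 + k0 / 2.0
    above = np.nonzero(y >= half)[0]
    if above.size and above[0] > 0:
        i = above[0]
        # linear interpolation of the half-range crossing time
        y0, y1 = y[i - 1], y[i]
        frac = (half - y0) / (y1 - y0) if y1 != y0 else 0.5
        l0 = float(t[i - 1] + frac * (t[i] - t[i - 1]))
    else:
        l0 = float(t[len(t) // 2])
    # logistic slope at L is K*r/4 -> r0 = 4*slope/K
    j = int(np.argmin(np.abs(t - l0)))
    lo, hi = max(j - 1, 0), min(j + 1, len(t) - 1)
    slope = (y[hi] - y[lo]) / (t[hi] - t[lo]) if t[hi] > t[lo] else 0.0
    r0 = 4.0 * slope / k0 if k0 > 0 else 0.1
    r0 = float(np.clip(r0, 1e-3, 10.0))
    return b0, max(k0, 1e-9), r0, l0


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -math.inf
    return 1.0 - ss_res / ss_tot


def fit_logistic(ts: TimeSeries, cfg: FitConfig = FitConfig()) -> GrowthCurveFit:
    """Least-squares logistic fit of one culture's time series.

    Returns a :class:`GrowthCurveFit`; optimizer non-convergence yields a
    fit with ``grew=False`` and ``converged=False`` rather than an
    exception.  95% confidence bounds for K, r and L come from the local
    curvature (observed information) of the least-squares objective.
    """
    t, y = ts.times, ts.intensities
    b0, k0, r0, l0 = _initial_guess(t, y)

    if np.ptp(y) == 0.0:
        # perfectly flat series: nothing to fit
        return GrowthCurveFit(
            ts.culture_id, math.nan, math.nan, math.nan, float(y[0]),
            math.nan, 1.0, {}, {}, grew=False, converged=True,
        )

    if cfg.fit_baseline:
        model = logistic
        p0 = [b0, k0, r0, l0]
        lower = [-np.inf, 0.0, 0.0, -np.inf]
        upper = [np.inf, np.inf, np.inf, np.inf]
    else:
        fixed_b = float(y[0])

        def model(tt, K, r, L):  # type: ignore[misc]
            return logistic(tt, fixed_b, K, r, L)

        p0 = [k0, r0, l0]
        lower = [0.0, 0.0, -np.inf]
        upper = [np.inf, np.inf, np.inf]

    try:
        popt, pcov = curve_fit(
            model, t, y, p0=p0, bounds=(lower, upper),
            xtol=cfg.tol, ftol=cfg.tol, gtol=cfg.tol, maxfev=cfg.max_iter,
        )
        converged = True
    except (RuntimeError, ValueError):
        return GrowthCurveFit(
            ts.culture_id, math.nan, math.nan, math.nan, b0,
            math.nan, -math.inf, {}, {}, grew=False, converged=False,
        )

    if cfg.fit_baseline:
        baseline, K, r, L = (float(v) for v in popt)
        idx = {"K": 1, "r": 2, "L": 3}
    else:
        K, r, L = (float(v) for v in popt)
        baseline = float(y[0])
        idx = {"K": 0, "r": 1, "L": 2}

    yhat = logistic(t, baseline, K, r, L)
    r2 = _r_squared(y, yhat)

    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    ci_lower = {p: float(popt[i] - 1.96 * se[i]) for p, i in idx.items()}
    ci_upper = {p: float(popt[i] + 1.96 * se[i]) for p, i in idx.items()}

    grew = growth_flag(K, r2, cfg)
    a = auc_closed_form(K, r, L, float(t[0]), float(t[-1])) if grew else math.nan
    if not grew:
        K = r = L = math.nan
        ci_lower = ci_upper = {}
    return GrowthCurveFit(
        ts.culture_id, K, r, L, baseline, a, r2,
        ci_lower, ci_upper, grew=grew, converged=converged,
    )


def growth_flag(K: float, r_squared: float, cfg: FitConfig) -> bool:
    """Growth call: False when K falls below ``k_min`` (exclusive) or the
    fit quality falls below ``r2_min``."""
    if not np.isfinite(K):
        return False
    return bool(K >= cfg.k_min and r_squared >= cfg.r2_min)


def detect_no_growth(ts: TimeSeries, cfg: FitConfig = FitConfig()) -> bool:
    """Fit the series and return its growth flag (True = grew)."""
    return fit_logistic(ts, cfg).grew


def _softplus(x: float) -> float:
    return float(np.logaddexp(0.0, x))


def auc_closed_form(K: float, r: float, L: float, t_start: float, t_end: float) -> float:
    """Area under the logistic (baseline excluded) over [t_start, t_end]:

        (K/r) * ln((1 + e^{r(t_end-L)}) / (1 + e^{r(t_start-L)}))
    """
    if K == 0.0:
        return 0.0
    if r == 0.0:
        return K / 2.0 * (t_end - t_start)
    return (K / r) * (_softplus(r * (t_end - L)) - _softplus(r * (t_start - L)))


def auc(fit: GrowthCurveFit, t_start: float, t_end: float) -> float:
    """Area under the fitted curve over [t_start, t_end]; NaN when the
    culture did not grow."""
    if not fit.grew:
        return math.nan
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    return auc_closed_form(fit.K, fit.r, fit.L, t_start, t_end)


def standardize_by_untreated(
    values_by_dose: Mapping[float, np.ndarray], untreated_dose: float = 0.0
) -> dict[float, np.ndarray]:
    """Z-standardize every dose group against the untreated group.

    Every value is transformed to (x - mean0) / sd0 with mean0 and sd0
    (sample sd) taken from the zero-dose group, so the untreated group is
    centred at 0 with unit spread and dose trends across different
    parameters become directly comparable.
    """
    if untreated_dose not in values_by_dose:
        raise DegenerateGroupError(f"no group at untreated dose {untreated_dose}")
    ref = np.asarray(values_by_dose[untreated_dose], dtype=float)
    if ref.size < 2:
        raise DegenerateGroupError(
            f"untreated group at dose {untreated_dose} needs >= 2 values"
        )
    mean0 = float(np.mean(ref))
    sd0 = float(np.std(ref, ddof=1))
    if sd0 == 0.0:
        raise DegenerateGroupError(
            f"untreated group at dose {untreated_dose} has zero variance"
        )
    return {
        dose: (np.asarray(vals, dtype=float) - mean0) / sd0
        for dose, vals in values_by_dose.items()
    }
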