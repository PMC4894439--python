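"""Derivative estimation by penalized smoothing splines.

The reconstruction step regresses the rate of change on candidate terms, so
the derivative of each noisy, possibly non-uniformly sampled series must be
estimated first. A cubic smoothing spline minimising

    sum_k (x(t_k) - s(t_k))^2 + lambda * int s''(t)^2 dt

is fitted per variable; ``lambda`` is chosen by generalized cross-validation
(GCV) unless given. Smoothing is always performed within one condition;
pooling across conditions happens later at the regression-sample level, never
at the smoothing level (the two conditions are different dynamical regimes).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline

from .exceptions import InsufficientDataError
from .timecourse import TimeCourseSet

__all__ = ["SmoothFit", "fit_smoother", "estimate_derivatives"]


class SmoothFit:
    """A fitted smoothing spline for one variable's series.

    Attributes
    ----------
    variable : str
    spline : scipy BSpline/PPoly
        The fitted, twice-differentiable curve.
    times, fitted, derivatives : ndarray
        Sample times and the curve / its first derivative evaluated there.
    penalty : float
        The curvature penalty lambda in effect (strictly positive; the
        interpolating 4-point fallback reports the smallest positive float).
        When GCV chose lambda internally (scipy keeps the value private), it
        is recovered on first access by residual matching, so plain
        derivative estimation never pays for it.
    """

    def __init__(self, variable, spline, times, observed, fitted, derivatives,
                 penalty=None):
        self.variable = variable
        self.spline = spline
        self.times = times
        self.observed = observed
        self.fitted = fitted
        self.derivatives = derivatives
        self._penalty = penalty

    def __call__(self, t):
        return self.spline(t)

    def derivative(self, t):
        return self.spline.derivative()(t)

    @property
    def penalty(self) -> float:
        if self._penalty is None:
            self._penalty = _match_lambda(self.times, self.observed, self.fitted)
        return self._penalty


def _collapse_duplicate_times(times, values):
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(times, kind="stable")
    times, values = times[order], values[order]
    uniq, inverse, counts = np.unique(times, return_inverse=True, return_counts=True)
    if uniq.size == times.size:
        return times, values
    warnings.warn("duplicate time stamps collapsed by averaging", stacklevel=3)
    sums = np.zeros(uniq.size)
    np.add.at(sums, inverse, values)
    return uniq, sums / counts


def fit_smoother(times, values, penalty="auto", variable: str = "") -> SmoothFit:
    """Fit a penalized cubic smoothing spline to one series.

    Parameters
    ----------
    times, values : array-like, shape (n,)
        Sample times (need not be uniform) and observations. Duplicate times
        are collapsed by averaging with a warning.
    penalty : "auto" or positive float
        Curvature penalty lambda; "auto" selects it by GCV.

    Notes
    -----
    With exactly 4 distinct time points the GCV criterion is not
    identifiable and an interpolating cubic spline (the ``lambda -> 0``
    limit) is used.
    """
    t, x = _collapse_duplicate_times(times, values)
    if t.size < 4:
        raise InsufficientDataError(
            f"need at least 4 distinct time points, got {t.size}"
            + (f" (variable '{variable}')" if variable else "")
        )
    lam: float | None
    if penalty == "auto":
        lam = None
    else:
        lam = float(penalty)
        if not lam > 0:
            raise InsufficientDataError("penalty must be positive or 'auto'")

    if t.size == 4:
        spline = CubicSpline(t, x)
        lam_known: float | None = np.finfo(float).tiny
    elif lam is None:
        spline = make_smoothing_spline(t, x)  # GCV-selected lambda
        lam_known = None
    else:
        spline = make_smoothing_spline(t, x, lam=lam)
        lam_known = lam

    return SmoothFit(variable, spline, t, x, spline(t), spline.derivative()(t),
                     penalty=lam_known)


def _match_lambda(t, x, fitted):
    """Recover an unreported lambda by matching the fit's residual norm.

    The smoothing-spline residual is non-decreasing in lambda, so bisection
    on log-lambda against the observed residual pins the value down.
    """
    target = float(np.sum((fitted - x) ** 2))
    lo, hi = -30.0, 30.0

    def resid(loglam):
        s = make_smoothing_spline(t, x, lam=float(np.exp(loglam)))
        return float(np.sum((s(t) - x) ** 2))

    if target <= resid(lo) + 1e-300:
        return float(np.exp(lo))
    if target >= resid(hi):
        return float(np.exp(hi))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if resid(mid) < target:
            lo = mid
        else:
            hi = mid
    return float(np.exp(0.5 * (lo + hi)))


def estimate_derivatives(tc: TimeCourseSet, penalty="auto") -> TimeCourseSet:
    """Return a copy of ``tc`` with spline-estimated derivatives attached.

    The penalty is selected per variable independently (variables differ by
    orders of magnitude in scale and noise). Existing derivatives are
    overwritten.
    """
    derivs = np.empty_like(tc.values)
    for i, vid in enumerate(tc.variable_ids):
        fit = fit_smoother(tc.times, tc.values[i], penalty=penalty, variable=vid)
        derivs[i] = fit.derivatives
    return tc.with_derivatives(derivs)
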