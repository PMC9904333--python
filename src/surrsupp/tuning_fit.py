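"""Exponential orientation-tuning fits of per-participant suppression curves.

Each included participant's five near-surround contrast decrements P(theta),
theta in {0, 20, 45, 70, 90} degrees, are fit by nonlinear least squares to

    P(theta) = -M * exp(-theta / w) + o

where M (percentage points) is the orientation-dependent modulation
magnitude, w (degrees) the tuning width and o (percentage points) the
orientation-insensitive offset -- the behavioral signature of untuned gain
control.  A fit is adequate when the population variance of the residuals is
strictly below the population variance of the raw data; inadequate fits are
excluded from analyses that use the fitted parameters as dependent variables.

Initialization: M0 = P(0) subtracted from P at the largest theta, w0 = 30,
o0 = P at the largest theta; w bounded to [1, 180], M and o unbounded; on
failure a small multistart over w0 in {10, 20, 30, 45, 60} is tried before
the fit is flagged as failed (and therefore inadequate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = ["TuningFit", "exponential_tuning", "fit_exponential", "fit_adequacy"]

W_BOUNDS = (1.0, 180.0)
W0_MULTISTART = (10.0, 20.0, 30.0, 45.0, 60.0)


def exponential_tuning(theta, m, w, o):
    """Suppression as a function of relative orientation (degrees)."""
    return -m * np.exp(-np.asarray(theta, dtype=float) / w) + o


@dataclass(frozen=True)
class TuningFit:
    m: float
    w: float
    o: float
    residual_variance: float
    data_variance: float
    adequate: bool
    converged: bool


def fit_adequacy(values, fitted_values) -> bool:
    """Strict variance-reduction rule: var(P - fit) < var(P), population
    (divide-by-n) convention for both."""
    values = np.asarray(values, dtype=float)
    fitted_values = np.asarray(fitted_values, dtype=float)
    if values.shape != fitted_values.shape:
        raise ValueError("values and fitted_values must have equal length")
    return bool(np.var(values - fitted_values) < np.var(values))


def _try_fit(thetas: np.ndarray, values: np.ndarray, w0: float):
    theta_max = thetas[np.argmax(thetas)]
    p_far = values[np.argmax(thetas)]
    p0 = [p_far - values[np.argmin(thetas)], w0, p_far]
    p0[1] = float(np.clip(p0[1], *W_BOUNDS))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OptimizeWarning)
        popt, _ = curve_fit(
            exponential_tuning, thetas, values, p0=p0,
            bounds=([-np.inf, W_BOUNDS[0], -np.inf], [np.inf, W_BOUNDS[1], np.inf]),
            xtol=1e-8, maxfev=10000,
        )
    return popt


def fit_exponential(thetas, values) -> TuningFit:
    """Least-squares fit of the exponential tuning model to one participant.

    Requires >= 4 distinct nonnegative orientations.  Optimizer failure is not
    an exception: the fit is returned with NaN parameters, ``converged=False``
    and ``adequate=False``.
    """
    thetas = np.asarray(thetas, dtype=float)
    values = np.asarray(values, dtype=float)
    if thetas.shape != values.shape or thetas.ndim != 1:
        raise ValueError("thetas and values must be 1-d arrays of equal length")
    if thetas.size < 4:
        raise ValueError("need at least 4 points to fit 3 parameters")
    if np.unique(thetas).size != thetas.size or np.any(thetas < 0):
        raise ValueError("thetas must be distinct and nonnegative")

    data_var = float(np.var(values))
    popt = None
    for w0 in (30.0,) + tuple(w for w in W0_MULTISTART if w != 30.0):
        try:
            cand = _try_fit(thetas, values, w0)
        except RuntimeError:
            continue
        if np.all(np.isfinite(cand)):
            popt = cand
            break  # multistart is a fallback, not a best-of search
    if popt is None:
        return TuningFit(np.nan, np.nan, np.nan, np.nan, data_var,
                         adequate=False, converged=False)
    fitted = exponential_tuning(thetas, *popt)
    res_var = float(np.var(values - fitted))
    return TuningFit(float(popt[0]), float(popt[1]), float(popt[2]),
                     res_var, data_var,
                     adequate=fit_adequacy(values, fitted), converged=True)
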