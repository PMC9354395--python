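"""Weibull survival curves, per-cycle transition probabilities, and fitting.

The model extrapolates progression-free and overall survival with the Weibull
law S(t) = exp(-lam * t**gamma) with t measured in 21-day model cycles.  The
per-cycle transition probability follows from the ratio of consecutive
survival values,

    P(t) = 1 - exp(lam * (t-1)**gamma - lam * t**gamma) = 1 - S(t)/S(t-1),

which is time-dependent unless gamma = 1 (the exponential, memoryless case).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

from .params import WeibullParams


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood (or least-squares) Weibull fit."""

    params: WeibullParams
    se_lam: float
    se_gamma: float
    log_likelihood: float
    n: int
    converged: bool
    method: str = "mle"


def weibull_survival(params: WeibullParams, t) -> np.ndarray | float:
    """S(t) = exp(-lam * t**gamma); accepts scalars or arrays, t >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival time must be non-negative")
    out = np.exp(-params.lam * np.power(t, params.gamma))
    return out if out.ndim else float(out)


def cycle_transition_prob(params: WeibullParams, t) -> np.ndarray | float:
    """Probability of the event during cycle t given event-free at t-1.

    Evaluates 1 - exp(lam*(t-1)**gamma - lam*t**gamma) for integer cycle
    index t >= 1.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 1):
        raise ValueError("cycle index must be >= 1")
    lam, g = params.lam, params.gamma
    out = 1.0 - np.exp(lam * np.power(t - 1.0, g) - lam * np.power(t, g))
    return out if out.ndim else float(out)


def mean_survival(params: WeibullParams, horizon: float | None = None) -> float:
    """Mean survival time in cycles.

    Unrestricted (``horizon=None``) uses the closed form
    lam**(-1/gamma) * Gamma(1 + 1/gamma); otherwise the restricted mean
    integral of S over [0, horizon] is evaluated numerically.
    """
    if horizon is None:
        return float(params.lam ** (-1.0 / params.gamma)
                     * special.gamma(1.0 + 1.0 / params.gamma))
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    if horizon == 0:
        return 0.0
    value, _ = integrate.quad(lambda t: weibull_survival(params, t), 0.0, horizon)
    return float(value)


def _lifelines_to_native(lam_ll: float, rho_ll: float) -> WeibullParams:
    # lifelines parametrizes S(t) = exp(-(t/lambda)**rho)
    return WeibullParams(lam=float(lam_ll ** (-rho_ll)), gamma=float(rho_ll))


def fit_weibull(ipd) -> FitResult:
    """Censored maximum-likelihood Weibull fit to patient-level data.

    ``ipd`` is a sequence of records with ``time`` (cycles) and ``event``
    (1 observed, 0 right-censored) attributes, as produced by
    :mod:`btc_cea.synthetic`.  Standard errors for (lam, gamma) are obtained
    from the fitter's covariance by the delta method.
    """
    from lifelines import WeibullFitter

    times = np.asarray([r.time for r in ipd], dtype=float)
    events = np.asarray([r.event for r in ipd], dtype=int)
    if times.size < 2:
        raise ValueError("need at least two records to fit")
    if events.sum() == 0:
        raise ValueError("cannot fit with all records censored")

    wf = WeibullFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            wf.fit(times, event_observed=events)
            converged = True
        except Exception as exc:  # noqa: BLE001 - surfaced, never silent
            raise RuntimeError(f"Weibull fit did not converge: {exc}") from exc

    lam_ll, rho_ll = float(wf.lambda_), float(wf.rho_)
    params = _lifelines_to_native(lam_ll, rho_ll)
    cov = np.asarray(wf.variance_matrix_)
    # lam = lambda**(-rho): gradient wrt (lambda, rho)
    grad = np.array([
        -rho_ll * lam_ll ** (-rho_ll - 1.0),
        -np.log(lam_ll) * lam_ll ** (-rho_ll),
    ])
    var_lam = float(grad @ cov @ grad)
    se_gamma = float(np.sqrt(max(cov[1, 1], 0.0)))
    return FitResult(
        params=params,
        se_lam=float(np.sqrt(max(var_lam, 0.0))),
        se_gamma=se_gamma,
        log_likelihood=float(wf.log_likelihood_),
        n=int(times.size),
        converged=converged,
        method="mle",
    )


def fit_weibull_curve(times, survival) -> FitResult:
    """Least-squares Weibull fit to digitized curve coordinates.

    Regresses log(-log S) on log t, the linearization of the Weibull survival
    function; intended for (time, survival) tables sampled from published
    Kaplan-Meier curves.  Points with S in {0, 1} or t = 0 carry no
    information under this transform and are dropped.
    """
    t = np.asarray(times, dtype=float)
    s = np.asarray(survival, dtype=float)
    keep = (t > 0) & (s > 0) & (s < 1)
    t, s = t[keep], s[keep]
    if t.size < 2:
        raise ValueError("need at least two informative (t, S) points")
    x = np.log(t)
    y = np.log(-np.log(s))
    slope, intercept = np.polyfit(x, y, 1)
    params = WeibullParams(lam=float(np.exp(intercept)), gamma=float(slope))
    if params.lam <= 0 or params.gamma <= 0:
        raise RuntimeError("curve fit produced non-positive Weibull parameters")
    resid = y - (slope * x + intercept)
    # least-squares SEs on the log-log scale, mapped back for lam
    dof = max(t.size - 2, 1)
    s2 = float(resid @ resid) / dof
    sxx = float(np.sum((x - x.mean()) ** 2))
    se_slope = np.sqrt(s2 / sxx)
    se_inter = np.sqrt(s2 * (1.0 / t.size + x.mean() ** 2 / sxx))
    return FitResult(
        params=params,
        se_lam=float(params.lam * se_inter),
        se_gamma=float(se_slope),
        log_likelihood=float("nan"),
        n=int(t.size),
        converged=True,
        method="curve-lsq",
    )
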