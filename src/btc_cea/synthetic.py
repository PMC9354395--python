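"""Synthetic patient-level survival data with the model's Weibull structure.

The published analysis reconstructed pseudo individual-patient data (IPD) by
digitizing trial Kaplan-Meier curves.  This module replaces that step with
simulation from the assumed law S(t) = exp(-lam * t**gamma), so the fitting
stage and the cohort engine can be exercised end-to-end without any external
data: event times by inverse-transform sampling, optional independent
exponential censoring calibrated to a requested expected censor fraction, and
product-limit (Kaplan-Meier) estimation of the resulting curves.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import integrate, optimize

from .params import WeibullParams
from .survival import mean_survival


@dataclass(frozen=True)
class IPDRecord:
    """One pseudo-patient: follow-up time (cycles) and event indicator."""

    time: float
    event: int  # 1 = event observed, 0 = right-censored


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier step function: survival value reached at each event time."""

    times: np.ndarray
    survival: np.ndarray

    def evaluate(self, t) -> np.ndarray:
        """Step-function value S(t); 1.0 before the first event time."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return out


def _censor_rate_for_fraction(params: WeibullParams, frac: float) -> float:
    """Exponential censoring rate giving expected censored fraction ``frac``.

    Solves P(C < T) = 1 - E[exp(-mu*T)]... expressed through the identity
    P(censored) = integral of mu*exp(-mu*t)*S_T(t) dt over t >= 0.
    """
    upper = 50.0 * mean_survival(params)

    def censored_fraction(mu: float) -> float:
        val, _ = integrate.quad(
            lambda t: mu * np.exp(-mu * t)
            * np.exp(-params.lam * t ** params.gamma),
            0.0, upper, limit=200,
        )
        return val

    lo, hi = 1e-10, 1.0
    while censored_fraction(hi) < frac:
        hi *= 10.0
        if hi > 1e8:
            raise RuntimeError("could not bracket censoring rate")
    return float(optimize.brentq(lambda mu: censored_fraction(mu) - frac, lo, hi))


def simulate_ipd(
    params: WeibullParams,
    n: int,
    censor_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> list[IPDRecord]:
    """Draw ``n`` pseudo-patients from the Weibull survival law.

    Event times come from the inverse transform T = (-ln U / lam)**(1/gamma).
    With ``censor_rate`` > 0, independent exponential censoring times are
    drawn with their rate calibrated so the expected fraction of censored
    records equals ``censor_rate``.  Identical seeds give identical datasets.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= censor_rate < 1.0):
        raise ValueError("censor_rate must be in [0, 1)")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    u = rng.uniform(size=n)
    t_event = (-np.log(u) / params.lam) ** (1.0 / params.gamma)
    if censor_rate == 0.0:
        return [IPDRecord(float(t), 1) for t in t_event]
    mu = _censor_rate_for_fraction(params, censor_rate)
    t_cens = rng.exponential(scale=1.0 / mu, size=n)
    times = np.minimum(t_event, t_cens)
    events = (t_event <= t_cens).astype(int)
    return [IPDRecord(float(t), int(e)) for t, e in zip(times, events)]


def km_curve(ipd) -> KMCurve:
    """Product-limit estimate of the survival curve from IPD records."""
    if len(ipd) == 0:
        raise ValueError("cannot estimate a curve from no records")
    from lifelines import KaplanMeierFitter

    times = np.asarray([r.time for r in ipd], dtype=float)
    events = np.asarray([r.event for r in ipd], dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = t > 0  # drop the implicit S(0)=1 anchor; evaluate() restores it
    return KMCurve(times=t[keep], survival=s[keep])


def sample_curve_points(curve: KMCurve, grid) -> np.ndarray:
    """(time, survival) pairs on ``grid``, emulating digitized coordinates.

    Grid points beyond the last observed time are clamped to it with a
    warning; the returned array has shape (len(grid), 2) and is suitable as
    input to :func:`btc_cea.survival.fit_weibull_curve`.
    """
    grid = np.asarray(grid, dtype=float)
    if curve.times.size and np.any(grid > curve.times[-1]):
        warnings.warn(
            "grid extends beyond the observed curve; clamping to last event time",
            stacklevel=2,
        )
        grid = np.minimum(grid, curve.times[-1])
    return np.column_stack([grid, curve.evaluate(grid)])


def write_ipd(ipd, path: str | Path) -> None:
    """Write records as two-column CSV (time, event)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", "event"])
        for r in ipd:
            writer.writerow([repr(r.time), r.event])


def read_ipd(path: str | Path) -> list[IPDRecord]:
    with open(path, newline="") as fh:
        return [IPDRecord(float(row["time"]), int(row["event"]))
                for row in csv.DictReader(fh)]
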