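"""Deterministic and probabilistic sensitivity analysis.

One-way sweeps re-run the full base case with a single parameter at each end
of its configured range and record the ICER (tornado diagram, widest bar
first).  The probabilistic analysis draws every uncertain parameter from a
method-of-moments Beta (utilities, event probabilities) or Gamma (costs)
distribution whose mean is the baseline and whose standard deviation treats
the configured range as a 95% interval (sd = width / 3.92; a width / 4
alternative is available via ``settings.range_sd_rule``).  Parameters are
sampled independently.  Cost-effectiveness acceptability curves report, per
willingness-to-pay value, the fraction of draws in which each strategy has
the higher net monetary benefit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import compare_strategies, run_strategy
from .params import ModelConfig, Uncertain


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    icer_low: float | None    # ICER with the parameter at its low bound
    icer_high: float | None   # ... at its high bound
    width: float              # |icer_high - icer_low|


@dataclass(frozen=True)
class PSASample:
    draw: int
    parameters: dict[str, float]
    outcomes: dict[str, tuple[float, float]]  # strategy -> (cost, qaly)


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    probability: dict[str, float]  # strategy -> P(cost-effective)


@dataclass(frozen=True)
class DistributionSpec:
    """Calibrated sampling distribution for one uncertain parameter."""

    family: str            # beta | gamma | degenerate
    mean: float
    sd: float
    params: dict[str, float]

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.family == "degenerate":
            return self.mean if size is None else np.full(size, self.mean)
        if self.family == "beta":
            return rng.beta(self.params["alpha"], self.params["beta"], size=size)
        if self.family == "gamma":
            return rng.gamma(self.params["shape"], self.params["scale"], size=size)
        raise ValueError(f"unknown family {self.family!r}")


def calibrate_distribution(
    baseline: float,
    low: float,
    high: float,
    family: str,
    sd_rule: str = "ci95",
) -> DistributionSpec:
    """Method-of-moments Beta/Gamma parameters for a baseline and range.

    The mean is anchored at the baseline; the range is read as a 95% interval
    (sd = (high - low)/3.92) under the default rule, or as mean +- 2 sd
    (sd = width/4) under ``sd_rule="quarter"``.  A zero-width range (or a
    zero baseline for gamma) collapses to a point mass at the baseline.
    """
    if not (low <= baseline <= high):
        raise ValueError(f"baseline {baseline} outside range [{low}, {high}]")
    width = high - low
    if width == 0.0 or (family == "gamma" and baseline == 0.0):
        return DistributionSpec("degenerate", baseline, 0.0, {})
    sd = width / (3.92 if sd_rule == "ci95" else 4.0)
    var = sd * sd
    if family == "beta":
        if not (0.0 < baseline < 1.0):
            raise ValueError("beta family requires a baseline in (0, 1)")
        nu = baseline * (1.0 - baseline) / var - 1.0
        if nu <= 0:
            raise ValueError(
                "range too wide for a beta distribution with this baseline"
            )
        return DistributionSpec(
            "beta", baseline, sd,
            {"alpha": baseline * nu, "beta": (1.0 - baseline) * nu},
        )
    if family == "gamma":
        if baseline < 0:
            raise ValueError("gamma family requires a non-negative baseline")
        shape = baseline * baseline / var
        return DistributionSpec(
            "gamma", baseline, sd, {"shape": shape, "scale": var / baseline}
        )
    if family == "fixed":
        return DistributionSpec("degenerate", baseline, 0.0, {})
    raise ValueError(f"unknown distribution family {family!r}")


def _icer_at(config: ModelConfig) -> tuple[float | None, str]:
    names = config.strategy_names
    a = run_strategy(config, names[0])
    b = run_strategy(config, names[1])
    inc = compare_strategies(a, b)
    return inc.icer, inc.dominance


def one_way_sweep(config: ModelConfig, parameter: str) -> TornadoEntry:
    """Re-run the base case at the low and high bound of one parameter."""
    registry = config.uncertain_parameters()
    if parameter not in registry:
        raise KeyError(f"unknown parameter {parameter!r}")
    u = registry[parameter]
    icer_low, _ = _icer_at(config.with_overrides({parameter: u.low}))
    icer_high, _ = _icer_at(config.with_overrides({parameter: u.high}))
    width = (abs(icer_high - icer_low)
             if icer_low is not None and icer_high is not None else float("inf"))
    return TornadoEntry(parameter, icer_low, icer_high, width)


def build_tornado(config: ModelConfig) -> list[TornadoEntry]:
    """One-way sweep of every configured parameter, widest ICER bar first."""
    entries = [one_way_sweep(config, name) for name in config.uncertain_parameters()]
    entries.sort(key=lambda e: e.width, reverse=True)
    return entries


def psa_distributions(config: ModelConfig) -> dict[str, DistributionSpec]:
    """Calibrated sampling distribution for every PSA-eligible parameter."""
    sd_rule = config.econ.range_sd_rule
    out = {}
    for name, u in config.uncertain_parameters().items():
        if not u.psa:
            continue
        out[name] = calibrate_distribution(u.value, u.low, u.high, u.dist, sd_rule)
    return out


def run_psa(config: ModelConfig, n_iter: int, seed: int) -> list[PSASample]:
    """Monte-Carlo parameter uncertainty propagation.

    Each draw samples all uncertain parameters simultaneously from their
    calibrated distributions, re-runs both strategies, and records
    (cost, QALY) per strategy.  Reproducible under a fixed seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    dists = psa_distributions(config)
    names = config.strategy_names
    samples: list[PSASample] = []
    for i in range(n_iter):
        drawn = {name: float(dist.sample(rng)) for name, dist in dists.items()}
        cfg_i = config.with_overrides(drawn)
        outcomes = {}
        for strat in names:
            res = run_strategy(cfg_i, strat)
            outcomes[strat] = (res.total_cost, res.total_qaly)
        samples.append(PSASample(draw=i, parameters=drawn, outcomes=outcomes))
    return samples


def default_wtp_grid(config: ModelConfig, step: float = 500.0) -> np.ndarray:
    """0 to $40,000/QALY in ``step`` increments, GDP anchors always included."""
    grid = np.arange(0.0, 40_000.0 + step, step)
    anchors = np.asarray(config.econ.wtp_per_qaly, dtype=float)
    return np.unique(np.concatenate([grid, anchors]))


def ceac(samples: list[PSASample], wtp_grid) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve from PSA samples.

    At each threshold the probability assigned to a strategy is the fraction
    of draws in which its net monetary benefit is highest; for two
    strategies the probabilities sum to 1.
    """
    if not samples:
        raise ValueError("need at least one PSA sample")
    wtp_grid = np.atleast_1d(np.asarray(wtp_grid, dtype=float))
    if wtp_grid.size == 0:
        raise ValueError("willingness-to-pay grid is empty")
    names = list(samples[0].outcomes)
    costs = {n: np.array([s.outcomes[n][0] for s in samples]) for n in names}
    qalys = {n: np.array([s.outcomes[n][1] for s in samples]) for n in names}
    points = []
    for wtp in wtp_grid:
        nmb = np.stack([wtp * qalys[n] - costs[n] for n in names])
        winner = np.argmax(nmb, axis=0)
        probs = {n: float(np.mean(winner == j)) for j, n in enumerate(names)}
        points.append(CEACPoint(wtp=float(wtp), probability=probs))
    return points


def ceac_at_anchors(
    samples: list[PSASample], config: ModelConfig, strategy: str | None = None
) -> dict[float, float]:
    """P(cost-effective) for one strategy at the configured WTP anchors."""
    strategy = strategy or config.strategy_names[0]
    points = ceac(samples, np.asarray(config.econ.wtp_per_qaly))
    return {p.wtp: p.probability[strategy] for p in points}
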