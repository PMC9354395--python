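"""Three-state cohort model: PFS -> PS -> Death, with PFS -> Death disallowed.

State occupancy is partitioned directly from the two survival curves:
progression-free occupancy is S_pfs(t), death is 1 - S_os(t), and the
progressed state holds the remainder S_os(t) - S_pfs(t).  Where the fitted
curves cross (extrapolated PFS exceeding OS), PFS occupancy is clamped to
min(S_pfs, S_os) so the progressed state is never negative — the standard
partitioned-survival repair.

Accrual conventions (configurable via the ``settings`` section):

* ``membership`` — whose occupancy a cycle's rewards are weighted by:
  ``start`` (beginning-of-cycle, the default; mirrors stage-0 reward accrual
  in cohort-simulation software), ``end``, or ``half`` (half-cycle
  correction, the average of the two).
* Costs and QALYs discount continuously per cycle fraction of a 365-day
  year: disc(t) = (1 + r)**(-t * cycle_days / 365).
* Terminal care is charged once per incident death, at the end of the cycle
  in which the death occurs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .costing import CycleCostBreakdown, state_cost
from .params import ModelConfig
from .survival import weibull_survival

_COST_COMPONENTS = ("drug", "administration", "followup", "sae", "bsc", "terminal")


@dataclass(frozen=True)
class CohortTrace:
    """Occupancy fractions at cycle boundaries t = 0..horizon."""

    strategy: str
    cycles: np.ndarray   # 0..H
    pfs: np.ndarray
    ps: np.ndarray
    dead: np.ndarray

    def occupancy(self, t: int) -> tuple[float, float, float]:
        return float(self.pfs[t]), float(self.ps[t]), float(self.dead[t])


@dataclass(frozen=True)
class StrategyResult:
    """Discounted totals plus the per-cycle accrual vectors behind them."""

    strategy: str
    total_cost: float
    total_qaly: float
    life_years: float          # undiscounted
    trace: CohortTrace
    disc_cost_increments: np.ndarray   # one entry per cycle 1..H
    disc_qaly_increments: np.ndarray
    cost_components: dict[str, float]  # discounted totals by component


@dataclass(frozen=True)
class IncrementalResult:
    """Strategy-pair comparison on unrounded totals (a versus b)."""

    delta_cost: float
    delta_qaly: float
    icer: float | None         # None when delta_qaly == 0
    dominance: str             # dominant | dominated | tradeoff | equivalent


def run_cohort_trace(config: ModelConfig, strategy: str) -> CohortTrace:
    """Evaluate state occupancy over the configured horizon."""
    econ = config.econ
    curves = config.survival(strategy)
    t = np.arange(0, econ.horizon_cycles + 1, dtype=float)
    s_pfs = weibull_survival(curves.pfs, t)
    s_os = weibull_survival(curves.os, t)
    pfs = np.minimum(s_pfs, s_os)
    dead = 1.0 - s_os
    ps = s_os - pfs
    alive_end = 1.0 - dead[-1]
    if alive_end > 1e-3:
        warnings.warn(
            f"{alive_end:.2%} of the {strategy} cohort is still alive at the "
            f"{econ.horizon_cycles}-cycle horizon; lifetime-horizon assumption "
            "violated",
            stacklevel=2,
        )
    return CohortTrace(strategy=strategy, cycles=t, pfs=pfs, ps=ps, dead=dead)


def _membership_weights(trace: CohortTrace, convention: str):
    """Per-cycle (w_pfs, w_ps, discount time) for cycles 1..H."""
    t = trace.cycles
    if convention == "start":
        return trace.pfs[:-1], trace.ps[:-1], t[:-1]
    if convention == "end":
        return trace.pfs[1:], trace.ps[1:], t[1:]
    if convention == "half":
        return (
            0.5 * (trace.pfs[:-1] + trace.pfs[1:]),
            0.5 * (trace.ps[:-1] + trace.ps[1:]),
            0.5 * (t[:-1] + t[1:]),
        )
    raise ValueError(f"unknown membership convention {convention!r}")


def accrue_outcomes(
    trace: CohortTrace, config: ModelConfig, strategy: str
) -> StrategyResult:
    """Accrue discounted costs and QALYs over the trace."""
    econ = config.econ
    util = config.utilities
    spec = config.strategy(strategy)
    cyc_yr = econ.cycle_years

    w_pfs, w_ps, t_disc = _membership_weights(trace, econ.membership)
    disc = (1.0 + econ.discount_annual) ** (-t_disc * cyc_yr)

    qaly_inc = (w_pfs * util.u_pfs + w_ps * util.u_ps) * cyc_yr * disc
    life_years = float(np.sum((w_pfs + w_ps) * cyc_yr))

    horizon = econ.horizon_cycles
    comp_vectors = {c: np.zeros(horizon) for c in _COST_COMPONENTS}
    for k in range(1, horizon + 1):
        pfs_cost = state_cost(spec, "PFS", k, econ)
        ps_cost = state_cost(spec, "PS", k, econ)
        for comp in ("drug", "administration", "followup", "sae"):
            comp_vectors[comp][k - 1] = getattr(pfs_cost, comp) * w_pfs[k - 1]
        comp_vectors["bsc"][k - 1] = ps_cost.bsc * w_ps[k - 1]

    # one-time terminal care on incident deaths, end-of-cycle timing
    new_deaths = np.diff(trace.dead)
    disc_end = (1.0 + econ.discount_annual) ** (-trace.cycles[1:] * cyc_yr)
    cost_inc = sum(comp_vectors[c] for c in _COST_COMPONENTS) * disc
    terminal_inc = new_deaths * econ.terminal_cost_once * disc_end
    cost_inc = cost_inc + terminal_inc

    components = {
        c: float(np.sum(comp_vectors[c] * disc)) for c in _COST_COMPONENTS
    }
    components["terminal"] = float(np.sum(terminal_inc))

    return StrategyResult(
        strategy=strategy,
        total_cost=float(np.sum(cost_inc)),
        total_qaly=float(np.sum(qaly_inc)),
        life_years=life_years,
        trace=trace,
        disc_cost_increments=cost_inc,
        disc_qaly_increments=qaly_inc,
        cost_components=components,
    )


def run_strategy(config: ModelConfig, strategy: str) -> StrategyResult:
    """Trace + accrual in one call."""
    return accrue_outcomes(run_cohort_trace(config, strategy), config, strategy)


def compare_strategies(a: StrategyResult, b: StrategyResult) -> IncrementalResult:
    """Incremental cost-effectiveness of ``a`` versus ``b`` (unrounded)."""
    d_cost = a.total_cost - b.total_cost
    d_qaly = a.total_qaly - b.total_qaly
    icer = None if d_qaly == 0.0 else d_cost / d_qaly
    if d_cost == 0.0 and d_qaly == 0.0:
        dominance = "equivalent"
    elif d_cost <= 0.0 and d_qaly >= 0.0:
        dominance = "dominant"
    elif d_cost >= 0.0 and d_qaly <= 0.0:
        dominance = "dominated"
    else:
        dominance = "tradeoff"
    return IncrementalResult(
        delta_cost=d_cost, delta_qaly=d_qaly, icer=icer, dominance=dominance
    )


def net_monetary_benefit(result: StrategyResult, wtp: float) -> float:
    """NMB = WTP x QALYs - cost; higher is better at the given threshold."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * result.total_qaly - result.total_cost


def basecase_summary(config: ModelConfig) -> dict:
    """Run both strategies and the comparison; return a summary mapping."""
    results = {name: run_strategy(config, name) for name in config.strategy_names}
    a, b = (results[n] for n in config.strategy_names[:2])
    inc = compare_strategies(a, b)
    return {
        "strategies": {
            r.strategy: {
                "qaly": r.total_qaly,
                "cost": r.total_cost,
                "life_years": r.life_years,
                "cost_components": r.cost_components,
            }
            for r in results.values()
        },
        "incremental": {
            "comparator": f"{a.strategy} vs {b.strategy}",
            "delta_cost": inc.delta_cost,
            "delta_qaly": inc.delta_qaly,
            "icer": inc.icer,
            "dominance": inc.dominance,
        },
        "conventions": {
            "membership": config.econ.membership,
            "rounding_policy": config.econ.rounding_policy,
            "followup_scope": config.econ.followup_scope,
        },
    }
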