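"""Per-cycle and one-time cost components.

Drug acquisition is dosed by body surface area (BSA): per administration each
drug delivers dose_per_m2 x BSA mg, repeated administrations_per_cycle times
on days_per_cycle_dosed days of the 21-day cycle.  Pack consumption follows
the configured rounding policy — ``fractional`` bills exact milligrams
(no wastage), ``whole_unit`` bills whole packs per administration (ceiling).

Serious adverse events (SAEs) are costed as expected values, incidence x unit
cost, charged once in the first treatment cycle.  Progression-free cycles
carry drug + administration + follow-up testing while on treatment (first
``max_treatment_cycles`` cycles) and, depending on the configured scope,
follow-up testing afterwards; progressed cycles carry best supportive care
(BSC) only.  Terminal care is a one-time cost on entering death, handled by
the cohort engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import EconSettings, StrategySpec


@dataclass(frozen=True)
class CycleCostBreakdown:
    """Per-person cost components (USD) for one state-cycle."""

    drug: float = 0.0
    administration: float = 0.0
    followup: float = 0.0
    sae: float = 0.0
    bsc: float = 0.0
    terminal: float = 0.0

    @property
    def total(self) -> float:
        return (self.drug + self.administration + self.followup
                + self.sae + self.bsc + self.terminal)


def drug_cost_per_cycle(
    strategy: StrategySpec, bsa: float, rounding: str = "fractional"
) -> float:
    """Acquisition cost (USD) of one treatment cycle for a BSA-dosed patient."""
    if bsa <= 0:
        raise ValueError("body surface area must be > 0")
    if rounding not in ("fractional", "whole_unit"):
        raise ValueError(f"unknown rounding policy {rounding!r}")
    total = 0.0
    for drug in strategy.drugs:
        doses = drug.administrations_per_cycle * drug.days_per_cycle_dosed
        units_per_admin = drug.dose_per_m2 * bsa / drug.unit_size_mg
        if rounding == "whole_unit":
            units_per_admin = math.ceil(units_per_admin)
        total += units_per_admin * doses * drug.unit_cost
    return total


def expected_sae_cost(profile) -> float:
    """Sum of incidence x unit treatment cost over the SAE profile."""
    total = 0.0
    for item in profile:
        if item.probability < 0 or item.unit_cost < 0:
            raise ValueError(
                f"negative rate or cost for SAE {item.event!r}"
            )
        total += item.probability * item.unit_cost
    return total


def state_cost(
    strategy: StrategySpec,
    state: str,
    cycle_index: int,
    econ: EconSettings,
) -> CycleCostBreakdown:
    """Per-person cost breakdown for occupying ``state`` during ``cycle_index``.

    ``state`` is ``"PFS"`` or ``"PS"``; cycles are 1-based.  Terminal care is
    not a state cost (it is weighted by incident deaths in the cohort
    engine) and is always 0 here.
    """
    if state not in ("PFS", "PS"):
        raise ValueError(f"unknown state {state!r}")
    if cycle_index < 1:
        raise ValueError("cycle index must be >= 1")
    if state == "PS":
        return CycleCostBreakdown(bsc=econ.bsc_cost_per_cycle)
    on_treatment = cycle_index <= strategy.max_treatment_cycles
    followup = (
        econ.followup_cost_per_cycle
        if (econ.followup_scope == "all_pfs" or on_treatment)
        else 0.0
    )
    return CycleCostBreakdown(
        drug=(drug_cost_per_cycle(strategy, econ.bsa_m2, econ.rounding_policy)
              if on_treatment else 0.0),
        administration=strategy.admin_cost_per_cycle if on_treatment else 0.0,
        followup=followup,
        sae=expected_sae_cost(strategy.sae_profile) if cycle_index == 1 else 0.0,
    )
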