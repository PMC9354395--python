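"""Domain types and model-configuration I/O.

The whole decision model is driven by one declarative YAML file holding the
regimens, Weibull survival parameters, health-state utilities, unit costs and
their uncertainty ranges.  :class:`ModelConfig` wraps the parsed tree and
exposes resolved, typed views (:class:`StrategySpec`, :class:`SurvivalSet`,
:class:`UtilitySet`, :class:`EconSettings`).  Validation is report-based so a
partially broken file can be diagnosed in one pass.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterator

import yaml

STRATEGY_NAMES = ("XELOX", "GEMOX")

MEMBERSHIP_CONVENTIONS = ("start", "end", "half")
ROUNDING_POLICIES = ("fractional", "whole_unit")
FOLLOWUP_SCOPES = ("treatment", "all_pfs")
SD_RULES = ("ci95", "quarter")


class SchemaError(ValueError):
    """Raised when a configuration file violates the documented schema."""


@dataclass(frozen=True)
class Uncertain:
    """A scalar model input with its one-way range and PSA sampling family."""

    value: float
    low: float
    high: float
    dist: str = "fixed"  # beta | gamma | fixed
    psa: bool = True

    @property
    def degenerate(self) -> bool:
        return self.low == self.high == self.value


@dataclass(frozen=True)
class WeibullParams:
    """Weibull survival curve S(t) = exp(-lam * t**gamma), t in model cycles.

    ``lam`` is the scale-like weight in the exponent (per cycle**gamma) and
    ``gamma`` the dimensionless shape; both must be positive.
    """

    lam: float
    gamma: float


@dataclass(frozen=True)
class SurvivalSet:
    """PFS and OS curves for one strategy."""

    pfs: WeibullParams
    os: WeibullParams


@dataclass(frozen=True)
class DrugLine:
    """One drug of a regimen with its pack price and per-cycle dosing."""

    name: str
    unit_cost: float          # USD per pack unit
    unit_size_mg: float       # mg per pack unit
    dose_per_m2: float        # mg per m2 per administration
    administrations_per_cycle: int
    days_per_cycle_dosed: int  # >1 only for oral daily dosing


@dataclass(frozen=True)
class SAEItem:
    """One serious adverse event: incidence in cycle 1 and unit treatment cost."""

    event: str
    probability: float
    unit_cost: float


@dataclass(frozen=True)
class StrategySpec:
    name: str
    drugs: tuple[DrugLine, ...]
    admin_cost_per_cycle: float
    max_treatment_cycles: int
    sae_profile: tuple[SAEItem, ...]


@dataclass(frozen=True)
class UtilitySet:
    u_pfs: float
    u_ps: float


@dataclass(frozen=True)
class EconSettings:
    cycle_days: float
    discount_annual: float
    bsa_m2: float
    followup_cost_per_cycle: float  # hospitalization + laboratory + CT
    bsc_cost_per_cycle: float
    terminal_cost_once: float
    horizon_cycles: int
    wtp_per_qaly: tuple[float, ...]
    rounding_policy: str = "fractional"
    membership: str = "start"
    followup_scope: str = "treatment"
    range_sd_rule: str = "ci95"

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / 365.0


@dataclass(frozen=True)
class Violation:
    field: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    def add(self, field_name: str, message: str) -> None:
        self.violations.append(Violation(field_name, message))

    @property
    def ok(self) -> bool:
        return not self.violations

    def __iter__(self) -> Iterator[Violation]:
        return iter(self.violations)

    def __len__(self) -> int:
        return len(self.violations)

    def __str__(self) -> str:
        if self.ok:
            return "configuration valid"
        return "\n".join(f"{v.field}: {v.message}" for v in self.violations)


def _parse_uncertain(node: Any, default_psa: bool = True) -> Uncertain:
    if isinstance(node, (int, float)):
        v = float(node)
        return Uncertain(v, v, v, "fixed", psa=False)
    return Uncertain(
        value=float(node["value"]),
        low=float(node.get("low", node["value"])),
        high=float(node.get("high", node["value"])),
        dist=str(node.get("dist", "fixed")),
        psa=bool(node.get("psa", default_psa)),
    )


class ModelConfig:
    """Parsed model configuration.

    Holds the raw nested tree (canonical for serialization and overrides) and
    builds typed views on demand.  Instances are treated as immutable; use
    :meth:`with_overrides` to derive perturbed configurations.
    """

    def __init__(self, data: dict):
        self.data = data

    # -- typed views ------------------------------------------------------

    @property
    def strategy_names(self) -> tuple[str, ...]:
        return tuple(s["name"] for s in self.data["strategies"])

    def _strategy_node(self, name: str) -> dict:
        for s in self.data["strategies"]:
            if s["name"] == name:
                return s
        raise KeyError(f"unknown strategy {name!r}")

    def strategy(self, name: str) -> StrategySpec:
        node = self._strategy_node(name)
        drugs = []
        for line in node["regimen"]:
            drug = line["drug"]
            dnode = self.data["drugs"][drug]
            drugs.append(
                DrugLine(
                    name=drug,
                    unit_cost=_parse_uncertain(dnode["unit_cost"]).value,
                    unit_size_mg=float(dnode["unit_size_mg"]),
                    dose_per_m2=float(line["dose_per_m2"]),
                    administrations_per_cycle=int(line["administrations_per_cycle"]),
                    days_per_cycle_dosed=int(line["days_per_cycle_dosed"]),
                )
            )
        profile = []
        for event, rate in node["sae_rates"].items():
            cost = _parse_uncertain(self.data["sae_unit_costs"][event]).value
            profile.append(SAEItem(event, _parse_uncertain(rate).value, cost))
        return StrategySpec(
            name=name,
            drugs=tuple(drugs),
            admin_cost_per_cycle=_parse_uncertain(
                self.data["economics"]["administration_per_cycle"]
            ).value,
            max_treatment_cycles=int(node["max_treatment_cycles"]),
            sae_profile=tuple(profile),
        )

    def survival(self, name: str) -> SurvivalSet:
        node = self.data["survival"][name]
        return SurvivalSet(
            pfs=WeibullParams(float(node["pfs"]["lam"]), float(node["pfs"]["gamma"])),
            os=WeibullParams(float(node["os"]["lam"]), float(node["os"]["gamma"])),
        )

    @property
    def utilities(self) -> UtilitySet:
        u = self.data["utilities"]
        return UtilitySet(
            u_pfs=_parse_uncertain(u["pfs"]).value,
            u_ps=_parse_uncertain(u["ps"]).value,
        )

    @property
    def econ(self) -> EconSettings:
        s = self.data["settings"]
        e = self.data["economics"]
        followup = sum(
            _parse_uncertain(v).value for v in e["followup_per_cycle"].values()
        )
        return EconSettings(
            cycle_days=float(s["cycle_days"]),
            discount_annual=float(s["discount_annual"]),
            bsa_m2=_parse_uncertain(s["bsa_m2"]).value,
            followup_cost_per_cycle=followup,
            bsc_cost_per_cycle=_parse_uncertain(e["bsc_per_cycle"]).value,
            terminal_cost_once=_parse_uncertain(e["terminal_once"]).value,
            horizon_cycles=int(s["horizon_cycles"]),
            wtp_per_qaly=tuple(float(w) for w in s["wtp_per_qaly"]),
            rounding_policy=str(s.get("rounding_policy", "fractional")),
            membership=str(s.get("membership", "start")),
            followup_scope=str(s.get("followup_scope", "treatment")),
            range_sd_rule=str(s.get("range_sd_rule", "ci95")),
        )

    # -- uncertain-parameter registry -------------------------------------

    def uncertain_parameters(self) -> dict[str, Uncertain]:
        """Flat name -> :class:`Uncertain` map of every ranged input.

        Names follow a dotted scheme (``utility.pfs``, ``drug_cost.gemcitabine``,
        ``sae_rate.GEMOX.neutropenia``, ``followup.ct_scan``, ``bsc``,
        ``terminal``, ``administration``, ``bsa``) shared by the tornado and
        PSA machinery and by :meth:`with_overrides`.
        """
        out: dict[str, Uncertain] = {}
        out["utility.pfs"] = _parse_uncertain(self.data["utilities"]["pfs"])
        out["utility.ps"] = _parse_uncertain(self.data["utilities"]["ps"])
        for drug, node in self.data["drugs"].items():
            out[f"drug_cost.{drug}"] = _parse_uncertain(node["unit_cost"])
        e = self.data["economics"]
        out["administration"] = _parse_uncertain(e["administration_per_cycle"])
        for comp, node in e["followup_per_cycle"].items():
            out[f"followup.{comp}"] = _parse_uncertain(node)
        out["bsc"] = _parse_uncertain(e["bsc_per_cycle"])
        out["terminal"] = _parse_uncertain(e["terminal_once"])
        for event, node in self.data["sae_unit_costs"].items():
            out[f"sae_cost.{event}"] = _parse_uncertain(node)
        for strat in self.data["strategies"]:
            for event, node in strat["sae_rates"].items():
                out[f"sae_rate.{strat['name']}.{event}"] = _parse_uncertain(node)
        out["bsa"] = _parse_uncertain(self.data["settings"]["bsa_m2"], default_psa=False)
        return out

    def _value_path(self, name: str) -> list:
        """Resolve a flat parameter name to its container and key."""
        d = self.data
        if name.startswith("utility."):
            return [d["utilities"][name.split(".", 1)[1]], "value"]
        if name.startswith("drug_cost."):
            return [d["drugs"][name.split(".", 1)[1]]["unit_cost"], "value"]
        if name == "administration":
            return [d["economics"]["administration_per_cycle"], "value"]
        if name.startswith("followup."):
            return [d["economics"]["followup_per_cycle"][name.split(".", 1)[1]], "value"]
        if name == "bsc":
            return [d["economics"]["bsc_per_cycle"], "value"]
        if name == "terminal":
            return [d["economics"]["terminal_once"], "value"]
        if name.startswith("sae_cost."):
            return [d["sae_unit_costs"][name.split(".", 1)[1]], "value"]
        if name.startswith("sae_rate."):
            _, strat, event = name.split(".", 2)
            return [self._strategy_node(strat)["sae_rates"][event], "value"]
        if name == "bsa":
            return [d["settings"]["bsa_m2"], "value"]
        raise KeyError(f"unknown parameter name {name!r}")

    def with_overrides(self, overrides: dict[str, float]) -> "ModelConfig":
        """Return a new config with the named baseline values replaced."""
        new = ModelConfig(copy.deepcopy(self.data))
        for name, value in overrides.items():
            container, key = new._value_path(name)
            container[key] = float(value)
        return new

    def with_settings(self, **settings: Any) -> "ModelConfig":
        """Return a new config with entries of the ``settings`` section replaced."""
        new = ModelConfig(copy.deepcopy(self.data))
        for key, value in settings.items():
            if key not in new.data["settings"]:
                raise KeyError(f"unknown setting {key!r}")
            new.data["settings"][key] = value
        return new

    def to_dict(self) -> dict:
        return copy.deepcopy(self.data)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ModelConfig) and self.data == other.data


# ---------------------------------------------------------------------------
# validation


def _check_uncertain(report: ValidationReport, name: str, node: Any) -> None:
    try:
        u = _parse_uncertain(node)
    except (KeyError, TypeError, ValueError) as exc:
        report.add(name, f"not a valid value/range entry ({exc})")
        return
    if not (u.low <= u.value <= u.high):
        report.add(name, f"baseline {u.value} outside range [{u.low}, {u.high}]")
    if u.dist not in ("beta", "gamma", "fixed"):
        report.add(name, f"unknown distribution family {u.dist!r}")


def validate_config(config: ModelConfig) -> ValidationReport:
    """Check every invariant; return a report listing all violations."""
    report = ValidationReport()
    d = config.data

    for section in ("settings", "utilities", "survival", "drugs", "economics",
                    "sae_unit_costs", "strategies"):
        if section not in d:
            report.add(section, "missing section")
    if not report.ok:
        return report

    s = d["settings"]
    econ_checks = [
        ("settings.cycle_days", float(s["cycle_days"]) > 0, "must be > 0"),
        ("settings.discount_annual", float(s["discount_annual"]) >= 0, "must be >= 0"),
        ("settings.horizon_cycles", int(s["horizon_cycles"]) >= 1, "must be >= 1"),
    ]
    for name, ok, msg in econ_checks:
        if not ok:
            report.add(name, msg)
    if s.get("membership", "start") not in MEMBERSHIP_CONVENTIONS:
        report.add("settings.membership", f"must be one of {MEMBERSHIP_CONVENTIONS}")
    if s.get("rounding_policy", "fractional") not in ROUNDING_POLICIES:
        report.add("settings.rounding_policy", f"must be one of {ROUNDING_POLICIES}")
    if s.get("followup_scope", "treatment") not in FOLLOWUP_SCOPES:
        report.add("settings.followup_scope", f"must be one of {FOLLOWUP_SCOPES}")
    if s.get("range_sd_rule", "ci95") not in SD_RULES:
        report.add("settings.range_sd_rule", f"must be one of {SD_RULES}")
    if _parse_uncertain(s["bsa_m2"]).value <= 0:
        report.add("settings.bsa_m2", "body surface area must be > 0")
    if any(float(w) < 0 for w in s["wtp_per_qaly"]):
        report.add("settings.wtp_per_qaly", "thresholds must be >= 0")

    for state in ("pfs", "ps"):
        _check_uncertain(report, f"utilities.{state}", d["utilities"][state])
        u = _parse_uncertain(d["utilities"][state])
        if not (0.0 <= u.value <= 1.0):
            report.add(f"utilities.{state}", f"utility {u.value} outside [0, 1]")

    for strat, node in d["survival"].items():
        for endpoint in ("pfs", "os"):
            for par in ("lam", "gamma"):
                v = float(node[endpoint][par])
                if v <= 0:
                    report.add(f"survival.{strat}.{endpoint}.{par}",
                               f"must be > 0, got {v}")

    for drug, node in d["drugs"].items():
        _check_uncertain(report, f"drugs.{drug}.unit_cost", node["unit_cost"])
        if _parse_uncertain(node["unit_cost"]).value < 0:
            report.add(f"drugs.{drug}.unit_cost", "must be >= 0")
        if float(node["unit_size_mg"]) <= 0:
            report.add(f"drugs.{drug}.unit_size_mg", "must be > 0")

    e = d["economics"]
    _check_uncertain(report, "economics.administration_per_cycle",
                     e["administration_per_cycle"])
    for comp, node in e["followup_per_cycle"].items():
        _check_uncertain(report, f"economics.followup_per_cycle.{comp}", node)
    _check_uncertain(report, "economics.bsc_per_cycle", e["bsc_per_cycle"])
    _check_uncertain(report, "economics.terminal_once", e["terminal_once"])

    for event, node in d["sae_unit_costs"].items():
        _check_uncertain(report, f"sae_unit_costs.{event}", node)
        if _parse_uncertain(node).value < 0:
            report.add(f"sae_unit_costs.{event}", "unit cost must be >= 0")

    for strat in d["strategies"]:
        name = strat.get("name", "?")
        if int(strat["max_treatment_cycles"]) < 1:
            report.add(f"strategies.{name}.max_treatment_cycles", "must be >= 1")
        if name not in d["survival"]:
            report.add(f"strategies.{name}", "no survival curves configured")
        for line in strat["regimen"]:
            prefix = f"strategies.{name}.regimen.{line.get('drug', '?')}"
            if line["drug"] not in d["drugs"]:
                report.add(prefix, "drug not in drugs table")
            for fld in ("dose_per_m2", "administrations_per_cycle", "days_per_cycle_dosed"):
                if float(line[fld]) <= 0:
                    report.add(f"{prefix}.{fld}", "must be > 0")
        for event, node in strat["sae_rates"].items():
            prefix = f"strategies.{name}.sae_rates.{event}"
            _check_uncertain(report, prefix, node)
            p = _parse_uncertain(node).value
            if not (0.0 <= p <= 1.0):
                report.add(prefix, f"probability {p} outside [0, 1]")
            if event not in d["sae_unit_costs"]:
                report.add(prefix, "no unit cost configured for this event")
    return report


# ---------------------------------------------------------------------------
# load / save


def load_model_config(path: str | Path | None = None) -> ModelConfig:
    """Load and validate a configuration file.

    With ``path=None`` the packaged base-case configuration (the published
    parameter tables) is loaded.  Raises :class:`SchemaError` naming every
    offending field if validation fails.
    """
    if path is None:
        text = resources.files("btc_cea").joinpath("data/default_config.yaml").read_text()
    else:
        text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SchemaError(f"configuration is not valid YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise SchemaError("configuration root must be a mapping")
    config = ModelConfig(data)
    try:
        report = validate_config(config)
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"configuration is structurally incomplete: {exc!r}") from exc
    if not report.ok:
        raise SchemaError(str(report))
    return config


def save_model_config(config: ModelConfig, path: str | Path) -> None:
    """Serialize a configuration back to YAML (round-trip identity)."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
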