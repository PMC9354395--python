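"""Result serialization: tidy CSVs, JSON summaries, and run manifests.

Every subcommand writes a ``manifest.json`` next to its results recording the
configuration digest, seed, package version and the modelling conventions in
force, so any output file can be reproduced exactly from its manifest.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import StrategyResult
from .params import ModelConfig
from .sensitivity import CEACPoint, PSASample, TornadoEntry


def config_digest(config: ModelConfig) -> str:
    """SHA-256 of the canonical YAML serialization of the configuration."""
    canonical = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def write_manifest(
    out_dir: Path,
    config: ModelConfig,
    subcommand: str,
    seed: int | None = None,
    extra: dict | None = None,
) -> Path:
    econ = config.econ
    manifest = {
        "subcommand": subcommand,
        "config_digest": config_digest(config),
        "seed": seed,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "conventions": {
            "membership": econ.membership,
            "rounding_policy": econ.rounding_policy,
            "followup_scope": econ.followup_scope,
            "range_sd_rule": econ.range_sd_rule,
        },
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def write_trace_csv(results: list[StrategyResult], out_dir: Path) -> Path:
    """Long-format occupancy (trace.csv) and per-cycle accruals (accruals.csv)."""
    occ_rows, acc_rows = [], []
    for res in results:
        tr = res.trace
        for t in range(tr.cycles.size):
            for state, arr in (("PFS", tr.pfs), ("PS", tr.ps), ("Death", tr.dead)):
                occ_rows.append(
                    {"strategy": res.strategy, "cycle": t, "state": state,
                     "occupancy": arr[t]}
                )
        for k in range(res.disc_cost_increments.size):
            acc_rows.append(
                {"strategy": res.strategy, "cycle": k + 1,
                 "disc_cost_increment": res.disc_cost_increments[k],
                 "disc_qaly_increment": res.disc_qaly_increments[k]}
            )
    pd.DataFrame(occ_rows).to_csv(out_dir / "trace.csv", index=False)
    pd.DataFrame(acc_rows).to_csv(out_dir / "accruals.csv", index=False)
    return out_dir / "trace.csv"


def write_summary_json(summary: dict, out_dir: Path) -> Path:
    path = out_dir / "summary.json"
    path.write_text(json.dumps(summary, indent=2) + "\n")
    return path


def write_tornado_csv(entries: list[TornadoEntry], out_dir: Path) -> Path:
    df = pd.DataFrame(
        [{"parameter": e.parameter, "icer_low": e.icer_low,
          "icer_high": e.icer_high, "width": e.width} for e in entries]
    )
    path = out_dir / "tornado.csv"
    df.to_csv(path, index=False)
    return path


def write_psa_csv(samples: list[PSASample], out_dir: Path) -> Path:
    rows = [
        {"draw": s.draw, "strategy": strat, "cost": cost, "qaly": qaly}
        for s in samples
        for strat, (cost, qaly) in s.outcomes.items()
    ]
    path = out_dir / "psa_samples.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_ceac_csv(points: list[CEACPoint], out_dir: Path) -> Path:
    names = list(points[0].probability)
    rows = [
        {"wtp": p.wtp, **{f"p_{n}": p.probability[n] for n in names}}
        for p in points
    ]
    path = out_dir / "ceac.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
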