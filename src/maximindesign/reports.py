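"""Scenario runner and CSV/JSON report writers.

:func:`run_scenario` ties the engines together: per requested design it
computes the maximin solution, the sample-size plan, the relative
efficiency against the other designs and, when ``n_sim > 0``, a simulated
power check.  Report columns use the package's symbol names (``rho_A``,
``rho_B``, ``allocation_ratio``, ...) so CSV output round-trips through
ordinary readers without loss.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import ScenarioConfig
from .maximin import maximin_params, relative_efficiency
from .samplesize import maximin_sample_size
from .simulate import monte_carlo_power

__all__ = ["ScenarioReport", "run_scenario", "write_reports"]

COLUMNS = [
    "design",
    "effect",
    "rho_A",
    "rho_B",
    "branch",
    "allocation_ratio",
    "p1",
    "variance",
    "relative_efficiency",
    "efficiency_pct",
    "n_raw",
    "n1",
    "n2",
    "N",
    "correction_per_arm",
    "power_sim",
    "power_pi_low",
    "power_pi_high",
]


def round_half_up_pct(ratio: float) -> int:
    """Whole-percent, half-up rounding used in the textual reports.

    A small epsilon keeps exact rational ties (e.g. 17/40 = 42.5%) on the
    half-up side when floating point lands them a few ulps below .5.
    """
    return int(math.floor(100.0 * ratio + 0.5 + 1e-9))


@dataclass(frozen=True)
class ScenarioReport:
    config: ScenarioConfig
    table: pd.DataFrame

    def to_json_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "results": self.table.to_dict(orient="records"),
        }


def run_scenario(config: ScenarioConfig) -> ScenarioReport:
    """Evaluate every design in the scenario and assemble the report table."""
    spec = config.power_spec
    solutions = [
        maximin_params(d, config.effect, config.costs, config.rect)
        for d in config.designs
    ]
    effs = relative_efficiency(solutions)
    rows = []
    for design, sol, eff in zip(config.designs, solutions, effs):
        plan = maximin_sample_size(design, config.effect, spec, config.costs, config.rect)
        row = {
            "design": design.value,
            "effect": config.effect.value,
            "rho_A": sol.rho_at[0],
            "rho_B": sol.rho_at[1],
            "branch": "degenerate" if config.rect.is_point else sol.branch,
            "allocation_ratio": sol.allocation_ratio,
            "p1": sol.p1,
            "variance": sol.variance,
            "relative_efficiency": eff,
            "efficiency_pct": round_half_up_pct(eff),
            "n_raw": plan.n_raw,
            "n1": plan.n1,
            "n2": plan.n2,
            "N": plan.N,
            "correction_per_arm": plan.correction_per_arm,
            "power_sim": None,
            "power_pi_low": None,
            "power_pi_high": None,
        }
        if config.n_sim > 0:
            mc = monte_carlo_power(
                design,
                config.effect,
                spec,
                config.costs,
                config.rect,
                sigma_y_sq=config.sigma_y_sq,
                n_sim=config.n_sim,
                seed=config.seed,
            )
            row["power_sim"] = mc.power
            row["power_pi_low"], row["power_pi_high"] = mc.predictive_interval
        rows.append(row)
    return ScenarioReport(config=config, table=pd.DataFrame(rows, columns=COLUMNS))


def write_reports(report: ScenarioReport, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the report as ``<name>.csv`` and ``<name>.json`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = report.config.name
    csv_path = out_dir / f"{stem}.csv"
    json_path = out_dir / f"{stem}.json"
    report.table.to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2)
    return csv_path, json_path
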