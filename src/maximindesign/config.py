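"""Scenario configuration: a named bundle of costs, ICC ranges and power goals.

Config files are flat YAML key-value mappings whose keys match the symbol
names used throughout the package (``c_A``, ``c_B``, ``c_t``, ``c_sp``,
``c_s2p``, ``c_ts``, ``rhoA_low``, ``rhoA_high``, ``rhoB_low``,
``rhoB_high``, ``ES``, ``alpha``, ``power``, ``designs``, ``effect``,
``sigma_y_sq``, ``n_sim``, ``seed``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .model import CostStructure, DesignKind, EffectOfInterest, ICCRectangle
from .samplesize import PowerSpec

__all__ = ["ScenarioConfig", "load_config", "example_config_path"]

_COST_KEYS = ("c_A", "c_B", "c_t", "c_sp", "c_s2p", "c_ts")
_RECT_KEYS = ("rhoA_low", "rhoA_high", "rhoB_low", "rhoB_high")


@dataclass(frozen=True)
class ScenarioConfig:
    """Validated inputs for one planning scenario."""

    costs: CostStructure
    rect: ICCRectangle
    power_spec: PowerSpec
    designs: tuple[DesignKind, ...]
    effect: EffectOfInterest
    sigma_y_sq: float = 2.0
    n_sim: int = 0  # 0 disables power simulation
    seed: int = 0
    name: str = "scenario"

    def __post_init__(self) -> None:
        if self.sigma_y_sq <= 0:
            raise ValueError("sigma_y_sq must be > 0")
        if self.n_sim < 0:
            raise ValueError("n_sim must be >= 0")
        if not self.designs:
            raise ValueError("at least one design is required")
        if (
            self.effect is EffectOfInterest.TREATMENT_BY_PERIOD
            and DesignKind.PARALLEL in self.designs
        ):
            raise ValueError(
                "designs: the parallel design cannot estimate the "
                "treatment-by-period interaction"
            )

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        raw = dict(raw)
        errors: list[str] = []

        def grab(key, default=None, required=False):
            if key in raw:
                return raw.pop(key)
            if required:
                errors.append(f"{key}: missing required key")
            return default

        cost_kwargs = {k: float(grab(k, 0.0)) for k in _COST_KEYS}
        rect_kwargs = {k: grab(k, required=True) for k in _RECT_KEYS}
        es = grab("ES", required=True)
        alpha = grab("alpha", 0.05)
        power = grab("power", 0.80)
        designs = grab("designs", [d.value for d in DesignKind])
        if isinstance(designs, str):
            designs = [designs]
        effect = grab("effect", EffectOfInterest.TREATMENT.value)
        sigma_y_sq = float(grab("sigma_y_sq", 2.0))
        n_sim = int(grab("n_sim", 0))
        seed = int(grab("seed", 0))
        name = str(grab("name", "scenario"))
        if raw:
            errors.append(f"unknown keys: {sorted(raw)}")
        if errors:
            raise ValueError("invalid scenario config: " + "; ".join(errors))

        def build(label, fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (ValueError, TypeError) as exc:
                errors.append(f"{label}: {exc}")
                return None

        costs = build("costs", CostStructure, **cost_kwargs)
        rect = build(
            "rect", lambda: ICCRectangle(**{k: float(v) for k, v in rect_kwargs.items()})
        )
        power_spec = build(
            "power", PowerSpec, alpha=float(alpha), power=float(power), es=float(es)
        )
        design_tuple = build(
            "designs", lambda: tuple(DesignKind(d) for d in designs)
        )
        effect_val = build("effect", EffectOfInterest, effect)
        if errors:
            raise ValueError("invalid scenario config: " + "; ".join(errors))
        return cls(
            costs=costs,
            rect=rect,
            power_spec=power_spec,
            designs=design_tuple,
            effect=effect_val,
            sigma_y_sq=sigma_y_sq,
            n_sim=n_sim,
            seed=seed,
            name=name,
        )

    def to_dict(self) -> dict:
        d = {k: getattr(self.costs, k) for k in _COST_KEYS}
        d.update({k: getattr(self.rect, k) for k in _RECT_KEYS})
        d.update(
            name=self.name,
            ES=self.power_spec.es,
            alpha=self.power_spec.alpha,
            power=self.power_spec.power,
            designs=[dk.value for dk in self.designs],
            effect=self.effect.value,
            sigma_y_sq=self.sigma_y_sq,
            n_sim=self.n_sim,
            seed=self.seed,
        )
        return d


def load_config(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    return ScenarioConfig.from_dict(raw)


def example_config_path() -> Path:
    """Path to the packaged COPD bronchodilator planning example."""
    return Path(resources.files("maximindesign") / "data" / "copd_example.yaml")
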