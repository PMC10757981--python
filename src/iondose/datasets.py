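"""Packaged example data: the five-step replenishment benchmark.

Ships the benchmark's target schedule and the per-step fertilizer
injections recorded under both dosing methods, used by the comparison
pipeline and the worked examples.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .mass_balance import TargetRecipe
from .simulation import Scenario, TankState

__all__ = ["load_stepwise_scenario", "load_stepwise_injections", "scenario_from_dict"]


def _read_text(name: str) -> str:
    return resources.files("iondose.data").joinpath(name).read_text(encoding="utf-8")


def scenario_from_dict(payload: dict, method: str = "decision_tree") -> Scenario:
    """Build a :class:`~iondose.simulation.Scenario` from a parsed YAML mapping."""
    steps = []
    for entry in payload["steps"]:
        entry = dict(entry)
        volume = entry.pop("volume")
        steps.append(TargetRecipe(concentrations=entry, volume=volume))
    init = payload["initial"]
    return Scenario(
        steps=steps,
        initial=TankState(volume=init["volume"], concentrations=dict(init["concentrations"])),
        concentration_limit=payload.get("concentration_limit", 20.0),
        volume_limit=payload.get("volume_limit", 10.0),
        method=method,  # type: ignore[arg-type]
    )


def load_stepwise_scenario(method: str = "decision_tree") -> Scenario:
    """The packaged five-step target schedule as a runnable scenario."""
    return scenario_from_dict(yaml.safe_load(_read_text("stepwise_scenario.yaml")), method)


def load_stepwise_injections() -> pd.DataFrame:
    """Per-step salt injections (mg) for both methods: columns step, method, salt, mass_mg."""
    with resources.files("iondose.data").joinpath("stepwise_injections.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        return pd.read_csv(fh)
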