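"""Closed-loop stepwise replenishment harness.

Reproduces the structure of a stepwise bench test: at each step the
tank is measured (optionally through the noisy electrode model), the
per-ion demand is computed against that step's target recipe, a dose is
planned with either the decision tree or the simplex baseline, and the
tank state is advanced under perfect instantaneous mixing. Plant uptake
and evapotranspiration are not modelled — the harness isolates the
dosing algorithm from crop dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from . import decision_tree, simplex_baseline
from .actuation import DosePlan, PumpSpec, build_plan, quantize_plan
from .chemistry import SaltSpec, StockSolution, default_registry, salt_masses_to_ion_masses
from .emissions import EmissionFactors, MethodEmissions, co2eq
from .mass_balance import (
    IonRequirements,
    MeasuredState,
    TargetRecipe,
    UptakeRatios,
    WaterProfile,
    required_ion_masses,
)
from .sensing import ISEModel, measure_tank

__all__ = [
    "TankState",
    "Scenario",
    "StepResult",
    "Trajectory",
    "apply_dose",
    "run_stepwise",
    "generate_random_state",
    "default_stocks",
    "default_pumps",
]

Method = Literal["decision_tree", "simplex"]


@dataclass
class TankState:
    """Volume (L) and per-ion concentrations (mg/L) of the mixing tank."""

    volume: float
    concentrations: dict[str, float]

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise ValueError("tank volume must be non-negative")
        for ion, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {ion}: {c}")

    def ion_masses(self) -> dict[str, float]:
        return {ion: c * self.volume for ion, c in self.concentrations.items()}


@dataclass(frozen=True)
class Scenario:
    """A stepwise replenishment schedule.

    ``concentration_limit`` / ``volume_limit`` are the closed-loop lower
    limits in percent below target that trigger a replenishment when
    ``triggered`` mode is used; scheduled mode (the default, matching
    the bench protocol) replenishes at every step regardless.
    """

    steps: Sequence[TargetRecipe]
    initial: TankState
    water: WaterProfile = field(default_factory=WaterProfile)
    ratios: UptakeRatios = field(default_factory=UptakeRatios)
    concentration_limit: float = 20.0
    volume_limit: float = 10.0
    method: Method = "decision_tree"
    trigger_mode: Literal["scheduled", "triggered"] = "scheduled"

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("a scenario needs at least one step")
        for limit in (self.concentration_limit, self.volume_limit):
            if not 0 < limit <= 100:
                raise ValueError("limits must lie in (0, 100]")


@dataclass
class StepResult:
    """Everything one replenishment step produced."""

    step: int
    target: TargetRecipe
    measured: MeasuredState
    requirements: IonRequirements
    dose: decision_tree.SaltDose
    plan: DosePlan
    state_after: TankState
    emissions: MethodEmissions
    signed_solution: simplex_baseline.SignedSaltSolution | None = None
    skipped: bool = False


@dataclass
class Trajectory:
    """Ordered step results plus scenario-level accumulators."""

    steps: list[StepResult]

    @property
    def total_salt_mass(self) -> float:
        return sum(r.dose.total_mass for r in self.steps)

    def salt_totals(self) -> dict[str, float]:
        totals: dict[str, float] = {}
        for r in self.steps:
            for salt, m in r.dose.masses.items():
                totals[salt] = totals.get(salt, 0.0) + m
        return totals


def default_stocks(registry: Mapping[str, SaltSpec] | None = None) -> dict[str, StockSolution]:
    """20,000 mg/L single-salt stocks on 1 mL/s metering pumps."""
    reg = default_registry() if registry is None else registry
    return {name: StockSolution(salt=spec) for name, spec in reg.items()}


def default_pumps(registry: Mapping[str, SaltSpec] | None = None) -> dict[str, PumpSpec]:
    reg = default_registry() if registry is None else registry
    return {name: PumpSpec(discharge=1e-3, step=0.1) for name in reg}


def apply_dose(
    state: TankState,
    plan: DosePlan,
    water: WaterProfile | None = None,
    registry: Mapping[str, SaltSpec] | None = None,
) -> TankState:
    """Advance the tank under perfect instantaneous mixing.

    New ion mass = old mass + salt deliveries + make-up-water content;
    the stock solutions' carrier water contributes volume but no tracked
    ions. Raises on a zero final volume.
    """
    water = water or WaterProfile()
    delivered = salt_masses_to_ion_masses(plan.salt_masses, registry)
    masses = state.ion_masses()
    for ion, m in delivered.items():
        masses[ion] = masses.get(ion, 0.0) + m
    # Make-up water carries the source-water ion profile; the
    # micronutrient concentrate carries no tracked macro-ions.
    for ion, c in water.concentrations.items():
        masses[ion] = masses.get(ion, 0.0) + c * plan.water_volume
    volume = state.volume + plan.total_added_volume
    if volume <= 0:
        raise ValueError("tank volume is zero after dosing")
    return TankState(volume=volume, concentrations={i: m / volume for i, m in masses.items()})


def _needs_replenishment(scenario: Scenario, target: TargetRecipe, measured: MeasuredState) -> bool:
    if scenario.trigger_mode == "scheduled":
        return True
    c_floor = 1.0 - scenario.concentration_limit / 100.0
    v_floor = 1.0 - scenario.volume_limit / 100.0
    if measured.volume < v_floor * target.volume:
        return True
    return any(
        measured.get_ise(ion) < c_floor * target.get(ion)
        for ion in measured.ise
        if target.get(ion) > 0
    )


def run_stepwise(
    scenario: Scenario,
    sensors: Mapping[str, ISEModel] | None = None,
    seed: int | None = None,
    stocks: Mapping[str, StockSolution] | None = None,
    pumps: Mapping[str, PumpSpec] | None = None,
    factors: EmissionFactors | None = None,
    registry: Mapping[str, SaltSpec] | None = None,
    mg_p_mode: Literal["measured", "ratio"] = "ratio",
    concentrate_multiple: float = 200.0,
    quantize: bool = False,
) -> Trajectory:
    """Run measure → compute → dose → mix over every scenario step.

    With ``sensors=None`` measurement is exact. A fixed seed makes the
    noisy run reproducible. ``quantize=True`` snaps runtimes to the pump
    grid before mixing.
    """
    reg = default_registry() if registry is None else registry
    stocks = stocks or default_stocks(reg)
    pumps = pumps or default_pumps(reg)
    rng = np.random.default_rng(seed)
    state = TankState(scenario.initial.volume, dict(scenario.initial.concentrations))
    results: list[StepResult] = []

    for i, target in enumerate(scenario.steps, start=1):
        if sensors is None:
            measured = MeasuredState(
                ise={ion: state.concentrations.get(ion, 0.0) for ion in ("Ca", "K", "NO3")},
                volume=state.volume,
                lab={
                    ion: state.concentrations.get(ion, 0.0)
                    for ion in ("Mg", "H2PO4")
                }
                if mg_p_mode == "measured"
                else None,
            )
        else:
            lab = (
                {ion: state.concentrations.get(ion, 0.0) for ion in ("Mg", "H2PO4")}
                if mg_p_mode == "measured"
                else None
            )
            measured = measure_tank(state, sensors, rng, lab=lab)

        skipped = not _needs_replenishment(scenario, target, measured)
        req = required_ion_masses(
            target, measured, scenario.water, scenario.ratios, mg_p_mode
        )

        signed = None
        if skipped:
            dose = decision_tree.SaltDose(masses={s: 0.0 for s in reg})
        elif scenario.method == "decision_tree":
            dose = decision_tree.plan_salts(req, reg)
        elif scenario.method == "simplex":
            signed = simplex_baseline.solve_simplex(req, reg)
            dose = simplex_baseline.clip_to_actuation(signed)
        else:
            raise ValueError(f"unknown method {scenario.method!r}")

        v_target = target.volume if not skipped else measured.volume
        plan = build_plan(
            dose.masses, stocks, v_target, measured.volume, concentrate_multiple
        )
        if quantize:
            plan = quantize_plan(plan, pumps)
        state = apply_dose(state, plan, scenario.water, reg)
        results.append(
            StepResult(
                step=i,
                target=target,
                measured=measured,
                requirements=req,
                dose=dose,
                plan=plan,
                state_after=TankState(state.volume, dict(state.concentrations)),
                emissions=co2eq(dose.masses, factors, reg),
                signed_solution=signed,
                skipped=skipped,
            )
        )
    return Trajectory(steps=results)


def generate_random_state(
    recipe: TargetRecipe, deviation_pct: float, seed: int | np.random.Generator | None = None
) -> TankState:
    """A tank state scattered uniformly within ±deviation% of a recipe.

    Useful as a fixture generator spanning the band of target levels a
    stepwise test explores; deviation 0 returns the recipe itself.
    """
    if deviation_pct < 0:
        raise ValueError("deviation must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = deviation_pct / 100.0
    conc = {
        ion: c * rng.uniform(1.0 - d, 1.0 + d) for ion, c in recipe.concentrations.items()
    }
    return TankState(volume=recipe.volume, concentrations=conc)
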