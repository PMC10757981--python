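"""Closed-loop harness: mixing physics, convergence, method comparison."""

import numpy as np
import pytest

from iondose.actuation import build_plan
from iondose.chemistry import salt_masses_to_ion_masses
from iondose.datasets import load_stepwise_scenario
from iondose.mass_balance import TargetRecipe, WaterProfile
from iondose.simulation import (
    Scenario,
    TankState,
    apply_dose,
    default_stocks,
    generate_random_state,
    run_stepwise,
)

# A recipe whose demand structure the tree can satisfy exactly for the
# measured ions: calcium's coupled nitrate stays below the nitrate
# demand and potassium is generous enough that KNO3 carries the nitrate
# remainder with K2SO4 absorbing the potassium balance.
CONFLICT_FREE = TargetRecipe(
    concentrations={"Ca": 80.0, "K": 140.4, "NO3": 434.0, "Mg": 24.3, "H2PO4": 97.0},
    volume=20.0,
)


def test_empty_plan_leaves_state_unchanged(registry):
    state = TankState(volume=12.0, concentrations={"K": 100.0, "NO3": 300.0})
    plan = build_plan({}, default_stocks(registry), v_target=12.0, v_current=12.0)
    after = apply_dose(state, plan)
    assert after.volume == state.volume
    for ion, c in state.concentrations.items():
        assert after.concentrations[ion] == pytest.approx(c)
    assert all(c == 0.0 for i, c in after.concentrations.items()
               if i not in state.concentrations)


def test_pure_water_addition_dilutes(registry):
    state = TankState(volume=10.0, concentrations={"K": 100.0})
    plan = build_plan({}, default_stocks(registry), v_target=20.0, v_current=10.0,
                      concentrate_multiple=1e12)  # negligible concentrate volume
    after = apply_dose(state, plan)
    assert after.volume == pytest.approx(20.0)
    assert after.concentrations["K"] == pytest.approx(50.0, rel=1e-9)


def test_mass_and_volume_conservation(registry):
    """Per-ion mass before + injected = after, to 1e-9 relative; volume adds exactly."""
    rng = np.random.default_rng(17)
    stocks = default_stocks(registry)
    for _ in range(50):
        state = TankState(
            volume=float(rng.uniform(5, 30)),
            concentrations={i: float(rng.uniform(10, 500)) for i in ("Ca", "K", "NO3", "Mg", "H2PO4", "NH4")},
        )
        masses = {n: float(rng.uniform(0, 5000)) for n in registry}
        v_t = state.volume + float(rng.uniform(1, 10))
        plan = build_plan(masses, stocks, v_t, state.volume)
        after = apply_dose(state, plan)
        assert after.volume == pytest.approx(state.volume + plan.total_added_volume, abs=1e-12)
        delivered = salt_masses_to_ion_masses(masses, registry)
        before = state.ion_masses()
        for ion, m_after in after.ion_masses().items():
            expect = before.get(ion, 0.0) + delivered.get(ion, 0.0)
            assert m_after == pytest.approx(expect, rel=1e-9, abs=1e-9)


def test_closed_loop_convergence_without_conflicts():
    """From an under-target diluted state with exact sensing, one
    replenishment lands the measured ions within 0.1% of target."""
    initial = TankState(
        volume=14.0,
        concentrations={k: 0.75 * v for k, v in CONFLICT_FREE.concentrations.items()},
    )
    scenario = Scenario(steps=[CONFLICT_FREE], initial=initial)
    traj = run_stepwise(scenario)
    final = traj.steps[-1].state_after
    assert final.volume == pytest.approx(CONFLICT_FREE.volume, abs=1e-9)
    for ion in ("Ca", "K", "NO3"):
        rel = abs(final.concentrations[ion] / CONFLICT_FREE.get(ion) - 1.0)
        assert rel < 1e-3, (ion, final.concentrations[ion])


def test_idempotence_at_target():
    """A second scheduled replenishment at the same target doses nothing."""
    initial = TankState(
        volume=14.0,
        concentrations={k: 0.75 * v for k, v in CONFLICT_FREE.concentrations.items()},
    )
    scenario = Scenario(steps=[CONFLICT_FREE, CONFLICT_FREE], initial=initial)
    traj = run_stepwise(scenario)
    second = traj.steps[1]
    assert second.dose.total_mass == pytest.approx(0.0, abs=1e-6)
    for ion in ("Ca", "K", "NO3"):
        assert second.state_after.concentrations[ion] == pytest.approx(
            traj.steps[0].state_after.concentrations[ion], rel=1e-9
        )


def test_at_target_single_step_doses_nothing():
    state = TankState(volume=CONFLICT_FREE.volume, concentrations=dict(CONFLICT_FREE.concentrations))
    traj = run_stepwise(Scenario(steps=[CONFLICT_FREE], initial=state))
    assert traj.steps[0].dose.total_mass == pytest.approx(0.0, abs=1e-9)
    assert traj.steps[0].plan.water_volume == pytest.approx(0.0, abs=1e-12)


def test_stepwise_benchmark_tree_lighter_than_simplex():
    """On the packaged five-step schedule under exact sensing, the tree's
    total injected salt never exceeds the clipped simplex total, and both
    runs hit every target volume."""
    dt = run_stepwise(load_stepwise_scenario("decision_tree"))
    sx = run_stepwise(load_stepwise_scenario("simplex"))
    assert dt.total_salt_mass <= sx.total_salt_mass + 1e-6
    for traj in (dt, sx):
        for r in traj.steps:
            assert r.state_after.volume == pytest.approx(r.target.volume, abs=1e-9)
    # sole-source salts agree between the two methods at every step
    for a, b in zip(dt.steps, sx.steps):
        assert a.dose.masses["MgSO4·7H2O"] == pytest.approx(
            b.dose.masses["MgSO4·7H2O"], abs=1e-6
        )


def test_triggered_mode_skips_in_band_states():
    """Within the 20%/10% lower limits nothing is dosed in triggered mode."""
    near = TankState(
        volume=0.95 * CONFLICT_FREE.volume,
        concentrations={k: 0.9 * v for k, v in CONFLICT_FREE.concentrations.items()},
    )
    scenario = Scenario(steps=[CONFLICT_FREE], initial=near, trigger_mode="triggered")
    traj = run_stepwise(scenario)
    assert traj.steps[0].skipped
    assert traj.steps[0].dose.total_mass == 0.0
    # a 25% concentration deficit breaches the 20% limit and triggers
    low = TankState(
        volume=0.95 * CONFLICT_FREE.volume,
        concentrations={k: 0.75 * v for k, v in CONFLICT_FREE.concentrations.items()},
    )
    traj2 = run_stepwise(Scenario(steps=[CONFLICT_FREE], initial=low, trigger_mode="triggered"))
    assert not traj2.steps[0].skipped
    assert traj2.steps[0].dose.total_mass > 0.0


def test_generate_random_state_bounds_and_determinism():
    recipe = CONFLICT_FREE
    assert generate_random_state(recipe, 0.0, seed=1).concentrations == pytest.approx(
        dict(recipe.concentrations)
    )
    s1 = generate_random_state(recipe, 20.0, seed=42)
    s2 = generate_random_state(recipe, 20.0, seed=42)
    assert s1.concentrations == pytest.approx(s2.concentrations)
    rng = np.random.default_rng(0)
    for _ in range(300):
        s = generate_random_state(recipe, 20.0, seed=rng)
        for ion, c in s.concentrations.items():
            t = recipe.get(ion)
            assert 0.8 * t - 1e-9 <= c <= 1.2 * t + 1e-9
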