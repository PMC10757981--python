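"""Decision-tree allocation: traces, caps, overdose discipline, optimality."""

import numpy as np
import pytest

from conftest import make_requirements, random_requirements
from iondose.chemistry import ion_mass_fraction
from iondose.decision_tree import dose_mg_salt, plan_salts, verify_overdose

import oracle_utils


def test_zero_and_negative_requirements_dose_nothing():
    for mg in (0.0, -10.0):
        req = make_requirements({"Mg": mg})
        assert dose_mg_salt(req) == 0.0
    dose = plan_salts(make_requirements({ion: -5.0 for ion in ("Ca", "K", "NO3", "NH4", "H2PO4", "Mg")}))
    assert all(m == 0.0 for m in dose.masses.values())
    assert len(dose.masses) == 7


def test_mg_salt_one_millimole():
    req = make_requirements({"Mg": 24.305})
    assert dose_mg_salt(req) == pytest.approx(246.5, abs=0.1)


def test_ammonium_phosphate_capped_by_phosphate():
    """The phosphate check supersedes the ammonium-driven candidate."""
    req = make_requirements({"NH4": 50.0, "H2PO4": 10.0})
    dose = plan_salts(req)
    frac = ion_mass_fraction("NH4H2PO4", "H2PO4")
    assert dose.masses["NH4H2PO4"] == pytest.approx(10.0 / frac)
    assert dose.masses["KH2PO4"] == 0.0
    entry = next(t for t in dose.trace if t.salt == "NH4H2PO4")
    assert entry.leaf == "final 2"
    assert entry.candidate > entry.chosen


def test_calcium_coupling_suppresses_nitrate_salts():
    """When calcium's coupled nitrate covers the NO3 demand, the nitrate
    salts stay off while P, K and NH4 are served by the sulfate/phosphate
    routes (the qualitative first-step pattern of the benchmark)."""
    ca = 600.0
    coupled_no3 = ca / ion_mass_fraction("Ca(NO3)2·4H2O", "Ca") * ion_mass_fraction(
        "Ca(NO3)2·4H2O", "NO3"
    )
    # NH4 small enough that the ammonium phosphate leaves phosphate for KH2PO4
    req = make_requirements(
        {"Ca": ca, "NO3": 0.8 * coupled_no3, "K": 400.0, "NH4": 15.0, "H2PO4": 120.0}
    )
    dose = plan_salts(req)
    assert dose.masses["KNO3"] == 0.0
    assert dose.masses["NH4NO3"] == 0.0
    assert dose.masses["NH4H2PO4"] > 0.0
    assert dose.masses["KH2PO4"] > 0.0
    assert dose.masses["K2SO4"] > 0.0
    report = verify_overdose(req, dose)
    assert report.flagged == ()
    assert report.overshoot["NO3"] > 0.0
    assert report.overshoot["NO3"] <= report.ca_coupled_no3 + 1e-6


def test_overdose_report_zero_on_zero():
    req = make_requirements({})
    dose = plan_salts(req)
    report = verify_overdose(req, dose)
    assert report.flagged == ()
    assert all(v == pytest.approx(0.0, abs=1e-9) for v in report.overshoot.values())


def test_no_uncoupled_overdose_on_random_suite(requirement_suite):
    """Across 1000 random demand vectors no ion is overdosed except
    nitrate through the calcium salt; masses are always non-negative."""
    for req in requirement_suite:
        dose = plan_salts(req)
        assert all(m >= 0.0 for m in dose.masses.values())
        report = verify_overdose(req, dose, tolerance=1e-6)
        assert report.flagged == (), (req.raw, dose.masses, report.overshoot)


def test_trace_covers_every_nonzero_dose(requirement_suite):
    for req in requirement_suite[:50]:
        dose = plan_salts(req)
        traced = {t.salt for t in dose.trace if t.chosen > 0}
        nonzero = {s for s, m in dose.masses.items() if m > 0}
        assert nonzero == traced


def test_priority_respect_under_lower_priority_reductions():
    """Shrinking the NO3 demand never hurts Ca, P or K, and shrinking the
    NH4 demand never hurts Ca or K. (Ammonium is the carrier ion of
    NH4H2PO4, so a smaller NH4 demand can legitimately reduce the
    deliverable phosphate when potassium is scarce; phosphate is
    therefore not asserted under NH4 reductions.)"""
    rng = np.random.default_rng(7)

    def shortfalls(req):
        dose = plan_salts(req)
        delivered = dose.delivered_ions()
        return {i: max(req.get(i) - delivered.get(i, 0.0), 0.0) for i in ("Ca", "H2PO4", "K")}

    for _ in range(200):
        req = random_requirements(rng, allow_negative=False)
        base = shortfalls(req)
        for ion, protected in (("NO3", ("Ca", "H2PO4", "K")), ("NH4", ("Ca", "K"))):
            reduced = dict(req.raw)
            reduced[ion] *= rng.uniform(0.0, 0.9)
            after = shortfalls(make_requirements(reduced))
            for p in protected:
                assert after[p] <= base[p] + 1e-6


def test_matches_grid_oracle_on_sparse_instances():
    """On instances with at most three active ions, no feasible grid
    point beats the tree's allocation on the priority-ordered objective
    (shortfalls of Ca, then P+K, then NO3, then uncoupled overdose,
    then total mass) by more than the grid resolution."""
    rng = np.random.default_rng(42)
    subsets = [
        ("Ca",), ("H2PO4",), ("K",), ("NO3",), ("NH4",),
        ("Ca", "NO3"), ("K", "NO3"), ("NH4", "H2PO4"), ("H2PO4", "K"),
        ("Ca", "K", "NO3"), ("K", "NO3", "NH4"), ("H2PO4", "K", "NH4"),
        ("Ca", "H2PO4", "K"),
    ]
    scale = {"Ca": 800, "H2PO4": 500, "K": 900, "NO3": 2500, "NH4": 200}
    for subset in subsets:
        for _ in range(3):
            raw = {ion: float(rng.uniform(0.2, 1.0) * scale[ion]) for ion in subset}
            req = make_requirements(raw)
            dose = plan_salts(req)
            plan_obj = oracle_utils.plan_objective(dose.masses, raw)
            best, tol = oracle_utils.grid_search(raw)
            assert best is not None
            assert not oracle_utils.beats(best, plan_obj, tol), (
                subset, raw, dose.masses, plan_obj, best, tol,
            )
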