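"""Priority-ordered decision-tree allocation of fertilizer salts.

Two trees convert per-ion replenishment masses into salt doses. The
magnesium tree is trivial: MgSO4·7H2O is the sole Mg source and its
sulfate is not tracked, so it is dosed independently. The main tree
walks the remaining six salts in a fixed order with the ion priority

    Ca > H2PO4 = K > NO3 > NH4

maintaining a running ledger of remaining per-ion demand. At each salt
node a candidate mass is computed from the node's driver ion
("final 1"); if injecting that candidate would overdose the node's
coupled check ion, the mass is recomputed from the check ion's
remaining demand instead ("final 2"), which supersedes the candidate.
Calcium nitrate's nitrate load is injected regardless — there is no
decoupled calcium source — and potassium sulfate is the terminal
potassium sink because sulfate is unconstrained.

The resulting plan never overdoses any ion except NO3 (through the
unavoidable Ca coupling) and SO4, at the cost of accepting shortfalls
in low-priority ions rather than overshooting high-priority ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .chemistry import SaltSpec, default_registry, salt_masses_to_ion_masses

__all__ = [
    "EPSILON_MG",
    "PRIORITY",
    "TREE_SEQUENCE",
    "TraceEntry",
    "SaltDose",
    "OverdoseReport",
    "dose_mg_salt",
    "plan_salts",
    "verify_overdose",
]

# Remaining demand below this (mg) counts as satisfied; exact zeros take
# the no-injection branch.
EPSILON_MG = 1e-9

# Lower number = higher priority; H2PO4 and K share a rank.
PRIORITY: Mapping[str, int] = {"Ca": 0, "H2PO4": 1, "K": 1, "NO3": 2, "NH4": 3}

# (salt, driver ion, check ion) in traversal order. The driver sets the
# candidate mass; the check ion, when present, caps it.
TREE_SEQUENCE: tuple[tuple[str, str, str | None], ...] = (
    ("Ca(NO3)2·4H2O", "Ca", None),
    ("NH4H2PO4", "NH4", "H2PO4"),
    ("KH2PO4", "H2PO4", "K"),
    ("KNO3", "K", "NO3"),
    ("NH4NO3", "NO3", "NH4"),
    ("K2SO4", "K", None),
)


@dataclass(frozen=True)
class TraceEntry:
    """One decision node: which leaf fired and with what numbers (mg)."""

    salt: str
    driver: str
    candidate: float  # "final 1" mass from the driver ion
    check_ion: str | None
    chosen: float  # mass actually planned
    leaf: str  # "no-injection", "final 1" or "final 2"


@dataclass
class SaltDose:
    """Planned mass per salt (mg) with the decision trace that produced it."""

    masses: dict[str, float]
    trace: list[TraceEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        for salt, m in self.masses.items():
            if m < 0:
                raise ValueError(f"negative planned mass for {salt}: {m}")

    @property
    def total_mass(self) -> float:
        return sum(self.masses.values())

    def delivered_ions(self, registry: Mapping[str, SaltSpec] | None = None) -> dict[str, float]:
        return salt_masses_to_ion_masses(self.masses, registry)


def dose_mg_salt(
    req, registry: Mapping[str, SaltSpec] | None = None
) -> float:
    """Mass of MgSO4·7H2O (mg) covering the magnesium demand.

    Operates independently of the main tree: magnesium has a single
    source and its co-ion (sulfate) is untracked.
    """
    reg = default_registry() if registry is None else registry
    frac = reg["MgSO4·7H2O"].ion_fraction("Mg")
    return max(req.get("Mg"), 0.0) / frac


def plan_salts(
    req, registry: Mapping[str, SaltSpec] | None = None
) -> SaltDose:
    """Allocate all seven salts for an :class:`~iondose.mass_balance.IonRequirements`.

    Walks :data:`TREE_SEQUENCE` with a running remaining-demand ledger;
    each node takes the no-injection branch when its driver demand is
    exhausted, otherwise plans the driver-derived candidate unless the
    check ion would be overdosed, in which case the check-derived cap
    supersedes it. Degenerate inputs (all demands <= 0) yield all-zero
    doses.
    """
    reg = default_registry() if registry is None else registry
    remaining = {ion: req.get(ion) for ion in ("Ca", "H2PO4", "K", "NO3", "NH4")}
    masses: dict[str, float] = {}
    trace: list[TraceEntry] = []

    for salt_name, driver, check in TREE_SEQUENCE:
        spec = reg[salt_name]
        d_frac = spec.ion_fraction(driver)
        if remaining[driver] <= EPSILON_MG:
            masses[salt_name] = 0.0
            trace.append(TraceEntry(salt_name, driver, 0.0, check, 0.0, "no-injection"))
            continue
        candidate = remaining[driver] / d_frac
        mass, leaf = candidate, "final 1"
        if check is not None:
            c_frac = spec.ion_fraction(check)
            if candidate * c_frac > remaining[check] + EPSILON_MG:
                mass = max(remaining[check], 0.0) / c_frac
                leaf = "final 2"
        masses[salt_name] = mass
        trace.append(TraceEntry(salt_name, driver, candidate, check, mass, leaf))
        for ion in spec.composition:
            if ion in remaining:
                remaining[ion] -= mass * spec.ion_fraction(ion)

    mg_mass = dose_mg_salt(req, reg)
    masses["MgSO4·7H2O"] = mg_mass
    leaf = "final 1" if mg_mass > 0 else "no-injection"
    trace.append(TraceEntry("MgSO4·7H2O", "Mg", mg_mass, None, mg_mass, leaf))
    return SaltDose(masses=masses, trace=trace)


@dataclass(frozen=True)
class OverdoseReport:
    """Per-ion overshoot of delivered over required mass (mg).

    ``flagged`` lists ions whose overshoot exceeds tolerance and is not
    explained by the sole-source Ca -> NO3 coupling.
    """

    overshoot: Mapping[str, float]
    flagged: tuple[str, ...]
    ca_coupled_no3: float


def verify_overdose(
    req,
    dose: SaltDose,
    registry: Mapping[str, SaltSpec] | None = None,
    tolerance: float = 1e-6,
) -> OverdoseReport:
    """Audit a plan: delivered minus required mass per ion.

    Nitrate overshoot up to the nitrate injected by the calcium salt is
    attributed to the unavoidable coupling; anything else above
    ``tolerance`` is flagged.
    """
    reg = default_registry() if registry is None else registry
    delivered = salt_masses_to_ion_masses(dose.masses, reg)
    ca_no3 = dose.masses.get("Ca(NO3)2·4H2O", 0.0) * reg["Ca(NO3)2·4H2O"].ion_fraction("NO3")
    overshoot = {
        ion: delivered.get(ion, 0.0) - req.get(ion)
        for ion in ("Ca", "H2PO4", "K", "NO3", "NH4", "Mg")
    }
    flagged = []
    for ion, over in overshoot.items():
        if over <= tolerance:
            continue
        if ion == "NO3" and over <= ca_no3 + tolerance:
            continue
        flagged.append(ion)
    return OverdoseReport(overshoot=overshoot, flagged=tuple(flagged), ca_coupled_no3=ca_no3)
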