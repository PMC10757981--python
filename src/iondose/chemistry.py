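"""Fertilizer-salt stoichiometry for closed-hydroponic dosing.

Converts between salt masses, constituent nutrient-ion masses, and
elemental N/P/K content. The default registry holds the seven
single-salt fertilizers that give every major ion at least two sources
except calcium and magnesium:

    Ca(NO3)2·4H2O, KH2PO4, NH4H2PO4, KNO3, NH4NO3, MgSO4·7H2O, K2SO4

All masses are milligrams unless noted. Ion species are tracked as the
ions a salt dissolves into (NO3, NH4, K, Ca, Mg, H2PO4, SO4) rather
than as elements; phosphorus bookkeeping therefore happens on the
dihydrogen-phosphate ion, with :func:`h2po4_to_p` / :func:`p_to_h2po4`
bridging to elemental P for emission accounting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ATOMIC_WEIGHTS",
    "Ion",
    "SaltSpec",
    "StockSolution",
    "ION_NAMES",
    "get_ion",
    "default_registry",
    "ion_mass_fraction",
    "salt_masses_to_ion_masses",
    "elemental_npk",
    "h2po4_to_p",
    "p_to_h2po4",
    "registry_to_yaml",
    "registry_from_yaml",
]

# IUPAC standard atomic weights, abridged to >= 4 significant decimals.
ATOMIC_WEIGHTS: Mapping[str, float] = {
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "Mg": 24.305,
    "P": 30.973762,
    "S": 32.06,
    "K": 39.0983,
    "Ca": 40.078,
}

# Atom counts of each tracked ion species.
_ION_FORMULAS: Mapping[str, Mapping[str, int]] = {
    "NO3": {"N": 1, "O": 3},
    "NH4": {"N": 1, "H": 4},
    "K": {"K": 1},
    "Ca": {"Ca": 1},
    "Mg": {"Mg": 1},
    "H2PO4": {"H": 2, "P": 1, "O": 4},
    "SO4": {"S": 1, "O": 4},
}

ION_NAMES: tuple[str, ...] = tuple(_ION_FORMULAS)

# Which fertilizer element, if any, each ion carries. Sulfate carries
# sulfur only, which is not accounted for (it is not harmful to crops
# and has no emission factor here).
_ELEMENT_OF_ION: Mapping[str, str] = {"NO3": "N", "NH4": "N", "H2PO4": "P", "K": "K"}


def _formula_mass(atoms: Mapping[str, int | float]) -> float:
    return sum(ATOMIC_WEIGHTS[el] * n for el, n in atoms.items())


_WATER_MASS = _formula_mass({"H": 2, "O": 1})


@dataclass(frozen=True)
class Ion:
    """A nutrient-ion species with its formula mass and elemental content.

    ``elemental_map`` maps the fertilizer elements N, P, K to the mass
    fraction of the ion attributable to that element (empty for Ca, Mg
    and SO4).
    """

    name: str
    formula_mass: float
    elemental_map: Mapping[str, float]


def _build_ion(name: str) -> Ion:
    atoms = _ION_FORMULAS[name]
    mass = _formula_mass(atoms)
    elemental: dict[str, float] = {}
    element = _ELEMENT_OF_ION.get(name)
    if element is not None:
        elemental[element] = ATOMIC_WEIGHTS[element] * atoms.get(element, 1) / mass
    return Ion(name, mass, elemental)


_IONS: Mapping[str, Ion] = {name: _build_ion(name) for name in ION_NAMES}


def get_ion(name: str) -> Ion:
    """Return the :class:`Ion` for ``name``, raising ``KeyError`` if unknown."""
    try:
        return _IONS[name]
    except KeyError:
        raise KeyError(
            f"unknown ion {name!r}; tracked species are {', '.join(ION_NAMES)}"
        ) from None


@dataclass(frozen=True)
class SaltSpec:
    """Stoichiometry of one fertilizer salt.

    ``composition`` maps tracked ion names to counts per formula unit;
    ``hydration`` is the number of waters of crystallisation, which
    contribute to the molar mass but to no tracked ion.
    """

    name: str
    composition: Mapping[str, int]
    hydration: int = 0
    molar_mass: float = field(default=0.0)

    def __post_init__(self) -> None:
        for ion_name in self.composition:
            get_ion(ion_name)  # validate
        if not any(self.composition.values()):
            raise ValueError(f"salt {self.name!r} contains no tracked ion")
        computed = (
            sum(get_ion(i).formula_mass * n for i, n in self.composition.items())
            + self.hydration * _WATER_MASS
        )
        if self.molar_mass == 0.0:
            object.__setattr__(self, "molar_mass", computed)
        elif abs(self.molar_mass - computed) > 0.01:
            raise ValueError(
                f"molar mass of {self.name!r} ({self.molar_mass}) disagrees with "
                f"its composition ({computed:.3f} g/mol)"
            )

    def ion_fraction(self, ion_name: str) -> float:
        """Mass fraction of the salt contributed by ``ion_name`` (0 if absent)."""
        count = self.composition.get(ion_name, 0)
        if count == 0:
            return 0.0
        return count * get_ion(ion_name).formula_mass / self.molar_mass


@dataclass(frozen=True)
class StockSolution:
    """A dissolved single-salt stock and the metering pump that doses it.

    ``concentration`` is mg of salt per litre of stock (default 20,000,
    the working concentration of the bench system this models);
    ``discharge`` is the pump's flow in L/s.
    """

    salt: SaltSpec
    concentration: float = 20_000.0
    discharge: float = 1e-3

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("stock concentration must be positive")
        if self.discharge <= 0:
            raise ValueError("pump discharge must be positive")


_DEFAULT_SALTS: tuple[tuple[str, Mapping[str, int], int], ...] = (
    ("Ca(NO3)2·4H2O", {"Ca": 1, "NO3": 2}, 4),
    ("KH2PO4", {"K": 1, "H2PO4": 1}, 0),
    ("NH4H2PO4", {"NH4": 1, "H2PO4": 1}, 0),
    ("KNO3", {"K": 1, "NO3": 1}, 0),
    ("NH4NO3", {"NH4": 1, "NO3": 1}, 0),
    ("MgSO4·7H2O", {"Mg": 1, "SO4": 1}, 7),
    ("K2SO4", {"K": 2, "SO4": 1}, 0),
)


def default_registry() -> dict[str, SaltSpec]:
    """The seven-salt fertilizer registry used throughout the package."""
    return {
        name: SaltSpec(name, dict(comp), hyd) for name, comp, hyd in _DEFAULT_SALTS
    }


def _lookup(registry: Mapping[str, SaltSpec] | None, salt: str | SaltSpec) -> SaltSpec:
    if isinstance(salt, SaltSpec):
        return salt
    reg = default_registry() if registry is None else registry
    try:
        return reg[salt]
    except KeyError:
        raise KeyError(
            f"unknown salt {salt!r}; registry holds {', '.join(sorted(reg))}"
        ) from None


def ion_mass_fraction(
    salt: str | SaltSpec, ion_name: str, registry: Mapping[str, SaltSpec] | None = None
) -> float:
    """Mass fraction of ``salt`` contributed by ``ion_name``.

    Returns 0 for an ion the salt does not contain; unknown salt or ion
    names raise ``KeyError``.
    """
    get_ion(ion_name)
    return _lookup(registry, salt).ion_fraction(ion_name)


def salt_masses_to_ion_masses(
    doses: Mapping[str, float], registry: Mapping[str, SaltSpec] | None = None
) -> dict[str, float]:
    """Per-ion delivered mass (mg) from a salt-dose map (mg per salt).

    Linear in the doses; negative doses are rejected (use the signed
    report type of the simplex baseline for signed bookkeeping).
    """
    out = {name: 0.0 for name in ION_NAMES}
    for salt_name, mass in doses.items():
        if mass < 0:
            raise ValueError(f"negative dose for {salt_name!r}: {mass}")
        spec = _lookup(registry, salt_name)
        for ion_name in spec.composition:
            out[ion_name] += mass * spec.ion_fraction(ion_name)
    return out


def elemental_npk(
    doses: Mapping[str, float], registry: Mapping[str, SaltSpec] | None = None
) -> dict[str, float]:
    """Elemental N, P and K masses (mg) delivered by a salt-dose map.

    N counts nitrogen in both nitrate and ammonium moieties; P the
    phosphorus of dihydrogen phosphate; K all potassium.
    """
    ions = salt_masses_to_ion_masses(doses, registry)
    out = {"N": 0.0, "P": 0.0, "K": 0.0}
    for ion_name, mass in ions.items():
        for element, frac in get_ion(ion_name).elemental_map.items():
            out[element] += mass * frac
    return out


def h2po4_to_p(mass_h2po4: float) -> float:
    """Convert a dihydrogen-phosphate ion mass to elemental phosphorus mass."""
    ion = get_ion("H2PO4")
    return mass_h2po4 * ion.elemental_map["P"]


def p_to_h2po4(mass_p: float) -> float:
    """Convert an elemental phosphorus mass to the equivalent H2PO4 ion mass."""
    ion = get_ion("H2PO4")
    return mass_p / ion.elemental_map["P"]


def registry_to_yaml(registry: Mapping[str, SaltSpec]) -> str:
    """Serialize a salt registry to YAML (name, composition, hydration, molar mass)."""
    payload = {
        name: {
            "composition": dict(spec.composition),
            "hydration": spec.hydration,
            "molar_mass": round(spec.molar_mass, 4),
        }
        for name, spec in registry.items()
    }
    return yaml.safe_dump(payload, allow_unicode=True, sort_keys=True)


def registry_from_yaml(text: str) -> dict[str, SaltSpec]:
    """Inverse of :func:`registry_to_yaml`; accepts JSON too (JSON is YAML)."""
    payload = yaml.safe_load(text)
    out = {}
    for name, entry in payload.items():
        out[name] = SaltSpec(
            name,
            dict(entry["composition"]),
            int(entry.get("hydration", 0)),
            float(entry.get("molar_mass", 0.0)),
        )
    return out


def registry_to_json(registry: Mapping[str, SaltSpec]) -> str:
    payload = yaml.safe_load(registry_to_yaml(registry))
    return json.dumps(payload, ensure_ascii=False, indent=2, sort_keys=True)
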