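"""Method-comparison pipeline over per-step injection tables.

Takes a tidy injection table with columns (step, method, salt, mass_mg)
and reduces it to per-salt totals, delivered ion masses, elemental
N/P/K, CO2 equivalents, and percent differences between two dosing
methods — the full bookkeeping needed to compare a priority decision
tree against the simplex baseline on fertilizer mass and emissions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .chemistry import SaltSpec, default_registry, salt_masses_to_ion_masses
from .emissions import EmissionComparison, EmissionFactors, compare_methods, co2eq

__all__ = ["MethodSummary", "ComparisonReport", "summarize_method", "compare_injection_table"]

REQUIRED_COLUMNS = ("step", "method", "salt", "mass_mg")

# Salts whose dissolution releases nitrate.
NITRATE_SALTS = ("Ca(NO3)2·4H2O", "KNO3", "NH4NO3")


@dataclass(frozen=True)
class MethodSummary:
    """Aggregates for one dosing method."""

    method: str
    salt_totals_mg: Mapping[str, float]
    total_salt_mg: float
    ion_masses_mg: Mapping[str, float]
    nitrate_from_salts_mg: float
    npk_g: Mapping[str, float]
    co2eq_g: Mapping[str, float]
    total_co2eq_g: float


@dataclass(frozen=True)
class ComparisonReport:
    """Two method summaries plus the headline percent differences.

    Percentages follow the convention of the emission module:
    ``*_higher`` is method A over method B, ``*_reduction`` the saving
    of B relative to A.
    """

    a: MethodSummary
    b: MethodSummary
    emissions: EmissionComparison
    fertilizer_percent_higher: float
    fertilizer_percent_reduction: float
    nitrate_percent_higher: float


def _validate(table: pd.DataFrame, registry: Mapping[str, SaltSpec]) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"injection table lacks columns: {', '.join(missing)}")
    unknown = sorted(set(table["salt"]) - set(registry))
    if unknown:
        raise ValueError(
            f"unknown salts {unknown}; registry holds {sorted(registry)}"
        )


def summarize_method(
    table: pd.DataFrame,
    method: str,
    factors: EmissionFactors | None = None,
    registry: Mapping[str, SaltSpec] | None = None,
) -> MethodSummary:
    """Reduce one method's injections to totals, ion masses, N/P/K and CO2eq."""
    reg = default_registry() if registry is None else registry
    _validate(table, reg)
    sub = table[table["method"] == method]
    if sub.empty:
        raise ValueError(f"no rows for method {method!r}")
    totals = sub.groupby("salt")["mass_mg"].sum().to_dict()
    ions = salt_masses_to_ion_masses(totals, reg)
    nitrate = sum(
        totals.get(s, 0.0) * reg[s].ion_fraction("NO3") for s in NITRATE_SALTS
    )
    em = co2eq(totals, factors, reg)
    return MethodSummary(
        method=method,
        salt_totals_mg=totals,
        total_salt_mg=float(sum(totals.values())),
        ion_masses_mg=ions,
        nitrate_from_salts_mg=nitrate,
        npk_g=dict(em.element_mass_g),
        co2eq_g=dict(em.co2eq_g),
        total_co2eq_g=em.total_co2eq_g,
    )


def compare_injection_table(
    table: pd.DataFrame,
    method_a: str = "simplex",
    method_b: str = "decision_tree",
    factors: EmissionFactors | None = None,
    registry: Mapping[str, SaltSpec] | None = None,
) -> ComparisonReport:
    """Full comparison of two dosing methods recorded in one injection table."""
    reg = default_registry() if registry is None else registry
    sa = summarize_method(table, method_a, factors, reg)
    sb = summarize_method(table, method_b, factors, reg)
    em = compare_methods(sa.salt_totals_mg, sb.salt_totals_mg, factors, reg)
    fert_higher = 100.0 * (sa.total_salt_mg / sb.total_salt_mg - 1.0)
    fert_reduction = 100.0 * (sa.total_salt_mg - sb.total_salt_mg) / sa.total_salt_mg
    nitrate_higher = 100.0 * (sa.nitrate_from_salts_mg / sb.nitrate_from_salts_mg - 1.0)
    return ComparisonReport(
        a=sa,
        b=sb,
        emissions=em,
        fertilizer_percent_higher=fert_higher,
        fertilizer_percent_reduction=fert_reduction,
        nitrate_percent_higher=nitrate_higher,
    )
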