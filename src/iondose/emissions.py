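"""CO2-equivalent accounting for fertilizer doses.

Fertilizer production carries an embodied greenhouse-gas cost that is
conventionally expressed per gram of elemental nutrient. A salt-dose
map is reduced to elemental N, P and K masses and multiplied by fixed
emission factors (g CO2eq per g of element); two dosing methods are
compared element-by-element and in total. Factors vary by country and
producer, so they are plain configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .chemistry import SaltSpec, elemental_npk

__all__ = ["ELEMENTS", "EmissionFactors", "MethodEmissions", "EmissionComparison", "co2eq", "compare_methods"]

ELEMENTS: tuple[str, ...] = ("N", "P", "K")


@dataclass(frozen=True)
class EmissionFactors:
    """g CO2eq per g of elemental nutrient."""

    N: float = 1.526
    P: float = 1.631
    K: float = 0.6545

    def __post_init__(self) -> None:
        for el in ELEMENTS:
            if getattr(self, el) <= 0:
                raise ValueError(f"emission factor for {el} must be positive")

    def get(self, element: str) -> float:
        return float(getattr(self, element))


@dataclass(frozen=True)
class MethodEmissions:
    """Elemental masses (g) and CO2 equivalents (g) for one dosing method."""

    element_mass_g: Mapping[str, float]
    co2eq_g: Mapping[str, float]

    @property
    def total_mass_g(self) -> float:
        return sum(self.element_mass_g.values())

    @property
    def total_co2eq_g(self) -> float:
        return sum(self.co2eq_g.values())


@dataclass(frozen=True)
class EmissionComparison:
    """Two methods side by side with percent differences.

    ``percent_higher[el]`` is how much method A exceeds method B for
    element ``el`` (100·(a/b − 1)); ``percent_reduction[el]`` is the
    saving of B relative to A (100·(a − b)/a). The two satisfy
    (1 + h/100)(1 − r/100) = 1. Keys include ``"total"``.
    """

    a: MethodEmissions
    b: MethodEmissions
    percent_higher: Mapping[str, float]
    percent_reduction: Mapping[str, float]


def co2eq(
    doses: Mapping[str, float],
    factors: EmissionFactors | None = None,
    registry: Mapping[str, SaltSpec] | None = None,
) -> MethodEmissions:
    """Reduce a salt-dose map (mg) to elemental masses and CO2eq (g)."""
    factors = factors or EmissionFactors()
    npk_mg = elemental_npk(doses, registry)
    mass_g = {el: npk_mg[el] / 1000.0 for el in ELEMENTS}
    return MethodEmissions(
        element_mass_g=mass_g,
        co2eq_g={el: mass_g[el] * factors.get(el) for el in ELEMENTS},
    )


def _percentages(a: float, b: float) -> tuple[float, float]:
    if a == 0.0 and b == 0.0:
        return 0.0, 0.0
    higher = 100.0 * (a / b - 1.0) if b != 0 else float("inf")
    reduction = 100.0 * (a - b) / a if a != 0 else float("-inf")
    return higher, reduction


def compare_methods(
    doses_a: Mapping[str, float],
    doses_b: Mapping[str, float],
    factors: EmissionFactors | None = None,
    registry: Mapping[str, SaltSpec] | None = None,
) -> EmissionComparison:
    """Compare the CO2eq footprints of two dose maps over the same registry."""
    ea = co2eq(doses_a, factors, registry)
    eb = co2eq(doses_b, factors, registry)
    higher: dict[str, float] = {}
    reduction: dict[str, float] = {}
    for el in ELEMENTS:
        higher[el], reduction[el] = _percentages(ea.co2eq_g[el], eb.co2eq_g[el])
    higher["total"], reduction["total"] = _percentages(ea.total_co2eq_g, eb.total_co2eq_g)
    return EmissionComparison(a=ea, b=eb, percent_higher=higher, percent_reduction=reduction)
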