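"""Per-ion replenishment masses from tank state, targets and water profile.

The replenishment demand for each directly measured ion x in
{Ca, K, NO3} is a straight mass balance over the mixing tank:

    N_x = T_x * V_target - D_x * V_current - W_x * (V_target - V_current)

where T is the target concentration (mg/L), D the concentration
measured by the ion-selective electrodes, W the ion content of the
make-up water, and V the tank volumes (L). Ammonium, for which no
robust electrode exists, is pegged to the nitrate demand through an
uptake ratio; magnesium and phosphate are either taken from laboratory
measurements (``measured`` mode) or pegged to calcium and nitrate
respectively (``ratio`` mode).

Raw demands may be negative when an ion is over target; ions cannot be
selectively removed from a recirculating solution, so dosing operates
on the clamped-at-zero view while the raw values are kept for
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

__all__ = [
    "REQUIREMENT_IONS",
    "TargetRecipe",
    "MeasuredState",
    "WaterProfile",
    "UptakeRatios",
    "IonRequirements",
    "required_ion_masses",
    "clamp_nonnegative",
]

# Ions with an explicit replenishment demand, in dosing-priority order.
REQUIREMENT_IONS: tuple[str, ...] = ("Ca", "H2PO4", "K", "NO3", "NH4", "Mg")

MgPMode = Literal["measured", "ratio"]


@dataclass(frozen=True)
class TargetRecipe:
    """Target ion concentrations (mg/L) and target tank volume (L).

    Phosphate targets are expressed as H2PO4 ion mass; use
    :func:`iondose.chemistry.p_to_h2po4` when a recipe is written in
    elemental P.
    """

    concentrations: Mapping[str, float]
    volume: float

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("target volume must be positive")
        for ion, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative target concentration for {ion}: {c}")

    def get(self, ion: str) -> float:
        return float(self.concentrations.get(ion, 0.0))


@dataclass(frozen=True)
class MeasuredState:
    """Tank state as seen by the controller.

    ``ise`` holds the electrode readings for Ca, K and NO3 (mg/L);
    ``lab`` optionally holds externally analysed Mg and H2PO4
    concentrations; ``volume`` is the level-sensor reading (L).
    """

    ise: Mapping[str, float]
    volume: float
    lab: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise ValueError("measured volume must be non-negative")
        for src in (self.ise, self.lab or {}):
            for ion, c in src.items():
                if c < 0:
                    raise ValueError(f"negative concentration for {ion}: {c}")

    def get_ise(self, ion: str) -> float:
        return float(self.ise.get(ion, 0.0))

    def get_lab(self, ion: str) -> float | None:
        if self.lab is None or ion not in self.lab:
            return None
        return float(self.lab[ion])


@dataclass(frozen=True)
class WaterProfile:
    """Ion content of the make-up water (mg/L); all zeros by default."""

    concentrations: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ion, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative water concentration for {ion}: {c}")

    def get(self, ion: str) -> float:
        return float(self.concentrations.get(ion, 0.0))


@dataclass(frozen=True)
class UptakeRatios:
    """Mass ratios pegging unmeasured ions to measured ones.

    ``nh4_per_no3``: NH4 demand per unit NO3 demand; ``mg_per_ca``: Mg
    demand per unit Ca demand; ``h2po4_per_no3``: H2PO4 demand per unit
    NO3 demand. Shipped defaults are the ion-mass ratios of a modified
    Hoagland solution for leafy vegetables (NH4 18, Mg 24.3, H2PO4 97
    mg/L against NO3 434 and Ca 80 mg/L).
    """

    nh4_per_no3: float = 18.0 / 434.0
    mg_per_ca: float = 24.3 / 80.0
    h2po4_per_no3: float = 97.0 / 434.0

    def __post_init__(self) -> None:
        for name in ("nh4_per_no3", "mg_per_ca", "h2po4_per_no3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class IonRequirements:
    """Raw (signed) and clamped per-ion replenishment masses in mg.

    ``mg_mode`` / ``p_mode`` record whether magnesium and phosphate used
    laboratory concentrations or uptake ratios.
    """

    raw: Mapping[str, float]
    mg_mode: MgPMode = "ratio"
    p_mode: MgPMode = "ratio"

    def __post_init__(self) -> None:
        for ion, v in self.raw.items():
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"non-finite requirement for {ion}")

    @property
    def clamped(self) -> dict[str, float]:
        return {ion: max(v, 0.0) for ion, v in self.raw.items()}

    def get(self, ion: str, clamped: bool = True) -> float:
        v = float(self.raw.get(ion, 0.0))
        return max(v, 0.0) if clamped else v


def _balance(t: float, meas: float, w: float, v_t: float, v_c: float) -> float:
    return t * v_t - meas * v_c - w * (v_t - v_c)


def required_ion_masses(
    recipe: TargetRecipe,
    state: MeasuredState,
    water: WaterProfile | None = None,
    ratios: UptakeRatios | None = None,
    mg_p_mode: MgPMode = "ratio",
) -> IonRequirements:
    """Compute the signed replenishment mass of each major ion.

    Raises ``ValueError`` when the tank already holds more than the
    target volume (drainage is not modelled) and when ``measured`` mode
    is requested without laboratory Mg/H2PO4 values.
    """
    water = water or WaterProfile()
    ratios = ratios or UptakeRatios()
    v_t, v_c = recipe.volume, state.volume
    if v_t < v_c:
        raise ValueError(
            f"target volume {v_t} L below current volume {v_c} L; "
            "drainage is not modelled"
        )
    dv = v_t - v_c

    raw: dict[str, float] = {}
    for ion in ("Ca", "K", "NO3"):
        raw[ion] = _balance(recipe.get(ion), state.get_ise(ion), water.get(ion), v_t, v_c)

    # Ammonium is never measured: peg it to the signed nitrate demand so
    # that an over-supplied nitrate pool implies no ammonium demand.
    raw["NH4"] = ratios.nh4_per_no3 * raw["NO3"] - water.get("NH4") * dv

    mg_mode: MgPMode
    p_mode: MgPMode
    if mg_p_mode == "measured":
        c_mg = state.get_lab("Mg")
        c_p = state.get_lab("H2PO4")
        if c_mg is None or c_p is None:
            raise ValueError(
                "mg_p_mode='measured' requires laboratory Mg and H2PO4 values"
            )
        raw["Mg"] = _balance(recipe.get("Mg"), c_mg, water.get("Mg"), v_t, v_c)
        raw["H2PO4"] = _balance(recipe.get("H2PO4"), c_p, water.get("H2PO4"), v_t, v_c)
        mg_mode = p_mode = "measured"
    elif mg_p_mode == "ratio":
        raw["Mg"] = ratios.mg_per_ca * raw["Ca"] - water.get("Mg") * dv
        raw["H2PO4"] = ratios.h2po4_per_no3 * raw["NO3"] - water.get("H2PO4") * dv
        mg_mode = p_mode = "ratio"
    else:
        raise ValueError(f"unknown mg_p_mode {mg_p_mode!r}")

    return IonRequirements(raw=raw, mg_mode=mg_mode, p_mode=p_mode)


def clamp_nonnegative(req: IonRequirements) -> IonRequirements:
    """Replace every raw demand by max(demand, 0), keeping modes.

    The clamped view is what dosing operates on; the original signed
    values remain available on the input object.
    """
    return replace(req, raw=req.clamped)
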