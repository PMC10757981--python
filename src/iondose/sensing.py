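"""Nernstian ion-selective electrode model with two-point calibration.

An ISE's electromotive force follows E = E0 + S·log10(c) over its
working range, with slope S near ±59.2/z mV per decade at 25 °C. The
bench system this models normalises each electrode against two mixed
standards bracketing the working range (NO3 100/1000, K 30/300,
Ca 24/240 mg/L) before every measurement cycle, which pins down (E0, S)
exactly; measurement error is therefore dominated by electrode noise,
modelled here in concentration space with standard deviations set to
the accuracies observed for this electrode family (RMSE 29.5, 10.1 and
6.1 mg/L for NO3, K and Ca). Each ion is read by a small replicate
array (3/3/2 electrodes) whose readings are averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .mass_balance import MeasuredState

__all__ = [
    "ISEModel",
    "CalibrationPair",
    "Calibration",
    "default_ise_array",
    "default_calibration_pairs",
    "emf",
    "two_point_calibrate",
    "measure_tank",
]


@dataclass(frozen=True)
class ISEModel:
    """One ion's electrode model: Nernstian response plus concentration noise."""

    ion: str
    e0: float  # mV
    slope: float  # mV per decade of concentration
    noise_sd: float = 0.0  # mg/L, applied post-inversion
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("Nernstian slope must be nonzero")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.replicates < 1:
            raise ValueError("at least one replicate electrode is required")


@dataclass(frozen=True)
class CalibrationPair:
    """Two (concentration mg/L, EMF mV) points for one electrode."""

    c1: float
    e1: float
    c2: float
    e2: float

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("calibration concentrations must be positive")
        if self.c1 == self.c2:
            raise ValueError("calibration concentrations must be distinct")


@dataclass(frozen=True)
class Calibration:
    """Recovered electrode parameters with the inverse (EMF -> mg/L) map."""

    e0: float
    slope: float

    def concentration(self, e: float) -> float:
        return 10.0 ** ((e - self.e0) / self.slope)


def default_ise_array(noise: bool = True) -> dict[str, ISEModel]:
    """The electrode array this package models: 3x NO3, 3x K, 2x Ca.

    Slopes are textbook Nernstian values for the respective charges
    (anionic NO3 responds with a negative slope, divalent Ca with half
    the monovalent slope). ``noise=False`` zeroes the noise for
    deterministic closed-loop studies.
    """
    sd = {"NO3": 29.5, "K": 10.1, "Ca": 6.1} if noise else {"NO3": 0.0, "K": 0.0, "Ca": 0.0}
    return {
        "NO3": ISEModel("NO3", e0=90.0, slope=-55.0, noise_sd=sd["NO3"], replicates=3),
        "K": ISEModel("K", e0=120.0, slope=56.0, noise_sd=sd["K"], replicates=3),
        "Ca": ISEModel("Ca", e0=60.0, slope=27.0, noise_sd=sd["Ca"], replicates=2),
    }


def default_calibration_pairs() -> dict[str, tuple[float, float]]:
    """Two-point standard concentrations (mg/L) per ion.

    The calcium pair defaults to 24/240 mg/L; a 26/260 pair is equally
    valid and can be passed explicitly wherever a pair is accepted.
    """
    return {"NO3": (100.0, 1000.0), "K": (30.0, 300.0), "Ca": (24.0, 240.0)}


def emf(conc: float, model: ISEModel) -> float:
    """Electrode EMF (mV) at concentration ``conc`` (mg/L); conc must be > 0."""
    if conc <= 0:
        raise ValueError("Nernstian response is undefined at non-positive concentration")
    return model.e0 + model.slope * math.log10(conc)


def two_point_calibrate(pair: CalibrationPair) -> Calibration:
    """Recover (E0, S) from two calibration points.

    Two points determine the line exactly: S = ΔE/Δlog10(c) and
    E0 = E1 − S·log10(c1).
    """
    dlog = math.log10(pair.c2) - math.log10(pair.c1)
    slope = (pair.e2 - pair.e1) / dlog
    e0 = pair.e1 - slope * math.log10(pair.c1)
    return Calibration(e0=e0, slope=slope)


def calibrate_from_model(model: ISEModel, standards: tuple[float, float]) -> Calibration:
    """Run the two-point normalisation of ``model`` against known standards."""
    c1, c2 = standards
    pair = CalibrationPair(c1, emf(c1, model), c2, emf(c2, model))
    return two_point_calibrate(pair)


def measure_tank(
    state,
    models: Mapping[str, ISEModel],
    seed: int | np.random.Generator | None = None,
    lab: Mapping[str, float] | None = None,
) -> MeasuredState:
    """Read a tank with the electrode array; deterministic under a fixed seed.

    Each ion's reading is the mean over its replicate electrodes of the
    noisy inverted EMF. The calibration inversion is exact for a freshly
    normalised electrode, so noise enters directly in concentration
    space and is clipped at zero. ``state`` needs ``volume`` and
    ``concentrations`` attributes (see :class:`iondose.simulation.TankState`).
    """
    if state.volume <= 0:
        raise ValueError("cannot measure an empty tank")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    readings: dict[str, float] = {}
    for ion, model in models.items():
        true_c = float(state.concentrations.get(ion, 0.0))
        reps = true_c + rng.normal(0.0, model.noise_sd, size=model.replicates)
        readings[ion] = float(np.clip(reps, 0.0, None).mean())
    return MeasuredState(ise=readings, volume=state.volume, lab=lab)
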