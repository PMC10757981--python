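"""Shared fixtures: registry, random requirement vectors, instance suites."""

from __future__ import annotations

import numpy as np
import pytest

from iondose.chemistry import default_registry
from iondose.mass_balance import IonRequirements


@pytest.fixture(scope="session")
def registry():
    return default_registry()


def make_requirements(raw: dict[str, float]) -> IonRequirements:
    base = {"Ca": 0.0, "H2PO4": 0.0, "K": 0.0, "NO3": 0.0, "NH4": 0.0, "Mg": 0.0}
    base.update(raw)
    return IonRequirements(raw=base)


def random_requirements(rng: np.random.Generator, allow_negative: bool = True) -> IonRequirements:
    """A requirement vector spanning realistic replenishment magnitudes (mg)."""
    scale = {"Ca": 2000, "H2PO4": 1000, "K": 2500, "NO3": 8000, "NH4": 500, "Mg": 700}
    lo = -0.3 if allow_negative else 0.0
    return make_requirements(
        {ion: float(rng.uniform(lo, 1.0) * s) for ion, s in scale.items()}
    )


@pytest.fixture(scope="session")
def requirement_suite():
    """1000 seeded random requirement vectors for property sweeps."""
    rng = np.random.default_rng(20231218)
    return [random_requirements(rng) for _ in range(1000)]
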