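"""Conventional simplex (matrix) dosing baseline.

The conventional approach solves the linear system A·m = b, where the
columns of A are the ion mass fractions of the six non-magnesium salts
over the rows {Ca, H2PO4, K, NO3, NH4} and b is the clamped per-ion
demand. With six unknowns and five equations the system is closed here
by minimising total |mass| subject to the equalities with the masses
unbounded below (an equality-constrained minimum-L1 program solved by
free-variable splitting). The exact ("complete") solution may contain
negative components; pumps cannot withdraw ions, so actuation simply
clips negatives to zero, which is what makes this baseline over-inject
relative to the decision tree. Magnesium is handled identically to the
decision tree since MgSO4·7H2O is its sole source.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .chemistry import SaltSpec, default_registry
from .decision_tree import SaltDose, TraceEntry

__all__ = [
    "ION_ROWS",
    "SOLVED_SALTS",
    "SignedSaltSolution",
    "system_matrix",
    "solve_simplex",
    "clip_to_actuation",
]

ION_ROWS: tuple[str, ...] = ("Ca", "H2PO4", "K", "NO3", "NH4")
SOLVED_SALTS: tuple[str, ...] = (
    "Ca(NO3)2·4H2O",
    "KH2PO4",
    "NH4H2PO4",
    "KNO3",
    "NH4NO3",
    "K2SO4",
)


def system_matrix(registry: Mapping[str, SaltSpec] | None = None) -> np.ndarray:
    """5x6 matrix of ion mass fractions, rows :data:`ION_ROWS`, columns :data:`SOLVED_SALTS`."""
    reg = default_registry() if registry is None else registry
    return np.array(
        [[reg[s].ion_fraction(ion) for s in SOLVED_SALTS] for ion in ION_ROWS]
    )


@dataclass(frozen=True)
class SignedSaltSolution:
    """The complete (signed) solution and its clipped consequences.

    ``signed_masses`` may contain negative components; ``residual`` is
    delivered-minus-required per ion after clipping negatives to zero;
    ``feasible`` is False only when the equality system could not be
    met and a least-squares solution is reported instead.
    """

    signed_masses: Mapping[str, float]
    residual: Mapping[str, float]
    feasible: bool

    @property
    def has_negative(self) -> bool:
        return any(m < -1e-9 for m in self.signed_masses.values())


def solve_simplex(
    req, registry: Mapping[str, SaltSpec] | None = None
) -> SignedSaltSolution:
    """Solve the dosing equality system for the clamped demand of ``req``.

    Returns the signed per-salt masses (mg). The magnesium salt's signed
    mass is the raw Mg demand divided by its Mg fraction.
    """
    reg = default_registry() if registry is None else registry
    A = system_matrix(reg)
    b = np.array([req.get(ion) for ion in ION_ROWS])

    n = len(SOLVED_SALTS)
    # m = p - q with p, q >= 0; minimise sum(p) + sum(q) = ||m||_1.
    res = linprog(
        c=np.ones(2 * n),
        A_eq=np.hstack([A, -A]),
        b_eq=b,
        bounds=[(0, None)] * (2 * n),
        method="highs",
    )
    feasible = bool(res.success)
    if feasible:
        m = res.x[:n] - res.x[n:]
    else:
        m, *_ = np.linalg.lstsq(A, b, rcond=None)

    signed = dict(zip(SOLVED_SALTS, (float(v) for v in m)))
    signed["MgSO4·7H2O"] = req.get("Mg", clamped=False) / reg["MgSO4·7H2O"].ion_fraction("Mg")

    clipped = np.maximum(m, 0.0)
    residual = dict(zip(ION_ROWS, (float(v) for v in A @ clipped - b)))
    mg_clip = max(signed["MgSO4·7H2O"], 0.0)
    residual["Mg"] = mg_clip * reg["MgSO4·7H2O"].ion_fraction("Mg") - req.get("Mg")
    return SignedSaltSolution(signed_masses=signed, residual=residual, feasible=feasible)


def clip_to_actuation(sol: SignedSaltSolution) -> SaltDose:
    """Zero the negative components of a signed solution.

    This is exactly what the dosing hardware does: pumps whose computed
    runtime is negative simply do not run.
    """
    masses = {s: max(m, 0.0) for s, m in sol.signed_masses.items()}
    trace = [
        TraceEntry(
            salt=s,
            driver="simplex",
            candidate=float(sol.signed_masses[s]),
            check_ion=None,
            chosen=masses[s],
            leaf="clipped" if sol.signed_masses[s] < 0 else "exact",
        )
        for s in masses
    ]
    return SaltDose(masses=masses, trace=trace)
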