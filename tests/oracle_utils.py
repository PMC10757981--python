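"""Independent grid-search oracle for the decision-tree allocator.

Enumerates salt-dose combinations on a per-salt grid, keeps those that
never overdose an ion without a sole-source excuse (only the calcium
salt may overshoot nitrate), and ranks them lexicographically by
(Ca shortfall, P+K shortfall, NO3 shortfall, uncoupled overdose,
total salt mass). Terminal-priority ammonium is deliberately not a
ranking tier: the allocator tolerates ammonium shortfall rather than
re-splitting nitrate between its carrier salts.

Deliberately brute force and independent of the tree traversal. A grid
point "beats" a plan only when it is decisively better in some tier
(beyond the grid resolution) without being genuinely worse in any
earlier tier — trading a real worsening of a high-priority tier for
savings in a lower one never counts.
"""

from __future__ import annotations

import numpy as np

from iondose.chemistry import default_registry

IONS = ("Ca", "H2PO4", "K", "NO3", "NH4")
SALTS = ("Ca(NO3)2·4H2O", "KH2PO4", "NH4H2PO4", "KNO3", "NH4NO3", "K2SO4")


def _fractions():
    reg = default_registry()
    return np.array([[reg[s].ion_fraction(i) for s in SALTS] for i in IONS])


FRAC = _fractions()
_NO3 = IONS.index("NO3")
_CA_COL = SALTS.index("Ca(NO3)2·4H2O")
CA_SALT_NO3 = FRAC[_NO3, _CA_COL]


def _objective_columns(delivered: np.ndarray, req: np.ndarray, mass: np.ndarray,
                       ca_dose: np.ndarray) -> np.ndarray:
    """Tier matrix (rows = candidates, columns = tiers, lower is better)."""
    short = np.clip(req - delivered, 0.0, None)
    over = np.clip(delivered - req, 0.0, None)
    allowed_no3 = ca_dose * CA_SALT_NO3
    uncoupled = over.sum(axis=1) - np.minimum(over[:, _NO3], allowed_no3)
    return np.column_stack([
        short[:, IONS.index("Ca")],
        short[:, IONS.index("H2PO4")] + short[:, IONS.index("K")],
        short[:, _NO3],
        uncoupled,
        mass,
    ])


def plan_objective(masses: dict[str, float], req_map: dict[str, float]) -> tuple:
    req = np.array([max(req_map.get(i, 0.0), 0.0) for i in IONS])
    dose = np.array([[masses.get(s, 0.0) for s in SALTS]])
    cols = _objective_columns(dose @ FRAC.T, req, dose.sum(axis=1), dose[:, _CA_COL])
    return tuple(float(v) for v in cols[0])


def grid_search(req_map: dict[str, float], max_points: int = 300_000):
    """Lexicographically best feasible grid point and the grid resolution.

    Feasibility: no ion delivered beyond its requirement except nitrate
    from the calcium salt. Returns (best_objective_tuple, tier_tolerance).
    """
    req = np.array([max(req_map.get(i, 0.0), 0.0) for i in IONS])
    maxima = []
    for j, salt in enumerate(SALTS):
        caps = []
        for k, ion in enumerate(IONS):
            f = FRAC[k, j]
            if f <= 0:
                continue
            if ion == "NO3" and j == _CA_COL:
                continue  # sole-source coupling is exempt
            caps.append(req[k] / f)
        maxima.append(min(caps) if caps else 0.0)

    active = [j for j, m in enumerate(maxima) if m > 0]
    if not active:
        n_axis = 1
    else:
        n_axis = min(41, max(3, int(max_points ** (1.0 / len(active)))))
    axes = []
    steps = []
    for j, mx in enumerate(maxima):
        if mx > 0:
            grid = np.linspace(0.0, mx, n_axis)
            steps.append(grid[1] - grid[0])
        else:
            grid = np.array([0.0])
        axes.append(grid)

    mesh = np.meshgrid(*axes, indexing="ij")
    doses = np.column_stack([m.ravel() for m in mesh])
    delivered = doses @ FRAC.T
    allowed = np.tile(req, (doses.shape[0], 1))
    allowed[:, _NO3] += doses[:, _CA_COL] * CA_SALT_NO3
    feasible = np.all(delivered <= allowed + 1e-6, axis=1)
    doses = doses[feasible]
    cols = _objective_columns(
        delivered[feasible], req, doses.sum(axis=1), doses[:, _CA_COL]
    )
    order = np.lexsort(tuple(cols[:, i] for i in range(cols.shape[1] - 1, -1, -1)))
    best = tuple(float(v) for v in cols[order[0]])
    # One grid step per salt bounds how much any tier can change between
    # adjacent grid points (ion fractions are <= 1).
    tol = float(sum(steps))
    return best, tol


def beats(a: tuple, b: tuple, tol: float, eps: float = 1e-6) -> bool:
    """True when ``a`` is decisively better than ``b``.

    Walks the tiers in priority order: genuinely worse at any tier
    (beyond ``eps``) disqualifies ``a``; better by more than the grid
    tolerance at some tier, with no earlier genuine worsening, wins.
    """
    for x, y in zip(a, b):
        if x > y + eps:
            return False
        if x < y - tol:
            return True
    return False
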