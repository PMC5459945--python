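"""Independent brute-force oracles used to validate the implementation.

These deliberately share no code with the package's algorithms: elementary
modes come from exhaustive support enumeration plus LP feasibility, minimal
cut sets from exhaustive subset search, and the protein-cost bound from a
dense grid over log-concentration space.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.optimize import linprog

from orthodesign.model import StoichiometricModel, split_reversible


def support_feasible(S: np.ndarray, support: tuple[int, ...], n_rxns: int) -> bool:
    """Is there v >= 0 with S v = 0 and v_i >= 1 exactly on the support?"""
    bounds = [(1.0, None) if j in support else (0.0, 0.0) for j in range(n_rxns)]
    res = linprog(
        np.zeros(n_rxns),
        A_eq=S if S.size else None,
        b_eq=np.zeros(S.shape[0]) if S.size else None,
        bounds=bounds,
        method="highs",
    )
    return res.status == 0


def exhaustive_efm_supports(model: StoichiometricModel) -> list[frozenset[str]]:
    """All elementary-mode supports by testing every reaction subset.

    Feasible supports that contain no smaller feasible support are exactly
    the elementary modes (after reversible splitting; two-cycle artifacts
    of the split are dropped).  Only usable for networks of ~12 reactions.
    """
    split, mapping = split_reversible(model)
    rids = split.reaction_ids
    S = split.S
    n = len(rids)
    feasible: list[tuple[int, ...]] = []
    for k in range(1, n + 1):
        for sub in combinations(range(n), k):
            if support_feasible(S, sub, n):
                feasible.append(sub)
    sets = [frozenset(s) for s in feasible]
    minimal = [s for s in sets if not any(o < s for o in sets)]
    two_cycles = {
        frozenset({rids.index(f), rids.index(b)}) for f, b in mapping.values()
    }
    minimal = [s for s in minimal if s not in two_cycles]
    return sorted(
        (frozenset(rids[i] for i in s) for s in minimal),
        key=lambda s: tuple(sorted(s)),
    )


def brute_force_hitting_sets(
    supports: list[frozenset[str]], universe: set[str], max_cardinality: int
) -> list[frozenset[str]]:
    """All minimal hitting sets by exhaustive subset enumeration."""
    elements = sorted(universe)
    hitting = []
    for k in range(1, max_cardinality + 1):
        for sub in combinations(elements, k):
            s = frozenset(sub)
            if all(s & sup for sup in supports):
                hitting.append(s)
    minimal = [s for s in hitting if not any(o < s for o in hitting)]
    return sorted(minimal, key=lambda s: (len(s), tuple(sorted(s))))


def grid_min_cost(pathway, kinetics, thermo, points_per_dim: int = 50) -> float:
    """Minimum total protein cost over a dense log-concentration lattice.

    Vectorized over the full grid; infeasible points (any dG' >= 0) cost
    infinity.  Serves as an upper-bound certificate for the optimizer.
    """
    mets = []
    for r, _ in pathway:
        for mid in r.stoichiometry:
            if mid not in mets:
                mets.append(mid)
    axes = [
        np.linspace(*thermo.bounds_for(m), points_per_dim) for m in mets
    ]
    grids = np.meshgrid(*axes, indexing="ij")
    logc = {m: g for m, g in zip(mets, grids)}
    rt = thermo.rt
    total = np.zeros_like(grids[0])
    feasible = np.ones_like(grids[0], dtype=bool)
    for r, rel in pathway:
        kin = kinetics[r.id]
        dg = np.full_like(grids[0], thermo.reaction_dg0[r.id])
        for mid, nu in r.stoichiometry.items():
            dg = dg + rt * float(nu) * logc[mid]
        feasible &= dg < 0
        eta_t = 1.0 - np.exp(np.minimum(dg, -1e-12) / rt)
        eta_s = np.ones_like(grids[0])
        for mid, nu in r.stoichiometry.items():
            if float(nu) < 0 and mid in kin.km:
                ratio = np.exp(logc[mid]) / kin.km[mid]
                eta_s = eta_s * ratio / (1.0 + ratio)
        total = total + rel * kin.enzyme_mass / (kin.kcat * eta_t * eta_s)
    total = np.where(feasible, total, np.inf)
    return float(total.min())
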