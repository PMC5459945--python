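"""Linear-programming machinery: FBA, FVA and valve-throttled envelopes.

All LPs are solved with HiGHS through :func:`scipy.optimize.linprog` on the
standard steady-state polytope ``{v : S v = 0, lb <= v <= ub}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .model import StoichiometricModel

LP_TOL = 1e-9


class LPError(Exception):
    pass


class InfeasibleError(LPError):
    pass


class UnboundedError(LPError):
    pass


def _solve(model: StoichiometricModel, c: np.ndarray, what: str):
    S = model.S
    res = linprog(
        c,
        A_eq=S if S.size else None,
        b_eq=np.zeros(S.shape[0]) if S.size else None,
        bounds=model.bounds(),
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleError(f"LP infeasible while {what} on {model.name}")
    if res.status == 3:
        raise UnboundedError(f"LP unbounded while {what} on {model.name}")
    if not res.success:
        raise LPError(f"LP failed ({res.message}) while {what}")
    return res


def fba(
    model: StoichiometricModel, objective_id: str, sense: str = "max"
) -> tuple[float, dict[str, float]]:
    """Flux balance analysis: optimize one reaction's flux.

    Returns the optimum and one optimal flux vector keyed by reaction id.
    """
    rids = model.reaction_ids
    if objective_id not in rids:
        raise LPError(f"objective reaction {objective_id!r} not in model")
    sign = -1.0 if sense == "max" else 1.0
    c = np.zeros(len(rids))
    c[rids.index(objective_id)] = sign
    res = _solve(model, c, f"optimizing {objective_id} ({sense})")
    return sign * res.fun, dict(zip(rids, res.x))


def _with_bounds(model: StoichiometricModel, overrides: dict[str, tuple[float, float]]):
    out = model.copy()
    out.reactions = [
        r.with_bounds(*overrides[r.id]) if r.id in overrides else r for r in out.reactions
    ]
    return out


def fva(
    model: StoichiometricModel,
    reaction_ids: list[str] | None = None,
    fixed: dict[str, float] | None = None,
) -> dict[str, tuple[float, float]]:
    """Flux variability analysis: each reaction's attainable flux range.

    ``fixed`` pins named reactions to a flux value (e.g. biomass at its
    optimum) before scanning.
    """
    work = _with_bounds(model, {rid: (v, v) for rid, v in (fixed or {}).items()})
    out = {}
    for rid in reaction_ids or model.reaction_ids:
        lo, _ = fba(work, rid, sense="min")
        hi, _ = fba(work, rid, sense="max")
        out[rid] = (lo, hi)
    return out


def delete_reactions(model: StoichiometricModel, rids) -> StoichiometricModel:
    """Constrain the named reactions to zero flux (knockout)."""
    return _with_bounds(model, {rid: (0.0, 0.0) for rid in rids})


@dataclass
class ProductionEnvelope:
    """The attainable (biomass, product) region at one valve opening."""

    valve_fraction: float
    points: list[tuple[float, float, float]]  # (biomass, product_min, product_max)
    area: float
    basis: str = "flux"


def envelope_area(points) -> float:
    """Trapezoidal area of the band between product_min and product_max."""
    xs = np.array([p[0] for p in points])
    width = np.array([p[2] - p[1] for p in points])
    if len(xs) < 2:
        return 0.0
    return float(np.trapezoid(width, xs))


def production_envelope(
    model: StoichiometricModel,
    valve_id: str,
    fractions: list[float] = (1.0, 0.5, 0.2, 0.1, 0.05),
    n_points: int = 50,
    biomass_id: str | None = None,
    target_id: str | None = None,
    basis: str = "yield",
) -> list[ProductionEnvelope]:
    """Production envelopes as a valve is throttled.

    "Percent open" is defined against the valve's flux at the wild-type
    growth optimum (its FVA maximum with biomass fixed at the optimum): for
    each fraction f the valve's upper bound is capped at f times that
    reference, biomass is swept from 0 to its constrained maximum over
    ``n_points``, and the product's min/max flux are recorded per point.
    With ``basis='yield'`` both axes are divided by the substrate uptake
    bound, matching a mol-per-mol reading.
    """
    biomass_id = biomass_id or model.biomass_reaction.id
    target_id = target_id or model.target_reaction.id
    mu_wt, _ = fba(model, biomass_id, "max")
    v_star = fva(model, [valve_id], fixed={biomass_id: mu_wt})[valve_id][1]
    uptake_ub = model.uptake_reaction.upper_bound
    scale = uptake_ub if basis == "yield" else 1.0

    out = []
    for f in fractions:
        capped = _with_bounds(model, {valve_id: (model.reaction(valve_id).lower_bound, f * v_star)})
        mu_max, _ = fba(capped, biomass_id, "max")
        points = []
        for mu in np.linspace(0.0, mu_max, n_points):
            at_mu = _with_bounds(capped, {biomass_id: (mu, mu)})
            pmin, _ = fba(at_mu, target_id, "min")
            pmax, _ = fba(at_mu, target_id, "max")
            points.append((mu / scale, pmin / scale, pmax / scale))
        out.append(
            ProductionEnvelope(
                valve_fraction=f, points=points, area=envelope_area(points), basis=basis
            )
        )
    return out
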