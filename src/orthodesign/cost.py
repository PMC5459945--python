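"""Thermodynamic driving force and minimal protein cost of a pathway.

Each reaction's flux is described by a separable Michaelis–Menten rate law:
an enzyme at mass ``M`` and turnover ``kcat`` supports a flux of
``kcat * eta_sat * eta_therm`` per active site, where

* ``eta_therm = 1 - exp(dG'/RT)`` is the thermodynamic efficiency — the
  fraction of capacity left after the backward flux implied by the reaction
  driving force ``dG' = dG'0 + RT * sum_i nu_i ln c_i``;
* ``eta_sat = prod_substrates (c/Km) / (1 + c/Km)`` is the substrate
  saturation of the enzyme.

The protein cost of carrying a unit pathway flux through the reaction is
then ``M / (kcat * eta_sat * eta_therm)`` (g s mol^-1), scaled by the
reaction's flux relative to the pathway input.  Minimizing total cost over
metabolite log-concentrations is a smooth but nonconvex-looking problem
that is in practice well behaved; we first solve the max–min driving force
LP (which is exact and certifies thermodynamic feasibility) and then run a
deterministic local descent from that point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog, minimize

from .model import Reaction

R_GAS = 8.314462618e-3  # kJ mol^-1 K^-1
DEFAULT_T = 298.15
#: physiological metabolite concentration window, 1 uM .. 10 mM
DEFAULT_CONC_BOUNDS = (1e-6, 1e-2)


class CostError(Exception):
    pass


class InfeasibleDirectionError(CostError):
    """The reaction cannot carry net forward flux (dG' >= 0)."""


class ThermodynamicInfeasibilityError(CostError):
    def __init__(self, bottlenecks):
        self.bottlenecks = list(bottlenecks)
        super().__init__(
            "no concentration assignment gives every reaction a negative dG'; "
            f"bottleneck reaction(s): {self.bottlenecks}"
        )


class InfiniteCostError(CostError):
    """A zero efficiency makes the required enzyme amount unbounded."""


@dataclass(frozen=True)
class EnzymeKinetics:
    reaction_id: str
    kcat: float  # s^-1
    km: dict[str, float]  # M, keyed by metabolite id
    enzyme_mass: float  # g mol^-1

    def __post_init__(self):
        if self.kcat <= 0:
            raise CostError(f"{self.reaction_id}: kcat must be positive")
        if self.enzyme_mass <= 0:
            raise CostError(f"{self.reaction_id}: enzyme mass must be positive")
        if any(v <= 0 for v in self.km.values()):
            raise CostError(f"{self.reaction_id}: all Km must be positive")


@dataclass
class ThermoState:
    """Standard reaction energies plus a metabolite concentration assignment."""

    reaction_dg0: dict[str, float]  # kJ mol^-1, transformed standard
    log_conc: dict[str, float] = field(default_factory=dict)  # ln(c / 1 M)
    conc_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    temperature: float = DEFAULT_T

    @property
    def rt(self) -> float:
        return R_GAS * self.temperature

    def bounds_for(self, mid: str) -> tuple[float, float]:
        lo, hi = self.conc_bounds.get(mid, DEFAULT_CONC_BOUNDS)
        return math.log(lo), math.log(hi)


@dataclass
class PathwayCostResult:
    per_reaction: dict[str, tuple[float, float, float]]  # cost, eta_therm, eta_sat
    total_cost: float
    thermo_contribution: float  # percent of total cost attributable to backpressure
    optimal_log_conc: dict[str, float]
    mdf: float  # max-min driving force, kJ mol^-1


def driving_force(state: ThermoState, reaction: Reaction) -> float:
    """dG' = dG'0 + RT * sum_i nu_i ln c_i (kJ mol^-1)."""
    dg0 = state.reaction_dg0[reaction.id]
    total = 0.0
    for mid, nu in reaction.stoichiometry.items():
        if mid not in state.log_conc:
            raise CostError(f"no concentration for metabolite {mid!r}")
        total += float(nu) * state.log_conc[mid]
    return dg0 + state.rt * total


def efficiencies(
    state: ThermoState,
    kinetics: EnzymeKinetics,
    reaction: Reaction,
    flux_direction: int = 1,
) -> tuple[float, float]:
    """(eta_therm, eta_sat) for the reaction in the given direction."""
    dg = flux_direction * driving_force(state, reaction)
    if dg >= 0:
        raise InfeasibleDirectionError(
            f"{reaction.id}: dG' = {dg:+.3f} kJ/mol in the flux direction; "
            "net flux needs a negative driving force"
        )
    eta_therm = 1.0 - math.exp(dg / state.rt)
    eta_sat = 1.0
    for mid, nu in reaction.stoichiometry.items():
        if flux_direction * float(nu) < 0:  # substrate
            c = math.exp(state.log_conc[mid])
            km = kinetics.km.get(mid)
            if km is None:
                continue
            ratio = c / km
            eta_sat *= ratio / (1.0 + ratio)
    return eta_therm, eta_sat


def reaction_cost(
    relative_flux: float,
    kinetics: EnzymeKinetics,
    eta_therm: float,
    eta_sat: float,
) -> float:
    """Protein cost (g s mol^-1) per unit of pathway input flux."""
    if eta_therm <= 0 or eta_sat <= 0:
        raise InfiniteCostError(
            f"{kinetics.reaction_id}: zero efficiency implies unbounded enzyme demand"
        )
    return relative_flux * kinetics.enzyme_mass / (kinetics.kcat * eta_sat * eta_therm)


# ---------------------------------------------------------------------------
# Pathway-level optimization


def _pathway_mets(reactions: list[Reaction]) -> list[str]:
    seen = []
    for r in reactions:
        for mid in r.stoichiometry:
            if mid not in seen:
                seen.append(mid)
    return seen


def max_min_driving_force(
    reactions: list[Reaction], thermo: ThermoState
) -> tuple[float, dict[str, float]]:
    """The max–min driving force LP.

    Variables are the metabolite log-concentrations plus the worst-case
    driving force B; maximize B subject to -dG'_j >= B for every reaction
    and box bounds on each log-concentration.  Returns (B*, log_conc*).
    """
    mets = _pathway_mets(reactions)
    idx = {m: i for i, m in enumerate(mets)}
    n = len(mets)
    rt = thermo.rt
    # maximize B == minimize -B; x = [ln c_1..n, B]
    c = np.zeros(n + 1)
    c[-1] = -1.0
    A_ub, b_ub = [], []
    for r in reactions:
        row = np.zeros(n + 1)
        for mid, nu in r.stoichiometry.items():
            row[idx[mid]] = rt * float(nu)
        row[-1] = 1.0  # dg0 + RT*sum + B <= 0
        A_ub.append(row)
        b_ub.append(-thermo.reaction_dg0[r.id])
    bounds = [thermo.bounds_for(m) for m in mets] + [(None, None)]
    res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub), bounds=bounds, method="highs")
    if not res.success:
        raise ThermodynamicInfeasibilityError([r.id for r in reactions])
    log_conc = {m: res.x[idx[m]] for m in mets}
    return -res.fun, log_conc


def _total_cost(
    x: np.ndarray,
    mets: list[str],
    pathway: list[tuple[Reaction, float]],
    kinetics: dict[str, EnzymeKinetics],
    thermo: ThermoState,
    force_eta_therm_one: bool = False,
) -> float:
    state = ThermoState(
        reaction_dg0=thermo.reaction_dg0,
        log_conc=dict(zip(mets, x)),
        conc_bounds=thermo.conc_bounds,
        temperature=thermo.temperature,
    )
    total = 0.0
    for r, rel_flux in pathway:
        try:
            eta_t, eta_s = efficiencies(state, kinetics[r.id], r)
        except InfeasibleDirectionError:
            return float("inf")
        if force_eta_therm_one:
            eta_t = 1.0
        total += reaction_cost(rel_flux, kinetics[r.id], eta_t, eta_s)
    return total


def minimize_pathway_cost(
    pathway: list[tuple[Reaction, float]],
    kinetics: dict[str, EnzymeKinetics],
    thermo: ThermoState,
) -> PathwayCostResult:
    """Minimal total protein cost over metabolite concentrations.

    ``pathway`` pairs each reaction with its flux relative to the pathway
    input.  Feasibility is certified first by the max–min driving force LP
    (an MDF <= 0 means no concentration assignment drives every step
    forward, and the bottleneck reactions are reported); the cost is then
    minimized by deterministic L-BFGS-B descent started at the MDF point,
    with driving forces kept negative by a soft barrier at -1e-3 kJ/mol.
    """
    reactions = [r for r, _ in pathway]
    mdf, start = max_min_driving_force(reactions, thermo)
    if mdf <= 0:
        # identify the reactions pinned at the (non-positive) optimum
        state = ThermoState(thermo.reaction_dg0, start, thermo.conc_bounds, thermo.temperature)
        tight = [r.id for r in reactions if driving_force(state, r) >= -abs(mdf) - 1e-6]
        raise ThermodynamicInfeasibilityError(tight or [r.id for r in reactions])

    mets = _pathway_mets(reactions)
    x0 = np.array([start[m] for m in mets])
    bounds = [thermo.bounds_for(m) for m in mets]
    margin = min(1e-3, 0.5 * mdf)

    def objective(x):
        state = ThermoState(thermo.reaction_dg0, dict(zip(mets, x)), thermo.conc_bounds, thermo.temperature)
        total = 0.0
        for r, rel_flux in pathway:
            dg = driving_force(state, r)
            if dg > -margin:
                # smooth penalty keeps the line search inside the feasible cone
                total += 1e6 * (dg + margin) ** 2
                dg = -margin
            eta_t = 1.0 - math.exp(dg / state.rt)
            _, eta_s = _sat_only(state, kinetics[r.id], r)
            total += reaction_cost(rel_flux, kinetics[r.id], eta_t, eta_s)
        return total

    res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10})
    x_opt = res.x if res.fun <= objective(x0) else x0

    state = ThermoState(thermo.reaction_dg0, dict(zip(mets, x_opt)), thermo.conc_bounds, thermo.temperature)
    per_reaction = {}
    total = 0.0
    for r, rel_flux in pathway:
        eta_t, eta_s = efficiencies(state, kinetics[r.id], r)
        cost = reaction_cost(rel_flux, kinetics[r.id], eta_t, eta_s)
        per_reaction[r.id] = (cost, eta_t, eta_s)
        total += cost
    ideal = _total_cost(x_opt, mets, pathway, kinetics, thermo, force_eta_therm_one=True)
    thermo_contribution = 100.0 * (total - ideal) / total if total > 0 else 0.0
    return PathwayCostResult(
        per_reaction=per_reaction,
        total_cost=total,
        thermo_contribution=thermo_contribution,
        optimal_log_conc=dict(zip(mets, x_opt)),
        mdf=mdf,
    )


def _sat_only(state: ThermoState, kin: EnzymeKinetics, reaction: Reaction) -> tuple[float, float]:
    eta_sat = 1.0
    for mid, nu in reaction.stoichiometry.items():
        if float(nu) < 0 and mid in kin.km:
            ratio = math.exp(state.log_conc[mid]) / kin.km[mid]
            eta_sat *= ratio / (1.0 + ratio)
    return 1.0, eta_sat
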