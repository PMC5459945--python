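"""ValveFind: minimal-cut-set strain designs with a growth-restoring valve.

The workflow mirrors a two-stage fermentation design problem:

1. select the *target* modes — every elementary mode whose product yield
   falls below the demanded threshold (this includes all biomass-only
   modes); the surviving modes guarantee the yield without demanding growth;
2. enumerate the minimal hitting sets (minimal cut sets, MCS) of the target
   modes' supports over the deletable reactions, so that applying a cut set
   leaves only high-yield production modes;
3. within each cut set, look for a single *valve* reaction whose restoration
   brings FBA growth back above a threshold fraction of wild type (default
   90%) — such a cut set is a candidate branched topology;
4. audit each design with the valve closed (precursors still synthesizable,
   guaranteed product yield) and rank designs by the orthogonality score of
   the reduced network with the valve open.

Minimal hitting sets are enumerated by Berge's incremental transversal
construction, which is exact; a MILP enumerator could substitute as long as
it returns the identical family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .efm import EFMSet, enumerate_efms, mode_yield, partition_modes
from .fba import LP_TOL, delete_reactions, fba
from .model import StoichiometricModel
from .orthogonality import OrthogonalityResult, UndefinedScoreError, orthogonality_score


class DesignError(Exception):
    pass


class InfeasibleDesignError(DesignError):
    """No elementary mode satisfies the demanded product yield."""


class UncuttableModeError(DesignError):
    def __init__(self, mode_index: int, support):
        self.mode_index = mode_index
        super().__init__(
            f"target mode {mode_index} (support {sorted(support)}) intersects "
            "no deletable reaction and cannot be cut"
        )


@dataclass
class TargetModeSet:
    mode_indices: set[int]
    yield_threshold: float


@dataclass(frozen=True)
class CutSet:
    reaction_ids: frozenset[str]

    @property
    def cardinality(self) -> int:
        return len(self.reaction_ids)

    def sort_key(self):
        return (self.cardinality, tuple(sorted(self.reaction_ids)))


@dataclass
class ValveDesign:
    cutset: CutSet
    valve_id: str
    restored_growth_fraction: float
    score_valve_on: float | None
    score_result: OrthogonalityResult | None
    precursors_on_count: int
    precursors_off_count: int
    product_yield_valve_off: float
    score_undefined: bool = False
    valve_candidates: list[tuple[str, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------


def select_target_modes(
    efms: EFMSet,
    yield_threshold: float = 1.0,
    uptake_id: str | None = None,
    target_id: str | None = None,
) -> TargetModeSet:
    """Modes to eliminate: product-per-substrate yield below the threshold.

    A mode with no substrate uptake counts as yield zero.  Raises if no
    mode at all meets the yield demand (the design would leave a dead
    network).
    """
    target_id = target_id or efms.target_id
    if target_id is None:
        raise DesignError("partition the mode set (target reaction unknown)")
    if uptake_id is None:
        raise DesignError("substrate uptake reaction must be named")
    targets = set()
    for i, mode in enumerate(efms.modes):
        up = mode.net_flux(uptake_id)
        y = float(mode.net_flux(target_id) / up) if abs(up) > LP_TOL else 0.0
        if y < yield_threshold:
            targets.add(i)
    if len(targets) == len(efms.modes) and efms.modes:
        raise InfeasibleDesignError(
            f"no elementary mode reaches product yield {yield_threshold}; "
            "the demanded yield is unattainable"
        )
    return TargetModeSet(mode_indices=targets, yield_threshold=yield_threshold)


def _berge_transversals(hypersets: list[frozenset[str]], max_cardinality: int) -> list[frozenset[str]]:
    """Minimal hitting sets of a family of sets, Berge's algorithm."""
    transversals: list[frozenset[str]] = [frozenset()]
    for hs in hypersets:
        nxt: list[frozenset[str]] = []
        for t in transversals:
            if t & hs:
                nxt.append(t)
                continue
            for e in sorted(hs):
                cand = t | {e}
                if len(cand) > max_cardinality:
                    continue
                # keep only minimal extensions
                if any(other <= cand for other in nxt if other != cand):
                    continue
                nxt.append(cand)
        # global minimality sweep
        nxt = sorted(set(nxt), key=lambda s: (len(s), tuple(sorted(s))))
        minimal = []
        for cand in nxt:
            if not any(prev < cand for prev in minimal):
                minimal.append(cand)
        transversals = minimal
    return transversals


def enumerate_mcs(
    targets: TargetModeSet,
    efms: EFMSet,
    deletable: set[str],
    max_cardinality: int = 5,
) -> list[CutSet]:
    """All minimal cut sets hitting every target mode, up to a cardinality.

    Supports are restricted to the deletable reactions first; a target mode
    whose restricted support is empty cannot be disabled by any deletion.
    """
    if not targets.mode_indices:
        return []
    restricted = []
    for i in sorted(targets.mode_indices):
        sup = frozenset(efms.modes[i].support) & frozenset(deletable)
        if not sup:
            raise UncuttableModeError(i, efms.modes[i].support)
        restricted.append(sup)
    # deduplicate identical supports; order by size for pruning efficiency
    restricted = sorted(set(restricted), key=lambda s: (len(s), tuple(sorted(s))))
    hits = _berge_transversals(restricted, max_cardinality)
    cutsets = [CutSet(frozenset(h)) for h in hits if h]
    return sorted(cutsets, key=CutSet.sort_key)


def verify_cutset_minimal(cutset: CutSet, supports: list[frozenset[str]]) -> bool:
    """Brute-force check: hits every support and no proper subset does."""
    cs = cutset.reaction_ids
    if not all(cs & s for s in supports):
        return False
    for k in range(len(cs)):
        for sub in combinations(sorted(cs), k):
            if all(frozenset(sub) & s for s in supports):
                return False
    return True


def find_valves(
    model: StoichiometricModel,
    cutset: CutSet,
    growth_fraction: float = 0.9,
    biomass_id: str | None = None,
) -> list[tuple[str, float]]:
    """Reactions in the cut set whose sole restoration rescues growth.

    For each member r: delete the rest of the cut set, FBA-maximize biomass
    and record the restored fraction of the wild-type growth rate.  Only
    candidates at or above ``growth_fraction`` are returned, best first.
    """
    biomass_id = biomass_id or model.biomass_reaction.id
    mu_wt, _ = fba(model, biomass_id, "max")
    if mu_wt <= LP_TOL:
        raise DesignError("wild-type model does not grow; no valve can restore growth")
    out = []
    for rid in sorted(cutset.reaction_ids):
        reduced = delete_reactions(model, cutset.reaction_ids - {rid})
        mu, _ = fba(reduced, biomass_id, "max")
        frac = mu / mu_wt
        if frac >= growth_fraction - LP_TOL:
            out.append((rid, frac))
    return sorted(out, key=lambda t: (-t[1], t[0]))


def count_synthesizable_precursors(
    model: StoichiometricModel, tol: float = 1e-6
) -> int:
    """Precursors that a temporary drain can pull flux through (FBA > tol)."""
    from .model import Metabolite, Reaction

    count = 0
    for mid in sorted(model.precursor_ids):
        probe = model.copy()
        probe.reactions = probe.reactions + [
            Reaction(f"__drain_{mid}", {mid: -1}, upper_bound=1000.0)
        ]
        vmax, _ = fba(probe, f"__drain_{mid}", "max")
        if vmax > tol:
            count += 1
    return count


def audit_valve_off(
    model: StoichiometricModel, cutset: CutSet, uptake_id: str | None = None
) -> tuple[int, float]:
    """With the whole cut set applied (valve closed): what still works?

    Returns the number of synthesizable biomass precursors and the
    FBA-maximal product yield per substrate taken up.
    """
    uptake_id = uptake_id or model.uptake_reaction.id
    closed = delete_reactions(model, cutset.reaction_ids)
    n_prec = count_synthesizable_precursors(closed)
    target_id = model.target_reaction.id
    vmax, flux = fba(closed, target_id, "max")
    up = flux.get(uptake_id, 0.0)
    prod_yield = vmax / up if abs(up) > LP_TOL else 0.0
    return n_prec, prod_yield


def rank_designs(
    model: StoichiometricModel,
    cutsets: list[CutSet],
    growth_fraction: float = 0.9,
    max_modes: int = 500_000,
) -> list[ValveDesign]:
    """Build and rank valve designs: orthogonality first, then parsimony.

    For each cut set with at least one valve candidate, the scored network
    is the reduced model with the cut set applied but the valve left open;
    designs whose reduced network loses all biomass-only or all product-only
    modes are flagged score-undefined and ranked last.  Valve tie-break
    among equal-growth candidates: fewer precursors synthesizable when
    closed (fewer leak paths), then lexicographic.
    """
    biomass_id = model.biomass_reaction.id
    target_id = model.target_reaction.id
    designs = []
    for cs in cutsets:
        candidates = find_valves(model, cs, growth_fraction, biomass_id)
        if not candidates:
            continue
        best_growth = candidates[0][1]
        tied = [rid for rid, g in candidates if abs(g - best_growth) <= 1e-9]
        audits = {rid: audit_valve_off(model, cs) for rid in tied}
        valve = min(tied, key=lambda rid: (audits[rid][0], rid))
        prec_off, yield_off = audits[valve]

        reduced = delete_reactions(model, cs.reaction_ids - {valve})
        prec_on = count_synthesizable_precursors(reduced)
        score = result = None
        undefined = False
        # zero-bounded reactions cannot carry flux but still exist as
        # columns; drop them so EFMs reflect the reduced network
        pruned = reduced.copy()
        pruned.reactions = [
            r for r in reduced.reactions if not (r.upper_bound == 0 and r.lower_bound == 0)
        ]
        efms = partition_modes(enumerate_efms(pruned, max_modes), biomass_id, target_id)
        try:
            result = orthogonality_score(efms, model=pruned)
            score = result.score
        except UndefinedScoreError:
            undefined = True
        designs.append(
            ValveDesign(
                cutset=cs,
                valve_id=valve,
                restored_growth_fraction=best_growth,
                score_valve_on=score,
                score_result=result,
                precursors_on_count=prec_on,
                precursors_off_count=prec_off,
                product_yield_valve_off=yield_off,
                score_undefined=undefined,
                valve_candidates=candidates,
            )
        )
    return sorted(
        designs,
        key=lambda d: (
            d.score_undefined,
            -(d.score_valve_on if d.score_valve_on is not None else -1.0),
            d.cutset.cardinality,
            tuple(sorted(d.cutset.reaction_ids)),
        ),
    )
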