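"""Deterministic toy networks used throughout the test-suite and docs.

``branched_toy`` is the normative example: substrate A feeds two fully
separate subsystems, a biomass branch (A→B→{C,D}→E→biomass) and a product
branch (A→P→target).  It has exactly three elementary flux modes — two
biomass-only, one product-only — and reaction ``v1`` is the textbook
metabolic valve: deleting it abolishes growth while leaving the product
route untouched.
"""

from __future__ import annotations

from .model import Metabolite, Reaction, StoichiometricModel

FIXTURE_NAMES = (
    "branched_toy",
    "branched_toy_redundant",
    "linear_chain",
    "diamond_coupled",
    "strong_coupled",
    "mini_glycolysis",
)


def _mets(ids: str | list[str]) -> list[Metabolite]:
    if isinstance(ids, str):
        ids = ids.split()
    return [Metabolite(id=i) for i in ids]


def _branched_toy_reactions(uptake_rate: float = 20.0) -> list[Reaction]:
    ub = 1000.0
    return [
        Reaction("R_up", {"A": 1}, role="uptake", upper_bound=uptake_rate),
        Reaction("v1", {"A": -1, "B": 1}, upper_bound=ub),
        Reaction("v2", {"B": -1, "C": 1}, upper_bound=ub),
        Reaction("v3", {"B": -1, "D": 1}, upper_bound=ub),
        Reaction("v4", {"C": -1, "E": 1}, upper_bound=ub),
        Reaction("v5", {"D": -1, "E": 1}, upper_bound=ub),
        Reaction("v_bio", {"E": -1}, role="biomass", upper_bound=ub),
        Reaction("v7", {"A": -1, "P": 1}, upper_bound=ub),
        Reaction("v8", {"P": -1}, role="target", upper_bound=ub),
    ]


def build_fixture(name: str, uptake_rate: float = 20.0) -> StoichiometricModel:
    """Build one of the named toy models.

    All fixtures are irreversible, fully connected and pass validation; the
    substrate uptake defaults to 20 mmol gDW^-1 h^-1.
    """
    ub = 1000.0
    if name == "branched_toy":
        return StoichiometricModel(
            metabolites=_mets("A B C D E P"),
            reactions=_branched_toy_reactions(uptake_rate),
            name="branched_toy",
        )
    if name == "branched_toy_redundant":
        rxns = _branched_toy_reactions(uptake_rate)
        rxns.append(Reaction("v9", {"A": -1, "C": 1}, upper_bound=ub))
        return StoichiometricModel(
            metabolites=_mets("A B C D E P"),
            reactions=rxns,
            name="branched_toy_redundant",
        )
    if name == "linear_chain":
        # one biomass route, a target exchange that nothing can feed: S_t empty
        return StoichiometricModel(
            metabolites=_mets("A B P"),
            reactions=[
                Reaction("R_up", {"A": 1}, role="uptake", upper_bound=uptake_rate),
                Reaction("v1", {"A": -1, "B": 1}, upper_bound=ub),
                Reaction("v_bio", {"B": -1}, role="biomass", upper_bound=ub),
                # P is produced by nothing, so the target reaction can never
                # carry steady-state flux: S_t is empty by construction
                Reaction("v8", {"P": -1}, role="target", upper_bound=ub),
            ],
            name="linear_chain",
        )
    if name == "diamond_coupled":
        # shared trunk A→B→C: every biomass mode shares >=2 internal
        # reactions (v1, v2) with every product mode
        return StoichiometricModel(
            metabolites=_mets("A B C P"),
            reactions=[
                Reaction("R_up", {"A": 1}, role="uptake", upper_bound=uptake_rate),
                Reaction("v1", {"A": -1, "B": 1}, upper_bound=ub),
                Reaction("v2", {"B": -1, "C": 1}, upper_bound=ub),
                Reaction("v_bio", {"C": -1}, role="biomass", upper_bound=ub),
                Reaction("v4", {"C": -1, "P": 1}, upper_bound=ub),
                Reaction("v8", {"P": -1}, role="target", upper_bound=ub),
            ],
            name="diamond_coupled",
        )
    if name == "strong_coupled":
        # biomass formation obligatorily co-produces the target: no
        # biomass-only mode exists, so the orthogonality score is undefined
        return StoichiometricModel(
            metabolites=_mets("A B P"),
            reactions=[
                Reaction("R_up", {"A": 1}, role="uptake", upper_bound=uptake_rate),
                Reaction("v1", {"A": -1, "B": 1, "P": 1}, upper_bound=ub),
                Reaction("v_bio", {"B": -1}, role="biomass", upper_bound=ub),
                Reaction("v8", {"P": -1}, role="target", upper_bound=ub),
            ],
            name="strong_coupled",
        )
    if name == "mini_glycolysis":
        # lumped glycolysis variant: G6P→F6P→2 GAP→PEP→PYR, biomass drains
        # PEP+PYR, a reductive branch carries PYR to the target acid
        return StoichiometricModel(
            metabolites=_mets("g6p f6p gap pep pyr suc"),
            reactions=[
                Reaction("R_glc", {"g6p": 1}, role="uptake", upper_bound=uptake_rate),
                Reaction("pgi", {"g6p": -1, "f6p": 1}, upper_bound=ub),
                Reaction("fba", {"f6p": -1, "gap": 2}, upper_bound=ub),
                Reaction("gapA", {"gap": -1, "pep": 1}, upper_bound=ub),
                Reaction("pyk", {"pep": -1, "pyr": 1}, upper_bound=ub),
                Reaction("v_bio", {"pep": -1, "pyr": -1}, role="biomass", upper_bound=ub),
                Reaction("frd", {"pyr": -1, "suc": 1}, upper_bound=ub),
                Reaction("EX_suc", {"suc": -1}, role="target", upper_bound=ub),
            ],
            precursor_ids={"g6p", "f6p", "gap", "pep", "pyr"},
            name="mini_glycolysis",
        )
    raise ValueError(f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}")
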