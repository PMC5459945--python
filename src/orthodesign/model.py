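"""Stoichiometric model data structures, validation, I/O and editing.

A :class:`StoichiometricModel` is a plain constraint-based model: internal
metabolites balanced at steady state (``S v = 0``), reactions with flux
bounds and a functional *role* (internal, uptake, exchange, biomass or
target).  Stoichiometric coefficients are stored as exact rationals
(:class:`fractions.Fraction`) so that elementarity and rank tests downstream
are exact; floats appear only at the I/O boundary.

Models are read either from a small JSON dialect (documented in
``docs/json_dialect.md``) or from SBML Level 3 + FBC with a YAML sidecar
naming the uptake/biomass/target reactions (SBML carries no such semantics).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

#: Fluxes below this magnitude are treated as zero (mmol gDW^-1 h^-1).
FLUX_TOL = 1e-9

#: Canonical 12 biomass precursor metabolites of central carbon metabolism.
#: The set is configurable per model; this default is an assumption, as the
#: precursor list is conventional rather than universal.
CANONICAL_PRECURSORS = (
    "g6p", "f6p", "r5p", "e4p", "gap", "3pg",
    "pep", "pyr", "accoa", "akg", "succoa", "oaa",
)

ROLES = ("internal", "uptake", "exchange", "biomass", "target")

#: Roles that are non-deletable by default (exchange machinery and the two
#: objective reactions); overridable per reaction.
NON_DELETABLE_ROLES = frozenset({"uptake", "exchange", "biomass", "target"})


class ModelError(Exception):
    """Base class for model construction/validation errors."""


class ModelValidationError(ModelError):
    pass


class ModelFormatError(ModelError):
    """Raised when a model file cannot be parsed."""


def _to_fraction(x) -> Fraction:
    """Coerce ints, floats, strings like ``'2/3'`` and Fractions exactly."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, float):
        # exact decimal reading: 0.1 -> 1/10, not the binary expansion
        return Fraction(repr(x))
    if isinstance(x, str):
        return Fraction(x)
    raise TypeError(f"cannot interpret {x!r} as a rational coefficient")


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    is_external: bool = False
    is_precursor: bool = False


@dataclass(frozen=True)
class Reaction:
    """A reaction with exact rational stoichiometry.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    consumed, positive = produced).  External metabolites may appear; they
    are simply not balanced.
    """

    id: str
    stoichiometry: Mapping[str, Fraction]
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    role: str = "internal"
    deletable: bool | None = None

    def __post_init__(self):
        object.__setattr__(
            self,
            "stoichiometry",
            {m: _to_fraction(c) for m, c in self.stoichiometry.items() if _to_fraction(c) != 0},
        )
        if self.role not in ROLES:
            raise ModelValidationError(f"reaction {self.id!r}: unknown role {self.role!r}")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > upper_bound {self.upper_bound}"
            )
        if not self.reversible and self.lower_bound < 0:
            raise ModelValidationError(
                f"reaction {self.id!r}: irreversible but lower_bound {self.lower_bound} < 0"
            )
        if self.deletable is None:
            object.__setattr__(self, "deletable", self.role not in NON_DELETABLE_ROLES)

    def with_bounds(self, lb: float, ub: float) -> "Reaction":
        return replace(self, lower_bound=lb, upper_bound=ub)


@dataclass
class StoichiometricModel:
    """A validated stoichiometric network.

    Rows of :attr:`S` are the *internal* metabolites in declaration order;
    columns are reactions in declaration order.
    """

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    precursor_ids: set[str] = field(default_factory=set)
    name: str = "model"

    def __post_init__(self):
        self.precursor_ids = set(self.precursor_ids) | {
            m.id for m in self.metabolites if m.is_precursor
        }
        validate_model(self)

    # -- lookups -----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def internal_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if not m.is_external]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def reactions_with_role(self, role: str) -> list[Reaction]:
        return [r for r in self.reactions if r.role == role]

    def _unique_role(self, role: str) -> Reaction:
        rs = self.reactions_with_role(role)
        if len(rs) != 1:
            raise ModelValidationError(
                f"expected exactly one {role} reaction, found {[r.id for r in rs]}"
            )
        return rs[0]

    @property
    def biomass_reaction(self) -> Reaction:
        return self._unique_role("biomass")

    @property
    def target_reaction(self) -> Reaction:
        return self._unique_role("target")

    @property
    def uptake_reaction(self) -> Reaction:
        return self._unique_role("uptake")

    # -- matrices ----------------------------------------------------------
    def stoich_matrix_fraction(self) -> list[list[Fraction]]:
        """Exact S over internal metabolites (rows) x reactions (columns)."""
        rows = self.internal_metabolite_ids
        return [
            [r.stoichiometry.get(mid, Fraction(0)) for r in self.reactions]
            for mid in rows
        ]

    @property
    def S(self) -> np.ndarray:
        return np.array(
            [[float(c) for c in row] for row in self.stoich_matrix_fraction()],
            dtype=float,
        )

    def bounds(self) -> list[tuple[float, float]]:
        return [(r.lower_bound, r.upper_bound) for r in self.reactions]

    def copy(self) -> "StoichiometricModel":
        return copy.deepcopy(self)


def validate_model(model: StoichiometricModel) -> None:
    """Check id uniqueness, coefficient references and bound sanity."""
    mids = [m.id for m in model.metabolites]
    if len(set(mids)) != len(mids):
        dup = sorted({x for x in mids if mids.count(x) > 1})
        raise ModelValidationError(f"duplicate metabolite id(s): {dup}")
    rids = [r.id for r in model.reactions]
    if len(set(rids)) != len(rids):
        dup = sorted({x for x in rids if rids.count(x) > 1})
        raise ModelValidationError(f"duplicate reaction id(s): {dup}")
    known = set(mids)
    for r in model.reactions:
        missing = set(r.stoichiometry) - known
        if missing:
            raise ModelValidationError(
                f"reaction {r.id!r} references unknown metabolite(s) {sorted(missing)}"
            )
    # a declared-internal metabolite that no reaction touches can never be
    # balanced away and indicates a broken model
    touched = {m for r in model.reactions for m in r.stoichiometry}
    orphans = [m.id for m in model.metabolites if not m.is_external and m.id not in touched]
    if orphans:
        raise ModelValidationError(
            f"internal metabolite(s) with no reactions: {orphans}"
        )
    unknown_prec = model.precursor_ids - known
    if unknown_prec:
        raise ModelValidationError(
            f"precursor id(s) not in model: {sorted(unknown_prec)}"
        )


# ---------------------------------------------------------------------------
# Pathway augmentation


@dataclass
class PathwayConfig:
    """A set of edits turning a base model into a pathway-specific variant."""

    name: str = "pathway"
    added_reactions: list[Reaction] = field(default_factory=list)
    removed_reaction_ids: set[str] = field(default_factory=set)
    bound_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    added_metabolites: list[Metabolite] = field(default_factory=list)


def apply_pathway(model: StoichiometricModel, cfg: PathwayConfig) -> StoichiometricModel:
    """Return a new model with the config applied; the original is untouched."""
    existing = set(model.reaction_ids)
    collide = {r.id for r in cfg.added_reactions} & existing
    if collide:
        raise ModelValidationError(f"added reaction id(s) already present: {sorted(collide)}")
    missing = cfg.removed_reaction_ids - existing
    if missing:
        raise ModelValidationError(f"cannot remove unknown reaction(s): {sorted(missing)}")
    protected = {r.id for r in model.reactions if r.role in ("biomass", "target")}
    clash = cfg.removed_reaction_ids & protected
    if clash:
        raise ModelValidationError(
            f"refusing to remove biomass/target reaction(s): {sorted(clash)}"
        )
    mets = list(model.metabolites)
    have = {m.id for m in mets}
    for m in cfg.added_metabolites:
        if m.id not in have:
            mets.append(m)
            have.add(m.id)
    reactions = [
        copy.deepcopy(r) for r in model.reactions if r.id not in cfg.removed_reaction_ids
    ] + list(cfg.added_reactions)
    reactions = [
        r.with_bounds(*cfg.bound_overrides[r.id]) if r.id in cfg.bound_overrides else r
        for r in reactions
    ]
    return StoichiometricModel(
        metabolites=mets,
        reactions=reactions,
        precursor_ids=set(model.precursor_ids),
        name=f"{model.name}+{cfg.name}" if cfg.name else model.name,
    )


# ---------------------------------------------------------------------------
# Reversible splitting


def split_reversible(model: StoichiometricModel) -> tuple[StoichiometricModel, dict[str, tuple[str, str]]]:
    """Replace each reversible reaction by an irreversible forward/backward pair.

    Returns the split model and a mapping ``original id -> (fwd id, bwd id)``.
    The two-cycle flux modes this creates (forward + backward of the same
    reaction) are removed during EFM enumeration.
    """
    mapping: dict[str, tuple[str, str]] = {}
    out: list[Reaction] = []
    for r in model.reactions:
        if not r.reversible:
            out.append(copy.deepcopy(r))
            continue
        fwd_id, bwd_id = r.id, f"{r.id}__rev"
        mapping[r.id] = (fwd_id, bwd_id)
        out.append(
            Reaction(
                id=fwd_id,
                stoichiometry=dict(r.stoichiometry),
                reversible=False,
                lower_bound=max(0.0, r.lower_bound),
                upper_bound=max(0.0, r.upper_bound),
                role=r.role,
                deletable=r.deletable,
            )
        )
        out.append(
            Reaction(
                id=bwd_id,
                stoichiometry={m: -c for m, c in r.stoichiometry.items()},
                reversible=False,
                lower_bound=max(0.0, -r.upper_bound),
                upper_bound=max(0.0, -r.lower_bound),
                role=r.role,
                deletable=r.deletable,
            )
        )
    if not mapping:
        return model.copy(), {}
    return (
        StoichiometricModel(
            metabolites=list(model.metabolites),
            reactions=out,
            precursor_ids=set(model.precursor_ids),
            name=model.name,
        ),
        mapping,
    )


# ---------------------------------------------------------------------------
# JSON dialect I/O


def _coeff_to_json(c: Fraction):
    if c.denominator == 1:
        return int(c)
    return f"{c.numerator}/{c.denominator}"


def model_to_dict(model: StoichiometricModel) -> dict:
    return {
        "name": model.name,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "is_external": m.is_external,
                "is_precursor": m.id in model.precursor_ids,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": {m: _coeff_to_json(c) for m, c in sorted(r.stoichiometry.items())},
                "reversible": r.reversible,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "role": r.role,
                "deletable": r.deletable,
            }
            for r in model.reactions
        ],
    }


def model_from_dict(d: dict) -> StoichiometricModel:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                is_external=bool(m.get("is_external", False)),
                is_precursor=bool(m.get("is_precursor", False)),
            )
            for m in d["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                stoichiometry={m: _to_fraction(c) for m, c in r["stoichiometry"].items()},
                reversible=bool(r.get("reversible", False)),
                lower_bound=float(r.get("lower_bound", 0.0)),
                upper_bound=float(r.get("upper_bound", 1000.0)),
                role=r.get("role", "internal"),
                deletable=r.get("deletable"),
            )
            for r in d["reactions"]
        ]
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"malformed model JSON: {exc}") from exc
    return StoichiometricModel(metabolites=mets, reactions=rxns, name=d.get("name", "model"))


def write_model_json(model: StoichiometricModel, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(model_to_dict(model), indent=2, sort_keys=False) + "\n"
    )


def load_model(path: str | Path, format: str = "json", sidecar: str | Path | None = None) -> StoichiometricModel:
    """Load a model from ``json`` (native dialect) or ``sbml`` (L3 + FBC).

    For SBML a sidecar YAML naming ``substrate_uptake``, ``biomass_reaction``
    and ``target_reaction`` is required unless the file's FBC objective
    identifies biomass and roles are otherwise derivable.
    """
    path = Path(path)
    if not path.exists():
        raise ModelFormatError(f"model file not found: {path}")
    if format == "json":
        try:
            d = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
        return model_from_dict(d)
    if format == "sbml":
        from .sbml import load_sbml_model

        return load_sbml_model(path, sidecar=sidecar)
    raise ModelFormatError(f"unknown model format {format!r} (expected 'json' or 'sbml')")


def retag_roles(
    model: StoichiometricModel,
    *,
    uptake: str | None = None,
    biomass: str | None = None,
    target: str | None = None,
    precursors: Iterable[str] | None = None,
    non_deletable: Iterable[str] | None = None,
) -> StoichiometricModel:
    """Return a copy with role/precursor designations applied."""
    role_for = {}
    if uptake:
        role_for[uptake] = "uptake"
    if biomass:
        role_for[biomass] = "biomass"
    if target:
        role_for[target] = "target"
    nondel = set(non_deletable or ())
    rxns = []
    for r in model.reactions:
        role = role_for.get(r.id, r.role)
        deletable = r.deletable
        if r.id in role_for:
            deletable = None  # re-derive from the new role
        if r.id in nondel:
            deletable = False
        rxns.append(replace(r, role=role, deletable=deletable))
    return StoichiometricModel(
        metabolites=list(model.metabolites),
        reactions=rxns,
        precursor_ids=set(precursors) if precursors is not None else set(model.precursor_ids),
        name=model.name,
    )
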