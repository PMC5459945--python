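"""Elementary flux mode enumeration and partitioning.

The enumerator is a nullspace-style double-description method over exact
rationals: starting from the standard basis of the nonnegative flux orthant,
each steady-state balance (one row of S per internal metabolite) is imposed
in turn; surviving rays are kept and adjacent positive/negative ray pairs
are combined.  For a fully irreversible network the extreme rays of the
resulting pointed cone are exactly the elementary flux modes.  Reversible
reactions are split into forward/backward pairs beforehand and the spurious
two-cycle modes this creates are removed afterwards.

Exact Fraction arithmetic makes the elementarity (zero-set) tests exact;
this is deliberate — support-minimality degrades badly under float noise.
The method is intended for core-scale networks, not genome scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd

from .model import FLUX_TOL, StoichiometricModel, split_reversible

LABELS = ("S_x", "S_t", "coupled", "neither")


class EfmError(Exception):
    pass


class ResourceError(EfmError):
    """Mode count exceeded the requested budget."""

    def __init__(self, partial_count: int, max_modes: int):
        self.partial_count = partial_count
        self.max_modes = max_modes
        super().__init__(
            f"elementary mode enumeration exceeded max_modes={max_modes} "
            f"(at least {partial_count} intermediate rays)"
        )


class UndefinedYieldError(EfmError):
    pass


@dataclass(frozen=True)
class FluxMode:
    """One elementary mode: nonnegative coefficients over split reactions.

    Coefficients are normalized so the largest equals 1; ``support`` is the
    set of reaction ids carrying non-zero flux.
    """

    coefficients: dict[str, Fraction]
    support: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        coeffs = {r: c for r, c in self.coefficients.items() if c != 0}
        peak = max(coeffs.values())
        object.__setattr__(self, "coefficients", {r: c / peak for r, c in coeffs.items()})
        object.__setattr__(self, "support", frozenset(coeffs))

    def net_flux(self, rid: str) -> Fraction:
        """Flux through an original reaction (forward minus backward half)."""
        return self.coefficients.get(rid, Fraction(0)) - self.coefficients.get(
            f"{rid}__rev", Fraction(0)
        )


@dataclass
class EFMSet:
    """The full mode set of a network plus its biomass/product partition."""

    modes: list[FluxMode]
    reaction_ids: list[str]
    split_mapping: dict[str, tuple[str, str]] = field(default_factory=dict)
    partition: dict[int, str] = field(default_factory=dict)
    biomass_id: str | None = None
    target_id: str | None = None

    def indices(self, label: str) -> list[int]:
        return [i for i, lab in sorted(self.partition.items()) if lab == label]

    @property
    def m(self) -> int:
        """Number of product-only modes (S_t)."""
        return len(self.indices("S_t"))

    @property
    def n(self) -> int:
        """Number of biomass-only modes (S_x)."""
        return len(self.indices("S_x"))

    def modes_in(self, label: str) -> list[FluxMode]:
        return [self.modes[i] for i in self.indices(label)]


# ---------------------------------------------------------------------------
# Double description core


def _reduce(ray: tuple[Fraction, ...]) -> tuple[Fraction, ...]:
    """Scale a rational ray to coprime integers (keeps arithmetic small)."""
    from math import lcm

    denoms = [c.denominator for c in ray if c != 0]
    if not denoms:
        return ray
    scale = lcm(*denoms)
    ints = [int(c * scale) for c in ray]
    g = 0
    for v in ints:
        g = gcd(g, v)
    return tuple(Fraction(v // g) for v in ints)


def _extreme_rays(rows: list[list[Fraction]], dim: int, max_rays: int) -> list[tuple[Fraction, ...]]:
    rays: list[tuple[Fraction, ...]] = [
        tuple(Fraction(int(i == j)) for j in range(dim)) for i in range(dim)
    ]
    for row in rows:
        dots = [sum(a * b for a, b in zip(row, ray)) for ray in rays]
        zero = [r for r, d in zip(rays, dots) if d == 0]
        pos = [(r, d) for r, d in zip(rays, dots) if d > 0]
        neg = [(r, d) for r, d in zip(rays, dots) if d < 0]
        zsets = {r: frozenset(i for i, c in enumerate(r) if c == 0) for r in rays}
        new = list(zero)
        for p, dp in pos:
            for n, dn in neg:
                meet = zsets[p] & zsets[n]
                # adjacency: no third ray's zero set contains the meet
                adjacent = True
                for w in rays:
                    if w is p or w is n:
                        continue
                    if meet <= zsets[w]:
                        adjacent = False
                        break
                if adjacent:
                    combo = tuple(-dn * pc + dp * nc for pc, nc in zip(p, n))
                    new.append(_reduce(combo))
        if len(new) > max_rays:
            raise ResourceError(len(new), max_rays)
        rays = new
    return rays


def enumerate_efms(model: StoichiometricModel, max_modes: int = 500_000) -> EFMSet:
    """Enumerate all elementary flux modes of a model (up to scaling).

    Reversible reactions are split internally; two-cycle artifacts are
    removed; modes are returned in lexicographic order of their supports.
    An infeasible network yields an empty set, not an error.
    """
    split, mapping = split_reversible(model)
    rids = split.reaction_ids
    rows = split.stoich_matrix_fraction()
    rays = _extreme_rays(rows, len(rids), max_modes)

    two_cycles = {frozenset(pair) for pair in mapping.values()}
    modes = []
    for ray in rays:
        coeffs = {rid: c for rid, c in zip(rids, ray) if c != 0}
        if not coeffs:
            continue
        if frozenset(coeffs) in two_cycles:
            continue
        modes.append(FluxMode(coefficients=coeffs))
    modes.sort(key=lambda m: tuple(sorted(m.support)))
    if len(modes) > max_modes:
        raise ResourceError(len(modes), max_modes)
    return EFMSet(modes=modes, reaction_ids=rids, split_mapping=mapping)


def partition_modes(efms: EFMSet, biomass_id: str, target_id: str, tol: float = FLUX_TOL) -> EFMSet:
    """Label each mode S_x (biomass only), S_t (product only), coupled or neither."""
    if biomass_id not in efms.reaction_ids:
        raise EfmError(f"biomass reaction {biomass_id!r} not in network")
    if target_id not in efms.reaction_ids:
        raise EfmError(f"target reaction {target_id!r} not in network")
    partition = {}
    for i, mode in enumerate(efms.modes):
        bio = abs(mode.net_flux(biomass_id)) > tol
        tgt = abs(mode.net_flux(target_id)) > tol
        if bio and tgt:
            partition[i] = "coupled"
        elif bio:
            partition[i] = "S_x"
        elif tgt:
            partition[i] = "S_t"
        else:
            partition[i] = "neither"
    efms.partition = partition
    efms.biomass_id = biomass_id
    efms.target_id = target_id
    return efms


def mode_yield(mode: FluxMode, numerator_id: str, denominator_id: str) -> float:
    """Scale-invariant molar yield of one flux through another within a mode."""
    den = mode.net_flux(denominator_id)
    if abs(den) <= FLUX_TOL:
        raise UndefinedYieldError(
            f"denominator reaction {denominator_id!r} carries no flux in this mode"
        )
    return float(mode.net_flux(numerator_id) / den)
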