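"""Finite abelian groups, automorphism-subgroup actions, and the named
substitution models (CFN, JC, K2P, K3P).

A group is a direct product of cyclic groups; elements are tuples of
residues under componentwise addition.  A model pairs a group ``G`` with a
subgroup ``B`` of ``Aut(G)`` given by permutations of the element set; the
``B``-orbits define the free parameters (``l + 1`` of them per edge).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "GroupSpec",
    "AutomorphismAction",
    "ModelSpec",
    "make_group",
    "trivial_action",
    "make_action",
    "compute_orbits",
    "named_model",
    "generic_model",
    "NAMED_MODELS",
    "InvalidGroupError",
    "InvalidActionError",
]

GroupElement = tuple[int, ...]


class InvalidGroupError(ValueError):
    pass


class InvalidActionError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSpec:
    """A finite abelian group: direct product of Z/n_i with n_i >= 2."""

    invariant_factors: tuple[int, ...]
    elements: tuple[GroupElement, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        for n in self.invariant_factors:
            if not isinstance(n, int) or n < 2:
                raise InvalidGroupError(
                    f"invariant factors must be integers >= 2, got {n!r}"
                )
        elems = tuple(
            itertools.product(*(range(n) for n in self.invariant_factors))
        )
        object.__setattr__(self, "elements", elems)

    @property
    def order(self) -> int:
        return len(self.elements)

    @property
    def identity(self) -> GroupElement:
        return (0,) * len(self.invariant_factors)

    def add(self, a: GroupElement, b: GroupElement) -> GroupElement:
        return tuple(
            (x + y) % n for x, y, n in zip(a, b, self.invariant_factors)
        )

    def neg(self, a: GroupElement) -> GroupElement:
        return tuple((-x) % n for x, n in zip(a, self.invariant_factors))

    def sum(self, elems) -> GroupElement:
        total = self.identity
        for e in elems:
            total = self.add(total, e)
        return total

    def index(self, a: GroupElement) -> int:
        return self.elements.index(a)

    def __contains__(self, a) -> bool:
        return a in self.elements


def make_group(invariant_factors: Sequence[int]) -> GroupSpec:
    """Build the direct product of cyclic groups of the given orders."""
    return GroupSpec(tuple(invariant_factors))


@dataclass(frozen=True)
class AutomorphismAction:
    """A subgroup of Aut(G), stored as permutations of the element set.

    Permutations map element -> element; the stored set is the closure of
    the generators under composition.  Every permutation must fix the
    identity and respect addition (checked exhaustively at construction).
    """

    group: GroupSpec
    generators: tuple[dict, ...]
    permutations: frozenset = field(init=False, compare=False)

    def __post_init__(self) -> None:
        for g in self.generators:
            _check_automorphism(self.group, g)
        closure = _generate_closure(self.group, self.generators)
        object.__setattr__(self, "permutations", closure)

    @property
    def is_trivial(self) -> bool:
        return len(self.permutations) == 1

    def orbit(self, a: GroupElement) -> frozenset:
        return frozenset(dict(p)[a] for p in self.permutations)


def _check_automorphism(group: GroupSpec, perm: dict) -> None:
    elems = group.elements
    if set(perm.keys()) != set(elems) or set(perm.values()) != set(elems):
        raise InvalidActionError("permutation is not a bijection on the group")
    if perm[group.identity] != group.identity:
        raise InvalidActionError("permutation does not fix the identity")
    for a in elems:
        for b in elems:
            if perm[group.add(a, b)] != group.add(perm[a], perm[b]):
                raise InvalidActionError(
                    f"permutation is not additive at ({a}, {b})"
                )


def _generate_closure(group: GroupSpec, generators) -> frozenset:
    identity = tuple(sorted((a, a) for a in group.elements))
    seen = {identity}
    frontier = [identity]
    gens = [tuple(sorted(g.items())) for g in generators]
    while frontier:
        cur = frontier.pop()
        cur_d = dict(cur)
        for g in gens:
            g_d = dict(g)
            comp = tuple(sorted((a, g_d[cur_d[a]]) for a in group.elements))
            if comp not in seen:
                seen.add(comp)
                frontier.append(comp)
    return frozenset(seen)


def trivial_action(group: GroupSpec) -> AutomorphismAction:
    return AutomorphismAction(group, ())


def make_action(group: GroupSpec, generators: Sequence[dict]) -> AutomorphismAction:
    """Action from generator permutations given as element->element dicts."""
    return AutomorphismAction(group, tuple(dict(g) for g in generators))


@dataclass(frozen=True)
class ModelSpec:
    """A group-based model (G, B): orbits and canonical representatives.

    ``l + 1`` is the number of B-orbits.  Representatives are the
    lexicographically smallest tuple in each orbit; the identity always
    represents its own (singleton) orbit.
    """

    group: GroupSpec
    action: AutomorphismAction
    orbits: tuple[frozenset, ...] = field(init=False, compare=False)
    representatives: tuple[GroupElement, ...] = field(init=False, compare=False)
    name: str = "generic"

    def __post_init__(self) -> None:
        orbits, reps = compute_orbits(self.group, self.action)
        object.__setattr__(self, "orbits", orbits)
        object.__setattr__(self, "representatives", reps)

    @property
    def l(self) -> int:
        return len(self.orbits) - 1

    @property
    def n_orbits(self) -> int:
        return len(self.orbits)

    def orbit_rep(self, a: GroupElement) -> GroupElement:
        return self._rep_of[a]

    @property
    def _rep_of(self) -> dict:
        cache = getattr(self, "__rep_cache", None)
        if cache is None:
            cache = {}
            for orb, rep in zip(self.orbits, self.representatives):
                for a in orb:
                    cache[a] = rep
            object.__setattr__(self, "__rep_cache", cache)
        return cache


def compute_orbits(group: GroupSpec, action: AutomorphismAction):
    """Partition the group into B-orbits with lex-smallest representatives.

    Returns ``(orbits, representatives)`` where both are tuples ordered by
    representative; the identity's orbit comes first.
    """
    if action.group != group:
        raise InvalidActionError("action was built for a different group")
    remaining = set(group.elements)
    pairs = []
    while remaining:
        a = min(remaining)
        orb = action.orbit(a)
        pairs.append((min(orb), orb))
        remaining -= orb
    pairs.sort(key=lambda p: p[0])
    reps = tuple(p[0] for p in pairs)
    orbits = tuple(p[1] for p in pairs)
    assert reps[0] == group.identity
    return orbits, reps


def _klein4() -> GroupSpec:
    return make_group([2, 2])


def _perm_from_cycle(group: GroupSpec, cycle: Sequence[GroupElement]) -> dict:
    perm = {a: a for a in group.elements}
    for a, b in zip(cycle, cycle[1:] + type(cycle)([cycle[0]])):
        perm[a] = b
    return perm


def _jc_action() -> AutomorphismAction:
    g = _klein4()
    nz = [(0, 1), (1, 0), (1, 1)]
    swap = _perm_from_cycle(g, [nz[0], nz[1]])
    rot = _perm_from_cycle(g, nz)
    return make_action(g, [swap, rot])


def _k2p_action() -> AutomorphismAction:
    g = _klein4()
    swap = _perm_from_cycle(g, [(0, 1), (1, 0)])
    return make_action(g, [swap])


def _named_specs():
    z2 = make_group([2])
    k4 = _klein4()
    return {
        "CFN": ModelSpec(z2, trivial_action(z2), name="CFN"),
        "JC": ModelSpec(k4, _jc_action(), name="JC"),
        "K2P": ModelSpec(k4, _k2p_action(), name="K2P"),
        "K3P": ModelSpec(k4, trivial_action(k4), name="K3P"),
    }


NAMED_MODELS = ("CFN", "JC", "K2P", "K3P")


def named_model(name: str, group: GroupSpec | None = None) -> ModelSpec:
    """Return one of the named models, or a generic model for ``group``.

    ``CFN`` is the general model on Z/2; ``K3P`` the general model on the
    Klein four-group; ``JC``/``K2P`` act on the Klein four-group by the full
    symmetric group on nonzero elements / a single transposition.
    """
    if name == "generic":
        if group is None:
            raise ValueError("generic model requires a GroupSpec")
        return generic_model(group)
    specs = _named_specs()
    if name not in specs:
        raise ValueError(
            f"unknown model {name!r}; valid names: {', '.join(NAMED_MODELS)}, generic"
        )
    return specs[name]


def generic_model(group: GroupSpec, name: str | None = None) -> ModelSpec:
    """General group-based model: trivial B, one orbit per element."""
    label = name or "Z" + "x".join(str(n) for n in group.invariant_factors)
    return ModelSpec(group, trivial_action(group), name=label)
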