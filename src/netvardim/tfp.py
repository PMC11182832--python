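"""Toric fiber products for network gluing along a cut edge.

Coordinates of the two pieces carry a multigrading by B-orbits: the degree
of a coordinate is the orbit of the induced label of the cut edge, i.e. the
sum of the leaf labels on the designated ("+") side.  Quadratic binomial
generators (Quad_B) swap the two sides of equal-degree coordinate pairs;
lifts turn a generator of one factor's ideal into polynomials in the glued
coordinates, one per choice of equal-degree co-factor generators.

Polynomials in q-coordinates are plain coefficient/monomial term lists; no
term orders or Groebner machinery are involved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

from .groups import ModelSpec
from .networks import consistent_labellings

__all__ = [
    "QPoly",
    "Multigrading",
    "multidegree",
    "quad_b_generators",
    "lift",
    "lift_monomial",
    "LiftedPolynomial",
    "tfp_dimension_formula",
    "tree_quadratic_binomials",
    "NotHomogeneousError",
]


class NotHomogeneousError(ValueError):
    pass


@dataclass(frozen=True)
class QPoly:
    """Polynomial in q-coordinates: ordered terms (coeff, monomial), the
    monomial being a tuple of leaf labellings (each a tuple of group
    elements).  Term order is preserved for rendering."""

    terms: tuple

    @staticmethod
    def make(terms: Sequence) -> "QPoly":
        return QPoly(tuple((int(c), tuple(map(tuple, mono))) for c, mono in terms))

    def combined(self) -> dict:
        """Coefficients accumulated on canonically sorted monomials."""
        acc: dict = {}
        for coeff, mono in self.terms:
            key = tuple(sorted(mono))
            acc[key] = acc.get(key, 0) + coeff
        return {k: v for k, v in acc.items() if v != 0}

    @property
    def is_zero(self) -> bool:
        return not self.combined()

    def evaluate(self, coordinate_values: dict, p: int | None = None):
        total = 0
        for coeff, mono in self.terms:
            val = coeff
            for lab in mono:
                val = val * coordinate_values[lab]
                if p is not None:
                    val %= p
            total = total + val if p is None else (total + val) % p
        return total

    def render(self) -> str:
        parts = []
        for i, (coeff, mono) in enumerate(self.terms):
            body = "".join(
                "q_{" + "".join(_fmt(g) for g in lab) + "}" for lab in mono
            )
            mag = abs(coeff)
            prefix = "" if mag == 1 else f"{mag}*"
            if i == 0:
                sign = "-" if coeff < 0 else ""
                parts.append(f"{sign}{prefix}{body}")
            else:
                sign = "-" if coeff < 0 else "+"
                parts.append(f" {sign} {prefix}{body}")
        return "".join(parts) if parts else "0"


def _fmt(g: tuple) -> str:
    return str(g[0]) if len(g) == 1 else "".join(str(x) for x in g)


@dataclass(frozen=True)
class Multigrading:
    """Grading induced by a cut edge directed toward the '+' side.

    ``n_plus`` original leaves lie on the '+' side; '+' coordinates carry
    the cut-leaf label last, '-' coordinates carry it first.  The degree of
    any coordinate is the B-orbit of the sum of the '+'-side original leaf
    labels (equivalently the induced label of the cut edge).
    """

    model: ModelSpec
    n_plus: int

    def degree_glued(self, labelling: tuple) -> tuple:
        s = self.model.group.sum(labelling[: self.n_plus])
        return self.model.orbit_rep(s)

    def degree_plus(self, labelling: tuple) -> tuple:
        return self.model.orbit_rep(self.model.group.sum(labelling[:-1]))

    def degree_minus(self, labelling: tuple) -> tuple:
        return self.model.orbit_rep(labelling[0])

    def glue(self, plus_lab: tuple, minus_lab: tuple) -> tuple:
        """Combine factor labellings into a glued labelling; they must agree
        exactly across the cut (g- = -g+)."""
        group = self.model.group
        if minus_lab[0] != group.neg(plus_lab[-1]):
            raise ValueError(
                f"incompatible cut labels: {plus_lab[-1]} vs {minus_lab[0]}"
            )
        return plus_lab[:-1] + minus_lab[1:]

    def split(self, labelling: tuple) -> tuple:
        """The gluing monomial map phi_B on coordinates: glued labelling ->
        (plus labelling, minus labelling)."""
        group = self.model.group
        s = group.sum(labelling[: self.n_plus])
        plus = labelling[: self.n_plus] + (group.neg(s),)
        minus = (s,) + labelling[self.n_plus :]
        return plus, minus

    def plus_generators(self, degree: tuple) -> list[tuple]:
        group = self.model.group
        return [
            lab
            for lab in consistent_labellings(self.n_plus + 1, group)
            if self.degree_plus(lab) == degree
        ]

    def minus_generators(self, n_minus: int, degree: tuple) -> list[tuple]:
        group = self.model.group
        return [
            lab
            for lab in consistent_labellings(n_minus + 1, group)
            if self.degree_minus(lab) == degree
        ]


def multidegree(labelling: tuple, grading: Multigrading) -> tuple:
    """Degree (orbit representative) of a glued q-coordinate."""
    return grading.degree_glued(labelling)


def quad_b_generators(grading: Multigrading, n_total: int) -> list[QPoly]:
    """All nonzero Quad_B binomials in the glued coordinates:
    ``q_g q_h - q_(g_head, h_tail) q_(h_head, g_tail)`` over unordered pairs
    of labellings with equal cut-edge label.

    Pairs are matched on the exact cut-edge label (not just its orbit) so
    that the swapped labellings are consistent; degenerate swaps are
    dropped.
    """
    group = grading.model.group
    k = grading.n_plus
    by_label: dict = {}
    for lab in consistent_labellings(n_total, group):
        by_label.setdefault(group.sum(lab[:k]), []).append(lab)
    out = []
    for labs in by_label.values():
        for g, h in itertools.combinations(labs, 2):
            swapped1 = g[:k] + h[k:]
            swapped2 = h[:k] + g[k:]
            if {swapped1, swapped2} == {g, h}:
                continue
            assert group.sum(swapped1) == group.identity
            out.append(QPoly(((1, (g, h)), (-1, (swapped1, swapped2)))))
    return out


@dataclass(frozen=True)
class LiftedPolynomial:
    source: QPoly
    k: tuple
    side: str
    result: QPoly


def _slot_sorted(mono: tuple, degree_of) -> tuple:
    """Factors of a monomial ordered by (degree, labelling) for slot
    alignment across the terms of a homogeneous polynomial."""
    return tuple(sorted(mono, key=lambda lab: (degree_of(lab), lab)))


def lift(
    f: QPoly, k: Sequence[tuple], grading: Multigrading, side: str = "plus"
) -> LiftedPolynomial:
    """Lift a homogeneous polynomial of one factor to the glued coordinates
    using the co-factor generators ``k`` (one per degree slot).

    ``side`` names the factor that ``f`` lives in.  Applying the gluing map
    to the result recovers (co-factor monomial) x f.
    """
    if side not in ("plus", "minus"):
        raise ValueError("side must be 'plus' or 'minus'")
    deg_f = grading.degree_plus if side == "plus" else grading.degree_minus
    deg_k = grading.degree_minus if side == "plus" else grading.degree_plus
    slot_degrees = None
    sorted_terms = []
    for coeff, mono in f.terms:
        ordered = _slot_sorted(mono, deg_f)
        degs = tuple(deg_f(lab) for lab in ordered)
        if slot_degrees is None:
            slot_degrees = degs
        elif degs != slot_degrees:
            raise NotHomogeneousError(
                "polynomial is not homogeneous in the cut multigrading"
            )
        sorted_terms.append((coeff, ordered))
    if slot_degrees is None:
        raise ValueError("cannot lift the zero polynomial")
    k = tuple(map(tuple, k))
    if len(k) != len(slot_degrees):
        raise ValueError(
            f"need {len(slot_degrees)} co-factor generators, got {len(k)}"
        )
    for kj, dj in zip(k, slot_degrees):
        if deg_k(kj) != dj:
            raise ValueError(
                f"co-factor generator {kj} has degree {deg_k(kj)}, slot needs {dj}"
            )
    lifted = []
    for coeff, ordered in sorted_terms:
        if side == "plus":
            glued = tuple(grading.glue(lab, kj) for lab, kj in zip(ordered, k))
        else:
            glued = tuple(grading.glue(kj, lab) for lab, kj in zip(ordered, k))
        lifted.append((coeff, glued))
    return LiftedPolynomial(source=f, k=k, side=side, result=QPoly(tuple(lifted)))


def lift_monomial(
    gen: tuple, grading: Multigrading, n_other: int, side: str = "plus"
) -> list[tuple]:
    """Lift of a single degree-1 generator by every equal-degree generator
    of the co-factor: the set of glued coordinates it can map to."""
    gen = tuple(gen)
    if side == "plus":
        degree = grading.degree_plus(gen)
        cofactors = grading.minus_generators(n_other, degree)
        return [grading.glue(gen, kj) for kj in cofactors]
    degree = grading.degree_minus(gen)
    cofactors = grading.plus_generators(degree)
    return [grading.glue(kj, gen) for kj in cofactors]


def tfp_dimension_formula(dim_I: int, dim_J: int, r: int) -> int:
    """Codimension-zero toric fiber product: dim I + dim J - |A|."""
    return dim_I + dim_J - r


def tree_quadratic_binomials(param) -> list[QPoly]:
    """Quadratic binomials vanishing on a *tree* parameterization, found by
    matching products of coordinate monomials with equal exponent vectors.

    Exhaustive over unordered coordinate pairs, so intended for small trees
    (quartets and the like).  Independent of any printed generating set.
    """
    if len(param.trees) != 1:
        raise ValueError("quadratic-binomial search expects a tree (k = 0)")
    mono_of = {
        lab: tuple(sorted(param.monomial(lab, 0).items()))
        for lab in param.labellings
    }
    classes: dict = {}
    for a, b in itertools.combinations_with_replacement(param.labellings, 2):
        key = tuple(
            sorted(itertools.chain(mono_of[a], mono_of[b]))
        )
        classes.setdefault(key, []).append((a, b))
    out = []
    for pairs in classes.values():
        first = pairs[0]
        for other in pairs[1:]:
            out.append(QPoly(((1, first), (-1, other))))
    return out
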