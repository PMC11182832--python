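"""Fourier-coordinate parameterization of a group-based model on a level-1
network.

Every consistent leaf labelling indexes one coordinate; its value is a sum
of one squarefree monomial per displayed tree, the monomial being the
product over the tree's edges of the parameter ``a_e^{[xi(e)]}`` where
``xi(e)`` is the induced edge label and ``[.]`` the B-orbit representative.
Parameters are indexed by ``(edge id, orbit representative)`` pairs, so
there are ``m (l+1)`` of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Hashable

from .groups import ModelSpec
from .networks import (
    DisplayedTree,
    SemiDirectedNetwork,
    _edge_key,
    consistent_labellings,
    displayed_trees,
)

__all__ = [
    "ParameterIndex",
    "Parameterization",
    "build_parameterization",
    "evaluate",
    "jacobian",
    "orbit_project",
    "render_coordinate",
    "render_symbolic_coordinates",
]

# a parameter is (edge id, orbit representative)
ParameterIndex = tuple


@dataclass
class Parameterization:
    """Structured polynomial data of the map phi_N for one (network, model).

    ``coordinate(labelling)`` returns the list of sparse exponent vectors
    (dicts ParameterIndex -> 1), one per displayed tree in sigma order.
    """

    network: SemiDirectedNetwork
    model: ModelSpec
    trees: list[DisplayedTree] = field(init=False)
    labellings: list[tuple] = field(init=False)
    param_order: list[ParameterIndex] = field(init=False)
    _param_pos: dict = field(init=False, repr=False)
    _tree_sides: list = field(init=False, repr=False)

    def __post_init__(self) -> None:
        net, model = self.network, self.model
        self.trees = displayed_trees(net)
        self.labellings = list(
            consistent_labellings(net.n_leaves, model.group)
        )
        edges = net.sorted_edges()
        self.param_order = [
            (e.id, rep) for e in edges for rep in model.representatives
        ]
        self._param_pos = {p: i for i, p in enumerate(self.param_order)}
        order = net.leaf_order
        pos = {label: i for i, label in enumerate(order)}
        self._tree_sides = []
        for tree in self.trees:
            sides = []
            for e in sorted(tree.edges, key=lambda e: _edge_key(e.id)):
                sides.append(
                    (e.id, tuple(pos[v] for v in tree.head_side(e.id)))
                )
            self._tree_sides.append(sides)

    # -- structure --------------------------------------------------------

    @property
    def n_coordinates(self) -> int:
        return len(self.labellings)

    @property
    def n_parameters(self) -> int:
        return len(self.param_order)

    @property
    def n_monomials(self) -> int:
        return len(self.trees)

    def edge_labels(self, labelling: tuple, tree_index: int) -> dict:
        """Map edge id -> group element for one displayed tree."""
        group = self.model.group
        out = {}
        for eid, positions in self._tree_sides[tree_index]:
            out[eid] = group.sum(labelling[i] for i in positions)
        return out

    def monomial(self, labelling: tuple, tree_index: int) -> dict:
        """Sparse exponent vector of one displayed-tree monomial."""
        rep = self.model.orbit_rep
        vec: dict = {}
        for eid, lab in self.edge_labels(labelling, tree_index).items():
            key = (eid, rep(lab))
            vec[key] = vec.get(key, 0) + 1
        return vec

    def coordinate(self, labelling: tuple) -> list[dict]:
        return [self.monomial(labelling, t) for t in range(len(self.trees))]

    # -- numerics ---------------------------------------------------------

    def evaluate(self, point: dict, p: int | None = None) -> list:
        """Evaluate every coordinate at a parameter point (exact).

        ``point`` maps every ParameterIndex to an integer or Fraction; with
        ``p`` given, arithmetic is mod p.
        """
        self._check_point(point)
        values = []
        for lab in self.labellings:
            total = 0
            for t in range(len(self.trees)):
                mon = self._monomial_value(lab, t, point, p)
                total = total + mon if p is None else (total + mon) % p
            values.append(total)
        return values

    def evaluate_coordinate_map(self, point: dict, p: int | None = None) -> dict:
        """Labelling -> coordinate value, for plugging into q-polynomials."""
        vals = self.evaluate(point, p)
        return dict(zip(self.labellings, vals))

    def _monomial_value(self, lab, tree_index, point, p):
        rep = self.model.orbit_rep
        group = self.model.group
        mon = 1
        for eid, positions in self._tree_sides[tree_index]:
            v = point[(eid, rep(group.sum(lab[i] for i in positions)))]
            mon = mon * v if p is None else (mon * v) % p
        return mon

    def jacobian(self, point: dict, p: int | None = None) -> list[list]:
        """Exact Jacobian at a point: rows = coordinates, columns follow
        ``param_order``.  Entries are integers (or residues mod p) when the
        point is integral; monomials are squarefree so each partial
        derivative is the monomial divided by the parameter value.
        """
        self._check_point(point)
        npar = self.n_parameters
        pos = self._param_pos
        rep = self.model.orbit_rep
        group = self.model.group
        if p is not None:
            inv = {k: pow(int(v) % p, p - 2, p) for k, v in point.items()}
        rows = []
        for lab in self.labellings:
            row = [0] * npar
            for sides in self._tree_sides:
                keys = []
                mon = 1
                for eid, positions in sides:
                    key = (eid, rep(group.sum(lab[i] for i in positions)))
                    keys.append(key)
                    mon = mon * point[key] if p is None else (mon * point[key]) % p
                for key in keys:
                    j = pos[key]
                    if p is None:
                        v = point[key]
                        row[j] = row[j] + (
                            mon // v if mon % v == 0 else Fraction(mon, v)
                        )
                    else:
                        row[j] = (row[j] + mon * inv[key]) % p
            rows.append(row)
        return rows

    def _check_point(self, point: dict) -> None:
        missing = [k for k in self.param_order if k not in point]
        if missing:
            raise KeyError(f"point is missing parameter values, e.g. {missing[0]}")


def build_parameterization(
    net: SemiDirectedNetwork, model: ModelSpec
) -> Parameterization:
    return Parameterization(net, model)


def evaluate(param: Parameterization, point: dict, p: int | None = None) -> list:
    return param.evaluate(point, p)


def jacobian(param: Parameterization, point: dict, p: int | None = None):
    return param.jacobian(point, p)


def orbit_project(vector: dict, model: ModelSpec) -> dict:
    """Project a vector over (edge, group element) axes to (edge, orbit
    representative) axes by summing coefficients within each orbit."""
    out: dict = {}
    for (eid, g), coeff in vector.items():
        key = (eid, model.orbit_rep(g))
        out[key] = out.get(key, 0) + coeff
    return {k: v for k, v in out.items() if v != 0}


# ---------------------------------------------------------------------------
# plain-text rendering


def _format_element(g) -> str:
    if len(g) == 1:
        return str(g[0])
    return "".join(str(x) for x in g)


def render_coordinate(param: Parameterization, labelling: tuple) -> str:
    """One coordinate as text, e.g. ``q_{01} = a1^{0} a2^{1} + ...``."""
    name = "q_{" + "".join(_format_element(g) for g in labelling) + "}"
    terms = []
    for t in range(len(param.trees)):
        labels = param.edge_labels(labelling, t)
        factors = [
            f"a{eid}^{{{_format_element(param.model.orbit_rep(lab))}}}"
            for eid, lab in sorted(labels.items(), key=lambda kv: _edge_key(kv[0]))
        ]
        terms.append(" ".join(factors))
    return f"{name} = " + " + ".join(terms)


def render_symbolic_coordinates(net: SemiDirectedNetwork) -> str:
    """The generic coordinate of the general (trivial-B) model as text, with
    formal leaf labels g1..gn: ``q_{g1g2..} = a1^{g1} ... + ...``.

    Edge labels are formal sums of the leaf labels on the arrow side.
    """
    order = net.leaf_order
    names = {label: f"g{i + 1}" for i, label in enumerate(order)}
    trees = displayed_trees(net)
    terms = []
    for tree in trees:
        factors = []
        for e in sorted(tree.edges, key=lambda e: _edge_key(e.id)):
            side = tree.head_side(e.id)
            label = "+".join(names[v] for v in sorted(side, key=lambda x: order.index(x)))
            factors.append(f"a{e.id}^{{{label}}}")
        terms.append(" ".join(factors))
    name = "q_{" + "".join(names[label] for label in order) + "}"
    return f"{name} = " + " + ".join(terms)
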