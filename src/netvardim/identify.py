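"""Dimension-based distinguishability of networks and quartet invariants.

Two networks with irreducible varieties of equal dimension are
distinguishable when some leaf-subset restriction exhibits non-containment;
witnesses used here are dimension gaps between restrictions (via the
closed-form dimensions), a tree-versus-network gap, or distinct restricted
trees (separated by quartet invariants).  "Not decided" is an honest
outcome: the tool never claims indistinguishability.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, asdict
from typing import Hashable, Iterable

from .dimension import cfn_dimension, expected_dimension, jacobian_dimension
from .fourier import Parameterization, build_parameterization
from .groups import ModelSpec
from .networks import (
    Edge,
    SemiDirectedNetwork,
    restrict,
    tree_splits,
)
from .tfp import QPoly

__all__ = [
    "DistinguishabilityReport",
    "make_quartet_tree",
    "quartet_invariant",
    "vanishes_symbolically_on_tree",
    "vanishes_on",
    "formula_dimension",
    "distinguishable_by_dimension",
]


@dataclass(frozen=True)
class DistinguishabilityReport:
    verdict: str  # "distinguishable" | "not-decided"
    witness: dict | None
    dims: tuple
    note: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["witness"] and "subset" in d["witness"]:
            d["witness"]["subset"] = sorted(d["witness"]["subset"], key=str)
        return d


def make_quartet_tree(split_pair: tuple = (1, 2)) -> SemiDirectedNetwork:
    """The 4-leaf binary tree whose internal edge separates ``split_pair``
    from the other two leaves.  Leaf order is always (1, 2, 3, 4)."""
    a, b = sorted(split_pair)
    c, d = sorted(set((1, 2, 3, 4)) - {a, b})
    edges = (
        Edge(a, "v1", a),
        Edge(b, "v1", b),
        Edge(c, "v2", c),
        Edge(d, "v2", d),
        Edge(5, "v1", "v2"),
    )
    leaves = tuple((i, i) for i in (1, 2, 3, 4))
    return SemiDirectedNetwork(edges, leaves).validate()


def quartet_invariant(model: ModelSpec, g, h) -> QPoly:
    """The quadratic ``q_g q_h - q_g' q_h'`` with index tuples
    (g,-g,g,-g), (h,-h,h,-h), (g,-g,h,-h), (h,-h,g,-g); it vanishes
    identically on the split-12|34 quartet tree.  Requires h outside g's
    B-orbit."""
    group = model.group
    g, h = tuple(g), tuple(h)
    if model.orbit_rep(g) == model.orbit_rep(h):
        raise ValueError("g and h must lie in distinct B-orbits")
    ng, nh = group.neg(g), group.neg(h)
    gg = (g, ng, g, ng)
    hh = (h, nh, h, nh)
    gh = (g, ng, h, nh)
    hg = (h, nh, g, ng)
    return QPoly(((1, (gg, hh)), (-1, (gh, hg))))


def vanishes_symbolically_on_tree(param: Parameterization, poly: QPoly) -> bool:
    """Exact symbolic membership check of a q-polynomial in the toric ideal
    of a *tree*: substitute each coordinate's single monomial and verify the
    coefficients cancel per exponent vector."""
    if len(param.trees) != 1:
        raise ValueError("symbolic check requires a tree parameterization")
    acc: dict = {}
    for coeff, mono in poly.terms:
        total: dict = {}
        for lab in mono:
            for key, exp in param.monomial(lab, 0).items():
                total[key] = total.get(key, 0) + exp
        fro = tuple(sorted(total.items()))
        acc[fro] = acc.get(fro, 0) + coeff
    return all(v == 0 for v in acc.values())


def vanishes_on(
    net: SemiDirectedNetwork,
    poly: QPoly,
    model: ModelSpec,
    trials: int = 5,
    seed: int = 0,
) -> tuple[bool, dict | None]:
    """Probabilistic vanishing of a q-polynomial on a network's model.

    Evaluates the polynomial at the image of random integer parameter
    points with exact arithmetic.  Returns ``(False, certificate)`` on the
    first nonzero value (exact non-membership witness), else
    ``(True, None)`` after all trials vanished.
    """
    param = build_parameterization(net, model)
    rng = random.Random(seed)
    for trial in range(trials):
        point = {k: rng.randint(2, 997) for k in param.param_order}
        coords = param.evaluate_coordinate_map(point)
        value = poly.evaluate(coords)
        if value != 0:
            return False, {"trial": trial, "value": value}
    return True, None


def formula_dimension(net: SemiDirectedNetwork, model: ModelSpec) -> int | None:
    """Closed-form affine dimension when one applies, else None.

    Trees: l m + 1.  CFN: m - (c_ge5 + 2 c4 + 3 c3) + 1 for any level-1
    network.  |G| >= 3: l (m - c) + 1 for triangle-free networks; no closed
    form covers triangles for |G| > 2.
    """
    stats = net.stats()
    if net.contracted:
        raise ValueError("closed forms use the uncontracted edge count")
    if stats.c == 0:
        return model.l * stats.m + 1
    if model.group.order == 2:
        return cfn_dimension(stats)
    if stats.c3 == 0:
        return expected_dimension(stats, model)
    return None


def _full_dimension(net, model, trials, seed):
    d = formula_dimension(net, model)
    if d is not None:
        return d
    return jacobian_dimension(
        build_parameterization(net, model), trials=trials, seed=seed
    ).computed_dim


def distinguishable_by_dimension(
    net1: SemiDirectedNetwork,
    net2: SemiDirectedNetwork,
    model: ModelSpec,
    trials: int = 3,
    seed: int = 0,
    subset_sizes: Iterable[int] | None = None,
) -> DistinguishabilityReport:
    """Search leaf subsets for a restriction witness of distinguishability.

    Subsets of size n-1 are tried first, then quartets.  For each subset the
    rules are: a dimension gap between the restricted varieties (closed
    forms only, so the verdict is exact), a tree against a network, or two
    distinct restricted trees (distinguishable via quartet invariants).
    """
    leaves1 = set(net1.leaf_order)
    if leaves1 != set(net2.leaf_order):
        raise ValueError("networks must share a leaf set")
    n = len(leaves1)
    d1 = _full_dimension(net1, model, trials, seed)
    d2 = _full_dimension(net2, model, trials, seed)
    if d1 != d2:
        return DistinguishabilityReport(
            verdict="not-decided",
            witness=None,
            dims=(d1, d2),
            note=(
                "full dimensions differ; a dimension gap alone rules out only "
                "one containment"
            ),
        )
    if subset_sizes is None:
        subset_sizes = [n - 1, 4]
    ordered = sorted(leaves1, key=str)
    for size in subset_sizes:
        if size < 3 or size > n:
            continue
        for subset in itertools.combinations(ordered, size):
            witness = _subset_witness(net1, net2, model, frozenset(subset))
            if witness is not None:
                return DistinguishabilityReport(
                    verdict="distinguishable",
                    witness=witness,
                    dims=(d1, d2),
                )
    return DistinguishabilityReport(
        verdict="not-decided", witness=None, dims=(d1, d2)
    )


def _subset_witness(net1, net2, model, subset):
    r1 = restrict(net1, subset)
    r2 = restrict(net2, subset)
    s1, s2 = r1.stats(), r2.stats()
    if s1.c == 0 and s2.c == 0:
        if tree_splits(r1) != tree_splits(r2):
            return {
                "subset": subset,
                "rule": "distinct trees",
                "dims": (model.l * s1.m + 1, model.l * s2.m + 1),
            }
        return None
    f1 = formula_dimension(r1, model)
    f2 = formula_dimension(r2, model)
    if f1 is None or f2 is None:
        return None
    if f1 != f2:
        rule = (
            "tree vs network"
            if (s1.c == 0) != (s2.c == 0)
            else "dimension gap"
        )
        return {"subset": subset, "rule": rule, "dims": (f1, f2)}
    return None
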