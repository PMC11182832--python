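"""Level-1 semi-directed phylogenetic networks.

A network is a mixed graph: undirected tree edges (each carrying an
auxiliary stored orientation used to read off edge labels) and directed
reticulation edges, exactly two of which point into each reticulation
vertex.  Level-1 means every cycle of the underlying undirected graph
contains exactly one reticulation vertex, so cycles are vertex-disjoint.

Networks are stored uncontracted (binary) as the normal form; contraction
is an explicit operation.  Sunlet constructors follow the figure
conventions of the reference worked examples: leaf edges ``e1..en``, cycle
edges ``e_{n+1}..e_{2n}`` with ``e_{n+1}`` and ``e_{2n}`` the reticulation
edges, leaf 1 at the reticulation vertex.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field, replace
from typing import Hashable, Iterable, Iterator, Sequence

import networkx as nx

from .groups import GroupSpec

__all__ = [
    "Edge",
    "SemiDirectedNetwork",
    "NetworkStats",
    "DisplayedTree",
    "NetworkValidationError",
    "make_sunlet",
    "make_contracted_sunlet",
    "contract",
    "displayed_trees",
    "consistent_labellings",
    "induced_edge_labelling",
    "cut_at",
    "restrict",
    "random_level1",
    "is_isomorphic",
    "tree_splits",
]


class NetworkValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Edge:
    """One edge; ``tail -> head`` is the stored orientation.

    For reticulation edges the orientation is structural (into the
    reticulation vertex); for tree edges it is an auxiliary convention that
    fixes which leaf-side defines the edge label.
    """

    id: Hashable
    tail: Hashable
    head: Hashable
    reticulation: bool = False

    def other(self, v: Hashable) -> Hashable:
        return self.head if v == self.tail else self.tail

    @property
    def ends(self) -> frozenset:
        return frozenset((self.tail, self.head))


def _edge_key(edge_id: Hashable):
    return (0, edge_id) if isinstance(edge_id, int) else (1, str(edge_id))


@dataclass(frozen=True)
class NetworkStats:
    n: int
    m: int
    c: int
    c3: int
    c4: int
    c_ge5: int


@dataclass(frozen=True)
class SemiDirectedNetwork:
    edges: tuple[Edge, ...]
    leaves: tuple[tuple[Hashable, Hashable], ...]  # (label, vertex) pairs in order
    contracted: bool = False

    # -- basic accessors -------------------------------------------------

    @property
    def leaf_order(self) -> tuple:
        return tuple(label for label, _ in self.leaves)

    @property
    def leaf_vertex(self) -> dict:
        return dict(self.leaves)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def vertices(self) -> set:
        out = set()
        for e in self.edges:
            out.add(e.tail)
            out.add(e.head)
        return out

    def edge(self, edge_id: Hashable) -> Edge:
        for e in self.edges:
            if e.id == edge_id:
                return e
        raise KeyError(f"no edge with id {edge_id!r}")

    def incident(self, v: Hashable) -> list[Edge]:
        return [e for e in self.edges if v in (e.tail, e.head)]

    def degree(self, v: Hashable) -> int:
        return len(self.incident(v))

    @property
    def reticulation_vertices(self) -> list:
        heads = {}
        for e in self.edges:
            if e.reticulation:
                heads.setdefault(e.head, []).append(e)
        return sorted(heads, key=str)

    def reticulation_edges_at(self, v: Hashable) -> list[Edge]:
        es = [e for e in self.edges if e.reticulation and e.head == v]
        return sorted(es, key=lambda e: _edge_key(e.id))

    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edges, key=lambda e: _edge_key(e.id))

    def underlying_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        for e in self.edges:
            g.add_edge(e.tail, e.head, id=e.id, reticulation=e.reticulation)
        return g

    def with_flipped_edge(self, edge_id: Hashable) -> "SemiDirectedNetwork":
        """Reverse the stored orientation of one non-reticulation edge."""
        e = self.edge(edge_id)
        if e.reticulation:
            raise ValueError("cannot flip a reticulation edge")
        flipped = Edge(e.id, e.head, e.tail, False)
        new_edges = tuple(flipped if x.id == edge_id else x for x in self.edges)
        return replace(self, edges=new_edges)

    # -- structure -------------------------------------------------------

    def cycles(self) -> list[dict]:
        """Cycle blocks of the underlying graph.

        Each entry has the block's vertices, edges and its reticulation
        vertices.  Raises if some block is neither an edge nor a simple
        cycle (i.e. the network is not level-1).
        """
        g = self.underlying_graph()
        retic = set(self.reticulation_vertices)
        out = []
        for comp in nx.biconnected_components(g):
            if len(comp) <= 2:
                continue
            block_edges = [
                e for e in self.edges if e.tail in comp and e.head in comp
            ]
            if len(block_edges) != len(comp):
                raise NetworkValidationError(
                    f"block on vertices {sorted(map(str, comp))} is not a simple "
                    "cycle; the network is not level-1"
                )
            out.append(
                {
                    "vertices": set(comp),
                    "edges": block_edges,
                    "reticulations": sorted(comp & retic, key=str),
                }
            )
        return out

    def stats(self) -> NetworkStats:
        cyc = self.cycles()
        lens = [len(c["edges"]) for c in cyc]
        return NetworkStats(
            n=self.n_leaves,
            m=len(self.edges),
            c=len(cyc),
            c3=sum(1 for L in lens if L == 3),
            c4=sum(1 for L in lens if L == 4),
            c_ge5=sum(1 for L in lens if L >= 5),
        )

    def validate(self) -> "SemiDirectedNetwork":
        g = self.underlying_graph()
        if len(self.edges) != g.number_of_edges():
            raise NetworkValidationError("parallel edges are not allowed")
        if g.number_of_nodes() and not nx.is_connected(g):
            raise NetworkValidationError("network is not connected")
        ids = [e.id for e in self.edges]
        if len(set(ids)) != len(ids):
            raise NetworkValidationError("duplicate edge ids")
        leaf_map = self.leaf_vertex
        if len(leaf_map) != len(self.leaves):
            raise NetworkValidationError("duplicate leaf labels")
        retic = set(self.reticulation_vertices)
        for label, v in self.leaves:
            deg = self.degree(v)
            if self.contracted and v in retic:
                if deg != 2:
                    raise NetworkValidationError(
                        f"contracted reticulation leaf {label!r} must have degree 2"
                    )
            elif deg != 1:
                raise NetworkValidationError(
                    f"leaf {label!r} has degree {deg}, expected 1"
                )
        leaf_vertices = set(leaf_map.values())
        for v in self.vertices:
            if v in leaf_vertices:
                continue
            deg = self.degree(v)
            if self.degree(v) == 1:
                raise NetworkValidationError(
                    f"degree-1 vertex {v!r} is not a labelled leaf"
                )
            if not self.contracted:
                if v in retic:
                    if deg != 3:
                        raise NetworkValidationError(
                            f"reticulation vertex {v!r} has degree {deg}, expected 3"
                        )
                elif deg != 3:
                    raise NetworkValidationError(
                        f"internal vertex {v!r} has degree {deg}, expected 3"
                    )
        for v in retic:
            in_edges = self.reticulation_edges_at(v)
            if len(in_edges) != 2:
                raise NetworkValidationError(
                    f"reticulation vertex {v!r} has {len(in_edges)} incoming "
                    "reticulation edges, expected 2"
                )
        for e in self.edges:
            if e.reticulation and e.head not in retic:
                raise NetworkValidationError(
                    f"reticulation edge {e.id!r} does not point into a "
                    "reticulation vertex"
                )
            if not e.reticulation and e.tail in retic and e.head in retic:
                # such an edge could not be directed away from both of its
                # reticulation endpoints in any rooting
                raise NetworkValidationError(
                    f"tree edge {e.id!r} joins two reticulation vertices"
                )
        cyc = self.cycles()  # raises on non-cycle blocks
        seen_retics = set()
        for c in cyc:
            block_ids = {e.id for e in c["edges"]}
            # the cycle's own reticulations: both incoming reticulation
            # edges lie on the cycle.  In contracted networks another
            # cycle's reticulation vertex may sit on this cycle as well.
            own = []
            for r in c["reticulations"]:
                in_block = [
                    e for e in self.reticulation_edges_at(r) if e.id in block_ids
                ]
                if len(in_block) == 1:
                    raise NetworkValidationError(
                        f"reticulation vertex {r!r} has only one reticulation "
                        "edge on its cycle"
                    )
                if len(in_block) == 2:
                    own.append(r)
            if len(own) != 1:
                raise NetworkValidationError(
                    f"cycle on {sorted(map(str, c['vertices']))} contains "
                    f"{len(own)} reticulation vertices, expected 1"
                )
            if not self.contracted and len(c["reticulations"]) != 1:
                raise NetworkValidationError(
                    f"cycle on {sorted(map(str, c['vertices']))} passes through "
                    "a foreign reticulation vertex"
                )
            seen_retics.update(own)
        if seen_retics != set(retic):
            raise NetworkValidationError(
                "some reticulation vertex does not lie on any cycle"
            )
        return self


# ---------------------------------------------------------------------------
# constructors


def make_sunlet(n: int) -> SemiDirectedNetwork:
    """The n-sunlet: a single length-n cycle with one pendant leaf per cycle
    vertex; leaf 1 hangs off the reticulation vertex.

    Edges: ``e_i`` (i = 1..n) from cycle vertex ``c_i`` to leaf i;
    reticulation edges ``e_{n+1} = (c2 -> c1)`` and ``e_{2n} = (cn -> c1)``;
    remaining cycle edges ``e_{n+i}`` join ``c_i`` and ``c_{i+1}``.
    """
    if n < 3:
        raise ValueError("a sunlet needs at least 3 leaves")
    c = [f"c{i}" for i in range(n + 1)]  # c[1..n]
    edges = [Edge(i, c[i], i) for i in range(1, n + 1)]
    edges.append(Edge(n + 1, c[2], c[1], reticulation=True))
    for i in range(2, n - 1):
        edges.append(Edge(n + i, c[i + 1], c[i]))
    edges.append(Edge(2 * n - 1, c[n - 1], c[n]))
    edges.append(Edge(2 * n, c[n], c[1], reticulation=True))
    leaves = tuple((i, i) for i in range(1, n + 1))
    return SemiDirectedNetwork(tuple(edges), leaves).validate()


def make_contracted_sunlet(n: int) -> SemiDirectedNetwork:
    """The contracted n-sunlet: leaf 1 *is* the reticulation vertex.

    Edges: reticulation edges ``e1 = (u2 -> 1)`` and ``e_{n+1} = (un -> 1)``;
    leaf edges ``e_i = (u_i -> i)`` for i = 2..n; cycle edges
    ``e_{n+i}`` joining ``u_i`` and ``u_{i+1}`` for i = 2..n-1.
    """
    if n < 3:
        raise ValueError("a sunlet needs at least 3 leaves")
    u = [f"u{i}" for i in range(n + 1)]
    edges = [Edge(1, u[2], 1, reticulation=True)]
    edges.extend(Edge(i, u[i], i) for i in range(2, n + 1))
    edges.append(Edge(n + 1, u[n], 1, reticulation=True))
    for i in range(2, n - 1):
        edges.append(Edge(n + i, u[i + 1], u[i]))
    edges.append(Edge(2 * n - 1, u[n - 1], u[n]))
    leaves = ((1, 1),) + tuple((i, i) for i in range(2, n + 1))
    return SemiDirectedNetwork(tuple(edges), leaves, contracted=True).validate()


def contract(net: SemiDirectedNetwork) -> SemiDirectedNetwork:
    """Contract the (unique) outgoing non-reticulation edge of every binary
    reticulation vertex, merging it into its child.  Idempotent; edge count
    drops by the number of contracted reticulations."""
    merged: dict = {}
    removed_ids = set()
    for r in net.reticulation_vertices:
        incident = net.incident(r)
        if len(incident) != 3:
            continue  # already contracted at this vertex
        out = [e for e in incident if not e.reticulation]
        if len(out) != 1:
            raise NetworkValidationError(
                f"reticulation vertex {r!r} has {len(out)} non-reticulation edges"
            )
        e = out[0]
        merged[r] = e.other(r)
        removed_ids.add(e.id)

    def resolve(v):
        while v in merged:
            v = merged[v]
        return v

    new_edges = tuple(
        Edge(e.id, resolve(e.tail), resolve(e.head), e.reticulation)
        for e in net.edges
        if e.id not in removed_ids
    )
    new_leaves = tuple((label, resolve(v)) for label, v in net.leaves)
    out_net = SemiDirectedNetwork(new_edges, new_leaves, contracted=True)
    return out_net.validate()


# ---------------------------------------------------------------------------
# displayed trees and labellings


@dataclass(frozen=True)
class DisplayedTree:
    """One tree displayed by the network: keep one reticulation edge per
    reticulation vertex, as selected by the bit vector sigma (bit 0 keeps
    the lower-numbered reticulation edge)."""

    network: SemiDirectedNetwork
    sigma: tuple[int, ...]
    edges: tuple[Edge, ...]
    removed_ids: tuple = ()
    _head_sides: dict = field(default_factory=dict, compare=False, repr=False)

    def head_side(self, edge_id: Hashable) -> tuple:
        """Leaf labels on the head (arrow) side of an edge of this tree."""
        if not self._head_sides:
            self._compute_head_sides()
        return self._head_sides[edge_id]

    def _compute_head_sides(self) -> None:
        adj: dict = {}
        for e in self.edges:
            adj.setdefault(e.tail, []).append(e)
            adj.setdefault(e.head, []).append(e)
        leaf_of_vertex = {}
        for label, v in self.network.leaves:
            leaf_of_vertex[v] = label
        for e in self.edges:
            seen = {e.tail, e.head}
            stack = [e.head]
            labels = []
            while stack:
                v = stack.pop()
                if v in leaf_of_vertex:
                    labels.append(leaf_of_vertex[v])
                for f in adj[v]:
                    if f is e:
                        continue
                    w = f.other(v)
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
            self._head_sides[e.id] = tuple(sorted(labels, key=str))

    def is_tree(self) -> bool:
        g = nx.Graph()
        for e in self.edges:
            g.add_edge(e.tail, e.head)
        return nx.is_connected(g) and g.number_of_edges() == g.number_of_nodes() - 1


def displayed_trees(net: SemiDirectedNetwork) -> list[DisplayedTree]:
    """All 2^k displayed trees, ordered lexicographically by sigma."""
    retics = net.reticulation_vertices
    choices = [net.reticulation_edges_at(r) for r in retics]
    trees = []
    for sigma in itertools.product((0, 1), repeat=len(retics)):
        removed = [pair[1 - bit].id for pair, bit in zip(choices, sigma)]
        kept = tuple(e for e in net.edges if e.id not in removed)
        tree = DisplayedTree(net, sigma, kept, tuple(removed))
        trees.append(tree)
    return trees


def consistent_labellings(
    n: int, group: GroupSpec
) -> Iterator[tuple]:
    """All assignments of group elements to n leaves summing to zero, in
    lexicographic order over the first n-1 positions; there are |G|^(n-1)."""
    if n < 1:
        raise ValueError("need at least one leaf")
    for prefix in itertools.product(group.elements, repeat=n - 1):
        last = group.neg(group.sum(prefix))
        yield prefix + (last,)


def induced_edge_labelling(
    tree: DisplayedTree, labelling: dict, group: GroupSpec
) -> dict:
    """Label every edge of a displayed tree with the sum of the leaf labels
    on its arrow side.  ``labelling`` maps leaf label -> group element and
    must be consistent (labels sum to the identity)."""
    total = group.sum(labelling[label] for label, _ in tree.network.leaves)
    if total != group.identity:
        raise ValueError("leaf labelling is not consistent (labels must sum to 0)")
    out = {}
    for e in tree.edges:
        out[e.id] = group.sum(labelling[v] for v in tree.head_side(e.id))
    return out


# ---------------------------------------------------------------------------
# cutting and restriction


def cut_at(
    net: SemiDirectedNetwork, edge_id: Hashable, new_leaf: Hashable | None = None
) -> tuple[SemiDirectedNetwork, SemiDirectedNetwork]:
    """Cut the network at a (non-reticulation) cut edge.

    Returns ``(plus, minus)``: the piece the edge points into gets the new
    leaf appended last in its leaf order, the tail-side piece gets it
    prepended.  Both keep a copy of the cut edge with its orientation.
    """
    e = net.edge(edge_id)
    if e.reticulation:
        raise ValueError("cannot cut at a reticulation edge")
    g = net.underlying_graph()
    g.remove_edge(e.tail, e.head)
    if nx.has_path(g, e.tail, e.head):
        raise ValueError(f"edge {edge_id!r} is not a cut edge")
    head_comp = nx.node_connected_component(g, e.head)
    tail_comp = nx.node_connected_component(g, e.tail)
    if new_leaf is None:
        new_leaf = f"n_{edge_id}"
    if new_leaf in set(net.leaf_order) | net.vertices:
        raise ValueError(f"new leaf name {new_leaf!r} collides with the network")

    def build(comp, cut_edge, leaf_list):
        edges = tuple(
            x for x in net.edges if x.tail in comp and x.head in comp
        ) + (cut_edge,)
        return SemiDirectedNetwork(
            edges, tuple(leaf_list), contracted=net.contracted
        ).validate()

    plus_leaves = [(lbl, v) for lbl, v in net.leaves if v in head_comp]
    plus_leaves.append((new_leaf, new_leaf))
    minus_leaves = [(new_leaf, new_leaf)]
    minus_leaves += [(lbl, v) for lbl, v in net.leaves if v in tail_comp]
    plus = build(head_comp, Edge(e.id, new_leaf, e.head), plus_leaves)
    minus = build(tail_comp, Edge(e.id, e.tail, new_leaf), minus_leaves)
    return plus, minus


def restrict(
    net: SemiDirectedNetwork, leafset: Iterable[Hashable]
) -> SemiDirectedNetwork:
    """Restrict to a nonempty subset of the leaves.

    Deletes the other leaves with their pendant edges, removes reticulation
    vertices left with no leaf below them (together with both reticulation
    edges), and suppresses degree-2 vertices.  Merged edges get fresh
    composite ids and an arbitrary stored orientation.
    """
    keep = set(leafset)
    labels = set(net.leaf_order)
    if not keep:
        raise ValueError("leafset must be nonempty")
    if not keep <= labels:
        raise ValueError(f"unknown leaves: {sorted(keep - labels, key=str)}")

    edges = {e.id: e for e in net.edges}
    kept_vertices = {v for lbl, v in net.leaves if lbl in keep}

    def degree(v):
        return sum(1 for e in edges.values() if v in (e.tail, e.head))

    # drop pruned leaves
    for lbl, v in net.leaves:
        if lbl not in keep:
            for e in list(edges.values()):
                if v in (e.tail, e.head):
                    del edges[e.id]

    changed = True
    counter = itertools.count()
    while changed:
        changed = False
        verts = set()
        for e in edges.values():
            verts.add(e.tail)
            verts.add(e.head)
        # demote spurious reticulations (only one in-edge left)
        in_retic: dict = {}
        for e in edges.values():
            if e.reticulation:
                in_retic.setdefault(e.head, []).append(e)
        for v, es in in_retic.items():
            if len(es) == 1:
                e = es[0]
                edges[e.id] = Edge(e.id, e.tail, e.head, False)
                changed = True
        if changed:
            continue
        for v in sorted(verts, key=str):
            if v in kept_vertices:
                continue
            inc = [e for e in edges.values() if v in (e.tail, e.head)]
            if len(inc) == 1:
                del edges[inc[0].id]
                changed = True
                break
            if len(inc) == 2:
                if all(e.reticulation and e.head == v for e in inc):
                    # reticulation vertex with nothing below: drop the cycle
                    for e in inc:
                        del edges[e.id]
                    changed = True
                    break
                # suppress the degree-2 vertex
                e1, e2 = sorted(inc, key=lambda e: _edge_key(e.id))
                a, b = e1.other(v), e2.other(v)
                retic = e1.reticulation or e2.reticulation
                if retic:
                    head = e1.head if e1.reticulation else e2.head
                    tail = b if head == a else a
                    new = Edge(f"({e1.id}|{e2.id})", tail, head, True)
                else:
                    new = Edge(f"({e1.id}|{e2.id})", a, b, False)
                del edges[e1.id], edges[e2.id]
                edges[new.id] = new
                changed = True
                break

    new_leaves = tuple((lbl, v) for lbl, v in net.leaves if lbl in keep)
    out = SemiDirectedNetwork(tuple(edges.values()), new_leaves, net.contracted)
    return out.validate()


# ---------------------------------------------------------------------------
# random generation


def random_level1(
    n: int,
    c: int,
    min_cycle_len: int = 3,
    seed: int = 0,
    max_cycle_len: int | None = None,
) -> SemiDirectedNetwork:
    """Random binary level-1 network with n leaves and c (disjoint) cycles,
    each of length >= min_cycle_len.  Deterministic per seed; the edge
    count is always 2n - 3 + 3c."""
    if n < 3:
        raise ValueError("need n >= 3")
    if min_cycle_len < 3:
        raise ValueError("cycles have length >= 3")
    if max_cycle_len is None:
        max_cycle_len = min_cycle_len + 2
    rng = random.Random(seed)
    for _ in range(200):
        net = _try_random_level1(n, c, min_cycle_len, max_cycle_len, rng)
        if net is not None:
            return net.validate()
    raise ValueError(
        f"could not build a level-1 network with n={n}, c={c}, "
        f"min_cycle_len={min_cycle_len}"
    )


def _try_random_level1(n, c, lo, hi, rng):
    next_id = itertools.count(1)
    next_v = itertools.count(1)
    # random unrooted binary tree by sequential leaf attachment
    v0 = f"i{next(next_v)}"
    edges = {e.id: e for e in (Edge(next(next_id), v0, i) for i in (1, 2, 3))}
    for leaf in range(4, n + 1):
        target = rng.choice(sorted(edges, key=_edge_key))
        e = edges.pop(target)
        mid = f"i{next(next_v)}"
        for a, b in ((e.tail, mid), (mid, e.head), (mid, leaf)):
            eid = next(next_id)
            edges[eid] = Edge(eid, a, b)

    leaf_set = set(range(1, n + 1))
    used = set()
    for _ in range(c):
        internal = sorted(
            {v for e in edges.values() for v in (e.tail, e.head)}
            - leaf_set
            - used,
            key=str,
        )
        if not internal:
            return None
        length = rng.randint(lo, hi)
        target_size = length - 2
        # grow a random connected set of unused internal vertices
        start = rng.choice(internal)
        chosen = {start}
        while len(chosen) < target_size:
            frontier = sorted(
                {
                    e.other(v)
                    for v in chosen
                    for e in edges.values()
                    if v in (e.tail, e.head)
                }
                - chosen
                - leaf_set
                - used,
                key=str,
            )
            if not frontier:
                break
            chosen.add(rng.choice(frontier))
        if len(chosen) < target_size:
            length = len(chosen) + 2
            if length < lo:
                return None
        # boundary edges leave the chosen set; internal edges are removed
        boundary = []
        for e in sorted(edges.values(), key=lambda e: _edge_key(e.id)):
            t_in, h_in = e.tail in chosen, e.head in chosen
            if t_in and h_in:
                del edges[e.id]
            elif t_in or h_in:
                boundary.append(e)
        assert len(boundary) == length
        rng.shuffle(boundary)
        cyc = [f"x{next(next_v)}" for _ in range(length)]
        for e, x in zip(boundary, cyc):
            del edges[e.id]
            if e.tail in chosen:
                edges[e.id] = Edge(e.id, x, e.head, e.reticulation)
            else:
                edges[e.id] = Edge(e.id, e.tail, x, e.reticulation)
        r_idx = rng.randrange(length)
        for i in range(length):
            a, b = cyc[i], cyc[(i + 1) % length]
            eid = next(next_id)
            if (i + 1) % length == r_idx:
                edges[eid] = Edge(eid, a, b, reticulation=True)
            elif i == r_idx:
                edges[eid] = Edge(eid, b, a, reticulation=True)
            else:
                edges[eid] = Edge(eid, a, b)
        used |= set(cyc)

    leaves = tuple((i, i) for i in range(1, n + 1))
    try:
        return SemiDirectedNetwork(tuple(edges.values()), leaves).validate()
    except NetworkValidationError:
        return None


# ---------------------------------------------------------------------------
# comparison helpers


def is_isomorphic(a: SemiDirectedNetwork, b: SemiDirectedNetwork) -> bool:
    """Equality as semi-directed networks: a leaf-label-preserving graph
    isomorphism that maps reticulation vertices to reticulation vertices.
    Auxiliary tree-edge orientations are ignored."""

    def decorated(net):
        g = net.underlying_graph()
        labels = {v: lbl for lbl, v in net.leaves}
        retic = set(net.reticulation_vertices)
        for v in g.nodes:
            g.nodes[v]["leaf"] = labels.get(v)
            g.nodes[v]["retic"] = v in retic
        return g

    nm = nx.algorithms.isomorphism.categorical_node_match(
        ["leaf", "retic"], [None, False]
    )
    em = nx.algorithms.isomorphism.categorical_edge_match("reticulation", False)
    return nx.is_isomorphic(decorated(a), decorated(b), node_match=nm, edge_match=em)


def tree_splits(net: SemiDirectedNetwork) -> frozenset:
    """Nontrivial leaf splits of a tree (network with no reticulations)."""
    if net.reticulation_vertices:
        raise ValueError("splits are defined for trees only")
    all_leaves = frozenset(net.leaf_order)
    leaf_of_vertex = {v: lbl for lbl, v in net.leaves}
    adj: dict = {}
    for e in net.edges:
        adj.setdefault(e.tail, []).append(e)
        adj.setdefault(e.head, []).append(e)
    splits = set()
    for e in net.edges:
        seen = {e.tail, e.head}
        stack = [e.head]
        side = set()
        while stack:
            v = stack.pop()
            if v in leaf_of_vertex:
                side.add(leaf_of_vertex[v])
            for f in adj[v]:
                if f is e:
                    continue
                w = f.other(v)
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        side = frozenset(side)
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(frozenset({side, all_leaves - side}))
    return frozenset(splits)
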