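"""Reading and writing semi-directed level-1 networks.

Two formats: extended Newick with ``#H`` hybrid tags (the rooted text form;
the root is suppressed on reading, justified by reorientation invariance of
the model) and a JSON edge-list dialect::

    {"leaves": [...], "tree_edges": [[u, v], ...],
     "reticulations": [{"head": v, "tails": [a, b]}]}
"""

from __future__ import annotations

import itertools
import json
import re
from pathlib import Path

from .networks import Edge, NetworkValidationError, SemiDirectedNetwork

__all__ = ["parse_network", "write_network", "parse_enewick", "write_enewick",
           "parse_json_network", "write_json_network", "ParseError"]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# JSON dialect


def parse_json_network(text: str) -> SemiDirectedNetwork:
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}") from exc
    for key in ("leaves", "tree_edges", "reticulations"):
        if key not in data:
            raise ParseError(f"JSON network needs a {key!r} field")

    def norm(v):
        return tuple(v) if isinstance(v, list) else v

    counter = itertools.count(1)
    edges = []
    for u, v in data["tree_edges"]:
        edges.append(Edge(next(counter), norm(u), norm(v)))
    for ret in data["reticulations"]:
        head = norm(ret["head"])
        tails = ret["tails"]
        if len(tails) != 2:
            raise ParseError("each reticulation needs exactly 2 tails")
        for t in tails:
            edges.append(Edge(next(counter), norm(t), head, reticulation=True))
    leaves = tuple((norm(x), norm(x)) for x in data["leaves"])
    return SemiDirectedNetwork(tuple(edges), leaves).validate()


def write_json_network(net: SemiDirectedNetwork) -> str:
    retic = {}
    tree_edges = []
    for e in net.sorted_edges():
        if e.reticulation:
            retic.setdefault(e.head, []).append(e.tail)
        else:
            tree_edges.append([e.tail, e.head])
    data = {
        "leaves": list(net.leaf_order),
        "tree_edges": tree_edges,
        "reticulations": [
            {"head": head, "tails": tails} for head, tails in sorted(
                retic.items(), key=lambda kv: str(kv[0])
            )
        ],
    }
    return json.dumps(data, default=str)


# ---------------------------------------------------------------------------
# extended Newick


_TOKEN = re.compile(r"\(|\)|,|;|[^(),;\s]+")


def parse_enewick(text: str) -> SemiDirectedNetwork:
    """Parse an eNewick string with #H hybrid tags into a semi-directed
    network.  The root is suppressed when it has two children; degree-2
    vertices are suppressed."""
    tokens = _TOKEN.findall(text.strip())
    if not tokens:
        raise ParseError("empty input")
    pos = 0

    node_counter = itertools.count(1)
    parents: list[tuple] = []  # (parent, child) pairs
    hybrids: dict = {}

    def node_for(name: str | None):
        if name and "#H" in name:
            tag = name[name.index("#H"):]
            if tag not in hybrids:
                hybrids[tag] = f"hybrid_{tag[2:]}"
            return hybrids[tag], True
        if name:
            return name, False
        return f"_v{next(node_counter)}", False

    def parse_node():
        nonlocal pos
        children = []
        if pos < len(tokens) and tokens[pos] == "(":
            pos += 1
            while True:
                children.append(parse_node())
                if pos >= len(tokens):
                    raise ParseError("unbalanced parentheses")
                if tokens[pos] == ",":
                    pos += 1
                    continue
                if tokens[pos] == ")":
                    pos += 1
                    break
                raise ParseError(f"unexpected token {tokens[pos]!r} at {pos}")
        name = None
        if pos < len(tokens) and tokens[pos] not in "(),;":
            name = tokens[pos]
            pos += 1
        v, is_hybrid = node_for(name)
        for child in children:
            parents.append((v, child))
        return v

    root = parse_node()
    if pos < len(tokens) and tokens[pos] == ";":
        pos += 1
    if pos != len(tokens):
        raise ParseError(f"trailing tokens from position {pos}")

    hybrid_nodes = set(hybrids.values())
    indeg: dict = {}
    outdeg: dict = {}
    for p, c in parents:
        indeg[c] = indeg.get(c, 0) + 1
        outdeg[p] = outdeg.get(p, 0) + 1
    for h in hybrid_nodes:
        if indeg.get(h, 0) != 2:
            raise ParseError(f"hybrid node {h} has {indeg.get(h, 0)} parents")

    counter = itertools.count(1)
    edges = {}
    for p, c in parents:
        eid = next(counter)
        edges[eid] = Edge(eid, p, c, reticulation=c in hybrid_nodes)

    # suppress a binary root: replace its two out-edges by one tree edge
    root_edges = [e for e in edges.values() if root in (e.tail, e.head)]
    if len(root_edges) == 2 and all(e.tail == root for e in root_edges):
        e1, e2 = root_edges
        del edges[e1.id], edges[e2.id]
        eid = next(counter)
        if e1.reticulation or e2.reticulation:
            ret = e1 if e1.reticulation else e2
            other = e2 if e1.reticulation else e1
            edges[eid] = Edge(eid, other.head, ret.head, reticulation=True)
        else:
            edges[eid] = Edge(eid, e1.head, e2.head)

    # suppress remaining degree-2 vertices (never hybrids)
    changed = True
    while changed:
        changed = False
        verts = {v for e in edges.values() for v in (e.tail, e.head)}
        for v in sorted(verts, key=str):
            if v in hybrid_nodes:
                continue
            inc = [e for e in edges.values() if v in (e.tail, e.head)]
            if len(inc) != 2:
                continue
            e1, e2 = inc
            a, b = e1.other(v), e2.other(v)
            retic = e1.reticulation or e2.reticulation
            del edges[e1.id], edges[e2.id]
            eid = next(counter)
            if retic:
                head = e1.head if e1.reticulation else e2.head
                if head == v:  # reticulation edge pointed at the suppressed vertex
                    raise ParseError("degree-2 hybrid structure is malformed")
                tail = b if head == a else a
                edges[eid] = Edge(eid, tail, head, reticulation=True)
            else:
                edges[eid] = Edge(eid, a, b)
            changed = True
            break

    verts = {v for e in edges.values() for v in (e.tail, e.head)}
    degree = {v: 0 for v in verts}
    for e in edges.values():
        degree[e.tail] += 1
        degree[e.head] += 1
    leaf_vertices = sorted((v for v, d in degree.items() if d == 1), key=str)

    def label_of(v):
        try:
            return int(v)
        except (TypeError, ValueError):
            return v

    leaves = tuple((label_of(v), v) for v in leaf_vertices)
    net = SemiDirectedNetwork(tuple(edges.values()), leaves)
    try:
        return net.validate()
    except NetworkValidationError as exc:
        raise ParseError(f"parsed graph is not a valid level-1 network: {exc}")


def write_enewick(net: SemiDirectedNetwork) -> str:
    """Render as eNewick by rooting on some tree edge that admits a
    consistent orientation (one always exists for networks built from a
    rooted one)."""
    if net.contracted:
        raise ValueError("eNewick output supports uncontracted networks only")
    for e in net.sorted_edges():
        if e.reticulation:
            continue
        result = _try_root(net, e)
        if result is not None:
            return result
    raise ValueError("network admits no consistent rooting")


def _try_root(net: SemiDirectedNetwork, root_edge: Edge) -> str | None:
    retic_vertices = set(net.reticulation_vertices)
    children: dict = {"_root": [root_edge.tail, root_edge.head]}
    oriented = {root_edge.id}
    visited = {"_root", root_edge.tail, root_edge.head}
    queue = [root_edge.tail, root_edge.head]
    while queue:
        x = queue.pop(0)
        for e in sorted(net.incident(x), key=lambda e: str(e.id)):
            if e.id in oriented:
                continue
            if e.reticulation:
                if e.tail == x:
                    oriented.add(e.id)
                    children.setdefault(x, []).append(e.head)
                    if e.head not in visited:
                        visited.add(e.head)
                        queue.append(e.head)
                continue
            y = e.other(x)
            if y in retic_vertices:
                continue  # the tree edge at a reticulation leaves it downward
            if y in visited:
                return None  # would create a second parent at a tree vertex
            oriented.add(e.id)
            children.setdefault(x, []).append(y)
            visited.add(y)
            queue.append(y)
    if len(oriented) != len(net.edges) or len(visited) != len(net.vertices) + 1:
        return None

    labels = {v: str(lbl) for lbl, v in net.leaves}
    hybrid_tag = {
        v: f"#H{i + 1}" for i, v in enumerate(net.reticulation_vertices)
    }
    emitted = set()

    def emit(v) -> str:
        if v in hybrid_tag:
            if v in emitted:
                return hybrid_tag[v]
            emitted.add(v)
            kids = children.get(v, [])
            inner = ",".join(emit(c) for c in kids)
            return f"({inner}){hybrid_tag[v]}" if kids else hybrid_tag[v]
        if v in labels and not children.get(v):
            return labels[v]
        inner = ",".join(emit(c) for c in children.get(v, []))
        return f"({inner})"

    a, b = children["_root"]
    return f"({emit(a)},{emit(b)});"


# ---------------------------------------------------------------------------
# front door


def parse_network(source: str | Path, fmt: str = "auto") -> SemiDirectedNetwork:
    """Parse a network from text or a path, in eNewick or the JSON dialect."""
    text = str(source)
    path = Path(text)
    if ("\n" not in text and len(text) < 4096) and path.is_file():
        text = path.read_text()
    text = text.strip()
    if fmt == "auto":
        fmt = "json" if text.startswith("{") else "enewick"
    if fmt == "json":
        return parse_json_network(text)
    if fmt == "enewick":
        return parse_enewick(text)
    raise ValueError(f"unknown format {fmt!r}")


def write_network(net: SemiDirectedNetwork, fmt: str = "enewick") -> str:
    if fmt == "json":
        return write_json_network(net)
    if fmt == "enewick":
        return write_enewick(net)
    raise ValueError(f"unknown format {fmt!r}")
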