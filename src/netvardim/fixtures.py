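"""Worked-example fixtures: the figure networks used by the golden tests.

``make_fig3_network`` is the 6-leaf network with one 4-cycle whose cut edge
(id 4) separates a 4-sunlet on leaves {1,2,3} + cut from a quartet tree on
cut + {4,5,6}; the cut edge is directed toward the sunlet side.
"""

from __future__ import annotations

from .networks import Edge, SemiDirectedNetwork

__all__ = ["make_fig3_network", "FIG3_CUT_EDGE", "fig3_json"]

FIG3_CUT_EDGE = 4


def make_fig3_network() -> SemiDirectedNetwork:
    edges = (
        Edge(1, "c1", 1),
        Edge(2, "c2", 2),
        Edge(3, "c3", 3),
        Edge(4, "t1", "c4"),  # the cut edge e, directed toward the sunlet
        Edge(5, "c2", "c1", reticulation=True),
        Edge(6, "c3", "c2"),
        Edge(7, "c3", "c4"),
        Edge(8, "c4", "c1", reticulation=True),
        Edge(9, "t1", 4),
        Edge(10, "t1", "t2"),
        Edge(11, "t2", 5),
        Edge(12, "t2", 6),
    )
    leaves = tuple((i, i) for i in range(1, 7))
    return SemiDirectedNetwork(edges, leaves).validate()


def fig3_json() -> str:
    """The Fig. 3 network in the JSON dialect."""
    from .fileio import write_json_network

    return write_json_network(make_fig3_network())
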