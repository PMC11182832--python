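import pytest

import netvardim as nv


@pytest.fixture(scope="session")
def cfn():
    return nv.named_model("CFN")


@pytest.fixture(scope="session")
def jc():
    return nv.named_model("JC")


@pytest.fixture(scope="session")
def k2p():
    return nv.named_model("K2P")


@pytest.fixture(scope="session")
def k3p():
    return nv.named_model("K3P")


@pytest.fixture(scope="session")
def z3():
    return nv.generic_model(nv.make_group([3]))


@pytest.fixture(scope="session")
def z4():
    return nv.generic_model(nv.make_group([4]))


@pytest.fixture(scope="session")
def fig3():
    from netvardim.fixtures import make_fig3_network

    return make_fig3_network()


def sunlet_with_order(order):
    """n-sunlet whose cyclic leaf order is ``order``; the first entry hangs
    off the reticulation vertex."""
    n = len(order)
    c = [f"c{i}" for i in range(n + 1)]
    edges = [nv.Edge(i + 1, c[i + 1], order[i]) for i in range(n)]
    edges.append(nv.Edge(n + 1, c[2], c[1], reticulation=True))
    for i in range(2, n - 1):
        edges.append(nv.Edge(n + i, c[i + 1], c[i]))
    edges.append(nv.Edge(2 * n - 1, c[n - 1], c[n]))
    edges.append(nv.Edge(2 * n, c[n], c[1], reticulation=True))
    leaves = tuple((o, o) for o in sorted(order))
    return nv.SemiDirectedNetwork(tuple(edges), leaves).validate()
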