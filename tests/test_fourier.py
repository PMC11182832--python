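import itertools
from fractions import Fraction

import pytest
import sympy

import netvardim as nv
from netvardim._linalg import rank_exact_rationals
from netvardim.fourier import render_coordinate, render_symbolic_coordinates

EXAMPLE1_GOLDEN = (
    "q_{g1g2g3g4} = "
    "a1^{g1} a2^{g2} a3^{g3} a4^{g4} a5^{g1} a6^{g1+g2} a7^{g4}"
    " + "
    "a1^{g1} a2^{g2} a3^{g3} a4^{g4} a6^{g2} a7^{g1+g4} a8^{g1}"
)


class TestBuild:
    def test_example1_rendering(self):
        assert render_symbolic_coordinates(nv.make_sunlet(4)) == EXAMPLE1_GOLDEN

    def test_coordinate_and_monomial_counts(self, z3, cfn):
        for net, model in [
            (nv.make_sunlet(4), cfn),
            (nv.make_sunlet(3), z3),
            (nv.random_level1(5, 2, 3, seed=1), cfn),
        ]:
            param = nv.build_parameterization(net, model)
            n, k = net.n_leaves, len(net.reticulation_vertices)
            assert param.n_coordinates == model.group.order ** (n - 1)
            assert param.n_parameters == len(net.edges) * (model.l + 1)
            for lab in param.labellings[:6]:
                monos = param.coordinate(lab)
                assert len(monos) == 2**k
                for mono, tree in zip(monos, param.trees):
                    assert sum(mono.values()) == len(tree.edges)

    def test_tree_single_monomial(self, z3):
        t = nv.random_level1(5, 0, seed=2)
        param = nv.build_parameterization(t, z3)
        for lab in param.labellings[:10]:
            assert len(param.coordinate(lab)) == 1

    def test_contracted_sunlet_closed_form(self, z3):
        # the two monomials of the contracted 4-sunlet coordinate
        param = nv.build_parameterization(nv.make_contracted_sunlet(4), z3)
        g = z3.group
        for lab in param.labellings:
            g1, g2, g3, g4 = lab
            common = [(2, g2), (3, g3), (4, g4)]
            t1 = sorted(common + [(1, g1), (6, g.add(g1, g2)), (7, g4)])
            t2 = sorted(common + [(5, g1), (6, g2), (7, g.add(g1, g4))])
            got = [sorted(m.keys()) for m in param.coordinate(lab)]
            assert got == [t1, t2]


class TestEvaluate:
    @pytest.mark.parametrize("c", [0, 1, 2])
    def test_all_ones_gives_2_to_k(self, c, cfn):
        net = nv.random_level1(6, c, 4, seed=3)
        param = nv.build_parameterization(net, cfn)
        point = {k: 1 for k in param.param_order}
        assert set(param.evaluate(point)) == {2**c}

    def test_lemma4_reparameterization(self, z3):
        # contracting a sunlet is absorbed by multiplying the reticulation
        # edge parameters by the contracted leaf-edge parameters
        n = 4
        unc = nv.build_parameterization(nv.make_sunlet(n), z3)
        con = nv.build_parameterization(nv.make_contracted_sunlet(n), z3)
        import random

        rng = random.Random(5)
        w = {k: rng.randint(2, 97) for k in unc.param_order}
        u = {}
        for eid, rep in con.param_order:
            if eid == 1:  # contracted reticulation edge e_{n+1} of the sunlet
                u[(eid, rep)] = w[(1, rep)] * w[(n + 1, rep)]
            elif eid == n + 1:  # the other reticulation edge e_{2n}
                u[(eid, rep)] = w[(1, rep)] * w[(2 * n, rep)]
            else:
                u[(eid, rep)] = w[(eid, rep)]
        assert con.evaluate_coordinate_map(u) == {
            lab: v for lab, v in unc.evaluate_coordinate_map(w).items()
        }

    def test_zeroing_one_tree(self, cfn):
        s = nv.make_sunlet(4)
        param = nv.build_parameterization(s, cfn)
        point = {k: 3 for k in param.param_order}
        for rep in cfn.representatives:
            point[(8, rep)] = 0  # kill the sigma=1 tree (contains e8)
        values = param.evaluate(point)
        only_first = [
            param._monomial_value(lab, 0, point, None) for lab in param.labellings
        ]
        assert values == only_first

    def test_missing_parameter(self, cfn):
        param = nv.build_parameterization(nv.make_sunlet(3), cfn)
        with pytest.raises(KeyError):
            param.evaluate({})


def _sympy_jacobian_rank(param, point):
    """Independent oracle: build the coordinate polynomials in sympy,
    differentiate symbolically, substitute and take the exact rank."""
    syms = {k: sympy.Symbol(f"a_{i}") for i, k in enumerate(param.param_order)}
    coords = []
    for lab in param.labellings:
        expr = 0
        for mono in param.coordinate(lab):
            term = 1
            for key, exp in mono.items():
                term *= syms[key] ** exp
            expr += term
        coords.append(expr)
    jac = sympy.Matrix(
        [
            [sympy.diff(c, syms[k]) for k in param.param_order]
            for c in coords
        ]
    )
    subs = {syms[k]: point[k] for k in param.param_order}
    return jac.subs(subs).rank()


class TestJacobian:
    def test_matches_sympy_oracle_3claw(self, cfn):
        t = nv.random_level1(3, 0, seed=0)  # the 3-claw tree
        param = nv.build_parameterization(t, cfn)
        import random

        rng = random.Random(1)
        point = {k: rng.randint(2, 97) for k in param.param_order}
        mine = rank_exact_rationals(param.jacobian(point))
        assert mine == _sympy_jacobian_rank(param, point) == 4  # 3l + 1

    def test_matches_sympy_oracle_3sunlet_z3(self, z3):
        param = nv.build_parameterization(nv.make_sunlet(3), z3)
        import random

        rng = random.Random(2)
        point = {k: rng.randint(2, 97) for k in param.param_order}
        assert rank_exact_rationals(param.jacobian(point)) == _sympy_jacobian_rank(
            param, point
        )

    def test_4_sunlet_cfn_rank7(self, cfn):
        param = nv.build_parameterization(nv.make_sunlet(4), cfn)
        assert nv.jacobian_dimension(param, seed=1).computed_dim == 7

    def test_shape(self, z3):
        param = nv.build_parameterization(nv.make_sunlet(3), z3)
        import random

        rng = random.Random(3)
        point = {k: rng.randint(2, 97) for k in param.param_order}
        rows = param.jacobian(point)
        assert len(rows) == 9 and len(rows[0]) == 18

    def test_mod_p_agrees_with_rationals(self, cfn):
        from netvardim._linalg import DEFAULT_PRIME, rank_mod_p

        param = nv.build_parameterization(nv.make_sunlet(4), cfn)
        import random

        rng = random.Random(4)
        point = {k: rng.randint(2, 997) for k in param.param_order}
        r_qq = rank_exact_rationals(param.jacobian(point))
        r_fp = rank_mod_p(param.jacobian(point, DEFAULT_PRIME), DEFAULT_PRIME)
        assert r_qq == r_fp


class TestOrbitProject:
    def test_trivial_action_identity(self, k3p):
        vec = {(1, g): i + 1 for i, g in enumerate(k3p.group.elements)}
        assert nv.orbit_project(vec, k3p) == vec

    def test_jc_single_edge(self, jc):
        vec = {(1, (0, 0)): 5, (1, (0, 1)): 1, (1, (1, 0)): 2, (1, (1, 1)): 3}
        assert nv.orbit_project(vec, jc) == {(1, (0, 0)): 5, (1, (0, 1)): 6}

    def test_projects_exponent_vectors(self, jc, k3p):
        # p(alpha_i) = alpha_i': the general Klein-4 model's monomial
        # exponents project onto the JC model's
        net = nv.make_contracted_sunlet(4)
        general = nv.build_parameterization(net, k3p)
        jc_param = nv.build_parameterization(net, jc)
        for lab in general.labellings[:20]:
            for t in range(2):
                assert (
                    nv.orbit_project(general.monomial(lab, t), jc)
                    == jc_param.monomial(lab, t)
                )

    def test_kernel_dimension(self, jc):
        # surjective with kernel (|G| - l - 1) m on a single edge
        group = jc.group
        images = set()
        for g in group.elements:
            proj = nv.orbit_project({(1, g): 1}, jc)
            images.add(tuple(sorted(proj.items())))
        assert len(images) == jc.l + 1


class TestInvariances:
    @pytest.mark.parametrize("n", [3, 4, 5])
    @pytest.mark.parametrize("model_name", ["CFN", "Z3"])
    def test_contraction_invariance(self, n, model_name, cfn, z3):
        model = cfn if model_name == "CFN" else z3
        a = nv.jacobian_dimension(
            nv.build_parameterization(nv.make_sunlet(n), model), seed=9
        ).computed_dim
        b = nv.jacobian_dimension(
            nv.build_parameterization(nv.contract(nv.make_sunlet(n)), model), seed=9
        ).computed_dim
        assert a == b

    def test_reorientation_invariance(self, z3):
        net = nv.make_sunlet(4)
        flipped = net.with_flipped_edge(6)
        p1 = nv.build_parameterization(net, z3)
        p2 = nv.build_parameterization(flipped, z3)
        # parameters pair up as g <-> -g on the flipped edge
        g = z3.group
        for lab in p1.labellings:
            for t in range(2):
                m1 = p1.monomial(lab, t)
                m2 = p2.monomial(lab, t)
                remapped = {
                    (eid, g.neg(rep) if eid == 6 else rep): v
                    for (eid, rep), v in m1.items()
                }
                assert remapped == m2
        assert (
            nv.jacobian_dimension(p1, seed=8).computed_dim
            == nv.jacobian_dimension(p2, seed=8).computed_dim
        )

    def test_all_ones_constant(self, cfn, z3):
        for model in (cfn, z3):
            param = nv.build_parameterization(nv.make_sunlet(4), model)
            point = {k: 1 for k in param.param_order}
            assert set(param.evaluate(point)) == {2}


class TestRenderConcrete:
    def test_cfn_coordinate(self, cfn):
        param = nv.build_parameterization(nv.make_contracted_sunlet(3), cfn)
        text = render_coordinate(param, ((1,), (1,), (0,)))
        assert text.startswith("q_{110} = ")
        assert " + " in text
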