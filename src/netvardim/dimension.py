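"""Dimension of the network variety: exact generic Jacobian rank, tropical
lower-bound certificates, closed-form dimensions and deficiencies, and the
toric-fiber-product gluing formula.

Conventions: affine (cone) dimension throughout.  The expected dimension is
``l(m - c) + 1`` computed from the *uncontracted* edge count; deficiency is
expected minus computed.  Random points are drawn uniformly from integers
in [2, 997] for rational arithmetic, or from F_p (p = 2^31 - 1) for large
instances; the maximum rank over the trials is reported.  A rank over F_p
is a lower bound for the rank over Q; the report records the field used.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict
from typing import Hashable

from ._linalg import DEFAULT_PRIME, rank_exact_rationals, rank_mod_p
from .groups import ModelSpec
from .fourier import Parameterization, build_parameterization
from .networks import (
    NetworkStats,
    SemiDirectedNetwork,
    contract,
    make_contracted_sunlet,
)

__all__ = [
    "TropicalCertificate",
    "DimensionReport",
    "expected_dimension",
    "cfn_dimension",
    "parameter_upper_bound",
    "random_point",
    "jacobian_dimension",
    "tropical_lower_bound",
    "tropical_certificate_search",
    "sunlet_witness_lambda",
    "submatrix_B_rank",
    "deficiency",
    "tfp_combine",
    "TieError",
    "WitnessUnsupportedError",
]

# switch to F_p above this Jacobian size (rows x cols)
_QQ_SIZE_LIMIT = 6000


class TieError(ValueError):
    """A weight vector failed to select a unique monomial somewhere."""


class WitnessUnsupportedError(ValueError):
    """The published witness construction does not apply (e.g. 3-sunlets)."""


@dataclass(frozen=True)
class TropicalCertificate:
    lam: dict
    columns: list  # one argmin exponent vector per coordinate (dict or None)
    rank: int
    ties: list  # labellings where the minimum was attained >= 2 times

    @property
    def certified(self) -> bool:
        return not self.ties


@dataclass(frozen=True)
class DimensionReport:
    computed_dim: int
    expected_dim: int
    upper_bound: int
    deficiency: int
    trials: int
    seed: int
    field: str
    tropical_lower: int | None = None
    trial_ranks: tuple = ()
    n_coordinates: int = 0
    n_parameters: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# closed forms


def expected_dimension(stats: NetworkStats, model: ModelSpec) -> int:
    """l(m - c) + 1 with m the uncontracted (binary) edge count."""
    return model.l * (stats.m - stats.c) + 1


def cfn_dimension(stats: NetworkStats) -> int:
    """Exact CFN dimension for any level-1 network:
    m - (c_{>=5} + 2 c_4 + 3 c_3) + 1."""
    return stats.m - (stats.c_ge5 + 2 * stats.c4 + 3 * stats.c3) + 1


def parameter_upper_bound(contracted_stats: NetworkStats, model: ModelSpec) -> int:
    """l m' + 1 for the contracted edge count m' (dimension upper bound)."""
    return model.l * contracted_stats.m + 1


def tfp_combine(dim_plus: int, dim_minus: int, model: ModelSpec) -> int:
    """Affine dimension of the glued network from the dimensions of the two
    pieces obtained by cutting at a cut edge: dim+ + dim- - (l + 1)."""
    return dim_plus + dim_minus - (model.l + 1)


# ---------------------------------------------------------------------------
# generic Jacobian rank


def random_point(
    param: Parameterization, rng: random.Random, p: int | None = None
) -> dict:
    if p is None:
        return {k: rng.randint(2, 997) for k in param.param_order}
    return {k: rng.randint(1, p - 1) for k in param.param_order}


def _pick_field(param: Parameterization, field_choice: str) -> str:
    if field_choice == "auto":
        size = param.n_coordinates * param.n_parameters
        return "QQ" if size <= _QQ_SIZE_LIMIT else "Fp"
    if field_choice in ("QQ", "Fp"):
        return field_choice
    raise ValueError(f"unknown field {field_choice!r}; use QQ, Fp or auto")


def jacobian_dimension(
    param: Parameterization,
    trials: int = 3,
    seed: int = 0,
    field: str = "auto",
) -> DimensionReport:
    """Dimension as the maximum exact Jacobian rank over random points."""
    if trials < 1:
        raise ValueError("need at least one trial")
    used = _pick_field(param, field)
    rng = random.Random(seed)
    ranks = []
    for _ in range(trials):
        if used == "QQ":
            point = random_point(param, rng)
            ranks.append(rank_exact_rationals(param.jacobian(point)))
        else:
            point = random_point(param, rng, DEFAULT_PRIME)
            ranks.append(
                rank_mod_p(param.jacobian(point, DEFAULT_PRIME), DEFAULT_PRIME)
            )
    computed = max(ranks)
    stats = param.network.stats()
    m_unc = stats.m + (stats.c if param.network.contracted else 0)
    expected = param.model.l * (m_unc - stats.c) + 1
    contracted_m = stats.m if param.network.contracted else stats.m - stats.c
    upper = param.model.l * contracted_m + 1
    return DimensionReport(
        computed_dim=computed,
        expected_dim=expected,
        upper_bound=upper,
        deficiency=expected - computed,
        trials=trials,
        seed=seed,
        field="F_%d" % DEFAULT_PRIME if used == "Fp" else "QQ",
        trial_ranks=tuple(ranks),
        n_coordinates=param.n_coordinates,
        n_parameters=param.n_parameters,
    )


def deficiency(
    net: SemiDirectedNetwork,
    model: ModelSpec,
    trials: int = 3,
    seed: int = 0,
    field: str = "auto",
) -> DimensionReport:
    """Full dimension report for a network; the Jacobian is computed on the
    contracted network (same variety, fewer parameters)."""
    work = net if net.contracted else contract(net)
    param = build_parameterization(work, model)
    return jacobian_dimension(param, trials=trials, seed=seed, field=field)


# ---------------------------------------------------------------------------
# tropical lower bound


def _weight(lam: dict, exponents: dict):
    return sum(lam.get(k, 0) * v for k, v in exponents.items())


def tropical_lower_bound(
    param: Parameterization, lam: dict
) -> TropicalCertificate:
    """Build A_lambda: per coordinate the exponent vector of the monomial
    minimizing <lambda, alpha>; ties are reported (not fatal) and the tied
    coordinates are dropped from the rank computation."""
    columns = []
    ties = []
    for lab in param.labellings:
        monos = param.coordinate(lab)
        weights = [_weight(lam, m) for m in monos]
        best = min(weights)
        argmins = [m for m, w in zip(monos, weights) if w == best]
        if len(argmins) > 1:
            distinct = {tuple(sorted(m.items())) for m in argmins}
            if len(distinct) > 1:
                ties.append(lab)
                columns.append(None)
                continue
        columns.append(argmins[0])
    matrix = [
        [col.get(p, 0) for col in columns if col is not None]
        for p in param.param_order
    ]
    rank = rank_exact_rationals(matrix) if matrix and matrix[0] else 0
    return TropicalCertificate(lam=lam, columns=columns, rank=rank, ties=ties)


def tropical_certificate_search(
    param: Parameterization, seed: int = 0, max_tries: int = 20
) -> TropicalCertificate:
    """Resample integer weight vectors until one is tie-free; return the
    best certificate found (highest rank among tie-free ones)."""
    rng = random.Random(seed)
    best = None
    for _ in range(max_tries):
        lam = {k: rng.randint(-(10**6), 10**6) for k in param.param_order}
        cert = tropical_lower_bound(param, lam)
        if cert.certified and (best is None or cert.rank > best.rank):
            best = cert
    if best is None:
        raise TieError("no tie-free weight vector found")
    return best


def sunlet_witness_lambda(n: int, model: ModelSpec) -> dict:
    """The published witness weight vectors on the contracted n-sunlet's
    parameter axes.

    For |G| > 2: weight -2 on (e_{n+2}, [0]) and 1 on every (e_{n+1}, [g]).
    For Z/2 (CFN): weight 1 on both states of e_{n+1} and 2 on state 0 of
    e_{n+3}; needs n >= 5 (n = 4 is allowed but known deficient).
    Unsupported for n = 3, where the construction breaks down.
    """
    if n <= 3:
        raise WitnessUnsupportedError(
            "the witness construction does not apply to 3-sunlets"
        )
    group = model.group
    zero = group.identity
    lam: dict = {}
    if group.order > 2:
        lam[(n + 2, model.orbit_rep(zero))] = -2
        for rep in model.representatives:
            lam[(n + 1, rep)] = 1
    else:
        one = model.group.elements[1]
        lam[(n + 1, zero)] = 1
        lam[(n + 1, one)] = 1
        lam[(n + 3, zero)] = 2
    return lam


def submatrix_B_rank(param: Parameterization, lam: dict) -> int:
    """Exact rank of the reduced tropical block B for a contracted sunlet.

    Columns are restricted to consistent labellings with g1 != 0; the rows
    for edge 2 (resp. edge n) are replaced by their differences with the
    rows of edge n+2 (resp. 2n-1); rows are then restricted to the
    parameters of edges 1, 2, n and n+1.  Ties under lambda are errors.
    """
    net = param.network
    if not net.contracted:
        raise ValueError("block-B reduction is defined on the contracted sunlet")
    n = net.n_leaves
    if n < 4:
        raise WitnessUnsupportedError("block-B reduction needs n >= 4")
    zero = param.model.group.identity
    cols = []
    for lab in param.labellings:
        if lab[0] == zero:
            continue
        monos = param.coordinate(lab)
        weights = [_weight(lam, m) for m in monos]
        best = min(weights)
        argmins = [m for m, w in zip(monos, weights) if w == best]
        if len(argmins) > 1:
            raise TieError(f"witness lambda ties at labelling {lab}")
        cols.append(argmins[0])
    reps = param.model.representatives
    rows = []
    for edge, partner in ((1, None), (2, n + 2), (n, 2 * n - 1), (n + 1, None)):
        for rep in reps:
            row = []
            for col in cols:
                entry = col.get((edge, rep), 0)
                if partner is not None:
                    entry -= col.get((partner, rep), 0)
                row.append(entry)
            rows.append(row)
    return rank_exact_rationals(rows)


def sunlet_block_rank(n: int, model: ModelSpec) -> int:
    """Convenience wrapper: witness lambda + block-B rank on the contracted
    n-sunlet."""
    param = build_parameterization(make_contracted_sunlet(n), model)
    return submatrix_B_rank(param, sunlet_witness_lambda(n, model))
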