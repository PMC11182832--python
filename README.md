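# netvardim

Algebraic machinery for **group-based Markov models on level-1 semi-directed
phylogenetic networks**: build the Fourier-coordinate parameterization of any
model `(G, B)` on any level-1 network, compute the dimension of the
associated variety (exact generic Jacobian rank, tropical lower-bound
certificates, closed-form dimension/deficiency formulas, toric-fiber-product
gluing), and run dimension-based identifiability tests.

## What's inside

| module                  | contents |
|-------------------------|----------|
| `netvardim.groups`      | finite abelian groups, automorphism-subgroup actions, B-orbits; named models CFN / JC / K2P / K3P |
| `netvardim.networks`    | level-1 semi-directed networks: sunlets, contraction, displayed trees, consistent labellings, cutting, restriction, random generation |
| `netvardim.fourier`     | sparse Fourier parameterization, exact evaluation and Jacobians, orbit projection, plain-text rendering |
| `netvardim.dimension`   | expected/closed-form dimensions, generic Jacobian rank (exact over Q or a prime field), tropical certificates with the sunlet witness weights, deficiency reports, TFP gluing formula |
| `netvardim.tfp`         | cut-edge multigradings, Quad_B generators, lifts, codimension-zero dimension formula |
| `netvardim.identify`    | quartet invariants, vanishing tests, distinguishability search over leaf-subset restrictions |
| `netvardim.fileio`      | extended Newick (`#H` hybrid tags) and a JSON edge-list dialect |
| `netvardim.cli`         | the `netvardim` command |

All rank decisions use exact arithmetic: rationals by default, the prime
field F_p with p = 2^31 - 1 for large instances (recorded in every report).

## CLI

```sh
# dimension of a network variety (JSON report)
netvardim dim --network net.enewick --model K3P --method jacobian --seed 1

# deficiency: expected dimension l(m-c)+1 minus the computed dimension
netvardim deficiency --network net.enewick --model JC

# the sunlet deficiency table (CSV), n = 3..nmax, one column per model
netvardim table1 --nmax 6 --groups Z2,Z3,JC,K2P,K3P,Z4,Z5,Z6,Z7

# distinguishability of two networks over a model
netvardim distinguish --a a.enewick --b b.enewick --model JC --seed 1

# fixtures and rendering
netvardim random-network --n 6 --cycles 1 --min-cycle-len 4 --seed 1
netvardim render-param --network net.enewick --symbolic
```

Models are named (`CFN`, `JC`, `K2P`, `K3P`), cyclic-group tokens (`Z5`,
`Z2xZ2`), or JSON configs
`{"group": [2,2], "action_generators": [[0,2,1,3]]}` (permutations of the
lexicographically ordered element list).  Exit code 2 flags invalid input
networks.

Example:

```sh
$ netvardim table1 --nmax 4 --groups Z2,Z3,JC
n,Z2,Z3,JC
3,2,2,1
4,1,0,0
```

## Notes on conventions

- Networks are stored uncontracted (binary) as the normal form; contraction
  is an explicit, idempotent operation and leaves the variety unchanged.
- Sunlet edge numbering and orientations follow the worked-example figures
  (leaf edges `e1..en`, cycle edges `e_{n+1}..e_{2n}`, reticulation edges
  `e_{n+1}` and `e_{2n}`), so the rendered parameterizations reproduce the
  printed formulas verbatim.
- "Expected dimension" always means `l(m - c) + 1` on the uncontracted
  network; deficiency = expected - computed.  Affine (cone) dimensions
  throughout.
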