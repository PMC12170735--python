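# restlessreach

Restless reachability in temporal contact networks, computed exactly (up to
a quantified one-sided error) by algebraic fingerprinting over GF(2^b).

## The problem

A temporal graph is a directed graph whose edges carry integer timestamps
t ∈ [τ]: the edge (u, v, t) can be crossed only at time t.  A disease, a
rumor or a packet moving through such a contact network follows a
*time-respecting* path (non-decreasing timestamps), but with a twist
motivated by SIR-type epidemics: at every intermediate vertex v the process
may wait at most δ(v) time steps between arriving and departing — the
*resting time*, the window during which a carrier remains infectious.  A
time-respecting path obeying all waiting windows and repeating no vertex is
a **restless path**.

Deciding whether a restless path of k vertices connects s to d is NP-hard,
so practical exact computation needs parameterized machinery.  This package
implements a randomized algebraic engine that answers, in one run over a
graph with m edges and maximum resting time Δ, the *fine-grained* question:

> for every vertex u and every timestamp i, does a restless path of length
> ℓ−1 from the source end at u with last-edge timestamp i?

in time O(2^ℓ ℓ m Δ), with zero false positives and a false-negative
probability of at most (2ℓ−1)·2^(−b) per evaluation (b = 64 by default:
below 10^(−16), rarer than hardware failure).  Color-constrained variants
(path vertex colors must agree with a query multiset — "graph motifs") and
separator exclusion (immunized vertices that no path may cross) come from
the same machinery at no extra asymptotic cost.

## The method in one paragraph

All restless *walks* of length ℓ−1 ending at u at time i are encoded as the
monomials of a polynomial χ_{u,ℓ,i}(x, y) built by a dynamic program over
(time, vertex) cells: level 1 sets χ_{u,1,i} = x_u, and level ℓ extends
walks along in-edges within the admissible waiting window, each extension
multiplied by a fresh edge variable y_{uv,ℓ−1,i−j}.  A monomial is
*multilinear* (no repeated variable) exactly when its walk is a path.
Multilinearity is detected by the characteristic-2 sieve: substitute for
each x_u a lane sum z_u^L = Σ_{j∈L} z_{u,j} and XOR the evaluations over
all 2^ℓ label subsets L ⊆ [ℓ]; monomials with a repeated vertex cancel
identically, while path monomials survive with a random nonzero value with
high probability.  Color multiplicities are enforced by *shades*: color s
with multiplicity μ(s) receives μ(s) private shade ids and
z_{u,j} = Σ_{d ∈ S_{c(u)}} γ_{u,d}·ω_{d,j}, so any vertex whose color is
absent from the query multiset vanishes from every lane.  All arithmetic is
carried out in GF(2^64) (other widths: 4, 8, 16, 32 — the small ones exist
to make false negatives frequent enough to measure).

An optimal path (minimum last-edge timestamp) is *extracted* with k oracle
queries by walking the table backwards: delete the endpoint, drop its color
from the multiset, cap the horizon at the arrival time, re-query, and
commit any in-neighbor whose row is true inside the waiting window.

Everything is cross-validated against exhaustive search (temporal DFS and
full path enumeration) and against an independent formulation: restless
paths correspond to *rainbow paths* in a static δ-expansion whose nodes are
(vertex, time) pairs colored by the original vertex.

## Worked example

The five-vertex instance used throughout the docs: edges
(1,2,1), (2,3,2), (3,4,3), (4,2,4), (2,5,5), horizon τ = 5, resting time
δ ≡ 2.

```python
from restlessreach import *

g, delta = five_vertex_example()
opts = SieveOptions(ell=2, repeats=3, seed=11)

k_restless_reach(g, delta, 1, 4, opts).true_cells()
# {(4, 3)}                      -- the only 3-edge restless path from v1
#                                  is v1 v2 v3 v4, arriving at time 3

atm_k_restless_reach(g, delta, 1, 4, opts).min_time
# {2: 1, 3: 2, 4: 3}            -- v5 is absent: the walk v1 v2 v3 v4 v2 v5
#                                  respects all windows but revisits v2,
#                                  so no restless *path* reaches v5

restless_reach(g, delta, 3, opts).min_time
# {4: 3, 2: 4, 5: 5}            -- from v3 the path v3 v4 v2 v5 exists

extract_optimal_path(g, delta, 1, 4, opts, k=4)
# RestlessPathWitness(vertices=(1, 2, 3, 4), times=(1, 2, 3))
```

The same through the CLI (plain-text `.tel` edge lists, header `n m tau`):

```
$ restlessreach reach --graph five.tel --source 1 --k 4 --mode atmost \
      --delta 2 --seed 5 --out reach.tsv
$ cat reach.tsv
vertex  min_time  min_length
2       1         1
3       2         2
4       3         3
```

`restlessreach gen` produces d-regular and power-law configuration-model
instances with uniform random timestamps, `restlessreach immunize` computes
reachability time series with a fraction of vertices immunized (random or
max-temporal-degree selection), and `restlessreach selftest` runs the
built-in field and fixture checks.

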