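# Methods

## Model and conventions

A temporal graph G = (V, E) has vertices 1..n and directed edges (u, v, t)
with integer timestamps 1 ≤ t ≤ τ.  Resting times δ: V → ℕ bound the
waiting gap at *internal* vertices of a walk: consecutive edge timestamps
t_i ≤ t_{i+1} must satisfy t_{i+1} − t_i ≤ δ(v_{i+1}), where v_{i+1} is the
vertex between the two edges.  The start vertex may depart at any
timestamp — this is what the dynamic program's base case (the level-1
polynomial is x_u at *every* timestamp) implies, and it matches the
epidemic reading in which the index case is infectious from the outset.
Helpers that build per-vertex resting times for applications set
δ(source) = τ explicitly for the same reason.  Waiting windows are
inclusive, {0, …, δ(v)}; δ = 0 is legal (departure must share the arrival
timestamp) although the generators default to δ ≥ 1.  Self-loops are
rejected (no path can use one) and duplicate edge triples are dropped at
construction with a reported count — the polynomial encoding gains nothing
from them.

Vertices carry at most one color.  A coloring that maps vertices to *sets*
of colors would generalize the machinery (the shade sum would range over
the union of the vertex's color shades) but is not implemented.

## Generating polynomial and sieve

χ_{u,1,i} = x_u; for ℓ ≥ 2,

  χ_{u,ℓ,i} = x_u · Σ_{(v,u,i) ∈ E} Σ_{j ∈ {0..δ(v)}, i−j ≥ 1}
              y_{vu, ℓ−1, i−j} · χ_{v, ℓ−1, i−j}.

Monomials of χ_{u,ℓ,i} are in bijection with restless walks of length ℓ−1
ending at u at time i; a monomial is multilinear iff its walk is a path
(the y variables are unique per level, so only x repetitions matter).  The
sieve evaluates ζ_{u,ℓ,i} = XOR over all L ⊆ [ℓ] of χ evaluated at
x := z^L; in characteristic 2 every non-multilinear monomial cancels
identically and ζ is (as a polynomial in the remaining variables) nonzero
iff a properly colored multilinear monomial exists.  Shades enforce the
color multiset: for each color s with multiplicity μ(s), μ(s) globally
distinct shade ids; z_{u,j} = Σ_{d ∈ S_{c(u)}} γ_{u,d} ω_{d,j}.  Plain
(uncolored) sieving is the special case of one color and multiset {1^ℓ} —
one code path serves both.

Randomized evaluation has strictly one-sided error.  Reported cells are
always real (soundness is an algebraic identity); a true cell is missed
with probability at most (2ℓ−1)·2^(−b) per repeat, the classical
Schwartz–Zippel-style bound, which the validation suite measures directly
at b = 8 on planted single-witness instances.  Note the cancellation of
walk monomials is exact and does not depend on the random values: the
five-vertex fixture at walk length 5 (a walk exists, no path does) is
false at every seed, not merely with high probability.

## Randomness: a keyed PRF, not a stream

Every random field element is a pure function of (master seed, role, key):
y values are keyed by (edge id, level, arrival time) — any injective keying
preserves correctness since the proof needs only per-level uniqueness of
the y variables — γ by (vertex, shade) and ω by (shade, label).  The mixer
is a splitmix64-style avalanche; the contract is bit-reproducibility across
platforms plus approximate uniformity, not cryptographic strength.  A PRF
rather than a stream generator is essential: the same variable must receive
the same value in all 2^ℓ lanes of one evaluation, and lane order (Gray
code in the compiled kernel, naive in the reference path) must not matter.
Independent repeats derive fresh sub-seeds through the same PRF; a cell is
reported reachable once any repeat certifies it, driving the false-negative
rate down multiplicatively.  The "2^ℓ random substitutions" of the lane sum
and the independent repeats are deliberately separate notions: the lanes
*are* the sieve, the repeats reduce the error.

## Field arithmetic

Supported widths b ∈ {4, 8, 16, 32, 64} with one tabulated irreducible
modulus per width (x⁴+x+1, x⁸+x⁴+x³+x+1, x¹⁶+x⁵+x³+x+1, x³²+x⁷+x³+x²+1,
x⁶⁴+x⁴+x³+x+1).  Any irreducible choice yields an isomorphic field, so
correctness never depends on the table; fixing it maximizes
reproducibility.  Multiplication is schoolbook shift-XOR with interleaved
reduction — adequate at the problem sizes this package targets; no
hardware carry-less-multiply intrinsics and no asymptotically fast
O(b log b) multiplication are attempted.  Irreducibility is verified by
exhaustive trial division for b ≤ 16 in the test suite.  b = 64 is the
production default (per-cell miss probability < 10^(−17); three repeats in
the validation suite push it far below any observable rate); b ∈ {4, 8}
exist to make false negatives measurable at all.

## Oracle evaluation order and cost

The compiled kernel enumerates the 2^ℓ lanes in Gray-code order,
maintaining z^L incrementally (one XOR per vertex per lane); the empty
subset contributes a zero pass and is skipped — the output is provably
identical either way (XOR associativity), and the reference implementation
can replay naive subset order to prove it.  Within a lane the dynamic
program runs level by level over a (τ × n) table; memory is two levels of
that table, O(nτ), matching the fine-grained output's own footprint.  (An
O(nΔ) sliding-window layout exists in principle but is pointless here
because the fine-grained answer itself is Θ(nτ).)  Cost per lane is
O(ℓ·(mΔ + nτ)) field multiplications.

## Problem reductions

* Exact-length reachability from s: private color for s, in-edges of s
  deleted, multiset {1^(k−1), 2}.
* Motif reachability from s: super-source s′ with a fresh color, one edge
  (s′, s, i) at every departure time i of s, multiset extended by the fresh
  color, ℓ = k+1.  The zero-gap pairing (s′ arrives exactly when s departs)
  always exists, so δ(s′) and the waiting window at s never constrain
  feasibility; extra pairings are genuine restless paths.  The two
  constructions agree cell-for-cell on unit-colored instances and the test
  suite checks it.
* At-most-k and full reachability: union of exact-length tables for
  ℓ = 2..k (resp. 2..n).  The full-reach loop runs to ℓ = n, covering the
  Hamiltonian-length path of n vertices, since the longest simple path has
  n−1 edges.
* Multi-source: super-source adjacent to every member; a k′-vertex path
  from s′ is a (k′−1)-vertex path from some member, so summaries shift
  lengths by one and drop the artificial single-hop tables.
* Shortest (minimum length) and fastest (minimum arrival) summaries read
  directly off the per-length tables.  A "minimum total waiting time"
  variant is *not* provided: the boolean tables do not determine waiting
  times, and no sound procedure follows from them alone.

## Extraction

Backward extraction spends exactly k oracle queries on success: one to pin
(d, i*) with i* the minimum true timestamp of the destination row, then one
per predecessor step on the shrinking instance (endpoint deleted, its color
multiplicity removed, horizon capped at the arrival time).  Any candidate
(v, i) with an edge (v, u, i_u), i ≤ i_u ≤ i + δ(v) and a true cell is
safe: its certified prefix is vertex-disjoint from the committed suffix and
color-compatible by construction, so greedy commitment never dead-ends when
the oracle answers truthfully.  Determinism: among valid candidates the
smallest arrival time wins, ties broken by smallest vertex id.  A dead end
can only be a sieve false negative; the failing query is retried with a
fresh derived seed (default 3 retries) and an exception is raised if the
retries are exhausted — at b = 64 this path is expected never to fire.
The returned witness is re-validated against the original graph before
being handed to the caller, so a completed extraction is its own
certificate.

## Exhaustive baselines and the expansion cross-check

Temporal DFS enumerates simple restless paths from a source with worst-case
cost O(d_max^k); no memoization is attempted because admissible
continuations depend on the entire visited set, making (vertex, time)
caching unsound for simple paths.  Enumeration refuses instances beyond a
d_max^k ≤ 10^7 guard.  The independent cross-check builds the static
δ-expansion — nodes (v, t), arcs ((v_i, t), (v_j, t′)) iff (v_i, v_j, t) is
an edge and 0 ≤ t′ − t ≤ δ(v_j), t′ ≤ τ, node color = original vertex id —
and searches for a rainbow (no repeated color) path by brute force.
Restless s→d paths exist iff rainbow paths between the timestamp copies of
s and d exist.  Node set is defined as the set of arc endpoints; the arc
count is at most (Δ+1)m with equality exactly when no arc is clipped by the
τ horizon (the five-vertex fixture gives 12 < 15).

## Synthetic generators

The generators emulate the synthetic conditions used to exercise the
engine: configuration-model pairing of degree stubs, d-regular or power-law
degree sequences, i.i.d. uniform timestamps on [1, τ].  The power-law
support has w geometrically spaced integer degree values with vertex counts
largest-remainder-rounded from frequencies ∝ degree^α, and the support cap
is fixed by a deterministic grid search so the stub sum lands near D·n;
after rounding the stub sum and the frequency law cannot both hold exactly,
and the frequency law at the support points is prioritized (the realized
stub sum is reported).  Self-loops and duplicate triples produced by the
pairing are deleted and counted, so realized degrees deviate from their
targets exactly by the removals — an accounting identity the tests check.
The random streams come from numpy's seeded PCG64 only.

What the generators do *not* emulate: burstiness and daily periodicity of
real contact timestamps, degree–degree correlations, community structure,
and repeated contacts between the same pair.  Passing tests on these
instances therefore certify the algorithms' correctness contracts, not
sociological realism of any particular dataset.

Planted instances for the false-negative measurement place one chain of k
vertices with admissible times ending strictly before τ and add decoy edges
that all carry timestamp τ and never point into the destination — no decoy
can extend to the planted cell, so the witness at that cell is unique by
construction, and an exhaustive verification re-checks uniqueness anyway.

## Immunization pipeline

Separators are excluded algebraically (a color outside the multiset zeroes
their substitution); the pipeline never edits the graph, and the test suite
verifies cell-for-cell agreement with explicit vertex deletion.  Selection
strategies: uniform random (a prefix of one seeded permutation, so plans at
growing fractions are nested and the reachability series are pointwise
non-increasing by construction) and maximum temporal degree (ties to the
smaller id).  The reachability series divides by the number of
non-separator, non-source vertices; the source is excluded from the
denominator as it is never "reached".  Fraction sweeps that resample
separators independently would not be monotone; the nested design makes
monotonicity a testable invariant.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: 300 random instances
with n ∈ [4, 12], m ∈ [n, 5n], τ ∈ [3, 8], Δ ∈ [1, 3], k ∈ [2, 6] and up
to 3 colors for the sieve-versus-enumeration comparison (b = 64, 3
repeats); 20 000 planted instances (n = 8, k = 4, τ = 8, Δ = 2, 8 decoys)
at b = 8 with a single repeat for the false-negative rate; 100 solvable
pairs for extraction; 200 instances (n ≤ 8) for the expansion equivalence;
n = 10^4 vertices for the power-law slope and ≈10^5 edges for the
timestamp-uniformity check.  These sizes keep every check exhaustive or
statistically well-powered at desk scale.

## Known limitations

Single color per vertex; no interval (non-instantaneous) contact
semantics; no transition-time/delay path variants; no minimum-total-waiting
("foremost") optimization; the deterministic rainbow-path route is a
brute-force cross-check, not a scalable solver; no SIMD/thread parallelism —
determinism and clarity are preferred, and the compiled kernel is fast
enough for the package's target scale.  The false-negative bound is per
cell and per repeat; users who need simultaneous guarantees across many
cells should raise `repeats` (the error multiplies) rather than rely on the
single-run bound.
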