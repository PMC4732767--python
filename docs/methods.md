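# Methods

## Model

A finite Markov chain is specified by three procedures: `arbitrary_state`
(instance → start state), `neighbours` (state → complete proposal list
with proposal probabilities κ), and `weights` (full state list → positive
Metropolis weights). A proposal list always sums to κ = 1: every random
choice that keeps the state is materialised as one explicit self-proposal,
and distinct choices producing the same successor are aggregated, so
κ(x, y) is a well-defined pairwise function and Σ_y κ(x, y) = 1 is a
machine-checkable invariant (tolerance 1e-12).

The state graph Γ = (Ω, Ψ) is the closure of the start state under
`neighbours`, found by a FIFO graph scan with canonical state encodings
(sorted edge tuples for matchings, row-major bit strings for 0/1
matrices) used for deduplication. Transition probabilities follow the
Metropolis rule P(x, y) = κ(x, y) · min(1, w(y)/w(x)) with the rejected
mass joining the self-loop; π = w/Σw. Weights are applied in a second
pass after the scan because globally-defined weights (the hole-class
counts of the weighted matching chain) need the complete state list.
Finalization asserts row sums (1e-10), positivity of π (1e-12) and
detailed balance π_i P_ij = π_j P_ji (1e-10); the scan itself is
order-independent (BFS and DFS traversals are compared in tests).

Construction relies on the chain's irreducibility: only the component
reachable from the arbitrary start state is built. Completeness is
verified against brute-force enumeration on every fixture up to 4+4
(all margin-constrained matrices; all perfect and near-perfect
matchings); at larger sizes an independent counting argument (below)
stands in.

## Built-in chains

*Uniform-edge matching chain* (`broder`): draw an edge of the host graph
uniformly; remove it (perfect state), add it (both endpoints are the
holes), or slide it along the matched partner edge of its matched
endpoint. Unit weights; κ = (#choices)/|E|. For a near-perfect matching
of a balanced graph there is exactly one hole per side, so the two slide
cases are mutually exclusive for any drawn edge.

*Weighted matching chain* (`jsv`): a perfect matching removes one of its
n edges (κ = 1/n); a near-perfect matching with holes (u, v) draws a
vertex z among all 2n (κ = 1/(2n) each): both z = u and z = v add
{u, v} when it is an edge (aggregated κ = 1/n), any other z slides the
matched edge at z toward the hole on the opposite side. Weights are 1 on
perfect matchings and |M|/|N_{u,v}| on the hole class N_{u,v}, computed
exactly from the enumerated state list, so every hole class carries the
same stationary mass as the perfect class. Approximating these counts
(as a sampler in the wild must) is deliberately out of scope.

*Switch chain* (`switch1`): draw i ≤ k, j ≤ l uniformly; if the rectangle
{u_i, u_k} × {v_j, v_l} carries exactly one perfect alternating diagonal,
swap it. Each non-loop arc has constant κ = [2/(n(n+1))]·[2/(n′(n′+1))];
degenerate draws (i = k or j = l) and blocked rectangles are loop mass.

*Loop-reduced switch chain* (`switch2`): draw an unordered pair of
non-adjacent edges uniformly from E ∪ {u₀v₀}, where {u₀, v₀} is an
artificial edge on two extra vertices that keeps the proposal
distribution well-defined (and the chain aperiodic) when no switchable
pair exists. The number of non-adjacent pairs is determined by the degree
sequence alone, hence equal in every state, hence κ is symmetric and π
uniform. The source that introduces this chain does not spell out κ;
uniform-over-non-adjacent-pairs is this package's reading, and the
intended design effect — self-loop mass never exceeding the classical
switch chain's, state for state — is verified exhaustively on all ≤ 4+4
instances.

Arbitrary states: realizations come from the greedy Gale–Ryser
construction (each row fills the columns of highest residual demand,
ties to the lowest index), which succeeds exactly on realizable pairs;
matchings come from an augmenting-path maximum matching, rejecting hosts
without a perfect matching.

## Total mixing time

d(t) = max_a ‖p_a^(t) − π‖_TV is read off the rows of P^t and decreases
monotonically in t (standard for reversible lazy chains; additionally
guarded by the bracket invariant below). τ(ε) = min{t : d(t) ≤ ε} is
found in two phases: (1) square P until d(2^i) ≤ ε, storing every
P^(2^k); (2) binary-search (l, r] = (2^(i−1), 2^i] maintaining
d(l) > ε ≥ d(r), each probe a single product P^m = P^l · P^(m−l) with
m − l a stored power of two. Cost: O(log τ) matrix products and O(|Ω|²)
memory; the default state cap of 20,000 for mixing-time work reflects
that quadratic footprint, and a configurable exponent cap (2^60) stops
effectively-non-mixing inputs.

Numerics: double precision throughout; comparisons with ε are `≤` with
an absolute slack of 1e-12 to absorb accumulated rounding from repeated
multiplication. The step-wise oracle applies the identical rule, which
is why the fast path and the oracle agree *exactly* on every fixture
(verified across all four chains, all ergodic ≤ 4+4 instances, several
ε). τ = 0 is returned when every point mass is already within ε.
Mixing-time routines refuse non-ergodic inputs (strong connectivity of
the non-loop arc graph; aperiodicity via loop presence or
non-bipartiteness — cheaper than a cycle-gcd computation and sufficient
for these chains; detailed balance within 1e-10).

## Bounds

Symmetrization uses P_sym = D^(1/2) P D^(−1/2) (D = diag π), the
conjugation that is symmetric exactly under detailed balance and shares
P's spectrum. λ_max = max(|λ₂|, |λ_min|) excludes the Perron eigenvalue;
a dense symmetric solver is used below 500 states and Lanczos/ARPACK
above (tolerance 1e-10, maxiter 10·|Ω|, dense fallback on
non-convergence). Both extreme eigenvalues are always computed — with
loop-heavy chains λ_min rarely dominates, but it can after loop
reduction (see below).

The congestion bound routes one simple path per ordered pair (x, y)
through a pluggable scheme (register_path_scheme). The built-in default
is deterministic BFS shortest paths with the predecessor chosen as the
smallest-index in-neighbour one level closer to the source. The original
canonical-path schemes attached to the matching and switch chains are
defined in their sources' proofs, depend on arbitrary vertex/cycle
orderings, and are not reproduced here; the shortest-path default is this
package's own scheme, so congestion numbers are comparable across runs
but not to those historical constructions. Accumulation is a plain
float sum per arc and is checked to be order-invariant to 1e-9.

## Loop reduction

With P_min = min_i P_ii, the transform
P′ = (P − 0.99 P_min I)/(1 − 0.99 P_min) removes 99% of the minimal loop
probability from every state and rescales so rows sum to one again. (The
subtract-then-rescale composition restores row sums exactly; rescaling
only the off-diagonal arcs and refilling the diagonal gives the identical
matrix.) It preserves symmetry, hence the uniform stationary
distribution, the arc support, and reversibility; it is refused for
non-uniform π. It is **not** monotone in τ per instance: on loop-light
graphs removing the common loop mass overshoots into a dominant
*negative* eigenvalue and the chain oscillates — e.g. the two-state
switch graph of (1,1),(1,1) moves from λ = 7/9 to λ = −0.852 and
τ(10⁻³) rises from 25 to 39 — while on loop-dominated instances the
effect is dramatic in the intended direction (the two-state
(6,6,6,6,5,5) graph drops from τ = 1368 to 14). The aggregate claim that
motivates the transform (the worst case over the ≤ 6+6 sweep collapsing
to 63) is reproduced by the sweep test.

## Instance generators

The generators define the study conditions; they are code, not fixtures.

- `enumerate_sequence_pairs(max_left, max_right, ordered, realizable_only)`:
  non-increasing positive sequences in a size box, paired by equal sums.
  The census convention — unordered pairs {a, b}, no realizability
  pre-filter — reproduces the historical instance count at 6+6 (19,378);
  the drivers feed the chains the ordered, Gale–Ryser-filtered variant
  (15,583 at 6+6) since only realizable pairs have a state graph.
  Completeness is cross-checked against margin multisets of exhaustive
  matrix enumeration up to 3+3.
- `count_realizations`: column-by-column dynamic program over the
  multiset of residual row demands with binomial multiplicities — an
  independent count of margin-constrained 0/1 matrices used as the
  cross-oracle for switch-chain state-graph sizes (297,200 for the
  3-regular 6+6 pair).
- `scaling_sequence`: the half-regular families A (n−1, n−2, 2, 1),
  B (n−1, n−2, 3), C (n−1, n−2, 1, 1, 1), each against n twos; emitted
  sorted non-increasing.
- `enumerate_bipartite_graphs`: brute force over all biadjacency matrices
  (capped at 4+4), with connectivity / perfect-matching filters and
  optional isomorphism dedup via a canonical form (minimum over column
  permutations of the row-sorted matrix). This is a desk-scale stand-in
  for isomorph-free exhaustive generation at 6+6, which needs external
  tooling and is out of scope.
- `random_bipartite_graph`: seeded PCG64, independent edges.

What the fixtures do **not** emulate: real degree sequences are larger,
sparser and heavy-tailed, and real null-model uses run the chain without
ever materialising Ω. Passing tests certify the analysis machinery on
exhaustively checkable instances, not mixing behaviour of field-scale
networks.

## Performance choices

The classical switch chain's κ is a single constant per non-loop arc, so
its whole state graph is determined by adjacency. A bit-packed scan
(states as int64 row-major bit masks, switches as precomputed
rectangle/diagonal bit tables, numba-JIT with an identical pure-Python
fallback that the tests also exercise) enumerates the 297,200-state
3-regular graph in seconds and powers the loop-reduction sweep. The
sweep filters instances by the counting DP *before* building graphs and
analyses every ≤ 6+6 instance with |Ω| ≤ 500 (6,189 instances, ~30 s);
the maximum reduced mixing time is already attained in that range.
Transition matrices are dense below 500 states and CSR-sparse above;
the mixing module densifies on demand.

## Known limitations

- Everything is exact and exhaustive, hence exponential: instance
  enumeration and state-graph construction are meant for n, n′ ≤ ~6.
- τ computation is O(|Ω|²) memory; above the 20,000-state cap only the
  spectral/congestion machinery (sparse) applies, with the linear
  lower-spectral-bound → τ predictor (`fit_tau_predictor`, OLS) as the
  documented extrapolation device.
- Aperiodicity detection by loops/bipartiteness is sufficient for the
  built-in chains but is not a general cycle-gcd test.
- The congestion numbers depend on the path scheme; only the built-in
  shortest-path scheme ships.
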