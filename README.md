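# mixtime

Exact mixing-time analysis of Markov-chain Monte Carlo samplers via
explicit state graphs.

MCMC samplers — for example the *switch chain* used throughout network
biology to draw degree-preserving random bipartite networks (ecological
co-occurrence null models, gene–condition incidence matrices, contingency
tables with fixed margins), or the matching chains used to sample perfect
matchings — are usually run for a number of steps chosen by folklore.
`mixtime` answers, for small instances, the question those heuristics
dodge: *how many steps does the walk actually need?* It builds the full
state graph Γ = (Ω, Ψ) of a chain on a concrete instance, computes the
exact total mixing time, and compares it with the classical spectral and
canonical-path (congestion) bounds, so that the tightness of those bounds
can be measured instead of conjectured.

## What it computes

For a chain with proposal probabilities κ, weight function *w*, Metropolis
transition matrix P(x, y) = κ(x, y) · min(1, w(y)/w(x)) and stationary
distribution π ∝ w:

- **Total mixing time** τ(ε) = max_a min{t : ‖p_a^(t) − π‖ ≤ ε}, with
  ‖·‖ the total variation distance, computed *exactly* by repeated matrix
  squaring followed by binary search on the bracket (2^(i−1), 2^i]
  (each probe is a single matrix product P^m = P^l · P^(m−l)).
- **Spectral bounds** from λ_max = max(|λ₂|, |λ_min|) of the symmetrized
  matrix P_sym = D^(1/2) P D^(−1/2):
  ½ · λ_max/(1−λ_max) · ln(1/2ε) ≤ τ(ε) ≤ (1−λ_max)^(−1) · (ln ε^(−1) + ln π_min^(−1)).
- **Congestion bound** ρ(𝒫) · (ln ε^(−1) + ln π_min^(−1)) for a pluggable
  canonical-path scheme 𝒫, where ρ is the maximum over arcs (u, v) of
  Σ_{p ∋ (u,v)} |p| π(x) π(y) / (π(u) P(u, v)).
- **Network metrics** (diameter, average path length), **ergodicity
  diagnostics** (connectivity, aperiodicity, detailed balance), and the
  **99% loop-reduction** transform P′ = (P − 0.99 P_min I)/(1 − 0.99 P_min).

Four chains are built in: `broder` and `jsv` (uniform-edge and weighted
vertex-pick chains on perfect/near-perfect matchings of a bipartite
graph) and `switch1`/`switch2` (the classical and the loop-reduced
switch chain on bipartite realizations of a degree-sequence pair).
User-defined chains plug in through the same three-method contract
(arbitrary state, neighbour proposals with κ, weights).

## Worked example

Analyse the switch chain on the degree-sequence pair (2,1,1), (2,1,1):

```sh
$ mixtime analyze --chain switch1 "2,1,1;2,1,1"
instance_id: 2,1,1;2,1,1
chain: switch1
num_states: 5
num_arcs: 21
epsilon: 0.001
mixing_time: 72
spectral_lower: 34.180344541322185
spectral_upper: 102.2063182969952
congestion_bound: 183.97137293459076
lambda2: 0.916666666666667
lambda_max: 0.916666666666667
pi_min: 0.2
diameter: 2
avg_path_length: 1.2
avg_loop_probability: 0.9111111111111111
```

Reading: the pair has 5 realizations; starting from the worst of them the
walk needs exactly 72 steps to come within total-variation distance 10⁻³
of uniform. The spectral bounds bracket τ as 34.2 ≤ 72 ≤ 102.2, while the
canonical-path bound (184, shortest-path scheme) is ~2.6× the truth —
the bound-quality gap this tool exists to measure. 91% of each state's
outgoing probability is loop mass, which is why τ is large for a 5-state
graph.

Other entry points: `mixtime enumerate` (degree-sequence census),
`mixtime experiment` (batch CSV over all instances up to a size box,
resumable), `mixtime reduce-loops` (paired rows before/after loop
reduction), `mixtime export-graph` (TSV of the transition matrix). The
same functionality is importable (`mixtime.build_state_graph`,
`mixtime.total_mixing_time`, `mixtime.spectral_report`,
`mixtime.congestion`, ...).

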