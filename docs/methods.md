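# Methods

This note documents the models implemented in `netctrl`, the choices made
where the design was genuinely open, and what the validation studies do
and do not show. Nothing here states an empirical number that the test
suite or `scripts/acceptance.py` does not itself compute.

## System model and conventions

All machinery targets linear time-invariant dynamics `x'(t) = A x(t) +
B u(t)` on a finite horizon `[0, t_f]`. `A` is the weighted adjacency
matrix of a directed network: a link from node *i* to node *j* means
node *j*'s state equation receives node *i*'s influence, so the weight of
edge `i → j` is stored at **row j, column i**. One convention, used
everywhere, including file I/O (Matrix Market) and the input matrices.
Node identifiers are opaque strings; dense 0-based indices appear only at
the matrix boundary, in node insertion order.

Path lengths `L_i` count **nodes**; segments between inputs on a closed
circle are measured in **edges**. Both conventions are standard and each
is used where it is the natural unit (the min-max allocator's worked
example `{7, 3} → max{⌈7/2⌉, 3} = 4` is in nodes; the circle cost study's
"longest segment" is in edges).

Defaults: horizon `t_f = 1` (no canonical value exists for the
dimensionless model; every entry point exposes it), initial-state second
moment `Σ₀ = I` (i.i.d. zero-mean unit-variance components), edge weight
1 when unspecified.

## Local-game matching (LM)

LM approximates a maximum matching with strictly local information. The
implementation runs **synchronous rounds**: requests are computed from the
state at the start of a round and exchanged simultaneously; u-degrees
(counts of still-unmatched neighbours) are recomputed between rounds.

- A node without a matched child sends a child request to its unmatched
  child neighbour of minimal u-input degree; a node without a matched
  parent symmetrically requests the parent of minimal u-output degree.
- Only a **mutual** request pair fixes a match. The matched parent drops
  its other outgoing links, the matched child its other incoming links;
  self-loops may self-match.
- Ties among minimal-degree candidates: with probability `ω` (default 0)
  the node waits this round, otherwise it breaks the tie uniformly at
  random. The waiting decision is taken per tie event. All randomness
  comes from one seeded generator and nodes are visited in network order,
  so runs are exactly reproducible.
- Termination: when no requests can be sent; additionally, a round that
  sends requests but produces no match **and** involved no random draw is
  a fixed point (with a single consistent degree ordering a cyclic
  preference chain is impossible, so a deterministic no-progress round
  can only repeat itself) and stops the protocol. A generous round cap
  guards the remaining stochastic corner cases.

The fixed matches decompose the nodes into directed control paths (DCPs)
and circled control paths (CCPs); DCP heads are the driver nodes. The
number of required independent inputs is the DCP count, one for a
non-empty all-CCP network, zero for the empty network.

**Known limitation (measured, not hidden).** LM always produces a valid
*maximal* matching — after termination no edge between an unmatched
parent and an unmatched child survives — and therefore never needs fewer
inputs than the exact optimum. But it is a one-shot greedy protocol with
no augmenting paths, and above mean degree ≈ e the optimum deficiency
collapses to O(1) nodes while any greedy matcher retains a small Θ(N)
excess. In that regime the *ratio* of LM to exact driver counts is large
even though the excess is only a few nodes per thousand. Experiments in
`tests/test_acceptance.py` quantify this at N=500–1000: the ratio-based
and driver-histogram-based comparisons with the exact oracle fail their
nominal thresholds at mean degrees ≥ 4 for exactly this reason, while the
absolute excess stays below a few percent of N (asserted in the unit
suite). Variants we measured — sequential one-match-at-a-time cascading,
waiting probabilities up to 0.9 — do not change this picture; closing the
gap requires global prioritization of forced matches, which contradicts
the local-information premise.

## Exact maximum matching oracle

Hopcroft–Karp on the bipartite out-copy/in-copy representation (via
networkx), `N_D = max(N − |matching|, 1)`; the unmatched in-copies form
one realization of the driver set (any node serves when the matching is
perfect). Verified against exhaustive edge-subset search on small graphs.

## Min-max input allocation (MLCP) and placement

Given merged path lengths and a budget `m₀`, the allocator repeatedly
grants one input to the path with the largest current ratio
`L_i/(1+n_i)`, ties toward the lowest index, with exact fraction
arithmetic so ties are never rounding artefacts. An exchange argument
makes greedy optimal for the min-max objective; the suite additionally
checks equality with exhaustive enumeration on hundreds of random
instances.

CCPs need no input of their own and are folded onto effective paths
first: largest CCP onto the currently shortest effective path; when only
CCPs exist, a single virtual path (seeded by the largest CCP) hosts the
one mandatory input. The fold details are an open design point in the
source method; this balancing rule is our choice and is isolated in one
function.

**Placement.** Each path's `1 + n_i` inputs are distributed over the
path's *pieces* (the hosting DCP and each folded CCP): the DCP always
keeps the driver-node input, pieces without any input have priority
(their nodes are otherwise reachable only the long way round through the
hook-up), and remaining inputs go to the piece with the worst
`length/assigned` stretch. Within a piece, input *j* of *k* sits at node
`⌊j·L/k⌋ + 1`, so segments differ by at most one node. Placing inputs on
the literal concatenation of DCP and CCP node sequences instead is
measurably wrong — the DCP tail has no edge into the folded CCP, and the
mismeasured distances occasionally produce catastrophically
ill-conditioned Gramians; this failure mode drove the piece-aware design.

Input matrices are unit-column indicators (`BᵀB = I_M` by construction),
matching the binary-connection restriction of allocation-based control.
The random-allocation baseline (RAM) takes one exact-matching driver set
plus uniformly random distinct extra nodes.

## Energy machinery

- **Gramian.** `W_B = ∫₀^{t_f} e^{At} B Bᵀ e^{Aᵀt} dt` via the Van Loan
  block-exponential construction (`expm` of `[[−A, BBᵀ], [0, Aᵀ]]·t_f`),
  symmetrized. Cross-checked against adaptive quadrature to ≤ 1e-8
  relative error on random stable systems up to n = 8.
- **Minimum-energy control.** `u(t) = −Bᵀ e^{Aᵀ(t_f−t)} W_B^{-1}
  e^{At_f} x₀` with cost `x₀ᵀ e^{Aᵀt_f} W_B^{-1} e^{At_f} x₀`; validated
  by ODE integration (terminal state ≤ 1e-6·‖x₀‖) and by checking that
  terminal-state-preserving input perturbations only increase the energy.
- **Expected cost.** `E(B) = tr(W_B^{-1} e^{At_f} Σ₀ e^{Aᵀt_f})`, equal to
  the Monte-Carlo mean of realized costs for unit-variance initial states
  (checked within 3 standard errors at 10⁴ draws).
- **Gradient.** Direct matrix calculus gives `∂E/∂B = −2 S B` with
  `S = ∫₀^{t_f} e^{Aᵀt} W_B^{-1} e^{At_f} Σ₀ e^{Aᵀt_f} W_B^{-1} e^{At}
  dt` (PSD), evaluated with the same Van Loan machinery and validated
  against central finite differences (≤ 1e-4 relative on well-conditioned
  instances; with condition numbers beyond ~1e12 finite differences
  themselves carry no significant digits, so the comparison is only run
  where double precision is meaningful). Note the sign: `∂E/∂B` is a
  *negative*-semidefinite multiple of `B` — growing `B` always lowers the
  cost, which is precisely why the orthonormality constraint exists. The
  optimizer steps along `−∂E/∂B`.
- **OPGM.** `B̂ = B − η (I − BBᵀ) ∂E/∂B`, then rescale by
  `sqrt(tr(B̂ᵀB̂)/tr((B̂ᵀB̂)²))`, which enforces `tr((BᵀB)²) = tr(BᵀB)`
  exactly (both equal M at orthonormality). Initialization: random matrix
  with orthonormalized columns from the seeded generator. Stopping:
  relative cost change below `tol` or an iteration cap; repeated cost
  increases or iterate overflow raise a divergence error suggesting a
  smaller `η`. `η` is problem-dependent: the gradient magnitude scales
  with `W_B^{-2}`, so ill-conditioned systems need small steps (the
  monotone-descent tests use 1e-5 on a 3-node stem and 1e-8 on a 4-node
  circle). The optimizer runs in double precision; extended precision is
  provided for cost *evaluation* (below), where long control paths
  actually demand it.

### Extended precision

Beyond condition number ~1e12 (the trust limit, surfaced as a warning)
double-precision costs lose all significant digits — the numerical
controllability transition. `expected_cost(..., precision=digits)`
evaluates `E(B)` with mpmath: the Gramian integrand `(e^{At}B)(e^{At}B)ᵀ`
uses truncated-Taylor exponentials (truncation set by the target digits)
integrated by Gauss–Legendre quadrature whose node count matches the
truncation order, with nodes computed at working precision by Newton
iteration on the Legendre recurrence. `cost_vs_longest_path` switches to
this backend automatically per layout, sizing the digit count from the
longest inter-input gap (`digits ≈ 2·log₁₀((gap)!) + 25`). Agreement with
double precision on well-conditioned layouts is ~1e-11 relative.

## Synthetic networks

Every generator is a pure function of its spec including the seed.

- **er**: directed G(N, p) with `p = μ/(N−1)`, giving mean degree
  (L/N) `μ`.
- **ba**: directed preferential attachment; each new node sends `m`
  out-edges to distinct targets chosen ∝ in-degree + 1. (The literature
  has no single canonical directed BA; this variant is fixed and `m`
  exposed.)
- **chi2 / weibull / gamma**: in- and out-degree sequences drawn i.i.d.
  from the named law rescaled to mean `μ` (shapes default to 2, 1.5, 2),
  rounded, the in/out sums balanced by random unit increments, realized
  by a directed configuration model with parallel edges collapsed.
  Realized mean degree is within 10% of `μ` at N = 2000 (tested).
- **stem / circle / dilation**: the elementary control topologies; the
  dilation is parameterized (trunk and two branch lengths) since only its
  shape, not its exact size, is canonical.

What the generators do *not* emulate: degree correlations, communities,
clustering, weighted-edge heterogeneity. Conclusions from the validation
studies therefore speak to homogeneous random topologies; real networks
may place the controllability transition elsewhere.

## Study conditions for the validation experiments

Chosen once, as desk-scale versions of the reference studies:

- LM vs exact oracle: 100 networks, N = 500, ER and BA alternating, mean
  degrees cycling 1–8, `ω = 0`.
- Driver-degree statistics: ER, N = 1000, μ = 6, five seeds pooled,
  total-variation distance on normalized in-/out-degree histograms.
- Circle cost study: 20-node circle, M ∈ {2, 4, 5, 10}, 8 random layouts
  each, Spearman correlation of cost with longest segment.
- MLCP vs RAM: ER, N = 100, μ = 2 (and μ = 6 for the dense comparison),
  `m₀ = 10`, 50 seeds, identical spectrum-floored cost evaluation for
  both methods so singular cases do not favour either side.

## Known limitations

- LM's excess over the exact optimum at mean degree ≳ 4 (see above); the
  package reports both counts so users can judge the regime.
- The min-max objective treats path lengths as a proxy for cost; twin
  nodes (identical in-neighbourhoods) can keep the Gramian numerically
  singular no matter how the path-based inputs are placed — more inputs,
  not better placement, is the remedy there.
- OPGM is a local descent method on a non-convex problem: different
  seeds can converge to different input configurations (the elementary
  dilation genuinely has multiple basins); only cost monotonicity and
  stationarity properties are guaranteed, not global optimality.
- The energy layer builds dense matrix exponentials: practical up to a
  few hundred nodes (the pipeline skips the energy stage beyond a
  configurable cap, default 200).
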