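# Methods

This note documents the models implemented in `grnclamp`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
fixtures do and do not establish about real regulatory networks.

## Topology and centrality

A topology is a signed directed graph read from the `.topo` dialect
(`Source Target Type`, Type 1 = activation, 2 = inhibition). Node indices
are assigned by first appearance and define the coordinate system for the
interaction matrix `J` (`J[i, j]` = sign of edge `j -> i`), spin states and
expression vectors. Parsing is fail-loud: malformed rows, unknown edge
types and duplicate ordered pairs raise with the offending line number.
Because the format has no node section, node order can only be recovered
from edge order; `read -> write -> read` is exactly idempotent, but an
in-memory topology constructed with a different node order round-trips its
edge set and signs, not its order.

Group betweenness centrality follows the Everett–Borgatti convention:
directed, unweighted, signs ignored; for every ordered pair of distinct
nodes *outside* the group, the fraction of shortest paths passing through
at least one group member is accumulated, with no normalization. It is
computed exactly via two BFS path-counting passes per source (full graph,
and graph with the group deleted — surviving equal-length paths are
precisely the group-avoiding ones). Note that under this convention the
score is *not* monotone when the group grows, because pairs whose endpoint
joins the group stop counting; `include_endpoints=True` switches to the
monotone variant in which such pairs contribute fully.

## Boolean spin model

State: spins `s_i = ±1` (+1 = high expression). Pseudo-energy
`E = -Σ_ij s_i J_ij s_j`; one unit time = `N` random single-node update
attempts; a flip is accepted with probability `min(1, exp(-ΔE/T))` with
`ΔE = +2 s_i Σ_j J_ij s_j`. With this sign, states aligned with their local
fields — equivalently, low-frustration states — are locally stable, which
is the property the whole construction relies on; the sign is exposed as a
config switch (`energy_sign`) for auditability. Zero-field flips
(`ΔE = 0`) are accepted with probability 1, exactly as the formula
dictates; at `T = 0` the rule degenerates to greedy descent with free
zero-field moves.

Frustration counts each directed link once:
`f = Σ_links θ(-s_i J_ij s_j)`. It is invariant under a global spin flip,
and the epithelial score `Σ_i σ_i s_i` is antisymmetric, which makes the
forward (E→M) and backward (M→E) protocols exact mirrors: flipping the
initial state, the clamp targets and the annotation reproduces the same
trajectory distribution, a property the tests verify bitwise at matched
seeds.

Transition protocol: find a start state by relaxing random states at the
protocol temperature until frustration ≤ `frustration_max` (default 10)
and epithelial score > `e_score_start_min` (default 4, against a default
maximum of 6); clamp the chosen nodes at their mesenchymal values
(epithelial-scored genes off, mesenchymal-scored genes on, both polarities
tried for unscored genes and the better one reported); run `t_c` unit
times at temperature `T`; release the clamp and quench at `T = 0.5` for 10
units; success iff the final score < `m_score_end_max` (default −4).
Success is evaluated directly on the quenched state with no extra
deterministic relaxation. The search temperature defaults to the protocol
temperature and is overridable (`init_T`), since the two need not
coincide. The inner update loop is numba-compiled; node choices and
acceptance draws are interleaved deterministically given the seed, with
per-phase kernel seeds drawn from the caller's generator.

## Randomized ODE ensemble

Per gene: `dA/dt = G_A/Π_act λ · Π_i H(B_i; B⁰_i, n_i, λ_i) − k_A A` with
the shifted Hill factor `H = λ + (1−λ)/(1+(B/B⁰)^n)`, which runs from 1
(regulator absent) to λ (saturated); λ > 1 activates, λ < 1 inhibits.
`G` is divided by the product of *activation* fold changes only, so `G_A`
is the true production ceiling (all activators saturated, inhibitors
absent); dividing by inhibitory λ as well would inflate baseline
production by 1/λ, contradicting the definition of `G` as a maximal rate.

Sampling ranges (overridable in `EnsembleConfig`): `G ~ U[1, 100]`,
`k ~ U[0.1, 1]`, integer Hill `n ~ U{1..6}`, `λ ~ U[1, 100]` (activation)
or `U[0.01, 1]` (inhibition). Thresholds follow the half-functional rule:
`B⁰ ~ U[0.02 M, 1.98 M]` where `M` is the median unregulated level `G/k`
over the sampling ranges (a Monte-Carlo constant computed once from a
fixed stream), so a regulator sits above or below its threshold with
roughly even odds across the ensemble.

Steady states: 200 initial conditions by default (50–60 in the scaled-down
test and acceptance runs), log-uniform between 10⁻² and each gene's
ceiling `G/k` — spanning the reachable range of the dynamics. Integration
is fixed-step explicit Euler (`h = 0.1`, max time 200) to a max-norm
residual below 10⁻⁶; trajectories not converged at max time are excluded
and counted in the diagnostics. Endpoints are deduplicated by rounding to
2 decimals on the log1p scale (the transform used for all downstream
analysis; raw-scale rounding is available via `dedup_on="raw"`).

Preprocessing: `log(1+x)` then per-gene z-scoring across all pooled
states (population s.d.; zero-variance genes map to 0 with a warning).
The fitted transform is stored and reused for trajectories, perturbed
endpoints and PCA, so every classification happens in one consistent
space. Clustering: Gaussian mixtures with diagonal covariance and 10
seeded restarts are fitted for k = 2..6 and silhouette scores recorded;
labels come from the 2-component fit, and the cluster with higher mean
expression of the epithelial marker gene (`Cdh1` on EMT networks; `A` on
the toggle fixture) is named E. Models with exactly two unique states, one
per cluster, form the bistable subset used by all screens.

## Perturbation protocol and noise

A signal locks 1–2 genes at the values they take in the model's *target*
steady state — the continuous analog of toggling a binary node that adapts
to each parameter set — for `t_signal` (default 500) time units, then
releases them for `t_relax` (default 50) units of deterministic
relaxation. Clamped values are reset after every Euler step, so they are
bit-identical to their targets at every sampled time in the signal window.

Ornstein–Uhlenbeck noise uses the exact discretization
`U(t+h) = U e^{−h/τ} + D_g √(1−e^{−2h/τ}) z`, with `τ = 10` and `D_g = D ×`
(mean expression of gene g across the model's known steady states), making
the noise proportional to each gene's scale. `D` is therefore the
*stationary standard deviation* multiplier (the source description calls
it a variance; dimensional consistency of the update rule requires the
s.d. reading, which is what is implemented and verified against the
closed-form stationary law). The OU term is added to the derivative each
Euler–Maruyama step, noise runs only during the signal window, and
expression is floored at 0 after every step.

Final (and sampled) states are classified E/M by majority vote among the
k = 25 nearest pooled reference states (Euclidean distance in processed
space); exact vote ties break toward M — a fixed, documented rule rather
than platform-dependent behavior. Two practical caveats scale with
reference size: k must not exceed the reference count, and when the pooled
reference is small a model's own boundary state can be outvoted by the
opposite cluster. Screens therefore run on the `classifier_consistent`
subset (models whose own E and M states classify correctly); at the full
study scale (hundreds of models, thousands of pooled states) this filter
removes nothing, but it is what makes the zero-noise control exactly 0%
on small fixtures.

Derived statistics: per-signal efficacy (percent of E-starting bistable
models ending in M, averaged over `n_trials`); no-signal spontaneous
switching rates in both directions per noise level; transition time (first
sampled time, 1-unit stride, at which a trajectory classifies as the
target); and the minimum-noise threshold scan, which holds the clamp
throughout, starts from a steady state of the clamped system and reports
the smallest grid noise level at which any trial ends closer (log1p
Euclidean) to the destination state than to the origin.

## Synthetic fixtures and what the tests show

The toggle switch (two mutually inhibiting, self-activating genes, A
scored epithelial and B mesenchymal) is the canonical bistable motif and
exercises every code path: its Boolean absorbing states are provably the
two anti-aligned corners, and a double-digit percentage of random
parameter sets are E/M bistable. Random signed GRNs
(`make_random_grn`) provide arbitrary-size property-test inputs, and the
acceptance script adds a five-node E/M motif (two mutually activating
pairs with cross-inhibition plus an unscored mediator) so the
dual-framework screen and centrality correlation run on a network with
nontrivial shortest-path structure.

These fixtures emulate the *mechanisms* — multistability, clamp-driven
basin escape, noise amplification, E/M marker structure — but not the
scale or wiring statistics of curated EMT networks: no microRNA-layer
asymmetry, no hubs with out-degree 11, and far fewer pooled steady states
(hence smaller KNN references, see above). Passing tests certify the
engines and statistics, not any biological claim about a specific network.
The published 26-node EMT network is supported as a drop-in user input
(`grnclamp.datasets.load_emt_network`, files from the original study's
repository); the published-number tests run against it when present, at
reduced ensemble scale (200 models × 50 initial conditions, 100-model
noisy screen) chosen to keep a laptop-class run in minutes.

## Numerical choices and limitations

- Fixed-step Euler/Euler–Maruyama keeps deterministic and stochastic
  trajectories on the same discretization; `h = 0.1` against degradation
  rates ≤ 1 keeps the scheme stable. Stiff or adaptive solvers are out of
  scope.
- Steady-state enumeration can miss states whose basins are small at the
  chosen number of initial conditions; more initial conditions never lose
  states (property-tested at matched seeds).
- GMM and KNN results depend on the pooled reference; both are seeded and
  restarted for determinism.
- The Boolean engine's random-sequential updates make single-trajectory
  gene ordering noisy by construction; only ensemble statistics are
  meaningful.
- The acceptance script's problem sizes (200-model toggle ensemble, 40-run
  Boolean screens, 15-signal motif screen) are the package's chosen
  demonstration scale; all are config parameters.
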