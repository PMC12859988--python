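# Methods

## Model

Each modelled TF's scaled expression x_i ∈ [0, 1] decays at unit rate and
is produced through a saturating Hill term driven by its regulators:

    τ ẋ_i = −x_i + a_i / (S^n + a_i + b_i),
    a_i = Σ_{j∈V_act(i)} W_ji x_j^n,   b_i = Σ_{j∈V_inh(i)} W_ji x_j^n.

The Hill term lies in [0, 1), so for W ≥ 0 and x(0) ∈ [0, 1]^N the flow
cannot leave the unit box: ẋ_i ≥ 0 at x_i = 0 and ẋ_i ≤ 0 at x_i = 1. This
matches expression data scaled into [0.1, 0.9] and is verified empirically
over random models in the test suite. Because activating input appears in
numerator and denominator, a single strong activator can saturate a target
regardless of in-degree. Weights are static over the modelled process; no
noise term is modelled.

Assumptions worth keeping in mind: one population of cells (no branching),
regulation representable by a single signed weight per ordered pair, and
identifiability only at the trajectory level — different W can produce
near-identical trajectories, which is why driver ranking is aggregated
over repeated fits rather than read off a single weight matrix.

### Up-/down-regulation

A controlled input p acts on one TF: p_act = max(p, 0) is added to that
TF's numerator and denominator, p_inh = max(−p, 0) to the denominator only.
An isolated perturbed node equilibrates at p/(S^n + p) — 0.75 at p = 3 with
S = 1 — so the grid bound |p| ≤ 3 corresponds to forcing a node to at most
three quarters of its ceiling when it has no other input. p_act and p_inh
are never both nonzero.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| S (half-occupation) | 1 | scaled expression | Hill midpoint |
| n (Hill coefficient) | 3 | – | sigmoid steepness; n = 3 makes bistability representable (demonstrated by the toggle scenario; n = 1 loses it) |
| τ | 1 | days | system time scale; fixed, not fitted — the data time axis is experiment days and fitted weights absorb residual scale |
| C (L1 coefficient) | 0.005 | – | sparsity pressure; small enough that fit quality dominates |
| learning rate | 0.1 | – | ADAM step; deliberately high — smaller rates were not more stable in our fits and the best-iterate rule tolerates oscillation |
| n_a, n_i | 70 / 40 | edges | activating/inhibiting edge quotas (data-set specific; the synthetic benchmarks use truth-sized quotas) |
| n_top_influence / n_general | 5 / 12 | TFs | selection quotas |
| influence max depth / α | 2 / 0.05 | – | influence approximation (below) |
| p grid | −3 … 3, step 1/20 | – | 121 perturbation strengths, symmetric, contains 0 |
| restarts | 10 | – | robustness statistics for the importance ranking |

## Influence approximation

The influence score ranks TFs between two time points on the differential
network (edges whose interaction score increased). The upstream tool this
score originates from does not publish a closed formula, so this package
uses an explicit approximation:

    influence(i) = Σ_g (1/2)^(d(i,g)−1) · max(0, log2FC_g) · 1[p_adj(g) < α]

over genes g ≠ i within `max_depth` directed edges, d = shortest-path edge
count. All four choices (depth halving, positive-FC clipping, significance
gate, depth cap) are config-exposed. TFs with influence exactly 0 are
excluded from top lists — padding selections with zero-influence TFs in
lexicographic order would be arbitrary.

Degree for the "generally important" TFs is counted on each time point's
`degree_top_k` strongest activating edges (default 10 000; small values for
toy data), because the raw scored network is fully connected and
unthresholded degree is constant.

## Numerical choices

* **Public simulation**: scipy's adaptive explicit Runge–Kutta (RK45),
  rtol = atol = 1e−6. States are reported unclipped; boundedness holds to
  solver tolerance.
* **Fitting and perturbation sweeps**: classical RK4 on a fixed grid that
  refines the data times to steps ≤ 0.25 days. The discretization is then a
  smooth deterministic function of the weights, gradients stay consistent
  with the simulated loss, and all 121 perturbation strengths integrate as
  one batched system (the p = 0 column is exactly the unperturbed
  trajectory, so z ≥ 0 holds identically).
* **Gradients**: forward sensitivity equations integrated jointly with the
  state (dS/dt = J_x S + J_W, S(0) = 0) with analytic Jacobians; central
  finite differences (step 1e−5) remain available via
  `FitConfig(gradient="fd")` and agree to ~1e−4 relative (unit-tested).
* **Optimizer**: ADAM (β₁ = 0.9, β₂ = 0.999), projection onto W ≥ 0 after
  every step, best-loss iterate returned. Stopping: 2000 steps or relative
  best-loss improvement < 1e−7 over 50 steps, checked only after 200 steps
  (the first iterations can climb before descending). Initialization is
  uniform on [0.1, 1.0], seeded.
* **Ties**: every top-k selection breaks ties lexicographically by
  (source, target); the maximizing perturbation p* prefers smallest |p|,
  then the positive sign (the mildest intervention).
* **Degenerate inputs**: constant genes scale to 0.5 (the scaling formula
  divides by zero there; the midpoint is sign-neutral); constant expression
  series sign as activating with a logged warning (r is undefined and
  repressive evidence is the weaker evidence class); a pair carries at most
  one signed edge — the correlation fixes the sign before selection.
* **L1 reporting**: fitted weights below 0.01 are reported as removed but
  kept in W; no hard threshold is applied to the dynamics.
* **L_av**: the grid-search criterion is L_av = L²/N as primary;
  L/N is also computed and exposed (`l_mean`) since the squared form is
  unusual and both are useful when comparing cells of similar N.

## Synthetic-data generator

The generator is the package's study design: every scenario fixes a
ground-truth signed network with weights W*, simulates the Hill model, and
fabricates all pipeline inputs consistently with that truth —

* expression: the simulated trajectory sampled at days (0, 2, 3, 4, 5, 9),
  plus truncated additive Gaussian noise (sd 0.02 on the scaled values),
  mapped into a plausible raw range by inverting the scaling formula with
  per-gene synthetic extremes;
* binding B: ~0.9 on true edges, ~0.1 elsewhere, Gaussian jitter (sd 0.05)
  — binding evidence co-located with true regulation;
* activity A: per time point, each TF's strongest outgoing true weight plus
  noise (sd 1.0), i.e. genuine regulators are genuinely active but measured
  activity fluctuates between time points;
* differential expression: log2 ratios of the noiseless trajectory versus
  the first day, with small adjusted p for |log2FC| > 0.25.

`random_sparse` emulates induced differentiation: a pair of pioneer TFs
starts high and decays (sustaining each other only weakly) while igniting
an activation wave through a densely ringed core whose high state locks in.
This design is deliberate: every gene traverses most of its dynamic range
within the horizon (so the per-gene scaling distorts shapes only mildly and
trajectory recovery is meaningful), sources lead their targets (so
correlation recovers edge signs), and every node keeps several activating
inputs (so one missed edge cannot cascade through pruning).
`dominant_driver` adds a pioneer-like driver whose pulse is the only
activation of two marker TFs; because the markers sag before the final day
and nothing else reaches them, only the driver's own perturbation can
re-lift them at t_N. `redundant_paths` gives two co-driven TFs parallel
edges onto one target with only one edge truly active. `bistable_toggle`
couples two mutually inhibiting TFs through a shared activating loop; the
builder verifies bistability by forward simulation from mirror states and
warns if the weights are monostable.

What the generator does *not* emulate: count noise, replicate structure,
batch effects, unmodelled confounding regulators, or binding matrices with
realistic false-positive structure. Passing tests therefore demonstrate
correctness of the algorithms under the stated evidence model, not
performance on real sequencing data.

## Problem sizes

The benchmarks run at 8 TFs × 6 time points (6 TFs for the grid search),
10 fit restarts, 200 random models for the boundedness study and 1000
random candidate sets for the assembly properties — sizes chosen so the
full suite completes in a few minutes on one CPU while still exercising
every stage at meaningful scale.

## Known limitations

* Edge signs rest on Pearson correlation of six samples; anti-phase
  activation (a falling activator of a rising target) is systematically
  mis-signed. The generator's induction design limits but does not remove
  this.
* Per-gene scaling onto [0.1, 0.9] amplifies low-variance genes; fitted
  input weights of genes whose sources are high at the gene's peak inflate
  toward S^n·0.9/(1−0.9) ≈ 9, which makes strong indirect routes compete
  with the capped direct perturbation (|p| ≤ 3) in the importance metric.
* W is generally non-identifiable from sparse time courses; only
  trajectory-level statements (and restart-aggregated rankings) are
  supported by the fit.
* The grid search reports L_av but does not enforce monotonicity in n_a;
  cell-to-cell comparison remains a modelling judgement.
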