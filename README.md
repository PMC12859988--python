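# tfdyn

Data-driven dynamic models of transcription-factor (TF) networks from
time-series multi-omics data. `tfdyn` is for computational biologists who
have, per time point, TF expression, genome-wide TF activity and TF-to-gene
binding probabilities (the outputs of enhancer-based GRN inference such as
ANANSE), plus a normalized expression time course — and who want a small
mechanistic ODE model that reproduces the expression dynamics and ranks TFs
by their predicted ability to drive a cell fate.

## The method

**1. Per-time-point interaction scores.** For each ordered TF pair (i, j)
at one time point, the activating interaction score is

    A_ij = ( S(E_i) + S(E_j) + S(A_i) + S(B_ij) ) / 4

where E is expression, A is genome-wide TF activity, B_ij the binding
probability of TF i near the gene of TF j, and S is min–max scaling onto
[0, 1] per quantity across the TF set. The inhibiting variant replaces
S(E_j) with 1 − S(E_j), preferring a lowly expressed target.

**2. TF selection and signed assembly.** TFs are selected by an influence
score computed on differential networks (interactions whose score increased
between the first and each later time point, compared in both directions)
plus the most densely connected TFs on average. Each pair is signed by the
Pearson correlation of source and target expression; per pair the maximum
mode-matched score over time points is the candidate score; the top `n_a`
activating and `n_i` inhibiting candidates are kept and nodes without an
incoming activating edge are pruned iteratively. Marker (output) TFs can be
injected afterwards with their top-2 incoming edges per sign.

**3. Hill-ODE dynamics.** On the assembled network each TF's scaled
expression x_i ∈ [0, 1] obeys

    τ ẋ_i = −x_i + ( Σ_{j∈V_act} W_ji x_j^n ) /
                   ( S^n + Σ_{j∈V_act} W_ji x_j^n + Σ_{j∈V_inh} W_ji x_j^n )

with S = 1, n = 3, τ = 1 by default. Trajectories started in [0, 1]^N stay
there for W ≥ 0.

**4. Sparse weight fitting.** Data are scaled gene-wise onto [0.1, 0.9] by
X = 4/(5(M−m))·(X̂−m) + 0.1 and the masked, nonnegative weights minimize

    L(W) = Σ_t Σ_i ( φ_i(t, W) − D_i(t) )² + C Σ |W_ij|,   C = 0.005

by ADAM (learning rate 0.1) with projection onto W ≥ 0; gradients come from
forward sensitivity equations on a fixed RK4 grid. A grid search over
(n_a, n_i) tabulates L_av = L²/N to pick a minimal network.

**5. Driver ranking.** A control input p ∈ {−3, −2.95, …, 3} is injected
into one TF's Hill term (p > 0 upregulates, p < 0 knocks down) and the
model is re-simulated over the data horizon. The importance of TF j for a
marker set T is

    z_j = max_p Σ_{i∈T} [ φ_i(t_N, p) − φ_i(t_N, 0) ] ≥ 0,

aggregated over repeated fits into mean, sd and top-rank frequency.

A first-class synthetic-data generator fabricates all inputs from known
ground-truth networks (four scenarios: `random_sparse`, `dominant_driver`,
`redundant_paths`, `bistable_toggle`), so the whole pipeline is testable
without any external data.

## Worked example

```sh
python examples/03_fit_dynamics.py
```

prints, for the noise-free 8-TF benchmark fitted with the true edge mask:

```
network      : 8 TFs, 28 weighted edges
final loss   : 0.4850 (data term 0.0628 + L1 penalty 0.4222)
L_av = L^2/N : 0.0294
trajectory RMSE at the sampled days: 0.0362
edges below the 0.01 reporting threshold: 10
```

The RMSE of 0.036 on the 0.1–0.9 scale means the fitted model reproduces
every gene's sampled trajectory to within a few percent of its dynamic
range; ten edges were effectively removed by the L1 penalty. The other
examples cover scoring (`01`), network assembly with ground-truth recovery
(`02`), driver ranking on the dominant-driver benchmark (`04`, the
designated driver ranks first with p* > 0 in every restart) and bistability
of the cross-inhibition motif (`05`).

The same stages are available as a CLI for shell use:

```sh
tfdyn --seed 5 --out-dir data  synth --scenario random_sparse
tfdyn --seed 5 --out-dir nets  assemble --input-dir data
tfdyn --seed 5 --out-dir fit   fit --network nets/network.tsv --series data/series.tsv
tfdyn --seed 5 --out-dir pert  perturb --input-dir data --network nets/network.tsv --targets auto
```

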