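"""Fit the Hill-ODE weight matrix to a noise-free synthetic time course.

Scales the expression data gene-wise onto [0.1, 0.9], optimizes the masked
nonnegative weights with ADAM under an L1 penalty, and reports the final
loss and the trajectory RMSE against the data.
"""

import numpy as np

from tfdyn import FitConfig, ScenarioSpec, fit, generate, scale_expression, simulate

dataset = generate(ScenarioSpec("random_sparse", noise_sd=0.0), seed=2)
network = dataset.scenario.network
scaled = scale_expression(dataset.series)

result = fit(network, scaled, FitConfig(C=0.005, learning_rate=0.1, rng_seed=0))

sub = scaled.subset(network.nodes)
traj = simulate(result.model(), sub.values[:, 0], sub.times)
rmse = float(np.sqrt(np.mean((traj.states - sub.values) ** 2)))

print(f"network      : {result.n_nodes} TFs, {len(result.edges)} weighted edges")
print(f"final loss   : {result.final_loss:.4f} "
      f"(data term {result.data_loss:.4f} + L1 penalty {result.penalty:.4f})")
print(f"L_av = L^2/N : {result.l_av:.4f}")
print(f"trajectory RMSE at the sampled days: {rmse:.4f}")
print(f"edges below the 0.01 reporting threshold: {len(result.removed_edges())}")
print()
print("An RMSE well under 0.05 on the 0.1-0.9 scale means the fitted model")
print("reproduces every gene's sampled trajectory almost exactly.")
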