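"""Demonstrate bistability of a cross-inhibition motif under steep Hill kinetics.

Builds the toggle scenario (two mutually inhibiting TFs over a shared
activating loop) and simulates it from two mirror-image initial states: with
Hill coefficient n = 3 the trajectories settle into two distinct stable
states, the dynamical signature of a cell-fate switch.
"""

import numpy as np

from tfdyn import ScenarioSpec, simulate
from tfdyn.synth import _bistable_toggle

for n in (3.0, 1.0):
    scenario = _bistable_toggle(ScenarioSpec("bistable_toggle", hill_n=n),
                                np.random.default_rng(0))
    model = scenario.model()
    a = simulate(model, np.array([0.5, 0.9, 0.1]), [0.0, 80.0]).final_state()
    b = simulate(model, np.array([0.5, 0.1, 0.9]), [0.0, 80.0]).final_state()
    sep = float(np.max(np.abs(a - b)))
    print(f"Hill n = {n:g}")
    fmt = lambda state: ", ".join(f"{n}={v:.3f}" for n, v in zip(model.nodes, state))
    print(f"  from XA-high start -> {fmt(a)}")
    print(f"  from XB-high start -> {fmt(b)}")
    print(f"  steady-state separation {sep:.3f} -> "
          f"{'bistable' if sep > 0.3 else 'monostable'}")
    print()

print("With n = 3 the steep sigmoid lets the winning TF suppress its rival")
print("(two attractors); at n = 1 the same weights give a single steady state.")
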