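"""Score one multi-omics snapshot into TF-TF interaction matrices.

Builds a three-TF snapshot by hand (expression, genome-wide activity,
binding probabilities), computes the activating and inhibiting interaction
scores, and prints both dense matrices.
"""

import numpy as np

from tfdyn import ACTIVATING, INHIBITING, OmicsSnapshot, score_snapshot

snapshot = OmicsSnapshot(
    time_label=0.0,
    expression={"SOX9": 2.0, "RXRA": 4.0, "USF2": 6.0},
    activity={"SOX9": 1.0, "RXRA": 3.0, "USF2": 2.0},
    binding={
        ("SOX9", "RXRA"): 0.9, ("SOX9", "USF2"): 0.2,
        ("RXRA", "SOX9"): 0.5, ("RXRA", "USF2"): 0.7,
        ("USF2", "SOX9"): 0.1, ("USF2", "RXRA"): 0.4,
    },
)

for mode in (ACTIVATING, INHIBITING):
    net = score_snapshot(snapshot, mode)
    print(f"{mode} interaction scores (rows = source TF, cols = target TF)")
    print("      " + "  ".join(f"{n:>6s}" for n in net.nodes))
    for i, src in enumerate(net.nodes):
        print(f"{src:>6s} " + "  ".join(f"{v:6.3f}" for v in net.scores[i]))
    print()

print("Each entry averages four unit-scaled evidence terms: source expression,")
print("target expression (inverted for the inhibiting mode), source activity")
print("and binding probability; 1.0 means maximal evidence on all four.")
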