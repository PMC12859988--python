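"""Ground-truth scenario generator for end-to-end testing of the pipeline.

Each scenario fixes a known signed TF network with true weights W*, then
fabricates every input the pipeline consumes, consistently with that truth:

* expression time series: the Hill-ODE model simulated from a chosen initial
  state, sampled at a few experiment days, optionally perturbed by additive
  Gaussian noise on the scaled values and mapped into a plausible raw
  expression range by inverting the model's scaling formula;
* per-time-point snapshots: E from the trajectory, genome-wide activity A
  proportional to each TF's outgoing weight mass (plus noise), and binding
  probabilities B that are high (~0.9) on true edges and low (~0.1)
  elsewhere, jittered -- binding evidence co-located with true regulation;
* differential-expression tables computed from the noiseless trajectory
  (log2 ratios versus the first time point, small adjusted p for fold
  changes above a threshold).

Scenarios:

``random_sparse``
    A decaying pioneer pair ignites an activation wave through a densely
    ringed TF core, plus random extra signed edges; the generic network- and
    trajectory-recovery benchmark.
``dominant_driver``
    A pioneer-like driver whose pulse is the sole upstream activation of the
    marker TFs; the driver must come out on top of the importance ranking.
``redundant_paths``
    Two co-driven TFs both offer an edge onto the same target but only one
    edge carries true weight; the L1 penalty should silence the spare one.
``bistable_toggle``
    Two mutually inhibiting TFs over a shared activating loop; with a steep
    Hill coefficient (n = 3) the system is bistable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    ACTIVATING,
    INHIBITING,
    DifferentialExpression,
    Edge,
    ExpressionSeries,
    OmicsSnapshot,
    SignedNetwork,
    ValidationError,
)
from .dynamics import DynamicModel, simulate
from .io import log_stage, logger

__all__ = [
    "ScenarioSpec",
    "Scenario",
    "SyntheticDataset",
    "build_scenario",
    "generate",
    "backward_de",
]

SCENARIO_NAMES = ("random_sparse", "dominant_driver", "redundant_paths",
                  "bistable_toggle")


@dataclass
class ScenarioSpec:
    """Study conditions for one synthetic scenario.

    Defaults emulate a short differentiation time course: six sampling days
    spread over nine days, mild measurement noise on scaled expression
    (sd 0.02), strong binding contrast between true edges (~0.9) and
    non-edges (~0.1) with jitter, and per-time-point activity that tracks
    each TF's strongest outgoing regulation with experiment-scale
    variability.
    """

    name: str = "random_sparse"
    n_tfs: int = 8
    times: tuple[float, ...] = (0.0, 2.0, 3.0, 4.0, 5.0, 9.0)
    noise_sd: float = 0.02
    binding_high: float = 0.9
    binding_low: float = 0.1
    binding_jitter_sd: float = 0.05
    activity_noise_sd: float = 1.0
    de_lfc_threshold: float = 0.25
    hill_S: float = 1.0
    hill_n: float = 3.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValidationError(f"unknown scenario {self.name!r}")
        if len(self.times) < 3:
            raise ValidationError("scenarios need at least three sampled times")
        if self.n_tfs < 4:
            raise ValidationError("scenarios need at least four TFs")


@dataclass
class Scenario:
    """A ground-truth network with weights, initial state and annotations."""

    spec: ScenarioSpec
    network: SignedNetwork
    W: np.ndarray
    x0: np.ndarray
    markers: list[str] = field(default_factory=list)
    driver: str | None = None
    redundant_edges: list[tuple[str, str]] = field(default_factory=list)
    bistable: bool | None = None

    def model(self) -> DynamicModel:
        return DynamicModel(self.network, self.W, self.spec.hill_S,
                            self.spec.hill_n, self.spec.tau)

    def true_edge_pairs(self) -> set[tuple[str, str]]:
        """Edges carrying true weight (> 0)."""
        idx = {tf: k for k, tf in enumerate(self.network.nodes)}
        return {(e.source, e.target) for e in self.network.edges
                if self.W[idx[e.target], idx[e.source]] > 0}


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, plus the generating truth."""

    scenario: Scenario
    snapshots: list[OmicsSnapshot]
    series: ExpressionSeries            # raw (inverse-scaled) expression
    scaled_truth: ExpressionSeries      # noiseless scaled trajectory
    de_forward: list[DifferentialExpression]

    @property
    def de_backward(self) -> list[DifferentialExpression]:
        return [backward_de(de) for de in self.de_forward]


def backward_de(de: DifferentialExpression) -> DifferentialExpression:
    """The reversed comparison: fold changes negate, significance persists."""
    return DifferentialExpression(
        (de.comparison[1], de.comparison[0]),
        {g: -v for g, v in de.log2fc.items()},
        dict(de.padj),
    )


def _names(n: int, prefix: str = "T") -> list[str]:
    return [f"{prefix}{k + 1:02d}" for k in range(n)]


def _weights_on(edges: list[Edge], nodes: list[str],
                values: dict[tuple[str, str], float]) -> np.ndarray:
    idx = {tf: k for k, tf in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for e in edges:
        W[idx[e.target], idx[e.source]] = values[(e.source, e.target)]
    return W


def _random_sparse(spec: ScenarioSpec, rng: np.random.Generator) -> Scenario:
    """Pioneer-induced activation wave through a densely ringed TF core.

    One pioneer TF starts high (the pre-differentiation state) and decays
    while strongly activating two ring TFs; the induced high state then
    spreads through a triple-stride activating ring and locks in. Every gene
    thus traverses nearly its full dynamic range within the sampled horizon,
    sources lead their targets (correlation recovers signs), and every node
    keeps multiple activating inputs (pruning cannot cascade off one missed
    edge).
    """
    nodes = _names(spec.n_tfs)
    pioneers, ring = nodes[:2], nodes[2:]
    n_ring = len(ring)
    edges: dict[tuple[str, str], str] = {}
    weights: dict[tuple[str, str], float] = {}
    for stride in (1, 2, n_ring - 1):
        for k in range(n_ring):
            src, tgt = ring[k], ring[(k + stride) % n_ring]
            if src != tgt and (src, tgt) not in edges:
                edges[(src, tgt)] = ACTIVATING
                weights[(src, tgt)] = float(rng.uniform(5.5, 6.5))
    # the two pioneers sustain each other only weakly (they co-decay, so
    # correlation signing keeps their mutual activating edges); the first
    # ignites three adjacent ring TFs and receives a weak input back
    p1, p2 = pioneers
    edges[(p1, p2)] = ACTIVATING
    edges[(p2, p1)] = ACTIVATING
    weights[(p1, p2)] = weights[(p2, p1)] = float(rng.uniform(1.2, 1.8))
    stim = int(rng.integers(0, n_ring))
    for tgt in (ring[stim], ring[(stim + 1) % n_ring], ring[(stim + 2) % n_ring]):
        edges[(p1, tgt)] = ACTIVATING
        weights[(p1, tgt)] = float(rng.uniform(9.0, 11.0))
    back = ring[int(rng.integers(0, n_ring))]
    edges[(back, p1)] = ACTIVATING
    weights[(back, p1)] = float(rng.uniform(0.15, 0.25))
    # extra random edges among ring TFs, ~70% activating
    n_extra = spec.n_tfs // 2
    attempts = 0
    while n_extra > 0 and attempts < 200:
        attempts += 1
        i, j = rng.integers(0, n_ring, size=2)
        if i == j or (ring[i], ring[j]) in edges:
            continue
        sign = ACTIVATING if rng.random() < 0.7 else INHIBITING
        edges[(ring[i], ring[j])] = sign
        weights[(ring[i], ring[j])] = float(rng.uniform(1.0, 2.0))
        n_extra -= 1
    edge_objs = [Edge(s, t, sign, 1.0) for (s, t), sign in sorted(edges.items())]
    net = SignedNetwork(nodes, edge_objs)
    W = _weights_on(edge_objs, nodes, weights)
    x0 = np.concatenate([rng.uniform(0.8, 0.9, size=2),
                         rng.uniform(0.02, 0.08, size=n_ring)])
    return Scenario(spec, net, W, x0)


def _dominant_driver(spec: ScenarioSpec, rng: np.random.Generator) -> Scenario:
    """A pioneer-like driver whose pulse is the markers' only activation.

    The driver starts high and decays (its only input is a weak back edge),
    so the marker TFs it solely activates pulse and sag before the final
    sampled time. Re-lifting the sagged markers at the end of the horizon is
    then possible only by re-lifting the driver, which only its own direct
    perturbation can do: the support wave never touches the markers, and the
    driver's upstream input is genuinely weak. This makes the driver the
    uniquely top-ranked TF for the marker target set.
    """
    n_support = max(4, spec.n_tfs - 3)
    support = _names(n_support, "A")
    pioneer, ring = support[0], support[1:]
    driver, markers = "DRV", ["MK1", "MK2"]
    nodes = sorted(support + [driver] + markers)
    edges = []
    weights: dict[tuple[str, str], float] = {}

    def add(src, tgt, sign, w):
        edges.append(Edge(src, tgt, sign, 1.0))
        weights[(src, tgt)] = float(w)

    n_ring = len(ring)
    for stride in (1, 2):  # dense activating ring among support TFs
        for k in range(n_ring):
            src, tgt = ring[k], ring[(k + stride) % n_ring]
            if src != tgt and (src, tgt) not in weights:
                add(src, tgt, ACTIVATING, rng.uniform(5.5, 6.5))
    for tgt in ring[:3]:  # the support pioneer ignites its own wave
        add(pioneer, tgt, ACTIVATING, rng.uniform(9.0, 11.0))
    add(ring[0], pioneer, ACTIVATING, rng.uniform(0.15, 0.25))
    # driver: starts high, weak input, sole upstream activator of T
    add(ring[1], driver, ACTIVATING, rng.uniform(0.15, 0.25))
    for mk in markers:
        add(driver, mk, ACTIVATING, rng.uniform(5.0, 6.0))
    edges = sorted(edges, key=lambda e: (e.source, e.target))
    net = SignedNetwork(nodes, edges, set(markers))
    W = _weights_on(edges, nodes, weights)
    x0 = np.zeros(len(nodes))
    for k, tf in enumerate(nodes):
        if tf in markers:
            x0[k] = float(rng.uniform(0.05, 0.1))
        elif tf == driver or tf == pioneer:
            x0[k] = float(rng.uniform(0.8, 0.9))
        else:
            x0[k] = float(rng.uniform(0.02, 0.08))
    return Scenario(spec, net, W, x0, markers=markers, driver=driver)


def _redundant_paths(spec: ScenarioSpec, rng: np.random.Generator) -> Scenario:
    nodes = ["A1", "A2", "CC", "SS"]
    edges = [
        Edge("SS", "A1", ACTIVATING, 1.0),
        Edge("SS", "A2", ACTIVATING, 1.0),
        Edge("A1", "CC", ACTIVATING, 1.0),
        Edge("A2", "CC", ACTIVATING, 1.0),   # redundant: true weight 0
        Edge("CC", "SS", ACTIVATING, 1.0),
    ]
    weights = {("SS", "A1"): 4.0, ("SS", "A2"): 2.5, ("A1", "CC"): 4.0,
               ("A2", "CC"): 0.0, ("CC", "SS"): 4.0}
    edges = sorted(edges, key=lambda e: (e.source, e.target))
    net = SignedNetwork(nodes, edges)
    W = _weights_on(edges, nodes, weights)
    x0 = np.array([0.2, 0.5, 0.3, 0.8])  # A1, A2, CC, SS
    return Scenario(spec, net, W, x0, redundant_edges=[("A2", "CC")])


def _bistable_toggle(spec: ScenarioSpec, rng: np.random.Generator,
                     cross_inhibition: float = 40.0,
                     support_weight: float = 10.0) -> Scenario:
    """Mutual inhibition between XA and XB over a shared activating loop.

    A common upstream TF UU activates both competitors and is activated by
    them in return (the cycle keeps every node pruning-consistent). With the
    default steep Hill coefficient (n = 3) and strong cross-inhibition the
    winner shuts its rival down and two mirror-image steady states coexist;
    without cross-inhibition (or with n = 1) both competitors settle into
    the same state.
    """
    nodes = ["UU", "XA", "XB"]
    edges = [
        Edge("UU", "XA", ACTIVATING, 1.0), Edge("UU", "XB", ACTIVATING, 1.0),
        Edge("XA", "UU", ACTIVATING, 1.0), Edge("XB", "UU", ACTIVATING, 1.0),
    ]
    weights = {("UU", "XA"): support_weight, ("UU", "XB"): support_weight,
               ("XA", "UU"): support_weight, ("XB", "UU"): support_weight}
    if cross_inhibition > 0:
        edges += [Edge("XA", "XB", INHIBITING, 1.0),
                  Edge("XB", "XA", INHIBITING, 1.0)]
        weights[("XA", "XB")] = cross_inhibition
        weights[("XB", "XA")] = cross_inhibition
    edges = sorted(edges, key=lambda e: (e.source, e.target))
    net = SignedNetwork(nodes, edges)
    W = _weights_on(edges, nodes, weights)
    x0 = np.array([0.6, 0.9, 0.1])  # UU, XA, XB: the A-dominant branch
    scenario = Scenario(spec, net, W, x0)
    scenario.bistable = _check_bistable(scenario)
    if not scenario.bistable:
        logger.warning(
            "toggle weights outside the bistable regime; emitting monostable scenario"
        )
    return scenario


def _check_bistable(scenario: Scenario, horizon: float = 80.0,
                    separation: float = 0.3) -> bool:
    """Mirror-image initial states must settle > ``separation`` apart."""
    model = scenario.model()
    n = len(model.nodes)
    ia = model.node_index("XA")
    ib = model.node_index("XB")
    xa = np.full(n, 0.5); xa[ia], xa[ib] = 0.9, 0.1
    xb = np.full(n, 0.5); xb[ia], xb[ib] = 0.1, 0.9
    t_eval = [0.0, horizon]
    sa = simulate(model, xa, t_eval).final_state()
    sb = simulate(model, xb, t_eval).final_state()
    return bool(np.max(np.abs(sa - sb)) > separation)


def build_scenario(spec: ScenarioSpec, rng: np.random.Generator) -> Scenario:
    builder = {
        "random_sparse": _random_sparse,
        "dominant_driver": _dominant_driver,
        "redundant_paths": _redundant_paths,
        "bistable_toggle": _bistable_toggle,
    }[spec.name]
    scenario = builder(spec, rng)
    # pruning consistency: every node must have an incoming activating edge
    unsupported = [n for n in scenario.network.nodes
                   if not scenario.network.incoming(n, ACTIVATING)]
    if unsupported:
        raise ValidationError(f"scenario nodes without activating input: {unsupported}")
    return scenario


def generate(spec: ScenarioSpec, seed: int = 0) -> SyntheticDataset:
    """Fabricate a complete, reproducible input set from one scenario spec."""
    rng = np.random.default_rng(seed)
    scenario = build_scenario(spec, rng)
    model = scenario.model()
    nodes = scenario.network.nodes
    times = np.asarray(spec.times, dtype=float)

    traj = simulate(model, scenario.x0, times)
    clean = np.clip(traj.states, 0.0, 1.0)          # (N, T) scaled expression
    noisy = clean if spec.noise_sd == 0 else np.clip(
        clean + rng.normal(0.0, spec.noise_sd, size=clean.shape), 0.0, 1.0
    )

    # invert the data-scaling formula with synthetic per-gene raw extremes;
    # spans are comparable across genes so that cross-TF scaling of raw
    # expression reflects relative state rather than arbitrary units
    m_raw = rng.uniform(2.8, 3.2, size=len(nodes))
    span_raw = rng.uniform(4.5, 5.5, size=len(nodes))
    def to_raw(x: np.ndarray) -> np.ndarray:
        return (x - 0.1) * (5.0 * span_raw[:, None] / 4.0) + m_raw[:, None]
    raw = to_raw(noisy)
    raw_clean = to_raw(clean)

    series = ExpressionSeries(times, list(nodes), raw)
    scaled_truth = ExpressionSeries(times, list(nodes), clean)

    # binding: high on true edges, low elsewhere; static across time
    edge_pairs = {(e.source, e.target) for e in scenario.network.edges}
    binding: dict[tuple[str, str], float] = {}
    for i in nodes:
        for j in nodes:
            if i == j:
                continue
            base = spec.binding_high if (i, j) in edge_pairs else spec.binding_low
            binding[(i, j)] = float(np.clip(
                base + rng.normal(0.0, spec.binding_jitter_sd), 0.0, 1.0))

    # activity tracks the strongest true outgoing regulation of each TF:
    # a TF that genuinely drives targets is genuinely "active"
    out_strength = scenario.W.max(axis=0)
    snapshots = []
    for k, t in enumerate(times):
        activity = {
            tf: float(max(out_strength[i]
                          + rng.normal(0.0, spec.activity_noise_sd), 1e-3))
            for i, tf in enumerate(nodes)
        }
        expression = {tf: float(raw[i, k]) for i, tf in enumerate(nodes)}
        snapshots.append(OmicsSnapshot(float(t), expression, activity, dict(binding)))

    # DE versus the first time point, from the noiseless trajectory
    de_forward = []
    for k in range(1, times.size):
        lfc = {tf: float(np.log2(raw_clean[i, k] / raw_clean[i, 0]))
               for i, tf in enumerate(nodes)}
        padj = {tf: (1e-6 if abs(v) > spec.de_lfc_threshold else 0.5)
                for tf, v in lfc.items()}
        de_forward.append(DifferentialExpression((times[0], float(times[k])),
                                                 lfc, padj))

    log_stage("generate", scenario=spec.name, tfs=len(nodes),
              times=times.size, noise_sd=spec.noise_sd, seed=seed)
    return SyntheticDataset(scenario, snapshots, series, scaled_truth, de_forward)
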