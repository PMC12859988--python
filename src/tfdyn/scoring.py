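"""Per-time-point TF-TF interaction scores and between-time-point influence.

Each snapshot yields a fully connected scored network. For an activating
interaction of TF i on target j the score is the mean of four unit-scaled
evidence terms,

    A_ij = (S(E_i) + S(E_j) + S(A_i) + S(B_ij)) / 4,

where E is expression, A is genome-wide TF activity and B is the binding
probability of i near j. The inhibiting variant prefers a lowly expressed
target and replaces S(E_j) with 1 - S(E_j). S is min-max scaling per
quantity across the snapshot's TF set.

Influence scoring compares two time points: only interactions whose score
increased enter the differential network, and a TF is influential when
significantly upregulated genes sit close to it (shortest-path distance) in
that network. The exact influence formula used by upstream GRN-inference
tooling is not fixed here; this module uses an explicit, configurable
approximation: contributions decay by half per extra edge of distance,
negative fold changes are clipped, and a significance gate is applied.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .datatypes import (
    ACTIVATING,
    INHIBITING,
    DifferentialExpression,
    InfluenceRanking,
    OmicsSnapshot,
    PipelineConfig,
    ScoredNetwork,
    TFSelection,
    ValidationError,
)
from .io import log_stage

__all__ = [
    "unit_scale",
    "activating_score",
    "inhibiting_score",
    "score_snapshot",
    "differential_network",
    "influence",
    "select_tfs",
]


def unit_scale(values: np.ndarray) -> np.ndarray:
    """Affinely map a vector onto [0, 1]; a constant vector maps to zeros."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot unit-scale an empty vector")
    if not np.all(np.isfinite(values)):
        raise ValidationError("cannot unit-scale non-finite values")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def _check_unit(name: str, *vals: float) -> None:
    for v in vals:
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name} inputs must lie in [0, 1], got {v}")


def activating_score(s_e_i: float, s_e_j: float, s_a_i: float, s_b_ij: float) -> float:
    """Mean of the four unit-scaled evidence terms."""
    _check_unit("activating_score", s_e_i, s_e_j, s_a_i, s_b_ij)
    return (s_e_i + s_e_j + s_a_i + s_b_ij) / 4.0


def inhibiting_score(s_e_i: float, s_e_j: float, s_a_i: float, s_b_ij: float) -> float:
    """As activating, but a lowly expressed target raises the score."""
    _check_unit("inhibiting_score", s_e_i, s_e_j, s_a_i, s_b_ij)
    return (s_e_i + (1.0 - s_e_j) + s_a_i + s_b_ij) / 4.0


def score_snapshot(snapshot: OmicsSnapshot, mode: str = ACTIVATING) -> ScoredNetwork:
    """Dense interaction scores for every ordered TF pair of one snapshot.

    Expression, activity and binding are each min-max scaled across the
    snapshot's TF set before entering the score formula. Diagonal (self)
    entries are computed like any other pair; downstream selection excludes
    them.
    """
    if mode not in (ACTIVATING, INHIBITING):
        raise ValidationError(f"unknown scoring mode {mode!r}")
    tfs = snapshot.tfs
    if len(tfs) < 2:
        raise ValidationError("scoring needs at least two TFs")
    s_e = unit_scale(np.array([snapshot.expression[t] for t in tfs]))
    s_a = unit_scale(np.array([snapshot.activity[t] for t in tfs]))
    b = np.array([[snapshot.binding_value(i, j) for j in tfs] for i in tfs])
    s_b = unit_scale(b.ravel()).reshape(b.shape)

    e_j = s_e[None, :] if mode == ACTIVATING else 1.0 - s_e[None, :]
    scores = (s_e[:, None] + e_j + s_a[:, None] + s_b) / 4.0
    return ScoredNetwork(snapshot.time_label, tfs, scores, mode)


def differential_network(net_from: ScoredNetwork, net_to: ScoredNetwork) -> nx.DiGraph:
    """Directed graph of interactions whose score increased from -> to.

    Edge weight is the (strictly positive) score increase.
    """
    if net_from.nodes != net_to.nodes:
        raise ValidationError("differential network requires identical node sets")
    g = nx.DiGraph()
    g.add_nodes_from(net_from.nodes)
    delta = net_to.scores - net_from.scores
    rows, cols = np.where(delta > 0)
    for i, j in zip(rows, cols):
        if i != j:
            g.add_edge(net_from.nodes[i], net_from.nodes[j], weight=float(delta[i, j]))
    return g


def influence(
    diff_net: nx.DiGraph,
    de: DifferentialExpression,
    max_depth: int = 2,
    alpha: float = 0.05,
    direction: str = "forward",
) -> InfluenceRanking:
    """Rank TFs by significant upregulation close to them in the differential net.

    influence(i) = sum over genes g != i within ``max_depth`` directed edges
    of (1/2)^(d(i,g)-1) * max(0, log2fc_g) * 1[padj_g < alpha], with d the
    shortest-path edge count. Genes missing from the DE table contribute 0.
    """
    if max_depth < 1:
        raise ValidationError("max_depth must be >= 1")
    if not (0 < alpha <= 1):
        raise ValidationError("alpha must lie in (0, 1]")
    scores: dict[str, float] = {}
    for tf in diff_net.nodes:
        total = 0.0
        dists = nx.single_source_shortest_path_length(diff_net, tf, cutoff=max_depth)
        for gene, d in dists.items():
            if gene == tf or d < 1:
                continue
            lfc = de.log2fc.get(gene, 0.0)
            if lfc > 0 and de.padj.get(gene, 1.0) < alpha:
                total += 0.5 ** (d - 1) * lfc
        scores[tf] = total
    return InfluenceRanking(de.comparison, direction, scores)


def _average_degree(scored_nets: list[ScoredNetwork], top_k: int,
                    allow_self: bool = False) -> dict[str, float]:
    """Mean per-TF degree over time points, counted on top-k edges by score."""
    counts: dict[str, float] = {tf: 0.0 for tf in scored_nets[0].nodes}
    for net in scored_nets:
        pairs = []
        for i, src in enumerate(net.nodes):
            for j, tgt in enumerate(net.nodes):
                if i == j and not allow_self:
                    continue
                pairs.append((-net.scores[i, j], src, tgt))
        pairs.sort()
        for _, src, tgt in pairs[:top_k]:
            counts[src] = counts.get(src, 0.0) + 1
            counts[tgt] = counts.get(tgt, 0.0) + 1
    n = len(scored_nets)
    return {tf: c / n for tf, c in counts.items()}


def select_tfs(
    influence_rankings: list[InfluenceRanking],
    scored_nets: list[ScoredNetwork],
    config: PipelineConfig,
) -> TFSelection:
    """Union of per-comparison influence top lists and globally connected TFs.

    Per comparison (and direction) the ``n_top_influence`` highest-influence
    TFs are kept; additionally the ``n_general`` TFs with the highest degree
    averaged over time points (degree counted on each time point's
    ``degree_top_k`` strongest activating edges) are kept. Duplicates are
    removed.
    """
    if not influence_rankings:
        raise ValidationError("at least one influence ranking is required")
    if not scored_nets:
        raise ValidationError("at least one scored network is required")
    per_comparison = {
        (r.comparison[0], r.comparison[1], r.direction): r.top(config.n_top_influence)
        for r in influence_rankings
    }
    activating_nets = [n for n in scored_nets if n.mode == ACTIVATING]
    degrees = _average_degree(activating_nets or scored_nets, config.degree_top_k,
                              config.allow_self_edges)
    general = [tf for tf, _ in sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))
               [: config.n_general]]
    sel = TFSelection(per_comparison, general)
    log_stage("select_tfs", comparisons=len(per_comparison),
              general=len(general), union=len(sel.union))
    return sel
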