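"""Assemble one signed, sparse TF network from per-time-point score matrices.

Every ordered TF pair is first signed by the Pearson correlation of the two
TFs' expression time courses (non-negative correlation -> activating). Each
pair's candidate score is the maximum over time points of the mode-matched
interaction score. The top n_a activating and top n_i inhibiting candidates
are kept, then nodes without any incoming activating edge are removed
iteratively (with their incident edges) until a fixed point. Marker (output)
TFs can be injected afterwards with their strongest incoming edges; they are
never pruned.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    ACTIVATING,
    INHIBITING,
    Edge,
    InfluenceRanking,
    ScoredNetwork,
    SignedNetwork,
    TFSelection,
    ValidationError,
)
from .io import log_stage, logger

__all__ = [
    "AssemblyError",
    "sign_edge",
    "sign_all_pairs",
    "max_over_time_scores",
    "assemble",
    "add_marker",
    "select_markers_data_driven",
]


class AssemblyError(ValidationError):
    """Network assembly cannot produce a valid network."""


def sign_edge(expr_source: np.ndarray, expr_target: np.ndarray) -> str:
    """Sign a pair by Pearson correlation of source and target expression.

    Non-negative correlation gives an activating edge. Degenerate (constant)
    series leave r undefined; the pair defaults to activating with a warning,
    since repressive evidence is weaker than activating evidence to begin
    with.
    """
    x = np.asarray(expr_source, dtype=float)
    y = np.asarray(expr_target, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("sign_edge needs two equal-length series of >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant expression series; defaulting edge sign to activating")
        return ACTIVATING
    r = np.corrcoef(x, y)[0, 1]
    return ACTIVATING if r >= 0 else INHIBITING


def sign_all_pairs(expression: dict[str, np.ndarray]) -> dict[tuple[str, str], str]:
    """Edge sign for every ordered pair of distinct TFs."""
    tfs = sorted(expression)
    signs: dict[tuple[str, str], str] = {}
    for i in tfs:
        for j in tfs:
            if i != j:
                signs[(i, j)] = sign_edge(expression[i], expression[j])
    return signs


def max_over_time_scores(
    scored_nets: dict[str, list[ScoredNetwork]],
    signs: dict[tuple[str, str], str],
) -> list[Edge]:
    """Per-pair candidate = max over time of the sign-matched interaction score.

    ``scored_nets`` maps mode -> per-time-point networks of that mode; a pair
    signed activating draws its scores from the activating-formula networks
    and vice versa.
    """
    for mode in (ACTIVATING, INHIBITING):
        nets = scored_nets.get(mode, [])
        if not nets:
            raise ValidationError(f"no scored networks for mode {mode!r}")
        nodes0 = nets[0].nodes
        for net in nets:
            if net.nodes != nodes0:
                raise ValidationError("node sets differ across time points")
    candidates = []
    for (i, j), sign in sorted(signs.items()):
        nets = scored_nets[sign]
        idx_i = nets[0].nodes.index(i)
        idx_j = nets[0].nodes.index(j)
        best = max(net.scores[idx_i, idx_j] for net in nets)
        candidates.append(Edge(i, j, sign, float(best)))
    return candidates


def _prune(nodes: set[str], edges: list[Edge],
           exempt: set[str] | None = None) -> tuple[set[str], list[Edge]]:
    """Iteratively drop nodes lacking incoming activating edges (cascade)."""
    exempt = exempt or set()
    while True:
        supported = {e.target for e in edges if e.sign == ACTIVATING and e.source in nodes}
        keep = {n for n in nodes if n in supported or n in exempt}
        if keep == nodes:
            return nodes, [e for e in edges if e.source in nodes and e.target in nodes]
        nodes = keep
        edges = [e for e in edges if e.source in nodes and e.target in nodes]


def _top_edges(candidates: list[Edge], sign: str, k: int) -> list[Edge]:
    pool = [e for e in candidates if e.sign == sign]
    pool.sort(key=lambda e: (-e.score, e.source, e.target))
    return pool[:k]


def assemble(
    candidates: list[Edge],
    tf_selection: TFSelection | list[str],
    n_a: int,
    n_i: int,
) -> SignedNetwork:
    """Build the signed network from edge candidates among the selected TFs.

    Takes the top ``n_a`` activating and top ``n_i`` inhibiting candidates by
    score (ties broken lexicographically by source then target id), then
    prunes nodes without incoming activating edges to a fixed point. Raises
    if pruning empties the network.
    """
    if n_a < 1 or n_i < 1:
        raise ValidationError("n_a and n_i must be >= 1")
    selected = set(tf_selection.union if isinstance(tf_selection, TFSelection)
                   else tf_selection)
    pool = [e for e in candidates
            if e.source in selected and e.target in selected and e.source != e.target]
    chosen = _top_edges(pool, ACTIVATING, n_a) + _top_edges(pool, INHIBITING, n_i)
    nodes, edges = _prune(set(selected), chosen)
    if not nodes:
        raise AssemblyError(
            "pruning removed every node; increase n_a to retain more activating edges"
        )
    net = SignedNetwork(sorted(nodes), sorted(edges, key=lambda e: (e.source, e.target)))
    log_stage("assemble", n_a=n_a, n_i=n_i, nodes=len(net.nodes), edges=len(net.edges))
    return net


def add_marker(network: SignedNetwork, tf_id: str,
               candidates: list[Edge]) -> SignedNetwork:
    """Add an output/marker TF with its strongest incoming edges.

    The marker's top two activating and top two inhibiting incoming
    candidates from the network's core (non-marker) nodes are injected (ties
    lexicographic by source), so injecting several markers gives the same
    edge set in any order. No pruning is re-run: markers are exempt from the
    incoming-activating requirement check but must have at least one
    activating candidate.
    """
    if tf_id in network.nodes:
        return SignedNetwork(list(network.nodes), list(network.edges),
                             set(network.marker_nodes) | {tf_id})
    node_set = set(network.nodes) - set(network.marker_nodes)
    incoming = [e for e in candidates
                if e.target == tf_id and e.source in node_set and e.source != tf_id]
    act = _top_edges(incoming, ACTIVATING, 2)
    inh = _top_edges(incoming, INHIBITING, 2)
    if not act:
        raise AssemblyError(f"marker {tf_id!r} has no incoming activating candidate")
    return SignedNetwork(
        sorted(network.nodes + [tf_id]),
        sorted(network.edges + act + inh, key=lambda e: (e.source, e.target)),
        set(network.marker_nodes) | {tf_id},
    )


def select_markers_data_driven(
    influence_rankings: list[InfluenceRanking], k: int, n_top: int = 5
) -> list[str]:
    """Markers = TFs recurring most often in forward influence top lists.

    TFs are ranked by how many forward comparisons place them in the top
    ``n_top`` by influence; the ``k`` most recurrent are returned, ties
    lexicographic.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    forward = [r for r in influence_rankings if r.direction == "forward"]
    if not forward:
        raise ValidationError("no forward influence rankings available")
    counts: dict[str, int] = {}
    for r in forward:
        for tf in r.top(n_top):
            counts[tf] = counts.get(tf, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [tf for tf, _ in ranked[:k]]
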