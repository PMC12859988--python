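"""End-to-end orchestration: snapshots -> signed network -> fits -> ranking.

Thin glue over the stage modules so the CLI and scripted analyses share one
code path. Influence comparisons follow the study design: each later time
point is compared against the first, in both directions, on the
activating-formula networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import add_marker, assemble, max_over_time_scores, sign_all_pairs
from .datatypes import (
    ACTIVATING,
    INHIBITING,
    DifferentialExpression,
    Edge,
    ExpressionSeries,
    InfluenceRanking,
    OmicsSnapshot,
    PipelineConfig,
    ScoredNetwork,
    SignedNetwork,
    TFSelection,
)
from .dynamics import DynamicModel, scale_expression
from .fitting import FitConfig, FitResult, fit
from .perturbation import ImportanceReport, TargetSet, rank_tfs
from .synth import backward_de

__all__ = ["NetworkBuild", "run_network_construction", "fit_restarts",
           "fit_and_rank"]


@dataclass
class NetworkBuild:
    """Everything produced while constructing the signed network."""

    network: SignedNetwork
    selection: TFSelection
    rankings: list[InfluenceRanking]
    candidates: list[Edge]
    scored_activating: list[ScoredNetwork]
    scored_inhibiting: list[ScoredNetwork]


def run_network_construction(
    snapshots: list[OmicsSnapshot],
    series: ExpressionSeries,
    de_forward: list[DifferentialExpression],
    config: PipelineConfig,
    markers: list[str] | None = None,
) -> NetworkBuild:
    """Score snapshots, rank influence, select TFs, assemble the network.

    ``de_forward`` holds one table per later time point, comparing it to the
    first (positive log2fc = up at the later time); backward comparisons are
    derived by negation. Markers, if given, are injected after pruning with
    their top incoming candidate edges.
    """
    from .scoring import differential_network, influence, score_snapshot, select_tfs

    snapshots = sorted(snapshots, key=lambda s: s.time_label)
    nets_act = [score_snapshot(s, ACTIVATING) for s in snapshots]
    nets_inh = [score_snapshot(s, INHIBITING) for s in snapshots]

    de_by_to = {de.comparison[1]: de for de in de_forward}
    rankings: list[InfluenceRanking] = []
    first = nets_act[0]
    for net in nets_act[1:]:
        de = de_by_to[net.time_label]
        fwd = differential_network(first, net)
        rankings.append(influence(fwd, de, config.influence_max_depth,
                                  config.influence_alpha, "forward"))
        bwd = differential_network(net, first)
        rankings.append(influence(bwd, backward_de(de), config.influence_max_depth,
                                  config.influence_alpha, "backward"))

    selection = select_tfs(rankings, nets_act, config)
    expr_by_tf = {g: series.row(g) for g in series.genes}
    signs = sign_all_pairs({tf: expr_by_tf[tf] for tf in nets_act[0].nodes})
    candidates = max_over_time_scores(
        {ACTIVATING: nets_act, INHIBITING: nets_inh}, signs
    )
    network = assemble(candidates, selection, config.n_a, config.n_i)
    for marker in markers or []:
        network = add_marker(network, marker, candidates)
    return NetworkBuild(network, selection, rankings, candidates, nets_act, nets_inh)


def fit_restarts(
    network: SignedNetwork,
    series: ExpressionSeries,
    config: PipelineConfig,
    fit_config: FitConfig | None = None,
    scale: bool = True,
) -> tuple[list[FitResult], ExpressionSeries]:
    """Fit ``config.n_restarts`` times with restart-derived seeds."""
    scaled = scale_expression(series) if scale else series
    base = fit_config or FitConfig(C=config.C, learning_rate=config.learning_rate,
                                   rng_seed=config.rng_seed)
    results = []
    for r in range(config.n_restarts):
        cfg = FitConfig(**{**base.__dict__, "rng_seed": base.rng_seed + 7919 * r})
        results.append(fit(network, scaled, cfg, config.hill_S, config.hill_n,
                           config.tau))
    return results, scaled


def fit_and_rank(
    network: SignedNetwork,
    series: ExpressionSeries,
    targets: TargetSet,
    config: PipelineConfig,
    fit_config: FitConfig | None = None,
) -> tuple[ImportanceReport, list[FitResult]]:
    """Repeated fits followed by the perturbation-importance ranking."""
    results, scaled = fit_restarts(network, series, config, fit_config)
    sub = scaled.subset(network.nodes)
    models = [r.model(config.hill_S, config.hill_n, config.tau) for r in results]
    report = rank_tfs(models, targets, sub.values[:, 0], sub.times,
                      config.p_grid())
    return report, results
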