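"""Rank TFs by how strongly their up-/down-regulation shifts marker TFs.

For each candidate TF j, a control input p from a symmetric grid (default
-3 to 3 in steps of 1/20, 121 values) is injected into j's Hill term and
the model is re-simulated from the data's initial condition over the data
horizon [t_0, t_N]. The importance of j is

    z_j = max_p sum_{i in T} [phi_i(t_N, p) - phi_i(t_N, 0)],

the maximal achievable increase of summed marker-TF expression at the final
time point; since p = 0 is in the grid, z_j >= 0 always. The maximizing
perturbation p* indicates the direction of the recommended intervention
(p* > 0: upregulate; p* < 0: knock down). Because repeated fits yield
slightly different weight matrices, importance is aggregated across fit
restarts into mean, standard deviation and top-rank frequency per TF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ValidationError
from .dynamics import DynamicModel, make_grid, rk4_batch
from .io import log_stage

__all__ = [
    "TargetSet",
    "ImportanceEntry",
    "ImportanceReport",
    "default_p_grid",
    "importance",
    "rank_tfs",
]


def default_p_grid() -> np.ndarray:
    """Symmetric perturbation grid -3 ... 3 in steps of 1/20 (121 points)."""
    return np.round(np.arange(-60, 61) / 20.0, 10)


@dataclass(frozen=True)
class TargetSet:
    """The marker/output TFs T whose upregulation defines the desired fate."""

    tf_ids: tuple[str, ...]
    origin: str = "manual"  # data_driven | manual | prior_knowledge

    def __post_init__(self) -> None:
        if not self.tf_ids:
            raise ValidationError("target set must be nonempty")
        if self.origin not in ("data_driven", "manual", "prior_knowledge"):
            raise ValidationError(f"unknown target-set origin {self.origin!r}")

    def validate_against(self, nodes: list[str]) -> None:
        missing = set(self.tf_ids) - set(nodes)
        if missing:
            raise ValidationError(f"target TFs not in network: {sorted(missing)}")


@dataclass
class ImportanceEntry:
    """Aggregated importance of one TF across fit restarts."""

    tf_id: str
    z_mean: float
    z_sd: float
    top_rank_freq: float
    p_star: float           # maximizer of the best restart's z
    direction: str          # upregulate | knock_down | none
    self_target: bool       # TF is itself in T (trivially self-inflating)
    z_per_restart: list[float] = field(default_factory=list)
    p_star_per_restart: list[float] = field(default_factory=list)


@dataclass
class ImportanceReport:
    """Per-TF importance entries, sorted by mean z descending."""

    entries: list[ImportanceEntry]
    target_set: TargetSet | None = None
    n_restarts: int = 1

    def __post_init__(self) -> None:
        self.entries.sort(key=lambda e: (-e.z_mean, e.tf_id))

    def top(self, k: int = 3) -> list[ImportanceEntry]:
        return self.entries[:k]

    def entry(self, tf_id: str) -> ImportanceEntry:
        for e in self.entries:
            if e.tf_id == tf_id:
                return e
        raise KeyError(tf_id)

    def to_dict(self) -> dict:
        return {
            "n_restarts": self.n_restarts,
            "targets": sorted(self.target_set.tf_ids) if self.target_set else [],
            "origin": self.target_set.origin if self.target_set else None,
            "tfs": [
                {
                    "tf": e.tf_id,
                    "z_mean": e.z_mean,
                    "z_sd": e.z_sd,
                    "top_rank_freq": e.top_rank_freq,
                    "p_star": e.p_star,
                    "direction": e.direction,
                    "self_target": e.self_target,
                    "z_per_restart": e.z_per_restart,
                    "p_star_per_restart": e.p_star_per_restart,
                }
                for e in self.entries
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImportanceReport":
        entries = [
            ImportanceEntry(t["tf"], t["z_mean"], t["z_sd"], t["top_rank_freq"],
                            t["p_star"], t["direction"], t["self_target"],
                            list(t["z_per_restart"]), list(t["p_star_per_restart"]))
            for t in d["tfs"]
        ]
        ts = TargetSet(tuple(d["targets"]), d["origin"]) if d.get("targets") else None
        return cls(entries, ts, d["n_restarts"])


def _pick_p_star(p_grid: np.ndarray, gains: np.ndarray) -> tuple[float, float]:
    """Max gain and its maximizer; ties -> smallest |p|, then positive."""
    z = float(gains.max())
    winners = p_grid[gains == gains.max()]
    order = sorted(winners, key=lambda p: (abs(p), p < 0))
    return z, float(order[0])


def importance(
    model: DynamicModel,
    tf_id: str,
    target_set: TargetSet,
    p_grid: np.ndarray | None = None,
    x0: np.ndarray | None = None,
    times: np.ndarray | None = None,
    dt_max: float = 0.25,
) -> tuple[float, float]:
    """(z, p*) for perturbing ``tf_id``: all grid strengths in one batch.

    ``x0`` defaults to nothing useful -- callers normally pass the scaled
    data's first column and the data times; both are required here.
    All perturbation strengths are integrated simultaneously on a fixed RK4
    grid, so the p = 0 column is exactly the unperturbed trajectory.
    """
    if x0 is None or times is None:
        raise ValidationError("importance requires x0 and times from the fit data")
    p_grid = default_p_grid() if p_grid is None else np.asarray(p_grid, dtype=float)
    if not np.any(p_grid == 0):
        raise ValidationError("perturbation grid must contain 0")
    target_set.validate_against(model.nodes)
    pert_idx = model.node_index(tf_id)
    w_act, w_inh = model.split_weights()
    grid, _ = make_grid(np.asarray(times, dtype=float), dt_max)
    n_p = p_grid.size
    x0_batch = np.repeat(np.asarray(x0, dtype=float)[:, None], n_p, axis=1)
    states = rk4_batch(
        w_act, w_inh, x0_batch, grid,
        model.hill_S ** model.hill_n, model.hill_n, model.tau,
        pert_idx=pert_idx,
        p_act=np.maximum(p_grid, 0.0),
        p_inh=np.maximum(-p_grid, 0.0),
    )
    final = states[-1]                             # (N, n_p)
    t_idx = [model.node_index(t) for t in target_set.tf_ids]
    sums = final[t_idx].sum(axis=0)
    gains = sums - sums[p_grid == 0][0]
    return _pick_p_star(p_grid, gains)


def rank_tfs(
    models: list[DynamicModel],
    target_set: TargetSet,
    x0: np.ndarray,
    times: np.ndarray,
    p_grid: np.ndarray | None = None,
    dt_max: float = 0.25,
) -> ImportanceReport:
    """Importance of every network TF, aggregated across restart models.

    All models must share one node set (they are fits of the same network).
    Top-rank frequency counts restarts in which the TF attains the strictly
    highest z (ties broken lexicographically by TF id).
    """
    if not models:
        raise ValidationError("at least one fitted model is required")
    nodes = models[0].nodes
    for m in models[1:]:
        if m.nodes != nodes:
            raise ValidationError("restart models have inconsistent node sets")
    target_set.validate_against(nodes)
    p_grid = default_p_grid() if p_grid is None else np.asarray(p_grid, dtype=float)

    z_mat = np.zeros((len(models), len(nodes)))
    p_mat = np.zeros((len(models), len(nodes)))
    for r, model in enumerate(models):
        for j, tf in enumerate(nodes):
            z_mat[r, j], p_mat[r, j] = importance(
                model, tf, target_set, p_grid, x0, times, dt_max
            )
    top_counts = np.zeros(len(nodes))
    for r in range(len(models)):
        order = sorted(range(len(nodes)), key=lambda j: (-z_mat[r, j], nodes[j]))
        top_counts[order[0]] += 1

    entries = []
    for j, tf in enumerate(nodes):
        best_r = int(np.argmax(z_mat[:, j]))
        z_mean = float(z_mat[:, j].mean())
        p_star = float(p_mat[best_r, j])
        if z_mat[best_r, j] == 0:
            direction = "none"
        else:
            direction = "upregulate" if p_star > 0 else "knock_down"
        entries.append(ImportanceEntry(
            tf_id=tf,
            z_mean=z_mean,
            z_sd=float(z_mat[:, j].std()),
            top_rank_freq=float(top_counts[j] / len(models)),
            p_star=p_star,
            direction=direction,
            self_target=tf in target_set.tf_ids,
            z_per_restart=[float(v) for v in z_mat[:, j]],
            p_star_per_restart=[float(v) for v in p_mat[:, j]],
        ))
    report = ImportanceReport(entries, target_set, len(models))
    log_stage("rank_tfs", tfs=len(nodes), restarts=len(models),
              targets=len(target_set.tf_ids))
    return report
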