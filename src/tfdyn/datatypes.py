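"""Core domain types shared across the pipeline.

The pipeline moves through a fixed sequence of containers: per-time-point
omics snapshots (expression, genome-wide TF activity, TF->gene binding
probabilities) are scored into dense TF x TF interaction matrices; those are
reduced to a single signed, sparse network; a Hill-function ODE model is
posed on that network and fitted to a scaled expression time series; finally
single-TF perturbations of the fitted model rank candidate driver TFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

ACTIVATING = "activating"
INHIBITING = "inhibiting"

__all__ = [
    "ACTIVATING",
    "INHIBITING",
    "OmicsSnapshot",
    "ExpressionSeries",
    "DifferentialExpression",
    "PipelineConfig",
    "Edge",
    "ScoredNetwork",
    "InfluenceRanking",
    "TFSelection",
    "SignedNetwork",
]


class ValidationError(ValueError):
    """An input table or container violates a structural invariant."""


@dataclass(frozen=True)
class OmicsSnapshot:
    """One time point's multi-omics evidence for a set of TFs.

    Parameters
    ----------
    time_label
        Ordinal time point in experiment days.
    expression
        TF id -> nonnegative normalized expression E_i (arbitrary units).
    activity
        TF id -> genome-wide TF activity A_i (arbitrary units).
    binding
        (source TF, target gene) -> binding probability B_ij in [0, 1].
        Pairs absent from the mapping are read as B_ij = 0.
    """

    time_label: float
    expression: Mapping[str, float]
    activity: Mapping[str, float]
    binding: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        for tf, e in self.expression.items():
            if not np.isfinite(e) or e < 0:
                raise ValidationError(
                    f"expression for {tf!r} must be finite and >= 0, got {e}"
                )
        for (i, j), b in self.binding.items():
            if not np.isfinite(b) or not (0.0 <= b <= 1.0):
                raise ValidationError(
                    f"binding probability for ({i!r}, {j!r}) outside [0, 1]: {b}"
                )
        binding_tfs = {i for i, _ in self.binding} | {j for _, j in self.binding}
        missing_expr = binding_tfs - set(self.expression)
        if missing_expr:
            raise ValidationError(
                f"TFs in binding table lack expression entries: {sorted(missing_expr)}"
            )
        missing_act = binding_tfs - set(self.activity)
        if missing_act:
            raise ValidationError(
                f"TFs in binding table lack activity entries: {sorted(missing_act)}"
            )

    @property
    def tfs(self) -> list[str]:
        """Sorted TF identifiers covered by this snapshot."""
        return sorted(self.expression)

    def binding_value(self, source: str, target: str) -> float:
        """B_ij, defaulting to 0 for pairs without binding evidence."""
        return float(self.binding.get((source, target), 0.0))


@dataclass
class ExpressionSeries:
    """Normalized expression of genes over strictly increasing time points."""

    times: np.ndarray
    genes: list[str]
    values: np.ndarray  # shape (n_genes, n_times)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValidationError("time points must be strictly increasing")
        if self.values.shape != (len(self.genes), self.times.size):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {self.times.size} times"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")

    @property
    def maxima(self) -> np.ndarray:
        """Per-gene maximum M_i."""
        return self.values.max(axis=1)

    @property
    def minima(self) -> np.ndarray:
        """Per-gene minimum m_i."""
        return self.values.min(axis=1)

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.genes.index(gene)]

    def subset(self, genes: Sequence[str]) -> "ExpressionSeries":
        """Restrict to the given genes, preserving the requested order."""
        idx = [self.genes.index(g) for g in genes]
        return ExpressionSeries(self.times.copy(), list(genes), self.values[idx])


@dataclass(frozen=True)
class DifferentialExpression:
    """Per-gene log2 fold change and adjusted p for one time-point comparison.

    ``comparison`` is (time_label_from, time_label_to): positive log2fc means
    higher expression at ``to`` than at ``from``.
    """

    comparison: tuple[float, float]
    log2fc: Mapping[str, float]
    padj: Mapping[str, float]

    def __post_init__(self) -> None:
        for g, p in self.padj.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"adjusted p for {g!r} outside [0, 1]: {p}")


@dataclass
class PipelineConfig:
    """All pipeline tunables; every random choice flows from ``rng_seed``."""

    n_top_influence: int = 5     # TFs kept per pairwise comparison
    n_general: int = 12          # TFs kept by average degree
    n_a: int = 70                # activating edges in the assembled network
    n_i: int = 40                # inhibiting edges
    C: float = 0.005             # L1 penalty on the weight matrix
    learning_rate: float = 0.1   # ADAM step size
    hill_n: float = 3.0          # Hill coefficient
    hill_S: float = 1.0          # half-occupation value
    tau: float = 1.0             # system time scale (experiment days)
    p_min: float = -3.0          # perturbation grid bounds and step
    p_max: float = 3.0
    p_step: float = 0.05
    n_restarts: int = 10
    influence_max_depth: int = 2
    influence_alpha: float = 0.05
    degree_top_k: int = 10_000   # edges per time point counted toward degree
    allow_self_edges: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_top_influence", "n_general", "n_a", "n_i", "n_restarts",
                     "influence_max_depth", "degree_top_k"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValidationError(f"{name} must be a positive integer, got {v!r}")
        if self.C < 0:
            raise ValidationError("C must be >= 0")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if not (0 < self.influence_alpha <= 1):
            raise ValidationError("influence_alpha must lie in (0, 1]")
        grid = self.p_grid()
        if not np.any(grid == 0) or not np.allclose(grid, -grid[::-1]):
            raise ValidationError("perturbation grid must be symmetric and contain 0")

    def p_grid(self) -> np.ndarray:
        """The perturbation grid implied by p_min/p_max/p_step."""
        n = int(round((self.p_max - self.p_min) / self.p_step))
        return np.round(self.p_min + self.p_step * np.arange(n + 1), 10)


@dataclass(frozen=True, order=True)
class Edge:
    """A signed, scored directed interaction between two TFs."""

    source: str
    target: str
    sign: str
    score: float

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATING, INHIBITING):
            raise ValidationError(f"unknown edge sign {self.sign!r}")


@dataclass
class ScoredNetwork:
    """Dense TF x TF interaction scores for one time point and one mode."""

    time_label: float
    nodes: list[str]
    scores: np.ndarray  # (i, j) = score of TF i acting on TF j
    mode: str = ACTIVATING

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.nodes)
        if self.scores.shape != (n, n):
            raise ValidationError("score matrix shape must be (n_nodes, n_nodes)")
        if np.any(self.scores < -1e-12) or np.any(self.scores > 1 + 1e-12):
            raise ValidationError("interaction scores must lie in [0, 1]")

    def score(self, source: str, target: str) -> float:
        return float(self.scores[self.nodes.index(source), self.nodes.index(target)])


@dataclass
class InfluenceRanking:
    """TFs ranked by influence for one directed time-point comparison."""

    comparison: tuple[float, float]
    direction: str  # "forward" (later vs first) or "backward"
    scores: dict[str, float]

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ValidationError(f"unknown direction {self.direction!r}")
        if any(v < 0 for v in self.scores.values()):
            raise ValidationError("influence scores must be >= 0")

    def top(self, k: int) -> list[str]:
        """Top-k TFs with strictly positive influence, ties lexicographic."""
        ranked = sorted(
            ((tf, s) for tf, s in self.scores.items() if s > 0),
            key=lambda kv: (-kv[1], kv[0]),
        )
        return [tf for tf, _ in ranked[:k]]


@dataclass
class TFSelection:
    """The TFs chosen to populate the model."""

    per_comparison: dict[tuple[float, float, str], list[str]]
    general: list[str]

    @property
    def union(self) -> list[str]:
        seen: dict[str, None] = {}
        for tfs in self.per_comparison.values():
            for tf in tfs:
                seen.setdefault(tf)
        for tf in self.general:
            seen.setdefault(tf)
        return sorted(seen)


@dataclass
class SignedNetwork:
    """Sparse signed TF network: the substrate of the dynamic model."""

    nodes: list[str]
    edges: list[Edge]
    marker_nodes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.source == e.target:
                raise ValidationError(f"self-edge on {e.source!r} not allowed")
            if (e.source, e.target) in seen:
                raise ValidationError(f"duplicate edge {(e.source, e.target)}")
            seen.add((e.source, e.target))
            if e.source not in node_set or e.target not in node_set:
                raise ValidationError(f"edge {e} references unknown node")
        if not self.marker_nodes <= node_set:
            raise ValidationError("marker nodes must be network nodes")

    def incoming(self, node: str, sign: str | None = None) -> list[Edge]:
        return [e for e in self.edges
                if e.target == node and (sign is None or e.sign == sign)]

    def outgoing(self, node: str, sign: str | None = None) -> list[Edge]:
        return [e for e in self.edges
                if e.source == node and (sign is None or e.sign == sign)]

    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edges, key=lambda e: (e.source, e.target))
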