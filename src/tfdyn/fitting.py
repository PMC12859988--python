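"""Fit the network's weight matrix to scaled expression time series.

The free parameters are the nonnegative weights on the network's edges. The
objective is the squared mismatch between the simulated trajectory (started
at the data's first time point) and the data at the sampled times, plus an
L1 penalty C * sum|W| that removes edges not needed to explain the data:

    L(W) = sum_t sum_i (phi_i(t, W) - D_i(t))^2 + C sum_ij |W_ij|.

Optimization is ADAM (learning rate 0.1 by default) with projection onto
W >= 0 after every step; the best iterate seen is returned. Gradients come
from forward sensitivity equations integrated jointly with the state on a
fixed RK4 grid, so simulation and differentiation share one discretization;
central finite differences are available as a cross-check
(``FitConfig.gradient = "fd"``).

A grid search over the number of activating/inhibiting connections
(n_a, n_i) re-runs assembly and fitting per cell and tabulates the
node-count-normalized loss L_av = L^2 / N used to pick a minimal network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import AssemblyError, assemble
from .datatypes import (
    ACTIVATING,
    Edge,
    ExpressionSeries,
    SignedNetwork,
    TFSelection,
    ValidationError,
)
from .dynamics import DynamicModel, make_grid, rk4_batch, scale_expression
from .io import log_stage

__all__ = ["FitConfig", "FitResult", "GridSearchResult", "loss", "fit", "grid_search"]

#: fitted weights below this are reported as removed by the L1 penalty
L1_REMOVAL_THRESHOLD = 0.01


@dataclass
class FitConfig:
    """Optimizer settings for one weight fit."""

    C: float = 0.005
    learning_rate: float = 0.1
    max_steps: int = 2000
    rel_tol: float = 1e-7        # relative best-loss change over tol_window steps
    tol_window: int = 50
    init_low: float = 0.1        # uniform initialization bounds for weights
    init_high: float = 1.0
    rng_seed: int = 0
    restarts: int = 10
    gradient: str = "sensitivity"  # or "fd" (central differences, step 1e-5)
    fd_step: float = 1e-5
    dt_max: float = 0.25         # fixed-grid integration step bound (days)

    def __post_init__(self) -> None:
        if self.C < 0:
            raise ValidationError("C must be >= 0")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.max_steps < 1:
            raise ValidationError("max_steps must be >= 1")
        if self.gradient not in ("sensitivity", "fd"):
            raise ValidationError(f"unknown gradient method {self.gradient!r}")


@dataclass
class FitResult:
    """Outcome of one weight optimization."""

    nodes: list[str]
    edges: list[Edge]            # network edges with fitted weights as scores
    loss_trace: list[float]
    final_loss: float            # best total loss seen
    data_loss: float             # squared-error part of the best iterate
    penalty: float               # L1 part of the best iterate
    n_nodes: int
    l_av: float                  # L^2 / N
    l_mean: float                # L / N, for comparison
    converged: bool
    steps: int
    seed: int

    @property
    def W(self) -> np.ndarray:
        idx = {tf: k for k, tf in enumerate(self.nodes)}
        W = np.zeros((len(self.nodes), len(self.nodes)))
        for e in self.edges:
            W[idx[e.target], idx[e.source]] = e.score
        return W

    def model(self, hill_S: float = 1.0, hill_n: float = 3.0,
              tau: float = 1.0) -> DynamicModel:
        net = SignedNetwork(list(self.nodes), list(self.edges))
        return DynamicModel(net, self.W, hill_S, hill_n, tau)

    def removed_edges(self) -> list[Edge]:
        """Edges whose fitted weight fell below the L1 removal threshold."""
        return [e for e in self.edges if e.score < L1_REMOVAL_THRESHOLD]

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "edges": [
                {"source": e.source, "target": e.target, "sign": e.sign,
                 "weight": e.score}
                for e in sorted(self.edges, key=lambda e: (e.source, e.target))
            ],
            "final_loss": self.final_loss,
            "data_loss": self.data_loss,
            "penalty": self.penalty,
            "n_nodes": self.n_nodes,
            "l_av": self.l_av,
            "l_mean": self.l_mean,
            "converged": self.converged,
            "steps": self.steps,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        edges = [Edge(e["source"], e["target"], e["sign"], e["weight"])
                 for e in d["edges"]]
        return cls(list(d["nodes"]), edges, [], d["final_loss"], d["data_loss"],
                   d["penalty"], d["n_nodes"], d["l_av"], d["l_mean"],
                   d["converged"], d["steps"], d["seed"])


class _Problem:
    """Precomputed arrays for one (network, data) fitting problem."""

    def __init__(self, network: SignedNetwork, data: ExpressionSeries,
                 hill_S: float, hill_n: float, tau: float, dt_max: float):
        missing = set(network.nodes) - set(data.genes)
        if missing:
            raise ValidationError(f"data lacks rows for nodes: {sorted(missing)}")
        if data.times.size < 3:
            raise ValidationError("fitting needs at least three time points")
        self.network = network
        self.nodes = list(network.nodes)
        self.edges = network.sorted_edges()
        idx = {tf: k for k, tf in enumerate(self.nodes)}
        self.src = np.array([idx[e.source] for e in self.edges], dtype=int)
        self.tgt = np.array([idx[e.target] for e in self.edges], dtype=int)
        self.is_act = np.array([e.sign == ACTIVATING for e in self.edges])
        self.n = len(self.nodes)
        self.p = len(self.edges)
        sub = data.subset(self.nodes)
        self.data = sub.values                      # (N, T)
        self.x0 = sub.values[:, 0].copy()
        self.grid, self.data_idx = make_grid(sub.times, dt_max)
        self.s_pow = hill_S ** hill_n
        self.hill_n = hill_n
        self.tau = tau

    def split(self, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        w_act = np.zeros((self.n, self.n))
        w_inh = np.zeros((self.n, self.n))
        w_act[self.tgt[self.is_act], self.src[self.is_act]] = w[self.is_act]
        w_inh[self.tgt[~self.is_act], self.src[~self.is_act]] = w[~self.is_act]
        return w_act, w_inh

    def data_loss(self, w: np.ndarray) -> float:
        w_act, w_inh = self.split(w)
        states = rk4_batch(w_act, w_inh, self.x0, self.grid,
                           self.s_pow, self.hill_n, self.tau)
        resid = states[self.data_idx].T - self.data
        return float(np.sum(resid ** 2))

    def loss_and_grad(self, w: np.ndarray, C: float) -> tuple[float, np.ndarray]:
        """Total loss and its gradient via forward sensitivities."""
        w_act, w_inh = self.split(w)
        N, P = self.n, self.p
        x = self.x0.copy()
        S = np.zeros((N, P))
        data_term = 0.0
        grad = np.zeros(P)
        next_data = 0
        if self.data_idx[0] == 0:
            resid = x - self.data[:, 0]
            data_term += float(resid @ resid)      # zero by construction
            next_data = 1

        def f_aug(x, S):
            xc = np.clip(x, 0.0, None)
            xp = xc ** self.hill_n
            xpm1 = self.hill_n * xc ** (self.hill_n - 1)
            a = w_act @ xp
            b = w_inh @ xp
            D = self.s_pow + a + b
            dx = (-x + a / D) / self.tau
            dHda = (self.s_pow + b) / D ** 2
            dHdb = -a / D ** 2
            Jx = (dHda[:, None] * w_act + dHdb[:, None] * w_inh) * xpm1[None, :]
            Jx[np.arange(N), np.arange(N)] -= 1.0
            Jx /= self.tau
            JW = np.zeros((N, P))
            coef = np.where(self.is_act, dHda[self.tgt], dHdb[self.tgt])
            JW[self.tgt, np.arange(P)] = coef * xp[self.src] / self.tau
            return dx, Jx @ S + JW

        for k in range(len(self.grid) - 1):
            h = self.grid[k + 1] - self.grid[k]
            k1x, k1s = f_aug(x, S)
            k2x, k2s = f_aug(x + 0.5 * h * k1x, S + 0.5 * h * k1s)
            k3x, k3s = f_aug(x + 0.5 * h * k2x, S + 0.5 * h * k2s)
            k4x, k4s = f_aug(x + h * k3x, S + h * k3s)
            x = x + h / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
            S = S + h / 6.0 * (k1s + 2 * k2s + 2 * k3s + k4s)
            while next_data < self.data_idx.size and self.data_idx[next_data] == k + 1:
                resid = x - self.data[:, next_data]
                data_term += float(resid @ resid)
                grad += 2.0 * (resid @ S)
                next_data += 1
        total = data_term + C * float(np.sum(np.abs(w)))
        grad = grad + C * np.sign(w)
        return total, grad

    def loss_and_grad_fd(self, w: np.ndarray, C: float,
                         step: float = 1e-5) -> tuple[float, np.ndarray]:
        """Central finite-difference gradient of the same discretized loss."""
        base = self.data_loss(w) + C * float(np.sum(np.abs(w)))
        grad = np.zeros_like(w)
        for k in range(w.size):
            wp, wm = w.copy(), w.copy()
            wp[k] += step
            wm[k] -= step
            grad[k] = (self.data_loss(wp) - self.data_loss(wm)) / (2 * step)
        grad += C * np.sign(w)
        return base, grad


def loss(
    W: np.ndarray,
    network: SignedNetwork,
    data: ExpressionSeries,
    C: float = 0.005,
    hill_S: float = 1.0,
    hill_n: float = 3.0,
    tau: float = 1.0,
    dt_max: float = 0.25,
) -> float:
    """L(W) for a full weight matrix on the network's edge support."""
    prob = _Problem(network, data, hill_S, hill_n, tau, dt_max)
    w = np.array([W[prob.tgt[k], prob.src[k]] for k in range(prob.p)])
    if np.any(w < 0):
        raise ValidationError("W must be nonnegative")
    return prob.data_loss(w) + C * float(np.sum(np.abs(W)))


def fit(
    network: SignedNetwork,
    data: ExpressionSeries,
    config: FitConfig | None = None,
    hill_S: float = 1.0,
    hill_n: float = 3.0,
    tau: float = 1.0,
) -> FitResult:
    """ADAM-optimize the masked, nonnegative weight vector.

    Weights start uniform on [init_low, init_high] (seeded), are projected
    onto >= 0 after every update, and the best-loss iterate is returned.
    Stops early when the best loss improves by less than ``rel_tol``
    (relatively) over ``tol_window`` steps.
    """
    config = config or FitConfig()
    prob = _Problem(network, data, hill_S, hill_n, tau, config.dt_max)
    rng = np.random.default_rng(config.rng_seed)
    w = rng.uniform(config.init_low, config.init_high, size=prob.p)

    grad_fn = (prob.loss_and_grad if config.gradient == "sensitivity"
               else lambda w, C: prob.loss_and_grad_fd(w, C, config.fd_step))

    m = np.zeros(prob.p)
    v = np.zeros(prob.p)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    best_w = w.copy()
    best_loss = np.inf
    trace: list[float] = []
    converged = False
    step = 0
    for step in range(1, config.max_steps + 1):
        total, grad = grad_fn(w, config.C)
        if not np.isfinite(total):
            raise RuntimeError(
                f"non-finite loss at step {step} (seed {config.rng_seed})"
            )
        trace.append(total)
        if total < best_loss:
            best_loss = total
            best_w = w.copy()
        m = beta1 * m + (1 - beta1) * grad
        v = beta2 * v + (1 - beta2) * grad ** 2
        mhat = m / (1 - beta1 ** step)
        vhat = v / (1 - beta2 ** step)
        w = w - config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        w = np.maximum(w, 0.0)
        if step >= max(4 * config.tol_window, 200):
            prev = min(trace[: step - config.tol_window])
            if prev - best_loss < config.rel_tol * max(best_loss, 1e-12):
                converged = True
                break

    data_term = prob.data_loss(best_w)
    penalty = config.C * float(np.sum(np.abs(best_w)))
    final = data_term + penalty
    edges = [Edge(e.source, e.target, e.sign, float(best_w[k]))
             for k, e in enumerate(prob.edges)]
    result = FitResult(
        nodes=list(prob.nodes),
        edges=edges,
        loss_trace=trace,
        final_loss=final,
        data_loss=data_term,
        penalty=penalty,
        n_nodes=prob.n,
        l_av=final ** 2 / prob.n,
        l_mean=final / prob.n,
        converged=converged,
        steps=step,
        seed=config.rng_seed,
    )
    log_stage("fit", nodes=prob.n, edges=prob.p, steps=step,
              loss=f"{final:.6g}", seed=config.rng_seed)
    return result


@dataclass
class GridSearchResult:
    """Per-(n_a, n_i) fit summaries; cells whose assembly failed are None."""

    cells: dict[tuple[int, int], dict | None] = field(default_factory=dict)

    def l_av(self, n_a: int, n_i: int) -> float:
        cell = self.cells[(n_a, n_i)]
        return np.nan if cell is None else cell["l_av_mean"]

    def to_dict(self) -> dict:
        return {f"{na},{ni}": cell for (na, ni), cell in sorted(self.cells.items())}


def grid_search(
    candidates: list[Edge],
    tf_selection: TFSelection | list[str],
    data: ExpressionSeries,
    grid: list[tuple[int, int]],
    config: FitConfig | None = None,
    hill_S: float = 1.0,
    hill_n: float = 3.0,
    tau: float = 1.0,
    scale: bool = True,
) -> GridSearchResult:
    """Re-run assembly + repeated fits for each (n_a, n_i) cell.

    Each cell records the mean L_av over ``config.restarts`` restarts plus
    network size; a cell whose assembly empties the network records None and
    the search continues.
    """
    if not grid:
        raise ValidationError("grid must be nonempty")
    config = config or FitConfig()
    scaled = scale_expression(data) if scale else data
    result = GridSearchResult()
    for n_a, n_i in grid:
        try:
            network = assemble(candidates, tf_selection, n_a, n_i)
        except AssemblyError:
            result.cells[(n_a, n_i)] = None
            continue
        fits = []
        for r in range(config.restarts):
            cfg = FitConfig(**{**config.__dict__,
                               "rng_seed": config.rng_seed + 7919 * r})
            fits.append(fit(network, scaled, cfg, hill_S, hill_n, tau))
        retained = sum(len(f.edges) - len(f.removed_edges()) for f in fits)
        result.cells[(n_a, n_i)] = {
            "l_av_mean": float(np.mean([f.l_av for f in fits])),
            "l_av_sd": float(np.std([f.l_av for f in fits])),
            "l_mean_mean": float(np.mean([f.l_mean for f in fits])),
            "nodes": len(network.nodes),
            "edges": len(network.edges),
            "retained_mean": retained / len(fits),
            "seed": config.rng_seed,
        }
    log_stage("grid_search", cells=len(grid), restarts=config.restarts)
    return result
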