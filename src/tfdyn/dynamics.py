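"""Hill-function ODE dynamics on a signed TF network.

Each TF's scaled expression x_i in [0, 1] decays linearly and is produced
through a saturating Hill term driven by its regulators:

    tau * dx_i/dt = -x_i + (sum_act W_ji x_j^n)
                           / (S^n + sum_act W_ji x_j^n + sum_inh W_ji x_j^n)

with W >= 0 supported on the network's edges, half-occupation S (default 1)
and Hill coefficient n (default 3; a steep sigmoid makes bistability
representable). Because the Hill term lies in [0, 1), trajectories started
in [0, 1]^N stay there, matching scaled expression data.

Up-/down-regulation of one TF adds a controlled input p to that TF's Hill
term: p_act = max(p, 0) enters numerator and denominator, p_inh = max(-p, 0)
the denominator only, so p -> +inf drives the node to 1 and p < 0 suppresses
it.

Expression data are mapped into the model range gene-wise by

    X_it = 4 / (5 (M_i - m_i)) * (Xhat_it - m_i) + 0.1,

an affine map sending each gene's minimum to 0.1 and maximum to 0.9 so that
no gene is dynamically invisible to the fit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .datatypes import (
    ACTIVATING,
    ExpressionSeries,
    SignedNetwork,
    ValidationError,
)

__all__ = [
    "DynamicModel",
    "Perturbation",
    "Trajectory",
    "scale_expression",
    "rhs",
    "simulate",
]


def scale_expression(series: ExpressionSeries) -> ExpressionSeries:
    """Scale each gene's series affinely onto [0.1, 0.9].

    A constant gene (M_i = m_i) maps to the sign-neutral midpoint 0.5; the
    affine formula is undefined there.
    """
    M = series.maxima[:, None]
    m = series.minima[:, None]
    span = M - m
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = 4.0 / (5.0 * span) * (series.values - m) + 0.1
    scaled = np.where(span == 0, 0.5, scaled)
    return ExpressionSeries(series.times.copy(), list(series.genes), scaled)


@dataclass(frozen=True)
class Perturbation:
    """A single-TF control input p; p >= 0 upregulates, p < 0 knocks down."""

    tf_id: str
    p: float

    @property
    def p_act(self) -> float:
        return max(self.p, 0.0)

    @property
    def p_inh(self) -> float:
        return max(-self.p, 0.0)


@dataclass
class DynamicModel:
    """A Hill-ODE model: a signed network plus its weight matrix.

    ``W[i, j]`` is the weight of edge j -> i (effect of TF j on TF i),
    nonnegative and zero off the network's edge support.
    """

    network: SignedNetwork
    W: np.ndarray
    hill_S: float = 1.0
    hill_n: float = 3.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.network.nodes)
        if self.W.shape != (n, n):
            raise ValidationError("W must be (n_nodes, n_nodes)")
        if np.any(self.W < 0):
            raise ValidationError("W must be elementwise nonnegative")
        if self.hill_n < 1 or self.tau <= 0:
            raise ValidationError("hill_n must be >= 1 and tau > 0")
        off_support = ~self.edge_mask()[0] & ~self.edge_mask()[1]
        if np.any(self.W[off_support] != 0):
            raise ValidationError("W has weight outside the network's edge support")

    @property
    def nodes(self) -> list[str]:
        return self.network.nodes

    def node_index(self, tf_id: str) -> int:
        return self.network.nodes.index(tf_id)

    def edge_mask(self) -> tuple[np.ndarray, np.ndarray]:
        """(activating, inhibiting) boolean masks, indexed [target, source]."""
        n = len(self.network.nodes)
        idx = {tf: k for k, tf in enumerate(self.network.nodes)}
        act = np.zeros((n, n), dtype=bool)
        inh = np.zeros((n, n), dtype=bool)
        for e in self.network.edges:
            (act if e.sign == ACTIVATING else inh)[idx[e.target], idx[e.source]] = True
        return act, inh

    def split_weights(self) -> tuple[np.ndarray, np.ndarray]:
        act, inh = self.edge_mask()
        return self.W * act, self.W * inh

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(",".join(self.network.nodes).encode())
        for e in self.network.sorted_edges():
            h.update(f"{e.source}>{e.target}:{e.sign}".encode())
        h.update(np.ascontiguousarray(self.W).tobytes())
        h.update(np.array([self.hill_S, self.hill_n, self.tau]).tobytes())
        return h.hexdigest()[:16]


@dataclass
class Trajectory:
    """Simulated states on a time grid, with provenance for reproducibility."""

    times: np.ndarray
    nodes: list[str]
    states: np.ndarray  # shape (n_nodes, n_times)
    provenance: dict = field(default_factory=dict)

    def final_state(self) -> np.ndarray:
        return self.states[:, -1]

    def at(self, tf_id: str) -> np.ndarray:
        return self.states[self.nodes.index(tf_id)]


def rhs(
    state: np.ndarray,
    model: DynamicModel,
    perturbation: Perturbation | None = None,
) -> np.ndarray:
    """Time derivative of the model at ``state`` (optionally perturbed).

    ``state`` may be a vector (n_nodes,) or a batch (n_nodes, m); the
    derivative has the same shape.
    """
    w_act, w_inh = model.split_weights()
    p_act = p_inh = 0.0
    pert_idx = -1
    if perturbation is not None:
        pert_idx = model.node_index(perturbation.tf_id)
        p_act, p_inh = perturbation.p_act, perturbation.p_inh
    return _rhs_arrays(
        np.asarray(state, dtype=float), w_act, w_inh,
        model.hill_S ** model.hill_n, model.hill_n, model.tau,
        pert_idx, p_act, p_inh,
    )


def _rhs_arrays(x, w_act, w_inh, s_pow, n, tau, pert_idx, p_act, p_inh):
    xp = np.clip(x, 0.0, None) ** n
    a = w_act @ xp
    b = w_inh @ xp
    if pert_idx >= 0:
        a = a.copy()
        a[pert_idx] = a[pert_idx] + p_act
        denom = s_pow + a + b
        denom[pert_idx] = denom[pert_idx] + p_inh
    else:
        denom = s_pow + a + b
    return (-x + a / denom) / tau


def simulate(
    model: DynamicModel,
    x0: np.ndarray,
    t_eval: Sequence[float],
    perturbation: Perturbation | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-6,
) -> Trajectory:
    """Integrate the model with an adaptive explicit Runge-Kutta solver.

    States are reported as computed (no clipping inside the solver); for
    W >= 0 and x0 in [0, 1]^N they remain in [0, 1]^N up to solver tolerance.
    """
    x0 = np.asarray(x0, dtype=float)
    t_eval = np.asarray(t_eval, dtype=float)
    if x0.shape != (len(model.nodes),):
        raise ValidationError("x0 must have one entry per network node")
    w_act, w_inh = model.split_weights()
    s_pow = model.hill_S ** model.hill_n
    p_act = p_inh = 0.0
    pert_idx = -1
    if perturbation is not None:
        pert_idx = model.node_index(perturbation.tf_id)
        p_act, p_inh = perturbation.p_act, perturbation.p_inh

    def f(_t, x):
        return _rhs_arrays(x, w_act, w_inh, s_pow, model.hill_n, model.tau,
                           pert_idx, p_act, p_inh)

    sol = solve_ivp(f, (t_eval[0], t_eval[-1]), x0, t_eval=t_eval,
                    method="RK45", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(
            f"ODE solver failed for model {model.content_hash()}: {sol.message}"
        )
    return Trajectory(
        times=sol.t,
        nodes=list(model.nodes),
        states=sol.y,
        provenance={
            "model_hash": model.content_hash(),
            "perturbation": None if perturbation is None
            else {"tf_id": perturbation.tf_id, "p": perturbation.p},
            "rtol": rtol,
            "atol": atol,
        },
    )


# --- fixed-grid integrator -------------------------------------------------
#
# Fitting and perturbation sweeps integrate on a fixed grid with classical
# RK4: the discretization is then a smooth, deterministic function of the
# weights, which keeps gradients consistent and lets many perturbation
# strengths be integrated as one batch.

def make_grid(times: np.ndarray, dt_max: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly refine the data times so no step exceeds ``dt_max``.

    Returns (grid, data_index) with grid[data_index] == times.
    """
    times = np.asarray(times, dtype=float)
    grid = [times[0]]
    data_idx = [0]
    for a, b in zip(times[:-1], times[1:]):
        steps = max(1, int(np.ceil((b - a) / dt_max)))
        seg = a + (b - a) * np.arange(1, steps + 1) / steps
        grid.extend(seg)
        data_idx.append(len(grid) - 1)
    return np.asarray(grid), np.asarray(data_idx)


def rk4_batch(
    w_act: np.ndarray,
    w_inh: np.ndarray,
    x0: np.ndarray,
    grid: np.ndarray,
    s_pow: float,
    n: float,
    tau: float,
    pert_idx: int = -1,
    p_act: np.ndarray | float = 0.0,
    p_inh: np.ndarray | float = 0.0,
) -> np.ndarray:
    """RK4 states at every grid node; ``x0`` may be (N,) or a batch (N, m).

    With batched states, ``p_act``/``p_inh`` may be length-m vectors applying
    a different perturbation strength to each batch column of the same node.
    Returns an array of shape (len(grid),) + x0.shape.
    """
    x = np.asarray(x0, dtype=float).copy()
    out = np.empty((len(grid),) + x.shape)
    out[0] = x

    def f(state):
        return _rhs_arrays(state, w_act, w_inh, s_pow, n, tau,
                           pert_idx, p_act, p_inh)

    for k in range(len(grid) - 1):
        h = grid[k + 1] - grid[k]
        k1 = f(x)
        k2 = f(x + 0.5 * h * k1)
        k3 = f(x + 0.5 * h * k2)
        k4 = f(x + h * k3)
        x = x + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[k + 1] = x
    return out
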