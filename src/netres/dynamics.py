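"""Networked nonlinear dynamics on weighted directed graphs.

The state of node ``i`` evolves as ``dx_i/dt = f(x_i, a) + sum_j M_ji
g(x_i, x_j, b)``: a self-dynamics term plus coupling terms scaled by the
influence weights ``M_ji`` (effect of node j on node i).  Model parameters
may be fixed reals or :class:`~netres.random_inputs.RandomInput` references;
uncertainty is either *shared* (one draw for all nodes) or *iid-per-node*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import ClassVar, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .random_inputs import RandomInput

__all__ = [
    "WeightedDigraph",
    "DynamicsModel",
    "GenericBistable",
    "Mutualistic",
    "Commuter",
    "full_rhs",
    "simulate",
    "remove_links",
    "scale_to_average_weight",
    "DomainError",
    "IntegrationError",
]

_LOG_GUARD = 1e-12  # floor inside alpha*log(x); the coupling is undefined at 0


class DomainError(ValueError):
    """State outside the model's admissible domain."""


class IntegrationError(RuntimeError):
    """ODE integration failed or blew up."""


# --------------------------------------------------------------------------
# graphs
# --------------------------------------------------------------------------


class WeightedDigraph:
    """N nodes with non-negative influence weights ``M[j, i] = M_ji``.

    Derived statistics: in-weights ``w_in[i] = sum_j M_ji`` (column sums),
    out-weights ``w_out[j] = sum_i M_ji`` (row sums), total weight ``m`` and
    average weighted degree ``w_av = m / N``.
    """

    def __init__(self, M: np.ndarray):
        M = np.asarray(M, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError(f"M must be square, got shape {M.shape}")
        if np.any(M < 0):
            raise ValueError("influence weights must be non-negative")
        self.M = M

    @classmethod
    def from_edges(cls, n: int, edges: Sequence[tuple[int, int, float]]
                   ) -> "WeightedDigraph":
        """Build from (source, target, weight) triples: source influences target."""
        if n < 1:
            raise ValueError("graph needs at least one node")
        M = np.zeros((n, n))
        for src, dst, w in edges:
            M[src, dst] += w
        return cls(M)

    @property
    def N(self) -> int:
        return self.M.shape[0]

    @property
    def w_in(self) -> np.ndarray:
        return self.M.sum(axis=0)

    @property
    def w_out(self) -> np.ndarray:
        return self.M.sum(axis=1)

    @property
    def m(self) -> float:
        return float(self.M.sum())

    @property
    def w_av(self) -> float:
        return self.m / self.N

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.M))

    def copy(self) -> "WeightedDigraph":
        return WeightedDigraph(self.M.copy())

    def remove_links(self, fraction: float, seed=None) -> "WeightedDigraph":
        """Delete a uniformly random ``fraction`` of the existing edges."""
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        rng = np.random.default_rng(seed)
        rows, cols = np.nonzero(self.M)
        n_remove = int(round(fraction * rows.size))
        M = self.M.copy()
        if n_remove:
            pick = rng.choice(rows.size, size=n_remove, replace=False)
            M[rows[pick], cols[pick]] = 0.0
        return WeightedDigraph(M)

    def scale_to_average_weight(self, target_w_av: float) -> "WeightedDigraph":
        """Multiply all weights by one constant so that ``w_av == target``."""
        if target_w_av < 0:
            raise ValueError("target average weight must be >= 0")
        if self.m == 0:
            if target_w_av == 0:
                return self.copy()
            raise ValueError("cannot scale an edgeless graph to a positive w_av")
        return WeightedDigraph(self.M * (target_w_av / self.w_av))


def remove_links(graph: WeightedDigraph, fraction: float, seed=None) -> WeightedDigraph:
    return graph.remove_links(fraction, seed)


def scale_to_average_weight(graph: WeightedDigraph, target_w_av: float) -> WeightedDigraph:
    return graph.scale_to_average_weight(target_w_av)


# --------------------------------------------------------------------------
# models
# --------------------------------------------------------------------------


@dataclass
class DynamicsModel:
    """Base class: parameters, uncertainty bookkeeping, f and g.

    ``params`` maps parameter names to fixed reals, per-node arrays, or
    :class:`RandomInput` references.  ``mode`` selects how uncertain
    parameters are drawn: ``"shared"`` (one value for every node) or
    ``"iid"`` (an independent copy per node).
    """

    params: dict = field(default_factory=dict)
    mode: str = "shared"

    F_PARAMS: ClassVar[tuple[str, ...]] = ()  # parameters entering the self-dynamics
    G_PARAMS: ClassVar[tuple[str, ...]] = ()  # parameters entering the coupling

    def __post_init__(self) -> None:
        if self.mode not in ("shared", "iid"):
            raise ValueError("uncertainty mode must be 'shared' or 'iid'")
        unknown = set(self.params) - set(self.F_PARAMS) - set(self.G_PARAMS)
        if unknown:
            raise ValueError(f"unknown parameters for {type(self).__name__}: {unknown}")
        if self.l > 10:
            raise ValueError("at most 10 uncertain parameters are supported")

    # -- uncertainty bookkeeping ------------------------------------------

    @property
    def uncertain_labels(self) -> tuple[str, ...]:
        """Uncertain parameter names: f-parameters first, then g-parameters."""
        names = [n for n in self.F_PARAMS if isinstance(self.params.get(n), RandomInput)]
        names += [n for n in self.G_PARAMS if isinstance(self.params.get(n), RandomInput)]
        return tuple(names)

    @property
    def uncertain_inputs(self) -> tuple[RandomInput, ...]:
        return tuple(self.params[n] for n in self.uncertain_labels)

    @property
    def l(self) -> int:
        return len(self.uncertain_labels)

    @property
    def l1(self) -> int:
        """Number of uncertain parameters living in the self-dynamics."""
        return sum(1 for n in self.F_PARAMS
                   if isinstance(self.params.get(n), RandomInput))

    def realize(self, realization=None) -> dict:
        """Concrete parameter dict for one realization of the uncertainty.

        ``realization`` may be None (means are used), a mapping from labels
        to values, or a sequence ordered like :attr:`uncertain_labels`.
        Values may be scalars or per-node arrays (iid mode).
        """
        labels = self.uncertain_labels
        if realization is None:
            values = {n: self.params[n].mean for n in labels}
        elif isinstance(realization, Mapping):
            missing = set(labels) - set(realization)
            if missing:
                raise ValueError(f"realization missing values for {sorted(missing)}")
            values = {n: realization[n] for n in labels}
        else:
            realization = list(realization)
            if len(realization) != len(labels):
                raise ValueError(
                    f"realization must supply {len(labels)} values "
                    f"for {labels}, got {len(realization)}"
                )
            values = dict(zip(labels, realization))
        out = {}
        for name, val in self.params.items():
            out[name] = values[name] if name in values else val
        return out

    def draw_realization(self, rng: np.random.Generator, n_nodes: int | None = None):
        """Sample one realization dict; per-node arrays in iid mode."""
        out = {}
        for name in self.uncertain_labels:
            inp: RandomInput = self.params[name]
            if self.mode == "iid":
                if n_nodes is None:
                    raise ValueError("iid mode needs the node count to draw")
                out[name] = inp.sample(n_nodes, rng)
            else:
                out[name] = float(inp.sample(1, rng)[0])
        return out

    # -- dynamics ----------------------------------------------------------

    def f(self, x, p):  # pragma: no cover - abstract
        raise NotImplementedError

    def g(self, xi, xj, p):  # pragma: no cover - abstract
        raise NotImplementedError

    def x_max(self, p) -> float:
        """Upper end of the state scan domain."""
        raise NotImplementedError

    def check_domain(self, x: np.ndarray) -> None:
        """Raise :class:`DomainError` if the state is inadmissible."""

    def coupling(self, x: np.ndarray, graph: WeightedDigraph, p) -> np.ndarray:
        """Full coupling vector ``sum_j M_ji g(x_i, x_j)`` (pairwise default).

        Per-node g-parameters are interpreted with the neighbor index where
        the model says so (see subclasses).
        """
        G = self.pair_matrix(x, p)
        return np.einsum("ji,ji->i", graph.M, G)

    def pair_matrix(self, x: np.ndarray, p) -> np.ndarray:
        """Matrix ``G[j, i] = g(x_i, x_j)`` for the pairwise coupling."""
        xi = x[None, :]
        xj = x[:, None]
        return self.g(xi, xj, p)

    def reduced_coupling(self, node: int, x, x_e0: float,
                         graph: WeightedDigraph, p):
        """Out-weight-averaged neighbor effect for the one-node reduction.

        ``w_in[i] * sum_j w_out[j] g(x, x_e0; b_j) / sum_j w_out[j]``.
        """
        w_out = graph.w_out
        total = w_out.sum()
        if total <= 0:
            raise ValueError("all-zero out-weights; reduction undefined")
        x = np.asarray(x, float)
        hetero = any(np.ndim(p[name]) > 0 for name in self.G_PARAMS if name in p)
        if not hetero:
            gval = self.g(x, x_e0, p)
        else:
            acc = 0.0
            xj = np.full(graph.N, float(x_e0))
            vals = self.g(x[..., None], xj, p)  # broadcast over neighbor axis
            gval = (vals * w_out).sum(axis=-1) / total
        return graph.w_in[node] * gval


@dataclass
class GenericBistable(DynamicsModel):
    """Cubic bistable self-dynamics with a saturating product coupling.

    ``f(x) = -(x - x_lo)(x - x_mid)(x - x_hi)`` has stable roots at ``x_lo``
    (unhealthy) and ``x_hi`` (healthy); ``g(x_i, x_j) = x_i x_j /
    (s + x_i x_j)`` saturates for large states.
    """

    F_PARAMS = ("x_lo", "x_mid", "x_hi")
    G_PARAMS = ("s",)

    def f(self, x, p):
        return -(x - p["x_lo"]) * (x - p["x_mid"]) * (x - p["x_hi"])

    def g(self, xi, xj, p):
        prod = xi * xj
        return prod / (p["s"] + prod)

    def x_max(self, p) -> float:
        return 2.0 * float(np.max(p["x_hi"]))


@dataclass
class Mutualistic(DynamicsModel):
    """Bistable pollinator dynamics with migration, Allee effect and
    saturating mutualistic coupling.

    ``f(x) = B + x (1 - x/K)(x/C - 1)`` and
    ``g(x_i, x_j) = x_i x_j / (D + E x_i + H x_j)``, where ``H`` is carried
    by the neighbor (sending) node.
    """

    F_PARAMS = ("B", "C", "K")
    G_PARAMS = ("D", "E", "H")

    def __post_init__(self) -> None:
        super().__post_init__()
        p = self.params
        for name, cond in (("K", lambda v: v > 0), ("C", lambda v: v > 0),
                           ("D", lambda v: v > 0), ("B", lambda v: v >= 0),
                           ("E", lambda v: v >= 0), ("H", lambda v: v >= 0)):
            v = p.get(name)
            if v is not None and not isinstance(v, RandomInput):
                if not np.all(cond(np.asarray(v, float))):
                    raise ValueError(f"invalid mutualistic parameter {name}={v}")

    def f(self, x, p):
        return p["B"] + x * (1.0 - x / p["K"]) * (x / p["C"] - 1.0)

    def g(self, xi, xj, p):
        # H is indexed by the sending node j; with pair_matrix broadcasting
        # (xj varies along axis 0) a per-node H must be a column vector.
        H = p["H"]
        if np.ndim(H) == 1 and np.ndim(xj) == 2:
            H = np.asarray(H)[:, None]
        return xi * xj / (p["D"] + p["E"] * xi + H * xj)

    def x_max(self, p) -> float:
        return 2.0 * float(np.max(p["K"]))


@dataclass
class Commuter(DynamicsModel):
    """Competitive commuter-flow dynamics between cities.

    Self-dynamics is logistic growth with an Allee threshold:
    ``f(x) = x (1 - x/K)(x/C - 1)``.  The coupling routes each sender's
    out-flow across receivers as competitive shares depending on destination
    attractiveness ``exp(alpha log x)`` and distance cost ``d^beta``
    (``coupling_mode="share"``); ``coupling_mode="literal"`` reproduces the
    non-normalized printed form with the attractiveness argument fixed at
    the receiving node.
    """

    distances: np.ndarray | None = None
    coupling_mode: str = "share"

    F_PARAMS = ("K", "C")
    G_PARAMS = ("alpha", "beta")

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.coupling_mode not in ("share", "literal"):
            raise ValueError("coupling_mode must be 'share' or 'literal'")
        if self.distances is None:
            raise ValueError("commuter dynamics requires a distance matrix")
        d = np.asarray(self.distances, float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(d[~np.eye(d.shape[0], dtype=bool)] <= 0):
            raise ValueError("off-diagonal distances must be positive")
        self.distances = d
        K = self.params.get("K", 1.0)
        C = self.params.get("C", 0.5)
        if not isinstance(K, RandomInput) and not isinstance(C, RandomInput):
            K, C = np.asarray(K, float), np.asarray(C, float)
            if not (np.all(K > 0) and np.all(C > 0) and np.all(K > C)):
                raise ValueError("commuter parameters require K_i > C_i > 0")

    def f(self, x, p):
        return x * (1.0 - x / p["K"]) * (x / p["C"] - 1.0)

    def check_domain(self, x) -> None:
        if np.any(np.asarray(x) < 0):
            raise DomainError("commuter states must be non-negative "
                              "(log-attractiveness undefined)")

    def _attractiveness(self, x: np.ndarray, p) -> np.ndarray:
        xs = np.maximum(np.asarray(x, float), _LOG_GUARD)
        return np.power(xs, p["alpha"])  # exp(alpha log x)

    def coupling(self, x: np.ndarray, graph: WeightedDigraph, p) -> np.ndarray:
        self.check_domain(x)
        d_cost = np.exp(-self.distances ** p["beta"])  # [j, i] = exp(-d_ji^beta)
        if self.coupling_mode == "share":
            A = self._attractiveness(x, p)  # per destination
            S = graph.M * d_cost * A[None, :]  # sender j -> receiver i scores
            denom = S.sum(axis=1)  # per sender
            with np.errstate(invalid="ignore", divide="ignore"):
                shares = np.where(denom[:, None] > 0, S / denom[:, None], 0.0)
            return shares.T @ x  # inflow_i = sum_j shares[j,i] * x_j
        # literal printed form: attractiveness argument is the receiver state
        out = np.zeros(graph.N)
        for i in range(graph.N):
            terms = graph.M[:, i] * x * np.exp(
                p["alpha"] * np.log(np.maximum(x[i], _LOG_GUARD))
                - self.distances[:, i] ** p["beta"]
            )
            denom = np.array([
                np.sum(graph.M[j] * x * np.exp(
                    p["alpha"] * np.log(np.maximum(x[i], _LOG_GUARD))
                    - self.distances[j] ** p["beta"]))
                for j in range(graph.N)
            ])
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(denom > 0, terms / denom, 0.0)
            out[i] = frac.sum()
        return out

    def reduced_coupling(self, node, x, x_e0, graph, p):
        # neighbor states clamped to x_e0, node state free
        x = np.atleast_1d(np.asarray(x, float))
        out = np.empty_like(x)
        state = np.full(graph.N, float(x_e0))
        for k, xv in enumerate(x):
            state[node] = xv
            out[k] = self.coupling(state, graph, p)[node]
        state[node] = x_e0
        return out if out.size > 1 else float(out[0])

    def x_max(self, p) -> float:
        return 2.0 * float(np.max(p["K"]))


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def full_rhs(model: DynamicsModel, graph: WeightedDigraph, x: np.ndarray,
             realization=None) -> np.ndarray:
    """Derivative vector ``f(x_i, a) + sum_j M_ji g(x_i, x_j, b)``."""
    x = np.asarray(x, dtype=float)
    if x.shape != (graph.N,):
        raise ValueError(f"state must have length {graph.N}, got {x.shape}")
    model.check_domain(x)
    p = model.realize(realization)
    return model.f(x, p) + model.coupling(x, graph, p)


@dataclass
class SimulationResult:
    t: np.ndarray
    y: np.ndarray  # (N, n_times)
    rtol: float
    atol: float

    @property
    def terminal(self) -> np.ndarray:
        return self.y[:, -1]


def simulate(model: DynamicsModel, graph: WeightedDigraph, x0: np.ndarray,
             horizon: float, realization=None, rtol: float = 1e-8,
             atol: float = 1e-10, n_report: int = 200) -> SimulationResult:
    """Adaptive ODE integration of the full networked system."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    x0 = np.asarray(x0, dtype=float)
    p = model.realize(realization)

    def rhs(t, x):
        return model.f(x, p) + model.coupling(x, graph, p)

    sol = solve_ivp(rhs, (0.0, horizon), x0, method="LSODA", rtol=rtol,
                    atol=atol, t_eval=np.linspace(0.0, horizon, n_report))
    if not sol.success:
        raise IntegrationError(f"integration failed at t={sol.t[-1]:.4g}: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        bad = np.where(~np.isfinite(sol.y).all(axis=0))[0]
        raise IntegrationError(f"integration blew up at t={sol.t[bad[0]]:.4g}")
    return SimulationResult(sol.t, sol.y, rtol, atol)
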