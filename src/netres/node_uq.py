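"""Node-level resilience estimation and its polynomial-chaos surrogate.

Two-step sequential scheme: the mean-field healthy equilibrium ``x_e0``
(a function of the uncertain parameters) stands in for every neighbor, and
each node's dynamics reduces to one equation driven by its in-weight.  The
node indicator ``tau_i`` — the first interior local minimum of that reduced
right-hand side — is expanded in the moment-based orthonormal basis of the
actual input distributions, and the probability of node resilience is the
fraction of the product measure where the surrogate is positive.  A direct
Monte Carlo estimator over full indicator evaluations provides the
reference baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .dynamics import DynamicsModel, WeightedDigraph
from .meanfield import EffectiveDynamics, healthy_equilibrium, resilience_indicator
from .network_uq import ObservationNoise, ResilienceProbability
from .random_inputs import (
    MultivariateBasis,
    RandomInput,
    multivariate_basis,
    quadrature_rule,
    tensor_quadrature,
)

__all__ = [
    "NodeIndicator",
    "APCSurrogate",
    "NodeResilienceReport",
    "node_reduced_rhs",
    "node_indicator",
    "fit_apc_surrogate",
    "fit_node_apc",
    "node_resilience_probability",
    "mc_node_probability",
    "obs_noise_node_probability",
    "APCFitError",
]


class APCFitError(RuntimeError):
    """Indicator evaluation failed at a design point."""


@dataclass
class NodeIndicator:
    node: int
    tau: float
    x_min: float
    w_in: float
    interior: bool

    @property
    def resilient(self) -> bool:
        return self.tau > 0


@dataclass
class NodeResilienceReport:
    node: int | str
    w_in: float
    probability: float
    method: str
    order: int | None = None
    n_samples: int | None = None
    seed: int | None = None
    stderr: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability {self.probability} outside [0, 1]")


# --------------------------------------------------------------------------
# reduced dynamics and indicator
# --------------------------------------------------------------------------


def node_reduced_rhs(model: DynamicsModel, graph: WeightedDigraph, node: int,
                     x_e0, realization=None) -> EffectiveDynamics:
    """One-node dynamics with neighbors frozen at the mean-field estimate.

    ``x_e0`` may be a number or a callable of the realization.  The coupling
    is the out-weight-averaged neighbor effect scaled by the node's
    in-weight; at ``w_in = 0`` it reduces exactly to the self-dynamics.
    """
    if graph.w_out.sum() <= 0:
        raise ValueError("all out-weights are zero; the reduction is undefined")
    if not 0 <= node < graph.N:
        raise IndexError(f"node {node} outside graph of size {graph.N}")
    p = model.realize(realization)
    xe = float(x_e0(realization)) if callable(x_e0) else float(x_e0)

    def rhs(x):
        x = np.asarray(x, float)
        return model.f(x, p) + model.reduced_coupling(node, x, xe, graph, p)

    return EffectiveDynamics(rhs, model.x_max(p),
                             {"node": node, "x_e0": xe,
                              "w_in": float(graph.w_in[node])})


def node_indicator(model: DynamicsModel, graph: WeightedDigraph, node: int,
                   realization=None, x_e0=None) -> NodeIndicator:
    """Resilience indicator of the reduced node dynamics at one realization."""
    if x_e0 is None:
        x_e0, _ = healthy_equilibrium(model, graph, realization)
    eff = node_reduced_rhs(model, graph, node, x_e0, realization)
    ind = resilience_indicator(eff)
    return NodeIndicator(node, ind.tau, ind.x_min,
                         float(graph.w_in[node]), ind.interior)


# --------------------------------------------------------------------------
# aPC surrogate fitting
# --------------------------------------------------------------------------


@dataclass
class APCSurrogate:
    """Expansion of an indicator over the orthonormal multivariate basis."""

    basis: MultivariateBasis
    coeffs: np.ndarray
    method: str  # tensor-collocation | least-squares
    residual: float
    order: int

    def __post_init__(self) -> None:
        if self.coeffs.shape != (self.basis.Z,):
            raise ValueError("one coefficient per basis function is required")

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        return self.basis.evaluate_matrix(points) @ self.coeffs

    __call__ = evaluate


def _design_points(inputs: Sequence[RandomInput], n: int,
                   rng: np.random.Generator) -> np.ndarray:
    try:
        return np.column_stack([inp.sample(n, rng) for inp in inputs])
    except ValueError:
        # moment-only inputs cannot be sampled; use stratified quadrature nodes
        pts, _ = tensor_quadrature(inputs, max(2, math.ceil(n ** (1 / len(inputs)))))
        idx = rng.choice(pts.shape[0], size=min(n, pts.shape[0]), replace=False)
        return pts[idx]


def fit_apc_surrogate(fn: Callable[[np.ndarray], float],
                      inputs: Sequence[RandomInput], order: int,
                      method: str = "auto", seed: int | None = 0,
                      n_validation: int = 20) -> APCSurrogate:
    """Fit a scalar function of the inputs on the orthonormal basis.

    ``tensor-collocation`` (default for up to 3 inputs) projects on a
    tensorized Gauss grid with ``order + 1`` nodes per dimension — exact for
    polynomial integrands of total degree ``<= order``.  ``least-squares``
    solves a seeded oversampled design of ``2 Z`` points.
    """
    l = len(inputs)
    if l < 1:
        raise ValueError("at least one uncertain input is required")
    if method == "auto":
        method = "tensor-collocation" if l <= 3 else "least-squares"
    if method not in ("tensor-collocation", "least-squares"):
        raise ValueError(f"unknown fit method {method!r}")
    basis = multivariate_basis(inputs, order)
    rng = np.random.default_rng(seed)

    def eval_fn(points: np.ndarray) -> np.ndarray:
        out = np.empty(points.shape[0])
        for i, pt in enumerate(points):
            try:
                out[i] = fn(pt)
            except Exception as exc:  # noqa: BLE001 - reported with the point
                raise APCFitError(
                    f"indicator evaluation failed at design point {pt}: {exc}"
                ) from exc
        return out

    if method == "tensor-collocation":
        points, weights = tensor_quadrature(inputs, order + 1)
        values = eval_fn(points)
        Phi = basis.evaluate_matrix(points)
        coeffs = Phi.T @ (weights * values)
    else:
        points = _design_points(inputs, 2 * basis.Z, rng)
        values = eval_fn(points)
        Phi = basis.evaluate_matrix(points)
        coeffs, *_ = np.linalg.lstsq(Phi, values, rcond=None)

    val_pts = _design_points(inputs, n_validation, rng)
    val_true = eval_fn(val_pts)
    val_hat = basis.evaluate_matrix(val_pts) @ coeffs
    residual = float(np.max(np.abs(val_true - val_hat))) if len(val_pts) else np.nan
    return APCSurrogate(basis, coeffs, method, residual, order)


def _indicator_fn(model: DynamicsModel, graph: WeightedDigraph,
                  node: int) -> Callable[[np.ndarray], float]:
    labels = model.uncertain_labels

    def fn(point: np.ndarray) -> float:
        realization = dict(zip(labels, np.asarray(point, float)))
        return node_indicator(model, graph, node, realization).tau

    return fn


def fit_node_apc(model: DynamicsModel, graph: WeightedDigraph, node: int,
                 inputs: Sequence[RandomInput] | None = None, order: int = 3,
                 method: str = "auto", seed: int | None = 0) -> APCSurrogate:
    """Surrogate of the node indicator over the uncertain model parameters."""
    if inputs is None:
        inputs = model.uncertain_inputs
    if len(inputs) != model.l:
        raise ValueError(
            f"{model.l} uncertain parameters but {len(inputs)} inputs supplied")
    return fit_apc_surrogate(_indicator_fn(model, graph, node), inputs,
                             order, method, seed)


# --------------------------------------------------------------------------
# probabilities
# --------------------------------------------------------------------------


def node_resilience_probability(surrogate: APCSurrogate,
                                inputs: Sequence[RandomInput],
                                n_samples: int = 1_000_000,
                                seed: int | None = 0,
                                node: int | str = "node",
                                w_in: float = float("nan"),
                                ) -> NodeResilienceReport:
    """Fraction of the input product measure where the surrogate is positive."""
    if n_samples < 10_000:
        raise ValueError("n_samples must be >= 10^4 for a stable estimate")
    rng = np.random.default_rng(seed)
    chunk = 200_000
    positive = 0
    remaining = n_samples
    while remaining > 0:
        n = min(chunk, remaining)
        pts = np.column_stack([inp.sample(n, rng) for inp in inputs])
        positive += int(np.count_nonzero(surrogate.evaluate(pts) > 0))
        remaining -= n
    p = positive / n_samples
    se = math.sqrt(p * (1 - p) / n_samples)
    return NodeResilienceReport(node, w_in, p, "apc", order=surrogate.order,
                                n_samples=n_samples, seed=seed, stderr=se)


def mc_node_probability(model: DynamicsModel, graph: WeightedDigraph, node: int,
                        inputs: Sequence[RandomInput] | None = None,
                        n_samples: int = 2000, seed: int | None = 0,
                        max_failure_fraction: float = 0.01,
                        ) -> NodeResilienceReport:
    """Direct Monte Carlo over full indicator evaluations (no surrogate)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if inputs is None:
        inputs = model.uncertain_inputs
    labels = model.uncertain_labels
    rng = np.random.default_rng(seed)
    draws = np.column_stack([inp.sample(n_samples, rng) for inp in inputs]) \
        if inputs else np.zeros((n_samples, 0))
    positive = 0
    failures = 0
    for row in draws:
        realization = dict(zip(labels, row))
        try:
            tau = node_indicator(model, graph, node, realization).tau
        except Exception:  # noqa: BLE001 - counted and bounded below
            failures += 1
            continue
        if tau > 0:
            positive += 1
    if failures > max_failure_fraction * n_samples:
        raise APCFitError(
            f"{failures}/{n_samples} indicator evaluations failed "
            f"(> {max_failure_fraction:.0%})")
    n_ok = n_samples - failures
    p = positive / n_ok
    se = math.sqrt(p * (1 - p) / n_ok)
    return NodeResilienceReport(node, float(graph.w_in[node]), p, "mc",
                                n_samples=n_samples, seed=seed, stderr=se)


def obs_noise_node_probability(tau2: float, noise: ObservationNoise,
                               literal: bool = False) -> ResilienceProbability:
    """Probability that the node survives additive observation noise.

    The node is resilient when ``tau2 + gamma > 0``, i.e. with probability
    ``P(gamma > -tau2)``.  ``literal`` evaluates ``P(gamma > tau2)``
    instead, reproducing the non-negated printed integral bound.
    """
    threshold = tau2 if literal else -tau2
    if noise.delta_gamma == 0.0 or noise.input is None:
        return ResilienceProbability(
            1.0 if noise.mu_gamma > threshold else 0.0, "closed-form")
    inp = noise.input
    if inp.kind == "moment-sequence":
        n_nodes = max((inp.spec["moments"].size - 1) // 2, 1)
        nodes, weights = quadrature_rule(inp, n_nodes)
        value = float(weights[nodes > threshold].sum())
        return ResilienceProbability(value, "closed-form",
                                     meta={"quadrature_nodes": n_nodes})
    return ResilienceProbability(float(1.0 - inp.cdf(threshold)), "closed-form")
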