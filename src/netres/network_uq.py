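"""Network-level uncertainty quantification.

With an independent copy of each uncertain parameter per node, the node
averages in the mean-field equation become Gaussian by the central limit
theorem; the whole effective curve is then driven by a single standard
normal variable ``zeta`` with spread shrinking as ``1/sqrt(N)``.  The
resilience indicator ``tau(zeta)`` is expanded in normalized probabilists'
Hermite polynomials and the probability of resilience is the Gaussian
measure of ``{tau > 0}``, evaluated analytically from the surrogate's
roots.  A closed form covers additive observation noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial import hermite_e as herme
from numpy.polynomial import polynomial as npoly
from scipy.interpolate import CubicSpline
from scipy.stats import norm

from .dynamics import DynamicsModel, WeightedDigraph
from .meanfield import EffectiveDynamics, resilience_indicator
from .random_inputs import RandomInput, tensor_quadrature

__all__ = [
    "CLTStatistics",
    "GaussianEnsemble",
    "PCESurrogate",
    "ResilienceProbability",
    "ObservationNoise",
    "clt_statistics",
    "xi_realization",
    "fit_tau_pce",
    "network_resilience_probability",
    "obs_noise_network_probability",
    "PCEFitError",
]


class PCEFitError(RuntimeError):
    """The indicator could not be evaluated at a quadrature node."""


@dataclass
class CLTStatistics:
    """Mean and spread of the self- and coupling terms on a state grid."""

    x_grid: np.ndarray
    mu_f: np.ndarray
    delta_f: np.ndarray
    mu_g: np.ndarray
    delta_g: np.ndarray
    provenance: dict = field(default_factory=dict)


@dataclass
class ResilienceProbability:
    value: float
    method: str
    stderr: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"probability {self.value} outside [0, 1]")

    def __float__(self) -> float:
        return self.value


@dataclass
class ObservationNoise:
    """Additive observation noise with mean ``mu_gamma`` and spread ``delta_gamma``."""

    input: RandomInput | None
    mu_gamma: float
    delta_gamma: float

    def __post_init__(self) -> None:
        if self.delta_gamma < 0:
            raise ValueError("delta_gamma must be >= 0")

    @classmethod
    def from_input(cls, inp: RandomInput) -> "ObservationNoise":
        return cls(inp, inp.mean, inp.std)

    @classmethod
    def gaussian(cls, mu: float, delta: float) -> "ObservationNoise":
        inp = RandomInput.gaussian(mu, delta, label="gamma") if delta > 0 else None
        return cls(inp, mu, delta)


# --------------------------------------------------------------------------
# CLT propagation
# --------------------------------------------------------------------------


def _group_statistics(func, x_grid: np.ndarray, model: DynamicsModel,
                      group: Sequence[str], n_quad: int):
    """Quadrature mean/spread of ``func(x; params)`` over the group's inputs."""
    p0 = model.realize(None)
    labels = [n for n in group if n in model.uncertain_labels]
    if not labels:
        vals = np.asarray(func(x_grid, p0), float)
        return vals, np.zeros_like(vals)
    inputs = [model.params[n] for n in labels]
    points, weights = tensor_quadrature(inputs, n_quad)
    mean = np.zeros_like(x_grid, dtype=float)
    second = np.zeros_like(x_grid, dtype=float)
    for pt, w in zip(points, weights):
        p = dict(p0)
        p.update(dict(zip(labels, pt)))
        vals = np.asarray(func(x_grid, p), float)
        mean += w * vals
        second += w * vals**2
    delta = np.sqrt(np.maximum(second - mean**2, 0.0))
    return mean, delta


def clt_statistics(model: DynamicsModel, x_grid: np.ndarray,
                   quadrature_size: int = 8) -> CLTStatistics:
    """Tabulate ``mu_f, delta_f, mu_g, delta_g`` on the state grid.

    Valid in the iid-per-node regime; a warning is raised for shared-draw
    models, whose network probability should go through the moment-based
    surrogate path instead.
    """
    if model.mode != "iid":
        warnings.warn(
            "CLT propagation assumes iid-per-node uncertainty; the model is "
            "in 'shared' mode", stacklevel=2)
    x_grid = np.asarray(x_grid, float)
    mu_f, delta_f = _group_statistics(model.f, x_grid, model,
                                      model.F_PARAMS, quadrature_size)
    g_of_x = lambda x, p: model.g(x, x, p)
    mu_g, delta_g = _group_statistics(g_of_x, x_grid, model,
                                      model.G_PARAMS, quadrature_size)
    return CLTStatistics(x_grid, mu_f, delta_f, mu_g, delta_g,
                         {"model": type(model).__name__,
                          "quadrature_size": quadrature_size})


@dataclass
class GaussianEnsemble:
    """Family of effective curves driven by a standard normal ``zeta``."""

    stats: CLTStatistics
    graph: WeightedDigraph

    def spread(self) -> np.ndarray:
        N, m = self.graph.N, self.graph.m
        return np.sqrt(self.stats.delta_f**2 / N
                       + m * self.stats.delta_g**2 / N**2)

    def mean_curve(self) -> np.ndarray:
        return self.stats.mu_f + (self.graph.m / self.graph.N) * self.stats.mu_g

    def realize(self, zeta: float) -> EffectiveDynamics:
        values = self.mean_curve() + self.spread() * zeta
        spline = CubicSpline(self.stats.x_grid, values)
        return EffectiveDynamics(spline, float(self.stats.x_grid[-1]),
                                 {"zeta": zeta, "N": self.graph.N})


def xi_realization(stats: CLTStatistics, graph: WeightedDigraph,
                   zeta: float) -> EffectiveDynamics:
    """One realization of the effective dynamics for a draw of ``zeta``."""
    if graph.N < 30:
        warnings.warn(f"CLT approximation is crude for N={graph.N} < 30",
                      stacklevel=2)
    return GaussianEnsemble(stats, graph).realize(zeta)


# --------------------------------------------------------------------------
# Hermite PCE of tau(zeta)
# --------------------------------------------------------------------------

def _normalized_hermite_design(z: np.ndarray, order: int) -> np.ndarray:
    """Matrix ``[He_k(z)/sqrt(k!)]`` of shape (len(z), order+1)."""
    cols = []
    for k in range(order + 1):
        e_k = np.zeros(k + 1)
        e_k[k] = 1.0
        cols.append(herme.hermeval(z, e_k) / math.sqrt(math.factorial(k)))
    return np.column_stack(cols)


@dataclass
class PCESurrogate:
    """Hermite expansion of the network indicator ``tau`` in ``zeta``."""

    order: int
    coeffs: np.ndarray  # on the normalized probabilists' Hermite basis
    residual: float
    n_quad: int
    fallback_nodes: tuple[float, ...] = ()

    def evaluate(self, zeta) -> np.ndarray:
        scaled = self.coeffs / np.array(
            [math.sqrt(math.factorial(k)) for k in range(self.order + 1)])
        return herme.hermeval(np.asarray(zeta, float), scaled)

    __call__ = evaluate

    def power_coefficients(self) -> np.ndarray:
        scaled = self.coeffs / np.array(
            [math.sqrt(math.factorial(k)) for k in range(self.order + 1)])
        return herme.herme2poly(scaled)


def _tau_of_zeta(ensemble: GaussianEnsemble, zeta: float, strict: bool):
    ind = resilience_indicator(ensemble.realize(zeta))
    if not ind.interior and strict:
        raise PCEFitError(
            f"indicator has no interior local minimum at zeta={zeta:.4g}")
    return ind.tau, ind.interior


def fit_tau_pce(stats: CLTStatistics, graph: WeightedDigraph, order: int,
                n_quad: int | None = None, strict: bool = False) -> PCESurrogate:
    """Discrete projection of ``tau(zeta)`` on Gauss-Hermite nodes.

    ``n_quad`` defaults to ``2 * order + 2``.  With ``strict`` the fit fails
    on any node where the indicator has no interior minimum; otherwise the
    flagged fallback value is used and the node recorded.
    """
    if order < 1:
        raise ValueError("PCE order must be >= 1")
    n_quad = 2 * order + 2 if n_quad is None else n_quad
    if n_quad < order + 1:
        raise ValueError("n_quad must be at least order + 1")
    ensemble = GaussianEnsemble(stats, graph)
    z, w = herme.hermegauss(n_quad)
    w = w / w.sum()
    taus = np.empty(n_quad)
    fallback = []
    for i, zi in enumerate(z):
        taus[i], interior = _tau_of_zeta(ensemble, zi, strict)
        if not interior:
            fallback.append(float(zi))
    design = _normalized_hermite_design(z, order)
    coeffs = design.T @ (w * taus)
    # held-out validation nodes
    z_val, _ = herme.hermegauss(n_quad + 3)
    tau_val = np.array([_tau_of_zeta(ensemble, zv, False)[0] for zv in z_val])
    approx = _normalized_hermite_design(z_val, order) @ coeffs
    residual = float(np.max(np.abs(tau_val - approx)))
    return PCESurrogate(order, coeffs, residual, n_quad, tuple(fallback))


def network_resilience_probability(surrogate: PCESurrogate) -> ResilienceProbability:
    """Standard-normal measure of ``{zeta : tau_r(zeta) > 0}``, exactly.

    Real roots of the degree-r surrogate split the line into intervals; the
    probability is the sum of the Gaussian measures of those where the
    surrogate is positive.
    """
    power = surrogate.power_coefficients()
    power = np.trim_zeros(power, "b")
    if power.size <= 1:
        value = 1.0 if (power.size and power[0] > 0) else 0.0
        return ResilienceProbability(value, "pce-analytic")
    roots = npoly.polyroots(power)
    real = np.sort(np.unique(np.real(
        roots[np.abs(np.imag(roots)) < 1e-9 * (1 + np.abs(roots))])))
    edges = np.concatenate(([-np.inf], real, [np.inf]))
    prob = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        if a == b:
            continue
        if np.isinf(a) and np.isinf(b):
            mid = 0.0
        elif np.isinf(a):
            mid = b - 1.0
        elif np.isinf(b):
            mid = a + 1.0
        else:
            mid = 0.5 * (a + b)
        if npoly.polyval(mid, power) > 0:
            prob += norm.cdf(b) - norm.cdf(a)
    return ResilienceProbability(float(min(max(prob, 0.0), 1.0)), "pce-analytic",
                                 meta={"order": surrogate.order,
                                       "residual": surrogate.residual,
                                       "coefficients": surrogate.coeffs.tolist()})


# --------------------------------------------------------------------------
# observation noise, network level
# --------------------------------------------------------------------------


def obs_noise_network_probability(tau1: float, noise: ObservationNoise,
                                  N: int) -> ResilienceProbability:
    """Gaussian tail probability for additive observation noise.

    The node-averaged noise is ``N(mu_gamma, delta_gamma^2 / N)``; the
    system is resilient when it exceeds ``-tau1``.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    shift = tau1 + noise.mu_gamma
    if noise.delta_gamma == 0.0:
        return ResilienceProbability(1.0 if shift > 0 else 0.0, "closed-form")
    value = float(norm.cdf(shift * math.sqrt(N) / noise.delta_gamma))
    return ResilienceProbability(value, "closed-form", meta={"N": N})
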