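"""One-dimensional mean-field reduction, equilibria, and resilience indicators.

The N coupled node equations collapse to a single effective equation
``Xi(x) = (1/N) sum_i f(x, a) + (1/N) sum_{i,j} M_ji g(x, x, b)`` which, for
homogeneous parameters, is ``f(x) + w_av * g(x, x)``.  Resilience is read
off the geometry of ``Xi``: the value ``tau`` of its first interior local
minimum is positive exactly when only the healthy equilibrium survives, and
the average weight at which ``tau`` crosses zero is the saddle-node
threshold ``w*``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .dynamics import Commuter, DynamicsModel, WeightedDigraph

__all__ = [
    "EffectiveDynamics",
    "EquilibriumSet",
    "ResilienceIndicator",
    "CriticalCurve",
    "ThresholdResult",
    "effective_rhs",
    "equilibria",
    "resilience_indicator",
    "healthy_equilibrium",
    "critical_threshold",
    "critical_weight_curve",
]

ROOT_TOL = 1e-10
MIN_TOL = 1e-8
N_GRID = 2000


@dataclass
class EffectiveDynamics:
    """A 1-D right-hand side with its scan domain and provenance."""

    rhs: Callable[[np.ndarray], np.ndarray]
    x_max: float
    provenance: dict = field(default_factory=dict)

    def __call__(self, x):
        return self.rhs(x)


@dataclass
class EquilibriumSet:
    """Roots of the effective dynamics with stability from the slope sign."""

    roots: np.ndarray
    stable: np.ndarray

    @property
    def n_stable(self) -> int:
        return int(np.count_nonzero(self.stable))

    @property
    def healthy(self) -> float | None:
        """Largest stable root (the desired state far from the origin)."""
        st = self.roots[self.stable]
        return float(st[-1]) if st.size else None

    @property
    def unhealthy(self) -> float | None:
        """Stable root near the origin, present only in the bistable regime."""
        st = self.roots[self.stable]
        return float(st[0]) if st.size > 1 else None


@dataclass
class ResilienceIndicator:
    """Value and location of the relevant local minimum of the rhs."""

    tau: float
    x_min: float
    interior: bool  # False when no strict interior minimum was found

    @property
    def resilient(self) -> bool:
        return self.tau > 0


@dataclass
class ThresholdResult:
    """Saddle-node location in average weight, with the final bisection bracket."""

    w_star: float
    lo: float
    hi: float

    def __float__(self) -> float:
        return self.w_star


@dataclass
class CriticalCurve:
    w_av: np.ndarray
    w_crit: np.ndarray
    x_e0: np.ndarray
    tau: np.ndarray
    w_star: float | None
    discontinuities: np.ndarray  # w_av locations of jumps in w_crit


# --------------------------------------------------------------------------
# effective dynamics
# --------------------------------------------------------------------------


def effective_rhs(model: DynamicsModel, graph: WeightedDigraph,
                  realization=None) -> EffectiveDynamics:
    """Mean-field right-hand side for a fixed parameter realization."""
    p = model.realize(realization)
    x_max = model.x_max(p)
    homogeneous = all(np.ndim(v) == 0 for v in p.values())
    if homogeneous and not isinstance(model, Commuter):
        w_av = graph.w_av

        def rhs(x):
            x = np.asarray(x, float)
            return model.f(x, p) + w_av * model.g(x, x, p)

    else:
        N = graph.N

        def rhs(x):
            xs = np.atleast_1d(np.asarray(x, float))
            out = np.empty_like(xs)
            for k, xv in enumerate(xs):
                state = np.full(N, xv)
                out[k] = (np.mean(model.f(state, p))
                          + model.coupling(state, graph, p).sum() / N)
            return out if np.ndim(x) else float(out[0])

    return EffectiveDynamics(rhs, x_max,
                             {"model": type(model).__name__, "N": graph.N,
                              "w_av": graph.w_av, "realization": realization})


# --------------------------------------------------------------------------
# equilibria and indicators
# --------------------------------------------------------------------------


def equilibria(eff: EffectiveDynamics, n_grid: int = N_GRID) -> EquilibriumSet:
    """All roots on [0, x_max] by sign-scan plus bracketed refinement."""
    xs = np.linspace(0.0, eff.x_max, n_grid + 1)
    v = np.asarray(eff.rhs(xs), float)
    roots = []
    for i in range(n_grid):
        a, b = v[i], v[i + 1]
        if a == 0.0:
            roots.append(xs[i])
        elif a * b < 0:
            roots.append(brentq(eff.rhs, xs[i], xs[i + 1], xtol=ROOT_TOL / 10,
                                rtol=4 * np.finfo(float).eps))
    if v[-1] == 0.0:
        roots.append(xs[-1])
    roots = np.array(sorted(set(roots)))
    if roots.size == 0:
        warnings.warn("no equilibrium found on the scan domain", stacklevel=2)
        return EquilibriumSet(roots, np.zeros(0, dtype=bool))
    h = max(eff.x_max * 1e-7, 1e-9)
    lo = np.maximum(roots - h, 0.0)  # stay inside the model domain
    hi = np.minimum(roots + h, eff.x_max)
    slope = (np.asarray(eff.rhs(hi)) - np.asarray(eff.rhs(lo))) / (hi - lo)
    return EquilibriumSet(roots, slope < 0)


def _indicator(eff: EffectiveDynamics, n_grid: int = N_GRID) -> ResilienceIndicator:
    eqs = equilibria(eff, n_grid)
    x_hi = eqs.healthy if eqs.healthy is not None else eff.x_max
    xs = np.linspace(0.0, x_hi, n_grid)
    v = np.asarray(eff.rhs(xs), float)
    interior = np.where((v[1:-1] < v[:-2]) & (v[1:-1] < v[2:]))[0]
    if interior.size:
        i = int(interior[0]) + 1
        res = minimize_scalar(lambda x: float(eff.rhs(x)),
                              bounds=(xs[i - 1], xs[i + 1]), method="bounded",
                              options={"xatol": MIN_TOL / 10})
        return ResilienceIndicator(float(res.fun), float(res.x), True)
    # monotone-then-down shape: report the minimum over the open interval
    j = int(np.argmin(v[1:-1])) + 1 if v.size > 2 else 0
    return ResilienceIndicator(float(v[j]), float(xs[j]), False)


def resilience_indicator(eff: EffectiveDynamics,
                         n_grid: int = N_GRID) -> ResilienceIndicator:
    """First strict interior local minimum of the rhs on (0, x_healthy)."""
    return _indicator(eff, n_grid)


def healthy_equilibrium(model: DynamicsModel, graph: WeightedDigraph,
                        realization=None) -> tuple[float, bool]:
    """Largest non-negative root of the effective dynamics.

    Returns ``(x_e0, multiple_stable)``; the flag marks coexistence of an
    unhealthy stable root (the estimate is single-valued only in the
    resilient regime).
    """
    eff = effective_rhs(model, graph, realization)
    eqs = equilibria(eff)
    if eqs.roots.size == 0:
        raise ValueError("effective dynamics has no root on the scan domain")
    return float(eqs.roots[-1]), eqs.n_stable > 1


# --------------------------------------------------------------------------
# critical weights
# --------------------------------------------------------------------------


def _require_deterministic(model: DynamicsModel) -> dict:
    if model.l:
        raise ValueError("critical-weight analysis requires deterministic "
                         f"parameters; {model.uncertain_labels} are uncertain")
    return model.realize(None)


def _mean_field_rhs(model: DynamicsModel, w_av: float, p: dict) -> EffectiveDynamics:
    def rhs(x):
        x = np.asarray(x, float)
        return model.f(x, p) + w_av * model.g(x, x, p)
    return EffectiveDynamics(rhs, model.x_max(p), {"w_av": w_av})


def tau_of_w_av(model: DynamicsModel, w_av: float) -> float:
    """Network indicator of the homogeneous mean-field system at ``w_av``."""
    p = _require_deterministic(model)
    return _indicator(_mean_field_rhs(model, w_av, p)).tau


def critical_threshold(model: DynamicsModel, bracket: tuple[float, float] = (0.0, 20.0),
                       tol: float = 5e-4) -> ThresholdResult:
    """Bisection on ``w_av`` for the zero crossing of ``tau``.

    The returned bracket has width below ``2 * tol`` (< 1e-3 by default).
    """
    p = _require_deterministic(model)
    lo, hi = bracket
    tau_lo = _indicator(_mean_field_rhs(model, lo, p)).tau
    tau_hi = _indicator(_mean_field_rhs(model, hi, p)).tau
    if tau_lo > 0 or tau_hi < 0:
        raise ValueError(
            f"tau does not change sign over bracket {bracket}: "
            f"tau({lo})={tau_lo:.4g}, tau({hi})={tau_hi:.4g}"
        )
    while hi - lo > 2 * tol:
        mid = 0.5 * (lo + hi)
        if _indicator(_mean_field_rhs(model, mid, p)).tau > 0:
            hi = mid
        else:
            lo = mid
    return ThresholdResult(0.5 * (lo + hi), lo, hi)


def _collapse_equilibrium(eqs: EquilibriumSet) -> float:
    """Equilibrium reached from the collapsed (near-zero) state.

    In the bistable regime this is the unhealthy root near the origin; once
    that root vanishes the state jumps to the healthy branch — the source of
    the discontinuity in the critical-weight curve.
    """
    st = eqs.roots[eqs.stable]
    if st.size == 0:
        raise ValueError("no stable equilibrium")
    return float(st[0])


def _node_tau(model: DynamicsModel, w_in: float, x_e0: float, p: dict) -> float:
    def rhs(x):
        x = np.asarray(x, float)
        return model.f(x, p) + w_in * model.g(x, x_e0, p)
    return _indicator(EffectiveDynamics(rhs, model.x_max(p))).tau


def critical_weight_curve(model: DynamicsModel, w_av_grid: Sequence[float],
                          w_in_cap: float = 1e4, tol: float = 1e-4) -> CriticalCurve:
    """Critical in-weight ``w_crit`` versus average weight ``w_av``.

    For each grid point the neighbor-state estimate ``x_e0`` is the
    equilibrium reached from the collapsed state; ``w_crit`` is the smallest
    in-weight at which the one-node reduced dynamics becomes resilient
    (0 when the node indicator is positive already at ``w_in = 0``).
    """
    p = _require_deterministic(model)
    w_av_grid = np.asarray(w_av_grid, float)
    if w_av_grid.size == 0 or np.any(np.diff(w_av_grid) <= 0):
        raise ValueError("w_av grid must be non-empty and sorted ascending")
    w_crit = np.empty_like(w_av_grid)
    x_e0s = np.empty_like(w_av_grid)
    taus = np.empty_like(w_av_grid)
    for idx, w_av in enumerate(w_av_grid):
        eff = _mean_field_rhs(model, w_av, p)
        eqs = equilibria(eff)
        x_e0 = _collapse_equilibrium(eqs)
        taus[idx] = _indicator(eff).tau
        x_e0s[idx] = x_e0
        if _node_tau(model, 0.0, x_e0, p) > 0:
            w_crit[idx] = 0.0
            continue
        lo, hi = 0.0, 1.0
        while _node_tau(model, hi, x_e0, p) <= 0:
            hi *= 2.0
            if hi > w_in_cap:
                w_crit[idx] = np.inf
                break
        else:
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                if _node_tau(model, mid, x_e0, p) > 0:
                    hi = mid
                else:
                    lo = mid
            w_crit[idx] = 0.5 * (lo + hi)
    try:
        w_star = critical_threshold(
            model, bracket=(float(w_av_grid[0]), float(w_av_grid[-1]))).w_star
    except ValueError:
        w_star = None
    finite = np.isfinite(w_crit)
    jumps = np.abs(np.diff(np.where(finite, w_crit, np.nan)))
    with np.errstate(invalid="ignore"):
        disc = w_av_grid[1:][jumps > max(1.0, 10 * np.nanmedian(jumps))]
    return CriticalCurve(w_av_grid, w_crit, x_e0s, taus, w_star, disc)
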