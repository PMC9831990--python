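"""Uncertain inputs of arbitrary distribution and their moment-based polynomial bases.

An uncertain parameter may be described three ways: a named distribution
family, a finite set of empirical samples, or a finite sequence of raw
moments.  All three feed the same downstream machinery, because everything
here is driven purely by raw moments ``mu_k = E[xi^k]``:

* a triangle of *monic* orthogonal polynomials, each obtained by solving a
  Hankel-type linear system in the raw moments,
* their orthonormalized counterparts (positive leading coefficient),
* Gauss quadrature rules obtained from the three-term recurrence of the
  monic polynomials (Golub-Welsch),
* graded multi-index sets and tensor-product multivariate bases for several
  independent inputs.

For numerical sanity every input is standardized to zero mean and unit
variance before any moment matrix is formed; evaluation maps back through
the affine transform, so results are expressed in the original variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product as _iproduct
from typing import Callable, Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import stats

__all__ = [
    "RandomInput",
    "MomentTable",
    "UnivariateBasis",
    "MultiIndexSet",
    "MultivariateBasis",
    "raw_moments",
    "monic_orthogonal_basis",
    "orthonormalize",
    "multi_index_set",
    "evaluate_basis",
    "quadrature_rule",
    "IllConditionedError",
    "DegenerateMeasureError",
]

#: Hankel solves with condition number above this are rejected.
CONDITION_THRESHOLD = 1e12

#: Largest supported polynomial degree (moment determinacy becomes
#: unreliable for sampled data beyond this).
MAX_DEGREE = 10


class IllConditionedError(ValueError):
    """Moment matrix too ill-conditioned to build the requested basis."""


class DegenerateMeasureError(ValueError):
    """The measure has too few support atoms for the requested operation."""


# --------------------------------------------------------------------------
# moment tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MomentTable:
    """Raw moments ``mu_k`` for ``k = 0..max_order`` of a scalar measure.

    ``std_values`` optionally carries the moments of the standardized
    variable computed directly at the source (exact for most input kinds);
    without it they are recovered by a binomial transform of the raw
    moments, which loses precision when ``|mean|/std`` is large.
    """

    max_order: int
    values: np.ndarray
    std_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.std_values is not None:
            sv = np.asarray(self.std_values, dtype=float)
            if sv.shape != vals.shape:
                raise ValueError("std_values must match values in length")
            object.__setattr__(self, "std_values", sv)
        if vals.shape != (self.max_order + 1,):
            raise ValueError(
                f"expected {self.max_order + 1} moment values, got {vals.shape}"
            )
        if not np.isclose(vals[0], 1.0, atol=1e-12):
            raise ValueError(f"mu_0 must equal 1, got {vals[0]!r}")
        even = vals[::2]
        if np.any(even < -1e-12):
            raise ValueError("even-order raw moments must be non-negative")
        if self.max_order >= 2 and vals[2] - vals[1] ** 2 < -1e-12:
            raise ValueError("central variance mu_2 - mu_1^2 must be >= 0")

    def __getitem__(self, k: int) -> float:
        if not 0 <= k <= self.max_order:
            raise IndexError(f"moment order {k} outside table (max {self.max_order})")
        return float(self.values[k])

    @property
    def mean(self) -> float:
        return self[1]

    @property
    def variance(self) -> float:
        return self[2] - self[1] ** 2

    def standardized(self) -> "MomentTable":
        """Moments of ``z = (xi - mean)/std``."""
        if self.std_values is not None:
            return MomentTable(self.max_order, self.std_values)
        m, var = self.mean, self.variance
        if var <= 0:
            raise DegenerateMeasureError("cannot standardize a zero-variance measure")
        s = math.sqrt(var)
        out = np.zeros(self.max_order + 1)
        for k in range(self.max_order + 1):
            terms = [math.comb(k, i) * (-m) ** (k - i) * self.values[i]
                     for i in range(k + 1)]
            out[k] = math.fsum(terms) / s**k
        return MomentTable(self.max_order, out)


# --------------------------------------------------------------------------
# random inputs
# --------------------------------------------------------------------------

_NAMED_FAMILIES = ("uniform", "gaussian", "beta", "gamma", "discrete-pmf")


@dataclass
class RandomInput:
    """An uncertain scalar parameter.

    ``kind`` is one of ``named-distribution``, ``empirical-samples`` or
    ``moment-sequence``; ``spec`` carries the family parameters, the sample
    array, or the raw-moment list respectively.
    """

    label: str
    kind: str
    spec: dict = field(default_factory=dict)
    support: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind == "named-distribution":
            self._init_named()
        elif self.kind == "empirical-samples":
            self._init_samples()
        elif self.kind == "moment-sequence":
            self._init_moments()
        else:
            raise ValueError(f"unknown input kind {self.kind!r}")

    # -- constructors ------------------------------------------------------

    @classmethod
    def uniform(cls, lower: float, upper: float, label: str = "xi") -> "RandomInput":
        return cls(label, "named-distribution",
                   {"family": "uniform", "lower": lower, "upper": upper})

    @classmethod
    def gaussian(cls, mean: float, std: float, label: str = "xi") -> "RandomInput":
        return cls(label, "named-distribution",
                   {"family": "gaussian", "mean": mean, "std": std})

    @classmethod
    def beta(cls, a: float, b: float, lower: float = 0.0, upper: float = 1.0,
             label: str = "xi") -> "RandomInput":
        return cls(label, "named-distribution",
                   {"family": "beta", "a": a, "b": b, "lower": lower, "upper": upper})

    @classmethod
    def gamma(cls, shape: float, scale: float = 1.0, loc: float = 0.0,
              label: str = "xi") -> "RandomInput":
        return cls(label, "named-distribution",
                   {"family": "gamma", "shape": shape, "scale": scale, "loc": loc})

    @classmethod
    def discrete(cls, atoms: Sequence[float], probs: Sequence[float],
                 label: str = "xi") -> "RandomInput":
        return cls(label, "named-distribution",
                   {"family": "discrete-pmf", "atoms": list(atoms),
                    "probs": list(probs)})

    @classmethod
    def from_samples(cls, samples: Sequence[float], label: str = "xi") -> "RandomInput":
        return cls(label, "empirical-samples", {"samples": np.asarray(samples, float)})

    @classmethod
    def from_moments(cls, moments: Sequence[float], label: str = "xi") -> "RandomInput":
        return cls(label, "moment-sequence", {"moments": np.asarray(moments, float)})

    # -- kind-specific initialisation -------------------------------------

    def _init_named(self) -> None:
        fam = self.spec.get("family")
        if fam not in _NAMED_FAMILIES:
            raise ValueError(f"unknown distribution family {fam!r}")
        if fam == "uniform":
            lo, hi = self.spec["lower"], self.spec["upper"]
            if not hi > lo:
                raise ValueError(f"uniform requires upper > lower, got [{lo}, {hi}]")
            self._dist = stats.uniform(loc=lo, scale=hi - lo)
            self.support = (lo, hi)
        elif fam == "gaussian":
            mean, std = self.spec["mean"], self.spec["std"]
            if std <= 0:
                raise ValueError(f"gaussian requires std > 0, got {std}")
            self._dist = stats.norm(loc=mean, scale=std)
        elif fam == "beta":
            a, b = self.spec["a"], self.spec["b"]
            lo = self.spec.get("lower", 0.0)
            hi = self.spec.get("upper", 1.0)
            if a <= 0 or b <= 0:
                raise ValueError("beta requires a > 0 and b > 0")
            if not hi > lo:
                raise ValueError("beta requires upper > lower")
            self._dist = stats.beta(a, b, loc=lo, scale=hi - lo)
            self.support = (lo, hi)
        elif fam == "gamma":
            shape = self.spec["shape"]
            scale = self.spec.get("scale", 1.0)
            loc = self.spec.get("loc", 0.0)
            if shape <= 0 or scale <= 0:
                raise ValueError("gamma requires shape > 0 and scale > 0")
            self._dist = stats.gamma(shape, loc=loc, scale=scale)
            self.support = (loc, math.inf)
        else:  # discrete-pmf
            atoms = np.asarray(self.spec["atoms"], float)
            probs = np.asarray(self.spec["probs"], float)
            if atoms.shape != probs.shape or atoms.ndim != 1 or atoms.size == 0:
                raise ValueError("discrete-pmf needs matching 1-D atoms and probs")
            if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
                raise ValueError("discrete-pmf probabilities must be >= 0 and sum to 1")
            self._atoms, self._probs = atoms, probs
            self._dist = None
            self.support = (float(atoms.min()), float(atoms.max()))

    def _init_samples(self) -> None:
        samples = np.asarray(self.spec["samples"], float)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("empirical-samples requires at least 2 sample values")
        if np.var(samples) <= 0:
            raise ValueError("empirical-samples requires positive sample variance")
        self.spec["samples"] = samples
        self.support = (float(samples.min()), float(samples.max()))

    def _init_moments(self) -> None:
        mu = np.asarray(self.spec["moments"], float)
        if mu.ndim != 1 or mu.size < 1:
            raise ValueError("moment-sequence requires a 1-D list of raw moments")
        if not np.isclose(mu[0], 1.0):
            raise ValueError(f"moment-sequence must start with mu_0 = 1, got {mu[0]}")
        # Hankel positive-semidefiniteness up to the largest square block.
        n = (mu.size + 1) // 2
        H = np.array([[mu[i + j] for j in range(n)] for i in range(n)])
        scale = max(1.0, np.abs(H).max())
        if np.linalg.eigvalsh(H).min() < -1e-8 * scale:
            raise ValueError("moment-sequence Hankel matrix is not positive semidefinite")
        self.spec["moments"] = mu

    # -- queries -----------------------------------------------------------

    def moment(self, k: int) -> float:
        """Raw moment ``E[xi^k]``."""
        if k < 0:
            raise ValueError("moment order must be >= 0")
        if k == 0:
            return 1.0
        if self.kind == "moment-sequence":
            mu = self.spec["moments"]
            if k >= mu.size:
                raise ValueError(
                    f"moment of order {k} requested but only orders up to "
                    f"{mu.size - 1} were supplied for input {self.label!r}"
                )
            return float(mu[k])
        if self.kind == "empirical-samples":
            return float(np.mean(self.spec["samples"] ** k))
        if self.spec["family"] == "discrete-pmf":
            return float(np.dot(self._probs, self._atoms**k))
        val = float(self._dist.moment(k))
        if not np.isfinite(val):
            raise ValueError(f"moment of order {k} does not exist for {self.label!r}")
        return val

    @property
    def mean(self) -> float:
        return self.moment(1)

    @property
    def std(self) -> float:
        return math.sqrt(max(self.moment(2) - self.moment(1) ** 2, 0.0))

    def standardized_moment(self, k: int) -> float | None:
        """``E[z^k]`` for ``z = (xi - mean)/std``, computed at the source.

        Exact closed forms where available; ``None`` signals that only the
        binomial transform of the raw moments is possible (moment-sequence
        inputs).
        """
        if k == 0:
            return 1.0
        if k == 1:
            return 0.0
        if self.kind == "empirical-samples":
            samples = self.spec["samples"]
            z = (samples - samples.mean()) / samples.std()
            return float(np.mean(z**k))
        if self.kind == "moment-sequence":
            return None
        fam = self.spec["family"]
        if fam == "uniform":
            return math.sqrt(3.0) ** k / (k + 1) if k % 2 == 0 else 0.0
        if fam == "gaussian":
            if k % 2:
                return 0.0
            acc = 1.0
            for j in range(k - 1, 0, -2):
                acc *= j
            return acc
        if fam == "discrete-pmf":
            z = (self._atoms - self.mean) / self.std
            return float(np.dot(self._probs, z**k))
        m, s = self.mean, self.std
        return float(self._dist.expect(lambda x: ((x - m) / s) ** k))

    def cdf(self, x: float) -> float:
        if self.kind == "empirical-samples":
            return float(np.mean(self.spec["samples"] <= x))
        if self.kind == "named-distribution":
            if self.spec["family"] == "discrete-pmf":
                return float(self._probs[self._atoms <= x].sum())
            return float(self._dist.cdf(x))
        raise ValueError("moment-sequence inputs have no CDF; use quadrature")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` iid values (bootstrap resampling for empirical inputs)."""
        if self.kind == "empirical-samples":
            return rng.choice(self.spec["samples"], size=n, replace=True)
        if self.kind == "named-distribution":
            if self.spec["family"] == "discrete-pmf":
                return rng.choice(self._atoms, size=n, p=self._probs)
            return self._dist.rvs(size=n, random_state=rng)
        raise ValueError(
            f"cannot sample from moment-sequence input {self.label!r}; "
            "use a quadrature rule instead"
        )


def raw_moments(input: RandomInput, max_order: int) -> MomentTable:
    """Raw moments of ``input`` up to ``max_order`` as a validated table.

    Empirical samples use power-sum averages, named distributions closed
    forms, and moment sequences are passed through after validation.
    """
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    values = np.array([input.moment(k) for k in range(max_order + 1)])
    std_values = None
    if input.moment(2) - input.moment(1) ** 2 > 0:
        raw_std = [input.standardized_moment(k) for k in range(max_order + 1)]
        if all(v is not None for v in raw_std):
            std_values = np.array(raw_std)
    return MomentTable(max_order, values, std_values)


# --------------------------------------------------------------------------
# univariate bases
# --------------------------------------------------------------------------


@dataclass
class UnivariateBasis:
    """Triangle of orthogonal polynomials of one standardized variable.

    ``coeffs_std`` holds the *monic* coefficient triangles in the
    standardized variable ``z = (xi - shift)/scale`` (ascending powers);
    ``factors[k]`` converts degree-``k`` evaluation back to the original
    variable: ``P_k(xi) = factors[k] * p_k(z(xi))``.  For the monic basis
    ``factors[k] = scale**k`` (leading coefficient in ``xi`` is exactly 1);
    for the orthonormal basis ``factors[k] = 1/||p_k||``.
    """

    max_degree: int
    shift: float
    scale: float
    coeffs_std: tuple[np.ndarray, ...]
    factors: np.ndarray
    norms_std: np.ndarray
    orthonormal: bool = False

    def evaluate(self, k: int, x) -> np.ndarray | float:
        if not 0 <= k <= self.max_degree:
            raise IndexError(f"degree {k} outside basis (max {self.max_degree})")
        z = (np.asarray(x, float) - self.shift) / self.scale
        return npoly.polyval(z, self.coeffs_std[k]) * self.factors[k]

    __call__ = evaluate

    def coefficients(self, k: int) -> np.ndarray:
        """Ascending-power coefficients of degree-``k`` polynomial in ``xi``."""
        zpoly = np.array([-self.shift / self.scale, 1.0 / self.scale])
        acc = np.zeros(k + 1)
        power = np.array([1.0])
        for i, c in enumerate(self.coeffs_std[k]):
            acc[: power.size] += c * power
            power = npoly.polymul(power, zpoly)
        return acc * self.factors[k]


def _hankel_system(nu: np.ndarray, k: int) -> np.ndarray:
    """The (k+1)x(k+1) raw-moment matrix whose solution is the monic triangle."""
    A = np.zeros((k + 1, k + 1))
    for i in range(k):
        A[i] = nu[i : i + k + 1]
    A[k, k] = 1.0
    return A


def monic_orthogonal_basis(moments: MomentTable, r: int) -> UnivariateBasis:
    """Monic orthogonal polynomials up to degree ``r`` from raw moments.

    For each degree ``k`` the coefficient vector solves the moment linear
    system whose first ``k`` rows impose orthogonality to all lower powers
    and whose last row pins the leading coefficient to 1.  The solve is
    performed in standardized coordinates and rejected if the moment matrix
    condition number exceeds :data:`CONDITION_THRESHOLD`.
    """
    if r < 0:
        raise ValueError("degree r must be >= 0")
    if r > MAX_DEGREE:
        raise ValueError(f"degree r={r} exceeds supported maximum {MAX_DEGREE}")
    if r > 0 and moments.max_order < 2 * r - 1:
        raise ValueError(
            f"moments up to order {2 * r - 1} required for degree {r}, "
            f"table has {moments.max_order}"
        )
    m = moments.mean
    if r == 0:
        return UnivariateBasis(0, m, 1.0, (np.array([1.0]),),
                               np.array([1.0]), np.array([1.0]))
    if moments.variance <= 0:
        raise DegenerateMeasureError(
            "measure has zero variance; no orthogonal polynomials beyond degree 0"
        )
    s = math.sqrt(moments.variance)
    std = moments.standardized()
    nu = np.zeros(2 * r + 1)
    avail = min(std.max_order, 2 * r)
    nu[: avail + 1] = std.values[: avail + 1]

    coeffs: list[np.ndarray] = [np.array([1.0])]
    for k in range(1, r + 1):
        A = _hankel_system(nu, k)
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > CONDITION_THRESHOLD:
            raise IllConditionedError(
                f"moment matrix for degree {k} has condition number {cond:.3e} "
                f"(threshold {CONDITION_THRESHOLD:.0e}); the measure may have "
                f"fewer than {k + 1} support atoms"
            )
        rhs = np.zeros(k + 1)
        rhs[-1] = 1.0
        c = np.linalg.solve(A, rhs)
        c += np.linalg.solve(A, rhs - A @ c)  # one refinement step
        coeffs.append(c)

    # Norms via Cholesky of the Hankel matrix: ||p_k||^2 = det H_{k+1}/det H_k
    # = R_kk^2, which avoids the catastrophic cancellation of the naive
    # coefficient double sum at higher degrees.  The top-degree norm needs
    # nu_{2r}; when the table stops at 2r-1 it is left NaN (the monic basis
    # is still fully determined, only normalization is unavailable).
    have_top = avail >= 2 * r
    size = r + 1 if have_top else r
    H = np.array([[nu[i + j] for j in range(size)] for i in range(size)])
    try:
        R = np.linalg.cholesky(H).T
    except np.linalg.LinAlgError as exc:
        raise IllConditionedError(
            f"Hankel moment matrix of order {r} is numerically not positive "
            "definite; the measure may have too few support atoms"
        ) from exc
    norms = np.full(r + 1, np.nan)
    norms[:size] = np.diag(R)

    factors = np.array([s**k for k in range(r + 1)])
    return UnivariateBasis(r, m, s, tuple(coeffs), factors, norms)


def orthonormalize(basis: UnivariateBasis, moments: MomentTable) -> UnivariateBasis:
    """Divide each monic polynomial by its norm under the input measure.

    Sign convention: positive leading coefficient.  ``moments`` must cover
    order ``2 * max_degree`` so the norms are well defined.
    """
    if basis.orthonormal:
        return basis
    if moments.max_order < 2 * basis.max_degree:
        raise ValueError(
            f"moments up to order {2 * basis.max_degree} required to normalize"
        )
    if np.any(~np.isfinite(basis.norms_std)) or np.any(basis.norms_std <= 0):
        raise DegenerateMeasureError("zero or undefined polynomial norm; "
                                     "degenerate measure or missing moments")
    factors = 1.0 / basis.norms_std
    return UnivariateBasis(
        basis.max_degree, basis.shift, basis.scale, basis.coeffs_std,
        factors, np.ones_like(basis.norms_std), orthonormal=True,
    )


def orthonormal_basis(input: RandomInput, r: int) -> UnivariateBasis:
    """Convenience: moments -> monic triangle -> orthonormal basis."""
    moments = raw_moments(input, max(2 * r, 1))
    return orthonormalize(monic_orthogonal_basis(moments, r), moments)


# --------------------------------------------------------------------------
# multi-indices and multivariate bases
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MultiIndexSet:
    """All length-``l`` multi-indices of total degree <= ``r``, graded lex order."""

    l: int
    r: int
    indices: tuple[tuple[int, ...], ...]

    @property
    def Z(self) -> int:
        return len(self.indices)


def _compositions(total: int, parts: int):
    """Weak compositions of ``total`` into ``parts`` parts, lexicographic."""
    if parts == 1:
        yield (total,)
        return
    for head in range(total + 1):
        for tail in _compositions(total - head, parts - 1):
            yield (head,) + tail


def multi_index_set(l: int, r: int) -> MultiIndexSet:
    """Graded-lexicographic multi-index set; count is ``(l+r)!/(l! r!)``."""
    if l < 1:
        raise ValueError("number of variables l must be >= 1")
    if r < 0:
        raise ValueError("total degree r must be >= 0")
    indices = []
    for degree in range(r + 1):
        indices.extend(_compositions(degree, l))
    mset = MultiIndexSet(l, r, tuple(indices))
    expected = math.comb(l + r, r)
    assert mset.Z == expected, "multi-index enumeration mismatch"
    return mset


@dataclass
class MultivariateBasis:
    """Tensor-product basis ``Phi_i(xi) = prod_j P_j^{(alpha_j^i)}(xi_j)``."""

    bases: tuple[UnivariateBasis, ...]
    index_set: MultiIndexSet

    def __post_init__(self) -> None:
        if len(self.bases) != self.index_set.l:
            raise ValueError("one univariate basis per variable is required")

    @property
    def Z(self) -> int:
        return self.index_set.Z

    @property
    def l(self) -> int:
        return self.index_set.l

    def evaluate(self, point: Sequence[float], index: int) -> float:
        point = np.asarray(point, float)
        if point.shape != (self.l,):
            raise ValueError(f"point must have length {self.l}, got {point.shape}")
        if not 0 <= index < self.Z:
            raise IndexError(f"basis index {index} outside [0, {self.Z})")
        alpha = self.index_set.indices[index]
        out = 1.0
        for j, (basis, deg) in enumerate(zip(self.bases, alpha)):
            out *= float(basis.evaluate(deg, point[j]))
        return out

    def evaluate_matrix(self, points: np.ndarray) -> np.ndarray:
        """Design matrix ``(n_points, Z)`` of all basis functions."""
        points = np.atleast_2d(np.asarray(points, float))
        if points.shape[1] != self.l:
            raise ValueError(f"points must have {self.l} columns")
        # per-variable tables of P_j^{(d)} at all points
        tables = [
            np.stack([b.evaluate(d, points[:, j]) for d in range(b.max_degree + 1)])
            for j, b in enumerate(self.bases)
        ]
        out = np.empty((points.shape[0], self.Z))
        for i, alpha in enumerate(self.index_set.indices):
            acc = np.ones(points.shape[0])
            for j, d in enumerate(alpha):
                if d:
                    acc = acc * tables[j][d]
            out[:, i] = acc
        return out


def multivariate_basis(inputs: Sequence[RandomInput], r: int) -> MultivariateBasis:
    """Orthonormal tensor-product basis for independent inputs."""
    bases = tuple(orthonormal_basis(inp, r) for inp in inputs)
    return MultivariateBasis(bases, multi_index_set(len(inputs), r))


def evaluate_basis(mbasis: MultivariateBasis, point: Sequence[float],
                   index: int) -> float:
    return mbasis.evaluate(point, index)


# --------------------------------------------------------------------------
# quadrature
# --------------------------------------------------------------------------


def _recurrence(moments: MomentTable, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Three-term recurrence coefficients (alpha, beta) in standardized coords.

    Obtained from the Cholesky factor of the (n+1)x(n+1) standardized Hankel
    matrix (the numerically stable route from raw moments).
    """
    std = moments.standardized()
    if std.max_order < 2 * n:
        raise ValueError(f"moments up to order {2 * n} required for {n} nodes")
    nu = std.values
    H = np.array([[nu[i + j] for j in range(n + 1)] for i in range(n + 1)])
    try:
        R = np.linalg.cholesky(H).T
    except np.linalg.LinAlgError as exc:
        raise IllConditionedError(
            f"Hankel moment matrix for a {n}-node rule is numerically not "
            "positive definite; moment sequence too short or degenerate"
        ) from exc
    d = np.diag(R)
    alphas = np.empty(n)
    betas = np.empty(n)
    betas[0] = 1.0
    for k in range(n):
        alphas[k] = R[k, k + 1] / d[k] - (R[k - 1, k] / d[k - 1] if k else 0.0)
        if k:
            betas[k] = (d[k] / d[k - 1]) ** 2
    return alphas, betas


def _named_rule(input: RandomInput, n: int) -> tuple[np.ndarray, np.ndarray] | None:
    """Closed-form Gauss rules for the classical families (stable at any n)."""
    from scipy.special import roots_genlaguerre, roots_hermitenorm, roots_jacobi, roots_legendre

    fam = input.spec["family"]
    if fam == "uniform":
        lo, hi = input.spec["lower"], input.spec["upper"]
        x, w = roots_legendre(n)
        return lo + 0.5 * (x + 1.0) * (hi - lo), w / w.sum()
    if fam == "gaussian":
        z, w = roots_hermitenorm(n)
        return input.spec["mean"] + input.spec["std"] * z, w / w.sum()
    if fam == "beta":
        a, b = input.spec["a"], input.spec["b"]
        lo = input.spec.get("lower", 0.0)
        hi = input.spec.get("upper", 1.0)
        x, w = roots_jacobi(n, b - 1.0, a - 1.0)
        return lo + 0.5 * (x + 1.0) * (hi - lo), w / w.sum()
    if fam == "gamma":
        shape = input.spec["shape"]
        x, w = roots_genlaguerre(n, shape - 1.0)
        return input.spec.get("loc", 0.0) + input.spec.get("scale", 1.0) * x, w / w.sum()
    if fam == "discrete-pmf" and n >= input._atoms.size:
        return input._atoms.copy(), input._probs.copy()  # exact finite measure
    return None


def quadrature_rule(input: RandomInput, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss rule with ``n_nodes`` nodes for the input's measure.

    Named families use the classical closed-form rules; empirical-sample and
    moment-sequence inputs go through the Jacobi matrix of the moment-based
    recurrence (Golub-Welsch).  Weights are positive, sum to 1, and the rule
    integrates polynomials of degree ``<= 2 n - 1`` exactly against the
    measure.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    mean = input.moment(1)
    var = input.moment(2) - mean**2
    if var <= 0:  # point mass
        if n_nodes == 1:
            return np.array([mean]), np.array([1.0])
        raise DegenerateMeasureError("point-mass measure supports only n_nodes = 1")
    if input.kind == "named-distribution":
        rule = _named_rule(input, n_nodes)
        if rule is not None:
            return rule
    if n_nodes == 1:
        return np.array([mean]), np.array([1.0])
    moments = raw_moments(input, 2 * n_nodes)
    alphas, betas = _recurrence(moments, n_nodes)
    J = np.diag(alphas) + np.diag(np.sqrt(betas[1:]), 1) + np.diag(np.sqrt(betas[1:]), -1)
    z, vecs = np.linalg.eigh(J)
    weights = vecs[0] ** 2
    weights = weights / weights.sum()
    s = math.sqrt(var)
    return mean + s * z, weights


def tensor_quadrature(inputs: Sequence[RandomInput],
                      n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensorized Gauss rule over independent inputs.

    Returns ``(points, weights)`` with ``points`` of shape
    ``(n_nodes**l, l)``.
    """
    rules = [quadrature_rule(inp, n_nodes) for inp in inputs]
    nodes = [r[0] for r in rules]
    weights = [r[1] for r in rules]
    points = np.array(list(_iproduct(*nodes)))
    w = np.ones(points.shape[0])
    for combo_idx, combo in enumerate(_iproduct(*weights)):
        w[combo_idx] = math.prod(combo)
    return points, w
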