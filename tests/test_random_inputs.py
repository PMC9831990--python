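"""Moment tables, monic/orthonormal bases, multi-indices and quadrature."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats
from scipy.special import eval_hermitenorm, eval_legendre

from netres.random_inputs import (
    DegenerateMeasureError,
    IllConditionedError,
    MomentTable,
    RandomInput,
    evaluate_basis,
    monic_orthogonal_basis,
    multi_index_set,
    multivariate_basis,
    orthonormal_basis,
    orthonormalize,
    quadrature_rule,
    raw_moments,
    tensor_quadrature,
)


# --------------------------------------------------------------------------
# raw moments
# --------------------------------------------------------------------------


class TestRawMoments:
    def test_uniform_second_moment(self):
        u = RandomInput.uniform(-1, 1)
        assert raw_moments(u, 2)[2] == pytest.approx(1 / 3, abs=1e-12)

    def test_point_mass_powers(self):
        c = 1.7
        pm = RandomInput.discrete([c], [1.0])
        table = raw_moments(pm, 5)
        for k in range(6):
            assert table[k] == pytest.approx(c**k, rel=1e-12)

    def test_standard_normal_recursion(self):
        # oracle: mu_k = (k-1) mu_{k-2} for the standard normal
        g = RandomInput.gaussian(0, 1)
        expected = [1.0, 0.0]
        for k in range(2, 9):
            expected.append((k - 1) * expected[k - 2])
        table = raw_moments(g, 8)
        assert table.values == pytest.approx(expected, abs=1e-10)
        assert table[4] == pytest.approx(3.0)

    def test_empirical_power_sums(self):
        samples = np.array([1.0, 2.0, 4.0])
        emp = RandomInput.from_samples(samples)
        assert raw_moments(emp, 3)[3] == pytest.approx(np.mean(samples**3))

    def test_moment_sequence_passthrough_and_overrun(self):
        inp = RandomInput.from_moments([1.0, 0.0, 1.0, 0.0, 3.0])
        assert raw_moments(inp, 4).values == pytest.approx([1, 0, 1, 0, 3])
        with pytest.raises(ValueError, match="order 5"):
            raw_moments(inp, 5)

    @pytest.mark.parametrize("bad", [
        lambda: RandomInput.uniform(1.0, -1.0),
        lambda: RandomInput.gaussian(0.0, -2.0),
        lambda: RandomInput.beta(-1.0, 2.0),
        lambda: RandomInput.gamma(0.0),
        lambda: RandomInput.discrete([0, 1], [0.7, 0.7]),
        lambda: RandomInput.from_samples([3.0]),
        lambda: RandomInput.from_samples([3.0, 3.0]),
        lambda: RandomInput.from_moments([2.0, 0.0, 1.0]),
        lambda: RandomInput.from_moments([1.0, 0.0, -1.0]),
    ])
    def test_invalid_specs_fail(self, bad):
        with pytest.raises(ValueError):
            bad()

    def test_moment_table_invariants(self):
        with pytest.raises(ValueError):
            MomentTable(2, [1.0, 0.0, -0.5])
        with pytest.raises(ValueError):
            MomentTable(2, [0.9, 0.0, 1.0])


# --------------------------------------------------------------------------
# monic bases
# --------------------------------------------------------------------------


def _quad_inner(pdf, lo, hi, f1, f2):
    val, _ = integrate.quad(lambda x: f1(x) * f2(x) * pdf(x), lo, hi,
                            limit=200, epsabs=1e-13, epsrel=1e-13)
    return val


def _gram_schmidt_monic(pdf, lo, hi, r):
    """Independent oracle: Gram-Schmidt on monomials under the pdf."""
    polys = [np.array([1.0])]
    for k in range(1, r + 1):
        mono = np.zeros(k + 1)
        mono[-1] = 1.0
        for p in polys:
            coeff = (
                _quad_inner(pdf, lo, hi, lambda x, m=mono: np.polyval(m[::-1], x),
                            lambda x, q=p: np.polyval(q[::-1], x))
                / _quad_inner(pdf, lo, hi, lambda x, q=p: np.polyval(q[::-1], x),
                              lambda x, q=p: np.polyval(q[::-1], x)))
            mono[: p.size] -= coeff * p
        polys.append(mono)
    return polys


class TestMonicBasis:
    def test_uniform_degree_two(self):
        # hand-solved 3x3 moment system for uniform[-1,1]: xi^2 - 1/3
        u = RandomInput.uniform(-1, 1)
        basis = monic_orthogonal_basis(raw_moments(u, 4), 2)
        assert basis.coefficients(2) == pytest.approx([-1 / 3, 0.0, 1.0], abs=1e-12)

    def test_zero_mean_degree_one(self):
        for inp in (RandomInput.uniform(-2, 2), RandomInput.gaussian(0, 3)):
            basis = monic_orthogonal_basis(raw_moments(inp, 2), 1)
            assert basis.coefficients(1) == pytest.approx([0.0, 1.0], abs=1e-12)

    def test_normal_degree_three_is_hermite(self):
        g = RandomInput.gaussian(0, 1)
        basis = monic_orthogonal_basis(raw_moments(g, 6), 3)
        assert basis.coefficients(3) == pytest.approx([0.0, -3.0, 0.0, 1.0], abs=1e-10)

    @pytest.mark.parametrize("pdf,lo,hi,make", [
        (lambda x: 0.5, -1.0, 1.0, lambda: RandomInput.uniform(-1, 1)),
        (lambda x: stats.beta(2, 5).pdf(x), 0.0, 1.0, lambda: RandomInput.beta(2, 5)),
    ])
    def test_matches_gram_schmidt_oracle(self, pdf, lo, hi, make):
        r = 5
        basis = monic_orthogonal_basis(raw_moments(make(), 2 * r), r)
        oracle = _gram_schmidt_monic(pdf, lo, hi, r)
        for k in range(r + 1):
            assert basis.coefficients(k) == pytest.approx(oracle[k], abs=1e-8)

    def test_too_few_support_atoms_rejected(self):
        two_atoms = RandomInput.discrete([0.0, 1.0], [0.5, 0.5])
        monic_orthogonal_basis(raw_moments(two_atoms, 3), 1)  # fine
        with pytest.raises((IllConditionedError, DegenerateMeasureError)):
            monic_orthogonal_basis(raw_moments(two_atoms, 6), 3)

    def test_point_mass_degenerate(self):
        pm = RandomInput.discrete([2.0], [1.0])
        with pytest.raises(DegenerateMeasureError):
            monic_orthogonal_basis(raw_moments(pm, 2), 1)


class TestOrthonormal:
    def test_degree_zero_is_one(self):
        for inp in (RandomInput.uniform(0, 2), RandomInput.gamma(3.0)):
            basis = orthonormal_basis(inp, 2)
            assert basis.evaluate(0, 0.37) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_degree_one(self):
        basis = orthonormal_basis(RandomInput.uniform(-1, 1), 1)
        assert basis.coefficients(1) == pytest.approx([0.0, math.sqrt(3)], abs=1e-10)

    def test_normal_degree_two(self):
        basis = orthonormal_basis(RandomInput.gaussian(0, 1), 2)
        assert basis.coefficients(2) == pytest.approx(
            [-1 / math.sqrt(2), 0.0, 1 / math.sqrt(2)], abs=1e-10)

    def test_positive_leading_coefficient(self):
        basis = orthonormal_basis(RandomInput.beta(2, 5), 5)
        for k in range(6):
            assert basis.coefficients(k)[-1] > 0

    @pytest.mark.parametrize("inp,pdf,lo,hi", [
        (RandomInput.uniform(-1, 1), lambda x: 0.5, -1, 1),
        (RandomInput.gaussian(0, 1), stats.norm.pdf, -12, 12),
        (RandomInput.beta(2, 5), stats.beta(2, 5).pdf, 0, 1),
    ])
    def test_gram_identity_by_quadrature(self, inp, pdf, lo, hi):
        r = 5
        basis = orthonormal_basis(inp, r)
        G = np.empty((r + 1, r + 1))
        for i in range(r + 1):
            for j in range(r + 1):
                G[i, j] = _quad_inner(pdf, lo, hi,
                                      lambda x, d=i: basis.evaluate(d, x),
                                      lambda x, d=j: basis.evaluate(d, x))
        assert np.max(np.abs(G - np.eye(r + 1))) < 1e-6

    def test_moment_sequence_gram_identity(self):
        # uniform[-1,1] given purely as a raw-moment list
        mu = [1.0 if k == 0 else (1 / (k + 1) if k % 2 == 0 else 0.0)
              for k in range(11)]
        inp = RandomInput.from_moments(mu)
        basis = orthonormal_basis(inp, 5)
        G = np.empty((6, 6))
        for i in range(6):
            for j in range(6):
                G[i, j] = _quad_inner(lambda x: 0.5, -1, 1,
                                      lambda x, d=i: basis.evaluate(d, x),
                                      lambda x, d=j: basis.evaluate(d, x))
        assert np.max(np.abs(G - np.eye(6))) < 1e-6

    def test_empirical_gram_identity_on_own_measure(self):
        rng = np.random.default_rng(42)
        samples = rng.uniform(-1, 1, 100_000)
        basis = orthonormal_basis(RandomInput.from_samples(samples), 5)
        Phi = np.stack([basis.evaluate(k, samples) for k in range(6)])
        G = Phi @ Phi.T / samples.size
        assert np.max(np.abs(G - np.eye(6))) < 1e-8

    def test_hermite_match_to_degree_five(self):
        basis = orthonormal_basis(RandomInput.gaussian(0, 1), 5)
        xs = np.linspace(-3, 3, 41)
        for k in range(6):
            expected = eval_hermitenorm(k, xs) / math.sqrt(math.factorial(k))
            assert basis.evaluate(k, xs) == pytest.approx(expected, abs=1e-8)

    def test_legendre_match_on_shifted_support(self):
        lo, hi = 2.0, 5.0
        basis = orthonormal_basis(RandomInput.uniform(lo, hi), 5)
        xs = np.linspace(lo, hi, 41)
        t = 2 * (xs - lo) / (hi - lo) - 1
        for k in range(6):
            expected = eval_legendre(k, t) * math.sqrt(2 * k + 1)
            assert basis.evaluate(k, xs) == pytest.approx(expected, abs=1e-8)


# --------------------------------------------------------------------------
# multi-indices and multivariate bases
# --------------------------------------------------------------------------


class TestMultiIndex:
    @pytest.mark.parametrize("l,r,Z", [(2, 3, 10), (1, 4, 5), (3, 0, 1)])
    def test_counts(self, l, r, Z):
        assert multi_index_set(l, r).Z == Z

    def test_l3_r0_single_zero_index(self):
        assert multi_index_set(3, 0).indices == ((0, 0, 0),)

    @given(l=st.integers(1, 5), r=st.integers(0, 5))
    @settings(max_examples=36, deadline=None)
    def test_z_formula_and_order(self, l, r):
        mset = multi_index_set(l, r)
        assert mset.Z == math.factorial(l + r) // (math.factorial(l) * math.factorial(r))
        assert len(set(mset.indices)) == mset.Z
        keys = [(sum(a), a) for a in mset.indices]
        assert keys == sorted(keys)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            multi_index_set(0, 2)
        with pytest.raises(ValueError):
            multi_index_set(2, -1)


class TestMultivariateBasis:
    def test_index_zero_is_one(self):
        mb = multivariate_basis([RandomInput.uniform(-1, 1),
                                 RandomInput.gaussian(0, 1)], 3)
        for pt in ([0.0, 0.0], [1.0, -2.0], [0.3, 0.7]):
            assert evaluate_basis(mb, pt, 0) == pytest.approx(1.0, abs=1e-12)

    def test_degree_one_product(self):
        mb = multivariate_basis([RandomInput.uniform(-1, 1)] * 2, 2)
        idx = mb.index_set.indices.index((1, 1))
        assert evaluate_basis(mb, [1.0, 1.0], idx) == pytest.approx(3.0, abs=1e-9)

    def test_dimension_mismatch(self):
        mb = multivariate_basis([RandomInput.uniform(-1, 1)] * 2, 1)
        with pytest.raises(ValueError):
            mb.evaluate([1.0, 2.0, 3.0], 0)
        with pytest.raises(IndexError):
            mb.evaluate([0.0, 0.0], mb.Z)

    def test_monte_carlo_gram_near_identity(self):
        # sampling oracle for pairwise orthonormality of the product basis
        rng = np.random.default_rng(7)
        inputs = [RandomInput.uniform(-1, 1), RandomInput.beta(2, 5)]
        mb = multivariate_basis(inputs, 2)
        pts = np.column_stack([inp.sample(1_000_000, rng) for inp in inputs])
        Phi = mb.evaluate_matrix(pts)
        G = Phi.T @ Phi / pts.shape[0]
        off = G - np.eye(mb.Z)
        assert np.max(np.abs(off)) < 0.01


# --------------------------------------------------------------------------
# quadrature
# --------------------------------------------------------------------------


class TestQuadrature:
    def test_normal_two_point(self):
        nodes, weights = quadrature_rule(RandomInput.gaussian(0, 1), 2)
        assert nodes == pytest.approx([-1.0, 1.0], abs=1e-12)
        assert weights == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_single_node_at_mean(self):
        for inp in (RandomInput.uniform(1, 3), RandomInput.gamma(2.0, 0.5),
                    RandomInput.from_samples([1.0, 2.0, 4.0])):
            nodes, weights = quadrature_rule(inp, 1)
            assert nodes == pytest.approx([inp.mean])
            assert weights == pytest.approx([1.0])

    def test_uniform_two_point_gauss_legendre(self):
        nodes, weights = quadrature_rule(RandomInput.uniform(-1, 1), 2)
        assert nodes == pytest.approx([-1 / math.sqrt(3), 1 / math.sqrt(3)], abs=1e-12)
        assert weights == pytest.approx([0.5, 0.5], abs=1e-12)

    @pytest.mark.parametrize("inp", [
        RandomInput.uniform(0.9, 1.1),
        RandomInput.gaussian(2.0, 0.5),
        RandomInput.beta(2, 5, 0, 2),
        RandomInput.gamma(3.0, 2.0),
        RandomInput.discrete([0.0, 0.5, 1.0, 2.0, 3.0], [0.1, 0.2, 0.3, 0.2, 0.2]),
        RandomInput.from_samples(np.random.default_rng(0).normal(1, 2, 5000)),
    ])
    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_degree_exactness(self, inp, n):
        nodes, weights = quadrature_rule(inp, n)
        assert np.all(weights > 0)
        assert weights.sum() == pytest.approx(1.0, abs=1e-10)
        for k in range(2 * n):
            quad = float(np.dot(weights, nodes**k))
            exact = inp.moment(k)
            assert quad == pytest.approx(exact, rel=1e-7, abs=1e-9)

    def test_point_mass_rule(self):
        pm = RandomInput.discrete([2.5], [1.0])
        nodes, weights = quadrature_rule(pm, 1)
        assert nodes == pytest.approx([2.5])
        with pytest.raises(DegenerateMeasureError):
            quadrature_rule(pm, 2)

    def test_tensor_rule_weights(self):
        inputs = [RandomInput.uniform(-1, 1), RandomInput.gaussian(0, 1)]
        pts, w = tensor_quadrature(inputs, 3)
        assert pts.shape == (9, 2)
        assert w.sum() == pytest.approx(1.0)
        # integrates xi1^2 * xi2^2 = 1/3 * 1
        assert np.dot(w, pts[:, 0] ** 2 * pts[:, 1] ** 2) == pytest.approx(1 / 3)
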