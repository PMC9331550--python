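import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal

from svclogit.gmrf import (
    car_logdensity,
    car_structure,
    car_structure_from_scale,
    icar_conditional,
    icar_precision,
    rw2_precision,
    rw2_structure_matrix,
)
from svclogit.graph import build_region_graph

from .conftest import random_connected_graph


class TestIcar:
    def test_constant_vector_in_null_space(self, path_graph):
        prec = icar_precision(path_graph, 1.0)
        f = np.ones(3)
        assert f @ prec.Q @ f == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_form_is_sum_of_squared_differences(self, path_graph):
        prec = icar_precision(path_graph, 1.0)
        f = np.array([0.0, 1.0, 3.0])
        assert f @ prec.Q @ f == pytest.approx(5.0)

    def test_row_sums_zero_and_psd(self, sa_graph):
        prec = icar_precision(sa_graph, 2.5)
        S = prec.structure
        assert np.allclose(S.sum(axis=1), 0.0, atol=1e-12)
        lam = np.linalg.eigvalsh(prec.Q)
        assert lam.min() > -1e-10
        assert np.sum(np.abs(lam) < 1e-9) == 1      # one null vector (connected)

    @given(st.integers(min_value=0, max_value=1000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_quadratic_form_identity_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        g = random_connected_graph(int(rng.integers(3, 9)), rng)
        tau = float(rng.uniform(0.1, 5.0))
        prec = icar_precision(g, tau)
        f = rng.standard_normal(g.n_regions)
        direct = tau * sum((f[i] - f[j]) ** 2 for i, j in g.edges)
        assert f @ prec.Q @ f == pytest.approx(direct, rel=1e-10)

    def test_rejects_bad_tau_and_isolates(self, path_graph):
        with pytest.raises(ValueError, match="tau_str"):
            icar_precision(path_graph, 0.0)
        g = build_region_graph([("A", "B")], ["A", "B", "C"])
        with pytest.raises(ValueError, match="isolated"):
            icar_precision(g, 1.0)


class TestIcarConditional:
    def test_neighbour_average_and_variance(self, path_graph):
        prec = icar_precision(path_graph, 1.0)
        mean, var = icar_conditional(prec, 1, np.array([2.0, np.nan, 4.0]))
        assert mean == pytest.approx(3.0)
        assert var == pytest.approx(0.5)

    def test_single_neighbour_tau4(self, path_graph):
        prec = icar_precision(path_graph, 4.0)
        mean, var = icar_conditional(prec, 0, np.array([7.0, 7.0]))  # len n-1
        assert mean == pytest.approx(7.0)
        assert var == pytest.approx(0.25)

    @given(st.integers(min_value=0, max_value=500))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_matches_schur_complement_oracle(self, seed):
        # the ICAR conditional must agree with the dense-Gaussian conditional
        # computed from the generalized inverse of Q
        rng = np.random.default_rng(seed)
        g = random_connected_graph(int(rng.integers(3, 8)), rng)
        tau = float(rng.uniform(0.5, 3.0))
        prec = icar_precision(g, tau)
        vals = rng.standard_normal(g.n_regions)
        for j in range(g.n_regions):
            mean, var = icar_conditional(prec, j, vals)
            others = np.delete(np.arange(g.n_regions), j)
            Qjj = prec.Q[j, j]
            oracle_mean = -prec.Q[j, others] @ vals[others] / Qjj
            assert mean == pytest.approx(oracle_mean, abs=1e-10)
            assert var == pytest.approx(1.0 / Qjj, rel=1e-12)


class TestProperCar:
    def test_rho_zero_is_diagonal_independence(self, sa_graph):
        car = car_structure_from_scale(sa_graph, sigma2=2.0, rho=0.0)
        assert np.allclose(car.G, 0.0)
        assert np.allclose(car.B, np.diag(1.0 / np.diag(car.H)))

    def test_two_region_hand_computation(self):
        # equal tau^2, rho = 0.5, g = rho*a/d: B = (1/sigma2) [[1,-.5],[-.5,1]]
        # with sigma2 = tau2 * d = tau2; here tau2 = 4 -> B = [[.25,-.125],...]
        g = build_region_graph([("A", "B")], ["A", "B"])
        car = car_structure(g, np.array([4.0, 4.0]), rho=0.5)
        assert np.allclose(car.B, np.array([[0.25, -0.125], [-0.125, 0.25]]))
        assert np.allclose(np.diag(car.B), 1.0 / np.diag(car.H))

    @pytest.mark.parametrize("rho", [0.0, 0.5, 0.9, 0.99])
    def test_symmetric_positive_definite(self, rho):
        rng = np.random.default_rng(int(rho * 100))
        for seed in range(5):
            g = random_connected_graph(int(rng.integers(3, 10)), rng)
            car = car_structure_from_scale(g, float(rng.uniform(0.1, 4.0)), rho=rho)
            assert np.max(np.abs(car.B - car.B.T)) < 1e-10 * max(np.max(np.abs(car.B)), 1)
            assert np.linalg.eigvalsh(car.B).min() > 0

    def test_symmetry_condition_on_gh(self, sa_graph):
        car = car_structure_from_scale(sa_graph, 1.5, rho=0.8)
        t2 = np.diag(car.H)
        for i, k in sa_graph.edges:
            assert car.G[i, k] * t2[k] == pytest.approx(car.G[k, i] * t2[i], rel=1e-10)

    def test_invalid_inputs(self, sa_graph):
        with pytest.raises(ValueError, match="rho"):
            car_structure_from_scale(sa_graph, 1.0, rho=1.0)
        with pytest.raises(ValueError, match="proportional to 1/degree"):
            car_structure(sa_graph, np.ones(9), rho=0.5)


class TestCarLogDensity:
    def test_zero_vector_is_normalizer_only(self, sa_graph):
        car = car_structure_from_scale(sa_graph, 1.0, rho=0.9)
        k = car.k
        sign, logdet = np.linalg.slogdet(car.B)
        expected = -0.5 * k * np.log(2 * np.pi) + 0.5 * logdet
        assert car_logdensity(np.zeros(k), car) == pytest.approx(expected)

    def test_matches_scipy_mvn_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            g = random_connected_graph(int(rng.integers(3, 9)), rng)
            car = car_structure_from_scale(g, float(rng.uniform(0.2, 3.0)),
                                           rho=float(rng.uniform(0, 0.95)))
            phi = rng.standard_normal(car.k)
            oracle = multivariate_normal(mean=np.zeros(car.k),
                                         cov=np.linalg.inv(car.B)).logpdf(phi)
            assert car_logdensity(phi, car) == pytest.approx(oracle, abs=1e-8)

    def test_dimension_mismatch(self, sa_graph):
        car = car_structure_from_scale(sa_graph, 1.0)
        with pytest.raises(ValueError, match="length"):
            car_logdensity(np.zeros(3), car)


class TestRw2:
    def test_affine_null_space(self):
        prec = rw2_precision(8, 1.3)
        g = prec.bin_grid
        for f in (np.ones(8), g, 2.0 + 0.7 * g):
            assert f @ prec.K @ f == pytest.approx(0.0, abs=1e-10)

    def test_second_difference_sum(self):
        prec = rw2_precision(4, 1.0)
        f = np.array([0.0, 0.0, 1.0, 0.0])
        assert f @ prec.K @ f == pytest.approx(5.0)

    @pytest.mark.parametrize("n", range(3, 13))
    def test_rank_deficiency_two(self, n):
        K = rw2_structure_matrix(n)
        assert np.linalg.matrix_rank(K, tol=1e-9) == n - 2

    @given(st.integers(min_value=0, max_value=300))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_adding_affine_leaves_quadratic_form_unchanged(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 15))
        prec = rw2_precision(n, float(rng.uniform(0.1, 5)))
        f = rng.standard_normal(n)
        a, b = rng.standard_normal(2)
        g = f + a + b * prec.bin_grid
        assert g @ prec.K @ g == pytest.approx(f @ prec.K @ f, rel=1e-8, abs=1e-8)

    def test_too_few_bins(self):
        with pytest.raises(ValueError, match="at least 3"):
            rw2_precision(2, 1.0)
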