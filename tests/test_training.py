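import numpy as np
import pytest

from fjwnn.dataset import Dataset
from fjwnn.ica import ICAConfig, ica_optimize
from fjwnn.model import FJWNN
from fjwnn.selection import GAConfig, SelectionConfig
from fjwnn.training import (
    GenomeSpec,
    InitConfig,
    decode_genome,
    solve_consequent_ls,
)
from tests.conftest import make_two_rule_system


class TestDecodeGenome:
    spec = GenomeSpec(m=2, n_a=3)

    def _genome(self, code_vals):
        g = np.zeros(self.spec.length)
        mn = 2 * 3
        g[mn:2 * mn] = 0.5  # su
        g[2 * mn:2 * mn + 3] = 0.7  # v
        g[2 * mn + 3:] = code_vals
        return g

    def test_code_floor_zero_excludes_input(self):
        _, _, _, codes = decode_genome(self._genome(0.4), self.spec)
        assert np.all(codes == 0)

    def test_code_floor_selects_pool_member(self):
        _, _, _, codes = decode_genome(self._genome(2.7), self.spec)
        assert np.all(codes == 2)

    def test_code_clamped_to_n_a(self):
        _, _, _, codes = decode_genome(self._genome(9.9), self.spec)
        assert np.all(codes == 3)

    def test_su_clamped_and_v_clipped(self):
        g = self._genome(1.0)
        mn = 6
        g[mn] = -1.0  # su below the floor
        g[2 * mn] = 1.7  # v above one
        mu, su, v, _ = decode_genome(g, self.spec)
        assert su.ravel()[0] == pytest.approx(1e-3)
        assert v[0] == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            decode_genome(np.zeros(5), self.spec)


class TestSolveConsequents:
    def test_single_global_linear_rule_recovers_slope(self, rng):
        Xn = rng.random((50, 1))
        y = 2.0 * Xn[:, 0]
        s = np.ones((50, 1))  # v=1, mubar=1
        weights, fitted = solve_consequent_ls([np.empty((50, 0))], Xn, s, y)
        assert weights[0][0] == pytest.approx(2.0, rel=1e-9)
        np.testing.assert_allclose(fitted, y, atol=1e-9)

    def test_exact_recovery_from_known_weights(self, rng):
        N = 200
        Xn = rng.random((N, 2))
        Phi = [rng.normal(size=(N, 3)), rng.normal(size=(N, 2))]
        s = np.abs(rng.random((N, 2))) + 0.1
        true = [rng.normal(size=5), rng.normal(size=4)]
        y = sum(
            s[:, l] * (np.hstack([Phi[l], Xn]) @ true[l]) for l in range(2)
        )
        weights, fitted = solve_consequent_ls(Phi, Xn, s, y)
        for got, want in zip(weights, true):
            np.testing.assert_allclose(got, want, atol=1e-8)
        assert np.sqrt(np.mean((y - fitted) ** 2)) < 1e-10

    def test_duplicated_columns_finite_minimum_norm(self, rng):
        N = 40
        Xn = rng.random((N, 1))
        G = rng.normal(size=(N, 1))
        Phi = [np.hstack([G, G])]  # exactly collinear wavelet columns
        s = np.ones((N, 1))
        y = G[:, 0] * 3.0
        with pytest.warns(UserWarning, match="rank-deficient"):
            weights, fitted = solve_consequent_ls(Phi, Xn, s, y, warn_rank=True)
        assert np.all(np.isfinite(weights[0]))
        np.testing.assert_allclose(fitted, y, atol=1e-8)

    def test_all_zero_design_rejected(self):
        with pytest.raises(ValueError):
            solve_consequent_ls(
                [np.zeros((10, 1))], np.zeros((10, 1)), np.zeros((10, 1)), np.ones(10)
            )

    def test_ls_optimality_first_order(self, rng):
        """Perturbing the solved weights in random directions never reduces
        the training residual (least-squares stationarity)."""
        N = 100
        Xn = rng.random((N, 2))
        Phi = [rng.normal(size=(N, 2))]
        s = np.abs(rng.random((N, 1))) + 0.2
        y = rng.normal(size=N)
        weights, fitted = solve_consequent_ls(Phi, Xn, s, y)
        base = np.mean((y - fitted) ** 2)
        A = np.hstack([Phi[0] * s, Xn * s])
        w = np.concatenate(weights)
        for _ in range(10):
            d = rng.normal(size=w.size)
            pert = A @ (w + 1e-4 * d)
            assert np.mean((y - pert) ** 2) >= base - 1e-12


class TestICA:
    def test_recovers_quadratic_minimum(self):
        cfg = ICAConfig(max_iterations=60, population=200, seed=3)
        res = ica_optimize(
            lambda x: (x[0] - 3.0) ** 2, np.array([-10.0]), np.array([10.0]), cfg
        )
        assert abs(res.x[0] - 3.0) < 0.01

    def test_sphere_function_5d(self):
        cfg = ICAConfig(max_iterations=60, population=300, seed=5)
        res = ica_optimize(
            lambda x: float(x @ x), np.full(5, -5.0), np.full(5, 5.0), cfg
        )
        assert res.cost < 1e-3

    def test_best_cost_non_increasing(self):
        cfg = ICAConfig(max_iterations=30, population=60, seed=1)
        res = ica_optimize(
            lambda x: float(np.sum(np.abs(x))), np.full(3, -2.0), np.full(3, 2.0), cfg
        )
        assert all(res.trace[i + 1] <= res.trace[i] for i in range(len(res.trace) - 1))

    def test_deterministic_given_seed(self):
        cfg = ICAConfig(max_iterations=15, population=40)
        f = lambda x: float((x[0] + 1) ** 2 + x[1] ** 2)
        r1 = ica_optimize(f, np.full(2, -3.0), np.full(2, 3.0), cfg, seed=9)
        r2 = ica_optimize(f, np.full(2, -3.0), np.full(2, 3.0), cfg, seed=9)
        np.testing.assert_array_equal(r1.x, r2.x)
        np.testing.assert_array_equal(r1.trace, r2.trace)

    def test_non_finite_cost_rejected(self):
        cfg = ICAConfig(max_iterations=10, population=30, seed=2)
        def f(x):
            return np.inf if x[0] < 0 else float(x[0])
        res = ica_optimize(f, np.array([-1.0]), np.array([1.0]), cfg)
        assert np.isfinite(res.cost)


def _small_configs(**ica_kw):
    sel = SelectionConfig(
        max_terms=12,
        max_centers_per_scale=30,
        ga=GAConfig(population_size=30, generations=5),
    )
    ica_kw.setdefault("population", 40)
    ica_kw.setdefault("max_iterations", 12)
    return sel, ICAConfig(**ica_kw)


class TestFitPipeline:
    def test_noiseless_linear_system_recovered(self, rng):
        N = 150
        U = rng.uniform(-1, 1, size=(N, 2))
        y = 1.5 * U[:, 0] - 0.5 * U[:, 1]
        sel, ica = _small_configs()
        res = FJWNN(Dataset(U, y), selection=sel, ica=ica).fit(seed=0)
        Ut = rng.uniform(-1, 1, size=(80, 2))
        yt = 1.5 * Ut[:, 0] - 0.5 * Ut[:, 1]
        test_rmse = np.sqrt(np.mean((yt - res.predict(Ut)) ** 2))
        assert test_rmse < 1e-6

    def test_recovery_of_known_two_rule_model(self, rng):
        sigma = 0.05
        truth = make_two_rule_system()
        U = rng.random((400, 2))
        y = truth.predict(U) + sigma * rng.standard_normal(400)
        sel, ica = _small_configs(population=60, max_iterations=20)
        res = FJWNN(Dataset(U, y), selection=sel, ica=ica).fit(seed=1)
        Ut = rng.random((200, 2))
        yt = truth.predict(Ut)
        test_rmse = np.sqrt(np.mean((yt - res.predict(Ut)) ** 2))
        assert test_rmse <= 2 * sigma

    def test_cost_trace_non_increasing_and_seed_reproducible(self, rng):
        U = rng.uniform(-1, 1, size=(120, 1))
        y = np.sin(3 * U[:, 0]) + 0.5 * U[:, 0]
        sel, ica = _small_configs()
        ds = Dataset(U, y)
        r1 = FJWNN(ds, selection=sel, ica=ica).fit(seed=7)
        r2 = FJWNN(ds, selection=sel, ica=ica).fit(seed=7)
        trace = r1.cost_trace
        assert all(trace[i + 1] <= trace[i] + 1e-15 for i in range(len(trace) - 1))
        np.testing.assert_array_equal(r1.predict(U), r2.predict(U))
        assert r1.n_parameters == r2.n_parameters

    def test_parameter_count_accounting(self, rng):
        U = rng.uniform(-1, 1, size=(120, 1))
        y = np.sin(3 * U[:, 0]) + 0.5 * U[:, 0]
        sel, ica = _small_configs()
        res = FJWNN(Dataset(U, y), selection=sel, ica=ica).fit(seed=0)
        sys = res.system
        expect = (
            sum(r.w.size for r in sys.rules)
            + 2 * sum(int(np.count_nonzero(r.ca)) for r in sys.rules)
            + sys.n_rules
        )
        assert res.n_parameters == expect
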