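import numpy as np
import pytest

from fjwnn.benchmarks import (
    EMGSynthConfig,
    MGConfig,
    add_noise,
    gen_example1,
    gen_synthetic_emg,
    load_emg_trials,
    load_gas_furnace,
    make_regressors,
    piecewise_fn,
    plant_regressor_lags,
    simulate_mackey_glass,
    simulate_plant,
    train_input,
)
from fjwnn.benchmarks import test_input as plant_test_input


class TestPiecewise:
    @pytest.mark.parametrize(
        "x, expected",
        [
            (-10.0, -2.186 * -10 - 12.864),  # 8.996
            (-1.0, -4.246),
            (0.0, 10.0),
            (5.0, 10 * np.exp(-0.25) - 0.5 * np.sin((0.03 * 5 + 0.7) * 5)),
        ],
    )
    def test_branch_values(self, x, expected):
        assert piecewise_fn(x) == pytest.approx(expected, rel=1e-12)

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            piecewise_fn(10.5)

    def test_example1_shape_domain_and_determinism(self):
        ds = gen_example1(seed=4)
        assert ds.n == 200 and ds.m == 1
        assert np.all(ds.U >= -10) and np.all(ds.U <= 10)
        np.testing.assert_allclose(ds.y, piecewise_fn(ds.U[:, 0]))
        ds2 = gen_example1(seed=4)
        np.testing.assert_array_equal(ds.U, ds2.U)


def oracle_plant(pid, u):
    """Straight-loop re-implementation of each difference equation, written
    independently with explicit history variables."""
    n = len(u)
    y = [0.0] * n
    g = lambda seq, k: seq[k] if k >= 0 else 0.0
    for k in range(n):
        if pid == "2-1":
            y[k] = (0.72 * g(y, k - 1) + 0.025 * g(y, k - 2) * g(u, k - 2)
                    + 0.01 * g(u, k - 3) ** 2 + 0.2 * g(u, k - 4))
        elif pid == "2-2":
            s = np.sin
            y[k] = (0.3 * g(y, k - 1) + 0.6 * g(y, k - 2) + 0.6 * s(np.pi * u[k])
                    + 0.3 * s(3 * np.pi * u[k]) + 0.1 * s(5 * np.pi * u[k]))
        elif pid == "2-3":
            a, b = g(y, k - 1), g(y, k - 2)
            y[k] = a * b * (a + 0.5) * (b - 1) / (1 + a * a + b * b) + u[k]
        elif pid == "2-4":
            a, c = g(y, k - 1), g(u, k - 1)
            y[k] = a * (a + 0.3) / (1 + a * a) + c * (c + 0.8) * (c - 0.5)
        elif pid == "2-5":
            a, b, c = g(y, k - 1), g(y, k - 2), g(y, k - 3)
            y[k] = ((a * b * c * g(u, k - 2) * (c - 1) + g(u, k - 1))
                    / (1 + b * b + c * c))
    return np.array(y)


class TestPlants:
    @pytest.mark.parametrize("pid", ["2-1", "2-2", "2-3", "2-4", "2-5"])
    def test_matches_independent_recursion_oracle(self, pid, rng):
        u = rng.uniform(-2, 2, size=100)
        got = simulate_plant(pid, u)
        np.testing.assert_allclose(got, oracle_plant(pid, u), atol=1e-12)

    @pytest.mark.parametrize("pid", ["2-1", "2-3"])
    def test_zero_input_zero_state_stays_zero(self, pid):
        np.testing.assert_array_equal(simulate_plant(pid, np.zeros(50)), np.zeros(50))

    def test_plant21_constant_input_hand_recursion(self):
        # manual recursion of the first plant with u = 1,1,1,...
        u = np.ones(5)
        y = np.zeros(5)
        # k=0,1,2: all delayed terms zero except u(k-3), u(k-4) appearing later
        y_hand = []
        prev = [0.0, 0.0]  # y(k-1), y(k-2)
        for k in range(5):
            uk2 = 1.0 if k >= 2 else 0.0
            uk3 = 1.0 if k >= 3 else 0.0
            uk4 = 1.0 if k >= 4 else 0.0
            val = 0.72 * prev[0] + 0.025 * prev[1] * uk2 + 0.01 * uk3 ** 2 + 0.2 * uk4
            y_hand.append(val)
            prev = [val, prev[0]]
        np.testing.assert_allclose(simulate_plant("2-1", u), y_hand, atol=1e-15)

    def test_training_inputs(self):
        u = train_input("2-1", seed=0)
        assert u.size == 900
        assert np.all(np.abs(u[:450]) <= 2.0)
        k = np.arange(450, 900)
        np.testing.assert_allclose(u[450:], 1.05 * np.sin(np.pi * k / 45))
        u2 = train_input("2-2", seed=1)
        assert u2.size == 1000 and np.all(np.abs(u2) <= 1.0)

    def test_test_signal_values(self):
        u = plant_test_input("2-1")
        assert u[299] == 1.0  # branch 250 < k <= 500
        assert u[99] == pytest.approx(np.sin(4 * np.pi), abs=1e-12)  # k=100
        u8 = plant_test_input("2-2")
        assert u8.size == 600
        assert u8[299] == pytest.approx(0.7608, abs=5e-5)  # k=300

    def test_divergence_detection(self):
        with pytest.raises(FloatingPointError):
            simulate_plant("2-3", np.full(2000, 1e3))


class TestMackeyGlass:
    def test_equilibrium_constant_solution(self):
        # x=1 with unit history solves the delay equation exactly
        cfg = MGConfig(tau=17.0, x0=1.0, history=1.0, n_points=200)
        series = simulate_mackey_glass(cfg)
        np.testing.assert_allclose(series, 1.0, atol=1e-9)

    def test_default_run_length_and_band(self):
        series = simulate_mackey_glass(MGConfig())
        assert series.size == 1200
        assert series[0] == 1.2
        post = series[124:]
        assert post.min() > 0.0 and post.max() < 1.5

    def test_halved_dt_agreement_before_chaotic_divergence(self):
        # deterministic comparison is only meaningful before trajectory
        # divergence amplifies integration differences exponentially
        c1 = MGConfig(n_points=200)
        c2 = MGConfig(n_points=200, dt=0.05)
        s1, s2 = simulate_mackey_glass(c1), simulate_mackey_glass(c2)
        assert np.max(np.abs(s1[124:] - s2[124:])) < 1e-3


class TestNoise:
    def test_absent_snr_is_identity(self, rng):
        x = rng.normal(size=100)
        np.testing.assert_array_equal(add_noise(x, None), x)

    def test_realised_snr_matches_request(self, rng):
        x = np.sin(np.linspace(0, 20, 500)) + 1.0
        noisy = add_noise(x, 10.0, seed=3)
        noise = noisy - x
        snr = 10 * np.log10(np.mean(x ** 2) / np.mean(noise ** 2))
        assert snr == pytest.approx(10.0, abs=0.1)

    def test_uniform_support_bound(self, rng):
        x = np.ones(2000)
        noise = add_noise(x, 0.0, seed=1) - x
        sigma = np.std(noise)
        assert np.max(np.abs(noise)) <= np.sqrt(3) * sigma * 1.02

    def test_zero_power_signal_rejected(self):
        with pytest.raises(ValueError):
            add_noise(np.zeros(10), 10.0)


class TestRegressors:
    def test_toy_series_alignment_hand_checked(self):
        x = np.arange(10.0)  # x[t] = t
        ds = make_regressors(x, lags=[1, 2])
        # rows t = 2..9: regressors (t-1, t-2), target t
        assert ds.n == 8
        np.testing.assert_array_equal(ds.y, np.arange(2.0, 10.0))
        np.testing.assert_array_equal(ds.U[:, 0], np.arange(1.0, 9.0))
        np.testing.assert_array_equal(ds.U[:, 1], np.arange(0.0, 8.0))

    def test_horizon_shifts_target(self):
        x = np.arange(10.0)
        ds = make_regressors(x, lags=[1], ph=2)
        # row t predicts x[t+2]
        np.testing.assert_array_equal(ds.y, np.arange(3.0, 10.0))
        np.testing.assert_array_equal(ds.U[:, 0], np.arange(0.0, 7.0))

    def test_mackey_glass_preset_dimension(self):
        series = simulate_mackey_glass(MGConfig(n_points=300))
        ds = make_regressors(series, lags=[6, 12, 18, 24])
        assert ds.m == 4

    def test_plant_lag_registry_consistency(self):
        for pid, (ylags, ulags) in plant_regressor_lags.items():
            assert all(l >= 0 for l in ylags + ulags)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            make_regressors(np.arange(3.0), lags=[5])


class TestMackeyGlassTask:
    def test_noisy_regressors_with_clean_or_noisy_target(self):
        from fjwnn.benchmarks import mackey_glass_dataset

        tr_n, te_n = mackey_glass_dataset(tau=17.0, snr_db=20.0, seed=0, target="noisy")
        tr_c, te_c = mackey_glass_dataset(tau=17.0, snr_db=20.0, seed=0, target="clean")
        # same observed regressors under both conventions
        np.testing.assert_array_equal(tr_n.U, tr_c.U)
        # targets differ by exactly the additive noise
        assert not np.allclose(tr_n.y, tr_c.y)
        clean_tr, _ = mackey_glass_dataset(tau=17.0, snr_db=None, seed=0)
        np.testing.assert_allclose(tr_c.y, clean_tr.y)


class TestGasFurnace:
    def _write(self, path, n=296):
        rng = np.random.default_rng(0)
        u = rng.normal(size=n)
        y = 50 + np.cumsum(rng.normal(size=n)) * 0.1
        with open(path, "w") as fh:
            for a, b in zip(u, y):
                fh.write(f"{a:.6f}  {b:.6f}\n")

    def test_equal_split_sizes(self, tmp_path):
        f = tmp_path / "gas.dat"
        self._write(f)
        train, test = load_gas_furnace(f)
        # 296 raw rows, 3 lost to the max output lag, halves of the rest
        assert train.m == 6
        assert abs(train.n - test.n) <= 1
        assert train.n + test.n == 296 - 3

    def test_wrong_row_count_warns(self, tmp_path):
        f = tmp_path / "gas.dat"
        self._write(f, n=100)
        with pytest.warns(UserWarning, match="296"):
            load_gas_furnace(f)

    def test_malformed_line_reports_number(self, tmp_path):
        f = tmp_path / "gas.dat"
        with open(f, "w") as fh:
            fh.write("1.0 2.0\nbad line here\n")
        with pytest.raises(ValueError, match="line 2"):
            load_gas_furnace(f)


class TestSyntheticEMG:
    def test_shapes_and_columns(self):
        ds = gen_synthetic_emg(EMGSynthConfig(seed=0))
        assert ds.n == 796 and ds.m == 4
        assert ds.column_names == ["BB", "BR", "TBL", "TBM"]

    def test_clean_linear_config_has_exact_linear_map(self):
        cfg = EMGSynthConfig(noise_level=0.0, crosstalk=0.0, nonlinearity=1.0, seed=0)
        ds = gen_synthetic_emg(cfg)
        coef, *_ = np.linalg.lstsq(ds.U, ds.y, rcond=None)
        pred = ds.U @ coef
        vaf = 100 * (1 - np.var(ds.y - pred) / np.var(ds.y))
        assert vaf == pytest.approx(100.0, abs=1e-6)

    def test_seeded_reproducibility(self):
        a = gen_synthetic_emg(EMGSynthConfig(seed=9))
        b = gen_synthetic_emg(EMGSynthConfig(seed=9))
        np.testing.assert_array_equal(a.U, b.U)
        np.testing.assert_array_equal(a.y, b.y)

    def test_loader_round_trip_and_tagging(self, tmp_path):
        ds = gen_synthetic_emg(EMGSynthConfig(seed=1, mvc_percent=30))
        f = tmp_path / "S3_30mvc_trial1.csv"
        ds.to_csv(f, target_name="torque")
        trials = load_emg_trials(tmp_path)
        assert len(trials) == 1
        t = trials[0]
        assert t["participant"] == "3" and t["mvc"] == 30
        np.testing.assert_allclose(t["dataset"].U, ds.U)
        np.testing.assert_allclose(t["dataset"].y, ds.y)

    def test_missing_torque_column_rejected(self, tmp_path):
        ds = gen_synthetic_emg(EMGSynthConfig(seed=1))
        df = ds.to_dataframe(target_name="force")
        f = tmp_path / "S1_50mvc.csv"
        df.to_csv(f, index=False)
        with pytest.raises(ValueError, match="torque"):
            load_emg_trials(tmp_path)
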