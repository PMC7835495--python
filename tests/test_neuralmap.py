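"""Velocity encoding, anti-identity loss, the mapper network and shift scans."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import beekin as bk
from beekin.neuralmap import (MapperConfig, MapperModel,
                              default_velocity_scale, shift_pairs)
from beekin.classifier import WindowSpec

from conftest import make_velocity

SCALE = default_velocity_scale(500.0)


class TestEncoding:
    def test_zero_velocity(self):
        assert bk.encode_velocity(0.0, SCALE).tolist() == [1.0, 0.0]

    def test_quarter_turn(self):
        theta = np.pi / 2
        enc = bk.encode_velocity(theta / SCALE, SCALE)
        assert np.allclose(enc, [0.0, 1.0], atol=1e-12)

    def test_roundtrip_random(self, rng):
        omega = rng.uniform(-0.9 * np.pi / SCALE, 0.9 * np.pi / SCALE, 1000)
        back = bk.decode_velocity(bk.encode_velocity(omega, SCALE), SCALE)
        assert np.max(np.abs(back - omega)) < 1e-9 / SCALE * 1e-3

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(st.floats(-0.99 * np.pi, 0.99 * np.pi))
    def test_decode_inverts_encode_property(self, theta):
        omega = theta / SCALE
        back = bk.decode_velocity(bk.encode_velocity(omega, SCALE), SCALE)
        assert back * SCALE == pytest.approx(theta, abs=1e-9)

    def test_out_of_range_names_frame(self):
        omega = np.array([0.0, 2 * np.pi / SCALE])
        with pytest.raises(ValueError, match="frame 1"):
            bk.encode_velocity(omega, SCALE)

    def test_decode_scale_invariance_and_zero_vector(self):
        assert bk.decode_velocity([0.5, 0.0], SCALE) == bk.decode_velocity(
            [1.0, 0.0], SCALE) == 0.0
        assert bk.decode_velocity([0.0, -1.0], SCALE) == pytest.approx(
            -np.pi / 2 / SCALE)
        with pytest.raises(ValueError):
            bk.decode_velocity([0.0, 0.0], SCALE)


def zero_model(n_in=3, n_hidden=4):
    cfg = MapperConfig(n_hidden=n_hidden, window_ms=5.0)
    return MapperModel(config=cfg, W1=np.zeros((n_in, n_hidden)),
                       b1=np.zeros(n_hidden), W2=np.zeros((n_hidden, 2)),
                       b2=np.zeros(2))


class TestForward:
    def test_zero_weights_give_zero_output(self):
        model = zero_model()
        assert np.allclose(bk.mlp_forward(model, np.ones((5, 3))), 0.0)

    def test_output_bias_passes_through_tanh(self):
        model = zero_model()
        model.b2 = np.array([0.3, -0.7])
        out = bk.mlp_forward(model, np.zeros((2, 3)))
        assert np.allclose(out, np.tanh([0.3, -0.7]))

    def test_matches_independent_matrix_oracle(self, rng):
        """Dual implementation: plain per-sample loops with explicit
        bias concatenation."""
        n_in, N = 7, 5
        cfg = MapperConfig(n_hidden=N, window_ms=13.0)
        model = MapperModel(config=cfg,
                            W1=rng.normal(size=(n_in, N)), b1=rng.normal(size=N),
                            W2=rng.normal(size=(N, 2)), b2=rng.normal(size=2))
        X = rng.normal(size=(11, n_in))
        got = bk.mlp_forward(model, X)
        for i in range(11):
            h = np.concatenate([X[i], [1.0]]) @ np.vstack([model.W1, model.b1])
            h = np.where(h > 0, h, 0.0)
            o = np.tanh(np.concatenate([h, [1.0]]) @ np.vstack([model.W2, model.b2]))
            assert np.allclose(got[i], o, atol=1e-9)

    def test_wrong_window_length_rejected(self):
        with pytest.raises(ValueError):
            bk.mlp_forward(zero_model(), np.ones((2, 5)))


class TestLoss:
    def test_zero_when_output_matches_target(self, rng):
        enc = bk.encode_velocity(rng.uniform(-100, 100, 8), SCALE)
        other = bk.encode_velocity(rng.uniform(-100, 100, 8), SCALE)
        assert bk.anti_identity_loss(enc, other, enc) == 0.0

    def test_identity_output_hits_epsilon_denominator(self):
        """When the output reproduces the source encoding the denominator
        collapses to epsilon: loss = d / 0.1 with d the squared gap."""
        head = np.array([[1.0, 0.0]])
        thorax = np.array([[0.8, 0.6]])
        d = float(np.sum((head - thorax) ** 2))
        loss = bk.anti_identity_loss(head, thorax, thorax)
        assert loss == pytest.approx(d / 0.1)

    def test_orthogonal_encodings_give_twenty(self):
        head = np.array([[0.0, 1.0]])     # theta = pi/2
        thorax = np.array([[1.0, 0.0]])   # theta = 0
        out = np.array([[1.0, 0.0]])
        assert bk.anti_identity_loss(head, thorax, out) == pytest.approx(20.0)

    def test_epsilon_must_be_positive(self):
        a = np.ones((1, 2))
        with pytest.raises(ValueError):
            bk.anti_identity_loss(a, a, a, epsilon=0.0)


class TestShiftPairs:
    def test_tau_zero_is_centered(self, rng):
        src = make_velocity(rng.normal(0, 100, 50))
        tgt = make_velocity(rng.normal(0, 100, 50))
        w = WindowSpec(12.0)  # 7 samples, h=3
        X, t_om, s_om = shift_pairs(src, tgt, 0.0, w)
        assert X.shape == (44, 7)
        assert np.array_equal(t_om, tgt.omega_z[3:-3])
        assert np.array_equal(s_om, src.omega_z[3:-3])

    def test_backcast_target_precedes_window(self):
        src = make_velocity(np.arange(30.0))
        tgt = make_velocity(100 + np.arange(30.0))
        w = WindowSpec(8.0)  # 5 samples
        X, t_om, _ = shift_pairs(src, tgt, 4.0, w)  # tau = +2 samples
        # window starts at a, target at a-2
        assert np.array_equal(X[:, 0], src.omega_z[2:-4])
        assert np.array_equal(t_om, tgt.omega_z[:X.shape[0]])

    def test_forecast_window_entirely_precedes_target(self):
        src = make_velocity(np.arange(30.0))
        tgt = make_velocity(np.arange(30.0))
        w = WindowSpec(8.0)  # 5 samples
        X, t_om, _ = shift_pairs(src, tgt, -6.0, w)  # tau = -3 samples
        for row, target in zip(X, t_om):
            assert row[-1] < target  # last observation strictly before target

    @pytest.mark.parametrize("tau_ms", [-10.0, -2.0, 0.0, 2.0, 10.0])
    def test_pair_count(self, rng, tau_ms):
        L = int(rng.integers(40, 120))
        src = make_velocity(rng.normal(0, 10, L))
        tgt = make_velocity(rng.normal(0, 10, L))
        w = WindowSpec(12.0)
        X, _, _ = shift_pairs(src, tgt, tau_ms, w)
        k = abs(int(round(tau_ms * 500 / 1000)))
        assert X.shape[0] == L - (w.n_samples - 1) - k

    def test_non_representable_tau(self):
        src = make_velocity(np.zeros(30))
        with pytest.raises(ValueError, match="whole number"):
            shift_pairs(src, src, 1.0, WindowSpec(4.0))  # 0.5 samples at 500fps

    def test_too_long_shift_warns_empty(self):
        src = make_velocity(np.zeros(10))
        with pytest.warns(RuntimeWarning):
            X, _, _ = shift_pairs(src, src, 40.0, WindowSpec(8.0))
        assert X.shape[0] == 0


class TestErrorAngle:
    def test_trivial_angles(self):
        assert bk.unsigned_error_angle([1, 0], [1, 0])[0] == 0.0
        assert bk.unsigned_error_angle([1, 0], [-1, 0])[0] == pytest.approx(np.pi)
        assert bk.unsigned_error_angle([1, 0], [0, 1])[0] == pytest.approx(np.pi / 2)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            bk.unsigned_error_angle([0, 0], [1, 0])


def coupled_series(n=2500, gain=0.8, noise=5.0, seed=0, fps=500.0):
    rng = np.random.default_rng(seed)
    base = np.convolve(rng.normal(0, 200, n), np.ones(9) / 9, mode="same")
    src = make_velocity(base, fps=fps)
    tgt = make_velocity(gain * base + rng.normal(0, noise, n), fps=fps)
    return src, tgt


class TestTraining:
    def test_loss_decreases_on_learnable_task(self):
        src, tgt = coupled_series()
        cfg = MapperConfig(n_hidden=4, window_ms=5.0, epochs=10, seed=1)
        model = bk.train_mapper([src], [tgt], cfg)
        assert model.loss_history[-1] < model.loss_history[0]

    def test_bitwise_reproducible(self):
        src, tgt = coupled_series()
        cfg = MapperConfig(n_hidden=4, window_ms=5.0, epochs=3, seed=9)
        a = bk.train_mapper([src], [tgt], cfg)
        b = bk.train_mapper([src], [tgt], cfg)
        assert np.array_equal(a.W1, b.W1) and np.array_equal(a.W2, b.W2)
        assert a.loss_history == b.loss_history

    def test_beats_constant_predictor(self):
        """On a linearly coupled pair the trained mapper's median error angle
        must undercut the best constant output (the circular median
        direction of the targets)."""
        src, tgt = coupled_series(seed=3)
        cfg = MapperConfig(n_hidden=8, window_ms=9.0, epochs=20, seed=0)
        model = bk.train_mapper([src], [tgt], cfg)
        X, t_om, _ = shift_pairs(src, tgt, 0.0, cfg.window)
        enc_t = bk.encode_velocity(t_om, cfg.velocity_scale)
        pred = model.forward(X * cfg.velocity_scale)
        med_model = np.median(bk.unsigned_error_angle(pred, enc_t))
        # best constant: grid over candidate constant directions
        best_const = min(
            np.median(bk.unsigned_error_angle(
                np.tile(bk.encode_velocity(c, cfg.velocity_scale), (t_om.size, 1)),
                enc_t))
            for c in np.linspace(-300, 300, 121))
        assert med_model < best_const

    def test_independent_noise_gives_no_correlation(self):
        rs = []
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            src = make_velocity(np.convolve(rng.normal(0, 200, 2000),
                                            np.ones(5) / 5, "same"))
            tgt = make_velocity(np.convolve(rng.normal(0, 200, 2000),
                                            np.ones(5) / 5, "same"))
            cfg = MapperConfig(n_hidden=4, window_ms=5.0, epochs=10, seed=seed)
            split = 1400
            model = bk.train_mapper(
                [bk.VelocitySeries(times=src.times[:split], fps=500.0,
                                   part="head", omega_z=src.omega_z[:split])],
                [bk.VelocitySeries(times=tgt.times[:split], fps=500.0,
                                   part="thorax", omega_z=tgt.omega_z[:split])],
                cfg)
            X, t_om, _ = shift_pairs(
                bk.VelocitySeries(times=src.times[split:], fps=500.0,
                                  part="head", omega_z=src.omega_z[split:]),
                bk.VelocitySeries(times=tgt.times[split:], fps=500.0,
                                  part="thorax", omega_z=tgt.omega_z[split:]),
                0.0, cfg.window)
            pred = model.predict_velocity(X * cfg.velocity_scale * 0 + X * cfg.velocity_scale)
            r = np.corrcoef(pred, t_om)[0, 1]
            rs.append(0.0 if np.isnan(r) else r)
        assert np.max(np.abs(rs)) < 0.25
        assert abs(np.mean(rs)) < 0.1


class TestGridSearchMapper:
    def _flights(self, n_flights=3, seed=0):
        srcs, tgts = [], []
        for i in range(n_flights):
            s, t = coupled_series(n=1500, seed=seed + i)
            srcs.append(s); tgts.append(t)
        return srcs, tgts

    def test_single_cell(self):
        srcs, tgts = self._flights()
        base = MapperConfig(epochs=3, seed=0)
        cfg, table = bk.grid_search_mapper(srcs, tgts, N_grid=[4],
                                           delta_t_grid=[5], base=base)
        assert len(table) == 1
        assert cfg.n_hidden == 4 and cfg.window_ms == 5

    def test_table_size(self):
        srcs, tgts = self._flights()
        base = MapperConfig(epochs=2, seed=0)
        _, table = bk.grid_search_mapper(srcs, tgts, N_grid=[2, 4],
                                         delta_t_grid=[1, 5, 9], base=base)
        assert len(table) == 6

    def test_wider_window_helps_lagged_coupling(self):
        """Target built from the source 2 samples back: a 9 ms window covers
        the informative lag, a 1 ms window cannot."""
        srcs, tgts = [], []
        for i in range(3):
            rng = np.random.default_rng(40 + i)
            base = np.convolve(rng.normal(0, 200, 2000), np.ones(5) / 5, "same")
            src = make_velocity(base)
            lagged = np.roll(base, 2)
            lagged[:2] = 0
            tgts.append(make_velocity(0.9 * lagged))
            srcs.append(src)
        cfg, table = bk.grid_search_mapper(
            srcs, tgts, N_grid=[8], delta_t_grid=[1, 9],
            base=MapperConfig(epochs=15, seed=0))
        med = table.set_index("delta_t_ms")["median_error_angle"]
        assert med[9] <= med[1]
        assert cfg.window_ms == 9


class TestCorrelationVsShift:
    def test_identity_task_without_regularization(self):
        """Mapping a series onto an exact copy of itself: with the
        anti-identity penalty disabled the network may learn the identity and
        r(0) approaches 1."""
        srcs = []
        for i in range(2):
            s, _ = coupled_series(n=2000, seed=60 + i)
            srcs.append(s)
        cfg = MapperConfig(n_hidden=16, window_ms=5.0, epochs=150, seed=0,
                           lambda_reg=0.0, learning_rate=0.02)
        table = bk.correlation_vs_shift(srcs, srcs, [0.0], cfg)
        assert table.loc[0, "r"] > 0.99

    def test_lag_recovery(self):
        """Target delayed by 10 ms: the forecasting side of the scan peaks at
        a shift of ~10 ms magnitude."""
        srcs, tgts = [], []
        for i in range(3):
            rng = np.random.default_rng(70 + i)
            base = np.convolve(rng.normal(0, 200, 3000), np.ones(7) / 7, "same")
            delayed = np.roll(base, 5)  # 10 ms at 500 fps
            delayed[:5] = 0.0
            srcs.append(make_velocity(base))
            tgts.append(make_velocity(delayed + rng.normal(0, 3, 3000)))
        cfg = MapperConfig(n_hidden=8, window_ms=3.0, epochs=15, seed=0)
        taus = [-16.0, -14.0, -12.0, -10.0, -8.0, -6.0, -4.0, 0.0, 4.0, 8.0]
        table = bk.correlation_vs_shift(srcs, tgts, taus, cfg)
        peak = table.loc[table["r"].idxmax(), "tau_ms"]
        assert -12.0 <= peak <= -8.0


class TestFacade:
    def test_fit_summary_and_shift_scan(self, small_flights):
        cfg = MapperConfig(n_hidden=4, window_ms=5.0, epochs=5, seed=0)
        vm = bk.VelocityMapper.from_flights(small_flights, "thorax2head", cfg)
        res = vm.fit()
        assert 0 <= res.validation["median_error_angle"] <= np.pi
        assert "Velocity mapper" in res.summary()
        table = vm.shift_scan([-4.0, 0.0, 4.0])
        assert list(table["tau_samples"]) == [-2, 0, 2]
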