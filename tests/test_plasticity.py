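"""Unit and property tests of the STDP/metaplasticity rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcplast.plasticity import (
    PlasticityParams,
    apply_weight_update,
    detect_events,
    pair_nearest_neighbor,
    run_on_streams,
    update_amplitudes,
    update_spike_average,
)
from oracles import brute_force_weights, random_streams


class TestDetectEvents:
    def test_constant_subthreshold_trace(self):
        t = np.arange(0, 100, 0.2)
        assert len(detect_events(t, np.full_like(t, -70.0), -37.0)) == 0

    def test_triangle_wave_single_crossing_interpolated(self):
        # ramp -70 -> -20 over 10 ms then back: crossing of -37 at t = 6.6 ms
        t = np.arange(0, 20.0001, 0.2)
        v = np.where(t <= 10, -70 + 5 * t, -20 - 5 * (t - 10))
        ev = detect_events(t, v, -37.0)
        assert len(ev) == 1
        assert ev[0] == pytest.approx((70 - 37) / 5.0, abs=1e-9)

    def test_debounce_merges_rapid_crossings(self):
        t = np.arange(0, 10, 0.2)
        v = -70 + 40 * (np.sin(2 * np.pi * t / 2.0) > 0)  # 2 ms period square-ish
        ev = detect_events(t, v, -37.0, debounce=5.0)
        assert len(ev) == 2  # crossings at ~0.2 and ~6 ms survive, rest debounced

    def test_nonfinite_rejected(self):
        t = np.arange(0, 1, 0.2)
        v = np.array([0.0, np.nan, 0, 0, 0])
        with pytest.raises(ValueError):
            detect_events(t, v, -37.0)


class TestSpikeAverage:
    def test_no_spikes_stays_zero(self):
        c = 0.0
        for _ in range(1000):
            c = update_spike_average(c, False, 0.2, 60.0, 2500.0)
        assert c == 0.0

    def test_single_spike_decay_matches_integral(self):
        # after one spike, ⟨c⟩(t) = (α/τ)·dt·exp(−(t−t0)/τ)
        dt, tau_s, alpha = 0.2, 60.0, 2500.0
        c = update_spike_average(0.0, True, dt, tau_s, alpha)
        assert c == pytest.approx(alpha / (tau_s * 1000.0) * dt)
        for _ in range(5000):
            c = update_spike_average(c, False, dt, tau_s, alpha)
        expected = (alpha / (tau_s * 1000.0)) * dt * np.exp(-5000 * dt / (tau_s * 1000.0))
        assert c == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("dt,alpha", [(0.2, 2500.0), (0.1, 5000.0)])
    def test_steady_state_is_alpha_dt_rate(self, dt, alpha):
        """Regular 2 Hz spiking -> ⟨c⟩ = α·dt·rate = 1, invariant under dt with α·dt fixed."""
        c = 0.0
        period_steps = int(round(500.0 / dt))  # 2 Hz
        for k in range(int(round(300_000.0 / dt))):  # 300 s
            c = update_spike_average(c, k % period_steps == 0, dt, 60.0, alpha)
        assert c == pytest.approx(alpha * dt * 2e-3, rel=0.02)


class TestAmplitudes:
    def test_unity_scaling(self):
        p = PlasticityParams()
        assert update_amplitudes(1.0, p) == (pytest.approx(0.003), pytest.approx(0.001))

    def test_reciprocal_scaling(self):
        p = PlasticityParams()
        a_p, a_d = update_amplitudes(3.0, p)
        assert a_p == pytest.approx(0.001)
        assert a_d == pytest.approx(0.003)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_product_conserved(self, c):
        p = PlasticityParams()
        a_p, a_d = update_amplitudes(c, p)
        assert a_p * a_d == pytest.approx(3e-6, rel=1e-12)

    def test_floor_keeps_amplitudes_finite(self):
        p = PlasticityParams()
        a_p, a_d = update_amplitudes(0.0, p)
        assert np.isfinite(a_p) and a_p == pytest.approx(0.003 / p.c_floor)

    def test_freeze_flags(self):
        p = PlasticityParams(freeze_a_p=True)
        a_p, a_d = update_amplitudes(5.0, p)
        assert a_p == 0.003 and a_d == pytest.approx(0.005)

    def test_homeostasis_direction(self):
        """Higher sustained firing lowers A_p and raises A_d monotonically."""
        p = PlasticityParams()
        cs = [0.5, 1.0, 2.0, 4.0]
        aps, ads = zip(*(update_amplitudes(c, p) for c in cs))
        assert all(x > y for x, y in zip(aps, aps[1:]))
        assert all(x < y for x, y in zip(ads, ads[1:]))


class TestPairing:
    def test_between_two_posts(self):
        assert pair_nearest_neighbor(100.0, np.array([90.0, 130.0])) == (-10.0, 30.0)

    def test_no_posts(self):
        assert pair_nearest_neighbor(100.0, np.array([])) == (None, None)

    def test_single_shared_post(self):
        posts = np.array([150.0])
        assert pair_nearest_neighbor(100.0, posts) == (None, 50.0)
        assert pair_nearest_neighbor(200.0, posts) == (-50.0, None)

    def test_coincident_post_is_before_neighbor(self):
        before, after = pair_nearest_neighbor(100.0, np.array([100.0, 140.0]))
        assert before == 0.0 and after == 40.0

    @given(
        st.lists(st.floats(0, 1000), min_size=0, max_size=20),
        st.floats(0, 1000),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_search(self, posts, pre):
        posts = np.sort(np.asarray(posts))
        before, after = pair_nearest_neighbor(pre, posts)
        deltas = posts - pre
        exp_before = deltas[deltas <= 0].max() if (deltas <= 0).any() else None
        exp_after = deltas[deltas > 0].min() if (deltas > 0).any() else None
        assert before == (pytest.approx(exp_before) if exp_before is not None else None)
        assert after == (pytest.approx(exp_after) if exp_after is not None else None)


class TestWeightUpdate:
    def test_potentiation_at_one_window_width(self):
        w = apply_weight_update(1.0, None, 20.0, 0.003, 0.001, 20.0, 70.0, 1.0)
        assert w == pytest.approx(1.0 + 0.003 * np.exp(-1.0), rel=1e-9)

    def test_depression_at_one_window_width(self):
        w = apply_weight_update(1.0, -70.0, None, 0.003, 0.001, 20.0, 70.0, 1.0)
        assert w == pytest.approx(1.0 - 0.001 * np.exp(-1.0), rel=1e-9)

    def test_coincident_events_change_nothing(self):
        assert apply_weight_update(1.0, 0.0, None, 0.003, 0.001, 20.0, 70.0, 1.0) == 1.0

    def test_saturation_at_double_baseline(self):
        w = 1.0
        for _ in range(5000):
            w = apply_weight_update(w, None, 1.0, 0.01, 0.001, 20.0, 70.0, 1.0)
        assert w == pytest.approx(2.0)

    def test_monotonic_in_timing(self):
        """|Δw| strictly decreases as the pair separates in time."""
        dws = [
            apply_weight_update(1.0, None, d, 0.003, 0.001, 20.0, 70.0, 1.0) - 1.0
            for d in (1.0, 5.0, 20.0, 50.0)
        ]
        assert all(a > b > 0 for a, b in zip(dws, dws[1:]))
        dwd = [
            1.0 - apply_weight_update(1.0, -d, None, 0.003, 0.001, 20.0, 70.0, 1.0)
            for d in (1.0, 5.0, 70.0, 200.0)
        ]
        assert all(a > b > 0 for a, b in zip(dwd, dwd[1:]))

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            apply_weight_update(0.0, None, 1.0, 0.003, 0.001, 20.0, 70.0, 1.0)


class TestStreamingEngine:
    def _params(self):
        # frozen amplitudes isolate the pairing arithmetic
        return PlasticityParams(freeze_a_p=True, freeze_a_d=True)

    def test_no_events_only_decay(self):
        res = run_on_streams(
            [np.array([])], [np.array([])], np.array([]), 100.0, 0.2, self._params()
        )
        assert np.all(res["w"] == 1.0)
        assert np.all(res["c_avg"] == 0.0)

    def test_handbuilt_stream_matches_oracle(self):
        pre = [np.array([10.0, 35.0, 60.0, 61.0, 95.0])]
        post = [np.array([20.0, 50.0, 90.0])]
        params = self._params()
        res = run_on_streams(pre, post, np.array([]), 120.0, 0.2, params)
        expected = brute_force_weights(
            pre, post, 120.0, 0.2, params.a_p0, params.a_d0,
            params.tau_p, params.tau_d, np.ones(1),
        )
        assert res["state"].w == pytest.approx(expected, rel=1e-12)

    def test_streaming_equals_brute_force_on_random_streams(self):
        """Pre-centered pairing: streaming vs exhaustive enumeration (seeded fuzz)."""
        params = self._params()
        rng = np.random.default_rng(2024)
        for _ in range(200):
            pre, post = random_streams(rng, 150.0, debounce=params.debounce)
            res = run_on_streams([pre], [post], np.array([]), 160.0, 0.2, params)
            expected = brute_force_weights(
                [pre], [post], 160.0, 0.2, params.a_p0, params.a_d0,
                params.tau_p, params.tau_d, np.ones(1), lapse=params.lapse,
            )
            np.testing.assert_allclose(res["state"].w, expected, rtol=1e-12)

    def test_weight_bounds_never_violated_under_fuzz(self):
        params = PlasticityParams(a_p0=0.2, a_d0=0.15)  # exaggerated amplitudes
        rng = np.random.default_rng(7)
        for _ in range(20):
            pre, post = random_streams(rng, 300.0)
            soma = np.sort(rng.uniform(0, 300.0, size=rng.integers(0, 20)))
            res = run_on_streams([pre], [post], soma, 310.0, 0.2, params)
            assert np.all(res["w"] > 0)
            assert np.all(res["w"] <= 2.0 + 1e-12)
            assert np.all(res["w"] >= 0.0)

    def test_amplitude_product_conserved_during_run(self):
        params = PlasticityParams()
        rng = np.random.default_rng(11)
        pre, post = random_streams(rng, 500.0)
        soma = np.sort(rng.uniform(0, 500.0, size=10))
        res = run_on_streams([pre], [post], soma, 510.0, 0.2, params)
        np.testing.assert_allclose(res["a_p"] * res["a_d"], 3e-6, rtol=1e-12)

    def test_warmup_freezes_weights_but_tracks_c(self):
        pre = [np.array([10.0, 120.0])]
        post = [np.array([15.0, 125.0])]
        soma = np.array([15.0, 125.0])
        res = run_on_streams(
            pre, post, soma, 200.0, 0.2, PlasticityParams(), warmup=100.0, record_every=1.0
        )
        i_early = np.searchsorted(res["times"], 50.0)
        assert res["w"][i_early, 0] == 1.0  # no change during warm-up
        assert res["c_avg"][i_early] > 0  # but ⟨c⟩ already integrating
        assert res["state"].w[0] > 1.0  # potentiation after warm-up
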