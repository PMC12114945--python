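"""Entropy-trend detector: smoothing, slope rule, modes, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgonset import (
    Config,
    EmgSignal,
    SynthSpec,
    detect,
    detect_onset,
    entropy_sequence,
    generate,
    plan_windows,
    smooth_trend,
)
from emgonset.preprocess import WindowPlan

FS = 1500.0


def _plan(K: int, s: int = 96, t0: float = 0.0) -> WindowPlan:
    return WindowPlan(L_samples=192, s_samples=s, K=K, t0=t0, fs=FS)


class TestSmoothTrend:
    def test_spike_spread_with_edge_truncation(self):
        np.testing.assert_allclose(
            smooth_trend(np.array([0, 0, 1, 0, 0.0]), 3), [0, 1 / 3, 1 / 3, 1 / 3, 0]
        )

    def test_length_one_is_identity(self):
        m = np.array([0.3, 0.9, 0.1])
        np.testing.assert_array_equal(smooth_trend(m, 1), m)

    def test_constants_preserved(self):
        np.testing.assert_allclose(smooth_trend(np.full(9, 0.7), 5), np.full(9, 0.7))

    def test_even_length_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth_trend(np.zeros(10), 4)


class TestDetectOnset:
    def test_worked_example(self):
        T = np.array([0.90, 0.88, 0.85, 0.60, 0.55])
        res = detect_onset(T, _plan(5))
        assert res.k_star == 3
        assert res.t_star == pytest.approx(0.128)
        np.testing.assert_allclose(res.diagnostics["delta"], [-0.02, -0.03, -0.25, -0.05])

    def test_tied_slopes_take_earliest(self):
        res = detect_onset(np.array([1.0, 0.5, 0.0, -0.5]), _plan(4, t0=1.5))
        assert res.k_star == 1
        assert res.t_star == 1.5

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=50))
    @settings(max_examples=300, derandomize=True)
    def test_matches_exhaustive_scan(self, values):
        T = np.array(values)
        res = detect_onset(T, _plan(T.size))
        best_k, best_v = None, np.inf
        for k in range(T.size - 1):
            d = T[k + 1] - T[k]
            if d < best_v:
                best_k, best_v = k + 1, d
        assert res.k_star == best_k

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            detect_onset(np.array([0.5]), _plan(1))


class TestEntropySequence:
    def test_pure_tone_windows_agree(self, tone):
        sig = tone(100.0, duration_s=2.0)
        trend = entropy_sequence(sig, plan_windows(sig))
        assert np.ptp(trend.M) <= 0.15
        assert np.all((trend.M >= 0) & (trend.M <= 1))

    def test_stationary_noise_has_no_trend(self):
        sig, _ = generate(SynthSpec(seed=11, snr_db=None, duration=4.0))
        trend = entropy_sequence(sig, plan_windows(sig))
        assert trend.M.std() <= 0.1

    def test_single_window_signal(self, fs):
        sig = EmgSignal(np.random.default_rng(0).standard_normal(192), fs=fs)
        trend = entropy_sequence(sig, plan_windows(sig))
        assert trend.M.shape == (1,)

    def test_dead_windows_inherit_previous_value(self, fs):
        x = np.concatenate([np.random.default_rng(1).standard_normal(192 * 3), np.zeros(96 * 3)])
        sig = EmgSignal(x, fs=fs)
        trend = entropy_sequence(sig, plan_windows(sig))
        assert trend.n_failed_windows > 0
        assert np.all(np.isfinite(trend.M))


class TestDetectModes:
    def test_mse_only_takes_global_minimum(self):
        from emgonset.detect import EntropyTrend, onset_from_trend

        T = np.array([0.9, 0.8, 0.3, 0.4])
        trend = EntropyTrend(M=T.copy(), T=T.copy(), plan=_plan(4), smooth_len=1)
        cfg = Config(detector_smooth_len=1)
        assert onset_from_trend(trend, "mse-only", cfg).k_star == 3
        trend2 = EntropyTrend(M=T.copy(), T=T.copy(), plan=_plan(4), smooth_len=1)
        assert onset_from_trend(trend2, "mse", cfg).k_star == 2

    def test_high_snr_recovery_within_tolerance(self):
        sig, t_on = generate(SynthSpec(seed=2, snr_db=30.0, rise=0.5, t_on=2.0))
        res = detect(sig, "mse")
        assert res.t_star == pytest.approx(t_on, abs=0.2)

    def test_time_shift_equivariance(self):
        sig, _ = generate(SynthSpec(seed=3, snr_db=30.0, rise=0.5, t_on=1.5, duration=4.0))
        res0 = detect(sig, "mse")
        q = 5
        pad = np.random.default_rng(99).standard_normal(q * 96) * sig.samples[:200].std()
        shifted = EmgSignal(np.concatenate([pad, sig.samples]), fs=sig.fs)
        res1 = detect(shifted, "mse")
        step = 96 / sig.fs
        assert abs((res1.t_star - res0.t_star) - q * step) <= step

    def test_runs_are_deterministic(self):
        sig, _ = generate(SynthSpec(seed=5, rise=0.8))
        a = detect(sig, "mse")
        b = detect(sig, "mse")
        assert a.t_star == b.t_star and a.k_star == b.k_star

    @pytest.mark.parametrize("mode", ["energy-slope", "mse-nowindow"])
    def test_ablation_modes_detect_high_snr_activation(self, mode):
        sig, t_on = generate(SynthSpec(seed=4, snr_db=30.0, rise=0.5, t_on=2.0))
        res = detect(sig, mode)
        assert res.detected
        assert res.method == mode
        assert sig.t0 <= res.t_star <= sig.t0 + sig.duration

    def test_energy_slope_finds_amplitude_step(self, fs):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(int(4 * fs))
        x[int(2.0 * fs):] *= 6.0
        res = detect(EmgSignal(x, fs=fs), "energy-slope", Config(filter_enabled=False))
        assert res.t_star == pytest.approx(2.0, abs=0.15)

    def test_rejection_rule_silences_pure_noise(self):
        sig, _ = generate(SynthSpec(seed=21, snr_db=None, duration=4.0))
        cfg = Config(detector_reject_delta=0.02)
        assert not detect(sig, "mse", cfg).detected

    def test_unknown_mode_rejected(self, tone):
        with pytest.raises(ValueError, match="unknown method"):
            detect(tone(100.0), "nonsense")
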