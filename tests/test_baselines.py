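"""Amplitude/energy baseline detectors: analytic identities and recovery."""

import numpy as np
import pytest

from emgonset import EmgSignal, plan_windows
from emgonset.baselines import (
    BaselineParams,
    detect_rms,
    detect_threshold,
    detect_tke,
    detect_wavelet,
    tke_operator,
)

FS = 1500.0
PARAMS = BaselineParams()


class TestTkeOperator:
    def test_quarter_period_cosine_identity(self):
        # cos at Omega = pi/2: psi = A^2 sin^2(Omega) = 1 on the interior
        np.testing.assert_allclose(tke_operator(np.array([0.0, 1.0, 0.0, -1.0, 0.0]))[1:-1], 1.0)

    def test_constant_signal_has_zero_energy(self):
        np.testing.assert_allclose(tke_operator(np.full(10, 3.0)), 0.0, atol=1e-12)

    @pytest.mark.parametrize("A", [1.0, 2.0])
    @pytest.mark.parametrize("omega", [np.pi / 4, np.pi / 2])
    def test_tone_identity(self, A, omega):
        n = np.arange(300)
        psi = tke_operator(A * np.cos(omega * n))
        expected = A**2 * np.sin(omega) ** 2
        np.testing.assert_allclose(psi[1:-1], expected, atol=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            tke_operator(np.array([1.0, 2.0]))


class TestThreshold:
    def test_linear_ramp_crosses_at_30_percent(self):
        sig = EmgSignal(np.linspace(0.0, 1.0, int(FS) + 1), fs=FS)
        res = detect_threshold(sig, PARAMS)
        assert res.t_star == pytest.approx(0.30, abs=0.01)

    def test_step_envelope_within_filter_lag(self):
        n = int(2 * FS)
        env = np.where(np.arange(n) / FS >= 0.5, 1.0, 0.0)
        res = detect_threshold(EmgSignal(env + 1e-9, fs=FS), PARAMS)
        assert res.t_star == pytest.approx(0.5, abs=0.05)

    def test_scale_invariant(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(int(3 * FS))
        x[int(1.5 * FS):] *= 8.0
        t1 = detect_threshold(EmgSignal(x, fs=FS), PARAMS).t_star
        t10 = detect_threshold(EmgSignal(10 * x, fs=FS), PARAMS).t_star
        assert t1 == t10

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            detect_threshold(EmgSignal(np.ones(1000), fs=FS), PARAMS)


class TestTke:
    def test_abrupt_step_recovered(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(int(3 * FS))
        x[int(1.0 * FS):] *= 5.0
        res = detect_tke(EmgSignal(x, fs=FS), PARAMS)
        assert res.t_star == pytest.approx(1.0, abs=0.1)

    def test_pure_noise_stays_silent(self):
        from emgonset.synth import SynthSpec, generate

        absent = 0
        for seed in range(20):
            sig, _ = generate(SynthSpec(seed=seed, snr_db=None, duration=3.0))
            if not detect_tke(sig, PARAMS).detected:
                absent += 1
        assert absent == 20

    def test_zero_variance_baseline_triggers_on_first_energy(self):
        x = np.zeros(int(FS))
        x[600:] = np.sin(2 * np.pi * 100 * np.arange(x.size - 600) / FS)
        res = detect_tke(EmgSignal(x, fs=FS), PARAMS)
        assert res.detected
        assert res.t_star >= 600 / FS - 0.05

    def test_baseline_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            detect_tke(EmgSignal(np.ones(100), fs=FS), PARAMS)

    def test_scale_invariant(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(int(3 * FS))
        x[int(1.2 * FS):] *= 5.0
        sig = EmgSignal(x, fs=FS)
        sig10 = EmgSignal(10 * x, fs=FS)
        assert detect_tke(sig, PARAMS).t_star == detect_tke(sig10, PARAMS).t_star


class TestRmsAndWavelet:
    @staticmethod
    def _step_signal(step_window: int = 10, n_windows: int = 20):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(192 * n_windows)
        x[192 * (step_window - 1):] *= 4.0
        return EmgSignal(x, fs=FS)

    def test_rms_finds_step_window(self):
        sig = self._step_signal()
        plan = plan_windows(sig, 128, 0.0)
        res = detect_rms(sig, PARAMS, plan)
        assert res.k_star == 10
        assert res.t_star == pytest.approx(plan.window_start_time(10))

    def test_wavelet_agrees_with_rms_on_step(self):
        sig = self._step_signal()
        plan = plan_windows(sig, 128, 0.0)
        k_rms = detect_rms(sig, PARAMS, plan).k_star
        k_wav = detect_wavelet(sig, PARAMS, plan).k_star
        assert abs(k_wav - k_rms) <= 1

    def test_constant_amplitude_stays_silent(self):
        # a baseline long enough for a stable sigma estimate (15 windows);
        # with the default 300 ms baseline the mu+3sigma level is itself
        # noisy and occasional false alarms are expected
        params = BaselineParams(baseline_ms=960.0)
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(192 * 40)
            sig = EmgSignal(x, fs=FS)
            assert not detect_rms(sig, params, plan_windows(sig, 128, 0.5)).detected

    def test_persistence_suppresses_single_window_spike(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(192 * 20)
        x[192 * 12 : 192 * 13] *= 6.0  # lone spiky window
        sig = EmgSignal(x, fs=FS)
        plan = plan_windows(sig, 128, 0.0)
        res_consec1 = detect_rms(sig, BaselineParams(consec=1), plan)
        res_consec2 = detect_rms(sig, BaselineParams(consec=2), plan)
        assert res_consec1.detected
        assert not res_consec2.detected

    def test_wavelet_ignores_slow_drift(self):
        t = np.arange(int(4 * FS)) / FS
        sig = EmgSignal(np.sin(2 * np.pi * 1.0 * t), fs=FS)
        res = detect_wavelet(sig, PARAMS, plan_windows(sig))
        assert not res.detected

    def test_wavelet_scale_invariant(self):
        sig = self._step_signal()
        plan = plan_windows(sig, 128, 0.0)
        sig10 = EmgSignal(10 * sig.samples, fs=FS)
        assert (
            detect_wavelet(sig, PARAMS, plan).k_star
            == detect_wavelet(sig10, PARAMS, plan).k_star
        )

    def test_baseline_under_two_windows_rejected(self):
        sig = self._step_signal()
        plan = plan_windows(sig, 128, 0.0)  # 128 ms step > 300/2 ms
        with pytest.raises(ValueError):
            detect_rms(sig, BaselineParams(baseline_ms=150.0), plan)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(threshold_frac=0.0),
            dict(threshold_frac=1.0),
            dict(tke_j=-1.0),
            dict(consec=0),
            dict(wavelet_levels=0),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BaselineParams(**kwargs)
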