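"""Four classical amplitude/energy onset detectors used as comparators.

* ``threshold`` — rectified linear-envelope crossing of 30% of the envelope
  maximum; the standard single-threshold rule.
* ``tke`` — Teager-Kaiser energy operator Psi(i) = x(i)^2 - x(i-1)x(i+1),
  smoothed, against a baseline-statistics threshold mu_b + j*sigma_b.
* ``rms`` — per-window root mean square against mu_b + 3*sigma_b of the
  quiescent opening windows, with a persistence requirement.
* ``wavelet`` — per-window energy of discrete-wavelet detail coefficients
  (energy redistribution across scales), same decision rule as ``rms``.

All four assume the opening ``baseline_ms`` of the recording is quiescent
(the recordings this pipeline targets start at rest) and all are
scale-invariant: thresholds are relative to the signal or to its own
baseline statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .config import Config
from .preprocess import WindowPlan
from .signal import EmgSignal, OnsetResult

__all__ = [
    "BaselineParams",
    "detect_threshold",
    "tke_operator",
    "detect_tke",
    "detect_rms",
    "detect_wavelet",
]

_ENVELOPE_CUTOFF_HZ = 10.0  # rectified-EMG linear-envelope low-pass corner
_ENVELOPE_ORDER = 2
_TKE_SMOOTH_MS = 50.0
_SIGMA_MULT = 3.0  # mu_b + 3 sigma_b rule for rms/wavelet


@dataclass(frozen=True)
class BaselineParams:
    """Knobs of the comparison detectors (defaults are config-exposed)."""

    threshold_frac: float = 0.30
    tke_j: float = 8.0
    baseline_ms: float = 300.0
    consec: int = 2
    wavelet_name: str = "db4"
    wavelet_levels: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.threshold_frac < 1):
            raise ValueError("threshold_frac must be in (0, 1)")
        if self.tke_j <= 0 or self.baseline_ms <= 0:
            raise ValueError("tke_j and baseline_ms must be positive")
        if self.consec < 1 or self.wavelet_levels < 1:
            raise ValueError("consec and wavelet_levels must be >= 1")

    @classmethod
    def from_config(cls, cfg: Config) -> "BaselineParams":
        return cls(
            threshold_frac=cfg.baseline_threshold_frac,
            tke_j=cfg.baseline_tke_j,
            baseline_ms=cfg.baseline_baseline_ms,
            consec=cfg.baseline_consec,
            wavelet_name=cfg.baseline_wavelet,
            wavelet_levels=cfg.baseline_levels,
        )


def _sample_result(method: str, signal: EmgSignal, idx, diagnostics: dict) -> OnsetResult:
    diagnostics = dict(diagnostics, index_kind="sample")
    if idx is None:
        return OnsetResult(method=method, diagnostics=diagnostics)
    return OnsetResult(
        method=method,
        k_star=int(idx) + 1,  # 1-based sample index
        t_star=signal.t0 + int(idx) / signal.fs,
        diagnostics=diagnostics,
    )


def linear_envelope(signal: EmgSignal) -> np.ndarray:
    """Rectify and low-pass (2nd-order zero-phase Butterworth, 10 Hz)."""
    sos = sps.butter(_ENVELOPE_ORDER, _ENVELOPE_CUTOFF_HZ, btype="low", fs=signal.fs, output="sos")
    return sps.sosfiltfilt(sos, np.abs(signal.samples))


def detect_threshold(signal: EmgSignal, params: BaselineParams) -> OnsetResult:
    """Mark onset where the linear envelope first exceeds
    ``threshold_frac`` (default 30%) of its own maximum."""
    if np.ptp(signal.samples) == 0:
        raise ValueError("threshold detection is undefined on a constant signal")
    env = linear_envelope(signal)
    level = params.threshold_frac * float(env.max())
    above = np.nonzero(env > level)[0]
    idx = int(above[0]) if above.size else None
    return _sample_result("threshold", signal, idx, {"envelope": env, "level": level})


def tke_operator(x: np.ndarray) -> np.ndarray:
    """Teager-Kaiser energy Psi(i) = x(i)^2 - x(i-1)*x(i+1).

    Defined on interior samples; endpoints copy the nearest interior value
    so the output length matches the input.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("TKE needs at least 3 samples")
    psi = np.empty_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    psi[0] = psi[1]
    psi[-1] = psi[-2]
    return psi


def _first_run_start(above: np.ndarray, run_len: int):
    """Index where ``above`` is True for at least ``run_len`` consecutive
    entries, or None."""
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= run_len:
            return i - run_len + 1
    return None


def detect_tke(signal: EmgSignal, params: BaselineParams) -> OnsetResult:
    """TKE energy against a quiescent-baseline threshold.

    The TKE trace is smoothed with a 50 ms moving average; the threshold is
    ``mu_b + tke_j * sigma_b`` over the opening ``baseline_ms``, and the
    onset is the start of the first stretch that stays above it for
    ``consec`` x 50 ms.
    """
    fs = signal.fs
    n_baseline = int(round(params.baseline_ms / 1000.0 * fs))
    if n_baseline > signal.samples.size:
        raise ValueError("baseline window longer than the signal")
    psi = tke_operator(signal.samples)
    n_smooth = max(1, int(round(_TKE_SMOOTH_MS / 1000.0 * fs)))
    kernel = np.ones(n_smooth) / n_smooth
    smooth = np.convolve(psi, kernel, mode="same")
    base = smooth[:n_baseline]
    level = float(base.mean() + params.tke_j * base.std())
    idx = _first_run_start(smooth > level, params.consec * n_smooth)
    return _sample_result("tke", signal, idx, {"psi_smooth": smooth, "level": level})


def _persistence_window_result(
    method: str, feature: np.ndarray, plan: WindowPlan, params: BaselineParams
) -> OnsetResult:
    step_ms = plan.s_samples / plan.fs * 1000.0
    B = int(round(params.baseline_ms / step_ms))
    if B < 2:
        raise ValueError(
            f"baseline of {params.baseline_ms} ms spans fewer than 2 windows (step {step_ms:g} ms)"
        )
    B = min(B, feature.size)
    base = feature[:B]
    level = float(base.mean() + _SIGMA_MULT * base.std())
    k0 = _first_run_start(feature > level, params.consec)
    diagnostics = {"feature": feature, "level": level, "n_baseline_windows": B, "index_kind": "window"}
    if k0 is None:
        return OnsetResult(method=method, diagnostics=diagnostics)
    return OnsetResult(
        method=method,
        k_star=k0 + 1,
        t_star=plan.t0 + k0 * plan.s_seconds,
        diagnostics=diagnostics,
    )


def detect_rms(signal: EmgSignal, params: BaselineParams, plan: WindowPlan) -> OnsetResult:
    """Per-window RMS against mu_b + 3 sigma_b of the opening windows;
    onset at the left edge of the first ``consec`` supra-threshold windows."""
    x = signal.samples
    rms = np.array(
        [
            np.sqrt(np.mean(x[k * plan.s_samples : k * plan.s_samples + plan.L_samples] ** 2))
            for k in range(plan.K)
        ]
    )
    return _persistence_window_result("rms", rms, plan, params)


def detect_wavelet(signal: EmgSignal, params: BaselineParams, plan: WindowPlan) -> OnsetResult:
    """Detail-coefficient energy per window, same decision rule as ``rms``.

    The signal is decomposed with a multi-level DWT (db4, 4 levels by
    default); each detail coefficient's squared magnitude is booked at the
    sample nearest the centre of its dyadic support, approximation
    coefficients (slow drift) are ignored, and per-window energies are the
    window sums of that series.
    """
    x = signal.samples
    if x.size < 2**params.wavelet_levels:
        raise ValueError(
            f"signal of {x.size} samples too short for {params.wavelet_levels} DWT levels"
        )
    coeffs = pywt.wavedec(x, params.wavelet_name, level=params.wavelet_levels)
    energy = np.zeros(x.size)
    for level, detail in enumerate(reversed(coeffs[1:]), start=1):
        scale = 2**level
        centers = np.minimum(
            ((np.arange(detail.size) + 0.5) * scale).astype(int), x.size - 1
        )
        np.add.at(energy, centers, detail**2)
    win_energy = np.array(
        [
            energy[k * plan.s_samples : k * plan.s_samples + plan.L_samples].sum()
            for k in range(plan.K)
        ]
    )
    return _persistence_window_result("wavelet", win_energy, plan, params)
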