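"""Filtering, sliding-window segmentation and per-window normalisation.

The standard conditioning chain for surface EMG: a 20-450 Hz zero-phase
Butterworth band-pass (removes motion artefact and low-frequency drift below
the EMG band, and out-of-band noise above it), segmentation into 128 ms
windows with 50% overlap, and z-scoring of each window so downstream spectral
features are amplitude-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import signal as sps

from .signal import EmgSignal

__all__ = ["WindowPlan", "bandpass", "plan_windows", "zscore_window", "iter_windows"]


@dataclass(frozen=True)
class WindowPlan:
    """Layout of overlapping analysis windows over a signal.

    Window ``k`` (1-based) covers samples ``[(k-1)*s_samples,
    (k-1)*s_samples + L_samples)`` and starts at time
    ``t0 + (k-1) * s_samples / fs``.  Trailing samples that do not fill a
    whole window are dropped.
    """

    L_samples: int
    s_samples: int
    K: int
    t0: float
    fs: float

    def __post_init__(self) -> None:
        if self.L_samples < 2:
            raise ValueError("window length must be at least 2 samples")
        if not (1 <= self.s_samples <= self.L_samples):
            raise ValueError("step must satisfy 1 <= s_samples <= L_samples")
        if self.K < 1:
            raise ValueError("plan must contain at least one window")

    @property
    def s_seconds(self) -> float:
        """Window step in seconds."""
        return self.s_samples / self.fs

    def window_start_time(self, k: int) -> float:
        """Start time (s) of 1-based window ``k``."""
        if not (1 <= k <= self.K):
            raise IndexError(f"window index {k} outside 1..{self.K}")
        return self.t0 + (k - 1) * self.s_seconds


def bandpass(
    signal: EmgSignal,
    low: float = 20.0,
    high: float = 450.0,
    order: int = 5,
) -> EmgSignal:
    """Zero-phase Butterworth band-pass.

    A band-pass prototype of the given order is applied forward and backward
    (``sosfiltfilt``), cancelling phase distortion so event timing is
    preserved; the effective magnitude response is that of a filter of twice
    the order.  Edges are handled by odd reflection padding.
    """
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= signal.fs / 2:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {signal.fs / 2} Hz")
    if order < 1:
        raise ValueError("order must be >= 1")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=signal.fs, output="sos")
    # default padlen of sosfiltfilt is too small to damp the startup transient
    # of a band-pass with a 20 Hz corner at 1500 Hz; use ~3 low-corner periods
    padlen = int(3 * signal.fs / low)
    if signal.samples.size <= padlen:
        raise ValueError("signal too short for stable two-pass filtering")
    filtered = sps.sosfiltfilt(sos, signal.samples, padtype="odd", padlen=padlen)
    return signal.replace_samples(filtered)


def plan_windows(signal: EmgSignal, L_ms: float = 128.0, overlap_frac: float = 0.5) -> WindowPlan:
    """Lay out sliding windows of ``L_ms`` milliseconds with fractional overlap.

    ``L_samples = round(L_ms * fs / 1000)``; the step is
    ``max(1, round(L_samples * (1 - overlap_frac)))`` and the number of
    windows is ``floor((N - L_samples) / s_samples) + 1``.
    """
    if not (0 <= overlap_frac < 1):
        raise ValueError("overlap_frac must be in [0, 1)")
    L = int(round(L_ms * signal.fs / 1000.0))
    if L < 2:
        raise ValueError(f"{L_ms} ms is under 2 samples at fs={signal.fs} Hz")
    N = signal.samples.size
    if N < L:
        raise ValueError(f"signal of {N} samples is shorter than one {L}-sample window")
    s = max(1, int(round(L * (1 - overlap_frac))))
    K = (N - L) // s + 1
    return WindowPlan(L_samples=L, s_samples=s, K=K, t0=signal.t0, fs=signal.fs)


def zscore_window(window: np.ndarray) -> np.ndarray:
    """Normalise a window to zero mean and unit population (1/N) variance.

    A window with (scale-aware) negligible variance — e.g. a constant
    segment — maps to all zeros rather than dividing by ~0.
    """
    w = np.asarray(window, dtype=float)
    if w.size < 2:
        raise ValueError("window must have at least 2 samples")
    mean = w.mean()
    std = w.std()  # population (ddof=0)
    eps = 1e-12 * max(1.0, float(np.max(np.abs(w))) if w.size else 1.0)
    if std < eps:
        return np.zeros_like(w)
    return (w - mean) / std


def iter_windows(signal: EmgSignal, plan: WindowPlan) -> Iterator[np.ndarray]:
    """Yield the raw sample vector of each window, in order (views, not copies)."""
    x = signal.samples
    for k in range(plan.K):
        start = k * plan.s_samples
        yield x[start : start + plan.L_samples]
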