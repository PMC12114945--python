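"""Entropy-trend onset detection and its ablation variants.

The full detector: slide 128 ms windows (50% overlap) over the filtered
signal; per window, z-score, decompose with EMD, build the Hilbert marginal
spectrum and take its normalised Shannon entropy.  The entropy sequence M is
smoothed with a centred moving average into a trend T; the first difference
Delta_k = T_{k+1} - T_k is scanned for its most negative value and the onset
is reported at the left edge of the winning window:

    k* = argmin_k Delta_k,      t* = t0 + (k* - 1) * s

with s the window step in seconds.  At rest the spectrum is broad (high
entropy); as the muscle engages, spectral mass concentrates in the EMG band
and the entropy drops — the steepest drop marks the onset without any
amplitude threshold.

Ablation modes kept for comparison:

``energy-slope``
    The entropy is replaced by per-window mean squared amplitude
    (max-normalised); activation *raises* energy, so the steepest rise of
    the smoothed energy trend is taken instead of the steepest drop.
``mse-only``
    No slope analysis: the onset is the global minimum of the trend itself.
``mse-nowindow``
    No sliding window: one EMD of the whole signal, then the entropy of the
    *cumulative* marginal spectrum evaluated on a coarse time grid; the
    steepest drop of that sequence is the onset.  One defensible reading of
    "remove the window mechanism", documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import baselines as _baselines
from .config import Config
from .emd import emd
from .entropy import compute_mse
from .hht import analytic_attrs, marginal_spectrum
from .preprocess import WindowPlan, bandpass, iter_windows, plan_windows, zscore_window
from .signal import EmgSignal, OnsetResult

__all__ = [
    "EntropyTrend",
    "entropy_sequence",
    "energy_sequence",
    "smooth_trend",
    "detect_onset",
    "onset_from_trend",
    "detect",
    "WINDOWED_MODES",
    "ALL_METHODS",
]

WINDOWED_MODES = ("mse", "energy-slope", "mse-only", "mse-nowindow")
ALL_METHODS = WINDOWED_MODES + ("threshold", "tke", "rms", "wavelet")


@dataclass
class EntropyTrend:
    """Per-window feature sequence M with its smoothed trend T."""

    M: np.ndarray
    T: Optional[np.ndarray]
    plan: WindowPlan
    smooth_len: int = 1
    n_failed_windows: int = 0


def entropy_sequence(signal: EmgSignal, plan: WindowPlan, config: Optional[Config] = None) -> EntropyTrend:
    """Normalised marginal-spectrum entropy of every window (trend unfilled).

    Each window is (optionally) z-scored, decomposed independently with EMD,
    and scored by :func:`~emgonset.entropy.compute_mse`.  A window whose
    spectrum comes out empty (e.g. a dead stretch that z-scores to zeros)
    inherits the previous window's value; if it is the first window it falls
    back to 1.0, the maximal-uncertainty value.  More than half the windows
    failing signals unusable input and raises.
    """
    cfg = config or Config()
    M = np.empty(plan.K)
    failed = 0
    for k, w in enumerate(iter_windows(signal, plan)):
        if cfg.window_zscore:
            w = zscore_window(w)
        try:
            imfset = emd(
                w,
                max_imfs=cfg.emd_max_imfs,
                sd_tol=cfg.emd_sd_tol,
                max_iters=cfg.emd_max_sift_iters,
            )
            attrs = [
                analytic_attrs(c, signal.fs, edge_exclude=cfg.hht_edge_exclude)
                for c in imfset.imfs
            ]
            spec = marginal_spectrum(
                attrs,
                signal.fs,
                n_bins=cfg.hht_n_bins,
                f_max=cfg.hht_f_max_hz,
                power=cfg.hht_power_spectrum,
            )
            M[k] = compute_mse(spec).value
        except ValueError:
            failed += 1
            M[k] = M[k - 1] if k > 0 else 1.0
    if failed > plan.K / 2:
        raise RuntimeError(
            f"{failed}/{plan.K} windows produced no usable spectrum; input looks unusable"
        )
    return EntropyTrend(M=M, T=None, plan=plan, n_failed_windows=failed)


def energy_sequence(signal: EmgSignal, plan: WindowPlan) -> EntropyTrend:
    """Per-window mean squared amplitude, normalised by its maximum.

    The z-scoring step is deliberately skipped — it would erase exactly the
    amplitude information this ablation relies on.  Max-normalisation keeps
    the sequence in [0, 1] and the detector scale-invariant.
    """
    E = np.array([float(np.mean(w * w)) for w in iter_windows(signal, plan)])
    peak = E.max()
    if peak > 0:
        E = E / peak
    return EntropyTrend(M=E, T=None, plan=plan)


def smooth_trend(M: np.ndarray, smooth_len: int = 5) -> np.ndarray:
    """Centred moving average, truncated (not padded) at the edges.

    ``smooth_len`` must be odd so the average is centred; 1 is the identity.
    """
    M = np.asarray(M, dtype=float)
    if smooth_len < 1 or smooth_len > M.size:
        raise ValueError("smooth_len must satisfy 1 <= smooth_len <= len(M)")
    if smooth_len % 2 == 0:
        raise ValueError("smooth_len must be odd (centred average)")
    if smooth_len == 1:
        return M.copy()
    half = smooth_len // 2
    csum = np.concatenate([[0.0], np.cumsum(M)])
    k = np.arange(M.size)
    lo = np.maximum(k - half, 0)
    hi = np.minimum(k + half + 1, M.size)
    return (csum[hi] - csum[lo]) / (hi - lo)


def detect_onset(T: np.ndarray, plan: WindowPlan) -> OnsetResult:
    """Steepest-drop rule on a trend sequence.

    Computes Delta_k = T_{k+1} - T_k, picks the earliest k attaining the
    minimum, and maps it to t* = t0 + (k* - 1) * s.  Always detects.
    """
    T = np.asarray(T, dtype=float)
    if T.size < 2:
        raise ValueError("need at least 2 trend values to form a slope")
    delta = np.diff(T)
    k0 = int(np.argmin(delta))  # argmin returns the earliest tie
    k_star = k0 + 1  # 1-based window index
    t_star = plan.t0 + (k_star - 1) * plan.s_seconds
    return OnsetResult(
        method="mse",
        k_star=k_star,
        t_star=t_star,
        diagnostics={"delta": delta, "min_delta": float(delta[k0]), "index_kind": "window"},
    )


def _fill_trend(trend: EntropyTrend, cfg: Config) -> EntropyTrend:
    if trend.T is None:
        smooth_len = min(cfg.detector_smooth_len, trend.M.size)
        if smooth_len % 2 == 0:
            smooth_len -= 1
        trend.T = smooth_trend(trend.M, smooth_len)
        trend.smooth_len = smooth_len
    return trend


def onset_from_trend(trend: EntropyTrend, mode: str, cfg: Config) -> OnsetResult:
    """Apply one decision rule to a precomputed feature trend."""
    trend = _fill_trend(trend, cfg)
    T, plan = trend.T, trend.plan
    reject = cfg.detector_reject_delta > 0
    diagnostics: dict = {
        "M": trend.M,
        "T": T,
        "smooth_len": trend.smooth_len,
        "index_kind": "window",
    }
    k_star: Optional[int]
    if mode in ("mse", "mse-nowindow"):
        res = detect_onset(T, plan)
        diagnostics.update(res.diagnostics)
        k_star, t_star = res.k_star, res.t_star
        if reject and diagnostics["min_delta"] > -cfg.detector_reject_delta:
            k_star = t_star = None
    elif mode == "energy-slope":
        delta = np.diff(T)
        k0 = int(np.argmax(delta))
        diagnostics.update(delta=delta, max_delta=float(delta[k0]))
        k_star = k0 + 1
        t_star = plan.t0 + (k_star - 1) * plan.s_seconds
        if reject and diagnostics["max_delta"] < cfg.detector_reject_delta:
            k_star = t_star = None
    elif mode == "mse-only":
        k0 = int(np.argmin(T))
        depth = float(np.median(T) - T[k0])
        diagnostics.update(depth=depth)
        k_star = k0 + 1
        t_star = plan.t0 + (k_star - 1) * plan.s_seconds
        if reject and depth <= cfg.detector_reject_depth:
            k_star = t_star = None
    else:
        raise ValueError(f"unknown trend mode {mode!r}")
    return OnsetResult(
        method=mode,
        k_star=k_star,
        t_star=t_star,
        params=_params_record(cfg, mode),
        diagnostics=diagnostics,
    )


def _cumulative_entropy_trend(signal: EmgSignal, cfg: Config) -> EntropyTrend:
    """Global-EMD variant: entropy of the cumulative marginal spectrum on a
    coarse grid with the same step as the windowed plan."""
    plan = plan_windows(signal, cfg.window_length_ms, cfg.window_overlap)
    imfset = emd(
        signal.samples,
        max_imfs=cfg.emd_max_imfs,
        sd_tol=cfg.emd_sd_tol,
        max_iters=cfg.emd_max_sift_iters,
    )
    n_bins = cfg.hht_n_bins
    width = cfg.hht_f_max_hz / n_bins
    dt = 1.0 / signal.fs
    n = signal.samples.size
    # per-sample (bin, weight) contributions pooled over IMFs
    contrib = np.zeros((n, n_bins))
    for c in imfset.imfs:
        at = analytic_attrs(c, signal.fs, edge_exclude=cfg.hht_edge_exclude)
        m = at.valid_mask
        idx = np.minimum((at.frequency[m] / width).astype(int), n_bins - 1)
        a = at.amplitude[m]
        if cfg.hht_power_spectrum:
            a = a * a
        np.add.at(contrib, (np.nonzero(m)[0], idx), a * dt)
    grid = np.arange(plan.s_samples, n + 1, plan.s_samples)
    cum = np.cumsum(contrib, axis=0)
    M = np.empty(grid.size)
    last = 1.0
    for g_i, g in enumerate(grid):
        h = cum[g - 1]
        if h.sum() > 0:
            last = compute_mse(h).value
        M[g_i] = last
    grid_plan = WindowPlan(
        L_samples=plan.s_samples,
        s_samples=plan.s_samples,
        K=grid.size,
        t0=signal.t0,
        fs=signal.fs,
    )
    return EntropyTrend(M=M, T=M.copy(), plan=grid_plan, smooth_len=1)


def _params_record(cfg: Config, mode: str) -> dict:
    return {
        "mode": mode,
        "window_length_ms": cfg.window_length_ms,
        "window_overlap": cfg.window_overlap,
        "smooth_len": cfg.detector_smooth_len,
        "emd_max_imfs": cfg.emd_max_imfs,
        "n_bins": cfg.hht_n_bins,
        "reject_delta": cfg.detector_reject_delta,
    }


def detect(signal: EmgSignal, mode: str = "mse", config: Optional[Config] = None) -> OnsetResult:
    """Run one named detector end to end on a signal.

    ``mode`` is one of ``mse``, ``energy-slope``, ``mse-only``,
    ``mse-nowindow`` (entropy-trend family, this module) or ``threshold``,
    ``tke``, ``rms``, ``wavelet`` (baseline family,
    :mod:`emgonset.baselines`).  Band-pass preprocessing is applied first
    unless ``filter.enabled`` is off (e.g. when the caller already filtered).
    """
    cfg = config or Config()
    if mode not in ALL_METHODS:
        raise ValueError(f"unknown method {mode!r}; choose from {ALL_METHODS}")
    if cfg.filter_enabled:
        signal = bandpass(signal, cfg.filter_low_hz, cfg.filter_high_hz, cfg.filter_order)
    if mode in ("mse", "mse-only"):
        plan = plan_windows(signal, cfg.window_length_ms, cfg.window_overlap)
        trend = entropy_sequence(signal, plan, cfg)
        return onset_from_trend(trend, mode, cfg)
    if mode == "energy-slope":
        plan = plan_windows(signal, cfg.window_length_ms, cfg.window_overlap)
        return onset_from_trend(energy_sequence(signal, plan), mode, cfg)
    if mode == "mse-nowindow":
        trend = _cumulative_entropy_trend(signal, cfg)
        return onset_from_trend(trend, "mse-nowindow", cfg)
    params = _baselines.BaselineParams.from_config(cfg)
    if mode == "threshold":
        return _baselines.detect_threshold(signal, params)
    if mode == "tke":
        return _baselines.detect_tke(signal, params)
    plan = plan_windows(signal, cfg.window_length_ms, cfg.window_overlap)
    if mode == "rms":
        return _baselines.detect_rms(signal, params, plan)
    return _baselines.detect_wavelet(signal, params, plan)
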