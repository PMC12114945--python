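"""Model-style front end: detector objects built from a signal whose
``fit()`` returns a results object.

    >>> from emgonset import MseOnset, synth
    >>> sig, t_on = synth.generate(synth.SynthSpec(seed=7))
    >>> res = MseOnset(sig).fit()
    >>> res.t_star, t_on        # doctest: +SKIP
    >>> print(res.summary())    # doctest: +SKIP

Each model class wraps one named method of :func:`emgonset.detect.detect`
with the shared :class:`~emgonset.config.Config`; keyword overrides map to
config fields (``smooth_len=7`` -> ``detector_smooth_len``).  The results
object carries the detection, the per-window diagnostics, a ``summary()``
table and a diagnostic ``plot()``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .config import Config
from .detect import ALL_METHODS, detect
from .signal import EmgSignal, OnsetResult

__all__ = [
    "OnsetModel",
    "OnsetResults",
    "MseOnset",
    "EnergySlopeOnset",
    "MseMinimumOnset",
    "GlobalMseOnset",
    "ThresholdOnset",
    "TkeOnset",
    "RmsOnset",
    "WaveletOnset",
]

# ergonomic keyword -> config field aliases accepted by model constructors
_ALIASES = {
    "smooth_len": "detector_smooth_len",
    "reject_delta": "detector_reject_delta",
    "reject_depth": "detector_reject_depth",
    "window_ms": "window_length_ms",
    "overlap": "window_overlap",
    "max_imfs": "emd_max_imfs",
    "n_bins": "hht_n_bins",
}


class OnsetModel:
    """Base class: an onset detector bound to one signal and one config."""

    method: str = ""

    def __init__(self, signal: EmgSignal, config: Optional[Config] = None, **overrides):
        if self.method not in ALL_METHODS:
            raise TypeError("instantiate a concrete detector subclass")
        cfg = config or Config()
        mapped = {_ALIASES.get(k, k): v for k, v in overrides.items()}
        self.config = cfg.replace(**mapped)
        self.signal = signal

    def fit(self) -> "OnsetResults":
        """Run the detector; returns the results object."""
        record = detect(self.signal, self.method, self.config)
        return OnsetResults(self, record)


class MseOnset(OnsetModel):
    """Full marginal-spectrum-entropy detector (trend + steepest drop)."""

    method = "mse"


class EnergySlopeOnset(OnsetModel):
    """Ablation: windowed signal energy with slope analysis, no entropy."""

    method = "energy-slope"


class MseMinimumOnset(OnsetModel):
    """Ablation: global minimum of the entropy trend, no slope analysis."""

    method = "mse-only"


class GlobalMseOnset(OnsetModel):
    """Ablation: no sliding window; cumulative-spectrum entropy of one
    whole-signal decomposition."""

    method = "mse-nowindow"


class ThresholdOnset(OnsetModel):
    """Baseline: linear envelope crossing 30% of its maximum."""

    method = "threshold"


class TkeOnset(OnsetModel):
    """Baseline: smoothed Teager-Kaiser energy over a baseline threshold."""

    method = "tke"


class RmsOnset(OnsetModel):
    """Baseline: windowed RMS over mu_b + 3 sigma_b with persistence."""

    method = "rms"


class WaveletOnset(OnsetModel):
    """Baseline: windowed DWT detail energy with the RMS decision rule."""

    method = "wavelet"


class OnsetResults:
    """Detection outcome with diagnostics, ``summary()`` and ``plot()``."""

    def __init__(self, model: OnsetModel, record: OnsetResult):
        self.model = model
        self.record = record

    @property
    def method(self) -> str:
        return self.record.method

    @property
    def detected(self) -> bool:
        return self.record.detected

    @property
    def k_star(self) -> Optional[int]:
        return self.record.k_star

    @property
    def t_star(self) -> Optional[float]:
        return self.record.t_star

    @property
    def diagnostics(self) -> dict:
        return self.record.diagnostics

    def summary(self) -> str:
        """Plain-text summary of the detection and the parameters behind it."""
        sig = self.model.signal
        cfg = self.model.config
        lines = [
            "Onset detection results",
            "=" * 47,
            f"{'method':<24}{self.method:>23}",
            f"{'n samples':<24}{len(sig):>23d}",
            f"{'sampling rate (Hz)':<24}{sig.fs:>23g}",
            f"{'duration (s)':<24}{sig.duration:>23.4f}",
            f"{'onset detected':<24}{str(self.detected):>23}",
        ]
        if self.detected:
            kind = self.record.diagnostics.get("index_kind", "window")
            lines += [
                f"{'k* (1-based %s)' % kind:<24}{self.k_star:>23d}",
                f"{'t* (s)':<24}{self.t_star:>23.4f}",
            ]
        lines.append("-" * 47)
        for key in (
            "filter.low_hz",
            "filter.high_hz",
            "window.length_ms",
            "window.overlap",
            "detector.smooth_len",
            "detector.reject_delta",
        ):
            lines.append(f"{key:<24}{cfg.to_dict()[key]!s:>23}")
        extra = self.record.diagnostics
        if "min_delta" in extra:
            lines.append(f"{'min trend slope':<24}{extra['min_delta']:>23.5f}")
        if "level" in extra:
            lines.append(f"{'threshold level':<24}{extra['level']:>23.5g}")
        lines.append("=" * 47)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Signal with the detection mark and, when available, the trend.

        Returns the matplotlib figure (lazy import; purely diagnostic).
        """
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        sig = self.model.signal
        if ax is None:
            fig, ax = plt.subplots(figsize=(9, 4))
        else:
            fig = ax.figure
        ax.plot(sig.times, sig.samples, lw=0.4, color="0.55", label="sEMG")
        ax.set_xlabel("time (s)")
        ax.set_ylabel(f"amplitude ({sig.units})")
        diag = self.record.diagnostics
        if "T" in diag and diag["T"] is not None:
            plan = getattr(diag.get("plan"), "K", None)
            tw = sig.t0 + np.arange(len(diag["T"])) * (
                self.model.config.window_length_ms
                * (1 - self.model.config.window_overlap)
                / 1000.0
            )
            ax2 = ax.twinx()
            ax2.plot(tw, diag["T"], color="tab:blue", label="trend")
            ax2.set_ylabel("trend value")
        if self.detected:
            ax.axvline(self.t_star, color="tab:red", ls="--", label=f"t* = {self.t_star:.3f} s")
        ax.legend(loc="upper left", fontsize=8)
        ax.set_title(f"{self.method} onset detection")
        fig.tight_layout()
        return fig
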