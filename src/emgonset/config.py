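"""Flat key/value configuration shared by the library, CLI and benchmark.

Every tunable parameter of the pipeline lives here under a dotted key
(``filter.low_hz``, ``emd.sd_tol``, ...).  Config files are plain text, one
``key = value`` pair per line, ``#`` comments allowed; CLI flags override
file values which override the defaults below.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Union

__all__ = ["Config"]

# dotted config-file key -> dataclass field
_KEY_MAP = {
    "filter.enabled": "filter_enabled",
    "filter.low_hz": "filter_low_hz",
    "filter.high_hz": "filter_high_hz",
    "filter.order": "filter_order",
    "window.length_ms": "window_length_ms",
    "window.overlap": "window_overlap",
    "window.zscore": "window_zscore",
    "emd.max_imfs": "emd_max_imfs",
    "emd.sd_tol": "emd_sd_tol",
    "emd.max_sift_iters": "emd_max_sift_iters",
    "hht.n_bins": "hht_n_bins",
    "hht.f_max_hz": "hht_f_max_hz",
    "hht.edge_exclude": "hht_edge_exclude",
    "hht.power_spectrum": "hht_power_spectrum",
    "detector.mode": "detector_mode",
    "detector.smooth_len": "detector_smooth_len",
    "detector.reject_delta": "detector_reject_delta",
    "detector.reject_depth": "detector_reject_depth",
    "baseline.threshold_frac": "baseline_threshold_frac",
    "baseline.tke_j": "baseline_tke_j",
    "baseline.baseline_ms": "baseline_baseline_ms",
    "baseline.consec": "baseline_consec",
    "baseline.wavelet": "baseline_wavelet",
    "baseline.levels": "baseline_levels",
    "eval.tolerance_s": "eval_tolerance_s",
    "eval.reference_method": "eval_reference_method",
}
_FIELD_TO_KEY = {v: k for k, v in _KEY_MAP.items()}


@dataclass(frozen=True)
class Config:
    """All pipeline parameters with their defaults.

    Filtering: 5th-order Butterworth band-pass 20-450 Hz applied forward and
    backward (zero phase).  Windowing: 128 ms sliding windows, 50% overlap,
    per-window z-scoring.  Decomposition: at most 6 intrinsic mode functions,
    Cauchy sifting tolerance 0.2.  Spectrum: 45 equal-width bins over
    0-450 Hz (10 Hz resolution), amplitude-weighted.  Detector: 5-window
    moving-average trend, steepest-drop rule; rejection off by default
    (``detector.reject_delta = 0`` means always declare an onset).
    """

    filter_enabled: bool = True
    filter_low_hz: float = 20.0
    filter_high_hz: float = 450.0
    filter_order: int = 5
    window_length_ms: float = 128.0
    window_overlap: float = 0.5
    window_zscore: bool = True
    emd_max_imfs: int = 6
    emd_sd_tol: float = 0.2
    emd_max_sift_iters: int = 100
    hht_n_bins: int = 45
    hht_f_max_hz: float = 450.0
    hht_edge_exclude: float = 0.05
    hht_power_spectrum: bool = False
    detector_mode: str = "mse"
    detector_smooth_len: int = 5
    detector_reject_delta: float = 0.0
    detector_reject_depth: float = 0.1
    baseline_threshold_frac: float = 0.30
    baseline_tke_j: float = 8.0
    baseline_baseline_ms: float = 300.0
    baseline_consec: int = 2
    baseline_wavelet: str = "db4"
    baseline_levels: int = 4
    eval_tolerance_s: float = 0.2
    eval_reference_method: str = "threshold"

    def replace(self, **overrides) -> "Config":
        return replace(self, **overrides)

    def to_dict(self) -> dict:
        """Dotted-key view of every parameter."""
        return {_FIELD_TO_KEY[f.name]: getattr(self, f.name) for f in fields(self)}

    def to_file(self, path: Union[str, Path]) -> None:
        lines = [f"{k} = {_format(v)}" for k, v in sorted(self.to_dict().items())]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "Config":
        """Parse a flat ``key = value`` config file; unknown keys are errors."""
        overrides: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" in line:
                key, value = line.split("=", 1)
            elif ":" in line:
                key, value = line.split(":", 1)
            else:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key = key.strip()
            if key not in _KEY_MAP:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            field_name = _KEY_MAP[key]
            overrides[field_name] = _parse(value.strip(), type(getattr(cls(), field_name)))
        return cls(**overrides)


def _format(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def _parse(text: str, target_type: type):
    if target_type is bool:
        lowered = text.lower()
        if lowered in ("true", "1", "yes", "on"):
            return True
        if lowered in ("false", "0", "no", "off"):
            return False
        raise ValueError(f"cannot parse boolean from {text!r}")
    if target_type is int:
        return int(text)
    if target_type is float:
        return float(text)
    return text.strip().strip('"').strip("'")
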