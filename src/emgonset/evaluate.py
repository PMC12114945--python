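"""Detection metrics and the multi-method benchmark runner.

Scoring convention (declared explicitly, since the literature rarely is): on a
signal with a true onset, a detection within ``tolerance_s`` of the truth is
a true positive and anything else (no detection, or a detection outside the
tolerance) a false negative; on a no-activation signal any detection is a
false positive, silence a true negative.  Onset-time RMSE is computed over
true positives only.  Detection advance for method X is the mean of
``t_ref - t_X`` over signals where both X and the reference method (the
fixed-threshold detector by default) declare an onset, so the reference's
own advance is 0 by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .config import Config
from .detect import (
    ALL_METHODS,
    entropy_sequence,
    onset_from_trend,
    detect as _run_method,
)
from .preprocess import bandpass, plan_windows
from .signal import EmgSignal, OnsetResult

__all__ = ["EvalReport", "score_detection", "summarize", "run_benchmark", "reports_to_frame"]


@dataclass
class EvalReport:
    """Per-method detection metrics on a labelled signal set."""

    method: str
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    fnr: Optional[float] = None
    fpr: Optional[float] = None
    rmse_s: Optional[float] = None
    advance_s: Optional[float] = None
    tolerance_s: float = 0.2
    reference_method: str = "threshold"
    n_signals: int = 0
    extras: dict = field(default_factory=dict)


def score_detection(
    t_hat: Optional[float], t_true: Optional[float], tolerance_s: float
) -> str:
    """Label one (detection, truth) pair as ``"TP"``/``"FP"``/``"TN"``/``"FN"``."""
    if tolerance_s <= 0:
        raise ValueError("tolerance_s must be positive")
    if t_true is None:
        return "FP" if t_hat is not None else "TN"
    if t_hat is not None and abs(t_hat - t_true) <= tolerance_s:
        return "TP"
    return "FN"


def summarize(
    method: str,
    t_hats: Sequence[Optional[float]],
    t_trues: Sequence[Optional[float]],
    reference_t_hats: Optional[Sequence[Optional[float]]] = None,
    tolerance_s: float = 0.2,
    reference_method: str = "threshold",
) -> EvalReport:
    """Aggregate one method's detections over a labelled set into a report.

    Rates whose denominator is zero (e.g. specificity without negative
    cases) are reported as None, not 0.
    """
    if len(t_hats) != len(t_trues):
        raise ValueError("t_hats and t_trues must be parallel")
    report = EvalReport(
        method=method,
        tolerance_s=tolerance_s,
        reference_method=reference_method,
        n_signals=len(t_hats),
    )
    sq_errors = []
    for t_hat, t_true in zip(t_hats, t_trues):
        label = score_detection(t_hat, t_true, tolerance_s)
        setattr(report, label.lower(), getattr(report, label.lower()) + 1)
        if label == "TP":
            sq_errors.append((t_hat - t_true) ** 2)
    if report.tp + report.fn > 0:
        report.sensitivity = report.tp / (report.tp + report.fn)
        report.fnr = 1.0 - report.sensitivity
    if report.tn + report.fp > 0:
        report.specificity = report.tn / (report.tn + report.fp)
        report.fpr = 1.0 - report.specificity
    if sq_errors:
        report.rmse_s = math.sqrt(float(np.mean(sq_errors)))
    if reference_t_hats is not None:
        diffs = [
            t_ref - t_hat
            for t_hat, t_ref in zip(t_hats, reference_t_hats)
            if t_hat is not None and t_ref is not None
        ]
        if diffs:
            report.advance_s = float(np.mean(diffs))
    return report


def _detect_all(
    signal: EmgSignal, methods: Sequence[str], cfg: Config
) -> dict[str, OnsetResult]:
    """Run several methods on one signal with shared preprocessing.

    The entropy trend is computed once and reused by ``mse`` and
    ``mse-only`` (same feature, different decision rule); results are
    identical to independent :func:`emgonset.detect.detect` calls.
    """
    if cfg.filter_enabled:
        signal = bandpass(signal, cfg.filter_low_hz, cfg.filter_high_hz, cfg.filter_order)
    inner = cfg.replace(filter_enabled=False)
    out: dict[str, OnsetResult] = {}
    trend = None
    for method in methods:
        if method in ("mse", "mse-only"):
            if trend is None:
                plan = plan_windows(signal, cfg.window_length_ms, cfg.window_overlap)
                trend = entropy_sequence(signal, plan, inner)
            out[method] = onset_from_trend(_copy_trend(trend), method, inner)
        else:
            out[method] = _run_method(signal, method, inner)
    return out


def _copy_trend(trend):
    """Shallow per-call copy so decision rules never mutate the shared trend."""
    from .detect import EntropyTrend

    return EntropyTrend(
        M=trend.M,
        T=trend.T,
        plan=trend.plan,
        smooth_len=trend.smooth_len,
        n_failed_windows=trend.n_failed_windows,
    )


def run_benchmark(
    dataset: Sequence[tuple[EmgSignal, Optional[float]]],
    methods: Sequence[str] = ALL_METHODS,
    config: Optional[Config] = None,
    out_dir: Union[str, Path, None] = None,
) -> tuple[dict[str, EvalReport], pd.DataFrame]:
    """Run every method on every labelled signal and tabulate the metrics.

    Rejection rules are switched on for rate computation (a no-activation
    case can only be scored if detectors may stay silent), so
    ``detector.reject_delta`` is forced to 0.02 when the caller left it at 0.

    Returns the per-method reports plus a per-signal onset table; with
    ``out_dir`` both are also written as tab-separated text.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    cfg = config or Config()
    if cfg.detector_reject_delta == 0:
        cfg = cfg.replace(detector_reject_delta=0.02)
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    rows = []
    failures = {m: 0 for m in methods}
    for i, (signal, t_true) in enumerate(dataset):
        row: dict = {"signal": f"S{i + 1:02d}", "t_true": t_true}
        try:
            results = _detect_all(signal, methods, cfg)
        except Exception:
            for m in methods:
                failures[m] += 1
                row[m] = None
        else:
            for m in methods:
                row[m] = results[m].t_star
        rows.append(row)
    worst = max(failures.values())
    if worst > len(dataset) / 2:
        bad = [m for m, c in failures.items() if c == worst]
        raise RuntimeError(f"methods {bad} failed on {worst}/{len(dataset)} signals")
    onsets = pd.DataFrame(rows)
    t_trues = [r["t_true"] for r in rows]
    ref = cfg.eval_reference_method
    ref_hats = [r.get(ref) for r in rows] if ref in methods else None
    reports = {
        m: summarize(
            m,
            [r[m] for r in rows],
            t_trues,
            reference_t_hats=ref_hats,
            tolerance_s=cfg.eval_tolerance_s,
            reference_method=ref,
        )
        for m in methods
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        reports_to_frame(reports).to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
        onsets.to_csv(out_dir / "onsets.tsv", sep="\t", index=False)
    return reports, onsets


def reports_to_frame(reports: dict[str, EvalReport]) -> pd.DataFrame:
    """Metric table with one row per method (benchmark-summary layout)."""
    return pd.DataFrame(
        [
            {
                "method": r.method,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "fnr": r.fnr,
                "fpr": r.fpr,
                "rmse_s": r.rmse_s,
                "advance_s": r.advance_s,
                "tp": r.tp,
                "fp": r.fp,
                "tn": r.tn,
                "fn": r.fn,
            }
            for r in reports.values()
        ]
    )
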