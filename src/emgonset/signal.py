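"""Core signal and result containers plus delimited-text I/O.

The package works on single-channel surface EMG held in :class:`EmgSignal`:
a uniformly sampled amplitude series with a sampling rate ``fs`` and the time
``t0`` of its first sample.  Detection output is an :class:`OnsetResult`
record.  Signals and results travel as plain comma/tab-delimited text so they
interoperate with spreadsheets and any acquisition export.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "EmgSignal",
    "OnsetResult",
    "read_signal",
    "write_result",
    "write_results",
    "read_results",
]

_NUMERIC_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


@dataclass(frozen=True, eq=False)
class EmgSignal:
    """Uniformly sampled single-channel EMG amplitude series.

    Parameters
    ----------
    samples : array-like of float
        Amplitude values (arbitrary units, typically mV).  At least two
        samples, all finite.
    fs : float
        Sampling rate in Hz, strictly positive.
    t0 : float, default 0.0
        Time of the first sample in seconds.
    units : str, default "mV"
        Opaque amplitude-unit label; all algorithms are unit-agnostic.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    units: str = "mV"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if samples.size < 2:
            raise ValueError("an EMG signal needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("all samples must be finite")
        if not (self.fs > 0 and np.isfinite(self.fs)):
            raise ValueError("sampling rate fs must be positive and finite")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "fs", float(self.fs))
        object.__setattr__(self, "t0", float(self.t0))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Span from first to last sample in seconds: ``(n - 1) / fs``."""
        return (self.samples.size - 1) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Per-sample time axis in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def replace_samples(self, samples: np.ndarray) -> "EmgSignal":
        """Return a copy of this signal with new sample values."""
        return EmgSignal(samples=samples, fs=self.fs, t0=self.t0, units=self.units)


@dataclass
class OnsetResult:
    """A single detector's decision on one signal.

    ``k_star`` is the 1-based index of the detected analysis unit (sliding
    window for windowed detectors, sample for the sample-based baselines —
    see ``diagnostics['index_kind']``).  ``k_star`` and ``t_star`` are either
    both present or both absent (no onset declared).
    """

    method: str
    k_star: Optional[int] = None
    t_star: Optional[float] = None
    params: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if (self.k_star is None) != (self.t_star is None):
            raise ValueError("k_star and t_star must be both present or both absent")
        if self.k_star is not None:
            self.k_star = int(self.k_star)
            self.t_star = float(self.t_star)

    @property
    def detected(self) -> bool:
        return self.t_star is not None


def _looks_numeric(token: str) -> bool:
    token = token.strip().strip('"')
    return bool(token) and bool(_NUMERIC_RE.match(token))


def _sniff(path: Path) -> tuple[str, bool]:
    """Return (delimiter, has_header) for a delimited numeric text file."""
    with open(path, "r") as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line.strip()
                break
    if not first:
        raise ValueError(f"{path}: file is empty")
    delim = "\t" if "\t" in first else ("," if "," in first else None)
    tokens = first.split(delim) if delim else first.split()
    has_header = not all(_looks_numeric(t) for t in tokens)
    return (delim if delim is not None else r"\s+"), has_header


def read_signal(
    path: Union[str, Path],
    fs: Optional[float] = None,
    column: Union[int, str, None] = None,
    time_column: Union[int, str, None] = "auto",
) -> EmgSignal:
    """Read an EMG time series from delimited text.

    The dialect (comma, tab or whitespace; optional single header row) is
    auto-detected: a non-numeric first row is treated as a header.

    Parameters
    ----------
    path : str or Path
    fs : float, optional
        Sampling rate in Hz.  Required when the file carries no time column;
        otherwise cross-checked against the median time step (a >1%
        discrepancy warns, the time-derived rate given here wins).
    column : int or str, optional
        Amplitude column, by 0-based position or header name.  Default: the
        only column of a single-column file, else the second column.
    time_column : int, str, or None
        Time column (seconds).  ``"auto"`` (default) uses the first column of
        a multi-column file; ``None`` disables time parsing.

    Returns
    -------
    EmgSignal
        ``t0`` is the first time value when a time column is used, else 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    delim, has_header = _sniff(path)
    df = pd.read_csv(path, sep=delim, header=0 if has_header else None, engine="python")
    if len(df) < 2:
        raise ValueError(f"{path}: need at least 2 data rows, found {len(df)}")

    def _col(sel: Union[int, str]) -> pd.Series:
        if isinstance(sel, int):
            return df.iloc[:, sel]
        if sel not in df.columns:
            raise ValueError(f"{path}: no column named {sel!r}")
        return df[sel]

    if time_column == "auto":
        time_column = 0 if (df.shape[1] >= 2 and column in (None, 1)) else None
    if column is None:
        column = 1 if time_column is not None else 0

    amp = pd.to_numeric(_col(column), errors="coerce")
    if amp.isna().any():
        raise ValueError(f"{path}: non-numeric amplitude values")
    t0 = 0.0
    if time_column is not None:
        times = pd.to_numeric(_col(time_column), errors="coerce")
        if times.isna().any():
            raise ValueError(f"{path}: non-numeric time values")
        dt = np.diff(times.to_numpy())
        med = float(np.median(dt))
        if med <= 0:
            raise ValueError(f"{path}: time column is not strictly increasing")
        if np.max(np.abs(dt - med)) > 0.05 * med:
            raise ValueError(f"{path}: time step jitter exceeds 5% of the median step")
        fs_inferred = 1.0 / med
        if fs is not None and abs(fs - fs_inferred) / fs > 0.01:
            warnings.warn(
                f"stated fs={fs:g} Hz disagrees with time-column rate "
                f"{fs_inferred:g} Hz by more than 1%; using stated fs",
                stacklevel=2,
            )
        if fs is None:
            fs = fs_inferred
        t0 = float(times.iloc[0])
    if fs is None:
        raise ValueError("fs must be given when the file has no time column")
    return EmgSignal(samples=amp.to_numpy(dtype=float), fs=float(fs), t0=t0)


_RESULT_COLUMNS = ["method", "k_star", "t_star", "params"]


def write_results(results: Sequence[OnsetResult], path: Union[str, Path]) -> None:
    """Write onset results as a flat delimited table (one row per result).

    Absent onsets are stored as empty fields; ``params`` is serialised as a
    JSON object.  ``diagnostics`` (bulky per-method intermediate series) are
    intentionally not persisted.
    """
    rows = [
        {
            "method": r.method,
            "k_star": "" if r.k_star is None else r.k_star,
            "t_star": "" if r.t_star is None else repr(r.t_star),
            "params": json.dumps(r.params, sort_keys=True),
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=_RESULT_COLUMNS).to_csv(path, index=False)


def write_result(result: OnsetResult, path: Union[str, Path]) -> None:
    """Write a single onset result (see :func:`write_results`)."""
    write_results([result], path)


def read_results(path: Union[str, Path]) -> list[OnsetResult]:
    """Read back results written by :func:`write_results` (lossless)."""
    df = pd.read_csv(path, dtype={"method": str, "params": str}, float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        k = row["k_star"]
        t = row["t_star"]
        absent = pd.isna(k) or str(k).strip() == ""
        out.append(
            OnsetResult(
                method=str(row["method"]),
                k_star=None if absent else int(float(k)),
                t_star=None if absent else float(t),
                params=json.loads(row["params"]) if isinstance(row["params"], str) else {},
            )
        )
    return out
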