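"""Seeded surrogate sEMG with a known slow-activation onset.

Each generated record emulates what the detector targets in practice: a
quiescent baseline followed by a gradually rising muscle contribution,

    x(t) = b(t) + e(t) * a(t)

* ``b`` — stationary measurement baseline: Gaussian noise band-limited to
  ``band`` (default 20-450 Hz, matching the preprocessing pass band) with
  unit standard deviation.
* ``a`` — the EMG-like activation process: Gaussian noise shaped by the
  Stulen-De Luca surface-EMG power spectrum
  S(f) proportional to f_h^4 f^2 / ((f^2 + f_l^2)(f^2 + f_h^2)^2), default
  corner frequencies f_l = 60 Hz, f_h = 120 Hz, restricted to ``band`` and
  scaled so that 20 log10(sigma_a / sigma_b) equals ``snr_db``.  The
  concentrated activation spectrum against the flat baseline reproduces the
  spectral redistribution a muscle switching on causes in real recordings.
* ``e`` — the activation envelope: 0 before the true onset ``t_on``, the
  smoothstep 3u^2 - 2u^3 over the rise interval, 1 afterwards.

``snr_db=None`` is the no-activation sentinel (sigma_a = 0): a pure-baseline
negative case.  Everything is reproducible from the integer ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

from .signal import EmgSignal

__all__ = ["SynthSpec", "smoothstep", "generate", "make_benchmark_set"]


@dataclass(frozen=True)
class SynthSpec:
    """Generation parameters for one surrogate recording."""

    fs: float = 1500.0
    duration: float = 5.0
    t_on: float = 2.0
    rise: float = 1.0
    snr_db: Optional[float] = 10.0  # None => no activation (negative case)
    band: tuple[float, float] = (20.0, 450.0)
    shape_f_low: float = 60.0  # Stulen-De Luca spectral corners of the
    shape_f_high: float = 120.0  # activation component
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr_db is not None and not (
            0 < self.t_on and self.t_on + self.rise < self.duration
        ):
            raise ValueError("need 0 < t_on and t_on + rise < duration")
        if self.rise < 0:
            raise ValueError("rise must be non-negative")
        low, high = self.band
        if not (0 < low < high < self.fs / 2):
            raise ValueError("band must lie inside (0, fs/2)")
        if self.snr_db is not None and not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite or None")


def smoothstep(u: np.ndarray) -> np.ndarray:
    """3u^2 - 2u^3 clamped to [0, 1]; non-decreasing on [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _unit_std(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return x / s if s > 0 else x


def _baseline_noise(rng: np.random.Generator, n: int, fs: float, band: tuple) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return _unit_std(sps.sosfiltfilt(sos, white))


def _activation_noise(rng: np.random.Generator, n: int, spec: SynthSpec) -> np.ndarray:
    """White noise shaped in the frequency domain by the Stulen-De Luca
    sEMG spectrum, zeroed outside the generation band."""
    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    fl, fh = spec.shape_f_low, spec.shape_f_high
    psd = (fh**4 * f**2) / ((f**2 + fl**2) * (f**2 + fh**2) ** 2)
    low, high = spec.band
    psd[(f < low) | (f > high)] = 0.0
    shaped = np.fft.irfft(np.fft.rfft(white) * np.sqrt(psd), n=n)
    return _unit_std(shaped)


def generate(spec: SynthSpec) -> tuple[EmgSignal, Optional[float]]:
    """Generate one surrogate recording.

    Returns
    -------
    (signal, truth)
        ``truth`` is the envelope ramp start ``t_on`` in seconds — the
        earliest physiologic activity — or None for a no-activation record.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = int(round(spec.duration * spec.fs))
    b = _baseline_noise(rng, n, spec.fs, spec.band)
    if spec.snr_db is None:
        return EmgSignal(samples=b, fs=spec.fs, t0=0.0), None
    sigma_a = 10.0 ** (spec.snr_db / 20.0)
    a = sigma_a * _activation_noise(rng, n, spec)
    t = np.arange(n) / spec.fs
    if spec.rise > 0:
        env = smoothstep((t - spec.t_on) / spec.rise)
    else:
        env = (t >= spec.t_on).astype(float)
    x = b + env * a
    return EmgSignal(samples=x, fs=spec.fs, t0=0.0), spec.t_on


def make_benchmark_set(
    n: int,
    rise_range: tuple[float, float] = (0.5, 2.0),
    snr_db: float = 10.0,
    seed0: int = 0,
    duration: float = 5.0,
    fs: float = 1500.0,
) -> list[tuple[EmgSignal, Optional[float]]]:
    """A labelled half-positive/half-negative benchmark set.

    The first ``n // 2`` records carry an activation with rise duration
    drawn uniformly from ``rise_range`` and onset uniform in
    ``[1.0, duration - rise - 1.0]``; the remainder are pure-baseline
    negatives.  Record ``i`` uses seed ``seed0 + i``; the whole set is
    deterministic in its arguments.

    Returns a list of ``(signal, t_on-or-None)`` pairs; the matching
    :class:`SynthSpec` of record ``i`` can be rebuilt from the same seeds.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    n_pos = n // 2
    for i in range(n):
        seed = seed0 + i
        if i < n_pos:
            meta = np.random.default_rng([seed, 17])  # separate stream for draws
            rise = float(meta.uniform(*rise_range))
            t_on = float(meta.uniform(1.0, duration - rise - 1.0))
            spec = SynthSpec(
                fs=fs, duration=duration, t_on=t_on, rise=rise, snr_db=snr_db, seed=seed
            )
        else:
            spec = SynthSpec(fs=fs, duration=duration, snr_db=None, seed=seed)
        out.append(generate(spec))
    return out
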