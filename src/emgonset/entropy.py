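"""Normalised Shannon entropy of the marginal spectrum (MSE).

The marginal spectrum h = [h_1 ... h_n] is normalised to a probability
vector p_i = h_i / sum(h); its Shannon entropy -sum p_i ln p_i (with the
limit convention 0*ln 0 = 0) is divided by its maximum possible value ln n,
giving a unit-free value in [0, 1]: 0 means all spectral mass in a single
bin, 1 a perfectly uniform spread.  The normalisation makes the logarithm
base irrelevant and the statistic invariant to amplitude scaling — a muscle
turning on changes the value only through spectral *redistribution*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .hht import MarginalSpectrum

__all__ = ["MseValue", "compute_mse"]


@dataclass(frozen=True)
class MseValue:
    """Normalised spectral entropy with its raw (nats) value."""

    value: float  # raw / ln(n), in [0, 1]
    raw: float  # nats
    n_bins_used: int  # bins with p_i > 0


def compute_mse(spectrum: Union[MarginalSpectrum, np.ndarray]) -> MseValue:
    """Normalised Shannon entropy of a marginal spectrum.

    Accepts a :class:`~emgonset.hht.MarginalSpectrum` or a bare non-negative
    bin vector with at least two bins.  Computed as
    ``ln(S) - sum(h_i ln h_i) / S`` with ``S = sum(h)``, which is exact for
    the degenerate cases (uniform -> 1, single occupied bin -> 0) and avoids
    forming small ratios.

    Raises
    ------
    ValueError
        For an all-zero spectrum ("undefined entropy"), negative bins or
        fewer than two bins.
    """
    h = spectrum.h if isinstance(spectrum, MarginalSpectrum) else np.asarray(spectrum, dtype=float)
    if h.ndim != 1 or h.size < 2:
        raise ValueError("spectrum must be a 1-D vector of at least 2 bins")
    if np.any(h < 0):
        raise ValueError("spectrum bins must be non-negative")
    total = float(h.sum())
    if total <= 0:
        raise ValueError("undefined entropy: all-zero spectrum")
    pos = h[h > 0]
    raw = math.log(total) - float(np.sum(pos * np.log(pos))) / total
    raw = max(raw, 0.0)  # guard round-off for near-degenerate spectra
    value = raw / math.log(h.size)
    value = min(max(value, 0.0), 1.0)
    return MseValue(value=value, raw=raw, n_bins_used=int(pos.size))
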