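"""Empirical mode decomposition by iterative sifting.

EMD adaptively splits a signal into intrinsic mode functions (IMFs): locally
zero-mean oscillations whose extrema and zero-crossing counts differ by at
most one.  Each sifting pass subtracts the local mean — the average of cubic
spline envelopes through the maxima and minima — and repeats until the Cauchy
criterion SD = sum((h_prev - h_new)^2) / sum(h_prev^2) falls below a
tolerance (the classical choice 0.2 is the default).  Extraction stops when
the residual is monotonic or carries too few extrema to envelope, or when a
configured maximum number of modes is reached.

The decomposition is complete by construction: the residual is maintained as
the running remainder, so IMFs plus residual always reconstruct the input to
round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["ImfSet", "InsufficientExtrema", "local_extrema", "envelope_mean", "sift_imf", "emd"]


class InsufficientExtrema(Exception):
    """Raised when a vector lacks the >=2 maxima and >=2 minima an envelope needs.

    Not a hard error: the decomposition loop treats it as "residual is a
    monotonic/trend component, stop here".
    """


@dataclass
class ImfSet:
    """Ordered IMFs plus the final residual of one decomposition."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    n_sift_iters: list[int] = field(default_factory=list)
    is_valid_imf: list[bool] = field(default_factory=list)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        """Sum of all IMFs and the residual (equals the input to round-off)."""
        out = self.residual.copy()
        for c in self.imfs:
            out += c
        return out


def local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of interior maxima and minima.

    Extrema are strict sign changes of the first difference; a flat plateau
    at a turning point counts once, at its midpoint.  Endpoints are never
    extrema.
    """
    x = np.asarray(x, dtype=float)
    d = np.diff(x)
    nz = np.nonzero(d)[0]
    if nz.size < 2:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    s = np.sign(d[nz])
    flips = np.nonzero(s[:-1] != s[1:])[0]
    if flips.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    # plateau between the end of one run and the start of the next: midpoint
    idx = (nz[flips] + 1 + nz[flips + 1]) // 2
    rising = s[flips] > 0
    return idx[rising], idx[~rising]


def _count_zero_crossings(x: np.ndarray) -> int:
    x = np.asarray(x, dtype=float)
    nz = x[x != 0]
    if nz.size < 2:
        return 0
    return int(np.count_nonzero(np.sign(nz[:-1]) != np.sign(nz[1:])))


def is_imf(x: np.ndarray) -> bool:
    """IMF count check: |#extrema - #zero-crossings| <= 1 on interior samples."""
    maxima, minima = local_extrema(x)
    n_ext = maxima.size + minima.size
    return abs(n_ext - _count_zero_crossings(x)) <= 1


def _local_mean_small(x: np.ndarray, frac: float = 0.1) -> bool:
    """Second IMF condition: envelope mean negligible against the mode's RMS
    (mean |m| <= frac * RMS over the 10%-trimmed interior)."""
    try:
        m = envelope_mean(x)
    except InsufficientExtrema:
        return True  # too few extrema to form envelopes; nothing to enforce
    edge = max(1, x.size // 10)
    interior = slice(edge, x.size - edge)
    rms = float(np.sqrt(np.mean(x[interior] ** 2)))
    if rms == 0.0:
        return True
    return float(np.mean(np.abs(m[interior]))) <= frac * rms


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Spline envelope through extrema at ``idx``, with the two nearest
    extrema mirrored about each signal end to suppress edge swings."""
    n = x.size
    left = (-idx[1::-1])[: min(2, idx.size)]  # reflect first two about sample 0
    right = (2 * (n - 1) - idx[-1:-3:-1])[: min(2, idx.size)]
    knots_i = np.concatenate([left, idx, right])
    knots_v = np.concatenate([x[idx[1::-1]][: left.size], x[idx], x[idx[-1:-3:-1]][: right.size]])
    order = np.argsort(knots_i)
    knots_i, knots_v = knots_i[order], knots_v[order]
    keep = np.concatenate([[True], np.diff(knots_i) > 0])
    knots_i, knots_v = knots_i[keep], knots_v[keep]
    grid = np.arange(n)
    if knots_i.size >= 4:
        return CubicSpline(knots_i, knots_v, bc_type="natural")(grid)
    return np.interp(grid, knots_i, knots_v)


def envelope_mean(x: np.ndarray) -> np.ndarray:
    """Local mean m(t) = (upper envelope + lower envelope) / 2.

    Upper/lower envelopes are natural cubic splines through the local
    maxima/minima (linear interpolation when fewer than four knots are
    available on a side), with boundary extrema mirrored about each end.

    Raises
    ------
    InsufficientExtrema
        If there are fewer than two interior maxima or minima.
    """
    x = np.asarray(x, dtype=float)
    maxima, minima = local_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        raise InsufficientExtrema(
            f"need >=2 maxima and >=2 minima, found {maxima.size}/{minima.size}"
        )
    upper = _envelope(x, maxima)
    lower = _envelope(x, minima)
    return (upper + lower) / 2.0


def sift_imf(x: np.ndarray, sd_tol: float = 0.2, max_iters: int = 100) -> tuple[np.ndarray, int]:
    """Sift a candidate IMF out of ``x``.

    Iterates ``h <- h - envelope_mean(h)`` until the Cauchy SD criterion
    drops below ``sd_tol`` *and* the iterate satisfies both IMF defining
    conditions (extrema/zero-crossing count, negligible envelope mean), or
    ``max_iters`` is reached (the defining conditions can lag the SD
    criterion by a few passes on noisy input).
    An identically zero input (or an iterate whose extrema vanish) is
    returned as-is.

    Returns
    -------
    (imf, iterations)
    """
    h = np.asarray(x, dtype=float).copy()
    if not np.any(h):
        return h, 0
    iters = 0
    while iters < max_iters:
        try:
            m = envelope_mean(h)
        except InsufficientExtrema:
            break
        h_new = h - m
        iters += 1
        denom = float(np.sum(h * h))
        if denom == 0.0:
            h = h_new
            break
        sd = float(np.sum((h - h_new) ** 2)) / denom
        h = h_new
        if sd < sd_tol and is_imf(h) and _local_mean_small(h):
            break
    return h, iters


def emd(
    signal,
    max_imfs: int = 6,
    sd_tol: float = 0.2,
    max_iters: int = 100,
) -> ImfSet:
    """Decompose a signal into IMFs plus a residual.

    Parameters
    ----------
    signal : EmgSignal or 1-D array
    max_imfs : int
        Upper bound on the number of extracted modes (default 6).
    sd_tol, max_iters : float, int
        Per-IMF sifting stop criterion (see :func:`sift_imf`).

    Notes
    -----
    Extraction stops early when the running residual becomes monotonic or
    has too few extrema for envelope construction; a monotonic input yields
    zero IMFs with the input itself as residual.
    """
    x = np.asarray(getattr(signal, "samples", signal), dtype=float)
    if x.ndim != 1:
        raise ValueError("emd expects a 1-D signal")
    if x.size < 16:
        raise ValueError(f"signal of {x.size} samples is too short for EMD (need >= 16)")
    residual = x.copy()
    out = ImfSet(imfs=[], residual=residual)
    for _ in range(max_imfs):
        maxima, minima = local_extrema(out.residual)
        if maxima.size < 2 or minima.size < 2:
            break
        imf, iters = sift_imf(out.residual, sd_tol=sd_tol, max_iters=max_iters)
        if not np.any(imf):
            break
        out.imfs.append(imf)
        out.n_sift_iters.append(iters)
        out.is_valid_imf.append(is_imf(imf))
        out.residual = out.residual - imf
    return out
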