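"""Region-wise time-series features: mean, SD, MSSD, fALFF."""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np

from .types import ParcellatedTimeSeries

logger = logging.getLogger(__name__)

__all__ = ["regional_mean", "regional_sd", "regional_mean_sd", "mssd", "falff"]


def _ts_data(ts) -> np.ndarray:
    if isinstance(ts, ParcellatedTimeSeries):
        return ts.data
    return np.atleast_2d(np.asarray(ts, dtype=float))


def regional_mean(ts) -> np.ndarray:
    """Temporal mean per region."""
    return _ts_data(ts).mean(axis=0)


def regional_sd(ts) -> np.ndarray:
    """Sample standard deviation per region (denominator N-1)."""
    x = _ts_data(ts)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 frames for a sample SD")
    return x.std(axis=0, ddof=1)


def regional_mean_sd(ts) -> tuple[np.ndarray, np.ndarray]:
    return regional_mean(ts), regional_sd(ts)


def mssd(ts) -> np.ndarray:
    """BOLD variability: mean squared successive difference per region.

    MSSD = (1/(N-1)) * sum_{i=1}^{N-1} (x_{i+1} - x_i)^2, quantifying the
    moment-to-moment change in signal. Invariant to adding a constant and
    quadratic under rescaling.
    """
    x = _ts_data(ts)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 frames for MSSD")
    return np.sum(np.diff(x, axis=0) ** 2, axis=0) / (n - 1)


def falff(
    ts,
    tr: float | None = None,
    low_band: tuple[float, float] = (0.01, 0.08),
    mode: Literal["amplitude", "power"] = "amplitude",
) -> np.ndarray:
    """Fractional amplitude of low-frequency fluctuations per region.

    The ratio of the FFT amplitude spectrum summed over bins whose frequency
    lies in ``low_band`` (closed interval, default 0.01-0.08 Hz) to the sum
    over all positive-frequency bins, computed on the demeaned concatenated
    series. Values lie in [0, 1]; zero-variance regions yield 0 (logged).
    ``mode='power'`` sums squared amplitudes instead.
    """
    if isinstance(ts, ParcellatedTimeSeries):
        data, tr = ts.data, ts.tr
    else:
        data = np.atleast_2d(np.asarray(ts, dtype=float))
        if tr is None:
            raise ValueError("tr is required when passing a bare array")
    t = data.shape[0]
    if t < 16:
        raise ValueError("need at least 16 frames for a meaningful spectrum")
    if tr <= 0:
        raise ValueError("tr must be positive")
    lo, hi = low_band
    nyquist = 0.5 / tr
    if not (0 <= lo < hi):
        raise ValueError("low_band must satisfy 0 <= lo < hi")
    if hi >= nyquist:
        raise ValueError(f"band upper edge {hi} Hz must be below Nyquist {nyquist} Hz")

    x = data - data.mean(axis=0, keepdims=True)
    amp = np.abs(np.fft.rfft(x, axis=0))
    freqs = np.fft.rfftfreq(t, d=tr)
    pos = freqs > 0
    band = (freqs >= lo) & (freqs <= hi)
    if mode == "power":
        amp = amp**2
    elif mode != "amplitude":
        raise ValueError(f"unknown mode {mode!r}")
    total = amp[pos].sum(axis=0)
    degenerate = total == 0
    if np.any(degenerate):
        logger.warning(
            "falff: %d zero-variance region(s) set to 0", int(degenerate.sum())
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(degenerate, 0.0, amp[band].sum(axis=0) / np.where(degenerate, 1.0, total))
    return out
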