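"""Smoothing and differentiation operators used throughout the pipeline.

The measurement chain relies on four 1-D operators applied to uniformly
sampled series: Savitzky–Golay local-polynomial smoothing, a zero-phase
(forward–backward) Butterworth low-pass, central finite differencing, and a
sliding maximum used for peak extraction.  All operators preserve the input
length so that series stay frame-aligned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.signal import butter, savgol_filter, sosfiltfilt

from .errors import ConfigurationError, InsufficientDataError

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "sg_smooth",
    "butter_zerophase",
    "central_diff",
    "sliding_max",
]


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the smoothing/differentiation chain.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz (the video frame rate).
    sg_window : int
        Savitzky–Golay window length in frames; must be odd and larger than
        ``sg_order``.  Default 9 (0.18 s at 50 fps).
    sg_order : int
        Savitzky–Golay polynomial order.  Default 3.
    butter_cutoff : float
        Low-pass cutoff in Hz for the zero-phase Butterworth stage.
        Default 6 Hz, well below the Nyquist rate of 50 fps video but above
        the frequency content of a press repetition.
    butter_order : int
        Butterworth order (per pass).  Default 4.
    """

    fs: float
    sg_window: int = 9
    sg_order: int = 3
    butter_cutoff: float = 6.0
    butter_order: int = 4

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError(f"fs must be positive, got {self.fs}")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ConfigurationError(
                f"sg_window must be odd and > sg_order; got window="
                f"{self.sg_window}, order={self.sg_order}"
            )
        if not 0 < self.butter_cutoff < self.fs / 2:
            raise ConfigurationError(
                f"butter_cutoff must lie in (0, fs/2)=(0, {self.fs / 2}); "
                f"got {self.butter_cutoff}"
            )
        if self.butter_order < 1:
            raise ConfigurationError("butter_order must be >= 1")


def _effective_window(n: int, window: int, order: int) -> int:
    """Largest valid odd SG window <= min(n, window), at least order + 2."""
    w = min(window, n)
    if w % 2 == 0:
        w -= 1
    # smallest usable odd window: strictly > order and >= order + 2
    w_min = order + 2
    if w_min % 2 == 0:
        w_min += 1
    if w < w_min:
        raise InsufficientDataError(
            f"series of length {n} too short for SG order {order} "
            f"(needs >= {w_min} samples)"
        )
    return w


def sg_smooth(x: np.ndarray, cfg: FilterConfig) -> np.ndarray:
    """Savitzky–Golay smoothing with polynomial-fit edge handling.

    If the series is shorter than the configured window, the window shrinks
    to the largest valid odd length (logged) so short concentric phases
    remain analysable; series shorter than ``sg_order + 2`` samples raise
    :class:`InsufficientDataError`.
    """
    x = np.asarray(x, dtype=float)
    w = _effective_window(x.size, cfg.sg_window, cfg.sg_order)
    if w != cfg.sg_window:
        logger.warning(
            "SG window shrunk from %d to %d for series of length %d",
            cfg.sg_window, w, x.size,
        )
    return savgol_filter(x, w, cfg.sg_order, mode="interp")


def butter_zerophase(x: np.ndarray, cfg: FilterConfig) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward–backward pass, DC gain 1).

    Uses a second-order-section realisation and even-extension edge padding.
    No cutoff pre-warping is applied for the double pass, so the effective
    -3 dB point sits slightly below ``butter_cutoff``.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= 3 * cfg.butter_order:
        raise InsufficientDataError(
            f"series of length {x.size} too short for order-"
            f"{cfg.butter_order} forward-backward filtering"
        )
    sos = butter(cfg.butter_order, cfg.butter_cutoff, btype="low",
                 fs=cfg.fs, output="sos")
    return sosfiltfilt(sos, x, padtype="even")


def central_diff(x: np.ndarray, dt: float) -> np.ndarray:
    """Central difference derivative; one-sided first difference at the ends.

    Interior samples use ``(x[i+1] - x[i-1]) / (2 dt)``, exact for
    polynomials up to degree two.
    """
    if dt <= 0:
        raise ConfigurationError(f"dt must be positive, got {dt}")
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("central difference needs >= 3 samples")
    return np.gradient(x, dt, edge_order=1)


def sliding_max(x: np.ndarray, k: int) -> np.ndarray:
    """Centred sliding maximum of window ``k`` (odd), edges truncated."""
    if k < 1 or k % 2 == 0:
        raise ConfigurationError(f"window k must be odd and >= 1, got {k}")
    x = np.asarray(x, dtype=float)
    # 'nearest' replication equals a max over the truncated in-range window
    return maximum_filter1d(x, size=k, mode="nearest")
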