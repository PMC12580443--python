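"""Windowed least-squares derivative estimation.

The rate of force development (RFD, the first time derivative of force, also
called yank) and the second derivative F''(t) are estimated with a moving
least-squares slope: at each sample the slope of a straight line fitted to a
short centered window is reported.  F''(t) is the moving slope applied to the
RFD series with the same window.  The default 50 ms window at 200 Hz spans 11
samples.

Near the edges the full-width window is shifted to stay in bounds and the
slope of that window's fit is reported; a straight-line slope does not depend
on where in the window it is evaluated, so the output has the same length as
the input and is exact for linear signals everywhere, including edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .recording_io import ForceRecording, MalformedInputError

__all__ = ["DerivativeSet", "window_samples", "moving_slope", "compute_derivatives"]


def window_samples(window_ms: float, sample_rate: float) -> int:
    """Number of samples spanned by ``window_ms``, forced odd (rounding up).

    A centered window needs odd length; 50 ms at 200 Hz gives 11 samples,
    which spans exactly 50 ms of inter-sample intervals.
    """
    if window_ms <= 0 or sample_rate <= 0:
        raise ValueError("window_ms and sample_rate must be positive")
    w = int(round(window_ms * sample_rate / 1000.0))
    if w % 2 == 0:
        w += 1
    return max(w, 3)


@dataclass(frozen=True)
class DerivativeSet:
    """RFD and F''(t) series aligned sample-for-sample to a recording."""

    rfd: np.ndarray  # %MVC/s
    f2: np.ndarray  # %MVC/s^2
    window_ms: float
    window_samples: int
    source_length: int

    def __post_init__(self) -> None:
        if self.rfd.size != self.source_length or self.f2.size != self.source_length:
            raise ValueError("derivative series must match the source length")


def moving_slope(series, sample_rate: float, window_ms: float = 50.0) -> np.ndarray:
    """Least-squares straight-line slope in a sliding window.

    Parameters
    ----------
    series : array-like
        Input samples.
    sample_rate : float
        Sampling rate in Hz; slopes are returned in input units per second.
    window_ms : float
        Window span in milliseconds (default 50).

    Returns
    -------
    numpy.ndarray
        Slope series of the same length as the input.
    """
    y = np.asarray(series, dtype=float)
    w = window_samples(window_ms, sample_rate)
    n = y.size
    if n < w:
        raise MalformedInputError(
            f"series of {n} samples is shorter than the {w}-sample window"
        )
    half = w // 2
    # Centered abscissa offsets; slope of the LS fit is sum(k*y)/sum(k^2) / dt.
    k = np.arange(w, dtype=float) - half
    denom = float(np.sum(k * k))
    win_slopes = sliding_window_view(y, w) @ k / denom * sample_rate
    out = np.empty(n, dtype=float)
    out[half : n - half] = win_slopes
    out[:half] = win_slopes[0]
    out[n - half :] = win_slopes[-1]
    return out


def compute_derivatives(rec: ForceRecording, window_ms: float = 50.0) -> DerivativeSet:
    """RFD and F''(t) for a normalized recording.

    Both derivatives use the same window: F'' is the moving slope of the RFD
    series.  No smoothing beyond the two slope passes is applied; the
    acquisition low-pass is a property of the recording, not of the analysis.
    """
    if not rec.normalized:
        raise MalformedInputError(
            "derivatives require a %MVC-normalized recording; call normalize_to_mvc first"
        )
    w = window_samples(window_ms, rec.sample_rate)
    if rec.force.size < 2 * w:
        raise MalformedInputError(
            f"recording of {rec.force.size} samples too short for a {w}-sample window"
        )
    rfd = moving_slope(rec.force, rec.sample_rate, window_ms)
    f2 = moving_slope(rfd, rec.sample_rate, window_ms)
    return DerivativeSet(
        rfd=rfd,
        f2=f2,
        window_ms=float(window_ms),
        window_samples=w,
        source_length=rec.force.size,
    )
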