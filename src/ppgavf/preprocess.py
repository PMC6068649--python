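"""Signal conditioning for raw PPG: robust smoothing and de-trending.

Raw finger PPG carries high-frequency instrumentation noise, a DC offset and
slow baseline drift (respiration, probe pressure).  Conditioning is done in
two steps:

1. :func:`smooth` — robust local polynomial regression (LOESS): at each
   sample a weighted least-squares polynomial (degree 2 by default) is fitted
   over a window spanning a fixed fraction of the record (1% by default)
   with tricube distance weights, and the fit is re-weighted over a few
   robustness iterations using bisquare weights of the scaled residuals so
   that isolated spikes do not drag the fit.  Windows are truncated at the
   record boundaries; no padding is used.  A plain moving average is
   provided as an alternative (:func:`moving_average`) but is not the
   default.
2. :func:`detrend` — subtraction of the ordinary least-squares line, which
   removes the offset and any linear drift; the output has zero mean and
   zero best-fit slope.  Slope features are differences of nearby samples,
   so they are insensitive to the removed trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import PpgRecording

__all__ = ["SmootherConfig", "smooth", "moving_average", "detrend"]


@dataclass(frozen=True)
class SmootherConfig:
    """Parameters of the robust local-regression smoother.

    span : window length as a fraction of the record length (default 0.01).
    degree : local polynomial degree, 1 or 2 (default 2).
    robust_iterations : bisquare re-weighting passes (default 5; 0 disables
    robustness, leaving plain weighted least squares).
    """

    span: float = 0.01
    degree: int = 2
    robust_iterations: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.span <= 1:
            raise ValueError(f"span must lie in (0, 1], got {self.span}")
        if self.degree not in (1, 2):
            raise ValueError(f"degree must be 1 or 2, got {self.degree}")
        if self.robust_iterations < 0:
            raise ValueError("robust_iterations must be >= 0")


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w**3


def _fit_windows(y_win: np.ndarray, w_win: np.ndarray, offsets: np.ndarray, degree: int) -> np.ndarray:
    """Weighted polynomial fit value at offset 0 for a batch of windows.

    y_win, w_win : (n_windows, w) sample values and weights
    offsets : (w,) window abscissae relative to the fitted point
    Returns the fitted value at each window's centre point.
    """
    X = np.vander(offsets, degree + 1, increasing=True)  # (w, degree+1)
    # normal equations per window: (X^T W X) beta = X^T W y
    A = np.einsum("wa,nw,wb->nab", X, w_win, X)
    b = np.einsum("wa,nw->na", X, w_win * y_win)
    # tiny ridge guards rank deficiency when robustness zeroes most weights
    A = A + 1e-12 * np.eye(degree + 1)
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    return beta[:, 0]  # value at offset 0 (increasing powers)


def smooth(recording: PpgRecording, config: SmootherConfig | None = None) -> PpgRecording:
    """Robust LOESS smoothing of a recording; length and metadata preserved."""
    if config is None:
        config = SmootherConfig()
    y = recording.samples
    n = y.size
    window = int(round(config.span * n))
    if window % 2 == 0:
        window += 1
    min_window = config.degree + 2
    if window < min_window:
        raise ValueError(
            f"span {config.span} gives a {window}-point window; at least "
            f"{min_window} points are needed for degree {config.degree}"
        )
    half = window // 2

    robust_w = np.ones(n)
    fitted = y.copy()
    for iteration in range(config.robust_iterations + 1):
        fitted = _loess_pass(y, robust_w, half, config.degree)
        if iteration == config.robust_iterations:
            break
        resid = y - fitted
        scale = 6.0 * np.median(np.abs(resid))
        # residuals at numerical-noise level mean the fit is already exact;
        # reweighting on them would zero out arbitrary points
        if scale <= 1e-12 * max(1.0, float(np.max(np.abs(y)))):
            break
        u = np.clip(resid / scale, -1.0, 1.0)
        robust_w = (1.0 - u**2) ** 2
    return recording.with_samples(fitted)


def _loess_pass(y: np.ndarray, robust_w: np.ndarray, half: int, degree: int) -> np.ndarray:
    """One weighted local-regression sweep over all points."""
    n = y.size
    fitted = np.empty(n)
    offsets = np.arange(-half, half + 1, dtype=float)
    tricube = _tricube(offsets / (half + 1e-9) if half > 0 else offsets + 1.0)
    if half == 0:
        return y.copy()

    interior = np.arange(half, n - half)
    if interior.size:
        y_win = np.lib.stride_tricks.sliding_window_view(y, 2 * half + 1)
        r_win = np.lib.stride_tricks.sliding_window_view(robust_w, 2 * half + 1)
        w_win = r_win * tricube[None, :]
        fitted[interior] = _fit_windows(y_win, w_win, offsets, degree)

    # truncated windows at the record boundaries
    edge = [*range(min(half, n)), *range(max(n - half, 0), n)]
    for i in edge:
        lo, hi = max(0, i - half), min(n, i + half + 1)
        off = np.arange(lo, hi, dtype=float) - i
        max_d = max(np.abs(off).max(), 1.0)
        w = robust_w[lo:hi] * _tricube(off / (max_d + 1e-9))
        fitted[i] = _fit_windows(y[None, lo:hi], w[None, :], off, degree)[0]
    return fitted


def moving_average(recording: PpgRecording, window: int) -> PpgRecording:
    """Plain boxcar moving average (edge windows truncated)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    y = recording.samples
    kernel = np.ones(window)
    sums = np.convolve(y, kernel, mode="same")
    counts = np.convolve(np.ones_like(y), kernel, mode="same")
    return recording.with_samples(sums / counts)


def detrend(recording: PpgRecording) -> PpgRecording:
    """Remove the best-fit line (offset + linear drift) from a recording."""
    t = recording.times
    slope, intercept = np.polyfit(t, recording.samples, 1)
    return recording.with_samples(recording.samples - (slope * t + intercept))
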