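"""BOLD preprocessing: physiological-noise regression and low-pass filtering.

The cleaning contract is deliberately minimal: recorded cardiac and
respiratory traces are removed voxelwise by ordinary least squares (together
with an intercept and a linear trend), and the residual series are low-pass
filtered so that only fluctuations below 0.08 Hz — the band carrying
resting-state connectivity — survive.  Filtering is zero-phase (a 4th-order
Butterworth run forward and backward), so correlations downstream are not
distorted by temporal shifts.  Neither operation changes array shape, affine
or sampling interval.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthetic import PhysioTrace


class PreprocessError(ValueError):
    pass


@dataclass
class Bold4D:
    """4-D BOLD run: (x, y, z, t) intensities with a voxel-to-world affine."""

    data: np.ndarray
    tr_seconds: float
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise PreprocessError("BOLD data must be 4-D (x, y, z, t)")
        if self.data.shape[-1] < 2:
            raise PreprocessError("BOLD run must have at least 2 timepoints")
        if self.tr_seconds <= 0:
            raise PreprocessError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.tr_seconds


def _resample_to_frames(physio: PhysioTrace, frame_times: np.ndarray) -> np.ndarray:
    t0, t1 = physio.time_s[0], physio.time_s[-1]
    eps = 1e-9
    if frame_times[0] < t0 - eps or frame_times[-1] > t1 + eps:
        raise PreprocessError(
            f"physio recording [{t0}, {t1}] s does not cover the BOLD run "
            f"[{frame_times[0]}, {frame_times[-1]}] s"
        )
    cardiac = np.interp(frame_times, physio.time_s, physio.cardiac)
    respiratory = np.interp(frame_times, physio.time_s, physio.respiratory)
    return np.column_stack([cardiac, respiratory])


def regress_physio(bold: Bold4D, physio: PhysioTrace) -> Bold4D:
    """Residualize every voxel series against [1, trend, cardiac, respiratory].

    The traces are linearly interpolated to the frame times; residuals are
    exact least-squares residuals, hence orthogonal to every retained design
    column.  Columns that are (numerically) constant are dropped with a
    warning rather than left to make the design rank-deficient.
    """
    t = bold.frame_times()
    n = len(t)
    regressors = _resample_to_frames(physio, t)
    names = ["intercept", "trend", "cardiac", "respiratory"]
    cols = [np.ones(n), np.linspace(-1.0, 1.0, n), regressors[:, 0], regressors[:, 1]]
    keep, kept_names = [cols[0]], [names[0]]
    for name, col in zip(names[1:], cols[1:]):
        if np.ptp(col) < 1e-12 * max(1.0, np.abs(col).max()):
            warnings.warn(
                f"physio regression: dropping constant design column {name!r}",
                stacklevel=2,
            )
            continue
        keep.append(col)
        kept_names.append(name)
    x = np.column_stack(keep)
    y = bold.data.reshape(-1, n).T  # (t, voxels)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return Bold4D(
        data=resid.T.reshape(bold.data.shape),
        tr_seconds=bold.tr_seconds,
        affine=bold.affine.copy(),
    )


# forward-backward application squares the magnitude response, pulling the
# -3 dB point inward; scaling the design frequency by (sqrt(2)-1)^(-1/(2n))
# restores it to the nominal cutoff for an order-n Butterworth
_FILTFILT_CUTOFF_CORRECTION = (np.sqrt(2.0) - 1.0) ** (-1.0 / 8.0)
_FILTER_ORDER = 4


def lowpass(bold: Bold4D, cutoff_hz: float = 0.08) -> Bold4D:
    """Zero-phase Butterworth low-pass along time.

    The combined forward-backward response has its -3 dB point at
    ``cutoff_hz``; gain exceeds 0.9 below 0.8x the cutoff and falls below
    0.1 above 2x the cutoff.  DC is preserved exactly.
    """
    nyquist = 1.0 / (2.0 * bold.tr_seconds)
    if cutoff_hz <= 0:
        raise PreprocessError("cutoff_hz must be positive")
    design_hz = cutoff_hz * _FILTFILT_CUTOFF_CORRECTION
    if design_hz >= nyquist:
        raise PreprocessError(
            f"cutoff {cutoff_hz} Hz at TR={bold.tr_seconds}s reaches the "
            f"Nyquist frequency {nyquist} Hz"
        )
    b, a = sps.butter(_FILTER_ORDER, design_hz / nyquist)
    filtered = sps.filtfilt(b, a, bold.data, axis=-1)
    return Bold4D(
        data=filtered, tr_seconds=bold.tr_seconds, affine=bold.affine.copy()
    )
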