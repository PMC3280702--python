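"""Sliding-window cross-power connectivity matrices and their SVD statistic.

The connectivity matrix of one 5-s window is ``A_ij = |integral of the
cross-power spectral density of channels i and j over a frequency band|``.
Cross-spectra are Welch estimates with 1-s Hann sub-windows and 50% overlap;
band integration is a trapezoidal sum over the FFT bins whose centers lie in
``[lb, ub]`` inclusive.  Taking the magnitude of the (complex) band-integrated
cross-spectrum guarantees a symmetric nonnegative real matrix; the real part
is selectable instead.

Matrices are computed causally: the matrix indexed by second ``k`` uses the
samples in ``(k-5, k]``, so a detector reading ``sigma1(k)`` uses no future
data.  The per-window statistic is the largest singular value ``sigma1`` and
its right singular vector ``v1`` (sign-fixed so the largest-magnitude
component is positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import signal as sps

from .errors import DataError
from .synthetic import MultichannelRecord

#: Frequency-band presets in Hz.  The beta preset follows the 13-30 Hz
#: convention of the patient tables.
BAND_PRESETS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

WINDOW_S = 5
SLIDE_S = 1


@dataclass(frozen=True)
class BandSpec:
    """A frequency band ``[lb, ub]`` in Hz."""

    name: str
    lb: float
    ub: float

    def __post_init__(self) -> None:
        if not 0.0 < self.lb < self.ub:
            raise ValueError(f"need 0 < lb < ub, got [{self.lb}, {self.ub}]")

    @classmethod
    def preset(cls, name: str) -> "BandSpec":
        if name not in BAND_PRESETS:
            raise ValueError(f"unknown band preset {name!r}; "
                             f"choose from {sorted(BAND_PRESETS)}")
        lb, ub = BAND_PRESETS[name]
        return cls(name, lb, ub)

    @classmethod
    def custom(cls, lb: float, ub: float) -> "BandSpec":
        return cls("custom", lb, ub)


@dataclass
class ConnectivitySeries:
    """One symmetric nonnegative matrix per whole second of usable signal."""

    matrices: np.ndarray            # (n_windows, n_channels, n_channels)
    times_s: np.ndarray             # second index k of each window's right edge
    band: BandSpec
    window_s: int = WINDOW_S
    slide_s: int = SLIDE_S


@dataclass
class SvdStatisticSeries:
    """Per-second leading singular value/vector of the connectivity matrices."""

    sigma1: np.ndarray              # (n_windows,)
    v1: np.ndarray                  # (n_windows, n_channels)
    times_s: np.ndarray
    all_singular_values: np.ndarray | None = None


def band_crosspower(window: np.ndarray, rate: float, band: BandSpec,
                    mode: Literal["magnitude", "real"] = "magnitude",
                    ) -> np.ndarray:
    """Band-integrated cross-power matrix of one multichannel window.

    Parameters
    ----------
    window
        ``(n_channels, n_samples)`` real matrix.
    rate
        Sampling rate in Hz.
    band
        Integration band; must lie below the Nyquist frequency.
    mode
        ``"magnitude"`` (default) returns ``|integral of P_ij|``;
        ``"real"`` returns the real part of the integral.

    Returns
    -------
    A symmetric ``(n_channels, n_channels)`` matrix including the diagonal
    auto-power terms.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2:
        raise ValueError("window must be a channels x samples matrix")
    if np.isnan(window).any():
        raise DataError("window contains NaN samples")
    nperseg = int(round(rate))
    if window.shape[1] < nperseg:
        raise ValueError(
            f"window of {window.shape[1]} samples is shorter than one "
            f"1-s spectral sub-segment ({nperseg} samples)"
        )
    if band.ub >= rate / 2:
        raise ValueError(f"band upper edge {band.ub} Hz is not below "
                         f"Nyquist ({rate / 2} Hz)")

    freqs, pxy = sps.csd(
        window[:, np.newaxis, :], window[np.newaxis, :, :],
        fs=rate, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        axis=-1,
    )
    mask = (freqs >= band.lb) & (freqs <= band.ub)
    if mask.sum() >= 2:
        integral = np.trapezoid(pxy[..., mask], freqs[mask], axis=-1)
    else:
        # degenerate one-bin band: rectangle rule
        df = freqs[1] - freqs[0]
        integral = pxy[..., mask].sum(axis=-1) * df

    a = np.abs(integral) if mode == "magnitude" else integral.real
    return 0.5 * (a + a.T)  # symmetrize away floating-point asymmetry


def connectivity_series(record: MultichannelRecord, band: BandSpec,
                        mode: Literal["magnitude", "real"] = "magnitude",
                        ) -> ConnectivitySeries:
    """Sliding 5-s / 1-s-slide connectivity matrices of a whole recording.

    The matrix at second ``k`` (``k = 5, 6, ...``) covers samples in
    ``(k-5, k]``; a record of ``floor(duration)`` whole seconds yields
    ``floor(duration) - 4`` matrices.
    """
    n_seconds = int(np.floor(record.duration_s))
    if n_seconds < WINDOW_S:
        raise ValueError(
            f"record of {record.duration_s:.2f} s is shorter than one "
            f"{WINDOW_S}-s analysis window"
        )
    sr = int(round(record.rate))
    ks = np.arange(WINDOW_S, n_seconds + 1)
    matrices = np.stack([
        band_crosspower(
            record.samples[:, (k - WINDOW_S) * sr:k * sr], record.rate,
            band, mode=mode)
        for k in ks
    ])
    return ConnectivitySeries(matrices, ks.astype(float), band)


def svd_statistic(series: ConnectivitySeries,
                  keep_spectra: bool = True) -> SvdStatisticSeries:
    """Leading singular value/vector of each connectivity matrix.

    For the symmetric nonnegative-definite matrices produced here the singular
    values equal the eigenvalue magnitudes.  ``v1`` is sign-normalized so its
    largest-magnitude component is positive (the SVD sign is arbitrary).
    """
    mats = np.asarray(series.matrices, dtype=float)
    if not np.isfinite(mats).all():
        raise DataError("connectivity matrices contain non-finite entries")
    _, s, vh = np.linalg.svd(mats)
    sigma1 = s[:, 0]
    v1 = vh[:, 0, :]
    pivot = np.take_along_axis(
        v1, np.abs(v1).argmax(axis=1, keepdims=True), axis=1)
    v1 = v1 * np.sign(np.where(pivot == 0.0, 1.0, pivot))
    return SvdStatisticSeries(
        sigma1=sigma1, v1=v1, times_s=series.times_s,
        all_singular_values=s if keep_spectra else None)
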