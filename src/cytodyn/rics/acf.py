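"""High-pass detrending and arbitrary-region spatial autocorrelation.

The correlation surface is computed over spatial lags (ξ, ψ) as

    G(ξ, ψ) = <δI(x, y) · δI(x+ξ, y+ψ)> / <I>²

where both pixels of every contributing pair must lie inside the region
mask, δI is the deviation from the masked mean, and <I> is the masked
mean intensity of the (detrend-corrected) frame.  The masked average is
evaluated per frame and the per-frame surfaces are averaged.

Implementation: masked images are zero-filled outside the mask and
correlated with a zero-padded FFT; the raw products are normalised by
the mask's own autocorrelation, which counts the pixel pairs that
contribute at each lag.  A literal quadruple-loop evaluation of the
same formula is kept in the test-suite as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage, signal

from ..core import ImageSeries, RegionMask

__all__ = ["CorrelationSurface", "highpass_detrend", "arbitrary_region_acf"]


def highpass_detrend(series: ImageSeries, window: int = 10) -> ImageSeries:
    """Remove slow per-pixel intensity drift with a moving-average high-pass.

    Each pixel's time trace has its centered moving average (circular
    boundary, ``window`` frames) subtracted and the global series mean
    added back, so the output mean equals the input mean to floating
    precision.  ``window == n_frames`` degenerates to subtracting the
    per-pixel temporal mean.
    """
    T = series.n_frames
    if not 2 <= window <= T:
        raise ValueError(f"window must satisfy 2 <= window <= n_frames ({T}), got {window}")
    data = np.asarray(series.data, dtype=float)
    moving = ndimage.uniform_filter1d(data, size=window, axis=0, mode="wrap")
    out = data - moving + data.mean()
    return series.with_data(out)


@dataclass
class CorrelationSurface:
    """G(ξ, ψ) sampled on an integer lag grid.

    ``G[j, i]`` corresponds to lag ``(xi_lags[i], psi_lags[j])`` with ξ
    along the fast scan axis and ψ along the slow axis.  ``n_pairs``
    counts the pixel pairs contributing at each lag; lags with no pairs
    hold NaN.
    """

    G: np.ndarray
    xi_lags: np.ndarray
    psi_lags: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        self.xi_lags = np.asarray(self.xi_lags, dtype=int)
        self.psi_lags = np.asarray(self.psi_lags, dtype=int)
        self.n_pairs = np.asarray(self.n_pairs)
        if self.G.shape != (len(self.psi_lags), len(self.xi_lags)):
            raise ValueError("G shape does not match lag axes")

    def value(self, xi: int, psi: int) -> float:
        i = int(np.flatnonzero(self.xi_lags == xi)[0])
        j = int(np.flatnonzero(self.psi_lags == psi)[0])
        return float(self.G[j, i])

    @property
    def max_xi(self) -> int:
        return int(self.xi_lags.max())

    @property
    def max_psi(self) -> int:
        return int(self.psi_lags.max())


def _full_correlate(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Zero-padded cross-correlation Σ_xy a(x,y)·b(x+ξ,y+ψ) on the full lag grid."""
    return signal.fftconvolve(b, a[::-1, ::-1], mode="full")


def arbitrary_region_acf(
    series: ImageSeries,
    mask: RegionMask,
    max_lag_xi: Optional[int] = None,
    max_lag_psi: Optional[int] = None,
) -> CorrelationSurface:
    """Masked spatial autocorrelation surface, averaged over frames.

    Parameters
    ----------
    series : ImageSeries
        Detrended raster series (T×Y×X).
    mask : RegionMask
        Pixels included in the region of interest; both endpoints of a
        pixel pair must fall inside the mask.
    max_lag_xi, max_lag_psi : int, optional
        Half-extent of the returned lag grid; defaults to nx//2, ny//2.
    """
    data = np.asarray(series.data, dtype=float)
    if data.ndim != 3:
        raise ValueError("arbitrary_region_acf expects a T×Y×X series")
    ny, nx = data.shape[1:]
    m = mask.mask
    if m.shape != (ny, nx):
        raise ValueError(f"mask shape {m.shape} does not match frames {(ny, nx)}")
    if mask.n_pixels < 1:
        raise ValueError("mask is empty")

    if max_lag_xi is None:
        max_lag_xi = nx // 2
    if max_lag_psi is None:
        max_lag_psi = ny // 2

    mf = m.astype(float)
    # pair counts per lag: autocorrelation of the mask indicator
    n_pairs = np.rint(_full_correlate(mf, mf)).astype(np.int64)

    acc = np.zeros_like(n_pairs, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        for frame in data:
            mean_f = frame[m].mean()
            if mean_f <= 0:
                raise ValueError(
                    "masked mean intensity is <= 0; normalization undefined"
                )
            dI = np.where(m, frame - mean_f, 0.0)
            num = _full_correlate(dI, dI)
            acc += np.where(n_pairs > 0, num / np.maximum(n_pairs, 1), np.nan) / mean_f**2
    G_full = acc / data.shape[0]
    # the pair set of (ξ,ψ) and (−ξ,−ψ) is identical: enforce symmetry exactly
    G_full = 0.5 * (G_full + G_full[::-1, ::-1])

    # crop lag window; full grid spans ξ ∈ [-(nx-1), nx-1], ψ ∈ [-(ny-1), ny-1]
    xi = np.arange(-max_lag_xi, max_lag_xi + 1)
    psi = np.arange(-max_lag_psi, max_lag_psi + 1)
    ci, cj = nx - 1, ny - 1
    G = G_full[np.ix_(cj + psi, ci + xi)]
    npair = n_pairs[np.ix_(cj + psi, ci + xi)]
    return CorrelationSurface(G=G, xi_lags=xi, psi_lags=psi, n_pairs=npair)
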