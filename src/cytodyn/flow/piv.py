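"""Multipass FFT cross-correlation PIV for F-actin displacement fields.

Two coarse-to-fine passes (32 px then 16 px interrogation windows by
default); the second pass shifts its windows by the interpolated
first-pass prediction and adds the correlation residual.  Sub-pixel
peaks use a 3-point Gaussian fit per axis.  Sign convention: a feature
moving toward +x between frames yields u > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import fftconvolve
from skimage.exposure import equalize_adapthist
from skimage.morphology import disk

from ..core import ImageSeries

__all__ = ["PIVConfig", "VectorField", "preprocess", "piv_pass",
           "multipass_piv", "filter_vectors", "mean_velocity"]


@dataclass(frozen=True)
class PIVConfig:
    """Interrogation and preprocessing parameters."""

    window_sizes: Tuple[int, ...] = (32, 16)
    overlap: float = 0.5
    clahe_tile: int = 20
    denoise_radius: int = 3
    contrast_threshold: Optional[float] = None   # None → 5th pct of window stds
    outlier_residual: float = 2.0
    enable_preprocess: bool = True

    def __post_init__(self) -> None:
        if any(b >= a for a, b in zip(self.window_sizes, self.window_sizes[1:])):
            raise ValueError("window_sizes must be strictly decreasing")
        if not 0.0 <= self.overlap <= 0.75:
            raise ValueError(f"overlap must be in [0, 0.75], got {self.overlap}")


@dataclass
class VectorField:
    """Gridded displacement field with validity flags.

    ``x``/``y`` are window-center coordinates in px; ``u``/``v`` are
    displacements in px per frame interval.  Invalid vectors are
    excluded from every aggregate.
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    window_std: np.ndarray
    frame_interval_s: Optional[float] = None
    pixel_size_nm: Optional[float] = None

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def preprocess(frame: np.ndarray, config: PIVConfig = PIVConfig()) -> np.ndarray:
    """CLAHE (tile size ``clahe_tile``) followed by median denoising.

    The output intensity range is rescaled to [0, max(frame)].
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("preprocess expects a single 2D frame")
    if min(frame.shape) < config.clahe_tile:
        raise ValueError(
            f"frame {frame.shape} smaller than one CLAHE tile ({config.clahe_tile} px)"
        )
    vmax = frame.max()
    if vmax <= frame.min():
        return frame.copy()     # constant frame: no contrast to equalize
    norm = (frame - frame.min()) / (vmax - frame.min())
    eq = equalize_adapthist(norm, kernel_size=config.clahe_tile)
    den = ndimage.median_filter(eq, footprint=disk(config.denoise_radius))
    return den * vmax


def _gaussian_subpixel(cm1: float, c0: float, cp1: float) -> float:
    """3-point Gaussian peak interpolation; parabolic fallback."""
    if cm1 > 0 and c0 > 0 and cp1 > 0:
        lm, l0, lp = np.log(cm1), np.log(c0), np.log(cp1)
        denom = 2 * lm - 4 * l0 + 2 * lp
        if denom != 0:
            return float((lm - lp) / denom)
    denom = 2 * (cm1 - 2 * c0 + cp1)
    if denom != 0:
        return float((cm1 - cp1) / denom)
    return 0.0


def _window_grid(shape: Tuple[int, int], window: int, overlap: float
                 ) -> Tuple[np.ndarray, np.ndarray]:
    step = max(1, int(round(window * (1.0 - overlap))))
    ny, nx = shape
    ys = np.arange(0, ny - window + 1, step)
    xs = np.arange(0, nx - window + 1, step)
    return ys, xs


def _correlation_peak(a: np.ndarray, b: np.ndarray) -> Tuple[float, float, bool]:
    """Displacement (u, v) of b relative to a from the correlation peak."""
    w = a.shape[0]
    a0 = a - a.mean()
    b0 = b - b.mean()
    if a0.std() == 0 or b0.std() == 0:
        return 0.0, 0.0, False
    corr = fftconvolve(b0, a0[::-1, ::-1], mode="full")
    # normalize by the per-lag overlap count: the triangular envelope of
    # the linear correlation otherwise biases the sub-pixel peak fit
    n1 = w - np.abs(np.arange(-(w - 1), w))
    corr /= np.outer(n1, n1)
    half = w // 4    # standard one-quarter rule for reliable peaks
    c = w - 1
    sub = corr[c - half:c + half + 1, c - half:c + half + 1]

    # peak with ties broken toward the smaller displacement
    peak = sub.max()
    cand = np.argwhere(sub >= peak - 1e-12 * abs(peak))
    lags = cand - half
    order = np.lexsort((np.abs(lags).sum(axis=1),))
    py, px = cand[order[0]]
    if px in (0, sub.shape[1] - 1) or py in (0, sub.shape[0] - 1):
        return float(px - half), float(py - half), True

    du = _gaussian_subpixel(sub[py, px - 1], sub[py, px], sub[py, px + 1])
    dv = _gaussian_subpixel(sub[py - 1, px], sub[py, px], sub[py + 1, px])
    return float(px - half + du), float(py - half + dv), True


def piv_pass(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    window: int,
    overlap: float = 0.5,
    predictor: Optional[VectorField] = None,
) -> VectorField:
    """Single interrogation pass between two frames.

    With a ``predictor``, each frame-B window is extracted at the
    position shifted by the rounded interpolated prediction, and the
    result is that shift plus the correlation residual (discrete window
    shifting).  Flat windows yield invalid vectors, never exceptions.
    """
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must share a shape")
    if window < 8:
        raise ValueError(f"window must be >= 8 px, got {window}")
    ny, nx = frame_a.shape
    ys, xs = _window_grid(frame_a.shape, window, overlap)
    cy = ys + window / 2.0
    cx = xs + window / 2.0

    pred_u = pred_v = None
    if predictor is not None:
        pred_u, pred_v = _interpolate_predictor(predictor, cy, cx)

    U = np.zeros((len(ys), len(xs)))
    V = np.zeros_like(U)
    valid = np.zeros(U.shape, dtype=bool)
    stds = np.zeros_like(U)

    for j, y0 in enumerate(ys):
        for i, x0 in enumerate(xs):
            a_win = frame_a[y0:y0 + window, x0:x0 + window]
            stds[j, i] = a_win.std()
            su = sv = 0
            if pred_u is not None:
                su = int(round(pred_u[j, i]))
                sv = int(round(pred_v[j, i]))
            by0, bx0 = y0 + sv, x0 + su
            if by0 < 0 or bx0 < 0 or by0 + window > ny or bx0 + window > nx:
                continue
            b_win = frame_b[by0:by0 + window, bx0:bx0 + window]
            u, v, ok = _correlation_peak(a_win, b_win)
            if ok:
                U[j, i] = su + u
                V[j, i] = sv + v
                valid[j, i] = True

    X, Y = np.meshgrid(cx, cy)
    return VectorField(x=X, y=Y, u=U, v=V, valid=valid, window_std=stds)


def _interpolate_predictor(field: VectorField, cy: np.ndarray, cx: np.ndarray
                           ) -> Tuple[np.ndarray, np.ndarray]:
    gy = field.y[:, 0]
    gx = field.x[0, :]
    u = field.u.copy()
    v = field.v.copy()
    if field.n_valid:
        fill_u = np.median(field.u[field.valid])
        fill_v = np.median(field.v[field.valid])
    else:
        fill_u = fill_v = 0.0
    u[~field.valid] = fill_u
    v[~field.valid] = fill_v
    out_u = np.empty((len(cy), len(cx)))
    out_v = np.empty((len(cy), len(cx)))
    pts = np.stack(np.meshgrid(cy, cx, indexing="ij"), axis=-1).reshape(-1, 2)
    for src, dst in ((u, out_u), (v, out_v)):
        interp = RegularGridInterpolator((gy, gx), src, bounds_error=False,
                                         fill_value=None)
        dst[...] = interp(pts).reshape(len(cy), len(cx))
    return out_u, out_v


def multipass_piv(series: ImageSeries, config: PIVConfig = PIVConfig()
                  ) -> List[VectorField]:
    """Coarse-to-fine PIV over every consecutive frame pair."""
    data = np.asarray(series.data, dtype=float)
    if data.ndim != 3 or data.shape[0] < 2:
        raise ValueError("multipass_piv needs a T×Y×X series with >= 2 frames")

    if config.enable_preprocess:
        frames = np.stack([preprocess(f, config) for f in data])
    else:
        frames = data

    fields: List[VectorField] = []
    for a, b in zip(frames[:-1], frames[1:]):
        field_prev: Optional[VectorField] = None
        for w in config.window_sizes:
            field_prev = piv_pass(a, b, window=w, overlap=config.overlap,
                                  predictor=field_prev)
        assert field_prev is not None
        field_prev.frame_interval_s = series.frame_interval_s
        field_prev.pixel_size_nm = series.pixel_size_nm
        fields.append(filter_vectors(field_prev, config))
    return fields


def filter_vectors(field: VectorField, config: PIVConfig = PIVConfig()) -> VectorField:
    """Invalidate low-contrast windows and isolated outliers.

    Vectors whose source-window intensity standard deviation falls
    below ``contrast_threshold`` (default: the 5th percentile of all
    window stds) are flagged invalid.  A normalized-median test over the
    3×3 neighborhood then invalidates vectors whose normalized residual
    exceeds ``outlier_residual``.
    """
    valid = field.valid.copy()
    thr = config.contrast_threshold
    if thr is None:
        thr = float(np.percentile(field.window_std, 5.0))
    valid &= ~(field.window_std < thr)

    # Westerweel/Scarano universal outlier (normalized median) test
    eps = 0.1
    nyg, nxg = field.u.shape
    for comp in (field.u, field.v):
        resid = np.zeros_like(comp)
        for j in range(nyg):
            for i in range(nxg):
                if not valid[j, i]:
                    continue
                nb = [comp[jj, ii]
                      for jj in range(max(0, j - 1), min(nyg, j + 2))
                      for ii in range(max(0, i - 1), min(nxg, i + 2))
                      if (jj, ii) != (j, i) and valid[jj, ii]]
                if len(nb) < 3:
                    continue
                nb = np.asarray(nb)
                med = np.median(nb)
                rm = np.median(np.abs(nb - med))
                resid[j, i] = abs(comp[j, i] - med) / (rm + eps)
        valid &= resid <= config.outlier_residual
    return replace(field, valid=valid)


def mean_velocity(field: VectorField) -> float:
    """Mean valid vector magnitude converted to nm/min."""
    if field.n_valid == 0:
        raise ValueError("no valid vectors: mean velocity undefined")
    if field.pixel_size_nm is None or field.frame_interval_s is None:
        raise ValueError("field lacks physical calibration (pixel size / interval)")
    mean_px = float(field.magnitude[field.valid].mean())
    return mean_px * field.pixel_size_nm / (field.frame_interval_s / 60.0)
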