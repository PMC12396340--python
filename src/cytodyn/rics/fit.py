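"""Nonlinear least-squares fitting of the raster correlation model.

Free parameters are the diffusion coefficient D, the mean number of
particles in focus N, and a constant baseline offset; γ and ω_r are
fixed by the scan configuration.  The zero-lag point is excluded
(uncorrelated shot noise inflates G(0,0)) and residuals are weighted by
the square root of the pair counts contributing to each lag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ..core import ImageSeries, RasterScanConfig, RegionMask
from .acf import CorrelationSurface, arbitrary_region_acf, highpass_detrend
from .model import rics_model

__all__ = ["RICSFit", "fit_rics", "compare_regions"]

#: default half-extent of the fit window in (ξ, ψ)
DEFAULT_FIT_WINDOW = (16, 4)


@dataclass
class RICSFit:
    """Result of a correlation-surface fit."""

    D: float                 # µm²/s
    N: float                 # mean particles in focus
    offset: float            # constant baseline
    converged: bool
    residual_norm: float
    covariance: Optional[np.ndarray] = None   # 2x2 over (D, N)
    label: str = ""

    def as_dict(self) -> dict:
        return {
            "label": self.label, "D_um2_per_s": self.D, "N": self.N,
            "offset": self.offset, "converged": self.converged,
            "residual_norm": self.residual_norm,
        }


def _fit_points(
    surface: CorrelationSurface, window: Tuple[int, int]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    wx, wy = window
    wx = min(wx, surface.max_xi)
    wy = min(wy, surface.max_psi)
    XI, PSI = np.meshgrid(surface.xi_lags, surface.psi_lags)
    sel = (np.abs(XI) <= wx) & (np.abs(PSI) <= wy)
    sel &= ~((XI == 0) & (PSI == 0))          # exclude zero lag
    sel &= np.isfinite(surface.G) & (surface.n_pairs > 0)
    w = np.sqrt(surface.n_pairs[sel].astype(float))
    return XI[sel].astype(float), PSI[sel].astype(float), surface.G[sel], w / w.max()


def _coarse_init(
    xi: np.ndarray, psi: np.ndarray, g: np.ndarray, w: np.ndarray,
    scan: RasterScanConfig,
) -> Tuple[float, float, float]:
    """Grid-search D with (amplitude, offset) solved linearly at each candidate."""
    best = None
    for D in np.geomspace(1e-3, 1e3, 61):
        shape = rics_model(xi, psi, D, 1.0, scan)       # amplitude γ/1
        A = np.stack([shape * w, w], axis=1)
        coef, *_ = np.linalg.lstsq(A, g * w, rcond=None)
        resid = A @ coef - g * w
        cost = float(resid @ resid)
        if coef[0] > 0 and (best is None or cost < best[0]):
            best = (cost, D, coef[0], coef[1])
    if best is None:
        return 1.0, 1.0, 0.0
    _, D0, amp, off = best
    return D0, scan.gamma / amp, off


def fit_rics(
    surface: CorrelationSurface,
    scan: RasterScanConfig,
    init: Optional[Tuple[float, float]] = None,
    fit_window: Tuple[int, int] = DEFAULT_FIT_WINDOW,
) -> RICSFit:
    """Fit (D, N, offset) to a correlation surface.

    Parameters
    ----------
    surface : CorrelationSurface
        Must cover at least ±8 px of lag along the fast axis.
    scan : RasterScanConfig
        Fixes γ, ω_r and the scan timing.
    init : (D0, N0), optional
        Starting point; by default D is grid-searched with the linear
        parameters solved exactly at each candidate.
    fit_window : (int, int)
        Half-extent (ξ, ψ) of the lag window used for fitting.

    Notes
    -----
    Non-convergence is reported through ``converged=False``, never an
    exception.
    """
    if surface.max_xi < 8:
        raise ValueError("correlation surface must cover at least ±8 px in ξ")
    xi, psi, g, w = _fit_points(surface, fit_window)
    if xi.size < 4:
        raise ValueError("not enough defined lags in the fit window")
    if not np.any(g != 0):
        raise ValueError("all-zero correlation surface cannot be fitted")

    if init is not None:
        D0, N0 = init
        off0 = 0.0
    else:
        D0, N0, off0 = _coarse_init(xi, psi, g, w, scan)
    D0 = max(D0, 1e-12)
    N0 = max(N0, 1e-12)

    def resid(p: np.ndarray) -> np.ndarray:
        D, N, off = p
        return (rics_model(xi, psi, D, N, scan) + off - g) * w

    res = least_squares(
        resid, x0=[D0, N0, off0],
        bounds=([0.0, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
        x_scale=[max(D0, 1e-6), max(N0, 1e-6), 1.0],
        ftol=1e-15, xtol=1e-15, gtol=1e-15, max_nfev=2000,
    )
    D, N, off = res.x
    cov = None
    try:
        J = res.jac
        dof = max(len(g) - 3, 1)
        s2 = 2.0 * res.cost / dof
        cov_full = s2 * np.linalg.inv(J.T @ J)
        cov = cov_full[:2, :2]
    except np.linalg.LinAlgError:
        pass
    return RICSFit(
        D=float(D), N=float(N), offset=float(off),
        converged=bool(res.success), residual_norm=float(np.linalg.norm(res.fun)),
        covariance=cov,
    )


def compare_regions(
    series: ImageSeries,
    masks: Sequence[RegionMask],
    detrend_window: int = 10,
    fit_window: Tuple[int, int] = DEFAULT_FIT_WINDOW,
) -> pd.DataFrame:
    """Fit D region-by-region with shared detrending.

    Returns a CSV-exportable table with one row per mask.
    """
    if len(masks) == 0:
        raise ValueError("at least one region mask is required")
    if series.scan is None:
        raise ValueError("series must carry a RasterScanConfig")
    detrended = highpass_detrend(series, window=min(detrend_window, series.n_frames))
    rows: List[dict] = []
    for mask in masks:
        mask.validate_for_fit()
        surf = arbitrary_region_acf(detrended, mask)
        fit = fit_rics(surf, series.scan, fit_window=fit_window)
        fit.label = mask.label
        rows.append(fit.as_dict())
    return pd.DataFrame(rows)
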