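"""Closed-form spatial autocorrelation model for raster-scanned diffusion.

The model value at spatial lag (ξ, ψ) pixels for a species diffusing with
coefficient ``D`` observed by a 2D Gaussian focus of waist ``ω_r``::

    G(ξ, ψ) = (γ / N) · (1 + 4·D·|ξ·τ_p + ψ·τ_l| / ω_r²)^(−1)
              · exp[ −δ_r²·(ξ² + ψ²) / (ω_r² + 4·D·|ξ·τ_p + ψ·τ_l|) ]

with γ = 2^(−3/2) for the 2D Gaussian, τ_p/τ_l the pixel and line dwell
times, and δ_r the pixel size.  Internally everything is converted to
µm and s, so ``D`` is in µm²/s.
"""

from __future__ import annotations

import numpy as np

from ..core import RasterScanConfig

__all__ = ["rics_model"]


def rics_model(xi, psi, D: float, N: float, scan: RasterScanConfig):
    """Evaluate the raster correlation model at lags (xi, psi) in pixels.

    Parameters
    ----------
    xi, psi : array-like
        Spatial lags in pixels along the fast (xi) and slow (psi) axes.
    D : float
        Diffusion coefficient, µm²/s.  Must be >= 0.
    N : float
        Mean number of particles in focus.  Must be > 0.
    scan : RasterScanConfig
        Acquisition geometry/timing (pixel size, dwell times, waist, γ).

    Returns
    -------
    ndarray or float
        Model correlation amplitude, broadcast over ``xi``/``psi``.
    """
    if N <= 0:
        raise ValueError(f"N must be > 0, got {N}")
    if D < 0:
        raise ValueError(f"D must be >= 0, got {D}")
    xi = np.asarray(xi, dtype=float)
    psi = np.asarray(psi, dtype=float)

    w2 = scan.omega_r_um ** 2           # µm²
    dr2 = scan.delta_r_um ** 2          # µm²
    tau = np.abs(xi * scan.tau_p_s + psi * scan.tau_l_s)   # s
    denom = w2 + 4.0 * D * tau          # µm²
    g = (scan.gamma / N) * (w2 / denom) * np.exp(-dr2 * (xi ** 2 + psi ** 2) / denom)
    return g if g.ndim else float(g)
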