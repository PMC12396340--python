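"""Shared domain types: scan geometry, image series, region masks.

All coordinates are 0-based with ``x`` the column / fast-scan axis and
``y`` the row / slow axis.  Physical calibration is carried explicitly
(nm for pixel sizes, seconds for intervals); diffusion coefficients are
reported in µm²/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

__all__ = ["RasterScanConfig", "ImageSeries", "RegionMask", "GAMMA_2D",
           "default_confocal_scan"]

#: Shape factor of the 2D Gaussian focal volume, 2**(-3/2).
GAMMA_2D: float = 2.0 ** (-1.5)


@dataclass(frozen=True)
class RasterScanConfig:
    """Raster-scan acquisition geometry and timing.

    Parameters
    ----------
    delta_r : float
        Pixel size in nm.
    tau_p : float
        Pixel dwell time in µs.
    tau_l : float
        Line time in ms.
    tau_frame : float
        Frame time in s.
    omega_r : float
        Lateral 1/e² waist of the excitation focus in nm.
    gamma : float
        Shape factor of the focal volume; defaults to 2**(-3/2).
    image_size : (int, int)
        Image shape as ``(ny, nx)``.
    """

    delta_r: float
    tau_p: float
    tau_l: float
    tau_frame: float
    omega_r: float
    image_size: Tuple[int, int] = (256, 256)
    gamma: float = GAMMA_2D

    def __post_init__(self) -> None:
        for name in ("delta_r", "tau_p", "tau_l", "tau_frame", "omega_r", "gamma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and strictly positive, got {v!r}")
        ny, nx = self.image_size
        if ny < 1 or nx < 1:
            raise ValueError(f"image_size must be positive, got {self.image_size}")
        if self.tau_p_s * nx > self.tau_l_s * (1 + 1e-9):
            raise ValueError("tau_p * nx must not exceed the line time tau_l")
        if self.tau_l_s * ny > self.tau_frame * (1 + 1e-9):
            raise ValueError("tau_l * ny must not exceed the frame time tau_frame")

    # -- unit-converted views (SI) ------------------------------------
    @property
    def delta_r_um(self) -> float:
        return self.delta_r * 1e-3

    @property
    def omega_r_um(self) -> float:
        return self.omega_r * 1e-3

    @property
    def tau_p_s(self) -> float:
        return self.tau_p * 1e-6

    @property
    def tau_l_s(self) -> float:
        return self.tau_l * 1e-3

    def pixel_time_offset(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Within-frame acquisition time of pixel (x, y), in seconds."""
        return np.asarray(y) * self.tau_l_s + np.asarray(x) * self.tau_p_s


def default_confocal_scan(image_size: Tuple[int, int] = (256, 256),
                          omega_r: float = 250.0) -> RasterScanConfig:
    """Convenience constructor with the default confocal acquisition timing
    (50 nm pixels, 8.19 µs dwell, 4.92 ms line, 1.26 s frame)."""
    return RasterScanConfig(
        delta_r=50.0, tau_p=8.19, tau_l=4.92, tau_frame=1.26,
        omega_r=omega_r, image_size=image_size,
    )


@dataclass
class ImageSeries:
    """A T×Y×X (optionally T×Z×Y×X) intensity series with calibration.

    ``scan`` is set for raster-correlation data; ``pixel_size_nm`` and
    ``frame_interval_s`` suffice for the time-lapse pipelines.
    """

    data: np.ndarray
    pixel_size_nm: Optional[float] = None
    frame_interval_s: Optional[float] = None
    scan: Optional[RasterScanConfig] = None
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"data must be T×Y×X or T×Z×Y×X, got shape {self.data.shape}")
        if self.scan is not None:
            if self.data.shape[-2:] != tuple(self.scan.image_size):
                raise ValueError(
                    f"data frame shape {self.data.shape[-2:]} does not match "
                    f"scan.image_size {self.scan.image_size}"
                )
            if self.pixel_size_nm is None:
                self.pixel_size_nm = self.scan.delta_r

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> Tuple[int, ...]:
        return self.data.shape[1:]

    def with_data(self, data: np.ndarray) -> "ImageSeries":
        return ImageSeries(data=data, pixel_size_nm=self.pixel_size_nm,
                           frame_interval_s=self.frame_interval_s,
                           scan=self.scan, channel=self.channel)


@dataclass
class RegionMask:
    """Boolean Y×X inclusion mask with a free-text label."""

    mask: np.ndarray
    label: str = ""

    #: minimum included pixels for a correlation fit to be attempted
    MIN_PIXELS = 64

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {self.mask.shape}")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def validate_for_fit(self) -> None:
        if self.n_pixels < self.MIN_PIXELS:
            raise ValueError(
                f"mask '{self.label}' has {self.n_pixels} pixels; "
                f"at least {self.MIN_PIXELS} are required for a fit"
            )
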