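"""Frame pairs with known rigid (possibly sub-pixel) displacement."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

__all__ = ["DisplacementSpec", "make_shifted_pair"]


@dataclass(frozen=True)
class DisplacementSpec:
    """Ground truth for a shifted frame pair.

    ``shift`` is the (dx, dy) displacement in pixels applied to the
    second frame relative to the first (fractional values allowed).
    """

    shift: Tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 0.0
    field: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self) -> None:
        dx, dy = self.shift
        if not (np.isfinite(dx) and np.isfinite(dy)):
            raise ValueError(f"shift must be finite, got {self.shift}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


def _broadband_texture(shape: Tuple[int, int], seed: int, smooth: float = 1.5) -> np.ndarray:
    rng = np.random.default_rng(seed)
    tex = rng.standard_normal(shape)
    tex = ndimage.gaussian_filter(tex, smooth, mode="wrap")
    tex -= tex.min()
    return tex / tex.max()


def make_shifted_pair(
    base_texture_seed: int,
    spec: DisplacementSpec,
    shape: Tuple[int, int] = (128, 128),
) -> Tuple[np.ndarray, np.ndarray]:
    """Return (frame_a, frame_b) where frame_b is frame_a displaced by
    ``spec.shift`` plus independent Gaussian noise.

    Integer shifts are an exact array roll; fractional shifts are applied
    in the Fourier domain (band-limited exactness on the periodic
    texture).
    """
    dx, dy = spec.shift
    ny, nx = shape
    if abs(dx) > nx / 2 or abs(dy) > ny / 2:
        raise ValueError(f"shift {spec.shift} exceeds half the frame {shape}")

    a = _broadband_texture(shape, base_texture_seed)
    if float(dx).is_integer() and float(dy).is_integer():
        b = np.roll(a, (int(dy), int(dx)), axis=(0, 1))
    else:
        b = np.fft.ifftn(ndimage.fourier_shift(np.fft.fftn(a), (dy, dx))).real
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        a = a + rng.standard_normal(shape) * spec.noise_sd
        b = b + rng.standard_normal(shape) * spec.noise_sd
    return a, b
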