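from __future__ import annotations

import numpy as np
import pytest

from cytodyn.core import ImageSeries, RegionMask, default_confocal_scan


@pytest.fixture
def small_scan():
    return default_confocal_scan(image_size=(64, 64))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def square_mask():
    sq = np.ones((10, 10), dtype=bool)
    return sq


def brute_force_acf(data: np.ndarray, mask: np.ndarray, max_xi: int, max_psi: int
                    ) -> np.ndarray:
    """Literal quadruple-loop evaluation of the masked autocorrelation.

    Independent oracle: per frame, G(xi, psi) averages dI(x,y)*dI(x+xi,y+psi)
    over all pixel pairs with both endpoints in the mask, divided by the
    squared masked mean; frames are averaged.
    """
    T, ny, nx = data.shape
    G = np.zeros((2 * max_psi + 1, 2 * max_xi + 1))
    for f in range(T):
        frame = data[f]
        mu = frame[mask].mean()
        for pj, psi in enumerate(range(-max_psi, max_psi + 1)):
            for pi, xi in enumerate(range(-max_xi, max_xi + 1)):
                s, n = 0.0, 0
                for y in range(ny):
                    for x in range(nx):
                        y2, x2 = y + psi, x + xi
                        if 0 <= y2 < ny and 0 <= x2 < nx \
                                and mask[y, x] and mask[y2, x2]:
                            s += (frame[y, x] - mu) * (frame[y2, x2] - mu)
                            n += 1
                if n:
                    G[pj, pi] += (s / n) / mu**2
                else:
                    G[pj, pi] = np.nan
    return G / T
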