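"""Raster-scanned images of Brownian fluorophores.

Pixel (x, y) of frame f is sampled at time

    t = f·τ_frame + y·τ_l + x·τ_p

and particle positions advance pixel-by-pixel through the scan, so the
intra-line and intra-frame dynamics that the raster correlation model
relies on are present in the synthetic data.  Particles diffuse in 2D
(per-step Gaussian increments of variance 2·D·Δt per axis) in a
periodic box that extends a guard margin of 3·ω_r beyond the imaged
field, keeping the particle density stationary.  Detection is shot-
noise limited: photon counts are Poisson draws on the expected
intensity Σ_particles brightness·exp(−2 r²/ω_r²) (photon-counting mode,
no read noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import ImageSeries, RasterScanConfig

__all__ = ["DiffusionSimSpec", "simulate_diffusion_raster", "expected_mean_intensity"]

GUARD_WAISTS = 3.0


@dataclass(frozen=True)
class DiffusionSimSpec:
    """Ground-truth parameters of a raster-scan diffusion simulation.

    Attributes
    ----------
    D_true : float
        Diffusion coefficient, µm²/s (>= 0).
    particle_density : float
        Particles per µm² (> 0).
    brightness : float
        Expected photons per particle per pixel dwell at the PSF center.
    scan : RasterScanConfig
        Acquisition geometry and timing.
    n_frames : int
        Number of frames (>= 2).
    seed : int
        RNG seed; the output is a pure function of the spec.
    """

    D_true: float
    particle_density: float
    brightness: float
    scan: RasterScanConfig
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("D_true", "particle_density", "brightness"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.D_true < 0:
            raise ValueError(f"D_true must be >= 0, got {self.D_true}")
        if self.particle_density <= 0:
            raise ValueError(f"particle_density must be > 0, got {self.particle_density}")
        if self.brightness <= 0:
            raise ValueError(f"brightness must be > 0, got {self.brightness}")
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")


def expected_mean_intensity(spec: DiffusionSimSpec) -> float:
    """Closed-form expected photon count per pixel dwell.

    Integrating the Gaussian detection profile over a uniform particle
    field gives brightness · density · (π·ω_r²/2).
    """
    w = spec.scan.omega_r_um
    return spec.brightness * spec.particle_density * (np.pi * w**2 / 2.0)


def simulate_diffusion_raster(spec: DiffusionSimSpec) -> ImageSeries:
    """Simulate a raster-scanned image series of diffusing particles.

    Returns an :class:`ImageSeries` of non-negative integer photon
    counts, deterministic for a given spec (seed included).
    """
    scan = spec.scan
    ny, nx = scan.image_size
    rng = np.random.default_rng(spec.seed)

    field_w = nx * scan.delta_r_um
    field_h = ny * scan.delta_r_um
    guard = GUARD_WAISTS * scan.omega_r_um
    box_w = field_w + 2 * guard
    box_h = field_h + 2 * guard

    n_particles = max(1, int(round(spec.particle_density * box_w * box_h)))
    # particle coordinates relative to the imaged field origin
    px = rng.uniform(-guard, field_w + guard, size=n_particles)
    py = rng.uniform(-guard, field_h + guard, size=n_particles)

    # per-pixel sample times within a frame, raveled in scan order
    xs = np.arange(nx) * scan.delta_r_um + scan.delta_r_um / 2.0
    ys = np.arange(ny) * scan.delta_r_um + scan.delta_r_um / 2.0
    pix_x = np.tile(xs, ny)
    pix_y = np.repeat(ys, nx)

    # time steps between consecutive pixel samples in scan order,
    # including the line-retrace gap and the frame-retrace gap
    dt = np.full(ny * nx, scan.tau_p_s)
    line_gap = scan.tau_l_s - nx * scan.tau_p_s
    dt[nx::nx] += line_gap          # first pixel of each new line
    frame_gap = scan.tau_frame - ny * scan.tau_l_s
    dt[0] = 0.0                     # placeholder; set per frame below

    n_pix = ny * nx
    sigma_base = np.sqrt(2.0 * spec.D_true)
    inv_w2 = 2.0 / scan.omega_r_um**2
    frames = np.empty((spec.n_frames, ny, nx), dtype=np.int64)

    step_dt = dt.copy()
    # chunk the scan order so trajectory arrays stay < ~64 MB
    chunk = max(1, int(4e6 // max(n_particles, 1)))
    for f in range(spec.n_frames):
        step_dt[0] = 0.0 if f == 0 else (scan.tau_p_s + line_gap + frame_gap)
        out = np.empty(n_pix)
        for start in range(0, n_pix, chunk):
            stop = min(start + chunk, n_pix)
            sl = slice(start, stop)
            n_sl = stop - start
            if spec.D_true > 0:
                sig = sigma_base * np.sqrt(step_dt[sl])
                incr_x = rng.standard_normal((n_sl, n_particles)) * sig[:, None]
                incr_y = rng.standard_normal((n_sl, n_particles)) * sig[:, None]
                traj_x = px + np.cumsum(incr_x, axis=0)
                traj_y = py + np.cumsum(incr_y, axis=0)
                px, py = traj_x[-1].copy(), traj_y[-1].copy()
            else:
                traj_x = np.broadcast_to(px, (n_sl, n_particles))
                traj_y = np.broadcast_to(py, (n_sl, n_particles))
            # minimal-image distance in the periodic box
            dx = (traj_x - pix_x[sl, None] + box_w / 2.0) % box_w - box_w / 2.0
            dy = (traj_y - pix_y[sl, None] + box_h / 2.0) % box_h - box_h / 2.0
            out[sl] = spec.brightness * np.exp(-inv_w2 * (dx**2 + dy**2)).sum(axis=1)
        frames[f] = rng.poisson(out).reshape(ny, nx)

    return ImageSeries(
        data=frames, scan=scan, frame_interval_s=scan.tau_frame,
        channel=f"sim-D{spec.D_true}",
    )
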