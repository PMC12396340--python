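# cytodyn

Image-quantification toolkit for cytoskeletal dynamics in fluorescence
microscopy, with synthetic ground-truth generators for every stage:

- **rics** — raster-scan image correlation spectroscopy: high-pass
  detrending, arbitrary-region (masked) spatial autocorrelation with
  pair-count normalization, and diffusion-coefficient fitting of the
  2D Gaussian focal model (shape factor γ = 2^(−3/2)).
- **flow** — multipass FFT cross-correlation PIV (32 → 16 px windows,
  CLAHE + median preprocessing, 3-point Gaussian subpixel peaks,
  contrast and normalized-median vector validation, mean vector
  velocity in nm/min).
- **lamella** — time-lapse preprocessing (median filter, rolling-ball
  background, rigid-body registration), Huang-threshold binarization,
  covered area from pairwise mask subtraction, CTCF, and binarized
  cross-section density profiles.
- **morpho** — 3D skeletons (SWC I/O, mask thinning), total branch
  length, exact segment–sphere Sholl profiles, motility index, and
  extension/retraction speeds from branch-tip tracks.
- **synapse** — top-percentile puncta detection, strict sub-50 nm
  one-to-one cross-channel colocalization, and whole-footprint
  engulfment scoring.
- **simgen** — synthetic inputs with known ground truth: raster-scanned
  Brownian fluorophores advanced pixel-by-pixel in scan order, shifted
  frame pairs, translating masks, star skeletons, planted puncta pairs
  and engulfment phantoms.
- **io_cli** — OME-TIFF readers/writers, provenance sidecars, and the
  `cytodyn` command-line interface.

## Test

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests for
the documented invariants, independent brute-force oracles (quadruple-
loop autocorrelation, literal Huang criterion, exhaustive matching),
and `tests/test_acceptance.py` with one test per acceptance criterion.

## CLI examples

```sh
cytodyn simulate --d 1.0 --size 64 --frames 50 --seed 1 --out sim.ome.tif
cytodyn rics --input sim.ome.tif --pixel-size 50 --dwell 8.19 \
    --line 4.92 --frame-time 1.26 --waist 250 --out fits.csv
cytodyn piv --input movie.ome.tif --interval 180 --pixel-size 100 --out field.csv
cytodyn coverage --input movie.ome.tif --interval 60 --span 300 --out coverage.csv
cytodyn sholl --swc cell.swc --step 1 --out profile.csv
cytodyn motility --input masks.ome.tif --out motility.csv
cytodyn synapse --ch-a psd95.ome.tif --ch-b vglut1.ome.tif \
    --pixel-size 47 --max-distance 50 --out synapses.csv
cytodyn engulf --puncta psd95.ome.tif --cells mask.ome.tif --out engulfed.csv
```

Every run writes CSV tables plus a `run_config.json` sidecar capturing
inputs, calibration, parameters and seed, so results are reproducible
from the sidecar alone.

## Conventions

Coordinates are 0-based with x the column/fast-scan axis and y the
row/slow axis; pixel (x, y) of a raster frame is acquired at time
offset y·τ_l + x·τ_p. Physical units: pixel sizes in nm, times in s
(dwell in µs, line time in ms where noted), diffusion coefficients in
µm²/s, speeds in µm/min, PIV velocities in nm/min.
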