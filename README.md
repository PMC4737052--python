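# phasemotion

Local-phase visual motion detection and phase-only image reconstruction.

The package computes per-block Gaussian-windowed local spectra of a video
(block STFT), extracts the temporal change of the local phase, and detects
motion by thresholding a Radon-transform statistic (the Phase Motion
Indicator, PMI) of each block's phase-change field, with a coarse direction
readout per block. It also contains:

- **phase_reconstruction** — reconstruction of a bandlimited (trigonometric
  polynomial) image, up to scale, from the phases of a bank of Gabor
  receptive-field responses alone, via the null space of a constraint
  matrix; plus SNR evaluation.
- **bio_detectors** — reference Reichardt (correlation) and Barlow-Levick
  (inhibition) elementary motion detector arrays operating on blurred,
  subsampled video on the same block grid.
- **radon_detector** — the detection back end: bounded-domain discrete
  Radon transform with line-length correction, PMI, direction estimation,
  and coarse-to-fine motion segmentation (32x32 blocks refined at 16x16).
- **synthetic** — seeded generators for moving ON/OFF edges, translating
  squares, drifting gratings, translating textures, and contrast/noise
  degradations, with ground truth in the video metadata.
- **video_core** — frames, overlapping block grids (spacing `b0`, block
  side `M`, first window centered at pixel (1,1)), Gaussian windows,
  zero-padded block extraction, and PNG-sequence I/O.

## CLI

```sh
# generate a synthetic stimulus (PNG sequence + JSON sidecar)
phasemotion simulate --kind edge --velocity 40,0 --size 64x64 --duration 0.5 --out frames/

# phase-based motion detection -> per-frame {k, l, pmi, theta_hat} JSON
phasemotion detect frames/ --sigma 4 --block 32 --spacing 6 --out results.json

# coarse-to-fine motion segmentation -> binary PNG masks
phasemotion segment frames/ --refine 16 --out masks/

# Reichardt / Barlow-Levick reference detectors
phasemotion biodetect frames/ --kind reichardt --threshold 2 --out bio.json

# phase-only reconstruction from serialized phase measurements
phasemotion reconstruct --orders 3,3 --in phases.json --out coeffs.json

# arrow overlays of detections onto the frames
phasemotion overlay frames/ results.json --out overlay/
```

`--eps` and `--threshold` default to automatic values: the denoising
constant is 1e-3 times the mean block amplitude of the first frame, and the
PMI threshold is 0.6 times the median PMI of a pure planar phase-change
field at 10 px/s (scale it with `--threshold-scale`, e.g. 1.6 for noisy
video).

## Conventions

- Intensities are unitless luminance in [0, 1]; pixel coordinates are
  1-based in the public API with block (k, l) centered at
  (k*b0 + 1, l*b0 + 1); x indexes columns, y indexes rows (+y downward).
- Block spectra are arrays of shape (K, L, M, M) indexed
  `[k, l, n + M/2, m + M/2]` on the signed frequency grid
  (m*2π/M, n*2π/M), DC at the middle index.
- Directions are angles in [0, 2π) in image coordinates (0 = rightward,
  π/2 = downward).
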