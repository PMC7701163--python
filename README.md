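# oximap

Tissue oxygen-saturation (StO2) mapping from structured-light images,
built entirely on synthetic phantoms:

- **`oximap.phantoms`** — synthetic tissue scenes (per-pixel hemoglobin
  concentrations + a scattering power law) and a structured-illumination
  renderer: sinusoidal projection at 0 and 0.2 mm⁻¹, phases
  {0, 2π/3, 4π/3}, wavelengths {659, 691, 731, 851} nm, detector gain,
  seeded noise, session drift, and a cuff-occlusion time-series
  generator.
- **`oximap.sfdi`** — the conventional multi-frame pipeline: three-phase
  demodulation, reference-phantom calibration, lookup-table inversion of
  the (DC, AC) diffuse-reflectance pair to (μa, μs′), non-negative
  Beer–Lambert chromophore fitting, and StO2 computation.
- **`oximap.ssop`** — the single-snapshot benchmark: anisotropic
  Fourier-domain filtering (sine-profile low-pass, Blackman-profile
  single-sideband high-pass) of one patterned frame, then the same
  inversion and fitting stages.
- **`oximap.gan`** — an end-to-end conditional adversarial network that
  maps two snapshot frames (plus a checkerboard reference-drift channel)
  directly to StO2: fusion generator (U-Net/ResNet hybrid, residual
  blocks of five 3×3 convolutions, additive skips), 70×70-receptive-field
  patch discriminator, spectral normalization everywhere, L1 weight 60,
  one-sided label smoothing 0.9, 64-image buffer, flip augmentation.
  Runs on a small built-in numpy autograd engine — no deep-learning
  framework required.
- **`oximap.metrics` / `oximap.cli`** — masked NMAE evaluation,
  receptive-field arithmetic, occlusion trend extraction, and the
  command-line surface.

The forward model is the spatially resolved diffusion approximation (a
closed form in μa, μs′, spatial frequency, and refractive-index
mismatch), which fills the inversion lookup table; any forward callable
with the same signature (e.g. a Monte Carlo surrogate) can be swapped
into `build_lut`.

## CLI

```bash
oximap simulate --seed 0 --out runs/demo --size 64          # scene + stacks + truth
oximap sfdi --stack runs/demo/ground_truth.tif \
            --reference runs/demo/reference.tif --out runs/demo/sfdi.tif
oximap ssop --stack runs/demo/snapshot.tif \
            --reference runs/demo/reference.tif --out runs/demo/ssop.tif
oximap train --seed 0 --out runs/model                      # toy-scale synthetic training
oximap predict --weights runs/model --stack runs/demo/snapshot.tif \
               --reference runs/demo/reference.tif --out runs/demo/gan.tif
oximap evaluate --pred runs/demo/gan.tif --truth runs/demo/truth_sto2.tif \
                --out runs/demo/report.json
oximap occlusion-demo --seed 0 --out runs/occ               # trend CSV + PNG
```

Stacks are multi-page TIFF with a JSON sidecar manifest (per-frame
wavelength/frequency/phase, protocol, seed); maps are 32-bit float TIFF
with JSON provenance; model weights are `.npz` plus a JSON descriptor.

`oximap train` accepts a YAML config (`n_patches`, `patch_size`,
`epochs`, `noise_sigma`, plus any training-scalar override). Defaults are
toy-scale so the full adversarial loop runs on one CPU in minutes; the
full-scale settings (200 epochs, 256-pixel patches, 64/128/256/512
widths) are preserved in `TrainConfig` / `GeneratorConfig` defaults.

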