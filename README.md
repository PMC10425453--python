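# samdenoise

Nonlocal transform-domain denoising for scanning acoustic microscopy (SAM)
volumes, with a synthetic phantom and a quantitative evaluation pipeline.

A reflection-mode acoustic microscope raster-scans a focused transducer and
records a time-domain echo (A-scan) at every lateral position, giving a 3-D
volume `z(x, y, t)`. When the excitation amplitude is low, the scans are
dominated by noise; the observation model is

    z(x) = y(x) + eta(x),        eta ~ N(0, sigma^2) i.i.d.

The core of the package is a two-stage volumetric block-matching filter:

1. **Hard-thresholding stage.** For each reference position, cubes of edge
   `L` that are photometrically close to the reference cube — distance
   `d(C_i, C_j) = ||C_i − C_j||² / L³` below a threshold `tau_match` — are
   stacked into a 4-D group. A separable orthonormal 4-D transform (DCT-II
   along each cube axis, Haar along the grouping axis) sparsifies the
   group; coefficients below `sigma · lambda_4D` are zeroed (the DC
   coefficient is always retained). The inverse transform yields one
   estimate per cube, and overlapping estimates are fused by a convex
   combination with group weights `w = 1 / (sigma² N)`, where `N` is the
   number of retained coefficients.
2. **Wiener stage.** The basic estimate is refined by an adaptive local
   Wiener filter, `P = mu + max(0, s² − v²) / max(s², v²) · (P_raw − mu)`,
   applied frame by frame (a group-wise collaborative empirical Wiener mode
   is also provided).

Around the core: a 2-D block-matching filter (BM3D) for amplitude images
and the BM4D→BM3D cascade; conventional comparison filters (Gaussian,
median, local Wiener along each A-scan); amplitude-image extraction, line
profiles, rigid registration (phase correlation plus polar rotation
estimation) and PSNR/SSIM scoring; multi-page TIFF + JSON sidecar I/O; and
a synthetic coin-like phantom so everything is testable without
experimental data.

Intended users: researchers processing volumetric ultrasonic or
photoacoustic scans who need a reference implementation of collaborative
volumetric denoising with a reproducible, fully synthetic benchmark.

## Worked example

```python
import samdenoise as sd

spec  = sd.PhantomSpec(nx=32, ny=32, nt=64, seed=0)
clean = sd.simulate_clean_volume(spec)                     # peak amplitude 100
noisy = sd.add_gaussian_noise(clean, sd.NoiseModel(10.0), seed=7)

config = sd.EvalConfig(bm4d=sd.BM4DParams(sigma=10.0))
report = sd.evaluate_filters(clean, noisy, config)
for name, psnr_db, ssim in report.rows:
    print(f"{name:<12}{psnr_db:>8.2f}{ssim:>8.3f}")
```

prints (PSNR in dB against the clean amplitude image, then SSIM):

```
unfiltered      9.34   0.450
gaussian       -0.22   0.532
median         -3.27   0.051
wiener          6.72   0.461
bm3d            6.99   0.036
bm4d           12.05   0.578
bm4d+bm3d      12.07   0.579
```

The volumetric filter and the cascade lead on both metrics here: they gain
about 3 dB of amplitude PSNR over the raw noisy input on this small raster
(about 9 dB on the full 64×64×128 benchmark) and clearly the highest
structural similarity. The per-scan filters cannot exploit redundancy
across scans and lose echo amplitude (Gaussian, median) or leave residual
noise (Wiener).

The `examples/` directory holds one short script per capability: phantom
simulation, the two-stage filter, the baselines, the cascade, the
evaluation report, and rigid registration. A thin command-line interface
(`samdenoise simulate|denoise|evaluate|profile`) wraps the same functions
for shell use; every run writes a JSON manifest with the resolved
parameters and seeds.

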