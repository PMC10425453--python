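# Methods

## Observation model and scope

A scan volume is a real array `z(x, y, t)` of A-scan samples, modelled as
`z = y + eta` with `eta` i.i.d. zero-mean Gaussian of standard deviation
`sigma`, either known or estimated. All processing operates on raw sampled
amplitudes; no envelope detection, attenuation correction or other acoustic
preprocessing is applied. Arithmetic is float64 internally; volumes are
stored and exchanged as float32.

## The volumetric filter

**Grouping.** Cubes have edge `L = 4`. Reference anchors advance with
stride 3 per axis, with a trailing anchor forced at `dim − L` so every
voxel is covered by at least one cube. Candidates come from a cubic search
window of half-width 5 anchors centred on the reference. The photometric
distance is the sum of squared differences over `L³`; candidates with
distance at most `tau_match` join the group, ordered by distance with
lexicographic tie-breaks (platform-independent determinism), reference
first, capped at `m_max = 16` members. `tau_match` defaults to
`3 sigma²`: for two cubes with identical clean content the distance has
expectation `2 sigma²`, so the default accepts true matches with margin
while rejecting cubes whose clean content differs by more than about
`sigma` per voxel r.m.s.

**Transform.** The group transform is separable and orthonormal: DCT-II
along each cube axis and a Haar transform along the grouping axis. Haar
needs a dyadic length, so group depth is padded to the next power of two by
replicating the last (most distant accepted) member and truncated after
inversion; replication biases the padded spectrum toward real content
rather than toward zero. Orthonormality gives exact Parseval equality,
which the tests exploit.

**Shrinkage and aggregation.** Hard thresholding zeroes coefficients with
magnitude below `sigma · lambda_4D` (`lambda_4D = 2.7`); the DC coefficient
is always retained, so the retained count `N >= 1`. Each group's cube
estimates are accumulated into numerator/denominator buffers with the
scalar weight `1/(sigma² N)` — sparser (better-matched) groups count more —
and the estimate is the voxel-wise ratio. No window is applied to the cube
footprint; the cubes are small enough that blocking artefacts are not a
concern. In the noise-free degenerate case `sigma = 0` every estimate
equals the data, so all weights are set to 1.

**Wiener stage.** Two modes are provided because the natural reading of
the design is ambiguous:

* `local` (default): the adaptive local Wiener filter
  `mu + max(0, s² − v²)/max(s², v²) · (P − mu)` applied to each time frame
  of the basic estimate, window 3×3, edge-replicated. The noise floor `v²`
  is pinned to the known `sigma²` rather than the mean local variance:
  with a known noise level that is the textbook choice, and it makes the
  stage exactly the identity on noise-free input (the mean-local-variance
  default of the standalone `wiener_local` would shrink clean structured
  data). The standalone function keeps mean-of-local-variance as its
  default with an explicit `v2_override` parameter.
* `collaborative`: regroup on the basic estimate (`tau` unchanged) and
  shrink the noisy group spectra by the empirical Wiener gain
  `B²/(B² + sigma²)`, aggregating with weights `1/(sigma² sum W²)`. This is
  the classical second stage of collaborative filtering; it reduces voxel
  MSE further than the local mode on the benchmark but costs a second full
  grouping pass.

The local stage helps when lateral structure is coarse relative to its 3×3
window; on very small rasters it can trade a little voxel MSE near relief
edges for lateral smoothness. Both modes are exercised by the tests.

**Noise estimation.** `estimate_sigma` is the robust median absolute
deviation of temporal first differences scaled by `1/(0.6745 sqrt 2)`. It
assumes the clean signal is smooth along `t` relative to the noise; on the
default phantom it recovers injected sigma within about 13% across
`sigma ∈ [2, 20]`, biased slightly upward by echo-slope leakage. For 2-D
images, `estimate_sigma_image` uses the MAD of the residual against a 5×5
median filter, which still senses noise with a correlation length of a
pixel or two. Neither estimator can see error components smoother than
their differencing scale; in particular, the residual left by a
collaborative denoiser is largely invisible to them, so the cascade's
re-estimated sigma is conservative and the BM3D polish is mild.

## The planar filter and the cascade

`bm3d_denoise` is the same engine one dimension lower: 8×8 blocks, stride
4, search half-width 12, `lambda_3D = 2.7`, distance normalized by `L²`.
It runs the hard-threshold stage only; an optional local Wiener pass is
available behind a flag. The cascade denoises the volume, reduces to an
amplitude image, and passes that image through the planar filter with
sigma re-estimated from the intermediate image.

## Evaluation protocol

The amplitude (C-scan) image is `max_t |A(t)|` per raster position by
default (`peak_to_peak` is available); the choice is a convention, as is
the PSNR/SSIM `peak`, fixed to the dynamic range of the clean reference
image. SSIM uses the standard construction: 11×11 Gaussian window
(sigma 1.5), `K1 = 0.01`, `K2 = 0.03`.

Rigid registration estimates translation by sub-pixel phase correlation
(on lightly smoothed copies) and rotation by circular correlation of
polar-warped images about the shared centre, alternating the two and
folding residuals back into a single final interpolation. Two safeguards
matter on noisy inputs: (i) a candidate transform is accepted only if it
outscores an interpolation-matched null — the moving image transformed
forth and back — because interpolation smooths pixel noise and would
otherwise make spurious rotations of a noisy-but-aligned pair look like
improvements; (ii) estimates below the estimator's resolution (0.06 px,
0.1°) snap to the exact identity, so born-aligned pairs pass through
untouched. Validation is by synthetic transforms: shifts up to ±5 px and
rotations up to ±5° on phantom amplitude images are recovered within
0.06 px / 0.06°.

`evaluate_filters` scores seven rows — unfiltered, Gaussian, median,
Wiener (each along A-scans, window 5 / sigma 1.0), planar BM3D on the
noisy amplitude image, the volumetric filter, and the cascade — all
registered to the clean amplitude image before PSNR/SSIM.

## The phantom

The generator emulates reflection-mode acquisition kinematically: a height
map delays a Ricker (Mexican-hat) pulse per pixel, `A(x, y, t) =
r(x, y) · psi(t − t0 − h(x, y))`, with the base delay `t0` at 25% of the
trace and reflectivity tied linearly to normalized height through a
contrast parameter. The default condition is a 64×64 raster of 128-sample
A-scans, pulse centre frequency 0.125 cycles per sample (8 samples per
period, well below Nyquist and comfortably resolved by 4-sample cubes),
a disc relief of height 10 samples with a ring and three seeded pits, and
contrast 0.3; the clean volume is normalized to peak amplitude 100 so
sigma reads as a percentage of dynamic range. Wavelet support is truncated
where `|psi|` falls below 1e-6 of peak, and specs whose echoes would leave
the trace are rejected. Surface and noise use independent, explicitly
seeded generators so geometry and noise vary factorially.

What the phantom does *not* model: diffraction, focusing, attenuation,
multiple echoes, speckle texture, and acquisition drift. Consequences for
interpretation: the amplitude image of the phantom is piecewise smooth,
which flatters any 2-D filter applied directly to it; real scans carry
fine surface texture that only a volumetric filter can separate from
noise. Passing benchmarks here demonstrates correctness of the machinery
and the qualitative superiority of collaborative volumetric filtering over
per-scan smoothing, not absolute performance figures on experimental data.

## Benchmark sizes and numerical choices

The benchmark runs at 64×64×128 voxels with noise at 10% and 15% of the
clean peak and fixed seeds; one full filter comparison takes well under a
minute per noise level on one CPU, keeping the suite and the reproduction
script desk-scale. Transform round-trips are exact to 1e-8 relative;
identity limits (`lambda = 0`, `sigma = 0`) hold to 1e-6 relative (float64
round-trip dust only). Matching ties break lexicographically; borders are
handled by forced trailing anchors (grouping) and edge replication
(windowed filters). Degenerate inputs are rejected early with specific
exceptions (`ParameterError`, `FormatError`, `CoverageError`,
`RegistrationError`).

## Known limitations

* At mild noise (10–15% of peak) the planar filter applied directly to the
  noisy amplitude image can exceed the volumetric filter's amplitude-image
  PSNR on this phantom, because the phantom's amplitude image is piecewise
  smooth and the `max_t` reduction re-concentrates part of the residual
  the volumetric filter leaves; the volumetric filter still leads clearly
  on SSIM, and at severe noise (30% of peak) it leads on both metrics.
* Relief steps of the order of the pulse wavelength create phase
  discontinuities that grouping cannot bridge; echo amplitude is locally
  attenuated at such edges.
* The sigma estimators are biased upward by strong signal gradients and
  blind to smooth residuals (see above).
* Registration assumes the rotation centre at the image centre and small
  angles (the search spans ±12°).
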