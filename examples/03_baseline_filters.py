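"""Apply the conventional comparison filters to the time-domain signals.

Gaussian smoothing, median filtering and the local adaptive Wiener filter
run independently along every A-scan.  They suppress noise but either blur
the echo (Gaussian, median) or leave residual noise (Wiener); the printed
amplitude-image PSNR quantifies that trade-off.
"""

import numpy as np

import samdenoise as sd

spec = sd.PhantomSpec(nx=32, ny=32, nt=64, seed=0)
clean = sd.simulate_clean_volume(spec)
noisy = sd.add_gaussian_noise(clean, sd.NoiseModel(10.0), seed=7)

ref = sd.amplitude_image(clean).values
peak = float(np.ptp(ref))

outputs = {
    "unfiltered": noisy,
    "gaussian": sd.gaussian_time_filter(noisy, sigma_g=1.0),
    "median": sd.median_time_filter(noisy, window=5),
    "wiener": sd.wiener_time_filter(noisy, window=5),
}
for name, vol in outputs.items():
    img = sd.amplitude_image(vol).values
    print(f"{name:<10} amplitude PSNR {sd.psnr(ref, img, peak):7.2f} dB   "
          f"SSIM {sd.ssim(ref, img, peak):.3f}")
print("Higher is better; per-scan filters cannot use inter-scan redundancy.")
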