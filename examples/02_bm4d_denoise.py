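"""Denoise a noisy scan volume with the two-stage block-matching filter.

Stage 1 groups mutually similar 4x4x4 cubes, shrinks the joint 4-D
transform spectrum by hard thresholding, and fuses the overlapping cube
estimates with sparsity-dependent weights.  Stage 2 refines the result with
an adaptive local Wiener filter.  The mean-squared error against the known
clean volume drops by an order of magnitude or more; on rasters this small
the Wiener stage trades a little voxel MSE near relief edges for smoother
lateral structure.
"""

import numpy as np

import samdenoise as sd

spec = sd.PhantomSpec(nx=32, ny=32, nt=64, seed=0)  # small for a quick demo
clean = sd.simulate_clean_volume(spec)
noisy = sd.add_gaussian_noise(clean, sd.NoiseModel(10.0), seed=7)

params = sd.BM4DParams(sigma=10.0)  # sigma="estimate" infers it from the data
basic = sd.hard_threshold_stage(noisy, params)
final = sd.wiener_stage(basic, noisy, params)


def mse(v):
    return float(np.mean((v.data.astype(float) - clean.data.astype(float)) ** 2))


print(f"MSE vs clean:  noisy {mse(noisy):8.2f}")
print(f"               stage1 {mse(basic):7.2f}   (hard thresholding)")
print(f"               stage2 {mse(final):7.2f}   (Wiener refinement)")
print("Stage 1 does the heavy lifting; stage 2 smooths laterally and may")
print("cost a little voxel MSE at relief edges on small rasters.")
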