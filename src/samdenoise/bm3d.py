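"""Planar block-matching denoiser (BM3D) and the BM4D→BM3D cascade.

The 2-D filter is the one-dimension-lower analogue of the volumetric
hard-threshold stage: ``L^2`` blocks grouped along a third axis, DCT-II per
block axis plus an orthonormal Haar transform along the stack, normalized
photometric distance with an ``L^2`` denominator, and sparsity-weighted
convex aggregation.  Its main use here is polishing the amplitude image of
an already-denoised volume, which in practice outperforms either filter
alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _engine
from .errors import ParameterError
from .volume import Volume

__all__ = ["BM3DParams", "bm3d_denoise", "bm4d_bm3d_cascade", "estimate_sigma_image"]


@dataclass
class BM3DParams:
    """Parameters of the planar filter; one dimension below BM4DParams.

    ``wiener`` enables an optional local adaptive Wiener pass after the
    hard-threshold stage (off by default: the cascade input is already
    denoised).
    """

    block_edge: int = 8
    step: int = 4
    search_radius: int = 12
    tau_match: float | None = None
    m_max: int = 16
    lambda_3d: float = 2.7
    sigma: float | str = "estimate"
    wiener: bool = False
    wiener_window: int = 3

    def __post_init__(self) -> None:
        if self.block_edge < 2:
            raise ParameterError("block_edge must be >= 2")
        if self.step < 1:
            raise ParameterError("step must be >= 1")
        if self.search_radius < 0:
            raise ParameterError("search_radius must be non-negative")
        if self.m_max < 1 or (self.m_max & (self.m_max - 1)) != 0:
            raise ParameterError(f"m_max must be a power of two, got {self.m_max}")
        if self.lambda_3d < 0:
            raise ParameterError("lambda_3d must be non-negative")
        if isinstance(self.sigma, str):
            if self.sigma != "estimate":
                raise ParameterError(
                    f"sigma must be a number or 'estimate', got {self.sigma!r}"
                )
        elif self.sigma < 0:
            raise ParameterError("sigma must be non-negative")
        if self.tau_match is not None and self.tau_match < 0:
            raise ParameterError("tau_match must be non-negative")
        if self.wiener_window < 1 or self.wiener_window % 2 == 0:
            raise ParameterError("wiener_window must be odd and >= 1")

    def resolved(self, img: np.ndarray) -> "BM3DParams":
        sigma = (
            estimate_sigma_image(img) if self.sigma == "estimate" else float(self.sigma)
        )
        tau = 3.0 * sigma * sigma if self.tau_match is None else self.tau_match
        return replace(self, sigma=sigma, tau_match=tau)


def estimate_sigma_image(img: np.ndarray) -> float:
    """Robust noise estimate for a 2-D image, tolerant of correlated noise.

    The image minus its 5x5 median-filtered version leaves (almost) pure
    noise in smooth regions; the median absolute deviation of that residual
    is robust to the minority of structure edges.  Unlike finest-scale
    wavelet estimators, this still senses noise whose correlation length is
    a pixel or two — the character of the residual left by a collaborative
    denoiser, which is what the cascade's second stage has to measure.
    For i.i.d. noise the residual std is inflated by sqrt(1 + 1/25) by the
    median's own variance, hence the correction factor.
    """
    from scipy.ndimage import median_filter

    img = np.asarray(img, dtype=np.float64)
    resid = img - median_filter(img, size=5, mode="nearest")
    mad = float(np.median(np.abs(resid - np.median(resid))))
    return mad / (0.6745 * np.sqrt(1.0 + 1.0 / 25.0))


def bm3d_denoise(img: np.ndarray, p: BM3DParams | None = None) -> np.ndarray:
    """Hard-threshold-stage BM3D on a 2-D image (optional Wiener pass)."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ParameterError("bm3d_denoise expects a 2-D image")
    p = (p or BM3DParams()).resolved(img)
    if any(n < p.block_edge for n in img.shape):
        raise ParameterError(
            f"image {img.shape} smaller than block edge {p.block_edge}"
        )
    out = _engine.hard_threshold_pass(
        img,
        L=p.block_edge,
        step=p.step,
        search_radius=p.search_radius,
        tau=p.tau_match,
        m_max=p.m_max,
        sigma=p.sigma,
        lam=p.lambda_3d,
    )
    if p.wiener:
        from .bm4d import wiener_local

        out = wiener_local(out, p.wiener_window, v2_override=p.sigma ** 2)
    return out


def bm4d_bm3d_cascade(
    z: Volume, p4: "object | None" = None, p3: BM3DParams | None = None
) -> np.ndarray:
    """Denoise the volume with BM4D, reduce to an amplitude image, and
    polish that image with BM3D.

    When the BM3D sigma is ``"estimate"`` it is re-estimated from the
    intermediate amplitude image (the residual noise after BM4D, not the raw
    volume noise).
    """
    from .bm4d import BM4DParams, bm4d_denoise
    from .evaluation import amplitude_image

    p4 = p4 or BM4DParams()
    p3 = p3 or BM3DParams()
    denoised = bm4d_denoise(z, p4)
    img = amplitude_image(denoised).values
    return bm3d_denoise(img, p3)
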