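"""Conventional comparison filters applied to the time-domain signals.

Gaussian smoothing, sliding-window median filtering and the local adaptive
Wiener filter, each applied along every A-scan (the default) or to the full
volume.  These are the standard denoisers the block-matching filter is
benchmarked against.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .errors import ParameterError
from .volume import Volume

__all__ = ["gaussian_time_filter", "median_time_filter", "wiener_time_filter"]

_MODES = ("along_t", "volumetric")


def _check_mode(mode: str) -> None:
    if mode not in _MODES:
        raise ParameterError(f"mode must be one of {_MODES}, got {mode!r}")


def gaussian_time_filter(
    z: Volume, sigma_g: float = 1.0, mode: str = "along_t"
) -> Volume:
    """Gaussian convolution, kernel truncated at 4 sigma, edge-replicated.

    ``along_t`` smooths each A-scan independently; ``volumetric`` applies
    the separable 3-D kernel.
    """
    if not sigma_g > 0:
        raise ParameterError(f"sigma_g must be positive, got {sigma_g}")
    _check_mode(mode)
    data = z.data.astype(np.float64)
    if mode == "along_t":
        out = ndi.gaussian_filter1d(data, sigma_g, axis=2, mode="nearest",
                                    truncate=4.0)
    else:
        out = ndi.gaussian_filter(data, sigma_g, mode="nearest", truncate=4.0)
    return z.with_data(out, provenance="filter:gaussian")


def median_time_filter(z: Volume, window: int = 5, mode: str = "along_t") -> Volume:
    """Sliding-window median with edge replication."""
    if window < 3 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 3, got {window}")
    _check_mode(mode)
    data = z.data.astype(np.float64)
    size = (1, 1, window) if mode == "along_t" else (window,) * 3
    out = ndi.median_filter(data, size=size, mode="nearest")
    return z.with_data(out, provenance="filter:median")


def wiener_time_filter(z: Volume, window: int = 5) -> Volume:
    """Local adaptive Wiener filter applied 1-D along each A-scan.

    Per scan: local mean and variance over the centered window
    (edge-replicated), noise floor ``v^2`` equal to that scan's mean local
    variance, and the gain ``max(0, s2 - v2) / max(s2, v2)``.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 1, got {window}")
    data = z.data.astype(np.float64)
    mu = ndi.uniform_filter1d(data, window, axis=2, mode="nearest")
    s2 = ndi.uniform_filter1d(data * data, window, axis=2, mode="nearest") - mu * mu
    s2 = np.clip(s2, 0.0, None)
    v2 = s2.mean(axis=2, keepdims=True)
    num = np.maximum(0.0, s2 - v2)
    den = np.maximum(s2, v2)
    gain = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    out = mu + gain * (data - mu)
    return z.with_data(out, provenance="filter:wiener")
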