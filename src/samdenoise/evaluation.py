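"""Amplitude images, rigid registration and PSNR/SSIM scoring.

A C-scan amplitude image reduces each A-scan to a scalar (by default the
maximum absolute amplitude), giving the 2-D map that quality metrics are
computed on.  Because a real reference scan and a noisy scan are acquired in
separate passes, they can be slightly translated/rotated against each other;
images are therefore rigidly registered to the reference before PSNR and
SSIM are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.metrics import structural_similarity
from skimage.registration import phase_cross_correlation

from .errors import ParameterError, RegistrationError
from .volume import Volume

__all__ = [
    "AmplitudeImage",
    "RegistrationResult",
    "QualityReport",
    "EvalConfig",
    "amplitude_image",
    "line_profile",
    "psnr",
    "ssim",
    "register_rigid",
    "evaluate_filters",
    "FILTER_NAMES",
]

REDUCTIONS = ("max_abs", "peak_to_peak")

#: Filters scored by :func:`evaluate_filters`, in report order.
FILTER_NAMES = ("unfiltered", "gaussian", "median", "wiener",
                "bm3d", "bm4d", "bm4d+bm3d")


@dataclass
class AmplitudeImage:
    """2-D C-scan map (x, y) plus the reduction that produced it."""

    values: np.ndarray
    reduction: str = "max_abs"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ParameterError("amplitude image must be 2-D")


@dataclass
class RegistrationResult:
    """Estimated rigid correction mapping ``moving`` onto ``ref``.

    ``registered = shift(rotate(moving, theta), (dx, dy))`` with bilinear
    interpolation; ``success_metric`` is the normalized cross-correlation of
    the registered image with the reference.
    """

    dx: float
    dy: float
    theta: float
    registered: np.ndarray
    success_metric: float


@dataclass
class QualityReport:
    """Per-filter PSNR/SSIM rows, one per scored filter."""

    rows: list[tuple[str, float, float]] = field(default_factory=list)

    def add(self, name: str, psnr_db: float, ssim_val: float) -> None:
        self.rows.append((name, float(psnr_db), float(ssim_val)))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows, columns=["filter", "psnr_db", "ssim"])

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {name: (p, s) for name, p, s in self.rows}


def amplitude_image(v: Volume, reduction: str = "max_abs") -> AmplitudeImage:
    """Reduce each A-scan to a scalar amplitude.

    ``max_abs`` (default): ``max_t |A(t)|``.  ``peak_to_peak``:
    ``max_t A - min_t A``.
    """
    if reduction not in REDUCTIONS:
        raise ParameterError(f"unknown reduction {reduction!r}; expected {REDUCTIONS}")
    data = v.data.astype(np.float64)
    if reduction == "max_abs":
        img = np.max(np.abs(data), axis=2)
    else:
        img = np.max(data, axis=2) - np.min(data, axis=2)
    return AmplitudeImage(img, reduction)


def line_profile(img: np.ndarray, row: int) -> np.ndarray:
    """Amplitude along x at a fixed raster line y = ``row``."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ParameterError("line profile expects a 2-D image")
    if not 0 <= row < img.shape[1]:
        raise ParameterError(f"row {row} outside [0, {img.shape[1]})")
    return img[:, row].copy()


def psnr(ref: np.ndarray, test: np.ndarray, peak: float) -> float:
    """Peak signal-to-noise ratio ``10 log10(peak^2 / MSE)`` in dB.

    Returns ``inf`` for identical images.
    """
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ParameterError(f"shapes differ: {ref.shape} vs {test.shape}")
    if not peak > 0:
        raise ParameterError(f"peak must be positive, got {peak}")
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak * peak / mse))


def ssim(ref: np.ndarray, test: np.ndarray, peak: float) -> float:
    """Mean structural similarity with the standard construction:
    11x11 Gaussian window (sigma 1.5), stabilizers ``C1 = (0.01 peak)^2`` and
    ``C2 = (0.03 peak)^2``."""
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ParameterError(f"shapes differ: {ref.shape} vs {test.shape}")
    if min(ref.shape) < 11:
        raise ParameterError("ssim needs images of at least 11 pixels per axis")
    if not peak > 0:
        raise ParameterError(f"peak must be positive, got {peak}")
    return float(
        structural_similarity(
            ref,
            test,
            data_range=peak,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
        )
    )


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.sum(a * b) / denom)


def _transform(moving: np.ndarray, theta: float, shift: np.ndarray) -> np.ndarray:
    out = moving
    if theta != 0.0:
        out = ndi.rotate(out, theta, reshape=False, order=1, mode="nearest")
    if np.any(shift != 0.0):
        out = ndi.shift(out, shift, order=1, mode="nearest")
    return out


def register_rigid(ref: np.ndarray, moving: np.ndarray) -> RegistrationResult:
    """Estimate the rigid correction aligning ``moving`` with ``ref``.

    Translation comes from sub-pixel phase correlation; rotation from the
    circular correlation of polar-warped images, iterated with the
    translation estimate.  A candidate transform is accepted only if it
    outscores an interpolation-matched null (the moving image transformed
    forth and back), so interpolation smoothing of noise cannot masquerade
    as alignment; sub-resolution estimates snap to the exact identity.
    Deterministic: no stochastic optimizer is involved.
    """
    ref = np.asarray(ref, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if ref.shape != moving.shape:
        raise ParameterError(f"shapes differ: {ref.shape} vs {moving.shape}")
    if np.ptp(ref) == 0 or np.ptp(moving) == 0:
        raise RegistrationError("constant image: rigid registration undefined")

    def smooth(a: np.ndarray) -> np.ndarray:
        return ndi.gaussian_filter(a, 1.0, mode="nearest")

    def rotate(a: np.ndarray, th: float) -> np.ndarray:
        if th == 0.0:
            return a
        return ndi.rotate(a, th, reshape=False, order=1, mode="nearest")

    ref_s = smooth(ref)
    p_ref = _polar_detail(ref_s)
    p_norm = float(np.sqrt(np.sum(p_ref * p_ref)))

    def ncc_s(img: np.ndarray) -> float:
        return _ncc(ref_s, smooth(img))

    def est_shift(img: np.ndarray) -> np.ndarray:
        shift, _, _ = phase_cross_correlation(ref_s, smooth(img),
                                              upsample_factor=50)
        return shift

    def apply_shift(img: np.ndarray, shift: np.ndarray) -> np.ndarray:
        if not np.any(shift):
            return img
        return ndi.shift(img, shift, order=1, mode="nearest")

    # Alternate translation (phase correlation) and rotation (circular
    # correlation of polar-warped images about the shared center) until the
    # rotation update is negligible.
    theta = 0.0
    for _ in range(3):
        rot_m = rotate(moving, theta)
        centered = apply_shift(rot_m, est_shift(rot_m))
        d_theta = _polar_rotation(p_ref, p_norm, _polar_detail(smooth(centered)))
        theta += d_theta
        if abs(d_theta) < 0.02:
            break

    # Interpolation during rotation smooths pixel noise, which by itself
    # raises the correlation of noisy image pairs; accept the rotation only
    # if it beats a null carrying the same interpolation footprint but no
    # net rotation (moving rotated forth and back).
    if theta != 0.0:
        cand = rotate(moving, theta)
        null = rotate(rotate(moving, -theta), theta)
        if ncc_s(apply_shift(cand, est_shift(cand))) <= ncc_s(
            apply_shift(null, est_shift(null))
        ):
            theta = 0.0
    if abs(theta) <= 0.10:  # the estimator's angular reproducibility floor
        theta = 0.0

    rot_m = rotate(moving, theta)
    shift = est_shift(rot_m)
    # the analogous null for translation (shift forth and back)
    if np.any(shift):
        shifted = apply_shift(rot_m, shift)
        null = apply_shift(shifted, -shift)
        if ncc_s(shifted) <= ncc_s(null):
            shift = np.zeros(2)
    shift = np.where(np.abs(shift) <= 0.06, 0.0, shift)

    dx, dy = float(shift[0]), float(shift[1])
    if theta == 0.0 and dx == 0.0 and dy == 0.0:
        registered = moving.copy()
    else:
        registered = _transform(moving, theta, np.array([dx, dy]))
        # fold residual rotation/translation of the registered image back
        # into the estimate (the final image is still interpolated once)
        for _ in range(3):
            d_theta = _polar_rotation(p_ref, p_norm,
                                      _polar_detail(smooth(registered)))
            if abs(d_theta) > 0.03 and theta != 0.0:
                theta += d_theta
            resid = est_shift(registered)
            resid = np.where(np.abs(resid) <= 0.02, 0.0, resid)
            if abs(d_theta) <= 0.03 and not np.any(resid):
                break
            dx += float(resid[0])
            dy += float(resid[1])
            registered = _transform(moving, theta, np.array([dx, dy]))
    return RegistrationResult(dx=dx, dy=dy, theta=theta, registered=registered,
                              success_metric=_ncc(ref, registered))


_POLAR_ANGLES = 1440  # 0.25 degrees per bin; parabolic peak fit goes finer


def _polar_detail(img: np.ndarray) -> np.ndarray:
    """Polar warp of an image about its center, prepared for rotation search.

    The over-sampled central region is dropped, the circularly symmetric
    component (uninformative about rotation) is removed per radius, and
    radii are weighted by the square root of their arc length so every image
    pixel contributes roughly equally.
    """
    from skimage.transform import warp_polar

    radius = min(img.shape) // 2 - 2
    inner = radius // 4
    p = warp_polar(img, radius=radius, output_shape=(_POLAR_ANGLES, radius))
    p = p[:, inner:]
    p = p - p.mean(axis=0, keepdims=True)
    return p * np.sqrt(np.arange(inner, radius, dtype=np.float64))


def _polar_rotation(p_ref: np.ndarray, p_norm: float, p_mov: np.ndarray,
                    max_bins: int = 48) -> float:
    """Rotation angle maximizing the circular correlation along the angle
    axis, refined by a parabolic fit around the best integer bin."""
    m_norm = float(np.sqrt(np.sum(p_mov * p_mov)))
    if p_norm == 0.0 or m_norm == 0.0:
        return 0.0
    ks = np.arange(-max_bins, max_bins + 1)
    cs = np.array(
        [np.sum(p_ref * np.roll(p_mov, k, axis=0)) for k in ks]
    ) / (p_norm * m_norm)
    i = int(np.argmax(cs))
    k = float(ks[i])
    if 0 < i < len(ks) - 1:
        den = cs[i - 1] - 2 * cs[i] + cs[i + 1]
        if den != 0.0:
            k += (cs[i - 1] - cs[i + 1]) / (2.0 * den)
    return -k * 360.0 / _POLAR_ANGLES


@dataclass
class EvalConfig:
    """Parameters of the filter-comparison protocol."""

    reduction: str = "max_abs"
    register: bool = True
    gaussian_sigma: float = 1.0
    median_window: int = 5
    wiener_window: int = 5
    bm4d: "object | None" = None   # BM4DParams
    bm3d: "object | None" = None   # BM3DParams


def _score(report: QualityReport, name: str, clean_img: np.ndarray,
           img: np.ndarray, peak: float, do_register: bool) -> None:
    if do_register:
        try:
            img = register_rigid(clean_img, img).registered
        except RegistrationError:
            pass
    report.add(name, psnr(clean_img, img, peak), ssim(clean_img, img, peak))


def evaluate_filters(clean: Volume, noisy: Volume,
                     config: EvalConfig | None = None) -> QualityReport:
    """Score every comparison filter on the amplitude image.

    Each filter's output is reduced to an amplitude image, rigidly
    registered to the clean reference image, and scored by PSNR and SSIM
    with ``peak`` equal to the reference image's dynamic range.  The report
    carries one row per filter plus an ``unfiltered`` baseline row.
    """
    from .baselines import (gaussian_time_filter, median_time_filter,
                            wiener_time_filter)
    from .bm3d import BM3DParams, bm3d_denoise
    from .bm4d import BM4DParams, bm4d_denoise

    if clean.shape != noisy.shape:
        raise ParameterError("clean and noisy volumes must share a shape")
    cfg = config or EvalConfig()
    p4 = cfg.bm4d or BM4DParams()
    p3 = cfg.bm3d or BM3DParams()

    clean_img = amplitude_image(clean, cfg.reduction).values
    peak = float(np.ptp(clean_img))
    if peak == 0:
        peak = max(float(np.max(np.abs(clean_img))), 1.0)

    report = QualityReport()

    def amp(v: Volume) -> np.ndarray:
        return amplitude_image(v, cfg.reduction).values

    noisy_img = amp(noisy)
    _score(report, "unfiltered", clean_img, noisy_img, peak, cfg.register)
    _score(report, "gaussian", clean_img,
           amp(gaussian_time_filter(noisy, cfg.gaussian_sigma)), peak, cfg.register)
    _score(report, "median", clean_img,
           amp(median_time_filter(noisy, cfg.median_window)), peak, cfg.register)
    _score(report, "wiener", clean_img,
           amp(wiener_time_filter(noisy, cfg.wiener_window)), peak, cfg.register)
    _score(report, "bm3d", clean_img,
           bm3d_denoise(noisy_img, p3), peak, cfg.register)
    bm4d_vol = bm4d_denoise(noisy, p4)
    bm4d_img = amp(bm4d_vol)
    _score(report, "bm4d", clean_img, bm4d_img, peak, cfg.register)
    p3c = p3
    _score(report, "bm4d+bm3d", clean_img,
           bm3d_denoise(bm4d_img, p3c), peak, cfg.register)
    return report
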