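"""Synthetic scanning-acoustic-microscopy phantom.

Reflection-mode acoustic microscopy raster-scans a focused transducer over a
sample and records, at each lateral position, the echo returned by the
surface: an A-scan.  The phantom emulates that acquisition kinematically: a
2-D relief surface delays a Mexican-hat (Ricker) excitation pulse per pixel,
a reflectivity map scales its amplitude, and i.i.d. zero-mean Gaussian noise
of known standard deviation is added on top — the observation model
``z = y + eta`` with ``eta ~ N(0, sigma^2)``.

No wave physics (diffraction, attenuation, lens geometry) is modelled: for
exercising a denoiser, the echo's position, shape and amplitude are what
matter.

The clean volume is normalized to peak amplitude ``PEAK_AMPLITUDE`` (100), so
noise levels read directly as a percentage of dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .volume import Volume

__all__ = [
    "PEAK_AMPLITUDE",
    "SURFACE_KINDS",
    "PhantomSpec",
    "NoiseModel",
    "ricker_wavelet",
    "wavelet_half_support",
    "make_surface",
    "simulate_clean_volume",
    "add_gaussian_noise",
    "default_benchmark_spec",
]

#: Peak absolute amplitude of the normalized clean signal.
PEAK_AMPLITUDE = 100.0

SURFACE_KINDS = ("disc_relief", "smooth_random", "flat")

#: Echo delay of the flat reference surface, as a fraction of the time axis.
_BASE_DELAY_FRACTION = 0.25

#: Wavelet support is truncated where |psi| falls below this fraction of peak.
_SUPPORT_TOL = 1e-6


@dataclass
class PhantomSpec:
    """Geometry and acquisition parameters of a synthetic scan.

    Defaults describe the package's benchmark condition: a 64x64 raster of
    128-sample A-scans with a coin-like embossed disc relief, pulse center
    frequency 0.125 cycles per sample (8 samples per period, comfortably
    below Nyquist), and a moderate reflectivity contrast.
    """

    nx: int = 64
    ny: int = 64
    nt: int = 128
    fc: float = 0.125          # wavelet center frequency, cycles per time unit
    dt: float = 1.0            # sampling interval, time units
    surface_kind: str = "disc_relief"
    relief_height: float = 10.0        # time-of-flight offset amplitude
    reflectivity_contrast: float = 0.3  # in [0, 1]
    base_reflectivity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nx", "ny", "nt"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ParameterError(f"{name} must be a positive integer, got {v!r}")
        if not self.fc > 0:
            raise ParameterError(f"fc must be positive, got {self.fc}")
        if not self.dt > 0:
            raise ParameterError(f"dt must be positive, got {self.dt}")
        if self.fc >= 1.0 / (2.0 * self.dt):
            raise ParameterError(
                f"fc={self.fc} violates the sampling limit 1/(2*dt)={1/(2*self.dt)}"
            )
        if self.surface_kind not in SURFACE_KINDS:
            raise ParameterError(
                f"unknown surface_kind {self.surface_kind!r}; expected one of {SURFACE_KINDS}"
            )
        if not 0.0 <= self.reflectivity_contrast <= 1.0:
            raise ParameterError(
                f"reflectivity_contrast must lie in [0, 1], got {self.reflectivity_contrast}"
            )


@dataclass
class NoiseModel:
    """Additive i.i.d. Gaussian noise of standard deviation ``sigma``."""

    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma >= 0:
            raise ParameterError(f"sigma must be non-negative, got {self.sigma}")


def ricker_wavelet(fc: float, t: np.ndarray) -> np.ndarray:
    """Mexican-hat (Ricker) pulse, ``psi(t) = (1 - 2 pi^2 fc^2 t^2) exp(-pi^2 fc^2 t^2)``.

    Normalized to peak value 1 at ``t = 0``.  ``fc`` is the center frequency
    in cycles per time unit.
    """
    if not fc > 0:
        raise ParameterError(f"fc must be positive, got {fc}")
    t = np.asarray(t, dtype=np.float64)
    a = (np.pi * fc) ** 2 * t * t
    return (1.0 - 2.0 * a) * np.exp(-a)


def wavelet_half_support(fc: float, tol: float = _SUPPORT_TOL) -> float:
    """Half-width beyond which ``|psi|`` stays below ``tol`` times its peak."""
    # |psi| is bounded by (1 + 2u) e^{-u}, u = (pi fc t)^2; solve on a grid.
    u = np.linspace(0.0, 60.0, 60001)
    env = (1.0 + 2.0 * u) * np.exp(-u)
    idx = np.searchsorted(-env, -tol)  # env is decreasing for u >= 0.5
    u_star = u[min(idx, len(u) - 1)]
    return float(np.sqrt(u_star) / (np.pi * fc))


def make_surface(spec: PhantomSpec) -> np.ndarray:
    """Height map (time units) of shape ``(nx, ny)``, deterministic per seed.

    ``disc_relief`` embosses a centered disc with a ring and a few seeded
    pits, loosely mimicking a small coin; ``smooth_random`` is a low-pass
    Gaussian random field with ``max|h| <= relief_height``; ``flat`` is zero.
    """
    h = float(spec.relief_height)
    x = np.arange(spec.nx, dtype=np.float64)[:, None]
    y = np.arange(spec.ny, dtype=np.float64)[None, :]
    cx, cy = (spec.nx - 1) / 2.0, (spec.ny - 1) / 2.0
    r = np.hypot(x - cx, y - cy)
    rmax = 0.5 * min(spec.nx, spec.ny)

    if spec.surface_kind == "flat":
        return np.zeros((spec.nx, spec.ny))

    if spec.surface_kind == "smooth_random":
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(spec.seed)
        field = rng.standard_normal((spec.nx, spec.ny))
        field = gaussian_filter(field, sigma=min(spec.nx, spec.ny) / 10.0,
                                mode="wrap")
        peak = np.max(np.abs(field))
        if peak > 0:
            field *= h / peak
        return field

    # disc_relief: a coin-like emboss — raised disc, a ring, a few seeded pits
    rng = np.random.default_rng(spec.seed)
    surf = np.zeros((spec.nx, spec.ny))
    disc = 0.72 * rmax
    surf[r <= disc] = 0.7 * h
    ring = (r >= 0.50 * rmax) & (r <= 0.60 * rmax)
    surf[ring] += 0.3 * h
    for _ in range(3):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.10, 0.38) * rmax
        px, py = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
        pit = np.hypot(x - px, y - py) <= 0.12 * rmax
        surf[pit] = 0.4 * h
    return surf


def _reflectivity_map(spec: PhantomSpec, surface: np.ndarray) -> np.ndarray:
    """Per-pixel echo reflectivity tied to the relief pattern."""
    span = np.ptp(surface)
    if span > 0:
        pattern = (surface - surface.min()) / span
    else:
        pattern = np.zeros_like(surface)
    return spec.base_reflectivity * (1.0 - spec.reflectivity_contrast * pattern)


def simulate_clean_volume(spec: PhantomSpec) -> Volume:
    """Noise-free phantom volume.

    The A-scan at raster position ``(x, y)`` is
    ``reflectivity(x, y) * psi(t - t0 - height(x, y))`` with the base delay
    ``t0`` at 25% of the time axis.  The result is normalized to peak
    absolute amplitude :data:`PEAK_AMPLITUDE` (skipped for an all-zero
    volume).
    """
    surface = make_surface(spec)
    refl = _reflectivity_map(spec, surface)
    t0 = _BASE_DELAY_FRACTION * spec.nt * spec.dt
    delay = t0 + surface
    support = wavelet_half_support(spec.fc)
    t_max = (spec.nt - 1) * spec.dt
    if np.max(delay) + support > t_max:
        raise ParameterError(
            f"echo delay {np.max(delay):.1f} plus wavelet support {support:.1f} "
            f"exceeds the time axis span {t_max:.1f}"
        )
    if np.min(delay) - support < 0:
        raise ParameterError("echo arrives before the start of the time axis")

    t = np.arange(spec.nt, dtype=np.float64) * spec.dt
    data = refl[:, :, None] * ricker_wavelet(
        spec.fc, t[None, None, :] - delay[:, :, None]
    )
    peak = np.max(np.abs(data))
    if peak > 0:
        data *= PEAK_AMPLITUDE / peak
    return Volume(data, dt=spec.dt, provenance="phantom:clean",
                  meta={"surface_kind": spec.surface_kind, "seed": spec.seed})


def add_gaussian_noise(v: Volume, noise: NoiseModel, seed: int) -> Volume:
    """Observation ``z = y + eta`` with ``eta`` i.i.d. ``N(0, sigma^2)``.

    ``seed`` governs the noise realization only and is independent of the
    surface seed, so noise and geometry can be varied factorially.
    """
    if noise.sigma == 0:
        return v.with_data(v.data.copy(), provenance=v.provenance)
    rng = np.random.default_rng(seed)
    eta = rng.normal(0.0, noise.sigma, size=v.shape)
    return v.with_data(
        v.data.astype(np.float64) + eta,
        provenance="phantom:noisy",
    )


def default_benchmark_spec(seed: int = 0) -> PhantomSpec:
    """The default 64x64x128 disc-relief benchmark condition."""
    return PhantomSpec(seed=seed)
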