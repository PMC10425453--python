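"""Two-stage volumetric block-matching denoiser (BM4D).

The filter exploits nonlocal self-similarity in a 3-D scan.  Stage 1
(hard thresholding): for each reference position, cubes of edge ``L`` that
are photometrically close to the reference cube are stacked into a 4-D
group; a separable orthonormal 4-D transform sparsifies the group, small
coefficients are zeroed at threshold ``sigma * lambda_4d``, and the inverse
transform yields one estimate per cube.  Overlapping estimates are fused by
a convex combination whose per-group weight ``1/(sigma^2 N)`` rewards sparse
(well-correlated) groups.  Stage 2 refines the basic estimate with Wiener
filtering — by default the local adaptive (mean/variance) filter applied
frame by frame, optionally a group-wise collaborative empirical Wiener pass.

The observation model is additive i.i.d. Gaussian noise of standard
deviation ``sigma``, which may be given or estimated from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import uniform_filter

from . import _engine
from .errors import ParameterError
from .volume import Volume

__all__ = [
    "Cube",
    "SimilaritySet",
    "Group",
    "GroupSpectrum",
    "AggregationBuffer",
    "BM4DParams",
    "cube_distance",
    "match_cubes",
    "build_group",
    "transform_group",
    "hard_threshold",
    "group_weight",
    "aggregate",
    "finalize_estimate",
    "hard_threshold_stage",
    "wiener_local",
    "wiener_stage",
    "estimate_sigma",
    "bm4d_denoise",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Cube:
    """An ``L^3`` sub-volume anchored at its minimal corner (0-based)."""

    values: np.ndarray
    anchor: tuple[int, int, int]
    L: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.L < 2:
            raise ParameterError(f"cube edge must be >= 2, got {self.L}")
        if self.values.shape != (self.L,) * 3:
            raise ParameterError(
                f"cube values shape {self.values.shape} != ({self.L},)*3"
            )


@dataclass
class SimilaritySet:
    """Anchors of mutually similar cubes; the reference is always first."""

    coords: list[tuple[int, int, int]]
    tau_match: float
    distances: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.coords:
            raise ParameterError("similarity set cannot be empty")
        if len(set(self.coords)) != len(self.coords):
            raise ParameterError("similarity set has duplicate coordinates")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class Group:
    """4-D stack (L, L, L, M) of the cubes of a similarity set, in order."""

    stack: np.ndarray

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=np.float64)
        if self.stack.ndim != 4 or self.stack.shape[-1] < 1:
            raise ParameterError("group stack must be 4-D with depth >= 1")

    @property
    def depth(self) -> int:
        return self.stack.shape[-1]


@dataclass
class GroupSpectrum:
    """Hard-thresholded 4-D coefficients plus the retained count ``N``."""

    coeffs: np.ndarray
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_retained < 1:
            raise ParameterError("n_retained must be >= 1 (DC is always kept)")


@dataclass
class AggregationBuffer:
    """Running numerator / denominator of the convex aggregation."""

    numerator: np.ndarray
    denominator: np.ndarray

    @classmethod
    def for_shape(cls, shape: tuple[int, ...]) -> "AggregationBuffer":
        return cls(np.zeros(shape), np.zeros(shape))


@dataclass
class BM4DParams:
    """Tunable parameters of the volumetric denoiser.

    ``sigma`` is the noise standard deviation on the working intensity
    scale, or the literal string ``"estimate"`` to infer it from the data.
    ``tau_match_ht`` defaults to ``3 sigma^2``: for two cubes with identical
    clean content the expected normalized distance is ``2 sigma^2``, so
    ``3 sigma^2`` accepts true matches with margin.
    """

    L: int = 4
    step: int = 3
    search_radius: int = 5
    tau_match_ht: float | None = None
    m_max: int = 16
    lambda_4d: float = 2.7
    wiener_mode: str = "local"
    wiener_window: int = 3
    sigma: float | str = "estimate"

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ParameterError(f"L must be >= 2, got {self.L}")
        if self.step < 1:
            raise ParameterError(f"step must be >= 1, got {self.step}")
        if self.search_radius < 0:
            raise ParameterError("search_radius must be non-negative")
        if self.m_max < 1 or (self.m_max & (self.m_max - 1)) != 0:
            raise ParameterError(f"m_max must be a power of two, got {self.m_max}")
        if self.lambda_4d < 0:
            raise ParameterError("lambda_4d must be non-negative")
        if self.wiener_mode not in ("local", "collaborative"):
            raise ParameterError(
                f"wiener_mode must be 'local' or 'collaborative', got {self.wiener_mode!r}"
            )
        if self.wiener_window < 1 or self.wiener_window % 2 == 0:
            raise ParameterError("wiener_window must be odd and >= 1")
        if isinstance(self.sigma, str):
            if self.sigma != "estimate":
                raise ParameterError(
                    f"sigma must be a number or 'estimate', got {self.sigma!r}"
                )
        elif self.sigma < 0:
            raise ParameterError("sigma must be non-negative")
        if self.tau_match_ht is not None and self.tau_match_ht < 0:
            raise ParameterError("tau_match_ht must be non-negative")

    def resolved(self, z: Volume) -> "BM4DParams":
        """Concrete parameters for a given volume: sigma estimated if asked,
        tau_match_ht filled with its ``3 sigma^2`` default."""
        sigma = estimate_sigma(z) if self.sigma == "estimate" else float(self.sigma)
        tau = 3.0 * sigma * sigma if self.tau_match_ht is None else self.tau_match_ht
        return replace(self, sigma=sigma, tau_match_ht=tau)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def cube_distance(a: Cube, b: Cube) -> float:
    """Photometric distance: sum of squared differences over ``L^3``."""
    if a.L != b.L:
        raise ParameterError(f"cube sizes differ: {a.L} vs {b.L}")
    return _engine.block_distance(a.values, b.values)


def extract_cube(v: Volume, anchor: tuple[int, int, int], L: int) -> Cube:
    """The cube of edge ``L`` whose minimal corner is ``anchor``."""
    ax, ay, at = (int(c) for c in anchor)
    nx, ny, nt = v.shape
    if not (0 <= ax <= nx - L and 0 <= ay <= ny - L and 0 <= at <= nt - L):
        raise ParameterError(f"anchor {anchor} with L={L} outside volume {v.shape}")
    return Cube(v.data[ax:ax + L, ay:ay + L, at:at + L], (ax, ay, at), L)


def match_cubes(v: Volume, ref: tuple[int, int, int], p: BM4DParams) -> SimilaritySet:
    """Cubes within the search window whose distance to the reference is at
    most ``tau_match_ht``, ordered by (distance, lexicographic coordinate),
    reference first, capped at ``m_max``."""
    if p.tau_match_ht is None or isinstance(p.sigma, str):
        p = p.resolved(v)
    extract_cube(v, ref, p.L)  # bounds check
    windows = sliding_window_view(v.data.astype(np.float64), (p.L,) * 3)
    coords, dists = _engine.match_window(
        windows, tuple(ref), p.search_radius, p.tau_match_ht, p.m_max
    )
    return SimilaritySet(
        coords=[tuple(int(c) for c in row) for row in coords],
        tau_match=float(p.tau_match_ht),
        distances=[float(d) for d in dists],
    )


def build_group(v: Volume, s: SimilaritySet, L: int) -> Group:
    """Stack the cubes of a similarity set along a fourth axis, in order."""
    stack = np.empty((L, L, L, len(s)), dtype=np.float64)
    for m, coord in enumerate(s.coords):
        stack[..., m] = extract_cube(v, coord, L).values
    return Group(stack)


def transform_group(
    g: Group | np.ndarray, direction: str, depth: int | None = None
) -> np.ndarray:
    """Separable orthonormal 4-D group transform.

    ``forward`` pads the grouping axis to the next power of two by
    replicating the last cube, then applies DCT-II along each cube axis and
    an orthonormal Haar transform along the grouping axis.  ``inverse``
    undoes the transform and, when ``depth`` is given, truncates the
    grouping axis back to the original depth.
    """
    arr = g.stack if isinstance(g, Group) else np.asarray(g, dtype=np.float64)
    if arr.ndim != 4:
        raise ParameterError("group transform expects a 4-D array")
    if direction == "forward":
        return _engine.forward_spectrum(_engine.pad_group(arr))
    if direction == "inverse":
        out = _engine.inverse_spectrum(arr)
        return out if depth is None else out[..., :depth]
    raise ParameterError(f"direction must be 'forward' or 'inverse', got {direction!r}")


def hard_threshold(spec: np.ndarray, sigma: float, lambda_4d: float) -> GroupSpectrum:
    """Zero coefficients below ``sigma * lambda_4d``; DC always retained."""
    if sigma < 0 or lambda_4d < 0:
        raise ParameterError("sigma and lambda_4d must be non-negative")
    coeffs, n_ret = _engine.hard_threshold_spectrum(
        np.asarray(spec, dtype=np.float64), sigma * lambda_4d
    )
    return GroupSpectrum(coeffs, n_ret)


def group_weight(sigma: float, n_retained: int) -> float:
    """Sparsity weight ``1/(sigma^2 N)``; 1 in the noise-free case."""
    return _engine.group_weight(sigma, n_retained)


def aggregate(
    buf: AggregationBuffer, estimates: Group, s: SimilaritySet, w: float
) -> AggregationBuffer:
    """Accumulate one group's cube estimates into the aggregation buffers:
    ``numerator += w * cube`` and ``denominator += w`` on each footprint.
    No window is applied to the cube (cubes are small)."""
    L = estimates.stack.shape[0]
    if estimates.depth != len(s):
        raise ParameterError("group depth does not match similarity set size")
    for m, coord in enumerate(s.coords):
        sl = tuple(slice(c, c + L) for c in coord)
        buf.numerator[sl] += w * estimates.stack[..., m]
        buf.denominator[sl] += w
    return buf


def finalize_estimate(buf: AggregationBuffer) -> np.ndarray:
    """Voxel-wise ``numerator / denominator`` of the convex combination."""
    if np.any(buf.denominator <= 0):
        from .errors import CoverageError

        raise CoverageError("zero aggregation weight at some voxel")
    return buf.numerator / buf.denominator


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def hard_threshold_stage(z: Volume, p: BM4DParams) -> Volume:
    """Stage 1: grouping, 4-D hard thresholding and weighted aggregation.

    Reference anchors advance by ``p.step`` per axis with a trailing anchor
    forced at ``dim - L`` so every voxel is covered by at least one cube.
    """
    p = p.resolved(z)
    out = _engine.hard_threshold_pass(
        z.data,
        L=p.L,
        step=p.step,
        search_radius=p.search_radius,
        tau=p.tau_match_ht,
        m_max=p.m_max,
        sigma=p.sigma,
        lam=p.lambda_4d,
    )
    return z.with_data(out, provenance="bm4d:basic")


def wiener_local(
    a: np.ndarray, window: int, v2_override: float | None = None
) -> np.ndarray:
    """Local adaptive Wiener filter (any dimensionality).

    Per element, with local mean ``mu`` and local variance ``s2`` over the
    centered window (edge-replicated borders) and noise floor ``v2`` (the
    mean of ``s2`` over the whole array unless overridden)::

        out = mu + max(0, s2 - v2) / max(s2, v2) * (a - mu)

    Elements whose local variance does not exceed the noise floor collapse
    to the local mean.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 1, got {window}")
    a = np.asarray(a, dtype=np.float64)
    mu = uniform_filter(a, size=window, mode="nearest")
    s2 = uniform_filter(a * a, size=window, mode="nearest") - mu * mu
    s2 = np.clip(s2, 0.0, None)
    v2 = float(np.mean(s2)) if v2_override is None else float(v2_override)
    if v2 < 0:
        raise ParameterError("v2_override must be non-negative")
    num = np.maximum(0.0, s2 - v2)
    den = np.maximum(s2, v2)
    gain = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return mu + gain * (a - mu)


def wiener_stage(basic: Volume, noisy: Volume, p: BM4DParams) -> Volume:
    """Stage 2: Wiener refinement of the basic estimate.

    ``local`` (default) applies the adaptive local Wiener filter to each
    time frame of the basic estimate, with the noise floor pinned to the
    known ``sigma^2`` (so the stage is the identity on noise-free data).
    ``collaborative`` regroups on the basic estimate and applies empirical
    Wiener shrinkage ``B^2/(B^2 + sigma^2)`` to the noisy group spectra.
    """
    if basic.shape != noisy.shape:
        raise ParameterError(
            f"basic {basic.shape} and noisy {noisy.shape} shapes differ"
        )
    p = p.resolved(noisy)
    if p.wiener_mode == "local":
        out = np.empty(basic.shape, dtype=np.float64)
        bdata = basic.data.astype(np.float64)
        v2 = float(p.sigma) ** 2
        for t in range(basic.nt):
            out[:, :, t] = wiener_local(bdata[:, :, t], p.wiener_window,
                                        v2_override=v2)
        return basic.with_data(out, provenance="bm4d:final")
    out = _engine.collaborative_wiener_pass(
        noisy.data,
        basic.data,
        L=p.L,
        step=p.step,
        search_radius=p.search_radius,
        tau=p.tau_match_ht,
        m_max=p.m_max,
        sigma=p.sigma,
    )
    return basic.with_data(out, provenance="bm4d:final")


def estimate_sigma(z: Volume) -> float:
    """Robust noise estimate from first differences along the time axis.

    For i.i.d. Gaussian noise the temporal first difference has standard
    deviation ``sigma * sqrt(2)``; the median absolute deviation divided by
    0.6745 estimates it robustly as long as the clean signal is smooth along
    ``t`` relative to the noise.
    """
    if z.nt < 2:
        raise ParameterError("sigma estimation needs at least 2 time samples")
    d = np.diff(z.data.astype(np.float64), axis=2).ravel()
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad / (0.6745 * np.sqrt(2.0)))


def bm4d_denoise(z: Volume, p: BM4DParams | None = None) -> Volume:
    """The full two-stage filter: hard thresholding then Wiener refinement."""
    p = (p or BM4DParams()).resolved(z)
    basic = hard_threshold_stage(z, p)
    return wiener_stage(basic, z, p)
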