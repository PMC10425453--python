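"""Dimension-generic grouping / collaborative-filtering engine.

Implements the machinery shared by the volumetric (3-D cubes, 4-D groups)
and planar (2-D blocks, 3-D groups) block-matching denoisers:

* photometric distance and exhaustive windowed matching,
* the separable orthonormal group transform (DCT-II along every block axis,
  Haar along the grouping axis),
* hard-threshold shrinkage with the DC coefficient always retained,
* sparsity-weighted convex aggregation of overlapping block estimates,
* a full hard-threshold pass and an optional collaborative Wiener pass.

Everything here operates on plain float64 ndarrays; the public modules wrap
these helpers in the domain types.
"""

from __future__ import annotations

import itertools

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import dctn, idctn

from .errors import CoverageError, ParameterError

__all__ = [
    "haar_matrix",
    "next_pow2",
    "pad_group",
    "forward_spectrum",
    "inverse_spectrum",
    "block_distance",
    "match_window",
    "hard_threshold_spectrum",
    "group_weight",
    "hard_threshold_pass",
    "collaborative_wiener_pass",
]

_HAAR_CACHE: dict[int, np.ndarray] = {}


def haar_matrix(n: int) -> np.ndarray:
    """Orthonormal Haar transform matrix of dyadic size ``n``.

    Row 0 is the constant (DC) vector ``1/sqrt(n)``; rows are orthonormal, so
    the transform is an isometry (Parseval holds exactly).
    """
    if n < 1 or (n & (n - 1)) != 0:
        raise ParameterError(f"Haar size must be a positive power of two, got {n}")
    cached = _HAAR_CACHE.get(n)
    if cached is not None:
        return cached
    h = np.array([[1.0]])
    while h.shape[0] < n:
        m = h.shape[0]
        top = np.kron(h, np.array([1.0, 1.0]))
        bot = np.kron(np.eye(m), np.array([1.0, -1.0]))
        h = np.vstack([top, bot]) / np.sqrt(2.0)
    _HAAR_CACHE[n] = h
    return h


def next_pow2(m: int) -> int:
    if m < 1:
        raise ParameterError(f"group depth must be >= 1, got {m}")
    return 1 << (m - 1).bit_length()


def pad_group(stack: np.ndarray) -> np.ndarray:
    """Pad the grouping (last) axis to the next power of two.

    Padding replicates the last member: replicated slices are real data, so
    they bias the group spectrum toward actual content rather than toward
    zero.
    """
    m = stack.shape[-1]
    p = next_pow2(m)
    if p == m:
        return stack
    reps = np.repeat(stack[..., -1:], p - m, axis=-1)
    return np.concatenate([stack, reps], axis=-1)


def forward_spectrum(stack: np.ndarray) -> np.ndarray:
    """Separable orthonormal forward transform of a (padded) group.

    DCT-II (``norm='ortho'``) along every block axis, orthonormal Haar along
    the grouping axis.  The grouping depth must be a power of two.
    """
    if stack.size == 0:
        raise ParameterError("empty group")
    block_axes = tuple(range(stack.ndim - 1))
    c = dctn(stack, axes=block_axes, norm="ortho", type=2)
    h = haar_matrix(stack.shape[-1])
    return c @ h.T


def inverse_spectrum(coeffs: np.ndarray) -> np.ndarray:
    """Inverse of :func:`forward_spectrum` (same padded depth)."""
    if coeffs.size == 0:
        raise ParameterError("empty spectrum")
    h = haar_matrix(coeffs.shape[-1])
    c = coeffs @ h
    block_axes = tuple(range(coeffs.ndim - 1))
    return idctn(c, axes=block_axes, norm="ortho", type=2)


def block_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Photometric distance: sum of squared differences over ``L^d``."""
    if a.shape != b.shape:
        raise ParameterError(f"block shapes differ: {a.shape} vs {b.shape}")
    diff = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    return float(np.sum(diff * diff) / a.size)


def match_window(
    windows: np.ndarray,
    ref: tuple[int, ...],
    radius: int,
    tau: float,
    m_max: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive matching within a centered search window.

    Parameters
    ----------
    windows:
        ``sliding_window_view`` of the data: shape = anchor grid + block.
    ref:
        Anchor (minimal corner) of the reference block, 0-based.
    radius:
        Half-width of the search window per axis (clipped at the grid edge).
    tau:
        Normalized-distance acceptance threshold.
    m_max:
        Cap on group size; the reference is always kept first.

    Returns
    -------
    coords : (M, d) int array — accepted anchors, reference first, then by
        (distance ascending, lexicographic coordinate).
    dists : (M,) float array of the matching distances.
    """
    nd = windows.ndim // 2
    grid = windows.shape[:nd]
    ref = tuple(int(r) for r in ref)
    if len(ref) != nd or any(not 0 <= r < g for r, g in zip(ref, grid)):
        raise ParameterError(f"reference anchor {ref} outside anchor grid {grid}")
    lo = [max(0, r - radius) for r in ref]
    hi = [min(g - 1, r + radius) for r, g in zip(ref, grid)]
    sl = tuple(slice(l, h + 1) for l, h in zip(lo, hi))
    cand = windows[sl]
    ref_block = windows[ref].astype(np.float64)
    block_axes = tuple(range(nd, 2 * nd))
    d = np.sum(
        (cand.astype(np.float64) - ref_block) ** 2, axis=block_axes
    ) / ref_block.size

    d_flat = d.ravel()
    coords = np.stack(
        [g.ravel() for g in np.meshgrid(
            *[np.arange(l, h + 1) for l, h in zip(lo, hi)], indexing="ij")],
        axis=1,
    )
    keep = d_flat <= tau
    # the reference distance is exactly 0 <= tau, but guard against tau < 0
    ref_idx_local = int(
        np.ravel_multi_index([r - l for r, l in zip(ref, lo)],
                             [h - l + 1 for l, h in zip(lo, hi)])
    )
    keep[ref_idx_local] = True
    d_flat = d_flat[keep]
    coords = coords[keep]
    # order: distance ascending, ties broken lexicographically by coordinate
    order = np.lexsort(tuple(coords[:, k] for k in range(nd - 1, -1, -1)) + (d_flat,))
    coords = coords[order]
    d_flat = d_flat[order]
    # force the reference to the front (it may tie at distance 0)
    ref_pos = int(np.nonzero((coords == np.array(ref)).all(axis=1))[0][0])
    if ref_pos != 0:
        idx = np.concatenate([[ref_pos], np.delete(np.arange(len(coords)), ref_pos)])
        coords = coords[idx]
        d_flat = d_flat[idx]
    if len(coords) > m_max:
        coords = coords[:m_max]
        d_flat = d_flat[:m_max]
    return coords, d_flat


def hard_threshold_spectrum(
    coeffs: np.ndarray, threshold: float
) -> tuple[np.ndarray, int]:
    """Zero coefficients with ``|c| < threshold``; the DC term is always kept.

    Returns the shrunk spectrum and the number of retained coefficients
    (>= 1 by the DC rule).
    """
    if threshold < 0:
        raise ParameterError(f"threshold must be non-negative, got {threshold}")
    mask = np.abs(coeffs) >= threshold
    mask[(0,) * coeffs.ndim] = True
    n_retained = int(mask.sum())
    return np.where(mask, coeffs, 0.0), n_retained


def group_weight(sigma: float, n_retained: int) -> float:
    """Aggregation weight ``1 / (sigma^2 N)``.

    ``N >= 1`` because the DC coefficient survives thresholding, so the
    weight is always finite.  The noise-free case ``sigma = 0`` degenerates
    (every estimate equals the data); any common weight is then correct and
    1 is used.
    """
    if sigma < 0:
        raise ParameterError(f"sigma must be non-negative, got {sigma}")
    if n_retained < 1:
        raise ParameterError(f"n_retained must be >= 1, got {n_retained}")
    if sigma == 0:
        return 1.0
    return 1.0 / (sigma * sigma * n_retained)


def _anchor_axis(n: int, L: int, step: int) -> np.ndarray:
    """Reference anchors along one axis: strided, with the trailing anchor
    ``n - L`` forced so every sample is covered by at least one block."""
    if n < L:
        raise ParameterError(f"axis of length {n} shorter than block edge {L}")
    anchors = list(range(0, n - L + 1, step))
    if anchors[-1] != n - L:
        anchors.append(n - L)
    return np.asarray(anchors)


def reference_anchors(shape: tuple[int, ...], L: int, step: int):
    """Iterator over reference anchors of a full pass."""
    axes = [_anchor_axis(n, L, step) for n in shape]
    return itertools.product(*axes)


def hard_threshold_pass(
    data: np.ndarray,
    L: int,
    step: int,
    search_radius: int,
    tau: float,
    m_max: int,
    sigma: float,
    lam: float,
) -> np.ndarray:
    """Full hard-threshold stage on a d-dimensional array.

    For every reference anchor: match -> group -> forward transform ->
    hard threshold (``sigma * lam``) -> inverse -> aggregate with the
    sparsity weight ``1/(sigma^2 N)``.  Returns the finalized estimate.
    """
    data = np.asarray(data, dtype=np.float64)
    nd = data.ndim
    if any(n < L for n in data.shape):
        raise ParameterError(
            f"data shape {data.shape} smaller than block edge {L} on some axis"
        )
    windows = sliding_window_view(data, (L,) * nd)
    num = np.zeros_like(data)
    den = np.zeros_like(data)
    threshold = sigma * lam
    for ref in reference_anchors(data.shape, L, step):
        coords, _ = match_window(windows, ref, search_radius, tau, m_max)
        m = len(coords)
        stack = np.empty((L,) * nd + (m,), dtype=np.float64)
        for k in range(m):
            stack[..., k] = windows[tuple(coords[k])]
        spec = forward_spectrum(pad_group(stack))
        spec, n_ret = hard_threshold_spectrum(spec, threshold)
        est = inverse_spectrum(spec)[..., :m]
        w = group_weight(sigma, n_ret)
        for k in range(m):
            sl = tuple(slice(c, c + L) for c in coords[k])
            num[sl] += w * est[..., k]
            den[sl] += w
    if np.any(den <= 0):
        raise CoverageError("aggregation left uncovered voxels (anchor stride bug)")
    return num / den


def collaborative_wiener_pass(
    noisy: np.ndarray,
    basic: np.ndarray,
    L: int,
    step: int,
    search_radius: int,
    tau: float,
    m_max: int,
    sigma: float,
) -> np.ndarray:
    """Group-wise empirical Wiener stage.

    Matching runs on the basic (stage-1) estimate; the noisy spectrum of each
    group is shrunk by ``W = B^2 / (B^2 + sigma^2)`` where ``B`` is the basic
    group's spectrum, and aggregated with weights ``1/(sigma^2 sum W^2)``.
    """
    noisy = np.asarray(noisy, dtype=np.float64)
    basic = np.asarray(basic, dtype=np.float64)
    if noisy.shape != basic.shape:
        raise ParameterError("noisy and basic shapes differ")
    nd = noisy.ndim
    if any(n < L for n in noisy.shape):
        raise ParameterError("data smaller than block edge")
    w_noisy = sliding_window_view(noisy, (L,) * nd)
    w_basic = sliding_window_view(basic, (L,) * nd)
    num = np.zeros_like(noisy)
    den = np.zeros_like(noisy)
    s2 = sigma * sigma
    for ref in reference_anchors(noisy.shape, L, step):
        coords, _ = match_window(w_basic, ref, search_radius, tau, m_max)
        m = len(coords)
        stack_n = np.empty((L,) * nd + (m,), dtype=np.float64)
        stack_b = np.empty_like(stack_n)
        for k in range(m):
            at = tuple(coords[k])
            stack_n[..., k] = w_noisy[at]
            stack_b[..., k] = w_basic[at]
        spec_n = forward_spectrum(pad_group(stack_n))
        spec_b = forward_spectrum(pad_group(stack_b))
        b2 = spec_b * spec_b
        shrink = b2 / (b2 + s2) if s2 > 0 else np.ones_like(b2)
        est = inverse_spectrum(shrink * spec_n)[..., :m]
        if s2 > 0:
            w = 1.0 / (s2 * max(float(np.sum(shrink * shrink)), 1e-30))
        else:
            w = 1.0
        for k in range(m):
            sl = tuple(slice(c, c + L) for c in coords[k])
            num[sl] += w * est[..., k]
            den[sl] += w
    if np.any(den <= 0):
        raise CoverageError("aggregation left uncovered voxels (anchor stride bug)")
    return num / den
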