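"""Unit tests of the volumetric denoiser's building blocks."""

import itertools

import numpy as np
import pytest

import samdenoise as sd
from samdenoise.bm4d import (
    AggregationBuffer,
    Cube,
    SimilaritySet,
    Group,
    aggregate,
    build_group,
    cube_distance,
    extract_cube,
    finalize_estimate,
    group_weight,
    hard_threshold,
    match_cubes,
)
from samdenoise.errors import CoverageError, ParameterError


def brute_force_match(volume, ref, L, radius, tau, m_max):
    """Exhaustive windowed matching written with plain loops."""
    data = volume.data.astype(float)
    nx, ny, nt = data.shape
    ref_cube = data[ref[0]:ref[0] + L, ref[1]:ref[1] + L, ref[2]:ref[2] + L]
    cands = []
    for ax in range(max(0, ref[0] - radius), min(nx - L, ref[0] + radius) + 1):
        for ay in range(max(0, ref[1] - radius), min(ny - L, ref[1] + radius) + 1):
            for at in range(max(0, ref[2] - radius), min(nt - L, ref[2] + radius) + 1):
                cube = data[ax:ax + L, ay:ay + L, at:at + L]
                d = float(np.sum((cube - ref_cube) ** 2) / L**3)
                if d <= tau or (ax, ay, at) == tuple(ref):
                    cands.append((d, (ax, ay, at)))
    cands.sort(key=lambda item: (item[0], item[1]))
    coords = [c for _, c in cands]
    coords.remove(tuple(ref))
    coords.insert(0, tuple(ref))
    return coords[:m_max]


class TestCubeDistance:
    def test_self_distance_zero(self):
        rng = np.random.default_rng(0)
        a = Cube(rng.standard_normal((4, 4, 4)), (0, 0, 0), 4)
        assert cube_distance(a, a) == 0.0

    def test_forced_arithmetic(self):
        a = Cube(np.ones((2, 2, 2)), (0, 0, 0), 2)
        b = Cube(np.full((2, 2, 2), 3.0), (0, 0, 0), 2)
        assert cube_distance(a, b) == pytest.approx(4.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(5)
        av, bv = rng.standard_normal((2, 4, 4, 4))
        total = 0.0
        for i, j, k in itertools.product(range(4), repeat=3):
            total += (av[i, j, k] - bv[i, j, k]) ** 2
        a = Cube(av, (0, 0, 0), 4)
        b = Cube(bv, (0, 0, 0), 4)
        assert cube_distance(a, b) == pytest.approx(total / 64.0, rel=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        a = Cube(rng.standard_normal((3, 3, 3)) + 1, (0, 0, 0), 3)
        b = Cube(rng.standard_normal((3, 3, 3)), (0, 0, 0), 3)
        assert cube_distance(a, b) == cube_distance(b, a)

    def test_size_mismatch_rejected(self):
        a = Cube(np.zeros((2, 2, 2)), (0, 0, 0), 2)
        b = Cube(np.zeros((3, 3, 3)), (0, 0, 0), 3)
        with pytest.raises(ParameterError):
            cube_distance(a, b)


class TestMatchCubes:
    def test_tau_zero_keeps_only_reference(self):
        rng = np.random.default_rng(1)
        v = sd.Volume(rng.standard_normal((10, 10, 10)))
        p = sd.BM4DParams(L=4, tau_match_ht=0.0, sigma=1.0)
        s = match_cubes(v, (3, 3, 3), p)
        assert s.coords == [(3, 3, 3)]

    def test_tiled_volume_returns_window_up_to_cap(self):
        v = sd.Volume(np.ones((12, 12, 12)))
        p = sd.BM4DParams(L=4, tau_match_ht=10.0, sigma=1.0, search_radius=2, m_max=16)
        s = match_cubes(v, (4, 4, 4), p)
        assert len(s) == 16
        assert s.coords[0] == (4, 4, 4)

    def test_equals_exhaustive_search(self):
        rng = np.random.default_rng(7)
        v = sd.Volume(10 * rng.standard_normal((12, 12, 12)))
        p = sd.BM4DParams(L=4, tau_match_ht=300.0, sigma=10.0,
                          search_radius=5, m_max=16)
        for ref in [(0, 0, 0), (4, 5, 6), (8, 8, 8)]:
            got = match_cubes(v, ref, p)
            want = brute_force_match(v, ref, 4, 5, 300.0, 16)
            assert got.coords == want

    def test_out_of_bounds_reference_rejected(self):
        v = sd.Volume(np.zeros((8, 8, 8)))
        p = sd.BM4DParams(L=4, tau_match_ht=1.0, sigma=1.0)
        with pytest.raises(ParameterError):
            match_cubes(v, (6, 0, 0), p)


class TestBuildGroup:
    def test_singleton_group_is_reference_cube(self):
        rng = np.random.default_rng(2)
        v = sd.Volume(rng.standard_normal((8, 8, 8)))
        s = SimilaritySet(coords=[(1, 2, 3)], tau_match=1.0)
        g = build_group(v, s, 4)
        np.testing.assert_allclose(
            g.stack[..., 0], v.data[1:5, 2:6, 3:7].astype(float), rtol=1e-6
        )

    def test_slices_match_per_coordinate_extraction(self):
        rng = np.random.default_rng(3)
        v = sd.Volume(rng.standard_normal((10, 10, 10)))
        coords = [(0, 0, 0), (2, 3, 4), (6, 6, 6)]
        s = SimilaritySet(coords=coords, tau_match=99.0)
        g = build_group(v, s, 4)
        for m, c in enumerate(coords):
            np.testing.assert_array_equal(
                g.stack[..., m], extract_cube(v, c, 4).values
            )

    def test_invalid_anchor_rejected(self):
        v = sd.Volume(np.zeros((6, 6, 6)))
        s = SimilaritySet(coords=[(4, 0, 0)], tau_match=1.0)
        with pytest.raises(ParameterError):
            build_group(v, s, 4)


class TestHardThreshold:
    def test_simple_spectrum(self):
        spec = np.zeros((3, 1, 1, 1))
        spec[:, 0, 0, 0] = [3.0, 0.5, -2.0]
        out = hard_threshold(spec, sigma=1.0, lambda_4d=1.0)
        np.testing.assert_array_equal(out.coeffs[:, 0, 0, 0], [3.0, 0.0, -2.0])
        assert out.n_retained == 2

    def test_zero_threshold_keeps_everything(self):
        rng = np.random.default_rng(4)
        spec = rng.standard_normal((2, 2, 2, 2))
        out = hard_threshold(spec, sigma=0.0, lambda_4d=2.7)
        np.testing.assert_array_equal(out.coeffs, spec)
        assert out.n_retained == spec.size

    def test_all_zero_spectrum_retains_dc(self):
        out = hard_threshold(np.zeros((2, 2, 2, 2)), sigma=1.0, lambda_4d=1.0)
        assert out.n_retained == 1
        assert not np.any(out.coeffs)


class TestGroupWeight:
    def test_unit_case(self):
        assert group_weight(1.0, 1) == 1.0

    def test_forced_arithmetic(self):
        assert group_weight(2.0, 5) == pytest.approx(0.05)

    @pytest.mark.parametrize("sigma,n", [(0.5, 3), (2.0, 4), (7.0, 11)])
    def test_doubling_n_halves_weight(self, sigma, n):
        assert group_weight(sigma, 2 * n) == pytest.approx(group_weight(sigma, n) / 2)

    def test_noise_free_degenerate_weight(self):
        assert group_weight(0.0, 7) == 1.0

    def test_invalid_n_rejected(self):
        with pytest.raises(ParameterError):
            group_weight(1.0, 0)


class TestAggregation:
    def test_single_cube_recovered_exactly(self):
        rng = np.random.default_rng(8)
        est = rng.standard_normal((4, 4, 4, 1))
        buf = AggregationBuffer.for_shape((4, 4, 4))
        s = SimilaritySet(coords=[(0, 0, 0)], tau_match=1.0)
        aggregate(buf, Group(est), s, w=0.37)
        np.testing.assert_allclose(finalize_estimate(buf), est[..., 0], rtol=1e-12)

    def test_two_cubes_weighted_mean(self):
        v1, v2, w1, w2 = 1.0, 4.0, 0.25, 0.75
        buf = AggregationBuffer.for_shape((4, 4, 4))
        s = SimilaritySet(coords=[(0, 0, 0)], tau_match=1.0)
        aggregate(buf, Group(np.full((4, 4, 4, 1), v1)), s, w1)
        aggregate(buf, Group(np.full((4, 4, 4, 1), v2)), s, w2)
        expected = (w1 * v1 + w2 * v2) / (w1 + w2)
        np.testing.assert_allclose(finalize_estimate(buf), expected)

    def test_matches_voxel_loop_oracle(self):
        rng = np.random.default_rng(9)
        shape = (8, 8, 8)
        buf = AggregationBuffer.for_shape(shape)
        num = np.zeros(shape)
        den = np.zeros(shape)
        for trial in range(5):
            coords = [tuple(rng.integers(0, 5, size=3)) for _ in range(3)]
            coords = list(dict.fromkeys(coords))
            est = rng.standard_normal((4, 4, 4, len(coords)))
            w = float(rng.uniform(0.1, 2.0))
            s = SimilaritySet(coords=coords, tau_match=99.0)
            aggregate(buf, Group(est), s, w)
            for m, (ax, ay, at) in enumerate(coords):
                for i, j, k in itertools.product(range(4), repeat=3):
                    num[ax + i, ay + j, at + k] += w * est[i, j, k, m]
                    den[ax + i, ay + j, at + k] += w
        covered = den > 0
        got = buf.numerator[covered] / buf.denominator[covered]
        np.testing.assert_allclose(got, num[covered] / den[covered], rtol=1e-10)

    def test_uncovered_voxel_raises(self):
        buf = AggregationBuffer.for_shape((4, 4, 4))
        with pytest.raises(CoverageError):
            finalize_estimate(buf)

    def test_result_within_contributing_range(self):
        rng = np.random.default_rng(10)
        buf = AggregationBuffer.for_shape((4, 4, 4))
        s = SimilaritySet(coords=[(0, 0, 0)], tau_match=1.0)
        stacks = [rng.standard_normal((4, 4, 4, 1)) for _ in range(4)]
        for st in stacks:
            aggregate(buf, Group(st), s, float(rng.uniform(0.2, 1.5)))
        out = finalize_estimate(buf)
        low = np.min(np.stack([st[..., 0] for st in stacks]), axis=0)
        high = np.max(np.stack([st[..., 0] for st in stacks]), axis=0)
        assert np.all(out >= low - 1e-12) and np.all(out <= high + 1e-12)
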