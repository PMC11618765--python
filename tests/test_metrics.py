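"""Metric tests: HSC semantics, Dice, surface-DSC and APL comparators."""

import numpy as np
import pytest

from contourhsc import (
    PhantomSpec,
    RasterGrid,
    SliceContour,
    Structure,
    adapted_hsc,
    apl,
    dsc,
    generate_phantom,
    hsc,
    surface_dsc,
)

from conftest import circle_contour, square_structure


def brute_force_one_to_one(final_pts, initial_pts, tol):
    """O(n²) oracle: all pairs, ascending-distance greedy, one-to-one."""
    pairs = []
    for fi, fp in enumerate(final_pts):
        for ij, ip in enumerate(initial_pts):
            d = float(np.linalg.norm(fp - ip))
            if d <= tol:
                pairs.append((d, fi, ij))
    pairs.sort()
    used_f, used_i, n = set(), set(), 0
    for _, fi, ij in pairs:
        if fi not in used_f and ij not in used_i:
            used_f.add(fi)
            used_i.add(ij)
            n += 1
    return n


class TestHSC:
    def test_identical_contours_score_one(self, small_phantom):
        r = hsc(small_phantom, small_phantom)
        assert r.value == 1.0
        assert r.n_untouched == r.n_total_final == small_phantom.total_points

    def test_fully_displaced_contour_scores_zero(self, small_phantom):
        assert hsc(small_phantom.translated(10.0), small_phantom).value == 0.0

    def test_half_modified_two_slice_case(self):
        z0, z1 = 0.0, 3.0
        sq = lambda z: SliceContour([(0, 0, z), (4, 0, z), (4, 4, z), (0, 4, z)])
        final = Structure("final", [sq(z0), sq(z1)], 3.0)
        moved = SliceContour([(1, 1, z1), (3, 1, z1), (3, 3, z1), (1, 3, z1)])
        initial = Structure("init", [sq(z0), moved], 3.0)
        r = hsc(initial, final)
        assert (r.n_untouched, r.n_total_final, r.value) == (4, 8, 0.5)

    def test_uniform_small_offset_exact_vs_adapted(self, small_phantom):
        offset = small_phantom.translated(0.2 / np.sqrt(2), 0.2 / np.sqrt(2))
        assert hsc(offset, small_phantom).value == 0.0
        assert adapted_hsc(offset, small_phantom, 0.5).value == 1.0

    def test_offset_beyond_clinical_tolerance(self, small_phantom):
        offset = small_phantom.translated(0.6, 0.0)
        assert adapted_hsc(offset, small_phantom, 0.5).value == 0.0

    def test_mixed_offsets_count_half(self):
        n = 16
        th = np.arange(n) * 2 * np.pi / n
        pts = np.column_stack([20 * np.cos(th), 20 * np.sin(th), np.zeros(n)])
        final = Structure("f", [SliceContour(pts)], 3.0)
        jitter = np.where(np.arange(n) % 2 == 0, 0.2, 1.0)  # alternating offsets
        moved = pts + np.column_stack([jitter, np.zeros(n), np.zeros(n)])
        initial = Structure("i", [SliceContour(moved)], 3.0)
        assert adapted_hsc(initial, final, 0.5).value == 0.5

    def test_monotone_in_match_tol(self, small_phantom):
        rng = np.random.default_rng(0)
        jittered = Structure(
            "j",
            [SliceContour(sl.points + np.append(rng.normal(0, 0.3, 2), 0.0))
             for sl in small_phantom.slices],
            small_phantom.slice_thickness,
        )
        tols = [1e-6, 0.1, 0.3, 0.5, 1.0, 2.0]
        vals = [hsc(jittered, small_phantom, t).value for t in tols]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert all(0 <= v <= 1 for v in vals)

    def test_asymmetric_when_point_counts_differ(self, small_phantom):
        from contourhsc import resample

        dense = Structure(
            "dense",
            [resample(sl, 2 * sl.n_points) for sl in small_phantom.slices],
            small_phantom.slice_thickness,
        )
        ab = hsc(small_phantom, dense, match_tol=1e-6)
        ba = hsc(dense, small_phantom, match_tol=1e-6)
        assert ab.n_total_final != ba.n_total_final
        assert ab.value != ba.value

    def test_empty_final_rejected(self, small_phantom):
        with pytest.raises(ValueError):
            hsc(small_phantom, Structure("e", [], 3.0))

    def test_one_to_one_stingier_than_many_to_one(self):
        # one near-stationary initial vertex sits near many final points
        final = Structure(
            "f", [SliceContour([(0, 0, 0), (0.2, 0, 0), (0.4, 0, 0),
                                (0.4, 5, 0), (0, 5, 0)])], 3.0)
        initial = Structure(
            "i", [SliceContour([(0.1, 0.1, 0), (10, 0, 0), (10, 10, 0)])], 3.0)
        many = hsc(initial, final, match_tol=0.6, matching="many_to_one")
        one = hsc(initial, final, match_tol=0.6, matching="one_to_one")
        assert many.n_untouched == 3
        assert one.n_untouched == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matcher_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 64))
        th = np.sort(rng.uniform(0, 2 * np.pi, n))
        r = 30 + rng.uniform(-3, 3, n)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros(n)])
        final = Structure("f", [SliceContour(pts)], 3.0)
        moved = pts + rng.normal(0, 0.4, (n, 3)) * [1, 1, 0]
        initial = Structure("i", [SliceContour(moved)], 3.0)
        tol = 0.5
        got = hsc(initial, final, match_tol=tol).n_untouched
        expected = brute_force_one_to_one(pts, moved, tol)
        assert got == expected


class TestDice:
    def test_identical_and_disjoint(self, small_phantom):
        assert dsc(small_phantom, small_phantom).value == 1.0
        far = small_phantom.translated(200.0)
        assert dsc(small_phantom, far).value == 0.0

    def test_symmetry(self, small_phantom):
        other = small_phantom.translated(5.0)
        g = RasterGrid.cover([small_phantom, other])
        assert dsc(small_phantom, other, g).value == dsc(other, small_phantom, g).value

    def test_half_overlapping_squares(self):
        a = square_structure(2.0, origin=(0, 0))
        b = square_structure(2.0, origin=(1, 0))
        g = RasterGrid.cover([a, b], pixel_size=0.02)
        assert dsc(a, b, g).value == pytest.approx(0.5, abs=0.01)

    def test_concentric_sphere_scaling_law(self):
        # nested spheres R and sR share slice planes; DSC -> 2s^3/(1+s^3)
        s = 0.9
        spec = PhantomSpec(n_slices=27, slice_thickness=3.0, max_radius=40.0,
                           points_per_slice=128, noise_amp=0.0, profile="sphere")
        big = generate_phantom(spec)
        small = generate_phantom(
            PhantomSpec(n_slices=27, slice_thickness=3.0, max_radius=40.0 * s,
                        points_per_slice=128, noise_amp=0.0, profile="sphere")
        )
        g = RasterGrid.cover([big, small], pixel_size=0.5)
        expected = 2 * s**3 / (1 + s**3)  # 0.8433
        assert dsc(big, small, g).value == pytest.approx(expected, abs=0.01)


class TestBoundaryComparators:
    def test_surface_dsc_identical_is_one(self, small_phantom):
        assert surface_dsc(small_phantom, small_phantom, tau=0.1) == 1.0

    def test_surface_dsc_concentric_circles(self):
        a = Structure("a", [circle_contour(10.0)], 1.0)
        b = Structure("b", [circle_contour(12.0)], 1.0)
        assert surface_dsc(a, b, tau=1.0) == 0.0  # gap 2 > 1
        assert surface_dsc(a, b, tau=3.0) == 1.0  # gap 2 <= 3

    def test_apl_identical_is_zero(self, small_phantom):
        assert apl(small_phantom, small_phantom, tau=0.1) == 0.0

    def test_apl_far_initial_is_full_perimeter(self, small_phantom):
        perim = sum(sl.perimeter for sl in small_phantom.slices)
        far = small_phantom.translated(500.0)
        assert apl(far, small_phantom, tau=1.0) == pytest.approx(perim)

    def test_apl_two_edges_covered(self):
        # final: square of perimeter 8; initial boundary contains its
        # bottom and left edges and retreats far elsewhere -> APL ~ 4
        final = square_structure(2.0)
        initial = Structure(
            "L",
            [SliceContour([(0, 0, 0), (2, 0, 0), (2, -10, 0), (-10, -10, 0),
                           (-10, 2, 0), (0, 2, 0)])],
            1.0,
        )
        tau = 0.01
        assert apl(initial, final, tau, n_samples=8192) == pytest.approx(4.0, abs=0.05)
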