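import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nvuquant import (
    BoundarySet,
    abluminal_boundary,
    analyze_pair,
    build_histogram,
    cdf_from_histogram,
    contact_fraction,
    ensheathment_coverage,
    extract_boundary,
    generate_capillary_volume,
    min_distances,
    stack_mean_histogram,
)
from nvuquant.phantom import PhantomParams, coverage_series_params
from nvuquant.volume import LabelVolume

from conftest import brute_force_min_distances, random_blob_mask


def _bs(pixels, z=0, name="a"):
    return BoundarySet(z=z, class_name=name, pixels=np.array(pixels))


class TestExtractBoundary:
    def test_filled_square_has_hollow_boundary(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[2:5, 2:5] = True
        b = extract_boundary(mask, 0, "x")
        assert len(b) == 8  # 3×3 square minus its interior pixel
        assert (3, 3) not in set(map(tuple, b.pixels))

    def test_single_pixel_is_its_own_boundary(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert set(map(tuple, extract_boundary(mask, 0, "x").pixels)) == {(2, 2)}

    def test_full_slice_boundary_is_the_border_frame(self):
        mask = np.ones((6, 6), dtype=bool)
        b = extract_boundary(mask, 0, "x")
        pix = set(map(tuple, b.pixels))
        assert len(b) == 20
        assert all(y in (0, 5) or x in (0, 5) for y, x in pix)


class TestMinDistances:
    def test_three_four_five_triangle(self):
        d = min_distances(_bs([(0, 0)]), _bs([(4, 3)]), dx_nm=6.0)
        assert d.tolist() == [30.0]

    def test_identical_sets_give_zeros(self):
        pix = [(1, 2), (3, 4), (5, 5)]
        assert (min_distances(_bs(pix), _bs(pix), 6.0) == 0).all()

    def test_parallel_columns(self):
        a = [(r, 0) for r in range(10)]
        b = [(r, 10) for r in range(10)]
        assert (min_distances(_bs(a), _bs(b), 6.0) == 60.0).all()

    def test_empty_b_raises_flagged_error(self):
        with pytest.raises(ValueError, match="absent"):
            min_distances(_bs([(0, 0)]), _bs(np.empty((0, 2))), 6.0)

    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            m1 = random_blob_mask(rng, (64, 64))
            m2 = random_blob_mask(rng, (64, 64))
            a = extract_boundary(m1, 0, "a")
            b = extract_boundary(m2, 0, "b")
            if len(a) == 0 or len(b) == 0:
                continue
            expected = brute_force_min_distances(a.pixels, b.pixels, 6.0)
            assert np.array_equal(min_distances(a, b, 6.0), expected)

    def test_global_minimum_is_symmetric(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            a = extract_boundary(random_blob_mask(rng, (48, 48)), 0, "a")
            b = extract_boundary(random_blob_mask(rng, (48, 48)), 0, "b")
            if len(a) == 0 or len(b) == 0:
                continue
            assert min_distances(a, b, 6.0).min() == min_distances(b, a, 6.0).min()


class TestHistogramAndCdf:
    def test_worked_binning_example(self):
        frac, edges = build_histogram(np.array([0, 0, 6, 30.0]), 6.0, 60.0)
        assert frac[0] == 0.5 and frac[1] == 0.25 and frac[5] == 0.25
        assert np.isinf(edges[-1])

    def test_overflow_bin_catches_everything_beyond_max(self):
        frac, _ = build_histogram(np.array([100.0, 200.0]), 6.0, 60.0)
        assert frac[-1] == 1.0

    @given(st.lists(st.floats(0, 5000), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_fractions_sum_to_one(self, values):
        frac, _ = build_histogram(np.array(values), 6.0, 2004.0)
        assert abs(frac.sum() - 1.0) < 1e-12

    def test_empty_input_flagged_by_zero_sum(self):
        frac, _ = build_histogram(np.array([]), 6.0, 60.0)
        assert frac.sum() == 0.0

    def test_stack_mean_of_identical_histograms(self):
        h = np.array([[0.5, 0.5, 0.0]] * 3)
        mean, sd, n_exc = stack_mean_histogram(h)
        assert np.array_equal(mean, [0.5, 0.5, 0.0]) and (sd == 0).all() and n_exc == 0

    def test_stack_mean_excludes_nan_slices_and_reports_them(self):
        h = np.array([[1.0, 0.0], [np.nan, np.nan], [0.0, 1.0]])
        mean, _, n_exc = stack_mean_histogram(h)
        assert np.allclose(mean, [0.5, 0.5]) and n_exc == 1
        assert abs(mean.sum() - 1.0) < 1e-12

    def test_stack_mean_all_absent_raises(self):
        with pytest.raises(ValueError, match="absent"):
            stack_mean_histogram(np.full((2, 3), np.nan))

    def test_cdf_running_sum_and_terminal_100(self):
        cdf = cdf_from_histogram([0.5, 0.25, 0, 0, 0, 0.25])
        assert np.allclose(cdf, [50, 75, 75, 75, 75, 100])
        assert (np.diff(cdf) >= 0).all()

    def test_cdf_reading_matches_brute_force_fraction(self):
        # CDF value at d == % of A-boundary pixels within d of B
        rng = np.random.default_rng(21)
        m1, m2 = (random_blob_mask(rng, (40, 40)) for _ in range(2))
        a = extract_boundary(m1, 0, "a")
        b = extract_boundary(m2, 0, "b")
        d = brute_force_min_distances(a.pixels, b.pixels, 6.0)
        frac, edges = build_histogram(d, 6.0, 2004.0)
        cdf = cdf_from_histogram(frac)
        for probe in (12.0, 48.0, 300.0):
            k = np.searchsorted(edges[1:], probe, side="right") - 1
            expected = (d < edges[k + 1]).mean() * 100.0
            assert abs(cdf[k] - expected) < 1e-9


class TestContactFraction:
    def test_identical_masks_full_contact(self):
        pix = [(0, 0), (0, 1), (1, 0)]
        assert contact_fraction(_bs(pix), _bs(pix), 6.0) == 100.0

    def test_edge_sharing_squares_one_third(self):
        mask_a = np.zeros((8, 12), dtype=bool)
        mask_b = np.zeros((8, 12), dtype=bool)
        mask_a[0:4, 0:4] = True
        mask_b[0:4, 4:8] = True
        a = extract_boundary(mask_a, 0, "a")
        b = extract_boundary(mask_b, 0, "b")
        got = contact_fraction(a, b, 6.0, contact_nm=10.0)
        d = brute_force_min_distances(a.pixels, b.pixels, 6.0)
        assert abs(got - (d <= 10).mean() * 100.0) < 1e-12
        assert abs(got - 100.0 / 3.0) < 1e-9  # 4 of the 12 boundary pixels

    def test_well_separated_masks_zero_contact(self):
        a = _bs([(0, 0), (0, 1)])
        b = _bs([(0, 5), (0, 6)])
        assert contact_fraction(a, b, 6.0, contact_nm=10.0) == 0.0


def _annulus_volume():
    """One-slice volume: lumen disk inside an endothelial annulus."""
    n = 41
    c = (n - 1) / 2
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - c, xx - c)
    vox = np.zeros((1, n, n), dtype=np.uint8)
    vox[0][r < 15] = 2
    vox[0][r < 8] = 1
    return LabelVolume(vox)


class TestAbluminal:
    def test_annulus_abluminal_is_outer_ring_only(self):
        vol = _annulus_volume()
        ab = abluminal_boundary(vol, 0)
        c = (41 - 1) / 2
        radii = np.hypot(*(ab.pixels - c).T)
        assert len(ab) > 0
        assert radii.min() > 10  # inner (luminal) ring excluded

    def test_no_lumen_contact_keeps_full_boundary(self):
        vox = np.zeros((1, 10, 10), dtype=np.uint8)
        vox[0, 2:6, 2:6] = 2
        vol = LabelVolume(vox)
        ab = abluminal_boundary(vol, 0)
        assert len(ab) == 12  # full boundary of the 4×4 square


class TestEnsheathmentCoverage:
    def test_full_sheath_is_100_percent_everywhere(self):
        vol, _ = generate_capillary_volume(
            PhantomParams(n_slices=3, pericyte_coverage_frac=1.0, jitter_nm=0.0, seed=5)
        )
        cov = ensheathment_coverage(vol)
        assert cov.mean_pct == 100.0 and cov.sd_pct == 0.0

    def test_no_pericyte_scores_zero(self):
        vol, _ = generate_capillary_volume(
            PhantomParams(n_slices=2, pericyte_coverage_frac=0.0, jitter_nm=0.0, seed=5)
        )
        cov = ensheathment_coverage(vol)
        assert cov.mean_pct == 0.0
        assert cov.pericyte_absent_slices == [0, 1]

    @pytest.mark.parametrize("target", [0.2, 0.5, 0.8])
    def test_parameter_recovery_within_two_points(self, target):
        vol, truth = generate_capillary_volume(
            coverage_series_params(target, seed=9, n_slices=3)
        )
        cov = ensheathment_coverage(vol)
        assert abs(cov.mean_pct - 100.0 * target) <= 2.0

    def test_coverage_monotone_in_threshold(self):
        vol, _ = generate_capillary_volume(
            coverage_series_params(0.5, seed=9, n_slices=2)
        )
        c100 = ensheathment_coverage(vol, coverage_nm=100.0).mean_pct
        c200 = ensheathment_coverage(vol, coverage_nm=200.0).mean_pct
        assert c100 <= c200


class TestAnalyzePair:
    def test_phantom_pair_statistics_are_consistent(self):
        vol, _ = generate_capillary_volume(
            PhantomParams(n_slices=3, pericyte_coverage_frac=1.0, jitter_nm=0.0, seed=5)
        )
        res = analyze_pair(vol, "pericyte", "endothelium")
        valid = ~np.isnan(res.per_slice_hist).any(axis=1)
        assert valid.all()
        assert np.allclose(res.per_slice_hist[valid].sum(axis=1), 1.0)
        assert abs(res.stack_mean_hist.sum() - 1.0) < 1e-12
        assert (np.diff(res.cdf_pct) >= -1e-12).all()
        assert abs(res.cdf_pct[-1] - 100.0) < 1e-9
        # separated by an intact BM: nothing within direct contact range
        assert res.contact_pct_mean == 0.0
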