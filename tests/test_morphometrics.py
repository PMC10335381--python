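import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

from nvuquant import (
    convex_hull_metrics,
    label_objects,
    measure_object,
    measure_volume,
    perimeter_from_chain,
    radius_stats,
    slice_class_summary,
    trace_freeman_chain,
)
from nvuquant.morphometrics import rasterise_hull
from nvuquant.proximity import boundary_mask

from conftest import cross_mask, disk_mask


def _square(side, pad=3):
    m = np.zeros((side + 2 * pad, side + 2 * pad), dtype=bool)
    m[pad : pad + side, pad : pad + side] = True
    return m


def shapely_hull_mask(mask):
    """Independent oracle: rasterise the hull of boundary pixel centres with
    shapely's point-in-polygon (inclusive of the boundary)."""
    pts = np.argwhere(boundary_mask(mask))
    poly = Polygon(pts).convex_hull
    out = np.zeros_like(mask)
    ys, xs = np.nonzero(mask)
    for y in range(ys.min(), ys.max() + 1):
        for x in range(xs.min(), xs.max() + 1):
            if poly.covers(Point(y, x)):
                out[y, x] = True
    return out


class TestChainTracing:
    def test_ten_by_ten_square_chain(self):
        chain = trace_freeman_chain(_square(10))
        assert len(chain) == 36
        assert all(c % 2 == 0 for c in chain)  # axial moves only

    def test_thin_line_traverses_out_and_back(self):
        m = np.zeros((5, 26), dtype=bool)
        m[2, 3:23] = True  # 1×20 line
        assert len(trace_freeman_chain(m)) == 38

    def test_chain_counts_translation_invariant(self):
        rng = np.random.default_rng(3)
        base = cross_mask()
        chain0 = trace_freeman_chain(base)
        for _ in range(3):
            dy, dx = rng.integers(0, 6, size=2)
            shifted = np.zeros((25, 25), dtype=bool)
            shifted[dy : dy + 13, dx : dx + 13] = base
            assert sorted(trace_freeman_chain(shifted)) == sorted(chain0)

    def test_single_pixel_has_empty_chain(self):
        m = np.zeros((3, 3), dtype=bool)
        m[1, 1] = True
        assert trace_freeman_chain(m) == []


class TestPerimeter:
    def test_square_perimeter_in_nm(self):
        chain = trace_freeman_chain(_square(10))
        assert perimeter_from_chain(chain, 6.0) == pytest.approx(216.0)

    @pytest.mark.parametrize("side", [8, 16, 32])
    def test_square_scaling_exact(self, side):
        m = _square(side)
        chain = trace_freeman_chain(m)
        assert perimeter_from_chain(chain, 1.0) == 4 * (side - 1)
        assert m.sum() == side**2

    def test_diagonal_steps_weighted_sqrt2(self):
        assert perimeter_from_chain([1, 3, 5, 7], 6.0) == pytest.approx(4 * np.sqrt(2) * 6)

    def test_perimeter_scales_linearly_with_pixel_size(self):
        chain = trace_freeman_chain(_square(8))
        assert perimeter_from_chain(chain, 12.0) == 2 * perimeter_from_chain(chain, 6.0)


class TestConvexHull:
    def test_convex_object_hull_identity(self):
        m = _square(9)
        ca, cp = convex_hull_metrics(m, 6.0)
        assert ca == m.sum() * 36.0
        assert cp == perimeter_from_chain(trace_freeman_chain(m), 6.0)

    def test_cross_against_shapely_oracle(self):
        m = cross_mask()
        hull = rasterise_hull(m)
        assert np.array_equal(hull, shapely_hull_mask(m))
        ca, cp = convex_hull_metrics(m, 6.0)
        a = m.sum() * 36.0
        p = perimeter_from_chain(trace_freeman_chain(m), 6.0)
        assert ca > a and cp < p
        # exact values from the oracle mask
        assert ca == pytest.approx(shapely_hull_mask(m).sum() * 36.0, abs=1e-9)
        assert cp == pytest.approx(
            perimeter_from_chain(trace_freeman_chain(shapely_hull_mask(m)), 6.0), abs=1e-9
        )

    def test_hull_area_never_below_object_area(self):
        rng = np.random.default_rng(4)
        from conftest import random_blob_mask
        from nvuquant import label_objects

        for _ in range(5):
            mask = random_blob_mask(rng, (40, 40))
            objs, _, _ = label_objects(mask, min_area_px=16)
            for obj in objs:
                ca, _ = convex_hull_metrics(obj, 1.0)
                if ca is not None:
                    assert ca >= obj.sum()

    def test_degenerate_line_flagged_none(self):
        m = np.zeros((5, 9), dtype=bool)
        m[2, 1:8] = True
        assert convex_hull_metrics(m, 6.0) == (None, None)

    def test_polygon_mode_square(self):
        ca, cp = convex_hull_metrics(_square(10), 6.0, mode="polygon")
        assert ca == pytest.approx(81 * 36.0)  # 9×9 nm² hull of pixel centres
        assert cp == pytest.approx(4 * 9 * 6.0)


class TestRadiiAndRatios:
    def test_square_radius_extremes_exact(self):
        r_mean, r_min, r_max = radius_stats(_square(10), 6.0)
        assert r_min == pytest.approx(np.sqrt(0.5**2 + 4.5**2) * 6.0)
        assert r_max == pytest.approx(4.5 * np.sqrt(2) * 6.0)
        assert r_min <= r_mean <= r_max

    def test_square_record_unit_ratios_and_sphericity(self):
        rec = measure_object(_square(10), 6.0)
        assert rec.convexity == pytest.approx(1.0)
        assert rec.solidity == pytest.approx(1.0)
        expected = np.sqrt(0.5**2 + 4.5**2) / (4.5 * np.sqrt(2))
        assert rec.sphericity == pytest.approx(expected)  # ≈ 0.711
        assert rec.sphericity == pytest.approx(0.711, abs=5e-4)

    def test_digital_disk_is_nearly_spherical(self):
        rec = measure_object(disk_mask(50), 6.0)
        assert rec.r_mean_nm == pytest.approx(50 * 6.0, rel=0.02)
        assert rec.sphericity >= 0.94
        assert 0.98 <= rec.convexity <= 1.0
        assert 0.98 <= rec.solidity <= 1.0

    def test_cross_ratios_below_one(self):
        rec = measure_object(cross_mask(), 6.0)
        assert rec.convexity < 1.0 and rec.solidity < 1.0


class TestObjectsAndSummary:
    def test_diagonal_blobs_merge_under_8_connectivity(self):
        m = np.zeros((10, 10), dtype=bool)
        m[0:5, 0:5] = True
        m[5:10, 5:10] = True
        objs, n_drop, _ = label_objects(m, min_area_px=16)
        assert len(objs) == 1 and n_drop == 0

    def test_small_components_dropped_and_counted(self):
        m = np.zeros((12, 12), dtype=bool)
        m[0:3, 0:3] = True  # 9 px, below the 16 px floor
        objs, n_drop, dropped_area = label_objects(m, min_area_px=16)
        assert objs == [] and n_drop == 1 and dropped_area == 9

    def test_empty_mask_yields_no_objects(self):
        objs, n_drop, _ = label_objects(np.zeros((5, 5), dtype=bool))
        assert objs == [] and n_drop == 0

    def test_area_conservation(self):
        rng = np.random.default_rng(6)
        from conftest import random_blob_mask

        mask = random_blob_mask(rng, (40, 40))
        objs, _, dropped_area = label_objects(mask, min_area_px=16)
        assert sum(o.sum() for o in objs) + dropped_area == mask.sum()

    def test_summary_weights_proportional_to_area(self):
        recs = pd.DataFrame(
            [
                {"z": 0, "class_name": "pericyte", "area_nm2": 300.0,
                 "perimeter_nm": 10.0, "r_mean_nm": 1.0, "convexity": 1.0,
                 "solidity": 1.0, "sphericity": 0.4},
                {"z": 0, "class_name": "pericyte", "area_nm2": 100.0,
                 "perimeter_nm": 20.0, "r_mean_nm": 2.0, "convexity": 0.5,
                 "solidity": 0.5, "sphericity": 0.8},
            ]
        )
        out = slice_class_summary(recs)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["sphericity"] == pytest.approx(0.75 * 0.4 + 0.25 * 0.8)
        assert row["convexity"] == pytest.approx(0.875)

    def test_single_object_summary_equals_its_metrics(self):
        rec = measure_object(_square(10), 6.0, z=0, class_name="neuron")
        df, _ = measure_volume(
            _volume_with_one_square(), classes=["neuron"], min_area_px=16
        )
        out = slice_class_summary(df)
        assert out.iloc[0]["sphericity"] == pytest.approx(rec.sphericity)
        assert out.iloc[0]["n_objects"] == 1


def _volume_with_one_square():
    from nvuquant.volume import LabelVolume

    vox = np.zeros((1, 16, 16), dtype=np.uint8)
    vox[0, 3:13, 3:13] = 6  # neuron
    return LabelVolume(vox)


def test_measure_volume_flags_border_objects():
    from nvuquant.volume import LabelVolume

    vox = np.zeros((1, 10, 10), dtype=np.uint8)
    vox[0, 0:5, 0:5] = 4
    df, _ = measure_volume(LabelVolume(vox), classes=["pericyte"])
    assert bool(df.iloc[0]["touches_border"])
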