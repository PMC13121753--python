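"""Cell geometry and intensity scoring: extraction, mean intensities, the
polar-coordinate cortex mask (vs an independent scaled-polygon oracle),
junction polarity, and apical-area kinetics."""

import numpy as np
import pandas as pd
import pytest
from shapely import affinity
from shapely.geometry import Point, Polygon

import jzquant as jz
from jzquant.io import ValidationError

from conftest import disk_pair, random_convex_cell


class TestExtractCells:
    def test_square_label(self):
        lbl = np.zeros((20, 20), np.int32)
        lbl[5:15, 5:15] = 1
        pair = jz.LabelledImagePair(lbl, {}, 1.0)
        (cell,) = jz.extract_cells(pair)
        assert cell.area_um2 == pytest.approx(100.0)
        assert cell.centroid_um == pytest.approx((9.5, 9.5))

    def test_two_labels_and_small_label_skipped(self, caplog):
        lbl = np.zeros((20, 20), np.int32)
        lbl[2:8, 2:8] = 1
        lbl[10:16, 10:16] = 2
        lbl[0, 19] = 3  # < 4 px
        with caplog.at_level("WARNING", logger="jzquant"):
            cells = jz.extract_cells(jz.LabelledImagePair(lbl, {}, 1.0))
        assert [c.label for c in cells] == [1, 2]
        assert "skipped 1" in caplog.text

    def test_area_sums_to_foreground(self, small_epithelium):
        pair, _, _ = small_epithelium
        cells = jz.extract_cells(pair)
        total = sum(c.area_um2 for c in cells)
        assert total == pytest.approx((pair.label_image > 0).sum() * pair.pixel_size_um**2)


class TestMeanIntensity:
    def test_uniform_and_painted(self):
        lbl = np.zeros((10, 10), np.int32)
        lbl[:5] = 1
        lbl[5:] = 2
        ch = np.full((10, 10), 7.0)
        pair = jz.LabelledImagePair(lbl, {"c": ch}, 1.0)
        means = jz.cell_mean_intensity(pair, "c")
        assert np.allclose(means, 7.0)
        ch2 = np.where(lbl == 1, 10.0, 0.0)
        means2 = jz.cell_mean_intensity(jz.LabelledImagePair(lbl, {"c": ch2}, 1.0), "c")
        assert means2[1] == 10.0 and means2[2] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        lbl = rng.integers(0, 5, size=(32, 32)).astype(np.int32)
        ch = rng.uniform(0, 100, size=(32, 32))
        pair = jz.LabelledImagePair(lbl, {"c": ch}, 1.0)
        means = jz.cell_mean_intensity(pair, "c")
        for l in means.index:
            assert means[l] == pytest.approx(ch[lbl == l].mean())


class TestNormalizeByReference:
    def test_ratio_and_homogeneity(self):
        idx = pd.Index([1, 2], name="label")
        t = pd.Series([50.0, 30.0], index=idx, name="t")
        r = pd.Series([25.0, 30.0], index=idx, name="r")
        out = jz.normalize_by_reference(t, r)
        assert out[1] == pytest.approx(2.0)
        assert out[2] == pytest.approx(1.0)
        scaled = jz.normalize_by_reference(t, 2.0 * r)
        np.testing.assert_allclose(scaled, out / 2.0)

    def test_nonpositive_reference_excluded(self, caplog):
        idx = pd.Index([1, 2], name="label")
        t = pd.Series([50.0, 30.0], index=idx, name="t")
        r = pd.Series([25.0, 0.0], index=idx, name="r")
        with caplog.at_level("WARNING", logger="jzquant"):
            out = jz.normalize_by_reference(t, r)
        assert list(out.index) == [1]


class TestCortexMask:
    def test_disk_area_ratio(self):
        pair = disk_pair(30)
        (cell,) = jz.extract_cells(pair)
        mask = jz.cortex_mask(cell, pair, 0.8)
        ratio = mask.n_pixels / (pair.label_image > 0).sum()
        assert ratio == pytest.approx(0.64, abs=0.02)

    def test_limits(self):
        pair = disk_pair(20)
        (cell,) = jz.extract_cells(pair)
        n_cell = (pair.label_image > 0).sum()
        big = jz.cortex_mask(cell, pair, 0.99).n_pixels
        small = jz.cortex_mask(cell, pair, 0.01).n_pixels
        assert big / n_cell > 0.95
        assert small / n_cell < 0.05

    def test_subset_of_cell(self, small_epithelium):
        pair, _, _ = small_epithelium
        for cell in jz.extract_cells(pair)[:8]:
            mask = jz.cortex_mask(cell, pair, 0.8)
            assert (pair.label_image[mask.rows, mask.cols] == cell.label).all()

    def test_matches_scaled_polygon_oracle(self):
        """Ray-cast cortex mask equals point-in-scaled-polygon containment on
        random convex cells (ties on the scaled boundary tolerated)."""
        rng = np.random.default_rng(17)
        for _ in range(25):
            lbl, hull = random_convex_cell(rng, return_hull=True)
            pair = jz.LabelledImagePair(lbl, {}, 1.0)
            rows, cols = np.nonzero(lbl)
            centroid = (cols.mean(), rows.mean())
            cell = jz.CellShape(1, centroid, hull, float(len(rows)))
            frac = 0.8
            mask = jz.cortex_mask(cell, pair, frac)
            got = set(zip(mask.rows.tolist(), mask.cols.tolist()))
            scaled = affinity.scale(Polygon(hull), xfact=frac, yfact=frac, origin=centroid)
            expected = {
                (r, c) for r, c in zip(rows.tolist(), cols.tolist())
                if scaled.covers(Point(c, r))
            }
            for px in got.symmetric_difference(expected):
                assert scaled.exterior.distance(Point(px[1], px[0])) < 1e-6


class TestJunctions:
    @pytest.mark.parametrize(
        "p1,expected", [((10, 0), 0.0), ((0, 10), 90.0), ((7, 7), 45.0)]
    )
    def test_orientation(self, p1, expected):
        assert jz.junction_orientation((0.0, 0.0), p1) == pytest.approx(expected)

    def test_orientation_reflection_invariant(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p0, p1 = rng.normal(size=2), rng.normal(size=2)
            a = jz.junction_orientation(tuple(p0), tuple(p1))
            ar = jz.junction_orientation((-p0[0], p0[1]), (-p1[0], p1[1]))
            au = jz.junction_orientation((p0[0], -p0[1]), (p1[0], -p1[1]))
            assert a == pytest.approx(ar) == pytest.approx(au)

    def test_coincident_endpoints_error(self):
        with pytest.raises(ValidationError):
            jz.junction_orientation((1.0, 1.0), (1.0, 1.0))

    @pytest.mark.parametrize("angle,expected", [(30.0, "ML"), (60.0, "AP"), (45.0, "AP")])
    def test_classification(self, angle, expected):
        assert jz.classify_junction(angle) == expected


class TestPolarityRatio:
    def _table(self, ml, ap, roi="r1"):
        rows = [
            {"roi_id": roi, "junction_id": f"m{i}", "angle_deg": 10.0, "mean_intensity": v,
             "channel": "c"} for i, v in enumerate(ml)
        ] + [
            {"roi_id": roi, "junction_id": f"a{i}", "angle_deg": 80.0, "mean_intensity": v,
             "channel": "c"} for i, v in enumerate(ap)
        ]
        return jz.JunctionTable(pd.DataFrame(rows))

    def test_class_mean_ratio(self):
        out = jz.polarity_ratio(self._table([4.0, 6.0], [5.0]))
        assert out["ratio"].iloc[0] == pytest.approx(1.0)
        assert out["n_ml"].iloc[0] == 2 and out["n_ap"].iloc[0] == 1

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        ml, ap = rng.uniform(1, 10, 5), rng.uniform(1, 10, 4)
        r1 = jz.polarity_ratio(self._table(ml, ap))["ratio"].iloc[0]
        r2 = jz.polarity_ratio(self._table(7.3 * ml, 7.3 * ap))["ratio"].iloc[0]
        assert r1 == pytest.approx(r2)

    def test_missing_class_flagged(self):
        out = jz.polarity_ratio(self._table([4.0], []))
        assert out["flagged"].iloc[0]
        assert np.isnan(out["ratio"].iloc[0])


class TestCorticalScoring:
    def test_cortical_patch_raises_cortical_mean(self):
        pair = disk_pair(20)
        (cell,) = jz.extract_cells(pair)
        ch = pair.channels["ch"].copy()
        yy, xx = np.mgrid[0 : ch.shape[0], 0 : ch.shape[1]]
        c = ch.shape[0] // 2
        ch[((yy - c) ** 2 + (xx - c) ** 2) <= 64] += 100.0
        pair2 = jz.LabelledImagePair(pair.label_image, {"ch": ch}, 1.0)
        mask = jz.cortex_mask(cell, pair2, 0.8)
        cortical = jz.cortical_mean_intensity(pair2, "ch", mask)
        whole = jz.cell_mean_intensity(pair2, "ch")[cell.label]
        assert cortical > whole

    def test_generator_patches_separate_cells(self, small_epithelium):
        pair, _, truth = small_epithelium
        cells = jz.extract_cells(pair)
        scores = {}
        for cell in cells:
            mask = jz.cortex_mask(cell, pair, 0.8)
            scores[cell.label] = jz.cortical_mean_intensity(pair, "cortical", mask)
        t = truth.per_item.set_index("label")
        flagged = t["cortical_true"]
        with_patch = [scores[l] for l in t.index[flagged] if l in scores]
        without = [scores[l] for l in t.index[~flagged] if l in scores]
        assert min(with_patch) > max(without)

    def test_enrichment_fraction(self):
        flags = pd.Series([True, True] + [False] * 8)
        regions = pd.Series(["medial"] * 10)
        out = jz.apical_enrichment_fraction(flags, regions)
        assert out.loc[out.region == "medial", "pct"].iloc[0] == pytest.approx(20.0)


class TestConstrictionSeries:
    def test_normalize_align_example(self):
        df = pd.DataFrame(
            {"cell_id": "c", "time_min": [0.0, 1, 2, 3, 4], "area_um2": [50.0, 80, 100, 60, 20]}
        )
        out = jz.normalize_align_series(df)
        np.testing.assert_allclose(out["norm_area"], [0.5, 0.8, 1.0, 0.6, 0.2])
        np.testing.assert_allclose(out["aligned_min"], [-2, -1, 0, 1, 2])

    def test_constant_series_ties_to_first(self):
        df = pd.DataFrame({"cell_id": "c", "time_min": [0.0, 5, 10], "area_um2": 40.0})
        out = jz.normalize_align_series(df)
        assert (out["norm_area"] == 1.0).all()
        assert out["aligned_min"].iloc[0] == 0.0

    def test_aggregate_identical_cells(self):
        base = pd.DataFrame(
            {"cell_id": "a", "time_min": [0.0, 5, 10, 15], "area_um2": [80.0, 100, 60, 30]}
        )
        df = pd.concat([base, base.assign(cell_id="b"), base.assign(cell_id="c")])
        agg = jz.aggregate_constriction(jz.normalize_align_series(df))
        assert np.allclose(agg["sem"], 0.0)
        assert agg.loc[agg["aligned_min"] == 0, "mean_norm_area"].iloc[0] == 1.0
        assert agg["mean_norm_area"].between(0, 1).all()

    def test_min_n_suppression(self):
        df = pd.DataFrame(
            {"cell_id": "a", "time_min": [0.0, 5, 10], "area_um2": [100.0, 60, 30]}
        )
        agg = jz.aggregate_constriction(jz.normalize_align_series(df), min_n=2)
        assert agg.empty

    @pytest.mark.parametrize(
        "norm,expected",
        [
            (np.maximum(1 - np.arange(0, 66.0, 6.0) / 60.0, 0.0), 54.0),  # linear collapse
            (np.full(5, 0.5), None),  # never below threshold
            (np.array([1.0, 0.05, 0.8, 0.9, 0.85]), None),  # dips then recovers
            (np.array([1.0, 0.5, 0.05, 0.5, 0.04, 0.03]), 20.0),  # flicker then persists
        ],
    )
    def test_detect_ingression_rules(self, norm, expected):
        df = pd.DataFrame(
            {"cell_id": "c", "time_min": np.arange(len(norm)) * (6.0 if len(norm) > 6 else 5.0),
             "norm_area": norm}
        )
        assert jz.detect_ingression(df, 0.1) == expected


class TestCorticalChange:
    def test_paired_difference(self, caplog):
        first = pd.Series({"a": 10.0, "b": 5.0, "c": 1.0})
        last = pd.Series({"a": 30.0, "b": 5.0})
        with caplog.at_level("WARNING", logger="jzquant"):
            out = jz.cortical_change(first, last)
        assert out.loc["a", "change"] == pytest.approx(20.0)
        assert out.loc["b", "change"] == pytest.approx(0.0)
        assert "c" not in out.index
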