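import numpy as np
import pytest
import scipy.ndimage as ndi

from phenocount import phenotyper as ph
from phenocount.registry import PhenotypeSpec, full_patterns
from conftest import small_fov


def disc_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


class TestFilterNucleusObjects:
    def test_midrange_disc_kept(self):
        m = disc_mask((64, 64), 32, 32, 12)  # area ~452
        lab, _ = ndi.label(m)
        out = ph.filter_nucleus_objects(lab)
        assert out.max() == 1

    def test_small_object_removed(self):
        m = disc_mask((64, 64), 32, 32, 5)  # area ~78 < 200
        lab, _ = ndi.label(m)
        assert ph.filter_nucleus_objects(lab).max() == 0

    def test_large_object_removed(self):
        m = disc_mask((128, 128), 64, 64, 30)  # area ~2800 > 2000
        lab, _ = ndi.label(m)
        assert ph.filter_nucleus_objects(lab).max() == 0

    def test_thin_bar_removed_by_eccentricity(self):
        m = np.zeros((64, 128), bool)
        m[30:34, 10:110]  = True  # 4 x 100 bar, area 400 in bounds
        lab, _ = ndi.label(m)
        assert ph.filter_nucleus_objects(lab).max() == 0

    def test_labels_recompacted(self):
        m = disc_mask((64, 160), 32, 30, 12) | disc_mask((64, 160), 32, 80, 5) \
            | disc_mask((64, 160), 32, 130, 12)
        lab, _ = ndi.label(m)
        out = ph.filter_nucleus_objects(lab)
        assert sorted(np.unique(out)) == [0, 1, 2]


class TestCytoplasmMask:
    def test_all_plus_identity(self):
        ones = np.ones((4, 4), bool)
        assert ph.build_cytoplasm_mask([ones, ones], {0: "+", 1: "+"}).all()

    def test_hand_example(self):
        c1 = np.array([[1, 1], [0, 0]], bool)
        c2 = np.array([[1, 0], [1, 0]], bool)
        out = ph.build_cytoplasm_mask([c1, c2], {0: "+", 1: "-"})
        assert np.array_equal(out, np.array([[0, 1], [0, 0]], bool))

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_patterns_partition_pixels(self, k, rng):
        masks = [rng.random((16, 16)) > 0.5 for _ in range(k)]
        total = np.zeros((16, 16), int)
        for spec in full_patterns(tuple(range(k))):
            pat = spec.active_pattern(k)
            total += ph.build_cytoplasm_mask(masks, pat).astype(int)
        assert np.all(total == 1)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ph.build_cytoplasm_mask([np.ones((4, 4), bool), np.ones((5, 5), bool)],
                                    {0: "+", 1: "+"})


class TestAreaRatioFilter:
    def test_identical_masks_nothing_removed(self):
        m = disc_mask((64, 64), 32, 32, 10)
        out, ratios = ph.area_ratio_filter(m, m)
        assert np.array_equal(out, m)
        assert all(r == pytest.approx(1.0) for r in ratios.values())

    def test_half_coverage_removed(self):
        full = disc_mask((64, 64), 32, 32, 12)
        masked = full & (np.arange(64)[None, :] < 32 - 3)  # ~0.4 of the disc
        out, ratios = ph.area_ratio_filter(masked, full)
        assert not out.any()

    def test_seventy_percent_kept(self):
        # masked 70 px of a filtered 100 px bar: ratio 0.7 >= 0.6 -> kept
        full = np.zeros((20, 40), bool)
        full[5:10, 5:25] = True            # 100 px
        masked = np.zeros_like(full)
        masked[5:10, 5:19] = True          # 70 px
        out, ratios = ph.area_ratio_filter(masked, full)
        assert out.sum() == 70
        assert list(ratios.values()) == [pytest.approx(0.7)]

    def test_seed_on_background_warns_and_removes(self):
        masked = disc_mask((64, 64), 32, 32, 8)
        filtered = np.zeros_like(masked)   # empty: seed falls on background
        with pytest.warns(UserWarning):
            out, _ = ph.area_ratio_filter(masked, filtered)
        assert not out.any()

    def test_respects_watershed_labels(self):
        # two touching bars split into two labels; masking one bar fully
        # must give ratio 1.0 against its own label, not the union
        labels = np.zeros((10, 20), np.int32)
        labels[2:8, 2:10] = 1
        labels[2:8, 10:18] = 2
        masked = labels == 1
        out, ratios = ph.area_ratio_filter(masked, labels)
        assert out.sum() == masked.sum()
        assert list(ratios.values()) == [pytest.approx(1.0)]


class TestMeasureDiameter:
    def test_closed_form(self):
        assert ph.measure_diameter(np.pi * 100, 1.0) == pytest.approx(20.0)

    def test_pixel_size_scaling(self):
        d1 = ph.measure_diameter(500, 1.0)
        assert ph.measure_diameter(500, 0.5) == pytest.approx(d1 / 2)

    def test_planted_disc_within_5pc(self):
        m = disc_mask((64, 64), 32, 32, 10)
        d = ph.measure_diameter(m.sum(), 1.0)
        assert abs(d - 20.0) / 20.0 <= 0.05

    def test_invalid_pixel_size(self):
        with pytest.raises(ValueError):
            ph.measure_diameter(100, 0)


class TestEnumerate:
    def test_empty_fov_zero_counts(self):
        fov, gt = small_fov(seed=1, mix={"P2": 0, "P1": 0})
        spec = PhenotypeSpec("P2", ("+",))
        records, count, overlay = ph.enumerate_phenotype(fov, spec)
        assert count == 0 and records == []

    def test_planted_counts_recovered(self):
        # well-separated scene: 3 cells C1+ / 5 cells C1- (clustering off)
        from phenocount import simgen as sg
        nuc = sg.NucleusPopulationSpec(clustering_probability=0.0)
        spec = sg.FOVSpec(width=256, height=256, n_marker_channels=1,
                          phenotype_mix={"P2": 3, "P1": 5}, seed=21,
                          channel_ids=(0,))
        fov, gt = sg.generate_fov(spec, nucleus=nuc)
        records, counts, _ = ph.enumerate_all(
            fov, [PhenotypeSpec("P2", ("+",)), PhenotypeSpec("P1", ("-",))])
        by = counts.rows.set_index("phenotype")["count"]
        assert by["P2"] == 3 and by["P1"] == 5

    def test_partition_property_clean_scene(self):
        from phenocount import simgen as sg
        nuc = sg.NucleusPopulationSpec(clustering_probability=0.0)
        spec = sg.FOVSpec(width=256, height=256, n_marker_channels=2,
                          phenotype_mix={"P5": 2, "P6": 2, "P7": 2, "P1": 2},
                          seed=8, channel_ids=(0, 1))
        fov, gt = sg.generate_fov(spec, nucleus=nuc)
        filtered, marker_masks, _ = ph.binarize_channels(fov)
        n_nuclei = filtered.max()
        records, counts, _ = ph.enumerate_all(fov, full_patterns((0, 1)))
        assert counts.rows["count"].sum() == n_nuclei

    def test_missing_channel_rejected(self):
        fov, _ = small_fov(seed=1, n_markers=1)
        spec = PhenotypeSpec("needs3", ("+", "+", "+"))
        with pytest.raises(ValueError):
            ph.enumerate_phenotype(fov, spec)

    def test_records_satisfy_invariants(self):
        fov, _ = small_fov(seed=33, size=256, mix={"P2": 6, "P1": 3})
        records, _, _ = ph.enumerate_phenotype(fov, PhenotypeSpec("P2", ("+",)))
        for r in records:
            assert 200 <= r.area <= 2000
            assert r.eccentricity <= 0.8


class TestExport:
    def test_files_written(self, tmp_path):
        fov, gt = small_fov(seed=44, size=256, mix={"P2": 4, "P1": 2})
        records, counts, overlays = ph.enumerate_all(
            fov, [PhenotypeSpec("P2", ("+",))], fov_id="f0")
        written = ph.export_results(records, counts, overlays, tmp_path,
                                    thumbnails=True, fov_images=fov)
        thumbs = [w for w in written if "thumb_" in str(w)]
        assert len(thumbs) == len(records)
        assert (tmp_path / "counts.csv").exists()
        assert (tmp_path / "positions.csv").exists()

    def test_corner_cell_thumbnail_padded(self):
        img = np.random.default_rng(0).random((100, 100))
        t = ph._thumbnail(img, 0, 0, size=120)
        assert t.shape == (120, 120)

    def test_zero_detections(self, tmp_path):
        import pandas as pd
        counts = ph.CountTable(pd.DataFrame(
            [{"fov_id": "f", "phenotype": "P2", "count": 0}]))
        written = ph.export_results([], counts, {}, tmp_path, thumbnails=False)
        assert (tmp_path / "counts.csv").exists()
        assert not [w for w in written if "thumb_" in str(w)]
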