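"""Skewness metric, segmentation, per-cell statistics and PI classification."""

import numpy as np
import pytest
import scipy.stats
import tifffile
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from uvcled import imaging as I
from uvcled import synthetic as S
from tests.conftest import capsule_mask


class TestSkewness:
    def test_symmetric_vector(self):
        g1, zv = I.intensity_skewness([1, 2, 3])
        assert g1 == pytest.approx(0.0, abs=1e-12) and not zv

    def test_single_outlier(self):
        g1, _ = I.intensity_skewness([0, 0, 0, 10])
        assert g1 == pytest.approx(2 / np.sqrt(3), abs=1e-9)

    def test_zero_variance_flag(self):
        g1, zv = I.intensity_skewness([5, 5, 5])
        assert g1 == 0.0 and zv

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            I.intensity_skewness([])

    @given(
        hnp.arrays(
            float,
            st.integers(3, 50),
            elements=st.floats(0, 1000, allow_nan=False, width=32),
        )
    )
    @settings(max_examples=1000, derandomize=True)
    def test_matches_brute_force_moments(self, x):
        """g1 equals the raw population-moment definition and scipy's biased skew."""
        g1, zv = I.intensity_skewness(x)
        d = x - x.mean()
        m2, m3 = (d**2).mean(), (d**3).mean()
        if m2 == 0:
            assert zv and g1 == 0.0
        else:
            assert g1 == pytest.approx(m3 / m2**1.5, rel=1e-9, abs=1e-9)
            assert g1 == pytest.approx(scipy.stats.skew(x, bias=True), rel=1e-7, abs=1e-7)

    @given(
        hnp.arrays(float, 25, elements=st.floats(0, 100, allow_nan=False, width=32)),
        st.floats(0.01, 100),
        st.floats(0, 1000),
    )
    @settings(max_examples=200, derandomize=True)
    def test_affine_invariance(self, x, a, b):
        g1, zv = I.intensity_skewness(x)
        g1t, zvt = I.intensity_skewness(a * x + b)
        if not zv and not zvt:
            assert g1t == pytest.approx(g1, abs=1e-9)


class TestSegmentation:
    def test_well_separated_cells_recovered(self):
        spec = S.SceneSpec(n_cells=10, image_shape=(256, 256), seed=21, pi_positive_prob=0.0)
        scene = S.render_scene(spec)
        mask = I.segment_cells(scene.to_stack(), clear_border=False)
        assert mask.n_labels == 10
        for lab in range(1, 11):
            tm = scene.truth_mask == lab
            seg_lab = np.bincount(mask.labels[tm]).argmax()
            assert seg_lab != 0
            sm = mask.labels == seg_lab
            iou = (tm & sm).sum() / (tm | sm).sum()
            assert iou >= 0.7

    def test_blank_image_empty_mask(self):
        stack = I.ChannelStack(channels={"membrane": np.zeros((64, 64))})
        assert I.segment_cells(stack).n_labels == 0

    def test_touching_rods_split_by_watershed(self):
        shape = (80, 80)
        m = capsule_mask(shape, (40, 25), 0.0, 20, 8) | capsule_mask(
            shape, (40, 44), 0.0, 20, 8
        )
        from skimage.measure import label as cc_label

        assert cc_label(m).max() == 1  # genuinely one touching blob
        stack = I.ChannelStack(channels={"membrane": np.where(m, 160.0, 10.0)})
        assert I.segment_cells(stack, clear_border=False, split=True).n_labels == 2
        assert I.segment_cells(stack, clear_border=False, split=False).n_labels == 1

    def test_missing_channel(self):
        stack = I.ChannelStack(channels={"dna": np.ones((32, 32))})
        with pytest.raises(KeyError):
            I.segment_cells(stack, channel="membrane")


class TestImportLabelMask:
    def test_relabels_to_contiguous(self, tmp_path):
        arr = np.zeros((32, 32), np.uint16)
        arr[2:6, 2:6] = 3
        arr[10:14, 10:14] = 7
        p = tmp_path / "mask.tif"
        tifffile.imwrite(p, arr)
        mask = I.import_label_mask(p)
        assert set(np.unique(mask.labels)) == {0, 1, 2}

    def test_truth_mask_round_trip(self, tmp_path, small_noiseless_scene):
        p = tmp_path / "truth.tif"
        tifffile.imwrite(p, small_noiseless_scene.truth_mask.astype(np.uint16))
        mask = I.import_label_mask(p)
        assert np.array_equal(mask.labels > 0, small_noiseless_scene.truth_mask > 0)
        assert mask.n_labels == small_noiseless_scene.truth_mask.max()

    def test_float_file_rejected(self, tmp_path):
        p = tmp_path / "bad.tif"
        tifffile.imwrite(p, np.ones((16, 16), np.float32))
        with pytest.raises(ValueError):
            I.import_label_mask(p)

    def test_disconnected_label_rejected(self, tmp_path):
        arr = np.zeros((32, 32), np.uint16)
        arr[2:4, 2:4] = 5
        arr[20:22, 20:22] = 5
        p = tmp_path / "split.tif"
        tifffile.imwrite(p, arr)
        with pytest.raises(ValueError):
            I.import_label_mask(p)


class TestPerCellStats:
    def test_flat_cell(self):
        labels = np.zeros((16, 16), np.int32)
        labels[4:8, 4:8] = 1
        stack = I.ChannelStack(channels={"dna": np.full((16, 16), 100.0)})
        (rec,) = I.per_cell_stats(stack, I.LabelMask(labels))
        st_ = rec.channel_stats["dna"]
        assert st_.mean == 100.0 and st_.sd == 0.0
        assert st_.skewness == 0.0 and st_.zero_variance

    def test_two_cells_two_records(self):
        labels = np.zeros((16, 16), np.int32)
        labels[2:5, 2:5] = 1
        labels[10:13, 10:13] = 2
        stack = I.ChannelStack(channels={"dna": np.random.default_rng(0).random((16, 16))})
        assert len(I.per_cell_stats(stack, I.LabelMask(labels))) == 2

    def test_shape_mismatch(self):
        stack = I.ChannelStack(channels={"dna": np.ones((8, 8))})
        with pytest.raises(ValueError):
            I.per_cell_stats(stack, I.LabelMask(np.zeros((16, 16), np.int32)))

    def test_full_condensation_every_cell_skewed(self):
        spec = S.SceneSpec(
            n_cells=30, kappa=1.0, image_shape=(256, 256), seed=4,
            shot_noise=False, gaussian_noise_sd=0.0,
        )
        scene = S.render_scene(spec)
        recs = I.per_cell_stats(scene.to_stack(), scene.truth_label_mask())
        assert all(r.channel_stats["dna"].skewness > 0 for r in recs)


class TestPIClassification:
    def test_truth_mask_fraction_matches_ground_truth(self, default_scene):
        recs = I.per_cell_stats(default_scene.to_stack(), default_scene.truth_label_mask())
        recs = I.classify_pi_positive(recs)
        found = {r.label for r in recs if r.pi_positive}
        truth = set(
            default_scene.truth_table.loc[default_scene.truth_table.pi_state, "label"]
        )
        assert found == truth

    def test_all_negative_scene_zero_fraction(self):
        spec = S.SceneSpec(n_cells=80, pi_positive_prob=0.0, seed=13, image_shape=(300, 300))
        scene = S.render_scene(spec)
        recs = I.classify_pi_positive(
            I.per_cell_stats(scene.to_stack(), scene.truth_label_mask())
        )
        assert sum(r.pi_positive for r in recs) == 0

    def test_missing_pi_channel(self):
        labels = np.zeros((8, 8), np.int32)
        labels[2:4, 2:4] = 1
        stack = I.ChannelStack(channels={"dna": np.ones((8, 8))})
        recs = I.per_cell_stats(stack, I.LabelMask(labels))
        with pytest.raises(KeyError):
            I.classify_pi_positive(recs)


class TestSummaries:
    def _records(self, n, n_pi):
        recs = []
        stats = {"dna": I.ChannelStats(1.0, 0.1, 0.2, False)}
        for i in range(n):
            recs.append(
                I.CellRecord(
                    label=i + 1, area_px=10, area_um2=0.1, centroid=(0, 0),
                    channel_stats=stats, pi_positive=i < n_pi,
                )
            )
        return recs

    def test_pi_fraction_percent(self):
        s = I.summarize_image(self._records(100, 2))
        assert s.pi_fraction == pytest.approx(2.0)
        assert s.n_cells == 100

    def test_condition_mean_and_sample_sd(self):
        # per-image fractions 0.5, 0.8, 1.1 % -> 0.8 ± 0.3 %
        imgs = [
            I.summarize_image(self._records(1000, k)) for k in (5, 8, 11)
        ]
        cond = I.summarize_condition(imgs)
        assert cond.pi_fraction_mean == pytest.approx(0.8, abs=1e-12)
        assert cond.pi_fraction_sd == pytest.approx(0.3, abs=1e-12)

    def test_single_image_sd_undefined(self):
        cond = I.summarize_condition([I.summarize_image(self._records(10, 1))])
        assert np.isnan(cond.pi_fraction_sd)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            I.summarize_image([])
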