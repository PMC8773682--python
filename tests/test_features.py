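import numpy as np
import pytest

from netscan.features import (
    CellRecord,
    TargetMaskParams,
    annexin_descriptors,
    build_target_mask,
    measure_objects,
)
from netscan.imaging_io import (
    ChannelImage,
    ChannelRole,
    ConfigurationError,
    FieldImage,
)
from netscan.segmentation import LabeledMask


def make_field(ch1, ch2=None, annexin=None, px=1.0):
    channels = {
        ChannelRole.NUCLEUS_ALL: ChannelImage(
            np.asarray(ch1, float), 16, ChannelRole.NUCLEUS_ALL, px)
    }
    if ch2 is not None:
        channels[ChannelRole.IMPERMEABLE_DNA] = ChannelImage(
            np.asarray(ch2, float), 16, ChannelRole.IMPERMEABLE_DNA, px)
    if annexin is not None:
        channels[ChannelRole.ANNEXIN] = ChannelImage(
            np.asarray(annexin, float), 16, ChannelRole.ANNEXIN, px)
    return FieldImage("A01", 1, channels)


def disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


class TestBuildTargetMask:
    def test_zero_dilation_is_identity(self):
        labels = disk_mask((50, 50), (25, 25), 8).astype(int)
        mask = LabeledMask(labels, 1)
        out = build_target_mask(mask, TargetMaskParams(dilation_um=0),
                                pixel_size_um=1.0)
        np.testing.assert_array_equal(out.labels, labels)

    def test_disk_dilation_matches_euclidean_growth(self):
        labels = disk_mask((64, 64), (32, 32), 10).astype(int)
        out = build_target_mask(
            LabeledMask(labels, 1), TargetMaskParams(dilation_um=5),
            pixel_size_um=1.0,
        )
        area = (out.labels == 1).sum()
        assert area == pytest.approx(np.pi * 15 ** 2, rel=0.02)
        # brute-force check: exactly pixels within 5 px of the input disk
        from scipy import ndimage as ndi
        dist = ndi.distance_transform_edt(labels == 0)
        np.testing.assert_array_equal(out.labels == 1, dist <= 5)

    def test_contested_pixels_partition_by_nearer_centroid(self):
        labels = np.zeros((40, 60), dtype=int)
        labels[disk_mask((40, 60), (20, 20), 6)] = 1
        labels[disk_mask((40, 60), (20, 40), 6)] = 2
        out = build_target_mask(
            LabeledMask(labels, 2), TargetMaskParams(dilation_um=6),
            pixel_size_um=1.0,
        )
        # every contested pixel assigned to exactly one object
        assert set(np.unique(out.labels)) == {0, 1, 2}
        # midline splits by centroid distance
        left = out.labels[:, :30]
        right = out.labels[:, 31:]
        assert not (left == 2).any() or (left == 2).sum() == 0
        assert not (right == 1).any()
        # each target region contains its own nucleus
        assert (out.labels[labels == 1] == 1).all()
        assert (out.labels[labels == 2] == 2).all()


class TestMeasureObjects:
    def test_no_ch2_foreground_gives_zero_target_area(self):
        labels = disk_mask((40, 40), (20, 20), 6).astype(int)
        field = make_field(np.full((40, 40), 800.0), np.zeros((40, 40)))
        mask = LabeledMask(labels, 1)
        targets = build_target_mask(mask, TargetMaskParams(dilation_um=4), 1.0)
        recs = measure_objects(
            field, mask, targets, np.zeros((40, 40), bool), TargetMaskParams())
        assert recs[0].target_area_ch2_um2 == 0.0

    def test_uniform_ch2_gives_exact_mean(self):
        labels = disk_mask((40, 40), (20, 20), 6).astype(int)
        field = make_field(np.full((40, 40), 800.0), np.full((40, 40), 500.0))
        mask = LabeledMask(labels, 1)
        targets = build_target_mask(mask, TargetMaskParams(dilation_um=4), 1.0)
        recs = measure_objects(
            field, mask, targets, np.ones((40, 40), bool), TargetMaskParams())
        assert recs[0].avg_intensity_ch2 == pytest.approx(500.0)

    def test_target_area_counts_cloud_pixels(self):
        # nucleus of ~80 px inside a 400 px Ch2-positive cloud fully within
        # its target region: target area = cloud area * pixel area
        shape = (80, 80)
        nucleus = disk_mask(shape, (40, 40), 5)
        labels = nucleus.astype(int)
        cloud = disk_mask(shape, (40, 40), 11)   # ~380-400 px
        ch2 = np.where(cloud, 900.0, 0.0)
        field = make_field(np.where(nucleus, 800.0, 0.0), ch2, px=1.0)
        mask = LabeledMask(labels, 1)
        targets = build_target_mask(mask, TargetMaskParams(dilation_um=10), 1.0)
        recs = measure_objects(field, mask, targets, ch2 >= 500.0,
                               TargetMaskParams())
        assert recs[0].target_area_ch2_um2 == float(cloud.sum())

    def test_record_count_equals_objects_and_sorted(self):
        labels = np.zeros((60, 60), dtype=int)
        labels[disk_mask((60, 60), (15, 15), 5)] = 1
        labels[disk_mask((60, 60), (45, 45), 5)] = 2
        field = make_field(np.full((60, 60), 100.0), np.zeros((60, 60)))
        mask = LabeledMask(labels, 2)
        targets = build_target_mask(mask, TargetMaskParams(dilation_um=2), 1.0)
        recs = measure_objects(field, mask, targets,
                               np.zeros((60, 60), bool), TargetMaskParams())
        assert [r.object_id for r in recs] == [1, 2]

    def test_target_area_never_exceeds_region_area(self):
        rng = np.random.default_rng(0)
        labels = np.zeros((60, 60), dtype=int)
        labels[disk_mask((60, 60), (20, 20), 6)] = 1
        labels[disk_mask((60, 60), (40, 42), 6)] = 2
        ch2 = rng.uniform(0, 1000, (60, 60))
        field = make_field(np.full((60, 60), 100.0), ch2)
        mask = LabeledMask(labels, 2)
        targets = build_target_mask(mask, TargetMaskParams(dilation_um=5), 1.0)
        recs = measure_objects(field, mask, targets, ch2 >= 300.0,
                               TargetMaskParams())
        for r in recs:
            region = (targets.labels == r.object_id).sum()
            assert r.target_area_ch2_um2 <= region
        total_fg_in_targets = ((ch2 >= 300.0) & (targets.labels > 0)).sum()
        assert sum(r.target_area_ch2_um2 for r in recs) == pytest.approx(
            total_fg_in_targets)

    def test_translation_invariance(self):
        base = np.zeros((80, 80))
        nucleus = disk_mask((80, 80), (30, 30), 6)
        base[nucleus] = 900.0
        ch2 = np.where(disk_mask((80, 80), (30, 30), 9), 700.0, 0.0)

        def run(shift):
            b = np.roll(base, shift, axis=(0, 1))
            c2 = np.roll(ch2, shift, axis=(0, 1))
            lab = np.roll(nucleus.astype(int), shift, axis=(0, 1))
            field = make_field(b, c2)
            mask = LabeledMask(lab, 1)
            tgt = build_target_mask(mask, TargetMaskParams(dilation_um=6), 1.0)
            return measure_objects(field, mask, tgt, c2 >= 300.0,
                                   TargetMaskParams())[0]

        a, b = run((0, 0)), run((13, 7))
        assert a.area_ch1_um2 == b.area_ch1_um2
        assert a.target_area_ch2_um2 == b.target_area_ch2_um2
        assert a.avg_intensity_ch2 == pytest.approx(b.avg_intensity_ch2)


class TestAnnexinDescriptors:
    def _setup(self, ann):
        labels = disk_mask((60, 60), (30, 30), 8).astype(int)
        mask = LabeledMask(labels, 1)
        field = make_field(np.full((60, 60), 500.0),
                           np.zeros((60, 60)), annexin=ann, px=1.0)
        targets = build_target_mask(mask, TargetMaskParams(dilation_um=4), 1.0)
        return field, mask, targets

    def test_uniform_annexin_ring_ratio_near_one_cv_near_zero(self):
        field, mask, targets = self._setup(np.full((60, 60), 400.0))
        ring, cv = annexin_descriptors(field, mask, targets,
                                       TargetMaskParams(shell_width_um=2.0))
        assert ring[0] == pytest.approx(1.0, abs=0.02)
        assert cv[0] == pytest.approx(0.0, abs=1e-9)

    def test_boundary_ring_gives_large_ratio(self):
        # Annexin confined to the outer 2 px of the target region
        ann = np.zeros((60, 60))
        outer = disk_mask((60, 60), (30, 30), 12)
        inner = disk_mask((60, 60), (30, 30), 10)
        ann[outer & ~inner] = 1000.0
        field, mask, targets = self._setup(ann)
        ring, _ = annexin_descriptors(field, mask, targets,
                                      TargetMaskParams(shell_width_um=2.0))
        assert ring[0] > 5.0

    def test_puncta_give_high_cv(self):
        # 5 disjoint bright puncta on a dark interior: two-valued
        # distribution with closed-form CV = sqrt(p(1-p))/p, p = bright frac
        ann = np.zeros((60, 60))
        centers = [(24, 24), (24, 36), (36, 24), (36, 36), (30, 30)]
        for c in centers:
            ann[disk_mask((60, 60), c, 1)] = 1000.0
        field, mask, targets = self._setup(ann)
        _, cv = annexin_descriptors(field, mask, targets, TargetMaskParams())
        region = targets.labels == 1
        p = (ann[region] > 0).mean()
        expected_cv = np.sqrt(p * (1 - p)) / p
        assert cv[0] == pytest.approx(expected_cv, rel=1e-6)
        assert cv[0] > 1.0

    def test_missing_annexin_channel_is_config_error(self):
        labels = disk_mask((40, 40), (20, 20), 6).astype(int)
        field = make_field(np.full((40, 40), 500.0))
        mask = LabeledMask(labels, 1)
        with pytest.raises(ConfigurationError):
            annexin_descriptors(field, mask, mask, TargetMaskParams())
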