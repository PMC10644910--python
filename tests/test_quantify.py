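import numpy as np
import pytest

from _oracles import covariance_by_loops
from ganglion3d import (
    InstanceLabelMap,
    MultiChannelStack,
    compare_shape_by_class,
    per_object_channel_intensity,
    quantify_objects,
    summarize_stack,
)
from ganglion3d.classify import CLASS_FRR, CLASS_NSRR, ObjectClassification


def _stack_for(labels, spacing=(1.0, 1.0, 1.0), channels=None):
    channels = channels or {"iba1": (labels > 0).astype(np.uint16) * 100}
    return MultiChannelStack(channels=channels, spacing=spacing, source_name="t.tif")


def _digitized_ellipsoid(shape, center, semi_axes):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return q <= 1.0


class TestQuantifyObjects:
    def test_cube_closed_form(self):
        labels = np.zeros((7, 7, 7), dtype=np.int32)
        labels[2:5, 2:5, 2:5] = 1
        m = InstanceLabelMap(labels=labels)
        table = quantify_objects(m, _stack_for(labels))
        row = table.iloc[0]
        assert row.volume_vox == 27
        assert row.volume_um3 == pytest.approx(27.0)
        assert (row.centroid_z_vox, row.centroid_y_vox, row.centroid_x_vox) == (3, 3, 3)

    def test_rod_axis_ratio_matches_covariance_oracle(self):
        labels = np.zeros((3, 3, 25), dtype=np.int32)
        labels[1, 1, 2:23] = 1  # 1x1x21 rod along x
        m = InstanceLabelMap(labels=labels)
        table = quantify_objects(m, _stack_for(labels))
        row = table.iloc[0]
        coords = np.argwhere(labels == 1)
        cov = covariance_by_loops(coords, (1.0, 1.0, 1.0))
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        expected_ratio = np.sqrt(eig[0] / eig[1])
        assert row.elongation == pytest.approx(expected_ratio, rel=1e-9)
        assert row.axis_a_um > row.axis_b_um
        # long axis is x: removing x from the coordinate spread kills the spread
        assert row.axis_b_um == pytest.approx(row.axis_c_um, rel=1e-9)

    def test_constant_channel_stats_exact(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[1:3, 1:3, 1:3] = 1
        stack = _stack_for(labels, channels={"c": np.full((4, 4, 4), 7.0)})
        table = quantify_objects(InstanceLabelMap(labels=labels), stack)
        row = table.iloc[0]
        assert row.c_mean == 7.0
        assert row.c_std == 0.0
        assert row.c_sum == 7.0 * row.volume_vox
        assert row.c_min == row.c_max == 7.0

    def test_volume_conservation(self, two_region_scene):
        m = two_region_scene.truth_labels
        table = quantify_objects(m, two_region_scene.stack)
        assert table.volume_vox.sum() == (m.labels > 0).sum()

    def test_shape_invariance_under_axis_permutation(self):
        # 90-degree rotations permute (a,b,c) without changing the multiset
        shape = (40, 40, 40)
        ell = _digitized_ellipsoid(shape, (20, 20, 20), (14, 8, 5))
        rotated = np.transpose(ell, (2, 0, 1))
        axes = []
        for grid in (ell, rotated):
            labels = grid.astype(np.int32)
            t = quantify_objects(InstanceLabelMap(labels=labels), _stack_for(labels))
            axes.append(tuple(t.iloc[0][["axis_a_um", "axis_b_um", "axis_c_um"]]))
        assert axes[0] == pytest.approx(axes[1], rel=1e-9)

    def test_translation_invariance(self):
        base = np.zeros((20, 20, 20), dtype=np.int32)
        ell = _digitized_ellipsoid((20, 20, 20), (8, 8, 8), (6, 4, 3))
        base[ell] = 1
        shifted = np.roll(base, (3, 4, 5), axis=(0, 1, 2))
        feats = []
        for labels in (base, shifted):
            t = quantify_objects(InstanceLabelMap(labels=labels), _stack_for(labels))
            feats.append(tuple(t.iloc[0][["elongation", "flatness", "ellipticity", "sphericity"]]))
        assert feats[0] == pytest.approx(feats[1], rel=1e-9)

    def test_anisotropic_spacing_enters_physical_axes(self):
        # a z-elongated voxel rod with coarse z-spacing is physically longer
        labels = np.zeros((20, 3, 3), dtype=np.int32)
        labels[2:18, 1, 1] = 1
        iso = quantify_objects(
            InstanceLabelMap(labels=labels, spacing=(1, 1, 1)),
            _stack_for(labels, spacing=(1, 1, 1)),
        ).iloc[0]
        coarse = quantify_objects(
            InstanceLabelMap(labels=labels, spacing=(3, 1, 1)),
            _stack_for(labels, spacing=(3, 1, 1)),
        ).iloc[0]
        assert coarse.axis_a_um == pytest.approx(3 * iso.axis_a_um, rel=1e-6)
        assert coarse.volume_um3 == pytest.approx(3 * iso.volume_um3)

    def test_invariants_on_scene(self, two_region_scene):
        table = quantify_objects(two_region_scene.truth_labels, two_region_scene.stack)
        assert (table.volume_vox >= 1).all()
        assert (table.axis_a_um >= table.axis_b_um - 1e-12).all()
        assert (table.axis_b_um >= table.axis_c_um - 1e-12).all()
        assert (table.elongation >= 1 - 1e-12).all()
        assert ((table.ellipticity >= 0) & (table.ellipticity < 1)).all()
        assert ((table.sphericity > 0) & (table.sphericity <= 1)).all()


class TestSummarizeStack:
    def test_empty_map_gives_zero(self):
        labels = np.zeros((5, 5, 5), dtype=np.int32)
        m = InstanceLabelMap(labels=labels)
        table = quantify_objects(m, _stack_for(labels))
        s = summarize_stack(m, table)
        assert (s.percent_volume == 0).all()
        assert (s["count"] == 0).all()

    def test_fifty_voxels_in_thousand_is_five_percent(self):
        labels = np.zeros((10, 10, 10), dtype=np.int32)
        labels[0, :5, :] = 1  # 50 voxels
        m = InstanceLabelMap(labels=labels)
        table = quantify_objects(m, _stack_for(labels))
        s = summarize_stack(m, table, denominator_mode="stack")
        overall = s[s.cell_class == "ALL"].iloc[0]
        assert overall.percent_volume == pytest.approx(5.0)
        assert overall["count"] == 1

    def test_percent_volume_tracks_generative_fraction(self, separated_scene):
        m = separated_scene.truth_labels
        table = quantify_objects(m, separated_scene.stack)
        s = summarize_stack(m, table)
        truth_fraction = (m.labels > 0).mean()
        overall = s[s.cell_class == "ALL"].iloc[0]
        assert overall.percent_volume == pytest.approx(100 * truth_fraction)

    def test_tissue_denominator_requires_region(self):
        labels = np.zeros((2, 2, 2), dtype=np.int32)
        m = InstanceLabelMap(labels=labels)
        table = quantify_objects(m, _stack_for(labels))
        with pytest.raises(ValueError, match="region"):
            summarize_stack(m, table, denominator_mode="tissue")


class TestShapeAndIntensityReadouts:
    def test_frr_cells_more_elongated_by_construction(self, two_region_scene):
        m = two_region_scene.truth_labels
        from ganglion3d import classify_objects

        c = classify_objects(m, two_region_scene.truth_region)
        table = quantify_objects(m, two_region_scene.stack, c)
        cmp = compare_shape_by_class(table, "elongation")
        means = dict(zip(cmp.cell_class, cmp["mean"]))
        assert means[CLASS_FRR] > means[CLASS_NSRR]

    def test_single_class_yields_one_row(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[1:3, 1:3, 1:3] = 1
        m = InstanceLabelMap(labels=labels)
        c = ObjectClassification(classes={1: CLASS_NSRR}, fractions={})
        table = quantify_objects(m, _stack_for(labels), c)
        assert len(compare_shape_by_class(table, "elongation")) == 1

    def test_unknown_feature_rejected(self, two_region_scene):
        table = quantify_objects(two_region_scene.truth_labels, two_region_scene.stack)
        with pytest.raises(ValueError, match="feature"):
            compare_shape_by_class(table, "roundness")

    def test_tracer_offset_separates_carriers(self):
        from ganglion3d import generate_scene, preset_params

        scene = generate_scene(preset_params("dextran", seed=9))
        table = quantify_objects(scene.truth_labels, scene.stack)
        values = per_object_channel_intensity(table, "dextran")
        truth = scene.truth_table.set_index("cell_id")["dextran_offset"]
        merged = values.set_index("object_id").join(truth)
        carriers = merged[merged.dextran_offset > 0].dextran_mean_intensity
        plain = merged[merged.dextran_offset == 0].dextran_mean_intensity
        assert len(carriers) and len(plain)
        # bimodal separation at the generative +50 offset
        assert carriers.min() > plain.max()
        assert carriers.mean() - plain.mean() == pytest.approx(50, abs=10)

    def test_unknown_channel_rejected(self, two_region_scene):
        table = quantify_objects(two_region_scene.truth_labels, two_region_scene.stack)
        with pytest.raises(ValueError, match="channel"):
            per_object_channel_intensity(table, "gfp")
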