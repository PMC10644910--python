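import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ganglion3d import (
    InstanceLabelMap,
    Manifest,
    ManifestError,
    MultiChannelStack,
    parse_manifest,
    read_label_map,
    read_stack,
    write_cell_table,
    write_label_map,
    write_stack,
)


def _write_manifest(tmp_path, text, name="manifest.txt"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestManifest:
    def test_parses_documented_dialect(self, tmp_path):
        p = _write_manifest(
            tmp_path,
            "channels: [iba1, dextran, cd31]\ntarget: iba1\nbackend: otsu\n",
        )
        m = parse_manifest(p)
        assert m.channel_names == ["iba1", "dextran", "cd31"]
        assert m.target_channel == "iba1"
        assert m.backend == "otsu"

    def test_target_must_be_a_named_channel(self, tmp_path):
        p = _write_manifest(tmp_path, "channels: [iba1, dapi]\ntarget: neun\n")
        with pytest.raises(ManifestError, match="neun"):
            parse_manifest(p)

    def test_misspelled_key_is_rejected_not_defaulted(self, tmp_path):
        p = _write_manifest(tmp_path, "chanels: [iba1]\ntarget: iba1\n")
        with pytest.raises(ManifestError, match="chanels"):
            parse_manifest(p)

    def test_missing_required_key(self, tmp_path):
        p = _write_manifest(tmp_path, "channels: [iba1]\n")
        with pytest.raises(ManifestError, match="target"):
            parse_manifest(p)

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(channel_names=["a", "a"], target_channel="a"), "duplicate"),
            (dict(channel_names=["a"], target_channel="a", backend="probmap"), "probmap_pattern"),
            (dict(channel_names=["a"], target_channel="a", region_source="probmap"), "region_pattern"),
            (dict(channel_names=["a"], target_channel="a", backend="unet"), "backend"),
        ],
    )
    def test_invariant_violations(self, kwargs, match):
        with pytest.raises(ManifestError, match=match):
            Manifest(**kwargs)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_manifest(tmp_path / "nope.txt")


class TestStackIO:
    def test_two_channel_stack_round_trip(self, tmp_path, rng):
        manifest = Manifest(channel_names=["iba1", "dapi"], target_channel="iba1")
        chans = {
            "iba1": rng.integers(0, 500, size=(30, 12, 14)).astype(np.uint16),
            "dapi": rng.integers(0, 500, size=(30, 12, 14)).astype(np.uint16),
        }
        stack = MultiChannelStack(channels=chans, spacing=(2.0, 0.5, 0.5))
        write_stack(stack, tmp_path / "s_stack.tif")
        back = read_stack(tmp_path / "s_stack.tif", manifest)
        assert list(back.channels) == ["iba1", "dapi"]
        assert back.shape == (30, 12, 14)
        assert back.spacing == pytest.approx((2.0, 0.5, 0.5))
        for name in chans:
            np.testing.assert_array_equal(back.channels[name], chans[name])

    def test_channel_count_mismatch(self, tmp_path, rng):
        one = Manifest(channel_names=["iba1"], target_channel="iba1")
        stack = MultiChannelStack(
            channels={"iba1": rng.integers(0, 9, size=(7, 4, 4)).astype(np.uint16)}
        )
        write_stack(stack, tmp_path / "s_stack.tif")
        three = Manifest(channel_names=["a", "b", "c"], target_channel="a")
        with pytest.raises(ValueError, match="not divisible"):
            read_stack(tmp_path / "s_stack.tif", three)

    def test_missing_spacing_warns_and_defaults(self, tmp_path, rng):
        import tifffile

        tifffile.imwrite(tmp_path / "bare.tif", rng.integers(0, 9, (3, 4, 4)).astype(np.uint16))
        m = Manifest(channel_names=["iba1"], target_channel="iba1")
        with pytest.warns(UserWarning, match="spacing"):
            s = read_stack(tmp_path / "bare.tif", m)
        assert s.spacing == (1.0, 1.0, 1.0)

    def test_inconsistent_channel_shapes_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            MultiChannelStack(
                channels={"a": np.zeros((2, 3, 3)), "b": np.zeros((2, 4, 4))}
            )


class TestLabelMapIO:
    def test_distinct_values_preserved(self, tmp_path):
        labels = np.zeros((3, 5, 5), dtype=np.int32)
        labels[0, 0, 0] = 1
        labels[1, 2, 2] = 2
        labels[2, 4, 4] = 7
        write_label_map(InstanceLabelMap(labels=labels), tmp_path / "m.tif")
        back = read_label_map(tmp_path / "m.tif")
        assert set(np.unique(back.labels)) == {0, 1, 2, 7}
        np.testing.assert_array_equal(back.labels, labels)

    def test_empty_map_round_trip(self, tmp_path):
        labels = np.zeros((4, 6, 6), dtype=np.int32)
        write_label_map(InstanceLabelMap(labels=labels), tmp_path / "m.tif")
        back = read_label_map(tmp_path / "m.tif")
        assert back.labels.shape == (4, 6, 6)
        assert back.labels.max() == 0

    def test_many_object_histogram_preserved(self, tmp_path, rng):
        labels = rng.integers(0, 501, size=(10, 40, 40)).astype(np.int32)
        m = InstanceLabelMap(labels=labels)
        write_label_map(m, tmp_path / "m.tif")
        back = read_label_map(tmp_path / "m.tif")
        np.testing.assert_array_equal(
            np.bincount(back.labels.ravel()), np.bincount(labels.ravel())
        )
        np.testing.assert_array_equal(back.labels, labels)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        labels=arrays(
            np.int32,
            st.tuples(st.integers(1, 3), st.integers(1, 6), st.integers(1, 6)),
            elements=st.integers(0, 40),
        )
    )
    def test_round_trip_is_identity(self, tmp_path_factory, labels):
        tmp = tmp_path_factory.mktemp("rt")
        write_label_map(InstanceLabelMap(labels=labels), tmp / "m.tif")
        np.testing.assert_array_equal(read_label_map(tmp / "m.tif").labels, labels)

    def test_negative_labels_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            InstanceLabelMap(labels=np.full((2, 2, 2), -1, dtype=np.int32))


class TestCellTableIO:
    def test_rows_carry_source_names(self, tmp_path):
        table = pd.DataFrame(
            {
                "source_name": ["a.tif", "a.tif", "b.tif"],
                "object_id": [1, 2, 1],
                "cell_class": ["NSRR", "FRR", "UNCLASSIFIED"],
                "volume_vox": [10, 20, 30],
            }
        )
        write_cell_table(table, tmp_path / "cells.csv")
        back = pd.read_csv(tmp_path / "cells.csv")
        assert len(back) == 3
        assert back["source_name"].tolist() == ["a.tif", "a.tif", "b.tif"]

    def test_empty_table_is_header_only(self, tmp_path):
        table = pd.DataFrame(columns=["source_name", "object_id", "cell_class"])
        write_cell_table(table, tmp_path / "cells.csv")
        lines = (tmp_path / "cells.csv").read_text().strip().splitlines()
        assert lines == ["source_name,object_id,cell_class"]
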