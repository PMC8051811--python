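"""Round-trips and layout conventions of every on-disk format."""

import numpy as np
import pytest

from nucannotate import imgio
from nucannotate.core import IntensityImage
from nucannotate.sizefilter import object_areas


class TestImageIO:
    @pytest.mark.parametrize("ext,depth", [(".tif", 16), (".tif", 8), (".png", 8), (".png", 16)])
    def test_round_trip_lossless(self, tmp_path, ext, depth):
        rng = np.random.default_rng(0)
        arr = rng.integers(0, 2**depth, size=(40, 56)).astype(
            np.uint16 if depth == 16 else np.uint8
        )
        path = imgio.write_image(IntensityImage(arr, depth), tmp_path / f"img{ext}")
        back = imgio.read_image(path)
        assert back.bit_depth == depth
        np.testing.assert_array_equal(back.pixels, arr)

    def test_all_zero_png_reads_back(self, tmp_path):
        path = imgio.write_image(IntensityImage(np.zeros((16, 16), np.uint8), 8), tmp_path / "z.png")
        back = imgio.read_image(path)
        assert back.bit_depth == 8 and back.pixels.max() == 0

    def test_rgb_with_identical_channels_collapses(self, tmp_path):
        import imageio.v3 as iio

        gray = np.arange(64, dtype=np.uint8).reshape(8, 8)
        iio.imwrite(tmp_path / "rgb.png", np.stack([gray] * 3, axis=-1))
        back = imgio.read_image(tmp_path / "rgb.png")
        np.testing.assert_array_equal(back.pixels, gray)

    def test_true_color_rejected(self, tmp_path):
        import imageio.v3 as iio

        rgb = np.zeros((8, 8, 3), np.uint8)
        rgb[:, :, 0] = 200
        iio.imwrite(tmp_path / "color.png", rgb)
        with pytest.raises(imgio.UnsupportedImageError):
            imgio.read_image(tmp_path / "color.png")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            imgio.read_image(tmp_path / "nope.tif")


class TestLabelMapIO:
    def test_round_trip(self, tmp_path):
        lab = np.zeros((20, 20), np.int32)
        for k in range(1, 11):
            lab[k, : k + 1] = k
        path = imgio.write_labelmap(lab, tmp_path / "lab.tif")
        np.testing.assert_array_equal(imgio.read_labelmap(path), lab)

    def test_all_zero_map(self, tmp_path):
        path = imgio.write_labelmap(np.zeros((8, 8), np.int32), tmp_path / "z.tif")
        assert imgio.read_labelmap(path).max() == 0

    def test_capacity_error_above_16bit(self, tmp_path):
        lab = np.full((4, 4), 70000, np.int64)
        with pytest.raises(ValueError, match="capacity"):
            imgio.write_labelmap(lab, tmp_path / "big.tif")


class TestInstanceMaskLayout:
    def _sample(self):
        lab = np.zeros((32, 32), np.int32)
        lab[2:8, 2:8] = 1
        lab[10:20, 10:18] = 2
        lab[25:30, 3:9] = 3
        img = IntensityImage((lab > 0).astype(np.uint8) * 200, 8)
        return img, lab

    def test_export_writes_one_mask_per_instance(self, tmp_path):
        img, lab = self._sample()
        root = imgio.export_instance_masks(img, lab, tmp_path, "s1")
        assert (root / "images" / "s1.png").exists()
        assert len(list((root / "masks").glob("*.png"))) == 3

    def test_reimport_reproduces_map_up_to_permutation(self, tmp_path):
        img, lab = self._sample()
        root = imgio.export_instance_masks(img, lab, tmp_path, "s1")
        back = imgio.read_instance_masks(root)
        # same foreground, and a bijection between label sets
        np.testing.assert_array_equal(back > 0, lab > 0)
        pairs = {(int(a), int(b)) for a, b in zip(lab[lab > 0], back[back > 0])}
        assert len(pairs) == 3  # one-to-one
        assert len({a for a, _ in pairs}) == 3 and len({b for _, b in pairs}) == 3

    def test_empty_map_warns_and_writes_no_masks(self, tmp_path):
        img = IntensityImage(np.zeros((16, 16), np.uint8), 8)
        with pytest.warns(UserWarning, match="empty"):
            root = imgio.export_instance_masks(img, np.zeros((16, 16), np.int32), tmp_path, "e")
        assert not (root / "masks").exists()


class TestObjectTableIO:
    def test_round_trip_identity(self, tmp_path):
        lab = np.zeros((30, 30), np.int32)
        lab[5:10, 5:10] = 1
        lab[15:25, 2:12] = 2
        table = object_areas(lab)
        table.loc[1, "kept"] = False
        table["class"] = ["single", "cluster"]
        path = imgio.write_object_table(table, tmp_path / "t.csv")
        back = imgio.read_object_table(path)
        import pandas as pd

        pd.testing.assert_frame_equal(back, table.reset_index(drop=True))

    def test_empty_table_is_header_only(self, tmp_path):
        path = imgio.write_object_table(object_areas(np.zeros((8, 8), np.int32)), tmp_path / "e.csv")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert imgio.read_object_table(path).empty

    def test_non_numeric_area_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "id,area_px,bbox_r0,bbox_c0,bbox_r1,bbox_c1,centroid_r,centroid_c,kept,class\n"
            "1,abc,0,0,2,2,1.0,1.0,True,single\n"
        )
        with pytest.raises(imgio.ObjectTableParseError, match="line 2"):
            imgio.read_object_table(path)

    def test_bbox_matches_brute_force_extents(self, small_field):
        _, gt = small_field
        for row in gt.objects.itertuples(index=False):
            rr, cc = np.nonzero(gt.label_map == row.id)
            assert (row.bbox_r0, row.bbox_c0) == (rr.min(), cc.min())
            assert (row.bbox_r1, row.bbox_c1) == (rr.max() + 1, cc.max() + 1)


class TestManifest:
    def test_manifest_round_trip_and_validation(self, tmp_path):
        arr = np.zeros((16, 16), np.uint8)
        imgio.write_image(IntensityImage(arr, 8), tmp_path / "a.tif")
        imgio.write_labelmap(np.zeros((16, 16), np.int32), tmp_path / "a_labels.tif")
        entries = [{"image_path": "a.tif", "labelmap_path": "a_labels.tif", "split": "train"}]
        path = imgio.write_manifest(entries, tmp_path)
        payload = imgio.read_manifest(path)
        assert payload["entries"] == entries

    def test_missing_reference_rejected(self, tmp_path):
        path = imgio.write_manifest(
            [{"image_path": "gone.tif", "split": "test"}], tmp_path
        )
        with pytest.raises(FileNotFoundError):
            imgio.read_manifest(path)
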