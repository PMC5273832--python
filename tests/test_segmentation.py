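import numpy as np
import pytest

import tmjmorph as tm
from tmjmorph.segmentation import CropBox, SegmentationConfig


class TestCrop:
    def test_box_containing_volume_is_identity(self, clean_phantom):
        bone = clean_phantom["bone"]
        box = CropBox(center=tuple(bone.world_center()), extents=(500.0, 500.0, 500.0))
        out = tm.crop(bone, box)
        assert out.shape == bone.shape
        assert np.array_equal(out.data, bone.data)

    def test_clinical_box_voxel_counts(self):
        """A 2.5 x 2.7 x 2.5 cm box on a 0.25 mm grid spans 100x108x100 voxels."""
        vol = tm.VoxelVolume(np.zeros((160, 160, 160)), spacing=(0.25, 0.25, 0.25))
        box = CropBox(center=(20.0, 20.0, 20.0), extents=(25.0, 27.0, 25.0))
        assert tm.crop(vol, box).shape == (100, 108, 100)

    def test_disjoint_box_rejected(self):
        vol = tm.VoxelVolume(np.zeros((10, 10, 10)), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="intersect"):
            tm.crop(vol, CropBox(center=(100.0, 0.0, 0.0), extents=(5.0, 5.0, 5.0)))
        with pytest.raises(ValueError):
            CropBox(center=(0, 0, 0), extents=(1.0, -1.0, 1.0))

    def test_crop_updates_origin(self):
        vol = tm.VoxelVolume(np.arange(1000).reshape(10, 10, 10).astype(float),
                             spacing=(1, 1, 1), origin=(0, 0, 0))
        out = tm.crop(vol, CropBox(center=(5.0, 5.0, 5.0), extents=(4.0, 4.0, 4.0)))
        assert np.allclose(out.origin, [3, 3, 3])
        assert out.data[0, 0, 0] == vol.data[3, 3, 3]


class TestThresholdSegment:
    def test_noise_free_bright_segmentation_is_exact(self, clean_phantom):
        mask = tm.threshold_segment(clean_phantom["bone"], SegmentationConfig())
        assert np.array_equal(mask.data, clean_phantom["condyle"].data)

    def test_noise_free_dark_segmentation_recovers_disc(self, clean_phantom):
        cfg = SegmentationConfig(threshold=0.12, polarity="dark")
        mask = tm.threshold_segment(clean_phantom["soft"], cfg)
        assert np.array_equal(mask.data, clean_phantom["disc"].data)

    def test_noisy_condyle_dice_above_095(self, noisy_phantom):
        mask = tm.threshold_segment(noisy_phantom["bone"], SegmentationConfig())
        dsi = tm.dice_similarity(mask, noisy_phantom["condyle"]).dsi
        assert dsi >= 0.95

    def test_all_background_raises_naming_stage(self):
        vol = tm.VoxelVolume(np.full((8, 8, 8), 0.3), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="threshold"):
            tm.threshold_segment(vol, SegmentationConfig(threshold=0.9, polarity="bright"))

    def test_min_component_filter_can_empty_mask(self):
        data = np.full((10, 10, 10), 0.1)
        data[2, 2, 2] = 1.0  # a single bright voxel
        vol = tm.VoxelVolume(data, spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="component"):
            tm.threshold_segment(vol, SegmentationConfig(threshold=0.5, min_component_size=5))

    def test_largest_component_selected(self):
        data = np.full((20, 10, 10), 0.0)
        data[0:2, 0:2, 0:2] = 1.0    # 8 voxels
        data[10:16, 2:8, 2:8] = 1.0  # 216 voxels
        vol = tm.VoxelVolume(data, spacing=(1, 1, 1))
        mask = tm.threshold_segment(vol, SegmentationConfig(threshold=0.5))
        assert mask.voxel_count == 216


class TestManualEdits:
    def make(self, shape=(6, 6, 6)):
        base = np.zeros(shape, dtype=np.uint8)
        base[1:4, 1:4, 1:4] = 1
        return tm.MaskVolume(base, spacing=(1, 1, 1))

    def test_empty_edits_are_identity(self):
        mask = self.make()
        out = tm.apply_manual_edits(mask)
        assert np.array_equal(out.data, mask.data)

    def test_erase_everything(self):
        mask = self.make()
        out = tm.apply_manual_edits(mask, erase_mask=mask)
        assert out.voxel_count == 0

    def test_erase_wins_over_add_and_is_idempotent(self):
        mask = self.make()
        add = tm.MaskVolume(np.ones_like(mask.data), spacing=(1, 1, 1))
        erase = self.make()
        once = tm.apply_manual_edits(mask, add_mask=add, erase_mask=erase)
        assert not np.logical_and(once.data, erase.data).any()
        twice = tm.apply_manual_edits(once, add_mask=add, erase_mask=erase)
        assert np.array_equal(once.data, twice.data)

    def test_grid_mismatch_rejected(self):
        mask = self.make()
        other = tm.MaskVolume(np.zeros((6, 6, 6), dtype=np.uint8), spacing=(2, 1, 1))
        with pytest.raises(ValueError, match="grid"):
            tm.apply_manual_edits(mask, add_mask=other)


class TestMaskToMesh:
    def test_sphere_area_within_3_percent(self):
        ball = tm.ball_mask(10.0, spacing=0.25)
        mesh = tm.mask_to_mesh(ball)
        assert mesh.area() == pytest.approx(4 * np.pi * 100.0, rel=0.03)

    def test_enclosed_volume_matches_voxel_count(self):
        ball = tm.ball_mask(10.0, spacing=0.25)
        assert tm.mask_to_mesh(ball).volume() == pytest.approx(ball.volume_mm3, rel=0.02)

    def test_condyle_volume_close_despite_rim_rounding(self, clean_phantom):
        # the half-ellipsoid's sharp base rim gets rounded by pre-smoothing;
        # the volume deficit stays small
        condyle = clean_phantom["condyle"]
        mesh = tm.mask_to_mesh(condyle)
        assert mesh.volume() == pytest.approx(condyle.volume_mm3, rel=0.04)

    def test_single_voxel_yields_closed_positive_volume(self):
        data = np.zeros((5, 5, 5), dtype=np.uint8)
        data[2, 2, 2] = 1
        mesh = tm.mask_to_mesh(tm.MaskVolume(data, spacing=(1, 1, 1)))
        assert mesh.volume() > 0

    def test_watertight_for_solid_mask(self, clean_phantom):
        mesh = tm.mask_to_mesh(clean_phantom["condyle"])
        edges = np.sort(mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        assert np.all(counts == 2)  # every edge shared by exactly two faces

    def test_empty_mask_rejected(self):
        empty = tm.MaskVolume(np.zeros((4, 4, 4), dtype=np.uint8), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            tm.mask_to_mesh(empty)

    def test_vertices_in_world_coordinates(self):
        ball = tm.ball_mask(5.0, spacing=0.5)
        mesh = tm.mask_to_mesh(ball)
        radii = np.linalg.norm(mesh.vertices, axis=1)  # ball centered at origin
        assert abs(radii.mean() - 5.0) < 0.2
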