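"""Segmentation, cropping, centroid alignment and surface labeling."""

import numpy as np
import pytest

import osteoadapt as oa
from osteoadapt.image import GrayImage
from osteoadapt.imageproc import BinaryMask, SurfaceClass

from conftest import PHANTOM_THRESHOLD


def _image_from_histogram(values, counts):
    """A flat 3D image realizing a given gray-value histogram."""
    data = np.repeat(np.asarray(values, dtype=float), counts)
    side = int(np.ceil(len(data) ** (1 / 3))) + 1
    arr = np.full(side**3, data[0])
    arr[: len(data)] = data
    return GrayImage(values=arr.reshape(side, side, side))


class TestGlobalThreshold:
    def test_midpoint_of_two_peaks(self):
        img = _image_from_histogram([50, 190], [500, 300])
        assert oa.select_global_threshold(img) == pytest.approx(120.0)

    @pytest.mark.parametrize("t", [30, 77, 150])
    def test_symmetric_peaks_give_center(self, t):
        img = _image_from_histogram([0, 2 * t], [400, 400])
        assert oa.select_global_threshold(img) == pytest.approx(float(t))

    def test_noisy_phantom_threshold_near_midpoint(self):
        spec = oa.standard_tube_spec(n_slices=40, noise_sd=5.0, seed=2)
        image, _ = oa.make_phantom(spec)
        thr = oa.select_global_threshold(image)
        assert abs(thr - PHANTOM_THRESHOLD) <= 2.0

    def test_unimodal_histogram_instructs_override(self):
        img = _image_from_histogram([100], [1000])
        with pytest.raises(ValueError, match="explicit threshold"):
            oa.select_global_threshold(img)


class TestBinarize:
    def test_all_background_empty_mask(self):
        img = GrayImage(values=np.full((4, 4, 4), 10.0))
        assert oa.binarize(img, 50.0).voxel_count == 0

    def test_noiseless_phantom_recovers_ground_truth(self):
        spec = oa.standard_tube_spec(n_slices=20)
        image, mask = oa.make_phantom(spec)
        got = oa.binarize(image, oa.select_global_threshold(image))
        assert np.array_equal(got.values, mask.values)

    def test_threshold_at_minimum_selects_everything(self):
        img = GrayImage(values=np.random.default_rng(0).uniform(5, 9, (3, 3, 3)))
        assert oa.binarize(img, float(img.values.min())).voxel_count == 27


class TestCropToLength:
    def test_full_fraction_is_identity(self):
        img = GrayImage(values=np.arange(150 * 4).reshape(150, 2, 2).astype(float))
        out = oa.crop_to_length(img, reference_slice=149, fraction=1.0)
        assert np.array_equal(out.values, img.values)

    def test_eighty_percent_of_150_slices(self):
        img = GrayImage(values=np.zeros((150, 2, 2)))
        out = oa.crop_to_length(img, reference_slice=149, fraction=0.8)
        assert out.n_slices == 120

    def test_crop_composition_lengths(self):
        img = GrayImage(values=np.zeros((150, 2, 2)))
        twice = oa.crop_to_length(
            oa.crop_to_length(img, 149, 0.8), 119, 0.8
        )
        once = oa.crop_to_length(img, 149, 0.64)
        assert twice.n_slices == once.n_slices == 96

    def test_output_keeps_distal_orientation(self):
        img = GrayImage(values=np.arange(20).reshape(20, 1, 1).astype(float) + 0 * np.zeros((20, 1, 1)))
        out = oa.crop_to_length(img, reference_slice=15, fraction=0.6)
        # 12 slices ending at the reference, slice 0 still most distal
        assert out.n_slices == 12
        assert out.values[0, 0, 0] == 4.0
        assert out.values[-1, 0, 0] == 15.0

    def test_too_short_result_rejected(self):
        img = GrayImage(values=np.zeros((15, 2, 2)))
        with pytest.raises(ValueError, match="10 sections"):
            oa.crop_to_length(img, 14, 0.5)


class TestAlignByCentroid:
    def test_identical_volumes_zero_shift(self):
        spec = oa.standard_tube_spec(n_slices=12)
        image, mask = oa.make_phantom(spec)
        _, _, shift, _ = oa.align_by_centroid(mask, image, mask)
        assert shift == (0, 0, 0)

    def test_translation_recovered(self):
        spec = oa.standard_tube_spec(n_slices=20)
        image, mask = oa.make_phantom(spec)
        nz, ny, nx = mask.shape
        ref_vals = np.full((nz + 10, ny, nx), 40.0)
        ref_mask = np.zeros((nz + 10, ny, nx), dtype=bool)
        ref_vals[3 : 3 + nz] = image.values
        ref_mask[3 : 3 + nz] = mask.values
        moved = np.roll(ref_vals, (5, -2, 3), axis=(0, 1, 2))
        moved_mask = np.roll(ref_mask, (5, -2, 3), axis=(0, 1, 2))
        _, mask_al, shift, ref_z = oa.align_by_centroid(
            BinaryMask(values=ref_mask),
            GrayImage(values=moved),
            BinaryMask(values=moved_mask),
        )
        assert shift == (-5, 2, -3)
        # aligned content matches the reference on the overlap
        assert np.array_equal(mask_al.values, ref_mask[ref_z, 2:, :-3])

    def test_subvoxel_offset_rounds_to_zero(self):
        spec = oa.standard_tube_spec(n_slices=12)
        _, ref_mask = oa.make_phantom(spec)
        shifted_spec = oa.PhantomSpec(
            grid_shape=spec.grid_shape,
            outer_radii=spec.outer_radii,
            inner_radii=spec.inner_radii,
            center_offset=(0.4 * spec.spacing, 0.0),
        )
        image, mask = oa.make_phantom(shifted_spec)
        _, _, shift, _ = oa.align_by_centroid(ref_mask, image, mask)
        assert shift == (0, 0, 0)

    def test_empty_mask_rejected(self):
        empty = BinaryMask(values=np.zeros((3, 3, 3), dtype=bool))
        img = GrayImage(values=np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            oa.align_by_centroid(empty, img, empty)


class TestFindSurfaces:
    def test_one_voxel_thick_ring(self):
        sl = np.zeros((9, 9), dtype=bool)
        sl[2:7, 2:7] = True
        sl[3:6, 3:6] = False  # hollow square ring, one voxel thick
        mask = BinaryMask(values=sl[None, :, :])
        labels = oa.find_surfaces(mask).labels[0]
        # every ring voxel touches the outside -> periosteal (tie-break)
        assert np.all(labels[sl] == SurfaceClass.PERIOSTEAL)
        assert not np.any(labels == SurfaceClass.ENDOSTEAL)

    def test_thick_ring_has_endosteal_interior_facing_voxels(self):
        sl = np.zeros((11, 11), dtype=bool)
        sl[2:9, 2:9] = True
        sl[4:7, 4:7] = False  # 2-voxel-thick walls
        mask = BinaryMask(values=sl[None, :, :])
        surf = oa.find_surfaces(mask)
        labels = surf.labels[0]
        assert np.any(labels == SurfaceClass.ENDOSTEAL)
        # endosteal voxels all touch the hole, never the exterior
        endo = labels == SurfaceClass.ENDOSTEAL
        assert np.all(sl[endo])

    def test_solid_disk_has_no_endosteal(self):
        yy, xx = np.mgrid[:15, :15]
        disk = (xx - 7) ** 2 + (yy - 7) ** 2 <= 25
        surf = oa.find_surfaces(BinaryMask(values=disk[None]))
        assert not surf.endosteal.any()
        assert surf.periosteal.any()

    def test_annulus_counts_match_brute_force(self):
        spec = oa.standard_tube_spec(n_slices=3)
        _, mask = oa.make_phantom(spec)
        surf = oa.find_surfaces(mask)
        bone = mask.values
        exterior, medullary = (
            surf.exterior,
            surf.medullary,
        )
        nz, ny, nx = bone.shape
        # brute-force neighbor scan (6-adjacency)
        peri = np.zeros_like(bone)
        endo = np.zeros_like(bone)
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    if not bone[z, y, x]:
                        continue
                    nbrs = []
                    for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                        zz, yy, xx = z + dz, y + dy, x + dx
                        if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                            nbrs.append((zz, yy, xx))
                    if any(exterior[n] for n in nbrs):
                        peri[z, y, x] = True
                    elif any(medullary[n] for n in nbrs):
                        endo[z, y, x] = True
        assert np.array_equal(surf.periosteal, peri)
        assert np.array_equal(surf.endosteal, endo)

    def test_labels_partition(self, tiny_tube):
        _, _, mask = tiny_tube
        surf = oa.find_surfaces(mask)
        assert not np.any(surf.periosteal & surf.endosteal)
        assert np.all(mask.values[surf.surface])


class TestFillPeriosteal:
    def test_annulus_fills_to_disk_count(self):
        spec = oa.standard_tube_spec(n_slices=2, outer_radius_vox=12, inner_radius_vox=7)
        _, mask = oa.make_phantom(spec)
        filled = oa.fill_periosteal(mask)
        # voxel-center disk-count oracle
        nx, ny, _ = spec.grid_shape
        h = spec.spacing
        cx = nx * h / 2
        n_disk = sum(
            ((ix + 0.5) * h - cx) ** 2 + ((iy + 0.5) * h - cx) ** 2 <= 124.8**2
            for ix in range(nx)
            for iy in range(ny)
        )
        assert filled.values[0].sum() == n_disk

    def test_solid_mask_unchanged(self):
        m = BinaryMask(values=np.ones((2, 5, 5), dtype=bool))
        assert np.array_equal(oa.fill_periosteal(m).values, m.values)

    def test_empty_mask_unchanged(self):
        m = BinaryMask(values=np.zeros((2, 5, 5), dtype=bool))
        assert oa.fill_periosteal(m).voxel_count == 0

    def test_bv_never_exceeds_tv(self, tiny_tube):
        _, _, mask = tiny_tube
        assert mask.voxel_count <= oa.fill_periosteal(mask).voxel_count
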