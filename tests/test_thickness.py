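"""Maximal-inscribed-sphere local thickness and the Tb.Th./Tb.Sp. statistics."""

import numpy as np
import pytest
from scipy import ndimage

from trabemorph import (VoxelImage, local_thickness, plate_stack, read_volume,
                        rod_array, sphere, tb_stats, thickness_map_export)
from trabemorph.errors import DegeneratePhaseError

H = 0.018


def _slab(n_layers, dims=(32, 32, 32)):
    """Full-extent slab of n layers centred along z."""
    data = np.zeros(dims, np.uint8)
    z0 = (dims[0] - n_layers) // 2
    data[z0:z0 + n_layers] = 1
    return VoxelImage(data, H, is_binary=True)


class TestLocalThickness:
    def test_slab_interior_plateau(self):
        img = _slab(11, (31, 40, 40))
        tmap = local_thickness(img, "foreground", "include_edges")
        interior = tmap.values[15, 10:30, 10:30]
        np.testing.assert_allclose(interior, 11 * H, atol=H + 1e-12)
        # plateau is uniform
        assert interior.std() == 0.0

    def test_rod_modal_thickness(self):
        img, gt = rod_array(d=15, s=None, dims=(48, 40, 40))
        tmap = local_thickness(img, "foreground", "include_edges")
        vals = tmap.values[tmap.values > 0]
        modal = np.bincount(np.round(vals / H).astype(int)).argmax()
        assert abs(modal - 15) <= 1

    def test_single_voxel_one_voxel_diameter(self):
        data = np.zeros((9, 9, 9), np.uint8)
        data[4, 4, 4] = 1
        tmap = local_thickness(VoxelImage(data, H, is_binary=True))
        assert tmap.values[4, 4, 4] == pytest.approx(H)

    def test_values_only_inside_phase_and_at_least_voxel(self):
        img, _ = rod_array(d=7, s=16, dims=(16, 32, 32))
        tmap = local_thickness(img, "foreground")
        fg = img.foreground_mask()
        assert (tmap.values[~fg] == 0).all()
        assert (tmap.values[fg] >= H - 1e-12).all()

    def test_axis_permutation_equivariance(self):
        img, _ = plate_stack(t=5, g=6, dims=(27, 20, 20))
        perm = VoxelImage(np.moveaxis(img.data, 0, 2).copy(), H, is_binary=True)
        a = local_thickness(img).values
        b = local_thickness(perm).values
        np.testing.assert_allclose(np.moveaxis(a, 0, 2), b, atol=1e-12)

    def test_monotone_under_dilation(self):
        from trabemorph import isotropic_foam

        img, _ = isotropic_foam(dims=(24, 24, 24), corr_length=3, seed=9)
        dilated = VoxelImage(
            ndimage.binary_dilation(img.foreground_mask()).astype(np.uint8),
            H, is_binary=True)
        before = local_thickness(img).values
        after = local_thickness(dilated).values
        fg = img.foreground_mask()
        assert (after[fg] >= before[fg] - 1e-12).all()

    def test_edge_policies_agree_for_interior_phantom(self):
        img, _ = sphere(r=8, dims=(28, 28, 28))
        inc = local_thickness(img, "foreground", "include_edges")
        exc = local_thickness(img, "foreground", "exclude_edge_voxels")
        np.testing.assert_allclose(inc.values, exc.values, atol=1e-12)
        assert not exc.excluded.any()

    def test_exclusion_only_near_roi_faces(self):
        # Structure touching the ROI faces: excluded voxels must hug the cut planes.
        img, _ = plate_stack(t=5, g=9, dims=(19, 24, 24))
        exc = local_thickness(img, "background", "exclude_edge_voxels")
        if exc.excluded.any():
            zz, yy, xx = np.nonzero(exc.excluded)
            dist_to_face = np.minimum.reduce([
                np.minimum(zz, 18 - zz), np.minimum(yy, 23 - yy),
                np.minimum(xx, 23 - xx)])
            assert dist_to_face.max() <= 9

    def test_degenerate_phases_raise(self):
        solid = VoxelImage(np.ones((6, 6, 6), np.uint8), H, is_binary=True)
        with pytest.raises(DegeneratePhaseError):
            local_thickness(solid, "background")
        with pytest.raises(DegeneratePhaseError):
            local_thickness(solid, "foreground", "exclude_edge_voxels")


class TestTbStats:
    def test_slab_mean_and_sd(self):
        img = _slab(11, (31, 48, 48))
        mean, sd = tb_stats(local_thickness(img))
        assert abs(mean - 11 * H) <= H
        # excluding cut-truncated voxels leaves the exact uniform plateau
        mean_x, sd_x = tb_stats(local_thickness(img, "foreground",
                                                "exclude_edge_voxels"))
        assert mean_x == pytest.approx(11 * H, abs=1e-12)
        assert sd_x == pytest.approx(0.0, abs=1e-15)

    def test_tb_sp_equals_complement_tb_th_exactly(self):
        img, _ = plate_stack(t=5, g=8, dims=(31, 20, 20))
        sp = local_thickness(img, "background", "include_edges")
        th_of_complement = local_thickness(img.complement(), "foreground",
                                           "include_edges")
        np.testing.assert_array_equal(sp.values, th_of_complement.values)

    def test_plate_gap_separation(self):
        # Odd gap: the centre-to-centre sphere convention is exact in the
        # interior; the ROI-face deficit at this extent stays below a voxel.
        img, gt = plate_stack(t=11, g=23, dims=(113, 128, 128))
        mean, _ = tb_stats(local_thickness(img, "background"))
        assert abs(mean - gt.tb_sp_mm) <= H

    def test_even_gap_centre_discretisation(self):
        # Even widths admit no voxel-centred maximal sphere of full width:
        # the plateau sits exactly one voxel below the nominal gap.
        img, gt = plate_stack(t=11, g=22, dims=(110, 48, 48))
        exc = local_thickness(img, "background", "exclude_edge_voxels")
        mean, sd = tb_stats(exc)
        assert mean == pytest.approx(21 * H, abs=1e-9)
        assert abs(mean - gt.tb_sp_mm) <= H + 1e-9

    def test_all_excluded_raises(self):
        data = np.zeros((7, 7, 7), np.uint8)
        data[3, 3, 3] = 1  # only background exists around a dot; exclude all fg? no:
        img = VoxelImage(1 - data, H, is_binary=True)  # background = single voxel
        tmap = local_thickness(img, "background", "include_edges")
        tmap.excluded[:] = True
        with pytest.raises(DegeneratePhaseError):
            tb_stats(tmap)


class TestThicknessExport:
    def test_roundtrip_and_plateau(self, tmp_path):
        img = _slab(11, (31, 24, 24))
        tmap = local_thickness(img)
        path = thickness_map_export(tmap, tmp_path / "th.mhd")
        back = read_volume(path)
        assert not back.is_binary
        np.testing.assert_allclose(back.data, tmap.values.astype(np.float32),
                                   rtol=0, atol=0)
        assert back.data[15, 12, 12] == pytest.approx(0.198, abs=1e-6)

    def test_edge_policy_difference_localised_to_faces(self, tmp_path):
        img, _ = plate_stack(t=7, g=9, dims=(23, 32, 32))
        inc = local_thickness(img, "foreground", "include_edges")
        exc = local_thickness(img, "foreground", "exclude_edge_voxels")
        diff_mask = ~np.isclose(inc.values, exc.values) | exc.excluded
        if diff_mask.any():
            zz, yy, xx = np.nonzero(diff_mask)
            dist = np.minimum.reduce([np.minimum(zz, 22 - zz),
                                      np.minimum(yy, 31 - yy),
                                      np.minimum(xx, 31 - xx)])
            assert dist.max() <= 7
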