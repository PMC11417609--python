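"""Distance-transform morphometry: oracle equivalence, phantom recovery,
derived outcomes, geometric invariances."""

import numpy as np
import pytest
from conftest import thickness_oracle

from xcal.morphometry import (
    bvtv,
    cortical_metrics,
    density_geometry,
    direct_tb_n,
    direct_tb_sp,
    direct_tb_th,
    indirect_morphometry,
    local_thickness,
    tb_1_n_sd,
)
from xcal.phantoms import PhantomSpec, generate_phantom
from xcal.volume import BinaryVolume, ImageVolume


class TestLocalThickness:
    def test_matches_brute_force_oracle_exactly(self, slab5, ball11, random_blobs):
        for phase in [slab5, ball11, *random_blobs]:
            got = local_thickness(phase, voxel_um=1.0).values_um
            want = thickness_oracle(phase)
            assert np.array_equal(np.nan_to_num(got), np.nan_to_num(want))

    def test_slab_five_voxels_thick(self, slab5):
        tm = local_thickness(slab5, voxel_um=1.0)
        vals = tm.values_um[slab5]
        assert np.all(np.abs(vals - 5.0) <= 0.5)

    def test_ball_diameter_eleven(self, ball11):
        tm = local_thickness(ball11, voxel_um=1.0)
        assert np.nanmax(tm.values_um) == pytest.approx(11.0, abs=1.0)

    def test_single_voxel(self):
        phase = np.zeros((8, 8, 8), bool)
        phase[4, 4, 4] = True
        tm = local_thickness(phase, voxel_um=1.0)
        assert tm.values_um[4, 4, 4] == 1.0

    def test_empty_phase_rejected(self):
        with pytest.raises(ValueError, match="empty phase"):
            local_thickness(np.zeros((8, 8, 8), bool), voxel_um=1.0)

    def test_physical_units_scale_with_voxel_size(self, slab5):
        tm = local_thickness(slab5, voxel_um=20.0)
        assert np.nanmax(tm.values_um) == pytest.approx(100.0)


class TestBvtv:
    def test_half_of_mask(self):
        mask = np.ones((10, 10, 10), bool)
        bone = np.zeros_like(mask)
        bone[:5] = True
        assert bvtv(bone, mask) == 0.5

    def test_no_bone(self):
        mask = np.ones((6, 6, 6), bool)
        assert bvtv(np.zeros_like(mask), mask) == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bvtv(np.ones((4, 4, 4), bool), np.zeros((4, 4, 4), bool))

    def test_plate_phantom_raster_matches_analytic(self):
        spec = PhantomSpec("plate_lattice", (2.0, 0.4, 0.4),
                           {"thickness_um": 200.0, "spacing_um": 1000.0})
        vol, truth = generate_phantom(spec, 20.0)
        mask = np.ones(vol.shape, bool)
        assert bvtv(vol, mask) == pytest.approx(truth.bvtv_true, abs=0.01)


def plate_volume(width=5, pitch=50, n_axial=150, lateral=12, voxel_um=20.0):
    """Plates of exactly `width` voxels repeating at `pitch`, near mid-gap
    volume borders."""
    start = (pitch - width) // 2
    z = np.arange(n_axial) % pitch
    inplate = (z >= start) & (z < start + width)
    voxels = np.zeros((n_axial, lateral, lateral), bool)
    voxels[inplate] = True
    return BinaryVolume(voxels, voxel_um)


class TestTrabecularOutcomes:
    def test_plate_thickness_recovered(self):
        # 11-voxel plates at 20 um: odd width, recovered exactly
        bone = plate_volume(width=11)
        mask = np.ones(bone.shape, bool)
        assert direct_tb_th(bone, mask) == pytest.approx(0.220, abs=0.02)

    def test_even_width_plate_documents_half_voxel_bias(self):
        # a 10-voxel (200 um) plate measures one voxel low: the largest
        # inscribed discrete sphere spans 9 voxels when no voxel centre
        # sits on the medial plane
        bone = plate_volume(width=10)
        mask = np.ones(bone.shape, bool)
        assert direct_tb_th(bone, mask) == pytest.approx(0.180, abs=1e-9)

    def test_plate_separation_recovered(self):
        bone = plate_volume(width=10)  # gaps of 40 voxels = 800 um
        mask = np.ones(bone.shape, bool)
        assert direct_tb_sp(bone, mask) == pytest.approx(0.800, abs=0.04)

    def test_all_solid_mask_has_no_separation(self):
        bone = BinaryVolume(np.ones((10, 10, 10), bool), 20.0)
        with pytest.raises(ValueError, match="empty phase"):
            direct_tb_sp(bone, np.ones(bone.shape, bool))

    def test_tb_n_matches_plate_pitch(self):
        bone = plate_volume(width=5, pitch=50)  # 1.0 mm pitch at 20 um
        mask = np.ones(bone.shape, bool)
        assert direct_tb_n(bone, mask) == pytest.approx(1.0, abs=0.05)

    def test_periodic_lattice_has_near_zero_inhomogeneity(self):
        bone = plate_volume(width=5, pitch=50)
        mask = np.ones(bone.shape, bool)
        assert tb_1_n_sd(bone, mask) < 0.02

    def test_interleaved_pitches_recover_spacing_sd(self):
        """Plates alternating 0.8/1.2 mm pitch: the SD of inter-axis
        distances approximates the constructed spacing distribution's SD
        (~0.196 mm, voxel-weighted)."""
        n = 291
        voxels = np.zeros((n, 10, 10), bool)
        centers = [c for c in range(20, n, 100)] + [c for c in range(60, n, 100)]
        for c in centers:
            voxels[max(0, c - 2):c + 3] = True
        bone = BinaryVolume(voxels, 20.0)
        mask = np.ones(bone.shape, bool)
        # oracle: gap values 0.78 and 1.18 mm weighted by gap width
        v = np.array([0.78, 1.18])
        w = v / v.sum()
        expected_sd = float(np.sqrt(np.sum(w * (v - np.sum(w * v)) ** 2)))
        assert tb_1_n_sd(bone, mask) == pytest.approx(expected_sd, rel=0.20)

    def test_single_plate_rejected(self):
        bone = BinaryVolume(np.zeros((40, 10, 10), bool), 20.0)
        bone.voxels[18:23] = True
        with pytest.raises(ValueError, match="fewer than 2"):
            direct_tb_n(bone, np.ones(bone.shape, bool))


class TestIndirect:
    def test_definitional_arithmetic(self):
        out = indirect_morphometry(240.0, 2.0, 1200.0)
        assert out == {"BV/TV": pytest.approx(0.2),
                       "Tb.Th": pytest.approx(0.1),
                       "Tb.Sp": pytest.approx(0.4)}

    def test_limits(self):
        zero = indirect_morphometry(0.0, 2.0, 1200.0)
        assert zero["Tb.Th"] == 0.0 and zero["Tb.Sp"] == pytest.approx(0.5)
        full = indirect_morphometry(1200.0, 2.0, 1200.0)
        assert full["Tb.Sp"] == 0.0

    def test_zero_tb_n_rejected(self):
        with pytest.raises(ValueError, match="Tb.N"):
            indirect_morphometry(240.0, 0.0)


class TestCortical:
    def test_carved_porosity_fraction(self):
        mask = np.ones((10, 10, 10), bool)
        bone = mask.copy()
        bone[:, :, :1] = False  # carve exactly 10% as pores
        out = cortical_metrics(BinaryVolume(bone, 20.0), mask)
        assert out["Ct.Po"] == pytest.approx(0.10)

    def test_no_pores_flags_missing_diameter(self):
        mask = np.ones((10, 10, 10), bool)
        out = cortical_metrics(BinaryVolume(mask.copy(), 20.0), mask)
        assert out["Ct.Po"] == 0.0
        assert out["Ct.Po.Dm"] is None

    def test_solid_wall_thickness(self):
        # 1.2 mm wall at 40 um = 30 voxels
        mask = np.ones((40, 40, 40), bool)
        bone = np.zeros_like(mask)
        bone[5:35] = True
        out = cortical_metrics(BinaryVolume(bone, 40.0), bone | ~bone)
        assert out["Ct.Th"] == pytest.approx(1.2, abs=0.06)

    def test_cylindrical_pore_diameter_recovered(self):
        spec = PhantomSpec("cortical_shell", (1.0, 2.0, 2.0),
                           {"shell_thickness_um": 800.0,
                            "pore_diameters_um": 150.0,
                            "target_porosity": 0.06}, seed=9)
        vol, truth = generate_phantom(spec, 20.0)
        from xcal.phantoms import shell_mask
        mask = shell_mask(spec, 20.0)
        pores = mask & ~vol.voxels
        assert pores.sum() / mask.sum() == pytest.approx(truth.ct_po_true,
                                                         abs=0.01)
        pore_dm = local_thickness(pores, vol.voxel_um).mean_mm()
        assert pore_dm == pytest.approx(0.150, abs=0.02)


class TestDensityGeometry:
    def make_masks(self, shape):
        total = np.zeros(shape, bool)
        total[:, 2:-2, 2:-2] = True
        trab = np.zeros(shape, bool)
        trab[:, 4:-4, 4:-4] = True
        cort = total & ~trab
        return {"total": total, "trabecular": trab, "cortical": cort}

    def test_uniform_density_recovered(self):
        shape = (10, 20, 20)
        masks = self.make_masks(shape)
        vol = ImageVolume(np.full(shape, 300.0), 100.0)
        out = density_geometry(vol, masks)
        assert out["Tb.BMD"] == pytest.approx(300.0)
        assert out["Tt.BMD"] == pytest.approx(300.0)

    def test_square_perimeter(self):
        # 10 mm square cross-section at 0.2 mm voxels
        shape = (5, 60, 60)
        total = np.zeros(shape, bool)
        total[:, 5:55, 5:55] = True
        masks = {"total": total, "trabecular": total, "cortical": total}
        vol = ImageVolume(np.full(shape, 500.0), 200.0)
        out = density_geometry(vol, masks)
        assert out["Ct.Pm"] == pytest.approx(40.0, rel=0.02)

    def test_circular_area(self):
        # radius 5 mm at 0.1 mm voxels
        shape = (3, 120, 120)
        y, x = np.ogrid[:120, :120]
        disk = (y - 60) ** 2 + (x - 60) ** 2 <= 50**2
        trab = np.broadcast_to(disk, shape).copy()
        masks = {"total": trab, "trabecular": trab, "cortical": trab}
        vol = ImageVolume(np.full(shape, 400.0), 100.0)
        out = density_geometry(vol, masks)
        assert out["Tb.Ar"] == pytest.approx(np.pi * 25.0, rel=0.01)

    def test_missing_mask_rejected(self):
        vol = ImageVolume(np.zeros((4, 4, 4)), 100.0)
        with pytest.raises(ValueError, match="missing mask"):
            density_geometry(vol, {"total": np.ones((4, 4, 4), bool)})


class TestInvariances:
    def test_translation_and_axis_permutation(self, random_blobs):
        # margin of 4 background layers: shifting by 2 keeps every phase
        # voxel's nearest-background witness inside the volume, so the
        # distance transform (and hence the thickness map) must not change
        blob = np.zeros((30, 30, 30), bool)
        blob[4:26, 4:26, 4:26] = random_blobs[0]
        mask = np.ones(blob.shape, bool)
        base_bv = bvtv(blob, mask)
        base_th = direct_tb_th(BinaryVolume(blob, 20.0), mask)
        shifted = np.roll(blob, (2, -2, 2), axis=(0, 1, 2))
        assert bvtv(shifted, mask) == base_bv
        assert direct_tb_th(BinaryVolume(shifted, 20.0), mask) == pytest.approx(
            base_th, abs=1e-12)
        permuted = np.transpose(blob, (2, 0, 1))
        assert direct_tb_th(BinaryVolume(permuted, 20.0), mask) == pytest.approx(
            base_th, abs=1e-12)

    def test_direct_equals_indirect_on_clean_phantom(self):
        """Direct and derived BV/TV agree when the matrix density matches
        the simulated tissue density."""
        bone = plate_volume(width=11)
        mask = np.ones(bone.shape, bool)
        direct = bvtv(bone, mask)
        tb_bmd = 1200.0 * direct  # noise-free, fully mineralised
        derived = indirect_morphometry(tb_bmd, direct_tb_n(bone, mask))["BV/TV"]
        assert derived == pytest.approx(direct, rel=0.02)
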