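"""Per-object measurements against analytic and generator oracles."""

import math

import numpy as np
import pytest

from mitomorph import LabelVolume, VoxelGeometry
from mitomorph import morphometry as M
from mitomorph.synthetic import generate_dumbbell_volume, generate_shape_population
import mitomorph.synthetic.volumes as SV


def ball_volume(radius_vox, pitch_nm=20.0, value=1):
    """Digital ball in an isotropic raster."""
    n = 2 * radius_vox + 5
    c = n // 2
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
    mask = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius_vox**2
    lab = np.where(mask, value, 0).astype(np.uint16)
    geom = VoxelGeometry(pitch_nm, pitch_nm, pitch_nm)
    return LabelVolume(lab, None, None, geom), radius_vox * pitch_nm


def single_object_volume(built, geom):
    canvas = SV._Canvas(tuple(s + 4 for s in built.mask.shape), geom)
    res = canvas.check(built, tuple(c + 2 for c in built.center_idx))
    canvas.paint(res[0], res[1], 1)
    return LabelVolume(canvas.labels, canvas.nucleus, canvas.sarcolemma, geom,
                       canvas.cell)


class TestVolume:
    def test_single_voxel_is_one_voxel_volume(self):
        lab = np.zeros((3, 3, 3), np.uint16)
        lab[1, 1, 1] = 1
        lv = LabelVolume(lab, None, None, VoxelGeometry())
        assert M.measure_volume(lv, 1) == pytest.approx(13.5 * 13.5 * 50.0)

    def test_digital_ball_matches_analytic_volume(self):
        lv, r_nm = ball_volume(20)
        analytic = 4.0 / 3.0 * math.pi * r_nm**3
        assert M.measure_volume(lv, 1) == pytest.approx(analytic, rel=0.02)

    def test_missing_label_raises(self):
        lab = np.zeros((2, 2, 2), np.uint16)
        lv = LabelVolume(lab, None, None, VoxelGeometry())
        with pytest.raises(M.LabelNotFoundError):
            M.measure_volume(lv, 7)

    def test_large_object_magnitude_no_overflow(self):
        # objects of order 7e8 nm^3 are routine for cardiac mitochondria
        lv, _ = ball_volume(25, pitch_nm=55.0)
        v = M.measure_volume(lv, 1)
        assert 5e8 < v < 2e10 and np.isfinite(v)


class TestSurfaceArea:
    def test_digital_sphere_within_five_percent(self):
        lv, r_nm = ball_volume(20)
        assert M.measure_surface_area(lv, 1) == pytest.approx(
            4.0 * math.pi * r_nm**2, rel=0.05
        )

    def test_axis_aligned_cube_within_five_percent(self):
        lab = np.zeros((36, 36, 36), np.uint16)
        lab[3:33, 3:33, 3:33] = 1
        lv = LabelVolume(lab, None, None, VoxelGeometry(10, 10, 10))
        assert M.measure_surface_area(lv, 1) == pytest.approx(
            6 * 300.0**2, rel=0.05
        )

    def test_empty_label_errors(self):
        lab = np.zeros((2, 2, 2), np.uint16)
        lv = LabelVolume(lab, None, None, VoxelGeometry())
        with pytest.raises(M.LabelNotFoundError):
            M.measure_surface_area(lv, 1)

    def test_single_voxel_falls_back_to_faces_with_warning(self):
        lab = np.zeros((3, 3, 3), np.uint16)
        lab[1, 1, 1] = 1
        lv = LabelVolume(lab, None, None, VoxelGeometry(10, 10, 10))
        with pytest.warns(UserWarning, match="single voxel"):
            area = M.measure_surface_area(lv, 1)
        assert area == pytest.approx(6 * 100.0)

    def test_scale_equivariance(self):
        lv, _ = ball_volume(12)
        v1, a1 = M.measure_volume(lv, 1), M.measure_surface_area(lv, 1)
        lv2 = LabelVolume(lv.labels, None, None, lv.geom.scaled(3.0))
        v2, a2 = M.measure_volume(lv2, 1), M.measure_surface_area(lv2, 1)
        assert v2 / v1 == pytest.approx(27.0, rel=1e-9)
        assert a2 / a1 == pytest.approx(9.0, rel=0.01)

    def test_sphere_sa_over_vol_limit(self):
        for r_vox in (15, 20):
            lv, r_nm = ball_volume(r_vox)
            ratio = M.measure_surface_area(lv, 1) / M.measure_volume(lv, 1)
            assert ratio == pytest.approx(3.0 / r_nm, rel=0.07)


class TestSubtypeAssignment:
    @staticmethod
    def tiny_volume():
        lab = np.zeros((5, 40, 40), np.uint16)
        sarc = np.zeros_like(lab, bool)
        nuc = np.zeros_like(lab, bool)
        sarc[:, 0:2, :] = True
        nuc[:, 20:24, 18:22] = True
        lab[2, 3:7, 5:9] = 1  # adjacent to the sarcolemma band
        lab[2, 14:17, 5:9] = 2  # free-floating: interfibrillar
        lab[2, 16:20, 18:22] = 3  # adjacent to the nucleus
        return LabelVolume(lab, nuc, sarc, VoxelGeometry())

    def test_rules(self):
        lv = self.tiny_volume()
        assert M.assign_subtype(lv, 1) == "SSM"
        assert M.assign_subtype(lv, 2) == "IFM"
        assert M.assign_subtype(lv, 3) == "PNM"

    def test_touching_both_is_excluded(self):
        lab = np.zeros((3, 30, 10), np.uint16)
        sarc = np.zeros_like(lab, bool)
        nuc = np.zeros_like(lab, bool)
        sarc[:, 0:2, :] = True
        nuc[:, 25:27, :] = True
        lab[1, 3:24, 4:7] = 1  # spans from sarcolemma to nucleus
        lv = LabelVolume(lab, nuc, sarc, VoxelGeometry())
        assert M.assign_subtype(lv, 1) == "excluded"

    def test_missing_masks_error(self):
        lab = np.zeros((3, 5, 5), np.uint16)
        lab[1, 2, 2] = 1
        lv = LabelVolume(lab, None, None, VoxelGeometry())
        with pytest.raises(M.MissingMaskError):
            M.assign_subtype(lv, 1)

    def test_recovery_on_generated_volume(self, wt_volume):
        _, vol, truth = wt_volume
        agree = sum(
            M.assign_subtype(vol, lab) == ot.subtype
            for lab, ot in truth.objects.items()
        )
        assert agree / len(truth.objects) >= 0.95


class TestShapeClassification:
    def test_plain_superellipsoid_is_oval(self):
        geom = VoxelGeometry()
        built = SV._build_object(np.random.default_rng(42), geom, 7e8, "oval", 0.0)
        lv = single_object_volume(built, geom)
        assert M.classify_shape(lv, 1) == "oval"

    def test_high_amplitude_blob_is_irregular(self):
        geom = VoxelGeometry()
        built = SV._build_object(
            np.random.default_rng(43), geom, 7e8, "irregular", 0.35
        )
        lv = single_object_volume(built, geom)
        assert M.classify_shape(lv, 1) == "irregular"

    def test_too_small_object_rejected(self):
        lab = np.zeros((3, 4, 4), np.uint16)
        lab[1, 1:3, 1:3] = 1
        lv = LabelVolume(lab, None, None, VoxelGeometry())
        with pytest.raises(M.TooSmallError):
            M.classify_shape(lv, 1)

    def test_population_agreement_at_default_amplitudes(
        self, ifm_population, ifm_population_classes
    ):
        _, truth = ifm_population
        agree = sum(
            ifm_population_classes[lab] == ot.shape_class
            for lab, ot in truth.objects.items()
        )
        assert agree / len(truth.objects) >= 0.90


class TestProjections:
    def test_plain_body_has_no_projections(self):
        geom = VoxelGeometry()
        built = SV._build_object(np.random.default_rng(7), geom, 7e8, "oval", 0.05)
        lv = single_object_volume(built, geom)
        assert M.detect_projections(lv, 1) == []

    def test_single_capsule_recovered_within_tolerance(self):
        geom = VoxelGeometry()
        built = SV._build_object(
            np.random.default_rng(8), geom, 7e8, "oval", 0.05,
            proj_dims_nm=[(600.0, 110.0)],
        )
        lv = single_object_volume(built, geom)
        recs = M.detect_projections(lv, 1)
        assert len(recs) == 1
        assert recs[0].length_um == pytest.approx(0.60, rel=0.10)
        assert recs[0].tip_width_um == pytest.approx(0.22, rel=0.20)


class TestNanotunnels:
    def test_disjoint_bodies_have_no_tunnels(self):
        vol, _ = generate_shape_population(
            n=2, oval_fraction=1.0, seed=9, mean_body_volume_nm3=7e8
        )
        assert M.detect_nanotunnels(vol) == []

    def test_dumbbell_recovered_within_ten_percent(self):
        vol, _ = generate_dumbbell_volume(
            tube_length_um=1.5, tube_diameter_um=0.30, seed=3
        )
        recs = M.detect_nanotunnels(vol)
        assert len(recs) == 1
        assert recs[0].tube_length_um == pytest.approx(1.5, rel=0.10)
        assert recs[0].tube_diameter_um == pytest.approx(0.30, rel=0.25)
        assert min(recs[0].body_equiv_diameters_um) >= 2 * recs[0].tube_diameter_um


class TestMorphometryTable:
    def test_empty_volume_empty_table(self):
        lab = np.zeros((4, 8, 8), np.uint16)
        lv = LabelVolume(lab, np.zeros_like(lab, bool), np.zeros_like(lab, bool),
                         VoxelGeometry())
        assert M.morphometry_table(lv) == []

    def test_batch_against_generator_truth(self, wt_volume):
        _, vol, truth = wt_volume
        records = M.morphometry_table(vol)
        assert len(records) == len(truth.objects)  # nothing excluded by design
        df = M.morphometry_dataframe(records)
        voxvol = vol.geom.voxel_volume_nm3
        exact_total = int((vol.labels > 0).sum()) * voxvol
        assert df.volume_nm3.sum() == pytest.approx(exact_total, rel=1e-12)
        by_label = df.set_index("label")
        for subtype in ("SSM", "IFM", "PNM"):
            got = df[df.subtype == subtype]
            true_vols = [
                o.voxel_volume_nm3 for o in truth.objects.values()
                if o.subtype == subtype
            ]
            assert got.volume_nm3.mean() == pytest.approx(
                np.mean(true_vols), rel=0.10
            )
            # surface truth exists for appendage-free bodies; compare matched
            plain = [
                (o.label, o.surface_area_nm2) for o in truth.objects.values()
                if o.subtype == subtype and o.surface_area_nm2 and not o.projections
            ]
            measured = [by_label.loc[lab, "surface_area_nm2"] for lab, _ in plain]
            assert np.mean(measured) == pytest.approx(
                np.mean([sa for _, sa in plain]), rel=0.10
            )
        # SA/Vol stored exactly as the quotient
        assert np.allclose(
            df.sa_over_vol_per_nm, df.surface_area_nm2 / df.volume_nm3
        )
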