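"""Cristae pipeline: threshold, profile, doublet detection, widths, quality."""

import numpy as np
import pytest

from mitomorph import cristae as C
from mitomorph.synthetic import CristaeImageParams, generate_cristae_scene
from mitomorph.volume import GreyImage


def flat_image(value=128, shape=(64, 64)):
    return GreyImage(np.full(shape, value, np.uint8), 2.0)


class TestImageGenerator:
    def test_zero_cristae_gives_blank_mitochondrion(self):
        sc = generate_cristae_scene(CristaeImageParams(seed=1, n_cristae=0))
        assert sc.truth.cristae == []
        assert not sc.membrane_mask.any()

    def test_lumen_wider_than_outer_width_rejected(self):
        with pytest.raises(ValueError, match="W_I"):
            CristaeImageParams(w_o_nm=(20.0, 1.0), w_i_nm=(25.0, 1.0)).validate()

    def test_default_widths_are_wild_type_averages(self):
        p = CristaeImageParams()
        assert (p.w_o_nm[0], p.w_i_nm[0]) == (36.0, 16.0)

    def test_rendered_mask_width_matches_request_within_a_pixel(self):
        # noiseless mask measured directly across the lamella normal
        sc = generate_cristae_scene(
            CristaeImageParams(seed=7, noise_sd=0, w_o_nm=(34.0, 0.0),
                               w_i_nm=(16.0, 0.0))
        )
        import math

        alpha = math.radians(sc.truth.lamella_angle_deg)
        h, w = sc.membrane_mask.shape
        cy, cx = sc.center_px
        yy, xx = np.mgrid[0:h, 0:w]
        u = ((xx - cx) * math.cos(alpha) + (yy - cy) * math.sin(alpha)) * 2.0
        for crista in sc.truth.cristae[2:4]:
            sel = sc.membrane_mask & (np.abs(u - crista.center_nm) < crista.w_o_nm)
            span = u[sel].max() - u[sel].min()
            assert span == pytest.approx(crista.w_o_nm, abs=2.0)


class TestThreshold:
    def test_constant_image_is_degenerate(self):
        with pytest.raises(C.DegenerateImageError):
            C.threshold_membranes(flat_image())

    def test_noiseless_scene_mask_matches_truth(self):
        sc = generate_cristae_scene(CristaeImageParams(seed=1, noise_sd=0))
        mask = C.threshold_membranes(sc.image)
        truth = sc.membrane_mask | sc.ring_mask
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.90

    def test_default_noise_mask_still_overlaps_truth(self):
        sc = generate_cristae_scene(CristaeImageParams(seed=1))
        mask = C.threshold_membranes(sc.image)
        truth = sc.membrane_mask | sc.ring_mask
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.85


class TestLineProfile:
    def test_out_of_bounds_line_rejected(self):
        with pytest.raises(IndexError):
            C.line_profile(flat_image(), (0, 0), (10, 999))

    def test_flat_region_profile_has_no_doublets(self):
        prof = C.line_profile(flat_image(), (5, 5), (5, 60))
        assert C.detect_doublets(prof) == []

    def test_profile_length_matches_euclidean_line(self):
        img = flat_image(shape=(100, 100))
        prof = C.line_profile(img, (10, 10), (70, 90))
        expected = np.hypot(60, 80) * img.pixel_size_nm
        assert prof.positions_nm[-1] == pytest.approx(expected, abs=2 * prof.step_nm)


class TestDoublets:
    @staticmethod
    def synthetic_profile(centers_nm, w_o=36.0, w_i=16.0, step=1.0, length=600.0):
        """Noise-free top-hat doublets at known positions."""
        pos = np.arange(0.0, length, step)
        vals = np.full_like(pos, 200.0)
        t = (w_o - w_i) / 2.0
        for c in centers_nm:
            for side in (-1, 1):
                lc = c + side * (w_o - t) / 2.0
                vals[np.abs(pos - lc) <= t / 2.0] = 40.0
        return C.CristaeProfile(pos, vals, step)

    def test_constructed_doublets_recovered_at_known_positions(self):
        centers = [150.0, 250.0, 370.0]
        prof = self.synthetic_profile(centers)
        doublets = C.detect_doublets(prof)
        assert len(doublets) == len(centers)
        for d, c in zip(doublets, centers):
            mid = (d.peak_left_nm + d.peak_right_nm) / 2.0
            assert mid == pytest.approx(c, abs=1.5 * prof.step_nm)

    def test_six_cristae_line_yields_six_doublets(self):
        sc = generate_cristae_scene(CristaeImageParams(seed=6, n_cristae=6))
        doublets = C.detect_doublets(
            C.line_profile(sc.image, *sc.default_profile_line())
        )
        assert len(doublets) == 6

    def test_inner_pair_nested_in_outer_pair(self):
        with pytest.raises(ValueError, match="nest"):
            C.Doublet(10.0, 20.0, 12.0, 30.0, 8.0, 18.0)


class TestDims:
    def test_construction_oracle_widths_and_spacing(self):
        prof = TestDoublets.synthetic_profile([200.0, 264.0])  # S = 28 nm
        dims = C.measure_dims(C.detect_doublets(prof))
        assert len(dims) == 2
        for d in dims:
            assert d.w_o_nm == pytest.approx(36.0, abs=1.5)
            assert d.w_i_nm == pytest.approx(16.0, abs=1.5)
        assert dims[0].s_gap_nm == pytest.approx(28.0, abs=1.5)
        assert dims[1].s_gap_nm is None

    def test_recovery_on_rendered_image(self):
        sc = generate_cristae_scene(CristaeImageParams(seed=4))
        dims = C.measure_image_dims(sc.image, *sc.default_profile_line())
        w_o = np.mean([d.w_o_nm for d in dims])
        w_i = np.mean([d.w_i_nm for d in dims])
        truth_o = np.mean([c.w_o_nm for c in sc.truth.cristae])
        truth_i = np.mean([c.w_i_nm for c in sc.truth.cristae])
        assert w_o == pytest.approx(truth_o, abs=2.0)
        assert w_i == pytest.approx(truth_i, abs=2.0)

    def test_lumen_always_narrower_than_outer_width(self):
        for seed in range(3):
            sc = generate_cristae_scene(CristaeImageParams(seed=seed))
            for d in C.measure_image_dims(sc.image, *sc.default_profile_line()):
                assert 0 < d.w_i_nm < d.w_o_nm

    def test_errors_grow_with_noise(self):
        errs = []
        for noise in (0.0, 8.0, 40.0):
            per_image = []
            for seed in (60, 61, 62, 63):
                sc = generate_cristae_scene(
                    CristaeImageParams(seed=seed, noise_sd=noise)
                )
                dims = C.measure_image_dims(sc.image, *sc.default_profile_line())
                if not dims:
                    per_image.append(5.0)  # detection collapse counts as error
                    continue
                truth_o = np.mean([c.w_o_nm for c in sc.truth.cristae])
                per_image.append(abs(np.mean([d.w_o_nm for d in dims]) - truth_o))
            errs.append(np.mean(per_image))
        assert errs[0] <= errs[1] + 0.3  # allow sub-pixel jitter at low noise
        assert errs[1] < errs[2]


class TestQuality:
    @pytest.mark.parametrize("qc", [1, 3, 5])
    def test_class_recovered(self, qc):
        sc = generate_cristae_scene(CristaeImageParams(seed=50 + qc, quality_class=qc))
        score = C.score_quality(sc.image, sc.interior_mask)
        assert score.score == qc

    def test_score_monotone_in_coverage(self):
        scores = []
        for cov in (0.95, 0.5, 0.05):
            sc = generate_cristae_scene(
                CristaeImageParams(seed=70, quality_class=3, ordered_coverage=cov)
            )
            scores.append(C.score_quality(sc.image, sc.interior_mask).score)
        assert scores == sorted(scores)

    def test_region_too_small_rejected(self):
        sc = generate_cristae_scene(CristaeImageParams(seed=1))
        tiny = np.zeros_like(sc.interior_mask)
        tiny[0:5, 0:5] = True
        with pytest.raises(C.RegionTooSmallError):
            C.score_quality(sc.image, tiny)
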