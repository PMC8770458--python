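"""Point-counting and surface-density estimators: formula layer and probes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitomorph import LabelVolume, VoxelGeometry
from mitomorph import stereology as S
from mitomorph.stereology import (
    GridSpec,
    PointCounts,
    Region,
    SvCounts,
    SvGridSpec,
    sv_from_counts,
)
from mitomorph.synthetic import CristaeImageParams, generate_cristae_scene


class TestVolumeFractionFormula:
    def test_hand_arithmetic_to_machine_precision(self):
        grid = GridSpec()
        counts = PointCounts(n_mito_points=100, n_cm_points=200, n_slices=3)
        expected = (100 * 2.674e6) / (200 * 13.368e6) * 100.0
        assert S.volume_fraction(counts, grid) == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(
        n_mito=st.integers(min_value=0, max_value=10_000),
        n_cm=st.integers(min_value=1, max_value=10_000),
        n_slices=st.integers(min_value=1, max_value=60),
        area_scale=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_formula_exact_for_any_integer_counts(
        self, n_mito, n_cm, n_slices, area_scale
    ):
        """The slice term cancels and the ratio is exact for all counts."""
        grid = GridSpec(
            red_area_nm2=13.368e6 * area_scale, green_area_nm2=2.674e6 * area_scale
        )
        got = S.volume_fraction(PointCounts(n_mito, n_cm, n_slices), grid)
        want = n_mito * grid.green_area_nm2 / (n_cm * grid.red_area_nm2) * 100.0
        assert got == pytest.approx(want, rel=1e-12)

    def test_zero_mito_points_zero_percent(self):
        assert S.volume_fraction(PointCounts(0, 50, 2), GridSpec()) == 0.0

    def test_zero_reference_points_undefined(self):
        with pytest.raises(S.UndefinedFractionError):
            S.volume_fraction(PointCounts(5, 0, 2), GridSpec())

    def test_saturated_volume_reads_one_hundred_percent(self):
        # frame an exact multiple of both lattice tiles, so the point
        # densities are exactly inverse to the per-point areas
        lab = np.ones((10, 400, 400), np.uint16)
        lv = LabelVolume(lab, None, None, VoxelGeometry(10.0, 10.0, 10.0))
        grid = GridSpec(
            red_area_nm2=200.0**2, green_area_nm2=100.0**2,
            placement="fixed", slice_interval=5, edge_rule=False,
        )
        counts = S.count_points(lv, grid, regions=[Region(0, 400, 0, 400, 0, 10)])
        assert S.volume_fraction(counts[0], grid) == pytest.approx(100.0, rel=1e-12)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(red_area_nm2=0.0)
        with pytest.raises(ValueError):
            GridSpec(slice_interval=0)


class TestCounting:
    def test_empty_raster_counts_no_mito_points(self):
        lab = np.zeros((25, 320, 320), np.uint16)
        lv = LabelVolume(lab, None, None, VoxelGeometry())
        for c in S.count_points(lv, GridSpec(seed=1)):
            assert c.n_mito_points == 0
            assert c.n_cm_points > 0

    def test_region_outside_volume_is_a_bounds_error(self):
        lab = np.zeros((10, 50, 50), np.uint16)
        lv = LabelVolume(lab, None, None, VoxelGeometry())
        with pytest.raises(IndexError):
            S.count_points(lv, GridSpec(), regions=[Region(0, 50, 0, 80, 0, 10)])

    def test_edge_rule_never_increases_counts(self):
        # one object clamped to the left border of the counting frame
        lab = np.zeros((4, 220, 220), np.uint16)
        lab[1:3, 40:160, 0:80] = 1
        lab[1:3, 40:160, 120:200] = 2
        lv = LabelVolume(lab, None, None, VoxelGeometry())
        region = [Region(0, 220, 0, 220, 0, 4)]
        rng_state = lambda: np.random.default_rng(3)
        grid_on = GridSpec(edge_rule=True, slice_interval=1)
        grid_off = GridSpec(edge_rule=False, slice_interval=1)
        on = S.count_points(lv, grid_on, regions=region, rng=rng_state())[0]
        off = S.count_points(lv, grid_off, regions=region, rng=rng_state())[0]
        assert on.n_mito_points <= off.n_mito_points
        # the border-touching object really is excluded at fixed placement
        fixed_on = S.count_points(
            lv, GridSpec(edge_rule=True, slice_interval=1, placement="fixed"),
            regions=region,
        )[0]
        fixed_off = S.count_points(
            lv, GridSpec(edge_rule=False, slice_interval=1, placement="fixed"),
            regions=region,
        )[0]
        assert fixed_on.n_mito_points < fixed_off.n_mito_points

    def test_per_subtype_counts_sum_to_total(self, wt_volume):
        _, vol, truth = wt_volume
        sub = {lab: ot.subtype for lab, ot in truth.objects.items()}
        counts = S.count_points(
            vol, GridSpec(), subtype_of=sub, rng=np.random.default_rng(2)
        )
        for c in counts:
            assert sum(c.per_subtype.values()) == c.n_mito_points


class TestSubpopulationFractions:
    def test_single_subtype_is_one_hundred_percent(self):
        c = PointCounts(10, 50, 1, per_subtype={"IFM": 10})
        assert S.subpopulation_fractions(c) == {"SSM": 0.0, "IFM": 100.0, "PNM": 0.0}

    def test_no_points_undefined(self):
        with pytest.raises(S.UndefinedFractionError):
            S.subpopulation_fractions(PointCounts(0, 10, 1))

    def test_shares_sum_to_one_hundred(self, wt_volume):
        _, vol, truth = wt_volume
        sub = {lab: ot.subtype for lab, ot in truth.objects.items()}
        counts = S.count_points(
            vol, GridSpec(), subtype_of=sub, rng=np.random.default_rng(4)
        )
        shares = S.subpopulation_fractions(counts)
        assert sum(shares.values()) == pytest.approx(100.0)


class TestSurfaceDensity:
    def test_formula_layer_exact(self):
        assert sv_from_counts(SvCounts(40, 100, 60.0)) == pytest.approx(
            2 * 40 / (60.0 * 100)
        )

    def test_no_intersections_zero(self):
        assert sv_from_counts(SvCounts(0, 50, 60.0)) == 0.0

    def test_no_points_undefined(self):
        with pytest.raises(S.UndefinedFractionError):
            sv_from_counts(SvCounts(5, 0, 60.0))

    def test_lamellar_phantom_within_ten_percent(self):
        ratios = []
        for seed in range(9, 15):
            sc = generate_cristae_scene(CristaeImageParams(seed=seed, noise_sd=0))
            sv_true = (
                4.0 / np.pi * sc.truth.membrane_length_nm / sc.truth.mito_area_nm2
            )
            sv = S.cristae_surface_density(
                sc.membrane_mask, sc.interior_mask, 2.0, n_placements=30, seed=2
            )
            ratios.append(sv / sv_true)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.10)

    def test_doubling_lamellar_density_doubles_sv(self):
        dense = generate_cristae_scene(
            CristaeImageParams(seed=20, noise_sd=0, s_nm=(28.0, 0.0))
        )
        sparse = generate_cristae_scene(
            CristaeImageParams(seed=20, noise_sd=0, s_nm=(92.0, 0.0))
        )
        sv_d = S.cristae_surface_density(
            dense.membrane_mask, dense.interior_mask, 2.0, n_placements=30, seed=3
        )
        sv_s = S.cristae_surface_density(
            sparse.membrane_mask, sparse.interior_mask, 2.0, n_placements=30, seed=3
        )
        truth_ratio = (
            dense.truth.membrane_length_nm / sparse.truth.membrane_length_nm
        )
        assert sv_d / sv_s == pytest.approx(truth_ratio, rel=0.10)

    def test_quality_exclusion_drops_disordered_mitochondria(self):
        scenes = [
            generate_cristae_scene(CristaeImageParams(seed=s, quality_class=q))
            for s, q in [(30, 1), (31, 3), (32, 5)]
        ]
        imgs = [sc.membrane_mask for sc in scenes]
        masks = [sc.interior_mask for sc in scenes]
        pooled = S.cristae_surface_density(
            imgs, masks, 2.0, quality_scores=[1, 3, 5], n_placements=10, seed=5
        )
        only_first = S.cristae_surface_density(
            imgs[0], masks[0], 2.0, n_placements=10, seed=5
        )
        assert pooled == pytest.approx(only_first)
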