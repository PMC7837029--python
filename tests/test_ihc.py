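"""Slide segmentation, tiling, ranking and the composed feature vector."""

import dataclasses

import numpy as np
import pytest

from heteroduo.ihc import (
    IhcConfig,
    RoiMask,
    SlideImage,
    TileGrid,
    build_tile_grid,
    distribution_shape,
    ihc_feature_vector,
    rank_cooccurrence,
    rank_ratio,
    segment_stain,
    segment_tissue,
)
from heteroduo.simulate import IhcSimParams, gen_ratio_field, render_slide
from heteroduo.texture import haralick_features

from .oracles import rank_cooccurrence_oracle


def _uniform_slide(rgb, shape=(8, 8)):
    return SlideImage(np.full(shape + (3,), rgb, dtype=np.uint8).reshape(*shape, 3))


class TestSegmentation:
    def test_white_is_neither_tissue_nor_stain(self):
        slide = SlideImage(np.full((4, 4, 3), 255, dtype=np.uint8))
        assert not segment_tissue(slide).any()
        assert not segment_stain(slide).any()

    def test_tissue_fraction_recovered(self):
        p = IhcSimParams(grid_shape=(4, 4), tile_px=40, tissue_fraction=0.4, seed=5)
        slide, truth = render_slide(gen_ratio_field(p), p)
        frac = segment_tissue(slide).mean()
        assert frac == pytest.approx(0.40, abs=0.03)

    def test_all_tissue_render(self):
        p = IhcSimParams(grid_shape=(3, 3), tile_px=32, tissue_fraction=1.0,
                         render_noise=0.0, seed=2)
        slide, _ = render_slide(gen_ratio_field(p), p)
        assert segment_tissue(slide).mean() == 1.0

    def test_stained_ratio_recovered(self):
        p = IhcSimParams(grid_shape=(1, 1), tile_px=96, tissue_fraction=1.0, seed=9)
        slide, _ = render_slide(np.array([[0.30]]), p)
        tissue = segment_tissue(slide)
        stain = segment_stain(slide) & tissue
        assert stain.sum() / tissue.sum() == pytest.approx(0.30, abs=0.05)

    def test_zero_stain_gives_zero_ratio(self):
        p = IhcSimParams(grid_shape=(1, 1), tile_px=48, tissue_fraction=1.0, seed=9)
        slide, _ = render_slide(np.array([[0.0]]), p)
        tissue = segment_tissue(slide)
        stain = segment_stain(slide) & tissue
        assert stain.sum() == 0


class TestRankRatio:
    @pytest.mark.parametrize(
        "ratio,level",
        [
            (0.0, 0),
            (0.05, 0),
            (0.10, 0),
            (0.1000001, 1),
            (0.2, 1),
            (0.3, 2),  # 0.3 is stored as 0.30000000000000004
            (0.95, 9),
            (1.0, 9),
        ],
    )
    def test_interval_boundaries(self, ratio, level):
        assert rank_ratio(ratio) == level

    @pytest.mark.parametrize("bad", [-0.01, 1.01])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            rank_ratio(bad)


class TestTileGrid:
    def test_grid_geometry(self):
        p = IhcSimParams(grid_shape=(2, 2), tile_px=40, tissue_fraction=1.0,
                         render_noise=0.0, seed=0)
        slide, _ = render_slide(np.full((2, 2), 0.5), p)
        grid = build_tile_grid(
            slide, RoiMask.full(slide), segment_tissue(slide),
            segment_stain(slide), tile_px=40,
        )
        assert len(grid.tiles) == 4
        assert len(grid.ranked()) == 4

    def test_ratio_definition(self):
        # half of the tissue pixels stained -> ratio exactly 0.5
        p = IhcSimParams(grid_shape=(1, 1), tile_px=32, tissue_fraction=1.0,
                         render_noise=0.0, seed=0)
        slide, _ = render_slide(np.array([[0.5]]), p)
        grid = build_tile_grid(
            slide, RoiMask.full(slide), segment_tissue(slide),
            segment_stain(slide), tile_px=32,
        )
        assert grid.tiles[0].stained_ratio == pytest.approx(0.5)

    def test_known_per_tile_ratios_recovered(self):
        p = IhcSimParams(grid_shape=(5, 5), tile_px=48, tissue_fraction=0.9, seed=3)
        field = gen_ratio_field(p)
        slide, _ = render_slide(field, p)
        grid = build_tile_grid(
            slide, RoiMask.full(slide), segment_tissue(slide),
            segment_stain(slide), tile_px=48,
        )
        got = np.full(field.shape, np.nan)
        for t in grid.tiles:
            got[t.row, t.col] = t.stained_ratio
        assert np.abs(got - field).mean() < 0.05

    def test_empty_grid_rejected(self):
        slide = SlideImage(np.full((16, 16, 3), 255, dtype=np.uint8))
        tissue = np.zeros((16, 16), bool)
        with pytest.raises(ValueError, match="empty grid"):
            build_tile_grid(slide, RoiMask.full(slide), tissue, tissue, tile_px=8)


class TestRankCooccurrence:
    def test_constant_grid_all_mass_on_diagonal(self):
        grid = TileGrid.from_ratios(np.full((2, 2), 0.35))
        m = rank_cooccurrence(grid)
        assert m.entries[3, 3] == pytest.approx(1.0)
        assert m.entries.sum() == pytest.approx(1.0)

    def test_two_tiles_symmetric_split(self):
        grid = TileGrid.from_ratios(np.array([[0.05, 1.0]]))
        m = rank_cooccurrence(grid)
        assert m.entries[0, 9] == pytest.approx(0.5)
        assert m.entries[9, 0] == pytest.approx(0.5)

    @pytest.mark.parametrize("adjacency", ["4", "8"])
    def test_matches_pair_enumeration_oracle(self, rng, adjacency):
        ratios = rng.random((6, 6))
        grid = TileGrid.from_ratios(ratios)
        m = rank_cooccurrence(grid, adjacency=adjacency)
        want = rank_cooccurrence_oracle(grid.rank_map(), adjacency)
        np.testing.assert_allclose(m.entries, want, atol=1e-12)

    def test_unranked_tiles_never_contribute(self, rng):
        ratios = rng.random((5, 5))
        ratios[2, 2] = np.nan
        grid = TileGrid.from_ratios(ratios)
        want = rank_cooccurrence_oracle(grid.rank_map())
        np.testing.assert_allclose(rank_cooccurrence(grid).entries, want, atol=1e-12)

    def test_isolated_tile_degenerate(self):
        grid = TileGrid.from_ratios(np.array([[0.5, np.nan, 0.7]]))
        with pytest.raises(ValueError, match="degenerate"):
            rank_cooccurrence(grid)


class TestDistributionShape:
    def test_symmetric_sample_zero_skew(self):
        assert distribution_shape([0.2, 0.4, 0.6, 0.8])["skewness"] == pytest.approx(0.0)

    def test_constant_sample_undefined(self):
        s = distribution_shape([0.3, 0.3, 0.3])
        assert np.isnan(s["skewness"]) and np.isnan(s["kurtosis"])

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            distribution_shape([0.1, 0.2])

    def test_beta_closed_form_skewness(self, rng):
        a, b = 2.0, 8.0
        analytic = 2 * (b - a) * np.sqrt(a + b + 1) / ((a + b + 2) * np.sqrt(a * b))
        x = rng.beta(a, b, 1000)
        assert distribution_shape(x)["skewness"] == pytest.approx(analytic, abs=0.15)


class TestFeatureVector:
    def test_homogeneous_slide_degenerate_features(self):
        p = IhcSimParams(grid_shape=(3, 3), tile_px=32, tissue_fraction=1.0,
                         render_noise=0.0, seed=1)
        slide, _ = render_slide(np.full((3, 3), 0.5), p)
        fv = ihc_feature_vector(slide, RoiMask.full(slide), IhcConfig(tile_px=32))
        assert fv.entropy == 0.0
        assert fv.energy == 1.0
        assert np.isnan(fv.skewness)

    def test_deterministic(self, small_ihc_params):
        slide, _ = render_slide(gen_ratio_field(small_ihc_params), small_ihc_params)
        cfg = IhcConfig(tile_px=small_ihc_params.tile_px)
        a = ihc_feature_vector(slide, RoiMask.full(slide), cfg)
        b = ihc_feature_vector(slide, RoiMask.full(slide), cfg)
        assert a == b

    def test_skewness_sign_recovered(self):
        hits = 0
        n = 30
        for s in range(n):
            for a, b, sign in ((2.0, 8.0, 1), (8.0, 2.0, -1)):
                p = IhcSimParams(grid_shape=(8, 8), tile_px=24, beta_a=a, beta_b=b,
                                 seed=1000 + s)
                slide, _ = render_slide(gen_ratio_field(p), p)
                fv = ihc_feature_vector(slide, RoiMask.full(slide),
                                        IhcConfig(tile_px=24))
                hits += np.sign(fv.skewness) == sign
        assert hits >= 0.9 * 2 * n

    def test_scale_invariance_on_noise_free_render(self):
        # ratios exactly representable at both resolutions
        field = np.array([[4, 9, 2], [11, 6, 14], [1, 8, 13]]) / 16.0
        feats = []
        for tile_px in (16, 32):
            p = IhcSimParams(grid_shape=(3, 3), tile_px=tile_px,
                             tissue_fraction=1.0, render_noise=0.0, seed=0)
            slide, _ = render_slide(field, p)
            fv = ihc_feature_vector(slide, RoiMask.full(slide),
                                    IhcConfig(tile_px=tile_px))
            feats.append(fv)
        for k, va in feats[0].as_dict().items():
            assert va == pytest.approx(feats[1].as_dict()[k], abs=1e-6), k


class TestPermutationSensitivity:
    def test_histogram_invariant_contrast_changes(self, rng):
        p = IhcSimParams(grid_shape=(10, 10), correlation_length=2.0, seed=4)
        field = gen_ratio_field(p)
        base_grid = TileGrid.from_ratios(field)
        base_contrast = haralick_features(rank_cooccurrence(base_grid))["contrast"]
        base_hist = np.sort(base_grid.rank_map().ravel())
        base_shape = distribution_shape(field.ravel())
        changed = 0
        for _ in range(50):
            perm = rng.permutation(field.size).reshape(field.shape)
            shuffled = field.ravel()[perm]
            grid = TileGrid.from_ratios(shuffled)
            np.testing.assert_array_equal(np.sort(grid.rank_map().ravel()), base_hist)
            shape = distribution_shape(shuffled.ravel())
            assert shape["skewness"] == pytest.approx(base_shape["skewness"])
            contrast = haralick_features(rank_cooccurrence(grid))["contrast"]
            changed += abs(contrast - base_contrast) > 1e-12
        assert changed >= 45
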