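"""Texture matrices against spec'd closed forms, hand counts, and
brute-force enumeration oracles on random small VOIs."""

import numpy as np
import pytest

from oracles import (
    oracle_glcm,
    oracle_glcm_features,
    oracle_glrlm,
    oracle_glzlm,
    oracle_ngldm,
    random_voi,
)
from perirad.features import (
    DIRECTIONS,
    DiscretizationScheme,
    extract_voi,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    glrlm_matrix,
    glzlm_features,
    glzlm_matrix,
    ngldm_components,
    ngldm_features,
)
from perirad.voi import ImageVolume

SCHEME8 = DiscretizationScheme(n_bins=8)


def _as_volume(levels):
    return np.asarray(levels, dtype=float)


class TestGLCM:
    def test_constant_voi_energy_one_contrast_zero(self):
        vol = np.full((4, 4, 4), 70.0)
        mask = np.ones((4, 4, 4), dtype=bool)
        with pytest.warns(UserWarning, match="Correlation"):
            f = glcm_features(vol, mask, SCHEME8)
        assert f["GLCM_Energy"] == 1.0
        assert f["GLCM_Contrast"] == 0.0
        assert f["GLCM_Dissimilarity"] == 0.0
        assert np.isnan(f["GLCM_Correlation"])

    def test_checkerboard_contrast_is_squared_level_gap(self):
        levels = np.zeros((3, 3, 6), dtype=np.int64)
        levels[..., 0::2] = 1
        levels[..., 1::2] = 3
        mask = np.ones(levels.shape, dtype=bool)
        mat = glcm_matrix(levels, mask, (0, 0, 1))
        p = mat / mat.sum()
        i = np.arange(1, p.shape[0] + 1)
        contrast = ((i[:, None] - i[None, :]) ** 2 * p).sum()
        assert contrast == pytest.approx((3 - 1) ** 2)

    def test_matrix_symmetric_and_normalizable(self, rng):
        levels, mask = random_voi(rng)
        for d in DIRECTIONS:
            mat = glcm_matrix(levels, mask, d)
            assert np.array_equal(mat, mat.T)

    @pytest.mark.parametrize("seed", range(5))
    def test_features_match_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        levels, mask = random_voi(rng)
        got = glcm_features(_as_volume(levels), mask,
                            DiscretizationScheme(n_bins=4, bounds=(0.5, 4.5)))
        per_dir = []
        for d in DIRECTIONS:
            mat = oracle_glcm(levels, mask, d)
            if mat.sum() > 0:
                per_dir.append(oracle_glcm_features(mat))
        for key in ("GLCM_Homogeneity", "GLCM_Energy", "GLCM_Contrast",
                    "GLCM_Entropy_log2", "GLCM_Dissimilarity"):
            expected = np.mean([f[key] for f in per_dir])
            assert got[key] == pytest.approx(expected, rel=1e-10)

    def test_shift_invariance_under_voi_tracking_bounds(self, rng):
        levels, mask = random_voi(rng)
        vol = _as_volume(levels) * 3.7
        scheme = DiscretizationScheme(n_bins=8)  # bounds track VOI min-max
        a = glcm_features(vol, mask, scheme)
        b = glcm_features(vol + 500.0, mask, scheme)
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-10, nan_ok=True)


class TestGLRLM:
    def test_single_line_run_closed_form(self):
        mask = np.ones((1, 1, 5), dtype=bool)
        levels = np.full((1, 1, 5), 3, dtype=np.int64)
        mat = glrlm_matrix(levels, mask, (0, 0, 1))
        assert mat.shape == (3, 5)
        assert mat[2, 4] == 1 and mat.sum() == 1
        # SRE = (1/25)/1, RP = 1/5 for this direction
        assert (mat / mat.sum() / np.arange(1, 6)[None, :] ** 2).sum() == pytest.approx(1 / 25)
        assert mat.sum() / mask.sum() == pytest.approx(1 / 5)

    def test_alternating_levels_all_runs_length_one(self):
        levels = np.ones((1, 1, 6), dtype=np.int64)
        levels[0, 0, 1::2] = 2
        mask = np.ones(levels.shape, dtype=bool)
        mat = glrlm_matrix(levels, mask, (0, 0, 1))
        assert mat.shape[1] == 1  # no run longer than 1
        assert mat.sum() == 6

    @pytest.mark.parametrize("seed", range(5))
    def test_matrix_matches_run_enumeration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        levels, mask = random_voi(rng)
        for d in DIRECTIONS:
            got = glrlm_matrix(levels, mask, d)
            exp = oracle_glrlm(levels, mask, d)
            np.testing.assert_array_equal(got[:exp.shape[0], :exp.shape[1]], exp)
            assert got.sum() == exp.sum()

    def test_index_identities_on_random_vois(self, rng):
        levels, mask = random_voi(rng)
        f = glrlm_features(_as_volume(levels), mask,
                           DiscretizationScheme(n_bins=4, bounds=(0.5, 4.5)))
        assert 0 < f["GLRLM_SRE"] <= 1
        assert 0 < f["GLRLM_RP"] <= 1
        assert f["GLRLM_LRE"] >= 1


class TestNGLDM:
    def test_constant_voi_contrast_zero(self):
        vol = np.full((3, 3, 3), 55.0)
        mask = np.ones((3, 3, 3), dtype=bool)
        with pytest.warns(UserWarning, match="degenerate"):
            f = ngldm_features(vol, mask, SCHEME8)
        assert f["NGLDM_Contrast"] == 0.0
        assert np.isnan(f["NGLDM_Busyness"])

    def test_two_level_line_hand_count(self):
        # levels 1,1,2 on a line: diffs are 0, 0.5 and 1.0
        levels = np.array([[[1, 1, 2]]], dtype=np.int64)
        mask = np.ones((1, 1, 3), dtype=bool)
        n_i, s_i = ngldm_components(levels, mask)
        np.testing.assert_array_equal(n_i, [2, 1])
        np.testing.assert_allclose(s_i, [0.5, 1.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_components_match_brute_force_neighbourhoods(self, seed):
        rng = np.random.default_rng(200 + seed)
        levels, mask = random_voi(rng)
        got_n, got_s = ngldm_components(levels, mask)
        exp_n, exp_s = oracle_ngldm(levels, mask)
        np.testing.assert_allclose(got_n[:len(exp_n)], exp_n)
        np.testing.assert_allclose(got_s[:len(exp_s)], exp_s, atol=1e-10)


class TestGLZLM:
    def test_constant_voi_single_zone_closed_form(self):
        vol = np.full((3, 4, 2), 42.0)
        mask = np.ones((3, 4, 2), dtype=bool)
        f = glzlm_features(vol, mask, SCHEME8)
        n = 24
        assert f["GLZLM_ZP"] == pytest.approx(1 / n)
        assert f["GLZLM_ZLNU"] == pytest.approx(1.0)
        assert f["GLZLM_GLNU"] == pytest.approx(1.0)

    def test_two_disjoint_equal_zones_same_level(self):
        levels = np.ones((1, 1, 7), dtype=np.int64)
        mask = np.zeros((1, 1, 7), dtype=bool)
        mask[0, 0, :3] = True
        mask[0, 0, 4:] = True
        mat = glzlm_matrix(levels, mask)
        exp = oracle_glzlm(levels, mask)
        np.testing.assert_array_equal(mat, exp)
        assert mat[0, 2] == 2  # two zones of size 3, one level row

    @pytest.mark.parametrize("seed", range(5))
    def test_matrix_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        levels, mask = random_voi(rng)
        got = glzlm_matrix(levels, mask)
        exp = oracle_glzlm(levels, mask)
        np.testing.assert_array_equal(got[:exp.shape[0], :exp.shape[1]], exp)


class TestExtractAll:
    def test_45_keys_per_voi_and_determinism(self, textured_phantom):
        from perirad.features import RETAINED_INDICES, extract_all

        volume, pair = textured_phantom
        vec = extract_all(volume, pair)
        assert len(vec) == 90
        tumor_keys = [k for k in vec if k.startswith("Portal_Tumor_")]
        assert len(tumor_keys) == 45
        assert {k.removeprefix("Portal_Tumor_") for k in tumor_keys} == set(RETAINED_INDICES)
        assert all(np.isfinite(v) for v in vec.values())
        again = extract_all(volume, pair)
        assert vec == again

    def test_constant_tumor_texture_contrasts_zero(self):
        vol = ImageVolume(np.full((10, 10, 10), 60.0), (1, 1, 1))
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[3:7, 3:7, 3:7] = True
        with pytest.warns(UserWarning):
            vec = extract_voi(vol, mask)
        assert vec["GLCM_Contrast"] == 0.0
        assert vec["NGLDM_Contrast"] == 0.0
        assert vec["Shape_Volume_mL"] == pytest.approx(64 / 1000)

    def test_margin_vector_differs_from_tumor_on_contrasted_phantom(self, textured_phantom):
        from perirad.features import extract_all

        volume, pair = textured_phantom
        vec = extract_all(volume, pair)
        tumor = {k.removeprefix("Portal_Tumor_"): v for k, v in vec.items()
                 if k.startswith("Portal_Tumor_")}
        margin = {k.removeprefix("Portal_Margin_"): v for k, v in vec.items()
                  if k.startswith("Portal_Margin_")}
        assert tumor["HUmean"] != margin["HUmean"]
        n_diff = sum(1 for k in tumor if tumor[k] != margin[k])
        assert n_diff > 30
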