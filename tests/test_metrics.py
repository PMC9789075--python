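"""Evaluation metrics against hand-evaluated and brute-force oracles."""

import numpy as np
from hypothesis import given, settings
from hypothesis import strategies as st
import pytest
from scipy import stats
from skimage.feature import graycomatrix, graycoprops

from accelt2 import (bland_altman, glcm_metrics, icc_single_rater,
                     pearson_roi, roi_nrmse, t2_equivalent)
from accelt2.metrics import _GLCM_OFFSETS, _quantize


class TestRoiNrmse:
    def test_identity_is_zero(self, rng):
        t = rng.uniform(20, 60, (8, 8))
        roi = np.ones((8, 8), bool)
        assert roi_nrmse(t, t, roi) == 0.0

    def test_homogeneity_of_norms(self, rng):
        t = rng.uniform(20, 60, (8, 8))
        roi = rng.random((8, 8)) < 0.5
        assert roi_nrmse(t, 1.1 * t, roi) == pytest.approx(0.1, rel=1e-12)

    def test_hand_evaluated_three_pixel_example(self):
        t = np.array([40.0, 50.0, 60.0])
        p = np.array([44.0, 50.0, 54.0])
        roi = np.ones(3, bool)
        expected = np.sqrt(16 + 0 + 36) / np.sqrt(40**2 + 50**2 + 60**2)
        assert roi_nrmse(t, p, roi) == pytest.approx(expected, rel=1e-12)

    def test_scale_equivariance(self, rng):
        t = rng.uniform(20, 60, (6, 6))
        p = t + rng.normal(0, 2, (6, 6))
        roi = np.ones((6, 6), bool)
        assert roi_nrmse(3 * t, 3 * p, roi) == pytest.approx(
            roi_nrmse(t, p, roi), rel=1e-12)

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError):
            roi_nrmse(np.ones(3), np.ones(3), np.zeros(3, bool))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(c=st.floats(0.01, 100), seed=st.integers(0, 10**6))
    def test_scale_equivariance_property(self, c, seed):
        r = np.random.default_rng(seed)
        t = r.uniform(20, 60, 12)
        p = t + r.normal(0, 3, 12)
        roi = np.ones(12, bool)
        assert roi_nrmse(c * t, c * p, roi) == pytest.approx(
            roi_nrmse(t, p, roi), rel=1e-9)


class TestT2Equivalent:
    def test_product_rule(self):
        t = np.full((4,), 50.0)
        assert t2_equivalent(0.1, t, np.ones(4, bool)) == pytest.approx(5.0)

    def test_zero_for_perfect_prediction(self, rng):
        t = rng.uniform(30, 60, (5, 5))
        roi = np.ones((5, 5), bool)
        nr = roi_nrmse(t, t, roi)
        assert t2_equivalent(nr, t, roi) == 0.0

    def test_cross_check_direct_computation(self, rng):
        t = rng.uniform(30, 60, (6, 6))
        p = t * 1.05
        roi = rng.random((6, 6)) < 0.6
        nr = roi_nrmse(t, p, roi)
        direct = nr * t[roi].mean()
        assert t2_equivalent(nr, t, roi) == pytest.approx(direct, rel=1e-12)


class TestBlandAltman:
    def test_identical_pairs(self):
        v = np.array([40.0, 45.0, 50.0])
        rep = bland_altman(v, v)
        assert rep.bias == 0 and rep.loa_high - rep.loa_low == 0

    def test_constant_offset(self):
        v = np.array([40.0, 45.0, 50.0])
        rep = bland_altman(v, v + 3.0)
        assert rep.bias == pytest.approx(3.0)
        assert rep.sd == 0.0

    def test_against_formula(self, rng):
        t = rng.uniform(30, 60, 20)
        p = t + rng.normal(0, 2, 20)
        rep = bland_altman(t, p)
        d = p - t
        assert rep.bias == pytest.approx(d.mean())
        assert rep.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
        assert rep.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0])


def brute_force_glcm(q, roi, offsets, n_levels):
    """Independent oracle: explicit pair enumeration per offset."""
    per_metric = {m: [] for m in ("contrast", "dissimilarity", "homogeneity",
                                  "asm", "energy")}
    for dy, dx in offsets:
        counts = np.zeros((n_levels, n_levels))
        h, w = q.shape
        for y in range(h):
            for x in range(w):
                y2, x2 = y + dy, x + dx
                if 0 <= y2 < h and 0 <= x2 < w and roi[y, x] and roi[y2, x2]:
                    counts[q[y, x], q[y2, x2]] += 1
                    counts[q[y2, x2], q[y, x]] += 1
        p = counts / counts.sum()
        i, j = np.indices((n_levels, n_levels))
        per_metric["contrast"].append((p * (i - j) ** 2).sum())
        per_metric["dissimilarity"].append((p * abs(i - j)).sum())
        per_metric["homogeneity"].append((p / (1 + (i - j) ** 2)).sum())
        per_metric["asm"].append((p ** 2).sum())
        per_metric["energy"].append(np.sqrt((p ** 2).sum()))
    return {m: float(np.mean(v)) for m, v in per_metric.items()}


class TestGlcm:
    def test_constant_roi(self):
        m = glcm_metrics(np.full((6, 6), 42.0), np.ones((6, 6), bool))
        assert m["contrast"] == 0 and m["dissimilarity"] == 0
        assert m["homogeneity"] == 1 and m["asm"] == 1 and m["energy"] == 1

    def test_checkerboard_matches_hand_counts(self):
        img = np.array([[0.0, 100.0], [100.0, 0.0]])
        roi = np.ones((2, 2), bool)
        m = glcm_metrics(img, roi, n_levels=2, t2_range=(0, 150))
        q = _quantize(img[..., None], roi[..., None], 2, (0, 150))[..., 0]
        oracle = brute_force_glcm(q, roi, _GLCM_OFFSETS, 2)
        for k in m:
            assert m[k] == pytest.approx(oracle[k], rel=1e-12)

    def test_matches_brute_force_on_random_masked_images(self, rng):
        img = rng.uniform(0, 150, (8, 8))
        roi = rng.random((8, 8)) < 0.7
        n_levels = 8
        m = glcm_metrics(img, roi, n_levels=n_levels, t2_range=(0, 150))
        q = _quantize(img[..., None], roi[..., None], n_levels, (0, 150))[..., 0]
        oracle = brute_force_glcm(q, roi, _GLCM_OFFSETS, n_levels)
        for k in m:
            assert m[k] == pytest.approx(oracle[k], rel=1e-12)

    def test_matches_skimage_on_full_roi(self, rng):
        # independent library cross-check (full mask, pooled offsets)
        img = rng.uniform(0, 150, (12, 12))
        n_levels = 16
        q = _quantize(img[..., None], np.ones((12, 12, 1), bool), n_levels,
                      (0, 150))[..., 0].astype(np.uint8)
        gm = graycomatrix(q, [1], [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                          levels=n_levels, symmetric=True, normed=True)
        ours = glcm_metrics(img, np.ones((12, 12), bool), n_levels=n_levels,
                            t2_range=(0, 150))
        for name, sk in (("contrast", "contrast"),
                         ("dissimilarity", "dissimilarity"),
                         ("homogeneity", "homogeneity"),
                         ("asm", "ASM"), ("energy", "energy")):
            assert ours[name] == pytest.approx(
                float(graycoprops(gm, sk).mean()), rel=1e-10)

    def test_transpose_invariance_after_orientation_averaging(self, rng):
        img = rng.uniform(0, 150, (10, 10))
        roi = rng.random((10, 10)) < 0.8
        a = glcm_metrics(img, roi)
        b = glcm_metrics(img.T, roi.T)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-12)

    def test_metric_ranges_and_energy_asm_relation(self, rng):
        img = rng.uniform(0, 150, (9, 9))
        m = glcm_metrics(img, np.ones((9, 9), bool))
        # energy = sqrt(asm) holds per offset; after orientation averaging
        # Jensen gives (mean sqrt(asm))^2 <= mean asm
        assert m["energy"] ** 2 <= m["asm"] + 1e-12
        assert 0 <= m["homogeneity"] <= 1
        assert 0 <= m["asm"] <= 1
        assert m["contrast"] >= 0 and m["dissimilarity"] >= 0

    def test_no_valid_pairs_raises(self):
        roi = np.zeros((5, 5), bool)
        roi[0, 0] = True  # isolated pixel: no neighbour pairs
        with pytest.raises(ValueError):
            glcm_metrics(np.ones((5, 5)), roi)


def anova_icc3(x, y):
    """Long-hand two-way ANOVA consistency ICC(3,1) oracle."""
    data = np.stack([x, y], axis=1)
    n, k = data.shape
    grand = data.mean()
    ms_rows = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ms_cols = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sst = ((data - grand) ** 2).sum()
    ss_err = sst - (n - 1) * ms_rows - (k - 1) * ms_cols
    ms_err = ss_err / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)


class TestIcc:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        icc, lo, hi, p = icc_single_rater(x, x)
        assert icc == pytest.approx(1.0)

    def test_additive_offset_invariance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        icc, *_ = icc_single_rater(x, x + 10.0)
        assert icc == pytest.approx(1.0)

    def test_matches_longhand_anova_on_toy_table(self):
        x = np.array([9.0, 6.0, 8.0, 7.0, 10.0])
        y = np.array([2.0, 1.0, 4.0, 1.0, 5.0])
        icc, lo, hi, p = icc_single_rater(x, y)
        assert icc == pytest.approx(anova_icc3(x, y), rel=1e-9)
        assert lo <= icc <= hi
        assert 0 <= p <= 1

    def test_matches_pingouin_consistency_icc(self, rng):
        import pandas as pd
        import pingouin as pg
        x = rng.uniform(20, 60, 8)
        y = x + rng.normal(0, 3, 8)
        icc, lo, hi, p = icc_single_rater(x, y)
        df = pd.DataFrame({"scan": np.tile(np.arange(8), 2),
                           "rater": np.repeat(["t", "p"], 8),
                           "value": np.concatenate([x, y])})
        table = pg.intraclass_corr(df, targets="scan", raters="rater",
                                   ratings="value")
        row = table[table["Type"].str.contains("C,1|ICC3$", regex=True)].iloc[0]
        assert icc == pytest.approx(float(row["ICC"]), rel=1e-9)
        assert p == pytest.approx(float(row["pval"]), rel=1e-6)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            icc_single_rater(np.ones(4), np.ones(4))


class TestPearson:
    def test_identity(self, rng):
        t = rng.uniform(20, 60, (6, 6))
        roi = np.ones((6, 6), bool)
        r, p = pearson_roi(t, t, roi)
        assert r == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        t = rng.uniform(20, 60, (6, 6))
        roi = np.ones((6, 6), bool)
        r, _ = pearson_roi(t, 2.0 * t + 5.0, roi)
        assert r == pytest.approx(1.0)

    def test_five_point_toy_matches_textbook_formula(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        p = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        r, pv = pearson_roi(t, p, np.ones(5, bool))
        rr, rp = stats.pearsonr(t, p)
        assert r == pytest.approx(rr) and pv == pytest.approx(rp)

    def test_degenerate_variance_raises(self):
        with pytest.raises(ValueError):
            pearson_roi(np.ones(5), np.arange(5.0), np.ones(5, bool))
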