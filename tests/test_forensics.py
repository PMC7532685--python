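import collections

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenocount import features as ft
from phenocount import forensics as fx
from phenocount import simgen as sg


@pytest.fixture(scope="module")
def clean_features(clean_nucleus_images):
    return ft.feature_matrix(clean_nucleus_images)


@pytest.fixture(scope="module")
def anomaly_model(clean_features):
    return fx.fit_robust_pca(clean_features, k=1, alpha=0.70, seed=0)


class TestRobustPCA:
    def test_clean_gaussian_mostly_regular(self):
        rng = np.random.default_rng(0)
        d = rng.standard_normal(166)
        d /= np.linalg.norm(d)
        X = np.outer(rng.standard_normal(400), d) * 5 \
            + rng.standard_normal((400, 166)) * 0.3
        model = fx.fit_robust_pca(X, k=1, alpha=0.70, seed=0, standardize=False)
        cats = collections.Counter(fx.diagnose(x, model).category for x in X)
        assert cats["regular"] / 400 >= 0.90
        assert cats["bad_leverage"] / 400 <= 0.075

    def test_duplicate_rows_rejected(self):
        X = np.tile(np.arange(166.0), (20, 1))
        with pytest.raises(ValueError):
            fx.fit_robust_pca(X)

    def test_breakdown_with_30pc_contamination(self):
        rng = np.random.default_rng(1)
        d = rng.standard_normal(166)
        d /= np.linalg.norm(d)
        orth = rng.standard_normal(166)
        orth -= (orth @ d) * d
        orth /= np.linalg.norm(orth)
        n = 300
        X = np.outer(rng.standard_normal(n), d) * 5 \
            + rng.standard_normal((n, 166)) * 0.3
        idx = rng.choice(n, size=int(0.3 * n), replace=False)
        clean_mean = np.delete(X, idx, axis=0).mean(axis=0)
        X[idx] += orth * 40
        model = fx.fit_robust_pca(X, k=1, alpha=0.70, seed=0, standardize=False)
        flagged = [fx.diagnose(X[i], model).category for i in idx]
        assert np.mean([c in ("bad_leverage", "orthogonal_outlier")
                        for c in flagged]) >= 0.95
        # robust centre stays near the clean mean despite the contamination
        se = 0.3 / np.sqrt(n - len(idx)) * np.sqrt(166)
        assert np.linalg.norm(model.center - clean_mean) <= 2 * se + 1.0

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            fx.fit_robust_pca(np.random.default_rng(0).random((50, 5)), alpha=0.4)


class TestDiagnose:
    def test_center_is_regular(self, anomaly_model):
        center_raw = anomaly_model.center * anomaly_model.pre_scale \
            + anomaly_model.pre_center
        d = fx.diagnose(center_raw, anomaly_model)
        assert d.category == "regular"
        assert d.score_distance == pytest.approx(0.0, abs=1e-6)

    def test_far_point_along_component_is_good_leverage(self, anomaly_model):
        m = anomaly_model
        shift = m.loadings[:, 0] * m.sd_cutoff * 50 * np.sqrt(m.score_cov[0, 0])
        v = (m.center + shift) * m.pre_scale + m.pre_center
        assert fx.diagnose(v, m).category == "good_leverage"

    def test_generated_anomalies_are_bad_leverage(self, anomaly_model,
                                                  clean_nucleus_images):
        base = clean_nucleus_images[0]
        for mode in sg.ANOMALY_MODES:
            an = sg.make_anomaly(base, mode, seed=7)
            d = fx.diagnose(ft.extract_features(an), anomaly_model)
            assert d.category == "bad_leverage", mode

    @given(sd=st.floats(0, 100), od=st.floats(0, 100),
           sd_cut=st.floats(0.1, 50), od_cut=st.floats(0.1, 50))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_category_rule_is_pure_2x2(self, sd, od, sd_cut, od_cut):
        cat = fx.categorize(sd, od, sd_cut, od_cut)
        expected = {(False, False): "regular", (True, False): "good_leverage",
                    (False, True): "orthogonal_outlier",
                    (True, True): "bad_leverage"}[(sd > sd_cut, od > od_cut)]
        assert cat == expected


class TestDetectors:
    def test_separable_labels_perfect_holdout(self, rng):
        X = rng.standard_normal((200, 166))
        y = (X[:, 0] > 0).astype(int)
        # widely separated classes across many coordinates
        X[:, :50] += np.where(y == 1, 20.0, -20.0)[:, None]
        for kind in ("tamper", "synthetic"):
            det = fx.train_detector(X, y, kind, seed=0)
            assert det.accuracy == 1.0

    def test_seed_reproducible(self, rng):
        X = rng.standard_normal((120, 166))
        y = (rng.random(120) > 0.5).astype(int)
        a = fx.train_detector(X, y, "tamper", seed=3)
        b = fx.train_detector(X, y, "tamper", seed=3)
        assert (a.sensitivity, a.specificity, a.accuracy) == \
               (b.sensitivity, b.specificity, b.accuracy)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((50, 166))
        with pytest.raises(ValueError):
            fx.train_detector(X, np.ones(50), "tamper")

    def test_unknown_kind_rejected(self, rng):
        X = rng.standard_normal((50, 166))
        y = (rng.random(50) > 0.5).astype(int)
        with pytest.raises(ValueError):
            fx.train_detector(X, y, "mystery")


class TestBlockNoise:
    def test_flat_block_near_zero(self):
        m = fx.estimate_block_noise(np.full((64, 64), 0.5), 64)
        assert m.noise_level[0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_map_dimensions_ceil(self, rng):
        img = rng.random((130, 70))
        m = fx.estimate_block_noise(img, 64)
        assert m.noise_level.shape == (3, 2)

    def test_known_sigma_within_20pc(self):
        est = [fx._pca_noise_sigma(
            np.full((64, 64), 100.0)
            + np.random.default_rng(s).normal(0, 5, (64, 64)))
            for s in range(50)]
        assert abs(np.median(est) - 5.0) / 5.0 <= 0.2

    def test_image_smaller_than_block_rejected(self):
        with pytest.raises(ValueError):
            fx.estimate_block_noise(np.zeros((32, 32)), 64)


class TestLocalizeTamper:
    def test_homogeneous_image_empty_mask(self):
        rng = np.random.default_rng(0)
        img = rng.normal(0.5, 0.02, (256, 256))
        cmap, mask, box = fx.localize_tamper(img, seed=0)
        assert not mask.any() and box is None

    def test_planted_noisy_region_localized(self):
        rng = np.random.default_rng(3)
        img = rng.normal(0.5, 0.02, (256, 256))
        img[96:128, 64:96] += rng.normal(0, 0.06, (32, 32))  # ~1.6% of pixels
        cmap, mask, box = fx.localize_tamper(img, seed=0)
        truth = np.zeros_like(mask)
        truth[96:128, 64:96] = True
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.3
        x0, x1, y0, y1 = box
        assert x0 <= 80 < x1 and y0 <= 112 < y1

    def test_never_returns_majority_class(self):
        # strong two-level noise split 50:50 must not be called tampered
        rng = np.random.default_rng(5)
        img = rng.normal(0.5, 0.01, (256, 256))
        img[:, 128:] += rng.normal(0, 0.05, (256, 128))
        cmap, mask, box = fx.localize_tamper(img, seed=0)
        assert mask.sum() <= 0.5 * mask.size


class TestClassifyImage:
    def test_verdict_deterministic_and_clean_unflagged(self, anomaly_model,
                                                       clean_features,
                                                       clean_nucleus_images,
                                                       rng):
        # separable stand-in detectors
        X = np.vstack([clean_features,
                       clean_features + 50 * rng.standard_normal((60, 166))])
        y = np.r_[np.zeros(60), np.ones(60)].astype(int)
        tamper = fx.train_detector(X, y, "tamper", seed=0)
        synth = fx.train_detector(X, y, "synthetic", seed=0)
        img = clean_nucleus_images[5]
        v1 = fx.classify_image(img, anomaly_model, tamper, synth)
        v2 = fx.classify_image(img, anomaly_model, tamper, synth)
        assert (v1.synthetic, v1.anomalous, v1.tampered) == \
               (v2.synthetic, v2.anomalous, v2.tampered)
        assert not v1.anomalous

    def test_verdict_frame(self, anomaly_model, clean_nucleus_images):
        d = fx.diagnose(ft.extract_features(clean_nucleus_images[0]), anomaly_model)
        v = fx.ForensicsVerdict(False, d.anomalous, False, diagnosis=d)
        frame = fx.verdicts_to_frame({"img0": v})
        assert list(frame["image"]) == ["img0"]
        assert "score_distance" in frame.columns
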