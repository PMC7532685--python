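import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenocount import evalstats as ev


class TestPercentageError:
    def test_perfect_agreement(self):
        err, m, s = ev.percentage_error([5, 10, 3], [5, 10, 3])
        assert m == 0 and s == 0

    def test_single_unit_arithmetic(self):
        _, m, _ = ev.percentage_error([10], [11])
        assert m == pytest.approx(10.0)

    def test_matches_loop_oracle(self, rng):
        x = rng.integers(1, 50, 40)
        y = rng.integers(0, 50, 40)
        err, m, s = ev.percentage_error(x, y)
        ref = [abs(b - a) / a * 100 for a, b in zip(x, y)]
        assert np.allclose(sorted(err), sorted(ref), atol=1e-12)
        assert m == pytest.approx(np.mean(ref), abs=1e-12)

    def test_zero_reference_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            err, m, _ = ev.percentage_error([0, 10], [3, 10])
        assert len(err) == 1 and m == 0


class TestDetectionMetrics:
    def test_perfect_prediction(self):
        cells = [dict(x=10, y=10, phenotype="A", radius=5),
                 dict(x=40, y=40, phenotype="B", radius=5)]
        res = ev.detection_metrics([(cells, cells)], bootstrap=0)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_empty_prediction_zero_sensitivity(self):
        truth = [dict(x=10, y=10, phenotype="A", radius=5)]
        res = ev.detection_metrics([([], truth)], bootstrap=0)
        assert res.sensitivity == 0.0

    def test_five_cell_scene_with_one_swap(self):
        truth = [dict(x=10 * i, y=10, phenotype="A", radius=4) for i in range(5)]
        preds = [dict(x=10 * i, y=10, phenotype="A") for i in range(4)]
        preds.append(dict(x=40, y=10, phenotype="B"))  # last cell mislabelled
        res = ev.detection_metrics([(preds, truth)], phenotypes=["A", "B"],
                                   bootstrap=0)
        assert res.tp == 4 and res.fn == 1
        assert res.sensitivity == pytest.approx(4 / 5)

    def test_bootstrap_cis_seeded(self):
        rng = np.random.default_rng(0)
        per_fov = []
        for _ in range(6):
            truth = [dict(x=float(rng.uniform(0, 100)), y=float(rng.uniform(0, 100)),
                          phenotype="A", radius=5) for _ in range(4)]
            per_fov.append((truth[:3], truth))
        a = ev.detection_metrics(per_fov, bootstrap=200, seed=1)
        b = ev.detection_metrics(per_fov, bootstrap=200, seed=1)
        assert a.sensitivity_ci == b.sensitivity_ci


class TestPassingBablok:
    def test_identity_line(self):
        x = np.arange(1, 15, dtype=float)
        fit = ev.passing_bablok(x, x)
        assert fit.slope == 1.0 and fit.intercept == 0.0
        assert fit.slope_ci[0] <= 1.0 <= fit.slope_ci[1]

    def test_exact_affine_recovery(self):
        x = np.arange(1, 15, dtype=float)
        fit = ev.passing_bablok(x, 2 * x + 3)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(3.0)
        assert fit.linearity_pass

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        for _ in range(5):
            x = rng.integers(0, 40, 15).astype(float)
            y = rng.integers(0, 40, 15).astype(float)
            fit = ev.passing_bablok(x, y)
            slopes = []
            for i in range(15):
                for j in range(i + 1, 15):
                    dx, dy = x[j] - x[i], y[j] - y[i]
                    if dx == 0 and dy == 0:
                        continue
                    s = dy / dx if dx != 0 else np.sign(dy) * np.inf
                    if s != -1:
                        slopes.append(s)
            slopes.sort()
            N, K = len(slopes), sum(s < -1 for s in slopes)
            if N % 2:
                want = slopes[(N - 1) // 2 + K]
            else:
                want = (slopes[N // 2 - 1 + K] + slopes[N // 2 + K]) / 2
            assert fit.slope == pytest.approx(want)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            ev.passing_bablok([1, 2, 3], [1, 2, 3])


class TestBlandAltman:
    def test_identity(self):
        r = ev.bland_altman([1, 2, 3, 4.], [1, 2, 3, 4.])
        assert r.bias == 0 and r.sd == 0
        assert r.loa_lower == 0 == r.loa_upper

    def test_constant_offset(self):
        r = ev.bland_altman([1, 2, 3.], [3, 4, 5.])
        assert r.bias == pytest.approx(2.0) and r.sd == 0

    def test_matches_direct_formulas(self, rng):
        x = rng.normal(10, 2, 30)
        y = x + rng.normal(1, 0.5, 30)
        r = ev.bland_altman(x, y)
        d = y - x
        assert r.bias == pytest.approx(d.mean())
        assert r.loa_upper == pytest.approx(d.mean() + 1.959963984540054 * d.std(ddof=1))
        assert r.loa_lower <= r.bias <= r.loa_upper


class TestGwetAC1:
    def test_perfect_agreement(self):
        r = ev.gwet_ac1([1, 0, 1, 1], [1, 0, 1, 1])
        assert r.ac1 == 1.0

    def test_hand_computed_small_table(self):
        a = np.array([1, 1, 1, 0, 0, 1, 1, 0, 1, 1])
        b = np.array([1, 1, 0, 0, 0, 1, 1, 1, 1, 1])
        r = ev.gwet_ac1(a, b)
        pa = np.mean(a == b)
        pi1 = (np.mean(a == 1) + np.mean(b == 1)) / 2
        pe = 2 * pi1 * (1 - pi1)
        assert r.ac1 == pytest.approx((pa - pe) / (1 - pe))
        assert r.ci[0] <= r.ac1 <= r.ci[1]

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 4000)
        b = rng.integers(0, 2, 4000)
        r = ev.gwet_ac1(a, b)
        assert abs(r.ac1) < 0.06

    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)),
                    min_size=2, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounded_and_one_iff_perfect(self, pairs):
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        r = ev.gwet_ac1(a, b)
        assert -1.0 <= r.ac1 <= 1.0 + 1e-12
        if np.all(a == b):
            assert r.ac1 == pytest.approx(1.0)


class TestCountModels:
    def test_zip_nests_poisson(self, rng):
        import warnings
        y = np.concatenate([rng.poisson(3, 150), rng.poisson(3, 150)])
        g = np.array(["h"] * 150 + ["s"] * 150)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits, best = ev.fit_count_models(y, g)
        ll = {f.family: f.loglik for f in fits if f.converged}
        # nesting up to optimiser tolerance (the inflation logit runs to -inf)
        assert ll["ZIP"] >= ll["P"] - 0.01
        assert best == "P"   # AIC penalises the unused inflation parameters

    def test_identical_groups_irr_near_one(self, rng):
        import warnings
        base = rng.poisson(4, 200)
        y = np.concatenate([base, base])
        g = np.array(["h"] * 200 + ["s"] * 200)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits, _ = ev.fit_count_models(y, g, families=("P",))
        f = fits[0]
        assert f.irr == pytest.approx(1.0, abs=1e-6)
        assert f.irr_ci[0] <= 1.0 <= f.irr_ci[1]

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError):
            ev.fit_count_models([1, 2, 3], ["a", "a", "a"])


class TestROC:
    def test_separated_scores_auc_one(self):
        assert ev.roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_b_zero_degenerate_contract(self):
        app, opt, adj = ev.roc_optimism_auc([1, 2, 10, 11], [0, 0, 1, 1], B=0)
        assert opt == 0.0 and adj == app

    def test_uninformative_scores_adjusted_near_half(self, rng):
        scores = rng.normal(size=300)
        labels = rng.integers(0, 2, 300)
        app, opt, adj = ev.roc_optimism_auc(scores, labels, B=100, seed=0)
        assert abs(adj - 0.5) < 0.08

    def test_seeded_reproducibility(self, rng):
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        a = ev.roc_optimism_auc(s, y, B=50, seed=9)
        b = ev.roc_optimism_auc(s, y, B=50, seed=9)
        assert a == b


class TestYouden:
    def test_separated_classes_tie_break_lowest(self):
        c = ev.youden_cutoff([10, 10, 20, 20.], [0, 0, 1, 1])
        assert c == 20.0  # >= convention: 20 is the lowest maximiser

    def test_matches_exhaustive_search(self, rng):
        scores = rng.normal(size=60)
        labels = (scores + rng.normal(size=60) > 0).astype(int)
        got = ev.youden_cutoff(scores, labels)
        best = (-np.inf, None)
        for c in np.unique(scores):
            pred = scores >= c
            sens = (pred & (labels == 1)).sum() / max((labels == 1).sum(), 1)
            spec = (~pred & (labels == 0)).sum() / max((labels == 0).sum(), 1)
            j = sens + spec - 1
            if j > best[0]:
                best = (j, c)
        assert got == best[1]

    def test_single_value_warns(self):
        with pytest.warns(UserWarning):
            assert ev.youden_cutoff([5, 5, 5], [0, 1, 1]) == 5


class TestDiagnostics2x2:
    def test_all_correct(self):
        d = ev.diagnostics_2x2(tp=5, fp=0, tn=5, fn=0)
        assert d.sensitivity == d.specificity == d.ppv == d.npv == d.accuracy == 1.0

    def test_matches_formula_oracle_on_random_tables(self, rng):
        for _ in range(100):
            tp, fp, tn, fn = rng.integers(1, 30, 4)
            d = ev.diagnostics_2x2(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn))
            assert d.sensitivity == pytest.approx(tp / (tp + fn))
            assert d.specificity == pytest.approx(tn / (tn + fp))
            assert d.ppv == pytest.approx(tp / (tp + fp))
            assert d.npv == pytest.approx(tn / (tn + fn))
            assert d.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn))

    def test_score_mode_with_loocv_and_cis(self, rng):
        scores = np.r_[rng.normal(0, 1, 15), rng.normal(2.5, 1, 15)]
        labels = np.r_[np.zeros(15), np.ones(15)].astype(int)
        d = ev.diagnostics_2x2(scores=scores, labels=labels, B=100,
                               loocv=True, seed=0)
        assert d.cutoff is not None
        assert set(d.cis) == {"sensitivity", "specificity", "ppv", "npv", "accuracy"}
        assert d.loocv is not None
        assert 0 <= d.loocv.sensitivity <= 1
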