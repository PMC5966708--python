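"""Consistency suite: closed-form statistics and the benchmark classifiers."""

import math

import numpy as np
import pandas as pd
import pytest

import cogrisk as cr
from cogrisk.consistency import (CartNode, _cm_from_pred,
                                 logistic_predict_proba)


class TestPairedT:
    def test_hand_computed_three_differences(self):
        # diffs {1,2,3}: mean 2, sd 1, se 1/sqrt(3)
        r = cr.paired_t_from_summary(2.0, 1.0, 3)
        assert r.se == pytest.approx(0.5774, abs=5e-5)
        assert r.t == pytest.approx(3.4641, abs=5e-5)
        assert r.df == 2

    def test_negating_differences_mirrors_everything(self):
        a = cr.paired_t_from_summary(-12.4, 9.3, 40)
        b = cr.paired_t_from_summary(12.4, 9.3, 40)
        assert a.t == pytest.approx(-b.t)
        assert a.ci_low == pytest.approx(-b.ci_high)
        assert a.ci_high == pytest.approx(-b.ci_low)
        assert a.p == pytest.approx(b.p)

    def test_ci_brackets_mean_and_signs_agree(self):
        r = cr.paired_t_from_summary(-5.0, 2.0, 12)
        assert r.ci_low <= r.mean_diff <= r.ci_high
        assert math.copysign(1, r.t) == math.copysign(1, r.mean_diff)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cr.paired_t_from_summary(1.0, 0.0, 10)
        with pytest.raises(ValueError):
            cr.paired_t_from_summary(1.0, 1.0, 1)


class TestConfusionMetrics:
    def test_identity_matrix_is_perfect(self):
        m = cr.confusion_metrics(cr.ConfusionMatrix2(10, 0, 0, 10))
        assert all(m[k] == 100.0 for k in ("recall_high_pct", "recall_low_pct",
                                           "overall_pct"))

    def test_empty_observed_class_gives_nan_recall(self):
        m = cr.confusion_metrics(cr.ConfusionMatrix2(5, 1, 0, 0))
        assert math.isnan(m["recall_low_pct"])
        assert m["overall_pct"] == pytest.approx(100 * 5 / 6)

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            cr.ConfusionMatrix2(-1, 0, 0, 2)
        with pytest.raises(ValueError):
            cr.ConfusionMatrix2(0, 0, 0, 0)


class TestLogistic:
    def test_matches_reference_fit_on_nonseparable_data(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 3))
        eta = X @ np.array([0.3, -1.0, 0.5])
        y = (rng.random(60) < 1 / (1 + np.exp(-eta))).astype(int)
        model = cr.logistic_fit(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(model.coef, ref.params, atol=1e-6)
        assert model.ll == pytest.approx(ref.llf, abs=1e-8)
        assert model.converged and not model.separation

    def test_null_data_r2_near_zero(self):
        # in-sample pseudo-R2 of p noise predictors inflates like
        # E[chi2]=p, so keep n >> p to isolate the null behaviour
        vals = []
        for s in range(10):
            rng = np.random.default_rng(s)
            X = rng.normal(size=(400, 2))
            y = rng.integers(0, 2, 400)
            m = cr.logistic_fit(X, y)
            vals.append(cr.nagelkerke_r2(m.ll_null, m.ll, 400))
        assert np.median(vals) < 0.05
        assert np.mean(vals) < 0.05

    def test_separable_data_flags_separation_and_classifies_perfectly(self):
        x = np.linspace(-2, 2, 30).reshape(-1, 1)
        y = (x.ravel() > 0).astype(int)
        m = cr.logistic_fit(x, y)
        assert m.separation
        cm50 = cr.logistic_classify(m, x, y, 0.50)
        cm70 = cr.logistic_classify(m, x, y, 0.70)
        assert cm50 == cm70  # same table at both cut-offs
        assert cr.confusion_metrics(cm50)["overall_pct"] == 100.0
        assert cr.nagelkerke_r2(m.ll_null, m.ll, 30) == pytest.approx(1.0, abs=1e-3)

    def test_cutoff_semantics_positive_class_is_low(self):
        m = cr.LogisticModel(coef=np.array([math.log(0.6 / 0.4)]),
                             ll=0, ll_null=-1, converged=True,
                             separation=False, n_obs=4, n_predictors=0)
        X = np.empty((4, 0))
        y = np.array([0, 0, 1, 1])
        probs = logistic_predict_proba(m, X)
        assert np.allclose(probs, 0.6)
        cm = cr.logistic_classify(m, X, y, 0.50)
        assert cm.n_hl == 2 and cm.n_ll == 2  # everyone predicted low
        cm = cr.logistic_classify(m, X, y, 0.70)
        assert cm.n_hh == 2 and cm.n_lh == 2  # everyone predicted high

    def test_nonbinary_outcome_rejected(self):
        with pytest.raises(ValueError):
            cr.logistic_fit(np.zeros((3, 1)), np.array([0, 1, 2]))


class TestNagelkerkeOmnibus:
    def test_null_model_scores_zero(self):
        assert cr.nagelkerke_r2(-10.0, -10.0, 20) == 0.0
        chi2, df, p = cr.omnibus_test(-10.0, -10.0, 5)
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_perfect_fit_scores_one(self):
        ll_null = 59 * math.log(59 / 70) + 11 * math.log(11 / 70)
        assert cr.nagelkerke_r2(ll_null, 0.0, 70) == pytest.approx(1.0)

    def test_hand_sized_case(self):
        # n=4, LL_null=ln(1/16), LL_model=ln(1/4):
        # Cox-Snell = 1-exp(-ln4/2)=0.5, max = 1-exp(ln(1/16)/2)=0.75
        r2 = cr.nagelkerke_r2(math.log(1 / 16), math.log(1 / 4), 4)
        assert r2 == pytest.approx(2 / 3, abs=1e-12)

    def test_even_split_perfect_model_closed_form(self):
        ll_null = 70 * math.log(0.5)
        chi2, _, _ = cr.omnibus_test(ll_null, 0.0, 24)
        assert chi2 == pytest.approx(2 * 70 * math.log(2), abs=1e-9)
        assert chi2 == pytest.approx(97.041, abs=5e-4)

    def test_r2_is_one_iff_chi2_is_minus_twice_null(self):
        ll_null = -30.0
        chi2, _, _ = cr.omnibus_test(ll_null, 0.0, 24)
        assert chi2 == pytest.approx(-2 * ll_null)
        assert cr.nagelkerke_r2(ll_null, 0.0, 70) == pytest.approx(1.0)
        assert cr.nagelkerke_r2(ll_null, -5.0, 70) < 1.0


class TestCart:
    def test_pure_labels_give_single_leaf(self):
        tree = cr.cart_fit(np.random.default_rng(0).normal(size=(10, 2)),
                           np.ones(10))
        assert tree.root.is_leaf and tree.n_nodes == 1

    def test_xor_needs_depth_two_and_memorizes(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([0, 1, 1, 0])
        tree = cr.cart_fit(X, y)
        assert tree.depth == 2
        np.testing.assert_array_equal(cr.cart_predict(tree, X), y)

    def test_threshold_function_recovers_root_split(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (60, 3))
        y = (X[:, 1] > 0.4).astype(int)
        tree = cr.cart_fit(X, y)
        assert tree.root.feature == 1
        xs = np.sort(X[:, 1])
        gap = xs[np.searchsorted(xs, 0.4)] - xs[np.searchsorted(xs, 0.4) - 1]
        assert abs(tree.root.threshold - 0.4) <= gap

    def test_memorizes_any_consistent_labelling(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 4))
        y = rng.integers(0, 2, 40)
        tree = cr.cart_fit(X, y, min_leaf=1, max_depth=None)
        assert (cr.cart_predict(tree, X) == y).all()

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            cr.cart_fit(np.empty((0, 2)), np.empty(0))


class TestMlp:
    def test_zero_weights_give_symmetric_probabilities(self):
        m = cr.mlp_fit(np.zeros((5, 3)), np.array([0, 1, 0, 1, 0]),
                       hidden_units=4, epochs=0, init_scale=0.0)
        probs = cr.mlp_proba(m, np.random.default_rng(0).normal(size=(7, 3)))
        np.testing.assert_allclose(probs, 0.5)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0)

    def test_linearly_separable_toy_reaches_full_accuracy(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(-2, 0.5, (20, 2)),
                       rng.normal(2, 0.5, (20, 2))])
        y = np.repeat([0, 1], 20)
        for seed in range(3):
            m = cr.mlp_fit(X, y, hidden_units=3, mode="batch", seed=seed,
                           epochs=500, lr=0.5)
            assert (cr.mlp_predict(m, X) == y).all()

    def test_batch_loss_non_increasing_with_small_step(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 3))
        y = (X[:, 0] > 0).astype(int)
        m = cr.mlp_fit(X, y, hidden_units=4, mode="batch", seed=1,
                       epochs=200, lr=0.05)
        trace = np.array(m.loss_trace)
        assert np.all(np.diff(trace) <= 1e-10)

    @pytest.mark.parametrize("mode", ["online", "minibatch"])
    def test_stochastic_modes_learn_separable_data(self, mode):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(-2, 0.4, (15, 2)),
                       rng.normal(2, 0.4, (15, 2))])
        y = np.repeat([0, 1], 15)
        m = cr.mlp_fit(X, y, hidden_units=3, mode=mode, seed=0,
                       epochs=300, lr=0.5)
        assert (cr.mlp_predict(m, X) == y).mean() >= 0.95

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            cr.mlp_fit(np.zeros((4, 2)), np.array([0, 1, 0, 1]), mode="ga")


class TestConsistencyReport:
    def test_single_feature_labels_reach_full_agreement(self, default_features):
        # label = thresholded single input column: every classifier family
        # can express it, so all tables are perfect
        feats = default_features
        X, pids, _ = cr.design_matrix(feats)
        y = X[:, 0] > np.median(X[:, 0])
        labels = pd.DataFrame({"participant": pids,
                               "general_risk": np.where(y, "low", "high")})
        rep = cr.consistency_report(feats, labels, seed=0,
                                    mlp_modes=("batch",), mlp_epochs=800)
        assert rep["logistic"]["cutoff_0.50"]["overall_pct"] == 100.0
        assert rep["cart"]["overall_pct"] == 100.0
        assert rep["mlp"]["batch"]["overall_pct"] == 100.0

    def test_design_matrix_is_six_by_four(self, default_features):
        feats = default_features
        M, pids, names = cr.design_matrix(feats)
        assert M.shape == (70, 24)
        assert len(names) == 24
        for tid in cr.DEFAULT_TASK_IDS:
            assert sum(n.startswith(f"{tid}:") for n in names) == 4

    def test_shuffled_labels_leave_logistic_near_chance(self, default_features):
        feats = default_features
        X, pids, _ = cr.design_matrix(feats)
        accs = []
        for s in range(5):
            rng = np.random.default_rng(s)
            y = rng.permutation(np.repeat([0, 1], 35))
            m = cr.logistic_fit((X - X.mean(0)) / X.std(0), y)
            cm = cr.logistic_classify(m, (X - X.mean(0)) / X.std(0), y, 0.5)
            accs.append(cr.confusion_metrics(cm)["overall_pct"])
        # in-sample fit with 24 free predictors overfits well above 50%,
        # but shuffled labels cannot be fit perfectly
        assert np.mean(accs) < 100.0


def test_cm_from_pred_round_trip():
    y = np.array([0, 0, 1, 1, 1])
    pred = np.array([0, 1, 1, 0, 1])
    cm = _cm_from_pred(y, pred)
    assert (cm.n_hh, cm.n_hl, cm.n_lh, cm.n_ll) == (1, 1, 1, 2)
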