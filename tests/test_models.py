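"""Classifier configurations, cross-validation mechanics and the metric suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from propriokit.models import (
    CANONICAL_SPECS,
    ModelSpec,
    auc,
    canonical_specs,
    evaluate,
    feature_importance,
    fit_logistic,
    single_class_baseline,
    stratified_kfold_indices,
)


def concordance_auc(scores, labels):
    """Exhaustive pairwise-concordance oracle: P(s+ > s-) + 0.5 P(tie)."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            wins += p > n
            ties += p == n
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_and_reversed_ranking(self):
        y = np.array([0, 0, 1, 1])
        assert auc(np.array([0.1, 0.2, 0.8, 0.9]), y) == 1.0
        assert auc(np.array([0.9, 0.8, 0.2, 0.1]), y) == 0.0

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_concordance_oracle_on_toy_sets(self, seed):
        rng = np.random.default_rng(seed)
        n_pos = rng.integers(1, 9)
        n_neg = rng.integers(1, 9)
        labels = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
        # coarse scores force ties
        scores = rng.integers(0, 4, size=n_pos + n_neg).astype(float)
        assert auc(scores, labels) == pytest.approx(concordance_auc(scores, labels), abs=1e-12)

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_concordance_property(self, data):
        n_pos = data.draw(st.integers(1, 8))
        n_neg = data.draw(st.integers(1, 8))
        scores = data.draw(
            st.lists(st.integers(0, 5), min_size=n_pos + n_neg, max_size=n_pos + n_neg)
        )
        labels = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
        assert auc(np.asarray(scores, float), labels) == pytest.approx(
            concordance_auc(scores, labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.array([0.4, 0.6]), np.array([1, 1]))


class TestBaseline:
    def test_study_prevalence(self):
        labels = np.array([1] * 48 + [0] * 85)
        hi, lo = single_class_baseline(labels)
        assert round(hi, 1) == 63.9
        assert round(lo, 1) == 36.1

    def test_balanced_and_degenerate(self):
        assert single_class_baseline(np.array([0, 1, 0, 1])) == (50.0, 50.0)
        assert single_class_baseline(np.array([1, 1, 1])) == (100.0, 0.0)


class TestStratifiedFolds:
    def test_divisible_case_exact(self):
        labels = np.array([1] * 40 + [0] * 60)
        folds = stratified_kfold_indices(labels, k=10, seed=0)
        for f in range(10):
            assert labels[folds == f].sum() == 4

    def test_study_size_counts(self):
        labels = np.array([1] * 48 + [0] * 85)
        folds = stratified_kfold_indices(labels, k=10, seed=1)
        pos_per_fold = [labels[folds == f].sum() for f in range(10)]
        # 48 positives over 10 folds: each fold holds 4 or 5
        assert set(pos_per_fold) <= {4, 5}
        assert sum(pos_per_fold) == 48

    def test_seed_determinism(self):
        labels = np.array([1] * 20 + [0] * 30)
        a = stratified_kfold_indices(labels, k=5, seed=7)
        b = stratified_kfold_indices(labels, k=5, seed=7)
        assert np.array_equal(a, b)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="at least k"):
            stratified_kfold_indices(np.array([1] * 5 + [0] * 50), k=10)


def make_table(rng, n, beta=None, n_noise=3):
    """Logistic data: label from a known slope on x0, plus noise features."""
    X = rng.standard_normal((n, 1 + n_noise))
    logits = (beta or 0.0) * X[:, 0]
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
    cols = {f"x{i}": X[:, i] for i in range(1 + n_noise)}
    cols["impaired_6mo"] = y
    return pd.DataFrame(cols)


class TestLogisticFit:
    def test_null_labels_give_null_coefficients(self):
        table = make_table(np.random.default_rng(0), 4000, beta=0.0)
        fit = fit_logistic(table, table["impaired_6mo"], ModelSpec("null", ("x0", "x1", "x2", "x3")))
        assert np.all(np.abs(fit.coef) < 0.1)

    def test_known_slope_recovered_within_ten_percent(self):
        beta = 1.0
        table = make_table(np.random.default_rng(1), 5000, beta=beta)
        fit = fit_logistic(table, table["impaired_6mo"], ModelSpec("slope", ("x0",)))
        # features are standardised; x0 ~ N(0,1) so the coefficient is beta itself
        assert fit.coef[0] == pytest.approx(beta, rel=0.10)

    def test_duplicated_column_rejected(self):
        table = make_table(np.random.default_rng(2), 200, beta=1.0)
        table["x0_copy"] = table["x0"]
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_logistic(table, table["impaired_6mo"], ModelSpec("dup", ("x0", "x0_copy")))

    def test_duplicate_feature_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ModelSpec("bad", ("x0", "x0"))


class TestEvaluate:
    def test_separable_data_is_perfect(self):
        rng = np.random.default_rng(3)
        n = 100
        y = np.array([0] * 50 + [1] * 50)
        table = pd.DataFrame({"x0": y * 10.0 + rng.normal(0, 0.1, n), "impaired_6mo": y})
        res = evaluate(ModelSpec("sep", ("x0",)), table, k=10, seed=0)
        assert res.accuracy == 100.0
        assert res.auc == 1.0

    def test_shuffled_labels_are_chance(self):
        rng = np.random.default_rng(4)
        table = make_table(rng, 600, beta=1.5)
        table["impaired_6mo"] = rng.permutation(table["impaired_6mo"].to_numpy())
        res = evaluate(ModelSpec("null", ("x0", "x1")), table, k=10, seed=0)
        assert abs(res.auc - 0.5) < 0.08
        majority = max(table["impaired_6mo"].mean(), 1 - table["impaired_6mo"].mean()) * 100
        assert abs(res.accuracy - majority) < 10

    def test_confusion_counts_sum_to_n(self, feature_table):
        res = evaluate(canonical_specs()[1], feature_table, k=10, seed=0)
        tp, fp, tn, fn = res.confusion
        assert tp + fp + tn + fn == len(feature_table)
        assert res.accuracy == pytest.approx(100 * (tp + tn) / len(feature_table))

    def test_aic_direction_over_seeds(self):
        """AIC drops when an informative feature joins a null model and rises
        when a pure-noise feature does (majority over seeds)."""
        inf_better = noise_worse = 0
        n_seeds = 10
        for seed in range(n_seeds):
            table = make_table(np.random.default_rng(100 + seed), 1500, beta=0.8)
            base = evaluate(ModelSpec("b", ("x1",)), table, k=5, seed=0).aic
            with_inf = evaluate(ModelSpec("i", ("x1", "x0")), table, k=5, seed=0).aic
            with_noise = evaluate(ModelSpec("n", ("x1", "x2")), table, k=5, seed=0).aic
            inf_better += with_inf < base
            noise_worse += with_noise > base
        assert inf_better >= 8
        assert noise_worse >= 6

    def test_basic_model_collapses_to_majority_class(self, feature_table):
        """With uninformative demographics the classifier mostly predicts the
        majority (unimpaired) class: near-zero sensitivity, high specificity."""
        res = evaluate(canonical_specs()[0], feature_table, k=10, seed=0)
        assert res.specificity > 75.0
        assert res.sensitivity < 40.0


class TestRidgeMode:
    def test_ridge_runs_but_reports_no_aic(self, feature_table):
        res = evaluate(
            ModelSpec("ridge", CANONICAL_SPECS["Clinical"], penalty="ridge", ridge_c=1.0),
            feature_table, k=5, seed=0,
        )
        assert 0 <= res.auc <= 1
        assert np.isnan(res.aic)


class TestCanonicalSpecs:
    def test_five_models_with_expected_features(self):
        specs = {s.name: s for s in canonical_specs()}
        assert set(specs) == {"Basic", "Clinical", "Imaging", "Robotic", "Augmented"}
        assert specs["Basic"].features == ("age", "sex", "affected_arm")
        assert set(specs["Clinical"].features) == {"age", "sex", "affected_arm", "tlt", "bit", "fim"}
        assert set(specs["Imaging"].features) == {"age", "sex", "affected_arm", "vlsm_mean_z", "lesion_volume"}
        assert len(specs["Robotic"].features) == 11
        assert len(specs["Augmented"].features) == 16
        assert set(specs["Augmented"].features) == set().union(*(s.features for s in specs.values()))


class TestImportance:
    def test_informative_feature_ranked_first(self):
        top1 = 0
        n_seeds = 20
        for seed in range(n_seeds):
            table = make_table(np.random.default_rng(300 + seed), 400, beta=1.2)
            ranked = feature_importance(
                ModelSpec("imp", ("x0", "x1", "x2", "x3")), table
            )
            top1 += ranked.iloc[0]["feature"] == "x0"
        assert top1 >= 18  # >= 90%

    def test_identical_effect_features_get_similar_weight(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(3000)
        y = (rng.random(3000) < 1 / (1 + np.exp(-x))).astype(int)
        table = pd.DataFrame({
            "a": x + rng.normal(0, 0.5, 3000),
            "b": x + rng.normal(0, 0.5, 3000),
            "impaired_6mo": y,
        })
        ranked = feature_importance(ModelSpec("twin", ("a", "b")), table).set_index("feature")
        ca, cb = ranked.loc["a", "coefficient"], ranked.loc["b", "coefficient"]
        assert ca == pytest.approx(cb, rel=0.35)


class TestModalityOrdering:
    def test_auc_ordering_reproduces_study_pattern(self, norm_model, pipeline_run):
        """Basic lags all richer models; Imaging does not beat the best of
        Clinical/Robotic/Augmented (study pattern, checked over seeds)."""
        import tempfile

        from propriokit.pipeline import RunConfig, run_pipeline
        from propriokit.synthetic import SyntheticConfig

        wins = 0
        n_seeds = 8
        for seed in range(n_seeds):
            rc = RunConfig(
                out_dir=tempfile.mkdtemp(),
                synthetic=SyntheticConfig(n_controls=150, n_stroke=133),
                seed=500 + seed,
            )
            run_pipeline(rc, stages=("simulate", "fit-norms", "score", "vlsm", "stats", "predict"))
            res = pd.read_csv(f"{rc.out_dir}/predict/model_results.csv").set_index("model")["auc"]
            basic_lowest = res["Basic"] == res.min()
            imaging_not_best = res["Imaging"] <= max(res["Clinical"], res["Robotic"], res["Augmented"]) + 0.02
            wins += basic_lowest and imaging_not_best
        assert wins >= int(0.8 * n_seeds)
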