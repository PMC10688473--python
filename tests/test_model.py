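"""Ensemble training, nested CV behavior, soft voting, attribution."""

import warnings

import numpy as np
import pandas as pd
import pytest

from varmode.constants import CLASS_ORDER
from varmode.model import (
    DEFAULT_ENSEMBLE_SIZE,
    DEFAULT_SEARCH_SPACE,
    attribute,
    fit_pipeline,
    grouped_folds,
    load_model,
    nested_cv,
    predict,
    sample_config,
    save_model,
    train_ensemble,
)
from varmode.simulate import SyntheticSpec, gen_variant_dataset

warnings.filterwarnings("ignore", module="lightgbm")


def numeric_xy(variants, features):
    X = features.select_dtypes(include=[np.number]).fillna(0.0)
    return X, variants["label"].to_numpy()


class TestSearchSpace:
    def test_sampled_config_within_bounds(self, rng):
        for _ in range(20):
            config = sample_config(DEFAULT_SEARCH_SPACE, rng)
            assert 5 <= config["n_members"] <= 31
            assert 1e-3 <= config["learning_rate"] <= 0.3
            assert 3 <= config["max_depth"] <= 12

    def test_default_final_ensemble_size(self):
        assert DEFAULT_ENSEMBLE_SIZE == 27


class TestGroupedFolds:
    def test_genes_never_straddle_folds(self, separable_dataset, rng):
        variants, _, _ = separable_dataset
        folds = grouped_folds(variants["label"].to_numpy(),
                              variants["gene"].to_numpy(), 5, rng)
        genes = variants["gene"].to_numpy()
        for tr, te in folds:
            assert not (set(genes[tr]) & set(genes[te]))

    def test_every_class_on_both_sides(self, separable_dataset, rng):
        variants, _, _ = separable_dataset
        labels = variants["label"].to_numpy()
        folds = grouped_folds(labels, variants["gene"].to_numpy(), 5, rng)
        for tr, te in folds:
            assert set(labels[tr]) == set(labels[te]) == set(CLASS_ORDER)


class TestTrainPredict:
    def test_member_count_respects_config(self, separable_dataset, rng, fast_config):
        variants, features, _ = separable_dataset
        X, y = numeric_xy(variants, features)
        model = train_ensemble(X, y, fast_config, rng)
        assert model.n_members == fast_config["n_members"]

    def test_invalid_member_count(self, separable_dataset, rng):
        variants, features, _ = separable_dataset
        X, y = numeric_xy(variants, features)
        with pytest.raises(ValueError):
            train_ensemble(X, y, {"n_members": 0}, rng)

    def test_members_differ_by_seed(self, separable_dataset, rng, fast_config):
        variants, features, _ = separable_dataset
        X, y = numeric_xy(variants, features)
        model = train_ensemble(X, y, fast_config, rng)
        p0 = model.members[0].predict_proba(np.asarray(X))
        differs = any(
            not np.allclose(p0, m.predict_proba(np.asarray(X)))
            for m in model.members[1:]
        )
        assert differs

    def test_probabilities_sum_to_one(self, separable_dataset, rng, fast_config):
        variants, features, _ = separable_dataset
        X, y = numeric_xy(variants, features)
        model = train_ensemble(X, y, fast_config, rng)
        probs = predict(model, X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_single_member_identity(self, separable_dataset, rng):
        variants, features, _ = separable_dataset
        X, y = numeric_xy(variants, features)
        model = train_ensemble(X, y, {"n_members": 1, "n_estimators": 30}, rng)
        probs = predict(model, X)
        np.testing.assert_allclose(
            probs, model.members[0].predict_proba(np.asarray(X)), atol=1e-12
        )

    def test_member_order_irrelevant(self, separable_dataset, rng, fast_config):
        variants, features, _ = separable_dataset
        X, y = numeric_xy(variants, features)
        model = train_ensemble(X, y, fast_config, rng)
        probs = predict(model, X)
        model.members.reverse()
        np.testing.assert_allclose(probs, predict(model, X), atol=1e-12)

    def test_column_mismatch_rejected(self, separable_dataset, rng, fast_config):
        variants, features, _ = separable_dataset
        X, y = numeric_xy(variants, features)
        model = train_ensemble(X, y, fast_config, rng)
        with pytest.raises(ValueError, match="columns"):
            predict(model, X[list(X.columns[::-1])])

    def test_save_load_roundtrip(self, separable_dataset, rng, fast_config, tmp_path):
        variants, features, _ = separable_dataset
        pipeline = fit_pipeline(features, variants["label"], config=fast_config, rng=rng)
        probs = pipeline.predict(features)
        save_model(pipeline, tmp_path / "model")
        back = load_model(tmp_path / "model")
        np.testing.assert_allclose(probs, back.predict(features), atol=1e-9)


class TestAttribution:
    def test_additivity_to_margin(self, separable_dataset, rng, fast_config):
        variants, features, _ = separable_dataset
        X, y = numeric_xy(variants, features)
        model = train_ensemble(X, y, fast_config, rng)
        contrib, base = attribute(model, X.iloc[:20])
        total = contrib.sum(axis=2) + base
        margins = np.mean(
            [m.booster_.predict(np.asarray(X.iloc[:20]), raw_score=True)
             for m in model.members],
            axis=0,
        )
        np.testing.assert_allclose(total, margins, atol=1e-6)

    def test_unused_feature_zero_attribution(self, rng, fast_config):
        n = 300
        X = pd.DataFrame({
            "signal": np.r_[np.zeros(n // 3), np.ones(n // 3), 2 * np.ones(n // 3)],
            "constant": np.zeros(n),
        })
        y = np.array(["GOF"] * (n // 3) + ["LOF"] * (n // 3) + ["NEUTRAL"] * (n // 3))
        model = train_ensemble(X, y, fast_config, rng)
        contrib, _ = attribute(model, X.iloc[:30])
        assert np.abs(contrib[:, :, 1]).max() == 0.0

    def test_informative_features_outrank_noise(self, fast_config):
        # Mean |attribution| must rank every planted informative numeric
        # feature above every noise feature in >= 8 of 10 seeds.
        wins = 0
        for seed in range(10):
            spec = SyntheticSpec(
                seed=seed, n_genes=40, variants_per_gene=6,
                class_mix=(0.25, 0.375, 0.375), n_informative_features=3,
                effect_size=1.5, n_noise_features=4, missing_rate=0.0,
            )
            variants, features, informative = gen_variant_dataset(spec)
            X = features.reset_index(drop=True).select_dtypes(include=[np.number])
            y = variants["label"].to_numpy()
            model = train_ensemble(X, y, fast_config, np.random.default_rng(seed))
            contrib, _ = attribute(model, X)
            importance = pd.Series(
                np.abs(contrib).mean(axis=(0, 1)), index=X.columns
            )
            inf_cols = [c for c in informative if c in X.columns]
            noise_cols = [c for c in X.columns if c.startswith("noise_")]
            if importance[inf_cols].min() > importance[noise_cols].max():
                wins += 1
        assert wins >= 8


class TestNestedCV:
    def test_separable_data_high_macro_f1(self, separable_dataset, fast_space):
        variants, features, _ = separable_dataset
        result = nested_cv(
            features, variants["label"].to_numpy(), variants["gene"].to_numpy(),
            space=fast_space, n_outer=3, n_inner=3, n_trials=2,
            rng=np.random.default_rng(0), final_selection=False,
        )
        assert len(result.outer_scores) == 3
        assert np.median(result.outer_scores) > 0.8
        assert set(result.best_config) == set(fast_space)

    def test_null_data_near_chance(self, null_dataset, fast_space):
        # Zero effect size: macro-F1 should sit near 3-class chance; this
        # also guards against leakage through oversampling order.
        variants, features, _ = null_dataset
        result = nested_cv(
            features, variants["label"].to_numpy(), variants["gene"].to_numpy(),
            space=fast_space, n_outer=3, n_inner=2, n_trials=2,
            rng=np.random.default_rng(0), final_selection=False,
        )
        assert np.median(result.outer_scores) < 0.45

    def test_outer_fold_count_default(self, separable_dataset, fast_space):
        variants, features, _ = separable_dataset
        result = nested_cv(
            features, variants["label"].to_numpy(), variants["gene"].to_numpy(),
            space=fast_space, n_outer=5, n_inner=2, n_trials=1,
            rng=np.random.default_rng(1), final_selection=False,
        )
        assert len(result.outer_scores) == 5

    def test_degenerate_trial_budget_still_valid(self, separable_dataset, fast_space):
        variants, features, _ = separable_dataset
        result = nested_cv(
            features, variants["label"].to_numpy(), variants["gene"].to_numpy(),
            space=fast_space, n_outer=2, n_inner=2, n_trials=1,
            rng=np.random.default_rng(2), final_selection=True,
        )
        assert isinstance(result.best_config, dict)
        assert 5 <= result.best_config["n_members"] <= 7
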