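"""Stacked model: OOF hygiene, rank transform, selection rule, wiring, search."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from cpimine.features import FeatureMatrix
from cpimine.stacker import (
    CLASSES,
    OTHER,
    StackerConfig,
    StratificationError,
    StackedModel,
    make_learner,
    oof_scores,
    predict_meta,
    randomized_search,
    rank_normalize,
    rfe_select,
    select_best_triplet,
)


class Memorizer:
    """Classifier that memorizes training rows exactly (leakage canary)."""

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        self.table = {tuple(row): label for row, label in zip(X, y)}
        return self

    def predict_proba(self, X):
        out = np.zeros((len(X), len(self.classes_)))
        pos = {c: j for j, c in enumerate(self.classes_)}
        for i, row in enumerate(X):
            label = self.table.get(tuple(row), self.classes_[0])
            out[i, pos[label]] = 1.0
        return out

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


class TestRankNormalize:
    def test_simple_cases(self):
        assert rank_normalize(np.array([0.1, 0.5, 0.9])).tolist() == [0.0, 0.5, 1.0]
        assert rank_normalize(np.array([7.0, 7.0, 7.0])).tolist() == [0.5, 0.5, 0.5]
        assert rank_normalize(np.array([42.0])).tolist() == [0.5]
        assert rank_normalize(np.array([])).size == 0

    def test_order_preserving_on_random_vectors(self, rng):
        for _ in range(50):
            v = rng.normal(size=int(rng.integers(3, 40)))
            r = rank_normalize(v)
            assert r.min() >= 0.0 and r.max() <= 1.0
            rho = spearmanr(v, r).statistic
            assert rho == pytest.approx(1.0)


class TestOOF:
    def test_fold_partition_recount(self, rng):
        X = rng.normal(size=(60, 4))
        y = np.array([0, 1] * 30)
        res = oof_scores(X, y, lambda: make_learner("rf", 0, StackerConfig(n_estimators=20)),
                         n_folds=10, seed=3)
        assert res.n_folds == 10 and len(res.fold_models) == 10
        # union of holdout rows = all rows, pairwise disjoint
        assert set(res.fold_of_row) == set(range(10))
        assert (res.fold_of_row >= 0).all()
        counts = np.bincount(res.fold_of_row)
        assert counts.sum() == 60

    def test_leakage_canary_memorizer(self, rng):
        """A memorizing learner aces resubstitution but not OOF scoring."""
        X = rng.normal(size=(50, 3))
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]  # both classes present
        mem = Memorizer().fit(X, y)
        assert (mem.predict(X) == y).mean() == 1.0
        res = oof_scores(X, y, Memorizer, n_folds=5, seed=0)
        oof_pred = res.classes[res.oof.argmax(axis=1)]
        assert (oof_pred == y).mean() < 1.0

    def test_single_member_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([0] * 9 + [1])
        with pytest.raises(StratificationError, match="class 1"):
            oof_scores(X, y, Memorizer, n_folds=5, seed=0)

    def test_stratification_fallback_warns(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.array([0] * 17 + [1] * 3)
        with pytest.warns(UserWarning, match="folds"):
            res = oof_scores(X, y, Memorizer, n_folds=10, seed=0)
        assert res.n_folds == 3

    def test_leave_one_out_like_fold_count(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([0, 1] * 5)
        res = oof_scores(X, y, Memorizer, n_folds=5, seed=0)
        assert len(res.fold_models) == 5


class TestPredictMeta:
    def test_average_of_fold_models(self, rng):
        X = rng.normal(size=(8, 2))
        y = np.array([0, 1] * 4)
        m1 = Memorizer().fit(X, y)
        m2 = Memorizer().fit(X, 1 - y)
        classes = np.array([0, 1])
        avg = predict_meta(X, [m1, m2], classes)
        assert np.allclose(avg, 0.5)  # the two memorizers disagree everywhere
        assert np.allclose(predict_meta(X, [m1, m1], classes),
                           predict_meta(X, [m1], classes))
        # permuting fold-model order changes nothing
        assert np.allclose(predict_meta(X, [m1, m2], classes),
                           predict_meta(X, [m2, m1], classes))


class TestSelectBestTriplet:
    def _scores(self, best_by_row):
        out = np.zeros((len(best_by_row), len(CLASSES)))
        for i, (cls, score) in enumerate(best_by_row):
            out[i, CLASSES.index(cls)] = score
            out[i, CLASSES.index(OTHER)] = 1 - score
        return out

    def test_agonist_triplet_wins(self):
        # the published worked example: three triplets for one pair
        scores = self._scores([(5, 0.7234), (3, 0.5118), (9, 0.3841)])
        i = select_best_triplet(scores, [1, 3, 8], ["agonist", "enhances", "caused"])
        assert i == 0

    def test_single_triplet_returns_itself(self):
        assert select_best_triplet(self._scores([(4, 0.2)]), [0], ["w"]) == 0

    def test_tie_breaks_by_position_then_word(self):
        scores = self._scores([(4, 0.6), (3, 0.6)])
        assert select_best_triplet(scores, [5, 2], ["b", "a"]) == 1
        assert select_best_triplet(scores, [2, 2], ["b", "a"]) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_triplet(np.zeros((0, 6)), [], [])

    def test_one_minus_other_mode(self):
        scores = np.zeros((2, 6))
        scores[0, CLASSES.index(OTHER)] = 0.9   # confident other
        scores[1, CLASSES.index(OTHER)] = 0.2
        assert select_best_triplet(scores, [0, 1], ["a", "b"],
                                   mode="one_minus_other") == 1


class TestModelWiring:
    def test_stage_registry_widths(self, trained_pipeline):
        pipe, *_ = trained_pipeline
        model = pipe.model
        fams = model.config.stage2_families()
        per_family = 2 * len(CLASSES)          # 6 class scores + argmax one-hot
        block = len(fams) * per_family
        want = len(pipe.pair_registry) + 2 * block + 1  # + no_triplet flag
        assert len(model.stage3_registry) == want
        for track in ("pair", "triplet"):
            art = model.tracks[track]
            assert set(art.stage1) == {"rf", "et", "xgb"}
            assert set(art.stage2) == set(fams)
            assert len(art.aug_registry) == len(art.registry) + 3  # 3 meta cols

    def test_oof_bookkeeping_no_leakage(self, trained_pipeline):
        """Every row's stage-I score comes from a model that excluded it."""
        pipe, *_ = trained_pipeline
        for track in ("pair", "triplet"):
            for fam, res in pipe.model.tracks[track].stage1.items():
                assert (res.fold_of_row >= 0).all()
                assert len(res.fold_models) == res.n_folds

    def test_degenerate_binary_target_rejected(self):
        X = FeatureMatrix(["a"], np.arange(24, dtype=float).reshape(-1, 1))
        y = [10] * 24  # all "other": stage-I target single-class
        with pytest.raises(StratificationError, match="degenerate"):
            StackedModel.fit(X, y, X, y, list(range(24)), [0] * 24, ["w"] * 24,
                             StackerConfig(n_folds=3, n_estimators=5, xgb_estimators=5))

    def test_predict_registry_mismatch_rejected(self, trained_pipeline):
        pipe, _, test_c, _ = trained_pipeline
        from cpimine.pipeline import featurize_corpus
        from cpimine.features import encode_matrix

        feats = featurize_corpus(test_c, pipe.dictionary, pipe._adapter(),
                                 pipe.feature_config)
        bad = encode_matrix(feats.pair_rows, fit=True)  # wrong registry order
        bad = FeatureMatrix(bad.columns[:3], bad.values[:, :3])
        with pytest.raises(ValueError, match="registry"):
            pipe.model.predict(bad, bad, [], [], [])


class TestSearchAndRFE:
    def _data(self, rng, n=90):
        X = rng.normal(size=(n, 6))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        return X, y

    def test_randomized_search_deterministic(self, rng):
        X, y = self._data(rng)
        a = randomized_search("rf", X, y, n_settings=5, cv=3, seed=11,
                              config=StackerConfig(n_estimators=10))
        b = randomized_search("rf", X, y, n_settings=5, cv=3, seed=11,
                              config=StackerConfig(n_estimators=10))
        assert a == b

    def test_single_setting_and_degenerate_distribution(self, rng):
        X, y = self._data(rng, n=40)
        params, score = randomized_search(
            "lr", X, y, n_settings=1, cv=3, seed=0,
            distributions={"C": [0.5]},
        )
        assert params == {"C": 0.5} and 0.0 <= score <= 1.0
        with pytest.raises(ValueError):
            randomized_search("lr", X, y, n_settings=0)

    def test_rfe_drops_noise_keeps_signal(self, rng):
        n = 150
        signal = rng.normal(size=(n, 2))
        y = (signal.sum(axis=1) > 0).astype(int)
        noise = rng.normal(size=(n, 5))
        X = FeatureMatrix(
            ["sig_a", "sig_b", "n1", "n2", "n3", "n4", "n5"],
            np.hstack([signal, noise]),
        )
        kept = rfe_select("rf", X, y, cv=3, seed=2,
                          config=StackerConfig(n_estimators=40))
        assert {"sig_a", "sig_b"} <= set(kept)
        assert len([c for c in kept if c.startswith("n")]) <= 2

    def test_rfe_rejects_importance_free_learner(self, rng):
        X = FeatureMatrix(["a"], rng.normal(size=(20, 1)))
        y = np.array([0, 1] * 10)
        with pytest.raises(ValueError, match="surrogate"):
            rfe_select("nb", X, y)

    def test_single_feature_retained(self, rng):
        X = FeatureMatrix(["only"], rng.normal(size=(30, 1)))
        y = (X.values[:, 0] > 0).astype(int)
        assert rfe_select("lr", X, y, cv=3, seed=0) == ["only"]
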