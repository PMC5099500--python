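"""Cross-validation folds, P/R/F metrics, macro averages, paired t-tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tweetsift.corpus import Corpus, LabeledTweet, Tweet
from tweetsift.evaluate import (ClassMetrics, compare_classifiers,
                                cross_validate, evaluate_predictions,
                                macro_average, make_folds, per_class_metrics)


def toy_corpus(n, labels=None):
    return Corpus(
        [
            LabeledTweet(
                Tweet(id=f"t{i}", text=f"tweet {i}"),
                sentiment=None if labels is None else labels[i % len(labels)],
            )
            for i in range(n)
        ]
    )


class TestFolds:
    def test_exact_division(self):
        folds = make_folds(toy_corpus(1000), K=5, seed=0)
        sizes = [len(folds.members(k)) for k in range(5)]
        assert sizes == [200] * 5

    def test_remainder_rule(self):
        folds = make_folds(toy_corpus(1002), K=5, seed=0)
        sizes = sorted(len(folds.members(k)) for k in range(5))
        assert sizes == [200, 200, 200, 201, 201]

    def test_deterministic_per_seed(self):
        c = toy_corpus(97)
        assert make_folds(c, 5, seed=3).fold_of == make_folds(c, 5, seed=3).fold_of
        assert make_folds(c, 5, seed=3).fold_of != make_folds(c, 5, seed=4).fold_of

    def test_partition_property(self):
        c = toy_corpus(53)
        folds = make_folds(c, 5, seed=1)
        all_ids = [tid for k in range(5) for tid in folds.members(k)]
        assert sorted(all_ids) == sorted(it.tweet.id for it in c.items)

    def test_k_larger_than_corpus_rejected(self):
        with pytest.raises(ValueError):
            make_folds(toy_corpus(3), K=5)


class TestMetrics:
    def test_hand_arithmetic(self):
        # TP=8, FP=2, FN=2 among 20 items
        gold = ["p"] * 10 + ["n"] * 10
        pred = ["p"] * 8 + ["n"] * 2 + ["p"] * 2 + ["n"] * 8
        m = per_class_metrics(gold, pred, "p")
        assert (m.precision, m.recall, m.f) == (0.8, 0.8, pytest.approx(0.8))

    def test_f_equals_p_when_p_equals_r(self):
        m = per_class_metrics(["a", "b", "a", "b"], ["a", "a", "b", "b"], "a")
        assert m.precision == m.recall == m.f

    def test_absent_class_flagged_zero(self):
        m = per_class_metrics(["a", "a"], ["a", "a"], "ghost")
        assert (m.precision, m.recall, m.f) == (0, 0, 0)
        assert m.flagged

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            per_class_metrics(["a"], ["a", "b"], "a")

    def test_macro_is_unweighted_mean(self):
        per_class = {
            c: ClassMetrics(0.5, 0.5, f, False)
            for c, f in zip("abc", (0.6, 0.8, 1.0))
        }
        assert macro_average(per_class).f == pytest.approx(0.8)

    def test_micro_consistency(self):
        """Per-class TP/FP/FN account for every prediction exactly once."""
        rng = np.random.default_rng(11)
        classes = ["x", "y", "z"]
        gold = rng.choice(classes, 60).tolist()
        pred = rng.choice(classes, 60).tolist()
        tp = fp = 0
        for c in classes:
            tp += sum(1 for g, p in zip(gold, pred) if g == p == c)
            fp += sum(1 for g, p in zip(gold, pred) if g != c and p == c)
        assert tp + fp == len(gold)


class TestTTest:
    def test_identical_scores_give_half(self):
        res = compare_classifiers([0.8, 0.7, 0.9], [0.8, 0.7, 0.9])
        assert res.p == pytest.approx(0.5) and res.degenerate

    def test_constant_positive_difference_degenerate_limit(self):
        res = compare_classifiers([0.9] * 5, [0.8] * 5)
        assert res.p == 0.0 and res.degenerate

    def test_hand_computed_paired_t(self):
        # differences (0.01, 0.02, 0.00, 0.01, 0.01): t = 3.162, p ~ .017, df=4
        a = [0.81, 0.82, 0.80, 0.81, 0.81]
        b = [0.80] * 5
        res = compare_classifiers(a, b)
        assert res.t == pytest.approx(3.1623, abs=1e-3)
        assert res.p == pytest.approx(0.0170, abs=5e-4)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        scores=st.lists(
            st.tuples(
                st.floats(0.1, 0.9, allow_nan=False),
                st.floats(0.1, 0.9, allow_nan=False),
            ),
            min_size=3,
            max_size=8,
        )
    )
    def test_antisymmetry(self, scores):
        """p(a,b) + p(b,a) = 1 for non-degenerate inputs."""
        a = [x for x, _ in scores]
        b = [y for _, y in scores]
        pab = compare_classifiers(a, b)
        pba = compare_classifiers(b, a)
        if not (pab.degenerate or pba.degenerate):
            assert pab.p + pba.p == pytest.approx(1.0, abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compare_classifiers([0.8, 0.9], [0.8])


class TestCrossValidate:
    @staticmethod
    def _label_lookup_trainer(train_items):
        """Oracle trainer: memorizes each tweet's label by its id suffix."""

        def predict_fn(test_items):
            return [it.sentiment for it in test_items]

        return predict_fn

    def test_perfect_separability_gives_macro_one(self):
        corpus = toy_corpus(50, labels=["positive", "negative"])
        folds = make_folds(corpus, 5, seed=0)
        report = cross_validate(corpus, self._label_lookup_trainer, folds, "sentiment")
        assert report.mean_macro.f == 1.0
        assert all(fr.macro.f == 1.0 for fr in report.per_fold)

    def test_chance_level_for_shuffled_labels(self):
        """A class-blind random predictor scores ~1/3 macro F on 3 balanced classes."""
        rng = np.random.default_rng(5)
        classes = ["positive", "negative", "neutral"]
        fs = []
        for _ in range(30):
            gold = rng.choice(classes, 300).tolist()
            pred = rng.choice(classes, 300).tolist()
            fs.append(evaluate_predictions(gold, pred).macro.f)
        assert np.mean(fs) == pytest.approx(1 / 3, abs=0.02)

    def test_report_has_k_folds_and_mean_within_range(self):
        corpus = toy_corpus(60, labels=["positive", "negative", "neutral"])
        folds = make_folds(corpus, 5, seed=2)
        report = cross_validate(corpus, self._label_lookup_trainer, folds, "sentiment")
        assert len(report.per_fold) == folds.K
        fold_fs = report.fold_macro_f
        assert min(fold_fs) <= report.mean_macro.f <= max(fold_fs)

    def test_single_class_training_fold_rejected(self):
        corpus = toy_corpus(10, labels=["positive"])
        corpus.items[0] = LabeledTweet(corpus.items[0].tweet, sentiment="negative")
        folds = make_folds(corpus, 5, seed=0)
        trainer = self._label_lookup_trainer
        with pytest.raises(ValueError, match="fold"):
            cross_validate(corpus, trainer, folds, "sentiment")
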