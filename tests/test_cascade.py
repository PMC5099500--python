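"""Cascade rules, personal filtering, binary task construction, pipeline runs."""

import json

import pytest

from tweetsift.cascade import (TaskSpec, classify_source, filter_personal,
                               make_binary_task, run_pipeline,
                               train_source_model)
from tweetsift.corpus import Corpus, LabeledTweet, Tweet, label_counts
from tweetsift.synth import SyntheticSpec, generate_corpus
from tweetsift.urls import UrlResolver

from conftest import make_corpus


class _ExplodingModel:
    """Stand-in model that fails if the cascade shortcut ever consults it."""

    feature_space = None

    def __getattr__(self, name):
        raise AssertionError("model must not be consulted for URL-less tweets")


def test_tweet_without_url_is_personal_without_model_call():
    tweet = Tweet(id="t", text="just vibes tonight")
    assert classify_source(tweet, _ExplodingModel(), 2, None) == "personal"


@pytest.fixture(scope="module")
def small_source():
    spec = SyntheticSpec(
        n=300,
        source_proportions={"media": 100, "retail": 100, "personal": 100},
        attach=("source",),
        url_rate_personal=1.0,
        seed=42,
    )
    return generate_corpus(spec)


def test_url_signal_drives_source_prediction(small_source):
    """Held-out tweets with retail-flavored expansions classify as retail."""
    corpus, resolver = small_source.corpus, small_source.resolver
    train_items = Corpus(corpus.items[:250], {})
    model = train_source_model(train_items, resolver, seed=0)
    held_out = corpus.items[250:]
    correct = sum(
        1
        for it in held_out
        if classify_source(it.tweet, model, 2, resolver) == it.source
    )
    assert correct / len(held_out) >= 0.9


def test_unresolved_url_still_classified(small_source):
    corpus = small_source.corpus
    model = train_source_model(corpus, small_source.resolver, seed=0)
    empty_resolver = UrlResolver(table={})  # every expansion fails
    tweet = next(it.tweet for it in corpus.items if it.tweet.urls)
    label = classify_source(tweet, model, 2, empty_resolver)
    assert label in ("personal", "media", "retail")


def test_filter_personal_subset_and_counts(small_source):
    corpus, resolver = small_source.corpus, small_source.resolver
    model = train_source_model(corpus, resolver, seed=0)
    filtered, report = filter_personal(corpus, model, 2, resolver)
    ids = [it.tweet.id for it in corpus.items]
    kept_ids = [it.tweet.id for it in filtered.items]
    assert set(kept_ids) <= set(ids)
    assert kept_ids == [i for i in ids if i in set(kept_ids)]  # order preserved
    assert report["kept"] + sum(report["removed_predicted"].values()) == len(corpus)


def test_filter_personal_no_urls_keeps_everything():
    corpus = make_corpus(
        [(f"t{i}", f"plain tweet {i}", [], None, "positive") for i in range(6)]
    )
    filtered, report = filter_personal(corpus, _ExplodingModel(), 2, None)
    assert len(filtered) == len(corpus) and report["kept"] == 6


class TestBinaryTasks:
    def test_sentiment_binary_removes_neutral(self, fixtures):
        corpus = fixtures["sentiment"].corpus
        spec = TaskSpec("sentiment_binary", approach=1)
        binary = make_binary_task(corpus, spec)
        assert len(binary) == 2213  # 3000 - 787 neutral
        counts = label_counts(binary, "sentiment").counts
        assert counts == {"positive": 1292, "negative": 921, "neutral": 0}

    def test_source_binary_relabels_keeping_size(self, small_source):
        spec = TaskSpec("source_binary", target="media")
        binary = make_binary_task(small_source.corpus, spec)
        assert len(binary) == len(small_source.corpus)
        labels = {it.source for it in binary.items}
        assert labels == {"media", "rest"}

    def test_no_neutral_is_identity(self):
        corpus = make_corpus(
            [("a", "x", [], None, "positive"), ("b", "y", [], None, "negative")]
        )
        binary = make_binary_task(corpus, TaskSpec("sentiment_binary"))
        assert len(binary) == 2


class TestRunPipeline:
    def test_report_shape_and_determinism(self, small_source, tmp_path):
        spec = TaskSpec("source_multiclass", algorithm="svm", approach=2, seed=9)
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        rep1 = run_pipeline(small_source.corpus, spec,
                            resolver=small_source.resolver, out_dir=out1)
        rep2 = run_pipeline(small_source.corpus, spec,
                            resolver=small_source.resolver, out_dir=out2)
        assert len(rep1.per_fold) == 5
        assert set(rep1.classes) == {"media", "personal", "retail"}
        assert (out1 / "report.tsv").read_bytes() == (out2 / "report.tsv").read_bytes()
        manifest = json.loads((out1 / "manifest.json").read_text())
        assert manifest["corpus_hash"] == rep2.metadata["corpus_hash"]

    def test_sentiment_approach2_records_bookkeeping(self, small_source):
        sc = generate_corpus(
            SyntheticSpec(
                n=400,
                source_proportions={"personal": 340, "media": 30, "retail": 30},
                sentiment_proportions={"positive": 170, "negative": 130, "neutral": 100},
                attach=("sentiment",),
                seed=7,
            )
        )
        source_model = train_source_model(
            small_source.corpus, small_source.resolver, seed=0
        )
        spec = TaskSpec("sentiment_binary", algorithm="nb", approach=2, seed=7)
        report = run_pipeline(sc.corpus, spec, resolver=sc.resolver,
                              source_model=source_model)
        assert "personal_filter" in report.metadata
        assert report.metadata["neutral_excluded"] >= 0
        assert report.metadata["n_evaluated"] <= 400

    def test_sentiment_approach2_requires_source_model(self, small_source):
        with pytest.raises(ValueError, match="source_model"):
            run_pipeline(
                small_source.corpus,
                TaskSpec("sentiment_multiclass", approach=2),
            )

    def test_approach2_sentiment_corpus_subset_of_approach1(self, small_source):
        """Personal-only evaluation sets are always subsets of the full ones."""
        sc = generate_corpus(
            SyntheticSpec(
                n=300,
                source_proportions={"personal": 240, "media": 30, "retail": 30},
                sentiment_proportions={"positive": 120, "negative": 100, "neutral": 80},
                attach=("sentiment",),
                seed=8,
            )
        )
        model = train_source_model(small_source.corpus, small_source.resolver, seed=0)
        filtered, _ = filter_personal(sc.corpus, model, 2, sc.resolver)
        a1_ids = {it.tweet.id for it in sc.corpus.items}
        a2_ids = {it.tweet.id for it in filtered.items}
        assert a2_ids <= a1_ids


def test_task_spec_validation():
    with pytest.raises(ValueError):
        TaskSpec("source_binary")  # missing target
    with pytest.raises(ValueError):
        TaskSpec("sentiment_multiclass", target="media")
    with pytest.raises(ValueError):
        TaskSpec("nonsense_task")
    with pytest.raises(ValueError):
        TaskSpec("source_multiclass", approach=3)
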