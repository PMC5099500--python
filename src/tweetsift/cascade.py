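"""End-to-end task assembly: source cascade, personal filtering, CV pipeline.

The cascade rule: a tweet without URLs is personal communication by
construction (media and retail tweets always link out), so the trained
source classifier is only ever consulted for URL-bearing tweets. Sentiment
classification can then be restricted to the tweets the source classifier
labels personal — the two-stage design that removes organizational "noise"
before measuring user sentiment.

Approaches
----------
For **source** tasks the approach selects the URL features: approach 1 uses
the short URLs' host tokens; approach 2 expands URLs through a resolver and
uses the expansion's host/path n-grams. For **sentiment** tasks the
approach selects the corpus: approach 1 trains/evaluates on all tweets,
approach 2 on the personal-communication subset produced by a source
classifier; the bag of words for sentiment is text-only.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from .classify import TrainedClassifier, predict_many, train
from .corpus import Corpus, LabeledTweet, Tweet, write_corpus
from .evaluate import EvalReport, FoldAssignment, cross_validate, make_folds
from .featurize import (FeatureSpace, build_feature_space, extract_ngrams,
                        tokenize, vectorize)
from .urls import UrlResolver, tweet_url_ngrams

__all__ = [
    "TaskSpec",
    "tweet_ngrams",
    "classify_source",
    "filter_personal",
    "make_binary_task",
    "train_source_model",
    "run_pipeline",
]

TASKS = ("source_multiclass", "source_binary", "sentiment_multiclass", "sentiment_binary")


@dataclass(frozen=True)
class TaskSpec:
    """One classification experiment: task, approach, algorithm, settings."""

    task: str
    algorithm: str = "svm"
    approach: int = 2
    target: str | None = None  # source_binary: class vs rest
    k_features: int = 500
    folds: int = 5
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.approach not in (1, 2):
            raise ValueError("approach must be 1 or 2")
        if self.task == "source_binary":
            if self.target not in ("personal", "media", "retail"):
                raise ValueError("source_binary requires target in {personal, media, retail}")
        elif self.target is not None:
            raise ValueError(f"target is only meaningful for source_binary")

    @property
    def axis(self) -> str:
        return "source" if self.task.startswith("source") else "sentiment"


def tweet_ngrams(
    item_or_tweet,
    resolver: UrlResolver | None = None,
    approach: int | None = None,
) -> Counter:
    """Text n-grams for one tweet, plus URL n-grams when an approach is given.

    ``approach=None`` (sentiment tasks) yields text features only.
    """
    tweet: Tweet = getattr(item_or_tweet, "tweet", item_or_tweet)
    grams = extract_ngrams(tokenize(tweet.text))
    if approach is not None:
        grams.update(tweet_url_ngrams(tweet.urls, resolver, approach))
    return grams


def classify_source(
    tweet: Tweet,
    model: TrainedClassifier,
    approach: int,
    resolver: UrlResolver | None,
) -> str:
    """Source label for one tweet under the cascade rule.

    A tweet without URLs is ``personal`` without consulting the model;
    otherwise the tweet is featurized (URL tokens per approach, unresolved
    links falling back to short-URL host tokens) and predicted. Total: never
    raises on unresolvable URLs.
    """
    if not tweet.urls:
        return "personal"
    grams = tweet_ngrams(tweet, resolver, approach)
    vec = vectorize(grams, model.feature_space, tweet_ref=tweet.id)
    return predict_many(model, [vec])[0]


def filter_personal(
    corpus: Corpus,
    model: TrainedClassifier,
    approach: int,
    resolver: UrlResolver | None,
) -> tuple[Corpus, dict]:
    """Keep the tweets classified as personal communication, order preserved.

    Returns the filtered corpus and a report with predicted-filter counts
    and, where gold source labels exist, the gold counts of what was removed
    (predicted and manual counts legitimately differ).
    """
    kept: list[LabeledTweet] = []
    removed_pred: Counter = Counter()
    removed_gold: Counter = Counter()
    for item in corpus.items:
        label = classify_source(item.tweet, model, approach, resolver)
        if label == "personal":
            kept.append(item)
        else:
            removed_pred[label] += 1
            if item.source is not None:
                removed_gold[item.source] += 1
    report = {
        "kept": len(kept),
        "removed_predicted": dict(removed_pred),
        "removed_gold": dict(removed_gold),
    }
    out = Corpus(kept, metadata={**corpus.metadata, "personal_filter": report})
    return out, report


def make_binary_task(corpus: Corpus, spec: TaskSpec) -> Corpus:
    """Relabel/subset a corpus for a binary task.

    ``source_binary``: target class versus ``rest``, all tweets kept.
    ``sentiment_binary``: neutral tweets removed, positive/negative kept.
    """
    if spec.task == "source_binary":
        items = []
        for it in corpus.items:
            if it.source is None:
                raise ValueError(f"tweet {it.tweet.id} lacks a source label")
            label = it.source if it.source == spec.target else "rest"
            items.append(LabeledTweet(tweet=it.tweet, source=label, sentiment=it.sentiment))
        meta = {**corpus.metadata, "binary_target": spec.target}
        return Corpus(items, meta)
    if spec.task == "sentiment_binary":
        items = [it for it in corpus.items if it.sentiment != "neutral"]
        for it in items:
            if it.sentiment is None:
                raise ValueError(f"tweet {it.tweet.id} lacks a sentiment label")
        n_neutral = len(corpus) - len(items)
        meta = {**corpus.metadata, "neutral_excluded": n_neutral}
        return Corpus(items, meta)
    raise ValueError(f"{spec.task!r} is not a binary task")


def _make_trainer(spec: TaskSpec, resolver: UrlResolver | None, axis_classes=None):
    """Trainer closure for cross_validate: selection + training on train folds only."""
    url_approach = spec.approach if spec.axis == "source" else None

    def trainer(train_items: Sequence[LabeledTweet]):
        if spec.axis == "source":
            # source models are trained on URL-bearing tweets only; the
            # no-URL shortcut handles the rest at prediction time
            train_items = [it for it in train_items if it.tweet.urls]
        docs = [tweet_ngrams(it, resolver, url_approach) for it in train_items]
        labels = [getattr(it, spec.axis) for it in train_items]
        space = build_feature_space(docs, labels, k=spec.k_features)
        vecs = [vectorize(d, space, it.tweet.id) for d, it in zip(docs, train_items)]
        model = train(spec.algorithm, vecs, labels, space,
                      hyperparameters=spec.hyperparameters, seed=spec.seed)

        def predict_source(item: LabeledTweet) -> str:
            if not item.tweet.urls:
                # cascade shortcut, mapped into the task's label set
                if spec.task == "source_binary":
                    return "personal" if spec.target == "personal" else "rest"
                return "personal"
            grams = tweet_ngrams(item, resolver, spec.approach)
            vec = vectorize(grams, space, item.tweet.id)
            return predict_many(model, [vec])[0]

        def predict_fn(test_items: Sequence[LabeledTweet]) -> list[str]:
            if spec.axis == "source":
                return [predict_source(it) for it in test_items]
            vecs = [
                vectorize(tweet_ngrams(it, resolver, None), space, it.tweet.id)
                for it in test_items
            ]
            return predict_many(model, vecs)

        return predict_fn

    return trainer


def train_source_model(
    corpus: Corpus,
    resolver: UrlResolver | None,
    algorithm: str = "svm",
    approach: int = 2,
    k_features: int = 500,
    seed: int = 0,
) -> TrainedClassifier:
    """Train a source classifier on the URL-bearing tweets of a labeled corpus."""
    items = [it for it in corpus.items if it.tweet.urls]
    if not items:
        raise ValueError("no URL-bearing tweets to train a source model on")
    docs = [tweet_ngrams(it, resolver, approach) for it in items]
    labels = [it.source for it in items]
    if any(lab is None for lab in labels):
        raise ValueError("all URL-bearing tweets need source labels")
    space = build_feature_space(docs, labels, k=k_features)
    vecs = [vectorize(d, space, it.tweet.id) for d, it in zip(docs, items)]
    return train(algorithm, vecs, labels, space, seed=seed)


def _corpus_hash(corpus: Corpus) -> str:
    h = hashlib.sha256()
    for it in corpus.items:
        h.update(it.tweet.id.encode())
        h.update(it.tweet.text.encode())
        h.update((it.source or "").encode())
        h.update((it.sentiment or "").encode())
    return h.hexdigest()[:16]


def run_pipeline(
    corpus: Corpus,
    spec: TaskSpec,
    resolver: UrlResolver | None = None,
    source_model: TrainedClassifier | None = None,
    out_dir: str | Path | None = None,
) -> EvalReport:
    """Execute one task end to end under K-fold CV and return its report.

    Sentiment approach 2 first filters the corpus to predicted-personal
    tweets using ``source_model`` (any trained source classifier may be
    injected; the conventional choice is an SVM trained with expanded-URL
    features). Feature selection and training happen strictly inside
    training folds. With ``out_dir`` set, the report, per-fold feature
    spaces, and a manifest (config + corpus hashes, seed, parameters) are
    written out.
    """
    prepared = corpus
    filter_report = None
    if spec.axis == "sentiment" and spec.approach == 2:
        if source_model is None:
            raise ValueError("sentiment approach 2 requires a trained source_model")
        prepared, filter_report = filter_personal(prepared, source_model, 2, resolver)
    if spec.task.endswith("binary"):
        prepared = make_binary_task(prepared, spec)

    folds = make_folds(prepared, K=spec.folds, seed=spec.seed)
    trainer = _make_trainer(spec, resolver)
    report = cross_validate(prepared, trainer, folds, axis=spec.axis)
    report.metadata.update(
        {
            "task": asdict(spec),
            "n_input": len(corpus),
            "n_evaluated": len(prepared),
            "corpus_hash": _corpus_hash(corpus),
            "config_hash": hashlib.sha256(
                json.dumps(asdict(spec), sort_keys=True).encode()
            ).hexdigest()[:16],
        }
    )
    if filter_report is not None:
        report.metadata["personal_filter"] = filter_report
    if spec.task == "sentiment_binary":
        report.metadata["neutral_excluded"] = prepared.metadata.get("neutral_excluded")

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.tsv").write_text(report.to_tsv(), encoding="utf-8")
        (out / "summary.txt").write_text(report.summary() + "\n", encoding="utf-8")
        (out / "manifest.json").write_text(
            json.dumps(report.metadata, indent=2, default=str), encoding="utf-8"
        )
        write_corpus(prepared, out / "evaluated_corpus.jsonl")
    return report
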