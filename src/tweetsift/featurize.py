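"""Tokenization, n-gram extraction, chi-square feature selection, tf-idf.

The featurization contract, kept deliberately plain because short informal
texts carry signal in function words and inflected forms:

* lowercase; stop words retained; no stemming;
* URLs are removed from the token stream (they are handled separately as
  ``url:``-namespaced features), ``#`` is stripped from hashtags keeping the
  word, and user mentions are anonymized to the placeholder token ``@user``;
* features are unigrams and adjacent bigrams;
* the top ``k`` (default 500) n-grams by chi-square association with the
  class labels are selected on training data only;
* weights are ``w(i,j) = tf(i,j) * ln(N / df(i))`` with raw term counts,
  natural log, no smoothing and no vector normalization.

The chi-square score of a feature is computed from its presence/absence
2x2 contingency table against each class versus the rest (no continuity
correction); for multiclass tasks the feature's score is the maximum over
classes.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "tokenize",
    "word_tokens",
    "extract_ngrams",
    "chi_square_scores",
    "select_features",
    "build_feature_space",
    "vectorize",
    "FeatureSpace",
    "FeatureVector",
]

_URL_RE = re.compile(r"https?://\S+", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
_TOKEN_RE = re.compile(r"@user|[a-z0-9']+")


def word_tokens(text: str) -> list[str]:
    """Plain lowercase word tokens: maximal runs of letters/digits/apostrophes.

    No URL or mention handling — used for phrase matching in the stream
    filter and inside :func:`tokenize`.
    """
    return [t for t in re.findall(r"[a-z0-9']+", text.lower()) if t.strip("'")]


def tokenize(text: str) -> list[str]:
    """Tokenize tweet text for classification.

    URLs are dropped, ``#`` is stripped (hashtag words kept), mentions become
    the single placeholder ``@user``, everything is lowercased, and remaining
    tokens are maximal runs of letters/digits/apostrophes. Stop words are
    retained and no stemming is applied.
    """
    text = _URL_RE.sub(" ", text)
    text = _MENTION_RE.sub(" @user ", text)
    text = text.replace("#", "")
    toks = _TOKEN_RE.findall(text.lower())
    return [t for t in toks if t == "@user" or t.strip("'")]


def extract_ngrams(tokens: Sequence[str]) -> Counter:
    """Unigrams plus adjacent bigrams (joined by one space), with multiplicity."""
    grams = Counter(tokens)
    for a, b in zip(tokens, tokens[1:]):
        grams[f"{a} {b}"] += 1
    return grams


# ---------------------------------------------------------------------------
# chi-square selection


def chi_square_scores(
    docs: Sequence[Iterable[str]],
    labels: Sequence[str],
    candidates: Sequence[str] | None = None,
) -> dict[str, float]:
    """Chi-square association score for each candidate n-gram.

    Per feature and class, a 2x2 presence/absence-by-class/rest table is
    formed and the chi-square statistic ``N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))``
    computed without continuity correction; the feature's score is the
    maximum over classes. Degenerate tables (a zero margin) score 0.

    Parameters
    ----------
    docs : sequence of n-gram containers (sets, Counters, lists)
        One per document; only presence/absence is used.
    labels : class label per document (>=2 distinct classes required).
    candidates : restrict scoring to these features (default: all observed).
    """
    if len(docs) != len(labels):
        raise ValueError("docs and labels must have equal length")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("chi-square selection requires >=2 classes")

    doc_sets = [set(d) for d in docs]
    if candidates is None:
        feats: list[str] = sorted(set().union(*doc_sets)) if doc_sets else []
    else:
        feats = list(candidates)
    if not feats:
        return {}
    f_index = {f: i for i, f in enumerate(feats)}

    n_docs = len(docs)
    n_feats = len(feats)
    # presence counts per (feature, class)
    present = np.zeros((n_feats, len(classes)), dtype=np.int64)
    c_index = {c: j for j, c in enumerate(classes)}
    class_sizes = np.zeros(len(classes), dtype=np.int64)
    for dset, lab in zip(doc_sets, labels):
        j = c_index[lab]
        class_sizes[j] += 1
        for f in dset:
            i = f_index.get(f)
            if i is not None:
                present[i, j] += 1

    total_present = present.sum(axis=1)  # docs containing the feature
    scores = np.zeros(n_feats)
    N = float(n_docs)
    for j in range(len(classes)):
        a = present[:, j].astype(float)               # present, in class
        b = (total_present - present[:, j]).astype(float)  # present, rest
        c = class_sizes[j] - a                        # absent, in class
        d = (n_docs - class_sizes[j]) - b             # absent, rest
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi = np.where(denom > 0, N * (a * d - b * c) ** 2 / denom, 0.0)
        scores = np.maximum(scores, chi)
    return dict(zip(feats, scores.tolist()))


@dataclass(frozen=True)
class FeatureSpace:
    """Selected n-gram vocabulary with document frequencies and chi2 scores.

    ``features`` is ordered by (chi2 descending, feature ascending); ``N`` is
    the number of training documents and ``df[f]`` the number containing
    ``f``. The space is immutable once built.
    """

    features: tuple[str, ...]
    df: dict[str, int]
    chi2: dict[str, float]
    N: int
    k: int
    _index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.features) > self.k:
            raise ValueError("more features than the selection cap k")
        for f in self.features:
            df = self.df.get(f, 0)
            if not (1 <= df <= self.N):
                raise ValueError(f"feature {f!r} has df={df} outside [1, N={self.N}]")
        object.__setattr__(self, "_index", {f: i for i, f in enumerate(self.features)})

    def index_of(self, feature: str) -> int | None:
        return self._index.get(feature)

    def idf(self, feature: str) -> float:
        return math.log(self.N / self.df[feature])

    # -- serialization: deterministic TSV so files are diffable ------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# N={self.N}\tk={self.k}\n")
            fh.write("feature\tdf\tchi2\n")
            for f in self.features:
                fh.write(f"{f}\t{self.df[f]}\t{self.chi2[f]:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureSpace":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().strip()
            meta = dict(part.split("=") for part in header.lstrip("# ").split("\t"))
            fh.readline()  # column header
            features, df, chi2 = [], {}, {}
            for line in fh:
                if not line.strip():
                    continue
                f, d, x = line.rstrip("\n").split("\t")
                features.append(f)
                df[f] = int(d)
                chi2[f] = float(x)
        return cls(tuple(features), df, chi2, N=int(meta["N"]), k=int(meta["k"]))


def select_features(
    scores: Mapping[str, float],
    k: int = 500,
    *,
    df: Mapping[str, int],
    N: int,
) -> FeatureSpace:
    """Keep the top-``k`` features by chi-square score.

    Ties at the boundary are broken by ascending lexicographic feature
    string; if there are fewer than ``k`` candidates all are kept.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if not scores:
        raise ValueError("no candidate features to select from")
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    feats = tuple(f for f, _ in ranked)
    return FeatureSpace(
        features=feats,
        df={f: int(df[f]) for f in feats},
        chi2={f: float(scores[f]) for f in feats},
        N=int(N),
        k=int(k),
    )


def build_feature_space(
    docs: Sequence[Counter], labels: Sequence[str], k: int = 500
) -> FeatureSpace:
    """Score, select and record document frequencies in one pass over training docs."""
    scores = chi_square_scores(docs, labels)
    df = Counter()
    for d in docs:
        df.update(set(d))
    return select_features(scores, k, df=df, N=len(docs))


@dataclass(frozen=True)
class FeatureVector:
    """Sparse tf-idf vector for one tweet; zero-weight entries are omitted."""

    weights: dict[str, float]
    tweet_ref: str


def vectorize(ngrams: Counter, space: FeatureSpace, tweet_ref: str = "") -> FeatureVector:
    """tf-idf weights for the selected features present in ``ngrams``.

    ``w(i,j) = tf(i,j) * ln(N / df(i))`` with tf the raw occurrence count.
    Features absent from the space are ignored; a selected feature with
    ``df == N`` gets weight 0 and is omitted (ln 1 = 0).
    """
    weights: dict[str, float] = {}
    for f, tf in ngrams.items():
        if space.index_of(f) is None:
            continue
        w = tf * space.idf(f)
        if w != 0.0:
            weights[f] = w
    return FeatureVector(weights=weights, tweet_ref=tweet_ref)


def vectors_to_csr(vectors: Sequence[FeatureVector], space: FeatureSpace):
    """Stack sparse vectors into a CSR matrix aligned with ``space.features``.

    Raises ``ValueError`` if any vector carries a feature outside the space.
    """
    from scipy.sparse import csr_matrix

    data, indices, indptr = [], [], [0]
    for vec in vectors:
        for f, w in vec.weights.items():
            i = space.index_of(f)
            if i is None:
                raise ValueError(
                    f"vector {vec.tweet_ref!r} carries feature {f!r} "
                    "absent from the feature space"
                )
            indices.append(i)
            data.append(w)
        indptr.append(len(indices))
    return csr_matrix(
        (data, indices, indptr), shape=(len(vectors), len(space.features))
    )
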