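"""Lexicon-and-rule sentiment baseline (VADER-style scoring contract).

Scores a token sequence from a valence dictionary with two heuristics —
negation (a negator within the 3 preceding tokens multiplies a token's
valence by -0.74) and boosting (a booster within the 3 preceding tokens
adds its increment toward the valence's sign) — then squashes the summed
valence S to a compound score S/sqrt(S^2 + 15) in (-1, 1). Compound scores
map to labels by symmetric thresholds: >= +0.05 positive, <= -0.05
negative, else neutral, so a tweet containing no lexicon words is neutral.

This is the comparison baseline the trained classifiers are judged
against: it encodes *conventional* word valences, which is exactly what
fails on domain-inverted usage ("faded", "wasted" meaning a desired high).
Capitalization emphasis, punctuation amplification and emoji handling of
the full published method are deliberately omitted — the tokenizer
lowercases — since the baseline's role here is the comparison contract,
not bit-compatibility with any particular release.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .corpus import Tweet
from .featurize import tokenize

__all__ = [
    "Lexicon",
    "score_text",
    "classify_sentiment_lexicon",
    "classify_tweet_lexicon",
    "default_lexicon",
    "NEGATION_FACTOR",
    "NORMALIZATION_ALPHA",
]

NEGATION_FACTOR = -0.74
NORMALIZATION_ALPHA = 15.0
CONTEXT_WINDOW = 3
POSITIVE_THRESHOLD = 0.05
NEGATIVE_THRESHOLD = -0.05


@dataclass(frozen=True)
class Lexicon:
    """Valence dictionary (token -> value in [-4, 4]) plus rule-word sets."""

    valence: dict[str, float]
    negators: frozenset[str] = frozenset()
    boosters: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "valence", {t.lower(): v for t, v in self.valence.items()}
        )
        object.__setattr__(self, "negators", frozenset(t.lower() for t in self.negators))
        object.__setattr__(
            self, "boosters", {t.lower(): v for t, v in self.boosters.items()}
        )

    def negate_all(self) -> "Lexicon":
        """Sign-flipped copy (used by symmetry tests)."""
        return Lexicon(
            valence={t: -v for t, v in self.valence.items()},
            negators=self.negators,
            boosters=dict(self.boosters),
        )

    # -- TSV: token<TAB>valence, with optional @negator/@booster rows ------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# token\tvalence\n")
            for t in sorted(self.valence):
                fh.write(f"{t}\t{self.valence[t]}\n")
            for t in sorted(self.negators):
                fh.write(f"@negator:{t}\t0\n")
            for t in sorted(self.boosters):
                fh.write(f"@booster:{t}\t{self.boosters[t]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        valence: dict[str, float] = {}
        negators: set[str] = set()
        boosters: dict[str, float] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                token, value = line.split("\t")
                if token.startswith("@negator:"):
                    negators.add(token[len("@negator:"):])
                elif token.startswith("@booster:"):
                    boosters[token[len("@booster:"):]] = float(value)
                else:
                    valence[token] = float(value)
        return cls(valence=valence, negators=frozenset(negators), boosters=boosters)


def default_lexicon() -> Lexicon:
    """Small illustrative lexicon of conventional valences for tests and demos."""
    return Lexicon(
        valence={
            "love": 3.2, "great": 3.1, "good": 1.9, "best": 3.2, "awesome": 3.1,
            "happy": 2.7, "amazing": 2.8, "relax": 1.5, "relief": 1.9,
            "hate": -2.7, "bad": -2.5, "worst": -3.1, "nasty": -2.2,
            "fake": -1.8, "sick": -1.5, "ridiculous": -1.9, "ignorant": -2.1,
            "wasted": -2.2, "faded": -1.7, "fucked": -2.6, "shit": -2.3,
            "dead": -2.9, "stupid": -2.4,
        },
        negators=frozenset({"not", "no", "never", "don't", "doesn't", "isn't",
                            "can't", "won't", "didn't", "ain't"}),
        boosters={"very": 0.293, "really": 0.293, "so": 0.293, "extremely": 0.293,
                  "totally": 0.293, "kinda": -0.293, "slightly": -0.293},
    )


def score_text(tokens: Sequence[str], lexicon: Lexicon) -> float:
    """Compound sentiment score in (-1, 1) for a token sequence.

    Each lexicon token contributes its valence, adjusted by boosters and
    negators in the 3 preceding tokens; the sum S is normalized to
    S/sqrt(S^2 + alpha) with alpha = 15.
    """
    total = 0.0
    for i, tok in enumerate(tokens):
        v = lexicon.valence.get(tok)
        if v is None:
            continue
        window = tokens[max(0, i - CONTEXT_WINDOW) : i]
        for prev in window:
            inc = lexicon.boosters.get(prev)
            if inc is not None:
                v += inc if v > 0 else -inc
        if any(prev in lexicon.negators for prev in window):
            v *= NEGATION_FACTOR
        total += v
    if total == 0.0:
        return 0.0
    return total / math.sqrt(total * total + NORMALIZATION_ALPHA)


def classify_sentiment_lexicon(
    compound: float,
    positive_threshold: float = POSITIVE_THRESHOLD,
    negative_threshold: float = NEGATIVE_THRESHOLD,
) -> str:
    """Map a compound score to positive/negative/neutral by thresholds."""
    if compound >= positive_threshold:
        return "positive"
    if compound <= negative_threshold:
        return "negative"
    return "neutral"


def classify_tweet_lexicon(tweet: Tweet, lexicon: Lexicon) -> str:
    """Tokenize a tweet and classify its sentiment with the lexicon rules."""
    return classify_sentiment_lexicon(score_text(tokenize(tweet.text), lexicon))
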