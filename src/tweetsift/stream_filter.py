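"""Keyword/blacklist relevance filtering with co-occurrence rules.

Emulates the collection-side relevance filter of a drug-trend infoveillance
stream: a tweet is kept when it mentions an unambiguous drug term (e.g.
"cannabis"), or an ambiguous slang term (e.g. "blunt", "spice") together
with at least one usage term bound to it (e.g. "smoke", "smoked",
"smoking"). A blacklist of phrases ("emily blunt", "pumpkin spice latte")
excludes irrelevant tweets and takes priority over every keyword rule.

Matching is case-insensitive on token boundaries — "blunted" never matches
"blunt" — and multiword phrases match as contiguous token sequences.
Tweets carrying a non-English language tag are dropped; tweets without a
tag are kept (the filter does not attempt language identification).

The shipped default configuration is illustrative, not an authoritative
reproduction of any production keyword list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import yaml

from .corpus import Tweet
from .featurize import word_tokens

__all__ = [
    "KeywordConfig",
    "FilterDecision",
    "compile_keyword_config",
    "load_keyword_config",
    "filter_tweet",
    "filter_corpus",
    "DEFAULT_CONFIG",
]

#: Illustrative default keyword configuration (non-authoritative).
DEFAULT_CONFIG: dict = {
    "unambiguous": ["cannabis", "marijuana", "synthetic cannabinoid", "thc edible"],
    "ambiguous": {
        "blunt": ["smoke", "smoked", "smoking", "roll", "rolled", "lit"],
        "spice": ["smoke", "smoked", "smoking", "high", "synthetic"],
        "dabs": ["smoke", "smoked", "smoking", "hit", "rig"],
        "lean": ["drink", "drank", "sip", "pour"],
    },
    "blacklist": ["emily blunt", "pumpkin spice latte", "spice girls"],
}


def _norm_phrase(phrase: str) -> tuple[str, ...]:
    toks = tuple(word_tokens(phrase))
    if not toks:
        raise ValueError(f"empty phrase {phrase!r} in keyword config")
    return toks


@dataclass(frozen=True)
class KeywordConfig:
    """Compiled, normalized (lowercase, tokenized) keyword configuration."""

    unambiguous: frozenset[tuple[str, ...]]
    ambiguous: Mapping[tuple[str, ...], frozenset[tuple[str, ...]]]
    blacklist: frozenset[tuple[str, ...]]

    def counts(self) -> dict[str, int]:
        return {
            "unambiguous": len(self.unambiguous),
            "ambiguous": len(self.ambiguous),
            "blacklist": len(self.blacklist),
        }


def compile_keyword_config(raw: Mapping) -> KeywordConfig:
    """Normalize a raw config document into a :class:`KeywordConfig`.

    ``raw`` has three sections: ``unambiguous`` (list of phrases),
    ``ambiguous`` (mapping phrase -> list of required usage terms) and
    ``blacklist`` (list of phrases). Terms are lowercased; the three term
    sets must be disjoint and the config non-empty.
    """
    unamb = frozenset(_norm_phrase(p) for p in raw.get("unambiguous", []))
    amb = {
        _norm_phrase(term): frozenset(_norm_phrase(u) for u in usages)
        for term, usages in (raw.get("ambiguous") or {}).items()
    }
    for term, usages in amb.items():
        if not usages:
            raise ValueError(
                f"ambiguous term {' '.join(term)!r} has no usage terms"
            )
    blacklist = frozenset(_norm_phrase(p) for p in raw.get("blacklist", []))
    if not (unamb or amb or blacklist):
        raise ValueError("empty keyword config")
    overlap = (unamb & blacklist) | (unamb & set(amb)) | (set(amb) & blacklist)
    if overlap:
        pretty = sorted(" ".join(t) for t in overlap)
        raise ValueError(f"term(s) listed in more than one section: {pretty}")
    return KeywordConfig(unambiguous=unamb, ambiguous=amb, blacklist=blacklist)


def load_keyword_config(path) -> KeywordConfig:
    """Load and compile a YAML keyword config file."""
    with open(path, encoding="utf-8") as fh:
        return compile_keyword_config(yaml.safe_load(fh))


def _contains_phrase(tokens: list[str], phrase: tuple[str, ...]) -> bool:
    n = len(phrase)
    return any(tuple(tokens[i : i + n]) == phrase for i in range(len(tokens) - n + 1))


class FilterDecision(NamedTuple):
    keep: bool
    matched: tuple[str, ...]
    reason: str


def filter_tweet(tweet: Tweet, config: KeywordConfig) -> FilterDecision:
    """Keep/drop decision for one tweet, with the matched terms.

    Precedence: non-English language tag -> drop; any blacklist phrase ->
    drop; any unambiguous term -> keep; any ambiguous term with one of its
    usage terms co-occurring -> keep; otherwise drop.
    """
    if tweet.lang is not None and not tweet.lang.lower().startswith("en"):
        return FilterDecision(False, (), "non-english")
    tokens = word_tokens(tweet.text)

    hits = tuple(
        " ".join(p) for p in sorted(config.blacklist) if _contains_phrase(tokens, p)
    )
    if hits:
        return FilterDecision(False, hits, "blacklist")

    hits = tuple(
        " ".join(p) for p in sorted(config.unambiguous) if _contains_phrase(tokens, p)
    )
    if hits:
        return FilterDecision(True, hits, "unambiguous")

    for term in sorted(config.ambiguous):
        if _contains_phrase(tokens, term):
            usage_hits = tuple(
                " ".join(u)
                for u in sorted(config.ambiguous[term])
                if _contains_phrase(tokens, u)
            )
            if usage_hits:
                return FilterDecision(
                    True, (" ".join(term),) + usage_hits, "ambiguous+usage"
                )
    return FilterDecision(False, (), "no-keyword")


def filter_corpus(items: Iterable, config: KeywordConfig):
    """Apply :func:`filter_tweet` over labeled tweets; return (kept, report).

    The report counts decisions by reason.
    """
    kept = []
    report: dict[str, int] = {}
    for item in items:
        decision = filter_tweet(item.tweet, config)
        report[decision.reason] = report.get(decision.reason, 0) + 1
        if decision.keep:
            kept.append(item)
    return kept, report
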