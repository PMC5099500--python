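"""Seeded generator of labeled tweet corpora with the pipeline's assumed structure.

The generator emulates the statistical skeleton of a manually labeled
drug-tweet corpus:

* a latent *source* (personal / media / retail) and *sentiment*
  (positive / negative / neutral) per tweet, with exact class counts;
* tweet text as background chatter (Zipf-weighted synthetic tokens) into
  which a small number of class-expressive tokens are inserted — a tweet
  expresses its class through one to three characteristic words, the way a
  real tweet carries sentiment in a short phrase rather than in every word;
* source-expressive *text* tokens are noisy (a confusable tweet may borrow
  another class's vocabulary), while the class signal carried by expanded
  URLs is clean: media and retail tweets always link out, and their
  expanded hosts/paths use news-like or shop-like words;
* a configurable fraction of positive tweets express their sentiment
  exclusively through *domain-inverted* slang — words whose conventional
  lexicon valence is negative ("faded", "wasted") used approvingly. The
  accompanying valence lexicon covers conventional sentiment words and part
  of the slang, so a lexicon-and-rule baseline degrades as the inversion
  rate rises while trained classifiers simply learn the inverted usage;
* a resolver table mapping every generated short URL to its expansion.

Everything is deterministic per seed, and the manifest records the
generating parameters and every tweet's latent assignment.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import NamedTuple

import numpy as np

from .corpus import Corpus, LabeledTweet, Tweet
from .lexicon import Lexicon, default_lexicon
from .urls import UrlResolver

__all__ = [
    "SyntheticSpec",
    "SyntheticCorpus",
    "generate_corpus",
    "canonical_fixtures",
]

# -- vocabulary pools --------------------------------------------------------
# Curated real drug-domain words (so tokenizer edge cases are exercised)
# plus synthetic background tokens. No real user content is embedded.

PERSONAL_VOCAB = ("blunt", "dabs", "smoking", "sesh", "homie", "tonight",
                  "roll", "bro", "joint", "wax")
MEDIA_VOCAB = ("legalization", "policy", "report", "study", "lawmakers",
               "vote", "article", "ban", "health", "officials")
RETAIL_VOCAB = ("sale", "shop", "discount", "vape", "order", "shipping",
                "deals", "store", "promo", "bundle")
SOURCE_VOCAB = {"personal": PERSONAL_VOCAB, "media": MEDIA_VOCAB, "retail": RETAIL_VOCAB}

# Sentiment vocabularies lean on slang: only part of each pool appears in
# the conventional valence lexicon, mirroring how lexicons miss domain argot.
POSITIVE_VOCAB = ("love", "great", "good", "happy", "dope", "fire",
                  "chill", "blessed", "gas", "loud")
NEGATIVE_VOCAB = ("hate", "bad", "worst", "nasty", "fake", "sketchy",
                  "bunk", "garbage", "wack", "ripoff")
#: Conventionally negative-valence words used approvingly in drug contexts.
INVERTED_VOCAB = ("faded", "wasted", "fucked", "dead", "lit", "zooted")
NEUTRAL_VOCAB = ("legalize", "question", "thoughts", "anyone", "curious",
                 "poll", "info", "laws", "states", "effects")
SENTIMENT_VOCAB = {
    "positive": POSITIVE_VOCAB, "negative": NEGATIVE_VOCAB, "neutral": NEUTRAL_VOCAB,
}

MEDIA_HOSTS = ("dailyheraldnews.example.com", "cannabispolicyreport.example.org",
               "statenewswire.example.net")
RETAIL_HOSTS = ("greenleafshop.example.com", "budmartstore.example.net",
                "vapedealsdepot.example.org")
PERSONAL_HOSTS = ("picshare.example.com", "tumblrlog.example.net",
                  "instapics.example.org")
SOURCE_HOSTS = {"personal": PERSONAL_HOSTS, "media": MEDIA_HOSTS, "retail": RETAIL_HOSTS}

#: Uninformative link targets (URL shorteners' landing pages, generic hosts):
#: used in place of the class-specific hosts when a tweet's URL carries no
#: class signal, so URL informativeness scales with ``signal_strength``.
NEUTRAL_HOSTS = ("linkhub.example.com", "shortstash.example.net",
                 "webpage.example.org")
NEUTRAL_URL_WORDS = ("page", "item", "view", "link", "ref", "share",
                     "redirect", "content", "media2", "site")

MEDIA_URL_WORDS = ("news", "cannabis", "legalization", "marijuana", "policy",
                   "vote", "study", "health", "article", "lawmakers")
RETAIL_URL_WORDS = ("buy", "vape", "discount", "oil", "strains",
                    "deals", "shipping", "promo", "order", "gear")
PERSONAL_URL_WORDS = ("photo", "day", "life", "post", "friends", "party",
                      "pic", "weekend", "trip", "status")
SOURCE_URL_WORDS = {
    "personal": PERSONAL_URL_WORDS, "media": MEDIA_URL_WORDS, "retail": RETAIL_URL_WORDS,
}

MENTION_NAMES = ("buddy42", "greenfriend", "ohiogal", "smokebro", "newsbot7")

#: Maximum expressive tokens per tweet per label axis; the realized number
#: is Binomial(EXPR_SLOTS, signal_strength).
EXPR_SLOTS = 3
TWEET_CHAR_LIMIT = 140  # the generator targets the classic tweet length


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for one synthetic corpus.

    ``source_proportions`` / ``sentiment_proportions`` map label -> exact
    count (each must sum to ``n`` when given); ``attach`` names the axes
    whose labels are written onto the tweets — the other axis, if
    configured, stays latent (recorded only in the manifest) and still
    drives text/URL generation.
    """

    n: int
    source_proportions: dict[str, int] | None = None
    sentiment_proportions: dict[str, int] | None = None
    attach: tuple[str, ...] = ("source", "sentiment")
    signal_strength: float = 0.8
    source_confusion: float = 0.25
    background_vocab_size: int = 200
    tweet_length_mean: float = 12.0
    url_rate_personal: float = 0.3
    inversion_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        for axis, props in (("source", self.source_proportions),
                            ("sentiment", self.sentiment_proportions)):
            if props is not None:
                if any(v < 0 for v in props.values()) or sum(props.values()) != self.n:
                    raise ValueError(
                        f"{axis}_proportions must be non-negative and sum to n={self.n}"
                    )
        for name in ("signal_strength", "source_confusion",
                     "url_rate_personal", "inversion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for axis in self.attach:
            if axis not in ("source", "sentiment"):
                raise ValueError(f"unknown attach axis {axis!r}")
            if getattr(self, f"{axis}_proportions") is None:
                raise ValueError(f"attach includes {axis!r} but no proportions given")


class SyntheticCorpus(NamedTuple):
    corpus: Corpus
    resolver: UrlResolver
    lexicon: Lexicon
    manifest: dict


def _assign_labels(props: dict[str, int] | None, n: int, rng) -> list[str | None]:
    if props is None:
        return [None] * n
    pool: list[str] = []
    for label in sorted(props):
        pool.extend([label] * props[label])
    return [pool[i] for i in rng.permutation(n)]


def _short_code(rng, taken: set[str]) -> str:
    alphabet = "abcdefghijklmnopqrstuvwxyz0123456789"
    while True:
        code = "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=8))
        if code not in taken:
            taken.add(code)
            return code


def generate_corpus(spec: SyntheticSpec) -> SyntheticCorpus:
    """Generate a corpus, its URL resolver table, the valence lexicon, and a manifest."""
    rng = np.random.default_rng(spec.seed)
    background = [f"w{i:03d}" for i in range(spec.background_vocab_size)]
    bg_weights = 1.0 / np.arange(1, spec.background_vocab_size + 1)
    bg_weights /= bg_weights.sum()

    sources = _assign_labels(spec.source_proportions, spec.n, rng)
    sentiments = _assign_labels(spec.sentiment_proportions, spec.n, rng)

    items: list[LabeledTweet] = []
    table: dict[str, str] = {}
    taken_codes: set[str] = set()
    tweet_records: list[dict] = []

    for i in range(spec.n):
        src, sent = sources[i], sentiments[i]
        length = max(3, int(rng.poisson(spec.tweet_length_mean)))
        tokens = list(rng.choice(background, size=length, p=bg_weights))

        inverted = False
        expr: list[str] = []
        if src is not None:
            for _ in range(int(rng.binomial(EXPR_SLOTS, spec.signal_strength))):
                if rng.random() < spec.source_confusion:
                    other = [c for c in sorted(SOURCE_VOCAB) if c != src]
                    vocab = SOURCE_VOCAB[other[int(rng.integers(len(other)))]]
                else:
                    vocab = SOURCE_VOCAB[src]
                expr.append(vocab[int(rng.integers(len(vocab)))])
        if sent is not None:
            if sent == "positive" and rng.random() < spec.inversion_rate:
                inverted = True
                vocab = INVERTED_VOCAB
            else:
                vocab = SENTIMENT_VOCAB[sent]
            for _ in range(int(rng.binomial(EXPR_SLOTS, spec.signal_strength))):
                expr.append(vocab[int(rng.integers(len(vocab)))])
        for tok in expr:
            pos = int(rng.integers(0, len(tokens) + 1))
            if rng.random() < 0.10:
                tok = "#" + tok
            tokens.insert(pos, tok)
        if rng.random() < 0.10:
            tokens.insert(0, "@" + MENTION_NAMES[int(rng.integers(len(MENTION_NAMES)))])

        # URLs: media/retail always link out; personal links with some probability
        urls: list[str] = []
        url_source = src if src is not None else "personal"
        wants_url = (url_source in ("media", "retail")) or (
            rng.random() < spec.url_rate_personal
        )
        if wants_url:
            short = f"https://t.co/{_short_code(rng, taken_codes)}"
            # each URL slot (host, every path word) carries class signal
            # with probability signal_strength, else a generic filler
            def _url_slot(pool, neutral):
                src_pool = pool if rng.random() < spec.signal_strength else neutral
                return src_pool[int(rng.integers(len(src_pool)))]

            host = _url_slot(SOURCE_HOSTS[url_source], NEUTRAL_HOSTS)
            n_words = int(rng.integers(2, 5))
            path_words = [
                _url_slot(SOURCE_URL_WORDS[url_source], NEUTRAL_URL_WORDS)
                for _ in range(n_words)
            ]
            expanded = f"https://{host}/{path_words[0]}/" + "-".join(path_words[1:])
            table[short] = expanded
            urls.append(short)

        text = " ".join(tokens) + (f" {urls[0]}" if urls else "")
        while len(text) > TWEET_CHAR_LIMIT and len(tokens) > 3:
            tokens.pop()  # trim background chatter to fit the platform limit
            text = " ".join(tokens) + (f" {urls[0]}" if urls else "")

        items.append(
            LabeledTweet(
                tweet=Tweet(id=f"t{i:06d}", text=text, urls=tuple(urls), lang="en"),
                source=src if "source" in spec.attach else None,
                sentiment=sent if "sentiment" in spec.attach else None,
            )
        )
        tweet_records.append(
            {"id": f"t{i:06d}", "source": src, "sentiment": sent,
             "inverted": inverted, "expressive_tokens": expr}
        )

    manifest = {"spec": asdict(spec), "tweets": tweet_records}
    corpus = Corpus(items, metadata={"generator": "tweetsift.synth", "seed": spec.seed})
    corpus.validate()
    return SyntheticCorpus(
        corpus=corpus,
        resolver=UrlResolver(mode="offline_table", table=table),
        lexicon=default_lexicon(),
        manifest=manifest,
    )


def canonical_fixtures(base_seed: int = 2016) -> dict[str, SyntheticCorpus]:
    """The three standard fixtures with the canonical label compositions.

    * ``source``: 1000 URL-bearing tweets — 330 media, 340 retail, 330
      personal (every tweet links out, as in a URL-bearing training subset);
    * ``sentiment``: 3000 tweets — 1292 positive, 921 negative, 787
      neutral/unidentifiable — with a latent source mix dominated by
      personal communication;
    * ``personal_sentiment``: the 2633-tweet personal-communication analogue
      — 1157 positive, 850 negative, 626 neutral/unidentifiable.
    """
    fixtures = {
        "source": SyntheticSpec(
            n=1000,
            source_proportions={"media": 330, "retail": 340, "personal": 330},
            sentiment_proportions=None,
            attach=("source",),
            url_rate_personal=1.0,
            seed=base_seed + 1,
        ),
        "sentiment": SyntheticSpec(
            n=3000,
            source_proportions={"personal": 2633, "media": 184, "retail": 183},
            sentiment_proportions={"positive": 1292, "negative": 921, "neutral": 787},
            attach=("sentiment",),
            seed=base_seed + 2,
        ),
        "personal_sentiment": SyntheticSpec(
            n=2633,
            source_proportions={"personal": 2633},
            sentiment_proportions={"positive": 1157, "negative": 850, "neutral": 626},
            attach=("sentiment",),
            seed=base_seed + 3,
        ),
    }
    return {name: generate_corpus(spec) for name, spec in fixtures.items()}
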