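"""Domain types for tweets and labels, plus corpus readers/writers.

A corpus is an ordered list of labeled tweets. Two on-disk formats are
supported: JSONL (canonical; one UTF-8 JSON object per line) and CSV
(RFC 4180 with a header row, ``urls`` joined by ``|``).

Label taxonomy
--------------
*Source* (type of communication): ``personal`` — an individual user's own
statement; ``media`` — official/news content; ``retail`` — marketing or
sales content.  *Sentiment*: ``positive``, ``negative``, ``neutral`` (the
neutral value also covers tweets whose sentiment cannot be identified).

A structural fact of this domain that the validator enforces: media- and
retail-related tweets always carry at least one URL, so a tweet without a
URL can only be personal communication.
"""

from __future__ import annotations

import csv
import io
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

__all__ = [
    "SOURCE_LABELS",
    "SENTIMENT_LABELS",
    "Tweet",
    "LabeledTweet",
    "Corpus",
    "CorpusError",
    "LabelCounts",
    "read_corpus",
    "write_corpus",
    "label_counts",
]

SOURCE_LABELS: tuple[str, ...] = ("personal", "media", "retail")
SENTIMENT_LABELS: tuple[str, ...] = ("positive", "negative", "neutral")

#: Maximum tweet length accepted by validation (current platform limit).
#: The synthetic generator targets the older 140-character limit.
DEFAULT_LENGTH_CAP = 280


class CorpusError(ValueError):
    """Raised for malformed corpus files or invariant violations."""


@dataclass(frozen=True)
class Tweet:
    """A single tweet: opaque id, text, URLs it contains, optional language tag."""

    id: str
    text: str
    urls: tuple[str, ...] = ()
    lang: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise CorpusError("tweet id must be non-empty")
        object.__setattr__(self, "urls", tuple(self.urls))


@dataclass(frozen=True)
class LabeledTweet:
    """A tweet with optional gold source and/or sentiment labels."""

    tweet: Tweet
    source: str | None = None
    sentiment: str | None = None

    def __post_init__(self) -> None:
        # "rest" is the synthetic complement class used by binary
        # (target-vs-rest) task relabeling, not a corpus-file label
        if self.source is not None and self.source not in SOURCE_LABELS + ("rest",):
            raise CorpusError(
                f"unknown source label {self.source!r}; expected one of {SOURCE_LABELS}"
            )
        if self.sentiment is not None and self.sentiment not in SENTIMENT_LABELS:
            raise CorpusError(
                f"unknown sentiment label {self.sentiment!r}; "
                f"expected one of {SENTIMENT_LABELS}"
            )


@dataclass
class Corpus:
    """Ordered collection of labeled tweets plus free-form provenance metadata."""

    items: list[LabeledTweet] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def validate(self, length_cap: int = DEFAULT_LENGTH_CAP) -> None:
        """Check corpus invariants; raise :class:`CorpusError` on violation.

        Checks: unique ids, length cap, and the structural rule that every
        media/retail tweet carries at least one URL (offenders are counted
        in the error message).
        """
        seen: set[str] = set()
        for item in self.items:
            if item.tweet.id in seen:
                raise CorpusError(f"duplicate tweet id {item.tweet.id!r}")
            seen.add(item.tweet.id)
            if len(item.tweet.text) > length_cap:
                raise CorpusError(
                    f"tweet {item.tweet.id!r} exceeds length cap {length_cap}"
                )
        offenders = [
            it.tweet.id
            for it in self.items
            if it.source in ("media", "retail") and not it.tweet.urls
        ]
        if offenders:
            raise CorpusError(
                f"{len(offenders)} media/retail tweet(s) without URLs "
                f"(e.g. {offenders[:3]}); media and retail tweets must carry >=1 URL"
            )

    def deduplicate(self) -> "Corpus":
        """Return a corpus keeping the first occurrence of each id."""
        seen: set[str] = set()
        kept = []
        for it in self.items:
            if it.tweet.id not in seen:
                seen.add(it.tweet.id)
                kept.append(it)
        return Corpus(kept, dict(self.metadata))


class LabelCounts(NamedTuple):
    counts: dict[str, int]
    unlabeled: int


def label_counts(corpus: Corpus, axis: str) -> LabelCounts:
    """Count items per label on one axis; unlabeled items are reported separately.

    Parameters
    ----------
    axis : {"source", "sentiment"}
    """
    if axis not in ("source", "sentiment"):
        raise ValueError(f"axis must be 'source' or 'sentiment', got {axis!r}")
    labels = SOURCE_LABELS if axis == "source" else SENTIMENT_LABELS
    counts = Counter(
        getattr(it, axis) for it in corpus.items if getattr(it, axis) is not None
    )
    unlabeled = sum(1 for it in corpus.items if getattr(it, axis) is None)
    return LabelCounts({lab: counts.get(lab, 0) for lab in labels}, unlabeled)


# ---------------------------------------------------------------------------
# I/O

_CSV_FIELDS = ("id", "text", "urls", "lang", "source", "sentiment")


def _item_to_record(item: LabeledTweet) -> dict:
    rec: dict = {
        "id": item.tweet.id,
        "text": item.tweet.text,
        "urls": list(item.tweet.urls),
    }
    if item.tweet.lang is not None:
        rec["lang"] = item.tweet.lang
    if item.source is not None:
        rec["source"] = item.source
    if item.sentiment is not None:
        rec["sentiment"] = item.sentiment
    return rec


def _record_to_item(rec: dict, lineno: int) -> LabeledTweet:
    for key in ("id", "text"):
        if key not in rec or rec[key] in (None, ""):
            raise CorpusError(f"line {lineno}: record missing required field {key!r}")
    urls = rec.get("urls") or []
    if isinstance(urls, str):  # CSV: '|'-joined
        urls = [u for u in urls.split("|") if u]
    lang = rec.get("lang") or None
    try:
        return LabeledTweet(
            tweet=Tweet(id=str(rec["id"]), text=rec["text"], urls=tuple(urls), lang=lang),
            source=rec.get("source") or None,
            sentiment=rec.get("sentiment") or None,
        )
    except CorpusError as exc:
        raise CorpusError(f"line {lineno}: {exc}") from exc


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("jsonl", "csv"):
            raise ValueError(f"format must be 'jsonl' or 'csv', got {format!r}")
        return format
    return "csv" if path.suffix.lower() == ".csv" else "jsonl"


def read_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Read a corpus from a JSONL or CSV file.

    Malformed records are rejected with their line numbers; duplicate ids and
    unknown label strings raise :class:`CorpusError` naming the offender.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    items: list[LabeledTweet] = []
    if fmt == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusError(f"line {lineno}: invalid JSON ({exc})") from exc
                items.append(_record_to_item(rec, lineno))
    else:
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "id" not in reader.fieldnames:
                raise CorpusError(f"{path}: CSV header row with an 'id' column required")
            for lineno, rec in enumerate(reader, start=2):
                items.append(_record_to_item(rec, lineno))
    corpus = Corpus(items, metadata={"source_file": str(path), "format": fmt})
    seen: set[str] = set()
    for it in corpus.items:
        if it.tweet.id in seen:
            raise CorpusError(f"{path}: duplicate tweet id {it.tweet.id!r}")
        seen.add(it.tweet.id)
    return corpus


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus to JSONL (canonical) or CSV.

    Round-trip safe: ``read_corpus`` on the written file reproduces the items.
    The ``urls`` field is always serialized, as an empty list when absent.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for item in corpus.items:
                fh.write(json.dumps(_item_to_record(item), ensure_ascii=False) + "\n")
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
            writer.writeheader()
            for item in corpus.items:
                writer.writerow(
                    {
                        "id": item.tweet.id,
                        "text": item.tweet.text,
                        "urls": "|".join(item.tweet.urls),
                        "lang": item.tweet.lang or "",
                        "source": item.source or "",
                        "sentiment": item.sentiment or "",
                    }
                )
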