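"""URL detection, short-URL expansion, and URL-derived n-gram features.

Twitter shortens every link, and the short form (an opaque ``t.co`` code)
carries almost no signal. The expanded URL does: its host and path words
("leafly", "news", "shop", "discount") often reveal whether a link points
at news coverage or a retail storefront. This module resolves short URLs —
by default through an offline lookup table so runs are reproducible without
network access — and tokenizes expanded URLs into ``url:``-prefixed
unigrams and bigrams that never collide with tweet-text features.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, NamedTuple
from urllib.parse import urlsplit

__all__ = [
    "extract_urls",
    "UrlResolver",
    "Expansion",
    "expand_url",
    "url_tokens",
    "tweet_url_ngrams",
]

_URL_RE = re.compile(r"https?://[^\s]+", re.IGNORECASE)
_TRAILING_PUNCT = ".,;:!?)\"'»”’"

URL_PREFIX = "url:"


def extract_urls(text: str) -> list[str]:
    """All http(s) URLs in the text, in order, trailing punctuation stripped."""
    return [m.group(0).rstrip(_TRAILING_PUNCT) for m in _URL_RE.finditer(text)]


class Expansion(NamedTuple):
    url: str | None  # expanded URL, or None when unresolved
    resolved: bool


@dataclass(frozen=True)
class UrlResolver:
    """Short-URL resolver: offline lookup table (default) or live redirects.

    Offline mode never touches the network and is a pure function of the
    table. Live mode follows HTTP redirects up to ``max_redirects``; a
    ``fetcher`` callable (url -> redirect Location or None) may be injected,
    otherwise urllib issues HEAD requests.
    """

    mode: str = "offline_table"
    table: dict[str, str] = field(default_factory=dict)
    max_redirects: int = 10
    fetcher: Callable[[str], str | None] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("offline_table", "live"):
            raise ValueError(f"unknown resolver mode {self.mode!r}")

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "UrlResolver":
        """Load a 2-column (short, expanded) TSV table."""
        table: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                short, expanded = line.split("\t")
                table[short] = expanded
        return cls(mode="offline_table", table=table, **kwargs)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# short\texpanded\n")
            for short in sorted(self.table):
                fh.write(f"{short}\t{self.table[short]}\n")


def _default_fetcher(url: str) -> str | None:
    """One HEAD request; return the redirect Location or None. Network-only path."""
    import urllib.request

    class _NoRedirect(urllib.request.HTTPRedirectHandler):
        def redirect_request(self, *args, **kwargs):
            return None

    opener = urllib.request.build_opener(_NoRedirect)
    req = urllib.request.Request(url, method="HEAD")
    try:
        opener.open(req, timeout=5)
    except urllib.error.HTTPError as exc:
        if 300 <= exc.code < 400:
            return exc.headers.get("Location")
        return None
    except Exception:
        return None
    return None


def expand_url(url: str, resolver: UrlResolver) -> Expansion:
    """Expand one short URL; failures yield an unresolved marker, not an exception."""
    if not _URL_RE.fullmatch(url):
        raise ValueError(f"malformed URL {url!r}")
    if resolver.mode == "offline_table":
        expanded = resolver.table.get(url)
        return Expansion(expanded, expanded is not None)
    fetch = resolver.fetcher or _default_fetcher
    current = url
    for _ in range(resolver.max_redirects):
        location = fetch(current)
        if location is None:
            # no further redirect: resolved iff we moved at least one hop
            return Expansion(current, current != url) if current != url else Expansion(None, False)
        current = location
    return Expansion(None, False)  # chain longer than max_redirects


def _split_tokens(fragment: str) -> list[str]:
    """Split on non-alphanumerics; drop pure-numeric and single-char tokens."""
    parts = re.split(r"[^a-z0-9]+", fragment.lower())
    return [p for p in parts if len(p) >= 2 and not p.isdigit()]


def url_tokens(expanded: str | None, original: str | None = None) -> Counter:
    """``url:``-prefixed unigrams and adjacent bigrams from an expanded URL.

    The scheme is dropped; host and path are split on non-alphanumeric
    characters; pure-numeric tokens and tokens shorter than 2 characters are
    discarded. When ``expanded`` is None (unresolved) only the host tokens
    of the original short URL are emitted, so an unresolved link still
    contributes its hosting service as a (weak) signal.
    """
    if expanded is None:
        if original is None:
            return Counter()
        host = urlsplit(original).netloc
        toks = _split_tokens(host)
    else:
        parts = urlsplit(expanded)
        toks = _split_tokens(parts.netloc) + _split_tokens(
            "/".join(filter(None, [parts.path, parts.query]))
        )
    prefixed = [URL_PREFIX + t for t in toks]
    grams = Counter(prefixed)
    for a, b in zip(prefixed, prefixed[1:]):
        grams[f"{a} {b}"] += 1
    return grams


def host_tokens(url: str) -> Counter:
    """``url:``-prefixed host tokens only (the short-URL feature set)."""
    return url_tokens(None, url)


def tweet_url_ngrams(urls, resolver: UrlResolver | None, approach: int) -> Counter:
    """URL-derived n-grams for one tweet under a source-classification approach.

    Approach 1 uses the short URLs' host tokens as-is; approach 2 expands
    each URL through the resolver and tokenizes the expansion, falling back
    to short-URL host tokens when a link cannot be resolved.
    """
    if approach not in (1, 2):
        raise ValueError(f"approach must be 1 or 2, got {approach!r}")
    grams: Counter = Counter()
    for url in urls:
        if approach == 1 or resolver is None:
            grams.update(host_tokens(url))
        else:
            expansion = expand_url(url, resolver)
            grams.update(url_tokens(expansion.url, url))
    return grams
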