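import pytest

from tweetsift.corpus import Corpus, LabeledTweet, Tweet
from tweetsift.synth import canonical_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """The three canonical synthetic fixtures (generated once per session)."""
    return canonical_fixtures(base_seed=2016)


def make_corpus(rows):
    """Build a corpus from (id, text, urls, source, sentiment) tuples."""
    return Corpus(
        [
            LabeledTweet(
                tweet=Tweet(id=i, text=t, urls=tuple(u)),
                source=src,
                sentiment=sent,
            )
            for i, t, u, src, sent in rows
        ]
    )
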