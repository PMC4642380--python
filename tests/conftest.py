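import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pytest

from forumlens.corpus_io import Corpus, ForumPost, StopWordList
from forumlens.lexicon_prevalence import Lexicon


@pytest.fixture(autouse=True)
def _close_figures():
    yield
    plt.close("all")


@pytest.fixture
def small_corpus() -> Corpus:
    posts = [
        ForumPost("vapetalk", "p1", "My atty burnt out after a week of vaping."),
        ForumPost("vapetalk", "p2", "Cold turkey was too hard, I got a new carto instead."),
        ForumPost("vapetalk", "p3", "Great throat hit with this juice!", thread_id="t2",
                  author="cloudchaser", timestamp="2014-05-01T12:00:00"),
        ForumPost("vapetalk", "p4", ""),
    ]
    return Corpus(forum_id="vapetalk", posts=posts)


@pytest.fixture
def ecig_lexicon() -> Lexicon:
    return Lexicon(
        "e-cigarette",
        "subject matter",
        frozenset({"atty", "carto", "vape", "vaping", "ecig"}),
    )


@pytest.fixture
def basic_stops() -> StopWordList:
    return StopWordList.from_words(
        ["the", "a", "of", "my", "i", "ill", "dont", "was", "too", "after",
         "with", "this", "got", "new", "instead"]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150929)
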