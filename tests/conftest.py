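import numpy as np
import pytest

import opinionpulse as op
from opinionpulse import synthetic
from opinionpulse.preprocess import tokenize_corpus


@pytest.fixture(scope="session")
def small_corpus_cfg():
    """Headline-trend corpus scaled down for fast unit tests."""
    return op.headline_corpus_config(seed=42, posts_per_year=300, n_years=4)


@pytest.fixture(scope="session")
def small_corpus(small_corpus_cfg):
    return synthetic.gen_corpus(small_corpus_cfg)


@pytest.fixture(scope="session")
def small_tokenized(small_corpus, small_corpus_cfg):
    return tokenize_corpus(small_corpus, synthetic.tag_lexicon(small_corpus_cfg))


@pytest.fixture(scope="session")
def small_on_topic(small_corpus, small_tokenized):
    on = {p.id for p in small_corpus if p.on_topic}
    return [tp for tp in small_tokenized if tp.post_id in on]


@pytest.fixture(scope="session")
def sentiment_truth(small_corpus):
    return {p.id: p.sentiment for p in small_corpus if p.sentiment is not None}


@pytest.fixture(scope="session")
def default_panel():
    return synthetic.gen_panel(op.headline_panel_config(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
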