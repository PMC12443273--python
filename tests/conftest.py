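import pytest

from ncd_listener import ingestion, knowledge_extraction, synthetic


@pytest.fixture(scope="session")
def lexicon():
    return knowledge_extraction.default_lexicon()


@pytest.fixture(scope="session")
def selector_config():
    return ingestion.SelectorConfig(
        platform="facebook",
        comment_container_selector="div.comment",
        field_selectors={
            "name": "span.author",
            "comment": "div.comment-text",
            "likes": "span.like-count",
            "replies": "span.reply-count",
        },
    )


@pytest.fixture(scope="session")
def small_corpus():
    """100-comment bilingual corpus with planted duplicates and shorts."""
    spec = synthetic.CorpusSpec(n_comments=100, seed=1)
    return synthetic.generate_corpus(spec)


@pytest.fixture(scope="session")
def clean_corpus():
    """200 distinct, full-length comments (no duplicates, no shorts)."""
    spec = synthetic.CorpusSpec(
        n_comments=200, duplicate_rate=0.0, short_rate=0.0, seed=2
    )
    return synthetic.generate_corpus(spec)
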