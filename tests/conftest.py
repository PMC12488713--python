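import pytest
from hypothesis import HealthCheck, settings

import policyscope as ps

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


# Reference instrument tally: 291 coded segments split 143 supply /
# 106 environment / 42 demand, with the reported named-subtool counts;
# remaining subtools filled to the category totals.
REFERENCE_COUNTS = {
    "public services": 40, "infrastructure development": 37,
    "talent development": 12, "financial investment": 12,
    "standards and guidelines": 12, "information technology": 30,
    "target planning": 20, "regulatory control": 20, "strategic measures": 39,
    "financial and tax policies": 6, "supervision and evaluation": 11,
    "social environment": 10,
    "government procurement": 3, "public-private partnership": 2,
    "international exchange": 1, "demonstration and pilot programs": 10,
    "public welfare and charity": 5, "medical insurance": 21,
}


@pytest.fixture(scope="session")
def reference_counts():
    return dict(REFERENCE_COUNTS)


@pytest.fixture(scope="session")
def planted():
    """Planted 3-topic corpus used across recovery-style tests."""
    return ps.generate_lda_corpus(n_topics=3, vocab_size=60, n_docs=200,
                                  doc_len=100, seed=1)


@pytest.fixture(scope="session")
def fitted(planted):
    cfg = ps.LdaConfig(n_topics=3, alpha=planted.gen_params["alpha"], seed=1)
    return ps.fit_lda(planted.corpus, cfg)


@pytest.fixture(scope="session")
def toy_corpus():
    """Tiny deterministic corpus for closed-form diagnostics."""
    docs = [
        ps.TokenDoc("d1", ("a", "a", "b")),
        ps.TokenDoc("d2", ("b", "c")),
        ps.TokenDoc("d3", ("a", "c", "c")),
    ]
    vocab = ps.build_vocabulary(docs)
    return ps.to_bow(docs, vocab)
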