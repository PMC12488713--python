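"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators — an LDA-generative corpus with retained ground truth,
instrument-segment sets with planted counts, and random binary coding
matrices — plus the packaged nine-policy primary-score fixture used by
the PMC cohort examples.  Every generator is seed-deterministic, and
everything it emits can be written to the same on-disk formats the
pipeline reads, so end-to-end runs need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

import numpy as np

from .corpus import BowCorpus, Vocabulary
from .instruments import CodedSegment, CodingFrame
from .pmc import (DEFAULT_SCHEMA, PMCResult, PolicyCoding, VariableSchema,
                  classify, pmc_index, pmc_matrix)

__all__ = [
    "PlantedCorpus",
    "Table7Fixture",
    "generate_lda_corpus",
    "generate_instrument_segments",
    "generate_coding_matrix",
    "table7_fixture",
]


@dataclass(frozen=True)
class PlantedCorpus:
    """A bag-of-words corpus drawn from the LDA generative process, with
    the planted θ (D×K) and φ (K×V) retained for recovery tests."""

    corpus: BowCorpus
    true_theta: np.ndarray
    true_phi: np.ndarray
    gen_params: Mapping[str, float]


def generate_lda_corpus(n_topics: int, vocab_size: int, n_docs: int, doc_len: int,
                        alpha: float = 0.5, beta: float = 0.1,
                        seed: int = 0) -> PlantedCorpus:
    """Sample a corpus from the LDA generative process.

    φ_k ~ Dirichlet(β·1_V), θ_d ~ Dirichlet(α·1_K); each document draws
    ``doc_len`` tokens by first choosing topics from θ_d and then words
    from the chosen topic's φ.  The default α = 0.5 plants sparse
    document mixtures — documents dominated by a few topics, as real
    policy texts are — which keeps the planted topics identifiable and
    recovery experiments well-posed (near-uniform mixtures, e.g.
    α = 50/K, make φ unidentifiable in the large-α limit).  β defaults
    to 0.1, matching the fitting prior.  Token multiplicities are drawn
    as nested multinomials, distributionally identical to
    token-by-token sampling.
    """
    if min(n_topics, vocab_size, n_docs, doc_len) < 1:
        raise ValueError("all dimensions must be >= 1")
    a = alpha
    if a <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    rng = np.random.default_rng(seed)
    phi = rng.dirichlet(np.full(vocab_size, beta), size=n_topics)
    theta = rng.dirichlet(np.full(n_topics, a), size=n_docs)
    width = len(str(vocab_size - 1))
    vocab = Vocabulary.from_terms([f"w{v:0{width}d}" for v in range(vocab_size)])
    counts, ids = [], []
    for d in range(n_docs):
        z_counts = rng.multinomial(doc_len, theta[d])
        w_counts = np.zeros(vocab_size, dtype=np.int64)
        for k in range(n_topics):
            if z_counts[k]:
                w_counts += rng.multinomial(z_counts[k], phi[k])
        counts.append({int(v): int(c) for v, c in enumerate(w_counts) if c})
        ids.append(f"doc{d:04d}")
    corpus = BowCorpus(vocab=vocab, doc_ids=tuple(ids), counts=tuple(counts),
                       doc_lengths=tuple([doc_len] * n_docs))
    return PlantedCorpus(corpus=corpus, true_theta=theta, true_phi=phi,
                         gen_params={"K": n_topics, "V": vocab_size, "D": n_docs,
                                     "doc_len": doc_len, "alpha": a, "beta": beta,
                                     "seed": seed})


def generate_instrument_segments(frame: CodingFrame, planted_counts: Mapping[str, int],
                                 seed: int = 0, n_docs: int = 50) -> list[CodedSegment]:
    """Emit a coded-segment list whose tally equals ``planted_counts``
    exactly; segment-to-document assignment is random but seeded."""
    known = {n for cat in frame.categories for n in frame.subtool_names(cat)}
    unknown = sorted(set(planted_counts) - known)
    if unknown:
        raise KeyError(f"planted counts name subtools outside the frame: {unknown}")
    if any(v < 0 for v in planted_counts.values()):
        raise ValueError("planted counts must be >= 0")
    rng = np.random.default_rng(seed)
    segments = []
    i = 0
    for cat in frame.categories:
        for sub in frame.subtool_names(cat):
            for _ in range(planted_counts.get(sub, 0)):
                doc = f"D{rng.integers(1, n_docs + 1):02d}"
                segments.append(CodedSegment(doc_id=doc, category=cat, subtool=sub,
                                             locator=f"seg-{i:04d}"))
                i += 1
    return segments


def generate_coding_matrix(schema: VariableSchema | None = None, n_policies: int = 9,
                           prevalence: float = 0.5, seed: int = 0) -> list[PolicyCoding]:
    """Random binary codings: each secondary indicator is 1 independently
    with probability ``prevalence``."""
    schema = schema or DEFAULT_SCHEMA
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sids = schema.all_secondary_ids
    out = []
    for p in range(n_policies):
        draws = rng.random(len(sids)) < prevalence
        out.append(PolicyCoding(policy_id=f"S{p + 1:03d}",
                                values={s: int(v) for s, v in zip(sids, draws)}))
    return out


# ---------------------------------------------------------------------------
# packaged nine-policy primary-score fixture

_FIXTURE_SCORES: dict[str, tuple[float, ...]] = {
    #        X1    X2    X3    X4    X5    X6    X7    X8    X9
    "P1": (0.67, 0.67, 1.00, 0.67, 0.25, 0.60, 0.67, 0.40, 0.67),
    "P2": (0.67, 1.00, 1.00, 0.83, 0.75, 0.50, 0.67, 0.40, 0.89),
    "P3": (1.00, 0.67, 1.00, 1.00, 1.00, 0.70, 1.00, 0.60, 1.00),
    "P4": (0.20, 0.33, 0.60, 0.67, 0.50, 0.70, 0.67, 0.20, 0.33),
    "P5": (1.00, 0.67, 1.00, 1.00, 0.75, 0.30, 1.00, 0.20, 0.67),
    "P6": (0.50, 0.33, 1.00, 1.00, 0.50, 0.80, 0.67, 0.20, 0.67),
    "P7": (0.83, 0.67, 1.00, 1.00, 0.75, 1.00, 0.67, 0.60, 0.78),
    "P8": (0.50, 0.67, 1.00, 0.83, 0.50, 0.60, 0.67, 0.60, 0.56),
    "P9": (0.50, 0.67, 0.80, 0.67, 0.75, 0.80, 0.67, 0.20, 0.67),
}

_PRIMARY_IDS = tuple(f"X{i}" for i in range(1, 10))


@dataclass(frozen=True)
class Table7Fixture:
    """Nine reference NCD policies (P1..P9) with their published
    primary-variable scores; the index, ratings and ranks are always
    recomputed from these scores, never stored."""

    scores: Mapping[str, tuple[float, ...]]

    @property
    def policy_ids(self) -> tuple[str, ...]:
        return tuple(self.scores)

    @property
    def primary_ids(self) -> tuple[str, ...]:
        return _PRIMARY_IDS

    def __getitem__(self, key: tuple[str, str]) -> float:
        policy, primary = key
        return self.scores[policy][_PRIMARY_IDS.index(primary)]

    def to_results(self) -> list[PMCResult]:
        """Per-policy PMC results computed from the fixture scores."""
        out = []
        for pid, vec in self.scores.items():
            pmc = pmc_index(vec)
            out.append(PMCResult(policy_id=pid,
                                 primary_scores=dict(zip(_PRIMARY_IDS, vec)),
                                 pmc=pmc, rating=classify(pmc),
                                 matrix=pmc_matrix(vec)))
        return out


def table7_fixture() -> Table7Fixture:
    """The packaged nine-policy × nine-primary score grid."""
    return Table7Fixture(scores=MappingProxyType(dict(_FIXTURE_SCORES)))
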