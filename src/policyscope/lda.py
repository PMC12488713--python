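"""Latent Dirichlet allocation by collapsed Gibbs sampling, with the three
model diagnostics used for topic-number selection: plug-in perplexity,
UMass coherence, and corpus-level topic strength.

The model: each document d draws a topic mixture θ_d ~ Dirichlet(α·1_K),
each topic k a word distribution φ_k ~ Dirichlet(β·1_V); every token
draws a topic z ~ Categorical(θ_d) and then a word w ~ Categorical(φ_z).
Inference integrates θ and φ out and Gibbs-samples the token-topic
assignments z; point estimates are read off the final count state:

    θ̂_dk = (n_dk + α) / (N_d + Kα),     φ̂_kv = (n_kv + β) / (n_k + Vβ).

All random draws are pre-generated from a seeded PCG64 stream, so a
given (corpus, config) pair always yields bit-identical assignments.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .corpus import BowCorpus

__all__ = [
    "LdaConfig",
    "TopicModel",
    "DocFrequencyIndex",
    "TopicScan",
    "fit_lda",
    "perplexity",
    "umass_coherence",
    "mean_model_coherence",
    "topic_strength",
    "select_num_topics",
    "top_terms",
]

DEFAULT_BETA = 0.1
DEFAULT_ITERATIONS = 100


@dataclass(frozen=True)
class LdaConfig:
    """Sampler settings.

    ``alpha=None`` resolves to the symmetric prior 50/K; ``beta``
    defaults to 0.1; ``iterations`` counts full Gibbs sweeps over every
    token from a seeded random initialization.
    """

    n_topics: int
    alpha: float | None = None
    beta: float = DEFAULT_BETA
    iterations: int = DEFAULT_ITERATIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    @property
    def resolved_alpha(self) -> float:
        return 50.0 / self.n_topics if self.alpha is None else self.alpha


@dataclass(frozen=True)
class TopicModel:
    """Fitted LDA state.

    ``theta`` is D×K (one row per corpus document, including empty ones,
    which receive the prior mean); ``phi`` is K×V.  Both are smoothed
    posterior-mean estimates, so every row is a strictly positive
    probability vector.  ``assignments`` holds the final token-topic
    labels of each non-empty document in corpus order.
    """

    config: LdaConfig
    vocab_terms: tuple[str, ...]
    doc_ids: tuple[str, ...]
    theta: np.ndarray = field(repr=False)
    phi: np.ndarray = field(repr=False)
    assignments: tuple[np.ndarray, ...] = field(repr=False)

    @property
    def n_topics(self) -> int:
        return self.phi.shape[0]

    @property
    def n_terms(self) -> int:
        return self.phi.shape[1]

    def to_json(self) -> str:
        return json.dumps({
            "config": {
                "n_topics": self.config.n_topics,
                "alpha": self.config.alpha,
                "beta": self.config.beta,
                "iterations": self.config.iterations,
                "seed": self.config.seed,
            },
            "terms": list(self.vocab_terms),
            "doc_ids": list(self.doc_ids),
            "theta": self.theta.tolist(),
            "phi": self.phi.tolist(),
            "assignments": [a.tolist() for a in self.assignments],
        }, ensure_ascii=False)

    @classmethod
    def from_json(cls, text: str) -> "TopicModel":
        d = json.loads(text)
        return cls(
            config=LdaConfig(**d["config"]),
            vocab_terms=tuple(d["terms"]),
            doc_ids=tuple(d["doc_ids"]),
            theta=np.asarray(d["theta"], dtype=float),
            phi=np.asarray(d["phi"], dtype=float),
            assignments=tuple(np.asarray(a, dtype=np.int64) for a in d["assignments"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TopicModel":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


@njit(cache=False)
def _gibbs(doc_of, word_of, z, ndk, nkv, nk, alpha, beta, uniforms, iterations):
    n_tokens = doc_of.shape[0]
    K = ndk.shape[1]
    V = nkv.shape[1]
    p = np.empty(K)
    u_idx = 0
    for _ in range(iterations):
        for i in range(n_tokens):
            d = doc_of[i]
            w = word_of[i]
            k = z[i]
            ndk[d, k] -= 1
            nkv[k, w] -= 1
            nk[k] -= 1
            total = 0.0
            for kk in range(K):
                val = (ndk[d, kk] + alpha) * (nkv[kk, w] + beta) / (nk[kk] + V * beta)
                p[kk] = val
                total += val
            u = uniforms[u_idx] * total
            u_idx += 1
            acc = 0.0
            knew = K - 1
            for kk in range(K):
                acc += p[kk]
                if u < acc:
                    knew = kk
                    break
            z[i] = knew
            ndk[d, knew] += 1
            nkv[knew, w] += 1
            nk[knew] += 1


def _flatten(corpus: BowCorpus) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Token stream (doc index, word index) in document order, terms sorted
    by index within each document so the stream is reproducible."""
    doc_of, word_of, fitted = [], [], []
    for d, counts in enumerate(corpus.counts):
        if corpus.doc_lengths[d] == 0:
            continue
        fitted.append(d)
        for v, c in sorted(counts.items()):
            doc_of.extend([d] * c)
            word_of.extend([v] * c)
    return (np.asarray(doc_of, dtype=np.int64),
            np.asarray(word_of, dtype=np.int64), fitted)


def fit_lda(corpus: BowCorpus, config: LdaConfig) -> TopicModel:
    """Run collapsed Gibbs sampling for ``config.iterations`` full sweeps.

    Estimates are taken from the final count state (no burn-in discard,
    no averaging over samples).  Documents with N_d = 0 are excluded
    from sampling and receive the prior-mean mixture 1/K.
    """
    K = config.n_topics
    V = corpus.n_terms
    D = corpus.n_docs
    alpha = config.resolved_alpha
    beta = config.beta

    doc_of, word_of, fitted = _flatten(corpus)
    if doc_of.size == 0:
        raise ValueError("all documents are empty; nothing to fit")
    if V < K:
        warnings.warn(f"vocabulary size {V} < n_topics {K}; topics will be degenerate",
                      stacklevel=2)

    rng = np.random.default_rng(config.seed)
    n_tokens = doc_of.size
    init_u = rng.random(n_tokens)
    sweep_u = rng.random(n_tokens * config.iterations)

    z = np.minimum((init_u * K).astype(np.int64), K - 1)
    ndk = np.zeros((D, K), dtype=np.int64)
    nkv = np.zeros((K, V), dtype=np.int64)
    nk = np.zeros(K, dtype=np.int64)
    np.add.at(ndk, (doc_of, z), 1)
    np.add.at(nkv, (z, word_of), 1)
    np.add.at(nk, z, 1)

    _gibbs(doc_of, word_of, z, ndk, nkv, nk, alpha, beta, sweep_u, config.iterations)

    n_d = np.asarray(corpus.doc_lengths, dtype=float)
    theta = (ndk + alpha) / (n_d[:, None] + K * alpha)
    phi = (nkv + beta) / (nk[:, None] + V * beta)
    if not (np.isfinite(theta).all() and np.isfinite(phi).all()):
        raise ValueError("non-finite sampling weights; corpus counts are corrupt")

    assignments = []
    for d in fitted:
        assignments.append(z[doc_of == d].copy())
    return TopicModel(config=config, vocab_terms=corpus.vocab.terms,
                      doc_ids=corpus.doc_ids, theta=theta, phi=phi,
                      assignments=tuple(assignments))


def perplexity(model: TopicModel, corpus: BowCorpus) -> float:
    """exp(−Σ_d log P̂(w_d) / Σ_d N_d) with the plug-in per-token likelihood
    P̂(v | d) = Σ_k θ̂_dk φ̂_kv.  Documents with N_d = 0 are skipped.
    Lower is better; the exact-uniform model scores V.
    """
    if model.vocab_terms != corpus.vocab.terms:
        raise ValueError("model and corpus vocabularies differ")
    total_tokens = corpus.total_tokens
    if total_tokens == 0:
        raise ValueError("corpus has no tokens")
    log_lik = 0.0
    for d, counts in enumerate(corpus.counts):
        if corpus.doc_lengths[d] == 0:
            continue
        idx = np.fromiter(counts.keys(), dtype=np.int64, count=len(counts))
        cnt = np.fromiter(counts.values(), dtype=np.int64, count=len(counts))
        p = model.theta[d] @ model.phi[:, idx]
        log_lik += float(cnt @ np.log(p))
    return math.exp(-log_lik / total_tokens)


@dataclass(frozen=True)
class DocFrequencyIndex:
    """Document frequencies D(w) and co-document frequencies D(w_i, w_j).

    Backed by per-term document sets so pair frequencies are computed
    (and cached) on demand; symmetric in its pair arguments.
    """

    doc_sets: Mapping[str, frozenset[int]]
    _co_cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_corpus(cls, corpus: BowCorpus) -> "DocFrequencyIndex":
        sets: dict[str, set[int]] = {t: set() for t in corpus.vocab.terms}
        for d, counts in enumerate(corpus.counts):
            for v in counts:
                sets[corpus.vocab.terms[v]].add(d)
        return cls(doc_sets={t: frozenset(s) for t, s in sets.items()})

    def df(self, term: str) -> int:
        if term not in self.doc_sets:
            raise KeyError(f"term {term!r} not in index")
        return len(self.doc_sets[term])

    def co_df(self, a: str, b: str) -> int:
        key = (a, b) if a <= b else (b, a)
        if key not in self._co_cache:
            self._co_cache[key] = len(self.doc_sets[key[0]] & self.doc_sets[key[1]])
        return self._co_cache[key]


def umass_coherence(top_terms_list: Sequence[str], index: DocFrequencyIndex,
                    epsilon: float = 1.0) -> float:
    """UMass coherence of an ordered top-term list:

        C = 2/(N(N−1)) · Σ_{i=2..N} Σ_{j<i} log((D(w_i, w_j) + ε) / D(w_j))

    Terms must be ordered by descending within-topic probability.  A
    single term has no pairs and scores 0 by convention.
    """
    n = len(top_terms_list)
    if n < 1:
        raise ValueError("need at least one term")
    for t in top_terms_list:
        if t not in index.doc_sets:
            raise KeyError(f"term {t!r} absent from the corpus index")
    if n == 1:
        return 0.0
    total = 0.0
    for j, i in combinations(range(n), 2):  # j < i
        dj = index.df(top_terms_list[j])
        if dj == 0:
            raise ValueError(f"term {top_terms_list[j]!r} occurs in no document")
        total += math.log((index.co_df(top_terms_list[i], top_terms_list[j]) + epsilon) / dj)
    return 2.0 / (n * (n - 1)) * total


def top_terms(model: TopicModel, k: int, n: int) -> list[str]:
    """The ``n`` highest-probability terms of topic ``k``; φ ties broken
    lexicographically."""
    if not 0 <= k < model.n_topics:
        raise IndexError(f"topic index {k} out of range")
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > model.n_terms:
        warnings.warn(f"requested {n} terms but vocabulary has {model.n_terms}; truncating",
                      stacklevel=2)
        n = model.n_terms
    order = sorted(range(model.n_terms),
                   key=lambda v: (-model.phi[k, v], model.vocab_terms[v]))
    return [model.vocab_terms[v] for v in order[:n]]


def mean_model_coherence(model: TopicModel, corpus: BowCorpus, n_top: int = 10) -> float:
    """Arithmetic mean of per-topic UMass coherence, each topic scored on
    its ``n_top`` highest-probability terms."""
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    index = DocFrequencyIndex.from_corpus(corpus)
    vals = [umass_coherence(top_terms(model, k, n_top), index)
            for k in range(model.n_topics)]
    return float(np.mean(vals))


def topic_strength(model: TopicModel) -> np.ndarray:
    """Corpus-level topic importance: Strength_k = (1/D) Σ_d θ̂_dk.  Rows of
    θ̂ each sum to 1 (empty documents carry the prior mean), so the
    strengths sum to 1 across topics."""
    return model.theta.mean(axis=0)


@dataclass(frozen=True)
class TopicScan:
    """Topic-number scan: one fitted model per candidate K, with both
    diagnostic curves and the coherence-selected K."""

    k_values: tuple[int, ...]
    perplexities: tuple[float, ...]
    coherences: tuple[float, ...]
    selected_k: int


def select_num_topics(corpus: BowCorpus, k_values: Sequence[int],
                      base_config: LdaConfig | None = None,
                      n_top: int = 10) -> TopicScan:
    """Fit one model per candidate K (same seed each, so runs are
    reproducible) and select the K with the highest mean UMass
    coherence, ties broken toward smaller K.  Perplexity is recorded
    for inspection but does not enter the selection rule.
    """
    if not k_values:
        raise ValueError("k_values must be non-empty")
    if any(k < 1 for k in k_values):
        raise ValueError("every candidate K must be >= 1")
    base = base_config or LdaConfig(n_topics=1)
    perp, coh = [], []
    for k in k_values:
        cfg = LdaConfig(n_topics=k, alpha=base.alpha, beta=base.beta,
                        iterations=base.iterations, seed=base.seed)
        try:
            model = fit_lda(corpus, cfg)
        except Exception as exc:
            raise RuntimeError(f"topic scan failed at K={k}") from exc
        perp.append(perplexity(model, corpus))
        coh.append(mean_model_coherence(model, corpus, n_top=n_top))
    best = max(range(len(k_values)), key=lambda i: (coh[i], -k_values[i]))
    return TopicScan(k_values=tuple(k_values), perplexities=tuple(perp),
                     coherences=tuple(coh), selected_k=k_values[best])
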