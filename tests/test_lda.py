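import math
from itertools import permutations

import numpy as np
import pytest

import policyscope as ps
from policyscope.lda import DocFrequencyIndex, TopicModel


def best_perm_tv(phi_hat, phi_true):
    """Mean total-variation distance under the best topic relabelling."""
    k = phi_true.shape[0]
    return min(0.5 * np.abs(phi_hat[list(p)] - phi_true).sum(axis=1).mean()
               for p in permutations(range(k)))


def uniform_model(vocab_size):
    """A 1-topic model assigning every token probability exactly 1/V."""
    terms = tuple(f"t{i}" for i in range(vocab_size))
    return TopicModel(config=ps.LdaConfig(n_topics=1),
                      vocab_terms=terms, doc_ids=("d",),
                      theta=np.array([[1.0]]),
                      phi=np.full((1, vocab_size), 1.0 / vocab_size),
                      assignments=(np.zeros(1, dtype=np.int64),))


class TestFit:
    def test_single_topic_degeneracy(self, toy_corpus):
        m = ps.fit_lda(toy_corpus, ps.LdaConfig(n_topics=1, seed=0))
        assert all((a == 0).all() for a in m.assignments)
        assert np.allclose(m.theta, 1.0)
        # phi = smoothed corpus frequencies
        tot = np.zeros(toy_corpus.n_terms)
        for c in toy_corpus.counts:
            for v, n in c.items():
                tot[v] += n
        beta = m.config.beta
        expect = (tot + beta) / (tot.sum() + toy_corpus.n_terms * beta)
        assert np.allclose(m.phi[0], expect)

    def test_same_seed_bit_identical(self, toy_corpus):
        cfg = ps.LdaConfig(n_topics=2, seed=7)
        m1, m2 = ps.fit_lda(toy_corpus, cfg), ps.fit_lda(toy_corpus, cfg)
        assert all((a == b).all() for a, b in zip(m1.assignments, m2.assignments))
        assert (m1.theta == m2.theta).all() and (m1.phi == m2.phi).all()

    def test_rows_are_probability_vectors(self, fitted):
        assert np.allclose(fitted.theta.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(fitted.phi.sum(axis=1), 1.0, atol=1e-9)
        assert (fitted.theta > 0).all() and (fitted.phi > 0).all()

    def test_parameter_recovery_on_planted_corpus(self, planted, fitted):
        assert best_perm_tv(fitted.phi, planted.true_phi) < 0.10

    def test_empty_corpus_and_few_terms(self):
        vocab = ps.Vocabulary.from_terms(["a"])
        empty = ps.to_bow([ps.TokenDoc("d", ())], vocab)
        with pytest.raises(ValueError, match="empty"):
            ps.fit_lda(empty, ps.LdaConfig(n_topics=1))
        one = ps.to_bow([ps.TokenDoc("d", ("a",))], vocab)
        with pytest.warns(UserWarning, match="vocabulary size"):
            ps.fit_lda(one, ps.LdaConfig(n_topics=2, seed=0))

    def test_empty_document_gets_prior_mean_row(self):
        vocab = ps.Vocabulary.from_terms(["a", "b"])
        bow = ps.to_bow([ps.TokenDoc("d", ("a", "b", "a")), ps.TokenDoc("e", ())], vocab)
        m = ps.fit_lda(bow, ps.LdaConfig(n_topics=2, seed=0))
        assert np.allclose(m.theta[1], 0.5)
        assert len(m.assignments) == 1  # only the non-empty doc was sampled

    def test_serialization_round_trip(self, fitted, tmp_path):
        p = tmp_path / "model.json"
        fitted.save(p)
        back = TopicModel.load(p)
        assert (back.theta == fitted.theta).all() and (back.phi == fitted.phi).all()
        assert back.config == fitted.config


class TestPerplexity:
    def test_uniform_model_scores_vocab_size(self):
        v = 7
        m = uniform_model(v)
        bow = ps.to_bow([ps.TokenDoc("d", ("t0", "t3", "t3"))],
                        ps.Vocabulary.from_terms(m.vocab_terms))
        assert ps.perplexity(m, bow) == pytest.approx(v, rel=1e-12)

    def test_certain_model_scores_one(self):
        m = TopicModel(config=ps.LdaConfig(n_topics=1), vocab_terms=("w",),
                       doc_ids=("d",), theta=np.array([[1.0]]),
                       phi=np.array([[1.0]]),
                       assignments=(np.zeros(2, dtype=np.int64),))
        bow = ps.to_bow([ps.TokenDoc("d", ("w", "w"))], ps.Vocabulary.from_terms(["w"]))
        assert ps.perplexity(m, bow) == pytest.approx(1.0, rel=1e-12)

    def test_matches_brute_force_enumeration(self, toy_corpus):
        """Independent per-token arithmetic reproduces the vectorized value."""
        m = ps.fit_lda(toy_corpus, ps.LdaConfig(n_topics=2, seed=3))
        log_lik, n_tok = 0.0, 0
        for d, counts in enumerate(toy_corpus.counts):
            for v, c in counts.items():
                p = sum(m.theta[d, k] * m.phi[k, v] for k in range(2))
                log_lik += c * math.log(p)
                n_tok += c
        expect = math.exp(-log_lik / n_tok)
        assert ps.perplexity(m, toy_corpus) == pytest.approx(expect, rel=1e-12)
        assert ps.perplexity(m, toy_corpus) >= 1.0

    def test_training_perplexity_at_least_one(self, fitted, planted):
        assert ps.perplexity(fitted, planted.corpus) >= 1.0

    def test_vocabulary_mismatch_and_empty(self, toy_corpus):
        m = uniform_model(3)
        with pytest.raises(ValueError, match="vocabular"):
            ps.perplexity(m, toy_corpus)


class TestCoherence:
    def test_hand_computed_zero_case(self):
        idx = DocFrequencyIndex(doc_sets={"a": frozenset({0, 1}), "b": frozenset({0})})
        assert ps.umass_coherence(["a", "b"], idx) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_log2_case(self):
        idx = DocFrequencyIndex(doc_sets={"a": frozenset({0}), "b": frozenset({0})})
        assert ps.umass_coherence(["a", "b"], idx) == pytest.approx(math.log(2), rel=1e-12)

    def test_single_term_is_zero_by_convention(self):
        idx = DocFrequencyIndex(doc_sets={"a": frozenset({0})})
        assert ps.umass_coherence(["a"], idx) == 0.0

    def test_absent_or_zero_df_term_errors(self):
        idx = DocFrequencyIndex(doc_sets={"a": frozenset({0}), "z": frozenset()})
        with pytest.raises(KeyError):
            ps.umass_coherence(["a", "q"], idx)
        with pytest.raises(ValueError, match="no document"):
            ps.umass_coherence(["z", "a"], idx)

    def test_index_invariants_on_planted_corpus(self, planted):
        idx = DocFrequencyIndex.from_corpus(planted.corpus)
        terms = planted.corpus.vocab.terms[:8]
        for i, a in enumerate(terms):
            for b in terms[i + 1:]:
                co = idx.co_df(a, b)
                assert co == idx.co_df(b, a) <= min(idx.df(a), idx.df(b))

    def test_mean_coherence_k1_and_symmetry(self, toy_corpus):
        m1 = ps.fit_lda(toy_corpus, ps.LdaConfig(n_topics=1, seed=0))
        idx = DocFrequencyIndex.from_corpus(toy_corpus)
        single = ps.umass_coherence(ps.top_terms(m1, 0, 3), idx)
        assert ps.mean_model_coherence(m1, toy_corpus, n_top=3) == pytest.approx(single)

    def test_mean_coherence_is_topic_average(self, fitted, planted):
        idx = DocFrequencyIndex.from_corpus(planted.corpus)
        per_topic = [ps.umass_coherence(ps.top_terms(fitted, k, 10), idx)
                     for k in range(3)]
        got = ps.mean_model_coherence(fitted, planted.corpus, n_top=10)
        assert got == pytest.approx(float(np.mean(per_topic)), rel=1e-12)
        assert all(np.isfinite(v) for v in per_topic)


class TestStrengthAndTerms:
    def test_k1_strength(self, toy_corpus):
        m = ps.fit_lda(toy_corpus, ps.LdaConfig(n_topics=1, seed=0))
        assert ps.topic_strength(m).tolist() == [1.0]

    def test_strength_sums_to_one(self, fitted):
        assert ps.topic_strength(fitted).sum() == pytest.approx(1.0, abs=1e-9)

    def test_strength_near_uniform_at_scale(self):
        # symmetric Dirichlet mixtures at D=500: each strength near 1/K
        pc = ps.generate_lda_corpus(3, 40, 500, 60, seed=2)
        m = ps.fit_lda(pc.corpus, ps.LdaConfig(n_topics=3, alpha=0.5, seed=2))
        assert np.abs(ps.topic_strength(m) - 1 / 3).max() < 0.05

    def test_top_terms_concentration_and_ties(self):
        terms = ("b", "a", "c")
        m = TopicModel(config=ps.LdaConfig(n_topics=2), vocab_terms=terms,
                       doc_ids=("d",),
                       theta=np.array([[0.5, 0.5]]),
                       phi=np.array([[0.8, 0.1, 0.1],
                                     [1 / 3, 1 / 3, 1 / 3]]),
                       assignments=(np.zeros(1, dtype=np.int64),))
        assert ps.top_terms(m, 0, 1) == ["b"]
        assert ps.top_terms(m, 1, 3) == ["a", "b", "c"]  # uniform row: lexicographic
        with pytest.warns(UserWarning, match="truncating"):
            assert len(ps.top_terms(m, 0, 10)) == 3

    def test_planted_top_mass_leads(self, planted, fitted):
        """The heaviest planted terms of a recovered topic lead its list."""
        perm = min(permutations(range(3)),
                   key=lambda p: np.abs(fitted.phi[list(p)] - planted.true_phi).sum())
        for k_true, k_fit in enumerate(perm):
            top_true = set(np.argsort(-planted.true_phi[k_true])[:3])
            top_fit = {planted.corpus.vocab.index[t]
                       for t in ps.top_terms(fitted, k_fit, 5)}
            assert len(top_true & top_fit) >= 2


class TestSelect:
    def test_singleton(self, toy_corpus):
        scan = ps.select_num_topics(toy_corpus, [3], ps.LdaConfig(n_topics=1, seed=0))
        assert scan.selected_k == 3 and scan.selected_k in scan.k_values

    def test_tie_broken_toward_smaller_k(self):
        # single-term vocabulary: every topic's 1-term list scores 0, all K tie
        vocab = ps.Vocabulary.from_terms(["w"])
        bow = ps.to_bow([ps.TokenDoc(f"d{i}", ("w",) * 4) for i in range(3)], vocab)
        with pytest.warns(UserWarning):
            scan = ps.select_num_topics(bow, [2, 3], ps.LdaConfig(n_topics=1, seed=0),
                                        n_top=1)
        assert scan.coherences[0] == scan.coherences[1] == 0.0
        assert scan.selected_k == 2

    def test_invalid_k_values(self, toy_corpus):
        with pytest.raises(ValueError):
            ps.select_num_topics(toy_corpus, [], ps.LdaConfig(n_topics=1))
        with pytest.raises(ValueError):
            ps.select_num_topics(toy_corpus, [0, 2], ps.LdaConfig(n_topics=1))

    def test_scan_records_both_curves_deterministically(self, planted):
        base = ps.LdaConfig(n_topics=1, alpha=0.5, seed=4)
        s1 = ps.select_num_topics(planted.corpus, [2, 3], base)
        s2 = ps.select_num_topics(planted.corpus, [2, 3], base)
        assert s1 == s2
        assert len(s1.perplexities) == len(s1.coherences) == 2
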