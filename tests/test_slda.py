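"""Supervised topic model: generative sampling, variational EM, inference."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.special import softmax

from newsworthy import (
    SLDAModel,
    SLDASimSpec,
    fit_slda,
    infer_document,
    make_slda_corpus,
    planted_slda_model,
    predict_label,
    sample_corpus,
    topic_report,
)


def assert_elbo_monotone(trace):
    """Each EM iteration may not lower the bound beyond 1e-6 relative slack."""
    el = np.asarray(trace.elbo)
    assert el.size >= 1 and np.all(np.isfinite(el))
    drops = np.diff(el) < -1e-6 * np.abs(el[:-1])
    assert not drops.any(), f"ELBO decreased at iterations {np.flatnonzero(drops)}"


def two_topic_model(eta1=0.0, eta2=0.0):
    beta = np.array([[0.6, 0.3, 0.05, 0.05],
                     [0.05, 0.05, 0.3, 0.6]])
    eta = np.array([[0.0, 0.0], [eta1, eta2]])
    return SLDAModel(K=2, V=4, alpha=1.0, beta=beta, eta=eta)


class TestSampleCorpus:
    def test_single_topic_words_follow_beta(self):
        beta = np.array([[0.5, 0.25, 0.25]])
        model = SLDAModel(K=1, V=3, alpha=1.0, beta=beta, eta=np.zeros((2, 1)))
        docs, labels, thetas, zs = sample_corpus(model, 200, 30, seed=0)
        assert np.allclose(thetas, 1.0)
        assert all(np.all(z == 0) for z in zs)
        freq = np.bincount(np.concatenate(docs), minlength=3) / (200 * 30)
        assert np.allclose(freq, beta[0], atol=3 * np.sqrt(0.5 * 0.5 / (200 * 30)) + 0.01)

    def test_zero_eta_gives_uniform_labels(self):
        model = two_topic_model()
        _, labels, _, _ = sample_corpus(model, 2000, 20, seed=1)
        p = labels.mean()
        assert abs(p - 0.5) < 3 * np.sqrt(0.25 / 2000)

    def test_word_marginal_matches_topic_mixture(self):
        """With alpha symmetric, E[theta] = 1/K so the word marginal is the topic average."""
        model = two_topic_model()
        docs, _, _, _ = sample_corpus(model, 1000, 50, seed=2)
        n_tokens = 1000 * 50
        freq = np.bincount(np.concatenate(docs), minlength=4) / n_tokens
        expected = 0.5 * model.beta[0] + 0.5 * model.beta[1]
        assert np.allclose(freq, expected, atol=3 * np.sqrt(0.25 / n_tokens) + 0.01)

    def test_seeded_determinism(self):
        model = two_topic_model(1.0, -1.0)
        a = sample_corpus(model, 10, 15, seed=7)
        b = sample_corpus(model, 10, 15, seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a[0], b[0]))
        assert np.array_equal(a[1], b[1])


class TestFitSLDA:
    def test_single_topic_recovers_empirical_frequencies(self, rng):
        docs = [rng.integers(0, 10, size=40) for _ in range(30)]
        labels = np.array([i % 2 for i in range(30)])
        model, _, trace = fit_slda(docs, labels, V=10, K=1, max_iter=20, seed=0)
        counts = np.bincount(np.concatenate(docs), minlength=10).astype(float)
        np.testing.assert_allclose(model.beta[0], counts / counts.sum(), atol=1e-6)
        assert_elbo_monotone(trace)

    def test_unsupervised_equals_supervised_for_single_topic(self, rng):
        """With K=1 the label cannot influence beta; both paths coincide."""
        docs = [rng.integers(0, 8, size=25) for _ in range(20)]
        labels = np.array([i % 2 for i in range(20)])
        m_sup, _, t_sup = fit_slda(docs, labels, V=8, K=1, max_iter=15, seed=1)
        m_uns, _, t_uns = fit_slda(docs, labels, V=8, K=1, max_iter=15, seed=1,
                                   supervised=False)
        np.testing.assert_allclose(m_sup.beta, m_uns.beta, atol=1e-8)
        assert_elbo_monotone(t_sup)
        assert_elbo_monotone(t_uns)

    def test_elbo_monotone_and_deterministic_on_planted_corpus(self):
        docs, labels, _, _, _ = make_slda_corpus(SLDASimSpec(n_docs=80, doc_length=30, seed=4))
        m1, s1, t1 = fit_slda(docs, labels, V=200, K=5, max_iter=25, seed=3)
        m2, s2, t2 = fit_slda(docs, labels, V=200, K=5, max_iter=25, seed=3)
        assert t1.elbo == t2.elbo
        np.testing.assert_array_equal(m1.beta, m2.beta)
        assert_elbo_monotone(t1)
        # simplex invariants
        np.testing.assert_allclose(m1.beta.sum(axis=1), 1.0, atol=1e-8)
        for st_ in s1[:10]:
            np.testing.assert_allclose(st_.phi.sum(axis=1), 1.0, atol=1e-8)
            assert st_.zbar.sum() == pytest.approx(1.0, abs=1e-8)

    def test_parameter_recovery_with_topic_matching(self):
        """Recovered topic-word distributions approach the planted ones."""
        docs, labels, true, _, _ = make_slda_corpus(SLDASimSpec(n_docs=300, doc_length=60, seed=8))
        model, _, trace = fit_slda(docs, labels, V=200, K=5, max_iter=60, seed=5)
        cost = np.array([[0.5 * np.abs(bf - bt).sum() for bt in true.beta] for bf in model.beta])
        r, c = linear_sum_assignment(cost)
        assert cost[r, c].mean() < 0.1
        assert_elbo_monotone(trace)

    def test_empty_document_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            fit_slda([np.array([1, 2]), np.array([], dtype=int)],
                     np.array([0, 1]), V=5, K=2)

    def test_single_class_labels_rejected(self, rng):
        docs = [rng.integers(0, 5, size=10) for _ in range(4)]
        with pytest.raises(ValueError, match="classes"):
            fit_slda(docs, np.zeros(4, dtype=int), V=5, K=2)


class TestInference:
    def test_pure_topic_document_concentrates(self):
        model = two_topic_model()
        # words 0,1 have 90% of topic-0 mass
        doc = np.array([0, 1, 0, 0, 1, 0, 1, 0])
        state = infer_document(model, doc)
        assert state.zbar[0] > 0.9

    def test_one_word_posterior_closed_form(self):
        """For a single word the update has an analytic fixed point.

        phi_k ∝ beta[k, w] * exp(digamma(alpha + phi_k)); we verify the
        returned phi satisfies it.
        """
        from scipy.special import digamma as dg
        model = two_topic_model()
        w = 2
        state = infer_document(model, np.array([w]), tol=1e-12)
        phi = state.phi[0]
        rhs = model.beta[:, w] * np.exp(dg(model.alpha + phi))
        np.testing.assert_allclose(phi, rhs / rhs.sum(), atol=1e-6)

    def test_duplicate_documents_get_identical_states(self):
        model = two_topic_model()
        doc = np.array([0, 3, 1, 2])
        s1 = infer_document(model, doc)
        s2 = infer_document(model, doc)
        np.testing.assert_array_equal(s1.phi, s2.phi)
        np.testing.assert_array_equal(s1.zbar, s2.zbar)

    def test_unknown_token_rejected(self):
        with pytest.raises(ValueError):
            infer_document(two_topic_model(), np.array([7]))


class TestPredictLabel:
    def test_zero_eta_gives_exact_uniform(self):
        model = two_topic_model()
        probs = predict_label(model, np.array([0, 1, 2, 3]))
        np.testing.assert_array_equal(probs, [0.5, 0.5])

    def test_discriminative_topic_pushes_probability(self):
        model = two_topic_model(eta1=5.0, eta2=-5.0)
        probs = predict_label(model, np.array([0, 0, 1, 0, 1]))  # topic-0 words
        assert probs[1] > 0.5
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_probabilities_equal_softmax_of_inferred_zbar(self):
        model = two_topic_model(eta1=1.0, eta2=-2.0)
        doc = np.array([0, 2, 1, 3, 0])
        state = infer_document(model, doc)
        expected = softmax(model.eta @ state.zbar)
        np.testing.assert_allclose(predict_label(model, doc), expected, atol=1e-10)
        # and the binary softmax is the logistic of the score difference
        score = model.eta[1] @ state.zbar
        assert expected[1] == pytest.approx(1.0 / (1.0 + np.exp(-score)), abs=1e-12)


class TestTopicReport:
    def test_hand_set_beta_word_order(self):
        beta = np.array([[0.5, 0.2, 0.2, 0.1]])
        model = SLDAModel(K=1, V=4, alpha=1.0, beta=beta, eta=np.zeros((2, 1)),
                          vocab_words=["dd", "bb", "aa", "cc"])
        rep = topic_report(model, [], top_m=3)
        # tie between bb/aa at 0.2 resolves lexicographically
        assert rep[0]["top_words"] == ["dd", "aa", "bb"]

    def test_zero_eta_orders_by_topic_index(self):
        model = planted_slda_model(SLDASimSpec(eta_pos=(0.0,) * 5))
        rep = topic_report(model, [])
        assert [r["topic"] for r in rep] == [0, 1, 2, 3, 4]
        assert all(r["coefficient"] == 0.0 for r in rep)

    def test_topics_sorted_by_coefficient(self):
        model = planted_slda_model(SLDASimSpec(eta_pos=(0.0, 2.0, -1.0, 0.5, 0.0)))
        rep = topic_report(model, [])
        assert [r["topic"] for r in rep] == [1, 3, 0, 4, 2]

    def test_prevalence_is_mean_zbar(self):
        from newsworthy import DocTopicState
        model = two_topic_model()
        states = [
            DocTopicState(theta_variational=np.ones(2), phi=np.array([[0.8, 0.2]]),
                          zbar=np.array([0.8, 0.2])),
            DocTopicState(theta_variational=np.ones(2), phi=np.array([[0.4, 0.6]]),
                          zbar=np.array([0.4, 0.6])),
        ]
        rep = topic_report(model, states)
        by_topic = {r["topic"]: r for r in rep}
        assert by_topic[0]["prevalence"] == pytest.approx(0.6)
        assert by_topic[1]["prevalence"] == pytest.approx(0.4)


def test_model_invariant_validation():
    bad_beta = np.array([[0.5, 0.4]])  # does not sum to 1
    with pytest.raises(ValueError):
        SLDAModel(K=1, V=2, alpha=1.0, beta=bad_beta, eta=np.zeros((2, 1)))
    with pytest.raises(ValueError, match="reference"):
        SLDAModel(K=1, V=2, alpha=1.0, beta=np.array([[0.5, 0.5]]),
                  eta=np.array([[1.0], [0.0]]))
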