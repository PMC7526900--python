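"""Collapsed Gibbs LDA: exact oracles, invariants, model selection."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp

import hictopics as ht
from hictopics import synthdata as sd
from hictopics.lda import log_likelihood, mean_pairwise_jsd, select_num_topics, train_lda

ALPHA, ETA = 0.8, 0.3

# tiny corpus: 2 cells x 3 LPs, 5 tokens -> 2^5 assignment states for T=2
TINY = np.array([[1, 1, 1], [1, 1, 0]], dtype=np.int8)
TINY_TOKENS = [(0, 0), (0, 1), (0, 2), (1, 0), (1, 1)]


def _counts_from_state(z, T, V):
    D = 1 + max(d for d, _ in TINY_TOKENS)
    C_ct = np.zeros((D, T), dtype=int)
    C_tl = np.zeros((T, V), dtype=int)
    for (d, w), t in zip(TINY_TOKENS, z):
        C_ct[d, t] += 1
        C_tl[t, w] += 1
    return C_ct, C_tl


def _sequential_predictive_loglik(z, T, V, alpha, eta):
    """Chain-rule evaluation of log P(w, z): product of Polya-urn
    predictive probabilities, an oracle independent of the closed form."""
    D = 1 + max(d for d, _ in TINY_TOKENS)
    C_ct = np.zeros((D, T))
    C_tl = np.zeros((T, V))
    C_t = np.zeros(T)
    n_d = np.zeros(D)
    ll = 0.0
    for (d, w), t in zip(TINY_TOKENS, z):
        ll += np.log((C_ct[d, t] + alpha) / (n_d[d] + T * alpha))
        ll += np.log((C_tl[t, w] + eta) / (C_t[t] + V * eta))
        C_ct[d, t] += 1
        C_tl[t, w] += 1
        C_t[t] += 1
        n_d[d] += 1
    return ll


def test_closed_form_likelihood_matches_sequential_oracle_on_all_states():
    """The collapsed joint evaluated from count matrices equals the
    chain-rule product over every one of the 2^5 assignment states."""
    for z in itertools.product(range(2), repeat=5):
        C_ct, C_tl = _counts_from_state(z, T=2, V=3)
        closed = log_likelihood(C_ct=C_ct, C_tl=C_tl, alpha=ALPHA, eta=ETA)
        seq = _sequential_predictive_loglik(z, T=2, V=3, alpha=ALPHA, eta=ETA)
        assert closed == pytest.approx(seq, rel=1e-10)


def test_sampler_draws_from_enumerated_posterior():
    """Final states of many independent short chains reproduce the exact
    posterior over all 32 assignment states of the tiny corpus."""
    states = list(itertools.product(range(2), repeat=5))
    logp = np.array(
        [
            log_likelihood(
                C_ct=_counts_from_state(z, 2, 3)[0],
                C_tl=_counts_from_state(z, 2, 3)[1],
                alpha=ALPHA,
                eta=ETA,
            )
            for z in states
        ]
    )
    post = np.exp(logp - logp.max())
    post /= post.sum()
    counts = dict.fromkeys(states, 0)
    n_chains = 1200
    for seed in range(n_chains):
        m = train_lda(
            sp.csr_matrix(TINY), 2, alpha=ALPHA, eta=ETA, n_iter=30, burnin=0, seed=seed
        )
        counts[tuple(int(t) for t in m.z)] += 1
    emp = np.array([counts[z] for z in states]) / n_chains
    tv = 0.5 * np.abs(emp - post).sum()
    assert tv < 0.12


def test_single_token_likelihood_is_log_inverse_vocab():
    ll = log_likelihood(
        C_ct=np.array([[1]]), C_tl=np.array([[1, 0, 0]]), alpha=0.7, eta=0.2
    )
    assert ll == pytest.approx(np.log(1 / 3))


def test_single_topic_degenerates_to_token_counts():
    X = sp.csr_matrix((np.random.default_rng(0).random((6, 12)) > 0.6).astype(np.int8))
    m = train_lda(X, 1, n_iter=5, burnin=1, seed=0)
    assert (m.z == 0).all()
    assert (m.C_ct[:, 0] == np.asarray(X.sum(axis=1)).ravel()).all()


def test_count_conservation_after_every_sweep():
    """Both count-matrix marginals are conserved whatever the sweep count."""
    X = sp.csr_matrix((np.random.default_rng(1).random((10, 30)) > 0.5).astype(np.int8))
    row_sums = np.asarray(X.sum(axis=1)).ravel()
    for n_iter in (1, 2, 3, 7, 20):
        m = train_lda(X, 3, n_iter=n_iter, burnin=0, seed=4)
        assert (m.C_ct.sum(axis=1) == row_sums).all()
        assert (m.C_tl.sum(axis=1) == m.C_ct.sum(axis=0)).all()
        assert (m.C_ct >= 0).all() and (m.C_tl >= 0).all()


def test_seeded_determinism():
    X = sp.csr_matrix((np.random.default_rng(2).random((8, 40)) > 0.5).astype(np.int8))
    a = train_lda(X, 4, n_iter=50, burnin=10, seed=123)
    b = train_lda(X, 4, n_iter=50, burnin=10, seed=123)
    assert (a.z == b.z).all()
    assert (a.C_tl == b.C_tl).all()
    assert np.allclose(a.loglik_trace, b.loglik_trace)
    c = train_lda(X, 4, n_iter=50, burnin=10, seed=124)
    assert not (a.z == c.z).all()


def test_topic_label_permutation_invariance():
    X = sp.csr_matrix((np.random.default_rng(3).random((8, 40)) > 0.5).astype(np.int8))
    m = train_lda(X, 4, n_iter=30, burnin=0, seed=0)
    perm = np.array([2, 0, 3, 1])
    ll = log_likelihood(C_ct=m.C_ct, C_tl=m.C_tl, alpha=m.alpha, eta=m.eta)
    ll_p = log_likelihood(
        C_ct=m.C_ct[:, perm], C_tl=m.C_tl[perm], alpha=m.alpha, eta=m.eta
    )
    assert ll == pytest.approx(ll_p)
    assert mean_pairwise_jsd(m.C_tl) == pytest.approx(mean_pairwise_jsd(m.C_tl[perm]))


def test_trace_improves_from_random_start():
    sizes, bins, vocab = sd.make_toy_genome(1, 20_000_000, 500_000, 5_000_000)
    lbt, switch = sd.simulate_compartments(bins, 2, 5, 0.4, seed=0)
    topics, tt = sd.simulate_topics(vocab, lbt, switch, seed=1)
    cells, labels, _ = sd.simulate_cells(vocab, topics, tt, 30, 200, seed=2)
    mat, _ = ht.build_cell_lp_matrix(cells, vocab, bins)
    m = train_lda(mat, 4, n_iter=100, burnin=0, seed=0)
    assert np.mean(m.loglik_trace[-50:]) >= np.mean(m.loglik_trace[:10])


def test_mean_jsd_requires_positive_topics():
    with pytest.raises(ValueError):
        mean_pairwise_jsd(np.array([[1.0, 0.0], [0.0, 0.0]]))
    with pytest.raises(ValueError):
        mean_pairwise_jsd(np.array([[1.0, 1.0]]))


def test_train_rejects_bad_arguments():
    X = sp.csr_matrix(np.ones((2, 3), dtype=np.int8))
    with pytest.raises(ValueError):
        train_lda(X, 0)
    with pytest.raises(ValueError):
        train_lda(X, 2, n_iter=10, burnin=10)
    with pytest.raises(ValueError):
        train_lda(sp.csr_matrix((2, 3), dtype=np.int8), 2)


class TestSelectNumTopics:
    def test_planted_topic_number_recovered(self):
        """Grid {2, 6, 12} on a corpus planted with 6 well-separated topics
        selects 6 by embedding silhouette."""
        sizes, bins, vocab = sd.make_toy_genome(2, 30_000_000, 500_000, 10_000_000)
        lbt, switch = sd.simulate_compartments(bins, 3, 10, 0.5, seed=3)
        topics, tt = sd.simulate_topics(
            vocab, lbt, switch, n_general=0, n_specific_per_type=2, seed=4
        )
        assert topics.shape[0] == 6
        cells, labels, _ = sd.simulate_cells(vocab, topics, tt, 60, 500, seed=5)
        mat, _ = ht.build_cell_lp_matrix(cells, vocab, bins)
        y = [labels[c] for c in mat.cell_ids]
        models, embeddings = [], []
        for T in (2, 6, 12):
            m = train_lda(mat, T, alpha=1.0, n_iter=300, burnin=150, seed=1, init="kmeans")
            models.append(m)
            norm = m.C_ct / np.maximum(m.C_ct.sum(axis=1, keepdims=True), 1)
            embeddings.append(ht.embed_2d(norm, "pca", seed=0).coords)
        best, table = select_num_topics(models, embeddings, y)
        assert best == 6
        assert set(table.columns) >= {"n_topics", "log_likelihood", "mean_jsd", "silhouette"}

    def test_dominating_model_chosen_and_ties_prefer_smaller(self):
        rng = np.random.default_rng(0)
        X = sp.csr_matrix((rng.random((12, 30)) > 0.5).astype(np.int8))
        m2 = train_lda(X, 2, n_iter=20, burnin=5, seed=0)
        m3 = train_lda(X, 3, n_iter=20, burnin=5, seed=0)
        labels = ["a"] * 6 + ["b"] * 6
        tight = np.vstack([np.zeros((6, 2)), np.ones((6, 2)) * 10])
        tight = tight + rng.normal(0, 0.01, tight.shape)
        loose = rng.normal(0, 1, (12, 2))
        best, _ = select_num_topics([m2, m3], [tight, loose], labels)
        assert best == 2  # dominating silhouette
        best_tie, _ = select_num_topics([m2, m3], [tight, tight], labels)
        assert best_tie == 2  # exact tie broken toward smaller T

    def test_requires_two_models_and_two_classes(self):
        X = sp.csr_matrix(np.ones((4, 6), dtype=np.int8))
        m = train_lda(X, 2, n_iter=5, burnin=1, seed=0)
        with pytest.raises(ValueError):
            select_num_topics([m], [np.zeros((4, 2))], ["a", "a", "b", "b"])
        with pytest.raises(ValueError):
            select_num_topics([m, m], [np.zeros((4, 2))] * 2, ["a"] * 4)
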