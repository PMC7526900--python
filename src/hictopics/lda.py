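"""Latent Dirichlet allocation by collapsed Gibbs sampling.

The binarized cell-by-locus-pair matrix is treated as a corpus: each cell is
a document and each observed locus pair a word token (binary input means at
most one token per (cell, LP) entry, so the sampler iterates the nonzero
entries only).  The sampler integrates out the topic mixtures and topic-word
distributions and resamples each token's topic from the standard collapsed
full conditional

    p(z = t | rest)  ∝  (C_ct[c,t] + alpha) * (C_tl[t,l] + eta) / (C_t[t] + V*eta)

with the token's own assignment removed from the counts.

Hyperparameter defaults are alpha = 50/T and eta = 0.1.  Estimates are taken
from the final state's count matrices; ``average=True`` additionally
accumulates post-burn-in means.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from numba import njit
from scipy.special import gammaln

from .lp_matrix import CellLPMatrix
from .stats import jensen_shannon_divergence

__all__ = [
    "LDAModel",
    "train_lda",
    "log_likelihood",
    "mean_pairwise_jsd",
    "select_num_topics",
]


@njit(cache=False)
def _loglik_counts(C_ct, C_tl, C_t, n_d, alpha, eta):
    D, T = C_ct.shape
    V = C_tl.shape[1]
    ll = 0.0
    lg_alpha = math.lgamma(alpha)
    lg_eta = math.lgamma(eta)
    for d in range(D):
        ll += math.lgamma(T * alpha) - math.lgamma(n_d[d] + T * alpha)
        for t in range(T):
            ll += math.lgamma(C_ct[d, t] + alpha) - lg_alpha
    for t in range(T):
        ll += math.lgamma(V * eta) - math.lgamma(C_t[t] + V * eta)
        for w in range(V):
            ll += math.lgamma(C_tl[t, w] + eta) - lg_eta
    return ll


@njit(cache=False)
def _run_gibbs(doc_ids, word_ids, z, C_ct, C_tl, C_t, n_d, V,
               alpha, eta, n_iter, burnin, seed, average):
    np.random.seed(seed)
    T = C_t.shape[0]
    N = doc_ids.size
    trace = np.empty(n_iter)
    cumprob = np.empty(T)
    avg_ct = np.zeros(C_ct.shape)
    avg_tl = np.zeros(C_tl.shape)
    n_avg = 0
    for sweep in range(n_iter):
        for n in range(N):
            d = doc_ids[n]
            w = word_ids[n]
            told = z[n]
            C_ct[d, told] -= 1
            C_tl[told, w] -= 1
            C_t[told] -= 1
            tot = 0.0
            for t in range(T):
                tot += (C_ct[d, t] + alpha) * (C_tl[t, w] + eta) / (C_t[t] + V * eta)
                cumprob[t] = tot
            u = np.random.random() * tot
            tnew = 0
            while cumprob[tnew] < u:
                tnew += 1
            z[n] = tnew
            C_ct[d, tnew] += 1
            C_tl[tnew, w] += 1
            C_t[tnew] += 1
        trace[sweep] = _loglik_counts(C_ct, C_tl, C_t, n_d, alpha, eta)
        if average and sweep >= burnin:
            avg_ct += C_ct
            avg_tl += C_tl
            n_avg += 1
    if n_avg > 0:
        avg_ct /= n_avg
        avg_tl /= n_avg
    return trace, avg_ct, avg_tl


@dataclass
class LDAModel:
    """State of a collapsed-Gibbs LDA run.

    ``C_ct`` (cells x T) and ``C_tl`` (T x V) are the topic-assignment count
    matrices of the final state; their marginals are conserved: each row of
    ``C_ct`` sums to the cell's token count and each row sum of ``C_tl``
    equals the corresponding column sum of ``C_ct``.
    """

    n_topics: int
    alpha: float
    eta: float
    C_ct: np.ndarray
    C_tl: np.ndarray
    z: np.ndarray
    doc_ids: np.ndarray
    word_ids: np.ndarray
    cell_ids: list[str]
    vocab_size: int
    loglik_trace: np.ndarray
    seed: int
    n_iter: int
    burnin: int
    avg_C_ct: np.ndarray | None = None
    avg_C_tl: np.ndarray | None = None

    @property
    def topic_totals(self) -> np.ndarray:
        return self.C_tl.sum(axis=1)

    def save(self, directory: str | Path) -> None:
        from scipy.io import mmwrite

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        mmwrite(directory / "cell_topic.mtx", sp.coo_matrix(self.C_ct))
        mmwrite(directory / "topic_lp.mtx", sp.coo_matrix(self.C_tl))
        (directory / "cells.txt").write_text("\n".join(self.cell_ids) + "\n")
        meta = {
            "n_topics": self.n_topics,
            "alpha": self.alpha,
            "eta": self.eta,
            "seed": self.seed,
            "n_iter": self.n_iter,
            "burnin": self.burnin,
            "vocab_size": self.vocab_size,
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
        np.savetxt(
            directory / "loglik_trace.tsv",
            np.column_stack([np.arange(self.n_iter), self.loglik_trace]),
            fmt=("%d", "%.6f"),
            delimiter="\t",
            header="iteration\tlog_likelihood",
            comments="",
        )


def _initial_assignments(
    X: sp.spmatrix, doc_ids: np.ndarray, n_topics: int, init: str, seed: int
) -> np.ndarray:
    """Initial token-topic assignments: uniform random or k-means informed.

    ``"kmeans"`` clusters the cells (rows) in a low-dimensional PCA space
    into ``n_topics`` groups and starts every token of a cell in its
    cluster's topic; the sampler then refines the state.  On sparse binary
    corpora this avoids the slowly-mixing regime where random-start chains
    merge related topics.
    """
    rng = np.random.default_rng(seed)
    if init == "random":
        return rng.integers(0, n_topics, size=doc_ids.size).astype(np.int64)
    if init == "kmeans":
        from sklearn.cluster import KMeans
        from sklearn.decomposition import PCA

        D, V = X.shape
        dense = X.toarray().astype(float)
        n_comp = min(10, D - 1, V - 1, n_topics + 2)
        pcs = PCA(n_components=max(1, n_comp), random_state=seed).fit_transform(dense)
        k = min(n_topics, D)
        clusters = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(pcs)
        return clusters[doc_ids].astype(np.int64)
    raise ValueError(f"unknown init {init!r}")


def train_lda(
    matrix: CellLPMatrix | sp.spmatrix,
    n_topics: int,
    alpha: float | None = None,
    eta: float = 0.1,
    n_iter: int = 500,
    burnin: int = 250,
    seed: int = 0,
    average: bool = False,
    init: str = "random",
) -> LDAModel:
    """Fit LDA to a binarized cell-LP matrix by collapsed Gibbs sampling.

    ``alpha`` defaults to 50 / n_topics.  The run is fully reproducible
    given ``seed``.  ``init="kmeans"`` starts the chain from a cell-cluster
    state instead of a uniform random assignment (see
    :func:`_initial_assignments`); recommended when distinct topics load on
    overlapping cell populations.
    """
    if n_topics < 1:
        raise ValueError(f"n_topics must be >= 1, got {n_topics}")
    if not n_iter > burnin >= 0:
        raise ValueError("require n_iter > burnin >= 0")
    if isinstance(matrix, CellLPMatrix):
        X = matrix.matrix
        cell_ids = list(matrix.cell_ids)
    else:
        X = sp.csr_matrix(matrix)
        cell_ids = [f"cell{i}" for i in range(X.shape[0])]
    coo = X.tocoo()
    if coo.nnz == 0:
        raise ValueError("matrix has no nonzero entries")
    order = np.lexsort((coo.col, coo.row))
    doc_ids = coo.row[order].astype(np.int64)
    word_ids = coo.col[order].astype(np.int64)
    D, V = X.shape
    if alpha is None:
        alpha = 50.0 / n_topics

    z = _initial_assignments(X, doc_ids, n_topics, init, seed)
    C_ct = np.zeros((D, n_topics), dtype=np.int64)
    C_tl = np.zeros((n_topics, V), dtype=np.int64)
    C_t = np.zeros(n_topics, dtype=np.int64)
    np.add.at(C_ct, (doc_ids, z), 1)
    np.add.at(C_tl, (z, word_ids), 1)
    np.add.at(C_t, z, 1)
    n_d = np.bincount(doc_ids, minlength=D).astype(np.int64)

    trace, avg_ct, avg_tl = _run_gibbs(
        doc_ids, word_ids, z, C_ct, C_tl, C_t, n_d, V,
        float(alpha), float(eta), int(n_iter), int(burnin),
        int(seed) % (2**31), 1 if average else 0,
    )
    return LDAModel(
        n_topics=n_topics,
        alpha=float(alpha),
        eta=float(eta),
        C_ct=C_ct,
        C_tl=C_tl,
        z=z,
        doc_ids=doc_ids,
        word_ids=word_ids,
        cell_ids=cell_ids,
        vocab_size=V,
        loglik_trace=trace,
        seed=int(seed),
        n_iter=int(n_iter),
        burnin=int(burnin),
        avg_C_ct=avg_ct if average else None,
        avg_C_tl=avg_tl if average else None,
    )


def log_likelihood(
    model: LDAModel | None = None,
    *,
    C_ct: np.ndarray | None = None,
    C_tl: np.ndarray | None = None,
    alpha: float | None = None,
    eta: float | None = None,
) -> float:
    """Collapsed joint log P(w, z | alpha, eta) of an assignment state.

    Closed form: a product of Dirichlet-multinomial normalizers over
    documents (topic mixtures integrated out) and over topics (word
    distributions integrated out).  Accepts either a trained model or raw
    count matrices.
    """
    if model is not None:
        C_ct, C_tl = model.C_ct, model.C_tl
        alpha, eta = model.alpha, model.eta
    C_ct = np.asarray(C_ct, dtype=float)
    C_tl = np.asarray(C_tl, dtype=float)
    D, T = C_ct.shape
    V = C_tl.shape[1]
    n_d = C_ct.sum(axis=1)
    C_t = C_tl.sum(axis=1)
    ll = float(
        D * gammaln(T * alpha)
        - gammaln(n_d + T * alpha).sum()
        + gammaln(C_ct + alpha).sum()
        - D * T * gammaln(alpha)
    )
    ll += float(
        T * gammaln(V * eta)
        - gammaln(C_t + V * eta).sum()
        + gammaln(C_tl + eta).sum()
        - T * V * gammaln(eta)
    )
    return ll


def mean_pairwise_jsd(model: LDAModel | np.ndarray) -> float:
    """Mean base-2 Jensen-Shannon divergence over all unordered topic pairs.

    Each topic's locus-pair counts are normalized to a distribution first.
    A low mean indicates redundant topics (too many T); the value lies in
    [0, 1] exactly because base-2 logarithms are used.
    """
    C_tl = model.C_tl if isinstance(model, LDAModel) else np.asarray(model, dtype=float)
    T = C_tl.shape[0]
    if T < 2:
        raise ValueError("need at least two topics")
    totals = C_tl.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("a topic has zero total assignments")
    dists = C_tl / totals[:, None]
    vals = [
        jensen_shannon_divergence(dists[a], dists[b], base=2.0)
        for a in range(T)
        for b in range(a + 1, T)
    ]
    return float(np.mean(vals))


def select_num_topics(
    models: Sequence[LDAModel],
    embeddings: Sequence[np.ndarray],
    labels: Sequence,
):
    """Model selection over a grid of topic counts.

    For every fitted model the final-state log-likelihood, the mean pairwise
    topic JSD, and the average silhouette of the supplied 2-D embedding
    under the given labels are tabulated.  The chosen T is the silhouette
    argmax (the likelihood and JSD columns bracket the plausible range);
    ties break toward smaller T (parsimony).

    Returns ``(best_T, table)`` where table is a pandas DataFrame.
    """
    import pandas as pd

    from .evaluate import silhouette

    if len(models) < 2:
        raise ValueError("need at least two fitted models to select among")
    if len(models) != len(embeddings):
        raise ValueError("one embedding per model required")
    if len(set(labels)) < 2:
        raise ValueError("silhouette needs at least two label classes")
    rows = []
    for model, emb in zip(models, embeddings):
        sil = silhouette(np.asarray(emb), labels)
        rows.append(
            {
                "n_topics": model.n_topics,
                "log_likelihood": log_likelihood(model),
                "mean_jsd": mean_pairwise_jsd(model) if model.n_topics >= 2 else np.nan,
                "silhouette": sil.overall,
            }
        )
    table = pd.DataFrame(rows).sort_values("n_topics").reset_index(drop=True)
    best = table.loc[table["silhouette"].idxmax(), "n_topics"]
    # idxmax returns the first maximum; with the table sorted ascending by T
    # this already breaks ties toward smaller T
    return int(best), table
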