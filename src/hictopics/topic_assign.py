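"""Topic specificity: topics -> cell types, locus pairs -> topics.

Two post-hoc assignments are made from the fitted model's count matrices.

Topics to cell types: per-topic assignment counts are normalized within each
topic (column-stochastic over cells), grouped by cell-type label, and a
candidate type must beat every other type in a one-sided two-sample
Wilcoxon rank-sum test (BH-corrected across the full family of topic x pair
tests, all adjusted p < alpha) and carry a mean normalized contribution at
least ``ratio_min`` times the second-highest type's mean.

Locus pairs to topics: topic rows are normalized (beta), converted to the
score

    P[l,t] = beta[l,t] * (ln beta[l,t] - mean_t ln beta[l,t])

min-max rescaled per topic, and a two-parameter gamma distribution is fitted
to each topic's positive scores; locus pairs scoring above the 99.75th
percentile of the fitted gamma are assigned to the topic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .genome import LPVocabulary
from .stats import bh_adjust

__all__ = [
    "normalize_cell_topics",
    "TopicCellTypeAssignment",
    "assign_topics_to_cell_types",
    "TopicLPScores",
    "lp_scores",
    "fit_gamma_threshold",
    "TopicLPAssignment",
    "assign_lps_to_topics",
    "topic_lp_distance_profile",
]


def normalize_cell_topics(C_ct: np.ndarray) -> np.ndarray:
    """Divide each topic's assignment counts by that topic's total.

    Returns a column-stochastic cells x T matrix (each topic column sums to
    one over cells).
    """
    C = np.asarray(C_ct, dtype=float)
    totals = C.sum(axis=0)
    if np.any(totals <= 0):
        bad = np.where(totals <= 0)[0]
        raise ValueError(f"topics with zero total assignments: {bad.tolist()}")
    return C / totals


@dataclass
class TopicCellTypeAssignment:
    """Per-topic cell-type assignment with the full test table."""

    assignment: dict[int, str | None]
    table: pd.DataFrame  # topic, candidate, other, pvalue, pvalue_adj
    ratios: dict[int, float]

    def assigned(self) -> dict[int, str]:
        return {t: c for t, c in self.assignment.items() if c is not None}


def assign_topics_to_cell_types(
    norm_matrix: np.ndarray,
    cell_labels: Sequence[str],
    alpha: float = 0.01,
    ratio_min: float = 1.5,
) -> TopicCellTypeAssignment:
    """Assign each topic to at most one cell type.

    For each topic the candidate is the type with the highest mean
    normalized contribution; it is tested against every other type with a
    one-sided Mann-Whitney (Wilcoxon rank-sum) test, alternative: candidate
    stochastically greater.  scipy's implementation enumerates the exact
    null for small untied samples and otherwise uses the tie- and
    continuity-corrected normal approximation.  BH correction pools the
    whole (topic x pair) family.
    """
    X = np.asarray(norm_matrix, dtype=float)
    labels = np.asarray(cell_labels)
    if X.shape[0] != labels.size:
        raise ValueError("one label per cell required")
    types = sorted(set(labels.tolist()))
    if len(types) < 2:
        raise ValueError("need at least two cell types")
    for ct in types:
        if not np.any(labels == ct):
            raise ValueError(f"cell type {ct!r} has zero cells")

    T = X.shape[1]
    rows = []
    ratios: dict[int, float] = {}
    candidates: dict[int, str] = {}
    for t in range(T):
        means = {ct: float(X[labels == ct, t].mean()) for ct in types}
        cand = max(means, key=means.get)
        second = max(v for ct, v in means.items() if ct != cand)
        ratios[t] = means[cand] / second if second > 0 else float("inf")
        candidates[t] = cand
        cand_vals = X[labels == cand, t]
        for other in types:
            if other == cand:
                continue
            res = st.mannwhitneyu(cand_vals, X[labels == other, t], alternative="greater")
            rows.append(
                {"topic": t, "candidate": cand, "other": other, "pvalue": float(res.pvalue)}
            )
    table = pd.DataFrame(rows)
    table["pvalue_adj"] = bh_adjust(table["pvalue"].to_numpy())

    assignment: dict[int, str | None] = {}
    for t in range(T):
        sub = table[table["topic"] == t]
        ok = bool((sub["pvalue_adj"] < alpha).all()) and ratios[t] >= ratio_min
        assignment[t] = candidates[t] if ok else None
    return TopicCellTypeAssignment(assignment=assignment, table=table, ratios=ratios)


@dataclass
class TopicLPScores:
    """Topic-normalized locus-pair scores.

    beta: T x V row-stochastic contributions; P: transformed probabilities;
    P_norm: per-topic min-max rescale of P into [0, 1].
    """

    beta: np.ndarray
    P: np.ndarray
    P_norm: np.ndarray


def lp_scores(C_tl: np.ndarray) -> TopicLPScores:
    """Transform topic-LP counts to per-topic normalized scores.

    Zero entries of beta are replaced by the smallest positive beta in the
    same topic row before taking logarithms (log 0 is undefined); the
    transform is invariant to rescaling any count row by a positive
    constant.
    """
    C = np.asarray(C_tl, dtype=float)
    totals = C.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("a topic row has zero total")
    beta = C / totals[:, None]
    beta_safe = beta.copy()
    for t in range(beta.shape[0]):
        pos = beta[t][beta[t] > 0]
        beta_safe[t][beta[t] == 0] = pos.min()
    logb = np.log(beta_safe)
    P = beta_safe * (logb - logb.mean(axis=0))
    lo = P.min(axis=1, keepdims=True)
    hi = P.max(axis=1, keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    P_norm = (P - lo) / span
    return TopicLPScores(beta=beta, P=P, P_norm=P_norm)


def fit_gamma_threshold(scores: np.ndarray, percentile: float = 99.75) -> float:
    """Gamma-quantile cutoff for one topic's scores.

    A two-parameter gamma (shape, scale; location fixed at zero) is fitted
    by maximum likelihood to the strictly positive scores and the inverse
    CDF at ``percentile``/100 is returned.
    """
    if not 0 <= percentile <= 100:
        raise ValueError(f"percentile must be in [0, 100], got {percentile}")
    x = np.asarray(scores, dtype=float)
    x = x[x > 0]
    if x.size < 50:
        raise ValueError(f"need at least 50 positive scores, got {x.size}")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate input: all scores equal")
    if percentile == 0:
        return 0.0
    shape, _, scale = st.gamma.fit(x, floc=0)
    thr = float(st.gamma.ppf(percentile / 100.0, shape, scale=scale))
    if not np.isfinite(thr) and percentile < 100:
        raise RuntimeError("gamma fit did not produce a finite threshold")
    return thr


@dataclass
class TopicLPAssignment:
    """Per-topic sets of assigned locus-pair column indices."""

    lps: dict[int, np.ndarray]
    thresholds: dict[int, float]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "topic": list(self.lps),
                "threshold": [self.thresholds[t] for t in self.lps],
                "n_lps": [len(v) for v in self.lps.values()],
            }
        )

    def all_assigned(self) -> np.ndarray:
        """Union of assigned LP columns over all topics."""
        if not self.lps:
            return np.empty(0, dtype=int)
        return np.unique(np.concatenate([v for v in self.lps.values()]))


def assign_lps_to_topics(
    scores: TopicLPScores, percentile: float = 99.75
) -> TopicLPAssignment:
    """Assign to each topic the locus pairs scoring above its gamma cutoff."""
    lps: dict[int, np.ndarray] = {}
    thresholds: dict[int, float] = {}
    for t in range(scores.P_norm.shape[0]):
        thr = fit_gamma_threshold(scores.P_norm[t], percentile=percentile)
        thresholds[t] = thr
        lps[t] = np.where(scores.P_norm[t] > thr)[0]
    return TopicLPAssignment(lps=lps, thresholds=thresholds)


def topic_lp_distance_profile(
    assignment: TopicLPAssignment, vocab: LPVocabulary, topic: int
) -> tuple[np.ndarray, float]:
    """Distance histogram and mean separation of a topic's locus pairs.

    Returns (hist, mean_bp) where hist[d] counts assigned pairs at bin
    separation d (index 0 unused) and mean_bp is the mean genomic
    separation.
    """
    cols = assignment.lps.get(topic)
    if cols is None or len(cols) == 0:
        raise ValueError(f"topic {topic} has no assigned locus pairs")
    sep = (vocab.bin_j[cols] - vocab.bin_i[cols]).astype(int)
    hist = np.bincount(sep, minlength=vocab.max_bin_distance + 1)
    mean_bp = float(sep.mean() * vocab.resolution)
    return hist, mean_bp


def export_topic_lps_bedpe(
    assignment: TopicLPAssignment,
    scores: TopicLPScores,
    vocab: LPVocabulary,
    path,
) -> None:
    """Write topic -> locus-pair sets as BEDPE with the topic and score."""
    res = vocab.resolution
    with open(path, "w") as fh:
        for t, cols in assignment.lps.items():
            for k in cols:
                c, i, j = vocab.lp_at(int(k))
                fh.write(
                    f"{c}\t{i * res}\t{(i + 1) * res}\t{c}\t{j * res}\t{(j + 1) * res}"
                    f"\ttopic{t}\t{scores.P_norm[t, k]:.6f}\n"
                )
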