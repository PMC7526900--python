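"""A/B compartment calling and topic-compartment enrichment statistics.

Compartments are called per cell type from bulk (or aggregated single-cell)
intra-chromosomal contact matrices: ICE balancing, distance-effect removal
(observed/expected), Spearman correlation of the O/E rows, eigendecomposition,
and per-chromosome selection of the first or second eigenvector by its
correlation with gene density.  The eigenvector sign is oriented so that
positive values (A, gene-dense/active) correlate positively with gene
density; negative values are B (inactive).

Downstream, each vocabulary locus pair receives an AA/AB/BB label from its
two end bins, compartment *switching regions* are bins where one cell type
disagrees with the unanimous call of all the others, and chi-square /
Fisher statistics quantify how strongly topic-associated locus pairs are
enriched for particular compartment configurations and switch regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .genome import BinTable, LPVocabulary
from .stats import bh_adjust

__all__ = [
    "ice_normalize",
    "oe_normalize",
    "CompartmentCalls",
    "call_compartments",
    "gene_density",
    "label_lp_compartments",
    "EnrichmentResult",
    "topic_compartment_enrichment",
    "SwitchRegions",
    "find_switch_regions",
    "switch_enrichment",
    "transition_direction_enrichment",
    "de_gene_bta_enrichment",
]


def ice_normalize(
    matrix: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-5,
    mask_percentile: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Iterative correction (matrix balancing) of a symmetric contact matrix.

    Bins with zero marginal, and bins whose marginal falls below the given
    percentile of positive marginals, are masked and excluded from
    balancing.  Bias factors are updated until the coefficient of variation
    of the unmasked row sums drops below ``tol`` or ``max_iter`` is reached.

    Returns ``(balanced, bias, mask)`` where ``balanced = M / (b b^T)`` on
    unmasked entries (zero elsewhere) and ``mask`` is True for excluded bins.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(M, M.T, atol=1e-8 * max(1.0, np.abs(M).max())):
        raise ValueError("matrix is not symmetric")
    if np.any(M < 0):
        raise ValueError("matrix has negative entries")
    marg = M.sum(axis=1)
    if np.all(marg == 0):
        raise ValueError("all-zero matrix cannot be balanced")
    pos = marg[marg > 0]
    # only genuinely low-coverage bins are masked: below the percentile AND
    # below half the median marginal, so a nearly-uniform (e.g. already
    # balanced) matrix masks nothing and balancing stays idempotent
    cutoff = min(np.percentile(pos, mask_percentile), 0.5 * np.median(pos))
    mask = (marg == 0) | (marg < cutoff)
    keep = ~mask

    bias = np.ones(M.shape[0])
    W = M.copy()
    W[mask, :] = 0.0
    W[:, mask] = 0.0
    for _ in range(max_iter):
        s = W.sum(axis=1)
        sk = s[keep]
        mean = sk.mean()
        if mean == 0:
            raise ValueError("balancing degenerated to zero row sums")
        cv = sk.std() / mean
        if cv < tol:
            break
        upd = np.ones_like(s)
        upd[keep] = s[keep] / mean
        upd[upd == 0] = 1.0
        bias *= upd
        W = M / np.outer(bias, bias)
        W[mask, :] = 0.0
        W[:, mask] = 0.0
    return W, bias, mask


def oe_normalize(balanced: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Remove the genomic-distance effect from a balanced matrix.

    Each entry is divided by the mean of its diagonal (same |i - j|)
    computed over unmasked pairs; entries on diagonals with zero mean, and
    masked entries, become NaN.  By construction the mean of every O/E
    diagonal over unmasked pairs is 1.
    """
    W = np.asarray(balanced, dtype=float)
    n = W.shape[0]
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    keep = ~mask
    oe = np.full_like(W, np.nan)
    for d in range(n):
        i = np.arange(n - d)
        j = i + d
        ok = keep[i] & keep[j]
        if not ok.any():
            continue
        m = W[i[ok], j[ok]].mean()
        if m == 0:
            continue
        oe[i[ok], j[ok]] = W[i[ok], j[ok]] / m
        oe[j[ok], i[ok]] = oe[i[ok], j[ok]]
    return oe


@dataclass
class CompartmentCalls:
    """Per-bin A/B labels for one cell type.

    ``labels[chrom]`` is an array of 'A' / 'B' / 'NA' strings;
    ``eigvec[chrom]`` holds the oriented eigenvector values (NaN on masked
    bins); ``ev_choice[chrom]`` records whether eigenvector 1 or 2 was used.
    """

    labels: dict[str, np.ndarray]
    eigvec: dict[str, np.ndarray] = field(default_factory=dict)
    ev_choice: dict[str, int] = field(default_factory=dict)
    ambiguous: set[str] = field(default_factory=set)

    def to_bed(self, path, resolution: int) -> None:
        with open(path, "w") as fh:
            for chrom, labs in self.labels.items():
                ev = self.eigvec.get(chrom)
                for b, lab in enumerate(labs):
                    v = ev[b] if ev is not None else float("nan")
                    fh.write(
                        f"{chrom}\t{b * resolution}\t{(b + 1) * resolution}\t{lab}\t{v:.6g}\n"
                    )


def call_compartments(
    oe_by_chrom: Mapping[str, np.ndarray],
    gene_density_by_chrom: Mapping[str, np.ndarray],
) -> CompartmentCalls:
    """Call A/B compartments per chromosome from O/E matrices.

    The Spearman correlation matrix of the O/E rows (restricted to bins
    with data) is eigendecomposed; of the top two eigenvectors, the one
    with larger |Spearman correlation| to gene density is chosen and
    oriented so that gene-dense bins score positive (A).  A chromosome
    with uniform gene density is flagged ambiguous and its labels are
    returned unoriented with a warning.  Chromosomes with fewer than three
    informative bins yield all-NA labels.
    """
    calls = CompartmentCalls(labels={})
    for chrom, oe in oe_by_chrom.items():
        gd = np.asarray(gene_density_by_chrom[chrom], dtype=float)
        n = oe.shape[0]
        if gd.size != n:
            raise ValueError(f"gene density not aligned to bins on {chrom}")
        labels = np.full(n, "NA", dtype="<U2")
        ev_full = np.full(n, np.nan)
        valid = ~np.all(np.isnan(oe), axis=1)
        if valid.sum() < 3:
            calls.labels[chrom] = labels
            calls.eigvec[chrom] = ev_full
            calls.ev_choice[chrom] = 0
            continue
        sub = oe[np.ix_(valid, valid)]
        sub = np.where(np.isnan(sub), np.nanmean(sub), sub)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=st.ConstantInputWarning)
            corr = st.spearmanr(sub, axis=1).statistic
        corr = np.atleast_2d(np.nan_to_num(corr, nan=0.0))
        evals, evecs = np.linalg.eigh(corr)
        top = evecs[:, [-1, -2]]  # eigenvectors of the two largest eigenvalues
        gdv = gd[valid]
        if np.allclose(gdv, gdv[0]):
            warnings.warn(
                f"{chrom}: uniform gene density, compartment orientation ambiguous"
            )
            calls.ambiguous.add(chrom)
            chosen, which, rho = top[:, 0], 1, 1.0
        else:
            rhos = []
            for k in range(2):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", category=st.ConstantInputWarning)
                    r = st.spearmanr(top[:, k], gdv).statistic
                rhos.append(0.0 if np.isnan(r) else r)
            which = int(np.argmax(np.abs(rhos))) + 1
            rho = rhos[which - 1]
            chosen = top[:, which - 1]
            if np.abs(rho) < 0.25:
                # neither eigenvector tracks gene density: no compartment
                # structure to orient (e.g. a flat O/E matrix)
                warnings.warn(
                    f"{chrom}: eigenvectors nearly uncorrelated with gene "
                    "density, compartment calls ambiguous"
                )
                calls.ambiguous.add(chrom)
        if rho < 0:
            chosen = -chosen
        ev_full[valid] = chosen
        labels[valid] = np.where(chosen > 0, "A", np.where(chosen < 0, "B", "NA"))
        calls.labels[chrom] = labels
        calls.eigvec[chrom] = ev_full
        calls.ev_choice[chrom] = which
    return calls


def gene_density(
    bins: BinTable, intervals: pd.DataFrame | Sequence[tuple[str, int, int]]
) -> dict[str, np.ndarray]:
    """Count gene intervals overlapping each bin (any overlap counts).

    A gene spanning several bins is counted in each of them, so per-genome
    totals can exceed the number of genes.  ``intervals`` is a BED-like
    table with columns (chrom, start, end), 0-based half-open.
    """
    if isinstance(intervals, pd.DataFrame):
        it = intervals.iloc[:, :3].itertuples(index=False)
    else:
        it = iter(intervals)
    counts = {c: np.zeros(bins.n_bins[c], dtype=int) for c in bins.chroms}
    res = bins.resolution
    for chrom, start, end in it:
        if chrom not in counts:
            raise ValueError(f"interval on unknown chromosome {chrom!r}")
        start, end = int(start), int(end)
        if end <= start or start < 0:
            raise ValueError(f"malformed interval {chrom}:{start}-{end}")
        b0 = start // res
        b1 = min((end - 1) // res, bins.n_bins[chrom] - 1)
        counts[chrom][b0 : b1 + 1] += 1
    return counts


def label_lp_compartments(vocab: LPVocabulary, calls: CompartmentCalls) -> np.ndarray:
    """AA/AB/BB/NA label for every vocabulary locus pair in one cell type.

    Orientation-free: (A, B) and (B, A) both map to "AB"; if either end is
    NA (or beyond the called bins) the pair is NA and excluded downstream.
    """
    out = np.full(len(vocab), "NA", dtype="<U2")
    for chrom in set(vocab.chroms):
        if chrom not in calls.labels:
            raise ValueError(f"no compartment calls for chromosome {chrom!r}")
    for k in range(len(vocab)):
        chrom, i, j = vocab.lp_at(k)
        labs = calls.labels[chrom]
        if i >= labs.size or j >= labs.size:
            continue
        a, b = labs[i], labs[j]
        if a == "NA" or b == "NA":
            continue
        out[k] = "".join(sorted((a, b)))
    return out


@dataclass
class EnrichmentResult:
    """Observed-vs-expected category proportions with a test."""

    observed: dict[str, float]
    expected: dict[str, float]
    log2_ratio: dict[str, float]
    statistic: float
    pvalue: float
    counts: dict[str, int]
    pvalue_adj: float | None = None


def _proportions(counts: np.ndarray) -> np.ndarray:
    total = counts.sum()
    if total == 0:
        raise ValueError("no counts to form proportions")
    return counts / total


def _log2_ratio(obs: float, exp: float) -> float:
    if exp == 0:
        return float("nan")
    if obs == 0:
        return float("-inf")
    return float(np.log2(obs / exp))


_COMPARTMENT_CATS = ("AA", "AB", "BB")


def topic_compartment_enrichment(
    topic_lp_sets: Mapping[int, np.ndarray],
    lp_labels: np.ndarray,
    alpha: float = 0.01,
) -> dict[int, EnrichmentResult]:
    """Per-topic AA/AB/BB enrichment against all topic-associated LPs.

    The expected proportions come from the union of LPs assigned to any
    topic; significance is a chi-square test of independence on the
    (focal vs rest) x (AA/AB/BB) contingency table without Yates
    correction, BH-corrected across topics.
    """
    lp_labels = np.asarray(lp_labels)
    union = np.unique(np.concatenate([np.asarray(v) for v in topic_lp_sets.values()]))
    union = union[lp_labels[union] != "NA"]
    if union.size == 0:
        raise ValueError("no labeled topic-associated locus pairs")
    bg_counts = np.array([(lp_labels[union] == c).sum() for c in _COMPARTMENT_CATS])
    bg_prop = _proportions(bg_counts)

    results: dict[int, EnrichmentResult] = {}
    pvals, topics = [], []
    for t, cols in topic_lp_sets.items():
        cols = np.asarray(cols)
        cols = cols[lp_labels[cols] != "NA"]
        if cols.size == 0:
            raise ValueError(f"topic {t} has no labeled locus pairs")
        obs_counts = np.array([(lp_labels[cols] == c).sum() for c in _COMPARTMENT_CATS])
        rest = bg_counts - np.array(
            [(lp_labels[np.intersect1d(cols, union)] == c).sum() for c in _COMPARTMENT_CATS]
        )
        obs_prop = _proportions(obs_counts)
        table = np.vstack([obs_counts, rest])
        # drop all-zero categories to keep the chi-square well-defined
        nz = table.sum(axis=0) > 0
        if nz.sum() < 2 or np.any(table.sum(axis=1) == 0):
            stat, p = 0.0, 1.0
        else:
            if np.any(st.contingency.expected_freq(table[:, nz]) < 5):
                warnings.warn(f"topic {t}: chi-square expected counts below 5")
            stat, p, _, _ = st.chi2_contingency(table[:, nz], correction=False)
        results[t] = EnrichmentResult(
            observed=dict(zip(_COMPARTMENT_CATS, obs_prop)),
            expected=dict(zip(_COMPARTMENT_CATS, bg_prop)),
            log2_ratio={
                c: _log2_ratio(o, e)
                for c, o, e in zip(_COMPARTMENT_CATS, obs_prop, bg_prop)
            },
            statistic=float(stat),
            pvalue=float(p),
            counts=dict(zip(_COMPARTMENT_CATS, obs_counts.tolist())),
        )
        pvals.append(p)
        topics.append(t)
    adj = bh_adjust(np.array(pvals))
    for t, q in zip(topics, adj):
        results[t].pvalue_adj = float(q)
    return results


@dataclass
class SwitchRegions:
    """Compartment switching bins per cell type.

    ``by_type[cell_type]`` maps (chrom, bin) -> direction, where direction
    "B-to-A" means all other cell types call the bin B and the focal type
    calls it A.
    """

    by_type: dict[str, dict[tuple[str, int], str]]

    def bins_of(self, cell_type: str) -> set[tuple[str, int]]:
        return set(self.by_type.get(cell_type, {}))

    def to_bed(self, path, resolution: int) -> None:
        with open(path, "w") as fh:
            for ct, d in self.by_type.items():
                for (chrom, b), direction in sorted(d.items()):
                    fh.write(
                        f"{chrom}\t{b * resolution}\t{(b + 1) * resolution}"
                        f"\t{ct}\t{direction}\n"
                    )


def _labels_of(calls) -> dict[str, np.ndarray]:
    return calls.labels if isinstance(calls, CompartmentCalls) else calls


def find_switch_regions(calls_by_type: Mapping[str, CompartmentCalls | dict]) -> SwitchRegions:
    """Bins where one cell type's call differs from the others' unanimous call.

    A bin qualifies as a switch for the focal type only when every other
    cell type carries the same non-NA label and the focal label is non-NA
    and different; the direction is consensus -> focal.
    """
    if len(calls_by_type) < 2:
        raise ValueError("need compartment calls for at least two cell types")
    labels = {ct: _labels_of(c) for ct, c in calls_by_type.items()}
    types = list(labels)
    by_type: dict[str, dict[tuple[str, int], str]] = {ct: {} for ct in types}
    chroms = set.intersection(*(set(l) for l in labels.values()))
    for chrom in sorted(chroms):
        n = min(labels[ct][chrom].size for ct in types)
        for b in range(n):
            labs = {ct: labels[ct][chrom][b] for ct in types}
            for focal in types:
                others = [labs[ct] for ct in types if ct != focal]
                if "NA" in others or labs[focal] == "NA":
                    continue
                if len(set(others)) != 1:
                    continue
                consensus = others[0]
                if labs[focal] != consensus:
                    by_type[focal][(chrom, b)] = f"{consensus}-to-{labs[focal]}"
    return SwitchRegions(by_type=by_type)


def _lp_bins(vocab: LPVocabulary, cols: np.ndarray):
    """(chrom, bin) pairs of both ends for each given vocabulary column."""
    for k in cols:
        chrom, i, j = vocab.lp_at(int(k))
        yield (chrom, i), (chrom, j)


def _touch_mask(vocab: LPVocabulary, cols: np.ndarray, bins_set: set) -> np.ndarray:
    out = np.zeros(len(cols), dtype=bool)
    for idx, (e1, e2) in enumerate(_lp_bins(vocab, cols)):
        out[idx] = e1 in bins_set or e2 in bins_set
    return out


def switch_enrichment(
    topic_lp_sets: Mapping[int, np.ndarray],
    topic_to_type: Mapping[int, str],
    switch: SwitchRegions,
    vocab: LPVocabulary,
) -> dict[str, EnrichmentResult]:
    """Enrichment of switch-region contacts in cell-type-specific topics.

    For each cell type, the observed proportion of specific-topic locus
    pairs touching (either end in) that type's switch bins is compared with
    the proportion among all topic-associated locus pairs; a 2x2 chi-square
    tests (specific vs all) x (touching vs not), and p-values are
    BH-corrected across cell types.
    """
    all_cols = np.unique(np.concatenate([np.asarray(v) for v in topic_lp_sets.values()]))
    results: dict[str, EnrichmentResult] = {}
    pvals, cts = [], []
    for ct in sorted(set(topic_to_type.values())):
        sbins = switch.bins_of(ct)
        if not sbins:
            raise ValueError(f"no switch regions for cell type {ct!r}")
        spec_cols = np.unique(
            np.concatenate(
                [np.asarray(topic_lp_sets[t]) for t, c in topic_to_type.items() if c == ct]
            )
        )
        spec_touch = int(_touch_mask(vocab, spec_cols, sbins).sum())
        all_touch = int(_touch_mask(vocab, all_cols, sbins).sum())
        if spec_touch == 0 and all_touch == 0:
            raise ValueError(f"no locus pairs touch switch regions for {ct!r}")
        obs = np.array([spec_touch, len(spec_cols) - spec_touch])
        exp = np.array([all_touch, len(all_cols) - all_touch])
        obs_p, exp_p = _proportions(obs), _proportions(exp)
        table = np.vstack([obs, exp])
        if np.all(table.sum(axis=0) > 0):
            stat, p, _, _ = st.chi2_contingency(table, correction=False)
        else:
            stat, p = 0.0, 1.0
        results[ct] = EnrichmentResult(
            observed={"switch": obs_p[0], "stable": obs_p[1]},
            expected={"switch": exp_p[0], "stable": exp_p[1]},
            log2_ratio={
                "switch": _log2_ratio(obs_p[0], exp_p[0]),
                "stable": _log2_ratio(obs_p[1], exp_p[1]),
            },
            statistic=float(stat),
            pvalue=float(p),
            counts={
                "specific_touching": spec_touch,
                "specific_total": int(len(spec_cols)),
                "all_touching": all_touch,
                "all_total": int(len(all_cols)),
            },
        )
        pvals.append(p)
        cts.append(ct)
    adj = bh_adjust(np.array(pvals))
    for ct, q in zip(cts, adj):
        results[ct].pvalue_adj = float(q)
    return results


_DIRECTIONS = ("A-to-B", "B-to-A")


def transition_direction_enrichment(
    topic_lp_sets: Mapping[int, np.ndarray],
    topic_to_type: Mapping[int, str],
    switch: SwitchRegions,
    vocab: LPVocabulary,
) -> dict[str, EnrichmentResult]:
    """Direction (A-to-B vs B-to-A) enrichment among touched switch bins.

    Observed: direction proportions among the focal type's switch bins
    touched by its specific-topic locus pairs; expected: proportions among
    switch bins touched by any topic-associated locus pair.  Directions
    absent from the expected set are reported as NaN.
    """
    all_cols = np.unique(np.concatenate([np.asarray(v) for v in topic_lp_sets.values()]))
    results: dict[str, EnrichmentResult] = {}
    for ct in sorted(set(topic_to_type.values())):
        dirs = switch.by_type.get(ct, {})
        if not dirs:
            raise ValueError(f"no switch regions for cell type {ct!r}")
        spec_cols = np.unique(
            np.concatenate(
                [np.asarray(topic_lp_sets[t]) for t, c in topic_to_type.items() if c == ct]
            )
        )

        def touched_bins(cols):
            touched = set()
            sbins = set(dirs)
            for e1, e2 in _lp_bins(vocab, cols):
                if e1 in sbins:
                    touched.add(e1)
                if e2 in sbins:
                    touched.add(e2)
            return touched

        spec_t = touched_bins(spec_cols)
        all_t = touched_bins(all_cols)
        if not spec_t and not all_t:
            raise ValueError(f"no touched switch bins for cell type {ct!r}")
        obs = np.array([sum(dirs[b] == d for b in spec_t) for d in _DIRECTIONS])
        exp = np.array([sum(dirs[b] == d for b in all_t) for d in _DIRECTIONS])
        obs_p = obs / obs.sum() if obs.sum() else np.zeros(2)
        exp_p = exp / exp.sum() if exp.sum() else np.zeros(2)
        log2 = {}
        for d, o, e in zip(_DIRECTIONS, obs_p, exp_p):
            log2[d] = float("nan") if e == 0 else _log2_ratio(o, e)
        table = np.vstack([obs, exp])
        nz = table.sum(axis=0) > 0
        if nz.sum() >= 2 and np.all(table.sum(axis=1) > 0):
            stat, p, _, _ = st.chi2_contingency(table[:, nz], correction=False)
        else:
            stat, p = 0.0, 1.0
        results[ct] = EnrichmentResult(
            observed=dict(zip(_DIRECTIONS, obs_p)),
            expected=dict(zip(_DIRECTIONS, exp_p)),
            log2_ratio=log2,
            statistic=float(stat),
            pvalue=float(p),
            counts={
                "specific_touched": dict(zip(_DIRECTIONS, obs.tolist())),
                "all_touched": dict(zip(_DIRECTIONS, exp.tolist())),
            },
        )
    return results


def de_gene_bta_enrichment(
    de_bins_by_type: Mapping[str, set],
    switch: SwitchRegions,
) -> dict[str, tuple[float, float, np.ndarray]]:
    """Fisher enrichment of B-to-A switches at upregulated-gene bins.

    For each cell type the 2x2 table over that type's switch bins crosses
    (bin contains an upregulated gene) x (direction is B-to-A); the
    returned tuple is (sample odds ratio ad/bc, two-sided Fisher exact p,
    table).  Upstream differential-expression fitting is out of scope: the
    input is the set of 500 kb bins containing each type's upregulated
    genes.
    """
    results = {}
    for ct, de_bins in de_bins_by_type.items():
        dirs = switch.by_type.get(ct, {})
        if not dirs:
            raise ValueError(f"no switch regions for cell type {ct!r}")
        de_bins = set(de_bins)
        a = b = c = d = 0
        for bin_key, direction in dirs.items():
            is_de = bin_key in de_bins
            is_bta = direction == "B-to-A"
            if is_de and is_bta:
                a += 1
            elif is_de:
                b += 1
            elif is_bta:
                c += 1
            else:
                d += 1
        table = np.array([[a, b], [c, d]])
        odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
        _, p = st.fisher_exact(table, alternative="two-sided")
        results[ct] = (float(odds), float(p), table)
    return results
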