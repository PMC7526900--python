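"""Compartment calling and enrichment statistics."""

import itertools
import warnings

import numpy as np
import pytest
import scipy.stats as st
from scipy.special import comb

from hictopics import synthdata as sd
from hictopics.compartments import (
    CompartmentCalls,
    SwitchRegions,
    call_compartments,
    de_gene_bta_enrichment,
    find_switch_regions,
    gene_density,
    ice_normalize,
    label_lp_compartments,
    oe_normalize,
    switch_enrichment,
    topic_compartment_enrichment,
    transition_direction_enrichment,
)
from hictopics.genome import ChromSizes, build_lp_vocabulary, make_bins


class TestICE:
    def test_already_balanced_matrix_unchanged_up_to_scale(self):
        M = np.array([[0.0, 3.0], [3.0, 0.0]])
        W, bias, mask = ice_normalize(M)
        assert not mask.any()
        ratio = W[0, 1] / M[0, 1]
        assert np.allclose(W / ratio, M)

    def test_row_sums_equalized(self):
        rng = np.random.default_rng(0)
        A = rng.random((20, 20)) + 0.1
        M = (A + A.T) / 2
        W, _, mask = ice_normalize(M, tol=1e-8)
        sums = W[~mask].sum(axis=1)
        assert sums.std() / sums.mean() < 1e-5

    def test_zero_marginal_bins_masked(self):
        rng = np.random.default_rng(1)
        A = rng.random((10, 10)) + 0.5
        M = (A + A.T) / 2
        M[3, :] = 0.0
        M[:, 3] = 0.0
        W, _, mask = ice_normalize(M)
        assert mask[3]
        assert (W[3] == 0).all() and (W[:, 3] == 0).all()

    def test_balancing_is_idempotent(self):
        rng = np.random.default_rng(2)
        A = rng.random((15, 15)) + 0.2
        M = (A + A.T) / 2
        W, _, mask = ice_normalize(M, tol=1e-10)
        W2, bias2, _ = ice_normalize(W, tol=1e-10)
        assert np.allclose(bias2[~mask], bias2[~mask][0], rtol=1e-4)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ice_normalize(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            ice_normalize(np.arange(16.0).reshape(4, 4))  # asymmetric


class TestOE:
    def test_toeplitz_input_becomes_ones(self):
        n = 12
        M = np.array([[2.0 ** -abs(i - j) for j in range(n)] for i in range(n)])
        oe = oe_normalize(M)
        assert np.allclose(oe, 1.0)

    def test_diagonal_means_are_one(self):
        rng = np.random.default_rng(3)
        A = rng.random((15, 15)) + 0.1
        M = (A + A.T) / 2
        oe = oe_normalize(M)
        for d in range(15):
            vals = np.array([oe[i, i + d] for i in range(15 - d)])
            assert np.nanmean(vals) == pytest.approx(1.0)

    def test_checkerboard_survives_decay_removal(self):
        # blocks of 4 so the same-compartment pattern is not a pure
        # function of |i - j| (which O/E would remove entirely)
        labels = np.repeat(["A", "B", "A", "B"], 4)
        M = sd.simulate_bulk_matrix(labels, checkerboard_strength=0.5, noise=0.0, seed=0)
        oe = oe_normalize(M)
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(16, dtype=bool)
        assert np.nanmean(oe[same & off]) > 1.0 > np.nanmean(oe[~same])


class TestCallCompartments:
    @staticmethod
    def _planted(n_blocks=8, block=6, strength=0.5, noise=0.05, seed=0):
        labels = np.repeat(["A", "B"] * (n_blocks // 2), block)
        M = sd.simulate_bulk_matrix(labels, checkerboard_strength=strength,
                                    noise=noise, seed=seed)
        W, _, mask = ice_normalize(M)
        oe = oe_normalize(W, mask)
        rng = np.random.default_rng(seed + 1)
        gd = np.where(labels == "A", 8.0, 1.0) + rng.normal(0, 0.3, labels.size)
        return labels, oe, gd

    def test_planted_checkerboard_recovered(self):
        hits, total = 0, 0
        for seed in range(3):
            labels, oe, gd = self._planted(seed=seed)
            calls = call_compartments({"c": oe}, {"c": gd})
            called = calls.labels["c"]
            known = called != "NA"
            hits += (called[known] == labels[known]).sum()
            total += known.sum()
        assert hits / total >= 0.95
        # gene-dense block oriented to A
        labels, oe, gd = self._planted(seed=5)
        calls = call_compartments({"c": oe}, {"c": gd})
        a_bins = calls.labels["c"] == "A"
        assert gd[a_bins].mean() > gd[~a_bins & (calls.labels["c"] != "NA")].mean()

    def test_uniform_gene_density_flagged_ambiguous(self):
        labels, oe, _ = self._planted()
        with pytest.warns(UserWarning, match="ambiguous"):
            calls = call_compartments({"c": oe}, {"c": np.ones(labels.size)})
        assert "c" in calls.ambiguous
        assert set(calls.labels["c"]) <= {"A", "B", "NA"}

    def test_too_few_informative_bins_gives_all_na(self):
        oe = np.full((5, 5), np.nan)
        calls = call_compartments({"c": oe}, {"c": np.ones(5)})
        assert (calls.labels["c"] == "NA").all()


class TestGeneDensity:
    def test_spanning_gene_counted_in_both_bins(self):
        bins = make_bins(ChromSizes({"c": 2_000_000}), 500_000, extra_bin=False)
        counts = gene_density(bins, [("c", 400_000, 600_000)])
        assert counts["c"].tolist() == [1, 1, 0, 0]

    def test_empty_annotation_gives_zeros(self):
        bins = make_bins(ChromSizes({"c": 2_000_000}), 500_000, extra_bin=False)
        counts = gene_density(bins, [])
        assert (counts["c"] == 0).all()

    def test_totals_at_least_gene_count(self):
        bins = make_bins(ChromSizes({"c": 5_000_000}), 500_000, extra_bin=False)
        rng = np.random.default_rng(4)
        genes = []
        for _ in range(30):
            start = int(rng.integers(0, 4_000_000))
            genes.append(("c", start, start + int(rng.integers(1, 900_000))))
        counts = gene_density(bins, genes)
        assert counts["c"].sum() >= 30

    def test_malformed_interval_rejected(self):
        bins = make_bins(ChromSizes({"c": 2_000_000}), 500_000)
        with pytest.raises(ValueError):
            gene_density(bins, [("c", 500, 100)])


class TestLabelLPCompartments:
    @staticmethod
    def _setup():
        bins = make_bins(ChromSizes({"c": 3_000_000}), 500_000, extra_bin=False)
        vocab = build_lp_vocabulary(bins, 3_000_000)
        labels = np.array(["A", "B", "B", "A", "NA", "A"])
        return vocab, CompartmentCalls(labels={"c": labels})

    def test_orientation_free_labels(self):
        vocab, calls = self._setup()
        out = label_lp_compartments(vocab, calls)
        assert out[vocab.index_of(("c", 0, 1))] == "AB"  # (A, B)
        assert out[vocab.index_of(("c", 1, 3))] == "AB"  # (B, A)
        assert out[vocab.index_of(("c", 1, 2))] == "BB"
        assert out[vocab.index_of(("c", 0, 3))] == "AA"

    def test_na_end_propagates(self):
        vocab, calls = self._setup()
        out = label_lp_compartments(vocab, calls)
        assert out[vocab.index_of(("c", 3, 4))] == "NA"


class TestTopicCompartmentEnrichment:
    def test_background_composition_gives_zero_log2(self):
        rng = np.random.default_rng(5)
        lp_labels = rng.choice(["AA", "AB", "BB"], 600, p=[0.3, 0.4, 0.3])
        focal = np.arange(0, 600, 3)
        rest = np.setdiff1d(np.arange(600), focal)
        # focal drawn from the same composition as the rest
        res = topic_compartment_enrichment({0: focal, 1: rest}, lp_labels)
        assert abs(res[0].log2_ratio["AA"]) < 0.35
        assert res[0].pvalue > 0.01
        for r in res.values():
            assert sum(r.observed.values()) == pytest.approx(1.0)
            assert sum(r.expected.values()) == pytest.approx(1.0)

    def test_planted_aa_heavy_topic_detected(self):
        rng = np.random.default_rng(6)
        n = 1000
        lp_labels = np.empty(n, dtype="<U2")
        focal = np.arange(200)
        rest = np.arange(200, n)
        lp_labels[focal] = rng.choice(["AA", "AB", "BB"], 200, p=[0.8, 0.1, 0.1])
        lp_labels[rest] = rng.choice(["AA", "AB", "BB"], 800, p=[0.4, 0.3, 0.3])
        res = topic_compartment_enrichment({0: focal, 1: rest}, lp_labels)
        assert res[0].log2_ratio["AA"] > 0
        assert res[0].pvalue_adj < 0.01


class TestSwitchRegions:
    def test_single_dissenter_is_a_switch(self):
        labels = {
            "t1": {"c": np.array(["A"])},
            "t2": {"c": np.array(["B"])},
            "t3": {"c": np.array(["B"])},
            "t4": {"c": np.array(["B"])},
            "t5": {"c": np.array(["B"])},
        }
        sw = find_switch_regions(labels)
        assert sw.by_type["t1"] == {("c", 0): "B-to-A"}
        assert all(not sw.by_type[t] for t in ["t2", "t3", "t4", "t5"])

    def test_split_vote_is_not_a_switch(self):
        labels = {
            "t1": {"c": np.array(["A"])},
            "t2": {"c": np.array(["A"])},
            "t3": {"c": np.array(["B"])},
            "t4": {"c": np.array(["B"])},
            "t5": {"c": np.array(["B"])},
        }
        sw = find_switch_regions(labels)
        assert all(not v for v in sw.by_type.values())

    def test_unanimous_bin_is_stable(self):
        labels = {f"t{i}": {"c": np.array(["A", "A"])} for i in range(5)}
        sw = find_switch_regions(labels)
        assert all(not v for v in sw.by_type.values())

    def test_na_anywhere_disqualifies(self):
        labels = {
            "t1": {"c": np.array(["A"])},
            "t2": {"c": np.array(["NA"])},
            "t3": {"c": np.array(["B"])},
        }
        sw = find_switch_regions(labels)
        assert all(not v for v in sw.by_type.values())


def _switch_vocab():
    bins = make_bins(ChromSizes({"c": 20_000_000}), 500_000, extra_bin=False)
    return build_lp_vocabulary(bins, 10_000_000)


class TestSwitchEnrichment:
    def test_planted_touching_topics_enriched(self):
        vocab = _switch_vocab()
        switch = SwitchRegions(by_type={"t1": {("c", 0): "B-to-A", ("c", 1): "B-to-A"}})
        touching = np.array(
            [k for k in range(len(vocab)) if vocab.bin_i[k] in (0, 1)]
        )
        non_touching = np.array(
            [k for k in range(len(vocab)) if vocab.bin_i[k] > 5][:200]
        )
        sets = {0: touching, 1: non_touching}
        res = switch_enrichment(sets, {0: "t1"}, switch, vocab)
        assert res["t1"].log2_ratio["switch"] > 0
        assert res["t1"].pvalue < 1e-3

    def test_identical_touching_rates_give_zero(self):
        vocab = _switch_vocab()
        switch = SwitchRegions(by_type={"t1": {("c", 0): "B-to-A"}})
        cols = np.arange(100)
        res = switch_enrichment({0: cols, 1: cols}, {0: "t1", 1: "t1"}, switch, vocab)
        assert res["t1"].log2_ratio["switch"] == pytest.approx(0.0)

    def test_empty_switch_set_rejected(self):
        vocab = _switch_vocab()
        switch = SwitchRegions(by_type={"t1": {}})
        with pytest.raises(ValueError):
            switch_enrichment({0: np.arange(5)}, {0: "t1"}, switch, vocab)


class TestDirectionEnrichment:
    def test_pure_bta_against_even_background(self):
        vocab = _switch_vocab()
        # switch bins: 0, 1 are B-to-A; 30, 31 are A-to-B -- far enough
        # apart that no locus pair touches bins from both groups
        switch = SwitchRegions(
            by_type={
                "t1": {
                    ("c", 0): "B-to-A",
                    ("c", 1): "B-to-A",
                    ("c", 30): "A-to-B",
                    ("c", 31): "A-to-B",
                }
            }
        )
        spec = np.array([k for k in range(len(vocab)) if vocab.bin_i[k] in (0, 1)])
        allset = np.array(
            [k for k in range(len(vocab)) if vocab.bin_i[k] in (0, 1, 30, 31)]
        )
        res = transition_direction_enrichment(
            {0: spec, 1: allset}, {0: "t1"}, switch, vocab
        )
        assert res["t1"].log2_ratio["B-to-A"] == pytest.approx(1.0)

    def test_matched_directions_give_zero(self):
        vocab = _switch_vocab()
        switch = SwitchRegions(
            by_type={"t1": {("c", 0): "B-to-A", ("c", 10): "A-to-B"}}
        )
        cols = np.array([k for k in range(len(vocab)) if vocab.bin_i[k] in (0, 10)])
        res = transition_direction_enrichment({0: cols}, {0: "t1"}, switch, vocab)
        assert res["t1"].log2_ratio["B-to-A"] == pytest.approx(0.0)
        assert res["t1"].log2_ratio["A-to-B"] == pytest.approx(0.0)

    def test_absent_direction_reported_nan(self):
        vocab = _switch_vocab()
        switch = SwitchRegions(by_type={"t1": {("c", 0): "B-to-A"}})
        cols = np.array([k for k in range(len(vocab)) if vocab.bin_i[k] == 0])
        res = transition_direction_enrichment({0: cols}, {0: "t1"}, switch, vocab)
        assert res["t1"].log2_ratio["B-to-A"] == pytest.approx(0.0)
        assert np.isnan(res["t1"].log2_ratio["A-to-B"])


def _fisher_two_sided_enumeration(table):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            comb(col1, x, exact=True)
            * comb(n - col1, row1 - x, exact=True)
            / comb(n, row1, exact=True)
        )

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
        if prob(x) <= p_obs * (1 + 1e-9)
    )


class TestDEGeneBtaEnrichment:
    @staticmethod
    def _switch_from_table(a, b, c, d):
        """Switch map with a+b DE-containing bins and a+c B-to-A bins."""
        m = {}
        k = 0
        de = set()
        for count, is_de, is_bta in [(a, 1, 1), (b, 1, 0), (c, 0, 1), (d, 0, 0)]:
            for _ in range(count):
                m[("c", k)] = "B-to-A" if is_bta else "A-to-B"
                if is_de:
                    de.add(("c", k))
                k += 1
        return SwitchRegions(by_type={"t1": m}), {"t1": de}

    def test_odds_ratio_example(self):
        switch, de = self._switch_from_table(8, 2, 40, 60)
        odds, p, table = de_gene_bta_enrichment(de, switch)["t1"]
        assert odds == pytest.approx(6.0)
        assert (table == np.array([[8, 2], [40, 60]])).all()

    def test_proportional_table_is_null(self):
        switch, de = self._switch_from_table(10, 10, 20, 20)
        odds, p, _ = de_gene_bta_enrichment(de, switch)["t1"]
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_fisher_p_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(0, 15, 4)
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            a, b, c, d = a + 1, b + 1, c + 1, d + 1
        switch, de = self._switch_from_table(int(a), int(b), int(c), int(d))
        _, p, table = de_gene_bta_enrichment(de, switch)["t1"]
        assert p == pytest.approx(_fisher_two_sided_enumeration(table), rel=1e-6)

    def test_empty_switch_set_rejected(self):
        with pytest.raises(ValueError):
            de_gene_bta_enrichment({"t1": set()}, SwitchRegions(by_type={"t1": {}}))
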