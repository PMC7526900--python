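"""Synthetic single-cell Hi-C corpora with known ground truth.

The generator mirrors the generative story the topic model assumes: each
cell type has a Dirichlet prior over topics skewed toward its own specific
topics; each cell draws a topic mixture, then tokens (locus pairs) by
sampling a topic and then a pair from the topic's multinomial.  Topics are
built on top of a planted compartment structure: general topics follow a
plain exponential distance decay, while each cell-type-specific topic
concentrates a stated mass fraction on locus pairs touching that type's
B-to-A compartment-switch blocks (restricted to compartment-consistent
AA/BB pairs).  Contacts are emitted at bin-center coordinates so binning
round-trips exactly.

Everything is seeded and the full truth (labels, switch bins, topic
distributions, mixtures) is retained for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compartments import SwitchRegions
from .contacts import CellContacts
from .genome import BinTable, ChromSizes, LPVocabulary, build_lp_vocabulary, make_bins

__all__ = [
    "SyntheticTruth",
    "make_toy_genome",
    "simulate_compartments",
    "simulate_topics",
    "simulate_cells",
    "simulate_bulk_matrix",
    "default_study",
]


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic study."""

    chrom_sizes: ChromSizes
    bins: BinTable
    vocab: LPVocabulary
    labels_by_type: dict[str, dict[str, np.ndarray]]
    switch: SwitchRegions
    topics: np.ndarray  # T x V row-stochastic
    topic_types: list[str | None]  # None for general topics
    mixtures: np.ndarray | None = None  # cells x T
    cell_labels: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    params: dict = field(default_factory=dict)


def make_toy_genome(
    n_chroms: int = 2,
    chrom_length: int = 60_000_000,
    resolution: int = 500_000,
    max_distance: int = 10_000_000,
    extra_bin: bool = False,
) -> tuple[ChromSizes, BinTable, LPVocabulary]:
    """Small deterministic genome for desk-scale experiments."""
    if n_chroms < 1 or chrom_length <= 0:
        raise ValueError("need positive genome dimensions")
    sizes = ChromSizes({f"chr{i + 1}": chrom_length for i in range(n_chroms)})
    bins = make_bins(sizes, resolution, extra_bin=extra_bin)
    vocab = build_lp_vocabulary(bins, max_distance)
    return sizes, bins, vocab


def simulate_compartments(
    bins: BinTable,
    n_cell_types: int = 3,
    block_bins: int = 10,
    switch_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[dict[str, dict[str, np.ndarray]], SwitchRegions]:
    """Plant alternating A/B blocks plus per-type compartment switches.

    A base alternating A/B block structure is shared by all cell types.  A
    ``switch_fraction`` of blocks is flipped, each in exactly one cell type
    (so the remaining types stay unanimous).  Flipped blocks are drawn
    stratified by base label and distributed round-robin over cell types,
    which guarantees every type receives switches of both directions when
    enough blocks are flipped.  Directions follow from the base label:
    flipping a base-B block gives that type a B-to-A switch.
    """
    if block_bins < 1:
        raise ValueError("block_bins must be >= 1")
    if not 0 <= switch_fraction <= 1:
        raise ValueError("switch_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    types = [f"type{i + 1}" for i in range(n_cell_types)]

    blocks = []  # (chrom, start_bin, end_bin, base_label)
    base_labels: dict[str, np.ndarray] = {}
    for chrom in bins.chroms:
        n = bins.n_bins[chrom]
        labs = np.empty(n, dtype="<U2")
        for k, start in enumerate(range(0, n, block_bins)):
            end = min(start + block_bins, n)
            lab = "A" if k % 2 == 0 else "B"
            labs[start:end] = lab
            blocks.append((chrom, start, end, lab))
        base_labels[chrom] = labs

    n_flip = int(round(switch_fraction * len(blocks)))
    a_blocks = [b for b in blocks if b[3] == "A"]
    b_blocks = [b for b in blocks if b[3] == "B"]
    rng.shuffle(a_blocks)
    rng.shuffle(b_blocks)
    n_from_b = min(len(b_blocks), (n_flip + 1) // 2)
    n_from_a = min(len(a_blocks), n_flip - n_from_b)
    chosen = b_blocks[:n_from_b] + a_blocks[:n_from_a]

    labels_by_type = {
        ct: {c: base_labels[c].copy() for c in bins.chroms} for ct in types
    }
    switch_map: dict[str, dict[tuple[str, int], str]] = {ct: {} for ct in types}
    for k, (chrom, start, end, lab) in enumerate(chosen):
        ct = types[k % n_cell_types]
        flipped = "B" if lab == "A" else "A"
        labels_by_type[ct][chrom][start:end] = flipped
        for b in range(start, end):
            switch_map[ct][(chrom, b)] = f"{lab}-to-{flipped}"
    return labels_by_type, SwitchRegions(by_type=switch_map)


def _contiguous_blocks(bin_keys):
    """Group sorted (chrom, bin) keys into runs of consecutive bins."""
    blocks, current = [], []
    for key in bin_keys:
        if current and (key[0] != current[-1][0] or key[1] != current[-1][1] + 1):
            blocks.append(current)
            current = []
        current.append(key)
    if current:
        blocks.append(current)
    return [set(b) for b in blocks]


def simulate_topics(
    vocab: LPVocabulary,
    labels_by_type: dict[str, dict[str, np.ndarray]],
    switch: SwitchRegions,
    n_general: int = 2,
    n_specific_per_type: int = 2,
    decay_scale: float = 1_000_000.0,
    concentration: float = 0.85,
    seed: int = 0,
) -> tuple[np.ndarray, list[str | None]]:
    """Plant topic-LP distributions over the vocabulary.

    General topics emulate contact-decay programs shared by all cells: the
    first follows exp(-distance / decay_scale) (short-range,
    interphase-like) and the second is a Gaussian band centred at 7 Mb
    (long-range, mitotic-like; further general topics re-use progressively
    doubled decay scales).

    Each cell-type-specific topic carries a ``concentration`` mass fraction
    spread uniformly over its target set: the union of (a) locus pairs with
    at least one end in the topic's own B-to-A switch blocks of that type
    (contiguous switch runs, distributed round-robin over the type's
    specific topics so sibling topics occupy distinct blocks) and (b) locus
    pairs touching the topic's private stable blocks (blocks switched in no
    cell type, assigned greedily so target sizes stay balanced) — in both
    components restricted to pairs whose two ends share the same non-NA
    label in that type (AA/BB-consistent), each pair claimed by at most one
    topic.  The remaining ``1 - concentration`` follows the short-range
    decay.  With ``concentration=0`` every specific topic equals the decay
    topic.  Rows are normalized.
    """
    V = len(vocab)
    d = vocab.distances().astype(float)
    decay = np.exp(-d / decay_scale)
    general = decay / decay.sum()

    types = sorted(labels_by_type)
    rows: list[np.ndarray] = []
    topic_types: list[str | None] = []
    for k in range(n_general):
        if k == 0:
            g = decay
        elif k == 1:
            g = np.exp(-(((d - 7e6) / 3e6) ** 2))
        else:
            g = np.exp(-d / (decay_scale * 2.0**k))
        rows.append(g / g.sum())
        topic_types.append(None)

    # stable blocks (never switched in any type), split round-robin across
    # all specific topics as private territories; long contiguous stable
    # runs are chunked to the typical switch-block size so territories stay
    # balanced across topics
    switched_bins = set()
    for m in switch.by_type.values():
        switched_bins.update(m)
    all_bins = [
        (c, b)
        for c in vocab.bins.chroms
        for b in range(vocab.bins.n_bins[c])
    ]
    stable_runs = _contiguous_blocks([b for b in all_bins if b not in switched_bins])
    sw_runs = _contiguous_blocks(sorted(switched_bins))
    chunk = int(np.median([len(r) for r in sw_runs])) if sw_runs else 10
    stable_blocks: list[set] = []
    for run in stable_runs:
        run_sorted = sorted(run)
        for start in range(0, len(run_sorted), chunk):
            stable_blocks.append(set(run_sorted[start : start + chunk]))
    n_specific = len(types) * n_specific_per_type
    claimed = np.zeros(V, dtype=bool)  # pairs already owned by a topic

    def _consistent_touch_mask(labs, target_bins, forbidden=frozenset()):
        """Pairs with >=1 end in ``target_bins``, same non-NA label at both
        ends, and no end in ``forbidden`` (used to keep a topic's pairs off
        other topics' switch territory)."""
        mask = np.zeros(V, dtype=bool)
        if not target_bins:
            return mask
        for k in range(V):
            chrom, i, j = vocab.lp_at(k)
            la = labs[chrom][i] if i < labs[chrom].size else "NA"
            lb = labs[chrom][j] if j < labs[chrom].size else "NA"
            if la != lb or la == "NA":
                continue
            if (chrom, i) in forbidden or (chrom, j) in forbidden:
                continue
            if (chrom, i) in target_bins or (chrom, j) in target_bins:
                mask[k] = True
        return mask

    # switch components first: each type's B-to-A runs split round-robin
    # over its sibling topics, pairs claimed exclusively
    spec_order: list[tuple[str, int]] = [
        (ct, s) for ct in types for s in range(n_specific_per_type)
    ]
    sw_masks: dict[tuple[str, int], np.ndarray] = {}
    for ct in types:
        bta = sorted(b for b, dr in switch.by_type.get(ct, {}).items() if dr == "B-to-A")
        bta_blocks = _contiguous_blocks(bta)
        labs = labels_by_type[ct]
        for s in range(n_specific_per_type):
            sw_bins = (
                set().union(*bta_blocks[s::n_specific_per_type])
                if bta_blocks
                else set()
            )
            m = _consistent_touch_mask(labs, sw_bins, switched_bins - sw_bins) & ~claimed
            claimed |= m
            sw_masks[(ct, s)] = m

    # private components: stable chunks assigned greedily to whichever
    # specific topic currently has the smallest target, keeping planted
    # topic supports balanced
    pv_masks: dict[tuple[str, int], np.ndarray] = {
        key: np.zeros(V, dtype=bool) for key in spec_order
    }
    sizes = {key: int(sw_masks[key].sum()) for key in spec_order}
    rng = np.random.default_rng(seed)
    chunk_order = list(range(len(stable_blocks)))
    rng.shuffle(chunk_order)
    for ci in chunk_order:
        key = min(spec_order, key=lambda k: sizes[k])
        labs = labels_by_type[key[0]]
        # both ends stable: private pairs never touch any switch region
        m = _consistent_touch_mask(labs, stable_blocks[ci], switched_bins) & ~claimed
        claimed |= m
        pv_masks[key] |= m
        sizes[key] += int(m.sum())

    for ct, s in spec_order:
        target = sw_masks[(ct, s)] | pv_masks[(ct, s)]
        if concentration > 0 and target.any():
            # uniform per-pair mass over the combined target, so top-scoring
            # pairs sample the switch and private components proportionally
            row = (1 - concentration) * general + concentration * target / target.sum()
        else:
            row = general.copy()
        rows.append(row / row.sum())
        topic_types.append(ct)
    return np.vstack(rows), topic_types


def simulate_cells(
    vocab: LPVocabulary,
    topics: np.ndarray,
    topic_types: list[str | None],
    n_per_type: int = 100,
    tokens_per_cell: int = 1000,
    alpha_own: float = 1.0,
    alpha_general: float = 0.5,
    alpha_other: float = 0.02,
    seed: int = 0,
) -> tuple[list[CellContacts], dict[str, str], np.ndarray]:
    """Draw cells from the planted topic model and emit contact records.

    Per cell: token count ~ Poisson(tokens_per_cell); topic mixture ~
    Dirichlet with concentration ``alpha_own`` on the cell type's specific
    topics, ``alpha_general`` on general topics and ``alpha_other``
    elsewhere; tokens are drawn topic-then-LP and written as contacts at
    bin-center coordinates.  The default concentrations give strongly
    cell-type-skewed mixtures (most mass on the type's own topics) with
    cell-to-cell variability in how that mass splits between them, the
    regime in which topic models of single-cell data operate.

    Returns (cells, cell_type_labels, mixtures).
    """
    if n_per_type < 1:
        raise ValueError("n_per_type must be >= 1")
    rng = np.random.default_rng(seed)
    types = sorted({ct for ct in topic_types if ct is not None})
    T, V = topics.shape
    res = vocab.resolution

    cells: list[CellContacts] = []
    labels: dict[str, str] = {}
    mixtures = []
    for ct in types:
        alpha = np.array(
            [
                alpha_general
                if tt is None
                else (alpha_own if tt == ct else alpha_other)
                for tt in topic_types
            ]
        )
        for n in range(n_per_type):
            cell_id = f"{ct}_cell{n:03d}"
            theta = rng.dirichlet(alpha)
            n_tok = max(1, rng.poisson(tokens_per_cell))
            topic_counts = rng.multinomial(n_tok, theta)
            cols = []
            for t, c in enumerate(topic_counts):
                if c == 0:
                    continue
                cols.append(
                    rng.choice(V, size=c, replace=True, p=topics[t])
                )
            cols = np.concatenate(cols)
            chroms = [vocab.chroms[c] for c in vocab.chrom_codes[cols]]
            p1 = vocab.bin_i[cols] * res + res // 2
            p2 = vocab.bin_j[cols] * res + res // 2
            table = pd.DataFrame(
                {"chrom1": chroms, "pos1": p1, "chrom2": chroms, "pos2": p2}
            )
            cells.append(CellContacts(cell_id, table))
            labels[cell_id] = ct
            mixtures.append(theta)
    return cells, labels, np.vstack(mixtures)


def simulate_bulk_matrix(
    labels: np.ndarray,
    decay_scale_bins: float = 4.0,
    checkerboard_strength: float = 0.5,
    noise: float = 0.1,
    depth: float = 1000.0,
    seed: int = 0,
) -> np.ndarray:
    """Bulk-like symmetric contact matrix with planted compartment structure.

    Entry means follow exp(-|i-j|/decay) * (1 + strength) for same-
    compartment pairs and * (1 - strength) otherwise, scaled by ``depth``
    and perturbed by multiplicative lognormal noise.  NA-labeled bins get
    zero rows (masked downstream).
    """
    if checkerboard_strength < 0 or noise < 0:
        raise ValueError("strengths must be non-negative")
    labels = np.asarray(labels)
    n = labels.size
    rng = np.random.default_rng(seed)
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    same = (labels[i] == labels[j]).astype(float)
    mod = 1.0 + checkerboard_strength * (2 * same - 1)
    mean = depth * np.exp(-np.abs(i - j) / decay_scale_bins) * mod
    if noise > 0:
        ln = rng.lognormal(mean=0.0, sigma=noise, size=(n, n))
        ln = np.sqrt(ln * ln.T)  # symmetric multiplicative noise
        mean = mean * ln
    mean = (mean + mean.T) / 2
    na = labels == "NA"
    mean[na, :] = 0.0
    mean[:, na] = 0.0
    return mean


def default_study(seed: int = 0):
    """The default desk-scale synthetic study.

    3 cell types x 100 cells on a 2-chromosome (2 x 60 Mb) genome at 500 kb
    with a 10 Mb locus-pair cutoff (V = 4380), 8 planted topics (2 general
    + 2 specific per type), ~1000 tokens per cell.  Returns a
    SyntheticTruth plus the simulated cells and their type labels.
    """
    sizes, bins, vocab = make_toy_genome()
    labels_by_type, switch = simulate_compartments(
        bins, n_cell_types=3, block_bins=10, switch_fraction=0.5, seed=seed
    )
    topics, topic_types = simulate_topics(
        vocab, labels_by_type, switch, n_general=2, n_specific_per_type=2, seed=seed + 1
    )
    cells, cell_labels, mixtures = simulate_cells(
        vocab, topics, topic_types, n_per_type=100, tokens_per_cell=1000, seed=seed + 2
    )
    truth = SyntheticTruth(
        chrom_sizes=sizes,
        bins=bins,
        vocab=vocab,
        labels_by_type=labels_by_type,
        switch=switch,
        topics=topics,
        topic_types=topic_types,
        mixtures=mixtures,
        cell_labels=cell_labels,
        seed=seed,
        params={
            "n_per_type": 100,
            "tokens_per_cell": 1000,
            "block_bins": 10,
            "switch_fraction": 0.5,
            "concentration": 0.85,
        },
    )
    return truth, cells, cell_labels
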