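"""Genome binning and the locus-pair vocabulary.

A genome is partitioned into fixed-width bins; the "words" of the topic model
are *locus pairs* (LPs): unordered pairs of distinct bins on the same
chromosome separated by at most a maximum genomic distance.  At 500 kb
resolution with a 10 Mb cutoff over the hg19 autosomes this vocabulary
contains 111,340 locus pairs.

Coordinates are 0-based, half-open: bin ``k`` covers
``[k*resolution, (k+1)*resolution)`` and the bin of position ``p`` is
``floor(p / resolution)``.

Bin-count convention
--------------------
By default each chromosome receives ``ceil(length / resolution) + 1`` bins
(``extra_bin=True``).  The trailing extra bin mirrors the convention of the
matrix files this method was developed against and is what makes the hg19
autosomal vocabulary enumerate to exactly 111,340 pairs; plain
``ceil(length / resolution)`` binning (``extra_bin=False``) yields 110,900.
The flag lets users choose either convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "HG19_AUTOSOMES",
    "ChromSizes",
    "BinTable",
    "LPVocabulary",
    "make_bins",
    "build_lp_vocabulary",
    "lp_distance",
]

#: hg19 autosome lengths in bp (UCSC chromInfo), embedded so the default
#: vocabulary needs no external download.
HG19_AUTOSOMES: dict[str, int] = {
    "chr1": 249_250_621,
    "chr2": 243_199_373,
    "chr3": 198_022_430,
    "chr4": 191_154_276,
    "chr5": 180_915_260,
    "chr6": 171_115_067,
    "chr7": 159_138_663,
    "chr8": 146_364_022,
    "chr9": 141_213_431,
    "chr10": 135_534_747,
    "chr11": 135_006_516,
    "chr12": 133_851_895,
    "chr13": 115_169_878,
    "chr14": 107_349_540,
    "chr15": 102_531_392,
    "chr16": 90_354_753,
    "chr17": 81_195_210,
    "chr18": 78_077_248,
    "chr19": 59_128_983,
    "chr20": 63_025_520,
    "chr21": 48_129_895,
    "chr22": 51_304_566,
}


@dataclass(frozen=True)
class ChromSizes:
    """Ordered map from chromosome name to length in bp."""

    entries: dict[str, int]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("chromosome sizes table is empty")
        for name, length in self.entries.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @classmethod
    def from_file(cls, path: str | Path) -> "ChromSizes":
        """Read a UCSC-style two-column (name, length) tab-separated file."""
        entries: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
                name = fields[0]
                if name in entries:
                    raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
                entries[name] = int(fields[1])
        return cls(entries)

    @classmethod
    def hg19_autosomes(cls) -> "ChromSizes":
        return cls(dict(HG19_AUTOSOMES))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def __getitem__(self, name: str) -> int:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def items(self):
        return self.entries.items()


@dataclass(frozen=True)
class BinTable:
    """Fixed-width binning of a genome with a contiguous global bin index.

    Global ids run 0..n_total-1 following the chromosome order of the input
    ``ChromSizes``.
    """

    resolution: int
    extra_bin: bool
    chroms: tuple[str, ...]
    n_bins: dict[str, int]
    chrom_lengths: dict[str, int]
    offsets: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.offsets:
            off, acc = {}, 0
            for c in self.chroms:
                off[c] = acc
                acc += self.n_bins[c]
            object.__setattr__(self, "offsets", off)

    @property
    def n_total(self) -> int:
        return sum(self.n_bins[c] for c in self.chroms)

    def bin_of(self, chrom: str, pos: int) -> int:
        """Bin ordinal (within chromosome) of a bp position."""
        if chrom not in self.n_bins:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if pos < 0:
            raise ValueError(f"negative position {pos}")
        b = pos // self.resolution
        if b >= self.n_bins[chrom]:
            raise ValueError(f"position {pos} beyond bins of {chrom}")
        return int(b)

    def global_id(self, chrom: str, bin_ordinal: int) -> int:
        if not 0 <= bin_ordinal < self.n_bins[chrom]:
            raise ValueError(f"bin {bin_ordinal} out of range for {chrom}")
        return self.offsets[chrom] + bin_ordinal

    def locate(self, global_id: int) -> tuple[str, int]:
        """Inverse of :meth:`global_id`."""
        for c in self.chroms:
            n = self.n_bins[c]
            if global_id < self.offsets[c] + n:
                return c, global_id - self.offsets[c]
        raise ValueError(f"global bin id {global_id} out of range")


def make_bins(chrom_sizes: ChromSizes, resolution: int, extra_bin: bool = True) -> BinTable:
    """Partition every chromosome into fixed-width bins.

    Parameters
    ----------
    chrom_sizes
        Chromosome lengths, in input order.
    resolution
        Bin width in bp (> 0).
    extra_bin
        If True (default), each chromosome gets ``ceil(L/res) + 1`` bins;
        otherwise ``ceil(L/res)``.  See the module docstring.
    """
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    n_bins = {}
    for name, length in chrom_sizes.items():
        n = -(-length // resolution)  # ceil division
        if extra_bin:
            n += 1
        n_bins[name] = int(n)
    return BinTable(
        resolution=int(resolution),
        extra_bin=extra_bin,
        chroms=chrom_sizes.names,
        n_bins=n_bins,
        chrom_lengths=dict(chrom_sizes.entries),
    )


@dataclass
class LPVocabulary:
    """Ordered catalogue of intra-chromosomal locus pairs within a distance cutoff.

    Pairs ``(chrom, bin_i, bin_j)`` satisfy ``i < j`` and
    ``1 <= j - i <= max_distance // resolution``, ordered by
    (chromosome order, bin_i, bin_j).  Column indices are contiguous
    from 0; the pair <-> index map is a bijection.
    """

    resolution: int
    max_distance: int
    chroms: tuple[str, ...]
    chrom_codes: np.ndarray  # (V,) int index into chroms
    bin_i: np.ndarray  # (V,) int
    bin_j: np.ndarray  # (V,) int
    bins: BinTable

    def __post_init__(self) -> None:
        self._index: dict[tuple[str, int, int], int] = {
            (self.chroms[c], int(i), int(j)): k
            for k, (c, i, j) in enumerate(zip(self.chrom_codes, self.bin_i, self.bin_j))
        }

    def __len__(self) -> int:
        return int(self.bin_i.size)

    @property
    def size(self) -> int:
        return len(self)

    @property
    def max_bin_distance(self) -> int:
        return self.max_distance // self.resolution

    def index_of(self, lp: tuple[str, int, int]) -> int:
        try:
            return self._index[(lp[0], int(lp[1]), int(lp[2]))]
        except KeyError:
            raise KeyError(f"locus pair {lp!r} not in vocabulary") from None

    def __contains__(self, lp: tuple[str, int, int]) -> bool:
        return (lp[0], int(lp[1]), int(lp[2])) in self._index

    def lp_at(self, k: int) -> tuple[str, int, int]:
        return (self.chroms[self.chrom_codes[k]], int(self.bin_i[k]), int(self.bin_j[k]))

    def distances(self) -> np.ndarray:
        """Genomic separation of every pair in bp."""
        return (self.bin_j - self.bin_i) * self.resolution

    def end_global_ids(self) -> tuple[np.ndarray, np.ndarray]:
        """Global bin ids of both ends of every pair, as two (V,) arrays."""
        offs = np.array([self.bins.offsets[c] for c in self.chroms])[self.chrom_codes]
        return offs + self.bin_i, offs + self.bin_j

    def to_tsv(self, path: str | Path) -> None:
        """Export as (chrom, start_i, end_i, start_j, end_j, column_index)."""
        res = self.resolution
        with open(path, "w") as fh:
            for k in range(len(self)):
                c, i, j = self.lp_at(k)
                fh.write(f"{c}\t{i * res}\t{(i + 1) * res}\t{j * res}\t{(j + 1) * res}\t{k}\n")


def build_lp_vocabulary(
    bins: BinTable,
    max_distance: int,
    chroms: Sequence[str] | None = None,
) -> LPVocabulary:
    """Enumerate all intra-chromosomal bin pairs within ``max_distance``.

    Self-pairs (distance 0) are excluded; the diagonal of a single-cell
    contact map is coverage-dominated and carries no pairing information.
    """
    if max_distance < bins.resolution:
        raise ValueError(
            f"max_distance {max_distance} smaller than resolution {bins.resolution}"
        )
    chroms = tuple(chroms) if chroms is not None else bins.chroms
    for c in chroms:
        if c not in bins.n_bins:
            raise KeyError(f"unknown chromosome {c!r}")
    dmax = max_distance // bins.resolution
    codes, lo, hi = [], [], []
    for ci, c in enumerate(chroms):
        n = bins.n_bins[c]
        for i in range(n - 1):
            j_end = min(i + dmax, n - 1)
            if j_end <= i:
                continue
            m = j_end - i
            codes.append(np.full(m, ci, dtype=np.int32))
            lo.append(np.full(m, i, dtype=np.int32))
            hi.append(np.arange(i + 1, j_end + 1, dtype=np.int32))
    if codes:
        chrom_codes = np.concatenate(codes)
        bin_i = np.concatenate(lo)
        bin_j = np.concatenate(hi)
    else:
        chrom_codes = np.empty(0, dtype=np.int32)
        bin_i = np.empty(0, dtype=np.int32)
        bin_j = np.empty(0, dtype=np.int32)
    return LPVocabulary(
        resolution=bins.resolution,
        max_distance=int(max_distance),
        chroms=chroms,
        chrom_codes=chrom_codes,
        bin_i=bin_i,
        bin_j=bin_j,
        bins=bins,
    )


def lp_distance(lp: tuple[str, int, int], vocab: LPVocabulary) -> int:
    """Genomic separation in bp of a vocabulary locus pair."""
    vocab.index_of(lp)  # raises if absent
    return (int(lp[2]) - int(lp[1])) * vocab.resolution
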