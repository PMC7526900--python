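"""Binarized cell-by-locus-pair matrix construction.

Cells play the role of documents and locus pairs the role of words: each
cell's cis contacts are mapped to vocabulary columns, duplicates collapse to
a single occurrence, and the result is a sparse binary cells x V matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .contacts import CellContacts
from .genome import BinTable, LPVocabulary

__all__ = ["CellLPMatrix", "CaptureReport", "build_cell_lp_matrix"]


@dataclass
class CaptureReport:
    """Tally of how contacts mapped into the vocabulary."""

    n_total: int
    n_trans: int
    n_cis: int
    n_self_pair: int
    n_beyond_distance: int
    n_unknown_chrom: int
    n_retained_cis: int
    empty_cells: list[str]

    @property
    def capture_fraction(self) -> float:
        """Fraction of cis contacts retained by the vocabulary."""
        if self.n_cis == 0:
            return 0.0
        return self.n_retained_cis / self.n_cis


@dataclass
class CellLPMatrix:
    """Sparse binary cells x locus-pairs matrix."""

    matrix: sp.csr_matrix
    cell_ids: list[str]
    vocab: LPVocabulary

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.vocab):
            raise ValueError("column count does not match vocabulary size")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    def token_counts(self) -> np.ndarray:
        """Number of distinct locus pairs observed per cell (row sums)."""
        return np.asarray(self.matrix.sum(axis=1)).ravel().astype(int)

    def to_mtx(self, directory: str | Path) -> None:
        """Serialize as MatrixMarket plus row/column label sidecars."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        from scipy.io import mmwrite

        mmwrite(directory / "matrix.mtx", self.matrix.tocoo())
        (directory / "cells.txt").write_text("\n".join(self.cell_ids) + "\n")
        self.vocab.to_tsv(directory / "locus_pairs.tsv")

    @classmethod
    def from_mtx(cls, directory: str | Path, vocab: LPVocabulary) -> "CellLPMatrix":
        from scipy.io import mmread

        directory = Path(directory)
        mat = sp.csr_matrix(mmread(directory / "matrix.mtx"))
        cells = (directory / "cells.txt").read_text().splitlines()
        return cls(mat, cells, vocab)


def build_cell_lp_matrix(
    cells: Sequence[CellContacts],
    vocab: LPVocabulary,
    bins: BinTable,
    keep_empty: bool = False,
) -> tuple[CellLPMatrix, CaptureReport]:
    """Map each cell's contacts into the vocabulary and binarize.

    A contact maps to the column of ``(chrom, bin(pos1), bin(pos2))`` with
    the bin pair normalized to i < j (Hi-C contacts are unordered).  Trans
    contacts, self-bin pairs, pairs beyond the vocabulary distance cutoff,
    and contacts on chromosomes outside the vocabulary are dropped and
    tallied.  Duplicate observations of a pair collapse to a single 1.

    Cells with zero in-vocabulary contacts are excluded from the matrix by
    default (a document with no words has no posterior) and listed in the
    report; pass ``keep_empty=True`` to retain them as all-zero rows.
    """
    if not cells:
        raise ValueError("no cells supplied")
    if len(vocab) == 0:
        raise ValueError("empty vocabulary")

    chrom_set = set(vocab.chroms)
    dmax = vocab.max_bin_distance
    res = bins.resolution

    n_trans = n_cis = n_self = n_beyond = n_unknown = n_retained = 0
    rows, cols = [], []
    row_ids: list[str] = []
    empty: list[str] = []

    for cell in cells:
        t = cell.table
        cis_mask = (t["chrom1"] == t["chrom2"]).to_numpy()
        n_trans += int((~cis_mask).sum())
        cis = t[cis_mask]
        n_cis += len(cis)
        seen: set[int] = set()
        for chrom, p1, p2 in zip(cis["chrom1"], cis["pos1"], cis["pos2"]):
            if chrom not in chrom_set:
                n_unknown += 1
                continue
            b1, b2 = int(p1) // res, int(p2) // res
            if b1 == b2:
                n_self += 1
                continue
            i, j = (b1, b2) if b1 < b2 else (b2, b1)
            if j - i > dmax:
                n_beyond += 1
                continue
            n_retained += 1
            seen.add(vocab.index_of((chrom, i, j)))
        if not seen:
            empty.append(cell.cell_id)
            if not keep_empty:
                continue
        r = len(row_ids)
        row_ids.append(cell.cell_id)
        rows.extend([r] * len(seen))
        cols.extend(sorted(seen))

    report = CaptureReport(
        n_total=sum(c.n_total for c in cells),
        n_trans=n_trans,
        n_cis=n_cis,
        n_self_pair=n_self,
        n_beyond_distance=n_beyond,
        n_unknown_chrom=n_unknown,
        n_retained_cis=n_retained,
        empty_cells=empty,
    )
    mat = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(row_ids), len(vocab)),
    )
    return CellLPMatrix(mat, row_ids, vocab), report
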