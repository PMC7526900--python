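"""Per-cell contact records: reading, quality control, downsampling.

Single-cell Hi-C experiments yield, per cell, a sparse list of chromatin
contacts (pairs of genomic positions).  This module reads pairs-like text,
applies the standard cell-level quality filters (minimum contact count,
minimum cis/trans ratio), downsamples coverage without replacement, and
computes contact-distance features used to flag mitotic-like cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import ChromSizes

__all__ = [
    "CellContacts",
    "read_contacts",
    "qc_filter_cells",
    "downsample_cell",
    "contact_distance_fractions",
    "coverage_filter_and_downsample",
]

logger = logging.getLogger(__name__)

_COLUMNS = ["chrom1", "pos1", "chrom2", "pos2"]


@dataclass
class CellContacts:
    """All contact records of one cell.

    ``table`` has columns chrom1, pos1, chrom2, pos2 (bp positions,
    0-based).  Contacts are unordered; cis means chrom1 == chrom2.
    """

    cell_id: str
    table: pd.DataFrame
    n_cis: int = field(init=False)
    n_trans: int = field(init=False)

    def __post_init__(self) -> None:
        cis = (self.table["chrom1"] == self.table["chrom2"]).to_numpy()
        self.n_cis = int(cis.sum())
        self.n_trans = int(len(self.table) - self.n_cis)

    @property
    def n_total(self) -> int:
        return len(self.table)

    @property
    def cis_trans_ratio(self) -> float:
        """cis/trans ratio; +inf when the cell has no trans contacts."""
        if self.n_trans == 0:
            return float("inf")
        return self.n_cis / self.n_trans

    def cis_table(self) -> pd.DataFrame:
        return self.table[self.table["chrom1"] == self.table["chrom2"]]


def read_contacts(
    path: str | Path,
    fmt: str = "pairs_tsv",
    chrom_sizes: ChromSizes | None = None,
    resolution: int | None = None,
    on_malformed: str = "raise",
) -> list[CellContacts]:
    """Read per-cell contact records grouped by cell id.

    Parameters
    ----------
    fmt
        ``"pairs_tsv"``: columns cell_id, chrom1, pos1, chrom2, pos2 (a
        header line is auto-detected).  ``"binned_triplets"``: columns
        cell_id, chrom, bin_i, bin_j[, count]; requires ``resolution`` and
        emits ``count`` records per row at bin-center coordinates.
    chrom_sizes
        When given, records on unknown chromosomes or with out-of-range
        positions are treated as malformed.
    on_malformed
        ``"raise"`` (default) or ``"skip"``; skipped lines are logged with
        their line numbers.
    """
    if fmt not in ("pairs_tsv", "binned_triplets"):
        raise ValueError(f"unknown format {fmt!r}")
    if fmt == "binned_triplets" and resolution is None:
        raise ValueError("binned_triplets format requires a resolution")
    if on_malformed not in ("raise", "skip"):
        raise ValueError("on_malformed must be 'raise' or 'skip'")

    rows: list[tuple] = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and _looks_like_header(fields, fmt):
                continue
            try:
                cell, c1, p1, c2, p2, count = _parse_line(
                    fields, fmt, resolution, chrom_sizes
                )
            except (ValueError, IndexError) as exc:
                if on_malformed == "raise":
                    raise ValueError(f"{path}:{lineno}: {exc}") from None
                logger.warning("%s:%d skipped: %s", path, lineno, exc)
                n_bad += 1
                continue
            rows.extend([(cell, c1, p1, c2, p2)] * count)
    if n_bad:
        logger.warning("skipped %d malformed lines in %s", n_bad, path)
    if not rows:
        logger.warning("no contact records read from %s", path)
        return []

    df = pd.DataFrame(rows, columns=["cell_id", *_COLUMNS])
    cells = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        cells.append(CellContacts(str(cell_id), grp[_COLUMNS].reset_index(drop=True)))
    return cells


def _looks_like_header(fields: list[str], fmt: str) -> bool:
    idx = (2, 4) if fmt == "pairs_tsv" else (2, 3)
    try:
        for i in idx:
            int(fields[i])
    except (ValueError, IndexError):
        return True
    return False


def _parse_line(fields, fmt, resolution, chrom_sizes):
    count = 1
    if fmt == "pairs_tsv":
        cell, c1, p1, c2, p2 = (
            fields[0],
            fields[1],
            int(fields[2]),
            fields[3],
            int(fields[4]),
        )
    else:
        cell, c1 = fields[0], fields[1]
        b1, b2 = int(fields[2]), int(fields[3])
        if len(fields) > 4:
            count = int(fields[4])
            if count < 1:
                raise ValueError(f"non-positive count {count}")
        c2 = c1
        p1 = b1 * resolution + resolution // 2
        p2 = b2 * resolution + resolution // 2
    if p1 < 0 or p2 < 0:
        raise ValueError(f"negative position ({p1}, {p2})")
    if chrom_sizes is not None:
        for c, p in ((c1, p1), (c2, p2)):
            if c not in chrom_sizes:
                raise ValueError(f"unknown chromosome {c!r}")
            if p >= chrom_sizes[c]:
                raise ValueError(f"position {p} beyond length of {c}")
    return cell, c1, p1, c2, p2, count


def qc_filter_cells(
    cells: Sequence[CellContacts],
    min_contacts: int = 1000,
    min_cis_trans_ratio: float = 1.0,
) -> tuple[list[CellContacts], pd.DataFrame]:
    """Apply the cell-level quality filters.

    A cell is retained iff its total contact count is at least
    ``min_contacts`` AND its cis/trans ratio is at least
    ``min_cis_trans_ratio`` (a cell with zero trans contacts has ratio +inf
    and always passes the ratio criterion: the filter targets noisy
    high-trans cells).

    Returns the retained cells and a QC report with one row per input cell
    (cell_id, total, cis, trans, ratio, retained, reason).
    """
    kept, report = [], []
    for cell in cells:
        reasons = []
        if cell.n_total < min_contacts:
            reasons.append(f"total<{min_contacts}")
        if cell.cis_trans_ratio < min_cis_trans_ratio:
            reasons.append(f"cis/trans<{min_cis_trans_ratio}")
        retained = not reasons
        if retained:
            kept.append(cell)
        report.append(
            {
                "cell_id": cell.cell_id,
                "total": cell.n_total,
                "cis": cell.n_cis,
                "trans": cell.n_trans,
                "ratio": cell.cis_trans_ratio,
                "retained": retained,
                "reason": ";".join(reasons),
            }
        )
    return kept, pd.DataFrame(report)


def downsample_cell(cell: CellContacts, n: int, seed: int = 0) -> CellContacts:
    """Sample ``n`` contact records without replacement, reproducibly."""
    m = cell.n_total
    if not 0 <= n <= m:
        raise ValueError(f"cannot sample {n} from {m} contacts")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(m, size=n, replace=False))
    return CellContacts(cell.cell_id, cell.table.iloc[idx].reset_index(drop=True))


def contact_distance_fractions(
    cell: CellContacts,
    short_max: int = 2_000_000,
    mitotic_range: tuple[int, int] = (2_000_000, 12_000_000),
) -> dict[str, float]:
    """Fractions of cis contacts in the short-range and mitotic distance bands.

    Distance classes on |pos2 - pos1| of cis contacts: short = [0, short_max),
    mitotic = [mitotic_range[0], mitotic_range[1]].  Mitotic-like cells show
    a high mitotic fraction and a low short fraction.
    """
    cis = cell.cis_table()
    if len(cis) == 0:
        raise ValueError(f"cell {cell.cell_id} has no cis contacts")
    d = (cis["pos2"] - cis["pos1"]).abs().to_numpy()
    frac_short = float((d < short_max).mean())
    frac_mitotic = float(((d >= mitotic_range[0]) & (d <= mitotic_range[1])).mean())
    return {"frac_short": frac_short, "frac_mitotic": frac_mitotic}


def coverage_filter_and_downsample(
    cells: Sequence[CellContacts],
    quantile: float = 0.5,
    seed: int = 0,
) -> list[CellContacts]:
    """Equalize coverage: drop low-coverage cells, downsample the rest.

    Cells with fewer total contacts than the given quantile of per-cell
    totals are discarded; surviving cells are downsampled without
    replacement to that quantile count, so all survivors end with identical
    totals.
    """
    if not cells:
        raise ValueError("no cells supplied")
    totals = np.array([c.n_total for c in cells])
    target = int(np.quantile(totals, quantile))
    out = []
    for k, cell in enumerate(cells):
        if cell.n_total < target:
            continue
        out.append(downsample_cell(cell, target, seed=seed + k))
    return out
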