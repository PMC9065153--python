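"""Input/output and read-counting rules.

Covers cell-barcode filtering and correction, weighted counting of
mate-pair alignments into genomic windows, mappability masking, and
read/write of the standard on-disk formats (MatrixMarket count matrices,
window BED files, long-form TSV, mappability tables, SAM/BAM streams).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .grids import DEFAULT_MASK_THRESHOLD, CellCounts, WindowGrid

logger = logging.getLogger(__name__)

BARCODE_LENGTH = 16
MIN_MAPQ = 30
MATE_PAIR_DISTANCE = 20_000
MIN_BASE_QUALITY = 24


class NoValidBarcodesError(ValueError):
    """Raised when no whitelisted barcode passes the abundance filter."""


@dataclass
class AlignmentRecord:
    """Minimal view of one aligned read, as needed for window counting."""

    barcode: str
    chromosome: str
    position: int
    mapq: int
    is_primary: bool = True
    is_duplicate: bool = False
    mate_chromosome: str | None = None
    mate_position: int | None = None

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        if (self.mate_chromosome is None) != (self.mate_position is None):
            raise ValueError("mate fields must both be present or both absent")


@dataclass
class BarcodeStats:
    """Result of abundance-based barcode filtering.

    High-count barcodes are those with at least 1/10 the abundance of the
    most abundant barcode; the acceptance threshold is 1/10 of the 95th
    percentile of high-count abundances (linear-interpolation percentile).
    """

    abundances: dict[str, int]
    high_count_floor: float
    min_abundance_threshold: float
    accepted_set: set[str]


def build_barcode_set(raw_abundances: dict[str, int],
                      whitelist: set[str]) -> BarcodeStats:
    """Filter barcodes by abundance against a whitelist."""
    if not raw_abundances:
        raise ValueError("raw_abundances is empty")
    if not whitelist:
        raise ValueError("whitelist is empty")
    listed = {bc: n for bc, n in raw_abundances.items() if bc in whitelist}
    if not listed:
        raise NoValidBarcodesError("no valid barcodes: abundance table and "
                                   "whitelist are disjoint")
    counts = np.array(list(listed.values()), dtype=float)
    high_count_floor = counts.max() / 10.0
    high = counts[counts >= high_count_floor]
    threshold = float(np.percentile(high, 95)) / 10.0
    accepted = {bc for bc, n in listed.items() if n >= threshold}
    if not accepted:
        raise NoValidBarcodesError("no valid barcodes above abundance threshold")
    return BarcodeStats(dict(listed), high_count_floor, threshold, accepted)


def correct_barcode(observed: str, base_qualities: Sequence[int],
                    valid_set: set[str]) -> str | None:
    """Correct a barcode to a unique Hamming-distance-1 valid neighbor.

    Returns ``observed`` unchanged if already valid. Correction is only
    attempted when at most one base has quality < 24, and succeeds only
    when exactly one valid barcode lies at Hamming distance 1.
    """
    if len(observed) != BARCODE_LENGTH:
        raise ValueError(f"barcode must be {BARCODE_LENGTH} bp, "
                         f"got {len(observed)}")
    if len(base_qualities) != len(observed):
        raise ValueError("base_qualities length must match barcode length")
    if observed in valid_set:
        return observed
    if sum(q < MIN_BASE_QUALITY for q in base_qualities) > 1:
        return None
    neighbors = []
    for i in range(len(observed)):
        for base in "ACGT":
            if base == observed[i]:
                continue
            cand = observed[:i] + base + observed[i + 1:]
            if cand in valid_set:
                neighbors.append(cand)
                if len(neighbors) > 1:
                    return None
    return neighbors[0] if len(neighbors) == 1 else None


def _record_weight(rec: AlignmentRecord) -> float:
    # Mates on the same chromosome within 20 kb are two halves of one
    # fragment (0.5 each); distant or unpaired reads count fully.
    if (rec.mate_chromosome == rec.chromosome
            and rec.mate_position is not None
            and abs(rec.mate_position - rec.position) <= MATE_PAIR_DISTANCE):
        return 0.5
    return 1.0


def count_weighted_reads(records: Iterable[AlignmentRecord],
                         grid: WindowGrid) -> dict[str, CellCounts]:
    """Accumulate weighted read counts per window per barcode.

    Only primary, non-duplicate alignments with MAPQ >= 30 contribute. A
    read belongs to the window containing its leftmost aligned base;
    reads outside the grid are skipped (and logged).
    """
    per_barcode: dict[str, np.ndarray] = {}
    skipped = 0
    for rec in records:
        if not rec.is_primary or rec.is_duplicate or rec.mapq < MIN_MAPQ:
            continue
        idx = grid.window_index(rec.chromosome, rec.position)
        if idx is None:
            skipped += 1
            continue
        vec = per_barcode.get(rec.barcode)
        if vec is None:
            vec = per_barcode[rec.barcode] = np.zeros(grid.n_windows)
        vec[idx] += _record_weight(rec)
    if skipped:
        logger.info("count_weighted_reads: %d reads outside grid skipped", skipped)
    return {bc: CellCounts(bc, grid, vec) for bc, vec in per_barcode.items()}


def apply_mappability_mask(grid: WindowGrid, mappability: np.ndarray,
                           threshold: float = DEFAULT_MASK_THRESHOLD) -> WindowGrid:
    """Mask windows whose uniquely-mappable fraction is below ``threshold``."""
    mappability = np.asarray(mappability, dtype=float)
    if len(mappability) != grid.n_windows:
        raise ValueError("mappability length does not match grid")
    if np.any((mappability < 0) | (mappability > 1)):
        raise ValueError("mappability fractions must lie in [0, 1]")
    return WindowGrid(grid.chrom, grid.start, grid.end,
                      mappability, mappability < threshold)


# ---------------------------------------------------------------------------
# On-disk formats


def read_sam_records(path: str | Path, barcode_tag: str = "CB"
                     ) -> Iterable[AlignmentRecord]:
    """Stream alignment records from SAM/BAM, taking the barcode from a tag."""
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or not aln.has_tag(barcode_tag):
                continue
            mate_chrom = mate_pos = None
            if aln.is_paired and not aln.mate_is_unmapped \
                    and aln.next_reference_name is not None:
                mate_chrom = aln.next_reference_name
                mate_pos = aln.next_reference_start
            yield AlignmentRecord(
                barcode=str(aln.get_tag(barcode_tag)),
                chromosome=aln.reference_name,
                position=aln.reference_start,
                mapq=aln.mapping_quality,
                is_primary=not (aln.is_secondary or aln.is_supplementary),
                is_duplicate=aln.is_duplicate,
                mate_chromosome=mate_chrom,
                mate_position=mate_pos,
            )


def write_window_bed(grid: WindowGrid, path: str | Path,
                     scores: np.ndarray | None = None) -> None:
    df = grid.to_frame()
    if scores is not None:
        df["score"] = scores
    df.to_csv(path, sep="\t", header=False, index=False)


def read_window_bed(path: str | Path) -> WindowGrid:
    df = pd.read_csv(path, sep="\t", header=None)
    df.columns = ["chrom", "start", "end", "mappable_fraction", "masked",
                  "score"][:df.shape[1]]
    return WindowGrid.from_frame(df)


def write_count_matrix(cells: Sequence[CellCounts], prefix: str | Path) -> None:
    """Write counts as MatrixMarket (windows x cells) + window BED + cell list."""
    prefix = Path(prefix)
    if not cells:
        raise ValueError("no cells to write")
    grid = cells[0].grid
    mat = scipy.sparse.csc_matrix(
        np.column_stack([c.counts for c in cells]))
    scipy.io.mmwrite(str(prefix) + ".mtx", mat)
    write_window_bed(grid, str(prefix) + ".windows.bed")
    Path(str(prefix) + ".cells.txt").write_text(
        "".join(c.cell_id + "\n" for c in cells))


def read_count_matrix(prefix: str | Path) -> list[CellCounts]:
    prefix = Path(prefix)
    mat = scipy.io.mmread(str(prefix) + ".mtx").toarray()
    grid = read_window_bed(str(prefix) + ".windows.bed")
    cell_ids = Path(str(prefix) + ".cells.txt").read_text().split()
    if mat.shape != (grid.n_windows, len(cell_ids)):
        raise ValueError("matrix shape does not match windows/cells")
    return [CellCounts(cid, grid, mat[:, j]) for j, cid in enumerate(cell_ids)]


def write_counts_tsv(cells: Sequence[CellCounts], path: str | Path) -> None:
    """Long-form TSV: cell, chrom, start, end, count (nonzero rows only)."""
    frames = []
    for c in cells:
        nz = np.flatnonzero(c.counts)
        frames.append(pd.DataFrame({
            "cell": c.cell_id, "chrom": c.grid.chrom[nz],
            "start": c.grid.start[nz], "end": c.grid.end[nz],
            "count": c.counts[nz]}))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_mappability_tsv(path: str | Path) -> np.ndarray:
    """Per-window mappable fraction from a TSV (chrom, start, end, fraction)."""
    df = pd.read_csv(path, sep="\t")
    return df.iloc[:, -1].to_numpy(dtype=float)
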