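"""Genome window grids and per-cell binned counts.

The whole pipeline operates on read counts binned into genomic windows:
either fixed-size windows (20 kb by default) or variable-size windows that
each contain a fixed number of reads from an aggregated G1/G2 reference.
Coordinates are 0-based half-open throughout, as in BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_WINDOW_SIZE = 20_000
DEFAULT_MASK_THRESHOLD = 0.75

# integer codes for per-window replication / copy state
STATE_2N = 2        # unreplicated
STATE_4N = 4        # replicated
STATE_MASKED = -1   # no call


@dataclass
class WindowGrid:
    """A partition of the genome into sorted, non-overlapping windows.

    Parameters
    ----------
    chrom : array of str
        Chromosome name per window.
    start, end : array of int
        0-based half-open coordinates. Windows are sorted and
        non-overlapping within each chromosome.
    mappable_fraction : array of float
        Fraction of uniquely mappable positions in each window, in [0, 1].
    masked : array of bool
        True for windows excluded from analysis (low mappability).
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    mappable_fraction: np.ndarray
    masked: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.mappable_fraction = np.asarray(self.mappable_fraction, dtype=float)
        self.masked = np.asarray(self.masked, dtype=bool)
        n = len(self.chrom)
        if not (len(self.start) == len(self.end) == len(self.mappable_fraction)
                == len(self.masked) == n):
            raise ValueError("WindowGrid field lengths differ")
        if np.any(self.start >= self.end):
            raise ValueError("windows must satisfy start < end")
        if np.any((self.mappable_fraction < 0) | (self.mappable_fraction > 1)):
            raise ValueError("mappable_fraction must lie in [0, 1]")
        for _, idx in self.chrom_groups().items():
            if np.any(np.diff(self.start[idx]) <= 0):
                raise ValueError("windows within a chromosome must be sorted")
            if np.any(self.end[idx][:-1] > self.start[idx][1:]):
                raise ValueError("windows within a chromosome overlap")

    def __len__(self) -> int:
        return len(self.chrom)

    @property
    def n_windows(self) -> int:
        return len(self.chrom)

    @property
    def sizes(self) -> np.ndarray:
        return self.end - self.start

    @property
    def centers(self) -> np.ndarray:
        return (self.start + self.end) / 2.0

    @property
    def unmasked(self) -> np.ndarray:
        """Boolean selector for analysable windows."""
        return ~self.masked

    @property
    def unmasked_span_bp(self) -> int:
        return int(np.sum(self.sizes[~self.masked]))

    def chrom_groups(self) -> dict[str, np.ndarray]:
        """Window indices per chromosome, in grid order."""
        groups: dict[str, list[int]] = {}
        for i, c in enumerate(self.chrom):
            groups.setdefault(c, []).append(i)
        return {c: np.asarray(ix, dtype=np.int64) for c, ix in groups.items()}

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom, "start": self.start, "end": self.end,
            "mappable_fraction": self.mappable_fraction, "masked": self.masked,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WindowGrid":
        return cls(
            chrom=df["chrom"].to_numpy(dtype=object),
            start=df["start"].to_numpy(),
            end=df["end"].to_numpy(),
            mappable_fraction=df.get(
                "mappable_fraction", pd.Series(np.ones(len(df)))).to_numpy(),
            masked=df.get("masked", pd.Series(np.zeros(len(df), bool))).to_numpy(),
        )

    @classmethod
    def fixed_windows(cls, chrom_sizes: dict[str, int],
                      window_size: int = DEFAULT_WINDOW_SIZE) -> "WindowGrid":
        """Tile chromosomes with fixed-size windows; trailing remainder dropped."""
        chroms, starts, ends = [], [], []
        for c, size in chrom_sizes.items():
            n = size // window_size
            for i in range(n):
                chroms.append(c)
                starts.append(i * window_size)
                ends.append((i + 1) * window_size)
        n_tot = len(chroms)
        if n_tot == 0:
            raise ValueError("no chromosome long enough for one window")
        return cls(np.array(chroms, dtype=object), np.array(starts),
                   np.array(ends), np.ones(n_tot), np.zeros(n_tot, bool))

    def window_index(self, chrom: str, position: int) -> int | None:
        """Index of the window containing ``position``, or None if outside."""
        sel = np.flatnonzero(self.chrom == chrom)
        if len(sel) == 0:
            return None
        starts = self.start[sel]
        j = int(np.searchsorted(starts, position, side="right")) - 1
        if j < 0 or position >= self.end[sel[j]]:
            return None
        return int(sel[j])


@dataclass
class CellCounts:
    """Per-window (possibly weighted) read counts for one cell."""

    cell_id: str
    grid: WindowGrid
    counts: np.ndarray
    total_reads: float = field(init=False)
    coverage_per_mb: float = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != self.grid.n_windows:
            raise ValueError("counts length does not match grid")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        unmasked = self.grid.unmasked
        self.total_reads = float(np.sum(self.counts[unmasked]))
        span = self.grid.unmasked_span_bp
        self.coverage_per_mb = self.total_reads / span * 1e6 if span else float("nan")
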