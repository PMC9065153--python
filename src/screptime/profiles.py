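"""Aggregate S/G1 replication-timing profiles and sub-S-phase fractions.

Summing reads across all S-phase cells and dividing by the G1 reference in
fixed-coverage windows gives an ensemble replication-timing profile: early
regions are replicated in more S cells, so their S/G1 ratio is higher. The
raw ratio is smoothed per chromosome with a cubic smoothing spline and
z-normalized (mean 0, sd 1), the field's usual convention for timing
profiles. Cells can also be partitioned by S-phase progression into equal
population fractions whose summed counts visualize replication spreading
from discrete initiation sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.interpolate
import scipy.signal

from .g1windows import G1Windows
from .grids import CellCounts
from .hmm import CellReplicationProfile

# csaps-style smoothing parameter p in (0, 1]: the spline minimizes
# p * sum(residual^2) + (1-p) * integral(f'')^2 with base-pair abscissa,
# equivalent to lam = (1-p)/p in scipy's make_smoothing_spline.
DEFAULT_SMOOTHING_P = 1e-16
FRACTION_ANCHOR_LOW = 2.0    # value mapped from the 1st percentile
FRACTION_ANCHOR_HIGH = 4.0   # value mapped from the 99.9th percentile


@dataclass
class AggregateProfile:
    """Ensemble replication-timing profile on fixed-coverage windows."""

    windows: G1Windows
    raw_ratio: np.ndarray
    smoothed: np.ndarray
    normalized: np.ndarray
    smoothing_p: float = DEFAULT_SMOOTHING_P

    def value_at(self, chrom: str, position: int) -> float:
        idx = self.windows.grid.window_index(chrom, position)
        if idx is None:
            return float("nan")
        return float(self.normalized[idx])


def _smooth_chromosome(x: np.ndarray, y: np.ndarray, p: float) -> np.ndarray:
    if len(x) < 4:
        return y.copy()
    lam = (1.0 - p) / p
    spl = scipy.interpolate.make_smoothing_spline(x, y, lam=lam)
    return spl(x)


def aggregate_sg1_profile(windows: G1Windows, s_cells: list[CellCounts],
                          smoothing_p: float = DEFAULT_SMOOTHING_P
                          ) -> AggregateProfile:
    """S/G1 ratio per fixed-coverage window, smoothed and z-normalized.

    ``s_cells`` are fine-grid counts of S-phase cells; they are summed and
    re-counted in the reference-defined windows. Smoothing is fitted per
    chromosome over window centers (gap-aware: only windows with data
    enter the fit domain).
    """
    if not s_cells:
        raise ValueError("need at least one S-phase cell")
    s_total = np.zeros(windows.fine_grid.n_windows)
    for c in s_cells:
        s_total += c.counts
    s_counts = windows.count_cell(
        CellCounts("S_pool", windows.fine_grid, s_total)).counts
    ref = windows.ref_counts
    if np.any(ref <= 0):
        raise ValueError("reference windows with zero counts")
    raw = s_counts / ref
    grid = windows.grid
    smoothed = np.empty_like(raw)
    for _, idx in grid.chrom_groups().items():
        centers = grid.centers[idx]
        smoothed[idx] = _smooth_chromosome(centers, raw[idx], smoothing_p)
    sd = smoothed.std()
    if sd < 1e-12 * max(1.0, abs(float(smoothed.mean()))):
        raise ValueError("zero-variance profile: S counts proportional to "
                         "reference everywhere")
    normalized = (smoothed - smoothed.mean()) / sd
    return AggregateProfile(windows, raw, smoothed, normalized, smoothing_p)


@dataclass
class FractionMatrix:
    """Summed counts of cells binned by S-phase progression."""

    n_fractions: int
    raw: np.ndarray        # (n_fractions, n_windows) summed counts
    scaled: np.ndarray     # anchored to copy-number units (2 .. 4)
    cell_bins: list[list[str]]
    anchor_low_value: float
    anchor_high_value: float


def subfraction_matrix(profiles: list[CellReplicationProfile],
                       counts_by_cell: dict[str, CellCounts],
                       windows: G1Windows, n_fractions: int = 10
                       ) -> FractionMatrix:
    """Partition cells into equal-population bins by fraction replicated,
    sum their G1-window counts per bin, and rescale so the 1st percentile
    of all (fraction, window) values maps to 2 and the 99.9th to 4."""
    if n_fractions < 1 or n_fractions > len(profiles):
        raise ValueError("n_fractions must be in [1, number of cells]")
    order = sorted(profiles, key=lambda p: (p.fraction_replicated, p.cell_id))
    bins = np.array_split(np.arange(len(order)), n_fractions)
    raw = np.zeros((n_fractions, windows.grid.n_windows))
    cell_bins: list[list[str]] = []
    for bi, members in enumerate(bins):
        ids = []
        for k in members:
            cid = order[k].cell_id
            ids.append(cid)
            raw[bi] += windows.count_cell(counts_by_cell[cid]).counts
        cell_bins.append(ids)
    p1 = float(np.percentile(raw, 1))
    p999 = float(np.percentile(raw, 99.9))
    if p999 <= p1:
        raise ValueError("degenerate percentile anchors")
    scaled = (FRACTION_ANCHOR_LOW
              + (raw - p1) / (p999 - p1)
              * (FRACTION_ANCHOR_HIGH - FRACTION_ANCHOR_LOW))
    return FractionMatrix(n_fractions, raw, scaled, cell_bins, p1, p999)


def call_peaks(profile: AggregateProfile, min_prominence: float = 0.1
               ) -> list[int]:
    """Local maxima of the normalized profile (candidate initiation zones).

    Returns window indices of peaks with prominence >= ``min_prominence``
    (in sd units of the normalized profile), detected per chromosome.
    """
    grid = profile.windows.grid
    peaks = []
    for _, idx in grid.chrom_groups().items():
        y = profile.normalized[idx]
        loc, _ = scipy.signal.find_peaks(y, prominence=min_prominence)
        peaks.extend(int(idx[i]) for i in loc)
    return peaks


def correlate_with_bulk(profile: AggregateProfile,
                        bulk: pd.DataFrame) -> float:
    """Pearson correlation with a bulk timing profile.

    ``bulk`` is bedGraph-like (chrom, start, end, value); values are
    mapped onto the profile's windows by overlap-weighted averaging.
    """
    grid = profile.windows.grid
    mapped = np.full(grid.n_windows, np.nan)
    for chrom, idx in grid.chrom_groups().items():
        sub = bulk[bulk.iloc[:, 0] == chrom]
        if sub.empty:
            continue
        b_start = sub.iloc[:, 1].to_numpy()
        b_end = sub.iloc[:, 2].to_numpy()
        b_val = sub.iloc[:, 3].to_numpy(dtype=float)
        order = np.argsort(b_start)
        b_start, b_end, b_val = b_start[order], b_end[order], b_val[order]
        j0 = 0
        for ti in idx:
            t0, t1 = grid.start[ti], grid.end[ti]
            while j0 < len(b_start) and b_end[j0] <= t0:
                j0 += 1
            w = v = 0.0
            j = j0
            while j < len(b_start) and b_start[j] < t1:
                ov = min(t1, b_end[j]) - max(t0, b_start[j])
                if ov > 0:
                    w += ov
                    v += ov * b_val[j]
                j += 1
            if w > 0:
                mapped[ti] = v / w
    shared = np.isfinite(mapped)
    if shared.sum() < 100:
        raise ValueError("fewer than 100 shared windows with the bulk profile")
    return float(np.corrcoef(profile.normalized[shared], mapped[shared])[0, 1])
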