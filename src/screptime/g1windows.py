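"""G1 reference construction, fixed-coverage windows, and CNA masking.

Read depth in fixed-size genomic windows is biased by mappability and GC
content, and by copy-number variants shared across a library. Normalizing
against an in silico G1/G2 reference removes these shared biases: reads
from high-coverage non-replicating cells are aggregated, and the genome is
re-partitioned into variable-size windows that each contain a fixed number
of reference reads. Counting every cell in these "G1 windows" makes a
uniform-copy-number cell's expected counts flat across the genome.

Cell-specific copy-number aberrations (CNAs) are then detected per cell by
iteratively fitting a two-component Poisson mixture to ~300-kb aggregate
counts and masking regions that fit neither rate, with a lag-1
autocorrelation check to catch cells with residual undetected CNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grids import CellCounts, WindowGrid
from .mixture import (PoissonMixtureFit, component_scores, fit_poisson_mixture,
                      log_tail_probability)

logger = logging.getLogger(__name__)

DEFAULT_READS_PER_WINDOW = 200
DEFAULT_TARGET_WINDOW_KB = 20.0
CNA_AGGREGATE_SIZE = 15
AUTOCORR_THRESHOLD = 0.15


@dataclass
class G1Reference:
    """Aggregated counts from high-coverage G1/G2 cells on the fine grid."""

    cell_ids: list[str]
    grid: WindowGrid
    counts: np.ndarray
    reads_per_window: int
    target_met: bool = True

    @property
    def total_reads(self) -> float:
        return float(np.sum(self.counts[self.grid.unmasked]))


@dataclass
class G1Windows:
    """Variable-size fixed-coverage windows derived from a G1 reference.

    ``fine_slices`` maps each window to the half-open range of fine-grid
    bin indices it was built from, so cells counted on the fine grid can
    be re-counted here; masked fine bins inside a window contribute 0.
    """

    grid: WindowGrid
    ref_counts: np.ndarray
    fine_grid: WindowGrid
    fine_slices: list[tuple[int, int]]

    def count_cell(self, cell: CellCounts) -> CellCounts:
        if cell.grid is not self.fine_grid and \
                cell.grid.n_windows != self.fine_grid.n_windows:
            raise ValueError("cell counts are not on the reference fine grid")
        unmasked = self.fine_grid.unmasked
        vals = np.where(unmasked, cell.counts, 0.0)
        cum = np.concatenate([[0.0], np.cumsum(vals)])
        out = np.array([cum[b] - cum[a] for a, b in self.fine_slices])
        return CellCounts(cell.cell_id, self.grid, out)


def build_g1_reference(g1_cells: list[CellCounts],
                       reads_per_window: int = DEFAULT_READS_PER_WINDOW,
                       target_window_kb: float = DEFAULT_TARGET_WINDOW_KB
                       ) -> G1Reference:
    """Aggregate G1/G2 cells, highest coverage first, until the expected
    mean window size (genome span / expected number of windows) reaches
    the target."""
    if not g1_cells:
        raise ValueError("need at least one G1/G2 cell")
    grid = g1_cells[0].grid
    span_bp = grid.unmasked_span_bp
    target_bp = target_window_kb * 1000.0
    order = sorted(g1_cells, key=lambda c: c.coverage_per_mb, reverse=True)
    agg = np.zeros(grid.n_windows)
    used: list[str] = []
    total = 0.0
    for cell in order:
        agg += cell.counts
        used.append(cell.cell_id)
        total += cell.total_reads
        if total > 0 and span_bp / (total / reads_per_window) <= target_bp:
            return G1Reference(used, grid, agg, reads_per_window, True)
    logger.warning("G1 reference short of target: expected window %.1f kb",
                   span_bp / max(total / reads_per_window, 1e-12) / 1000)
    return G1Reference(used, grid, agg, reads_per_window, False)


def define_fixed_coverage_windows(reference: G1Reference,
                                  reads_per_window: int | None = None
                                  ) -> G1Windows:
    """Partition each chromosome into windows of ~``reads_per_window``
    reference reads.

    Walking fine bins left to right, a window boundary is emitted (at the
    fine-bin edge) each time the cumulative reference count reaches the
    next multiple of ``reads_per_window``; the trailing remainder of each
    chromosome is dropped. Masked fine bins contribute nothing and are
    spanned silently.
    """
    rpw = reads_per_window or reference.reads_per_window
    if reference.total_reads < rpw:
        raise ValueError("reference has fewer reads than one window requires")
    fine = reference.grid
    chroms, starts, ends, ref_counts = [], [], [], []
    slices: list[tuple[int, int]] = []
    for chrom, idx in fine.chrom_groups().items():
        vals = np.where(fine.unmasked[idx], reference.counts[idx], 0.0)
        if vals.sum() < rpw:
            logger.info("chromosome %s has < %d reference reads; no windows",
                        chrom, rpw)
            continue
        window_start_bin = 0  # position within idx
        window_count = 0.0
        for j, v in enumerate(vals):
            window_count += v
            # boundary snaps to the fine-bin edge where the running count
            # crosses the per-window quota, so every window holds at least
            # reads_per_window reference reads
            if window_count >= rpw:
                chroms.append(chrom)
                starts.append(fine.start[idx[window_start_bin]])
                ends.append(fine.end[idx[j]])
                ref_counts.append(window_count)
                slices.append((int(idx[window_start_bin]), int(idx[j]) + 1))
                window_start_bin = j + 1
                window_count = 0.0
    grid = WindowGrid(np.array(chroms, dtype=object), np.array(starts),
                      np.array(ends), np.ones(len(chroms)),
                      np.zeros(len(chroms), bool))
    return G1Windows(grid=grid, ref_counts=np.array(ref_counts),
                     fine_grid=fine, fine_slices=slices)


@dataclass
class CnaMaskResult:
    masked_regions: list[tuple[int, int]]   # half-open window index ranges
    iterations: int
    rate_fits: list[PoissonMixtureFit] = field(default_factory=list)
    mask: np.ndarray | None = None          # final per-window boolean mask
    flagged: bool = False                   # EM failed; no masking applied


def _aggregate_indices(grid: WindowGrid, active: np.ndarray,
                       size: int) -> list[np.ndarray]:
    """Runs of ``size`` consecutive active windows, within chromosomes."""
    out = []
    for _, idx in grid.chrom_groups().items():
        live = idx[active[idx]]
        for k in range(len(live) // size):
            out.append(live[k * size:(k + 1) * size])
    return out


def detect_and_mask_cna(cell: CellCounts,
                        aggregate_size: int = CNA_AGGREGATE_SIZE,
                        max_iterations: int = 50,
                        mixture_min_weight: float = 0.05,
                        region_tail_alpha: float = 1e-6) -> CnaMaskResult:
    """Iteratively find and mask copy-number-aberrant regions in one cell.

    Each round fits a two-rate Poisson mixture to aggregated counts
    (``aggregate_size`` windows, ~300 kb on 20-kb-scale windows; mixing
    weights floored so neither rate can specialize to a small aberrant
    region), scores every aggregate by its probability under the
    better-fitting rate, and grows a candidate region from the
    worst-scoring aggregate, greedily adding whichever neighbor most
    lowers the region's pooled tail probability. The region is masked
    when (a) its total count is a genuine outlier under both rates
    (one-sided tail probability below ``region_tail_alpha`` — at
    single-cell coverage individual 20-kb windows carry no usable signal,
    so the evidence is pooled over the region) and (b) its median
    aggregate probability is below the genome-wide median. Rounds repeat
    until no region qualifies.
    """
    grid = cell.grid
    active = grid.unmasked.copy()
    if np.all(cell.counts[active] == 0):
        raise ValueError("insufficient signal: all counts are zero")
    regions: list[tuple[int, int]] = []
    fits: list[PoissonMixtureFit] = []
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        aggs = _aggregate_indices(grid, active, aggregate_size)
        if len(aggs) < 30:
            break
        sums = np.array([cell.counts[a].sum() for a in aggs])
        try:
            fit = fit_poisson_mixture(sums, min_weight=mixture_min_weight)
        except ValueError:
            return CnaMaskResult(regions, iterations, fits, mask=None,
                                 flagged=True)
        if not fit.converged:
            return CnaMaskResult(regions, iterations, fits, mask=None,
                                 flagged=True)
        fits.append(fit)
        agg_scores = component_scores(sums, fit)
        med_agg = np.median(agg_scores)
        worst = int(np.argmin(agg_scores))
        lo = hi = worst
        total = float(sums[worst])
        logp = log_tail_probability(total, fit, 1)
        while True:
            # candidate extensions: one or two aggregates on either side
            # (two-step lookahead rides over a diluted boundary aggregate
            # when the deletion edge is not aggregate-aligned)
            options = []
            for dlo, dhi in ((1, 0), (0, 1), (2, 0), (0, 2)):
                nlo, nhi = lo - dlo, hi + dhi
                if nlo < 0 or nhi >= len(aggs):
                    continue
                t = float(sums[nlo:nhi + 1].sum())
                options.append((log_tail_probability(
                    t, fit, nhi - nlo + 1), nlo, nhi))
            if not options:
                break
            best = min(options)
            if best[0] >= logp:
                break
            logp, lo, hi = best
            total = float(sums[lo:hi + 1].sum())
        outlier = logp < np.log(region_tail_alpha)
        below_median = np.median(agg_scores[lo:hi + 1]) < med_agg
        if outlier and below_median:
            region_windows = np.concatenate(aggs[lo:hi + 1])
            active[region_windows] = False
            regions.append((int(region_windows.min()),
                            int(region_windows.max()) + 1))
        else:
            break
    mask = grid.unmasked & ~active
    return CnaMaskResult(regions, iterations, fits, mask=mask)


def autocorrelation_qc(cell: CellCounts, mask: np.ndarray | None = None,
                       threshold: float = AUTOCORR_THRESHOLD
                       ) -> tuple[bool, float]:
    """Lag-1 autocorrelation of unmasked window counts.

    Pairs never span masked gaps or chromosome boundaries. Returns
    (passed, statistic); cells above the threshold likely carry residual
    undetected CNAs. Constant counts have undefined correlation and are
    reported as 0 (pass).
    """
    grid = cell.grid
    usable = grid.unmasked.copy()
    if mask is not None:
        usable &= ~np.asarray(mask, dtype=bool)
    if usable.sum() < 100:
        raise ValueError("insufficient windows: need >= 100 unmasked")
    xs, ys = [], []
    for _, idx in grid.chrom_groups().items():
        u = usable[idx]
        pair = u[:-1] & u[1:]
        xs.append(cell.counts[idx[:-1][pair]])
        ys.append(cell.counts[idx[1:][pair]])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return True, 0.0
    stat = float(np.corrcoef(x, y)[0, 1])
    return stat <= threshold, stat
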