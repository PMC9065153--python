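"""Firing-order, firing-time, and firing-class analysis of IRs across cells.

If every cell fired the same initiation regions in the same order, a
cell's count of replicated IRs would fully determine which IRs those are:
the n earliest by ensemble timing. Deviations from that null — "premature"
replication of late IRs or "delayed" replication of early ones — quantify
cell-to-cell stochasticity in origin firing order. The observed range of
S-phase times at which an IR fires, and a three-way classification of
infrequently firing IRs (rarely-but-early, throughout S phase,
constitutively late), characterize firing-time variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .grids import STATE_2N, STATE_4N, STATE_MASKED
from .hmm import CellReplicationProfile
from .ir_calling import InitiationRegion, ReplicationTrack

CORROBORATION_WINDOW_PCT = 10.0
LATE_CLASS_EARLY_CUTOFF = 50.0       # % genome replicated defining "early S"
THROUGHOUT_MIN_LATE_CELLS = 5


def rank_irs_by_timing(irs: list[InitiationRegion]) -> list[InitiationRegion]:
    """IRs sorted earliest first (highest aggregate timing value)."""
    return sorted(irs, key=lambda ir: -ir.aggregate_timing)


def observed_ir_states(profiles: list[CellReplicationProfile],
                       irs: list[InitiationRegion],
                       tracks: list[ReplicationTrack],
                       rule: str = "track_overlap") -> np.ndarray:
    """Boolean matrix (cells x IRs): is each IR replicated in each cell?

    ``track_overlap`` (default): an IR is replicated in a cell when at
    least one of the cell's replicated tracks overlaps the IR's
    [start, end] span. ``center_window``: when the fixed window containing
    the IR center is 4N.
    """
    cell_index = {p.cell_id: i for i, p in enumerate(profiles)}
    out = np.zeros((len(profiles), len(irs)), dtype=bool)
    if rule == "track_overlap":
        by_cell_chrom: dict[tuple[str, str], list[ReplicationTrack]] = {}
        for t in tracks:
            by_cell_chrom.setdefault((t.cell_id, t.chromosome), []).append(t)
        for j, ir in enumerate(irs):
            for i, p in enumerate(profiles):
                for t in by_cell_chrom.get((p.cell_id, ir.chromosome), []):
                    if t.start_bp <= ir.end and t.end_bp >= ir.start:
                        out[i, j] = True
                        break
    elif rule == "center_window":
        for j, ir in enumerate(irs):
            for i, p in enumerate(profiles):
                wi = p.grid.window_index(ir.chromosome, int(ir.center))
                out[i, j] = wi is not None and p.states[wi] == STATE_4N
    else:
        raise ValueError(f"unknown rule: {rule}")
    del cell_index
    return out


def expected_states(observed: np.ndarray, irs: list[InitiationRegion]
                    ) -> np.ndarray:
    """Expected per-cell IR states under the deterministic-order null.

    A cell with n replicated IRs is expected to have replicated exactly
    the n earliest-ranked IRs (by aggregate timing).
    """
    rank = np.argsort(np.argsort(
        [-ir.aggregate_timing for ir in irs], kind="stable"), kind="stable")
    expected = np.zeros_like(observed)
    n_per_cell = observed.sum(axis=1)
    for i, n in enumerate(n_per_cell):
        expected[i] = rank < n
    return expected


@dataclass
class FiringOrderResult:
    n_premature: np.ndarray        # per IR
    n_delayed: np.ndarray
    n_cells_observed: int
    mismatch_fraction: np.ndarray
    timing: np.ndarray             # aggregate timing per IR
    parabola: np.ndarray | None    # quadratic coefficients (np.polyfit order)
    fit_irs: np.ndarray | None     # mask of IRs included in the fit
    degenerate_fit: bool = False

    @property
    def mean_mismatch(self) -> float:
        return float(np.mean(self.mismatch_fraction))


def firing_order_stats(observed: np.ndarray, expected: np.ndarray,
                       irs: list[InitiationRegion],
                       min_cells: int = 5) -> FiringOrderResult:
    """Per-IR mismatch with the fixed-order null, plus a quadratic trend.

    Premature: replicated although not expected; delayed: expected but
    unreplicated. The mismatch fraction is regressed on aggregate timing
    with a 2nd-order polynomial (IRs observed in fewer than ``min_cells``
    cells are excluded from the fit; the fit is refused when fewer than 3
    distinct timing values remain).
    """
    n_cells = observed.shape[0]
    premature = (observed & ~expected).sum(axis=0)
    delayed = (~observed & expected).sum(axis=0)
    mismatch = (premature + delayed) / n_cells
    timing = np.array([ir.aggregate_timing for ir in irs])
    fired_in = observed.sum(axis=0)
    fit_mask = fired_in >= min_cells
    parabola = None
    degenerate = False
    if len(np.unique(timing[fit_mask])) >= 3 and np.ptp(mismatch[fit_mask]) > 0:
        parabola = np.polyfit(timing[fit_mask], mismatch[fit_mask], 2)
    else:
        degenerate = True
    return FiringOrderResult(
        n_premature=premature, n_delayed=delayed, n_cells_observed=n_cells,
        mismatch_fraction=mismatch, timing=timing, parabola=parabola,
        fit_irs=fit_mask, degenerate_fit=degenerate)


@dataclass
class FiringRange:
    ir_id: int
    earliest_fired_pct: float
    latest_unfired_pct: float          # nan when no valid unfired cell
    earliest_corroborated: bool
    latest_corroborated: bool
    single_time: bool = False          # earliest > latest: one firing time


def _flanking_irs(ir: InitiationRegion, irs: list[InitiationRegion]
                  ) -> list[int]:
    """Indices (into irs) of the nearest IR on each side, same chromosome."""
    left = right = None
    left_d = right_d = np.inf
    for k, other in enumerate(irs):
        if other.ir_id == ir.ir_id or other.chromosome != ir.chromosome:
            continue
        d = other.center - ir.center
        if d < 0 and -d < left_d:
            left, left_d = k, -d
        elif d > 0 and d < right_d:
            right, right_d = k, d
    return [k for k in (left, right) if k is not None]


def firing_range(ir: InitiationRegion, ir_index: int,
                 profiles: list[CellReplicationProfile],
                 observed: np.ndarray, irs: list[InitiationRegion],
                 tracks: list[ReplicationTrack]) -> FiringRange:
    """Range of S-phase times (as % genome replicated) at which an IR fires.

    The earliest firing is the least-replicated cell with a track
    attributed to the IR; the latest non-firing is the most-replicated
    cell whose window at the IR center is still unreplicated, after
    dropping outlier cells that have not replicated either neighboring
    IR. Each end is corroborated when a second, distinct cell lies within
    10 percentage points of it.
    """
    pct = {p.cell_id: p.fraction_replicated * 100.0 for p in profiles}
    firing_cells = sorted({t.cell_id for t in tracks
                           if t.assigned_ir == ir.ir_id and t.cell_id in pct})
    if not firing_cells:
        raise ValueError("IR has no attributed tracks among these cells")
    fired_pcts = np.sort([pct[c] for c in firing_cells])
    earliest = float(fired_pcts[0])
    earliest_corr = bool(len(fired_pcts) > 1
                         and fired_pcts[1] - earliest <= CORROBORATION_WINDOW_PCT)

    flank = _flanking_irs(ir, irs)
    unfired_pcts = []
    for i, p in enumerate(profiles):
        wi = p.grid.window_index(ir.chromosome, int(ir.center))
        if wi is None or p.states[wi] != STATE_2N:
            continue
        if flank and not any(observed[i, k] for k in flank):
            continue  # outlier: no neighboring IR replicated either
        unfired_pcts.append(pct[p.cell_id])
    if unfired_pcts:
        unfired = np.sort(unfired_pcts)[::-1]
        latest = float(unfired[0])
        latest_corr = bool(len(unfired) > 1
                           and latest - unfired[1] <= CORROBORATION_WINDOW_PCT)
    else:
        latest = float("nan")
        latest_corr = False
    single = bool(np.isfinite(latest) and earliest > latest)
    return FiringRange(ir_id=ir.ir_id, earliest_fired_pct=earliest,
                       latest_unfired_pct=latest,
                       earliest_corroborated=earliest_corr,
                       latest_corroborated=latest_corr, single_time=single)


def classify_late_irs(irs: list[InitiationRegion],
                      profiles: list[CellReplicationProfile],
                      tracks: list[ReplicationTrack]) -> dict[int, str]:
    """Classify IRs firing in fewer than half of cells by when they fire.

    ``constitutive_late``: never fires in a cell that is < 50% replicated.
    ``throughout``: fires in more than 5 cells that are > 50% replicated
    (and at least once early). ``rare_early``: the remainder — fires in
    only a few, predominantly early, cells. IRs firing in at least half
    of cells are labeled ``early``. Updates ``firing_class`` in place and
    returns {ir_id: class}.
    """
    pct = {p.cell_id: p.fraction_replicated * 100.0 for p in profiles}
    firing: dict[int, list[float]] = {ir.ir_id: [] for ir in irs}
    for t in tracks:
        if t.assigned_ir is not None and t.cell_id in pct:
            firing[t.assigned_ir].append(pct[t.cell_id])
    n_cells = len(profiles)
    out = {}
    for ir in irs:
        pcts = np.array(firing[ir.ir_id])
        # deduplicate by cell happens upstream: one track per cell per IR
        # is typical; counting cells, not tracks
        cells_firing = {t.cell_id for t in tracks if t.assigned_ir == ir.ir_id}
        pcts = np.array(sorted(pct[c] for c in cells_firing if c in pct))
        if len(pcts) >= 0.5 * n_cells:
            cls = "early"
        elif not np.any(pcts < LATE_CLASS_EARLY_CUTOFF):
            cls = "constitutive_late"
        elif np.sum(pcts > LATE_CLASS_EARLY_CUTOFF) > THROUGHOUT_MIN_LATE_CELLS:
            cls = "throughout"
        else:
            cls = "rare_early"
        ir.firing_class = cls
        out[ir.ir_id] = cls
    return out


@dataclass
class PcaResult:
    coordinates: np.ndarray           # (cells, components)
    explained_variance_ratio: np.ndarray
    pc1_fraction_corr: float          # |r(PC1, fraction replicated)|
    cell_ids: list[str] = field(default_factory=list)


def pca_embedding(profiles: list[CellReplicationProfile],
                  n_components: int = 10,
                  autosomes_only: bool = True) -> PcaResult:
    """PCA of per-cell replication states over (autosomal) windows.

    Masked windows are imputed to the per-window mean state across cells.
    The first component tracks S-phase progression; its absolute
    correlation with per-cell fraction replicated is reported.
    """
    if len(profiles) < 10:
        raise ValueError("need >= 10 cells for the embedding")
    grid = profiles[0].grid
    keep = np.ones(grid.n_windows, bool)
    if autosomes_only:
        for chrom, idx in grid.chrom_groups().items():
            name = chrom.lower().removeprefix("chr")
            if not name.isdigit():
                keep[idx] = False
    mat = np.array([p.states[keep].astype(float) for p in profiles])
    mat[mat == STATE_MASKED] = np.nan
    col_mean = np.nanmean(mat, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, (STATE_2N + STATE_4N) / 2)
    nanmask = ~np.isfinite(mat)
    mat[nanmask] = np.broadcast_to(col_mean, mat.shape)[nanmask]
    if np.allclose(mat.std(axis=0), 0):
        raise ValueError("zero-variance state matrix")
    n_comp = min(n_components, len(profiles), mat.shape[1])
    pca = PCA(n_components=n_comp, random_state=0)
    coords = pca.fit_transform(mat)
    frac = np.array([p.fraction_replicated for p in profiles])
    if np.std(frac) == 0 or np.std(coords[:, 0]) == 0:
        r = float("nan")
    else:
        r = float(abs(np.corrcoef(coords[:, 0], frac)[0, 1]))
    return PcaResult(coordinates=coords,
                     explained_variance_ratio=pca.explained_variance_ratio_,
                     pc1_fraction_corr=r,
                     cell_ids=[p.cell_id for p in profiles])
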