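"""Replication-track extraction and initiation-region (IR) clustering.

A replication track is a maximal run of replicated (4N) windows in one
cell — the single-cell footprint of one or more replication origins that
fired and whose forks expanded bidirectionally. The midpoint of a short
track estimates the initiation site. Tracks from all cells are clustered,
shortest first, into initiation regions: a track founds a new IR when it
overlaps none, joins a uniquely overlapped IR when one of its candidate
midpoints lands inside a member track, and is set aside as uninformative
when it overlaps several IRs (it likely reflects merged initiation
events). No global length threshold is applied during clustering; only
relative track length matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grids import STATE_4N, STATE_MASKED, WindowGrid
from .hmm import CellReplicationProfile
from .profiles import AggregateProfile

logger = logging.getLogger(__name__)

MAX_BRIDGED_MASKED = 5          # masked windows a track may span
BOUNDARY_SLIP_WINDOWS = 2.5     # assumed possible boundary misplacement
RESCUE_MAX_LENGTH_BP = 1_000_000
MIN_TRACKS_FOR_WIDTH = 5


@dataclass
class ReplicationTrack:
    cell_id: str
    chromosome: str
    start_window: int            # inclusive fixed-grid indices
    end_window: int
    start_bp: int
    end_bp: int
    observed_midpoint: float
    candidate_midpoints: tuple[float, float, float]
    assigned_ir: int | None = None
    status: str = "unprocessed"  # founder / member / rescued / uninformative /
                                 # unattributed

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def extract_tracks(profile: CellReplicationProfile) -> list[ReplicationTrack]:
    """Maximal 4N runs, bridging up to 5 consecutive masked windows.

    Runs of 6 or more masked windows split tracks; unreplicated windows
    and chromosome ends always terminate them. Track boundaries are the
    first and last replicated windows (bridged masked windows at the
    edges are not included).
    """
    grid = profile.grid
    states = profile.states
    tracks: list[ReplicationTrack] = []

    def close(chrom: str, first: int, last: int) -> None:
        start_bp = int(grid.start[first])
        end_bp = int(grid.end[last])
        window_bp = float(np.median(grid.sizes))
        mid = (start_bp + end_bp) / 2.0
        slip = BOUNDARY_SLIP_WINDOWS / 2.0 * window_bp
        tracks.append(ReplicationTrack(
            cell_id=profile.cell_id, chromosome=chrom,
            start_window=first, end_window=last,
            start_bp=start_bp, end_bp=end_bp, observed_midpoint=mid,
            candidate_midpoints=(mid - slip, mid, mid + slip)))

    for chrom, idx in grid.chrom_groups().items():
        first = last = None
        masked_run = 0
        for i in idx:
            s = states[i]
            if s == STATE_4N:
                if first is None:
                    first = i
                last = i
                masked_run = 0
            elif s == STATE_MASKED:
                masked_run += 1
                if first is not None and masked_run > MAX_BRIDGED_MASKED:
                    close(chrom, first, last)
                    first = last = None
                    masked_run = 0
            else:  # unreplicated
                if first is not None:
                    close(chrom, first, last)
                first = last = None
                masked_run = 0
        if first is not None:
            close(chrom, first, last)
    return tracks


def candidate_midpoints(track: ReplicationTrack,
                        window_bp: float = 20_000.0,
                        direction: str = "outward"
                        ) -> tuple[float, float, float]:
    """The observed midpoint plus the midpoints under a single-boundary
    misplacement of 2.5 windows (outward by default: the track was
    under-called on one side)."""
    mid = track.observed_midpoint
    slip = BOUNDARY_SLIP_WINDOWS / 2.0 * window_bp
    if direction == "inward":
        slip = -slip
    return (mid - slip, mid, mid + slip)


@dataclass
class ProvisionalIR:
    ir_id: int
    chromosome: str
    lo: float                    # span of member candidate midpoints
    hi: float
    members: list[ReplicationTrack] = field(default_factory=list)

    def add(self, track: ReplicationTrack) -> None:
        self.members.append(track)
        self.lo = min(self.lo, min(track.candidate_midpoints))
        self.hi = max(self.hi, max(track.candidate_midpoints))

    @property
    def center(self) -> float:
        return float(np.median([t.observed_midpoint for t in self.members]))


def cluster_irs(tracks: list[ReplicationTrack]) -> list[ProvisionalIR]:
    """Shortest-first clustering of track midpoints into provisional IRs.

    Mutates track ``status``/``assigned_ir`` in place and returns the IRs.
    Ties in length are broken by genomic position, then cell id, so the
    result does not depend on input order.
    """
    if not tracks:
        raise ValueError("no tracks to cluster")
    order = sorted(tracks, key=lambda t: (t.length_bp, t.chromosome,
                                          t.start_bp, t.cell_id))
    irs: list[ProvisionalIR] = []
    by_chrom: dict[str, list[ProvisionalIR]] = {}
    for track in order:
        candidates = [ir for ir in by_chrom.get(track.chromosome, [])
                      if ir.lo < track.end_bp and ir.hi > track.start_bp]
        if not candidates:
            ir = ProvisionalIR(ir_id=len(irs), chromosome=track.chromosome,
                               lo=min(track.candidate_midpoints),
                               hi=max(track.candidate_midpoints))
            ir.add(track)
            irs.append(ir)
            by_chrom.setdefault(track.chromosome, []).append(ir)
            track.assigned_ir = ir.ir_id
            track.status = "founder"
        elif len(candidates) == 1:
            ir = candidates[0]
            # midpoint condition: some candidate midpoint must fall inside
            # a track already attributed to this IR
            ok = any(m.start_bp <= cand < m.end_bp
                     for cand in track.candidate_midpoints
                     for m in ir.members)
            if ok:
                ir.add(track)
                track.assigned_ir = ir.ir_id
                track.status = "member"
            else:
                track.status = "uninformative"
        else:
            track.status = "uninformative"
    return irs


def assign_remaining(tracks: list[ReplicationTrack],
                     irs: list[ProvisionalIR]) -> None:
    """Attribute leftover sub-megabase tracks to the nearest IR.

    Tracks still unattributed after clustering (they overlapped several
    IRs) are assigned to the same-chromosome IR whose current center is
    nearest their observed midpoint, provided they are shorter than 1 Mb;
    ties go to the IR with more member tracks, then the leftmost.
    """
    by_chrom: dict[str, list[ProvisionalIR]] = {}
    for ir in irs:
        by_chrom.setdefault(ir.chromosome, []).append(ir)
    for track in tracks:
        if track.assigned_ir is not None:
            continue
        if track.length_bp >= RESCUE_MAX_LENGTH_BP:
            track.status = "unattributed"
            continue
        cands = by_chrom.get(track.chromosome, [])
        if not cands:
            track.status = "unattributed"
            logger.info("track on %s has no IR to join", track.chromosome)
            continue
        best = min(cands, key=lambda ir: (abs(ir.center - track.observed_midpoint),
                                          -len(ir.members), ir.lo))
        best.members.append(track)   # counts for stats, span left unchanged
        track.assigned_ir = best.ir_id
        track.status = "rescued"


@dataclass
class InitiationRegion:
    ir_id: int
    chromosome: str
    center: float                 # bp; median of attributed track midpoints
    start: float                  # 25th percentile of midpoints
    end: float                    # 75th percentile
    n_tracks: int
    aggregate_timing: float = float("nan")
    firing_class: str = "unclassified"
    low_support: bool = False

    @property
    def width_bp(self) -> float:
        return self.end - self.start


def finalize_irs(irs: list[ProvisionalIR],
                 profile: AggregateProfile | None = None
                 ) -> list[InitiationRegion]:
    """Summarize each IR from the midpoints of its attributed tracks."""
    out = []
    for ir in irs:
        mids = np.array([t.observed_midpoint for t in ir.members])
        q25, q50, q75 = np.percentile(mids, [25, 50, 75])
        timing = float("nan")
        if profile is not None:
            timing = profile.value_at(ir.chromosome, int(q50))
        out.append(InitiationRegion(
            ir_id=ir.ir_id, chromosome=ir.chromosome, center=float(q50),
            start=float(q25), end=float(q75), n_tracks=len(ir.members),
            aggregate_timing=timing,
            low_support=len(ir.members) < MIN_TRACKS_FOR_WIDTH))
    return out


def call_initiation_regions(profiles: list[CellReplicationProfile],
                            aggregate: AggregateProfile | None = None
                            ) -> tuple[list[InitiationRegion],
                                       list[ReplicationTrack]]:
    """End-to-end IR calling: tracks, clustering, rescue, finalization."""
    tracks: list[ReplicationTrack] = []
    for p in profiles:
        tracks.extend(extract_tracks(p))
    if not tracks:
        return [], []
    provisional = cluster_irs(tracks)
    assign_remaining(tracks, provisional)
    return finalize_irs(provisional, aggregate), tracks
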