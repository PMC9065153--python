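"""High-level orchestration of the replication-state inference pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import STATE_MASKED, CellCounts, WindowGrid
from .hmm import (CellReplicationProfile, HMMResult, infer_states_hmm,
                  init_mixed_poisson, interpolate_states, qc_cell,
                  qc_chromosome_cross_cell)


@dataclass
class InferenceOutcome:
    """Profiles for decoded cells plus the reasons others were excluded."""

    profiles: list[CellReplicationProfile]
    results: dict[str, HMMResult] = field(default_factory=dict)
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def retained(self) -> list[CellReplicationProfile]:
        return [p for p in self.profiles if p.passed_qc]


def infer_profiles(cells: list[CellCounts],
                   target_grid: WindowGrid | None = None,
                   cross_cell_qc: bool = False,
                   decode: str = "viterbi",
                   train_transitions: bool = True) -> InferenceOutcome:
    """Run mixed-Poisson initialization, HMM decoding, and QC per cell.

    When ``target_grid`` is given (the fixed 20-kb grid), decoded states
    on the cells' (possibly variable) windows are interpolated onto it;
    otherwise states stay on the input grid. ``cross_cell_qc`` adds the
    per-chromosome cross-cell screen and masks excluded chromosomes.
    """
    outcome = InferenceOutcome(profiles=[])
    for cell in cells:
        init = init_mixed_poisson(cell)
        if not init.included:
            outcome.excluded[cell.cell_id] = init.reason
            continue
        res = infer_states_hmm(cell, init, decode=decode,
                               train_transitions=train_transitions)
        outcome.results[cell.cell_id] = res
        flags = qc_cell(res.states, cell.grid, res.ratio)
        if res.fell_back:
            flags.add("hmm_fallback")
        if target_grid is not None and target_grid is not cell.grid:
            states = interpolate_states(res.states, cell.grid, target_grid)
            grid = target_grid
        else:
            states = res.states
            grid = cell.grid
        outcome.profiles.append(CellReplicationProfile(
            cell_id=cell.cell_id, grid=grid, states=states,
            ratio_4n_over_2n=res.ratio, qc_flags=flags))
    if cross_cell_qc and len(outcome.profiles) >= 12:
        by_cell = {p.cell_id: p.states for p in outcome.profiles}
        grid = outcome.profiles[0].grid
        exclusions = qc_chromosome_cross_cell(by_cell, grid)
        groups = grid.chrom_groups()
        for p in outcome.profiles:
            for cid, chrom in exclusions:
                if cid == p.cell_id:
                    p.excluded_chromosomes.add(chrom)
                    p.states = p.states.copy()
                    p.states[groups[chrom]] = STATE_MASKED
    return outcome


def state_accuracy(states: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of windows whose inferred state matches the simulated truth,
    over windows unmasked in both."""
    ok = (states != STATE_MASKED) & (truth != STATE_MASKED)
    if not ok.any():
        raise ValueError("no comparable windows")
    return float(np.mean(states[ok] == truth[ok]))
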