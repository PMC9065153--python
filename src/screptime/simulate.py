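"""Synthetic single-cell replication data with known ground truth.

Two generative regimes are provided. *Deterministic-program* cells follow a
strictly determined replication-timing program: a smooth timing profile is
divided into 1000 equally spaced levels, each cell is a uniformly drawn
"time slice", and every window earlier than the slice is replicated (4N).
*Stochastic-firing* cells place discrete origins on the genome; each origin
fires independently with its own efficiency and firing-time distribution,
and replicated tracks expand symmetrically at constant fork speed, merging
on collision. In both regimes read counts are Poisson with the replicated
rate exactly twice the unreplicated rate, and per-cell mean coverage is
drawn from a configurable range (50-250 reads/Mb by default, matching
typical droplet-based single-cell whole-genome libraries).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage

from .grids import (DEFAULT_WINDOW_SIZE, STATE_2N, STATE_4N, STATE_MASKED,
                    CellCounts, WindowGrid)

DEFAULT_COVERAGE_RANGE = (50.0, 250.0)  # reads per Mb
DEFAULT_N_SLICES = 1000


@dataclass
class TimingProfile:
    """A per-window replication-timing profile (higher = earlier)."""

    grid: WindowGrid
    timing: np.ndarray
    n_slices: int = DEFAULT_N_SLICES

    def __post_init__(self) -> None:
        self.timing = np.asarray(self.timing, dtype=float)
        if len(self.timing) != self.grid.n_windows:
            raise ValueError("timing length does not match grid")
        unmasked = self.timing[self.grid.unmasked]
        if not np.all(np.isfinite(unmasked)):
            raise ValueError("timing must be finite over unmasked windows")
        if len(np.unique(unmasked)) < 2:
            raise ValueError("timing profile is constant")

    def slice_states(self, slice_index: int) -> np.ndarray:
        """True replication states for one of the equally spaced time slices.

        Slice 0 is the very start of S phase (nothing replicated); slice
        ``n_slices - 1`` is the end (everything replicated). Windows with
        timing above the slice's threshold level are 4N.
        """
        if not 0 <= slice_index < self.n_slices:
            raise ValueError("slice_index out of range")
        unmasked = self.grid.unmasked
        lo, hi = self.timing[unmasked].min(), self.timing[unmasked].max()
        tau = (slice_index + 0.5) / self.n_slices
        threshold = hi - tau * (hi - lo)
        states = np.where(self.timing > threshold, STATE_4N, STATE_2N)
        states[~unmasked] = STATE_MASKED
        return states

    def slice_for_fraction(self, fraction: float) -> int:
        """The time slice whose threshold replicates ~``fraction`` of the
        genome (nearest equally spaced level to the (1-f) timing quantile)."""
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        unmasked = self.grid.unmasked
        lo, hi = self.timing[unmasked].min(), self.timing[unmasked].max()
        threshold = float(np.quantile(self.timing[unmasked], 1.0 - fraction))
        tau = (hi - threshold) / (hi - lo)
        return int(np.clip(round(tau * self.n_slices - 0.5), 0,
                           self.n_slices - 1))


@dataclass
class Origin:
    """One replication origin in a stochastic firing program."""

    window: int               # grid window index of the origin
    mean_time: float          # mean firing time, in S-phase fraction units
    sd_time: float            # spread of the firing-time distribution
    efficiency: float         # probability of firing in any one cell
    label: str = "unlabeled"  # planted class: early/throughout/rare_early/...

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must lie in [0, 1]")


@dataclass
class StochasticProgram:
    """Origins plus a fork speed, defining a stochastic replication program."""

    grid: WindowGrid
    origins: list[Origin]
    fork_speed: float = 150.0  # windows replicated per unit S-phase time per fork

    def __post_init__(self) -> None:
        for o in self.origins:
            if not 0 <= o.window < self.grid.n_windows:
                raise ValueError("origin window outside grid")


@dataclass
class SimulatedCell:
    """One synthetic cell: true states, Poisson rates, and realized counts."""

    cell_id: str
    grid: WindowGrid
    true_state: np.ndarray          # 2, 4, or -1 (masked) per window
    counts: np.ndarray              # realized integer read counts
    rates: np.ndarray               # Poisson rate per window used to draw counts
    coverage_per_mb: float          # drawn target mean coverage
    slice_index: int | None = None  # deterministic regime only
    s_time: float | None = None     # stochastic regime only
    fired: dict[int, float] = field(default_factory=dict)  # origin idx -> time
    cna_regions: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def true_fraction_replicated(self) -> float:
        informative = self.true_state != STATE_MASKED
        return float(np.mean(self.true_state[informative] == STATE_4N))

    def to_cell_counts(self) -> CellCounts:
        return CellCounts(self.cell_id, self.grid, self.counts)


def make_timing_profile(n_windows: int, domain_scale_windows: int,
                        seed: int, grid: WindowGrid | None = None,
                        n_slices: int = DEFAULT_N_SLICES) -> TimingProfile:
    """Smooth synthetic timing profile from Gaussian-filtered white noise.

    ``domain_scale_windows`` sets the autocorrelation length of the profile
    (the typical size of early/late timing domains, in windows). The result
    is z-normalized to mean 0, sd 1 over unmasked windows.
    """
    if n_windows < 100:
        raise ValueError("n_windows must be >= 100")
    if domain_scale_windows < 10:
        raise ValueError("domain_scale_windows must be >= 10")
    if grid is None:
        grid = WindowGrid.fixed_windows(
            {"chr1": n_windows * DEFAULT_WINDOW_SIZE})
    elif grid.n_windows != n_windows:
        raise ValueError("grid size does not match n_windows")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n_windows)
    # sigma = scale/2 gives an autocorrelation length close to the scale
    smooth = scipy.ndimage.gaussian_filter1d(
        noise, sigma=domain_scale_windows / 2.0, mode="wrap")
    unmasked = grid.unmasked
    mu, sd = smooth[unmasked].mean(), smooth[unmasked].std()
    if sd == 0:
        raise ValueError("degenerate profile (zero variance)")
    return TimingProfile(grid, (smooth - mu) / sd, n_slices=n_slices)


def _draw_counts(grid: WindowGrid, states: np.ndarray, coverage_per_mb: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Poisson counts with rate(4N) = 2 x rate(2N), tuned so the expected
    mean count over unmasked windows matches the drawn coverage."""
    window_bp = grid.sizes.astype(float)
    unmasked = grid.unmasked
    frac = np.mean(states[unmasked] == STATE_4N) if unmasked.any() else 0.0
    mean_target = coverage_per_mb * np.mean(window_bp[unmasked]) / 1e6
    base = mean_target / (1.0 + frac)  # 2N rate for a mean-size window
    factor = np.where(states == STATE_4N, 2.0, 1.0)
    rates = base * factor * (window_bp / np.mean(window_bp[unmasked]))
    rates = rates * grid.mappable_fraction  # masked/partial windows lose reads
    counts = rng.poisson(rates)
    return counts, rates


def simulate_deterministic_cells(
        profile: TimingProfile, n_cells: int,
        coverage_range: tuple[float, float] = DEFAULT_COVERAGE_RANGE,
        seed: int = 0,
        fraction_range: tuple[float, float] | None = None
        ) -> list[SimulatedCell]:
    """Cells following a strictly determined replication order.

    Each cell is a uniformly drawn slice through the profile's equally
    spaced levels; every window with earlier timing than the slice is 4N.
    The replicated set of an earlier-slice cell is therefore always a
    subset of a later-slice cell's (the nesting property used by the
    firing-order null). When ``fraction_range`` is given, slices are
    instead chosen so the per-cell replicated fraction is uniform over
    that range (an S-phase population spanning a prescribed progression
    span).
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    lo, hi = coverage_range
    if not (0 < lo <= hi):
        raise ValueError("invalid coverage range")
    rng = np.random.default_rng(seed)
    cells = []
    for i in range(n_cells):
        if fraction_range is None:
            k = int(rng.integers(profile.n_slices))
        else:
            k = profile.slice_for_fraction(
                float(rng.uniform(*fraction_range)))
        cov = float(rng.uniform(lo, hi))
        states = profile.slice_states(k)
        counts, rates = _draw_counts(profile.grid, states, cov, rng)
        cells.append(SimulatedCell(
            cell_id=f"det{i:04d}", grid=profile.grid, true_state=states,
            counts=counts, rates=rates, coverage_per_mb=cov, slice_index=k))
    return cells


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Firing time on [0, 1]; rejection sampling with a clip fallback."""
    if sd <= 0:
        return float(np.clip(mean, 0.0, 1.0))
    for _ in range(100):
        t = rng.normal(mean, sd)
        if 0.0 <= t <= 1.0:
            return float(t)
    return float(np.clip(rng.normal(mean, sd), 0.0, 1.0))


def stochastic_states(program: StochasticProgram, s_time: float,
                      fired: dict[int, float]) -> np.ndarray:
    """True states at ``s_time`` given which origins fired when.

    Replicated intervals expand symmetrically at ``fork_speed`` windows per
    unit time from each fired origin and merge on collision; chromosome
    ends clip forks.
    """
    grid = program.grid
    states = np.full(grid.n_windows, STATE_2N)
    groups = grid.chrom_groups()
    chrom_of = {i: c for c, idx in groups.items() for i in idx}
    for oi, t_fire in fired.items():
        if t_fire >= s_time:
            continue
        origin = program.origins[oi]
        half = program.fork_speed * (s_time - t_fire)
        lo = origin.window - half
        hi = origin.window + half
        idx = groups[chrom_of[origin.window]]
        within = idx[(idx >= np.ceil(lo)) & (idx <= np.floor(hi))]
        states[within] = STATE_4N
    states[grid.masked] = STATE_MASKED
    return states


def simulate_stochastic_cells(
        program: StochasticProgram, n_cells: int,
        coverage_range: tuple[float, float] = DEFAULT_COVERAGE_RANGE,
        seed: int = 0) -> list[SimulatedCell]:
    """Cells from a stochastic origin-firing program.

    Each cell draws an observation time uniformly within S phase; every
    origin independently fires (with its efficiency) at a time from its
    own distribution, and tracks grow from fired origins until the
    observation time.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if not program.origins:
        raise ValueError("program needs at least one origin")
    rng = np.random.default_rng(seed)
    lo, hi = coverage_range
    cells = []
    for i in range(n_cells):
        s_time = float(rng.uniform(0.0, 1.0))
        fired: dict[int, float] = {}
        for oi, origin in enumerate(program.origins):
            if rng.uniform() < origin.efficiency:
                t = _truncated_normal(rng, origin.mean_time, origin.sd_time)
                if t < s_time:
                    fired[oi] = t
        cov = float(rng.uniform(lo, hi))
        states = stochastic_states(program, s_time, fired)
        counts, rates = _draw_counts(program.grid, states, cov, rng)
        cells.append(SimulatedCell(
            cell_id=f"sto{i:04d}", grid=program.grid, true_state=states,
            counts=counts, rates=rates, coverage_per_mb=cov,
            s_time=s_time, fired=fired))
    return cells


def simulate_g1_cells(grid: WindowGrid, n_cells: int,
                      coverage_range: tuple[float, float] = DEFAULT_COVERAGE_RANGE,
                      seed: int = 0) -> list[SimulatedCell]:
    """Non-replicating (G1/G2-like) cells: uniform 2N copy number."""
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rng = np.random.default_rng(seed)
    lo, hi = coverage_range
    states = np.full(grid.n_windows, STATE_2N)
    states[grid.masked] = STATE_MASKED
    cells = []
    for i in range(n_cells):
        cov = float(rng.uniform(lo, hi))
        counts, rates = _draw_counts(grid, states, cov, rng)
        cells.append(SimulatedCell(
            cell_id=f"g1_{i:04d}", grid=grid, true_state=states.copy(),
            counts=counts, rates=rates, coverage_per_mb=cov))
    return cells


def inject_cna(cell: SimulatedCell, region: tuple[int, int], fold: float,
               seed: int = 0) -> SimulatedCell:
    """Re-draw counts in ``region`` (window index range, half-open) with the
    Poisson rate multiplied by ``fold``; truth annotates the CNA."""
    lo, hi = region
    if not (0 <= lo < hi <= cell.grid.n_windows):
        raise ValueError("region outside grid or empty")
    if fold <= 0:
        raise ValueError("fold must be positive")
    rng = np.random.default_rng(seed)
    counts = cell.counts.copy()
    rates = cell.rates.copy()
    rates[lo:hi] *= fold
    counts[lo:hi] = rng.poisson(rates[lo:hi])
    return SimulatedCell(
        cell_id=cell.cell_id, grid=cell.grid, true_state=cell.true_state.copy(),
        counts=counts, rates=rates, coverage_per_mb=cell.coverage_per_mb,
        slice_index=cell.slice_index, s_time=cell.s_time,
        fired=dict(cell.fired),
        cna_regions=cell.cna_regions + [(lo, hi, fold)])


def make_origin_program(grid: WindowGrid, n_origins: int,
                        spacing_windows: int, seed: int = 0,
                        fork_speed: float = 150.0,
                        class_cycle: tuple[str, ...] = ("early",),
                        ) -> StochasticProgram:
    """Plant regularly spaced origins with class-typical firing parameters.

    Classes: ``early`` (efficient, early mean time), ``throughout``
    (moderate efficiency, broad firing times), ``rare_early`` (inefficient,
    early when it fires), ``constitutive_late`` (fires only late).
    """
    params = {
        "early": dict(mean_time=0.12, sd_time=0.06, efficiency=0.9),
        "throughout": dict(mean_time=0.5, sd_time=0.45, efficiency=0.35),
        "rare_early": dict(mean_time=0.15, sd_time=0.08, efficiency=0.12),
        "constitutive_late": dict(mean_time=0.8, sd_time=0.07, efficiency=0.6),
    }
    rng = np.random.default_rng(seed)
    start = spacing_windows // 2
    origins = []
    for k in range(n_origins):
        w = start + k * spacing_windows
        if w >= grid.n_windows:
            raise ValueError("grid too small for requested origins/spacing")
        label = class_cycle[k % len(class_cycle)]
        p = params[label]
        jitter = int(rng.integers(-spacing_windows // 10,
                                  spacing_windows // 10 + 1))
        w = int(np.clip(w + jitter, 0, grid.n_windows - 1))
        origins.append(Origin(window=w, label=label, **p))
    return StochasticProgram(grid=grid, origins=origins, fork_speed=fork_speed)


def make_class_program(seed: int = 0,
                       fork_speed: float = 150.0,
                       window_size: int = DEFAULT_WINDOW_SIZE
                       ) -> StochasticProgram:
    """A replication program with domain structure for firing-class studies.

    Mimics how the firing classes arise in real genomes, with distinct
    replication-timing domains along one chromosome: efficient early
    origins and inefficient rare-early origins share an early domain (so
    rare-early tracks merge into their neighborhood by mid-S and are
    attributable only in early cells); origins firing throughout S phase
    sit far apart in their own domain so their tracks stay attributable
    at any time; constitutively late origins occupy a late domain no fork
    reaches passively before late S.
    """
    # single-chromosome domain layout (in windows): early 1800 | spacer |
    # throughout 700 | spacer | late 500; spacers carry no origins and are
    # wide enough that early forks do not traverse them before late S
    early_n, spacer, thru_n, late_n = 1800, 250, 700, 500
    total = early_n + spacer + thru_n + spacer + late_n
    grid = WindowGrid.fixed_windows({"chr1": total * window_size})
    rng = np.random.default_rng(seed)
    origins: list[Origin] = []

    def place(base: int, offsets: list[int], label: str, **p) -> None:
        for off in offsets:
            w = int(base + off + rng.integers(-5, 6))
            origins.append(Origin(window=w, label=label, **p))

    thru_base = early_n + spacer
    late_base = thru_base + thru_n + spacer
    place(0, list(range(75, early_n, 150)), "early",
          mean_time=0.12, sd_time=0.06, efficiency=0.95)
    place(0, list(range(150, early_n - 50, 300)), "rare_early",
          mean_time=0.15, sd_time=0.08, efficiency=0.12)
    place(thru_base, list(range(100, thru_n, 175)), "throughout",
          mean_time=0.5, sd_time=0.45, efficiency=0.5)
    place(late_base, list(range(60, late_n, 110)), "constitutive_late",
          mean_time=0.85, sd_time=0.04, efficiency=0.6)
    # mid-late filler origins in the spacers: real genomes finish
    # replicating by the end of S phase, which keeps the per-cell
    # % replicated clock tight against elapsed S-phase time
    place(early_n, list(range(50, spacer, 100)), "filler",
          mean_time=0.7, sd_time=0.05, efficiency=0.9)
    place(thru_base + thru_n, list(range(50, spacer, 100)), "filler",
          mean_time=0.7, sd_time=0.05, efficiency=0.9)
    return StochasticProgram(grid=grid, origins=origins, fork_speed=fork_speed)


def write_scenario_yaml(program: StochasticProgram, path: str | Path,
                        n_cells: int | None = None,
                        coverage_range: tuple[float, float] = DEFAULT_COVERAGE_RANGE,
                        seed: int | None = None) -> None:
    """Record a stochastic scenario (origins, fork speed, conditions)."""
    import yaml

    doc = {
        "fork_speed_windows_per_unit_time": program.fork_speed,
        "coverage_range_reads_per_mb": list(coverage_range),
        "n_cells": n_cells,
        "seed": seed,
        "chromosomes": {c: int(program.grid.sizes[idx].sum())
                        for c, idx in program.grid.chrom_groups().items()},
        "origins": [{
            "window": o.window, "mean_time": o.mean_time,
            "sd_time": o.sd_time, "efficiency": o.efficiency,
            "label": o.label} for o in program.origins],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_scenario_yaml(path: str | Path,
                       window_size: int = DEFAULT_WINDOW_SIZE
                       ) -> StochasticProgram:
    """Rebuild a stochastic program from a scenario file."""
    import yaml

    doc = yaml.safe_load(Path(path).read_text())
    grid = WindowGrid.fixed_windows(doc["chromosomes"])
    origins = [Origin(window=o["window"], mean_time=o["mean_time"],
                      sd_time=o["sd_time"], efficiency=o["efficiency"],
                      label=o.get("label", "unlabeled"))
               for o in doc["origins"]]
    return StochasticProgram(
        grid=grid, origins=origins,
        fork_speed=doc["fork_speed_windows_per_unit_time"])


def write_truth_tsv(cells: list[SimulatedCell], path: str | Path) -> None:
    """Long-form truth table (cell, window index, true state)."""
    frames = [pd.DataFrame({"cell": c.cell_id,
                            "window": np.arange(c.grid.n_windows),
                            "true_state": c.true_state})
              for c in cells]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
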