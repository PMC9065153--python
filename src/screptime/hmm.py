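"""Per-cell replication-state inference with a two-state Poisson HMM.

Each S-phase cell's G1-normalized window counts are modeled as a mixture
of two Poisson processes: an unreplicated (2N) rate and a replicated (4N)
rate expected to be twice as large. A two-component Poisson mixture on
~300-kb aggregates initializes the model (and excludes cells whose rate
ratio is not ~2); a hidden Markov model with sticky transitions then
refines the per-window assignments. Decoding is by the most probable path
(Viterbi) by default, with posterior decoding available. Masked windows
are treated as missing observations: they contribute nothing to the
emission likelihood but the chain still passes through them.

The HMM is written directly (log-space Viterbi, scaled forward-backward
Baum-Welch) rather than through a library so that missing observations
and the rate-order constraint (replicated rate above unreplicated) are
handled exactly as the method requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .grids import STATE_2N, STATE_4N, STATE_MASKED, CellCounts, WindowGrid
from .g1windows import _aggregate_indices
from .mixture import PoissonMixtureFit, fit_poisson_mixture

RATIO_RANGE = (1.5, 2.5)
DEFAULT_SELF_TRANSITION = 0.99
CHROM_SD_THRESHOLD = 0.4
INIT_AGGREGATE_SIZE = 15


# ---------------------------------------------------------------------------
# Core HMM


@dataclass
class TwoStatePoissonHMM:
    """Two-state HMM with Poisson emissions and missing-data support.

    State 0 is unreplicated (low rate), state 1 replicated (high rate).
    """

    rates: np.ndarray                      # (2,) Poisson emission rates
    transmat: np.ndarray = None            # (2, 2), rows sum to 1
    startprob: np.ndarray = None           # (2,)
    converged: bool = False
    n_iterations: int = 0
    log_likelihood: float = float("-inf")

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.transmat is None:
            p = DEFAULT_SELF_TRANSITION
            self.transmat = np.array([[p, 1 - p], [1 - p, p]])
        if self.startprob is None:
            self.startprob = np.array([0.5, 0.5])

    # -- emissions ---------------------------------------------------------

    def _log_emissions(self, x: np.ndarray, missing: np.ndarray) -> np.ndarray:
        lam = np.maximum(self.rates, 1e-12)
        logb = (x[:, None] * np.log(lam)[None, :] - lam[None, :]
                - gammaln(x + 1.0)[:, None])
        logb[missing] = 0.0
        return logb

    # -- inference ---------------------------------------------------------

    def viterbi(self, x: np.ndarray, missing: np.ndarray | None = None
                ) -> np.ndarray:
        """Most probable state path (0/1 per window)."""
        x = np.asarray(x, dtype=float)
        if missing is None:
            missing = np.zeros(len(x), bool)
        logb = self._log_emissions(x, missing)
        lb0 = logb[:, 0].tolist()
        lb1 = logb[:, 1].tolist()
        with np.errstate(divide="ignore"):
            lt = np.log(self.transmat)
            ls = np.log(self.startprob)
        lt00, lt01, lt10, lt11 = lt[0, 0], lt[0, 1], lt[1, 0], lt[1, 1]
        n = len(x)
        back = [0] * n
        v0 = ls[0] + lb0[0]
        v1 = ls[1] + lb1[0]
        ptr0 = [0] * n
        ptr1 = [0] * n
        for t in range(1, n):
            a = v0 + lt00
            b = v1 + lt10
            if a >= b:
                nv0 = a + lb0[t]
                ptr0[t] = 0
            else:
                nv0 = b + lb0[t]
                ptr0[t] = 1
            a = v0 + lt01
            b = v1 + lt11
            if a >= b:
                nv1 = a + lb1[t]
                ptr1[t] = 0
            else:
                nv1 = b + lb1[t]
                ptr1[t] = 1
            v0, v1 = nv0, nv1
        path = np.empty(n, dtype=np.int8)
        s = 0 if v0 >= v1 else 1
        for t in range(n - 1, -1, -1):
            path[t] = s
            s = ptr0[t] if s == 0 else ptr1[t]
        return path

    def path_log_likelihood(self, x: np.ndarray, states: np.ndarray,
                            missing: np.ndarray | None = None) -> float:
        """Joint log probability of (states, observations); oracle hook."""
        x = np.asarray(x, dtype=float)
        states = np.asarray(states, dtype=int)
        if missing is None:
            missing = np.zeros(len(x), bool)
        logb = self._log_emissions(x, missing)
        with np.errstate(divide="ignore"):
            lt = np.log(self.transmat)
            ls = np.log(self.startprob)
        ll = ls[states[0]] + logb[0, states[0]]
        for t in range(1, len(x)):
            ll += lt[states[t - 1], states[t]] + logb[t, states[t]]
        return float(ll)

    def _forward_backward(self, x: np.ndarray, missing: np.ndarray):
        """Scaled forward-backward. Returns (gamma, xi_sums, loglik)."""
        logb = self._log_emissions(x, missing)
        rowmax = logb.max(axis=1)
        b = np.exp(logb - rowmax[:, None])
        const = float(rowmax.sum())
        b0 = b[:, 0].tolist()
        b1 = b[:, 1].tolist()
        t00, t01 = self.transmat[0]
        t10, t11 = self.transmat[1]
        n = len(x)
        a0l = [0.0] * n
        a1l = [0.0] * n
        cl = [0.0] * n
        a0 = self.startprob[0] * b0[0]
        a1 = self.startprob[1] * b1[0]
        c = a0 + a1
        a0 /= c
        a1 /= c
        a0l[0], a1l[0], cl[0] = a0, a1, c
        for t in range(1, n):
            na0 = (a0 * t00 + a1 * t10) * b0[t]
            na1 = (a0 * t01 + a1 * t11) * b1[t]
            c = na0 + na1
            a0 = na0 / c
            a1 = na1 / c
            a0l[t], a1l[t], cl[t] = a0, a1, c
        loglik = const + float(np.sum(np.log(cl)))
        # backward + posteriors + transition counts in one sweep
        g0l = [0.0] * n
        g1l = [0.0] * n
        be0 = 1.0
        be1 = 1.0
        xi00 = xi01 = xi10 = xi11 = 0.0
        g0l[n - 1] = a0l[n - 1]
        g1l[n - 1] = a1l[n - 1]
        for t in range(n - 2, -1, -1):
            e0 = b0[t + 1] * be0
            e1 = b1[t + 1] * be1
            ct1 = cl[t + 1]
            a0 = a0l[t]
            a1 = a1l[t]
            xi00 += a0 * t00 * e0 / ct1
            xi01 += a0 * t01 * e1 / ct1
            xi10 += a1 * t10 * e0 / ct1
            xi11 += a1 * t11 * e1 / ct1
            be0n = (t00 * e0 + t01 * e1) / ct1
            be1n = (t10 * e0 + t11 * e1) / ct1
            be0, be1 = be0n, be1n
            g0 = a0 * be0
            g1 = a1 * be1
            s = g0 + g1
            g0l[t] = g0 / s
            g1l[t] = g1 / s
        gamma = np.column_stack([g0l, g1l])
        xi = np.array([[xi00, xi01], [xi10, xi11]])
        return gamma, xi, loglik

    def fit(self, x: np.ndarray, missing: np.ndarray | None = None,
            max_iter: int = 200, tol: float = 1e-6,
            train_transitions: bool = True) -> "TwoStatePoissonHMM":
        """Baum-Welch training in place; rate order (high > low) enforced."""
        x = np.asarray(x, dtype=float)
        if missing is None:
            missing = np.zeros(len(x), bool)
        observed = ~missing
        prev_ll = -np.inf
        self.converged = False
        for it in range(1, max_iter + 1):
            gamma, xi, ll = self._forward_backward(x, missing)
            self.log_likelihood = ll
            self.n_iterations = it
            if np.isfinite(prev_ll) and \
                    abs(ll - prev_ll) < tol * (abs(prev_ll) + 1e-12):
                self.converged = True
                break
            prev_ll = ll
            g_obs = gamma[observed]
            x_obs = x[observed]
            denom = g_obs.sum(axis=0)
            if np.any(denom < 1e-10):
                break  # a state died; keep last parameters
            new_rates = (g_obs * x_obs[:, None]).sum(axis=0) / denom
            self.rates = np.maximum(new_rates, 1e-12)
            if train_transitions:
                rows = xi.sum(axis=1, keepdims=True)
                if np.all(rows > 0):
                    self.transmat = xi / rows
            self.startprob = np.maximum(gamma[0], 1e-12)
            self.startprob /= self.startprob.sum()
            if self.rates[0] > self.rates[1]:
                self.rates = self.rates[::-1].copy()
                self.transmat = self.transmat[::-1, ::-1].copy()
                self.startprob = self.startprob[::-1].copy()
        return self

    def posterior(self, x: np.ndarray, missing: np.ndarray | None = None
                  ) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if missing is None:
            missing = np.zeros(len(x), bool)
        gamma, _, _ = self._forward_backward(x, missing)
        return gamma


# ---------------------------------------------------------------------------
# Pipeline operations


@dataclass
class MixedPoissonInit:
    """Mixed-Poisson initialization of one cell, with the inclusion rule."""

    fit: PoissonMixtureFit | None
    included: bool
    reason: str
    initial_states: np.ndarray | None   # 0/1 per window (by nearer mean)
    aggregate_size: int = INIT_AGGREGATE_SIZE


def init_mixed_poisson(cell: CellCounts,
                       aggregate_size: int = INIT_AGGREGATE_SIZE,
                       extra_mask: np.ndarray | None = None
                       ) -> MixedPoissonInit:
    """Fit the two-rate aggregate mixture and decide cell inclusion.

    The cell is excluded when EM does not converge or when the ratio of
    the two rates is not ~2 (outside [1.5, 2.5], closed interval) — i.e.
    when its counts are not consistent with a genome part-way through
    replication at the expected twofold copy ratio.
    """
    grid = cell.grid
    active = grid.unmasked.copy()
    if extra_mask is not None:
        active &= ~np.asarray(extra_mask, bool)
    aggs = _aggregate_indices(grid, active, aggregate_size)
    if len(aggs) < 30:
        return MixedPoissonInit(None, False, "insufficient aggregates", None,
                                aggregate_size)
    sums = np.array([cell.counts[a].sum() for a in aggs])
    try:
        fit = fit_poisson_mixture(sums)
    except ValueError as exc:
        return MixedPoissonInit(None, False, str(exc), None, aggregate_size)
    if not fit.converged:
        return MixedPoissonInit(fit, False, "mixture EM did not converge",
                                None, aggregate_size)
    lo, hi = RATIO_RANGE
    if not lo <= fit.ratio <= hi:
        return MixedPoissonInit(fit, False,
                                f"rate ratio {fit.ratio:.2f} outside [{lo}, {hi}]",
                                None, aggregate_size)
    mean_lo = fit.lambda_low / aggregate_size
    mean_hi = fit.lambda_high / aggregate_size
    states = (np.abs(cell.counts - mean_hi)
              < np.abs(cell.counts - mean_lo)).astype(np.int8)
    return MixedPoissonInit(fit, True, "ok", states, aggregate_size)


@dataclass
class HMMResult:
    states: np.ndarray            # STATE_2N / STATE_4N / STATE_MASKED per window
    model: TwoStatePoissonHMM
    ratio: float                  # mean counts in 4N windows / 2N windows
    fell_back: bool = False       # EM failed; decoded under initial parameters


def ratio_4n_over_2n(counts: np.ndarray, states: np.ndarray) -> float:
    """Mean reads in replicated windows over mean reads in unreplicated."""
    rep = states == STATE_4N
    unrep = states == STATE_2N
    if not rep.any() or not unrep.any():
        return float("nan")
    denom = counts[unrep].mean()
    return float(counts[rep].mean() / denom) if denom > 0 else float("nan")


def infer_states_hmm(cell: CellCounts, init: MixedPoissonInit,
                     extra_mask: np.ndarray | None = None,
                     self_transition: float = DEFAULT_SELF_TRANSITION,
                     train_transitions: bool = True,
                     decode: str = "viterbi",
                     max_iter: int = 200, tol: float = 1e-6) -> HMMResult:
    """Refine the mixed-Poisson window assignments with the HMM."""
    if not init.included:
        raise ValueError(f"cell excluded at initialization: {init.reason}")
    grid = cell.grid
    missing = grid.masked.copy()
    if extra_mask is not None:
        missing |= np.asarray(extra_mask, bool)
    rates = np.array([init.fit.lambda_low, init.fit.lambda_high]) \
        / init.aggregate_size
    p = self_transition
    model = TwoStatePoissonHMM(rates=rates,
                               transmat=np.array([[p, 1 - p], [1 - p, p]]))
    model.fit(cell.counts, missing, max_iter=max_iter, tol=tol,
              train_transitions=train_transitions)
    fell_back = not model.converged
    if fell_back:
        model = TwoStatePoissonHMM(
            rates=rates, transmat=np.array([[p, 1 - p], [1 - p, p]]))
    if decode == "viterbi":
        path = model.viterbi(cell.counts, missing)
    elif decode == "posterior":
        path = (model.posterior(cell.counts, missing)[:, 1] > 0.5).astype(np.int8)
    else:
        raise ValueError(f"unknown decode method: {decode}")
    states = np.where(path == 1, STATE_4N, STATE_2N).astype(np.int8)
    states[missing] = STATE_MASKED
    return HMMResult(states=states, model=model,
                     ratio=ratio_4n_over_2n(cell.counts, states),
                     fell_back=fell_back)


# ---------------------------------------------------------------------------
# QC


def qc_cell(states: np.ndarray, grid: WindowGrid, ratio: float) -> set[str]:
    """Per-cell flags; any flag excludes the cell.

    ``ratio_out_of_range``: replicated/unreplicated read ratio outside
    [1.5, 2.5]. ``chrom_sd``: sd of per-chromosome mean copy number > 0.4.
    ``full_chrom_conflict``: one chromosome entirely replicated and
    another entirely unreplicated (a hallmark of an uncorrected CNA).
    """
    flags: set[str] = set()
    lo, hi = RATIO_RANGE
    if not (np.isfinite(ratio) and lo <= ratio <= hi):
        flags.add("ratio_out_of_range")
    chrom_means = []
    any_full_2n = any_full_4n = False
    for _, idx in grid.chrom_groups().items():
        s = states[idx]
        s = s[s != STATE_MASKED]
        if len(s) == 0:
            continue
        chrom_means.append(s.mean())
        any_full_4n |= bool(np.all(s == STATE_4N))
        any_full_2n |= bool(np.all(s == STATE_2N))
    if len(chrom_means) >= 2 and np.std(chrom_means) > CHROM_SD_THRESHOLD:
        flags.add("chrom_sd")
    if any_full_2n and any_full_4n:
        flags.add("full_chrom_conflict")
    return flags


def qc_chromosome_cross_cell(states_by_cell: dict[str, np.ndarray],
                             grid: WindowGrid, n_neighbors: int = 10,
                             outlier_k: float = 3.0
                             ) -> set[tuple[str, str]]:
    """Cross-cell chromosome screen for residual per-cell artifacts.

    For each chromosome, a (cell, chromosome) pair is excluded when the
    cell's mean correlation of replication states with all other cells is
    negative, or when its correlation with one of its 10 nearest
    neighbors (by genome-wide state correlation) falls below
    Q1 - ``outlier_k``*IQR of the chromosome's neighbor-correlation pool.
    """
    cells = list(states_by_cell)
    if len(cells) < 12:
        raise ValueError("need >= 12 cells for cross-cell chromosome QC")
    mat = pd.DataFrame(
        {cid: np.where(states_by_cell[cid] == STATE_MASKED, np.nan,
                       states_by_cell[cid].astype(float))
         for cid in cells})
    genome_corr = mat.corr()
    neighbors = {
        cid: list(genome_corr[cid].drop(index=cid)
                  .sort_values(ascending=False).index[:n_neighbors])
        for cid in cells}
    excluded: set[tuple[str, str]] = set()
    for chrom, idx in grid.chrom_groups().items():
        sub = mat.iloc[idx]
        informative = [c for c in cells if sub[c].std(skipna=True) > 0]
        if len(informative) < 2:
            continue
        corr = sub[informative].corr()
        pool = []
        per_cell_min: dict[str, float] = {}
        for cid in informative:
            others = corr[cid].drop(index=cid)
            if others.notna().any() and float(others.mean()) < 0:
                excluded.add((cid, chrom))
            nb = [n for n in neighbors[cid] if n in corr.index]
            vals = corr.loc[nb, cid].dropna()
            if len(vals):
                pool.extend(vals.tolist())
                per_cell_min[cid] = float(vals.min())
        if pool:
            q1, q3 = np.percentile(pool, [25, 75])
            cutoff = q1 - outlier_k * (q3 - q1)
            for cid, worst in per_cell_min.items():
                if worst < cutoff:
                    excluded.add((cid, chrom))
    return excluded


# ---------------------------------------------------------------------------
# Interpolation to the fixed grid, per-cell profile


@dataclass
class CellReplicationProfile:
    """Final per-cell replication calls on the fixed 20-kb grid."""

    cell_id: str
    grid: WindowGrid
    states: np.ndarray
    ratio_4n_over_2n: float
    qc_flags: set[str] = field(default_factory=set)
    excluded_chromosomes: set[str] = field(default_factory=set)

    @property
    def fraction_replicated(self) -> float:
        return percent_replicated(self.states)

    @property
    def passed_qc(self) -> bool:
        return not self.qc_flags


def interpolate_states(states: np.ndarray, source: WindowGrid,
                       target: WindowGrid,
                       excluded_chromosomes: set[str] = frozenset()
                       ) -> np.ndarray:
    """Carry copy states from variable windows onto a fixed grid.

    Each target window takes the overlap-length-weighted mean of the copy
    numbers (2 or 4) of the source windows it intersects; windows whose
    mean is not exactly an integer copy number straddle a state boundary
    and are masked, as are low-mappability target windows.
    """
    out = np.full(target.n_windows, STATE_MASKED, dtype=np.int8)
    src_groups = source.chrom_groups()
    for chrom, tidx in target.chrom_groups().items():
        if chrom in excluded_chromosomes or chrom not in src_groups:
            continue
        sidx = src_groups[chrom]
        s_start = source.start[sidx]
        s_end = source.end[sidx]
        s_state = states[sidx]
        j0 = 0
        for ti in tidx:
            if target.masked[ti]:
                continue
            t0, t1 = target.start[ti], target.end[ti]
            while j0 < len(sidx) and s_end[j0] <= t0:
                j0 += 1
            w_tot = 0.0
            v_tot = 0.0
            j = j0
            while j < len(sidx) and s_start[j] < t1:
                if s_state[j] != STATE_MASKED:
                    ov = min(t1, s_end[j]) - max(t0, s_start[j])
                    if ov > 0:
                        w_tot += ov
                        v_tot += ov * s_state[j]
                j += 1
            if w_tot == 0:
                continue
            mean = v_tot / w_tot
            if abs(mean - STATE_2N) < 1e-9:
                out[ti] = STATE_2N
            elif abs(mean - STATE_4N) < 1e-9:
                out[ti] = STATE_4N
    return out


def percent_replicated(states: np.ndarray) -> float:
    """Fraction of unmasked windows in the replicated (4N) state."""
    informative = states != STATE_MASKED
    if not informative.any():
        raise ValueError("no unmasked windows")
    return float(np.mean(states[informative] == STATE_4N))
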