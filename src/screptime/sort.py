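"""In silico flow cytometry: separating replicating from non-replicating cells.

Replicating (S-phase) cells carry two underlying copy-number states, so
their read depth fluctuates between adjacent genomic windows more than in
non-replicating (G1/G2) cells at the same coverage. The fluctuation is
quantified by MAPD — the median absolute pairwise difference of read counts
between adjacent aggregated windows — scaled by the square root of the mean
reads per aggregated window, which makes it coverage-stable for Poisson
noise. Cells then fall on two distinct lines in the (coverage, scaled MAPD)
plane; an EM mixture of two linear regressions recovers the lines, and
cells within a fixed residual of the lower (G1/G2) line are labeled
non-replicating.

Note the method cannot distinguish G2 from G1 cells: both have uniform
copy number genome-wide, hence the joint "G1/G2" label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .grids import CellCounts

DEFAULT_AGGREGATION = 50
DEFAULT_RESIDUAL_THRESHOLD = 0.05

# Expected scaled MAPD for a pure-Poisson (G1-like) cell: adjacent
# differences are ~N(0, 2*lambda), so median|diff|/sqrt(lambda) ->
# Phi^-1(0.75)*sqrt(2) ~= 0.954, independent of coverage.
G1_SCALED_MAPD_LIMIT = float(norm.ppf(0.75) * np.sqrt(2.0))


@dataclass
class CellQCMetrics:
    cell_id: str
    coverage_per_mb: float
    mapd: float
    scaled_mapd: float
    label: str = "unassigned"      # one of {"G1G2", "S", "unassigned"}
    residual_from_g1_line: float = float("nan")


@dataclass
class SortModel:
    """Two-line mixture model of scaled MAPD vs coverage."""

    slopes: np.ndarray            # per component
    intercepts: np.ndarray
    sigmas: np.ndarray            # Gaussian residual scales
    weights: np.ndarray           # mixing weights, sum to 1
    g1_line_index: int
    residual_threshold: float = DEFAULT_RESIDUAL_THRESHOLD
    converged: bool = False
    degenerate: bool = False
    n_iterations: int = 0
    log_likelihood: float = float("-inf")

    def predict(self, coverage: np.ndarray, component: int) -> np.ndarray:
        return self.intercepts[component] + self.slopes[component] * \
            np.asarray(coverage, dtype=float)


def aggregate_counts(counts: CellCounts, aggregation: int = DEFAULT_AGGREGATION
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Sums of runs of ``aggregation`` unmasked windows, per chromosome.

    Returns (aggregated sums, chromosome group id per aggregate). Runs do
    not span chromosome boundaries; trailing partial runs are dropped.
    """
    if aggregation < 1:
        raise ValueError("aggregation must be >= 1")
    grid = counts.grid
    sums, groups = [], []
    for gi, (chrom, idx) in enumerate(grid.chrom_groups().items()):
        vals = counts.counts[idx][grid.unmasked[idx]]
        n_full = len(vals) // aggregation
        if n_full == 0:
            continue
        agg = vals[:n_full * aggregation].reshape(n_full, aggregation).sum(axis=1)
        sums.append(agg)
        groups.append(np.full(n_full, gi))
    if not sums:
        return np.empty(0), np.empty(0, dtype=int)
    return np.concatenate(sums), np.concatenate(groups)


def compute_scaled_mapd(counts: CellCounts,
                        aggregation: int = DEFAULT_AGGREGATION,
                        form: str = "median_abs_diff") -> CellQCMetrics:
    """Coverage-scaled MAPD of one cell.

    ``form`` selects the statistic: ``median_abs_diff`` (median of
    |adjacent differences|, the default) or ``mad_of_diffs`` (median
    absolute deviation of the differences around their median).
    """
    agg, groups = aggregate_counts(counts, aggregation)
    if len(agg) < 2:
        raise ValueError("insufficient windows: need >= 2 aggregates")
    same_chrom = groups[1:] == groups[:-1]
    diffs = (agg[1:] - agg[:-1])[same_chrom]
    if len(diffs) == 0:
        raise ValueError("insufficient windows: no within-chromosome pairs")
    if form == "median_abs_diff":
        mapd = float(np.median(np.abs(diffs)))
    elif form == "mad_of_diffs":
        mapd = float(np.median(np.abs(diffs - np.median(diffs))))
    else:
        raise ValueError(f"unknown MAPD form: {form}")
    mean_agg = float(np.mean(agg))
    scaled = mapd / np.sqrt(mean_agg) if mean_agg > 0 else float("nan")
    return CellQCMetrics(cell_id=counts.cell_id,
                         coverage_per_mb=counts.coverage_per_mb,
                         mapd=mapd, scaled_mapd=scaled)


def _regression_mixture_em(x: np.ndarray, y: np.ndarray, resp0: np.ndarray,
                           max_iter: int, tol: float):
    """EM for a 2-component mixture of linear regressions with Gaussian noise."""
    n = len(x)
    resp = resp0.copy()
    X = np.column_stack([np.ones(n), x])
    slopes = np.zeros(2)
    intercepts = np.zeros(2)
    sigmas = np.ones(2)
    weights = np.full(2, 0.5)
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # M step: weighted least squares per component
        for k in range(2):
            w = np.maximum(resp[:, k], 1e-12)
            WX = X * w[:, None]
            beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ y, rcond=None)
            intercepts[k], slopes[k] = beta
            r = y - X @ beta
            sigmas[k] = max(np.sqrt((w * r * r).sum() / w.sum()), 1e-6)
            weights[k] = w.sum() / n
        weights /= weights.sum()
        # E step
        log_p = np.empty((n, 2))
        for k in range(2):
            r = y - (intercepts[k] + slopes[k] * x)
            log_p[:, k] = (np.log(weights[k])
                           - 0.5 * np.log(2 * np.pi * sigmas[k] ** 2)
                           - 0.5 * (r / sigmas[k]) ** 2)
        m = log_p.max(axis=1)
        norm_ = m + np.log(np.exp(log_p - m[:, None]).sum(axis=1))
        ll = float(norm_.sum())
        resp = np.exp(log_p - norm_[:, None])
        if abs(ll - prev_ll) < tol * (abs(prev_ll) + 1e-12):
            converged = True
            break
        prev_ll = ll
    return slopes, intercepts, sigmas, weights, ll, converged, it


def fit_sort_model(metrics: list[CellQCMetrics], seed: int = 0,
                   max_iter: int = 500, tol: float = 1e-10,
                   n_restarts: int = 10) -> SortModel:
    """Fit the two-line mixture over (coverage, scaled MAPD).

    Initialization splits cells at the within-coverage-bin median of
    scaled MAPD; additional randomized restarts guard against poor local
    optima, and the best log-likelihood fit is kept. The G1/G2 component
    is the line predicting the smaller scaled MAPD at the maximum
    observed coverage.
    """
    if len(metrics) < 20:
        raise ValueError("need >= 20 cells to fit the sort model")
    x = np.array([m.coverage_per_mb for m in metrics])
    y = np.array([m.scaled_mapd for m in metrics])
    if np.ptp(x) == 0:
        raise ValueError("coverage spread is zero")
    rng = np.random.default_rng(seed)

    # quantile-split initialization within coverage bins
    resp0 = np.zeros((len(x), 2))
    bins = np.quantile(x, np.linspace(0, 1, 6))
    which = np.clip(np.searchsorted(bins, x, side="right") - 1, 0, 4)
    for b in range(5):
        sel = which == b
        if sel.sum() == 0:
            continue
        med = np.median(y[sel])
        hi = sel & (y > med)
        resp0[sel, 0] = 0.9
        resp0[sel, 1] = 0.1
        resp0[hi, 0] = 0.1
        resp0[hi, 1] = 0.9

    best = None
    inits = [resp0] + [
        np.column_stack([u := rng.uniform(0.05, 0.95, len(x)), 1 - u])
        for _ in range(n_restarts - 1)]
    for r0 in inits:
        out = _regression_mixture_em(x, y, r0, max_iter, tol)
        if best is None or out[4] > best[4]:
            best = out
    slopes, intercepts, sigmas, weights, ll, converged, it = best

    xmax = x.max()
    pred_at_max = intercepts + slopes * xmax
    g1_idx = int(np.argmin(pred_at_max))
    # components that stay within a few residual widths of each other
    # over the observed coverage range describe a single population
    mean_sep = float(np.mean(np.abs((intercepts[0] - intercepts[1])
                                    + (slopes[0] - slopes[1]) * x)))
    degenerate = bool(mean_sep < 3 * max(sigmas))
    return SortModel(slopes=slopes, intercepts=intercepts, sigmas=sigmas,
                     weights=weights, g1_line_index=g1_idx,
                     converged=converged, degenerate=degenerate,
                     n_iterations=it, log_likelihood=ll)


def label_cells(metrics: list[CellQCMetrics], model: SortModel
                ) -> list[CellQCMetrics]:
    """Assign G1G2 vs S by absolute residual from the G1/G2 line."""
    out = []
    for m in metrics:
        pred = float(model.predict(np.array([m.coverage_per_mb]),
                                   model.g1_line_index)[0])
        resid = m.scaled_mapd - pred
        # tiny epsilon keeps the closed boundary robust to float round-off
        label = ("G1G2" if abs(resid) <= model.residual_threshold + 1e-9
                 else "S")
        out.append(CellQCMetrics(
            cell_id=m.cell_id, coverage_per_mb=m.coverage_per_mb,
            mapd=m.mapd, scaled_mapd=m.scaled_mapd, label=label,
            residual_from_g1_line=resid))
    return out
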