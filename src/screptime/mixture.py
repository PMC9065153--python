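"""Two-component Poisson mixture fitting by EM.

Used both to initialize per-cell replication-state inference (aggregated
read counts in an S-phase cell are a mixture of an unreplicated and a
replicated rate) and to screen cells for copy-number aberrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp


@dataclass
class PoissonMixtureFit:
    lambda_low: float
    lambda_high: float
    weight_low: float      # mixing weight of the low-rate component
    converged: bool
    n_iterations: int
    log_likelihood: float

    @property
    def ratio(self) -> float:
        return self.lambda_high / self.lambda_low


def _poisson_logpmf(x: np.ndarray, lam: float) -> np.ndarray:
    if lam <= 0:
        lam = 1e-12
    return x * np.log(lam) - lam - gammaln(x + 1.0)


def fit_poisson_mixture(values: np.ndarray, max_iter: int = 500,
                        tol: float = 1e-8,
                        min_weight: float = 0.0) -> PoissonMixtureFit:
    """EM fit of a two-component Poisson mixture; components ordered by rate.

    ``min_weight`` floors both mixing weights, preventing a component from
    specializing to a small outlier region (useful when the mixture should
    describe the bulk of the genome, not rare aberrations).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    if np.all(x == 0):
        raise ValueError("insufficient signal: all counts are zero")
    # moment-style init: split around the mean
    mean = x.mean()
    lam_lo = max(np.mean(x[x <= mean]), 1e-6)
    lam_hi = max(np.mean(x[x > mean]), lam_lo * 1.5) if np.any(x > mean) \
        else lam_lo * 2.0
    w_lo = 0.5
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_p = np.column_stack([
            np.log(max(w_lo, 1e-12)) + _poisson_logpmf(x, lam_lo),
            np.log(max(1 - w_lo, 1e-12)) + _poisson_logpmf(x, lam_hi)])
        norm = logsumexp(log_p, axis=1)
        ll = float(norm.sum())
        resp = np.exp(log_p - norm[:, None])
        n_lo = resp[:, 0].sum()
        n_hi = resp[:, 1].sum()
        if n_lo < 1e-10 or n_hi < 1e-10:
            break  # one component emptied out: degenerate
        w_lo = float(np.clip(n_lo / len(x), min_weight, 1 - min_weight))
        lam_lo = float(resp[:, 0] @ x / n_lo)
        lam_hi = float(resp[:, 1] @ x / n_hi)
        if lam_lo > lam_hi:
            lam_lo, lam_hi = lam_hi, lam_lo
            w_lo = 1 - w_lo
        if abs(ll - prev_ll) < tol * (abs(prev_ll) + 1e-12):
            converged = True
            break
        prev_ll = ll
    return PoissonMixtureFit(lambda_low=float(lam_lo), lambda_high=float(lam_hi),
                             weight_low=float(w_lo), converged=converged,
                             n_iterations=it, log_likelihood=float(ll))


def component_scores(values: np.ndarray, fit: PoissonMixtureFit,
                     scale: float = 1.0) -> np.ndarray:
    """Per-value probability under the better-fitting component.

    ``scale`` divides the fitted rates (e.g. 1/15 of an aggregate rate to
    score individual windows).
    """
    x = np.asarray(values, dtype=float)
    lp = np.maximum(_poisson_logpmf(x, fit.lambda_low * scale),
                    _poisson_logpmf(x, fit.lambda_high * scale))
    return np.exp(lp)


def log_tail_probability(total: float, fit: PoissonMixtureFit,
                         n_units: int = 1) -> float:
    """Log probability of a pooled count at least as extreme as observed.

    The pool of ``n_units`` aggregates may mix the two rates (e.g. a
    region straddling replicated and unreplicated domains), so the total
    is scored against every composition k*lambda_low +
    (n-k)*lambda_high and the most favorable one is kept: only counts
    extreme under *all* compositions are outliers.
    """
    from scipy.stats import poisson

    n_units = int(n_units)
    best = -np.inf
    for k in range(n_units + 1):
        lam = k * fit.lambda_low + (n_units - k) * fit.lambda_high
        if total < lam:
            lp = poisson.logcdf(total, lam)
        else:
            lp = poisson.logsf(total - 1, lam)
        best = max(best, float(lp))
    return best
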