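"""Two-state Poisson HMM: decoding, initialization, QC, interpolation."""

import numpy as np
import pytest

from screptime import (WindowGrid, infer_states_hmm, init_mixed_poisson,
                       interpolate_states, percent_replicated, qc_cell,
                       qc_chromosome_cross_cell)
from screptime.grids import STATE_2N, STATE_4N, STATE_MASKED, CellCounts
from screptime.hmm import TwoStatePoissonHMM, ratio_4n_over_2n


def enumerate_best_path(model, x, missing):
    """Independent decoding oracle: exhaustive search over all 2^T paths."""
    T = len(x)
    paths = np.array(np.meshgrid(*[[0, 1]] * T, indexing="ij")
                     ).reshape(T, -1).T
    logb = model._log_emissions(np.asarray(x, float), missing)
    with np.errstate(divide="ignore"):
        lt = np.log(model.transmat)
        ls = np.log(model.startprob)
    ll = ls[paths[:, 0]] + logb[np.arange(T), paths].sum(axis=1) \
        + lt[paths[:, :-1], paths[:, 1:]].sum(axis=1)
    return paths[np.argmax(ll)], ll.max()


def random_instance(rng):
    T = int(rng.integers(2, 13))
    rates = np.sort(rng.uniform(0.5, 10, 2))
    p = rng.uniform(0.55, 0.99)
    model = TwoStatePoissonHMM(
        rates=rates, transmat=np.array([[p, 1 - p], [1 - p, p]]),
        startprob=rng.dirichlet([1.0, 1.0]))
    x = rng.poisson(rng.choice(rates, T))
    missing = rng.uniform(size=T) < 0.2
    if missing.all():
        missing[0] = False
    return model, x, missing


class TestViterbiOracle:
    def test_matches_enumeration(self, rng):
        for _ in range(200):
            model, x, missing = random_instance(rng)
            vit = model.viterbi(x, missing)
            _, best_ll = enumerate_best_path(model, x, missing)
            assert model.path_log_likelihood(x, vit, missing) == \
                pytest.approx(best_ll, abs=1e-9)

    def test_single_rate_sticky_single_state(self, rng):
        model = TwoStatePoissonHMM(rates=np.array([5.0, 10.0]))
        x = rng.poisson(5.0, 200)
        path = model.viterbi(x)
        assert len(np.unique(path)) == 1

    def test_posterior_sums_to_one(self, rng):
        model, x, missing = random_instance(rng)
        gamma = model.posterior(x, missing)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-12)


class TestBaumWelch:
    def test_rate_recovery_block_structure(self, rng):
        truth = np.repeat(rng.integers(0, 2, 40), 50)
        x = rng.poisson(np.where(truth == 1, 6.0, 3.0))
        model = TwoStatePoissonHMM(rates=np.array([2.5, 7.0]))
        model.fit(x, max_iter=200)
        assert model.converged
        assert model.rates[0] == pytest.approx(3.0, rel=0.1)
        assert model.rates[1] == pytest.approx(6.0, rel=0.1)

    def test_label_symmetry(self, rng):
        truth = np.repeat(rng.integers(0, 2, 20), 50)
        x = rng.poisson(np.where(truth == 1, 6.0, 3.0))
        a = TwoStatePoissonHMM(rates=np.array([3.0, 6.0])).fit(x)
        b = TwoStatePoissonHMM(rates=np.array([6.2, 2.9])).fit(x)
        np.testing.assert_allclose(a.rates, b.rates, rtol=1e-3)
        np.testing.assert_array_equal(a.viterbi(x), b.viterbi(x))

    def test_monotone_log_likelihood(self, rng):
        x = rng.poisson(np.repeat([3.0, 6.0, 3.0], 100))
        model = TwoStatePoissonHMM(rates=np.array([2.0, 8.0]))
        lls = []
        for n in (1, 3, 10, 50):
            m = TwoStatePoissonHMM(rates=np.array([2.0, 8.0]))
            m.fit(x.copy(), max_iter=n, tol=0)
            lls.append(m.log_likelihood)
        assert np.all(np.diff(lls) >= -1e-8)


def _s_cell_counts(rng, n=3000, lam=3.0, block=80):
    truth = np.repeat(rng.integers(0, 2, (n + block - 1) // block), block)[:n]
    counts = rng.poisson(np.where(truth == 1, 2 * lam, lam))
    grid = WindowGrid.fixed_windows({"chr1": n * 20_000})
    return CellCounts("c", grid, counts), truth


class TestInitMixedPoisson:
    def test_mid_s_cell_included(self, rng):
        cell, _ = _s_cell_counts(rng)
        init = init_mixed_poisson(cell)
        assert init.included
        assert init.fit.ratio == pytest.approx(2.0, abs=0.3)

    def test_pure_g1_cell_excluded(self, rng):
        grid = WindowGrid.fixed_windows({"chr1": 3000 * 20_000})
        cell = CellCounts("c", grid, rng.poisson(3.0, 3000))
        init = init_mixed_poisson(cell)
        assert not init.included

    def test_nearer_mean_assignment(self, rng):
        cell, truth = _s_cell_counts(rng, lam=5.0)
        init = init_mixed_poisson(cell)
        agree = np.mean(init.initial_states == truth)
        assert agree > 0.75  # window-level, pre-HMM

    def test_ratio_boundary_closed_interval(self):
        from screptime.hmm import RATIO_RANGE
        assert RATIO_RANGE[0] <= 1.5 and RATIO_RANGE[1] >= 2.5


class TestInferStates:
    def test_block_boundaries_recovered(self, rng):
        cell, truth = _s_cell_counts(rng, lam=2.0, block=100)
        init = init_mixed_poisson(cell)
        res = infer_states_hmm(cell, init)
        decoded = (res.states == STATE_4N).astype(int)
        acc = np.mean(decoded == truth)
        assert acc > 0.95
        assert 1.5 <= res.ratio <= 2.5

    def test_masked_windows_stay_masked(self, rng):
        cell, _ = _s_cell_counts(rng)
        cell.grid.masked[100:120] = True
        init = init_mixed_poisson(cell)
        res = infer_states_hmm(cell, init)
        assert np.all(res.states[100:120] == STATE_MASKED)


class TestQcCell:
    def _grid(self, sizes):
        return WindowGrid.fixed_windows(
            {f"chr{i}": n * 20_000 for i, n in enumerate(sizes, 1)})

    def test_clean_cell_unflagged(self):
        grid = self._grid([100, 100])
        states = np.full(200, STATE_2N)
        states[40:70] = STATE_4N
        states[140:160] = STATE_4N
        assert qc_cell(states, grid, ratio=2.0) == set()

    def test_full_chromosome_conflict(self):
        grid = self._grid([100, 100])
        states = np.concatenate([np.full(100, STATE_4N),
                                 np.full(100, STATE_2N)])
        flags = qc_cell(states, grid, ratio=2.0)
        assert "full_chrom_conflict" in flags
        assert "chrom_sd" in flags  # sd over {2,4} means is 1 > 0.4

    def test_ratio_boundary_retained(self):
        grid = self._grid([100])
        states = np.full(100, STATE_2N)
        states[10:50] = STATE_4N
        assert "ratio_out_of_range" not in qc_cell(states, grid, ratio=2.5)
        assert "ratio_out_of_range" in qc_cell(states, grid, ratio=2.51)


class TestCrossCellQC:
    def _profiles(self, rng, n_cells=15, shuffle_one=False):
        grid = WindowGrid.fixed_windows({"chr1": 300 * 20_000,
                                         "chr2": 300 * 20_000})
        timing = np.concatenate([np.sin(np.linspace(0, 9, 300)),
                                 np.sin(np.linspace(1, 10, 300))])
        states = {}
        for i in range(n_cells):
            thr = rng.uniform(-0.3, 0.3)
            s = np.where(timing > thr, STATE_4N, STATE_2N).astype(np.int8)
            states[f"c{i}"] = s
        if shuffle_one:
            s = states["c0"].copy()
            rng.shuffle(s[300:])
            states["c0"] = s
        return states, grid

    def test_faithful_cohort_no_exclusions(self, rng):
        states, grid = self._profiles(rng)
        assert qc_chromosome_cross_cell(states, grid) == set()

    def test_shuffled_chromosome_excluded(self, rng):
        states, grid = self._profiles(rng, shuffle_one=True)
        excluded = qc_chromosome_cross_cell(states, grid)
        assert ("c0", "chr2") in excluded
        assert ("c0", "chr1") not in excluded

    def test_too_few_cells(self, rng):
        states, grid = self._profiles(rng, n_cells=5)
        with pytest.raises(ValueError):
            qc_chromosome_cross_cell(states, grid)


class TestInterpolation:
    def test_aligned_grids_identity(self):
        grid = WindowGrid.fixed_windows({"chr1": 50 * 20_000})
        states = np.full(50, STATE_2N, dtype=np.int8)
        states[10:30] = STATE_4N
        states[40] = STATE_MASKED
        out = interpolate_states(states, grid, grid)
        np.testing.assert_array_equal(out, states)

    def test_straddling_boundary_masked(self):
        source = WindowGrid(np.array(["chr1", "chr1"], dtype=object),
                            np.array([0, 30_000]), np.array([30_000, 60_000]),
                            np.ones(2), np.zeros(2, bool))
        target = WindowGrid.fixed_windows({"chr1": 3 * 20_000})
        states = np.array([STATE_2N, STATE_4N], dtype=np.int8)
        out = interpolate_states(states, source, target)
        assert out.tolist() == [STATE_2N, STATE_MASKED, STATE_4N]

    def test_low_mappability_target_masked(self):
        grid = WindowGrid.fixed_windows({"chr1": 10 * 20_000})
        target = WindowGrid.fixed_windows({"chr1": 10 * 20_000})
        target.masked[3] = True
        states = np.full(10, STATE_4N, dtype=np.int8)
        out = interpolate_states(states, grid, target)
        assert out[3] == STATE_MASKED


class TestPercentReplicated:
    def test_extremes(self):
        assert percent_replicated(np.full(10, STATE_2N)) == 0.0
        assert percent_replicated(np.full(10, STATE_4N)) == 1.0

    def test_ignores_masked(self):
        states = np.array([STATE_4N, STATE_MASKED, STATE_2N, STATE_MASKED])
        assert percent_replicated(states) == 0.5

    def test_all_masked_raises(self):
        with pytest.raises(ValueError):
            percent_replicated(np.full(4, STATE_MASKED))

    def test_accurate_on_simulation(self, timing_profile, det_cells):
        from screptime import infer_profiles
        cells = [c for c in det_cells if c.coverage_per_mb >= 100][:15]
        out = infer_profiles([c.to_cell_counts() for c in cells])
        truth = {c.cell_id: c.true_fraction_replicated for c in cells}
        for p in out.profiles:
            assert p.fraction_replicated == pytest.approx(
                truth[p.cell_id], abs=0.02)


def test_ratio_statistic():
    counts = np.array([2.0, 2, 4, 4])
    states = np.array([STATE_2N, STATE_2N, STATE_4N, STATE_4N])
    assert ratio_4n_over_2n(counts, states) == pytest.approx(2.0)
    assert np.isnan(ratio_4n_over_2n(counts, np.full(4, STATE_2N)))
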