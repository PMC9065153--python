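"""Firing order, firing time, late-IR classification, PCA embedding."""

import numpy as np
import pytest

from screptime import (classify_late_irs, expected_states, firing_order_stats,
                       firing_range, observed_ir_states, pca_embedding,
                       simulate_stochastic_cells)
from screptime.grids import STATE_2N, STATE_4N, WindowGrid
from screptime.hmm import CellReplicationProfile
from screptime.ir_calling import (InitiationRegion, ReplicationTrack,
                                  call_initiation_regions)
from screptime.simulate import make_class_program


def _irs(timings):
    return [InitiationRegion(ir_id=i, chromosome="chr1", center=1e6 * (i + 1),
                             start=1e6 * (i + 1) - 5e4,
                             end=1e6 * (i + 1) + 5e4, n_tracks=10,
                             aggregate_timing=t)
            for i, t in enumerate(timings)]


class TestExpectedStates:
    def test_zero_and_all(self):
        irs = _irs([3.0, 2.0, 1.0])
        observed = np.array([[False] * 3, [True] * 3])
        exp = expected_states(observed, irs)
        assert not exp[0].any()
        assert exp[1].all()

    def test_n_earliest_expected(self):
        irs = _irs([1.0, 3.0, 2.0])   # ranks: ir1 earliest, ir2, ir0
        observed = np.array([[True, False, True]])  # 2 replicated
        exp = expected_states(observed, irs)
        assert exp[0].tolist() == [False, True, True]


class TestFiringOrderStats:
    def test_deterministic_truth_zero_mismatch(self, timing_profile,
                                               det_cells):
        profiles = [CellReplicationProfile(c.cell_id, timing_profile.grid,
                                           c.true_state, 2.0)
                    for c in det_cells
                    if 0 < c.true_fraction_replicated < 1]
        irs, tracks = call_initiation_regions(profiles)
        observed = observed_ir_states(profiles, irs, tracks)
        # under exact nesting, replication frequency is the ensemble
        # timing: more cells have replicated earlier IRs
        for k, ir in enumerate(irs):
            ir.aggregate_timing = float(observed[:, k].mean())
        exp = expected_states(observed, irs)
        result = firing_order_stats(observed, exp, irs)
        assert np.all(result.mismatch_fraction == 0)

    def test_single_timing_value_refused(self):
        irs = _irs([1.0, 1.0, 1.0])
        observed = np.ones((10, 3), dtype=bool)
        exp = expected_states(observed, irs)
        result = firing_order_stats(observed, exp, irs)
        assert result.degenerate_fit
        assert result.parabola is None

    def test_mismatch_accounting(self):
        irs = _irs([3.0, 2.0, 1.0])
        # cell 0 replicated only the *latest* IR: 1 premature + 1 delayed
        observed = np.array([[False, False, True]])
        exp = expected_states(observed, irs)
        result = firing_order_stats(observed, exp, irs)
        assert result.n_premature.tolist() == [0, 0, 1]
        assert result.n_delayed.tolist() == [1, 0, 0]
        assert result.mismatch_fraction.tolist() == [1.0, 0.0, 1.0]


class TestClassifyLateIrs:
    def _setup(self, firing_pcts_by_ir, n_cells=40):
        grid = WindowGrid.fixed_windows({"chr1": 1000 * 20_000})
        profiles = []
        for i in range(n_cells):
            frac = (i + 0.5) / n_cells
            states = np.full(1000, STATE_2N, dtype=np.int8)
            states[:int(1000 * frac)] = STATE_4N
            profiles.append(CellReplicationProfile(
                f"c{i}", grid, states, 2.0))
        pct_to_cell = {round((i + 0.5) / n_cells * 100, 4): f"c{i}"
                       for i in range(n_cells)}
        irs, tracks = [], []
        for j, pcts in enumerate(firing_pcts_by_ir):
            irs.append(InitiationRegion(
                ir_id=j, chromosome="chr1", center=1e6 * (j + 1),
                start=1e6 * (j + 1) - 5e4, end=1e6 * (j + 1) + 5e4,
                n_tracks=len(pcts)))
            for pct in pcts:
                cell = pct_to_cell[min(pct_to_cell,
                                       key=lambda k: abs(k - pct))]
                t = ReplicationTrack(cell, "chr1", 0, 1, 0, 40_000,
                                     20_000, (0, 20_000, 40_000))
                t.assigned_ir = j
                tracks.append(t)
        return irs, profiles, tracks

    def test_rule_precedence(self):
        irs, profiles, tracks = self._setup([
            [55, 60, 70],                       # never early: late
            [20, 30, 40, 55, 60, 65, 70, 75, 80, 85],  # >5 late cells
            [20, 30, 55],                       # few cells, mostly early
        ])
        classes = classify_late_irs(irs, profiles, tracks)
        assert classes[0] == "constitutive_late"
        assert classes[1] == "throughout"
        assert classes[2] == "rare_early"

    def test_frequently_firing_labeled_early(self):
        irs, profiles, tracks = self._setup(
            [list(np.linspace(5, 95, 30))], n_cells=40)
        classes = classify_late_irs(irs, profiles, tracks)
        assert classes[0] == "early"

    def test_planted_class_recovery(self):
        prog = make_class_program(seed=80)
        cells = simulate_stochastic_cells(prog, 250, seed=81)
        profiles = [CellReplicationProfile(c.cell_id, prog.grid,
                                           c.true_state, 2.0)
                    for c in cells if 0 < c.true_fraction_replicated < 1]
        irs, tracks = call_initiation_regions(profiles)
        classify_late_irs(irs, profiles, tracks)
        ok = tot = 0
        for o in prog.origins:
            if o.label in ("early", "filler"):
                continue
            pos = o.window * 20_000 + 10_000
            near = [ir for ir in irs
                    if abs(ir.center - pos) <= 100_000]
            if not near:
                continue
            ir = min(near, key=lambda ir: abs(ir.center - pos))
            n_cells = len({t.cell_id for t in tracks
                           if t.assigned_ir == ir.ir_id})
            if n_cells < 10:
                continue
            tot += 1
            ok += ir.firing_class == o.label
        assert tot >= 5
        assert ok / tot >= 0.8


class TestFiringRange:
    def test_range_and_corroboration(self):
        prog = make_class_program(seed=82)
        cells = simulate_stochastic_cells(prog, 200, seed=83)
        profiles = [CellReplicationProfile(c.cell_id, prog.grid,
                                           c.true_state, 2.0)
                    for c in cells if 0 < c.true_fraction_replicated < 1]
        irs, tracks = call_initiation_regions(profiles)
        observed = observed_ir_states(profiles, irs, tracks)
        # early domain occupies the first 36 Mb, the late domain starts
        # at 60 Mb (see make_class_program layout)
        early = [(k, ir) for k, ir in enumerate(irs)
                 if ir.center < 36e6 and ir.n_tracks >= 20]
        late = [(k, ir) for k, ir in enumerate(irs)
                if ir.center > 60e6 and ir.n_tracks >= 10]
        assert early and late
        k, ir = early[0]
        fr = firing_range(ir, k, profiles, observed, irs, tracks)
        assert fr.earliest_fired_pct < 20
        k, ir = late[0]
        fr = firing_range(ir, k, profiles, observed, irs, tracks)
        assert fr.earliest_fired_pct > 50

    def test_single_firing_cell_uncorroborated(self):
        grid = WindowGrid.fixed_windows({"chr1": 100 * 20_000})
        states = np.full(100, STATE_2N, dtype=np.int8)
        states[40:60] = STATE_4N
        profiles = [CellReplicationProfile("c0", grid, states, 2.0)]
        ir = InitiationRegion(0, "chr1", 1_000_000, 950_000, 1_050_000, 1)
        t = ReplicationTrack("c0", "chr1", 40, 59, 800_000, 1_200_000,
                             1_000_000, (975_000, 1_000_000, 1_025_000))
        t.assigned_ir = 0
        fr = firing_range(ir, 0, profiles, np.ones((1, 1), bool), [ir], [t])
        assert not fr.earliest_corroborated


class TestPcaEmbedding:
    def _profiles(self, n=30):
        grid = WindowGrid.fixed_windows({"chr1": 500 * 20_000})
        out = []
        for i in range(n):
            states = np.full(500, STATE_2N, dtype=np.int8)
            states[:10 * i] = STATE_4N
            out.append(CellReplicationProfile(f"c{i}", grid, states, 2.0))
        return out

    def test_pc1_tracks_fraction_replicated(self):
        res = pca_embedding(self._profiles())
        assert res.pc1_fraction_corr >= 0.95

    def test_duplicate_cells_identical_coordinates(self):
        profiles = self._profiles()
        profiles[1] = CellReplicationProfile(
            "dup", profiles[0].grid, profiles[0].states.copy(), 2.0)
        profiles[0] = CellReplicationProfile(
            "orig", profiles[1].grid, profiles[1].states.copy(), 2.0)
        res = pca_embedding(profiles)
        np.testing.assert_allclose(res.coordinates[0], res.coordinates[1],
                                   atol=1e-9)

    def test_two_cell_types_separate(self):
        # two cell types share most of a deterministic firing order but
        # differ in one origin (block 8 vs block 9): S-phase progression
        # stays on PC1, the type contrast lands on a later component
        grid = WindowGrid.fixed_windows({"chr1": 500 * 20_000})
        rng = np.random.default_rng(9)
        common = [0, 1, 2, 3, 4, 5, 6, 7]
        profiles = []
        for i in range(40):
            typ = i % 2
            order = common[:3] + [8 if typ == 0 else 9] + common[3:]
            k = int(rng.integers(4, 10))  # past the type-specific origin
            states = np.full(500, STATE_2N, dtype=np.int8)
            for b in order[:k]:
                states[b * 50:(b + 1) * 50] = STATE_4N
            profiles.append(CellReplicationProfile(f"c{i}", grid,
                                                   states, 2.0))
        res = pca_embedding(profiles)
        assert res.pc1_fraction_corr >= 0.9
        from sklearn.cluster import KMeans
        labels = KMeans(2, n_init=10, random_state=0).fit_predict(
            res.coordinates[:, 1:3])
        truth = np.arange(40) % 2
        acc = max(np.mean(labels == truth), np.mean(labels != truth))
        assert acc >= 0.9

    def test_sex_chromosomes_excluded(self):
        grid = WindowGrid.fixed_windows({"chr1": 200 * 20_000,
                                         "chrX": 200 * 20_000})
        profiles = []
        for i in range(12):
            states = np.full(400, STATE_2N, dtype=np.int8)
            states[:i * 15] = STATE_4N
            profiles.append(CellReplicationProfile(f"c{i}", grid,
                                                   states, 2.0))
        res = pca_embedding(profiles, autosomes_only=True)
        assert res.coordinates.shape[0] == 12
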