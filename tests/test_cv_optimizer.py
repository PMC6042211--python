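import math

import numpy as np
import pytest

import locohcv.cv_optimizer as cvmod
from locohcv import (
    DegenerateHullsetError,
    ParameterError,
    ScoreSurface,
    SearchConfig,
    SplitScheme,
    Trajectory,
    Vmax,
    build_hullset,
    coarse_grid_search,
    compute_vmax,
    cv_score,
    log_density,
    optimize,
    refine_search,
    split_train_test,
)
from locohcv.cv_optimizer import _k_grid, _s_grid
from conftest import make_random_track
from oracles import naive_cv_score


class TestSplits:
    def test_partition_disjoint(self, two_patch_track):
        scheme = SplitScheme(n_splits=1, test_fraction=0.25, seed=1)
        (train, test), = split_train_test(two_patch_track, scheme)
        assert len(train) == 90 and len(test) == 30
        train_keys = {(f.t, f.x, f.y) for f in train}
        test_keys = {(f.t, f.x, f.y) for f in test}
        assert not train_keys & test_keys
        assert len(train_keys | test_keys) == len(two_patch_track)

    def test_same_seed_identical(self, two_patch_track):
        scheme = SplitScheme(n_splits=3, test_fraction=0.25, seed=5)
        a = split_train_test(two_patch_track, scheme)
        b = split_train_test(two_patch_track, scheme)
        for (tra, tea), (trb, teb) in zip(a, b):
            assert tra.fixes == trb.fixes and tea == teb

    def test_temporal_blocks_tile(self, two_patch_track):
        scheme = SplitScheme(n_splits=4, mode="temporal-blocks", seed=0)
        splits = split_train_test(two_patch_track, scheme)
        covered = []
        for _, test in splits:
            covered.extend(f.index for f in test)
        assert sorted(covered) == list(range(len(two_patch_track)))

    def test_tiny_test_fraction_rejected(self, two_patch_track):
        with pytest.raises(ParameterError):
            split_train_test(two_patch_track, SplitScheme(test_fraction=0.001, seed=0))

    def test_too_short_track_rejected(self):
        traj = make_random_track(seed=0, n=7)
        with pytest.raises(ParameterError):
            split_train_test(traj, SplitScheme(seed=0))


class TestLogDensity:
    def _hullset(self, traj, k=4, s=0.0):
        return build_hullset(traj, k, s, Vmax(2.0))

    def test_single_covering_hull(self):
        # one big triangle repeated: pick k = n so every hull is the global hull
        traj = Trajectory.from_arrays(
            np.array([0.0, 10.0, 0.0, 2.0]), np.array([0.0, 0.0, 10.0, 2.0]),
            600.0 * np.arange(4))
        hs = self._hullset(traj, k=4)
        # 4 identical hulls of area 50 -> A = 200; center covered by all 4
        assert log_density(hs, (2.0, 2.0)) == pytest.approx(math.log(4 / 200.0), rel=1e-12)
        # k_max algebra: log(n / (n * area)) = -log(area)
        assert log_density(hs, (2.0, 2.0)) == pytest.approx(-math.log(50.0), rel=1e-12)

    def test_fallback_squares_area(self):
        traj = Trajectory.from_arrays(
            np.array([0.0, 10.0, 0.0, 2.0]), np.array([0.0, 0.0, 10.0, 2.0]),
            600.0 * np.arange(4))
        hs = self._hullset(traj, k=4)
        out = log_density(hs, (1e6, 1e6))
        assert out == pytest.approx(-2.0 * math.log(200.0), rel=1e-12)

    def test_degenerate_area_rejected(self):
        traj = Trajectory.from_arrays(
            np.array([0.0, 1.0, 0.0, 0.2]), np.array([0.0, 0.0, 1.0, 0.2]),
            600.0 * np.arange(4))
        hs = self._hullset(traj, k=4)  # total area 2 m^2 > 1... shrink instead
        small = Trajectory.from_arrays(
            np.array([0.0, 0.5, 0.0, 0.1]), np.array([0.0, 0.0, 0.5, 0.1]),
            600.0 * np.arange(4))
        with pytest.raises(DegenerateHullsetError):
            log_density(self._hullset(small, k=4), (0.1, 0.1))
        assert hs.total_area > 1.0


class TestCvScore:
    def test_single_term_sum(self):
        # 1 split, 1 test point landing in exactly g hulls
        traj = make_random_track(seed=2, n=20, extent=100.0)
        scheme = SplitScheme(n_splits=1, test_fraction=0.05, seed=3)  # m = 1
        vmax = compute_vmax(traj)
        (train, test), = split_train_test(traj, scheme)
        hs = build_hullset(train, 6, 0.01, vmax)
        expected = log_density(hs, test[0])
        assert cv_score(traj, 6, 0.01, scheme, vmax) == pytest.approx(expected, rel=1e-12)

    def test_duplicated_splits_double_the_score(self, monkeypatch):
        traj = make_random_track(seed=6, n=30)
        scheme = SplitScheme(n_splits=1, test_fraction=0.25, seed=9)
        single = cv_score(traj, 5, 0.01, scheme)
        real = cvmod.split_train_test

        def doubled(t, s):
            out = real(t, s)
            return out + out

        monkeypatch.setattr(cvmod, "split_train_test", doubled)
        assert cv_score(traj, 5, 0.01, scheme) == pytest.approx(2 * single, rel=1e-12)

    def test_matches_end_to_end_brute_force(self):
        scheme = SplitScheme(n_splits=2, test_fraction=0.25, seed=13)
        traj = make_random_track(seed=21, n=60)
        vmax = compute_vmax(traj)
        got = cv_score(traj, 6, 0.0, scheme, vmax)
        want = naive_cv_score(traj, 6, 0.0, scheme, vmax.value)
        assert got == pytest.approx(want, abs=1e-9)

    def test_k_too_large_for_training_subset(self, two_patch_track):
        scheme = SplitScheme(n_splits=1, test_fraction=0.25, seed=0)
        with pytest.raises(ParameterError):
            cv_score(two_patch_track, 91, 0.0, scheme)

    def test_kmax_penalty_per_s(self, two_patch_track):
        """P at k_max sits below the per-s maximum on a clustered track."""
        scheme = SplitScheme(n_splits=2, test_fraction=0.25, seed=17)
        vmax = compute_vmax(two_patch_track)
        k_max = 90  # training size
        for s in (0.0, 0.02):
            scores = [cv_score(two_patch_track, k, s, scheme, vmax) for k in (6, 12, 24, 48)]
            at_kmax = cv_score(two_patch_track, k_max, s, scheme, vmax)
            assert at_kmax < max(scores)


class TestNormalization:
    def test_density_integrates_to_one(self, two_patch_track):
        hs = build_hullset(two_patch_track, 12, 0.01, compute_vmax(two_patch_track))
        rng = np.random.default_rng(0)
        minx, miny, maxx, maxy = (
            two_patch_track.coords[:, 0].min() - 200, two_patch_track.coords[:, 1].min() - 200,
            two_patch_track.coords[:, 0].max() + 200, two_patch_track.coords[:, 1].max() + 200,
        )
        n = 200_000
        xs = rng.uniform(minx, maxx, n)
        ys = rng.uniform(miny, maxy, n)
        g = hs.count_covering_hulls(xs, ys)
        box_area = (maxx - minx) * (maxy - miny)
        integral = box_area * g.mean() / hs.total_area
        assert integral == pytest.approx(1.0, abs=0.03)


class TestGridSearch:
    def test_default_coarse_grid_is_240_cells(self):
        ks = _k_grid(4, 800, 20)
        ss = _s_grid(0.0, 0.05, 0.01)
        assert len(ks) == 40 and ks[0] == 4 and ks[-1] == 784
        assert len(ss) == 6 and ss == [0.0, 0.01, 0.02, 0.03, 0.04, 0.05]

    def test_unique_maximum_is_argmax(self):
        surf = ScoreSurface(k_values=(4, 5), s_values=(0.0, 0.01),
                            scores=np.array([[1.0, 3.0], [0.0, 2.0]]))
        assert surf.best == (4, 0.01, 3.0)

    def test_all_equal_ties_to_kmin_smin(self):
        surf = ScoreSurface(k_values=(4, 5, 6), s_values=(0.0, 0.01),
                            scores=np.zeros((3, 2)))
        assert surf.best == (4, 0.0, 0.0)

    def test_refinement_never_worse_than_coarse(self, two_patch_track):
        scheme = SplitScheme(n_splits=2, test_fraction=0.25, seed=19)
        config = SearchConfig(k_max_grid=40, s_max=0.02)
        coarse, final = optimize(two_patch_track, scheme, config=config)
        assert final.best[2] >= coarse.best[2]

    def test_edge_peak_clips_windows(self):
        traj = make_random_track(seed=33, n=60)
        scheme = SplitScheme(n_splits=2, test_fraction=0.25, seed=3)
        config = SearchConfig(k_min=4, k_max_grid=12, k_step_coarse=8, s_max=0.01)
        coarse = coarse_grid_search(traj, scheme, config=config)
        final = refine_search(traj, scheme, config=config, coarse=coarse)
        assert min(final.k_values) >= 4
        assert max(final.k_values) <= 12
        assert min(final.s_values) >= 0.0
        assert max(final.s_values) <= 0.01 + 1e-12

    def test_deterministic_surfaces(self, two_patch_track):
        scheme = SplitScheme(n_splits=2, test_fraction=0.25, seed=23)
        config = SearchConfig(k_max_grid=24, s_max=0.01)
        runs = [optimize(two_patch_track, scheme, config=config)[1] for _ in range(2)]
        assert runs[0].k_values == runs[1].k_values
        assert runs[0].s_values == runs[1].s_values
        assert np.array_equal(runs[0].scores, runs[1].scores, equal_nan=True)
        assert runs[0].best == runs[1].best

    def test_kmin_above_feasible_k_rejected(self):
        traj = make_random_track(seed=3, n=20)
        scheme = SplitScheme(n_splits=1, test_fraction=0.25, seed=0)
        with pytest.raises(ParameterError):
            coarse_grid_search(traj, scheme, config=SearchConfig(k_min=50, k_max_grid=60))


class TestFallbackOrdering:
    def test_uncovered_scores_below_any_covered(self):
        for area in (1.5, 10.0, 1e8):
            assert -2.0 * math.log(area) < math.log(1.0 / area)
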