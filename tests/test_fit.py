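"""Poisson likelihood, c0 profiling, joint grid fit and bootstrap."""

import warnings

import numpy as np
import pytest
from scipy import stats

import aggscaff as ag


def _culture(counts, area=1.0, cid="c1"):
    return ag.ObservedCounts(cid, np.asarray(counts, dtype=int), area)


class TestPoissonLogLikelihood:
    def test_hand_values(self):
        # single bin at size 2: # = 1, n = 1 -> ln(e^-1) = -1
        assert ag.poisson_log_likelihood(_culture([0, 1]), np.array([9.0, 1.0])) \
            == pytest.approx(-1.0, abs=1e-12)
        # # = 3, n = 3 -> 3 ln 3 - 3 - ln 6
        expected = 3 * np.log(3.0) - 3.0 - np.log(6.0)
        assert ag.poisson_log_likelihood(_culture([0, 3]), np.array([9.0, 3.0])) \
            == pytest.approx(expected, abs=1e-12)

    def test_zero_counts_gives_minus_sum_of_means(self):
        obs = _culture([0, 0, 0, 1])  # i_max = 4, counts at 2..4 are 0,0,1
        means = np.array([5.0, 1.0, 2.0, 3.0])
        # only sizes >= 2 enter; with the size-4 count 1:
        expected = 1 * np.log(3.0) - (1.0 + 2.0 + 3.0)
        assert ag.poisson_log_likelihood(obs, means) == pytest.approx(expected)

    def test_matches_independent_reference(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(3.0, size=12)
        counts[-1] = max(counts[-1], 1)
        obs = _culture(counts)
        means = rng.uniform(0.5, 6.0, size=obs.i_max)
        ours = ag.poisson_log_likelihood(obs, means)
        ref = float(np.sum(stats.poisson.logpmf(obs.counts[1:], means[1:obs.i_max])))
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_zero_mean_with_positive_count(self):
        obs = _culture([0, 2])
        with pytest.warns(UserWarning):
            out = ag.poisson_log_likelihood(obs, np.array([1.0, 0.0]))
        assert out == -np.inf

    def test_monomer_bin_excluded(self):
        # changing the size-1 entries must not change the likelihood
        obs_a, obs_b = _culture([0, 2]), _culture([17, 2])
        means = np.array([4.0, 2.0])
        assert ag.poisson_log_likelihood(obs_a, means) == \
            ag.poisson_log_likelihood(obs_b, means)


class TestPredictedCounts:
    def test_area_scaling(self):
        a = ag.predicted_counts(1 / 30, 0.5, 2.0, area=1e3, i_max=64)
        b = ag.predicted_counts(1 / 30, 0.5, 2.0, area=2e3, i_max=64)
        assert np.allclose(b, 2 * a)
        assert np.all(a >= 0)

    def test_zero_area(self):
        assert np.all(ag.predicted_counts(1 / 30, 0.5, 2.0, area=0.0, i_max=16) == 0)

    def test_decreasing_tail_in_observed_regime(self):
        m = ag.predicted_counts(1 / 30, 0.5, 2.0, area=1e4, i_max=256)
        shoulder = int(np.argmax(m))
        assert np.all(np.diff(m[shoulder:]) <= 0)
        assert np.isfinite(m).all()


class TestProfiling:
    def test_single_point_grid(self, model_table):
        obs = _culture([5, 3, 1], area=100.0)
        grid1 = ag.FitGrid(k_over_D0=np.array([1 / 30]), sigma=np.array([0.5]),
                           c0=np.array([2.0]))
        table1 = ag.ModelTable(grid1, i_max=16)
        ci, logl, edge = ag.profile_c0(obs, 0, 0, table1)
        assert ci == 0 and edge  # single point is trivially on the boundary

    def test_boundary_flagged_for_monotone_likelihood(self, recovery_grid,
                                                      model_table):
        # a single observed dimer on a tiny area keeps every predicted mean
        # below 1, so the likelihood rises monotonically towards large c0
        # and the argmax lands (flagged) on the grid edge
        obs = _culture([3, 1], area=1.0)
        ci, logl, edge = ag.profile_c0(obs, 0, 2, model_table)
        assert ci == len(recovery_grid.c0) - 1
        assert edge


class TestJointFit:
    def test_duplicated_culture_same_argmax(self, recovery_grid, model_table):
        truth = ag.GroundTruth(sigma=0.5, D0_over_k=30.0, c0=(2.0,),
                               A_exp=(5e3,), seed=4)
        (culture,) = ag.sample_cluster_counts(truth)
        one = ag.grid_fit_joint([culture], recovery_grid, table=model_table)
        clone = ag.ObservedCounts("copy", culture.counts.copy(), culture.area)
        two = ag.grid_fit_joint([culture, clone], recovery_grid, table=model_table)
        assert (one.best_k_over_D0, one.best_sigma) == \
            (two.best_k_over_D0, two.best_sigma)
        assert two.logl_surface[np.isfinite(two.logl_surface)] == pytest.approx(
            2 * one.logl_surface[np.isfinite(one.logl_surface)])

    def test_recovery_from_large_area(self, recovery_grid, model_table):
        truth = ag.GroundTruth(sigma=0.5, D0_over_k=30.0, c0=(2.0,),
                               A_exp=(1e4,), seed=11)
        cultures = ag.sample_cluster_counts(truth)
        res = ag.grid_fit_joint(cultures, recovery_grid, table=model_table)
        assert res.best_sigma == 0.5
        assert res.best_k_over_D0 == pytest.approx(1 / 30)

    def test_no_cultures_rejected(self, recovery_grid):
        with pytest.raises(ValueError):
            ag.grid_fit_joint([], recovery_grid)

    def test_deterministic(self, recovery_grid, model_table):
        truth = ag.GroundTruth(sigma=0.5, D0_over_k=30.0, c0=(1.0, 3.0),
                               A_exp=(2e3, 2e3), seed=8)
        cultures = ag.sample_cluster_counts(truth)
        r1 = ag.grid_fit_joint(cultures, recovery_grid, table=model_table)
        r2 = ag.grid_fit_joint(cultures, recovery_grid, table=model_table)
        assert r1.best_k_over_D0 == r2.best_k_over_D0
        assert r1.per_culture_c0 == r2.per_culture_c0


class TestBootstrap:
    def test_no_variability_gives_single_point_region(self, recovery_grid,
                                                      model_table):
        # every observed cluster identical -> every resample identical
        obs = _culture([0, 40], area=1e3)
        res = ag.bootstrap_region([obs], recovery_grid, n_boot=150, seed=1,
                                  table=model_table)
        assert len(res.region) == 1

    def test_region_contains_full_data_argmax(self, recovery_grid, model_table):
        truth = ag.GroundTruth(sigma=0.5, D0_over_k=30.0, c0=(2.0,),
                               A_exp=(2e3,), seed=21)
        cultures = ag.sample_cluster_counts(truth)
        res = ag.bootstrap_region(cultures, recovery_grid, n_boot=1000, seed=2,
                                  table=model_table)
        assert (res.best_k_over_D0, res.best_sigma) in res.region

    def test_deterministic_given_seed(self, recovery_grid, model_table):
        truth = ag.GroundTruth(sigma=0.5, D0_over_k=30.0, c0=(2.0,),
                               A_exp=(1e3,), seed=31)
        cultures = ag.sample_cluster_counts(truth)
        r1 = ag.bootstrap_region(cultures, recovery_grid, n_boot=200, seed=5,
                                 table=model_table)
        r2 = ag.bootstrap_region(cultures, recovery_grid, n_boot=200, seed=5,
                                 table=model_table)
        assert r1.region == r2.region

    def test_larger_area_shrinks_region(self, recovery_grid, model_table):
        sizes = []
        for area, seed in ((3e2, 3), (3e4, 3)):
            truth = ag.GroundTruth(sigma=0.5, D0_over_k=30.0, c0=(2.0,),
                                   A_exp=(area,), seed=seed)
            cultures = ag.sample_cluster_counts(truth)
            res = ag.bootstrap_region(cultures, recovery_grid, n_boot=400,
                                      seed=7, table=model_table)
            sizes.append(len(res.region))
        assert sizes[1] < sizes[0]
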