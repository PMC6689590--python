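"""Tests of the individual-based simulator against the exact laws and maps.

Monte-Carlo comparisons use a fixed seed and a 4-sigma band.  Where the
sample standard error can degenerate to zero (rare-event regimes), the band
uses the a-priori bound SE <= sqrt(lam*N*f/reps), valid because per-replicate
offspring lie in [0, lam*N].
"""

import math

import numpy as np
import pytest
from scipy import stats

from unitcomp import allocation as al
from unitcomp import models as md
from unitcomp import simulator as sim
from unitcomp.params import CompetitionParams, FecundityLaw, ThresholdLaw


def mc_band(est: sim.MonteCarloEstimate, target: float, lamN: float) -> float:
    """4-sigma acceptance band with the a-priori variance bound as a floor."""
    se_bound = math.sqrt(max(lamN * target, 0.0) / est.reps)
    return 4.0 * max(est.stderr, se_bound, 1e-12)


class TestSimulateGeneration:
    def test_sole_individual_takes_whole_pool(self):
        p = CompetitionParams(lam=3.0, u=1.0, Rbar=5.0, s=2)
        out = sim.simulate_generation(1, p, R=10.0, rng=0)
        assert out.M == 10
        assert out.units_per_individual.tolist() == [10]
        assert out.n_successes == 1
        assert out.offspring_expectation == pytest.approx(3.0)

    def test_pool_below_threshold_nobody_reproduces(self):
        # pigeonhole: with M < s units in total, no individual can reach s
        p = CompetitionParams(lam=3.0, u=1.0, Rbar=5.0, s=4)
        out = sim.simulate_generation(7, p, R=3.0, rng=1)
        assert out.M == 3
        assert out.n_successes == 0
        assert out.offspring_expectation == 0.0

    def test_units_are_conserved(self):
        p = CompetitionParams(lam=2.0, u=0.5, Rbar=10.0, s=2)
        for seed in range(5):
            out = sim.simulate_generation(6, p, rng=seed)
            assert out.units_per_individual.sum() == out.M
            assert out.M == math.floor(out.R_drawn / p.u)

    def test_empty_population(self):
        p = CompetitionParams(lam=2.0, u=1.0, Rbar=5.0, s=1)
        out = sim.simulate_generation(0, p, rng=0)
        assert out.offspring_expectation == 0.0
        assert out.M == 0 and out.units_per_individual.size == 0

    def test_single_individual_count_law(self):
        # at fixed M the per-individual count must follow the binomial law
        p = CompetitionParams(lam=1.0, u=1.0, Rbar=50.0, s=1)
        N, M, reps = 5, 40, 20_000
        rng = np.random.default_rng(7)
        counts, _, _, _, _ = sim._draw_batch(
            reps, N, p, float(M), "fixed", None, "step", None, rng)
        observed = np.bincount(counts[:, 0], minlength=M + 1)
        expected = reps * np.array(
            [al.unit_count_pmf(m, M, N) for m in range(M + 1)])
        # pool sparse tail bins so every expected count is >= 5
        keep = expected >= 5
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(expected[keep], expected[~keep].sum())
        gof = stats.chisquare(obs, exp * obs.sum() / exp.sum())
        assert gof.pvalue > 1e-3

    def test_allocation_variance_law(self):
        # empirical Var[u*m] at fixed R against u*R*(1-1/N)/N
        p = CompetitionParams(lam=1.0, u=0.5, Rbar=50.0, s=1)
        N, R, reps = 4, 20.0, 50_000
        rng = np.random.default_rng(11)
        counts, _, _, _, _ = sim._draw_batch(
            reps, N, p, R, "fixed", None, "step", None, rng)
        amounts = p.u * counts.ravel()
        target = al.allocation_variance(p, R, N)
        # 4-sigma band from the exact sampling variance of the sample variance
        M = int(R / p.u)
        dist = stats.binom(M, 1.0 / N)
        mu = dist.mean()
        mu4 = float(np.sum((np.arange(M + 1) - mu) ** 4 * dist.pmf(np.arange(M + 1))))
        var_of_var = (mu4 - dist.var() ** 2 * (amounts.size - 3) / (amounts.size - 1))
        band = 4.0 * p.u**2 * math.sqrt(var_of_var / amounts.size)
        assert abs(amounts.var(ddof=1) - target) < band

    def test_pool_size_is_geometric(self):
        # M = floor(R/u) with exponential R must follow the geometric law
        p = CompetitionParams(lam=1.0, u=0.5, Rbar=1.0, s=1)
        reps = 50_000
        rng = np.random.default_rng(13)
        _, _, _, _, M = sim._draw_batch(
            reps, 2, p, None, "fixed", None, "step", None, rng)
        hi = int(M.max()) + 1
        observed = np.bincount(M, minlength=hi + 1)
        expected = reps * np.array(
            [al.unit_total_pmf(k, p) for k in range(hi + 1)])
        keep = expected >= 5
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(expected[keep], reps - expected[keep].sum())
        gof = stats.chisquare(obs, exp)
        assert gof.pvalue > 1e-3


class TestEstimateF:
    def test_requires_replication(self):
        p = CompetitionParams(lam=1.0, u=1.0, Rbar=5.0, s=1)
        with pytest.raises(ValueError):
            sim.estimate_f(2, p, reps=1, rng=0)

    def test_empty_population(self):
        p = CompetitionParams(lam=1.0, u=1.0, Rbar=5.0, s=1)
        est = sim.estimate_f(0, p, reps=10, rng=0)
        assert est.mean == 0.0 and est.stderr == 0.0

    def test_same_seed_bitwise_reproducible(self):
        p = CompetitionParams(lam=2.0, u=0.5, Rbar=2.0, s=2)
        a = sim.estimate_f(5, p, reps=2000, rng=123)
        b = sim.estimate_f(5, p, reps=2000, rng=123)
        assert a.mean == b.mean and a.stderr == b.stderr

    def test_fixed_pool_matches_success_probability(self):
        # f = lam*N*Q(M) exactly at fixed R; Q(2) = 0.75 for s=1, N=2
        p = CompetitionParams(lam=1.0, u=1.0, Rbar=5.0, s=1)
        est = sim.estimate_f(2, p, reps=50_000, R=2.0, rng=5)
        target = p.lam * 2 * al.success_prob(2, 1, 2)
        assert target == 1.5
        assert abs(est.mean - target) < mc_band(est, target, p.lam * 2)

    def test_exponential_pool_matches_hassell(self, ln2_params):
        est = sim.estimate_f(1, ln2_params, reps=100_000, rng=17)
        assert abs(est.mean - 0.5) < mc_band(est, 0.5, ln2_params.lam)

    @pytest.mark.parametrize("N", [2, 20])
    def test_nb_threshold_matches_closed_form(self, N):
        p = CompetitionParams(lam=2.0, u=0.5, Rbar=1.0, s=2)
        law = ThresholdLaw(s0=2, delta=0.5, k=2.0)
        est = sim.estimate_f(
            N, p, reps=50_000, threshold_mode="nb", threshold_law=law, rng=19)
        target = md.nb_full(N, p, law)
        assert abs(est.mean - target) < mc_band(est, target, p.lam * N)

    @pytest.mark.parametrize("N", [2, 20])
    def test_saturating_fecundity_matches_closed_form(self, N):
        p = CompetitionParams(lam=2.0, u=0.5, Rbar=1.0, s=2)
        law = FecundityLaw(lam=2.0, gamma=2.0, s=2, u=0.5)
        est = sim.estimate_f(
            N, p, reps=50_000, fecundity_mode="saturating", fecundity_law=law,
            rng=23)
        target = md.fecundity_full(N, p, law)
        assert abs(est.mean - target) < mc_band(est, target, p.lam * N)

    def test_gamma_threshold_matches_mixture_expectation(self):
        # target: lam*N*sum_m p_hat_m * P(s' <= u*m), s' gamma distributed
        p = CompetitionParams(lam=2.0, u=0.5, Rbar=1.0, s=2)
        law = ThresholdLaw.gamma_form(sbar_prime=1.0, k=2.0)
        N = 5
        ms = np.arange(0, 400)
        p_hat = np.array([al.obtained_units_pmf(int(m), N, p) for m in ms])
        cdf = stats.gamma.cdf(p.u * ms, a=law.k, scale=law.sbar_prime / law.k)
        target = p.lam * N * float(np.dot(p_hat, cdf))
        est = sim.estimate_f(
            N, p, reps=50_000, threshold_mode="gamma", threshold_law=law, rng=29)
        assert abs(est.mean - target) < mc_band(est, target, p.lam * N)


class TestTrajectory:
    def test_same_seed_identical_series(self):
        p = CompetitionParams(lam=2.0, u=0.5, Rbar=5.0, s=1)
        a = sim.stochastic_trajectory(10, p, 30, rng=31)
        b = sim.stochastic_trajectory(10, p, 30, rng=31)
        assert np.array_equal(a, b)

    def test_zero_is_absorbing(self):
        p = CompetitionParams(lam=2.0, u=0.5, Rbar=5.0, s=1)
        series = sim.stochastic_trajectory(0, p, 10, rng=0)
        assert np.all(series == 0)

    def test_subcritical_population_goes_extinct(self):
        # lam < 1: f(N) < N for all N, extinction is certain in the long run
        p = CompetitionParams(lam=0.5, u=0.5, Rbar=5.0, s=1)
        series = sim.stochastic_trajectory(30, p, 200, rng=37)
        assert series[-1] == 0

    def test_one_step_mean_matches_estimate_f(self):
        # law of total expectation: E[N_1] = E[offspring expectation]
        p = CompetitionParams(lam=2.0, u=0.5, Rbar=2.0, s=1)
        N0, reps = 5, 10_000
        rng = np.random.default_rng(41)
        ones = np.array([
            sim.stochastic_trajectory(N0, p, 1, rng=rng)[1] for _ in range(reps)
        ], dtype=float)
        est = sim.estimate_f(N0, p, reps=100_000, rng=43)
        se = ones.std(ddof=1) / math.sqrt(reps)
        assert abs(ones.mean() - est.mean) < 4 * (se + est.stderr)

    def test_round_expectation_mode_is_deterministic_given_seed(self):
        p = CompetitionParams(lam=2.0, u=0.5, Rbar=5.0, s=1)
        a = sim.stochastic_trajectory(
            10, p, 20, offspring_realization="round_expectation", rng=47)
        b = sim.stochastic_trajectory(
            10, p, 20, offspring_realization="round_expectation", rng=47)
        assert np.array_equal(a, b)

    def test_invalid_realization_mode(self):
        p = CompetitionParams(lam=2.0, u=0.5, Rbar=5.0, s=1)
        with pytest.raises(ValueError):
            sim.stochastic_trajectory(5, p, 5, offspring_realization="exact", rng=0)
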