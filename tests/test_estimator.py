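"""Likelihood, closed-form MLE, profile CI, ploidy bound and variants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from ednamix import (
    PopulationFrequencies,
    combine_loci,
    estimate_sample,
    estimate_site,
    log_likelihood,
    mle_contributors,
    mom_contributors,
    ploidy_minimum,
    profile_ci,
)
from ednamix.estimator import ci_ratio_bounds, deviation_statistic

from conftest import make_sample


def random_instance(rng, k=None):
    """Random (pi, f, xi) triple with informative frequencies."""
    k = k or rng.integers(3, 12)
    p = rng.dirichlet(np.ones(k) * 2)
    while p.min() < 1e-4:
        p = rng.dirichlet(np.ones(k) * 2)
    f = rng.dirichlet(p * rng.uniform(5, 200))
    xi = rng.uniform(1.0, 4.0)
    ids = tuple(f"h{i}" for i in range(k))
    return PopulationFrequencies(ids, p), f, xi


class TestLogLikelihood:
    def test_zero_deviation_grows_logarithmically(self, pi_half):
        f = [0.5, 0.5]
        base = -math.log(2 * math.pi * 0.25)
        for n in (1.0, 5.0, 40.0):
            assert log_likelihood(n, f, pi_half) == pytest.approx(
                math.log(n) + base
            )
        assert log_likelihood(50, f, pi_half) > log_likelihood(5, f, pi_half)

    def test_equals_sum_of_normal_log_densities(self, pi_half):
        n = 25.0
        value = log_likelihood(n, [0.6, 0.4], pi_half)
        oracle = sum(
            norm.logpdf(f, p, math.sqrt(p * (1 - p) / n))
            for f, p in [(0.6, 0.5), (0.4, 0.5)]
        )
        assert value == pytest.approx(oracle, rel=1e-12)

    def test_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pi, f, xi = random_instance(rng)
            n = rng.uniform(0.5, 300)
            oracle = sum(
                norm.logpdf(fi, p, math.sqrt(xi * p * (1 - p) / n))
                for fi, p in zip(f, pi.probs)
            )
            assert log_likelihood(n, f, pi, xi) == pytest.approx(
                oracle, rel=1e-10
            )

    def test_doubling_xi_and_n_preserves_deviation_term(self, pi_half):
        f = [0.6, 0.4]
        assert log_likelihood(10, f, pi_half, 1.0) == pytest.approx(
            log_likelihood(20, f, pi_half, 2.0), rel=1e-12
        )

    def test_invalid_arguments(self, pi_half):
        with pytest.raises(ValueError, match="positive"):
            log_likelihood(0, [0.6, 0.4], pi_half)
        with pytest.raises(ValueError, match="xi"):
            log_likelihood(5, [0.6, 0.4], pi_half, xi=0.5)

    def test_degenerate_reference_haplotypes_excluded(self):
        # a p=0 haplotype contributes nothing (and no division by zero)
        pi3 = PopulationFrequencies(("a", "b", "c"), np.array([0.5, 0.5, 0.0]))
        pi2 = PopulationFrequencies(("a", "b"), np.array([0.5, 0.5]))
        assert log_likelihood(10, [0.6, 0.4, 0.0], pi3) == pytest.approx(
            log_likelihood(10, [0.6, 0.4], pi2)
        )


class TestMle:
    def test_worked_closed_form(self, pi_half):
        # S = 0.01/0.25 * 2 = 0.08; N = 2 / 0.08 = 25
        assert mle_contributors([0.6, 0.4], pi_half) == pytest.approx(25.0)

    def test_maximal_deviation_gives_one(self, pi_half):
        assert mle_contributors([1.0, 0.0], pi_half) == pytest.approx(1.0)

    def test_linear_in_xi(self, pi_half):
        base = mle_contributors([0.6, 0.4], pi_half, xi=1.0)
        assert mle_contributors([0.6, 0.4], pi_half, xi=2.0) == pytest.approx(
            2 * base
        )

    def test_exact_match_is_divergent(self, pi_half):
        assert math.isinf(mle_contributors([0.5, 0.5], pi_half))

    def test_matches_numerical_maximiser_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            pi, f, xi = random_instance(rng)
            n_closed = mle_contributors(f, pi, xi)
            res = minimize_scalar(
                lambda n: -log_likelihood(n, f, pi, xi),
                bounds=(1e-6, max(1e4, 10 * n_closed)),
                method="bounded",
                options={"xatol": 1e-10},
            )
            assert n_closed == pytest.approx(res.x, rel=1e-6)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pi, f, xi = random_instance(rng)
        perm = rng.permutation(pi.n_haplotypes)
        pi_perm = PopulationFrequencies(
            tuple(pi.haplotype_ids[i] for i in perm), pi.probs[perm]
        )
        assert mle_contributors(f, pi, xi) == pytest.approx(
            mle_contributors(f[perm], pi_perm, xi), rel=1e-12
        )
        lo, hi = profile_ci(f, pi, xi)
        lo_p, hi_p = profile_ci(f[perm], pi_perm, xi)
        assert lo == pytest.approx(lo_p, rel=1e-9)
        assert hi == pytest.approx(hi_p, rel=1e-9)

    @given(st.integers(0, 2**31 - 1), st.floats(1.0, 8.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_xi_scale_law(self, seed, scale):
        rng = np.random.default_rng(seed)
        pi, f, xi = random_instance(rng)
        assert mle_contributors(f, pi, xi * scale) == pytest.approx(
            scale * mle_contributors(f, pi, xi), rel=1e-12
        )


class TestProfileCi:
    def test_interval_contains_mle(self, pi_half):
        lo, hi = profile_ci([0.6, 0.4], pi_half)
        assert lo < 25.0 < hi

    def test_matches_dense_grid_scan(self, pi_half):
        """Interval endpoints agree with a 0.001-resolution scan of lnL."""
        f = [0.6, 0.4]
        n_mle = mle_contributors(f, pi_half)
        drop = 3.841458820694124 / 2  # chi2(1) 95% quantile / 2
        grid = np.arange(0.001, 200.0, 0.001)
        k, s = 2, deviation_statistic(f, pi_half)
        lnl = 0.5 * k * np.log(grid) - grid * s / 2  # constants cancel
        lnl_max = 0.5 * k * math.log(n_mle) - n_mle * s / 2
        inside = grid[lnl >= lnl_max - drop]
        lo, hi = profile_ci(f, pi_half, alpha=0.05)
        assert lo == pytest.approx(inside.min(), abs=0.01)
        assert hi == pytest.approx(inside.max(), abs=0.01)

    def test_width_shrinks_as_alpha_grows(self, pi_half):
        f = [0.6, 0.4]
        widths = [
            np.diff(profile_ci(f, pi_half, alpha=a))[0]
            for a in (0.05, 0.5, 0.99, 0.9999)
        ]
        assert widths == sorted(widths, reverse=True)
        assert widths[-1] < 1.0  # collapses around the MLE

    def test_alpha_validation(self, pi_half):
        with pytest.raises(ValueError, match="alpha"):
            profile_ci([0.6, 0.4], pi_half, alpha=1.5)

    def test_ratio_bounds_bracket_one(self):
        lo, hi = ci_ratio_bounds(17, 0.05)
        assert 0 < lo < 1 < hi


class TestPloidyMinimum:
    @pytest.mark.parametrize(
        "k_obs,ploidy,expected",
        [(4, 1, 4), (4, 2, 2), (5, 2, 3), (3, None, 1), (0, 1, 0)],
    )
    def test_bounds(self, k_obs, ploidy, expected):
        assert ploidy_minimum(k_obs, ploidy) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ploidy_minimum(-1, 1)
        with pytest.raises(ValueError):
            ploidy_minimum(3, 4)


class TestEstimateSample:
    def test_worked_example(self, pi_half):
        est = estimate_sample(make_sample([60, 40], ids=("a", "b")), pi_half)
        assert est.n_mle == pytest.approx(25.0)
        assert est.ci_low < 25 < est.ci_high
        assert est.k_observed == 2
        assert not est.divergent

    def test_ploidy_censoring(self, pi_half):
        # raw MLE 2/1.28 = 1.5625 < k_observed = 2 under haploid constraint
        sample = make_sample([90, 10], ids=("a", "b"))
        est = estimate_sample(sample, pi_half)
        assert est.censored_at_min and est.n_mle == 2.0 and est.ci_low == 2.0
        raw = estimate_sample(sample, pi_half, apply_ploidy_min=False)
        assert not raw.censored_at_min
        assert raw.n_mle == pytest.approx(2 / 1.28)

    def test_empty_sample_errors(self, pi_half):
        with pytest.raises(ValueError, match="empty sample"):
            estimate_sample(make_sample([0, 0], ids=("a", "b")), pi_half)

    def test_divergent_sample_reports_unbounded_interval(self, pi_half):
        est = estimate_sample(make_sample([50, 50], ids=("a", "b")), pi_half)
        assert est.divergent
        assert math.isinf(est.ci_high)

    def test_novel_haplotype_hard_error_and_drop(self):
        pi = PopulationFrequencies(("a", "b", "c"), np.array([0.5, 0.5, 0.0]))
        sample = make_sample([50, 30, 20], ids=("a", "b", "c"))
        with pytest.raises(ValueError, match="re-estimate"):
            estimate_sample(sample, pi)
        est = estimate_sample(sample, pi, on_novel="drop")
        # after dropping haplotype c, f renormalises to (0.625, 0.375)
        assert est.n_mle == pytest.approx(
            2 / (2 * 0.125**2 / 0.25), rel=1e-9
        )

    def test_identical_single_haplotype_samples_get_identical_estimates(
        self, conserved6
    ):
        # samples detecting only the dominant haplotype are indistinguishable
        ests = [
            estimate_sample(
                make_sample(
                    [reads, 0, 0, 0, 0, 0], ids=conserved6.haplotype_ids
                ),
                conserved6,
            )
            for reads in (100, 5000)
        ]
        assert ests[0].n_mle == pytest.approx(ests[1].n_mle, rel=1e-12)


class TestEstimateSite:
    def test_identical_replicates_match_single_sample(self, pi_half):
        rep = make_sample([60, 40], "r1", ids=("a", "b"), group="site")
        single = estimate_sample(rep, pi_half)
        combined = estimate_site([rep, rep, rep], pi_half)
        assert combined.n_mle == pytest.approx(single.n_mle, rel=1e-12)

    def test_opposite_replicates_average_to_divergence(self, pi_half):
        reps = [
            make_sample([9, 0], "r1", ids=("a", "b"), group="site"),
            make_sample([0, 4], "r2", ids=("a", "b"), group="site"),
        ]
        est = estimate_site(reps, pi_half)
        assert est.divergent
        assert est.k_observed == 2  # union across replicates

    def test_matches_explicit_averaging_oracle(self, variable14):
        rng = np.random.default_rng(21)
        reps = [
            make_sample(
                rng.multinomial(1000, variable14.probs),
                f"r{i}",
                ids=variable14.haplotype_ids,
                group="site",
            )
            for i in range(3)
        ]
        est = estimate_site(reps, variable14)
        f_bar = np.mean([r.freqs for r in reps], axis=0)
        oracle = mle_contributors(f_bar, variable14)
        assert est.n_mle == pytest.approx(oracle, rel=1e-12)

    def test_pooling_flag_weights_by_reads(self, pi_half):
        reps = [
            make_sample([100, 0], "r1", ids=("a", "b"), group="site"),
            make_sample([0, 900], "r2", ids=("a", "b"), group="site"),
        ]
        pooled = estimate_site(
            reps, pi_half, combine="pool", apply_ploidy_min=False
        )
        oracle = mle_contributors([0.1, 0.9], pi_half)
        assert pooled.n_mle == pytest.approx(oracle, rel=1e-12)


class TestMethodOfMoments:
    def test_coincides_with_mle_for_two_haplotypes(self, pi_half):
        assert mom_contributors([0.6, 0.4], pi_half) == pytest.approx(25.0)

    def test_three_haplotype_hand_computation(self):
        pi = PopulationFrequencies(("a", "b", "c"), np.array([0.5, 0.3, 0.2]))
        f = [0.6, 0.25, 0.15]
        # MoM: (0.25+0.21+0.16) / (0.01+0.0025+0.0025) = 0.62/0.015
        assert mom_contributors(f, pi) == pytest.approx(0.62 / 0.015)
        # differs from the MLE, which weights by information content
        assert mle_contributors(f, pi) != pytest.approx(0.62 / 0.015)

    def test_linear_in_xi_and_divergence(self, pi_half):
        assert mom_contributors([0.6, 0.4], pi_half, xi=3.0) == pytest.approx(
            75.0
        )
        assert math.isinf(mom_contributors([0.5, 0.5], pi_half))


class TestCombineLoci:
    def test_single_locus_matches_single_estimate(self, pi_half):
        sample = make_sample([60, 40], ids=("a", "b"))
        single = estimate_sample(sample, pi_half)
        joint = combine_loci([(sample.freqs, pi_half, 1.0)])
        assert joint.n_mle == pytest.approx(single.n_mle, rel=1e-12)
        assert joint.ci_low == pytest.approx(single.ci_low, rel=1e-9)

    def test_duplicated_locus_narrows_interval(self, pi_half):
        f = np.array([0.6, 0.4])
        one = combine_loci([(f, pi_half, 1.0)], apply_ploidy_min=False)
        two = combine_loci([(f, pi_half, 1.0)] * 2, apply_ploidy_min=False)
        assert two.n_mle == pytest.approx(one.n_mle, rel=1e-12)
        assert (two.ci_high - two.ci_low) < (one.ci_high - one.ci_low)

    def test_matches_grid_maximisation_of_summed_curves(self):
        rng = np.random.default_rng(13)
        loci = [
            (f, pi, xi)
            for pi, f, xi in (random_instance(rng, k=5) for _ in range(2))
        ]
        joint = combine_loci(loci, apply_ploidy_min=False)
        # independent oracle: evaluate each locus curve by explicit loops
        # on a dense shared grid and maximise the sum
        grid = np.arange(0.01, 2000.0, 0.01)
        total = np.zeros_like(grid)
        for f, pi, xi in loci:
            s = sum(
                (fi - p) ** 2 / (p * (1 - p)) for fi, p in zip(f, pi.probs)
            )
            k = pi.k_informative
            total += 0.5 * k * np.log(grid) - grid * s / (2 * xi)
        assert joint.n_mle == pytest.approx(grid[np.argmax(total)], abs=0.01)
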