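"""Analytic expectations vs the segment-level Monte-Carlo oracle, and the
ancient-DNA age-heterogeneity machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from recne import (DemographicModel, SampleAgeTable, assign_sampling_times,
                   bin_ld_curve, expected_ibd_density, expected_ld,
                   expected_ld_time_het, p_ibd, pair_age_density,
                   pseudo_haploidize, scenario, simulate_ld_panel,
                   simulate_pairwise_ibd)
from recne.genmap import uniform_arm_table
from recne.simulate import oracle_histogram


def _ld_z(panel, gmap, mu):
    ld = bin_ld_curve(panel, gmap, seed=0)
    pooled = np.nanmean(ld.y, axis=0)
    n_reg = np.sum(~np.isnan(ld.y), axis=0)
    se = np.sqrt(np.nanvar(ld.y, axis=0, ddof=1) / n_reg)
    return (pooled - mu(ld)) / se


def assert_calibrated(z, max_mean=1.5, outlier_z=4.5, max_outliers=2):
    """Per-bin z-scores consistent with Monte-Carlo noise.

    With few regions the per-bin SE estimates are t-distributed with few
    degrees of freedom, so isolated large |z| values occur under the null;
    a systematic model-simulator mismatch instead inflates the mean |z| and
    produces many extreme bins.
    """
    z = np.asarray(z)
    assert np.nanmean(np.abs(z)) < max_mean
    assert np.sum(np.abs(z[~np.isnan(z)]) > outlier_z) <= max_outliers
    b = np.sum(~np.isnan(z))
    assert abs(np.nansum(z)) / np.sqrt(b) < 3.5  # no pooled bias


class TestExpectedIbdDensity:
    def test_degenerate_bin_is_zero(self):
        m = scenario("constant").model
        mu = expected_ibd_density(m, [0.02, 0.02])
        assert mu[0] == pytest.approx(0.0, abs=1e-15)

    def test_single_generation_limit(self):
        """With all coalescence mass at g = 1, the density over [u, inf) is
        2 exp(-2u)."""
        m = DemographicModel.constant(1.0 + 1e-9)
        u = 0.03
        mu = expected_ibd_density(m, [u, 50.0])  # upper edge effectively inf
        assert mu[0] == pytest.approx(2.0 * np.exp(-2.0 * u), rel=1e-6)

    @pytest.mark.parametrize("name", ["constant", "expansion", "collapse",
                                      "bottleneck"])
    def test_oracle_equivalence(self, name):
        """Per-bin segment counts from the pairwise simulator match
        mu_b * L * n_pairs within Monte-Carlo error."""
        scen = scenario(name)
        lengths = np.full(10, 0.9)
        n_pairs = 120_000
        segs = simulate_pairwise_ibd(scen, n_pairs, lengths, seed=hash(name) % 2**31)
        hist = oracle_histogram(segs, lengths, n_pairs)
        mu = expected_ibd_density(scen.model, hist.bin_edges_morgans)
        expected = mu * lengths.sum() * n_pairs
        observed = hist.counts.sum(axis=0)
        informative = expected > 5
        z = (observed[informative] - expected[informative]) / np.sqrt(expected[informative])
        assert_calibrated(z)

    def test_markov_mode_agrees_with_fast_in_arm_interior(self):
        """The sequential mode clips at arm boundaries, so compare rates for
        segments lying fully inside the arm, where both modes see the same
        stationary process."""
        scen = scenario("collapse")
        lengths = np.full(4, 1.0)
        fast = simulate_pairwise_ibd(scen, 4000, lengths, seed=1, mode="fast")
        markov = simulate_pairwise_ibd(scen, 4000, lengths, seed=2, mode="markov")

        def interior(df):
            return df[(df["start_m"] > 0.1) & (df["end_m"] < 0.9)]

        tot_f, tot_m = len(interior(fast)), len(interior(markov))
        z = (tot_f - tot_m) / np.sqrt(tot_f + tot_m)
        assert abs(z) < 4.0
        # and the length distributions match
        from scipy import stats

        ks = stats.ks_2samp(interior(fast)["length_m"], interior(markov)["length_m"])
        assert ks.pvalue > 0.001

    def test_forced_single_generation_lengths_exponential(self):
        """N_e -> 1 forces coalescence at g = 1; segment lengths are Exp(2)."""
        from scipy import stats

        model = DemographicModel.constant(1.0 + 1e-9)
        segs = simulate_pairwise_ibd(model, 200, np.array([50.0]), seed=3,
                                     u_min_morgans=0.0, mode="markov")
        inner = segs[segs["end_m"] < 49.999]  # drop the arm-end truncation
        ks = stats.kstest(inner["length_m"], "expon", args=(0, 0.5))
        assert ks.pvalue > 0.001

    def test_determinism(self):
        scen = scenario("constant")
        a = simulate_pairwise_ibd(scen, 500, np.array([1.0]), seed=9)
        b = simulate_pairwise_ibd(scen, 500, np.array([1.0]), seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestPIbd:
    def test_decay_limit_reaches_baseline(self):
        mu = expected_ld(scenario("constant").model, [500.0], 200)
        from recne import finite_sample_baseline

        assert mu[0] == pytest.approx(finite_sample_baseline(200, 200), rel=1e-3)

    def test_strictly_decreasing_in_distance(self):
        u = np.linspace(0.001, 0.5, 60)
        for name in ("constant", "collapse", "bottleneck"):
            p = p_ibd(scenario(name).model, u)
            assert np.all(np.diff(p) < 0)

    def test_larger_population_less_sharing(self):
        small = DemographicModel.constant(5_000.0)
        large = DemographicModel.constant(50_000.0)
        u = np.linspace(0.003, 0.3, 30)
        assert np.all(p_ibd(large, u) < p_ibd(small, u))

    @pytest.mark.parametrize("n", [1_000.0, 20_000.0, 200_000.0])
    def test_discrete_sum_matches_continuous_integral(self, n):
        """Constant size: the discrete-generation sum agrees with numerical
        integration of its continuous-time analogue (midpoint rule maps the
        unit-step sum to an integral from 0.5) within 1% for N >= 1000."""
        from scipy.integrate import quad

        for u in (0.005, 0.02, 0.1):
            p = p_ibd(DemographicModel.constant(n), [u], horizon=40 * 125)[0]
            integral = quad(lambda t: (1 / n) * (1 - 1 / n) ** (t - 1)
                            * np.exp(-2 * u * t), 0.5, np.inf, limit=400)[0]
            assert abs(p / integral - 1.0) < 0.01


class TestLdOracle:
    def test_constant_panel_matches_expectation(self, constant_panel):
        panel, gmap = constant_panel
        model = scenario("constant").model
        z = _ld_z(panel, gmap,
                  lambda ld: expected_ld(model, ld.bin_centers_cm, ld.n_haplotypes))
        assert_calibrated(z)

    def test_collapse_panel_matches_expectation(self, collapse_panel):
        panel, gmap = collapse_panel
        model = scenario("collapse").model
        z = _ld_z(panel, gmap,
                  lambda ld: expected_ld(model, ld.bin_centers_cm, ld.n_haplotypes))
        assert_calibrated(z)

    @pytest.mark.parametrize("name", ["expansion", "bottleneck"])
    def test_other_scenarios_match_expectation(self, name):
        arms = uniform_arm_table(6, 40.0)
        panel, gmap = simulate_ld_panel(scenario(name), n_samples=80,
                                        sites_per_arm=60, seed=77, arms=arms)
        model = scenario(name).model
        z = _ld_z(panel, gmap,
                  lambda ld: expected_ld(model, ld.bin_centers_cm, ld.n_haplotypes))
        assert_calibrated(z)

    def test_huge_population_indistinguishable_from_baseline(self):
        arms = uniform_arm_table(5, 40.0)
        panel, gmap = simulate_ld_panel(DemographicModel.constant(5e6),
                                        n_samples=60, sites_per_arm=50,
                                        seed=55, arms=arms)
        ld = bin_ld_curve(panel, gmap, seed=0)
        pooled = np.nanmean(ld.y, axis=0)
        base = np.nanmean(ld.baseline, axis=0)
        se = np.sqrt(np.nanvar(ld.y, axis=0, ddof=1)
                     / np.sum(~np.isnan(ld.y), axis=0))
        z = (pooled - base) / se
        assert_calibrated(z)

    def test_panel_determinism(self):
        arms = uniform_arm_table(2, 30.0)
        a, _ = simulate_ld_panel(scenario("constant"), 20, 30, seed=4, arms=arms)
        b, _ = simulate_ld_panel(scenario("constant"), 20, 30, seed=4, arms=arms)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)


class TestPseudoHaploid:
    def test_coverage_missingness_relation(self):
        from recne import coverage_to_missingness

        assert coverage_to_missingness(30.0) == pytest.approx(np.exp(-30.0))
        assert coverage_to_missingness(1.4) == pytest.approx(0.2466, abs=2e-4)

    def test_missing_fraction(self, constant_panel):
        panel, _ = constant_panel
        ph = pseudo_haploidize(panel, missingness=0.5, seed=1)
        n = ph.genotypes.size
        frac = np.isnan(ph.genotypes).mean()
        se = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) < 3 * se

    def test_heterozygote_resolution_balanced(self):
        from recne import GenotypePanel

        g = np.ones((200, 50))
        panel = GenotypePanel(g)
        ph = pseudo_haploidize(panel, missingness=0.0, seed=2)
        assert set(np.unique(ph.genotypes)) <= {0.0, 2.0}
        assert abs(np.mean(ph.genotypes) - 1.0) < 3 * 2 * np.sqrt(0.25 / g.size)

    @pytest.mark.parametrize("m", [0.0, 0.5])
    def test_pseudo_haploid_ld_matches_expectation(self, constant_panel, m):
        """Pseudo-haploidization (with and without missingness) changes the
        LD curve only through the finite-sample baseline."""
        panel, gmap = constant_panel
        ph = pseudo_haploidize(panel, missingness=m, seed=7)
        model = scenario("constant").model
        z = _ld_z(ph, gmap,
                  lambda ld: expected_ld(model, ld.bin_centers_cm, ld.n_haplotypes))
        assert_calibrated(z)

    def test_bad_arguments(self, constant_panel):
        panel, _ = constant_panel
        with pytest.raises(ValueError):
            pseudo_haploidize(panel)
        with pytest.raises(ValueError):
            pseudo_haploidize(panel, coverage=1.0, missingness=0.2)
        with pytest.raises(ValueError):
            pseudo_haploidize(panel, missingness=1.0)


class TestPairAgeDensity:
    def test_modern_point_mass(self):
        dens = pair_age_density(SampleAgeTable.zeros(["a", "b", "c"]))
        assert len(dens.weight) == 1
        assert (dens.a_old[0], dens.gap[0]) == (0, 0)

    def test_two_fixed_ages(self):
        ages = SampleAgeTable(pd.DataFrame(
            {"sample_id": ["a", "b"], "age_lo": [10, 30], "age_hi": [10, 30]}))
        dens = pair_age_density(ages)
        assert (dens.a_old[0], dens.gap[0]) == (30, 20)
        assert dens.weight[0] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        delta = 3
        n = 4
        ages = SampleAgeTable(pd.DataFrame(
            {"sample_id": list("abcd"), "age_lo": 0, "age_hi": delta}))
        dens = pair_age_density(ages)
        # independent brute force over all pairs and age combinations
        brute = {}
        pairs = list(itertools.combinations(range(n), 2))
        for _, _ in pairs:
            for ai in range(delta + 1):
                for aj in range(delta + 1):
                    key = (max(ai, aj), abs(ai - aj))
                    brute[key] = brute.get(key, 0.0) + 1.0 / ((delta + 1) ** 2 * len(pairs))
        for a, g, w in zip(dens.a_old, dens.gap, dens.weight):
            assert w == pytest.approx(brute[(a, g)], abs=1e-9)
        assert dens.weight.sum() == pytest.approx(1.0, abs=1e-9)

    def test_age_validation(self):
        with pytest.raises(ValueError):
            SampleAgeTable(pd.DataFrame({"sample_id": ["a"], "age_lo": [5],
                                         "age_hi": [2]}))


class TestTimeHeterogeneity:
    def test_zero_ages_reduce_to_modern_formula(self):
        model = scenario("constant").model
        ages = SampleAgeTable.zeros([f"s{i}" for i in range(5)])
        centers = np.arange(0.75, 30.0, 0.5)
        a = expected_ld_time_het(model, ages, centers, 200)
        b = expected_ld(model, centers, 200)
        assert np.max(np.abs(a - b)) < 1e-12

    def test_ignoring_ages_overstates_sharing(self):
        """Extra meioses between non-contemporary samples decay LD, so the
        age-naive p_IBD exceeds the age-aware one at every distance."""
        model = scenario("constant").model
        ages = assign_sampling_times(40, 10, seed=3)
        centers = np.arange(0.75, 30.0, 0.5)
        aware = expected_ld_time_het(model, ages, centers, 80)
        naive = expected_ld(model, centers, 80)
        assert np.all(naive > aware)

    def test_age_offset_panel_matches_age_aware_expectation(self):
        model = scenario("constant").model
        arms = uniform_arm_table(8, 40.0)
        ages = assign_sampling_times(100, 10, seed=13)
        panel, gmap = simulate_ld_panel(scenario("constant"), 100,
                                        sites_per_arm=70, seed=14, arms=arms,
                                        ages=ages)
        z = _ld_z(panel, gmap,
                  lambda ld: expected_ld_time_het(model, ages,
                                                  ld.bin_centers_cm,
                                                  ld.n_haplotypes))
        assert_calibrated(z)

    def test_sampling_times_support(self):
        ages = assign_sampling_times(200, 10, seed=1)
        a = ages.ages[["age_lo", "age_hi"]].to_numpy()
        assert a.min() >= 0 and a.max() <= 10
        zero = assign_sampling_times(5, 0, seed=1)
        assert zero.is_modern()
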