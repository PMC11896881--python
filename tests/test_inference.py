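import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermomorph.inference import (
    AnalysisSubset,
    bootstrap_ci,
    constrained_resample,
    correlation_curve,
    difference_curve,
    difference_of_means,
    resample_indices,
    spearman_rho,
)

from conftest import brute_spearman, make_null_subset


def make_subset(morphs, columns=None, series=None):
    n = len(morphs)
    return AnalysisSubset(
        species="sibiricus",
        sex="M",
        ids=np.array([f"i{k}" for k in range(n)], dtype=object),
        morph=np.array(morphs, dtype=object),
        summaries=columns or {},
        series=series or {},
    )


class TestConstrainedResample:
    def test_singleton_strata_forced(self):
        subset = make_subset(["green", "brown"], {"v": np.array([1.0, 2.0])})
        for seed in range(20):
            out = constrained_resample(subset, seed)
            assert sorted(out.ids) == ["i0", "i1"]

    def test_stratum_sizes_always_preserved(self):
        morphs = ["green"] * 3 + ["brown"] * 5
        subset = make_subset(morphs, {"v": np.arange(8.0)})
        for seed in range(50):
            out = constrained_resample(subset, seed)
            counts = out.morph_counts()
            assert counts == {"green": 3, "brown": 5}
            assert out.n == 8

    def test_inclusion_probability_matches_binomial(self):
        # stratum {a, b, c}: P(a drawn at least once) = 1 - (2/3)^3
        morphs = np.array(["green"] * 3, dtype=object)
        rng = np.random.default_rng(0)
        n_rep = 30000
        hits = 0
        for _ in range(n_rep):
            idx = resample_indices(morphs, rng)
            hits += int(0 in idx)
        p_expected = 1.0 - (2.0 / 3.0) ** 3
        se = math.sqrt(p_expected * (1 - p_expected) / n_rep)
        assert abs(hits / n_rep - p_expected) < 3 * se

    def test_empty_subset_rejected(self):
        subset = make_subset([])
        with pytest.raises(ValueError):
            constrained_resample(subset, 0)

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.sampled_from(["green", "brown", "dorsal-green"]), min_size=1,
                 max_size=12),
        st.integers(0, 2**31),
    )
    def test_property_strata_conserved(self, morphs, seed):
        subset = make_subset(morphs, {"v": np.arange(float(len(morphs)))})
        out = constrained_resample(subset, seed)
        assert out.morph_counts() == subset.morph_counts()


class TestBootstrapCI:
    def test_constant_statistic(self):
        subset = make_subset(["green", "green", "brown"], {"v": np.arange(3.0)})
        res = bootstrap_ci(subset, lambda s: 3.5, B=100, seed=0, label="const")
        assert res.ci_low == res.ci_high == res.estimate == 3.5
        assert res.excludes_zero

    def test_constant_zero_includes_zero(self):
        subset = make_subset(["green", "brown"], {"v": np.arange(2.0)})
        res = bootstrap_ci(subset, lambda s: 0.0, B=50, seed=0)
        assert not res.excludes_zero

    def test_degenerate_two_singletons(self):
        subset = make_subset(["green", "brown"], {"v": np.array([5.0, 2.0])})
        res = bootstrap_ci(
            subset, difference_of_means("v", "green", "brown"), B=200, seed=1
        )
        assert res.estimate == pytest.approx(3.0)
        assert res.ci_low == res.ci_high == pytest.approx(3.0)

    def test_point_estimate_from_original_subset(self):
        rng = np.random.default_rng(2)
        subset = make_subset(
            ["green"] * 10 + ["brown"] * 10, {"v": rng.normal(size=20)}
        )
        stat = difference_of_means("v", "green", "brown")
        expected = stat(subset)
        for seed in (0, 1, 2):
            res = bootstrap_ci(subset, stat, B=50, seed=seed)
            assert res.estimate == expected

    def test_enumeration_oracle_two_by_two(self):
        # strata (2, 2): 16 equally likely resamples enumerated exhaustively
        values = np.array([1.0, 4.0, 2.0, 9.0])
        subset = make_subset(["green", "green", "brown", "brown"], {"v": values})
        stats = []
        for ga in itertools.product([0, 1], repeat=2):
            for gb in itertools.product([2, 3], repeat=2):
                a = values[list(ga)].mean()
                b = values[list(gb)].mean()
                stats.append(a - b)
        assert len(stats) == 16
        # large-B percentile CI converges to the discrete distribution's
        # inverse-CDF quantiles (0.025 and 0.975 fall strictly inside
        # probability blocks here, so the limit is a single atom)
        exact = np.quantile(stats, [0.025, 0.975], method="inverted_cdf")
        res = bootstrap_ci(
            subset, difference_of_means("v", "green", "brown"), B=40000, seed=3
        )
        assert res.ci_low == pytest.approx(exact[0], abs=1e-9)
        assert res.ci_high == pytest.approx(exact[1], abs=1e-9)

    def test_enumeration_oracle_three_by_two(self):
        values = np.array([0.0, 1.0, 5.0, 2.0, 3.0])
        subset = make_subset(
            ["green", "green", "green", "brown", "brown"], {"v": values}
        )
        stats = []
        for ga in itertools.product([0, 1, 2], repeat=3):
            for gb in itertools.product([3, 4], repeat=2):
                stats.append(values[list(ga)].mean() - values[list(gb)].mean())
        assert len(stats) == 27 * 4
        exact = np.quantile(stats, [0.025, 0.975], method="inverted_cdf")
        res = bootstrap_ci(
            subset, difference_of_means("v", "green", "brown"), B=40000, seed=4
        )
        assert res.ci_low == pytest.approx(exact[0], abs=1e-9)
        assert res.ci_high == pytest.approx(exact[1], abs=1e-9)

    def test_missing_replicates_flagged_invalid(self):
        subset = make_subset(["green", "brown"], {"v": np.arange(2.0)})
        res = bootstrap_ci(subset, lambda s: float("nan"), B=20, seed=0)
        assert not res.valid
        assert res.n_missing == 20

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        subset = make_subset(["green"] * 4 + ["brown"] * 4, {"v": rng.normal(size=8)})
        stat = difference_of_means("v", "green", "brown")
        a = bootstrap_ci(subset, stat, B=100, seed=11)
        b = bootstrap_ci(subset, stat, B=100, seed=11)
        np.testing.assert_array_equal(a.replicates, b.replicates)


class TestDifferenceCurve:
    def _subset_with_series(self, n=6, T=10, offset=0.0, seed=0):
        rng = np.random.default_rng(seed)
        times = np.arange(T, dtype=float)
        mat = rng.normal(size=(2 * n, T))
        mat[:n] += offset
        morphs = ["green"] * n + ["brown"] * n
        return make_subset(morphs, series={"internal": (times, mat)})

    def test_identical_groups_zero_curve(self):
        times = np.arange(5.0)
        mat = np.tile(np.arange(5.0), (4, 1))
        subset = make_subset(
            ["green", "green", "brown", "brown"],
            series={"internal": (times, mat)},
        )
        curve = difference_curve(subset, "green", "brown", "internal", B=50, seed=0)
        np.testing.assert_allclose(curve.estimate, 0.0)
        np.testing.assert_allclose(curve.ci_low, 0.0)
        np.testing.assert_allclose(curve.ci_high, 0.0)

    def test_constant_offset_recovered(self):
        subset = self._subset_with_series(n=30, offset=2.5, seed=1)
        curve = difference_curve(subset, "green", "brown", "internal", B=200, seed=2)
        assert np.all(np.abs(curve.estimate - 2.5) < 1.0)
        assert np.all(curve.ci_low <= curve.estimate)
        assert np.all(curve.estimate <= curve.ci_high)

    def test_null_pointwise_exclusion_rate_near_alpha(self):
        # under the null, ~5% of time points should exclude zero (pointwise)
        n_datasets = 150
        T = 20
        count = total = 0
        for seed in range(n_datasets):
            subset = self._subset_with_series(n=15, offset=0.0, seed=seed)
            curve = difference_curve(
                subset, "green", "brown", "internal", B=400, seed=seed + 10_000
            )
            count += int(curve.excludes_zero().sum())
            total += T
        rate = count / total
        se = math.sqrt(0.05 * 0.95 / n_datasets / T)  # conservative (points correlate)
        assert abs(rate - 0.05) < max(3 * se, 0.03)

    def test_missing_group_rejected(self):
        subset = self._subset_with_series()
        with pytest.raises(ValueError):
            difference_curve(subset, "green", "dorsal-green", "internal", B=10, seed=0)

    def test_missing_channel_rejected(self):
        subset = self._subset_with_series()
        with pytest.raises(ValueError):
            difference_curve(subset, "green", "brown", "external", B=10, seed=0)


class TestSpearman:
    def test_monotone_increasing(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        assert spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_case(self):
        assert spearman_rho([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_all_permutations_match_brute_force(self):
        for n in (3, 4, 5):
            x = list(range(1, n + 1))
            for perm in itertools.permutations(x):
                got = spearman_rho(x, list(perm))
                want = brute_spearman(x, list(perm))
                assert got == pytest.approx(want, abs=1e-12)

    def test_tied_inputs_match_brute_force(self):
        cases = [
            ([1, 1, 2, 3], [4, 4, 2, 1]),
            ([1, 2, 2, 2, 5], [3, 3, 1, 4, 4]),
            ([0, 0, 0, 1], [1, 2, 3, 4]),
        ]
        for x, y in cases:
            assert spearman_rho(x, y) == pytest.approx(brute_spearman(x, y), abs=1e-12)

    def test_zero_variance_is_nan(self):
        assert np.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))

    def test_matches_scipy(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        assert spearman_rho(x, y) == pytest.approx(spearmanr(x, y).statistic)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [3, 4])


class TestCorrelationCurve:
    def test_perfect_correlation_at_matching_time(self):
        times = np.arange(3.0)
        rng = np.random.default_rng(9)
        mat = rng.normal(size=(8, 3))
        cov = mat[:, 1].copy()
        subset = make_subset(
            ["green"] * 4 + ["brown"] * 4,
            columns={"brightness": cov},
            series={"internal": (times, mat)},
        )
        curve = correlation_curve(subset, "brightness", "internal", B=50, seed=0)
        assert curve.estimate[1] == pytest.approx(1.0)

    def test_mass_ladder_perfect_negative(self, clean_sim):
        # noiseless generator: heavier is cooler at every t > 0 -> rho = -1
        from thermomorph.physiology import truncate_trace
        from thermomorph.synthetic import simulate_heatup_trace

        from conftest import make_individual

        masses = np.array([0.1, 0.15, 0.2, 0.3, 0.5])
        mats = []
        for i, m in enumerate(masses):
            tr = simulate_heatup_trace(
                make_individual(mass_g=m, ident=f"L{i}"), clean_sim
            )
            mats.append(truncate_trace(tr).temperatures_c)
        mat = np.vstack(mats)
        subset = make_subset(
            ["green", "green", "brown", "brown", "brown"],
            columns={"mass": masses},
            series={"internal": (np.arange(mat.shape[1], dtype=float), mat)},
        )
        curve = correlation_curve(subset, "mass", "internal", B=30, seed=0)
        np.testing.assert_allclose(curve.estimate, -1.0)

    def test_independent_covariate_null_coverage(self):
        # bands straddle zero at ~95% of time points under independence
        n_datasets = 100
        T = 15
        covered = total = 0
        rng = np.random.default_rng(17)
        for ds in range(n_datasets):
            mat = rng.normal(size=(20, T))
            cov = rng.normal(size=20)
            subset = make_subset(
                ["green"] * 10 + ["brown"] * 10,
                columns={"brightness": cov},
                series={"internal": (np.arange(T, dtype=float), mat)},
            )
            curve = correlation_curve(
                subset, "brightness", "internal", B=400, seed=1000 + ds
            )
            covered += int((~curve.excludes_zero()).sum())
            total += T
        rate = covered / total
        assert abs(rate - 0.95) < 0.04

    def test_nan_series_uses_available_cases(self):
        times = np.arange(4.0)
        rng = np.random.default_rng(21)
        mat = rng.normal(size=(10, 4))
        mat[0, 2] = np.nan
        cov = rng.normal(size=10)
        subset = make_subset(
            ["green"] * 5 + ["brown"] * 5,
            columns={"brightness": cov},
            series={"substrate": (times, mat)},
        )
        curve = correlation_curve(subset, "brightness", "substrate", B=30, seed=2)
        valid = np.isfinite(mat[:, 2])
        expected = spearman_rho(cov[valid], mat[valid, 2])
        assert curve.estimate[2] == pytest.approx(expected)


def test_coverage_of_null_heatup_difference():
    # smaller sibling of the acceptance-level coverage check
    n_datasets = 60
    excluded = 0
    for seed in range(n_datasets):
        subset = make_null_subset(12, 12, seed=seed)
        res = bootstrap_ci(
            subset,
            difference_of_means("heatup_internal", "green", "brown"),
            B=400,
            seed=seed + 50_000,
        )
        excluded += int(res.excludes_zero)
    assert excluded / n_datasets < 0.18
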