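"""Rank-sum test, Bonferroni machinery, permutation average effects and
the power analysis.

Oracles: scipy's exact Mann-Whitney null (tie-free) and scipy's exhaustive
permutation_test (with ties) are independent of the in-package exact
enumeration; planted effects on hand-built feature tables check the
average-effect estimator without any tree machinery.
"""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from morphobias.cohort import build_groups
from morphobias.morphometry import FeatureSample, FeatureTable
from morphobias.stats import (
    EligibilityError,
    average_effect,
    bonferroni,
    compare_group,
    global_null_rejected,
    power_analysis,
    proportion_matrix,
    rank_sum_test,
    smallest_n_for_power,
)

from conftest import make_record


# ---------------------------------------------------------------------------
# rank_sum_test
# ---------------------------------------------------------------------------


class TestRankSum:
    def test_identical_multisets_give_p_one(self):
        _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_clean_separation_exact_p(self):
        # all three x below all three y: 2 of C(6,3)=20 assignments are as
        # extreme, so the two-sided exact p is 0.1
        u, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert np.isclose(p, 0.1)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            rank_sum_test([], [1.0])

    def test_invalid_sides_raises(self):
        with pytest.raises(ValueError, match="sides"):
            rank_sum_test([1.0], [2.0], sides="both")

    def test_one_sided_pair_sums_to_more_than_one(self):
        x, y = [1.0, 3.0, 5.0], [2.0, 4.0, 6.0]
        _, p_less = rank_sum_test(x, y, "less")
        _, p_greater = rank_sum_test(x, y, "greater")
        # the two one-sided exact p-values overlap on the observed value
        assert p_less + p_greater >= 1.0

    def test_asymptotic_branch_matches_scipy(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=20), rng.normal(size=15) + 0.3
        u, p = rank_sum_test(x, y)
        ref = sps.mannwhitneyu(x, y, method="asymptotic", use_continuity=True)
        assert np.isclose(u, ref.statistic) and np.isclose(p, ref.pvalue)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=5),
        st.lists(st.floats(-50, 50), min_size=1, max_size=5),
    )
    def test_exact_branch_matches_scipy_exact_when_tie_free(self, x, y):
        if len(set(x) | set(y)) < len(x) + len(y):
            return  # scipy's exact method assumes no ties
        _, p = rank_sum_test(x, y)
        assert np.isclose(p, sps.mannwhitneyu(x, y, method="exact").pvalue)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_branch_matches_permutation_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n0, n1 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        pooled = rng.integers(0, 4, size=n0 + n1).astype(float)
        x, y = pooled[:n0], pooled[n0:]

        def stat(a, b, axis):
            return sps.mannwhitneyu(a, b, axis=axis).statistic

        ref = sps.permutation_test(
            (x, y), stat, permutation_type="independent",
            n_resamples=np.inf, alternative="two-sided",
        )
        _, p = rank_sum_test(x, y)
        assert np.isclose(p, ref.pvalue)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


def toy_table(values_by_neuron, feature="total_length"):
    table = FeatureTable()
    for sid, vals in values_by_neuron.items():
        vals = np.atleast_1d(np.asarray(vals, dtype=float))
        table.add_neuron(
            sid, {feature: FeatureSample(feature, "per_neuron", vals, [sid] * len(vals))}
        )
    return table


def two_method_group(n=6, shift=0.0, seed=0, feature="total_length"):
    rng = np.random.default_rng(seed)
    records, values = [], {}
    for method, delta in (("Golgi", 0.0), ("biocytin", shift)):
        for i in range(n):
            sid = f"{method}_{i}"
            records.append(make_record(sid, staining_method=method))
            values[sid] = rng.normal(loc=100 + delta, scale=5.0)
    (group,) = build_groups(records)
    return group, toy_table(values, feature)


class TestCompareGroup:
    def test_planted_shift_gives_small_p(self):
        group, table = two_method_group(n=10, shift=100.0)
        res = compare_group(group, "total_length", ("Golgi", "biocytin"), table)
        assert res.p_raw < 1e-3
        assert res.n0 == res.n1 == 10

    def test_missing_method_raises(self):
        group, table = two_method_group()
        with pytest.raises(EligibilityError, match="absent"):
            compare_group(group, "total_length", ("Golgi", "DiI"), table)

    def test_too_few_neurons_raises(self):
        group, table = two_method_group(n=6)
        with pytest.raises(EligibilityError, match="< 8"):
            compare_group(group, "total_length", ("Golgi", "biocytin"), table, min_samples=8)

    def test_statistic_invariant_under_neuron_relabeling(self):
        group, table = two_method_group(n=8, shift=10.0, seed=3)
        res = compare_group(group, "total_length", ("Golgi", "biocytin"), table)
        # swap the values of two neurons within the same method
        v0 = table.values("Golgi_0", "total_length").copy()
        table._data[("Golgi_0", "total_length")] = table.values("Golgi_1", "total_length")
        table._data[("Golgi_1", "total_length")] = v0
        res2 = compare_group(group, "total_length", ("Golgi", "biocytin"), table)
        assert res.statistic == res2.statistic and res.p_raw == res2.p_raw


class TestBonferroni:
    def _results(self, p_values, pair=("A", "B")):
        group, table = two_method_group()
        base = compare_group(group, "total_length", ("Golgi", "biocytin"), table)
        return [
            dataclasses.replace(base, p_raw=p, method_pair=pair) for p in p_values
        ]

    def test_single_test_unchanged(self):
        (r,) = bonferroni(self._results([0.03]))
        assert r.p_corrected == 0.03

    def test_family_of_twelve(self):
        rs = bonferroni(self._results([0.01] * 12))
        assert all(np.isclose(r.p_corrected, 0.12) for r in rs)

    def test_correction_caps_at_one(self):
        rs = bonferroni(self._results([0.5] * 12))
        assert all(r.p_corrected == 1.0 for r in rs)

    def test_per_pair_vs_global_family(self):
        rs = self._results([0.01] * 4, pair=("A", "B")) + self._results(
            [0.01] * 2, pair=("A", "C")
        )
        per_pair = bonferroni(rs, family="per_pair")
        glob = bonferroni(rs, family="global")
        assert {round(r.p_corrected, 10) for r in per_pair} == {0.04, 0.02}
        assert all(np.isclose(r.p_corrected, 0.06) for r in glob)

    def test_familywise_error_bounded_in_simulation(self):
        """Bonferroni on k independent uniforms keeps FWER <= alpha."""
        rng = np.random.default_rng(0)
        k, alpha, n_rep = 12, 0.05, 4000
        fwer = np.mean([np.any(rng.random(k) * k < alpha) for _ in range(n_rep)])
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert fwer <= alpha + 2 * se

    def test_intersection_null_rejection(self):
        rs = bonferroni(self._results([0.001, 0.5, 0.9]))
        assert global_null_rejected(rs)
        assert not global_null_rejected(bonferroni(self._results([0.5, 0.9])))


class TestProportionMatrix:
    def test_all_null_and_all_significant(self):
        rs_null = bonferroni(TestBonferroni()._results([1.0] * 6))
        cell = proportion_matrix(rs_null).proportions[("A", "B")]
        assert cell["significant"] == 0.0 and cell["highly_significant"] == 0.0
        rs_sig = bonferroni(TestBonferroni()._results([1e-8] * 6))
        cell = proportion_matrix(rs_sig).proportions[("A", "B")]
        assert cell["significant"] == 1.0 and cell["highly_significant"] == 1.0

    def test_highly_significant_never_exceeds_significant(self):
        rng = np.random.default_rng(1)
        rs = bonferroni(TestBonferroni()._results(list(rng.random(30) ** 3)))
        cell = proportion_matrix(rs).proportions[("A", "B")]
        assert cell["highly_significant"] <= cell["significant"]
        assert cell["n_tests"] == 30


# ---------------------------------------------------------------------------
# average effect
# ---------------------------------------------------------------------------


def multi_group_setup(n_groups=3, n=6, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    records, values = [], {}
    for gi in range(n_groups):
        region = f"region{gi}"
        for method, delta in (("Golgi", 0.0), ("biocytin", shift)):
            for i in range(n):
                sid = f"g{gi}_{method}_{i}"
                records.append(
                    make_record(sid, region_secondary=region, staining_method=method)
                )
                values[sid] = rng.normal(loc=50 + delta, scale=3.0)
    return build_groups(records), toy_table(values)


class TestAverageEffect:
    def test_planted_constant_shift_recovered(self):
        groups, table = multi_group_setup(n_groups=4, n=10, shift=20.0, seed=2)
        est = average_effect(groups, "total_length", ("Golgi", "biocytin"), table,
                             n_perm=500, seed=1)
        # Monte-Carlo error of the group-mean difference: sigma*sqrt(2/n)/sqrt(G)
        assert abs(est.beta - 20.0) < 3 * 3.0 * np.sqrt(2 / 10) / np.sqrt(4)
        assert est.p_perm < 0.05
        assert est.n_groups == 4

    def test_antisymmetric_in_pair_with_same_seed(self):
        groups, table = multi_group_setup(shift=5.0)
        a = average_effect(groups, "total_length", ("Golgi", "biocytin"), table,
                           n_perm=200, seed=7)
        b = average_effect(groups, "total_length", ("biocytin", "Golgi"), table,
                           n_perm=200, seed=7)
        assert a.beta == -b.beta
        assert a.p_perm == b.p_perm

    def test_bit_identical_given_seed(self):
        groups, table = multi_group_setup(shift=5.0)
        runs = [
            average_effect(groups, "total_length", ("Golgi", "biocytin"), table,
                           n_perm=300, seed=42)
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_group_missing_method_excluded_with_warning(self, caplog):
        groups, table = multi_group_setup(n_groups=2, shift=0.0)
        # strip one method from the second group
        g = groups[1]
        groups[1] = dataclasses.replace(g, members={"Golgi": g.members["Golgi"]})
        with caplog.at_level("WARNING", logger="morphobias.stats"):
            est = average_effect(groups, "total_length", ("Golgi", "biocytin"), table,
                                 n_perm=100, seed=0)
        assert est.n_groups == 1
        assert "excluded" in caplog.text

    def test_no_usable_group_raises(self):
        groups, table = multi_group_setup(n_groups=1)
        with pytest.raises(EligibilityError):
            average_effect(groups, "total_length", ("Golgi", "DiI"), table, n_perm=10)

    def test_add_one_permutation_p_in_range(self):
        groups, table = multi_group_setup(shift=0.0, seed=9)
        est = average_effect(groups, "total_length", ("Golgi", "biocytin"), table,
                             n_perm=99, seed=3)
        assert 1 / 100 <= est.p_perm <= 1.0


# ---------------------------------------------------------------------------
# power analysis
# ---------------------------------------------------------------------------


class TestPowerAnalysis:
    def test_invalid_alpha_raises(self):
        with pytest.raises(ValueError, match="alpha"):
            power_analysis(0.5, [10], alpha=1.5, n_sim=10)

    def test_negative_effect_raises(self):
        with pytest.raises(ValueError, match="non-negative"):
            power_analysis(-0.1, [10], n_sim=10)

    def test_size_at_null_near_alpha(self):
        (r,) = power_analysis(0.0, [30], alpha=0.05, n_sim=3000, seed=1)
        se = np.sqrt(0.05 * 0.95 / 3000)
        assert abs(r.power - 0.05) < 3 * se

    def test_power_monotone_in_n_and_d(self):
        by_n = power_analysis(0.8, [10, 40, 120], n_sim=1500, seed=2)
        powers = [r.power for r in by_n]
        assert powers[0] < powers[1] < powers[2]
        lo = power_analysis(0.2, [40], n_sim=1500, seed=3)[0].power
        hi = power_analysis(1.0, [40], n_sim=1500, seed=3)[0].power
        assert lo < hi

    def test_empirical_base_resampling(self):
        rng = np.random.default_rng(4)
        sample = rng.exponential(size=400)
        (r,) = power_analysis(1.0, [30], n_sim=800, seed=5, base="empirical",
                              empirical_sample=sample)
        assert 0.5 < r.power <= 1.0

    def test_empirical_base_requires_sample(self):
        with pytest.raises(ValueError, match="empirical"):
            power_analysis(0.5, [10], base="empirical", n_sim=10)

    def test_smallest_n_for_target_power(self):
        results = power_analysis(0.9, [5, 15, 30, 60], alpha=0.05, n_sim=1200, seed=6)
        n_req = smallest_n_for_power(results, 0.8)
        assert n_req in (15, 30)
        assert smallest_n_for_power(results, 0.9999) is None

    def test_reproducible_given_seed(self):
        a = power_analysis(0.5, [20], n_sim=500, seed=11)
        b = power_analysis(0.5, [20], n_sim=500, seed=11)
        assert a == b
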