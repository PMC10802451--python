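"""Plate-assay arithmetic and nonparametric statistics."""

import itertools

import numpy as np
import pytest
from scipy.stats import binom, mannwhitneyu

from mutmotif.assaystats import (AssayMeasurement, compare_groups,
                                 mann_whitney_one_sided, median_with_ci,
                                 mutation_frequency, titer_per_ml,
                                 viability_percent)


def mw_bitmask_oracle(x, y):
    """Exact one-sided permutation p by enumerating every subset of the
    pooled values as 'y', computing U by direct pairwise comparison."""
    pooled = list(x) + list(y)
    n, n2 = len(pooled), len(y)

    def u_of(ys, xs):
        return sum((yi > xi) + 0.5 * (yi == xi) for yi in ys for xi in xs)

    u_obs = u_of(list(y), list(x))
    hits = total = 0
    for idx in itertools.combinations(range(n), n2):
        ys = [pooled[i] for i in idx]
        xs = [pooled[i] for i in range(n) if i not in idx]
        total += 1
        if u_of(ys, xs) >= u_obs - 1e-9:
            hits += 1
    return hits / total


def measurement(freq, genotype="wt", treatment="water", i=0,
                viable=1e7):
    return AssayMeasurement(culture=f"c{i}", genotype=genotype,
                            treatment=treatment, canr_per_ml=freq * viable,
                            viable_per_ml=viable)


class TestFrequencyAndViability:
    def test_frequency_example(self):
        assert mutation_frequency(30, 1e7) == pytest.approx(3e-6)

    def test_zero_resistant_colonies(self):
        assert mutation_frequency(0, 1e7) == 0.0

    def test_zero_viable_rejected(self):
        with pytest.raises(ZeroDivisionError):
            mutation_frequency(30, 0)

    def test_scale_invariance(self):
        assert mutation_frequency(30, 1e7) == mutation_frequency(60, 2e7)
        assert viability_percent(5e6, 1e7) == viability_percent(1e7, 2e7)

    @pytest.mark.parametrize("treated,untreated,expected", [
        (5e6, 1e7, 50.0), (1e7, 1e7, 100.0), (1.2e7, 1e7, 120.0),
    ])
    def test_viability_not_clamped(self, treated, untreated, expected):
        assert viability_percent(treated, untreated) == pytest.approx(expected)

    def test_titer_conversion(self):
        # 60 colonies from 0.1 ml of a 1:100 dilution -> 6e4 per ml
        assert titer_per_ml(60, 0.1, 100) == pytest.approx(6e4)


class TestMedianCI:
    def test_odd_and_even_medians(self):
        assert median_with_ci([1, 2, 3, 4, 5]).median == 3
        assert median_with_ci([1, 2, 3, 4]).median == 2.5

    def test_n10_uses_second_and_ninth_order_statistics(self):
        values = list(range(1, 11))
        ci = median_with_ci(values)
        assert (ci.lower, ci.upper) == (2, 9)
        assert ci.coverage == pytest.approx(
            1 - 2 * binom.cdf(1, 10, 0.5))
        assert ci.coverage >= 0.95

    def test_small_n_falls_back_to_range(self):
        ci = median_with_ci([1, 2, 3])
        assert (ci.lower, ci.upper) == (1, 3)
        assert not ci.exact

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_with_ci([])

    @pytest.mark.parametrize("n", [8, 12, 36])
    def test_coverage_by_simulation(self, n):
        rng = np.random.default_rng(99)
        true_median = 0.0
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            ci = median_with_ci(rng.standard_normal(n))
            hits += ci.lower <= true_median <= ci.upper
        se = np.sqrt(0.95 * 0.05 / n_rep)
        assert hits / n_rep >= 0.95 - 3 * se


class TestMannWhitney:
    def test_complete_separation_example(self):
        u, p = mann_whitney_one_sided([1, 2, 3], [4, 5, 6])
        assert u == 9.0
        assert p == pytest.approx(1 / 20)

    def test_identical_samples_not_significant(self):
        _, p = mann_whitney_one_sided([1, 2, 3], [1, 2, 3])
        assert p >= 0.5

    def test_matches_bitmask_oracle_with_ties(self, rng):
        for _ in range(20):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 6))
            x = rng.integers(0, 4, size=n1).tolist()
            y = rng.integers(0, 4, size=n2).tolist()
            _, p = mann_whitney_one_sided(x, y)
            assert p == pytest.approx(mw_bitmask_oracle(x, y), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(20):
            x = rng.standard_normal(6).tolist()
            y = (rng.standard_normal(5) + 0.8).tolist()
            _, p = mann_whitney_one_sided(x, y)
            expected = mannwhitneyu(y, x, alternative="greater",
                                    method="exact").pvalue
            assert p == pytest.approx(expected, rel=1e-9)

    def test_exact_and_normal_branch_agree(self, rng):
        deltas = []
        for _ in range(30):
            x = rng.standard_normal(8).tolist()
            y = (rng.standard_normal(8) + 0.5).tolist()
            _, p_exact = mann_whitney_one_sided(x, y)
            _, p_approx = mann_whitney_one_sided(x, y, max_exact=1)
            deltas.append(abs(p_exact - p_approx))
        # the U distribution at 8 vs 8 is discrete with step ~1/12870;
        # the continuity-corrected normal tail tracks it to within ~0.008
        assert max(deltas) < 0.0075

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_one_sided([], [1.0])


class TestCompareGroups:
    def test_fold_change_from_medians(self):
        untreated = [measurement(f, i=i) for i, f in
                     enumerate([1e-6, 2e-6, 3e-6])]
        treated = [measurement(f, treatment="acetaldehyde", i=i)
                   for i, f in enumerate([5e-6, 5.5e-6, 6e-6])]
        comp = compare_groups(untreated, treated)
        assert comp.fold_change == pytest.approx(2.75)
        assert comp.p == pytest.approx(1 / 20)

    def test_identical_groups(self):
        group = [measurement(f, i=i) for i, f in
                 enumerate([1e-6, 2e-6, 3e-6, 4e-6])]
        treated = [measurement(m.frequency, treatment="x", i=i)
                   for i, m in enumerate(group)]
        comp = compare_groups(group, treated)
        assert comp.fold_change == pytest.approx(1.0)
        assert comp.p >= 0.5

    def test_reciprocal_folds_multiply_to_one(self):
        a = [measurement(f, i=i) for i, f in enumerate([1e-6, 2e-6, 4e-6])]
        b = [measurement(f, treatment="x", i=i)
             for i, f in enumerate([3e-6, 6e-6, 9e-6])]
        f_ab = compare_groups(a, b).fold_change
        b_as_ref = [measurement(m.frequency, i=i) for i, m in enumerate(b)]
        a_as_treat = [measurement(m.frequency, treatment="x", i=i)
                      for i, m in enumerate(a)]
        f_ba = compare_groups(b_as_ref, a_as_treat).fold_change
        assert f_ab * f_ba == pytest.approx(1.0)

    def test_zero_untreated_median_flagged(self):
        untreated = [measurement(0.0, i=i) for i in range(3)]
        treated = [measurement(1e-6, treatment="x", i=i) for i in range(3)]
        comp = compare_groups(untreated, treated)
        assert comp.fold_change is None
        assert "untreated_median_zero" in comp.flags

    def test_mixed_genotypes_rejected(self):
        with pytest.raises(ValueError, match="genotype"):
            compare_groups([measurement(1e-6)],
                           [measurement(1e-6, genotype="rad1", treatment="x")])

    def test_median_of_ratios_option(self):
        untreated = [measurement(1e-6, i=i) for i in range(3)]
        treated = [measurement(3e-6, treatment="x", i=i) for i in range(3)]
        comp = compare_groups(untreated, treated,
                              fold_method="median-of-ratios")
        assert comp.fold_change == pytest.approx(3.0)
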