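"""Diversity metrics, normalization and group statistics."""

import itertools
import math
import random
from io import StringIO

import numpy as np
import pandas as pd
import pytest

import taxdiv as td
from taxdiv.errors import ValidationError

SPECIES = ["A", "B", "C", "D"]


class TestShannon:
    def test_uniform_hits_max_entropy(self):
        assert td.shannon([5, 5, 5, 5]) == pytest.approx(math.log(4))

    def test_single_species_is_zero(self):
        assert td.shannon([0, 7, 0]) == 0.0

    def test_direct_evaluation(self):
        # p = (1/4, 1/4, 1/2): H = -sum p ln p
        assert td.shannon([1, 1, 2]) == pytest.approx(1.0397, abs=1e-4)

    def test_base_conversion(self):
        assert td.shannon([1, 1], base=2) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            td.shannon([0, 0])


class TestFaithsPD:
    def test_all_leaves_equal_total_length(self, t1):
        assert td.faiths_pd(t1, set(SPECIES)) == pytest.approx(2.1)

    def test_single_leaf_uses_rooted_path(self, t1):
        assert td.faiths_pd(t1, {"A"}) == pytest.approx(0.4)

    def test_two_leaves_across_the_root(self, t1):
        assert td.faiths_pd(t1, {"A", "C"}) == pytest.approx(1.4)

    def test_unrooted_variant_drops_root_paths(self, t1):
        assert td.faiths_pd(t1, {"A", "B"}, rooted=False) == pytest.approx(0.3)

    def test_monotone_in_species(self, t1):
        for r in range(1, 4):
            for sub in itertools.combinations(SPECIES, r):
                for extra in set(SPECIES) - set(sub):
                    assert td.faiths_pd(t1, set(sub) | {extra}) >= td.faiths_pd(
                        t1, set(sub)
                    )

    def test_unknown_species_listed_in_error(self, t1):
        with pytest.raises(ValidationError, match="Z"):
            td.faiths_pd(t1, {"A", "Z"})


class TestBrayCurtis:
    def test_identical_is_zero(self):
        assert td.bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_is_one(self):
        assert td.bray_curtis([1, 0], [0, 3]) == 1.0

    def test_direct_evaluation(self):
        assert td.bray_curtis([2, 0, 1], [1, 1, 0]) == pytest.approx(0.6)

    def test_both_zero_rejected(self):
        with pytest.raises(ValidationError):
            td.bray_curtis([0, 0], [0, 0])


class TestWeightedUnifrac:
    def test_identical_composition_is_zero(self, t1):
        assert td.weighted_unifrac(t1, [1, 2, 0, 0], [2, 4, 0, 0], SPECIES) == (
            pytest.approx(0.0)
        )

    def test_disjoint_lineages_saturate(self, t1):
        assert td.weighted_unifrac(t1, [1, 0, 0, 0], [0, 0, 1, 0], SPECIES) == (
            pytest.approx(1.0)
        )

    def test_branch_by_branch_evaluation(self, t1):
        assert td.weighted_unifrac(t1, [1, 0, 0, 0], [0, 1, 0, 0], SPECIES) == (
            pytest.approx(1 / 3)
        )

    def test_star_tree_closed_form(self):
        """On a star tree with unit branches the normalized distance is
        the L1 distance between relative abundances divided by 2."""
        star = td.read_newick("(A:1,B:1,C:1,D:1);")
        rng = np.random.default_rng(0)
        for _ in range(10):
            x, y = rng.random(4), rng.random(4)
            expected = np.abs(x / x.sum() - y / y.sum()).sum() / 2
            assert td.weighted_unifrac(star, x, y, SPECIES) == pytest.approx(expected)

    def test_symmetry(self, t1):
        x, y = [3, 1, 0, 2], [0, 1, 4, 1]
        assert td.weighted_unifrac(t1, x, y, SPECIES) == pytest.approx(
            td.weighted_unifrac(t1, y, x, SPECIES)
        )

    def test_missing_species_rejected(self, t1):
        with pytest.raises(ValidationError):
            td.weighted_unifrac(t1, [1, 0], [0, 1], ["A", "Z"])


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        table = pd.DataFrame({"s1": [3, 5, 7], "s2": [3, 5, 7]})
        assert np.allclose(td.size_factors(table), 1.0)

    def test_worked_halving_case(self):
        table = pd.DataFrame({"s1": [2.0, 4.0, 8.0], "s2": [1.0, 2.0, 4.0]})
        factors = td.size_factors(table)
        assert factors["s1"] == pytest.approx(math.sqrt(2))
        assert factors["s2"] == pytest.approx(1 / math.sqrt(2))
        assert factors["s1"] / factors["s2"] == pytest.approx(2.0)

    def test_scale_equivariance_of_factor_ratios(self):
        """Scaling one sample by c multiplies its factor by c relative to
        every other sample; the geometric-mean reference absorbs the
        remaining global constant."""
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            rng.integers(1, 50, size=(6, 4)).astype(float),
            columns=list("wxyz"),
        )
        base = td.size_factors(table)
        scaled = table.copy()
        scaled["y"] *= 7.5
        factors = td.size_factors(scaled)
        n = table.shape[1]
        assert factors["y"] / factors["w"] == pytest.approx(
            7.5 * base["y"] / base["w"]
        )
        assert factors["y"] == pytest.approx(7.5 ** (1 - 1 / n) * base["y"])
        # a global rescaling is absorbed entirely by the reference
        assert np.allclose(td.size_factors(table * 3.0), base)

    def test_no_all_positive_feature_needs_fallback(self):
        table = pd.DataFrame({"s1": [0.0, 2.0], "s2": [3.0, 0.0]})
        with pytest.raises(ValidationError, match="fallback"):
            td.size_factors(table)
        fallback = td.size_factors(table, positive_fallback=True)
        assert (fallback > 0).all()

    def test_normalized_counts_divide_by_factor(self):
        table = pd.DataFrame({"s1": [2.0, 4.0, 8.0], "s2": [1.0, 2.0, 4.0]})
        normalized = td.normalize_counts(table)
        assert np.allclose(normalized["s1"], normalized["s2"])


def exact_mw_p(a, b):
    """Independent oracle: exhaustive enumeration over all assignments of
    pooled ranks to group A."""
    pooled = sorted(a + b)
    n_a = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    n_total = 0
    n_extreme = 0
    u_mean = n_a * len(b) / 2
    for combo in itertools.combinations(range(len(pooled)), n_a):
        group_a = [pooled[i] for i in combo]
        group_b = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(1 for x in group_a for y in group_b if x > y)
        n_total += 1
        if abs(u - u_mean) >= abs(u_obs - u_mean):
            n_extreme += 1
    return n_extreme / n_total


class TestMannWhitney:
    def test_complete_separation_small_groups(self):
        u, p = td.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2/20 arrangements as extreme

    def test_interleaved_identical_groups(self):
        u, p = td.mann_whitney_u([1, 3, 5, 7], [2, 4, 6, 8])
        assert p > 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_p_matches_enumeration(self, seed):
        rng = random.Random(seed)
        n_a, n_b = rng.randint(2, 6), rng.randint(2, 6)
        values = rng.sample(range(1000), n_a + n_b)
        a, b = values[:n_a], values[n_a:]
        _, p = td.mann_whitney_u(a, b)
        assert p == pytest.approx(exact_mw_p(a, b), abs=1e-12)

    def test_large_or_tied_inputs_use_asymptotic(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 30)
        b = rng.normal(1, 1, 30)
        _, p = td.mann_whitney_u(a, b)
        assert 0 < p < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            td.mann_whitney_u([], [1.0])


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert td.bh_fdr([0.02]) == pytest.approx([0.02])

    def test_hand_computed_step_up(self):
        assert td.bh_fdr([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.04, 0.04])

    def test_equal_ps_unchanged(self):
        assert td.bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_permutation_equivariance_and_monotonicity(self):
        rng = np.random.default_rng(3)
        p = rng.random(12)
        adj = td.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        perm = rng.permutation(12)
        assert td.bh_fdr(p[perm]) == pytest.approx(adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            td.bh_fdr([0.5, 1.2])


class TestGroupComparisons:
    def test_identical_groups_are_null(self):
        values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        labels = ["a", "a", "a", "b", "b", "b"]
        comp = td.compare_groups(values, labels, "shannon")
        assert comp.p_value > 0.9

    def test_beta_matrix_is_a_proper_distance_matrix(self, t1):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(
            rng.integers(0, 40, size=(4, 6)) + 1, index=SPECIES
        )
        for metric in ("braycurtis", "wunifrac"):
            dm = td.beta_matrix(table, metric, tree=t1)
            assert np.allclose(dm.data, dm.data.T)
            assert np.allclose(np.diag(dm.data), 0)
            assert dm.data.max() <= 1.0 + 1e-12

    def test_compare_beta_contrasts_within_group_pairs(self, t1):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(
            rng.integers(1, 40, size=(4, 8)).astype(float), index=SPECIES
        )
        dm = td.beta_matrix(table, "braycurtis")
        comp = td.compare_beta(dm, ["g1"] * 4 + ["g2"] * 4)
        assert len(comp.values_a) == 6  # C(4,2) within-group pairs
        assert len(comp.values_b) == 6

    def test_fewer_than_two_samples_per_group_rejected(self, t1):
        dm = td.beta_matrix(
            pd.DataFrame([[1, 2, 3]], index=["A"]).astype(float), "braycurtis"
        )
        with pytest.raises(ValidationError):
            td.compare_beta(dm, ["g1", "g1", "g2"])

    def test_ld_hd_phylogenetic_alpha_metric_gains_power(self):
        """On the seeded LD/HD design, Faith's PD separates the groups
        while Shannon (blind to the tree) does not."""
        counts, labels, tree, _ = td.simulate_ld_hd(td.LdHdDesign(seed=1))
        comp = td.diversity_power_comparison(counts, labels, tree)
        assert comp["pd"].p_adjusted < 0.05
        assert comp["shannon"].p_adjusted > 0.05
        assert comp["wunifrac"].p_adjusted < comp["braycurtis"].p_adjusted


class TestTableIO:
    def test_round_trip(self):
        table = pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0]], index=["A", "B"], columns=["s1", "s2"]
        )
        again = td.read_table(td.write_table(table))
        pd.testing.assert_frame_equal(table, again)
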