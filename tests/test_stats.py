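import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from metapep.stats import (
    GroupDesign,
    bh_adjust,
    differential_features,
    differential_taxa,
    fold_change,
    kruskal_wallis,
    mann_whitney_u,
    season_pattern,
)


def mwu_permutation_p(a, b):
    """Exhaustive permutation two-sided p for the rank-sum statistic with
    average-rank ties (twice the smaller tail, capped at 1)."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = sps.rankdata(pooled)
    obs = ranks[:n1].sum()
    lo = hi = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        stat = ranks[list(idx)].sum()
        lo += stat <= obs + 1e-12
        hi += stat >= obs - 1e-12
        total += 1
    return min(1.0, 2 * min(lo, hi) / total)


class TestMannWhitney:
    def test_fully_separated_small_samples_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        # 2 extreme orderings out of C(6,3) = 20
        assert p == pytest.approx(0.1)

    def test_identical_samples_give_central_u(self):
        u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert u == 9 / 2
        assert p > 0.9

    def test_constant_data_no_evidence(self):
        u, p = mann_whitney_u([5, 5, 5], [5, 5])
        assert (u, p) == (3 * 2 / 2, 1.0)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_permutation_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 5, size=5).astype(float)
        b = rng.integers(0, 5, size=6).astype(float)
        _, p = mann_whitney_u(a, b)
        assert p == pytest.approx(mwu_permutation_p(a, b), abs=0.01)


class TestKruskalWallis:
    def test_hand_computed_three_groups(self):
        h, p = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert h == pytest.approx(32 / 7, abs=1e-3)  # 4.571
        assert p == pytest.approx(sps.chi2.sf(32 / 7, df=2), abs=1e-4)
        assert p == pytest.approx(0.1017, abs=1e-3)

    def test_constant_groups_no_evidence(self):
        assert kruskal_wallis([[2, 2], [2, 2], [2, 2]]) == (0.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0], []])

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_permutation_null(self, seed):
        # chi-squared approximation checked against a Monte-Carlo
        # permutation null at sample sizes where it is trustworthy
        rng = np.random.default_rng(seed)
        n = 12
        groups = [rng.normal(size=n) for _ in range(3)]
        h, p = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        n_perm = 3000
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            hp, _ = kruskal_wallis([perm[:n], perm[n : 2 * n], perm[2 * n :]])
            count += hp >= h - 1e-12
        assert p == pytest.approx(count / n_perm, abs=0.03)


class TestBhAdjust:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])

    def test_uniform_step_up(self):
        # step-up: min over j>=i of m*p_j/j; all collapse to 0.04
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_hand_step_up_vector(self):
        assert bh_adjust([0.005, 0.1, 0.9]) == pytest.approx(
            [0.015, 0.15, 0.9]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    def test_monotone_and_order_preserving(self):
        rng = np.random.default_rng(8)
        p = rng.random(50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestFoldChange:
    def test_hand_ratio(self):
        assert fold_change([4, 5, 6], [1, 2, 3]) == pytest.approx(2.5)

    def test_equal_means_give_one(self):
        assert fold_change([1, 3], [2, 2]) == pytest.approx(1.0)

    def test_zero_denominator_is_infinite(self):
        assert math.isinf(fold_change([1.0], [0.0, 0.0]))

    def test_both_zero_undefined(self):
        assert math.isnan(fold_change([0.0], [0.0]))

    def test_missing_dropped(self):
        assert fold_change([2.0, np.nan], [1.0]) == pytest.approx(2.0)

    def test_reciprocal_identity(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(5) + 0.1, rng.random(5) + 0.1
        assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0)


SEASONS = ["spring", "summer", "autumn"]


class TestSeasonPattern:
    def test_autumn_dominant(self):
        flags = {("autumn", "spring"): True, ("autumn", "summer"): True}
        assert season_pattern(flags, SEASONS) == "Au+"

    def test_no_significance(self):
        assert season_pattern({}, SEASONS) == "NS"

    def test_spring_and_autumn_over_summer(self):
        flags = {("spring", "summer"): True, ("autumn", "summer"): True}
        assert season_pattern(flags, SEASONS) == "Sp+Au+"

    def test_single_win_is_enough(self):
        assert season_pattern({("summer", "spring"): True}, SEASONS) == "Su+"

    def test_win_plus_loss_is_not_plus(self):
        flags = {("spring", "summer"): True, ("autumn", "spring"): True}
        assert season_pattern(flags, SEASONS) == "Au+"

    def test_contradiction_rejected(self):
        flags = {("spring", "summer"): True, ("summer", "spring"): True}
        with pytest.raises(ValueError, match="contradictory"):
            season_pattern(flags, SEASONS)


def _design(n_per_group, groups=SEASONS):
    labels = {}
    for g in groups:
        for i in range(n_per_group):
            labels[f"{g}_{i}"] = g
    return GroupDesign(labels, groups)


def _matrix(design, generator, n_features, seed):
    rng = np.random.default_rng(seed)
    samples = list(design.labels)
    data = {
        s: generator(rng, design.labels[s], n_features) for s in samples
    }
    return pd.DataFrame(data, index=[f"f{i}" for i in range(n_features)])


class TestDifferentialTaxa:
    def test_null_flagged_fraction_bounded(self):
        design = _design(10)
        matrix = _matrix(
            design, lambda rng, g, k: rng.lognormal(0, 0.3, size=k), 200, 21
        )
        diff = differential_taxa(matrix, design, alpha=0.01)
        assert diff["significant"].mean() <= 0.02

    def test_planted_fourfold_shift_flagged(self):
        design = _design(10)

        def gen(rng, group, k):
            vals = rng.lognormal(0, 0.2, size=k)
            if group == "autumn":
                vals[0] *= 4.0
            return vals

        matrix = _matrix(design, gen, 50, 22)
        diff = differential_taxa(matrix, design, alpha=0.01)
        assert bool(diff.loc["f0", "significant"])
        assert diff.loc["f0", "pattern"] == "Au+"

    def test_constant_taxon_not_flagged(self):
        design = _design(5)
        matrix = _matrix(design, lambda rng, g, k: np.ones(k), 3, 1)
        diff = differential_taxa(matrix, design)
        assert not diff["significant"].any()

    def test_unknown_group_rejected(self):
        design = _design(5)
        matrix = _matrix(
            design, lambda rng, g, k: rng.random(k), 3, 2
        ).rename(columns=lambda c: c.replace("autumn", "winter"))
        with pytest.raises(ValueError, match="absent"):
            differential_taxa(matrix, design)

    def test_carries_pairwise_fc_and_min_p(self):
        design = _design(5)
        matrix = _matrix(design, lambda rng, g, k: rng.random(k) + 1, 4, 3)
        diff = differential_taxa(matrix, design)
        for a, b in design.pairs():
            assert f"fc_{a}_vs_{b}" in diff.columns
            assert f"p_{a}_vs_{b}" in diff.columns
        pair_p = diff[[f"p_{a}_vs_{b}" for a, b in design.pairs()]]
        assert (diff["min_pair_p"] == pair_p.min(axis=1)).all()


class TestDifferentialFeatures:
    def test_fc_gate_blocks_small_effects(self):
        design = _design(10)

        def gen(rng, group, k):
            vals = rng.lognormal(0, 0.05, size=k)
            if group == "autumn":
                vals[0] *= 1.2  # significant but FC below the gate
            return vals

        matrix = _matrix(design, gen, 20, 31)
        diff = differential_features(matrix, design)
        assert diff.loc["f0", "kw_adj_p"] < 0.05  # would pass without gate
        assert not bool(diff.loc["f0", "significant"])

    def test_planted_eightfold_recovered_with_pattern(self):
        design = _design(10)
        planted = [f"f{i}" for i in range(50)]

        def gen(rng, group, k):
            vals = rng.lognormal(0, 0.25, size=k)
            if group == "autumn":
                vals[:50] *= 8.0
            return vals

        matrix = _matrix(design, gen, 1000, 32)
        diff = differential_features(matrix, design)
        recovered = diff.loc[planted, "significant"]
        assert recovered.mean() >= 0.9
        patterns = diff.loc[planted, "pattern"][recovered]
        assert (patterns == "Au+").all()

    def test_null_no_false_discoveries_with_planted(self):
        design = _design(10)

        def gen(rng, group, k):
            vals = rng.lognormal(0, 0.25, size=k)
            if group == "summer":
                vals[:30] *= 6.0
            return vals

        matrix = _matrix(design, gen, 600, 33)
        diff = differential_features(matrix, design)
        flagged = diff[diff["significant"]]
        truly_null = [f for f in flagged.index if int(f[1:]) >= 30]
        fdp = len(truly_null) / max(len(flagged), 1)
        assert fdp <= 0.05

    def test_invariant_to_sample_column_order(self):
        design = _design(6)
        matrix = _matrix(
            design, lambda rng, g, k: rng.lognormal(0, 0.3, size=k), 30, 34
        )
        shuffled = matrix[list(reversed(matrix.columns))]
        a = differential_features(matrix, design)
        b = differential_features(shuffled, design)
        pd.testing.assert_frame_equal(a, b)


class TestCalibration:
    def test_type_i_error_of_kw_and_mwu_under_null(self):
        rng = np.random.default_rng(2024)
        n_rep, alpha = 2000, 0.05
        kw_rej = mwu_rej = 0
        for _ in range(n_rep):
            g = [rng.normal(size=10) for _ in range(3)]
            _, p_kw = kruskal_wallis(g)
            _, p_mwu = mann_whitney_u(g[0], g[1])
            kw_rej += p_kw < alpha
            mwu_rej += p_mwu < alpha
        assert 0.03 <= kw_rej / n_rep <= 0.07
        assert 0.03 <= mwu_rej / n_rep <= 0.07
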