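import numpy as np
import pandas as pd
import pytest

from metapep.peptides import PeptideAssignment
from metapep.profiles import (
    group_ratio,
    prune_singletons,
    rank_profile,
    read_profile,
    shannon_index,
    taxon_rollup,
    write_profile,
)
from metapep.taxonomy import TaxonNode, TaxonomyTree


def _assign(pairs):
    return [
        PeptideAssignment(pep, frozenset(), taxon) for pep, taxon in pairs
    ]


@pytest.fixture
def family_tree():
    """root -> O -> F -> G (order, family, genus chain)."""
    return TaxonomyTree(
        [
            TaxonNode("root", "root", "root", "root"),
            TaxonNode("O", "root", "order", "O"),
            TaxonNode("F", "O", "family", "F"),
            TaxonNode("G", "F", "genus", "G"),
        ]
    )


class TestPruneSingletons:
    def test_minimal_instance_moves_singleton_to_parent(self, family_tree):
        out = prune_singletons(
            _assign([("p1", "G"), ("p2", "F"), ("p3", "F")]), family_tree
        )
        taxa = [a.taxon_id for a in out]
        assert taxa == ["F", "F", "F"]

    def test_no_singletons_is_identity(self, family_tree):
        assignments = _assign(
            [("p1", "G"), ("p2", "G"), ("p3", "F"), ("p4", "F")]
        )
        assert prune_singletons(assignments, family_tree) == assignments

    def test_cascade_to_fixpoint(self, family_tree):
        # p1 alone at G cascades G -> F -> O where p2, p3 already sit
        out = prune_singletons(
            _assign([("p1", "G"), ("p2", "O"), ("p3", "O")]), family_tree
        )
        assert [a.taxon_id for a in out] == ["O", "O", "O"]

    def test_root_never_removed(self, family_tree):
        out = prune_singletons(_assign([("p1", "G")]), family_tree)
        assert out[0].taxon_id == "root"

    def test_idempotent_and_no_singletons_remain(self, small_tree):
        rng = np.random.default_rng(2)
        taxa = sorted(small_tree.nodes)
        assignments = _assign(
            [(f"p{i}", taxa[rng.integers(0, len(taxa))]) for i in range(30)]
        )
        once = prune_singletons(assignments, small_tree)
        assert prune_singletons(once, small_tree) == once
        counts = pd.Series([a.taxon_id for a in once]).value_counts()
        assert not any(
            c == 1 and t != "root" for t, c in counts.items()
        )

    def test_peptide_set_unchanged(self, small_tree):
        assignments = _assign([("p1", "gen1"), ("p2", "fam1"), ("p3", "gen3")])
        out = prune_singletons(assignments, small_tree)
        assert {a.peptide for a in out} == {"p1", "p2", "p3"}


class TestRollup:
    def test_single_peptide_gives_100_percent_along_lineage(self, family_tree):
        matrix = pd.DataFrame({"s1": [10.0]}, index=["p1"])
        profile = taxon_rollup(matrix, _assign([("p1", "G")]), family_tree)
        for taxon in ("G", "F", "O", "root"):
            assert profile.percent_of_root.at[taxon, "s1"] == 100.0

    def test_hand_summed_family_split(self, small_tree):
        # p1=60 at gen1 (child of fam1), p2=40 at fam1
        matrix = pd.DataFrame({"s1": [60.0, 40.0]}, index=["p1", "p2"])
        profile = taxon_rollup(
            matrix, _assign([("p1", "gen1"), ("p2", "fam1")]), small_tree
        )
        assert profile.percent_of_root.at["fam1", "s1"] == 100.0
        assert profile.percent_of_root.at["gen1", "s1"] == 60.0
        assert profile.percent_of_root.at["root", "s1"] == 100.0

    def test_domain_split_30_70(self, small_tree):
        matrix = pd.DataFrame({"s1": [30.0, 70.0]}, index=["p1", "p2"])
        profile = taxon_rollup(
            matrix, _assign([("p1", "gen1"), ("p2", "gen3")]), small_tree
        )
        assert profile.percent_of_root.at["bact", "s1"] == pytest.approx(30.0)
        assert profile.percent_of_root.at["fung", "s1"] == pytest.approx(70.0)

    def test_missing_intensities_contribute_zero(self, small_tree):
        matrix = pd.DataFrame(
            {"s1": [50.0, np.nan], "s2": [np.nan, np.nan]},
            index=["p1", "p2"],
        )
        profile = taxon_rollup(
            matrix, _assign([("p1", "gen1"), ("p2", "gen3")]), small_tree
        )
        assert profile.cumulative.at["root", "s1"] == 50.0
        assert np.isnan(profile.percent_of_root.at["root", "s2"])

    def test_count_mode_counts_observed_peptides(self, small_tree):
        matrix = pd.DataFrame(
            {"s1": [5.0, 7.0, np.nan]}, index=["p1", "p2", "p3"]
        )
        profile = taxon_rollup(
            matrix,
            _assign([("p1", "gen1"), ("p2", "gen1"), ("p3", "gen3")]),
            small_tree,
            mode="count",
        )
        assert profile.cumulative.at["gen1", "s1"] == 2.0
        assert profile.cumulative.at["gen3", "s1"] == 0.0

    def test_count_and_intensity_agree_on_unit_intensities(self, small_tree):
        rng = np.random.default_rng(4)
        matrix = pd.DataFrame(
            np.where(rng.random((6, 4)) < 0.3, np.nan, 1.0),
            index=[f"p{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(4)],
        )
        taxa = ["gen1", "gen2", "gen3", "fam1", "bact", "fung"]
        assignments = _assign(list(zip(matrix.index, taxa)))
        a = taxon_rollup(matrix, assignments, small_tree, mode="intensity")
        b = taxon_rollup(matrix, assignments, small_tree, mode="count")
        pd.testing.assert_frame_equal(a.cumulative, b.cumulative)

    def test_cumulative_monotone_along_lineages(self, small_tree):
        rng = np.random.default_rng(9)
        peps = [f"p{i}" for i in range(20)]
        taxa = sorted(small_tree.nodes)
        matrix = pd.DataFrame(
            rng.random((20, 3)) * 100,
            index=peps,
            columns=["s1", "s2", "s3"],
        )
        assignments = _assign(
            [(p, taxa[rng.integers(0, len(taxa))]) for p in peps]
        )
        profile = taxon_rollup(matrix, assignments, small_tree)
        for tid, node in small_tree.nodes.items():
            if node.is_root:
                continue
            assert (
                profile.cumulative.loc[tid]
                <= profile.cumulative.loc[node.parent_id] + 1e-9
            ).all()

    def test_conservation_under_pruning(self, small_tree):
        rng = np.random.default_rng(12)
        peps = [f"p{i}" for i in range(15)]
        taxa = sorted(small_tree.nodes)
        matrix = pd.DataFrame(
            rng.random((15, 2)) * 10, index=peps, columns=["s1", "s2"]
        )
        assignments = _assign(
            [(p, taxa[rng.integers(0, len(taxa))]) for p in peps]
        )
        before = taxon_rollup(matrix, assignments, small_tree)
        after = taxon_rollup(
            matrix, prune_singletons(assignments, small_tree), small_tree
        )
        pd.testing.assert_series_equal(
            before.cumulative.loc["root"], after.cumulative.loc["root"]
        )


class TestRankProfileAndDiversity:
    def test_single_genus_gives_unit_fraction(self, family_tree):
        matrix = pd.DataFrame({"s1": [10.0]}, index=["p1"])
        profile = taxon_rollup(matrix, _assign([("p1", "G")]), family_tree)
        table = rank_profile(profile, "genus")
        assert list(table.index) == ["G"]
        assert table.at["G", "s1"] == 1.0

    def test_two_genera_60_40(self, small_tree):
        matrix = pd.DataFrame({"s1": [60.0, 40.0]}, index=["p1", "p2"])
        profile = taxon_rollup(
            matrix, _assign([("p1", "gen1"), ("p2", "gen2")]), small_tree
        )
        table = rank_profile(profile, "genus")
        assert table.at["gen1", "s1"] == pytest.approx(0.6)
        assert table.at["gen2", "s1"] == pytest.approx(0.4)

    def test_empty_rank_gives_empty_table(self, small_tree):
        matrix = pd.DataFrame({"s1": [1.0]}, index=["p1"])
        profile = taxon_rollup(matrix, _assign([("p1", "gen1")]), small_tree)
        assert rank_profile(profile, "species").empty

    def test_shannon_single_taxon_is_zero(self):
        assert shannon_index([1.0]) == 0.0

    def test_shannon_four_equal_taxa(self):
        assert shannon_index([0.25] * 4) == pytest.approx(np.log(4))

    def test_shannon_hand_value(self):
        # -sum p ln p for (0.5, 0.3, 0.2)
        expected = -(
            0.5 * np.log(0.5) + 0.3 * np.log(0.3) + 0.2 * np.log(0.2)
        )
        assert shannon_index([0.5, 0.3, 0.2]) == pytest.approx(expected)
        assert expected == pytest.approx(1.0297, abs=1e-4)

    def test_shannon_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([0.0, 0.0])

    def test_shannon_renormalizes(self):
        assert shannon_index([2.0, 2.0, 0.0]) == pytest.approx(np.log(2))


class TestGroupRatio:
    def _profile(self, small_tree, fungal, bacterial):
        matrix = pd.DataFrame({"s1": [bacterial, fungal]}, index=["p1", "p2"])
        return taxon_rollup(
            matrix, _assign([("p1", "gen1"), ("p2", "gen3")]), small_tree
        )

    def test_fungi_to_bacteria_ratio(self, small_tree):
        profile = self._profile(small_tree, fungal=70.0, bacterial=30.0)
        ratio = group_ratio(profile, ["fung"], ["bact"])
        assert ratio["s1"] == pytest.approx(70 / 30)

    def test_equal_sums_give_one(self, small_tree):
        profile = self._profile(small_tree, fungal=5.0, bacterial=5.0)
        assert group_ratio(profile, ["fung"], ["bact"])["s1"] == 1.0

    def test_empty_denominator_is_missing(self, small_tree):
        profile = self._profile(small_tree, fungal=5.0, bacterial=0.0)
        assert np.isnan(group_ratio(profile, ["fung"], ["bact"])["s1"])


class TestProfileIO:
    def test_roundtrip(self, small_tree, tmp_path):
        matrix = pd.DataFrame(
            {"s1": [60.0, 40.0], "s2": [np.nan, 10.0]}, index=["p1", "p2"]
        )
        profile = taxon_rollup(
            matrix, _assign([("p1", "gen1"), ("p2", "fam1")]), small_tree
        )
        path = tmp_path / "profile.tsv"
        write_profile(profile, path)
        again = read_profile(path, small_tree)
        pd.testing.assert_frame_equal(
            again.cumulative, profile.cumulative, check_names=False
        )
        pd.testing.assert_frame_equal(
            again.percent_of_root, profile.percent_of_root, check_names=False
        )
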