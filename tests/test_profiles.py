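"""Yield counting, shared/unique set algebra, peptides-per-protein and
exploratory clustering, each against a brute-force oracle."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from diaprm.profiles import (
    count_yields,
    dendrogram,
    group_correlation_matrix,
    group_presence,
    peptides_per_protein,
    shared_unique,
)
from tests.conftest import make_layout, matrix_from_frame


def _presence_pm(presence: dict[str, set[str]], proteins, replicates=2, rng=None):
    """Build a matrix realizing a given group->protein presence pattern."""
    groups = list(presence)
    layout = make_layout(groups, replicates)
    rng = rng or np.random.default_rng(0)
    ab = pd.DataFrame(np.nan, index=proteins, columns=layout.samples)
    for g in groups:
        for p in presence[g]:
            # observed in one replicate suffices for group presence
            ab.at[p, layout.samples_in_group(g)[0]] = rng.uniform(1, 100)
    return matrix_from_frame(ab, layout)


class TestSharedUnique:
    def test_enumerable_example(self):
        pm = _presence_pm({"A": {"P1", "P2"}, "B": {"P2", "P3"}}, ["P1", "P2", "P3"])
        bd = shared_unique(pm)
        assert bd.shared_pairs.at["A", "B"] == 1
        assert bd.unique == {"A": ["P1"], "B": ["P3"]}
        assert bd.core == ["P2"]

    def test_identical_groups(self):
        pm = _presence_pm({"A": {"P1", "P2"}, "B": {"P1", "P2"}}, ["P1", "P2"])
        bd = shared_unique(pm)
        assert bd.unique == {"A": [], "B": []}
        assert bd.core == ["P1", "P2"]

    def test_single_group_rejected(self):
        pm = _presence_pm({"A": {"P1"}}, ["P1"])
        with pytest.raises(ValueError, match=">= 2 groups"):
            shared_unique(pm)

    def test_random_four_groups_vs_set_oracle(self, rng):
        proteins = [f"P{i}" for i in range(50)]
        presence = {
            g: {p for p in proteins if rng.random() < 0.5} or {proteins[0]}
            for g in ("A", "B", "C", "D")
        }
        pm = _presence_pm(presence, proteins, rng=rng)
        bd = shared_unique(pm)
        groups = list(presence)
        for g in groups:
            others = set().union(*(presence[h] for h in groups if h != g))
            assert set(bd.unique[g]) == presence[g] - others
        for a, b in combinations(groups, 2):
            assert bd.shared_pairs.at[a, b] == len(presence[a] & presence[b])
        assert set(bd.core) == set.intersection(*presence.values())

    def test_partition_identity(self, rng):
        proteins = [f"P{i}" for i in range(40)]
        presence = {
            g: {p for p in proteins if rng.random() < 0.4} or {proteins[0]}
            for g in ("A", "B", "C", "D")
        }
        pm = _presence_pm(presence, proteins, rng=rng)
        bd = shared_unique(pm)
        all_present = set().union(*presence.values())
        n_unique = sum(len(v) for v in bd.unique.values())
        in_two_plus = {
            p for p in all_present if sum(p in presence[g] for g in presence) >= 2
        }
        assert n_unique + len(in_two_plus) == len(all_present)

    def test_core_monotone_under_added_group(self, rng):
        proteins = [f"P{i}" for i in range(30)]
        presence3 = {
            g: {p for p in proteins if rng.random() < 0.6} or {proteins[0]}
            for g in ("A", "B", "C")
        }
        presence4 = dict(presence3)
        presence4["D"] = {p for p in proteins if rng.random() < 0.6} or {proteins[0]}
        core3 = shared_unique(_presence_pm(presence3, proteins, rng=rng)).core
        core4 = shared_unique(_presence_pm(presence4, proteins, rng=rng)).core
        assert set(core4) <= set(core3)


class TestYields:
    def _qt(self, rows):
        return pd.DataFrame(
            rows, columns=["protein_id", "gene", "stripped_seq", "sample", "group", "quantity"]
        )

    def test_union_semantics_for_groups(self):
        layout = make_layout(("A",), 2)
        ab = pd.DataFrame(
            {"A_R1": [1.0, np.nan], "A_R2": [np.nan, 2.0]}, index=["P1", "P2"]
        )
        pm = matrix_from_frame(ab, layout)
        qt = self._qt(
            [
                ["P1", "G", "AAAK", "A_R1", "A", 1.0],
                ["P2", "G", "CCCK", "A_R2", "A", 2.0],
            ]
        )
        ys = count_yields(pm, qt)
        assert ys.per_group.loc[0, "proteins"] == 2  # union over replicates
        assert list(ys.per_sample["proteins"]) == [1, 1]

    def test_counts_match_distinct_count_oracle(self, dia_fixture):
        from diaprm.io import read_skyline_table
        from diaprm.preprocess import filter_multi_protein, rollup_protein

        layout = dia_fixture["layout"]
        qt = filter_multi_protein(
            read_skyline_table(dia_fixture["skyline"], layout, mode="dia")
        )
        pm = rollup_protein(qt, layout, method="sum")
        ys = count_yields(pm, qt)
        obs = qt[qt["quantity"] > 0]
        for _, row in ys.per_sample.iterrows():
            sub = obs[obs["sample"] == row["sample"]]
            assert row["peptides"] == len(set(sub["stripped_seq"]))
            assert row["proteins"] == len(set(sub["protein_id"]))


class TestPeptidesPerProtein:
    def _qt(self):
        rows = []
        for p in ("P1", "P2"):
            for j in range(3):
                rows.append([p, f"GENE_{p}", f"{p}PEP{j}K", "A_R1", "A", 1.0])
        return pd.DataFrame(
            rows, columns=["protein_id", "gene", "stripped_seq", "sample", "group", "quantity"]
        )

    def test_constant_counts_median(self):
        counts = peptides_per_protein(self._qt())
        assert counts.attrs["medians"]["A"] == 3.0

    def test_single_protein_query(self):
        res = peptides_per_protein(self._qt(), "GENE_P1")
        assert list(res["peptides"]) == [3]

    def test_unknown_protein_lists_near_matches(self):
        with pytest.raises(KeyError, match="GENE_P1"):
            peptides_per_protein(self._qt(), "GENE_P")


class TestDendrogram:
    def _pm(self, profiles_by_group, n=20, rng=None):
        rng = rng or np.random.default_rng(3)
        groups = list(profiles_by_group)
        layout = make_layout(groups, 1)
        ab = pd.DataFrame(
            {f"{g}_R1": profiles_by_group[g] for g in groups},
            index=[f"P{i}" for i in range(n)],
        )
        return matrix_from_frame(ab, layout)

    def test_identical_pair_merges_first(self, rng):
        base = rng.uniform(10, 100, 20)
        pm = self._pm({"A": base, "B": base, "C": base * 8})
        tree = dendrogram(pm, on="groups")
        first = tree.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}  # A and B
        assert first[2] == pytest.approx(0.0, abs=1e-9)

    def test_leaf_permutation_preserves_heights(self, rng):
        profs = {g: rng.uniform(10, 100, 20) for g in ("A", "B", "C", "D")}
        t1 = dendrogram(self._pm(profs), on="groups")
        rev = {g: profs[g] for g in reversed(list(profs))}
        pm2 = self._pm(rev)
        t2 = dendrogram(pm2, on="groups")
        assert np.allclose(sorted(t1.linkage[:, 2]), sorted(t2.linkage[:, 2]))

    def test_merge_heights_match_pairwise_oracle_four_leaves(self, rng):
        profs = {g: rng.uniform(10, 100, 15) for g in ("A", "B", "C", "D")}
        pm = self._pm(profs, n=15)
        tree = dendrogram(pm, on="groups")
        logs = {g: np.log2(profs[g]) for g in profs}
        d = {
            (a, b): np.sqrt(((logs[a] - logs[b]) ** 2).sum())
            for a, b in combinations(profs, 2)
        }
        # first merge height is the global minimum pairwise distance
        assert tree.linkage[0, 2] == pytest.approx(min(d.values()), rel=1e-12)
        assert np.all(np.diff(tree.linkage[:, 2]) >= -1e-12)

    def test_fewer_than_three_leaves_rejected(self, rng):
        pm = self._pm({"A": rng.uniform(1, 2, 5), "B": rng.uniform(1, 2, 5)}, n=5)
        with pytest.raises(ValueError, match=">= 3 leaves"):
            dendrogram(pm, on="groups")


class TestGroupCorrelation:
    def test_identical_groups_all_ones(self, rng):
        base = rng.uniform(1, 100, 25)
        layout = make_layout(("A", "B"), 1)
        ab = pd.DataFrame(
            {"A_R1": base, "B_R1": base}, index=[f"P{i}" for i in range(25)]
        )
        rho = group_correlation_matrix(matrix_from_frame(ab, layout))
        assert np.allclose(rho.values, 1.0)

    def test_matches_per_pair_recomputation(self, rng):
        from scipy import stats

        layout = make_layout(("A", "B", "C"), 2)
        ab = pd.DataFrame(
            rng.uniform(1, 100, (30, 6)),
            index=[f"P{i}" for i in range(30)],
            columns=layout.samples,
        )
        pm = matrix_from_frame(ab, layout)
        rho = group_correlation_matrix(pm)
        means = {
            g: np.log2(ab[layout.samples_in_group(g)]).mean(axis=1)
            for g in ("A", "B", "C")
        }
        for a, b in combinations("ABC", 2):
            expect = stats.spearmanr(means[a], means[b]).statistic
            assert rho.at[a, b] == pytest.approx(expect, rel=1e-12)
        assert np.allclose(rho.values, rho.values.T)


def test_group_presence_any_replicate_rule():
    layout = make_layout(("A",), 2)
    ab = pd.DataFrame({"A_R1": [1.0], "A_R2": [np.nan]}, index=["P1"])
    pres = group_presence(matrix_from_frame(ab, layout))
    assert pres == {"A": {"P1"}}
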