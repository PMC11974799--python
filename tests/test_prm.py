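"""SID-PRM absolute quantification, ANOVA/Tukey, and the compact letter
display, each against independent oracles (unit analysis, scipy's Tukey HSD,
pooled t-test identity, exhaustive letter-assignment search)."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diaprm.io import read_skyline_table
from diaprm.prm import (
    AbsQuantParams,
    anova_tukey,
    compact_letter_display,
    copies_per_cell,
    peptide_ratios,
    significance_matrix,
    stoichiometry_compare,
    trend,
)

EXAMPLE_PARAMS = AbsQuantParams(
    hlis_mw=1e5, spiked_mass_ng=1.0, injected_protein_ug=1.0, protein_per_cell_pg=10.0
)


def _ratio_df(rows):
    return pd.DataFrame(
        rows, columns=["protein_id", "gene", "stripped_seq", "sample", "group", "replicate", "ratio"]
    )


class TestPeptideRatios:
    def _prm(self, light, heavy):
        return pd.DataFrame(
            {
                "protein_id": "P1",
                "gene": "G1",
                "stripped_seq": [f"PEP{i}K" for i in range(len(light))],
                "run_id": "r1",
                "sample": "s1",
                "group": "A",
                "replicate": 1,
                "light_area": light,
                "heavy_area": heavy,
            }
        )

    def test_simple_ratio(self):
        out = peptide_ratios(self._prm([1000.0], [500.0]))
        assert out["ratio"].iloc[0] == 2.0

    def test_zero_light_gives_zero_ratio(self):
        out = peptide_ratios(self._prm([0.0], [500.0]))
        assert out["ratio"].iloc[0] == 0.0

    def test_zero_heavy_row_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="heavy area"):
            out = peptide_ratios(self._prm([100.0, 200.0], [500.0, 0.0]))
        assert len(out) == 1
        assert out.attrs["rows_excluded_no_heavy"] == 1

    def test_all_heavy_zero_flags_protein_unquantifiable(self):
        with pytest.warns(UserWarning):
            out = peptide_ratios(self._prm([100.0], [0.0]))
        assert out.attrs["unquantifiable_proteins"] == ["P1"]


class TestCopiesPerCell:
    def test_worked_unit_analysis_example(self):
        # R=1, MW=1e5 g/mol, 1 ng spike, 1 ug injected, 10 pg/nucleus:
        # 1e-9/1e5 = 1e-14 mol heavy; x 1e-5 ug/nucleus -> 1e-19 mol -> ~60221 copies
        out = copies_per_cell(
            _ratio_df([["P1", "G1", "AAAK", "s1", "A", 1, 1.0]]), EXAMPLE_PARAMS
        )
        assert out["copies"].iloc[0] == pytest.approx(6.02214076e4, rel=1e-12)

    def test_zero_ratio_zero_copies(self):
        out = copies_per_cell(
            _ratio_df([["P1", "G1", "AAAK", "s1", "A", 1, 0.0]]), EXAMPLE_PARAMS
        )
        assert out["copies"].iloc[0] == 0.0

    @pytest.mark.parametrize("rollup,expected", [("median", 2.0), ("mean", 8.0 / 3.0)])
    def test_rollup_over_peptides(self, rollup, expected):
        rows = [
            ["P1", "G1", "AAAK", "s1", "A", 1, 1.0],
            ["P1", "G1", "CCCK", "s1", "A", 1, 2.0],
            ["P1", "G1", "DDDK", "s1", "A", 1, 5.0],
        ]
        out = copies_per_cell(_ratio_df(rows), EXAMPLE_PARAMS, rollup=rollup)
        unit = EXAMPLE_PARAMS.ratio_to_copies(1.0)
        assert out["copies"].iloc[0] == pytest.approx(expected * unit, rel=1e-12)

    def test_dimensional_linearity_contracts(self):
        base = EXAMPLE_PARAMS
        r = 2.7
        c0 = base.ratio_to_copies(r)
        assert base.ratio_to_copies(3 * r) == pytest.approx(3 * c0, rel=1e-12)
        double_ppc = AbsQuantParams(1e5, 1.0, 1.0, 20.0)
        assert double_ppc.ratio_to_copies(r) == pytest.approx(2 * c0, rel=1e-12)
        double_mw = AbsQuantParams(2e5, 1.0, 1.0, 10.0)
        assert double_mw.ratio_to_copies(r) == pytest.approx(c0 / 2, rel=1e-12)
        double_inj = AbsQuantParams(1e5, 1.0, 2.0, 10.0)
        assert double_inj.ratio_to_copies(r) == pytest.approx(c0 / 2, rel=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            AbsQuantParams(0.0, 1.0, 1.0, 1.0)


class TestAnovaTukey:
    def test_all_identical_constants_degenerate(self):
        tk = anova_tukey({"A": [5.0, 5.0], "B": [5.0, 5.0], "C": [5.0, 5.0]})
        assert (tk.pairwise["p_value"] == 1.0).all()
        assert tk.anova_p == 1.0

    def test_group_with_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="'B'"):
            anova_tukey({"A": [1.0, 2.0], "B": [1.0]})

    def test_matches_scipy_tukey_hsd(self, rng):
        for _ in range(20):
            k = int(rng.integers(3, 6))
            vals = {f"g{j}": rng.normal(rng.uniform(-2, 2), 1, int(rng.integers(3, 7))) for j in range(k)}
            tk = anova_tukey(vals)
            ref = stats.tukey_hsd(*vals.values())
            names = list(vals)
            for _, row in tk.pairwise.iterrows():
                i, j = names.index(row["group_1"]), names.index(row["group_2"])
                assert row["p_value"] == pytest.approx(ref.pvalue[i, j], abs=1e-9)

    def test_two_group_equals_pooled_t_test(self, rng):
        for _ in range(100):
            a = rng.normal(0, 1, int(rng.integers(2, 8)))
            b = rng.normal(rng.uniform(-1, 1), 1, int(rng.integers(2, 8)))
            tk = anova_tukey({"a": a, "b": b})
            p_t = stats.ttest_ind(b, a, equal_var=True).pvalue
            assert tk.pairwise["p_value"].iloc[0] == pytest.approx(p_t, abs=1e-8)

    def test_separated_group_detected(self, rng):
        # means (0, 0, 5), sigma=1, n=4: the distant group separates
        hits = 0
        for s in range(10):
            r = np.random.default_rng(s)
            vals = {"g1": r.normal(0, 1, 4), "g2": r.normal(0, 1, 4), "g3": r.normal(5, 1, 4)}
            sig = significance_matrix(anova_tukey(vals), 0.05)
            hits += sig.at["g1", "g3"] and sig.at["g2", "g3"] and not sig.at["g1", "g2"]
        assert hits >= 8


def cld_is_valid(assignment: dict[str, str], sig: pd.DataFrame) -> bool:
    """Invariant: share a letter <=> not significantly different."""
    for g, letters in assignment.items():
        if not letters:
            return False
    for a, b in combinations(sig.index, 2):
        share = bool(set(assignment[a]) & set(assignment[b]))
        if share == bool(sig.at[a, b]):
            return False
    return True


def minimal_letter_count_oracle(sig: pd.DataFrame) -> int:
    """Exhaustive search: fewest letters (cliques of the non-significance
    graph) covering every group and every non-significant pair."""
    from itertools import combinations as combos

    groups = list(sig.index)
    nonsig_pairs = [
        (a, b) for a, b in combos(groups, 2) if not sig.at[a, b]
    ]
    # candidate letters = all subsets that contain no significant pair
    cliques = []
    for r in range(1, len(groups) + 1):
        for sub in combos(groups, r):
            if all(not sig.at[a, b] for a, b in combos(sub, 2)):
                cliques.append(set(sub))
    # a cover can need more letters than groups (edge clique cover)
    for size in range(1, len(cliques) + 1):
        for pick in combos(cliques, size):
            if all(any(g in c for c in pick) for g in groups) and all(
                any(a in c and b in c for c in pick) for a, b in nonsig_pairs
            ):
                return size
    raise AssertionError("unreachable")


def random_sig_matrix(rng, k: int) -> pd.DataFrame:
    groups = [f"g{i}" for i in range(k)]
    sig = pd.DataFrame(False, index=groups, columns=groups)
    for a, b in combinations(groups, 2):
        s = bool(rng.random() < 0.4)
        sig.at[a, b] = sig.at[b, a] = s
    return sig


class TestCompactLetterDisplay:
    def test_no_significant_pairs_single_letter(self):
        sig = random_sig_matrix(np.random.default_rng(0), 4)
        sig.loc[:, :] = False
        cld = compact_letter_display(sig)
        assert set(cld.values()) == {"a"}

    def test_all_pairs_significant_distinct_letters(self):
        groups = ["g0", "g1", "g2"]
        sig = pd.DataFrame(True, index=groups, columns=groups)
        for g in groups:
            sig.at[g, g] = False
        cld = compact_letter_display(sig)
        assert sorted(cld.values()) == ["a", "b", "c"]

    def test_invariant_and_minimality_on_random_matrices(self, rng):
        for _ in range(60):
            k = int(rng.integers(2, 6))
            sig = random_sig_matrix(rng, k)
            cld = compact_letter_display(sig)
            assert cld_is_valid(cld, sig), (cld, sig)
            n_letters = len(set("".join(cld.values())))
            assert n_letters == minimal_letter_count_oracle(sig)

    def test_deterministic_given_group_order(self, rng):
        sig = random_sig_matrix(rng, 5)
        assert compact_letter_display(sig) == compact_letter_display(sig.copy())


class TestStoichiometryAndTrend:
    def _copies(self):
        rows = []
        for p, mean in (("P1", 1000.0), ("P2", 1000.0), ("P3", 10000.0)):
            for rep, jitter in ((1, 0.98), (2, 1.0), (3, 1.02)):
                rows.append(
                    {"protein_id": p, "gene": p, "sample": f"A_R{rep}", "group": "A",
                     "replicate": rep, "copies": mean * jitter}
                )
        return pd.DataFrame(rows)

    def test_identical_proteins_share_letter(self):
        bars, cld, _ = stoichiometry_compare(self._copies(), ["P1", "P2"], "A")
        assert set(cld["P1"]) & set(cld["P2"])

    def test_planted_tenfold_difference_separates_letters(self):
        bars, cld, _ = stoichiometry_compare(self._copies(), ["P1", "P3"], "A")
        assert not (set(cld["P1"]) & set(cld["P3"]))

    def test_single_protein_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            stoichiometry_compare(self._copies(), ["P1"], "A")

    def test_absent_protein_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            bars, _, _ = stoichiometry_compare(self._copies(), ["P1", "P3", "PX"], "A")
        assert set(bars["protein_id"]) == {"P1", "P3"}

    def test_trend_order_follows_layout(self):
        df = self._copies()
        df2 = df.copy()
        df2["group"] = "B"
        df2["sample"] = df2["sample"].str.replace("A_", "B_")
        allc = pd.concat([df, df2])
        series = trend(allc, "P1", ["B", "A"])
        assert list(series["group"]) == ["B", "A"]

    def test_trend_unknown_protein(self):
        with pytest.raises(KeyError, match="near matches"):
            trend(self._copies(), "NOPE", ["A"])


class TestEndToEndSpikeRecovery:
    def test_noisy_fixture_recovery_within_planted_cv(self, prm_fixture):
        table = read_skyline_table(
            prm_fixture["csv"], prm_fixture["layout"], mode="prm_heavy"
        )
        ratios = peptide_ratios(table)
        copies = copies_per_cell(ratios, prm_fixture["truth"].params)
        truth = prm_fixture["truth"].true_copies
        rel_errors = []
        for _, row in copies.iterrows():
            t = truth.at[row["protein_id"], row["group"]]
            rel_errors.append(abs(row["copies"] - t) / t)
        assert np.median(rel_errors) < prm_fixture["spec"].ratio_cv / 100.0
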