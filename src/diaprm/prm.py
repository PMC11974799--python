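"""SID-PRM absolute quantification and stoichiometry statistics.

A known mass of an isotopically heavy labeled internal standard (HLIS,
e.g. a QconCAT concatemer) is spiked into each injection. The endogenous
(light) amount of each target peptide follows from the light/heavy peak-area
ratio R and the spike bookkeeping, and converts to protein copies per
nucleus (or per cell):

    mol_heavy/injection = spiked_mass / MW_HLIS
    mol_endogenous/µg   = R * mol_heavy / injected_protein
    copies/nucleus      = mol_endogenous/µg * protein_per_nucleus * N_A

with masses in g, injected protein in µg, protein-per-nucleus in µg and
Avogadro's constant N_A. Per-protein copies are the median over its
peptides (mean available). Group comparisons use one-way ANOVA with
Tukey's HSD post-hoc test and a compact letter display (CLD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .preprocess import ProteinMatrix

N_AVOGADRO = 6.02214076e23  # 1/mol


@dataclass(frozen=True)
class AbsQuantParams:
    """Spike-in bookkeeping for one HLIS.

    hlis_mw: molecular weight of the spiked standard, g/mol
    spiked_mass_ng: mass of HLIS spiked per injection, ng
    injected_protein_ug: sample protein loaded per injection, µg
    protein_per_cell_pg: total protein mass per nucleus (or cell), pg
    """

    hlis_mw: float
    spiked_mass_ng: float
    injected_protein_ug: float
    protein_per_cell_pg: float

    def __post_init__(self) -> None:
        for name in (
            "hlis_mw",
            "spiked_mass_ng",
            "injected_protein_ug",
            "protein_per_cell_pg",
        ):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v}")

    @property
    def mol_heavy_per_injection(self) -> float:
        return self.spiked_mass_ng * 1e-9 / self.hlis_mw

    def ratio_to_copies(self, ratio: float | np.ndarray) -> float | np.ndarray:
        """Convert a light/heavy area ratio to copies per nucleus/cell."""
        mol_per_ug = ratio * self.mol_heavy_per_injection / self.injected_protein_ug
        return mol_per_ug * (self.protein_per_cell_pg * 1e-6) * N_AVOGADRO

    def copies_to_ratio(self, copies: float | np.ndarray) -> float | np.ndarray:
        """Exact inverse of :meth:`ratio_to_copies` (fixture construction)."""
        mol_per_ug = copies / (self.protein_per_cell_pg * 1e-6) / N_AVOGADRO
        return mol_per_ug * self.injected_protein_ug / self.mol_heavy_per_injection

    @classmethod
    def from_yaml(cls, path) -> "AbsQuantParams":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        return cls(
            hlis_mw=float(d["hlis_mw"]),
            spiked_mass_ng=float(d["spiked_mass_ng"]),
            injected_protein_ug=float(d["injected_protein_ug"]),
            protein_per_cell_pg=float(d["protein_per_cell_pg"]),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "hlis_mw": self.hlis_mw,
                    "spiked_mass_ng": self.spiked_mass_ng,
                    "injected_protein_ug": self.injected_protein_ug,
                    "protein_per_cell_pg": self.protein_per_cell_pg,
                },
                fh,
                sort_keys=False,
            )


def peptide_ratios(prm: pd.DataFrame) -> pd.DataFrame:
    """Light/heavy area ratio per peptide x run.

    Rows with a zero or missing heavy area cannot be normalized and are
    excluded (count in ``df.attrs['rows_excluded_no_heavy']``); proteins
    whose every row lacks heavy signal are flagged unquantifiable in
    ``df.attrs['unquantifiable_proteins']``.
    """
    df = prm.copy()
    heavy = pd.to_numeric(df["heavy_area"], errors="coerce")
    light = pd.to_numeric(df["light_area"], errors="coerce")
    usable = heavy > 0
    excluded = int((~usable).sum())
    if excluded:
        warnings.warn(
            f"{excluded} row(s) with zero/missing heavy area excluded", stacklevel=2
        )
    all_prot = set(df["protein_id"])
    df = df[usable].copy()
    df["ratio"] = light[usable].fillna(0.0) / heavy[usable]
    unquant = sorted(all_prot - set(df["protein_id"]))
    out = df[
        ["protein_id", "gene", "stripped_seq", "sample", "group", "replicate", "ratio"]
    ].reset_index(drop=True)
    out.attrs["rows_excluded_no_heavy"] = excluded
    out.attrs["unquantifiable_proteins"] = unquant
    return out


def copies_per_cell(
    ratios: pd.DataFrame, params: AbsQuantParams, rollup: str = "median"
) -> pd.DataFrame:
    """Protein copies per nucleus/cell, per protein x sample.

    Each peptide ratio converts independently through the spike bookkeeping;
    the protein value is the median (default, robust to single-peptide
    interference) or mean over its peptides. Long format out:
    protein_id, gene, sample, group, replicate, copies.
    """
    if rollup not in ("median", "mean"):
        raise ValueError(f"rollup must be 'median' or 'mean', got {rollup!r}")
    df = ratios.copy()
    df["copies"] = params.ratio_to_copies(df["ratio"].values)
    grouped = (
        df.groupby(["protein_id", "gene", "sample", "group", "replicate"], sort=False)[
            "copies"
        ]
        .agg(rollup)
        .reset_index()
    )
    return grouped.sort_values(["protein_id", "sample"], kind="mergesort").reset_index(
        drop=True
    )


def copies_matrix(copies: pd.DataFrame) -> pd.DataFrame:
    """Pivot long copies to a protein x sample table."""
    return copies.pivot_table(
        index="protein_id", columns="sample", values="copies", sort=False
    )


# --------------------------------------------------------------------------
# ANOVA + Tukey HSD + compact letter display
# --------------------------------------------------------------------------


@dataclass
class TukeyResult:
    groups: list[str]
    means: dict[str, float]
    f_stat: float
    anova_p: float
    pairwise: pd.DataFrame  # columns: group_1, group_2, mean_diff, p_value


def anova_tukey(values: dict[str, np.ndarray], alpha: float = 0.05) -> TukeyResult:
    """One-way ANOVA and all-pairs Tukey HSD.

    Tukey p-values come from the studentized-range distribution with the
    pooled within-group variance. With every observation identical the
    within- and between-group variances both vanish; that degenerate case
    reports p = 1 everywhere (no evidence of any difference).
    """
    groups = list(values)
    if len(groups) < 2:
        raise ValueError("ANOVA requires >= 2 groups")
    arrs = {}
    for g in groups:
        a = np.asarray(values[g], dtype=float)
        a = a[~np.isnan(a)]
        if len(a) < 2:
            raise ValueError(f"group {g!r} has < 2 replicates")
        arrs[g] = a
    k = len(groups)
    ns = {g: len(a) for g, a in arrs.items()}
    ntot = sum(ns.values())
    grand = np.concatenate(list(arrs.values())).mean()
    ss_between = sum(ns[g] * (arrs[g].mean() - grand) ** 2 for g in groups)
    ss_within = sum(((arrs[g] - arrs[g].mean()) ** 2).sum() for g in groups)
    df_between, df_within = k - 1, ntot - k
    mse = ss_within / df_within

    if mse == 0.0:
        if ss_between == 0.0:
            f_stat, anova_p = 0.0, 1.0
            pair_p = {pair: 1.0 for pair in combinations(groups, 2)}
        else:
            f_stat, anova_p = np.inf, 0.0
            pair_p = {
                (a, b): (1.0 if arrs[a].mean() == arrs[b].mean() else 0.0)
                for a, b in combinations(groups, 2)
            }
    else:
        f_stat = (ss_between / df_between) / mse
        anova_p = float(stats.f.sf(f_stat, df_between, df_within))
        pair_p = {}
        for a, b in combinations(groups, 2):
            se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            q = abs(arrs[a].mean() - arrs[b].mean()) / se
            pair_p[(a, b)] = float(stats.studentized_range.sf(q, k, df_within))

    rows = [
        {
            "group_1": a,
            "group_2": b,
            "mean_diff": float(arrs[b].mean() - arrs[a].mean()),
            "p_value": min(pair_p[(a, b)], 1.0),
        }
        for a, b in combinations(groups, 2)
    ]
    return TukeyResult(
        groups=groups,
        means={g: float(arrs[g].mean()) for g in groups},
        f_stat=float(f_stat),
        anova_p=float(anova_p),
        pairwise=pd.DataFrame(rows),
    )


def significance_matrix(tukey: TukeyResult, alpha: float = 0.05) -> pd.DataFrame:
    """Boolean group x group matrix: True where the Tukey comparison is
    significant at ``alpha``."""
    g = tukey.groups
    sig = pd.DataFrame(False, index=g, columns=g)
    for _, row in tukey.pairwise.iterrows():
        s = row["p_value"] <= alpha
        sig.at[row["group_1"], row["group_2"]] = s
        sig.at[row["group_2"], row["group_1"]] = s
    return sig


def compact_letter_display(
    tukey: TukeyResult | pd.DataFrame, alpha: float = 0.05
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing at least one letter are exactly the pairs whose Tukey
    comparison is NOT significant at ``alpha``. Letters are assigned in the
    given group order starting at 'a'; redundant letters (columns whose
    group set is contained in another's) are absorbed, and the assignment is
    deterministic.
    """
    if isinstance(tukey, TukeyResult):
        sig = significance_matrix(tukey, alpha)
    else:
        sig = tukey.astype(bool)
    groups = list(sig.index)
    # letters as a list of group-sets; every group must belong to >= 1 letter
    letters: list[set[str]] = [set(groups)] if groups else []
    for a, b in combinations(groups, 2):
        if not sig.at[a, b]:
            continue
        new_letters: list[set[str]] = []
        for col in letters:
            if a in col and b in col:
                # split the violating letter into two columns
                new_letters.append(col - {b})
                new_letters.append(col - {a})
            else:
                new_letters.append(col)
        # absorb columns contained in another
        letters = []
        for col in sorted(new_letters, key=lambda c: (-len(c), sorted(c))):
            if col and not any(col <= kept for kept in letters):
                letters.append(col)
    # order letters by first group (display order) for a stable labeling
    first = {g: i for i, g in enumerate(groups)}
    letters.sort(key=lambda col: min(first[g] for g in col))
    assignment = {g: "" for g in groups}
    for i, col in enumerate(letters):
        ch = _letter(i)
        for g in groups:
            if g in col:
                assignment[g] += ch
    return assignment


def _letter(i: int) -> str:
    out = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        out = chr(ord("a") + r) + out
    return out


def stoichiometry_compare(
    copies: pd.DataFrame, proteins: list[str], group: str, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, str], TukeyResult]:
    """Compare absolute copies of several proteins within one group.

    ANOVA + Tukey + CLD across proteins on replicate-level copies. Proteins
    not quantified in the group are excluded with a warning; fewer than two
    quantifiable proteins is an error.
    """
    sub = copies[(copies["group"] == group)]
    present, missing = [], []
    vals: dict[str, np.ndarray] = {}
    for p in proteins:
        v = sub.loc[sub["protein_id"] == p, "copies"].values
        if len(v) >= 2:
            present.append(p)
            vals[p] = v
        else:
            missing.append(p)
    if missing:
        warnings.warn(
            f"excluded from stoichiometry comparison in {group!r}: {missing}",
            stacklevel=2,
        )
    if len(present) < 2:
        raise ValueError("stoichiometry comparison needs >= 2 quantified proteins")
    tk = anova_tukey(vals, alpha=alpha)
    cld = compact_letter_display(tk, alpha=alpha)
    bars = pd.DataFrame(
        {
            "protein_id": present,
            "mean_copies": [float(np.mean(vals[p])) for p in present],
            "sd_copies": [float(np.std(vals[p], ddof=1)) for p in present],
            "letters": [cld[p] for p in present],
        }
    )
    return bars, cld, tk


def trend(copies: pd.DataFrame, protein_or_gene: str, group_order: list[str]) -> pd.DataFrame:
    """Mean ± sd copies of one protein across groups, in layout group order."""
    q = protein_or_gene.upper()
    sub = copies[
        (copies["protein_id"].str.upper() == q) | (copies["gene"].str.upper() == q)
    ]
    if sub.empty:
        near = sorted(
            set(
                copies.loc[
                    copies["gene"].str.upper().str.contains(q, regex=False), "gene"
                ]
            )
        )[:10]
        raise KeyError(f"unknown protein/gene {protein_or_gene!r}; near matches: {near}")
    rows = []
    for g in group_order:
        v = sub.loc[sub["group"] == g, "copies"].values
        rows.append(
            {
                "group": g,
                "mean_copies": float(np.mean(v)) if len(v) else np.nan,
                "sd_copies": float(np.std(v, ddof=1)) if len(v) >= 2 else np.nan,
                "n": len(v),
            }
        )
    return pd.DataFrame(rows)


def relative_matrix(copies: pd.DataFrame, layout) -> ProteinMatrix:
    """View replicate-level copies as a protein x sample matrix so the QC,
    profiling and abundance tooling applies to PRM data unchanged."""
    mat = copies_matrix(copies).reindex(columns=layout.samples)
    genes = copies.groupby("protein_id")["gene"].first().reindex(mat.index)
    upep = mat.notna().astype(int)
    return ProteinMatrix(
        abundance=mat.where(mat > 0), unique_peptides=upep, genes=genes, layout=layout
    )
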