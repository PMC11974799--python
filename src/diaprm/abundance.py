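"""Protein abundance analysis: ranking, volcano differential abundance,
single-protein significance, heatmaps and iterative imputation.

The volcano test is a two-sample t-test on log2 abundances (Welch by
default; pooled available). Thresholds follow the conventional menus:
P in [0.001, 0.05] and fold change in [0.5, 10]; a fold-change cut below 1
is symmetrized (0.5 means |log2FC| >= 1) so the bound stays two-sided.
No multiple-testing correction drives significance status, but a
Benjamini-Hochberg column is carried in the output for transparency.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from statsmodels.stats.multitest import multipletests

from .preprocess import ProteinMatrix


def rank_abundance(pm: ProteinMatrix, group: str) -> pd.DataFrame:
    """Proteins ranked by group-mean abundance, descending; ties broken by
    protein_id so the order is deterministic."""
    cols = pm.group_columns(group)
    mean = pm.abundance[cols].mean(axis=1).dropna()
    out = pd.DataFrame(
        {
            "protein_id": mean.index,
            "gene": pm.genes.reindex(mean.index).values,
            "abundance": mean.values,
        }
    )
    out = out.sort_values(
        ["abundance", "protein_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def _two_sample_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool = False
) -> tuple[float, float]:
    """t statistic and two-sided p for b vs a on given values."""
    res = stats.ttest_ind(b, a, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def effective_fc_threshold(fc_thr: float) -> float:
    """Symmetrize a fold-change threshold: values below 1 mean the reciprocal
    bound (0.5 -> 2), so the cut is always a two-sided |log2FC| bound."""
    if fc_thr <= 0:
        raise ValueError(f"fold-change threshold must be > 0, got {fc_thr}")
    return max(fc_thr, 1.0 / fc_thr)


def volcano(
    pm: ProteinMatrix,
    group_a: str,
    group_b: str,
    p_thr: float = 0.05,
    fc_thr: float = 2.0,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Differential abundance of ``group_b`` vs ``group_a``.

    Per protein observed in >= 2 replicates of each group: log2FC =
    mean_b - mean_a of log2 abundances, two-sided t-test on the same values,
    and a status in {up, down, not_significant} from the P and fold-change
    thresholds. Proteins with insufficient replicates are excluded;
    the count is in ``df.attrs['excluded_insufficient_replicates']``.
    """
    fc_eff = effective_fc_threshold(fc_thr)
    lfc_cut = np.log2(fc_eff)
    ca, cb = pm.group_columns(group_a), pm.group_columns(group_b)
    if len(ca) < 2 or len(cb) < 2:
        raise ValueError("both groups need >= 2 replicates")
    la = np.log2(pm.abundance[ca])
    lb = np.log2(pm.abundance[cb])
    ok = (la.notna().sum(axis=1) >= 2) & (lb.notna().sum(axis=1) >= 2)
    excluded = int((~ok).sum())
    rows = []
    for prot in pm.abundance.index[ok]:
        va = la.loc[prot].dropna().values
        vb = lb.loc[prot].dropna().values
        lfc = float(vb.mean() - va.mean())
        _, p = _two_sample_t(va, vb, equal_var=equal_var)
        if np.isnan(p):  # zero variance in both groups, identical means
            p = 1.0
        rows.append((prot, pm.genes.get(prot), lfc, p))
    out = pd.DataFrame(rows, columns=["protein_id", "gene", "log2FC", "p_value"])
    out["neg_log10_p"] = -np.log10(out["p_value"])
    if len(out):
        out["p_adj_BH"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["p_adj_BH"] = []
    sig = out["p_value"] <= p_thr
    out["status"] = "not_significant"
    out.loc[sig & (out["log2FC"] >= lfc_cut), "status"] = "up"
    out.loc[sig & (out["log2FC"] <= -lfc_cut), "status"] = "down"
    out = out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    out.attrs["excluded_insufficient_replicates"] = excluded
    out.attrs["comparison"] = (group_a, group_b)
    out.attrs["thresholds"] = {"p": p_thr, "fc": fc_eff}
    return out


def protein_bar_stats(
    pm: ProteinMatrix,
    protein_or_gene: str,
    reference_group: str,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-group mean, sd and significance mark for one protein.

    Each non-reference group is tested against the reference with the same
    t-test the volcano uses; the mark is ``*`` when p <= alpha, otherwise
    ``n.s.``. The reference row carries no mark.
    """
    prot = pm.resolve(protein_or_gene)
    if reference_group not in pm.layout.group_order:
        raise ValueError(f"unknown reference group {reference_group!r}")
    ref = np.log2(pm.abundance.loc[prot, pm.group_columns(reference_group)]).dropna()
    rows = []
    for g in pm.layout.group_order:
        vals = pm.abundance.loc[prot, pm.group_columns(g)].dropna()
        mean = float(vals.mean()) if len(vals) else np.nan
        sd = float(vals.std(ddof=1)) if len(vals) >= 2 else np.nan
        if g == reference_group:
            mark = ""
        elif len(vals) >= 2 and len(ref) >= 2:
            _, p = _two_sample_t(ref.values, np.log2(vals.values), equal_var=equal_var)
            mark = "*" if (not np.isnan(p) and p <= alpha) else "n.s."
        else:
            mark = "n.s."
        rows.append({"group": g, "mean": mean, "sd": sd, "mark": mark})
    out = pd.DataFrame(rows)
    out.attrs["protein_id"] = prot
    return out


def impute_iterative(
    pm: ProteinMatrix, max_iter: int = 20, tol: float = 1e-3
) -> ProteinMatrix:
    """Fill missing abundances by chained-regression imputation on log2 scale.

    Each sample's column is iteratively regressed on the others until the
    largest update falls below ``tol`` (or ``max_iter`` sweeps); observed
    cells are never modified and the sweep order is fixed, so the result is
    deterministic. The returned matrix is complete on the proteins that had
    at least one observation.
    """
    ab = pm.abundance
    if ab.isna().all(axis=1).any():
        bad = list(ab.index[ab.isna().all(axis=1)])
        raise ValueError(f"cannot impute proteins with zero observations: {bad}")
    if ab.isna().all(axis=0).any():
        bad = list(ab.columns[ab.isna().all(axis=0)])
        raise ValueError(f"cannot impute samples with zero observations: {bad}")
    log = np.log2(ab.values)
    imp = IterativeImputer(
        max_iter=max_iter,
        tol=tol,
        imputation_order="roman",
        sample_posterior=False,
        random_state=0,
        keep_empty_features=True,
    )
    filled = np.exp2(imp.fit_transform(log))
    # observed cells are authoritative: restore them bit-for-bit
    mask = np.isnan(log)
    filled[~mask] = ab.values[~mask]
    out = pm.copy()
    out.abundance = pd.DataFrame(filled, index=ab.index, columns=ab.columns)
    # imputed cells keep a 0 unique-peptide count; downstream users can tell
    # imputed from observed through pm.unique_peptides
    return out


def heatmap_data(
    pm: ProteinMatrix,
    proteins: list[str] | None = None,
    by: str = "group",
    impute: bool = False,
    nd_marker: str = "n.d.",
) -> pd.DataFrame:
    """log2 abundance matrix for heatmap display.

    Selected-protein mode (``proteins`` given): no imputation, no
    clustering; missing cells carry ``n.d.``. Full-matrix mode with
    ``impute=True``: missing cells filled by :func:`impute_iterative`, rows
    ordered by hierarchical clustering (the same linkage the dendrogram
    uses) and columns in layout order.
    """
    if by not in ("group", "sample"):
        raise ValueError(f"by must be 'group' or 'sample', got {by!r}")
    if proteins is not None:
        if not proteins:
            raise ValueError("empty protein selection")
        idx = [pm.resolve(p) for p in proteins]
        mat = _collapse(pm, by).loc[idx]
        obj = mat.astype(object)
        return obj.where(mat.notna(), nd_marker)
    src = impute_iterative(pm) if impute else pm
    mat = _collapse(src, by)
    mat = mat.dropna()
    if len(mat) >= 3:
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import pdist

        z = hierarchy.linkage(pdist(mat.values), method="average")
        mat = mat.iloc[hierarchy.leaves_list(z)]
    return mat


def _collapse(pm: ProteinMatrix, by: str) -> pd.DataFrame:
    if by == "sample":
        return np.log2(pm.abundance)
    return pd.DataFrame(
        {
            g: np.log2(pm.abundance[pm.group_columns(g)]).mean(axis=1)
            for g in pm.layout.group_order
        }
    )


__all__ = [
    "rank_abundance",
    "volcano",
    "protein_bar_stats",
    "impute_iterative",
    "heatmap_data",
    "effective_fc_threshold",
]
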