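"""Peptide/protein yields, shared-vs-unique protein breakdown, and
exploratory structure (hierarchical clustering, group correlation matrix).

A protein counts as "present in a group" when it is observed (non-missing
after filtering) in at least one replicate of that group; group-level counts
are therefore unions over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import SampleLayout
from .preprocess import ProteinMatrix


@dataclass
class YieldSummary:
    per_sample: pd.DataFrame  # columns: sample, group, peptides, proteins
    per_group: pd.DataFrame  # columns: group, peptides, proteins


@dataclass
class SharedUniqueBreakdown:
    unique: dict[str, list[str]]  # group -> proteins present only in that group
    shared_pairs: pd.DataFrame  # group x group matrix of shared counts
    core: list[str]  # proteins present in every group
    presence: dict[str, set[str]]  # group -> full presence set


@dataclass
class LinkageTree:
    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]
    leaf_order: list[str]


def group_presence(pm: ProteinMatrix) -> dict[str, set[str]]:
    """Proteins observed in >= 1 replicate, per group."""
    out: dict[str, set[str]] = {}
    for g in pm.layout.group_order:
        cols = pm.group_columns(g)
        seen = pm.abundance[cols].notna().any(axis=1)
        out[g] = set(pm.abundance.index[seen])
    return out


def count_yields(pm: ProteinMatrix, qt: pd.DataFrame) -> YieldSummary:
    """Distinct peptide and protein counts per sample and per group (union)."""
    obs = qt[pd.to_numeric(qt["quantity"], errors="coerce") > 0]
    rows = []
    for e in pm.layout.entries:
        sub = obs[obs["sample"] == e.sample_name]
        prot = pm.abundance[e.sample_name].notna().sum() if e.sample_name in pm.abundance else 0
        rows.append(
            {
                "sample": e.sample_name,
                "group": e.group,
                "peptides": int(sub["stripped_seq"].nunique()),
                "proteins": int(prot),
            }
        )
    per_sample = pd.DataFrame(rows)
    presence = group_presence(pm)
    grows = []
    for g in pm.layout.group_order:
        sub = obs[obs["group"] == g]
        grows.append(
            {
                "group": g,
                "peptides": int(sub["stripped_seq"].nunique()),
                "proteins": len(presence[g]),
            }
        )
    return YieldSummary(per_sample=per_sample, per_group=pd.DataFrame(grows))


def shared_unique(pm: ProteinMatrix) -> SharedUniqueBreakdown:
    """Per-group unique proteins, pairwise shared counts and the core set
    (proteins detected in every group)."""
    groups = pm.layout.group_order
    if len(groups) < 2:
        raise ValueError("shared/unique breakdown requires >= 2 groups")
    presence = group_presence(pm)
    unique = {
        g: sorted(
            presence[g].difference(*(presence[h] for h in groups if h != g))
        )
        for g in groups
    }
    shared = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    for a, b in combinations(groups, 2):
        shared.at[a, b] = shared.at[b, a] = len(presence[a] & presence[b])
    for g in groups:
        shared.at[g, g] = len(presence[g])
    core = sorted(set.intersection(*(presence[g] for g in groups)))
    return SharedUniqueBreakdown(
        unique=unique, shared_pairs=shared, core=core, presence=presence
    )


def peptides_per_protein(
    qt: pd.DataFrame, protein_or_gene: str | None = None
) -> pd.DataFrame:
    """Distinct-peptide counts per protein.

    Without a query: one row per protein x group with its distinct stripped
    peptide count, plus the per-group median in ``df.attrs['medians']``.
    With a protein or gene query: per-sample peptide counts for that protein.
    """
    obs = qt[pd.to_numeric(qt["quantity"], errors="coerce") > 0]
    if protein_or_gene is None:
        counts = (
            obs.groupby(["group", "protein_id"])["stripped_seq"]
            .nunique()
            .rename("peptides")
            .reset_index()
        )
        counts.attrs["medians"] = {
            g: float(sub["peptides"].median())
            for g, sub in counts.groupby("group")
        }
        return counts
    q = protein_or_gene.upper()
    hit = obs[
        (obs["protein_id"].str.upper() == q) | (obs["gene"].str.upper() == q)
    ]
    if hit.empty:
        near = sorted(
            set(
                obs.loc[
                    obs["protein_id"].str.upper().str.contains(q, regex=False)
                    | obs["gene"].str.upper().str.contains(q, regex=False),
                    "gene",
                ]
            )
        )[:10]
        raise KeyError(f"unknown protein/gene {protein_or_gene!r}; near matches: {near}")
    return (
        hit.groupby(["sample", "group"])["stripped_seq"]
        .nunique()
        .rename("peptides")
        .reset_index()
    )


def _log2_profiles(pm: ProteinMatrix, on: str) -> pd.DataFrame:
    """log2 profiles over the complete-observation protein set; one column
    per leaf (group mean or sample)."""
    if on == "groups":
        cols = {}
        for g in pm.layout.group_order:
            cols[g] = np.log2(pm.abundance[pm.group_columns(g)]).mean(axis=1)
        mat = pd.DataFrame(cols)
    elif on == "samples":
        mat = np.log2(pm.abundance)
    else:
        raise ValueError(f"on must be 'groups' or 'samples', got {on!r}")
    return mat.dropna()


def dendrogram(
    pm: ProteinMatrix,
    on: str = "groups",
    metric: str = "euclidean",
    method: str = "average",
) -> LinkageTree:
    """Agglomerative clustering of log2 abundance profiles.

    Leaves are experimental groups (log2 group-mean profiles) or samples;
    only proteins observed in every leaf enter the distance computation.
    Defaults: Euclidean distance, average linkage.
    """
    mat = _log2_profiles(pm, on)
    labels = list(mat.columns)
    if len(labels) < 3:
        raise ValueError(f"dendrogram requires >= 3 leaves, got {len(labels)}")
    z = hierarchy.linkage(pdist(mat.T.values, metric=metric), method=method)
    order = [labels[i] for i in hierarchy.leaves_list(z)]
    return LinkageTree(linkage=z, labels=labels, leaf_order=order)


def group_correlation_matrix(pm: ProteinMatrix) -> pd.DataFrame:
    """Pairwise Spearman correlation of group-mean log2 abundances,
    pairwise-complete over proteins."""
    groups = pm.layout.group_order
    if len(groups) < 2:
        raise ValueError("correlation matrix requires >= 2 groups")
    means = pd.DataFrame(
        {g: np.log2(pm.abundance[pm.group_columns(g)]).mean(axis=1) for g in groups}
    )
    rho = pd.DataFrame(np.eye(len(groups)), index=groups, columns=groups)
    for a, b in combinations(groups, 2):
        pair = means[[a, b]].dropna()
        r = stats.spearmanr(pair[a], pair[b]).statistic if len(pair) >= 3 else np.nan
        rho.at[a, b] = rho.at[b, a] = r
    return rho
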