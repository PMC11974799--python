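"""Peptide/protein filters and peptide-to-protein rollup.

The filters implement the standard guards for discovery DIA data: drop
non-proteotypic peptides, drop peptides assigned to more than one protein
group, and require a minimum number of unique peptides per protein.
Rollup turns the long peptide x run table into a protein x sample matrix.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SampleLayout

_MULTI_ID_SPLIT = re.compile(r"[;,\s]+")


@dataclass
class ProteinMatrix:
    """Protein x sample abundance matrix with missingness preserved.

    ``abundance`` holds per-sample protein quantities (NaN = not detected);
    ``unique_peptides`` the count of distinct stripped sequences backing each
    cell. A cell is missing exactly when its unique-peptide count is 0, and
    every present abundance is strictly positive (zero intensities are
    treated as not-detected upstream).
    """

    abundance: pd.DataFrame  # index: protein_id, columns: sample names
    unique_peptides: pd.DataFrame  # same shape, int
    genes: pd.Series  # protein_id -> gene symbol
    layout: SampleLayout
    filter_report: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["protein", "reason", "samples_affected"])
    )

    def __post_init__(self) -> None:
        if not self.abundance.index.equals(self.unique_peptides.index) or not (
            self.abundance.columns.equals(self.unique_peptides.columns)
        ):
            raise ValueError("abundance and unique_peptides must be aligned")

    @property
    def proteins(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)

    def group_columns(self, group: str) -> list[str]:
        return [s for s in self.layout.samples_in_group(group) if s in self.abundance.columns]

    def resolve(self, protein_or_gene: str) -> str:
        """Resolve a protein accession or gene symbol to a protein_id."""
        if protein_or_gene in self.abundance.index:
            return protein_or_gene
        hits = self.genes[self.genes.str.upper() == protein_or_gene.upper()]
        if len(hits) == 1:
            return str(hits.index[0])
        if len(hits) > 1:
            raise KeyError(
                f"{protein_or_gene!r} matches multiple proteins: {list(hits.index)}"
            )
        near = [
            p
            for p in list(self.abundance.index) + list(self.genes.unique())
            if protein_or_gene.upper() in str(p).upper()
        ][:10]
        raise KeyError(f"unknown protein/gene {protein_or_gene!r}; near matches: {near}")

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(
            abundance=self.abundance.copy(),
            unique_peptides=self.unique_peptides.copy(),
            genes=self.genes.copy(),
            layout=self.layout,
            filter_report=self.filter_report.copy(),
        )


def filter_proteotypic(qt: pd.DataFrame) -> pd.DataFrame:
    """Keep only proteotypic peptides (those mapping to a single protein group).

    When the export carries no proteotypic flag (Skyline path) this is a
    no-op with a warning.
    """
    if "proteotypic" not in qt.columns or qt["proteotypic"].isna().all():
        warnings.warn("no proteotypic flag column; filter skipped", stacklevel=2)
        return qt
    out = qt[qt["proteotypic"].astype(bool)].reset_index(drop=True)
    removed = len(qt) - len(out)
    if removed == len(qt):
        warnings.warn("all rows were non-proteotypic; table is empty", stacklevel=2)
    out.attrs["rows_removed_proteotypic"] = removed
    return out


def is_multi_protein(ids: pd.Series) -> pd.Series:
    """True where a protein_id field contains more than one accession."""
    return ids.astype(str).str.strip().apply(
        lambda s: len([t for t in _MULTI_ID_SPLIT.split(s) if t]) > 1
    )


def filter_multi_protein(qt: pd.DataFrame) -> pd.DataFrame:
    """Drop peptides assigned to multiple protein accessions (``;``, ``,`` or
    whitespace separated)."""
    multi = is_multi_protein(qt["protein_id"])
    out = qt[~multi].reset_index(drop=True)
    out.attrs["rows_removed_multi_protein"] = int(multi.sum())
    return out


def rollup_protein(
    qt: pd.DataFrame,
    layout: SampleLayout,
    method: str = "sum",
) -> ProteinMatrix:
    """Roll the long peptide table up to a protein x sample matrix.

    method='sum' (default for Skyline exports) sums peptide quantities per
    protein and sample; method='median' takes the median;
    method='maxlfq_passthrough' (DIA-NN) takes the tool's own per-run
    protein-group quantity (``protein_quantity`` column) instead of
    recomputing one. Unique-peptide counts are distinct stripped sequences
    with a present quantity. Zero quantities count as missing.
    """
    if method not in ("sum", "median", "maxlfq_passthrough"):
        raise ValueError(f"unknown rollup method {method!r}")
    df = qt.copy()
    df["quantity"] = pd.to_numeric(df["quantity"], errors="coerce")
    df.loc[df["quantity"] <= 0, "quantity"] = np.nan
    observed = df[df["quantity"].notna()]

    samples = layout.samples
    universe = pd.Index(pd.unique(df["protein_id"]), name="protein_id")
    upep = (
        observed.groupby(["protein_id", "sample"])["stripped_seq"]
        .nunique()
        .unstack(fill_value=0)
        .reindex(index=universe, columns=samples, fill_value=0)
        .fillna(0)
    )

    if method == "maxlfq_passthrough":
        if "protein_quantity" not in df.columns:
            raise ValueError(
                "maxlfq_passthrough requires a protein_quantity column "
                "(per-run protein-group quantity from the upstream tool)"
            )
        pq = observed[observed["protein_quantity"].notna()]
        spread = pq.groupby(["protein_id", "sample"])["protein_quantity"].agg(["min", "max"])
        bad = spread[
            (spread["max"] - spread["min"])
            > 1e-6 * spread["max"].abs().clip(lower=1.0)
        ]
        if not bad.empty:
            raise ValueError(
                "disagreeing protein-group quantities within a run for: "
                f"{sorted({p for p, _ in bad.index})}"
            )
        ab = pq.groupby(["protein_id", "sample"])["protein_quantity"].first().unstack()
    else:
        agg = "sum" if method == "sum" else "median"
        ab = observed.groupby(["protein_id", "sample"])["quantity"].agg(agg).unstack()

    ab = ab.reindex(index=upep.index, columns=samples)
    ab = ab.where(upep > 0)
    genes = df.groupby("protein_id")["gene"].first().reindex(upep.index)
    return ProteinMatrix(
        abundance=ab.astype(float),
        unique_peptides=upep.astype(int),
        genes=genes,
        layout=layout,
    )


def filter_min_unique_peptides(
    pm: ProteinMatrix, n: int, scope: str = "per_sample"
) -> ProteinMatrix:
    """Require at least ``n`` unique peptides behind each protein quantity.

    scope='per_sample' (default; the threshold is applied to every sample)
    masks individual cells backed by fewer than ``n`` peptides.
    scope='global' drops a protein entirely unless some sample reaches ``n``.
    A report of removed proteins/cells is attached to the returned matrix.
    """
    if n < 1:
        raise ValueError(f"minimum unique-peptide threshold must be >= 1, got {n}")
    if scope not in ("per_sample", "global"):
        raise ValueError(f"unknown scope {scope!r}")
    out = pm.copy()
    records = []
    if scope == "per_sample":
        mask = out.unique_peptides >= n
        for prot in out.abundance.index:
            lost = [
                s
                for s in out.samples
                if not mask.at[prot, s] and pd.notna(out.abundance.at[prot, s])
            ]
            if lost:
                records.append(
                    {
                        "protein": prot,
                        "reason": f"unique peptides < {n}",
                        "samples_affected": ";".join(lost),
                    }
                )
        out.abundance = out.abundance.where(mask)
        out.unique_peptides = out.unique_peptides.where(mask, 0).astype(int)
    else:
        keep = out.unique_peptides.max(axis=1) >= n
        for prot in out.abundance.index[~keep]:
            records.append(
                {"protein": prot, "reason": f"max unique peptides < {n}", "samples_affected": "all"}
            )
        out.abundance = out.abundance[keep]
        out.unique_peptides = out.unique_peptides[keep]
        out.genes = out.genes[keep]
    report = pd.DataFrame(records, columns=["protein", "reason", "samples_affected"])
    out.filter_report = pd.concat([out.filter_report, report], ignore_index=True)
    return out
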