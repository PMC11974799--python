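"""Peptide-to-sequence matching and offline gene -> UniProt ID mapping.

``match_peptides`` counts detected peptides that are exact contiguous
substrings of a user-supplied amino-acid sequence (e.g. a protein domain),
per sample and per experimental group. ``map_gene_ids`` resolves gene
symbols to accessions through a local two-column mapping table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

_MOD_TAG = re.compile(r"\([^()]*\)|\[[^\[\]]*\]")
_AA = re.compile(r"^[A-Z]+$")


def strip_modifications(seq: str) -> str:
    """Remove bracketed/parenthesized modification tags from a peptide string.

    Idempotent; nested tags are removed by repeated stripping.
    """
    prev = None
    out = str(seq)
    while prev != out:
        prev = out
        out = _MOD_TAG.sub("", out)
    return out.upper()


@dataclass
class PepSeqReport:
    query: str
    per_sample: dict[str, list[str]] = field(default_factory=dict)
    per_group: dict[str, list[str]] = field(default_factory=dict)

    @property
    def counts(self) -> pd.DataFrame:
        rows = [
            {"scope": "sample", "name": s, "matches": len(v)}
            for s, v in self.per_sample.items()
        ] + [
            {"scope": "group", "name": g, "matches": len(v)}
            for g, v in self.per_group.items()
        ]
        return pd.DataFrame(rows, columns=["scope", "name", "matches"])

    def tabs(self) -> dict[str, pd.DataFrame]:
        """One tab per sample and group for the XLSX report."""
        out = {}
        for s, v in self.per_sample.items():
            out[f"sample_{s}"] = pd.DataFrame({"peptide": v})
        for g, v in self.per_group.items():
            out[f"group_{g}"] = pd.DataFrame({"peptide": v})
        return out


def match_peptides(qt: pd.DataFrame, query: str) -> PepSeqReport:
    """Detected peptides that are substrings of ``query``.

    Modification tags are stripped before the substring test; each distinct
    stripped sequence counts once per sample (and once per group).
    """
    q = str(query).strip().upper()
    if not _AA.match(q) or len(q) < 5:
        raise ValueError(
            "query must be plain amino-acid letters [A-Z], length >= 5"
        )
    df = qt.copy()
    df["_stripped"] = df["peptide_seq" if "peptide_seq" in df else "stripped_seq"].map(
        strip_modifications
    )
    df = df[df["_stripped"].str.len() > 0]
    df = df[df["_stripped"].map(lambda s: s in q)]
    report = PepSeqReport(query=q)
    for s in sorted(qt["sample"].unique()):
        report.per_sample[s] = sorted(df.loc[df["sample"] == s, "_stripped"].unique())
    for g in qt["group"].unique():
        report.per_group[g] = sorted(df.loc[df["group"] == g, "_stripped"].unique())
    return report


def read_gene_map(path: str | Path) -> pd.DataFrame:
    """Two-column TSV (gene, accession); extra columns ignored."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: gene map needs >= 2 columns (gene, accession)")
    df = df.iloc[:, :2]
    df.columns = ["gene", "accession"]
    return df


def map_gene_ids(
    genes: list[str], mapping: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Case-insensitive exact match of gene symbols to accessions.

    Returns (mapped table with one row per gene x accession, unmapped genes).
    Genes with several accessions yield all of them.
    """
    if not genes:
        raise ValueError("empty gene list")
    m = mapping.copy()
    m["_key"] = m["gene"].astype(str).str.upper()
    lut: dict[str, list[str]] = {
        k: sorted(sub["accession"].astype(str).unique())
        for k, sub in m.groupby("_key")
    }
    rows, unmapped = [], []
    for g in genes:
        accs = lut.get(str(g).upper())
        if accs:
            rows.extend({"gene": g, "accession": a} for a in accs)
        else:
            unmapped.append(g)
    return pd.DataFrame(rows, columns=["gene", "accession"]), unmapped
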