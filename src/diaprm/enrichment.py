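"""Offline over-representation analysis against GMT gene-set collections.

One-sided Fisher exact test (hypergeometric upper tail) per set, restricted
to the experiment's background (all quantified proteins by default — the
standard guard against detection bias), with Benjamini-Hochberg adjustment
within each namespace. Gene sets come from local GMT files (pathway-style
or GO-style), never from live services.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

VALID_NAMESPACES = ("pathway", "MF", "CC", "BP")


@dataclass
class AnnotationSets:
    """Named gene sets: set_id -> (name, namespace, member genes)."""

    sets: dict[str, tuple[str, str, frozenset[str]]] = field(default_factory=dict)

    def add(self, set_id: str, name: str, namespace: str, members) -> None:
        if set_id in self.sets:
            raise ValueError(f"duplicate set id {set_id!r}")
        mem = frozenset(str(m).upper() for m in members if str(m).strip())
        if not mem:
            raise ValueError(f"gene set {set_id!r} has no members")
        if namespace not in VALID_NAMESPACES:
            raise ValueError(f"namespace must be one of {VALID_NAMESPACES}")
        self.sets[set_id] = (name, namespace, mem)

    def __len__(self) -> int:
        return len(self.sets)


def overrepresentation_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Hypergeometric upper-tail P(X >= k) for an overlap of k query genes
    with a K-member set, query size n, background size N."""
    return float(min(stats.hypergeom.sf(k - 1, N, K, n), 1.0))


def read_gmt(path: str | Path, namespace: str = "pathway") -> AnnotationSets:
    """Parse a GMT file (tab-separated: set id, description, members...)."""
    out = AnnotationSets()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            out.add(parts[0], parts[1] or parts[0], namespace, parts[2:])
    return out


def enrich(
    query: list[str],
    background: list[str],
    sets: AnnotationSets,
    namespace: str | None = None,
) -> pd.DataFrame:
    """Over-representation of ``query`` genes within each annotation set.

    Per set S restricted to the background: with N = |background|,
    K = |S ∩ background|, n = |query| and k = |query ∩ S|, the p-value is
    the hypergeometric upper tail P(X >= k). BH adjustment is applied
    within each namespace; rows come back sorted by raw p.
    """
    bg = {str(g).upper() for g in background}
    q = {str(g).upper() for g in query}
    if not q <= bg:
        extra = sorted(q - bg)[:10]
        raise ValueError(f"query genes not in background: {extra}")
    n, N = len(q), len(bg)
    rows = []
    for set_id, (name, ns, members) in sets.sets.items():
        if namespace is not None and ns != namespace:
            continue
        in_bg = members & bg
        K = len(in_bg)
        if K == 0:
            continue
        overlap = sorted(q & in_bg)
        k = len(overlap)
        p = overrepresentation_pvalue(k, N, K, n)
        rows.append(
            {
                "set_id": set_id,
                "set_name": name,
                "namespace": ns,
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "background_size": N,
                "p_value": min(p, 1.0),
                "genes": ";".join(overlap),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "set_id",
            "set_name",
            "namespace",
            "overlap",
            "set_size",
            "query_size",
            "background_size",
            "p_value",
            "genes",
        ],
    )
    if len(out):
        out["p_adj_BH"] = 1.0
        for ns, idx in out.groupby("namespace").groups.items():
            out.loc[idx, "p_adj_BH"] = multipletests(
                out.loc[idx, "p_value"], method="fdr_bh"
            )[1]
        out = out.sort_values(
            ["p_value", "set_id"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        out["p_adj_BH"] = []
    return out
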