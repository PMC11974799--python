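"""Readers and writers for the external file dialects.

Two quantification exports are supported: the DIA-NN long-format report
(tab-separated, one row per precursor x run) and Skyline transition-level
exports (comma-separated), the latter in three flavours: DIA, label-free
PRM and heavy-label (stable isotope dilution) PRM.

Quantification tables are represented as plain :class:`pandas.DataFrame`
objects with a canonical column set (see :data:`QUANT_COLUMNS` and
:data:`PRM_COLUMNS`); the sample layout maps instrument run identifiers to
sample names, experimental groups and replicate indices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file does not match the expected dialect."""


#: canonical columns of a quantification table (peptide/precursor level)
QUANT_COLUMNS = [
    "protein_id",
    "gene",
    "peptide_seq",
    "stripped_seq",
    "proteotypic",
    "run_id",
    "sample",
    "group",
    "replicate",
    "quantity",
    "points_across_peak",
    "ms_level",
]

#: canonical columns of a paired light/heavy PRM table
PRM_COLUMNS = [
    "protein_id",
    "gene",
    "stripped_seq",
    "run_id",
    "sample",
    "group",
    "replicate",
    "light_area",
    "heavy_area",
]

#: default DIA-NN report column names (overridable via ``columns=``)
DIANN_COLUMNS = {
    "protein_id": "Protein.Group",
    "gene": "Genes",
    "peptide_seq": "Modified.Sequence",
    "stripped_seq": "Stripped.Sequence",
    "proteotypic": "Proteotypic",
    "run": "Run",
    "quantity": "Precursor.Quantity",
    "protein_quantity": "PG.MaxLFQ",  # optional, used by MaxLFQ passthrough
}

#: default Skyline export column names (overridable via ``columns=``)
SKYLINE_COLUMNS = {
    "protein_id": "Protein",
    "gene": "Protein Gene",  # optional
    "peptide": "Peptide",
    "run": "Replicate Name",
    "quantity": "Total Area Fragment",
    "points": "Points Across Peak",  # optional
    "label": "Isotope Label Type",  # PRM heavy-label mode
}


@dataclass(frozen=True)
class LayoutEntry:
    run_id: str
    sample_name: str
    group: str
    replicate: int


@dataclass
class SampleLayout:
    """Mapping from raw run identifiers to (sample, group, replicate).

    ``group_order`` fixes the display order of experimental groups in every
    table and plot downstream.
    """

    entries: list[LayoutEntry]
    group_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("layout has no entries")
        runs = [e.run_id for e in self.entries]
        if len(set(runs)) != len(runs):
            raise ValueError("run_ids in layout are not unique")
        pairs = [(e.group, e.replicate) for e in self.entries]
        if len(set(pairs)) != len(pairs):
            raise ValueError("(group, replicate) pairs in layout are not unique")
        for e in self.entries:
            if e.replicate < 1:
                raise ValueError(f"replicate index must be >= 1, got {e.replicate}")
        groups_seen = []
        for e in self.entries:
            if e.group not in groups_seen:
                groups_seen.append(e.group)
        if not self.group_order:
            self.group_order = groups_seen
        if set(self.group_order) != set(groups_seen):
            raise ValueError(
                "group_order and layout groups disagree: "
                f"{sorted(set(self.group_order) ^ set(groups_seen))}"
            )

    # -- convenience accessors -------------------------------------------------
    @property
    def run_ids(self) -> list[str]:
        return [e.run_id for e in self.entries]

    @property
    def samples(self) -> list[str]:
        """Sample names in group_order, replicates ascending within a group."""
        out = []
        for g in self.group_order:
            members = sorted(
                (e for e in self.entries if e.group == g), key=lambda e: e.replicate
            )
            out.extend(e.sample_name for e in members)
        return out

    def samples_in_group(self, group: str) -> list[str]:
        if group not in self.group_order:
            raise ValueError(f"unknown group {group!r}; known: {self.group_order}")
        members = sorted(
            (e for e in self.entries if e.group == group), key=lambda e: e.replicate
        )
        return [e.sample_name for e in members]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run_id": [e.run_id for e in self.entries],
                "sample": [e.sample_name for e in self.entries],
                "group": [e.group for e in self.entries],
                "replicate": [e.replicate for e in self.entries],
            }
        )

    @classmethod
    def from_dict(cls, d: dict) -> "SampleLayout":
        entries = [
            LayoutEntry(
                run_id=str(r["run"]),
                sample_name=str(r.get("sample", r["run"])),
                group=str(r["group"]),
                replicate=int(r["replicate"]),
            )
            for r in d["runs"]
        ]
        return cls(entries=entries, group_order=[str(g) for g in d.get("group_order", [])])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SampleLayout":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "group_order": list(self.group_order),
            "runs": [
                {
                    "run": e.run_id,
                    "sample": e.sample_name,
                    "group": e.group,
                    "replicate": e.replicate,
                }
                for e in self.entries
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _require_columns(df: pd.DataFrame, required: dict[str, str], path) -> None:
    missing = [v for v in required.values() if v not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")


def _apply_layout(df: pd.DataFrame, layout: SampleLayout, run_col: str) -> pd.DataFrame:
    """Rename runs per layout and drop rows whose run is not in the layout."""
    lf = layout.frame()
    before = len(df)
    out = df.merge(lf, left_on=run_col, right_on="run_id", how="inner")
    dropped = before - len(out)
    if dropped:
        logger.info("dropped %d rows from runs absent from the layout", dropped)
    out.attrs["rows_dropped_by_layout"] = dropped
    return out


def read_diann_report(
    path: str | Path,
    layout: SampleLayout,
    columns: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a DIA-NN long-format report into a canonical quantification table.

    Parameters
    ----------
    path : path to the tab-separated report
    layout : sample layout; rows from runs absent from it are dropped
    columns : optional overrides of :data:`DIANN_COLUMNS`

    Returns
    -------
    DataFrame with :data:`QUANT_COLUMNS` (plus ``protein_quantity`` when the
    report carries a per-run protein-group quantity), one row per
    precursor x run. ``df.attrs['rows_dropped_by_layout']`` holds the count of
    rows removed by layout filtering.
    """
    cols = {**DIANN_COLUMNS, **(columns or {})}
    try:
        raw = pd.read_csv(path, sep="\t", encoding="utf-8", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if raw.empty:
        raise FormatError(f"{path}: no data rows")
    mandatory = {k: v for k, v in cols.items() if k != "protein_quantity"}
    _require_columns(raw, mandatory, path)

    df = pd.DataFrame(
        {
            "protein_id": raw[cols["protein_id"]].astype(str),
            "gene": raw[cols["gene"]].astype(str),
            "peptide_seq": raw[cols["peptide_seq"]].astype(str),
            "stripped_seq": raw[cols["stripped_seq"]].astype(str),
            "proteotypic": raw[cols["proteotypic"]].astype(int).astype(bool),
            "quantity": pd.to_numeric(raw[cols["quantity"]], errors="raise"),
            "points_across_peak": pd.NA,
            "ms_level": 2,
        }
    )
    df["_run"] = raw[cols["run"]].astype(str)
    if cols.get("protein_quantity") in raw.columns:
        df["protein_quantity"] = pd.to_numeric(raw[cols["protein_quantity"]])
    if (df["quantity"].dropna() < 0).any():
        raise FormatError(f"{path}: negative quantities")
    df = _apply_layout(df, layout, "_run").drop(columns="_run")
    order = [c for c in QUANT_COLUMNS if c in df.columns] + [
        c for c in ("protein_quantity",) if c in df.columns
    ]
    return df[order + [c for c in df.columns if c not in order]].reset_index(drop=True)


def read_skyline_table(
    path: str | Path,
    layout: SampleLayout,
    mode: str = "dia",
    columns: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a Skyline CSV export.

    ``mode='dia'`` and ``mode='prm_free'`` return a quantification table
    (:data:`QUANT_COLUMNS`); ``mode='prm_heavy'`` joins light and heavy rows
    of the same peptide x run into one row of :data:`PRM_COLUMNS`.
    Orphan light rows (no heavy partner) are excluded with a warning;
    the count is in ``df.attrs['orphan_rows_excluded']``.
    """
    if mode not in ("dia", "prm_free", "prm_heavy"):
        raise ValueError(f"unknown mode {mode!r}")
    cols = {**SKYLINE_COLUMNS, **(columns or {})}
    try:
        raw = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if raw.empty:
        raise FormatError(f"{path}: no data rows")
    mandatory = {k: cols[k] for k in ("protein_id", "peptide", "run", "quantity")}
    _require_columns(raw, mandatory, path)

    gene = (
        raw[cols["gene"]].astype(str)
        if cols.get("gene") in raw.columns
        else raw[cols["protein_id"]].astype(str)
    )
    base = pd.DataFrame(
        {
            "protein_id": raw[cols["protein_id"]].astype(str),
            "gene": gene,
            "stripped_seq": raw[cols["peptide"]].astype(str).str.upper(),
            "quantity": pd.to_numeric(raw[cols["quantity"]], errors="coerce"),
            "_run": raw[cols["run"]].astype(str),
        }
    )
    base["peptide_seq"] = raw[cols["peptide"]].astype(str)
    if cols.get("points") in raw.columns:
        base["points_across_peak"] = pd.to_numeric(raw[cols["points"]], errors="coerce")
    else:
        base["points_across_peak"] = pd.NA

    if mode in ("dia", "prm_free"):
        df = base.copy()
        df["proteotypic"] = True
        df["ms_level"] = 2
        df = _apply_layout(df, layout, "_run").drop(columns="_run")
        return df[[c for c in QUANT_COLUMNS if c in df.columns]].reset_index(drop=True)

    # prm_heavy: pair light and heavy areas per peptide x run
    if cols["label"] not in raw.columns:
        raise FormatError(f"{path}: missing mandatory column(s) ['{cols['label']}']")
    base["label"] = raw[cols["label"]].astype(str).str.lower()
    if not (base["label"] == "heavy").any():
        raise FormatError(f"{path}: heavy-label mode but no heavy rows present")
    keys = ["protein_id", "gene", "stripped_seq", "_run"]
    light = base[base["label"] == "light"].set_index(keys)["quantity"]
    heavy = base[base["label"] == "heavy"].set_index(keys)["quantity"]
    joined = pd.DataFrame({"light_area": light, "heavy_area": heavy})
    orphans = int(joined["heavy_area"].isna().sum())
    if orphans:
        warnings.warn(
            f"{orphans} light row(s) without a heavy partner excluded", stacklevel=2
        )
        joined = joined[joined["heavy_area"].notna()]
    joined = joined[joined["light_area"].notna()]
    df = joined.reset_index()
    df = _apply_layout(df, layout, "_run").drop(columns="_run")
    df.attrs["orphan_rows_excluded"] = orphans
    return df[PRM_COLUMNS].reset_index(drop=True)


# --------------------------------------------------------------------------
# output folder contract
# --------------------------------------------------------------------------

TABLES_DIR = "TABLES"
PLOTS_DIR = "PLOTS"
SHARED_UNIQUE_SUBDIR = "SHARED_UNIQUE_PROTEINS"
VOLCANO_SUBDIR = "VOLCANO_PLOT_VALUES"


@dataclass
class OutputManifest:
    """Record of every artifact a run materialized on disk."""

    root: Path
    tables: list[Path] = field(default_factory=list)
    plots: list[Path] = field(default_factory=list)

    def validate(self) -> None:
        for p in self.tables + self.plots:
            if not p.exists():
                raise FileNotFoundError(f"manifest artifact missing on disk: {p}")

    @property
    def paths(self) -> list[Path]:
        return list(self.tables) + list(self.plots)


class OutputWriter:
    """Materialize tables (CSV/XLSX) and 300-dpi TIFF plots under a run root.

    Tables go under ``TABLES/`` (volcano lists under
    ``TABLES/VOLCANO_PLOT_VALUES/``, shared/unique protein lists under
    ``TABLES/SHARED_UNIQUE_PROTEINS/``); every figure is written to
    ``PLOTS/`` as TIFF at 300 dpi.
    """

    def __init__(self, root: str | Path):
        self.root = Path(root)
        try:
            (self.root / TABLES_DIR).mkdir(parents=True, exist_ok=True)
            (self.root / PLOTS_DIR).mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise OSError(f"output root not writable: {self.root}") from exc
        self.manifest = OutputManifest(root=self.root)

    def table_path(self, name: str, subfolder: str | None = None) -> Path:
        d = self.root / TABLES_DIR
        if subfolder:
            d = d / subfolder
            d.mkdir(parents=True, exist_ok=True)
        return d / name

    def write_table(
        self, df: pd.DataFrame, name: str, subfolder: str | None = None, index: bool = False
    ) -> Path:
        path = self.table_path(name, subfolder)
        if name.endswith(".xlsx"):
            df.to_excel(path, index=index)
        else:
            df.to_csv(path, index=index)
        self.manifest.tables.append(path)
        return path

    def write_excel_tabs(self, frames: dict[str, pd.DataFrame], name: str) -> Path:
        path = self.table_path(name)
        with pd.ExcelWriter(path, engine="openpyxl") as xl:
            for tab, df in frames.items():
                df.to_excel(xl, sheet_name=tab[:31], index=False)
        self.manifest.tables.append(path)
        return path

    def save_figure(self, fig, name: str) -> Path:
        if not name.endswith((".tif", ".tiff")):
            name += ".tiff"
        path = self.root / PLOTS_DIR / name
        fig.savefig(path, format="tiff", dpi=300)
        import matplotlib.pyplot as plt

        plt.close(fig)
        self.manifest.plots.append(path)
        return path
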