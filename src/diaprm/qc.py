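"""Quality-control metrics for replicate reproducibility.

Three metrics: the per-protein coefficient of variation across replicates of
each experimental group (CV% = 100 * sd / mean, sample sd), Spearman rank
correlation between replicate pairs, and the distribution of MS points
sampled across each chromatographic peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleLayout
from .preprocess import ProteinMatrix


@dataclass
class CvResult:
    """Per-group protein-level CV values (%) and group medians."""

    per_protein: dict[str, pd.Series]  # group -> CV% indexed by protein_id
    medians: dict[str, float]

    def table(self) -> pd.DataFrame:
        frames = []
        for g, s in self.per_protein.items():
            frames.append(pd.DataFrame({"protein_id": s.index, "group": g, "cv_percent": s.values}))
        if not frames:
            return pd.DataFrame(columns=["protein_id", "group", "cv_percent"])
        return pd.concat(frames, ignore_index=True)


@dataclass
class CorrelationResult:
    group: str
    rho: pd.DataFrame  # replicate-pair matrix of Spearman coefficients
    scatter: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)


@dataclass
class PointsResult:
    per_group: dict[str, pd.Series]  # group -> points values (one per peptide x run)
    medians: dict[str, float]


def compute_cv(pm: ProteinMatrix, layout: SampleLayout | None = None) -> CvResult:
    """Coefficient of variation across replicates, per protein per group.

    CV = 100 * sd / mean on the raw abundance scale, with the sample (n-1)
    standard deviation. A protein contributes to a group only when observed
    in at least two of its replicates; groups with a single replicate are
    skipped with a warning.
    """
    layout = layout or pm.layout
    per_protein: dict[str, pd.Series] = {}
    medians: dict[str, float] = {}
    for g in layout.group_order:
        cols = [s for s in layout.samples_in_group(g) if s in pm.abundance.columns]
        if len(cols) < 2:
            warnings.warn(f"group {g!r} has < 2 replicates; skipped", stacklevel=2)
            continue
        sub = pm.abundance[cols]
        nobs = sub.notna().sum(axis=1)
        sub = sub[nobs >= 2]
        cv = 100.0 * sub.std(axis=1, ddof=1) / sub.mean(axis=1)
        cv = cv.dropna()
        per_protein[g] = cv
        medians[g] = float(cv.median()) if len(cv) else float("nan")
    return CvResult(per_protein=per_protein, medians=medians)


def replicate_correlation(pm: ProteinMatrix, group: str) -> CorrelationResult:
    """Spearman rank correlation between every replicate pair of a group.

    Computed pairwise-complete: only proteins observed in both members of a
    pair enter the rank correlation. Fewer than 3 shared proteins yields a
    missing coefficient with a warning. Ties take average ranks.
    """
    cols = pm.group_columns(group)
    if len(cols) < 2:
        raise ValueError(f"group {group!r} has < 2 replicates")
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    scatter: dict[tuple[str, str], pd.DataFrame] = {}
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            pair = pm.abundance[[a, b]].dropna()
            if len(pair) < 3:
                warnings.warn(
                    f"< 3 shared proteins between {a} and {b}; rho missing", stacklevel=2
                )
                r = np.nan
            else:
                r = stats.spearmanr(pair[a], pair[b]).statistic
            rho.at[a, b] = rho.at[b, a] = r
            scatter[(a, b)] = pair
    return CorrelationResult(group=group, rho=rho, scatter=scatter)


def ms_points_distribution(
    qt: pd.DataFrame, layout: SampleLayout, level: int = 2
) -> PointsResult:
    """Distribution and median of MS points across chromatographic peaks,
    per experimental group, at the requested MS level (2 by default)."""
    if level not in (1, 2):
        raise ValueError("MS level must be 1 or 2")
    if "points_across_peak" not in qt.columns or qt["points_across_peak"].isna().all():
        raise ValueError(
            "points-across-peak unavailable: export lacks a 'Points Across Peak' column"
        )
    df = qt[qt.get("ms_level", 2) == level] if "ms_level" in qt.columns else qt
    df = df[pd.to_numeric(df["points_across_peak"], errors="coerce").notna()]
    per_group: dict[str, pd.Series] = {}
    medians: dict[str, float] = {}
    for g in layout.group_order:
        vals = pd.to_numeric(
            df.loc[df["group"] == g, "points_across_peak"], errors="coerce"
        ).dropna()
        per_group[g] = vals.reset_index(drop=True)
        medians[g] = float(vals.median()) if len(vals) else float("nan")
    return PointsResult(per_group=per_group, medians=medians)
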