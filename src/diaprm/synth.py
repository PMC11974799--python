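"""Synthetic fixture generation with planted ground truth.

Emits files in the three supported input dialects (DIA-NN report,
Skyline DIA export, Skyline heavy-label PRM export) from a fully specified
generative model, so every downstream operation can be tested against known
truth without touching deposited data.

Generative model (DIA): each protein gets a base log2 abundance per group;
planted differential proteins carry a fold change in the designated
"perturbed" group(s). Replicate abundances multiply the group value by
lognormal noise at the planted CV; peptide quantities split the replicate
abundance by fixed per-peptide shares, so the planted CV is realized at the
protein level after sum rollup. Missingness removes peptide rows at random
(or preferentially at low intensity). Defaults mirror a two-replicate
multi-time-point nuclear-proteome study design with ~10% replicate CV.

Generative model (PRM): true copies/nucleus per protein x group are pushed
through the inverse of the spike-in conversion to a true light/heavy ratio,
perturbed per peptide x replicate by multiplicative ratio noise, and paired
with arbitrary positive heavy areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import LayoutEntry, SampleLayout
from .prm import AbsQuantParams

DEFAULT_GROUPS = ("D0", "D2", "D4", "D6", "D8", "D10", "D11", "D12", "D14")


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study.

    replicate_cv is a percent CV of the multiplicative replicate noise;
    sigma_log2, when given, overrides it as a log2-scale replicate sd.
    The planted differential subset (n_de proteins, fold_change) perturbs
    ``de_group`` (last group by default) relative to all others.
    """

    groups: tuple[str, ...] = DEFAULT_GROUPS
    replicates: int = 2
    n_proteins: int = 200
    n_de: int = 0
    fold_change: float = 4.0
    de_group: str | None = None
    peptides_per_protein: tuple[int, int] = (2, 8)
    base_log2_mean: float = 17.0
    base_log2_sd: float = 2.0
    replicate_cv: float = 10.0
    sigma_log2: float | None = None
    missing_rate: float = 0.0
    missing_mechanism: str = "random"  # or "left_censored"
    frac_nonproteotypic: float = 0.05
    frac_multi_id: float = 0.05
    points_median: float = 8.0
    # PRM-specific
    prm_copies_range: tuple[float, float] = (150.0, 40000.0)
    ratio_cv: float = 10.0
    params: AbsQuantParams = field(
        default_factory=lambda: AbsQuantParams(
            hlis_mw=6.0e4,
            spiked_mass_ng=1.0,
            injected_protein_ug=1.0,
            protein_per_cell_pg=10.0,
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_proteins:
            raise ValueError("planted differential subset larger than the proteome")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.missing_mechanism not in ("random", "left_censored"):
            raise ValueError(f"unknown missingness mechanism {self.missing_mechanism!r}")
        if self.replicates < 1 or self.n_proteins < 1:
            raise ValueError("replicates and n_proteins must be >= 1")

    @property
    def sigma_ln(self) -> float:
        """Natural-log sd of the replicate noise."""
        if self.sigma_log2 is not None:
            return self.sigma_log2 * np.log(2.0)
        cv = self.replicate_cv / 100.0
        return float(np.sqrt(np.log1p(cv * cv)))


@dataclass
class GroundTruth:
    layout: SampleLayout
    protein_abundance: pd.DataFrame  # true protein x group values (pre-noise)
    de_proteins: list[str]
    fold_change: float
    peptide_shares: pd.DataFrame  # columns: protein_id, stripped_seq, share
    emitted: pd.DataFrame  # long table exactly as written (canonical names)
    true_copies: pd.DataFrame | None = None  # PRM: protein x group copies
    params: AbsQuantParams | None = None


def _make_layout(spec: FixtureSpec) -> SampleLayout:
    entries = [
        LayoutEntry(
            run_id=f"run_{g}_{r}", sample_name=f"{g}_R{r}", group=g, replicate=r
        )
        for g in spec.groups
        for r in range(1, spec.replicates + 1)
    ]
    return SampleLayout(entries=entries, group_order=list(spec.groups))


_AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA), size=length)) + rng.choice(["K", "R"])


def make_dia_fixture(
    spec: FixtureSpec, out_dir: str | Path
) -> tuple[Path, Path, SampleLayout, GroundTruth]:
    """Write paired DIA-NN- and Skyline-dialect DIA files with ground truth.

    Returns (report.tsv path, DIA_RESULTS.csv path, layout, truth).
    The two files describe the same underlying quantities.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    layout = _make_layout(spec)

    prots = [f"P{i:05d}" for i in range(spec.n_proteins)]
    genes = {p: f"GENE{i}" for i, p in enumerate(prots)}
    de_group = spec.de_group or spec.groups[-1]
    de_prots = list(rng.choice(prots, size=spec.n_de, replace=False)) if spec.n_de else []

    base = np.exp2(rng.normal(spec.base_log2_mean, spec.base_log2_sd, spec.n_proteins))
    truth = pd.DataFrame(
        {g: base.copy() for g in spec.groups}, index=pd.Index(prots, name="protein_id")
    )
    truth.loc[de_prots, de_group] *= spec.fold_change

    lo, hi = spec.peptides_per_protein
    npep = rng.integers(lo, hi + 1, size=spec.n_proteins)
    pep_rows = []
    seen: set[str] = set()
    for p, k in zip(prots, npep):
        shares = rng.dirichlet(np.ones(k) * 5.0)
        for s in shares:
            while True:
                seq = _random_peptide(rng, int(rng.integers(7, 15)))
                if seq not in seen:
                    seen.add(seq)
                    break
            pep_rows.append({"protein_id": p, "stripped_seq": seq, "share": float(s)})
    peptides = pd.DataFrame(pep_rows)

    # replicate-level protein abundances: group value x lognormal noise
    rows = []
    sigma = spec.sigma_ln
    for e in layout.entries:
        noise = np.exp(rng.normal(0.0, sigma, spec.n_proteins))
        rep_ab = truth[e.group].values * noise
        rep_map = dict(zip(prots, rep_ab))
        for _, pr in peptides.iterrows():
            q = rep_map[pr["protein_id"]] * pr["share"]
            rows.append(
                {
                    "protein_id": pr["protein_id"],
                    "gene": genes[pr["protein_id"]],
                    "stripped_seq": pr["stripped_seq"],
                    "run_id": e.run_id,
                    "sample": e.sample_name,
                    "group": e.group,
                    "replicate": e.replicate,
                    "quantity": q,
                    "protein_quantity": rep_map[pr["protein_id"]],
                    "points_across_peak": int(
                        np.clip(rng.normal(spec.points_median + 0.5, 1.5), 4, 16)
                    ),
                }
            )
    emitted = pd.DataFrame(rows)

    if spec.missing_rate > 0:
        if spec.missing_mechanism == "random":
            keep = rng.random(len(emitted)) >= spec.missing_rate
        else:  # left-censored: low-intensity rows are preferentially lost
            q = emitted["quantity"].rank(pct=True).values
            p_missing = spec.missing_rate * 2.0 * (1.0 - q)
            keep = rng.random(len(emitted)) >= p_missing
        emitted = emitted[keep].reset_index(drop=True)

    # decoy rows exercising the preprocessing filters (not in ground truth)
    decoys = []
    n_nonproteo = int(spec.frac_nonproteotypic * len(emitted))
    n_multi = int(spec.frac_multi_id * len(emitted))
    for i in range(n_nonproteo + n_multi):
        e = layout.entries[int(rng.integers(len(layout.entries)))]
        multi = i >= n_nonproteo
        decoys.append(
            {
                "protein_id": "P_DECOY1;P_DECOY2" if multi else f"P{int(rng.integers(spec.n_proteins)):05d}",
                "gene": "DECOY",
                "stripped_seq": _random_peptide(rng, 9),
                "run_id": e.run_id,
                "sample": e.sample_name,
                "group": e.group,
                "replicate": e.replicate,
                "quantity": float(np.exp2(rng.normal(12, 1))),
                "protein_quantity": np.nan,
                "points_across_peak": int(np.clip(rng.normal(8.5, 1.5), 4, 16)),
                "_proteotypic": 0 if not multi else 1,
            }
        )
    emitted["_proteotypic"] = 1
    full = pd.concat([emitted, pd.DataFrame(decoys)], ignore_index=True)

    diann = pd.DataFrame(
        {
            "Protein.Group": full["protein_id"],
            "Genes": full["gene"],
            "Modified.Sequence": full["stripped_seq"],
            "Stripped.Sequence": full["stripped_seq"],
            "Proteotypic": full["_proteotypic"].astype(int),
            "Run": full["run_id"],
            "Precursor.Quantity": full["quantity"],
            "PG.MaxLFQ": full["protein_quantity"],
        }
    )
    report_path = out_dir / "report.tsv"
    diann.to_csv(report_path, sep="\t", index=False, float_format="%.17g")

    # the Skyline dialect has no proteotypic flag, so non-proteotypic decoys
    # (unfilterable on that path) are a DIA-NN-only feature; multi-ID decoys
    # stay, since the multi-protein filter applies to both dialects
    sky_src = full[(full["_proteotypic"] == 1)]
    skyline = pd.DataFrame(
        {
            "Protein": sky_src["protein_id"],
            "Protein Gene": sky_src["gene"],
            "Peptide": sky_src["stripped_seq"],
            "Replicate Name": sky_src["run_id"],
            "Total Area Fragment": sky_src["quantity"],
            "Points Across Peak": sky_src["points_across_peak"],
        }
    )
    skyline_path = out_dir / "DIA_RESULTS.csv"
    skyline.to_csv(skyline_path, index=False, float_format="%.17g")

    layout_path = out_dir / "layout.yaml"
    layout.to_yaml(layout_path)

    gt = GroundTruth(
        layout=layout,
        protein_abundance=truth,
        de_proteins=sorted(map(str, de_prots)),
        fold_change=spec.fold_change,
        peptide_shares=peptides,
        emitted=emitted.drop(columns="_proteotypic"),
    )
    return report_path, skyline_path, layout, gt


def make_prm_fixture(
    spec: FixtureSpec, out_dir: str | Path, n_proteins: int | None = None
) -> tuple[Path, Path, SampleLayout, GroundTruth]:
    """Write a heavy-label Skyline PRM export plus spike parameter file.

    True copies/nucleus per protein x group are drawn log-uniformly from
    ``prm_copies_range``; planted differential proteins multiply the
    perturbed group's copies by ``fold_change``. Light areas are heavy
    areas times the (noise-perturbed) true ratio, so zero ratio noise makes
    the conversion exactly invertible.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    layout = _make_layout(spec)
    n_prot = n_proteins if n_proteins is not None else min(spec.n_proteins, 21)

    prots = [f"SUBUNIT{i:02d}" for i in range(n_prot)]
    lo, hi = np.log(spec.prm_copies_range[0]), np.log(spec.prm_copies_range[1])
    copies = pd.DataFrame(
        {g: np.exp(rng.uniform(lo, hi, n_prot)) for g in spec.groups},
        index=pd.Index(prots, name="protein_id"),
    )
    de_prots = list(rng.choice(prots, size=min(spec.n_de, n_prot), replace=False)) if spec.n_de else []
    de_group = spec.de_group or spec.groups[-1]
    copies.loc[de_prots, de_group] *= spec.fold_change

    npep = rng.integers(2, 5, size=n_prot)
    cv = spec.ratio_cv / 100.0
    sigma = float(np.sqrt(np.log1p(cv * cv))) if cv > 0 else 0.0
    rows, truth_rows = [], []
    seen: set[str] = set()
    pep_rows = []
    for p, k in zip(prots, npep):
        peps = []
        for _ in range(k):
            while True:
                seq = _random_peptide(rng, int(rng.integers(7, 14)))
                if seq not in seen:
                    seen.add(seq)
                    break
            peps.append(seq)
            pep_rows.append({"protein_id": p, "stripped_seq": seq, "share": 1.0 / k})
        for e in layout.entries:
            true_ratio = float(spec.params.copies_to_ratio(copies.at[p, e.group]))
            for seq in peps:
                noise = float(np.exp(rng.normal(0.0, sigma))) if sigma else 1.0
                heavy = float(np.exp(rng.normal(np.log(1e5), 0.3)))
                light = heavy * true_ratio * noise
                for label, area in (("light", light), ("heavy", heavy)):
                    rows.append(
                        {
                            "Protein": p,
                            "Protein Gene": p,
                            "Peptide": seq,
                            "Replicate Name": e.run_id,
                            "Isotope Label Type": label,
                            "Total Area Fragment": area,
                            "Points Across Peak": int(
                                np.clip(rng.normal(30, 2), 20, 40)
                            ),
                        }
                    )
            truth_rows.append({"protein_id": p, "group": e.group})

    csv_path = out_dir / "PRM_RESULTS_Heavy_label.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False, float_format="%.17g")
    params_path = out_dir / "abs_quant_params.yaml"
    spec.params.to_yaml(params_path)
    layout.to_yaml(out_dir / "layout.yaml")

    gt = GroundTruth(
        layout=layout,
        protein_abundance=copies.copy(),
        de_proteins=sorted(map(str, de_prots)),
        fold_change=spec.fold_change,
        peptide_shares=pd.DataFrame(pep_rows),
        emitted=pd.DataFrame(rows),
        true_copies=copies,
        params=spec.params,
    )
    return csv_path, params_path, layout, gt
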