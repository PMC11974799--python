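# diaprm

Downstream analysis and visualization for DIA and PRM mass-spectrometry
proteomics. `diaprm` picks up where the upstream search/quantification tools
stop: it consumes a DIA-NN long-format report (`report.tsv`) or Skyline
exports (`DIA_RESULTS.csv`, `PRM_RESULTS_Free_label.csv`,
`PRM_RESULTS_Heavy_label.csv`) together with a sample-layout file, and
produces the annotated tables, QC metrics, differential-abundance results,
offline enrichment results and — for heavy-label PRM — absolute protein
quantities (copies per nucleus or cell) with stoichiometry statistics.

It is written for proteomics practitioners who run discovery DIA
experiments (e.g. time-course studies of cell differentiation) and targeted
SID-PRM panels, and want a scripted, deterministic replacement for ad-hoc
notebook analysis.

## What it computes

**Discovery DIA pipelines** (`dia-diann`, `dia-skyline`, `prm-free`):

- Preprocessing: drop non-proteotypic peptides and peptides assigned to
  multiple protein groups; roll peptides up to a protein × sample matrix
  (summed fragment areas for Skyline, the tool's own MaxLFQ protein
  quantity for DIA-NN); require a minimum number of unique peptides per
  protein (default 2, applied per sample).
- QC: per-protein coefficient of variation across replicates,
  CV% = 100·sd/mean (sample sd); Spearman ρ between replicate pairs
  (pairwise-complete, average ranks); distribution of MS2 (or MS1) points
  across chromatographic peaks.
- Yields and structure: peptide/protein counts per sample and group
  (group = union over replicates), shared/unique/core protein breakdowns,
  peptides-per-protein densities, hierarchical clustering of log2 group
  profiles (Euclidean, average linkage) and a group-level Spearman
  correlation matrix.
- Abundance: protein ranking; volcano analysis between two groups with a
  two-sample t-test on log2 abundances (Welch by default),
  log2FC = mean_b − mean_a, user thresholds P ∈ [0.001, 0.05] and
  FC ∈ [0.5, 10] (FC < 1 is symmetrized, so 0.5 means |log2FC| ≥ 1);
  single-protein bar plots with `*`/`n.s.` marks; heatmaps with either
  explicit `n.d.` missing-value markers or chained-regression imputation.
- Enrichment: one-sided Fisher exact (hypergeometric upper tail) over
  local GMT gene sets, BH-adjusted within namespace, with the quantified
  proteome as the default background.

**Heavy-label SID-PRM pipeline** (`prm-heavy`): per-peptide light/heavy
ratios R convert to copies per nucleus through the spike bookkeeping

    copies = R · (spiked_mass / MW_HLIS) / injected_protein
               · protein_per_nucleus · N_A

with the per-protein value the median over its peptides. Group and
protein-stoichiometry comparisons use one-way ANOVA with Tukey's HSD
post-hoc test (studentized-range distribution, pooled variance) and a
compact letter display: groups share a letter exactly when they are not
significantly different at α (default 0.05).

**Utilities**: `pepseq` counts detected peptides that are substrings of a
query amino-acid sequence (per sample/group, XLSX report); `idmap` maps
gene symbols to protein accessions from a local two-column table; `synth`
generates DIA-NN-/Skyline-dialect fixtures with planted ground truth.

All tables are written under `TABLES/` (volcano lists under
`TABLES/VOLCANO_PLOT_VALUES/`, shared/unique lists under
`TABLES/SHARED_UNIQUE_PROTEINS/`) and every figure under `PLOTS/` as TIFF
at 300 dpi.

## Worked example

Generate a small synthetic two-group study and run the Skyline-DIA
pipeline on it:

```sh
diaprm synth dia --seed 3 --out fixture --groups Day0,Day2 --replicates 3 \
    --proteins 40 --n-de 5 --fold-change 4
diaprm dia-skyline fixture/DIA_RESULTS.csv --layout fixture/layout.yaml \
    --out run --min-peptides 2
```

The run log ends with

```
INFO wrote 16 tables, 10 plots under run
```

and `run/TABLES/cv_per_protein.csv` starts

```
protein_id,group,cv_percent
P00000,Day0,11.244625016724031
P00001,Day0,12.729468716038438
```

i.e. per-protein replicate CVs in percent (the fixture plants a 10% CV, so
values scatter around 10). The volcano table
`run/TABLES/VOLCANO_PLOT_VALUES/volcano_all_Day0_vs_Day2.csv` begins

```
protein_id,gene,log2FC,p_value,neg_log10_p,p_adj_BH,status
P00009,GENE9,1.9907205970660957,5.035236677998868e-05,4.29798011090319,0.002014094671199547,up
```

— a planted 4-fold protein recovered with log2FC ≈ 2 and status `up` at
the default thresholds (P ≤ 0.05, FC > |2|). Five proteins are flagged
`up` (none `down`); they are exactly the five planted fold changes.

For the heavy-label PRM path, with R = 1, a 100 kDa standard, 1 ng spiked
per injection, 1 µg injected and 10 pg protein per nucleus:

```python
>>> from diaprm import AbsQuantParams
>>> AbsQuantParams(1e5, 1.0, 1.0, 10.0).ratio_to_copies(1.0)
60221.40759999999
```

about 6.02 × 10⁴ copies per nucleus — the unit analysis
(1 ng / 10⁵ g·mol⁻¹ = 10⁻¹⁴ mol; × 10⁻⁵ µg/nucleus → 10⁻¹⁹ mol; × N_A).

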