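# Methods

This note records the statistical model behind each stage of `diaprm`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical corner cases.

## Input model and preprocessing

Both supported upstream tools emit long tables: one row per precursor (or
transition-summed peptide) per instrument run. The sample layout maps run
identifiers to (sample name, experimental group, replicate index) and fixes
the display order of groups; reading applies the layout as a pure
relabeling, dropping rows from runs it does not mention and reporting the
count. Column names are resolved through an overridable mapping, because
both tools let users customize their export columns; the documented
defaults are `Protein.Group`/`Genes`/`Modified.Sequence`/
`Stripped.Sequence`/`Proteotypic`/`Run`/`Precursor.Quantity` (+`PG.MaxLFQ`)
for DIA-NN and `Protein`/`Peptide`/`Replicate Name`/`Total Area Fragment`
(+`Points Across Peak`, `Isotope Label Type`, `Protein Gene`) for Skyline.
Decimals are plain-period only; files are UTF-8; unknown columns are
ignored. Readers parse floats in round-trip mode so that values written at
full precision survive a write–read cycle bit-exactly.

Three filters implement the usual guards for discovery data:

- **Proteotypic filter** — peptides mapping to more than one protein group
  cannot support protein-level inference; only rows flagged proteotypic are
  kept. Skyline exports carry no such flag, so there the filter is a no-op
  with a warning.
- **Multi-accession filter** — a protein-ID field that splits into more
  than one token on `;`, `,` or whitespace is ambiguous and dropped
  (DIA-NN separates grouped accessions with `;`).
- **Minimum unique peptides** — single-peptide quantities are unreliable;
  the default threshold is 2 unique (distinct stripped-sequence) peptides,
  applied *per sample* (each cell of the matrix must individually be backed
  by ≥ n peptides). A global mode (drop the protein unless some sample
  reaches n) is kept for convenience. Default scope is per-sample because
  the threshold is meant to hold for every sample in the dataset.

Rollup to the protein × sample matrix sums peptide quantities (Skyline
fragment-area convention) or passes through the upstream tool's own per-run
protein-group quantity (DIA-NN MaxLFQ); a median rollup is available.
Zero intensities are treated as missing, not as measured zeros, because
Skyline writes 0 for peaks it did not integrate. Passthrough verifies that
the protein-group quantity is constant within each run and names offenders
otherwise.

## Quality control

CV is computed per protein per group as 100·sd/mean on the **raw**
abundance scale with the **sample** (n−1) standard deviation. Replicate
counts in this kind of design are tiny (often n = 2), where the population
sd would bias CV down by ~20%; and CV is conventionally a raw-scale
statistic (the common ≤ 20% acceptability guidance refers to raw-scale CV).
A protein enters a group's CV only when observed in ≥ 2 of its replicates.
Replicate agreement uses Spearman's ρ on pairwise-complete proteins with
average ranks for ties — rank correlation because DIA intensity scales are
heavy-tailed and nonlinearly related between runs. Points-across-peak
distributions summarize quantification fidelity per group; MS2 is the
default level since DIA quantification is fragment-based.

## Yields, set algebra and exploratory structure

A protein is "present in a group" when observed in at least one replicate
after filtering (union semantics); group-level peptide/protein counts,
per-group unique lists, pairwise shared counts and the core set (present in
every group) all follow from that presence relation. The any-replicate rule
is a genuine design choice — requiring all replicates would conflate
missingness with absence; it is switchable by filtering the matrix first.

Hierarchical clustering operates on log2 profiles (group means by default)
over the complete-observation protein set, with Euclidean distance and
average linkage; neither choice is canonical in the field, so both are
parameters. The group correlation matrix is Spearman on group-mean log2
abundances, pairwise-complete.

## Differential abundance

The volcano test is a two-sample t-test on log2 abundances per protein
observed in ≥ 2 replicates of both groups, with log2FC = mean_b − mean_a.
**Welch** (unequal variances) is the default flavor: with 2–4 replicates
per group, variance heterogeneity between biological conditions is common
and the pooled test is anti-conservative under it; the pooled (Student)
variant is available by flag, and log2 transformation before testing is the
package's declared convention. Thresholds follow the conventional menus
(P from 0.05 down to 0.001; fold change 0.5–10). A fold-change threshold
below 1 is symmetrized to its reciprocal so the cut is always a two-sided
|log2FC| bound — a one-sided fold cut below 1 is meaningless in a volcano.
Raw P drives the up/down status, matching the exposed threshold menus; a
Benjamini–Hochberg column is written alongside for transparency but does
not affect status. No cross-sample normalization is applied before
testing: upstream MaxLFQ/Skyline quantities are trusted as delivered.

Imputation for the clustered heatmap is chained regression on the log2
scale (each sample's column iteratively regressed on the others), run
through scikit-learn's `IterativeImputer` with a fixed sweep order and
random state, so results are deterministic; observed cells are restored
bit-for-bit afterwards, and imputed cells remain identifiable by their 0
unique-peptide count. Initialization is at column means; on the matrices
this package sees (proteins ≫ samples, low missingness) the sweep converges
well inside the default 20 iterations at tol 1e-3. The selected-protein
heatmap performs **no** imputation and no clustering: missing cells carry
the marker `n.d.` so absence stays visible.

## Enrichment

Over-representation uses the one-sided Fisher exact test: with background
size N, set size K (restricted to the background), query size n and overlap
k, p = P(X ≥ k) for X hypergeometric. Gene sets come from local GMT files
(pathway-style or GO-style namespaces); live database queries are out of
scope for determinism and reproducibility. The default background is the
experiment's quantified proteome, not the genome — the standard guard
against detection bias in proteomics ORA. BH adjustment is applied within
each namespace.

## Absolute quantification (SID-PRM)

Each heavy-labeled internal standard (HLIS; e.g. a QconCAT concatemer)
contributes, per injection, `spiked_mass / MW` moles of every standard
peptide. A peptide's light/heavy area ratio R then gives endogenous moles
per injection, normalized by the injected sample protein mass (µg) and
scaled to a nucleus by the protein mass per nucleus (pg) and Avogadro's
number:

    copies/nucleus = R · (spiked_mass_ng·1e-9 / MW) / injected_µg
                       · (protein_per_nucleus_pg·1e-6) · N_A

Rows with zero or missing heavy area are excluded (no ruler); a light area
of 0 is a valid measurement giving 0 copies. The per-protein value is the
**median** over its peptides — robust to a single interfered peptide; mean
is available. Parameters are per-injection; a spike specified per-µg of
digest enters through the same `injected_µg` term.

Group comparisons (one protein across groups) and stoichiometry
comparisons (several proteins within a group) use one-way ANOVA followed by
Tukey's HSD with the studentized-range distribution on the pooled
within-group variance. When every observation is identical the within- and
between-group variances both vanish; that degenerate case reports p = 1
(no evidence of difference) instead of dividing by zero. The compact
letter display is built by insert-and-absorb: start from one letter
covering all groups, split any letter containing a significant pair, and
absorb letters contained in another; letters are ordered by first group in
display order. The defining invariant — two groups share a letter exactly
when their Tukey comparison is not significant at α (default 0.05) — is
validated in the tests against exhaustive search over letter assignments
for up to five groups, where the construction is also minimal.

## Peptide-sequence matching and ID mapping

`match_peptides` strips bracketed/parenthesized modification tags
(idempotently) and tests exact contiguous substring membership in the query
sequence — no I/L equivalence and no missed-cleavage expansion, since the
purpose is literal coverage of a user-specified region. Each distinct
stripped sequence counts once per sample and once per group. Gene → 
accession mapping is a case-insensitive exact join against a user-supplied
two-column table (e.g. a UniProt idmapping extract); genes with several
accessions return all of them, unmapped genes are listed separately.

## Synthetic-data generator

The generator emulates the study design this toolkit targets: multiple
time-point groups with **2 biological replicates** each (the default), ~200
proteins with 2–8 peptides per protein (Dirichlet-distributed peptide
shares), base log2 abundances N(17, 2), and **10% replicate CV** as
multiplicative lognormal noise applied at the protein level — so the
planted CV is what sum-rollup should recover. Planted differential proteins
multiply one group's abundance by a chosen fold change. Missingness removes
peptide rows at random, or preferentially at low intensity (left-censored
option) to emulate detection-limit dropout. Decoy rows exercise the
proteotypic and multi-accession filters on the DIA-NN dialect (the Skyline
dialect omits non-proteotypic decoys because that path has no flag to
filter them with). For PRM, true copies per protein × group are drawn
log-uniformly over ~150–40,000 copies/nucleus (the realistic span for
nuclear chromatin-remodeling subunits), inverted exactly through the
conversion formula to a true ratio, and perturbed by multiplicative ratio
noise; spike defaults are a 60 kDa standard, 1 ng per injection, 1 µg
injected, 10 pg protein per nucleus.

What the generator does **not** emulate: retention-time structure,
interference/co-elution, isotope impurity, batch effects, nonlinear
detector response, and correlated peptide-level noise. Passing tests
therefore demonstrate correctness of the downstream arithmetic and
statistics under the declared noise model, not robustness to every
real-data pathology.

Statistical benchmarks in `diaprm.evaluate` (run by the test suite and by
`scripts/acceptance.py`) use the sample sizes at which the checks are
informative yet quick: 20 seeds of a 2-group/4-replicate CV study, 20 seeds
of a 200-null + 20-planted-4-fold volcano study at σ_log2 = 0.25 with 3
replicates, 100 enrichment tuples against an exact integer-arithmetic tail
plus 1000 null draws for calibration, 500 random significance patterns for
the letter display, and 100 datasets for the Tukey/t identity.

## Numerical conventions

- Determinism: a single integer seed fixes every fixture and benchmark;
  identical configuration reproduces byte-identical CSV outputs.
- Fixture files are written with `%.17g` floats and read back in
  round-trip parsing mode, making generator → reader comparisons exact.
- Ties in abundance ranking break lexicographically by protein ID; volcano
  rows sort by p with a stable sort.
- A t-test on two zero-variance, equal-mean vectors returns NaN upstream;
  it is reported as p = 1 (no evidence of difference).
- Known limitations: no moderated/shrinkage statistics, no paired designs,
  no batch correction, no calibration-curve quantification, no isotope
  impurity correction; enrichment is ORA only (no GSEA-style rank tests).
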