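# Methods

## Statistical model and procedure

All analysis happens on the log2 intensity scale. The pipeline assumes
feature intensities are approximately Gaussian on that scale within each
sample group, with possibly very different variances between a large
heterogeneous tumour panel and a handful of normal reference samples —
which is why the default two-group test is Welch's unequal-variance
*t*-test rather than the pooled form (the pooled variant is available via
`equal_var=True`).

**Presence filtering.** A feature enters testing only if detected in at
least `frac_a` of one group and/or `frac_b` of another (defaults: 75% of
bone, 25% of cell lines, combined with OR). The OR keeps miRNAs expressed in
only a subgroup of the tumour panel. "At least" fractions convert to counts
by ceiling — 0.25 × 19 → 5 of 19, 0.75 × 4 → 3 of 4 — with a 1e−9 guard
against float round-up. When vendor detection calls are unavailable,
detection falls back to intensity above a configurable global quantile of
the matrix (default 0.25). In the source study this filter reportedly kept
340 miRNAs in the text but 361 in the corresponding figure legend; the
discrepancy is unexplained there and is recorded here rather than resolved.

**Multiple testing.** Benjamini–Hochberg runs over the presence-filtered
feature set only (filter-before-test); `bh_adjust` delegates to
statsmodels' `fdr_bh` and is held against a definition-based step-up oracle
in the tests. Degenerate features (zero variance in both groups) get
*p* = 1 when means agree — never NaN — so the step-up remains well defined;
exact separation with zero variance gets *p* = 0 and an infinite *t*.

**Fold changes.** Signed ratio convention: for log2 mean difference Δ,
2^Δ if Δ ≥ 0, else −2^−Δ, so |FC| ≥ 1 and equality maps to +1. Features
undetected throughout one group keep their fold change but are flagged
`overestimated`, since the group mean then rests on background-level
intensities.

**Clustering.** Samples are compared with d = 1 − |r| (absolute Pearson;
the signed 1 − r variant is a flag), merged by UPGMA. The UPGMA
implementation is authored here because the merge tie-break is pinned:
exact ties resolve toward the pair whose lexicographically smallest member
id sorts first, making trees deterministic on degenerate inputs; scipy's
average-linkage serves as an independent reference on tie-free instances in
the tests. Average linkage satisfies the reducibility property, so merge
heights are non-decreasing and the exported Newick is ultrametric (node age
= merge height / 2). Tree concordance between the miRNA- and mRNA-based
clusterings is exposed as an adjusted-Rand report at a chosen cut, never
asserted as a property of any data.

**Integration cascade.** Stage order: (1) prediction rows whose miRNA is a
differential-expression hit and whose gene is significant in both the
cell-line and the clinical contrast; (2) Pearson anti-correlation across
the cell-line samples only (tumour heterogeneity provides the variation
that makes the correlation informative; the subset is configurable);
(3) conservation; (4) multi-miRNA grouping. Boundary semantics are
deliberate and recorded in output metadata: r < −0.5 is strict (−0.5 itself
drops), P_CT ≥ 0.4 keeps the boundary, and pairs with no P_CT (star
strands) pass the conservation stage untouched. Genes represented by
several probes are scored by their most anti-correlated probe (most
favourable to detection); `require_all_probes=True` flips to the least
favourable. Whether the dual-cohort gene filter should be re-applied after
conservation is ambiguous in the narrative this mirrors; the cascade
implements the prose order exactly once and emits counts at every stage so
the question stays auditable.

**Hypergeometric overlap.** Upper-tail P(X ≥ k) accumulated as
logsumexp over log-gamma pmf terms. Rationale: genome-scale overlaps
produce p-values far below double-precision underflow (< 1e−1000), which a
plain survival function cannot represent; log10(p) is the primary output.

**qPCR arm.** ΔCt = Ct(target) − mean Ct(references); the two references
combine by arithmetic mean on the Ct scale (a geometric mean of their
linear quantities), chosen because no combination rule was stated in the
design this mirrors; a geometric-mean-of-RQ alternative would differ only
by reference weighting and is intentionally not the default. ΔΔCt subtracts
the calibrator-group mean (bone), so RQ = 2^−ΔΔCt is expression relative to
mean bone. Undetected wells impute to a 40-cycle ceiling before
quantification, with per-assay imputation counts logged. Technical
replicates average on the Ct scale. Any per-sample additive Ct shift common
to target and references cancels exactly — a tested invariant. Mann–Whitney
tests run on RQ values by default (ΔCt is an option; the two are
rank-equivalent only when references are shared consistently, which is why
the choice is explicit). Exact enumeration is used for min(n, m) ≤ 8 with
tie-free data, otherwise the tie- and continuity-corrected normal
approximation; the method used is recorded per result. No multiplicity
adjustment is applied across assays, matching the reporting convention of
the validation design (a BH option exists, off by default).

## Synthetic cohort generator

The generator (`osteomir.synthetic_data`) defines the conditions every
recovery claim refers to. Defaults:

| parameter | default | meaning |
|---|---|---|
| `n_cell_lines` / `n_bone` | 19 / 4 | array design |
| `n_clinical` / `n_osteoblast` | 12 / 5 | validation arms |
| `n_mirna` / `n_mrna` | 200 / 400 | panel sizes |
| `n_de_mirna`, `de_log2_effect` | 20, 3.0 | planted miRNA shifts (log2 units) |
| `n_true_pairs`, `coupling_slope` | 20, −1.0 | planted couplings (log2 mRNA per log2 miRNA) |
| `n_decoy_predictions` | 120 | ≥ 5 decoys per true pair |
| `noise_sd` | 0.3 | measurement noise (log2) |
| `tumor_sd` / `normal_sd` | 0.8 / 0.2 | per-sample biological spread |
| `pct_true_range` / `pct_decoy_range` | (0.5, 1) / (0, 1) | conservation scores |
| `frac_star` | 0.2 | star-strand fraction (no P_CT) |
| `frac_unexpressed` | 0.15 | background features the presence filter should drop |

The 3-log2-unit effect (8-fold) is conservative relative to the fold
changes such tumour-vs-bone panels report (routinely 4-fold to several
hundred-fold) while comfortably above the 2-log2-unit floor the recovery
conditions assume. Tumour-derived samples get larger biological spread than
normals, which (a) makes the Welch choice consequential, and (b) supplies
the across-cell-line variation that anti-correlation screening needs: with
slope −1, latent sd 0.8 and noise sd 0.3, true pairs have population
|r| ≈ 0.88 across cell lines. Latent deviations are centred within each
group so that zero-noise limits are exact closed forms (planted fold change
exactly ±2^effect; true-pair r exactly −1), which the tests pin. The
clinical arm receives half the cell-line shift — the intermediate-expression
gradient encoded as a generative assumption. Cluster members share one
latent factor (and an mRNA host gene coupled positively to it); multi-miRNA
target genes couple to the mean deviation of their miRNAs. Decoy
predictions are built half from DE-miRNA × independently-DE-gene pairs
(these reach the correlation stage and stress the r filter) and half from
inert combinations removed at the candidate stage.

What the generator does **not** emulate: array hybridization physics, probe
sequences, batch and lab effects, correlated noise between features,
copy-number structure, heavy-tailed intensity distributions, and realistic
miRNA nomenclature. Passing recovery tests therefore demonstrates that the
cascade's logic and calibration are correct under its stated model — not
that the thresholds are optimal for any particular real dataset.

## Problem sizes and determinism

Recovery metrics average 50 independent seeds of the default design; null
calibration uses 200 pure-null cohorts (no planted signal; the mRNA panel
is trimmed to 5 features there since only the miRNA contrast is scored).
These sizes give a standard error of ≈ 0.01 on the recovery proportions and
≈ 0.015 on the null false-discovery proportion. All randomness flows
through one integer seed per generator call (`numpy.random.default_rng`; no
global state), and child seeds in the acceptance script derive from the
single `--seed` argument. Fixed seed and config reproduce all on-disk
outputs byte-identically; the canonical TSV dialect writes floats via
`repr`, so read → write round trips are exact.

## Known limitations

* No moderated/empirical-Bayes variance shrinkage; with 4 reference
  samples, per-feature variance estimates are noisy and Welch is
  conservative rather than powerful.
* The mRNA arm is assumed already variance-stabilized and log-scale;
  real-data reproduction must apply VST upstream, and Illumina probe→gene
  collapsing is left as an explicit option (probe-level rows are kept by
  default).
* TargetScan-style predictions are consumed, not computed; era-specific
  star-strand naming (`*` suffix) is preserved rather than modernized to
  -3p/-5p.
* Pathway enrichment and copy-number integration are out of scope.
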