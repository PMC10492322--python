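# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions that make results reproducible.

## Rank-based gene and module scoring

For a two-group comparison (case group of size n1, control of size n2) the
Mann-Whitney statistic of the case group is computed from mid-ranks,
`U1 = R1 − n1(n1+1)/2`, which equals the number of (case, control) pairs
where the case value is larger, counting ties as ½. The control-group
statistic is `U2 = n1·n2 − U1`, and the gene score

    score = (U1 − U2) / (n1 + n2)

adjusts for group size so scores are comparable across cohorts; its range
is ±n1·n2/(n1+n2). P-values use the normal approximation with tie and
continuity correction; genes constant across all samples score 0 with
p = 1. Fold changes are ratios of linear-scale group means (matrices
flagged `log2` are exponentiated first).

Quantile normalization forces every sample column onto the per-rank mean
distribution of the input columns; ties within a column receive the mean of
the reference values at their tied ranks, so an all-constant column maps to
the reference mean. Note the method assumes most genes are unshifted
between groups: if a large fraction of the matrix carries a planted (or
real) shift, normalization redistributes part of that signal into the
remaining genes. The simulations used for calibration therefore plant
shifts in at most a few percent of genes.

A functional module's score is the **median** of its member gene scores
(even-length medians are the mean of the two central values — documented
because module scores feed a hard FDR threshold). Modules with fewer than
`min_genes` (default 3) members present are dropped with a warning.

### Permutation FDR

Group labels are shuffled among the samples of the two compared groups only
(other groups are untouched), all module scores are recomputed per
permutation (100 by default), and for module m with observed absolute score
s_m the pooled plug-in estimate is

    FDR(m) = E_perm[ #{modules: |null score| ≥ s_m} ]
             / #{modules: |observed score| ≥ s_m},

clipped to [0, 1]. Because the raw plug-in need not be monotone, each
module then takes the minimum of its own estimate and those of all less
extreme modules (q-value-style step-up), guaranteeing a module with a
larger |score| never receives a larger FDR. Absolute (two-sided) scores are
used throughout. Since a label permutation only changes which columns count
as case, combined-sample ranks are computed once per comparison and reused
across permutations, making 100 permutations on a 1000 × 60 matrix run in
well under a second.

Calibration and power under the defaults (50 disjoint 20-gene modules,
n1 = n2 = 30, 100 permutations): the all-null false-positive fraction at
FDR < 0.05 averages well below 0.05 over ten seeds, and a single module
planted at a +2 log2 shift is recovered in 20/20 seeds.

## Correlation minimum spanning tree

Over a chosen gene panel, each pair receives the Spearman rank correlation
(t-approximation p-value) computed on the union of the two compared groups'
samples by default (`correlation_scope` switches to case- or control-only).
The MST cost is `1 − |rho|`, so strongly (anti-)correlated pairs sit on
short edges; the Spearman p is carried as the display attribute
(edge width = −log10 p). Kruskal's algorithm runs on edges inserted in
lexicographic node-pair order with a stable sort, so weight ties break
deterministically and the output is independent of input row order.
Constant expression vectors have undefined correlation; they are recorded
as rho 0 (weight 1) with a warning. Node annotations cap −log10 p at 300 to
absorb p-value underflow. Module-level trees reuse the same code path with
module-score vectors as nodes.

## MRM quantitation

Response ratio = quantifier peak area / internal-standard area. The
analyte→IS pairing defaults to arginine vs ¹³C₆-arginine and SDMA/ADMA vs
D₇-ADMA; SDMA and ADMA carry no qualifier transition and are exempt from
ion-ratio QC. Calibration is weighted least squares of response ratio on
nominal concentration with weighting 1/x (options: none, 1/x²); r² is that
of the weighted fit, 1 − weighted RSS / weighted TSS about the weighted
mean, so the r² > 0.99 acceptance gate is exactly reproducible. A curve is
accepted only with r² > 0.99 and ≥ 4 distinct levels; individual calibrator
levels may be masked via config (manual-inspection analog) but no outlier
is removed automatically.

Back-calculation is `(ratio − intercept)/slope`. Values exactly at the
LLOQ (lowest calibrator: 4.00 µM arginine, 0.20 µM SDMA/ADMA) or ULOQ (top
calibrator: 200 µM / 10.0 µM) pass; outside they are reported numerically
with `below_lloq`/`above_uloq` flags rather than censored — the biomarker
stage owns the censoring policy (`lloq_policy`, default keep). Batch
acceptance requires pooled-serum CV < 15 % and |bias| < 15 % against a
previously characterized pooled nominal (a config input; without it the
bias gate is skipped with a warning). Ion ratios deviating > 15 % from the
calibrator-derived reference mean are flagged per sample. When the curve or
the batch fails, every reported row carries a `batch_failed` flag — no
concentration is reported silently.

## Biomarker evaluation

Group comparisons reuse the same U machinery as the expression half. ROC
curves sweep unique values (ties collapse to one operating point) and the
AUC is the trapezoidal area, which equals `U1/(n1·n2)` exactly under the
half-tie convention — this identity is asserted as a cross-module
consistency test. Direction is chosen automatically so AUC ≥ 0.5 (and
reported), because the ratio rises in disease while arginine alone falls;
it can be fixed per marker. Panels evaluate each marker (analyte column or
`A/B` ratio) against multiple control sets — `[normal]` and
`[normal, benign]` by default — and rank markers by AUC.

## Synthetic data: what it emulates, what it does not

**Expression generator.** Log2-scale i.i.d. Gaussian noise per gene ×
sample (SD 1.0) around per-gene baselines (mean 8, SD 1); planted module
effects add a log2 shift to the case group's mean for the stated
comparison, and a gene reached by contradictory shifts for one comparison
is rejected by name. The distributional form is deliberately simple: the
downstream statistics are rank-based, so the choice is inert. Default group
sizes mirror the tissue cohort (71 normal / 8 benign / 280 early / 1016
late); benign is generated but not contrasted. Not emulated: multi-study
heterogeneity and batch structure (one homogeneous matrix per simulation),
gene-gene correlation outside planted modules, and mean-variance coupling.
Passing tests therefore demonstrate correctness of the statistics under the
stated sampling model, not robustness to cross-platform integration.

**MRM generator.** Per analyte: six calibrator levels (0.20–10.0 µM for
SDMA/ADMA, 4.00–200 µM arginine) in clean matrix; pooled and unknown serum
injections get one matrix-suppression factor per (sample, analyte), uniform
on 25–52 %, applied equally to the quantifier and IS areas — the mechanism
IS normalization cancels. Injection-level drift likewise scales both areas;
the residual analytical CV of the response ratio is `tech_cv` (default 5 %,
matching reported assay precision), applied as mean-one log-normal noise.
Biological concentrations are log-normal with CV 25 % around group means
chosen once as realistic serum values (arginine 80 µM normal / 50 µM
cancer; SDMA 0.55 / 1.10 µM; ADMA 0.60 µM unchanged; benign tracks
normal): published figures for the cohort are graphical only, so these
defaults are free parameters of the simulator, not claims about the cohort.
Blood-cohort sizes default to 464 normal / 3 benign / 13 cancer with
pooled injections at 10 % of the unknown count. Not emulated:
chromatographic interference, carryover, calibrator-matrix mismatch, and
between-batch drift.

## Numerical and design choices

- One integer seed drives every random stream (numpy `default_rng`);
  derived stage seeds are small offsets. Fixed seed ⇒ byte-identical
  matrices, tables and CSVs; output headers carry version, config hash and
  seed, and deliberately exclude timestamps so reruns are comparable by
  checksum.
- Scoring one matrix per run is the supported design; scores from separate
  runs can be averaged weighted by (n1 + n2) since the gene score is
  already sample-size-adjusted.
- Problem sizes used by the shipped checks (50 × 20-gene modules,
  n1 = n2 = 30, 100 permutations; 40–464-control serum batches) were chosen
  as the smallest sizes at which the calibration and power properties are
  stable across seeds.
- Degenerate inputs are handled explicitly: constant genes (score 0,
  p = 1), constant correlation vectors (weight 1 + warning), identical ROC
  values (AUC 0.5 + warning), missing IS (`no_is` flag, row excluded from
  quantitation), < 2 pooled injections (batch verdict "unknown").

## Known limitations

- The permutation FDR pools all modules; with very few modules (< ~10) the
  denominator is coarse and estimates are conservative.
- Quantile normalization assumes most genes are non-differential (see
  above); heavily shifted matrices bias unplanted genes.
- The benign group in the shipped blood-cohort defaults has n = 3, so the
  normal-vs-(normal+benign) AUC difference is within noise, as expected at
  these sizes.
- ROC confidence intervals are not computed by default (a seeded bootstrap
  helper can be added at the call site); reported AUCs at n_case = 13 carry
  substantial sampling variance across seeds.
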