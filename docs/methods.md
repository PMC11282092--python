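# Methods

This note documents the statistical models, defaults and design choices
behind `rmsstates`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Synthetic cohort model

`simulate.generate_cohort` draws counts from a gamma–Poisson (negative
binomial) model: gene *g* in cell *i* has mean
`mu_ig = exp(log b_g + batch_sg + effect_ig) * l_i`, variance
`mu + mu²/r`.

- **Baseline abundances** `b_g`: lognormal (σ = 1) scaled so the average
  gene contributes `baseline_mean` counts. The default `baseline_mean = 1.0`
  gives a median library of ≈ 2,000 UMI over 2,000 genes — the depth range
  of droplet data that survives standard QC. (Shallower settings produce
  cells that real pipelines would discard and score noise that no real
  dataset shows.)
- **State effects**: each non-ground state owns a disjoint block of
  `marker_genes_per_state = 60` genes elevated by
  `marker_log_fold_change = 1.0` (natural log, ≈ 2.7×) in cells of that
  state — the low end of realistic state-marker contrasts. Ground cells
  carry no block, matching their definition as absence of enrichment.
- **Cell-cycle block**: 60 genes (S-like and G2/M-like halves) elevated by
  `cycle_log_fold_change = 2.0` in proliferative cells only. This is kept
  separate from the state-marker effect size because cell-cycle transcripts
  are near-silent outside cycling cells; contrasts far above those of
  ordinary state markers are the normal biological situation, and the S/G2M
  > 0 classification rule presupposes them.
- **Batch effect**: per-sample per-gene Gaussian shift on the log-mean
  (`batch_sd = 0.2`), reproducing the per-sample grouping merged cohorts
  show before any correction.
- **Library sizes**: lognormal with CV `library_size_cv = 0.3`.
- **Mitochondrial block**: 20 `MT-` genes; each cell's expected
  mitochondrial fraction is Beta(2, 38) (mean 5%), so QC filters have
  something to act on.
- **Composition**: cells are allocated to states by largest-remainder
  quotas (exact fractions; a multinomial draw is available by flag).
  On-treatment samples multiply selected state fractions by
  `treatment_shift` and renormalize.
- **Dispersion** `r = 2.0`: moderate overdispersion typical of UMI counts.

The default cohort is 6 samples × 300 cells — deliberately desk-scale; all
benchmark sizes below are stated explicitly. What the generator does *not*
model: transcriptome-wide co-expression, doublets, ambient RNA,
empty droplets, or length effects (synthetic "TPM" treats genes as
equal-length). Benchmarks passing on this generator therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to every artifact of real droplet data.

`generate_reference` builds a labeled developmental atlas
(default labels SkM.Mesen, MP, MB, MC, MB-MC, satellite) with one disjoint
marker block per label; an `overlap` weight mixes one label's effect vector
into another's (weight 1 ⇒ transcriptionally indistinguishable), emulating
adjacent stages of fetal myogenesis.

`generate_bulk` mixes per-state pseudobulk count profiles by specified
fractions and rescales each profile to sum to 10⁶.

## Preprocessing

- QC removes cells by mitochondrial fraction, detected-gene count, and
  (for xenografts) mouse-read fraction. Presets `danielli` (>15% mito,
  <200 or >8000 genes), `wei` (>20%, <1000 or >8000, >5% mouse), `patel`
  (>10%, <400 or >7000) and `rh41` (>15%, <200 or >8000) mirror the
  source-study rules.
- Log-normalization: `ln(1 + 10,000 · count / cell_total)`; 10,000 is the
  convention all source studies used.
- HVG selection ranks genes by the z-score of `log(var/mean)` within 20
  equal-frequency mean-expression bins (a dispersion statistic with a
  mean-variance trend correction); deterministic, zero-variance genes rank
  last.
- `center_batches` subtracts per-sample per-gene means from the
  log-normalized layer (restoring the global mean) — a lightweight
  alternative to anchor-based integration that removes additive batch
  shifts before scaling/PCA. Scoring and marker detection keep the
  uncorrected layer, since module scores compare genes within a cell and
  are insensitive to per-gene shifts.
- Clustering operates on the shared-nearest-neighbor graph (Euclidean KNN
  in PC space, `n_neighbors = 20`, Jaccard edge weights, pruned below
  1/15) with modularity optimization — Louvain multilevel by default,
  Leiden behind the same interface. Cluster ids are ordered by size;
  randomness is seed-controlled.
- Marker detection is one-vs-rest Wilcoxon rank-sum on log-normalized
  values, reported for genes with natural-log fold-change ≥ 0.25 (on
  de-logged means + 1) expressed in ≥ 25% of the cluster, BH-adjusted per
  cluster. Groups of ≤ 10 vs ≤ 10 cells (≤ 20 total) switch to exact
  enumeration of the rank-sum null with midranks.

### Model selection in the clustering benchmark

Real-cohort defaults are 15 PCs and resolution 0.3 (the published recipe).
The synthetic 4-state benchmark instead selects both data-dependently,
mirroring how the originals were chosen (elbow plot; resolution where the
cluster count stabilizes):

- `select_elbow_pcs`: the eigenvalue noise floor is the median of the
  leading 30 eigenvalues; components above 1.25× the floor count as
  signal, and twice that count is retained. The 2× padding matters:
  keeping only the signal dimensions makes the SNN graph over-fragment,
  while large noise-dimension counts blur the ground-state boundary.
- `select_stable_resolution`: cluster at resolutions 0.4–1.0, find the
  modal cluster count, return the median resolution achieving it.

On the default cohort this selects ~8 PCs and resolution 0.7–0.9, giving
k = 4 and ARI 0.92–0.96 across cohort seeds.

## Scoring

`module_score` follows the control-gene scheme: genes are ordered by mean
log-normalized expression (ties broken by name) and split into
`n_bins = 24` equal-frequency bins; each detected signature gene draws
`n_ctrl = 100` controls from its bin — without replacement when the bin is
large enough, with replacement otherwise — and the pooled controls (with
multiplicity) are averaged. Missing signature genes are logged and
dropped at scoring time, not at signature construction.

Scores are scaled per score vector to mean 0, unit sample variance
(constant vectors → 0). **MLS is computed on the scaled scores**
(`MLS = D − P`); a flag allows raw-score MLS for sensitivity analysis.
Cell-cycle classification applies the S > 0 / G2M > 0 rule to the *raw*
module scores; scores exactly 0 classify as low (the boundary case the
two threshold rules leave open).

Bulk profiles are scored by the identical code path after `ln(TPM + 1)`,
treating samples as cells; scaling a single profile is refused with a
pointer to `scale_scores=False`.

The packaged `cell_cycle_genes.gmt` contains the canonical S (43 genes)
and G2/M (54 genes) phase lists used throughout droplet single-cell
pipelines; `provisional_states.gmt` ships small starter lists for the
neuronal, interferon and apoptotic states, explicitly marked provisional —
real analyses should substitute curated programs.

## State assignment and composition

Cluster-level annotation labels each cluster by the state signature most
over-represented among its markers (hypergeometric, BH-adjusted, α = 0.05;
ties or non-significance → Ground) and collapses same-state clusters.

The per-cell rule is a two-tier threshold on scaled scores: arg-max state
when its score exceeds τ = 0; the transiting variant (TR-Progenitor /
TR-Differentiated) when the score lies in (τ, τ_hi = 1); Proliferative for
high-cycling cells with no score above τ; Ground otherwise. Arg-max ties
break by the fixed order Progenitor > Differentiated > Proliferative >
Neuronal > IFN > Apoptotic > Ground. This per-cell rule is a formalization
of the published cluster-level assignment — the source analysis assigned
states to clusters, not cells — so the τ/τ_hi tiers are this package's
explicit, configurable construction.

Per-sample composition reports counts and fractions; a sample is
neuronal-positive when its neuronal fraction exceeds 1%.

`compare_composition` tests per-state group differences on
centered-log-ratio transformed counts (pseudocount 0.5) with
label-permutation two-sided p-values (a +1-corrected estimator) and BH
control at FDR 0.05. This is a deliberately lightweight stand-in with the
same decision semantics as Bayesian compositional models (per-state
credible / not credible at a target FDR); the samples × states count table
it consumes is exactly what those tools ingest, so users can export it
unchanged. Measured on 10 vs 10 samples of 500 cells: type-I (any state
flagged under the null) ≈ 0.04–0.05 at nominal 0.05 over 1000 replicates;
power ≈ 1.0 against a 3-fold progenitor enrichment.

`paired_shift_test` computes the exact two-sided signed-rank null by
dynamic programming over (doubled, midrank-safe) rank sums for up to 25
informative pairs, and a tie- and continuity-corrected normal
approximation beyond. Zero differences are dropped; an all-zero set
returns p = 1 with a warning. Direction is the sign of the mean paired
difference.

## Label transfer

`transfer_labels` re-implements the correlation-with-fine-tuning scheme:
Spearman correlation of each test cell against reference profiles on the
union of pairwise top differential genes (top 50 per ordered label pair by
median log-expression difference), per-label aggregation at the 0.8
quantile, then iterative fine-tuning that keeps labels within
`tune_delta = 0.05` of the best and re-correlates on the surviving labels'
pairwise markers until one remains (final ties keep the higher pre-tuning
score). Two choices matter in the single-cell setting:

- reference cells are pooled into ≤ 20 pseudo-profiles per label (seeded
  partition, mean expression) before correlating — individual droplet
  profiles are too shallow to anchor rank correlations, and aggregated
  references are the recommended usage of the underlying framework for
  single-cell references;
- the reference is capped at 200 cells per label (seeded) for
  tractability; quantile scores are stable under this subsampling.

Held-out recovery on the default synthetic atlas is ≥ 0.99; with two
labels forced indistinguishable (overlap = 1) recovery within the pair
drops to chance while all other labels stay ≥ 0.95 — the intended
behavior, since the scheme cannot (and should not) separate identical
transcriptomes. Transfer is per-cell; per-cluster transfer is possible
future work.

## Pipeline

`run_pipeline` derives each stage's seed as
`sha256(f"{global_seed}:{stage}") mod 2³¹`, so toggling one stage never
perturbs another's randomness, and writes a manifest with stage seeds,
input hashes and cell/gene counts. The consensus stage of the synthetic
pipeline emulates its real-data counterpart by jittering the planted
marker lists into three pseudo-study lists (80% of genes kept each,
seeded) and applying the consensus rule with the planted list as the atlas
clause.

## Benchmark sizes and runtimes

All benchmarks run single-core in minutes: recovery benchmarks use the
default 6 × 300-cell cohort and a 900-cell reference atlas; shift-test
power uses 200 cohorts of 14 × 150 cells × 1000 genes; compositional
calibration uses 1000 replicates of 20 × 500-cell count tables with
500-permutation tests.

## Known limitations

- The generator's independence of genes given state means clustering and
  scoring benchmarks are easier than real data with correlated programs;
  conversely its shallow 2,000-UMI libraries and per-gene batch shifts are
  harsher than well-integrated deep data.
- The CLR permutation test treats samples as exchangeable within groups
  and ignores the uncertainty of very small cell counts per sample.
- Exact symbol matching only; no alias resolution is applied by default
  anywhere (an alias table hook exists on signatures).
- The per-cell TR- tiers depend on the score scaling population: scores
  scaled within a different cohort composition shift the τ boundaries.
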