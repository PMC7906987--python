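# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Preprocessing

Inputs are per-study gene × sample matrices assumed to be on the
expression scale of the originating platform.  When a matrix is not yet on
the log scale, `log2_transform(x, pseudocount)` applies
`log2(x + pseudocount)`; the transform is never applied automatically
because log-ness cannot be inferred reliably from the values.

Quantile normalization forces every sample (column) onto the common
empirical distribution defined by the row means of the column-sorted
matrix.  Ties within a column receive the mean of the reference values
their positions span — deterministic, and the standard choice.  Ties are
the one case where normalized columns do not share literally identical
sorted vectors; for continuous expression data this is immaterial.
Normalization is applied **within** each dataset: the meta-analysis pools
evidence *across* datasets and absorbs between-study location/scale
differences, so cross-study normalization is unnecessary and would couple
otherwise independent cohorts.

Probe-level matrices are collapsed to genes through a user-supplied
probe → gene table, either keeping the probe with the highest mean
expression (`max_mean_probe`, the default — it favors the best-hybridizing
probe) or taking per-sample medians over a gene's probes.  The chosen
probe (or probe count) is recorded per gene so the collapse is auditable;
unmapped probes are reported, never silently dropped.  Genes with missing
values in a dataset are dropped from that dataset and reported — no
imputation.

## DEG meta-analysis

Each compartment (tubule, glomerulus) is analyzed over its case/control
datasets; a dataset needs at least 2 samples per group.

**Effect-size route.** Hedges' g per gene per dataset (case minus
control), with genes of zero pooled SD flagged degenerate and excluded for
that dataset.  Fixed-effect inverse-variance pooling across datasets gives
`f_meta`, `se`, `z`, and a two-sided normal p; Cochran's Q and I² are
computed and logged per gene but never gate calls — the fixed-effect model
is the deliberate choice, estimating the average effect over these
specific cohorts.  BH FDR over all genes present in at least
`min_datasets_present` (default 2) datasets; cutoff `fdr_max = 0.05`.
`mean_log2fc` is the unweighted mean over datasets of the case−control
difference of log2 means (the paper-style fold change used only for the
≥1.5 enrichment-export filter, not for inference).

**SAM route.** Per dataset, `d_i = (x̄_case − x̄_ctrl)/(s_i + s0)` with
`s_i` the unequal-n standard error form of the pooled scatter.  The fudge
factor s0 is selected Tusher-style: candidates are the percentiles
{0,5,…,100} of the s distribution; the winner minimizes the coefficient of
variation of windowed MADs of d across 100 s-quantile windows (ties →
smallest candidate; below 100 genes the criterion is noise and the 5th
percentile of s is used).  q-values come from label permutations (all
`C(n, n₁)` assignments enumerated exactly when fewer than
`n_permutations = 1000` exist): the estimated FDR at threshold `|d|₍ᵢ₎` is
the mean pooled null count at or above the threshold divided by the
observed count, and q is its running minimum over more lenient
thresholds, hence monotone in the |d| ranking.  No π₀ estimate is applied
(conservative).  Null counts use a 1e-9 relative epsilon so permutations
reproducing the observed labeling are counted despite round-off in the
vectorized sums of squares.

**Cross-dataset combination.** Two readings are implemented.

- `fisher` (default): Fisher's method, `X = −2Σ ln pᵢ ~ χ²(2m)`, on the
  per-dataset pooled permutation p-values of |d| (add-one smoothed);
  cutoff `repl_p_max = 0.05`.
- `binomial`: the exact one-sided binomial tail `P(K ≥ k | m, 0.10)` on
  the number k of datasets calling the gene at q < `sam_q_max = 0.10` —
  the probability of k replications if per-dataset calls were null at the
  cutoff rate.

The Fisher default is a power decision this package stands behind: with m
small (4 cohorts) the binomial route needs q < 0.10 in ≥3 of 4 cohorts to
reach p ≤ 0.05, and per-cohort SAM power at desk-scale effect sizes
(g ≈ 1, 15v15) is only ~0.35, collapsing end-to-end sensitivity to ~0.11
(measured on synthetic data) while Fisher's combination reaches ~0.99 at
equal null calibration.  The binomial option remains for strict
replication-counting semantics.

**Final call**: a gene is a DEG iff effect-route `q_fdr ≤ 0.05` **and**
combined SAM `p ≤ 0.05`; its direction is the sign of `f_meta`.  Genes
missing from either route (absent from enough datasets, degenerate) are
never final DEGs and are reported with the reason.

## DEG comparison

Pure set algebra on the two compartments' final DEG sets (unique A, unique
B, shared), with counts logged.  The default overlap is identity-only; a
direction-aware variant (shared only when called with the same sign in
both compartments) is provided but off by default, matching how published
Venn counts are usually computed.

## Cross-compartment correlation screen

For each paired cohort, samples are matched by patient (patients present
in only one compartment are dropped pairwise; one sample per patient per
compartment).  The candidate universe is tubular-DEG × glomerular-DEG.
Each pair gets Pearson r (t-test p, df = n−2), Spearman ρ (Pearson on
average ranks, t approximation), and Kendall tau-b (tie-corrected,
asymptotic normal p).  Pearson and Spearman are computed as vectorized
cross-correlation matrices; Kendall, the expensive one, only on pairs
whose fate still depends on it.

Thresholds: magnitude > `r_min = 0.7` and p < `corr_p_max = 0.001`,
consensus rule `all_three` (every method must pass; `any_one` and
`pearson_only` available).  The magnitude cutoff is stated on the Pearson
scale.  Rank coefficients are intrinsically attenuated: under a bivariate
normal with correlation r, the population values are
`ρ_s = (6/π)·asin(r/2)` and `τ = (2/π)·asin(r)` (Greiner's relation), so
τ at r = 0.85 is only 0.647 — a verbatim τ > 0.7 cutoff would reject
essentially every genuinely strong pair while the p-value cutoff is
already enforced per method.  By default (`match_rank_thresholds = True`)
the Spearman/Kendall cutoffs are therefore mapped through these relations
(0.7 → 0.683 and 0.494), making the three magnitude tests equally
stringent; set the flag to False for verbatim thresholds.

Correlation p-values are deliberately **not** multiple-testing corrected
(the screen applies a raw p cutoff, replicated across every cohort); the
run log reports the implied expected false-pair bound
`n_tests · (p_max/2)^m` for transparency.

A consensus pair must appear in **all** paired cohorts with a consistent
Pearson sign (sign-conflicting pairs are rejected by default).  The pair
network labels genes tubule/glomerulus/both and carries the consensus sign
and the median Pearson r across cohorts per edge; it is exported as a SIF
edge list plus a node-side attribute table.

## Secretome annotation

The secreted-protein list is user-supplied (one gene id per line; such
lists drift between releases, so the file's SHA-256 is recorded in the run
log).  Ids are uppercased and trimmed on load.  Each consensus pair gains
`tubule_secreted`/`glom_secreted` flags; per-compartment summary counts
are of **distinct** genes, not pairs.  Pairs whose tubular gene is
secreted are ranked first: a secreted tubular product reaching the
glomerulus is the natural candidate ligand → target hypothesis.
Annotation never adds or removes pairs.

## Synthetic data

The generator emulates desk-scale versions of the multi-cohort studies the
pipeline targets, all on the log2 scale with Gaussian noise (microarray
data are approximately Gaussian after log transform and quantile
normalization):

- one shared baseline mean per gene ~ N(8, 2) (a single draw per
  collection — redrawing baselines per dataset would make the batch term
  redundant), plus a per-dataset scalar batch shift ~ N(0, 0.5) and
  per-cell noise ~ N(0, `noise_sd` = 1);
- planted DEGs shift case samples by ±`effect_size_true · noise_sd` (half
  down-regulated), so the true Hedges' g equals `effect_size_true`
  regardless of noise level;
- planted pairs share a patient-level latent factor:
  `x_tub = √|ρ|·z + √(1−|ρ|)·e₁`,
  `x_glom = sign(ρ)·√|ρ|·z + √(1−|ρ|)·e₂`, giving population
  cross-correlation exactly ρ;
- paired cohorts are generated as single-group disease cohorts feeding
  only the correlation stage, while case/control cohorts feed the
  meta-analysis — this separation keeps the planted-pair ground truth free
  of group-effect-induced correlations;
- in the full synthetic study, pair genes are drawn from the planted DEG
  sets so the DEG-restricted correlation universe contains the truth.

Default sizes (4 cohorts of 15v15 per compartment, 1,000 genes, 50 planted
DEGs at g = 1.0; 4 paired cohorts of 40 patients, 20 planted pairs at
ρ = 0.85) are the study conditions used throughout the calibration tests
and the reproduction script.  Not emulated: probe-level effects,
missingness, RNA-seq count overdispersion, disease heterogeneity across
cohorts, and correlated gene-gene background structure — so passing
recovery tests demonstrate correctness of the estimators under the stated
model, not performance on any particular real cohort.

## Numerical conventions and reproducibility

- One root seed; each stage (and each dataset within a stage) draws from
  its own derived stream keyed by a fixed stage code plus a CRC-32 of the
  dataset id, so adding a stage never perturbs another stage's draws.
- All TSV floats are written with 10 significant digits (`%.10g`); every
  writer round-trips through its paired reader.  Two runs with identical
  inputs and seed are byte-identical; the run log has no timestamps.
- Degenerate inputs are flagged, never coerced: zero-variance genes have
  undefined effect size/SAM d, constant vectors undefined correlation
  (NaN), and such genes/pairs are excluded with a recorded reason.
- Config validation happens before any computation; unknown keys are
  errors so silently misspelled thresholds cannot pass.

## Known limitations

- The fixed-effect model ignores between-study heterogeneity beyond
  logging Q/I²; strongly heterogeneous cohorts deserve a random-effects
  re-analysis outside this package's scope.
- The correlation screen is marginal: it does not distinguish direct
  interaction from shared confounding (disease severity will correlate
  many genes), and the paired cohorts provide no causal direction.
- Fisher's combination treats cohorts as independent; patients appearing
  in multiple cohorts would violate that.
- SAM permutation p-values are pooled across genes, which assumes
  approximately exchangeable null distributions after the s0
  stabilization.
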