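# Methods

This note documents the models, defaults and numerical choices behind
`ctcemt`, and what the synthetic cohorts do and do not establish about real
data.

## Preprocessing

The pipeline order is fixed: merge on common genes → cell filter → gene
filter → median normalization → log1p. Conventions:

* **Cell filter** (default 0.10): a cell is kept when its fraction of
  nonzero genes is *at least* the threshold — "fewer than 10 %" read
  literally, so a cell at exactly 10 % survives.
* **Gene filter** (defaults count ≥ 5 in ≥ 10 cells): both bounds
  inclusive. The stricter marker-matrix variant used before scoring (cells
  expressing ≥ 10 % of the *marker* genes; markers with count > 5 in ≥ 30 %
  of cells) is the same pair of operations with different parameters.
* **Median normalization**: each cell is scaled by (median library
  size)/(own library size), with the median taken over the cells that
  survived filtering, using the standard midpoint median for even counts.
  This preserves within-cell expression proportions exactly.
* **log1p** uses the natural logarithm; an optional `base` argument
  rescales. A provenance flag forbids double transformation.
* Gene identifiers match by exact string comparison after case
  normalization; no alias/synonym resolution is attempted (a documented
  limitation for real multi-study merges).

## E:M scoring

Within each cell, expression over the union of epithelial, mesenchymal and
CSC marker genes is standardized to mean 0, SD 1 (population SD, so the
hand-checkable example (1,2,3) → (−√(3/2), 0, +√(3/2)) holds exactly). The
phenotype score is the mean Z over that phenotype's markers. The
Z-transform axis is configurable (`axis="gene"` standardizes per gene
across cells); the within-cell reading is the default.

Two E:M score modes exist. The literal **ratio** `z_e/z_m` is reported for
every cell, with denominators below 1e−8 flagged non-finite and excluded
from ordering (the count is logged, never silent). The **difference**
`z_e − z_m` is the default *ordering* key: when the two phenotype scores
are strongly anti-correlated — the empirical regime for CTCs — the ratio
concentrates near −1 and flips sign as the denominator crosses zero
mid-continuum, so it cannot induce a monotone order, while the difference
is monotone along the continuum and satisfies the intended sign convention
(epithelial-enriched cells score large and positive and appear first).
Ordering is descending with deterministic lexicographic tie-breaks.

Other choices: moving-average window defaults to `max(5, ceil(0.1·n))`
with shrinking windows at the edges (output length = number of cells);
two-group stratification uses agglomerative clustering with Ward linkage
on Euclidean distances; all transcriptome-side correlations are Spearman
by default (Pearson available); the MHC summary in the PD-L1 table is the
mean over the available HLA class I genes (HLA-A/B/C), with a single-gene
variant (HLA-B) exposed through `genes_b`.

## Circuit ensemble

**Dynamics.** Every edge contributes a shifted Hill factor
`HS(X) = λ + (1−λ)/(1+(X/X0)^n)`; node dynamics are
`dY/dt = l·∏HS − k·Y`. Unregulated nodes settle at `l/k` exactly, which
the tests use as a closed-form anchor.

**Parameter ranges** (uniform, per model): production 1–100, degradation
0.1–1, integer Hill coefficient 1–6, activation fold-change 1–100,
inhibition fold-change 1/U(1,100). Thresholds follow a half-functional
rule: U(0.02·M, 1.98·M) with M = (median production)/(median degradation)
≈ 92, the median unregulated level of a regulator. This ignores in-network
modulation of the regulator's distribution — a simplification relative to
estimating each regulator's realized range by Monte Carlo.

**Shipped topology** (`data/emt_network.tsv`): SNAIL-type EMT inducer
activating ZEB and repressing miR-200; mutual repression miR-200⊣ZEB and
GRHL2⊣ZEB (the two double-negative feedback loops); CDH1 activated by
GRHL2 and repressed by ZEB and SNAIL; VIM activated by ZEB and repressed
by GRHL2. Treating the epithelial enforcer GRHL2 as VIM's repressor is a
design choice: SNAIL induces rather than represses VIM, and GRHL2⊣VIM
appears in published EMT-circuit models. The topology is data, not code —
any SIF-like TSV (`source  target  sign`) can be substituted. miR-200, a
microRNA, is modeled as an ordinary node with shifted-Hill regulation; the
specialized microRNA–mRNA sequestration formulation is out of scope.

**Integration.** Steady states are found by a positivity-preserving
exponential-Euler relaxation, `X ← X* + (X − X*)·exp(−k·dt)` with
`X* = l·∏HS(X)/k`, at dt = 0.1 up to t_max = 200, with a convergence test
every 5 time units; columns whose independently re-evaluated residual
`‖l·∏HS − k·X‖∞` falls below 1e−6 are frozen. The scheme is exact for the
linear degradation term, cannot converge to anything but a true fixed
point, and is stable for the stiff parameter corners (large fold-changes,
small thresholds) that trip explicit Runge–Kutta steps at practical step
sizes. The trade-off: transient trajectories are only first-order
accurate, so basin multiplicities are approximate; the steady states
themselves are not. Tests cross-check against `scipy.integrate.solve_ivp`
and against brute-force nullcline root-finding on two-node circuits.
Models where no initial condition converges within t_max are flagged and
excluded (the ensemble fails loudly if they exceed 50 %).

**Census.** Converged endpoints are clustered into distinct states at
relative L∞ distance 1e−2. Each (model, state) pair enters correlation
analyses once; basin multiplicity is recorded but not used as a weight.
Ensembles run in triplicate with replicate-offset seeds
(`default_rng([seed, replicate])`); the default ensemble size is 1000
converged models × 50 initial conditions per replicate, which one CPU
completes in well under a minute per replicate. Correlations between node
levels are computed on log2(x+1)-scaled values with Pearson's r by default
(the ensemble-simulation convention); Spearman is available.

## Classification harness

CTC is the positive class everywhere. Defaults: Gaussian naive Bayes on
log-expression; random forest with 500 trees; gradient boosting with 100
rounds of depth-3 trees at learning rate 0.1; PCA dimensionality 20 when
the `median+pca` variant is requested. The plain median-normalization
configuration is the reference. All stochastic components take mandatory
seeds.

Leave-one-dataset-out holds each batch/study out in turn. The median
library size, PCA basis and classifier are fitted on the training
partition only and applied frozen to held-out cells; the test suite
verifies this by perturbing held-out cells and asserting the fold's fitted
model is bit-identical. Mixed evaluation sets (held-out CTCs plus a seeded
sample of held-out PBMCs, default 500) are available via
`mixed_pbmc_sample`. Both per-fold and mean (macro) accuracies are
reported; micro-averaging can be recovered from the confusion counts in
the report.

Surface-marker ranking uses one-sided Wilcoxon rank-sum tests (CTC >
PBMC) with Benjamini–Hochberg correction at FDR 0.05 and log2 fold-changes
of pseudo-counted means, sorted by adjusted p then fold-change.

## Synthetic cohorts

The generator emulates the statistical structure of a multi-study
CTC/PBMC compendium. Defaults (chosen once as realistic for canonical
markers, and used by the test suite as the study conditions): 300 CTCs and
900 PBMCs over 3 batches and 2000 genes; marker panel of 16 epithelial,
39 mesenchymal, 26 CSC (split 13 late-up CD44-like / 13 late-down
CD24-like) and 10 leukocyte genes; latent continuum position t ~ U(0,1)
(a bimodal Beta mixture emulates pole-clustering); marker gradients span 3
log2 units (eight-fold) across the continuum, with the CSC arms ramping
only beyond t ≈ 0.6; library sizes U(20k, 60k); negative-binomial counts
with gene-level dispersion θ ~ lognormal(ln 10, 0.5); Bernoulli dropout at
rate 0.3 independent of expression level; multiplicative log-normal
gene×batch factors with σ = 0.25. PD-L1 rises and HLA class I falls along
the continuum in CTCs (HLA constitutively high in PBMCs), and three
surface genes (ITGB5, TACSTD2, SLC39A6) carry a planted +2.5 log2
CTC-vs-PBMC effect. A configurable fraction of cells can be planted below
the 10 % expression bar to exercise the quality filter.

What passing tests on these cohorts show — and do not. They establish
that the scoring recovers a monotone latent ordering *when one exists*,
that the classifier harness is leak-free and responds monotonically to
effect size, and that filters/metrics are exact. They do not establish
performance on real CTC data: the generator has no ambient RNA, no
platform-specific length/GC biases, no doublets, no correlated gene
modules beyond the planted ones, expression-independent dropout, and
batch effects that are purely multiplicative. Real multi-study integration
also faces gene-identifier heterogeneity that the exact-match policy does
not address.

## Pipeline

A single YAML config drives the stage sequence; unknown keys, duplicate
keys and out-of-range values are rejected with all violations listed at
once. The global seed fans out to per-stage sub-seeds via
`SeedSequence([seed, stage_index])`, so stages re-run in isolation
reproduce the pipeline's results. The manifest records each stage's
parameters, survivor counts, outputs with SHA-256 hashes, and timings;
identical configs reproduce identical hashes.

## Known limitations

* The ratio-mode E:M score is faithful to its definition but unusable as
  an ordering key under strong phenotype anti-correlation (see above);
  analyses that need the continuum should use the difference mode.
* Threshold sampling ignores in-network modulation of regulator levels.
* Basin multiplicities from the relaxation scheme are approximate.
* No stochastic (Langevin/Gillespie) circuit dynamics, no bifurcation
  continuation, no parameter fitting to expression data.
* Harmony-style batch integration is not reimplemented; the classifier
  accepts an externally corrected matrix through the same interface.
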