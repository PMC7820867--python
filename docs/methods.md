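# Methods

`cytodm` implements a two-step association analysis between a tissue
cytokine panel and the mucosal microbiota, together with the standard
community statistics used to characterize paired tumor/healthy 16S data sets,
and a ground-truthed simulator of the whole design. This note records the
models, the defaults and the reasoning behind every genuinely open design
choice.

## The regression response

The dependent variable of both analysis steps is a J-category composition
built from a genus-level count table: the `top_k` (default 3) most abundant
genera — in colorectal mucosa typically *Bacteroides*, *Prevotella* and
*Escherichia/Shigella* — keep their own categories and everything else is
pooled into a `residual` category. Pooling partitions the counts, so
per-sample totals are conserved exactly; ranking ties are broken
lexicographically and logged. Top-k ranking uses only the samples of the
tissue being analyzed, because tumor and healthy tissues are modelled
separately throughout.

## Step 1 — marginal screening (sure independence screening)

Each cytokine is evaluated alone: a Dirichlet regression with concentrations
`alpha_ij = exp(b_0j + x_i b_1j)` is fit by maximum likelihood and compared
with the intercept-only model by a likelihood-ratio test with J degrees of
freedom (one added coefficient per category). Cytokines are ranked by
ascending p-value (ties: statistic descending, then name) and the top `m`
(default 3, exposed everywhere) advance to step 2. The p-values serve only to
rank; no multiple-testing correction is applied because none is implied by a
screening rule.

Counts are mapped to strictly interior compositions with a 0.5 pseudocount
before the Dirichlet density is evaluated — a Dirichlet likelihood is
undefined on the simplex boundary and genus tables contain zeros.

Numerics: the free log-concentration ("alternative", common-reference-free)
parametrization is used, L-BFGS-B on the per-sample mean negative
log-likelihood with analytic gradients, deterministic start (intercepts at
the log mean composition scaled to total concentration 10, slopes 0).
Convergence is declared at max-abs gradient 1e-6 on the per-sample scale
(the optimizer itself targets 1e-8; observed optima land around 1e-9–1e-8).
Non-convergent single-cytokine fits receive p = 1 with a logged warning
rather than aborting the screen.

## Step 2 — Bayesian variable selection in Dirichlet-multinomial regression

Counts y_i follow a Dirichlet-multinomial with `alpha_i = exp(x_i' theta)`.
Sparsity comes from a hard-thresholding map on raw coefficients b:

    theta_kj = b_kj · 1[|b_kj| >= t]   (covariates), theta_0j = b_0j (intercepts)

with independent N(0, `prior_sd`²) priors on b (default sd 1.0) and a
uniform prior on the threshold t over (0, `t_max`] (default `t_max` 1.0; a
fixed threshold is also supported). A coefficient is "included" when it
survives the threshold; the posterior probability of inclusion (PPI) of a
cytokine-category pair is the posterior mass of |b_kj| ≥ t. Reported
posterior means are conditional on inclusion and exactly zero for pairs
never included, matching how sparse association tables are printed
(sub-threshold means remain available behind a flag). Intercepts are never
thresholded, so their PPI is 1 by construction.

Sampling is Metropolis-within-Gibbs, default 20 000 iterations with 10 000
burn-in:

- elementwise Gaussian random-walk updates of each b_kj (`proposal_sd`
  default 0.2), with likelihood deltas computed incrementally (an update of
  b_kj touches only concentration column j);
- a whole-row shift move per covariate: adding a constant to one covariate's
  coefficients across all categories rescales every concentration of a
  sample by a common factor and is therefore a weakly identified direction
  of the DM likelihood; without an explicit move along it the chain can
  lodge in a dense-row mode and escape only geometrically slowly;
- a random-walk update of t plus an independence draw from its prior, which
  lets the chain hop between threshold regimes.

Acceptance rates are reported per block. The "covariate" rate counts moves
of currently included coefficients — the part of the chain whose mixing
matters — and a tuning warning is emitted when it leaves [0.10, 0.60].
Births (excluded-to-included crossings), excluded prior-only moves, row
shifts and threshold moves are tallied separately.

Correctness of the sampler is checked two ways: seeded determinism and
category-permutation equivariance in the test suite, and agreement (within
0.05) of its inclusion probabilities with a dense-grid quadrature of the
exact posterior on a K=1, J=2, n=15 problem with fixed threshold. The
threshold is fixed for that check because it keeps the quadrature
four-dimensional; the uniform-threshold prior remains the sampler default.

Open choices committed here (all config-exposed): the threshold acts on the
raw coefficient scale and is global across categories; tumor and healthy
fits use the same selected cytokines unless an explicit list is given.

## Covariates

Luminex cytokine panels are right-skewed pg/ml concentrations with assay
quantification limits. Values strictly below the cytokine's LLOQ are
censored to 0 pg/ml (the censoring mask is kept); values above the ULOQ are
either clipped or flagged, per policy. The 26-cytokine LLOQ/ULOQ table of
the emulated assay ships as a packaged CSV. The default design transform is
log1p followed by per-column z-scoring — the analysis source does not state
its covariate scaling, and raw pg/ml scales would dominate the log link —
with the transform recorded in the design matrix and in all outputs.

## Community metrics

Shannon diversity uses the natural log, and evenness is S/ln(R) (Pielou's
index; the ratio is log-base invariant, so the configurable base only
affects the reported Shannon values). Chao1 uses the classic
singleton/doubleton estimator with the bias-corrected form when no
doubletons exist. Good's coverage is reported in percent. Rarefaction
curves use the exact hypergeometric expectation of richness at each depth
(grid `step` default 50 reads, always ending at the observed total) rather
than random subsampling, so they are deterministic; a Monte-Carlo
subsampling oracle validates them in the tests. A sample is flagged
saturated when the increment in expected taxa per read over the last grid
interval falls below 1e-5 (configurable). The paired-design check clusters
sqrt(count/total)-transformed samples with complete-linkage Euclidean
clustering and scores the fraction of patients whose two samples form a
direct merge in the dendrogram (each being the other's first partner) — the
dendrogram analogue of mutual nearest neighbors, adopted because the
emulated analysis reports "paired" samples without an explicit criterion.
The paired Wilcoxon signed-rank test drops zero differences, uses an exact
integer dynamic program over doubled midranks up to 25 nonzero differences
(handling ties exactly) and a tie-corrected normal approximation beyond.

## Synthetic studies

The generator emulates the study design end to end: `n_patients` (default
40, matching the sequenced pairs of the emulated study) each contribute a
tumor and a healthy sample; cytokines are log-normal (log-sd 1.0) with
log-median anchored at 4x the LLOQ so a realistic ~8% of values exercise
the censoring path, and tumor samples are shifted on the log scale
(default +0.5). The panel is censored and standardized exactly as the
analysis pipeline would do, and the resulting design drives the counts
through the same log-link DM model the inference assumes — so recorded
ground-truth coefficients are the estimands of the two-step analysis, with
a default of 2 active cytokine-category pairs of magnitude 1.5 among K=8
cytokines and J=4 categories.

Concentrations are `alpha_i = (s/J) exp(x_i' B)` with a single total
concentration scale s (default 50), so a zero coefficient matrix gives
total concentration exactly s; the scaling is an intercept shift and keeps
the generator inside the inference model's class. Sequencing depths are
uniform on [1e4, 1e5]. Intercepts grade the focal genera (0.5 down to 0.2)
under a dominant residual (1.2), mirroring real mucosa tables where the
pooled tail holds 40–50% of reads; the residual is split across 20
background genera with a moderate long-tail profile (lognormal sd 0.6) so
no background genus rivals the focal ones, and genera are further split
into 1–5 OTUs so aggregation, diversity and rarefaction all operate on
realistic sparse tables. A per-patient random effect on the log
concentrations (sd 0.3, shared by the patient's two samples) makes paired
samples more alike than strangers.

What the generator does not emulate: sequencing error, chimeras and
OTU-picking noise; phylogenetic correlation among genera; zero-inflation
beyond what the DM produces; tissue-specific coefficient matrices (supported
but off by default, since the emulated analysis is ambiguous on this point).
Passing recovery tests therefore demonstrate correctness of the inference
machinery under the stated model, not robustness to real-data violations of
it. In particular the patient effect is deliberately mild, so the
dendrogram pairing fraction on synthetic data is far below the near-90%
seen in real paired mucosa — the clustering check is validated instead by
its analytic extremes (identical pairs → 1, i.i.d. samples → low).

## Problem sizes and runtime

Default chains (20 000 iterations) take ~10 s at study size (n=40, K=8,
J=4) on one core. The statistical acceptance checks use: 500 replicates for
LRT null calibration (n=100), 50 replicate studies for screening power, 10
replicate studies at the default study conditions for BVS recovery, 5
chains against the quadrature oracle, and a 2 000-iteration chain for the
byte-identity determinism check (determinism does not depend on chain
length). The whole suite runs in a few minutes on one core.

## Known limitations

- The LRT null distribution is asymptotic; at n well below ~50 with J=4 the
  chi-square reference becomes approximate (calibration is verified at
  n=100).
- PPIs depend on the prior scale and threshold prior; they are posterior
  probabilities under this specific spike-free thresholding prior, not
  frequentist error rates.
- The screening step inherits the usual blindness of marginal methods to
  predictors that matter only jointly.
- Dirichlet regression treats compositions derived from counts as exact;
  very low-depth samples are better served by the DM screening switch
  (`screen` on DM likelihood is available as a sensitivity path through the
  same LRT machinery).
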