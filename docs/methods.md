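# Methods

## The generative model

Every model in this package starts from the same assumption: the count of
reads whose alignment starts at position *j* of gene *i* is

    n_ij ~ Poisson(mu_ij),    mu_ij = omega_ij * mu_i,

where mu_i = exp(nu_i) is the gene's expression level and omega_ij =
exp(a_ij) is the *sequencing preference* of the position — a
multiplicative factor determined by the local sequence around the read's
first base. Counts at different positions are independent. Overdispersion
of pooled counts within a gene (Fano factors far above 1) is then not
extra-Poisson noise but the signature of heterogeneous mu_ij; the
modeling task is to predict omega_ij from sequence.

The local context is a window of `w_up` bases upstream of the read's
first base and `w_down` bases from the first base onward (offset 0 *is*
the first read base). Each window position contributes three 0/1
indicators (A, C, G); T is the reference level, so a window of length
K = w_up + w_down yields 3K features, and an 80-nt window yields 240.

## The Poisson log-linear model

`poislin.fit_linear_pref` maximizes the joint likelihood in
(alpha, beta, nu) by alternating exact conditional maximizations:

1. initialize nu_i = log(N_i / L_i);
2. treat nu as known per-row offsets and fit the Poisson regression for
   (alpha, beta) by IRLS (statsmodels GLM, tolerance 1e-10);
3. update nu_i = log(N_i / W_i), where W_i = sum_j exp(alpha + x_ij'beta)
   is the gene's sum of preferences — the conditional MLE, which forces
   the fitted total sum_j mu_ij to equal N_i exactly;
4. stop when the relative deviance decrease falls below `rel_tol`
   (default 0.01, i.e. "less than 1%"), with a `max_iter = 50` guard.

Because each half-step is a conditional MLE, the deviance trajectory is
non-increasing (asserted on every fit) and the limit is the joint MLE: on
small instances the final deviance matches a directly fitted Poisson GLM
with gene-indicator columns to better than 1e-6 relative (tested).
alpha and the nu_i are confounded; the convention here keeps alpha inside
the preference and lets step 3 set the nu_i. For reporting, preferences
can additionally be rescaled to mean 1 over a gene corpus
(`poislin.normalized_preferences`), which removes the confounded scale.

Deviance is the standard Poisson GLM deviance
2 Σ [y log(y/mu) − (y − mu)] with y log y = 0 at y = 0 — the quantity
`glm()`-style software reports. The null model sets mu_ij = N_i/L_i
(uniform preference within each gene); R² = 1 − d/d0. Coefficient
standard errors come from the observed Fisher information of the final
offset regression, i.e. conditional on the fitted nu. The default
convergence tolerance (1%) is loose; parameter-recovery and
joint-MLE-equivalence tests tighten it to 1e-4 … 1e-12, which the
alternation reaches in tens of iterations on test-scale data.

Genes with zero reads are excluded from fitting (their nu is −infinity);
the top-expressed-gene filter makes this irrelevant on real data but
synthetic data can produce it.

## The boosted-trees model

`treepref` fits the nonlinear counterpart. Per training gene, each count
is divided by the gene mean N_i/L_i to give an empirical preference,
zeros first replaced by 0.5 so the log exists; the log preferences are
regressed on the window indicators by weighted squared-error gradient
tree boosting with per-row weight N_i/L_i (targets of highly expressed
genes have smaller sampling variance). Defaults: `interaction_depth = 10`
(number of splits per tree, i.e. 11-leaf trees grown best-first),
`shrinkage = 0.06`, `n_trees = 2000`, `subsample_fraction = 0.5`,
`min_node_weight = 10` (minimum total mean-normalized row weight per
leaf).

Backend notes. The ensemble is xgboost (`tree_method="hist"`,
`grow_policy="lossguide"`, `reg_lambda = 0`, single thread, seeded —
deterministic given the seed). Two semantics matter and are deliberate:

* *Tree size.* "Interaction depth" here counts **splits per tree**
  (R gbm's semantics, 11 terminal nodes), not maximum depth. Fully-grown
  depth-10 trees (up to 1024 leaves) interpolate the sampling noise of
  the log-count targets at moderate sample sizes and wreck the
  cross-validated R²; 11-leaf trees keep 2000 shrunken rounds
  well-behaved.
* *Minimum node size.* Row weights are rescaled to their mean before
  fitting — a weighted least-squares fit is invariant to that rescaling —
  so `min_node_weight = 10` means "roughly ten typical observations per
  leaf".

Cross-validation is at the **gene** level: sorted gene ids are shuffled
with a seeded RNG and dealt round-robin into 5 folds (so the split
depends only on the id set and seed, not input order). Per fold, the
model trains on 4/5 of the genes and predicts log preferences a_j on the
held-out genes; each held-out gene's expression is set to the closed-form
Poisson MLE nu = log(Σ n_j / Σ e^{a_j}) (which matches fitted and
observed totals exactly); the fold's deviance against mu_j = e^{nu+a_j}
and null deviance accumulate, and the pooled cross-validation R² is
1 − Σd/Σd0. Note the empirical targets are a *biased* estimate of the log
preference (E log n ≠ log E n, and the 0.5 replacement adds its own
distortion at low counts), so even an ideal fit sits slightly below the
R² of the true preference function; the bias shrinks as expression grows,
which is one reason training is restricted to the most expressed genes.

## Corrected expression, fold change, junctions, isoforms

With predicted preferences rescaled to mean 1 over the training corpus,
the SSP (sum of preferences) of a region is on the same scale as its
length. `express.estimate_gene` reports both N/L and N/SSP; the fold
change max(p̄, 1/p̄) with p̄ = SSP/L equals the ratio of the larger to
the smaller estimate and is 1 when the correction is immaterial. Because
p̄ is an average of positive, short-range-correlated preferences, fold
changes shrink toward 1 as regions grow — corrections matter most for
exons and junctions. Junction regions for read length R are the R−1
start positions spanning the boundary on the concatenated (intron-free)
transcript, trimmed (with a warning) where the transcript ends.

Isoform abundances maximize the Poisson likelihood of exon counts n_e
with means Σ_t theta_t s_et, where s_et is exon e's SSP *within* isoform
t (0 if absent; SSPs may be isoform-specific near junctions, and exon
lengths themselves may differ between isoforms). The likelihood is
concave in theta; the multiplicative EM update

    theta_t <- theta_t * (Σ_e n_e s_et / lambda_e) / Σ_e s_et

increases it monotonically (guarded at runtime). The stopping rule is
**parameter** change below 1e-10 relative to max(theta), not likelihood
change — the likelihood flattens long before theta settles and a
likelihood rule stops ~1e-4 short of the optimum in shares.
Rank-deficient incidence structures are flagged as non-identifiable (a
maximizer is still returned; the fitted exon means are unique even when
theta is not). KKT residuals at the solution are exposed for checking.

## The synthetic-data generator

`simulate` draws, per gene: a region length uniform over
`region_length_range` (minimum 100 nt — shorter regions are what the
extraction filter discards), an i.i.d. sequence from `base_composition`
with `flank_length` extra bases on both sides so context windows never
leave the sequence, a log expression nu_i uniform over
`expression_log_range`, and independent Poisson counts with
mu_ij = exp(nu_i + a_ij) where a comes from a planted log-linear
preference (or any custom position-wise function). Each gene uses its own
RNG streams derived from (seed, gene index, purpose), so subsetting genes
never changes their data.

Defaults are chosen to emulate the *training regime* of the models — the
most highly expressed genes of a run: `expression_log_range = (ln 5,
ln 500)` spans two orders of magnitude with a median per-position mean
count around 50, which under realistic preference variation produces
Fano factors in the tens to hundreds, the magnitudes seen in real
sub-datasets. What the generator deliberately does **not** emulate:
sequencing errors, quality scores, paired ends, mappability/structural
zeros (beyond what toy exact-match counting produces), non-uniform base
composition, correlated preferences beyond window overlap, or
extra-Poisson noise. Passing tests therefore demonstrate correctness of
the estimators under the model's own assumptions — not robustness to the
ways real libraries violate them.

`gen_reads` emits, for each position, count-many copies of the
read-length substring starting there; on a region whose k-mers are all
distinct this inverts the exact-match counter exactly, which is how the
counting path is round-trip tested.

## Problem sizes and numerical choices in the test suite

The behavioral suite runs at reduced scale chosen to keep the full run
under half a minute while leaving the statistics sharp: parameter
recovery uses 50 genes × 500 nt × 10 seeds over a (3,3) window (18
coefficients; ≥95% within 3 SE), the CV-calibration study uses 20 genes
× 500 nt with a planted (4,4)-window preference strong enough that the
true function's oracle R² ≈ 0.7 — the regime of the best-behaved real
datasets — and requires agreement within ±0.05, plus a no-signal run
bounded at cv R² ≤ 0.02. The isoform EM is checked against an
iteratively-refined dense grid search (11³ points per stage, 8 zoom
stages) — an exhaustive oracle sharper than 1e-4 in each share. Counting
is verified against a brute-force substring-scan oracle on random
instances. Serialization of the linear model uses `repr` round-tripping
for bit-exact reload; the boosted model embeds xgboost's native JSON in a
versioned container that validates feature-column order on load.

## Known limitations

* The exact-match toy counter treats uniqueness within a single region,
  not genome-wide; it exists to define the count data contract and for
  round-trip testing, not as a read mapper.
* Quasi-Poisson/negative-binomial variants, regularized fits, and
  dinucleotide or GC features are out of scope.
* The boosted model's empirical targets bias its cross-validated R²
  slightly downward relative to the true preference function (see above);
  at weak signal-to-noise this gap can reach a few R² points.
* `min_node_weight` interacts with total row weight: replicating rows
  k times at weight w/k is exactly fit-preserving only with the node-size
  floor disabled (how the invariance test runs) — with a floor, leaf
  feasibility can differ between the two encodings.
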