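# Methods

`netsig` discovers prognostic gene-expression signatures as *network
modules*: gene sets that are both topologically coherent in a static protein
functional-interaction (FI) network and co-expressed in a disease cohort,
and whose summary expression predicts patient survival. This note documents
the model, the numerical choices, and what the synthetic benchmark does and
does not demonstrate.

## Pipeline

1. **Disease-specific edge weighting.** For every FI edge whose two genes
   are measured, the Pearson correlation (PCC) of the genes' expression
   profiles across samples is computed; the edge weight is |PCC| and the
   signed value is kept as provenance. Edges with an unmeasured or constant
   gene are dropped (not zero-weighted), so the graph reflects actual
   coverage. A `unit` mode sets all retained weights to 1, reducing the
   pipeline to the tissue-agnostic unweighted network for comparison.
   Weights are not thresholded before clustering; all filtering happens
   after.

2. **Markov clustering (MCL).** The weighted graph is clustered by
   alternating expansion (squaring of the column-stochastic transition
   matrix) and inflation (elementwise power, renormalize, prune entries
   below 1e-5, renormalize). The inflation exponent is 5.0 by default — a
   deliberately aggressive setting that yields modules in the tens of genes
   rather than large communities. Iteration stops when the maximum
   elementwise change falls below 1e-6 (or at 200 iterations, returning the
   current clustering with a warning). Attractors are rows with positive
   mass in the limit matrix; each node joins the attractor carrying the
   largest mass on its column, ties going to the lexicographically smallest
   attractor gene, so the output is a deterministic partition.

   *Self-loops.* Every node receives a self-loop before normalization. The
   default loop weight is the graph's **maximum edge weight** (floored at
   1e-3), uniform across nodes. The classic per-node alternative (each
   node's own maximum incident weight) is available via
   `MCLParams(self_loop="max_incident")` but is not the default: on a
   correlation-weighted graph, a background gene attached to a tight module
   by a single weak edge then has a loop as weak as that edge, so half its
   column mass flows into the module and MCL absorbs it. A uniform loop on
   the scale of the strongest correlation lets such genes retain themselves
   as singletons while leaving flow within dense modules essentially
   unchanged. At inflation 5.0 the residual failure mode is the opposite
   one — a by-chance sparse module can split — which the benchmark
   quantifies (~2 of 20 seeds).

3. **Module filtering.** Modules with fewer than 8 genes or an average
   intra-module |PCC| below 0.25 are removed; both thresholds are
   inclusive. The average is taken over FI edges internal to the module
   (the quantity the weighted graph actually carries); an all-pairs
   correlation mode exists for sensitivity analysis. Survivors are
   renumbered 1..k by decreasing size. A module with no internal edge has
   an undefined average and fails the filter.

4. **Module expression matrix.** Each module is summarized per sample by
   the unweighted mean expression of its member genes. On validation
   cohorts the training module definitions are reused; unmeasured genes are
   dropped from the mean and per-module coverage is logged.

5. **Supervised principal components (superpc).** Each module (feature) is
   scored by the standardized Cox score statistic U(0)/sqrt(I(0)) of its
   expression against survival (Breslow ties; positive when higher
   expression associates with earlier events). Features with |score| at or
   above a threshold are retained, standardized by their training mean and
   SD (ddof=1), and the top right-singular vectors of the standardized
   submatrix give orthonormal loadings (components sign-fixed so the
   largest-|loading| entry is positive). Component scores are related to
   survival by one univariate Cox fit per component (HR, 95% Wald CI, Wald
   P). New cohorts are projected through the *training* center/scale and
   loadings — continuously (per-sample scores) or discretely (two groups
   split at the training-score median of a chosen component; scores exactly
   at the cutpoint go to "low"). The discrete component is selectable, so
   the second component can drive the grouping where it carries the
   prognosis.

   *Threshold selection.* 10-fold cross-validation, folds stratified by
   event status and seeded. Candidate thresholds are 20 values equally
   spaced between the smallest and largest |feature score| — the spacing
   the reference supervised-PC implementation uses; a quantile grid
   concentrates candidates where scores are dense and can leave the gap
   between a dominant feature and the rest uncovered. For each candidate,
   each training fold is re-scored and re-fitted, held-out samples are
   projected, and the partial-likelihood-ratio statistic of the held-out
   Cox fit on the leading component is recorded (scoring a joint
   multi-component fit would add ~1 to the held-out statistic per extra
   degree of freedom and systematically favor over-retention). The
   threshold with the best mean statistic wins; ties go to the smaller
   threshold. Candidates that retain nothing in some fold are skipped.
   Reported P-values always come from the Wald test; the LR statistic is
   used only inside CV.

6. **Survival machinery.** The Cox model is fitted by Newton–Raphson on
   the Breslow partial likelihood with step-halving, convergence at
   max |Δcoef| < 1e-8 or 50 iterations; monotone likelihood (perfect
   separation) is flagged as a non-converged fit. Breslow tie handling is
   the default because the resulting score test for a two-group covariate
   equals the log-rank chi-square *exactly* on tie-free data, which the
   test suite uses to cross-validate the Cox and Kaplan–Meier code paths
   against each other; Efron handling is available behind a flag. The
   log-rank variance uses the standard hypergeometric form (as in R's
   `survdiff`). Kaplan–Meier curves are product-limit estimates. Median
   splits send scores exactly at the median to "low". 95% CIs use the
   normal 1.96 quantile. Legacy per-module reports sometimes print a
   coefficient where a hazard ratio is labelled (hazard ratios cannot be
   negative), so every table here carries both `coef` and `HR`.

7. **Significance.** The module-discovery null permutes *gene-row labels*:
   each row keeps its values and its relation to survival, but gene
   identity — hence network position — is scrambled. This is the right null
   for "could a module this prognostic arise from this network by chance?";
   a within-row sample shuffle (destroying the survival relation instead)
   is provided behind a flag. Each permutation re-runs weighting,
   clustering and filtering and records the minimum module Cox P (1.0 when
   nothing passes the filters). Under this null the filters almost never
   pass — label shuffling destroys precisely the network/co-expression
   alignment that filtered modules require — so a small empirical P states
   that chance essentially never yields a *reportable* module at all, which
   is the claim the test is meant to support. Empirical P-values use the add-one
   estimator (r+1)/(n+1) and can never be 0. A second null draws random
   size-matched gene sets from the measured network genes. Gene-set overlap
   uses the upper-tail hypergeometric test with the measured network genes
   as the default background. Cross-cohort signature performance is the
   P-value score: mean of −log10 of the per-cohort Cox P-values (base
   configurable; only the scale changes). Bonferroni (multiply by m, cap at
   1) is the only multiplicity utility provided.

8. **Cross-platform pooling.** Module scores from different array
   platforms are mapped onto a reference cohort by the minimal affine
   transform matching mean and SD (a quantile-matching mode exists for
   sensitivity analysis); rescaled cohorts are concatenated with source
   labels for a pooled median-split Kaplan–Meier analysis. Cohorts whose
   endpoint is not overall survival (e.g. disease-free survival) carry an
   endpoint tag and are excluded from pooling unless explicitly included.

9. **Greedy baseline.** The supervised comparator grows a module from every
   seed gene, adding the candidate (within search depth 1 of the module and
   within depth 2 of the seed, the standard settings) that most improves
   −log10 of the module-mean Cox Wald P, while the improvement is positive.
   Module expression during the search is the member mean — the same
   scoring used by the main pipeline — rather than a normalized-sum
   activity score; results are deduplicated by gene set and ranked by
   score. Because the outcome drives every growth step, this baseline is
   the overtraining-prone design the unsupervised MCL route avoids.

## Synthetic benchmark

The generator plants co-expression modules in an FI network and ties
survival to one of them:

* network: dense blocks (within-module edge probability 0.8) over an
  Erdős–Rényi background (edge probability 0.01);
* expression: member gene = 0.8·f_m + sqrt(1−0.64)·noise with a per-sample
  module factor f_m ~ N(0,1), so two members correlate at 0.64 in
  expectation; non-members are N(0,1) noise;
* survival: exponential with hazard 0.1·exp(1.0·f_prognostic) per time
  unit, censored Uniform(0, 20) — the data follow the Cox model exactly,
  with the prognostic factor as the true risk score (event fraction ~0.55).

Defaults: 500 genes, 200 samples, 21 planted modules of 10 genes, the first
one prognostic — one strongly prognostic module among twenty decoys, a
regime comparable to a single microarray cohort after module filtering.
Validation cohorts are fresh draws from the same truth layout.

Problem sizes in the test suite and the acceptance script (20 seeds for the
recovery studies, 200 for null calibration, 99 pipeline permutations,
500 random-gene-set trials) were chosen as the smallest runs that give
stable rates.

What passing does **not** show: the generator has no platform/probe
effects, no heavy-tailed microarray noise, no overlapping modules, no
correlated censoring, and its survival times are exactly exponential–Cox;
real-data performance additionally depends on preprocessing (probe
collapsing, per-gene z-scoring, endpoint consistency) that the `io` module
implements but the benchmark exercises only lightly.

## Numerical details and degenerate inputs

* Determinism: node order, tie-breaks and module numbering are
  lexicographic; all randomness (CV folds, permutations, generators) flows
  from explicit integer seeds; two runs with equal inputs produce
  byte-identical reports.
* Z-scoring uses the sample (n−1) SD; constant rows are excluded with a
  drop log. Missing values are rejected at load time.
* Isolated nodes get a pure self-loop column and become singletons.
  Constant features score NaN and are never retained. Rank-deficient Cox
  designs and datasets with <2 events raise immediately.
* Probes mapping to multiple genes are removed; multiple probes for one
  gene are averaged elementwise.

## Known limitations

* The log-rank test is two-group only (the pipeline only ever compares a
  median split); multi-group comparisons need an external tool.
* MCL is dense-matrix; fine for the ~10k-node networks this method targets,
  but no out-of-core sparse optimizations are attempted.
* At inflation 5.0, a sparse-by-chance module can fragment and fall below
  the size filter; the acceptance run quantifies this (~10% of seeds under
  benchmark conditions).
* No FDR machinery beyond Bonferroni; no time-varying covariates,
  stratified Cox, or competing risks.
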