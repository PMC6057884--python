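# Methods

This note documents the models, estimators and design choices behind
`adprog`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, which
knobs matter, and what the synthetic benchmarks do and do not demonstrate.

## Synthetic cohorts

The generator produces study data shaped like a multi-modal observational
dementia cohort: ~900 patients followed for 96 months, a SNP panel with
population structure, ~70 mixed clinical variables, and right-censored
conversion times. Everything flows from one integer seed through named
sub-streams (`config.rng("genotypes")`, …), so any single stage can be
regenerated independently and byte-identically.

**Genotypes.** Ancestral minor-allele frequencies are uniform on
`maf_range` (default 0.05–0.5). Subpopulation frequencies follow the
Balding–Nichols construction: Beta(p(1−F)/F, (1−p)(1−F)/F) for divergence
F = `fst`, giving Var(p_s) = F·p(1−p) and an expected Hudson FST of F (the
package's `hudson_fst`, the Bhatia ratio-of-averages estimator, is the
audit). Linkage disequilibrium comes from a block-anchor copy process at the
haplotype level: within each block of `ld_block_size` SNPs, alleles copy the
block anchor with probability 1 − `ld_flip_prob` (default 0.05, giving
adjacent r² ≈ 0.8) and are redrawn from the block frequency otherwise. All
SNPs of a block share the anchor's subpopulation frequencies, so LD does not
distort the configured FST. This is a deliberately minimal LD model — it has
tunable within-block r² and abrupt block borders, not the smooth decay of
recombination-based simulators; it is sufficient for pruning and tagging
tests but not for fine-mapping realism.

**Clinical table.** A latent severity (standard normal) drives the
continuous variables through affine transforms plus Gaussian noise, tagged
alternately `neuropsych`/`imaging` for fusion and network constraints. Age
and education are independent of severity; the baseline diagnosis
(CN / EMCI / LMCI) is the severity tertile. Marginal shapes are a modeling
choice — real cohort variables are skewed and bounded in ways this does not
reproduce; tests that pass here show algorithmic correctness, not clinical
realism.

**Outcomes.** Conversion times are Weibull proportional hazards,
S(t|x) = exp(−(t/scale)^shape · e^lp), sampled by inverse CDF
(shape 1.5, scale 120 months by default). Censoring combines the
administrative 96-month cut-off with uniform dropout whose activation
probability is found by bisection against the realized draw, so the
censored fraction matches `censor_rate` (default 0.65, leaving roughly a
third of patients as observed converters, matching the cohort this
emulates). Missingness is MCAR only, with outcome columns protected —
nothing in the package models informative missingness.

**Planted hazard and calibration.** By default five coefficients of equal
magnitude and alternating sign are planted (clinical scores and
high-MAF SNPs). `make_cohort(..., target_c=0.85)` rescales them by
Monte-Carlo bisection until the noise-free linear predictor's Harrell C hits
the target; because C is measured on a single realized draw, the implied
per-feature log hazard ratios vary across seeds, and
`min_abs_coefficient=0.5` optionally floors them so every planted effect
stays individually detectable (the realized C then lands at or slightly
above the target).

**Ground-truth DAGs.** `random_dag` draws a DAG over a random topological
order with bounded in-degree; `random_cpts` gives each parent configuration
a dominant level (mass 0.85 by default); `sample_discrete_bn` is plain
ancestral sampling with validated CPT rows.

## Genotype processing

Dosages are oriented to the minor allele at construction (MAF ≤ 0.5 per
column). QC removes SNPs with MAF < 1% or missingness > 5% — the
conventional thresholds for this kind of panel.

**Kinship** uses the method-of-moments IBD estimator: genome-wide IBS
counts are combined with their allele-frequency expectations under IBD
states 0/1/2, solved sequentially for P(IBD=0), P(IBD=1), P(IBD=2);
PI-HAT = P(2) + P(1)/2, computed per pair over jointly observed SNPs. The
raw component estimates are *not* clipped individually before combining —
on desk-scale panels (thousands rather than hundreds of thousands of SNPs)
clipping correlates the sampling errors and biases PI-HAT upward by
0.05–0.1; only the final PI-HAT is truncated into [0, 1]. Two caveats are
inherent to the estimator, not this implementation: it assumes a
homogeneous sample (under strong stratification, within-subpopulation pairs
show inflated PI-HAT — the full-pipeline default therefore simulates mild
structure, FST 0.02), and at a few thousand SNPs the noise floor means a
0.1 threshold removes a small tail of truly unrelated pairs. Pairs with
fewer than 100 overlapping SNPs are flagged unreliable.

**Inbreeding** is the SNP-based moment estimator
F̂ = Σ[x² − (1+2p)x + 2p²] / Σ[2p(1−p)] over observed polymorphic SNPs.
The relatedness filter drops individuals with |F| above threshold, then
resolves related pairs greedily by descending PI-HAT (dropping the member
with more missing genotypes, then the lexicographically larger id). The
kinship threshold is interpreted as *removing* pairs **above** 0.1 —
removing unrelated individuals would be nonsensical, so the package treats
the opposite reading as a transcription artifact of its sources; the
behavior is documented here and configurable.

**LD pruning** scans SNPs in positional order and drops a candidate when
any retained SNP within `window` positions has r² ≥ `r2_max` (squared
Pearson correlation of dosages over jointly observed entries; monomorphic
overlaps count as not-computable and do not prune). The later SNP of a
conflicting pair is always the one dropped, making the pass deterministic;
window 50 / step 5 are configurable defaults since no canonical value
exists.

**PCA** standardizes dosages to (x − 2p)/√(2p(1−p)) with mean imputation,
then takes the top-k SVD — dense for small panels, a Lanczos-type iterative
solver (`scipy.sparse.linalg.svds`) for large ones; patient-space
eigenvectors (EV1, EV2, …) are the ancestry features. A probabilistic-PCA
EM variant (`method="ppca"`) provides a regularized subspace estimate for
panels with many more SNPs than patients; its hyperparameters are minimal
(isotropic noise, 50 EM iterations) and the default remains plain SVD. Sign
convention: the largest-|loading| entry of each component is positive.

**Pathway impact scores.** SNPs map to pathways through their annotated
genes (one SNP may land in several pathways; empty pathways are dropped).
The score is |{SNPs in the pathway set: flagged damaging AND dosage ≥ 1}| /
|pathway set|. The carrier rule (dosage ≥ 1) is what makes the score
patient-specific; a dosage-weighted variant (dosage/2 in the numerator) is
available behind `weighted=True` for sensitivity analyses. Damaging flags
are consumed as annotation input (SIFT-deleterious or PolyPhen
at-least-possibly-damaging); the predictors themselves are never run here.

## Boosted Cox model

The loss is the Breslow-form negative partial log-likelihood; gradient
(working residuals), and the diagonal curvature used for one-step Newton
leaf values, are computed in O(n log n) via a single time sort with
suffix/prefix cumulations. Residuals sum to zero exactly (martingale
identity) and the gradient is validated against central finite differences.

**Trees.** Features are pre-binned once per training matrix (≤ 64 bins,
quantile cuts; category codes for categoricals; a reserved missing bin), so
split search is a histogram scan vectorized across all features. Splits
maximize residual variance reduction; categorical features use the ordered
one-vs-rest trick (bins sorted by mean residual, then scanned like an
ordinal feature). Exact gain ties between features — duplicated columns
being the canonical case — are broken uniformly at random under the
training seed, so duplicated signals share influence instead of one column
absorbing it. Missing values never enter the split criterion; at routing
time they follow the best **surrogate split**: the feature/threshold whose
binary partition agrees most (in rate, judged on rows where both are
observed) with the primary split, falling back to the node's majority
direction. Leaf values are one-step Newton updates Σr/Σh with a zero-Hessian
guard.

**Boosting.** Learning rate ν = 0.05 by default (configurable; the scaled
benchmarks below use ν = 0.05 with a 300-step budget), bagging fraction 0.5
(without replacement, deterministic under seed), depth 3, minimum leaf 10.
The boosting-step count is the argmin of the mean validation negative
partial log-likelihood over inner event-stratified CV folds; a minimum
pinned at the budget edge triggers a warning. Importance is the cumulative
split gain per feature, normalized to sum 100 (relative influence); unused
features get exactly zero, which is what makes embedded selection possible.

**Two-step fusion.** Modalities differ wildly in width (dozens of clinical
columns vs. thousands of SNPs), which biases joint embedded selection
toward the widest block. Step 1 trains one model per modality and keeps
features with nonzero influence; step 2 retrains a single model on the
union. The same inner-CV protocol is reused in both steps. The final model
is seeded with the caller's seed, so a single-modality call reproduces a
plain fit exactly.

## Evaluation

Harrell's C counts a pair comparable iff the earlier time is an event (time
ties: event vs. censored only); risk ties score 0.5. Kaplan–Meier,
Nelson–Aalen and the log-rank test delegate to lifelines. The IPCW Brier
score weights by the censoring-distribution Kaplan–Meier, evaluated
just before the event time for early failures and at the horizon for
survivors; with no censoring it reduces exactly to the mean squared error
of the survival indicator. Converting boosted log-hazard scores to survival
curves uses the Breslow baseline cumulative hazard,
Ŝ(t|x) = exp(−Ĥ₀(t)·e^f) — the canonical choice where none is otherwise
dictated. Repeated CV stratifies folds by event status (refolding with a
warning if a fold ends up event-free) and ledgers per-feature selection
counts across all repeats × folds models. Extreme-decile stratification
takes the top/bottom ⌈qn⌉ patients by risk; group differences use Wilcoxon
rank-sum for continuous and contingency χ² for discrete features, with
Benjamini–Yekutieli adjustment (step-up with the harmonic-sum inflation
c(m) = Σ 1/i — valid under arbitrary dependence, and elementwise ≥ BH).
Constant features are recorded as skipped with q = 1.

## Bayesian networks

Missing values are imputed before discretization on the whole table
(missForest-style: random forests per variable, iterating until the
normalized change increases). Continuous variables are discretized into
three equal-width bins (left-closed, last bin right-closed); constant
columns are excluded with a warning. Six role-based rules compile into a
directed-edge blacklist (see `bnstruct.constraints`); the
imaging→neuropsych direction is configurable because the two plausible
readings of that rule disagree, and the censoring-indicator→event-time arc
is a one-edge whitelist present in every returned structure.

Scoring is decomposable BIC with multinomial MLE plug-in log-likelihood
(zero counts contribute zero; penalty coefficient exposed). Hill climbing
restarts from random admissible graphs; tabu search takes the best
non-tabu move even when it worsens the score, keeps inverse moves tabu for
`tabu_len` = 10 iterations, and stops after `max_stagnant` = 15
non-improving iterations or `max_iter` = 1000 — toolkit-style defaults, all
exposed. Both searches rescore only affected families with memoization, and
every returned structure is checked acyclic and blacklist-clean.
Learner comparison uses k-fold held-out log-likelihood with add-one
(Laplace) CPT smoothing, which keeps unseen test configurations at finite
probability. Bootstrap confidence resamples patients with replacement
(B configurable, 1000 in full runs, 100 in the scaled benchmarks), learns a
structure per replicate, and reports directed edge frequencies (undirected
frequencies as an auxiliary view); the stable graph keeps edges with
frequency strictly greater than 0.5.

## Mechanism mapping

Pathway–pathway edges are validated by the one-sided hypergeometric tail
P(X ≥ k) on gene-set overlap (the test is symmetric in which set plays the
draw), with BY adjustment across edges; the universe defaults to the union
of all gene symbols in the resource and is configurable. Mapping pathways
onto cause-effect subgraphs applies the same test across the full
pathway × subgraph matrix with one global BY correction; the best subgraph
per pathway is the smallest p (ties: larger overlap, then name). Mechanism
context extraction takes, for every (a, b) pair of mapped entities, one
hop-count shortest path with a deterministic lexicographic tie-break, and
returns the union as a typed subgraph; `all_shortest=True` keeps every tied
path, and `directed=False` searches the underlying undirected graph (edge
orientations are preserved in the output) for sources whose direction
convention is unreliable.

## Benchmark problem sizes

The acceptance benchmarks run at desk scale, chosen so the full suite fits
comfortably on one CPU: planted-hazard cohorts of 600 patients × 200
features (60 clinical + 140 independent SNPs, 30% censoring, oracle
C ≈ 0.85, planted |log HR| ≥ 0.5) over 10 seeds with 3×5-fold
cross-validated fusion; network recovery on 10–12-node DAGs at n = 2000
with B = 100 bootstrap; genotype audits at 5000 SNPs. These sizes exercise
every code path at meaningful signal-to-noise; they do not probe
hundreds-of-thousands-of-SNP scalability, where the iterative PCA path and
histogram trees are the relevant design choices.

## Known limitations

- The LD model has block structure, not recombination-distance decay.
- Moment-based kinship degrades under strong stratification and small
  panels (documented above); no ancestry-aware kinship estimator is
  included.
- MCAR missingness only; surrogate splits and missForest imputation are
  exercised under MCAR.
- Discrete Bayesian networks only (everything is binned to three levels);
  no conditional-Gaussian or hybrid networks, and no constraint-based
  learners.
- The mechanism graphs consumed are typed edge lists; no BEL parsing.
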