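# Methods

This note documents the statistical models implemented in `permclass`, the
design choices made where the methodology was genuinely open, the synthetic
cohort the package is validated on, and the limits of what those validations
show.

## Data model and the stacked-exam convention

A cohort is a longitudinal phenotype table (one row per individual × exam)
plus a categorical genotype matrix (up to four tokens per SNP including the
missing code `XX`).  Hypertension is defined as SBP > 140 mm Hg or
DBP > 90 mm Hg; ingestion flags rows violating this rule but keeps them,
since externally produced files may encode exceptions.  All models treat the
three repeated exams as three independent observations.  This is an
analytical convention, not a claim about real data: it buys power for the
time-varying covariates (age, smoking) at the price of ignoring
within-person correlation.  The synthetic generator draws exam outcomes
conditionally independently given the linear predictor, so under the
generator the convention is exactly right — which is precisely why the null
calibration test passes, and why passing it says nothing about residual
within-person correlation in real cohorts.

## Association scan

Baseline: `logit Pr(HTN=1) = Smoke + Age + Sex + Age×Sex + Mother + Father +
Pedigree`, with pedigree as fixed-effect indicator contrasts (reference =
most frequent level; category orders are frequency-then-token, so expansion
is deterministic).  Each SNP is added as a genotype-category factor —
including `XX` as its own level — and scored by the likelihood-ratio test
(LRT), with degrees of freedom equal to the non-aliased indicator columns
actually added.  A categorical (rather than additive) genotype term and the
LRT (rather than a Wald test) were chosen because the SNP enters as a
multi-level factor; this is flagged for sensitivity analysis.  Monomorphic
SNPs report p = 1 with 0 df.

Fitting is IRLS written directly on numpy:

* aliased columns are removed by a greedy keep-first Gram–Schmidt pass
  (residual norm ≤ 1e−8 of the column norm), so baseline covariates can
  never be displaced by a later genotype indicator;
* step-halving keeps the deviance nonincreasing; convergence is a relative
  deviance change < 1e−8, capped at 100 iterations;
* quasi-complete separation is flagged when any SD-scaled coefficient
  exceeds 15 while the deviance is still falling — the regime where stacking
  many rare-genotype indicators stops the fit from converging;
* extended fits warm-start from the cached baseline solution, which is what
  keeps a 500-SNP scan to a couple of seconds.

The fit is cross-checked in the test suite against `statsmodels` GLM
(coefficients and log-likelihood to 1e−6), which is used as an oracle only.

LD pruning codes genotypes as minor-allele dose (0/1/2, `XX` excluded
pairwise), computes |Pearson r|, and keeps a SNP iff its correlation with
every previously kept SNP is below the threshold (greedy, column order).
At threshold 1 only numerically exact duplicates (|r| ≥ 1 − 1e−12) are
removed.  Unsigned r is used; zero-variance SNPs correlate with nothing and
are kept.  Quantitative scans (SBP/DBP response) use the same covariate
terms with OLS partial F-tests for the genotype block.

## Rare-variant screen

A SNP is *rare* when its minor **allele** frequency, computed from the
characters of the non-missing diploid tokens over the whole study group, is
strictly below 0.05.  Screening is on the genotype scale: the carrier group
is the set of genotypes containing the minor allele, tested against HTN in a
2×2 carrier/non-carrier table over the stacked exam rows.  When only one
carrier genotype is observed this reduces to the published single-token
table layout.  Pearson chi-square with Yates continuity correction is
applied iff the table is 2×2; larger genotype-frequency tables are
uncorrected.  This correction rule is pinned by the reference tables in the
test suite (2×3 p = 0.0011; carrier tables p = 4.06×10⁻¹² and 2.64×10⁻¹⁰).
Perfect-duplicate carrier vectors are collapsed keeping the first SNP in
column order.  The screen is deliberately unadjusted for covariates (as is
conventional for this step), so pedigree clustering can inflate marginal
signal for null rare variants; the parameter-recovery benchmark quantifies
how much that matters under the generator.

## Permanental classifier

Each class's training points are treated as one realization of a permanental
point process with covariance `K(x,x′) = exp(−‖x−x′‖²/τ²)` (unit variance —
the covariance is taken as printed, with no amplitude multiplier).  The
α-permanent

    per_α(A) = Σ_σ α^cyc(σ) Π_i A[i, σ(i)]

is computed exactly by a cycle-expansion dynamic program: `C[V]`, the total
weight of simple cycles with support exactly V, is filled by a path DP
anchored at each subset's lowest vertex, and `f[S] = Σ_V α·C[V]·f[S∖V]`
peels the cycle through the lowest vertex of S.  The engine is O(3ⁿ) time,
O(2ⁿ) memory, numba-compiled, limited to n ≤ 14, and verified against an
independent brute-force permutation oracle with cycle counting (relative
1e−10).  With kernel entries in (0, 1] and unit diagonal, per_α lies between
αⁿ and the rising factorial α(α+1)…(α+n−1), so all ratios are safe in linear
64-bit arithmetic and no log-space evaluation is needed.

A query x\* is scored per class by the predictive-intensity ratio
`per_α(K[S∪{x*}]) / per_α(K[S])` over the class's `neighbor_budget` = m most
similar training points (largest kernel value; ties broken by training
index).  This subset restriction is the package's answer to the #P-hardness
of permanents over hundreds of points; it makes per-query cost O(3^(m+1))
with m defaulting to 10.  Membership probabilities are prior-weighted
normalized affinities, with class prior ∝ class size by default (a
"uniform" prior is a config switch, since the methodology leaves it open);
prediction uses the same ≥ 0.5 rule as the logistic model.

One consequence of the predictive-intensity formula worth knowing: a class
entirely beyond kernel range contributes its base intensity α, not zero.
For a query sitting on an n-point coincident cluster against a far class of
equal size, P(near) = (α+n)/(2α+n) exactly — e.g. 6/7 at α = 1, m = 5 —
approaching 1 only as α → 0 or the cluster grows.  The test suite freezes
this closed form.

## Comparison classifiers and feature construction

Selected SNPs are encoded as genotype indicators after **NS collapsing**:
the extended logistic model is fitted per SNP on training data, and levels
whose Wald p (against the most-frequent-genotype reference) is ≥ 0.05 pool
into one absorbing "Not Significant" category, along with the reference and
any token unseen in training.  Collapsing never increases a SNP's column
count; a SNP with no significant level contributes nothing.  The SVM and
permanental classifiers consume the same NS-collapsed indicators plus
standardized covariates (training mean/SD, frozen).  All encodings are
derived from training data once and fingerprinted (SHA-256) so the harness
can assert that prediction never mutates them.

Hyperparameters are tuned by stratified 10-fold CV on misclassification:
(γ, C) over a 7×7 log grid 10⁻³…10³ for the SVM, (α, τ) over
{0.5, 1, 2, 4} × {0.5, 1, 2, 4, 8} for the permanental classifier (the
methodology states 10-fold tuning but no grids; these are the package's
defaults).  Ties go to the earlier grid point; folds are deterministic given
the seed, and a fold that loses a class is refolded (≤ 5 attempts).

## Synthetic cohort generator

Defaults define the study conditions: 400 individuals in 20 pedigrees, 3
exams, 500 SNPs, 5 causal common SNPs (+1.0 log-odds per minor allele, MAF
drawn in [0.2, 0.5]), one planted rare risk variant (carrier log-odds 2.0,
MAF in [0.02, 0.04]), 20% of SNPs forced rare (MAF in [0.005, 0.05]), five
LD-tagged SNPs with one noisy copy each (5% regeneration noise), three
exactly duplicated columns, and 0.5% missing calls.

* **Pedigrees** are packed from nuclear families — founder couple plus two
  full-sib offspring — because extended pedigrees are mostly marry-in
  founders with small sibships; a single giant sibship would let one
  founder's rare allele dominate a pedigree's allele frequency and
  manufacture pedigree-confounded carrier signal.  Founders are
  Hardy–Weinberg draws at the SNP's MAF; offspring receive one Mendelian
  allele per parent.  No inbreeding loops; kinship beyond the pedigree label
  is out of scope because downstream models use Pedigree only as a factor.
* **Covariates**: age starts Uniform(25, 70) years and advances 4 years per
  exam; smoking starts at 25% and flips between exams with probability 0.05;
  sex is fixed within the founder couple.  Covariate log-odds (smoke 0.6,
  age 0.04/year centered at 50, sex 0.3, age×sex 0.02, mother/father 0.8,
  pedigree intercepts N(0, 0.3²), intercept −1.8) give ≈ 30% prevalence.
  Parental-history flags are Bernoulli(0.3) for founders and are the
  founders' own realized first-exam HTN for offspring, so the Mother/Father
  terms carry real signal.
* **Phenotypes**: HTN per exam is Bernoulli(sigmoid(lp)); causal doses and
  rare-carrier indicators enter lp centered at their expectation so the
  intercept alone controls prevalence.  SBP/DBP are truncated normals on the
  correct side of the 140/90 thresholds (margins at 140.1/139.9 and
  90.1/89.9 so 1-decimal rounding cannot break the rule), with means shifted
  4 mm Hg per logit unit of lp so causal SNPs also leave a quantitative
  trace for the SBP/DBP scans.  Hypertensive records exceed both thresholds
  with probability 0.45, SBP only 0.35, DBP only 0.20.
* **LD structure** is planted on non-causal SNPs only, keeping the truth
  sidecar's causal labels unambiguous for recovery benchmarks.
* **Replicates** share genotypes, covariate trajectories and pedigree
  intercepts; HTN, blood pressures and parental flags are re-drawn per
  replicate.  All randomness flows from one root seed via
  `numpy.random.SeedSequence` spawns (genotype stream, covariate stream, one
  stream per replicate), so equal seeds give byte-identical cohorts.

What the generator does **not** emulate: realistic human LD maps, imputation
artifacts, within-person outcome correlation beyond the shared covariates,
medication effects, or the 65,519-SNP chromosome scale (scale is a config
knob; the desk default is hundreds of SNPs).  Tests passing on this
generator demonstrate the pipeline's correctness and its qualitative
behavior under the assumed model, not the published absolute error rates,
which depend on access-restricted genotypes and are out of scope.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run at desk scale: recovery
benchmarks use 20 (tests) or 10 (script) cohorts of 400 individuals × 508
SNP columns; the classifier comparison uses one training + four testing
replicates (1,200 stacked rows each) at k ∈ {0, 20}; the null-calibration
cohort is 1,000 individuals × 200 SNPs with all causal effects removed,
checked by a Kolmogorov–Smirnov uniformity test at the 1% level.

## Known limitations

* The stacked-exam convention understates uncertainty whenever outcomes are
  correlated within individuals beyond the modeled covariates.
* The rare-variant screen is unadjusted; pedigree clustering can promote
  null rare variants, and the screen's ranking should be read as a
  hypothesis generator, not an inference.
* The neighbor-budget restriction makes the permanental classifier's scores
  an approximation whose quality degrades if a class's relevant structure
  needs more than m points; budgets above 13 exceed the exact engine.
* NS collapsing reuses the training response twice (selection and fitting),
  an optimism that the replicate-based testing errors expose but do not
  remove.
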