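# Methods

This note documents the models and procedures implemented in `cpca`, the
defaults and why they were chosen, what the synthetic-cohort generator
does and does not emulate, and the numerical conventions that make every
run reproducible.

## Composite phenotypes from subset PCA

Given a complete samples × k biomarker panel, the screen considers every
subset of at least two traits: Σ_{i=2..k} C(k,i) = 2ᵏ − k − 1 subsets
(26 at k = 5; 4,083 at k = 12; 2,097,130 at k = 21). For each subset the
composite phenotype (CP) is the first principal component of the subset's
*correlation* matrix — equivalently, PCA on standardized traits. Because
correlation-based PCA depends on the data only through the correlation
matrix, the k × k training correlation matrix is computed once and each
subset's eigenproblem is solved on its s × s submatrix (s ≤ k ≤ 21).
This turns millions of per-subset data decompositions into cheap dense
symmetric eigendecompositions with identical results; the test suite
checks the equivalence against an independent eigensolver.

Conventions that make CPs well-defined:

* **Loading sign.** Eigenvectors are sign-ambiguous, so the loading of
  the canonically-first member trait is made non-negative (first nonzero
  loading positive if it is zero).
* **Degenerate spectra.** If the top eigengap is below 10⁻¹² (e.g. an
  identity submatrix), the basis vector of the canonically-first trait is
  returned, keeping degenerate inputs deterministic.
* **Orientation.** After scoring the training samples, the CP is flipped
  (o = −1) when cases outscore non-cases, so a higher CP is always
  "protective". Ties keep o = +1.
* **Standardization constants.** Means and SDs come from the training
  split only and are frozen into the CP object, so scoring test samples
  (or an external replication cohort, via the JSON export) leaks no
  held-out information. Whether to standardize on combined or
  training-only moments was an open design choice; training-only is the
  conservative option.
* λ₁ ≥ 1 always holds for a correlation matrix (the average eigenvalue
  is 1), and λ₁ ≤ s; both bounds are asserted in tests.

## Missing data

Samples missing more than 30% of the panel are removed (a sample at
exactly 30% is kept). Remaining holes are filled by iterative low-rank
imputation: standardize, truncate the SVD to `n_components` (default 2),
refill only the missing cells, and repeat until the largest missing-cell
change drops below 10⁻⁶ (at most 100 passes; non-convergence is flagged
in the result rather than fatal). Trait means and SDs are re-estimated
from the completed matrix on every pass, which makes exactly-low-rank
panels exactly recoverable — the test suite checks a rank-1 panel and the
closed-form single-cell case. The default rank of 2 is deliberately
conservative for panels of 5–21 correlated traits and is configurable.
Observed cells are never modified.

## Classification evaluation

Scores follow the protective orientation, so AUC = P(non-case > case) +
½ P(tie), computed by the midrank Mann–Whitney estimator (identical to
the trapezoidal area under the empirical ROC; identical to brute-force
pair counting, which the tests enforce exactly). Confidence intervals use
the stratified percentile bootstrap — cases and non-cases resampled
separately, 2,000 replicates by default — percentile rather than BCa
because it is the simplest defensible interval. The paired CP-vs-reference
comparison resamples both markers with shared indices and refers
D = (AUC_a − AUC_b)/sd(bootstrap differences) to a standard normal,
two-sided; a DeLong asymptotic test is also provided and agrees with the
reference R implementation (pROC) to numerical precision on fixtures.

The screen fits CPs on a stratified 70% training split (per-stratum
counts rounded to the nearest sample), compares each CP to the reference
marker on that training split, applies the Bonferroni threshold
α / (number of enumerated subsets), and additionally requires the
training AUC difference to be positive and the test-split AUC to exceed
the reference's test AUC. The divisor defaults to the exact subset count;
a config switch accepts a rounded count (e.g. 2×10⁶, which gives the
familiar 2.5×10⁻⁸ at α = 0.05). Because a two-million-subset bootstrap is
infeasible, the screen optionally gates the 2,000-replicate bootstrap
behind a cheap DeLong pre-test (`delong_screen_alpha`); gated-out subsets
keep their DeLong p-value, are flagged in the `method` column, and can
never be selected, while every reported selection rests on a bootstrap
p-value. Per-subset bootstrap seeds derive from (master seed, subset
index), so chunked, checkpointed or parallel execution cannot change any
number; the checkpoint-equals-single-pass property is tested.

Ranking ("top candidates") sorts by test AUC descending, breaking ties by
fewer member traits, then lexicographic names — preferring the most
parsimonious composite among equals. Component-frequency tables count
traits, unordered pairs and triples across the selected subsets.

The CP–disease logistic model (status ~ CP + age + sex) is a standard
maximum-likelihood fit (statsmodels) reported as the odds ratio per unit
CP with a Wald 95% CI; quasi-separation is flagged. A protective OR of
0.419 corresponds to a (1 − 0.419)·100 = 58.1% decrease in odds per unit.

## Association scans and consensus loci

Phenotypes are inverse-normal transformed before scanning:
Φ⁻¹((r − 3/8)/(n + ¼)) with midranks for ties (the Blom offset, the
common GWAS convention). Each variant is tested by the linear model
phenotype ~ dosage + age + sex (+ optional genetic PC columns). The
covariates are QR-projected out of the phenotype and the whole dosage
matrix once; each variant then reduces to a simple regression on
residuals with the joint model's degrees of freedom — algebraically
identical to the per-variant multiple regression (Frisch–Waugh–Lovell),
which the tests enforce to 10⁻⁸ against a joint-fit oracle. One
projection serves every variant and every CP phenotype, which is what
makes scanning tens of thousands of CPs tractable. Monomorphic variants
are retained with β = 0, p = 1 and a failure flag.

Genome-wide significance is the strict p < 5×10⁻⁸. Loci are formed by
greedy distance clumping: the best-p unassigned variant leads a locus and
absorbs unassigned variants within ±500 kb on its chromosome (ties on p
break by lower chromosome, then position). A *consensus locus* must have
an overlapping significant locus in **every** CP's scan; window overlap
rather than exact lead-variant identity is used because lead SNPs
legitimately differ between highly correlated composites. The reported
lead is the best-p variant across all overlapping loci. Without linkage
disequilibrium in the simulator, each causal variant forms its own locus,
so the distance rule is exercised through explicitly constructed fixtures.

## Colocalization

Within a ±500 kb window (boundary inclusive) around a lead variant, the
two traits' summary statistics are harmonized on (chrom, pos, allele
pair) — β flipped when A1/A2 are swapped, strand-ambiguous palindromic
(A/T, C/G) variants dropped with a logged count. Each variant's Wakefield
log approximate Bayes factor is

    lABF = ½ [log(1 − r) + r z²],  r = W/(V + W),  z = β/se,  V = se²,

with prior effect variance W = 0.04 (prior SD 0.2 on the standardized
scale). Under one-causal-variant-per-trait, the five hypothesis weights
are accumulated entirely in log space (z² terms overflow naive
exponentials): H1/H2 from the single-trait lABF sums, H4 from the
same-variant sum, H3 from the cross-product sum minus the same-variant
terms via a log-difference, each multiplied by the priors
p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ (the canonical defaults of the ABF
colocalization framework; the framework's priors are exposed in config).
The β/se parameterization was chosen over p+MAF. Posteriors are checked
against an exhaustive enumeration over all causal configurations on small
regions. A region with a single shared variant has no H3 configuration;
it is computed with zero H3 mass and flagged. A locus is called
*colocalized* when PP4 strictly exceeds 0.7.

## Synthetic cohorts

The generator produces the minimal structure the workflow assumes:

* **Traits**: multivariate normal with a user-requested correlation
  matrix. Slightly non-PSD inputs are repaired by clipping eigenvalues at
  a small positive floor and renormalizing the diagonal; repairs moving
  the matrix by more than 0.05 in Frobenius norm are rejected rather than
  silently accepted.
* **Disease**: Bernoulli from a logistic liability on a weighted trait
  sum; the intercept is solved by bisection on [−20, 20] so the expected
  prevalence matches the target to 10⁻⁴. A logistic liability was chosen
  because the evaluation model downstream is logistic.
* **Genotypes**: independent biallelic variants, Binomial(2, MAF) per
  sample (Hardy–Weinberg), MAF ∈ (0, 0.5]. Variants add `effect × dosage`
  to their target traits — a variant touching many traits emulates a
  pleiotropic locus, one touching a single trait a pure biomarker locus.
  Simulated variants sit 2 Mb apart so each forms its own locus.
* **Missingness**: MCAR only, each cell masked independently; masked
  cells are NaN with an explicit mask, never zeros.
* **Covariates**: age ~ Uniform(40, 70) years, sex ~ Bernoulli(½),
  independent of traits — plumbing for the covariate interface, not a
  confounding model.

Every stage's seed is spawned from the cohort seed, so a fixed
configuration reproduces all outputs bit-exactly.

What the generator does **not** emulate — and therefore what passing
tests cannot certify about real cohorts: linkage disequilibrium and
population structure, relatedness, non-normal trait distributions and
measurement error, informative (non-MCAR) missingness, confounded
covariates, and case ascertainment. Results on real panels depend on all
of these; the simulator establishes correctness of the machinery, not
field performance.

## Simulation sizes used in tests and the acceptance script

The test suite exercises driver recovery on 5-trait cohorts of n = 20,000
(20 replicates, 500 bootstrap replicates, DeLong gate 10⁻³), null
family-wise error on all-noise 8-trait panels of n = 4,000 (50
replicates, 200 bootstrap replicates), GWAS calibration on 1,000 null
variants at n = 2,000 plus 50 effect-recovery replicates at n = 20,000,
and the pleiotropic-vs-single-trait consensus scenario at k = 8,
n = 10,000 with six variants. `scripts/acceptance.py` reruns the same
computations at 10 recovery and 20 null replicates — sizes chosen so the
Monte-Carlo error of each reported rate is small relative to the effect
being demonstrated while a full run stays at desk scale on one CPU.

## Known limitations

* The exhaustive screen is O(2ᵏ); k = 21 is practical only with the
  DeLong gate and chunked execution, and larger panels need the
  checkpointing interface.
* Consensus uses distance windows, not LD-aware clumping; in regions of
  long-range LD a fixed ±500 kb window can split or merge loci
  differently than an LD-based rule.
* The colocalization model assumes at most one causal variant per trait
  per window and takes summary statistics at face value (no LD matrix).
* Binary-trait (logistic) association scans are not implemented; all
  screened composites are quantitative.
* `fit_logistic_cp` reports Wald intervals, which degrade under
  separation; separation is flagged but not penalized.
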