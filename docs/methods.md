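# Methods

## Data model

A cohort is a set of patients rated twice — baseline and end point — on 12
ordinal items, each in {0, 1, 2, 3, 4}, with age, gender and the delay in
days between the two ratings. Item order is fixed package-wide
(`Agi, S/h, Sub, Cog, Phy, Hal, Dep, Oth, Rel, ADL, Liv, Occ`). A profile
is *severe* iff any item is ≥ 3; *treatment response* is reaching the
non-severe level at end point; analysis cohorts keep only patients severe
at baseline. Pairing is by an explicit `occasion` column
(`baseline`/`endpoint`); the delay is stored once per patient and must
agree across the two rows. Missing item scores or a missing occasion
exclude the patient complete-case, with a warning naming them.

## Individual-scores arm

**Signed-rank test.** Differences are baseline − end point, so improvement
yields a large V (the sum of ranks of positive differences). Zero
differences are dropped; midranks handle ties. For ≤ 25 nonzero
differences the two-sided p is exact: the null distribution of V over all
2^n sign assignments is built by subset-sum convolution over the doubled
midranks (equivalent to full enumeration but O(n · Σranks)), and the p is
the probability of outcomes at least as far from the null mean as
observed. Beyond 25, a normal approximation with the tie-corrected
variance `n(n+1)(2n+1)/24 − Σ(t³−t)/48` and a 0.5 continuity correction is
used; it agrees with scipy's corrected approximation to machine precision.
The 25-pair switch point is far below any regime where the approximation
error matters (the exact tail and the corrected normal differ by < 1e-3
there). No multiple-testing correction is applied across items by default,
matching routine outcome reporting; Holm/Bonferroni can be layered on by
the caller.

**Logistic regression.** Response ~ intercept + 12 baseline items + age +
male indicator, fitted by IRLS (Newton steps with step-halving, so the
deviance never increases), converged when max |score| < 1e-8 or the
relative deviance change < 1e-10, at most 100 iterations. Wald p-values
come from the observed information. Any coefficient beyond ±15 on the
log-odds scale flags (quasi-)separation and marks the p-values unreliable.
Unknown-gender patients are dropped from this model only (with a warning);
a rank-deficient design raises an error naming the collinear columns
rather than silently regularizing.

## Residualization

Each item is regressed on (intercept, delay) by OLS, separately per
occasion, and the residuals replace the scores. This removes the
spurious between-item correlation that variable follow-up intervals and
overall improvement would otherwise induce. OLS residuals have exactly
zero column means, so paired t statistics comparing baseline and end-point
residuals vanish (< 1e-8 numerically) — a built-in sanity check. If all
delays are equal the slope is undefined and the procedure degrades to
column centering (warned). Both occasions are residualized by default
(`residualize_baseline: true`); residuals stay on their natural scale since
the downstream correlation estimator is rank-based.

## Network estimation

**SKEPTIC correlation.** Pairwise Kendall τ-b (tie-corrected) mapped
through `r = sin(π/2·τ)`, which consistently estimates the latent
correlation under a Gaussian copula with arbitrary — including ordinal —
margins. The τ form is used rather than the Spearman form (the canonical
SKEPTIC choice; with ordinal ties τ-b is the natural variant). If the
entrywise estimate is indefinite, eigenvalues are clipped at 1e-4 and the
matrix rescaled to unit diagonal (`psd_repaired` flag). Constant columns
get zero correlations with a warning.

**Graphical lasso.** `max log det K − tr(SK) − λΣ_{i≠j}|K_ij|` by the
classic block coordinate descent on the working covariance, compiled with
numba because the permutation test and bootstrap re-fit whole paths tens of
thousands of times. Convergence is certified by a *true* duality gap: the
off-diagonal of W − S is projected into the feasible box [−λ, λ] and the
primal objective compared against `log det W_feasible + p`. (The usual
reconstruction-based pseudo-gap can touch zero at a non-optimal fixed
point mid-sweep; the projected gap cannot.) Tolerance 1e-6, at most 500
sweeps, error on non-convergence. λ = 0 returns the plain inverse. The
solver's optima agree with scikit-learn's implementation to ~1e-7 in
objective; scikit-learn is kept as a cross-check oracle in the tests, not
used in the pipeline.

**Model selection.** A 100-point log-spaced λ path from λ_max (the largest
absolute off-diagonal correlation — the empty graph) down to 0.01·λ_max,
following common EBIC-glasso practice. Per path point,
`EBIC = −2L + E log n + 4Eγ log p` with `L = (n/2)(log det K − tr(SK))`
and E the number of off-diagonal entries above 1e-10. Ties break toward
the sparser (larger-λ) model. The library default is γ = 0.5; the pipeline
preset for this analysis is γ = 0 (ordinary BIC), which keeps clinically
plausible edges at modest sample sizes at the cost of admitting small
spurious ones (see Limitations). The selected precision matrix is
converted to partial correlations.

## Network metrics and inference

* **Global strength** `Σ_{i<j}|w_ij|`; **node strength** `Σ_{j≠i}|w_ij|`,
  reported raw and z-standardized across the 12 nodes.
* **Comparison test.** Two-tailed permutation test of |ΔGS|: all rows of
  both samples are pooled and reassigned to two groups of the original
  sizes; the full SKEPTIC + EBIC-glasso pipeline is re-run per regrouping
  (1000 permutations by default); `p = (1 + #{perm ≥ obs})/(1 + n_perm)`,
  never zero. The default scheme regroups individuals independently even
  though baseline and end point are paired — the convention for this test
  family; a `paired` variant (within-patient occasion swapping) is
  available but off by default. Residualization happens once, before the
  test, not inside each permutation. Estimation failures in permutations
  are skipped; more than 5% aborts the test.
* **Case-drop stability.** For drop proportions 0.1–0.7, `n_boots`
  subsamples without replacement; per subsample the network and centrality
  are re-estimated and correlated (Pearson, across nodes) with the
  full-sample centrality; degenerate constant centralities count as
  correlation 0. The CS-coefficient is the largest drop proportion whose
  correlation stays ≥ 0.7 in ≥ 95% of subsamples; a measure is
  interpretable when CS ≥ 0.25. All three thresholds are config-exposed.
* **Closeness/betweenness** use distances 1/|w| (the conventional mapping;
  the weights themselves carry no path semantics) and are excluded from
  default reports: they are rarely stable at clinical sample sizes.

## Synthetic-cohort generator

The generator is a latent Gaussian copula — exactly the family under which
SKEPTIC is consistent, so recovery tests are fair rather than rigged.

* **Truth.** A random graph over the 66 node pairs (independent edges with
  probability `density`, default 0.15 at baseline and 0.4 at end point),
  weights uniform in ±[0.2, 0.4]; the unit-diagonal precision `I − W` is
  shrunk by factors of 0.9 until comfortably positive definite, and the
  latent correlation matrix is its rescaled inverse (partial correlations
  are preserved exactly by the rescaling).
* **Margins.** Per-item thresholds cut the latent normal into the five
  categories. The four cutpoints are an evenly spaced (1 SD) template
  shifted per item by monotone bisection so the implied ordinal means
  match a reference profile of a routine community mental-health cohort at
  intake (e.g. depressed mood 1.68, living conditions 0.33); implied SDs
  then fall near the reference values without further tuning.
* **Improvement.** A per-item latent mean *shift* (thresholds fixed),
  calibrated the same way to the end-point mean profile — improvement
  changes levels, not the conditional-dependence structure.
* **Pairing.** With `u, v` independent standard normal vectors and `A, B`
  the symmetric square roots of the two latent correlation matrices,
  baseline latent = `Au`, end-point latent = `B(ρu + √(1−ρ²)v) − shift`.
  Marginals are exact and the joint is positive definite for any
  ρ ∈ [0, 1); per-item cross-occasion correlation is ≈ ρ (default 0.3).
* **Covariates.** Delays truncated-normal(462.1, 170.3) at 1 day; ages
  truncated-normal(41.1, 13.7) in [18, 70]; 40.9% male. One master seed
  spawns an independent stream per patient, so cohorts are reproducible
  and insensitive to evaluation order.

What the generator does *not* emulate: rater effects and longitudinal
drift, item-level missingness, diagnostic subgroup structure, floor
effects beyond what the thresholds imply, and any real-world departure
from the copula. Passing recovery tests therefore demonstrates internal
correctness of the estimation chain under its own assumptions, not
robustness to clinical data pathologies.

## Validation studies and problem sizes

`scripts/acceptance.py` and the acceptance test suite run, per invocation:
signed-rank type-I error (n = 137, 2000 replicates; expected in
[0.03, 0.07]); comparison-test type-I error (n = 100 per group, 200
permutations, 200 replicates; expected in [0.02, 0.10] — permutation tests
are mildly conservative with the add-one convention); edge recovery at
n = 1000 over 20 truths; comparison-test power (empty vs dense, n = 300,
50 replicates, 200 permutations); and the full-pipeline connectivity
contrast (20 cohorts of n = 137, 400 permutations). Permutation counts in
the *studies* are set for p < 0.05 decision resolution; the single-run
pipeline default stays at 1000. These sizes keep the whole battery inside
roughly a quarter hour on one CPU while holding Monte-Carlo standard
errors of the reported rates below ~0.02.

## Known limitations

* **BIC (γ = 0) is liberal.** At n = 1000 the selected networks recover
  essentially every true edge (sensitivity ≈ 1.0) but admit small spurious
  partial correlations (|w| ≈ 0.002–0.05), with a false-positive edge rate
  around 0.22–0.25 against a 0.15-dense truth. This is inherent to
  EBIC-glasso selection without post-selection refitting: as λ decreases,
  the penalized likelihood keeps improving through shrinkage-bias
  reduction on the strong true edges, and tiny extra edges ride along.
  Raising γ restores sparsity at the cost of sensitivity at clinical
  sample sizes; the pipeline keeps γ = 0 as its preset and exposes γ.
* **Residualization breaks ordinal ties with a shared covariate.** After
  regressing each item on the delay, patients previously tied on an item
  are ordered by the (small, noisy) fitted slope times their shared delay.
  Because the delay is common to all items, these tie-breaks are
  correlated across items, inflating the magnitude of null rank
  correlations (in simulations at n ≈ 250, mean null |r| rises from ~0.15
  to ~0.21) and further densifying the selected networks on both
  occasions. The global-strength *difference* between occasions remains
  detectable, but with reduced contrast; this, together with BIC's
  liberality, is the main power limit of the comparison test at clinical
  sample sizes. The effect is inherent to the regress-then-rank-correlate
  design, which the pipeline reproduces deliberately.
* The permutation comparison test regroups paired observations as if
  independent (see above); with strong cross-occasion correlation this is
  conservative rather than anticonservative in the simulations run here.
* Exact-p enumeration treats midranks as fixed; for heavily tied tiny
  samples the signed-rank null is discrete and p-values are conservative.
* The latent improvement shift reproduces mean changes but not potential
  end-point variance compression beyond what thresholding implies.
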