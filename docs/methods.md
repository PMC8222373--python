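# Methods

## Model

Each bulk transcriptome is modeled as a non-negative combination of
reference cellular signals plus a flat intercept. With `m` genes, `n`
signals and samples indexed by `p`:

- reference signals `s_gc ≥ 0`, `Σ_g s_gc = 1`, built by summing **raw**
  counts over an annotated cell population and normalizing (log-normalized
  values are used only for similarity training, never for signal building);
- exposures `β_cp = exp(z_cp)`, solved in log space so they stay strictly
  positive;
- model mean `λ'_gp = (Σ_c s_gc β_cp + β_0p) · l_gp`, where `l_gp` is the
  effective gene length (fragment counts scale with gene length);
- likelihood `y_gp ~ Poisson(λ'_gp)`, minimized as the weighted NLL
  `Σ w_g (λ'_gp − y_gp log λ'_gp)` with optional per-gene weights
  (`w = 0.5` for housekeeping-type down-weighting, `w = 0` to exclude; the
  package ships no gene lists — they are user input).

The Poisson choice is justified analytically in `cellsignal.compound`: a
sum of independent negative-binomial components with means `μ_c` and
over-dispersions `φ_c` has moment-matched over-dispersion
`φ = Σ (μ_c/μ)² φ_c`, which for components of comparable mean decays as
`1/N`. The MGF of the compound distribution (product of NB factors, Poisson
factors for `φ_c = 0`) is provided for exact verification by finite
differences.

### Optimization

All `z_cp` are fitted jointly by Adam (first-order, adaptive moments;
learning rate 0.01). Samples are likelihood-independent, so the joint fit
equals per-sample fits. Initialization sets every exposure to
`(Σ_g y_gp / Σ_g l_gp) / (n+1)`, which makes the initial model mean match
the data scale (and, when all weights are 1, makes the starting NLL exactly
the intercept-only optimum, so the full fit can only improve on it).

Convergence is checked every 100 iterations and requires BOTH:

1. fractional NLL decrease `< tol` (default `1e-6`), and
2. fractional change of `Q = Σ σ(z_cp)` `< tol`, with an absolute fallback
   when `|Q| < 1`. `Q` is a soft count of active signals; without it the
   optimizer would stop while mass is still shuffling between near-zero
   exposures.

Checkpoint NLL is guaranteed monotone: on any increase or non-finite value
the state rewinds to the last checkpoint and the step size halves; repeated
failure aborts with a diagnostic naming the offending sample. A floor of
`1e-10` inside the log guards `λ' = 0` against `y > 0`.

### Post-processing

The intercept coefficient `β_0p` adds equally to every gene's rate, so the
exposure of the equivalent flat *signal* (profile `1/m`, summing to 1 like
every reference signal) is `m·β_0p`. This rescaled exposure joins the
signal exposures and all are normalized to sum to 1 per sample; the flat
signal's share is the **unexplained signal**, and the normalization makes
fractions comparable across libraries of different depth. (The reciprocal
rescaling — dividing by `m` — would shrink the intercept's share by `m²`
and it could never register; the package uses the multiplication, which is
what makes the withheld-population calibration behave.)

Goodness of fit is McFadden's pseudo-R²,
`1 − NLL_full / NLL_intercept-only`, where the intercept-only NLL has the
closed form optimum `β̂_0p = Σ w y / Σ w l`. Both NLLs include the
`log(y!)` terms (continuous extension via log-gamma for fractional
fragment counts): those constants cancel in the optimization but are
required for the ratio to stay in [0, 1]; with them dropped the NLL goes
negative at realistic sequencing depths and the ratio loses its meaning.
The pseudo-R² uses the same gene weights as the fit, for internal
consistency.

Gene alignment keeps bulk genes that are zero in every signal (they inform
the intercept) and drops signal genes absent from the bulk; signal columns
are *not* renormalized at alignment — renormalization is an explicit
reference-building step (`restrict_to_orthologs(renormalize=True)`).

## Reference building and QC

A cell fails QC if mitochondrial fraction > 0.05, it is a flagged doublet,
or it expresses < 500 distinct genes; an entire cluster is removed when
> 50% of its cells fail (cells transcriptionally similar to failing cells
are treated as suspect). The cluster rule is applied once, on the original
composition — iterating it after removals is a configuration choice left to
the caller, as the cascade it creates is rarely intended. Cycling cells
(S/G2M) and leucocytes are dropped by default so reference signals reflect
identity, not cell-cycle state or infiltrate; both removals are flags
because their appropriateness depends on the reference tissue.
Normalization for similarity training is `log(1 + 10⁴ · x/colsum)`.
Ortholog restriction keeps only one-to-one pairs (many-to-many dropped),
strips Ensembl-style `.N` version suffixes by default, and renormalizes
columns so the sum-to-1 invariant survives.

## Similarity scoring

One-vs-rest penalized logistic regression per reference class on
log-normalized expression, elastic net with `alpha = 0.99` (almost-lasso;
the small ridge component keeps strongly co-linear genes from being
arbitrarily excluded). The observed class fraction `f` enters as a fixed
offset `log(f/(1−f))`; because the offset is constant within a class's
binary problem, it is absorbed by the unpenalized intercept during fitting
and subtracted afterwards — exactly equivalent to offset training, and the
stored intercepts are already "offset 0", the convention used at scoring
time. Predictors are standardized for fitting and coefficients returned on
the original scale (configurable).

The penalty strength is chosen per class by 10-fold stratified, seeded CV
over a geometric path from the just-all-zero strength downward: the largest
strength whose CV loss is within one standard error of the path minimum.
The CV loss is binomial deviance by default (well-defined for probabilistic
output; misclassification available), since the training literature uses
both interchangeably.

Scores are raw logits `intercept_k + Σ coef_kg x_g`; no softmax, so a query
population resembling nothing in the reference scores low for every class.
Cluster annotation averages logits (not probabilities) over member cells
and labels a cluster "undecided" when no class mean reaches 1 logit. Model
genes missing from a query contribute zero — cross-dataset scoring is the
primary use; cross-species scoring requires an explicit ortholog
restriction first.

## Derived scores and statistics

- **Immaturity score**: summed normalized fractions of designated
  fetal/developmental signals; the denominator includes the unexplained
  entry, so the score is in [0, 1].
- **Normal reference range**: min–max of scores over designated normal
  samples (quantile ranges available but not default; the min–max mirrors
  shading an observed range).
- **Group comparison**: two-sided Wilcoxon rank-sum; exact enumeration for
  both groups ≤ 20 without ties, normal approximation with tie/continuity
  correction otherwise (the standard switch point).
- **Covariate scan**: two-sided t-tests (regression-slope t for numeric
  covariates, indicator-based two-sample t for categorical; one test per
  level beyond two), Benjamini–Hochberg FDR across all tests performed
  (Bonferroni optional). The paper-style threshold FDR < 0.01 is the
  caller's choice.
- **ROC**: cutoffs at every observed score plus sentinels, "score ≥ cutoff
  ⇒ positive"; AUC by trapezoid over (1−specificity, sensitivity), with
  ties ordered so vertical segments add no area. Callers negate scores for
  inverse markers.
- **TPM**: `10⁶ · (y/l) / Σ (y/l)`; the reverse conversion multiplies TPM
  by 10⁶, rounds, and sets unit lengths — the large totals are intentional
  (with unit lengths only relative abundances matter and rounding error
  becomes negligible).

## Synthetic data

`cellsignal.simulate` generates the regime the method is built for, with
defaults that define the package's benchmark conditions:

- 2,000 genes, 5 cell types, 500 cells/type, 50 markers/type at 8-fold
  change, per-cell NB over-dispersion φ = 0.3, log-normal(σ = 1) baselines
  drawn independently per type, mean cell depth 5,000 UMIs (log-normal,
  σ = 0.3), bulk depth 10⁶ fragments, gene lengths uniform on
  [200, 10,000].
- Independent per-type baselines emulate *distinct* cell types: real
  transcriptomes of unrelated populations are largely uncorrelated beyond
  housekeeping structure, and the withheld-population calibration is only
  meaningful when the withheld transcriptome is not a near-copy of a
  retained one. Marker blocks on top guarantee identifiability, so recovery
  failures in tests indicate bugs, not ill-posedness.
- Pseudo-bulk mixing proportions default to symmetric Dirichlet(1) (the
  benchmarking design does not dictate a distribution; this covers the
  simplex uniformly).
- Everything is a pure function of (spec, seed).

What the generator does **not** emulate: batch effects, ambient RNA,
doublets, cell-cycle structure, biological covariance between types
(housekeeping correlation), length biases beyond the linear exposure.
Passing the recovery benchmarks therefore demonstrates correctness of the
estimator under its own assumptions, not robustness to real-data artifacts.

## Problem sizes

The test suite and the acceptance script run the full benchmark conditions
(100 pseudo-bulks at the defaults above) for composition recovery and
intercept calibration; oracle-equivalence checks use ≤ 3 signals and ≤ 200
genes where a generic convex solver is a practical independent oracle; the
similarity benchmark uses 10 replicates of a 4-type, 160-gene, 100
cells/type design — sizes chosen so each property is measured with
comfortable margins at interactive runtimes.

## Known limitations

- Fractions are shares of mRNA signal, not cell-count proportions: no
  correction for per-cell mRNA content is attempted (that is deconvolution,
  which this method deliberately is not).
- The unexplained share under-reports mismatch when the missing population
  correlates with a retained signal; pseudo-R² is the complementary
  diagnostic for perturbations the intercept cannot absorb.
- The Q-based stop is a heuristic against mass-shuffling among near-zero
  exposures; pathological plateaus could still stop early (tighten
  `tolerance` if exposures look unsettled).
- The elastic-net trainer iterates a dense sklearn path; very large
  references (tens of thousands of cells × genes) will be slow compared to
  glmnet's coordinate descent.
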