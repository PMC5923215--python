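# Methods

## Model and assumptions

`macropath` implements confirmatory path analysis for cross-species data.
A causal hypothesis is a DAG over named traits; its testable content is the
d-separation basis set: for every non-adjacent pair (x, y), the claim
x ⊥ y | pa(x) ∪ pa(y).  The package assumes:

- the phylogeny is rooted, with non-negative branch lengths proportional to
  expected trait variance (time, under a clock);
- residual trait evolution is Brownian, optionally attenuated by Pagel's λ
  (off-diagonal elements of the shared branch-length matrix V multiplied by
  λ ∈ [0, 1]; λ = 0 is a star phylogeny, λ = 1 untransformed Brownian
  motion);
- traits are continuous, or categorical with exactly two levels (more levels
  are an error, by design, not silently recoded);
- the trait table is complete.  Missing values raise an error rather than
  dropping rows per statement: statement-wise sample sizes would make C and
  CICc incomparable across models.

Each claim is one regression of the pair member *later in the causal order*
on the conditioning set plus the earlier member (the focal term, always
rendered last).  Continuous dependents use GLS with covariance σ²·V(λ) and
λ estimated by maximum likelihood; the focal p-value is a two-sided t test
with n − (number of mean parameters) degrees of freedom.  Binary dependents
use a correlated-residual logistic model (see below) with Wald z p-values;
estimates toward binary dependents are on the logit scale.

Per model: C = −2 Σ ln pᵢ referred to χ²(2k); CICc = C + 2qn/(n−1−q) with
q = edges + vertices; ΔCICc, l = exp(−Δ/2), w = l/Σl.  Weights sum to one;
rows are sorted by CICc with alphabetical tie-breaks for determinism.

## The causal order and statement deduplication

Two conventions are not fixed by the mathematics and were calibrated to the
reference analysis this package reproduces:

- **Causal order.** Topological order computed by Kahn's algorithm with a
  stack (depth-first flavour), preferring the variable declared earliest in
  the path formulas.  When a model *set* is analysed, a single consensus
  order — computed on the union of all models' edges — orients every model's
  claims, so shared claims are fitted once.  If the union is cyclic (models
  that disagree on an arrow's direction), the fallback is the average
  per-model rank with alphabetical tie-breaks.  A plain alphabetical
  tie-break does not reproduce the reference rendering of the claims; the
  declaration-order rule does.
- **Uniqueness of regressions.** Two statements are the same regression when
  their rendered term sequences coincide: same dependent, same terms in the
  same order (conditioning sequences follow each model's own causal order).
  This reproduces the reference pooled/unique counts (36/18 on the
  four-model example).  A set-valued key would merge one further pair whose
  conditioning sets are equal but differently ordered across models; the two
  fits are numerically identical, so the only effect is the reported count
  of unique regressions.

## Standardization

All continuous columns are standardized (mean 0, sd 1 with the n−1
denominator) once, before any fitting, so coefficients are comparable
across paths; binary variables enter as 0/1 indicators (levels sorted,
second level coded 1) and are not rescaled.  The alternative — fitting on
raw scales and rescaling coefficients afterwards — differs when binary
variables are involved; standardize-first is the documented convention here,
not a reproduction claim.

## Numerical choices

- λ is profiled on [10⁻⁷, 1] by bounded scalar minimization restarted from
  three overlapping windows, plus explicit endpoint checks; the interior
  lower bound avoids a boundary-singular covariance on trees with zero-length
  terminal structure.  ML, not REML, so log-likelihoods are comparable
  across mean structures.
- GLS is computed through a Cholesky factor of V(λ) (whitening + least
  squares), never an explicit inverse; standard errors use the unbiased
  σ̂² = RSS/(n−p).
- p-values feed C in log space (`log(2) + logsf`), so claims with
  essentially zero p contribute a finite, accurate −2·log p rather than
  infinity.
- The binary engine solves the GEE score equations by Fisher scoring under
  the working correlation s·C + (1−s)·I, with C the phylogenetic correlation
  matrix; s is estimated by a Gaussian profile likelihood on the Pearson
  residuals, alternating with the β step until both stabilize.  On a star
  phylogeny the model reduces exactly to ordinary logistic regression.
  Quasi-complete separation is detected as a diverging linear predictor and
  raised with a diagnostic, never returned as a huge coefficient.
- Singular designs raise an error naming the collinear terms.
- Parametric bootstrap (`boot > 0`): continuous children are resimulated
  from the fitted λ model at the fitted parameters (nonparametric species
  resampling would break the tree); binary children are resimulated as
  independent Bernoulli draws at the fitted probabilities — a simplification
  that ignores residual correlation and slightly narrows those intervals.
  Percentile 95% intervals.

## Model averaging

Models with ΔCICc ≤ cut_off (default 2) are averaged with renormalized
weights.  Conditional averaging renormalizes per path over the models that
contain it (an alternative — global weights restricted to carriers without
renormalization — is not implemented); full averaging counts absent paths
as zero, shrinking them toward zero.  Standard errors are averaged with the
same weights; no between-model variance term is added, so averaged SEs are
optimistic when models disagree strongly.  Averaging over models with a
significant C only triggers a warning, as the decision is the analyst's.

## What the simulator emulates — and what it does not

`simulate_tree` draws Yule (pure-birth) trees: ultrametric, strictly
positive branch lengths.  `simulate_dag_traits` generates each trait in
causal order as child = Σ β·parent + ε with ε ~ MVN(0, σ²·V(λ)) through a
Cholesky factor, seed-deterministic.  Path coefficients are meant on the
standardized scale; choosing σ = √(1 − Σβ²) keeps child variances near one
so fitted standardized coefficients target β directly.  The returned table
is standardized by default; calibration checks use `standardize=False`
because rescaling by *realized* standard deviations (noisy under strong
phylogenetic correlation) adds scale error that regression standard errors
do not model.

The generator does not emulate: non-ultrametric sampling, extinction,
measurement error, within-species replication, selection-driven (OU)
dynamics, or discrete traits with their own evolutionary model (binary test
data are thresholded latent traits).  Passing tests therefore show
correctness under the method's own assumptions, not robustness to their
violation.

## Test problem sizes

The structural and arithmetic checks are exact and instant.  Statistical
calibration uses: coefficient coverage and λ recovery at n = 300 tips ×
100 replicates (β = 0.8, λ = 0.8); model ranking at n = 200 × 50 replicates
with all true coefficients 0.5.  Ranking is assessed among structurally
distinct hypotheses (null / direct / indirect).  A supermodel that nests the
truth (here `both`) is excluded from that particular check on purpose: when
the extra arrow is truly absent, its claim's p-value is uniform and the
nested pair's CICc difference reduces to 2q·n/(n−1−q) penalties against
−2·ln U, which prefers the supermodel a sizeable fraction of the time — an
inherent property of information-criterion selection between nested models,
not an implementation defect (the worked example shows exactly this
near-tie).

## Known limitations

- One binary computational method (the GEE-style engine); no alternative
  estimators for binary dependents.
- Evolution models beyond λ/Brownian motion (OU, EB, κ, δ) are out of scope.
- Dense covariance algebra: designed for hundreds of species, not tens of
  thousands.
- No latent variables, bidirectional edges, cyclic models, or causal
  discovery; the model set is the analyst's responsibility, including the
  "uninformative extra parameter" judgment for nested near-ties.
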