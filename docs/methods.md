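# Methods

## The model

For a tree with aboveground dry biomass AGB (kg), the component ratio of
component *c* ∈ {stem, branch, twig, foliage} is R_c = B_c / AGB, so the
four ratios sum to one.  The package models the three largest components
with one of two mean functions of a tree attribute X,

* nonlinear: R_c = exp(β₀c + β₁c / X)
* linear:    R_c = β₀c + β₁c·X

with X ∈ {dbh (cm), dbh² (cm², basal-area proxy), dbh²·ht (cm²·m,
volume proxy)}.  The foliage ratio is never estimated: it is defined as
1 − (R_stem + R_branch + R_twig).  Two consequences follow.  First,
predictions are additive by construction — component biomasses or CO₂
stores obtained by multiplying a total by the predicted ratios sum back to
that total at machine precision.  Second, the three estimated equations
share one observational unit per tree, so their errors are cross-correlated
and the system is estimated jointly by seemingly unrelated regression (SUR)
rather than equation by equation.

The foliage exclusion is supported by a pre-fit screen
(`sur.foliage_slope_screen`): at the study scale the foliage-ratio slope on
any of the three predictors does not differ significantly from zero.

## Estimation

Both estimators are feasible generalized least squares (FGLS) on the
stacked 3n-vector of responses with a block-diagonal design.

**LSUR.**  Stage 1 fits each equation by OLS; stage 2 estimates the 3×3
cross-equation residual covariance Σ̂ with
σ̂_ij = eᵢ'eⱼ / √((n−kᵢ)(n−kⱼ)) (geometric degrees-of-freedom divisor,
k = 2; a plain-n divisor is available); stage 3 solves the stacked GLS
normal equations, exploiting the shared-regressor block structure
(the (i,j) block of the normal matrix is σ̂⁻¹_ij·X'X).  Stages 2–3 iterate
until the largest coefficient change falls below 1e−8 (cap 200); a
classic one-step mode is available.  Because all three equations share
the same regressor matrix, FGLS coincides with per-equation OLS
(Kruskal's theorem) at every Σ̂ — the joint fit is still what supplies
the cross-equation correlation and system goodness of fit, and the
implementation handles unequal designs should the system ever be
generalized.

**NSUR.**  The exponential form log-linearizes exactly
(ln R = β₀ + β₁/X), so per-equation OLS of ln R on 1/X supplies starting
values that are exact on noiseless data.  The stacked criterion
e(β)'(Σ̂⁻¹⊗I)e(β) is minimized by Gauss–Newton with step-halving
(halving until the criterion does not increase; the per-iteration descent
is asserted), alternating coefficient steps with Σ̂ updates.  Convergence
requires a relative criterion change below 1e−10 and a maximum coefficient
step below 1e−8 (cap 500 iterations).  Non-convergence is a reported state
(`converged=False`), never an exception, so the model-selection grid can
always tabulate all six candidates.  When residuals collapse toward zero
(an exact fit) the residual covariance is singular; the weighting then
degrades continuously to the identity, which is the correct unweighted
limit.  The linear fitter instead raises an explicit
`SingularCovarianceError`, since a singular covariance there signals too
few trees or collinear responses rather than a perfect fit.

**Inference.**  Standard errors come from the inverse of the (final) GLS
normal matrix; p-values use a t reference with n − 2 degrees of freedom
per equation (df = 10 at the 12-tree study scale).  Per-equation RSE is
√(SSR/(n−2)); per-equation R² is 1 − SSR/SST.  The overall system R² is
McElroy's definition, 1 − ê'(Σ̂⁻¹⊗I)ê / ỹ'(Σ̂⁻¹⊗I)ỹ with centered
responses, recorded as such in every fit report because other system-R²
definitions would give different numbers from the same fit.

## Model selection

The six candidates ({nonlinear, linear} × {dbh, dbh², dbh²·ht}) are all
fitted; failures (e.g. missing heights for the volume-proxy predictor) are
recorded as infeasible rather than dropped.  Ranking is deterministic:
first the count of equations with a significant slope (p ≤ 0.05, more
first), then mean per-equation RSE (smaller first), then overall R², with
the candidate label as the final tie-break.  Significance precedes RSE
because a candidate whose slope cannot be distinguished from zero does not
describe an allocation trend at all, whatever its RSE.  The visual
residual-plot criterion is operationalized as an exportable long residual
table plus a dispersion statistic (SD of residuals within quantile bins of
the predicted values), which makes prediction-clustering — the failure mode
of the exponential form here — measurable.  Significance stars follow the
convention ns (p > 0.05), * (≤ 0.05), ** (≤ 0.01), *** (≤ 0.001),
**** (≤ 0.0001), boundaries inclusive.

## Synthetic plantation generator

The generator emulates a 9-year-old even-aged plantation census of 921
trees in five 5-cm diameter classes with probabilities proportional to
167/518/208/25/3, a stratified destructive sample of 12 trees allocated
2/4/3/3/0 across classes, and component biomasses whose ratios follow the
linear-in-dbh calibration truth with cross-component error correlation.
Defaults (all configurable):

| parameter | default | note |
|---|---|---|
| class edges (cm) | 2, 5, 10, 15, 20, 25 | dbh uniform within class; the open top class is truncated at 25 cm |
| ratio means (β₀, β₁) | stem (0.6790, −0.0188); branch (0.1437, 0.0222); twig (0.1441, −0.0045) | packaged reference fit |
| error SDs | 0.0658, 0.0711, 0.0243 | the reference per-equation RSEs |
| error correlation | stem–branch −0.8340, stem–twig −0.1400, branch–twig −0.3407 | reference residual correlation |
| AGB allometry | 0.10·dbh^2.40 kg | sets only the mass scale; ratios are scale-invariant, so this choice cannot affect any fitted quantity |
| height curve | 3.33·dbh^0.363 m | log–log fit through the four sampled-class (mean dbh, mean ht) pairs; lognormal noise at the class height CVs (18.9/15.9/15.1/26.0%, top class reusing 26.0%) |
| moisture ratios | 0.5 stem/branch/twig, 0.35 foliage | typical dry:fresh fractions for temperate broadleaf wood and foliage |
| subsample fraction | 0.1 | of each component's fresh weight |

Error triples are drawn from the trivariate normal and **redrawn** (cap
1000 per tree, then an explicit error) until every modeled ratio exceeds
0.01 and the three sum to below 0.98; the foliage complement is then in
(0.02, 1).  Rejection preserves the linear conditional mean better than
clipping would, but it is still truncation: with the default parameters
the mean ratio sum (≈0.965 ± 0.023) sits close to the 0.98 cap, so
accepted draws are shifted slightly downward, and because the branch
equation has the largest covariance with the sum, the realized branch
means sit ~0.005–0.01 below the nominal line (more at very small dbh).
This is a property of enforcing ratio validity, not of the estimators;
consequently the large-sample parameter-recovery checks draw errors from
the unconstrained trivariate normal that the SUR model itself assumes,
while study-scale (n = 12) replication checks run through the full
constrained generator, where the shift is well inside Monte-Carlo noise.

What the generator does *not* emulate: spatial structure, competition,
crown allometry beyond the ratio equations, measurement error in dbh/ht,
and any nonlinearity in the true allocation trend.  Passing tests
therefore demonstrate correctness of the estimators and pipeline under
the linear-allocation data-generating model, not the field validity of a
linear allocation for any particular species.

## Reference constants and the worked partition

The packaged `data/reference_fit.json` carries the final linear-dbh SUR
coefficient set (coefficients, SEs, p-values, RSEs, R², residual
correlation, overall R² 0.73, fitted dbh range 3.9–19.7 cm) and is used
as (a) the default prediction model, (b) the generator's calibration
truth.  P-values published only as "< 0.0001" are stored as 0.0001.  The
worked stand partition multiplies the mean observed component ratios
(0.463/0.399/0.092/0.046) by the 452.2 t CO₂ ha⁻¹ average stand stock,
giving 209.4/180.4/41.6/20.8 t CO₂ ha⁻¹ for stem/branch/twig/foliage.
The hybrid estimator composes a volume-to-biomass conversion (biomass
expansion factor, Mg m⁻³; published values 1.328 and 1.528 for 25- and
46-year-old stands of this species) with the ratio partition.

## Numerical choices and degenerate inputs

* Out-of-range predictions: by default each modeled ratio is clamped to
  [0, 1], a negative foliage complement is floored at zero, and the four
  values are renormalized to sum to one; the record is flagged `clamped`.
  A raw pass-through mode returns unclamped values (still summing to one).
  Predictions outside dbh 3.9–19.7 cm raise an `ExtrapolationWarning`.
* Predictors carry their natural units (cm, cm², cm²·m) with no rescaling.
* Zero-biomass components are allowed (ratio 0); a tree with zero AGB is
  an error.
* Moisture conversion is per tree by default (each tree was subsampled);
  pooling across trees is an option.
* Covariance estimates are symmetrized and checked for conditioning
  (threshold 1e12) before inversion.
* Fixed seeds make every pipeline stage bit-reproducible; the CLI embeds
  seed, config echo, and software version in every artifact.

## Problem sizes used in the checks

The verification suite runs at the study scale (n = 12) for replication
checks (200 replicates for median bias and 95%-interval coverage), at
n = 2000 for large-sample recovery, n = 1000–5000 for generator
correlation convergence, and 100 replicates of n = 200 for selection
consistency.  The brute-force oracles (dense stacked GLS; grid search
plus simplex polish for the nonlinear system) run on 12–50-point
instances, where they are exact enough to resolve the 1e−8/1e−4
agreement they are asked to certify.

## Known limitations

* The 12-tree reference fit cannot be exactly reproduced because the raw
  destructive-sample measurements are not published; the packaged
  coefficient set is a reference output and calibration truth, and
  emulated 12-tree fits scatter around it with the sampling variability
  the SEs describe.
* The residual-covariance divisor, FGLS iteration policy, and overall-R²
  definition behind the reference values are not documented at the
  source; this package's choices (geometric df divisor, iterated FGLS,
  McElroy R²) are stated in every report so results are comparable on
  their own terms.
* The exponential mean function must be positive, so the nonlinear
  estimator requires positive observed ratios for its start values.
* Ranking weights for disagreeing selection criteria are a convention
  (significance → RSE → system R²), exposed as such.
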