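# Methods

This note documents the statistical procedures implemented in
`ctmatch`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic-data validation does and does not
establish.

## Units and preprocessing

The analysis unit is the census tract on baseline boundaries. Tracts
below a minimum area (default 50 km²) are merged iteratively: the
smallest sub-threshold tract is absorbed into the same-municipality
neighbor sharing the longest border, until no tract is below the
threshold. Ties on border length break toward the lowest neighbor id so
merge logs are reproducible; a sub-threshold tract with no
same-municipality neighbor is retained with a warning rather than
dropped. Aggregation rules are an explicit registry per column:
extensive fields (areas, household counts, landholding counts, forest
km², income-category counts) add; intensive fields average with area
weights, or household weights where the quantity is a property of
people (income, literacy, sanitation, Gini inputs); presence flags OR;
gazettement years take the minimum. Mean income across merged tracts is
household-weighted, and the Gini of a merged tract is recomputed from
the summed income-category counts rather than averaging per-tract
Ginis — inequality indices do not aggregate linearly.

Attributes reported on later boundaries are harmonized onto baseline
tracts by areal interpolation under a homogeneous-population
assumption: counts are allocated in proportion to the share of the
source unit's area inside each target; rates are overlap-area-weighted
means of the sources intersecting the target. Targets with zero overlap
are flagged missing, never zero-filled. Overlap areas are inputs
(computed upstream in an equal-area projection); the package does no
geometry processing of its own.

## Outcomes

* **Forest**: inputs are baseline/endline forest areas from a
  cumulative old-growth-loss product, so endline > baseline is treated
  as a data error (no regrowth in the metric). The regression response
  is endline forest cover % — this makes baseline forest cover the
  natural baseline covariate — while percentage *effects* are expressed
  on the deforested-share scale (below).
* **Income**: mean monthly household income. When income arrives as
  counts per category (as in census aggregates), each category is
  represented by its midpoint; the open top category by 1.5× its lower
  edge (configurable). Endline income is divided by a supplied
  consumer-price deflator.
* **Gini**: computed from the grouped distribution,
  G = ΣᵢΣⱼ nᵢnⱼ|xᵢ−xⱼ| / (2N²μ), with within-category equality assumed.
  Two algebraically equivalent implementations (pairwise double sum and
  Lorenz trapezoid) are evaluated on every call and must agree to
  1e-12; a single household returns 0 by convention, an empty tract is
  flagged missing.
* **Literacy / sanitation**: simple percentages of household heads /
  households; zero denominators are missing, not zero.

## Cohorts

For arrangement A: treated ⇔ overlap(A) ≥ 10% and gazetted inside the
window; excluded if any *other* arrangement covers ≥ 1%, or if
overlap(A) lies in the ambiguous (1%, 10%) band, or if gazetted outside
the window; control candidates have all overlaps < 1%. Control subsets:
all non-protected tracts; sparsely populated (settled < 10%, no mines);
four agricultural classes by dominant landholding size (most properties
among <10 ha, 10–50 ha, 50–200 ha, >200 ha; ties break toward the
larger class to avoid over-labelling smallholder landscapes); mining
(≥1 licence after baseline, none at baseline). Agricultural classes
additionally exclude tracts with post-baseline mines so the control
classes are mutually disjoint. Comparisons apply symmetric
treated-side exclusions (settled ≥ 10% drops treated tracts from
agricultural/sparse comparisons; any baseline mine, or a treated-side
post-baseline mine, drops the tract from mining comparisons). Every
input tract lands in exactly one of treated/control/excluded, with the
rule recorded — cohorts are fully auditable. A tract may serve as a
control in several arrangement analyses; the analyses are independent.

The post-2006 robustness check is the same operation with
window = (2006, 2010). The 50%-threshold check raises the protection
threshold; its treated set is necessarily a subset of the 10% set.

## Matching

Propensity scores come from a logistic regression (IRLS to tolerance
1e-8, max 100 iterations) of treatment on internally standardized
covariates; rows with missing covariates are excluded listwise and
logged; perfect separation raises with advice to trim or use a caliper.
Distances are absolute differences of the linear predictor (logit
scale), the common convention.

**Full matching** partitions each exact stratum (state × baseline
mining; mining comparisons stratify on state only, since baseline mines
are excluded there) into subclasses of one treated with ≥1 controls or
one control with ≥1 treated, minimizing total within-subclass distance
subject to subclass-size bounds (default 10 controls per treated and
vice versa; infeasible bounds are relaxed with a log entry rather than
dropping units). The problem is solved exactly as the minimum-cost-flow
LP over the bipartite graph with unit lower bounds on every node's
degree; the constraint matrix is totally unimodular, so the HiGHS
simplex vertex is integral. Strata above 20,000 treated×control pairs
use a sparsified edge set (30 nearest controls per treated plus a
rank-aligned feasibility backbone) — a documented approximation that
does not affect small strata, where the solution is provably optimal
(tested against exhaustive enumeration of all star-forest partitions).
Weights implement the ATT estimand: treated weight 1, controls t/c per
subclass, so control weights sum to the treated count within every
stratum. Whether the original analyses used ATT or ATE weighting is
not documented; ATT is the estimand here and is flagged in the results
schema.

Balance is measured by the standardized mean difference with the
*pre-match treated-group SD* as denominator, held fixed before/after so
improvement is attributable to the weights (ATT convention). When any
covariate's post-match |SMD| exceeds 0.25, covariates are greedily
pruned from the propensity model: each candidate drop is rematched and
the drop minimizing the maximum |SMD| over the full covariate set is
kept; the loop stops when balanced or when no drop improves, returning
the best-found match with explicit unbalanced flags if 0.25 is never
reached. The outcome regression always receives the full covariate
set. The optional caliper is expressed in SDs of the linear predictor
(default off; 1.5 in the robustness configuration); treated units with
no control in range are discarded and logged, as are controls no
treated unit can reach (full matching must place every unit, so
out-of-range controls cannot be accommodated under a caliper).

## Estimation and inference

The outcome model is the matched-weight regression of the endline
outcome on treatment and the full covariate set including the baseline
outcome — endline-on-baseline rather than a change score, to avoid
spurious correlation from sharing the baseline between response and
regressor. Inference uses HC1:

Var(β̂) = n/(n−k) · (X′WX)⁻¹ X′W diag(e²) WX (X′WX)⁻¹,

with the matching weights inside the meat (this equals the
weighted-least-squares HC1 of statsmodels, cross-checked in tests).
Breusch–Pagan (studentized, LM = nR² on the whitened squared
residuals, χ² with k−1 df) is reported per model as the motivation for
robust errors. Percentage effects divide β₁ by the matching-weighted
mean *counterfactual* outcome of the treated (fitted values with
Tr := 0); for forest, the effect is mapped to the deforested-share
scale: avoided deforestation % = −β₁ / (counterfactual deforested
share), so protection that reduces loss appears as a negative
percentage. The counterfactual denominator is a design choice (the
source analyses do not state theirs); the control-group raw mean is
available as a sensitivity option. P-values are two-sided;
Benjamini–Hochberg FDR is applied within families defined as all
comparisons of one outcome (configurable).

## Robustness modules

* **Oster bounds**: β* = β̃ − δ(β̇−β̃)(r_max−R̃)/(R̃−Ṙ) with r_max
  defaulting to min(1.3·R̃, 1) (the customary convention); both β* at
  δ = 1 and the δ solving β* = 0 are reported, since either can serve
  as the headline statistic. R² movement of zero leaves the bound
  undefined and raises.
* **Moran's I** on regression residuals with row-standardized
  inverse-distance weights cut off at the 10% distance quantile (the
  weighting scheme is a package choice; no scheme is prescribed by the
  design being reimplemented); expectation −1/(n−1); p-values from 999
  permutations with a fixed seed; islands are dropped with a count.
  For matched sets above 1,200 units the dense distance matrix is
  subsampled to 1,200 units deterministically.
* **Two-period fixed effects**: within-transformation on the stacked
  panel with period effect and Tr×post term; for T = 2 this equals the
  first-difference estimator, an identity the tests verify to 1e-10.
* **Weighted one-way ANOVA** of post-matching group means (settled land
  and pasture across landholding classes), with weights normalized so
  the error degrees of freedom carry the unit count; groups of <2 units
  are excluded and reported.

## Synthetic landscapes

The generator emulates the features of a tract panel that matter for
validating this design, with defaults chosen to resemble the study
region's published aggregates:

* ~2,000 tracts on a 50×40 lattice (rook adjacency, shared borders =
  min cell side), lognormal areas (μ=6.4, σ=1 → mean ≈ 990 km²,
  matching the real panel's ~977 km² mean tract size), four contiguous
  state strata, 5×5-cell municipalities.
* Six covariate fields (slope, elevation, flood risk, travel time,
  population density, baseline forest cover) generated by Gaussian
  kernel smoothing of i.i.d. normals — cheap, and sufficient to give
  Moran's I something to detect; the correlation range is the kernel
  bandwidth in cells.
* Protection assigned by a logistic propensity favoring remote,
  forested, steep, sparsely populated tracts (intercept −2.9, slopes
  0.2–0.55 on standardized covariates → ≈6% per arrangement), the same
  covariates that slow deforestation and income growth — so the naive
  contrast is biased toward overstating avoided deforestation, by
  ≈ +9.5 points on the forest outcome under the defaults. Treated
  overlap is Uniform(0.10, 1); an explicit 5% of untreated tracts draw
  overlap in (0.01, 0.10) to exercise the ambiguous-band exclusion, and
  3% of treated tracts brush a second arrangement.
* Untreated tracts receive a land-use mosaic (30% sparse, 18/15/10/15%
  agricultural classes, 12% mining); 2% of all tracts have baseline
  mines and 1% post-baseline mines irrespective of class.
* Outcomes: endline = baseline + secular trend + additive effect +
  noise, with residual SD scaled by exp(0.5·z_popdensity) for
  heteroscedasticity. The secular decade trend is −18 points of forest
  cover, +150 R$ income, −0.02 Gini, +8 literacy points, −10 poor
  sanitation points, so "both groups improve, treated improves less"
  patterns are representable (the default IT income effect is −60 R$).
  Default forest effects are +5/+4/+7 points of retained cover for
  SPA/SUPA/IT. The secular loss level is deliberately high relative to
  effect + noise so the physical floor (endline ≤ baseline) truncates
  a negligible (~0.02-point) part of the effect; forest loss depends
  only on covariates the analyst can match on, making "matching on the
  true confounders" well defined.
* Income and inequality are realized through actual household draws:
  per tract, households (≈ density·area/3.5, capped at 30–400) draw
  lognormal incomes whose mean and Gini hit the tract's target values
  (σ from the lognormal identity G = 2Φ(σ/√2)−1), then are reported
  only as counts per income category, as census aggregates are.
  Binning compresses tail information, so income effects recovered from
  binned means are attenuated relative to the injected effect — a
  measurement property shared with the real data. The recovery
  experiments therefore use the forest outcome, whose effect is
  injected directly in outcome units.

What the generator does **not** emulate: real deforestation spatial
dynamics (frontier diffusion, roads), migration between tracts,
boundary changes (harmonization is tested on constructed overlap
tables), measurement error in covariates, or spillovers between
neighboring tracts. Passing recovery tests therefore show that the
estimator chain is consistent and calibrated under the design's own
assumptions — not that those assumptions hold in any real landscape.

## Validation results the package computes about itself

`tests/test_acceptance.py` and `scripts/acceptance.py` recompute, from
scratch: exact agreement of the full-matching optimum with exhaustive
enumeration on small instances; the 200-replicate recovery experiment
at 2,000 tracts (bias within 2 Monte-Carlo SEs, 95% CI coverage inside
[93%, 97%], naive bias large and positive); grouped-Gini agreement with
the brute-force pairwise formula to 1e-12; HC1 agreement with an
element-wise sandwich; the Benjamini–Hochberg hand example; Breusch–
Pagan size ≈ 5%; the merge and harmonization hand-traces; the panel
FE ≡ first-differences identity; the Oster formula check; and the
Moran's I null expectation. Problem sizes (200 replicates × 2,000
tracts; 999 permutations) were chosen so the whole validation runs in a
few minutes on one CPU while keeping Monte-Carlo error well below the
tolerances being checked.

## Numerical choices and edge cases

Logit fitting standardizes covariates internally (scores are invariant
to affine covariate rescaling); zero-variance covariates get unit scale
rather than dividing by zero. Collinear regression columns are dropped
with a log. Degenerate SMD denominators (constant covariate among
treated) are NaN-flagged, and NaNs are ignored when maximizing |SMD|
during pruning. Constant residuals make Breusch–Pagan degenerate
(p = 1) and Moran's I undefined (error). Percent effects with
counterfactual means below 1e-8 are reported missing. Empty cohorts
raise with diagnostic counts, and the pipeline skips such comparisons
with a warning (e.g., no treated mining tracts for some arrangements)
rather than aborting the grid.

## Known limitations

Matching weights are treated as fixed in the outcome regression
(standard practice; the recovery experiment shows ~93% coverage of
nominal-95% intervals, at the anticonservative edge of the accepted
band). Cluster-robust and bootstrap errors, spatial-lag models,
distance-band spillover analyses, genetic matching, and raster
processing of deforestation imagery are out of scope; tract-level
forest metrics are inputs. The Dataverse-deposited replication data is
not bundled; external tables are supplied via `tracts_path` /
`adjacency_path` in the documented schema.
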