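# Methods

`carescape` chains four analyses around a seeded synthetic study generator:
facility layout metrics, catchment-based accessibility, survey psychometrics,
and demand differentiation. This note records the models, the defaults and
why they were chosen, the numerical conventions, and what passing tests do
and do not establish about real data.

## Point-pattern layout metrics

The nearest-neighbor index is the Clark–Evans ratio
`NNI = (mean_i min_{j != i} d_ij) / (0.5 * sqrt(A / n))`, the observed mean
nearest-neighbor distance over its expectation under complete spatial
randomness in a region of area `A`. Values below 1 indicate clustering,
above 1 regularity. Significance uses the classical z statistic with
standard error `0.26136 / sqrt(n^2 / A)`; classification requires the
two-sided test to reject at `alpha` (default 0.05) before departing from
"random", and `alpha = 1` disables the test so the ratio alone decides.

Kernel density uses the planar normalization
`f(c) = 1/(n h^2) * sum_i K(||c - c_i|| / h)` with a radially symmetric
kernel integrating to one over the plane: Gaussian
(`K(u) = exp(-u^2/2) / (2*pi)`) by default, quartic/biweight
(`K(u) = (3/pi)(1-u^2)^2`, finite support) by name. The bandwidth is a
required argument; a rule-of-thumb default `sigma * n^(-1/6)` with
`sigma = sqrt((var_x + var_y)/2)` is provided for convenience only.
**No edge correction is applied**; density near the region boundary is
biased low. Raster cells hold midpoint densities, so the integrated grid
mass reaches 1 only up to midpoint-rule discretization error and truncation
at the grid edge.

## Two-step floating catchment accessibility

The classic form computes per-facility supply-demand ratios
`R_j = S_j / sum_{k: d_kj <= d0} D_k` and per-community scores
`A_i = sum_{j: d_ij <= d0} R_j`. Because each person is counted fully in
every catchment they touch, both demand and supply are inflated. The
improved form weights pairs with a truncated Gaussian decay

    w(d) = (exp(-(d/d0)^2 / 2) - exp(-1/2)) / (1 - exp(-1/2)),  d < d0

(1 at the facility, 0 at the cutoff, strictly decreasing between; the
boundary `d = d0` gets weight 0), then normalizes each demand point's
weights to sum to one across reachable facilities before using them in
both steps. That normalization was chosen among the two possible ones
because it makes the method conserve supply exactly:
`sum_i D_i A_i = sum_j S_j` over facilities with any allocated demand,
which is precisely the accounting defect of the classic form. The
column-wise (over-demands) normalization is exposed as an option but is
experimental and does not conserve supply.

Conventions: `R_j = 0` for facilities serving nobody, `A_i = 0` for
unreachable demand points, capacity defaults to 1 when a facility has none
recorded. `d0` is a required parameter (default 1.0 region units in the
pipeline config, 0.25 for the unit-square study); walking-time radii
convert as `distance = speed * minutes / 60` with a default walking speed
of 4.5 km/h when coordinates carry real units. Distances are straight-line
Euclidean unless a precomputed origin-destination matrix is supplied.

## Survey psychometrics

Cronbach's alpha is the raw covariance form
`k/(k-1) * (1 - sum var_i / var_total)` with `n-1` variances; a
standardized variant (z-scored items) is available by flag since scale
reports in this literature rarely say which was used. Corrected item-total
correlation is the Pearson correlation of an item with the sum of the other
items of its scale. KMO is `sum r_ij^2 / (sum r_ij^2 + sum p_ij^2)` over
off-diagonal pairs, with partial correlations taken from the scaled inverse
correlation matrix. Bartlett's sphericity statistic is
`-(n - 1 - (2k+5)/6) * ln det(R)` on `k(k-1)/2` degrees of freedom.
All four are computed per primary indicator by default (overall on
request), with listwise deletion of incomplete rows. Degenerate inputs
(zero total variance, singular or non-positive-definite correlation
matrices) raise explicit errors rather than returning NaN.

## Demand analysis

Descriptives: item means on the 1-5 scale, indicator means as the mean of
their items' means, and an overall mean weighted by item counts (equal to
the plain mean of all 11 item means). Walking-time items are tabulated as
three-category proportions.

Housing prices are tiered with one-dimensional K-means (`k = 3`, 10
restarts, seeded); tiers are relabeled low/medium/high by ascending center
and tier boundaries are midpoints between adjacent tiers' extreme members.

Group differences use classic one-way fixed-effects ANOVA per item (Welch
correction by flag), raw p-values with a 0.05 flag and **no multiple-testing
correction** — the reports are descriptive, and the absence of correction is
deliberate and noted here.

Logistic regression fits a maximum-likelihood model of a binary demand
outcome on ordinal attribute codes (education 1-3, income 1-4, self-care
1-3) entered as single numeric covariates, reporting coefficient, standard
error, Wald z, two-sided p and `OR = exp(coef)`. The outcome is either a
binary column of the survey or a primary indicator name, in which case the
respondent's mean item score on that indicator is dichotomized at a
threshold (default 3.0, "generally needed" or higher counts as demand).
The dichotomization threshold is the main reconstruction assumption for
surveys that record only Likert responses. Separation and non-convergence
raise errors with diagnostics instead of returning unstable estimates.

## The synthetic study generator

The generator emulates a proportional quota survey of a mid-sized Chinese
urban district: 20 communities on a unit-square planar region (the real
coordinate system is out of scope; all spatial math is metric-generic),
172 residential areas split 13 work-unit / 148 commercial / 11 demolished,
community aging rates uniform on [0.11, 0.16] (populations are drawn in
hundreds so rounded older-adult counts realize two-decimal rate bounds
exactly), and 447 respondents.

*Demographics* use largest-remainder quota allocation per variable —
exact configured counts, independently shuffled — mirroring proportional
quota sampling; variables are mutually independent and empirical margins
deviate from configured ones only by integer rounding. Self-care margins
are not part of the published demographic table; the default 0.60/0.30/0.10
(self-care / self-help / caregiver-dependent) split is a realistic
community profile chosen once.

*Demand outcomes and Likert items.* Each respondent carries one binary
demand indicator per primary scale drawn from a logistic model
`logit P = intercept + sum_a beta_a (x_a - E[x_a])` in the centered ordinal
attribute codes. Generating the indicator directly (rather than deriving it
from noisy item scores) makes the logistic fit on the stored indicator
exactly well-specified, so configured log-odds are recoverable with nominal
confidence-interval coverage; dichotomized item scores would attenuate
every coefficient through measurement error. The three latent scale factors
are exchangeably correlated standard normals (default correlation 0.3)
shifted by `1.2 * (indicator - 1/2)` and restandardized, so the Likert
items still carry the demand signal and the dichotomize-at-three analysis
route points the same way. Items are
`loading * factor + sqrt(1 - loading^2) * noise + location`, cut at fixed
thresholds (-1.5, -0.5, 0.5, 1.5) into codes 1-5. Loadings default to
0.72 / 0.81 / 0.70 per scale, calibrated so scale reliabilities center on
the published 0.766 / 0.820 / 0.747; item locations default to offsets that
reproduce the published descriptive profile (indicator means near
2.72 / 2.86 / 3.46). Default attribute effects are moderate log-odds
(0.25-0.90 per ordinal unit) sized to be detectable at survey scale.

*Prices.* Commercial areas draw prices from a three-component normal
mixture with centers 28k / 50k / 74k RMB, spreads 4-5k and weights
0.40 / 0.40 / 0.20, placed so K-means tier boundaries fall near the
published 39,000 and 62,000 RMB cuts.

*Walking-time items* are independent categorical draws; the healthcare and
night-care "within 5 minutes" probabilities (0.4827, 0.0398) match the two
published marginal values, the other nine items use plausible defaults.

*Facilities* come in three spatial modes: `clustered` (Gaussian offsets
around a few parent centers, the default, reflecting observed agglomeration
of urban care facilities), `random` (uniform) and `uniform` (jittered
grid), with integer capacities 20-120.

All randomness flows from one integer seed through
`numpy.random.SeedSequence` child streams (one per layer), so identical
configs give bit-identical studies and layers are reproducible in
isolation.

**What the generator does not emulate:** household structure, within-
community clustering of demographics, spatially correlated demand,
network travel distances, nonresponse, and ordinal measurement quirks
(acquiescence, central tendency). Passing calibration tests therefore
shows that the analysis chain recovers known structure of this synthetic
design at survey scale — not that the same estimates would be unbiased on
a real multistage survey.

## Numerical choices and problem sizes

- Oracle agreement tolerances: 1e-10 to 1e-12 against explicit-loop
  recomputation on small instances; conservation to 1e-10 relative.
- Parameter recovery uses 200 replicates of n = 5,000 respondents;
  reliability and price-boundary calibration use 200 and 100 replicates at
  the default study size; margin convergence is checked at n = 50,000.
  These sizes give stable Monte-Carlo summaries at a few seconds of
  runtime each.
- K-means ties are broken by scikit-learn's first-encountered assignment;
  degenerate inputs (fewer distinct prices than clusters) raise errors.
- Rounding in report files: 2 decimals for means and percentages, 3 for
  alpha/KMO/OR, 4 for p-values.

## Known limitations

- No edge correction in either NNI or KDE; both are biased for patterns
  hugging the region boundary.
- The over-demands weight normalization is exposed but untested beyond its
  algebraic definition.
- One published inconsistency is deliberately left unarbitrated: scale
  reliability is reported to 3 decimals and the module does not decide
  between the two published values (0.819 vs 0.820) for the medical scale.
- The number of surveyed communities is reported inconsistently at its
  source (22 in one place, 20 in another); the generator defaults to 20.
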