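# Methods

This note records the models the package implements, the assumptions they
make, the defaults and why they were chosen, and what the synthetic
test-bed does and does not establish about real survey data.

## The estimation problem

Trap surveys for tsetse flies yield, per deployment, a coordinate, an
exposure (trap-days) and a count per species.  The goal is a per-cell
habitat-suitability index on a 500 m grid, learned from presences only —
absences are unreliable because a zero catch over a short deployment is
weak evidence — while correcting for the fact that traps are placed where
flies were expected.  The package treats this as a presence–background
density-ratio problem (MaxEnt) with an explicit sampling-effort model, and
keeps the defensible absences aside as an independent validation set.

## Apparent density and rank tests

Apparent density (AD) is flies per trap per day.  Group summaries report
the mean ± sample (n−1) standard deviation of per-record ADs; a pooled
variant (total catch over total trap-days) is provided separately because
the two answer different questions (average trap experience vs population
catch rate).  Group comparisons use Kruskal–Wallis with tie correction —
catch counts are far from normal — with Dunn's pairwise z-tests run only
when the global test rejects at α = 0.05, Bonferroni-adjusted by default
(the adjustment is switchable; Bonferroni is the conservative choice when
no particular adjustment is mandated).  A one-way ANOVA pass-through
exists for comparison but is not part of the reported chain.

## Co-occurrence

The C-score over the species × site binary matrix is the mean of
checkerboard units `CU_ij = (R_i − S)(R_j − S)`; a normalized variant
`CU/(R_i R_j)` ∈ [0, 1] is always reported alongside because the raw score
scales with matrix fill.  Significance comes from a fixed-fixed null
(both margins preserved) sampled by a sequential 2×2 checkerboard-swap
chain with burn-in 10×(cells) and thinning = cells, with the add-one
Monte-Carlo two-sided p-value, (k+1)/(n+1).  Direction (aggregation vs
segregation) is read from the sign of the standardized effect size.

One combinatorial caveat matters in practice: **for a two-species matrix
the fixed-fixed null is degenerate** — with both margins fixed and only
two rows, the number of shared sites cannot change under swaps, so the
C-score never varies.  A two-species analysis therefore uses the
`fixed_rows` null (row totals preserved, occurrences placed equiprobably
across sites), which is the null under which a two-species C-score can be
significant at all.  A matrix that is its own margins' unique completion
returns p = 1 with a warning by default; `strict=True` raises instead.

## Spatial filtering and pseudo-absence design

Order: per-pixel thinning (densest-effort record kept, earliest on ties)
→ closed 2 km buffer removal of absences around presences (the species'
flight range; boundary points are removed) → absence significance filter.
The filter models a zero catch over `D` trap-days as Poisson with rate
μ₀·D, where μ₀ is the smallest catch rate worth detecting; the absence is
kept iff `exp(−μ₀·D) ≤ α`.  Defaults μ₀ = 0.1 flies/trap/day (the order
of the sparser species' observed AD) and α = 0.05 imply a ≥ 30 trap-day
requirement.  The pipeline applied twice equals the pipeline applied once
(idempotence is tested).

The sampling-effort kernel is a Gaussian kernel density of all trap
locations evaluated at cell centres, masked and renormalized.  The
library default bandwidth is Silverman's rule; the *pipeline* default is
1.5 km, because Silverman's rule assumes roughly unimodal data and
over-smooths strongly clustered trap patterns (to ~5 km on the reference
scenario), after which the background under-represents the true effort
concentration and residual survey bias leaks into the fitted
protected-area effect.  Backgrounds are sampled without replacement
∝ effort, one per cell at the cell centre, excluding the presence buffer
and any cells reserved for validation.  The pseudo-absence count defaults
to the presence count per submodel.

## ENFA

Covariates (categorical layers as indicators, first level dropped as the
reference) are standardized to the available space.  Marginality is the
presence-cell mean `m` of the standardized covariates; the index is
`‖m‖/1.96`, so 1 places the niche barycentre at the one-sided 97.5% bound
of the available space.  Specialization comes from the eigenvalues of
`P R_s^{-1/2} R_g R_s^{-1/2} P`, with `R_s` the used-space covariance
(ridge 1e-8 for stability), `R_g` the available-space covariance and `P`
the projector orthogonal to the marginality direction in the whitened
space.  Used = available gives eigenvalues ≈ 1; an eigenvalue of 9 means
the species occupies one ninth of the available variance on that axis.
Note that when marginality is essentially zero its direction is noise and
is preferentially drawn toward the strongest specialization axis by the
whitening; the planted-specialization test therefore plants marginality
on an orthogonal covariate, which is also the scientifically meaningful
configuration.

## MaxEnt

The fit minimizes `log Σ_bg exp(λ·f) − (1/m) Σ_pres λ·f + Σ_j β_j|λ_j|`
— convex, with the KKT soft-matching condition
`|E_q[f_j] − presence mean f_j| ≤ β_j` at the optimum (asserted in tests).
Numerics: features are internally scaled to background mean 0 / sd 1; the
L1 term is handled by the positive/negative split solved with L-BFGS-B,
followed by an active-set Newton polish that sharpens the solution to
near machine precision (the polish never accepts an objective increase
and falls back silently on singular systems).

Regularization: `β_j = β₀ · c_class · sd_j(presence)/√m` with background-sd
fallback, β₀ = 1.  Indicator features carry `c_class = 2` — echoing the
convention that categorical features are penalized harder — because a
handful of spatially clustered presences can otherwise hand spurious
weight to a smooth categorical layer.  Feature classes default to
linear + quadratic + indicators in `FeatureExpansion`; the *pipeline*
default disables the quadratic terms, which on smooth standardized
covariate summaries added estimation variance without representational
gain (up to 0.15 Spearman on truth recovery in the reference scenario).
Hinge features are an extension hook, not implemented.

In the ensemble and CLI fitting layer the presence samples are added to
the background before fitting (the standard MaxEnt convention): on
clustered fringe backgrounds the presence feature means can otherwise lie
outside the background's attainable range, making the penalized objective
unbounded and the fit divergent.

The logistic output is `c·q/(1 + c·q)` with `c = exp(H)`, `H` the entropy
of the fitted Gibbs distribution — the classic default under which a
typical presence site scores about 0.5.  Prediction covariates are
clamped to training ranges; an extrapolation mask flags cells outside
them.  Variable contributions are permutation importance: all features of
a covariate permuted jointly across the pooled training sample, drop in
training AUC averaged over permutations, floored at zero, normalized to
100.

## Ensemble, validation, uncertainty

Submodel k draws its background with seed base+k; the suitability map is
the cellwise mean of submodel logistic grids and the uncertainty map the
cellwise sd/mean (undefined where the mean is zero).  Validation scores
the mean grid at held-out presences (a ~30% block-stratified split,
10-cell blocks, to limit spatial leakage) against the retained true
absences, with an exact rank-based AUC (ties half).  Holdout cells are
reserved from the background draw so validation and training cells are
disjoint by construction.  Suitable area is the count of cells strictly
above the threshold (default 0.5) times the cell area.

Time-series covariate summaries (mean/min/max/range) drop values outside
`[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` per cell first, with type-7
(linear-interpolation) quartiles — stated because quartile conventions
differ.

## The synthetic test-bed

`SyntheticScenario` generates: spatially autocorrelated covariates
(Gaussian smoothing of white noise with kernel width = spatial_range — a
cheap, controllable stand-in for a Gaussian-process simulator),
contiguous protected reserves (thresholded smoothed field), a categorical
vegetation layer (quantile bins of a smoothed field), a logistic truth
`suitability = expit(Σ β_i·cov_i + β_p·protected)`, effort-biased trap
placement (∝ exp(effort_bias·protected)), uniform 3–60-day deployments
(the field protocols mixed 3–14-day and 19–244-trap-day deployments; this
range leaves a realistic share of absences above the 30-day significance
threshold), and negative-binomial catches with mean
ad_max·suitability·trap_days.

Key defaults, chosen to describe the survey regime in which this design
is informative and then frozen:

- `true_coefficients = (2.0, −1.5, 1.0)`, `protected_effect = 1.5`: the
  linear predictor has sd ≈ 2.7, i.e. a patchy, near-bimodal suitability
  surface — the species occupy pockets of good habitat, which is also
  what makes long zero-catch deployments concentrate in genuinely poor
  habitat.
- `ad_max = 0.1` flies/trap/day, the catch-rate scale of the sparser
  species.  At peak rates of several flies/day, detection saturates:
  ~95% of traps become presences, the presence sample mirrors trap
  placement instead of habitat, and no presence-background method can
  recover the truth.
- `dispersion (NB size) = 5`.  Counts stay overdispersed relative to
  Poisson (and strongly so marginally, through the suitability mixture),
  but the conditional zero probability remains compatible with the
  Poisson zero-catch model the absence filter assumes.  Under much
  heavier dispersion (size ≈ 1) zero catches stay common even in
  excellent habitat, so "significant" absences no longer indicate
  unsuitable habitat and validation against them measures the wrong
  thing.
- `effort_bias = 0.5` (~1.6× trap density inside reserves), 300 traps on
  a 100×100 grid.

What the generator does **not** emulate: temporal variation in catches
(seasonality enters only through the time-series fixture), trap
interference and differential trap efficacy between species, covariate
measurement error and cloud-gap patterns, multi-species interactions in
the truth (the two species' truths share a niche direction with damped
coefficients, giving aggregation without interaction), and real
geography.  Passing the recovery tests therefore shows the chain is
correct and well-calibrated under its own assumptions — not that any
particular field dataset meets them.

## Known limitations

- The effort kernel corrects survey bias only as well as its bandwidth
  represents the true effort field; the fitted protected-area weight
  absorbs what remains.
- The "probabilistic removal of non-significant absences" is a Poisson
  zero-catch screen with a configurable μ₀; other detection models would
  change which absences validate the map.
- ENFA is descriptive here; no suitability prediction is derived from it.
- The MaxEnt implementation makes no attempt to reproduce the proprietary
  reference software's exact numbers (feature classes and regularization
  tables differ); equivalence is established against the stated convex
  objective instead.
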