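# Methods

## Survey model and density standardization

The unit of observation is a surface neuston tow labelled `slick` or
`ambient`. All inference operates on densities: the count of a taxon (or
the summed counts of a family / functional group) in a tow divided by the
volume of water filtered (m³). The operation is linear in counts and
inversely linear in volume, so grouping-then-standardizing equals
standardizing-then-summing; tests exercise both identities. Debris is
handled identically with dry weight (mg m⁻³). Groups present (density > 0)
in fewer than 4 tows are excluded from between-habitat comparisons — too
rare to say anything stable about. A group is *slick-associated* when its
slick:ambient point ratio is at least 2, and *slick-exclusive* when it was
never recorded in ambient tows (exclusive implies associated; its ratio is
undefined and reported as infinite, and its regional share as 100%).

"Relative abundance in slicks" (the >90% near-exclusivity screen) is
computed from mean densities, d̄_slick/(d̄_slick + d̄_ambient), not pooled
raw counts, because tow volumes differ between gears and densities are the
unit of every other comparison.

## Resampling inference

**Bootstrap means.** Percentile bootstrap, resampling tows with replacement
within each habitat; 10,000 replicates by default (a 20,000-replicate
setting is used for fish length, where the per-fish sample is very large);
interval = empirical 2.5–97.5 percentiles, point estimate = plain mean.
Percentile (not BCa) intervals are used deliberately: they are what plain
"bootstrap intervals" mean and they are exactly reproducible from the
replicate vector, which every result object retains.

**Permutation probability.** P(d̄_slick > d̄_ambient) = the proportion of
label permutations whose mean difference is smaller than the observed one.
Ties count half, which preserves the complementarity
P(a, b) + P(b, a) ≈ 1 exactly under the symmetric null. The probability is
capped at 1 − 1/nperm and printed "≥ 0.9999" at nperm = 10,000 — an
empirical probability cannot resolve beyond its permutation count. The
permutation pools all tows unpaired even though part of the design is
paired; a paired design would permute within pairs, but the pooled version
is the survey-level convention this package targets and the paired subset
is available through `paired_log_response_ratios` for the confound screens.

**Response ratio.** Per replicate *i*: d̄_slick(i)/d̄_ambient(i),
summarized by mean and percentile interval. Zero-denominator correction:
if *any* ambient replicate mean is zero, every replicate's numerator is
divided by the grand mean of all nboot ambient replicate means and the
result is flagged `corrected`. The correction trigger is per group. The
corrected interval understates uncertainty (ambient variability is not
propagated); the flag keeps both paths auditable. The ratio is invariant
to rescaling all densities by a common factor. Per-group random sub-streams
are derived from a CRC32 of the group id, so summary tables are
reproducible and independent of row order.

## Community analyses

Densities are log-transformed before distance computation with the
zero-preserving convention log_b(x/m) + 1 for x > 0 (m = smallest positive
entry when below 1, so the smallest value maps to 1 and doubling adds one
unit at base 2; zeros stay zero). Base 2 by default, configurable.

Bray–Curtis dissimilarity d(i,j) = Σ|x_i − x_j| / Σ(x_i + x_j) between
tows; pairs of all-zero tows are undefined (0/0) and set to 0 with a
warning rather than silently propagated.

**Partial dbRDA.** Principal-coordinates embedding of the distance matrix
(Gower double-centering, eigendecomposition); axes with positive
eigenvalues are retained and the discarded negative inertia is recorded —
Bray–Curtis is generally non-Euclidean and this is the standard default of
constrained-ordination software. Site indicator variables (plus intercept)
are partialled out of both the coordinates and the habitat indicator; the
pseudo-F is (SS_constrained/df_model)/(SS_residual/df_residual). With a
binary constraint there is exactly one constrained axis. Significance uses
reduced-model residual permutation: rows of the site-conditioned
coordinates are shuffled, the condition re-partialled, F recomputed, and
p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) — never exactly zero. On
Euclidean-embeddable distances the pseudo-F equals classical RDA by
projection algebra (tested to 1e-8), and the implementation matches
vegan's partial `capscale` to ~1e-8 relative on a fixture (tested through
Rscript). Tests use 199–10,000 permutations depending on the p-resolution
they need; the library default is 10,000, configurable upward.

Shannon H′ = −Σ p ln p (natural log by default; H′ ≤ ln S) and richness S
per tow; group contrasts reuse the bootstrap/permutation machinery. Empty
tows have undefined H′ and are excluded from the H′ contrast with a
warning. Spearman predator–prey screens are computed per habitat on
(monotone-transformed) densities with unadjusted per-pair p-values at
α = 0.05; a multiplicity adjustment is deliberately not applied by default
to keep the screen descriptive.

## Size structure and debris

Occurrence proportion per 5-mm length bin: bootstrap the per-habitat mean
density of fish in the bin, form p = d̄_slick/(d̄_slick + d̄_ambient) from
the bootstrap grand means. Bins empty in both habitats are dropped. The
whole p column is squeezed off the boundary with the standard
(p·(n − 1) + 0.5)/n transform (n = number of bins) before the beta
regression, since observed shares of 0 or 1 are outside the beta support.

Beta regression: p ~ Beta(μφ, (1−μ)φ) with logit μ = β₀ + β₁·length and
constant precision φ (no dispersion covariates). Maximum likelihood via
`statsmodels` `BetaModel`; start values come from an OLS fit on the logit
scale plus a moment estimate of φ (clipped to [1, 10³]) because the
library's default start heuristic is fragile near the boundary.
z = β₁/SE(β₁) with the SE from the inverse observed information;
pseudo-R² is the squared correlation between link-scale fitted values and
logit(p). Fitted probabilities are monotone in length iff the slope sign
is constant — automatic with a single covariate and logit link.

Size classes for the debris regressions use half-open edges [0,5), [5,10),
[10,15), [15,20), [20,∞) mm, so a 5-mm fish belongs to the second class
unambiguously. OLS of log₁₀ fish density on log₁₀ debris mass per
(size class, habitat) stratum, excluding zero densities before the log;
strata under 3 points are skipped. Confound screens: one-way ANOVA of
paired log response ratios on year / day / gear / sampling order, and a
type-II ANCOVA of log density on log debris mass, minutes from solar noon
and habitat (three fish subsets: all, TL < 10 mm, TL > 10 mm). Minutes
from solar noon is an input column — no solar model is computed here.

## Regional scaling

P(a, r) = a·r / (a·r + (1 − a)) — strictly increasing in both arguments,
P(a, 1) = a, and P(a, r) + P(1 − a, 1/r) = 1. Uncertainty: the percentage
is formed per bootstrap replicate pair and averaged within each
remote-sensing scene (replicates whose ambient mean is zero contribute
P = 1, the limit of the formula), then mean ± SD across scenes. The
alternative order (average the replicate densities first) is exposed as an
option; the two differ by well under half a percentage point for realistic
ratios. Percentages are reported on the 0–100 scale.

## Synthetic surveys

The generator emulates the statistical structure the estimators assume:

* **Design** — 80 slick + 54 ambient tows, 52 of them paired, 8 sites
  (assigned at random; the site effect on densities defaults to zero, as no
  within-site correlation structure is being modelled).
* **Volumes** — log-normal, mean 390 m³ (a 0.79 m² net mouth towed
  ~495 m), log-SD 0.3, truncated below at 50 m³.
* **Counts** — negative binomial with mean = volume × base ambient
  density × enrichment (enrichment applied in slicks only) and dispersion
  k = 0.7; overdispersion is the norm for patchy plankton. The default
  community has 54 fish families (33 common, enrichments 1.2–100×;
  21 rare, expected in fewer than 4 tows so the rarity filter operates),
  8 invertebrate-larva taxa (2–10×), 4 holozooplankton (2.2–6.6×),
  eggs (3.1×) and insects (26.6×).
* **Lengths** — geometric over 1-mm bins (mean 6 mm, strongly
  right-skewed); a fish of length L sits in a slick with logit-linear
  probability (slope 0.1 per mm). Because overall fish counts already
  carry the enrichment ratios, the realized occurrence curve keeps the
  configured slope but its intercept shifts by the log of the aggregate
  fish enrichment; the truth record stores this *effective intercept* so
  recovery tests compare like with like.
* **Debris** — log-normal dry-weight densities per habitat and category;
  defaults put plastic near 260× and organic near 30× enrichment.
* **Randomness** — one `SeedSequence` per simulation, one child stream per
  taxon (keyed by taxon index), so adding a taxon never perturbs the draws
  of the others, and identical seeds give byte-identical tables.

What the generator does *not* emulate: spatial/temporal autocorrelation
between tows, within-site density correlation, gear selectivity
differences, taxon-specific length distributions, or any physical slick
dynamics. Passing recovery tests therefore show the estimators are correct
under independent overdispersed sampling — not that real surveys satisfy
those independence assumptions.

A tiny deterministic worked-example fixture complements the generator: its
group means are constructed to equal round headline values (all-debris
43.31/0.61 mg m⁻³, plastic 26.33/0.10, eggs 8.85/2.85 m⁻³, mean lengths
6.11/5.33 mm), giving exact-arithmetic checks of the point-ratio path
(71.0×, 263.3×, 3.1×, +14.6%). It is synthetic, not field data.

## Problem sizes and numerical choices

Monte-Carlo calibration tests use 500 simulated datasets per claim
(3·MC-SE acceptance bands), 2,000-replicate bootstraps and 199–2,000
permutations; the pipeline defaults to nboot = nperm = 2,000 with the
10,000/20,000/100,000 settings reachable by argument. Probabilities are
never reported as 0 or 1 (add-one permutation convention; 1 − 1/nperm
cap). Degenerate inputs fail loudly: empty groups, all-zero ratio
numerators and denominators, constant ordination constraints, and
sub-4-bin beta regressions all raise with a named cause.

## Known limitations

* The corrected response-ratio interval understates uncertainty for rare
  taxa (by construction); treat corrected intervals as lower bounds on
  width.
* The unpaired permutation ignores the pairing in the 52 paired tows,
  costing some power but no validity under the exchangeable null.
* The beta regression treats bins as independent, unweighted observations
  (no weighting by per-bin fish counts); heavily saturated bins squeezed
  off 1 attenuate the slope.
* dbRDA discards negative-eigenvalue inertia rather than applying a
  Lingoes/Cailliez correction; the discarded amount is reported.
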