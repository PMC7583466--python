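# Methods

This note documents the models, conventions, and numerical choices behind
`avipref`, and what the synthetic-data tests do and do not demonstrate
about real survey data.

## Importance values (availability)

A street-tree inventory is treated as a full census of stems along walking
routes. Basal area is the circle area implied by DBH,
`BA = π (DBH/200)²` (cm → m²). For species *s*:

* relative density = 100 · count(s) / Σ count,
* relative dominance = 100 · ΣBA(s) / ΣΣBA,
* importance value IV(s) = (relative density + relative dominance) / 2.

The frequency term is excluded by construction and no option enables it:
frequency requires plotless stand sampling, which a street transect census
is not. Family-level labels ("Fraxinus spp.") and "unknown nonnative" are
ordinary species labels. Relative values are computed over the pooled
all-route inventory by default — the convention under which per-km figures
such as a species' basal area per km mean "pooled total / pooled route
length". A per-route mode (`per_route=True`) normalizes within each route
instead; it exists because the mean-of-route-level-values convention is
also defensible, but pooled is the default and is what the preference
analysis uses. Percentages are carried at full precision; rounding (two
decimals, integer proportional use) happens only in report formatting.

Income terciles follow fixed cut points (defaults: low ≤ 53,219 USD,
high ≥ 70,720 USD, medium between); the thresholds are configuration, not
something the package estimates.

## Observation reduction

Raw detections are reduced to foraging units in a fixed order: flock
collapsing, then the 100-m rule, then the first-tree rule.

* A single-species flock is one unit regardless of size; a mixed-species
  flock contributes one unit per member species. Flock tallies are kept on
  the raw records so the information loss is measurable: `flock_sensitivity`
  reports the Spearman correlation between reduced per-route counts and
  full tallies.
* The 100-m rule drops a detection of species *s* at most 100 m
  (inclusive) past the previous **retained** detection of *s* on the same
  route × visit, unless the individuals are visibly distinct (sex
  dimorphism). Comparing to the previous retained rather than the previous
  raw detection is a choice; the alternative (previous raw) would allow a
  chain of sub-100-m detections to suppress arbitrarily long stretches.
  The rule is applied independently per visit: visits are weeks apart and
  bird turnover between them is assumed.
* The "ceased position" of an observation is the recorded detection
  position — the data model carries one position per detection.
* A bout over several trees is credited to the first tree only.

The reduction is idempotent and never invents units: every reduced unit
maps to one raw detection.

## Preference analysis

For a bird grouping (one species, the migratory pool, the year-round pool,
or all birds), `use(s)` is the percentage of the grouping's feeding
observations on tree species *s* over the full species universe (zero for
unused species). Then

* preference index `PI(s) = use(s) − IV(s)` — raw, non-renormalized IVs
  over the full inventory, the only convention under which `PI = −IV` for
  unused species and proportional use identities hold exactly;
* proportional use `PU(s) = 100 · use(s) / IV(s) = 100 · (IV + PI) / IV`.

The χ² goodness-of-fit test restricts to common species (IV strictly
greater than 1.5 % by default — rarely-encountered species say little
about preference) and to groupings with at least 30 observations (smaller
groupings are reported as excluded, not raised as errors). Expected counts
are `N · IV_i / Σ IV_included` by default, so expected and observed totals
match; `renormalize=False` gives `N · IV_i / 100` for users who prefer
absolute availability shares. The statistic is the textbook
`Σ (O − E)² / E` with `k − 1` degrees of freedom.

These indices describe observed disproportion, not resource selection in
the formal sense; no selection-ratio machinery is included.

## Community statistics

Bray–Curtis dissimilarity is computed on square-root-transformed counts by
default (`Σ|x−y| / Σ(x+y)`; two empty samples have distance 0). ANOSIM
ranks the `M = n(n−1)/2` dissimilarities with midranks and uses
`R = (r̄_between − r̄_within)/(M/2)`; the permutation p-value is the
add-one estimator `(1 + #{R_perm ≥ R_obs})/(n_perm + 1)`, which cannot
reach 0 and is reproducible under a seed. Pairwise contrasts re-run the
permutation test within each pair's submatrix (rather than deriving
pairwise p-values from the full-design permutations) and are judged at a
Bonferroni-adjusted α (0.05/3 for three groups). Constant dissimilarity
matrices and singleton groups are rejected — R is undefined there.

ANOVA, Kruskal–Wallis (tie-corrected), Tukey HSD, and rank-sum contrasts
delegate to scipy behind the module interface. The nonparametric
multiple-comparison branch is Bonferroni-adjusted pairwise Wilcoxon
rank-sum tests — a deliberate, documented substitution for the
relative-contrast-effects procedure, whose full machinery is out of scope
here. Group letters (compact letter display) are the maximal cliques of
the not-significantly-different graph. Spearman ρ is the Pearson
correlation of midranks with a two-sided permutation p (10⁴ permutations,
seeded).

## Negative-binomial GLM model sets

Feeding-bird densities per km are modelled as
`μ = exp(β₀ + β₁x [+ β₂x²])` with NB variance `μ + μ²/θ`. The response is
a non-integer density, so the NB log-likelihood is evaluated through its
continuous (gamma-function) extension — the behavior of standard GLM
software handed non-integer counts; `integer_mode=True` rounds first for a
strict count likelihood. θ is profiled: an outer bounded 1-D maximization
over log(1/θ) (tolerance 1e-8) around an inner IRLS fit (statsmodels GLM,
max 100 iterations, tolerance 1e-8). AIC counts θ as a parameter, so
`AIC = 2(k+1) − 2ℓ` for k mean parameters.

Coefficients are reported exponentiated (a value below 1 is a negative
relationship; the exponentiated intercept of the intercept-only model is
exactly the response mean). Significance markers come from Wald z-tests.
Predictors are not centered before squaring; near-collinearity of x and x²
is logged as a warning rather than prevented. The standard set fits nine
models per response — eight single street-tree predictors (richness/km,
Shannon diversity, total/native/nonnative density and basal area) plus the
intercept-only model — ranked by ΔAIC. Non-convergence flags the result
instead of raising. Overdispersion is diagnosed by the Pearson χ²
statistic and the residual deviance / residual df ratio, with a
configurable threshold (default 1.5).

## Synthetic-data generator

The generator emulates the study conditions the analysis assumes:
36 routes (12 per income class) of mean length 2.49 km (sd 0.1); per-route
tree counts Poisson with class densities 54/81/113 km⁻¹; class basal-area
targets 17/29/80 m² km⁻¹ met through class-specific lognormal DBH
(σ = 0.5; the meanlog solves the class's mean basal area per tree); an
85-species pool whose nonnative part follows a log-series (heavy-tailed)
rank-abundance profile with mild per-class composition jitter
(gamma-distributed weight multipliers, concentration `class_turnover`);
native stem fractions per class of 1.0 %/1.3 %/7.0 %, with coast live oak
and California sycamore as the two common natives. Native sizes are fixed
species traits (mean DBH 76.01 and 94.85 cm for the two common natives,
40 cm for the rare ones) rather than class-scaled: a species' typical size
is a property of the species, and fixing it keeps the natives'
availability stable across simulation replicates. Bird species are drawn
with weights equal to the study's per-species feeding-observation totals
(e.g. Yellow-rumped Warbler 348 … Allen's Hummingbird 23), preserving the
migratory/year-round mix.

Detections are sampled globally: each tree carries weight
`v_i = 1/(2N) + BA_i/(2·ΣBA)` — so a species' total weight is exactly its
pooled IV share — multiplied by the species' preference multiplier `w`.
The expected number of detections is `obs_rate × N_trees × n_visits`
(default 0.03 per tree-visit, ≈ 870 detections at default sizes). Two
consequences are built in rather than bolted on: a species with
multiplier `w` is fed on at `w × availability / (1 + (w−1)·q)` (≈ `w` for
small availability share `q`), and routes with more and larger trees
attract proportionally more feeding birds — the luxury-effect gradient in
feeding-bird density emerges from the tree weights alone. Flocking species
(Bushtit, House Finch) form flocks with probability 0.5 (size
2 + Poisson(3), mixed-species with probability 0.15); 25 % of bouts span a
second tree; 5 % of detections are marked sex-distinct; positions are the
trees' route positions, so the 100-m rule is exercised (≈ 6 % of default
detections are removed by it).

`mode="density_nb"` instead draws per-route detection counts from a
negative-binomial regression on route tree density
(`μ = exp(β₀ + β₁·density [+ β₂·density²])`, defaults β₀ = 1, β₁ = 0.02,
θ = 5; the quadratic term is off by default) — a known generating model
for exercising the GLM model-selection stage, including hump-shaped
relationships when β₂ < 0.

### What the generator does not emulate

Within-class route heterogeneity is limited (all routes of a class share
one composition vector, so ANOSIM separation is stronger than in real
cities); tree placement is 1-D and uniform along routes; detection
intensity is exactly proportional to tree attractiveness with no observer,
weather, or phenology effects; yard vegetation and distance to protected
areas do not exist. Passing recovery tests therefore demonstrates that the
pipeline's estimators are consistent under the stated generating model —
not that field data meet that model.

## Problem sizes and test design

The test suite verifies the permutation machinery against exhaustive
enumeration at n = 8, cross-checks ANOSIM R against an independent
implementation, and checks NB-GLM recovery over 100 replicates of n = 500.
The end-to-end preference-recovery experiment uses 50 generator seeds with
the boosted multiplier w = 3 and extends the survey to 80 visits: visits
are independent replicates of the same per-visit detection process, so
this scales estimator precision without altering the conditions the 100-m
rule operates under. The expected recovered proportional use is
`300/(1 + 2q) ≈ 280 %` for oak's availability share `q ≈ 0.03`, minus a
small dedup loss — within the 255–345 % recovery band used by the tests.

## Known limitations

* The dedup rule slightly suppresses use estimates for species
  concentrated on detection-dense routes (≈ 3 % relative at default
  rates); this is a property of the field protocol being modelled, not a
  bug, but it biases proportional-use recovery low.
* θ profiling assumes the inner IRLS fit converges for every candidate
  dispersion; pathological data can make the profile flat (the result's
  `converged` flag reflects this).
* The χ² test's expected counts assume availability measured without
  error; importance values estimated from small inventories propagate no
  uncertainty into the test.
* Report formatting assumes Table-style layouts (species × groupings);
  arbitrary custom groupings render but are not specially arranged.
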