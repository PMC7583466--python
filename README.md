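# avipref

Street-tree availability and bird foraging-preference analysis.

Urban street trees are a public resource whose value to wildlife is rarely
quantified. `avipref` implements a complete use-vs-availability analysis of
bird foraging on street trees, of the kind used to ask which tree species
feeding birds prefer or avoid across a city's socioeconomic gradient. It is
aimed at urban ecologists and municipal-forestry analysts working with
tree-inventory and foraging-observation data.

## What it computes

**Availability — importance values.** For each tree species *s* in an
inventory, with relative density (share of stems) and relative dominance
(share of basal area, from DBH via `BA = π(DBH/200)²`):

```
IV(s) = [ rel_density(s) + rel_dominance(s) ] / 2        (percent; Σ IV = 100)
```

The frequency term of the classical importance value is omitted by
construction: street-tree transects are full censuses, not plotless stand
samples.

**Observation reduction.** Raw bird detections become valid foraging units
("n = 1" = one feeding attempt of a bird on a tree) by: collapsing each
single-species flock to one unit (one unit per species for mixed flocks);
dropping re-detections of a species within 100 m of the previous retained
detection on the same route × visit (unless the individuals are visibly
distinct); and crediting multi-tree feeding bouts to the first tree only.

**Preference and aversion.** For a bird grouping with feeding-use
percentages `use(s)`:

```
PI(s)  = use(s) − IV(s)            (percentage points; + preference, − aversion)
PU(s)  = 100 · use(s) / IV(s)      (use as % of availability)
```

so `PI = −IV` exactly for a species never fed on, and `Σ PI = 0` over the
complete species set. A χ² goodness-of-fit test compares observed feeding
counts with availability-expected counts over the common species
(IV > 1.5 %), for groupings with ≥ 30 observations.

**Community and density statistics.** Square-root Bray–Curtis
dissimilarity with a one-way permutation ANOSIM
(`R = (r̄_between − r̄_within)/(M/2)`, 999 permutations, pairwise contrasts
at Bonferroni-adjusted α = 0.05/3); one-way ANOVA / Kruskal–Wallis with
Tukey HSD or rank-based contrasts and compact-letter displays; Spearman ρ
with a permutation p. Feeding-bird density per route is modelled with
nine-model negative-binomial GLM sets (log link, optional quadratic term,
θ profiled by maximum likelihood, Pearson-χ² overdispersion diagnostics,
ΔAIC ranking, exponentiated coefficients).

**Synthetic data.** A generator emulates a 36-route survey across
low/medium/high-income classes (tree densities ~54/81/113 km⁻¹, basal
areas ~17/29/80 m² km⁻¹, an 85-species pool with two common natives) with
feeding detections drawn in proportion to availability × configurable
preference multipliers, so every pipeline stage is testable end to end.

## Worked example

Simulate a survey in which birds feed on coast live oak at three times its
availability, then recover that preference:

```
$ printf 'preference_multipliers:\n  coast live oak: 3.0\nn_visits: 8\n' > sim.yaml
$ avipref --seed 42 simulate --config sim.yaml --out-dir demo
$ avipref preference --inventory demo/trees.csv --routes demo/routes.csv \
      --obs demo/birds.csv --out demo/pref.csv
$ avipref report --preference demo/pref.csv --out demo/report.csv
```

The preference table's coast-live-oak row (grouping `total`):

```
  tree_species grouping  n_obs  use_pct  iv_pct  preference_index  proportional_use
coast live oak    total    142   8.0866  3.1083            4.9782          260.1581
```

Oak received 8.09 % of feeding observations against an availability of
3.11 % — a preference of +4.98 points and a proportional use of 260 %
(`report` prints `260%`), close to the configured multiplier once the
multinomial renormalization over the other species is accounted for. The
accompanying χ² test rejects availability-proportional feeding
(χ² = 150.62, df = 19, p < 1e-21).

Community structure across the income gradient, on a neutral
(no-preference) survey:

```
$ avipref --seed 1 simulate --out-dir demo0
$ avipref --seed 1 anosim --inventory demo0/trees.csv --routes demo0/routes.csv \
      --out demo0/anosim.json
ANOSIM R = 0.740, p = 0.0010 (999 permutations)
$ avipref glm --inventory demo0/trees.csv --routes demo0/routes.csv \
      --obs demo0/birds.csv --response migratory_density --out demo0/models.json
best model: nonnative_basal_area (AIC 144.39)
```

Street-tree composition differs strongly by income class (R = 0.74, all
three pairwise contrasts significant at α = 0.017), and a tree
density/size variable is the best-supported predictor of migratory
feeding-bird density (ΔAIC of the intercept-only model ≫ 2) — the
generator's built-in luxury effect, recovered by the analysis.

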