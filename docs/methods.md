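# Methods

`dietscope` implements the quantitative core of a comparative gut-content
study of small fish (its defaults describe invasive eastern mosquitofish,
*Gambusia holbrooki*, sampled from several Mediterranean populations, but
nothing in the code is species-specific). This note records the models,
the parameter choices that matter, and the places where the design was
genuinely open.

## Data model

One `GutRecord` per dissected fish: sex, standard length SL (mm), gut
length (mm), gut fullness GF ∈ [0, 1], pregnancy state, integer counts
for ten countable prey categories (Araneae, Bivalvia, Branchiopoda,
Cladocera, Coleoptera, Diptera, Entognatha, Hemiptera, Hymenoptera,
Ostracoda), and presence flags for detritus and unidentifiable material.
Detritus and unidentifiable items cannot be counted as discrete prey, so
they never carry counts: they enter frequency of occurrence and niche
width as presence/absence and are excluded from every count-based index.
Unidentifiable material is additionally excluded from niche width — it is
a residual class, not a food category. The derived trait RGL
(relative gut length) is gut length / SL.

Gut condition classes partition the sample: *empty* (no counts, no
flags), *detritus/unidentifiable-only* (no counts, at least one flag),
and prey-bearing. Gut fullness is accepted as any score in [0, 1]; the
package does not assume a particular scoring protocol (visual score vs.
volume fraction), only the range.

Populations and categories are ordered lexicographically in every matrix
and table so outputs are deterministic and diffable. Missing gut length
or fullness is allowed; composition indices still run, and trait models
skip the incomplete records with a logged count.

## Composition indices

* **FO** — `100 · #(guts containing item) / n`. The default denominator
  is all examined guts (empty included); a `nonempty_guts` option
  restricts to guts with any content.
* **%N** — a category's share of all counted prey items in a population,
  from pooled counts.
* **IRI** — three variants, because published IRI values are not
  comparable across formulations and the classical variants differ by
  orders of magnitude: `hyslop_nv` (default) `(%N + %V) · %FO` with %V
  treated as 0 when no volumetric data exist; `fo_times_n` `%FO · %N`;
  and `raw_count` `FO(%) · count`. The variant used is always recorded in
  the output; no variant's values should be compared across studies
  without checking the formula.
* **Shannon–Wiener H** — entropy of the pooled countable-category
  proportions, natural log by default (configurable: the log base is a
  reporting convention that published tables rarely state).
* **RNW** — per-specimen breadth from k food categories in the gut
  (countable categories with positive counts, plus detritus) against K
  available. Default `zero_anchored` variant `(k − 1)/(K − 1)`, which
  maps a single-category diet to exactly 0 and a full diet to exactly 1 —
  matching the conventional range anchors; the literal proportion `k/K`
  is available. K defaults to 11 (ten prey categories plus detritus).
  Empty guts return no value and are excluded from population means.

Rounding happens only at presentation time; all internal computation is
double precision.

## Niche overlap and the Mantel test

Overlap is computed between *pooled population* diet proportion vectors
(not means of per-fish proportions), detritus excluded. Schoener's index
is computed as `Σ min(pᵢ, qᵢ)` — algebraically `1 − ½ Σ|pᵢ − qᵢ|`, but
exact at the disjoint-diet anchor in floating point. Pianka's index is
the normalized dot product `Σpᵢqᵢ / √(Σpᵢ² Σqᵢ²)`. Both live in [0, 1];
values **strictly greater than** 0.6 are flagged as biologically
significant overlap (a value of exactly 0.6 is not flagged). A population
with zero counted prey has undefined overlap, reported as missing rather
than 0.

The Mantel test correlates the strict lower triangles of two symmetric
matrices (Pearson) and builds its null by permuting one matrix's rows
and columns simultaneously. For n ≤ 7 populations all n! relabelings are
enumerated and the p-value is exact (the identity permutation counts, so
p ≥ 1/n!). Otherwise the default 10,000 random permutations are drawn
and the add-one estimator `(#hits + 1)/(B + 1)` keeps p > 0. The pipeline
passes the overlap *similarity* matrix directly against geographic
distance (great-circle, haversine on a sphere of radius 6371.0088 km), so
a negative r means nearby populations overlap more; the two-sided
alternative is the default.

## Size/population GLMs

Presence of each food category (ten prey categories plus detritus; 11
models) is modelled with a binomial GLM, logit link:
`presence ~ SL + population + SL:population`. The three gut traits (RGL,
GF, RNW) use gamma GLMs with log link and the same linear predictor.
Fitting is by IRLS (statsmodels); separation and non-convergence are
reported as `converged=False` with a diagnostic, never as silent
estimates.

**Interaction screening.** The single interaction term is tested first;
if p > 0.2 (strictly) it is removed and the model refitted, with the
dropped term preserved in brackets in the report. In the default
`numeric_as_paper` coding the screening statistic is the Wald z of the
single product term; in `categorical` coding it is a likelihood-ratio
test of the interaction dummy block. Screening at 0.2 retains a null
interaction about 20% of the time by construction — the test suite
verifies this calibration.

**Population coding.** `numeric_as_paper` maps sorted population ids
onto ordinals 1..n entered as one numeric covariate — it yields a single
Population coefficient per model, mirroring how such tables are often
printed, at the cost of imposing an arbitrary linear ordering on sites.
`categorical` treatment-codes the populations and is the statistically
defensible choice; both codings coincide exactly when there are two
populations. Recommendation: use `categorical` for inference and
`numeric_as_paper` only for comparability with ordinal-coded reports.

**Sex** is excluded as a covariate by design: in strongly size-dimorphic
poeciliids sex and SL are nearly collinear (males are much smaller), so
SL carries the sex signal and including both destabilises the fits.

**Gamma zeros.** Gamma support is strictly positive, so zero trait
values (an empty gut's fullness) are excluded by default with a logged
count; an optional shift mode adds half the smallest positive value
instead. The choice matters for GF in samples with many empty guts and
is always recorded.

**Joint population statistic.** As an omnibus check across the three
trait responses the package sums, over responses, the deviance explained
by adding population to an SL-only gamma model, and permutes population
labels across fish for the null (default 199–499 permutations). This is
a clearly labelled construction of this package — an omnibus
"multivariate gamma GLM" has no unique definition — and it is reported
separately from the per-response fits.

**Tukey HSD** contrasts compare trait means across all population pairs
with studentized-range adjustment at familywise α = 0.05 (statsmodels),
dropping populations with fewer than two usable values.

**Pregnancy post hoc.** Among females only, category presence is
regressed on pregnancy state (binomial, logit). The coefficient is the
log-odds difference for pregnant vs. non-pregnant females.

## Environment association

Site variables (latitude, longitude, conductivity mS/cm, dissolved
oxygen mg/L, pH, water temperature °C, daily mean/max/min temperature
°C, precipitation mm) mix units, so the PCA runs on the correlation
matrix (all variables standardized). Raw coordinates enter as plain
columns; this treats geography linearly and ignores the sphere, which is
acceptable at the sub-continental extents the package targets. Retention
keeps the smallest number of components reaching 90% cumulative
explained variance. Signs are fixed by making each component's
largest-magnitude loading positive. Missing cells are refused rather
than imputed; constant variables are an error naming the variable.

Per-population diet metrics are regressed on the retained scores by OLS
(slopes, SEs, per-slope p, overall F). Per-population prey totals and
empty-gut proportions are Pearson-correlated with each retained score.
With a typical study's ~9 sites these analyses are heavily underpowered;
every report carries a low-power flag when n < 15, and no
multiple-testing correction is applied by default (a Benjamini–Hochberg
style correction can be applied downstream; the package reports raw p
values, mirroring common practice in this literature).

## Synthetic-data generator

The generator defines the study conditions the package is tested under:

* 9 populations, per-population sample sizes (16, 19, 19, 23, 18, 20,
  20, 16, 12) totalling exactly 163 fish; 86 females and 77 males,
  assigned by a seeded global shuffle;
* SL from truncated normals — females 21.5 ± 3.5 mm on [10.1, 37.5],
  males 17 ± 2.5 mm on [11.4, 25.7];
* gut state drawn per fish: completely empty with probability 0.178,
  detritus/unidentifiable-only with probability 0.38, otherwise
  prey-bearing;
* for prey-bearing guts, per-category presence follows
  `logit P = β₀ + β₁·SL + β₂·pop + β₃·SL·pop` with counts given presence
  from a zero-truncated negative binomial (per-category mean and
  dispersion), so presence and abundance are controlled independently;
  a prey-bearing gut is guaranteed at least one countable item (the most
  probable category is forced if every Bernoulli draw fails);
* detritus co-occurs with prey with a per-population probability (zero
  for the first population); fullness is Beta-distributed around a
  size-dependent mean; RGL is lognormal around a per-population mean
  with a log-scale SL slope of 0.057 by default;
* sites carry a rank-4 latent-factor environment structure with small
  measurement noise, coordinates spanning ≈8° latitude × 18° longitude.

The default per-category β values are illustrative, chosen to reproduce
a sparse, Cladocera-dominated diet qualitatively; they are not estimates
of anything. All randomness flows from one integer seed through
numpy's PCG64 generator with per-stage spawned streams; a fixed seed
reproduces emitted tables byte for byte across platforms.

Presets: `paper_like` (the defaults), `null_effects` (all slopes zero,
for type-I-error checks), `strong_interaction` (the Cladocera SL slope
flips sign across the population gradient: +0.25 on the logit scale at
population 1, −0.25 at population 9, presence ≈0.5 at the mean SL
everywhere — a well-identified interaction), and `overlap_extremes`
(fixed per-fish diet templates giving one identical-diet pair and one
disjoint pair, anchoring the overlap indices at 1 and 0).

**What the generator does not emulate:** real spatial prey-availability
gradients (presence effects are smooth in an arbitrary population
ordinal), within-population overdispersion of diet beyond the
negative-binomial counts, correlation between gut state and fish size,
seasonal or diel variation, and measurement error in counts. Passing
tests therefore demonstrate that the estimators recover the generator's
structure, not that any field dataset satisfies these models.

## Numerical choices and test scales

Tolerances: overlap and RNW anchors are exact; simplex and symmetry
invariants are checked to 1e-12; PCA reconstruction to 1e-8. Monte-Carlo
calibrations use sizes chosen to balance resolution against runtime:
GLM CI coverage over 200 replicates of n = 2000; interaction-screening
retention over 400 null replicates of n = 400; pregnancy type-I error
over 400 replicates of 120 females; Tukey familywise error over 300
replicates of 5 × 12 values; Mantel p-value uniformity over 300
independent matrix pairs at 299 permutations each. Stochastic assertions
use 3-standard-error bands around their expected values (plus a small
discreteness allowance where the statistic is a rate over few hundred
trials).

## Known limitations

* The ordinal population coding is a faithful mirror of a common
  reporting style, not good statistics; use `categorical` for inference.
* IRI values are formulation-dependent; cross-study comparison requires
  identical variants.
* The joint trait statistic is a permutation construction, not a fitted
  multivariate model; its power properties are unexplored beyond the
  calibration tests.
* The environment association stage at 9 sites is descriptive only.
* The generator's interaction structure is linear in the population
  ordinal; it cannot express arbitrary per-population slope patterns.
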