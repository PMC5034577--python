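# Methods

This note documents the statistical procedures, the choices made where the
design was genuinely open, and the limits of what the synthetic-data tests
demonstrate.

## Counting unit

All indices count a *use report* as a distinct (informant, species,
use_category) triple. Repeated mentions of the same species-use by one
informant collapse to one report, and garden/wild variants of the same
triple collapse for counting while origin is kept as a report attribute.
This makes N<sub>ur</sub> well defined and matches the convention under
which the consensus factor was originally proposed. The alternative —
counting each mention — would inflate N<sub>ur</sub> without changing
N<sub>t</sub> and push every F<sub>IC</sub> toward 1; it is not offered.

"Plant-uses" in the cultural-importance sum are the ten closed use
categories, not free-text use details: at category granularity a
one-informant-two-category species scores CI = 2.00 exactly and evenly
split species score UD = ln 2 ≈ 0.69 and ln 3 ≈ 1.10, the fingerprints
such tables display. Free-text details are retained in the data model but
enter no statistic.

## Indices

* **F<sub>IC</sub>** = (N<sub>ur</sub> − N<sub>t</sub>)/(N<sub>ur</sub> − 1),
  defined for N<sub>ur</sub> ≥ 2. Categories with a single report return
  0.0 with a warning and a `degenerate` flag rather than NaN, so category
  tables have no missing cells.
* **CI** sums, over categories, the fraction of the species' reporting
  informants who name each category; it is ≥ 1 whenever the species is
  reported and exactly 1 iff single-category.
* **UD** is Shannon entropy in natural log (the community-ecology default),
  bounded by ln 10 under the fixed vocabulary.
* **UV** divides a species' reports by *all* informants interviewed in the
  scope, reporters or not, so adding a silent informant lowers every UV.
* **95th-percentile tables** use the linear-interpolation quantile; ties at
  the threshold are all included. Annotation columns list the regional
  top-percentile lists each species also appears on.

An unreported species has no metrics row (absent, not zero); UV of a named
species with zero reports in scope is 0 by the formula.

## Ordination

Distances are Bray–Curtis on report-count incidence (binary mode, where
Bray–Curtis coincides with Sørensen, is available via config). Informants
with empty inventories have undefined distances and are excluded from
ordination while remaining in all metadata.

NMDS minimises Kruskal stress-1,
sqrt(Σ(d̂ − δ)² / Σδ²), alternating (a) isotonic regression (pool-adjacent
violators, via `scipy.optimize.isotonic_regression`) of the configuration
distances δ onto the rank order of the input dissimilarities, with primary
tie treatment (ties in the input may be broken by δ), and (b) a Guttman
majorisation update. Defaults: k = 2, 20 restarts (the first from
classical Torgerson scaling, the rest random Gaussian), max 500
iterations, stress-change tolerance 1e-7. Stress is non-increasing within
a run (asserted in tests); the best run is returned centered and rotated
to principal axes. On a seeded 10×8 fixture the stress agrees with R
vegan's `metaMDS` to 1e-4 and the envfit r² values to 1e-6.

Environmental fitting follows the standard post-hoc scheme: vectors score
the OLS r² of the (centered) covariate on the scores, factors score
1 − SS<sub>within</sub>/SS<sub>total</sub> of score rows about level
centroids. Significance uses whole-vector shuffles of the covariate with
the add-one estimator p = (1 + #{r²<sub>perm</sub> ≥ r²<sub>obs</sub>}) /
(1 + n_perm), so 0.001 is the floor at the default 999 permutations.
Missing covariate values are dropped pairwise per variable, leaving the
ordination intact. The standard covariate table fits elevation (and age,
when at least 80 % of ordinated informants report it) as vectors and
gender, community and — when more than one region is present — region as
factors; elevation is the vector and community the factor where the two
roles could be argued either way, because community is categorical and its
elevation is the continuous quantity attached to it.

## Regional comparison

Venn partitions are exact set algebra over the 7 exclusive cells
(`sj_only` … `all`); a "use" item is a (species, use_category) pair, the
finest unit comparable across interviews. The home-garden variant keeps,
per region, the items with at least one garden-origin report there —
restriction can only shrink cells. Species origin classes are derived from
origin-known reports only; species whose every report has unknown origin
are counted separately rather than forced into a class, so class sums are
reported against the species total with an explicit consistency flag.

## Provenance trend

The trend takes one (metric, outcome) pair per origin-known report, the
metric being the species' overall-scope value (per-region values are
available via config) and the outcome 1 for garden origin. A report-level
outcome was chosen over a species-level one because mixed-provenance
species carry information precisely in how their reports split. The curve
is summarised by a two-parameter logistic model fitted by Fisher scoring
with step-halving (log-likelihood non-decreasing by construction; asserted
per iteration in tests), standard errors from the final information
matrix. Perfect separation has no finite maximiser; it is detected by
perfect classification of the fitted probabilities and flagged
`converged=False`. Equal-count bins (default 10, collapsed with a warning
when the metric has fewer distinct values) provide a model-free view. The
verdict per metric is increasing/decreasing/flat from the Wald test at
α = 0.05.

## Synthetic surveys

The generator encodes the study conditions the analyses assume: three
regions with 34/63/74 informants, four communities per region spanning
1100–2100 m (SJ), 600–2200 m (SR) and 1400–2500 m (TK), a 480-species pool
partitioned over the Venn cells with a 35 % three-region core and the
largest unique fraction (20 %) in TK, log-normal species popularity
(sd 1.0, so a few species reach UV ≫ 1 while most are rare), sparse
Dirichlet category profiles tilted toward food and medicinal uses, and
~60 expected reports per informant (each informant-species inclusion
yields 1–3 distinct category reports, P = 0.70/0.25/0.05). Inclusion is a
per-informant logistic draw over the regional pool with logit =
popularity + elevation_effect × loading × z(elevation), the intercept
calibrated by bisection to the target rate; the default elevation_effect
of 2.0 plants a strong, detectable gradient. Ages are present for ~80 % of
informants to exercise the coverage rule.

Provenance is drawn per report with
P(garden) = sigmoid(−2.0 + 3.0 × UV<sub>s</sub>), UV taken from the
realised report counts so the logistic model holds exactly for the data as
analysed, plus 3 % unknown origins. Two deliberate consequences:
report-level independence makes frequently reported species almost surely
mixed-provenance, so the generator's origin-class partition is dominated
by the "both" class, unlike field data where species-level cultivation
status is far more consistent; and because use diversity co-varies with
use value (popular species spread over more categories), the marginal
provenance trend on UD is also positive even though the planted coupling
acts only through UV. Passing recovery tests therefore demonstrate that
the pipeline recovers planted effects, not that real surveys look like
the generator: real data have species-level origin coherence, informant
heterogeneity beyond elevation, and taxonomic (not synthetic) inventories.

## Problem sizes and numerical choices

Replicate-based generator tests run either the full default survey (20
replicates for coupling recovery) or a reduced survey of 60 informants ×
120 species (15–20 replicates) — sizes chosen to keep the suite fast while
leaving binomial noise far below the margins asserted. Permutation
type-I calibration uses 500 replicates of 99 shuffles against fixed score
matrices. IRLS tolerance is 1e-8 on the log-likelihood, NMDS tolerance
1e-7 on stress; permutation p-values are deterministic given the seed, and
every result object records the seed that produced it.

## Known limitations

* The deposited-inventory reproduction (480 species / 249 genera /
  95 families and the regional/wild counts) requires the original survey
  inventory converted to the three-file format under `data/inventory/`;
  without it that check reports failure rather than silently passing.
* No PCoA/PERMANOVA/db-RDA alternatives, no 3-D ordinations, no
  proportional-area Venn rendering, and no fuzzy taxon-name resolution —
  species keys are caller-supplied normalised identifiers.
* F<sub>IC</sub> at N<sub>ur</sub> ≤ 1 is a convention (0.0), not an
  estimate; downstream consumers should respect the `degenerate` flag.
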