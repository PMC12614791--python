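# Methods

This note documents the statistical procedures implemented in `fossilbias`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real data.

## Occurrence cleaning and time binning

Records are removed, in order, when they are trace fossils, when their
geographic scale is `basin` or stratigraphic scale is `group` (too coarse
to treat the collection as a sampling unit), when coordinates are missing,
or when their clade path intersects the exclusion list (default:
Chiroptera, Cetacea, Sirenia, Pinnipedimorpha and Desmostylia, restricting
the dataset to terrestrial, non-volant mammals). Each record is logged
under the first rule it
trips, so input = kept + removed always holds. Clade matching is exact
string membership in the clade path; no fuzzy matching.

Time binning is majority-rule: an occurrence joins the unique bin
containing strictly more than 50% of its age range `[min_ma, max_ma]`.
An exact 50/50 split is dropped — the rule is "greater than 50%", and a tie
admits no unique bin. Zero-duration (point) ages use half-open
`[start_ma, end_ma)` membership, so a point on a bin boundary belongs to
the older bin; this is a deterministic convention, not a claim about
databases' intent. A configurable bin table is accepted; the default is a
set of equal-length bins spanning the Cenozoic.

## Mass estimation and size categories

Species masses come from log-linear allometric regressions on dental
proxies, `log10 M = a·log10 x + b`, with units declared per regression and
results converted to kg. The registry is user-supplied; the shipped one is
a small synthetic/illustrative set (it is also what the generator uses) and
is not a literature compilation. Regression selection takes the most
clade-specific applicable scope, with an integer priority breaking ties,
and falls back to an all-mammal regression when present; measurements are
averaged per (species, proxy) before the regression is applied.

Size categories are half-open intervals whose boundaries belong to the
upper category (1 kg is medium, not small; 30 kg is large). Masses within
one part in 10⁹ below a breakpoint are snapped up onto it, so that e.g. a
geometric mean of 50 and 200 kg lands in the 100–1000 kg decade rather
than a rounding error below it.

Unmeasured species are categorized from the geometric mean (mean of log10
masses) of their closest measured relatives, searching genus, then family,
then order. The geometric mean matches the log-scale error structure of
allometric estimates; an arithmetic mean would be dominated by the largest
relative. Imputed species carry a category but no mass, and are therefore
excluded from median-mass summaries automatically.

## Coverage and standardized diversity

Sampling units are collections; `Y_i` counts the collections containing
species *i* within one time-bin × size-category cell (occurrence-level
incidences are a configurable alternative). Reference-sample coverage is
the improved Good's *u*,

    Ĉ = 1 − (Q1/U) · (T−1)Q1 / ((T−1)Q1 + 2Q2),

which is exactly 1 when no singletons exist, and degrades to the classical
`1 − Q1/U` at `T = 1`, where the improvement factor is undefined.

Rarefied richness and coverage use the *exact* expectations over uniform
subsets of `t` sampling units:

    S(t) = S_obs − Σ_i C(T−Y_i, t)/C(T, t)
    Ĉ(t) = 1 − Σ_i (Y_i/U)·C(T−Y_i, t)/C(T, t)

computed with the numerically stable product form
`Π_{j<Y_i} (T−t−j)/(T−j)`. These equal exhaustive-enumeration means to
floating-point precision (the test suite enforces 1e-10). At the reference
point `t = T` the improved Good's *u* supersedes the naive within-sample
coverage value.

Quorum inversion finds the largest integer `t` with `Ĉ(t) ≤ q` and
interpolates richness linearly to `t+1`; a quorum already attained at one
unit reports the single-unit expectation (efforts below one sampling unit
are not meaningful). When `q` exceeds the reference coverage, the
closed-form extrapolated coverage is solved for the required effort `t*`
and richness follows the Chao2-anchored extrapolation

    S(T+t) = S_obs + Q̂0·[1 − (1 − Q1/(Q1 + T·Q̂0))^t],

with `Q̂0 = ((T−1)/T)·Q1²/(2Q2)` (bias-corrected `((T−1)/T)·Q1(Q1−1)/2`
when `Q2 = 0`). Extrapolations needing `t* > 2T` are reported but flagged
unreliable. Cells with fewer than 3 incidences are rejected as non-viable;
coverage estimation is meaninglessly noisy there.

Because the naive within-sample coverage at `t = T−1` can exceed the
improved Good's *u* at `t = T`, a narrow band of quorums just below the
reference coverage maps to the reference point itself; the inversion is
monotone in `q` by construction.

### Bootstrap confidence intervals

CIs resample the `T` sampling units with replacement and recompute the full
estimate per replicate (B = 1000 for coverage, configurable elsewhere;
deterministic given a seed). The interval is a *recentred* percentile
interval: resampling with replacement duplicates units, which shifts the
whole bootstrap distribution of coverage-standardized quantities downward
while reproducing its spread well, so the percentile interval is translated
to centre its mean on the point estimate. In calibration simulations
(heterogeneous detection probabilities, T = 30, the suite's capture test)
the plain percentile interval captured the expected standardized-diversity
value in well under half of trials, while the recentred interval captures
it in ≈94%.

The capture target in those simulations is the expected value of the
standardized estimate for a survey of the same size `T`. The exact
subsampling interpolation carries a small finite-`T` bias relative to the
population-level inversion (the sample's reference frequencies ignore
undetected species), and no resampling interval can see that bias; it
vanishes as `T` grows.

## Research-time analyses

Opinion replay resolves each name through every opinion published up to the
query year, following chains (A→B in 1920, B→C in 1950 gives A→C from
1950) to a fixed point, memoized per (name, year). Cycles and same-year
conflicting opinions raise errors rather than being silently resolved —
silent resolution would fabricate taxonomic history. Each occurrence
contributes the identification current in the query year (honouring dated
re-identifications); occurrences whose first publication postdates the year
are excluded, as are identifications not resolved to species level.

Discovery curves count distinct resolved species against publication year,
cumulative occurrences, or cumulative references, with the stable intra-year
order (publication year, reference id, occurrence id). Synonymization can
step a curve downward. Standardized discovery curves recompute the quorum-
standardized diversity from the occurrences available at each step, with
the 3-occurrence viability rule.

Skew and median-mass trajectories use presently-accepted names, so their
terminal values agree with the final body size distribution; discovery
curves use year-resolved names. The two conventions intentionally coexist.
Skewness is the biased moment estimator `g1 = m3/m2^(3/2)` over category
indices — invariant to any affine recoding of categories, so indices and
log-midpoints give identical trajectories. Undefined skew (n < 3 or zero
variance) yields a gap, never a zero.

## Spatial proxy

Sampled area is summarized as the total edge length of a minimum spanning
tree over unique collection coordinates, under haversine distance on a
6371 km sphere, with coordinates deduplicated on a 1e-4-degree grid. Note
that MST length is **not** monotone under point addition — an interior
point can re-route the tree more cheaply (square corners plus centre:
three sides become four shorter half-diagonals) — so cumulative MST series
may occasionally dip even as coverage grows.

## The synthetic world

The generator emulates the statistical structure of a continental fossil
mammal occurrence database; its defaults are the package's reference study
conditions:

| parameter | default | meaning |
|---|---|---|
| `n_species` | 500 | true species pool |
| `mixture` | (0.88, −0.8, 0.55), (0.12, 1.9, 0.45) | lognormal mass mixture: dominant small mode (~0.16 kg), accessory large mode (~80 kg); weights, mean and sd in log10 kg |
| `detection_base` | 0.15 | max per-collection detection probability scale |
| `detection_slope`, midpoint | 1.8, 0 log10 kg | logistic mass bias of detection (taphonomy + collector preference) |
| `occupancy` | Beta(0.8, 3) | per-species commonness; makes many species rare |
| `screenwash_year` | 1940 | year the small-taxon penalty is lifted (small-fossil sieving becomes routine; historically a 1925–1950 transition) |
| `small_penalty` | 0.12 | pre-adoption detection multiplier for <1 kg taxa |
| effort | 2 → 8 collections/yr | linear ramp over 1840–2024 |
| churn | oversplit 0.15, recombination 0.10, Exp(30 yr) delay | junior synonyms later merged; genus transfers; all emitted as dated opinions |

Collections belong to formations (each anchored in one time bin and one
geographic centre); references group occurrences by (year, formation);
occurrence age ranges are random sub-intervals of the bin, occasionally
crossing boundaries so the majority rule has work to do. Small fractions
(2% each) of occurrences carry the cleaning defects (trace, basin scale,
group scale, missing coordinates) so the filter rules are exercised
end-to-end. Measurements are emitted for 85% of species by inverting the
registry regression with 0.05 log10 noise, giving the mass stage realistic
but imperfect inputs.

What the generator does **not** emulate: phylogenetically structured trait
evolution, spatially explicit range dynamics, non-stationary formation
availability, and worker-interest feedbacks (e.g. monograph-driven
occurrence bursts). Passing tests therefore show the *machinery* recovers
known truth under mass-biased, churned, era-shifted sampling — not that any
particular real dataset is unbiased or correctable.

## Problem sizes and numerics

The test suite and the acceptance script run the generator at its defaults
(500 species, ~185 years, ~900 collections) and smaller variants; the
rarefaction oracle checks use tables with `T ≤ 15`, where exhaustive subset
enumeration is exact and fast. Bootstrap defaults are B = 1000 for
standalone coverage CIs and B = 200 inside the pipeline. All randomness
flows through `numpy.random.default_rng` seeded from a single
user-supplied seed; identical seeds give byte-identical outputs, and
analytical outputs are invariant to input row order.

Known limitations: extrapolation far beyond `2T` is reported but
unreliable (hence the flag); standardized skew uses frequency-weighted
moments on non-integer standardized counts, an interpretation choice;
imputation from relatives ignores within-clade mass structure beyond the
geometric mean; and coverage-based standardization itself cannot detect
changes in the scope of the sampling universe — demonstrating that failure
mode on synthetic data is one of the package's intended uses.
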