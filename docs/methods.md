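# Methods

This note documents the models and procedures implemented in
`chorus_effort`, the assumptions they make, the parameters that matter,
and the choices made where the design was genuinely open.

## The sampling design and its coordinate system

All timing is expressed as signed minute offsets of 1-min window starts
relative to local sunrise; clock time exists only in the scheduler.
This keeps the statistics free of time zones and daylight-saving
arithmetic, which matters because the design itself is sunrise-anchored:
bird vocal activity is organised around dawn, not around clock time.

Two one-hour day phases are sampled on a 3-min base grid:
dawn = window starts in [−60, 0), morning = starts in [180, 240)
(the hour beginning 3 h after sunrise). Windows are half-open and
labelled by their start minute, so each phase holds exactly 20 base
slots and the full base grid holds 40 per plot-day.

A *scenario* is (intensity, day phase, duration). Intensity `k`
(one window every `k` minutes, `k ∈ {3, 6, 15, 30, 60}`) keeps offsets
with `(offset − phase_start) mod k = 0`, i.e. selection is anchored at
each phase start. Anchoring there makes selections *nested* along every
intensity chain whose grids divide one another (60|30, 30|15, 30|6,
6|3, 15|3), and makes the per-scenario annotation cost come out exactly
as `(60/k) × phases × days` minutes (1–160 over the design grid).
Duration `d` selects the first `d` of the available recording days in
chronological order; the field design does not dictate which days
enter shorter subsets, and the first-`d` rule makes durations nested,
so duration comparisons measure pure accumulation. Nesting is load-
bearing: it forces zero turnover across duration pairs and monotone
pooled richness along chains, both of which are asserted as properties.

Genus-level-only identifications (e.g. "*Certhia* sp.") are excluded at
ingest and itemised in the ingest report; no downstream matrix ever
contains them. Species codes are opaque strings; no taxonomy is
validated.

## Sunrise and audio cutting

Sunrise is the moment the top edge of the solar disc reaches the
horizon: solar zenith 90.833° (16′ solar semi-diameter + 34′ standard
refraction), computed with the NOAA solar-position equations evaluated
at local noon of the civil date. Accuracy is about ±1 min at temperate
latitudes; a user-supplied sunrise table always overrides computation.
Polar day/night raises an explicit no-sunrise error. Test coverage
cross-checks against an independently coded low-precision almanac
(Cooper declination + sinusoidal equation of time) and physical anchors
(equator/equinox near 06:00, sunrise/sunset symmetry about solar noon).

Schedule clock times are rounded to the nearest second — a declared
choice, needed so audio cuts have a defined sample boundary. Cutting
preserves sample rate, bit depth and channel count, emits exactly
`60 × rate` frames per segment, and refuses to zero-pad or truncate: a
segment outside the file span is an error, never a silent partial file.
Recorders are assumed to run 04:30–11:00 local; any scheduled cut
outside that window aborts with all offenders listed.

## Richness estimation

Per scenario, detections collapse to a plots × species incidence
matrix. Local (alpha) richness is summarised by the per-plot mean and
sample SD (ddof = 1; undefined and reported as missing for a single
plot). Pooled richness is the species count across all plots.

Sample-size-based rarefaction/extrapolation of species richness (the
Hill number of order q = 0) uses incidence frequencies:

* interpolation: `E[S(t)] = S_obs − Σ_s C(T−Y_s, t)/C(T, t)`, computed
  exactly (integer binomials in the scalar path; an exact product
  recurrence in the vectorised batch path used by the bootstrap);
* extrapolation: `S(T+m) = S_obs + Q̂0·[1 − (1 − Q1/(Q1 + T·Q̂0))^m]`
  with the Chao2-type `Q̂0 = ((T−1)/T)·Q1²/(2Q2)` when duplicates
  exist, else `((T−1)/T)·Q1(Q1−1)/2`; with no uniques the curve is flat
  at `S_obs`.

The curve passes exactly through `S_obs` at `t = T`, is non-decreasing,
and the default endpoint is `2T` (the customary doubling; configurable).
Confidence bands are percentile 2.5/97.5 bootstrap over `B = 200`
(default) resamples of sampling units with replacement, fully seeded.
Percentile intervals do not mathematically guarantee containing the
point estimate, so bounds are widened to include it when needed — a
documented package choice. The interpolated estimates are verified
against brute-force enumeration of all unit subsets for `T ≤ 8`
(tolerance 1e−10) and the bootstrap against exhaustive enumeration of
all `T^T` resamples at `T = 4`.

## Composition

Pairwise dissimilarity between scenario assemblages is the Sørensen
partition: turnover `β_sim = min(b,c)/(a+min(b,c))` (Simpson pairwise
dissimilarity), total `β_sor = (b+c)/(2a+b+c)`, nestedness-resultant
`β_sne = β_sor − β_sim`. The identity `β_sim + β_sne = β_sor` holds to
1e−12 by construction and is property-tested; a nested pair has zero
turnover exactly. Degenerate conventions: two empty assemblages are
identical (all components 0); exactly one empty gives
`β_sor = β_sne = 1, β_sim = 0`. Scenario-level beta uses **pooled**
species sets (all plots merged per scenario) — the reading under which
the richness printed at pair intersections equals pooled study-area
richness; the per-plot alternative is served by
`assemblage_dissimilarity` on any incidence matrix.

The pipeline emits exactly three gradient families of comparisons:
10 intensity pairs in each of the 12 phase × duration cells, 3 phase
pairs in each of the 20 intensity × duration cells, and 6 duration
pairs in each of the 15 intensity × phase cells.

Gradient significance uses the classical two-sample Student t (pooled
variance, `df = n1+n2−2`, two-sided) on pooled richness per gradient
level, with Welch's test behind a flag; stars follow the conventional
mapping (* <.05 to **** <.0001) and no multiple-testing correction is
applied — each comparison is reported on its own.

The occurrence-by-time matrix counts, per species and base-grid offset,
the number of distinct plots with a detection at that offset on any day
(a plot detected on several days counts once). Rows are ordered by
earliest occupied offset, then by total plot-windows descending, then
species code; the direction of the secondary key is a package choice.

## NMDS

Kruskal's non-metric MDS: disparities are fitted to configuration
distances by pool-adjacent-violators monotone regression in
dissimilarity rank order (ties resolved by stable sort — the secondary
tie approach), and the configuration moves by a Guttman transform
toward the disparities; Kruskal stress-1 is tracked and an update is
accepted only while stress does not increase. Disparities are anchored
to a fixed sum of squares before each Guttman step: without that
anchor, tie-heavy binary-data distance matrices let the configuration
drift toward the origin (stress-1 is scale-invariant, so the drift is
invisible in the objective but destroys the coordinates). Defaults:
k = 2 axes, 20 seeded random starts (best kept), max 300 iterations,
tolerance 1e−6 on relative stress change. The returned configuration is
centred, rotated to principal axes and sign-fixed so identical seeds
give identical coordinates. Distance options for incidence rows:
euclidean (default) and Sørensen. The implementation is cross-checked
in tests against planar ground truths and against an independent
non-metric SMACOF implementation.

## The synthetic dawn chorus

The generator's defaults emulate the field design: 17 plots × 4 days,
both phases on the 3-min base grid, 50 species. Each species has a
Gaussian activity envelope `p_s(t) = p_max·exp(−(t−μ)²/2σ²)` — the
minimal unimodal form with interpretable peak and width — an occupancy
probability ψ (Bernoulli per plot, fixed across the 4-day window: one
breeding-season snapshot, no colonisation/extinction), and independent
per-window Bernoulli detections given occupancy. Four archetypes mix
20/40/30/10% by default (at least one species each):

| archetype        | μ (min)   | σ (min)  | ψ          | p_max      |
|------------------|-----------|----------|------------|------------|
| early_caller     | −40 ± 10  | 20 ± 5   | 0.60–0.90  | 0.10–0.30  |
| persistent       | 60 ± 30   | 110 ± 20 | 0.45–0.80  | 0.08–0.25  |
| morning_biased   | 200 ± 15  | 25 ± 8   | 0.35–0.70  | 0.08–0.30  |
| crepuscular_rare | −55 ± 4   | 12 ± 4   | 0.08–0.20  | 0.02–0.08  |

These are illustrative values for a temperate-forest breeding
community, not estimates fitted to any dataset. Peak per-minute
detectabilities are kept modest (≤ 0.3) because with higher values
pooled richness saturates at every intensity and the design gradients
become invisible — real annotation campaigns show strong intensity
effects. What the simulator deliberately omits: temporal autocorrelation
of vocalisation (song bouts, flocking), weather and noise masking,
abundance/vocal-rate structure, observer error, and between-day activity
drift. Passing tests therefore demonstrate correctness of the estimators
and the design engine under the stated model, not field performance;
with real data the discontinuous-sampling assumption of independent
windows is an approximation.

## Problem sizes and determinism

Default analyses run at the field-design scale (17 plots, 4 days, 50
species, 60 scenarios, bootstrap B = 200, 20 NMDS restarts), which
completes in seconds; tests use the same scale or smaller. One master
seed drives everything: per-stage seeds are derived via
`numpy.random.SeedSequence` spawning, and all outputs (CSV bytes and
manifest hashes) are reproducible from config + seed.

## Known limitations

* Extrapolation reliability degrades beyond ~2T, as for any Chao2-type
  estimator; the endpoint default reflects that.
* The bootstrap resamples plots only; it ignores day-level dependence.
* The classical t-test across scenario values treats scenarios as
  independent replicates of a gradient level, though nested scenarios
  share data — the test is descriptive, as in common practice for this
  design, and is labelled as such in outputs.
* NMDS with heavily tied dissimilarities can have many equal-stress
  configurations; determinism is per seed, not a claim of global
  optimality.
* Point-count ingestion supports richness/composition comparison only;
  no detectability modelling of the reference method is attempted.
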