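# Methods

## Data model

The atomic record is an *occurrence*: one species at one locality in one
time bin, with WGS84 decimal-degree coordinates and optional dental traits.
Time bins are named, contiguous, non-overlapping age intervals (older
bound > younger bound, Ma) with ordinals increasing toward the present;
the bundled MN/MQ scheme (23.0–0.01 Ma, MN7 and MN8 combined) follows
standard published correlations and is configuration, not code — analyses
should supply their own bin-bound CSV where better correlations exist.

Normalisation deduplicates (species, locality, bin) triples, drops rows
with unresolvable bins or missing coordinates (logged), and by default
removes open-nomenclature names ("sp.", "indet.", "cf.") whose identity
cannot anchor a first or last occurrence.  Hypsodonty categories map to an
ordinal scale (bra=1, mes=2, hyp=hys=3) and loph counts are capped at 2;
both conventions follow the calibration literature the transfer functions
come from.  First/last appearance bins (FAD/LAD) are always computed on
the full, unfiltered table: the regional window (default lon −25..40,
lat > 35; longitude endpoints inclusive, latitude strict) only selects
which occurrences enter the spatial statistics.  Every occurrence in a
species' FAD bin counts as a first occurrence, with multiplicity;
symmetrically for lasts.

## Spatial weighting

All spatial aggregation uses the linear decay kernel `w = max(0, 1 − d/R)`
with `d` the haversine great-circle distance (sphere radius 6371.0088 km).
`R` defaults to 500 km, with 100 km as the standard sensitivity setting.
An exponential kernel is available but not used by any default analysis.
Focal points live on a regular lon/lat lattice (configurable spacing,
default 1°); each cell also reports the distance to its nearest raw
occurrence so cells supported only by remote localities can be masked.

## Event model and exceedance test

For each locality in each eligible bin, the two covariates are the
weighted occurrence totals of the two bins spanning the transition —
(previous, current) for origination with the current bin as event bin,
(current, next) for extinction.  Origination uses every bin with an older
neighbour except the terminal bin; extinction every bin with a younger
neighbour.  One logistic regression per event direction is fit by maximum
likelihood on the pooled all-bins table, one unweighted row per occurrence
(the localisation enters through the locally weighted covariates, not
through per-locality fits; a per-bin stratified fit can be had by passing
per-bin row subsets to the fitter).  Single-class targets and (quasi-)
complete separation abort with a diagnostic rather than returning a
degenerate model.

At a grid node with weighted total `n`, weighted event count `k` and model
probability `p` evaluated at the node's own covariates, the reported tail
probability is `P(X ≥ k)` for `X ~ Binomial(n, p)`, extended to real
`k, n` by the regularised incomplete beta `I_p(k, n−k+1)` (`k = 0` gives
1).  Nearest-even rounding to integers is available as an alternative.
Cells need ≥ 1 weighted occurrence to be reported; classification uses
tail < 0.05 (hotspot) and tail > 0.95 (stable), and the two directions
combine into origination/extinction/turnover/stable/neutral.  No
multiple-testing correction is applied by default; a Benjamini–Hochberg
adjustment of the per-cell tails can be applied downstream but changes the
meaning of the maps and is therefore off.

## Sorting (immigration and local extinction)

For a focal point and adjacent bins (unit1, unit2), the candidate lists
are the species with at least one occurrence strictly inside the radius in
each bin, minus species whose global FAD is unit2 or global LAD is unit1
(those are true origination/extinction, not sorting).  Local extinction:
one candidate per species listed in unit1, event = absent from unit2's
list; immigration mirrors it on unit2.  Focal bins are those with both
neighbours; support requires ≥ 1 weighted occurrence in the focal,
preceding and subsequent bins.

The logistic model for candidate event probability uses the *area-total*
weighted sampling intensities of the focal area in the two units.  The
candidate's own weighted sums are tabulated but cannot serve as
covariates: presence in a unit's list is equivalent to a positive own-sum
there, so the later-unit own-sum is zero exactly when the event fires and
the likelihood is perfectly separated (the package raises the separation
diagnostic if this mode is forced).  With area totals, all candidates at a
node share one probability and the node-level exceedance reduces to a
plain binomial tail; the test is nevertheless implemented as an exact
Poisson-binomial upper tail (dynamic programming over the count
distribution) so heterogeneous probability variants remain exact.

Calibration note: on null synthetic worlds the origination detector is
strongly conservative (supported-cell flag rate ≈ 0.003–0.01 at nominal
0.05) because weighted counts are spatially dependent; the sorting
detector is near-nominal (≈ 0.10) because between-node heterogeneity in
the true disappearance probability is only partly captured by the two
sampling covariates.  Users comparing sorting maps across regions should
treat isolated single-cell flags with caution.

## Ecometrics

Grid-level community trait means use the same decay weighting over
occurrences (not species) of the large plant-eating orders
(Perissodactyla, Artiodactyla, Primates, Proboscidea, Hyracoidea);
an occurrence missing one trait is excluded from that trait's mean only,
and means require ≥ 2 weighted trait-bearing occurrences (the reported
support is the scarcer trait's).  HYP is ordinal but close enough to a
ratio scale for arithmetic means to be meaningful.  NPP (g C m⁻² yr⁻¹) is
a deterministic linear function of (mean HYP, mean LOP) with optional
interaction, clipped below at zero.  The coefficients are deliberately
configuration: they belong to published modern-community calibrations,
this package ships none, and all tests use synthetic coefficient sets.

## Species metrics

Longevity is the full observed span — FAD bin's older bound minus LAD
bin's younger bound — so single-bin species carry their bin's duration;
a midpoint-to-midpoint alternative is available (it gives single-bin
species zero).  Per-bin range area: 1 location → 0 km²; 2 locations →
great-circle distance × 10 km; ≥ 3 → planar convex-hull area (shapely)
after a Lambert azimuthal equal-area projection about the points'
centroid, with collinear clouds falling back to the farthest-pair
rectangle.  Spherical excess is negligible at the sub-continental ranges
involved.  A species' mean area averages over the bins where it actually
occurs.  Hotspot membership: at least one first (last) occurrence whose
nearest grid node is flagged in the matching bin.  Group comparisons
restrict to species whose FAD and LAD both fall strictly inside the
scheme, since edge species have censored lifespans.

## Synthetic worlds

The generator emulates the statistical structure the detectors assume:
discrete bins of equal duration (default 6 × 1 Myr), localities uniform
over a lon/lat window (default 35° × 17°, 60 per bin), per-locality
occurrence counts negative-binomial (mean 10, size 1.5) to mimic uneven
sampling and time averaging, species lifetimes geometric (mean 3 bins),
and species site fidelity: resampling draws species with probability
weights `exp(−d_home/150 km)`, so faunas are spatially coherent and local
disappearance is not dominated by pure sampling churn.  Background event
levels default to 8% first and 8% last occurrences per slot.  First
occurrences are realised by introducing new species; last occurrences by
globally retiring a drawn species (same-bin records of that species
elsewhere thereby also become lasts — lasts cluster by species, as in
real data); local extinctions by banning a fraction of the species seen
inside an area from re-sampling there in the next bin while they remain
available elsewhere.  A latent productivity surface declines linearly
west→east and shapes each species' dental traits at its origin.  Truth
records the realised FAD/LAD, so round-trips through the reader and the
FAD/LAD computation are exact.

What the generator does *not* emulate: taphonomic biases correlated with
environment, age-model (bin-assignment) error, diachronous bin boundaries
across regions, synonymy noise, and real dispersal dynamics.  Passing
power/calibration tests on these worlds therefore demonstrates the
statistical machinery under its own assumptions, not robustness to those
failure modes.

## Study sizes used by the test suite

Power and calibration studies run 100 seeded replicates per arm
(seeds 0–99) on default-size worlds with a 5° detection lattice and a
400 km radius; injected anomalies use 50% first occurrences vs 5%
background (origination) and 60% local species loss (sorting).  The
qualitative contrasts (hotspot-born species outliving the background;
arid-side hotspots showing lower estimated NPP) use 50 replicates each,
with short lifetimes (mean 1.5 bins, boost ×2) in the longevity arm so
the boosted cohort's full life fits inside the window — with long
lifetimes the edge-censoring filter preferentially removes exactly the
long-lived hotspot species and the contrast inverts, which is a real
feature of windowed survivorship data, not an artefact.

## Known limitations

- The binomial exceedance treats weighted counts at a node as if they were
  a sample of independent occurrences; spatial dependence makes the
  origination test conservative rather than exact.
- One pooled model per direction assumes transition dynamics comparable
  across bins; strong secular changes in preservation regime would be
  absorbed into hotspot signal.
- Grid cells share occurrences within a radius, so neighbouring flags are
  not independent discoveries.
- MN-style bins are treated as globally synchronous; known diachrony is
  not corrected.
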