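# fossilhotspots

Detection of exceptional origination, extinction and species-sorting
hotspots in spatiotemporal fossil occurrence records, with dental-ecometric
reconstruction of the environmental context and species longevity/range
comparisons.

## The problem

Some places and times in the fossil record produce far more new species
than others — "species factories" — while others act as extinction sinks
or as refugia that collect species going locally extinct elsewhere.  The
difficulty in detecting them is that raw counts of first or last
occurrences mostly track sampling intensity: a densely sampled basin will
always *look* like a hotspot.  This package implements a spatially
explicit baseline model for mammal-style occurrence data (one row per
species per locality per discrete time bin, e.g. the European MN/MQ land
mammal zones) and flags cells whose event counts exceed that baseline.

## The method

Occurrences around a focal point are counted with a linear decay weight

```
w(d) = max(0, 1 - d/R),        R = 500 km by default (100 km alternative)
```

where `d` is great-circle distance.  For each locality in each analysis
bin, two covariates are computed: the weighted occurrence counts of the
two bins spanning the transition (previous/current for origination,
current/next for extinction).  A logistic regression with one row per
occurrence — target: is this occurrence a global first (last) occurrence
of its species? — turns sampling intensities into a per-occurrence event
probability *p*.  At each grid node with weighted total *n* and weighted
event count *k*, the upper binomial tail

```
P(X >= k),  X ~ Binomial(n, p)     (regularised incomplete beta for real-valued k, n)
```

flags exceptional cells: tail < 0.05 is a hotspot, tail > 0.95 a
statistically stable cell.  Sorting (immigration / local extinction of
species that persist globally) is detected analogously from pruned
focal-area species lists, with an exact Poisson-binomial exceedance test.
Community-mean hypsodonty (HYP 1–3) and loph counts (LOP 0–2) of large
herbivores give grid-level net primary productivity through a configurable
linear transfer function, and species-level metrics (longevity in Myr,
per-bin convex-hull range areas in km²) compare hotspot-born species with
the background.

A bundled generator builds synthetic fossil records with known ground
truth (injected hotspots, trait/environment coupling, site-fidelity
sampling) so every stage is testable without any database access.

## Worked example

```python
from fossilhotspots import (HotspotSpec, WorldConfig, detect_hotspots,
                            generate_world, global_fad_lad, make_grid,
                            normalize_occurrences)

hs = HotspotSpec(lon=5, lat=46, radius_km=600, bin_index=3,
                 event="first", fraction=0.5)
world = generate_world(WorldConfig(seed=7, hotspots=[hs],
                                   background_first_frac=0.05))
occ = normalize_occurrences(world.occurrences_raw, world.scheme)
cells = detect_hotspots(occ, global_fad_lad(occ), world.scheme,
                        make_grid(-10, 25, 38, 55, 5.0),
                        radius_km=400, event="first")
print(cells[cells.klass == "hotspot"][["lon", "lat", "bin", "tail_prob"]])
```

prints (seed 7) the flagged cells, which cluster on the injected centre:

```
      lon   lat bin  tail_prob
 ...  5.0  48.0  B4      0.000
 ... 10.0  48.0  B4      0.000
```

i.e. in bin B4 those cells saw far more weighted first occurrences than
the sampling-based model predicts (upper-tail probability < 0.05).  The
`examples/` directory has one short narrative script per capability:
weighting arithmetic, origination detection, sorting detection, ecometric
NPP surfaces, and the species longevity/range contrast.  A thin CLI wraps
the full pipeline: `fossilhotspots all occurrences.csv --out results`.

## Layout

- `src/fossilhotspots/` — library: `bins`, `data`, `weighting`, `events`,
  `sorting`, `ecometrics`, `species_metrics`, `synthetic`, `pipeline`, `cli`
- `docs/methods.md` — model assumptions, parameter choices, limitations
- `examples/` — runnable narrative scripts
- `tests/` — pytest suite including detector power/calibration studies
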