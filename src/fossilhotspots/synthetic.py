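"""Synthetic fossil-record generator with known ground truth.

Builds occurrence tables with the statistical structure the detectors
assume: discrete time bins, localities scattered over a lon/lat window,
uneven per-locality sampling (negative-binomial occurrence counts), species
with geometric lifetimes, a longitudinal productivity gradient that shapes
dental traits, and optionally injected hotspots where the fraction of
first occurrences, last occurrences, or local disappearances is elevated
above background.

Mechanics of event injection:

* a *first* occurrence is realised by introducing a brand-new species at
  the sampled slot (its first appearance anywhere);
* a *last* occurrence is realised by globally retiring an existing species
  after the slot (any same-bin occurrences of that species elsewhere then
  also become last occurrences — last occurrences cluster by species, as
  in real data);
* a *local extinction* is realised by banning a fraction of the species
  seen inside the hotspot area from being re-sampled there in the next
  bin, while they remain available (hence globally extant) elsewhere.

Ground-truth first/last appearance bins are recorded from the realised
table, so recomputing them from the written CSV is exact by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bins import TimeBinScheme
from .weighting import great_circle_km

_HERBIVORE_CYCLE = ("Artiodactyla", "Perissodactyla", "Proboscidea",
                    "Primates", "Hyracoidea")
_HYP_CATEGORY = {1: "bra", 2: "mes", 3: "hyp"}


@dataclass(frozen=True)
class HotspotSpec:
    """An injected anomaly: at (lon, lat, radius_km) in one bin, the event
    fraction is raised to ``fraction`` (events per occurrence slot for
    first/last; per candidate species for local_extinction)."""

    lon: float
    lat: float
    radius_km: float
    bin_index: int  # 0-based index into the scheme
    event: str  # "first" | "last" | "local_extinction"
    fraction: float

    def __post_init__(self) -> None:
        if self.event not in ("first", "last", "local_extinction"):
            raise ValueError(f"unknown hotspot event {self.event!r}")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must be in [0, 1]")
        if not self.radius_km > 0:
            raise ValueError("radius_km must be positive")


@dataclass
class WorldConfig:
    """Study conditions for one synthetic world."""

    n_bins: int = 6
    bin_duration_myr: float = 1.0
    lon_min: float = -10.0
    lon_max: float = 25.0
    lat_min: float = 38.0
    lat_max: float = 55.0
    n_localities_per_bin: int = 60
    mean_occurrences_per_locality: float = 10.0
    sampling_dispersion: float = 1.5  # negative-binomial size; smaller = lumpier
    background_first_frac: float = 0.08
    background_last_frac: float = 0.08
    mean_lifetime_bins: float = 3.0
    hotspots: list[HotspotSpec] = field(default_factory=list)
    # latent productivity declines linearly from west to east
    npp_min: float = 200.0
    npp_max: float = 1200.0
    trait_coupling: float = 0.8  # 0 = traits independent of the gradient
    frac_herbivore: float = 0.6
    hotspot_longevity_boost: float = 1.0  # lifetime multiplier for hotspot-born
    home_range_km: float = 150.0  # e-folding scale of species site fidelity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_first_frac + self.background_last_frac > 1.0:
            raise ValueError("background first + last fractions exceed 1")
        for h in self.hotspots:
            if not (0 <= h.bin_index < self.n_bins):
                raise ValueError(f"hotspot bin_index {h.bin_index} out of range")


@dataclass
class SyntheticWorld:
    """A generated record: raw occurrence table + scheme + ground truth."""

    occurrences_raw: pd.DataFrame
    scheme: TimeBinScheme
    truth: dict
    config: WorldConfig


class _Species:
    __slots__ = ("sid", "fad_idx", "end_idx", "order", "hyp", "lop",
                 "retired", "home_lon", "home_lat")

    def __init__(self, sid, fad_idx, end_idx, order, hyp, lop,
                 home_lon, home_lat):
        self.sid = sid
        self.fad_idx = fad_idx
        self.end_idx = end_idx  # last bin index the species can be sampled in
        self.order = order
        self.hyp = hyp
        self.lop = lop
        self.retired = False
        self.home_lon = home_lon  # species keep site fidelity to their origin
        self.home_lat = home_lat


def latent_npp(lon: float, config: WorldConfig) -> float:
    """West-to-east declining productivity surface used for trait coupling."""
    x = (lon - config.lon_min) / max(config.lon_max - config.lon_min, 1e-9)
    return config.npp_max - (config.npp_max - config.npp_min) * x


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Draw one world; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    scheme = TimeBinScheme.uniform(config.n_bins, config.bin_duration_myr)
    names = scheme.names

    first_specs = [h for h in config.hotspots if h.event == "first"]
    last_specs = [h for h in config.hotspots if h.event == "last"]
    locex_specs = [h for h in config.hotspots if h.event == "local_extinction"]

    species: list[_Species] = []
    # per-bin exclusion: list of (spec, frozenset of banned species ids)
    exclusions: dict[int, list[tuple[HotspotSpec, set[str]]]] = {}
    rows: list[tuple] = []

    def new_species(b: int, lon: float, lat: float, boost: float) -> _Species:
        mean_life = config.mean_lifetime_bins * boost
        lifetime = rng.geometric(min(1.0, 1.0 / max(mean_life, 1.0)))
        order = (
            _HERBIVORE_CYCLE[len(species) % len(_HERBIVORE_CYCLE)]
            if rng.random() < config.frac_herbivore else "Rodentia"
        )
        hyp = lop = None
        if order != "Rodentia":
            npp_norm = (latent_npp(lon, config) - config.npp_min) / max(
                config.npp_max - config.npp_min, 1e-9)
            arid = (1.0 - npp_norm) * config.trait_coupling
            hyp_val = int(np.clip(np.rint(1.0 + 2.0 * arid + rng.normal(0, 0.4)),
                                  1, 3))
            hyp = _HYP_CATEGORY[hyp_val]
            if hyp == "hyp" and rng.random() < 0.2:
                hyp = "hys"
            lop = int(np.clip(np.rint(2.5 * arid + rng.normal(0, 0.5)), 0, 3))
        sp = _Species(f"S{len(species):05d}", b, b + lifetime - 1, order,
                      hyp, lop, lon, lat)
        species.append(sp)
        return sp

    for b in range(config.n_bins):
        lons = rng.uniform(config.lon_min, config.lon_max,
                           config.n_localities_per_bin)
        lats = rng.uniform(config.lat_min, config.lat_max,
                           config.n_localities_per_bin)
        alive_old = [s for s in species
                     if s.fad_idx < b and b <= s.end_idx and not s.retired]
        bin_exclusions = exclusions.get(b, [])
        # record, per local-extinction spec targeting transition b -> b+1,
        # which species are seen inside the area in bin b
        seen_in_area: dict[int, set[str]] = {i: set()
                                             for i in range(len(locex_specs))
                                             if locex_specs[i].bin_index == b}

        for li in range(config.n_localities_per_bin):
            lon, lat = float(lons[li]), float(lats[li])
            size = config.sampling_dispersion
            mean = config.mean_occurrences_per_locality
            n_occ = max(1, int(rng.negative_binomial(size, size / (size + mean))))

            f_first = config.background_first_frac
            f_last = config.background_last_frac
            boost = 1.0
            for h in first_specs:
                if h.bin_index == b and great_circle_km(
                        h.lon, h.lat, lon, lat) < h.radius_km:
                    f_first = h.fraction
                    boost = config.hotspot_longevity_boost
            for h in last_specs:
                if h.bin_index == b and great_circle_km(
                        h.lon, h.lat, lon, lat) < h.radius_km:
                    f_last = h.fraction
            if f_first + f_last > 1.0:
                raise ValueError("hotspot event fractions sum above 1 at "
                                 f"bin {b}, locality ({lon:.2f}, {lat:.2f})")

            banned: set[str] = set()
            for spec, sids in bin_exclusions:
                if great_circle_km(spec.lon, spec.lat, lon, lat) < spec.radius_km:
                    banned |= sids

            # slot types drawn per occurrence: first / last / plain resample
            u = rng.random(n_occ)
            n_first = int(np.sum(u < f_first))
            n_last = int(np.sum((u >= f_first) & (u < f_first + f_last)))
            n_old = n_occ - n_first  # lasts are drawn from the old pool too

            pool = [s for s in alive_old
                    if not s.retired and s.sid not in banned]
            drawn: list[_Species] = []
            if pool and n_old:
                # site fidelity: resampling favours species whose home is near
                d_home = great_circle_km(
                    lon, lat,
                    np.array([s.home_lon for s in pool]),
                    np.array([s.home_lat for s in pool]))
                wts = np.exp(-np.atleast_1d(d_home) / config.home_range_km) + 1e-12
                k = min(len(pool), n_old)
                idx = rng.choice(len(pool), size=k, replace=False,
                                 p=wts / wts.sum())
                drawn = [pool[i] for i in idx]
            for j, sp in enumerate(drawn):
                if j < n_last:  # this occurrence retires the species globally
                    sp.retired = True
                    sp.end_idx = b
            # shortfall in the old pool realises as extra first occurrences
            for _ in range(n_first + (n_old - len(drawn))):
                drawn.append(new_species(b, lon, lat, boost))
            for sp in drawn:
                rows.append((sp.sid, f"L{b}_{li:03d}", lon, lat, names[b],
                             sp.order, sp.hyp, sp.lop))
                for i, seen in seen_in_area.items():
                    h = locex_specs[i]
                    if great_circle_km(h.lon, h.lat, lon, lat) < h.radius_km:
                        seen.add(sp.sid)

        # choose which area species get locally banned next bin
        for i, seen in seen_in_area.items():
            h = locex_specs[i]
            candidates = sorted(seen)
            n_ban = int(np.floor(h.fraction * len(candidates)))
            if n_ban:
                picked = rng.choice(len(candidates), size=n_ban, replace=False)
                exclusions.setdefault(b + 1, []).append(
                    (h, {candidates[j] for j in picked}))

    occ = pd.DataFrame(rows, columns=["species", "locality", "lon", "lat",
                                      "bin", "order", "hypsodonty", "lophs"])

    by_sp = occ.groupby("species")["bin"].agg(
        fad=lambda s: min(names.index(x) for x in s),
        lad=lambda s: max(names.index(x) for x in s),
    )
    truth = {
        "seed": config.seed,
        "bin_names": names,
        "n_species": len(by_sp),
        "species": {
            sid: {"fad_bin": names[int(r.fad)], "lad_bin": names[int(r.lad)]}
            for sid, r in by_sp.iterrows()
        },
        # a spec whose fraction matches the background is not a true anomaly
        "hotspots": [
            {**asdict(h), "bin": names[h.bin_index]}
            for h in config.hotspots
            if h.fraction > {
                "first": config.background_first_frac,
                "last": config.background_last_frac,
                "local_extinction": 0.0,
            }[h.event]
        ],
    }
    return SyntheticWorld(occ, scheme, truth, config)


def write_fixture(world: SyntheticWorld, directory: str | Path) -> dict[str, Path]:
    """Write occurrences.csv, bins.csv and truth.json; returns the paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "occurrences": d / "occurrences.csv",
        "bins": d / "bins.csv",
        "truth": d / "truth.json",
    }
    world.occurrences_raw.to_csv(paths["occurrences"], index=False)
    world.scheme.to_csv(paths["bins"])
    with open(paths["truth"], "w") as fh:
        json.dump(world.truth, fh, indent=1)
    return paths
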