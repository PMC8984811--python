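import math

import numpy as np
import pandas as pd
import pytest

from fossilhotspots.bins import TimeBin, TimeBinScheme
from fossilhotspots.data import normalize_occurrences, global_fad_lad
from fossilhotspots.synthetic import WorldConfig, generate_world
from fossilhotspots.weighting import EARTH_RADIUS_KM


def km_north(km: float) -> float:
    """Latitude offset in degrees whose meridian arc is exactly `km`."""
    return math.degrees(km / EARTH_RADIUS_KM)


@pytest.fixture(scope="session")
def toy_scheme() -> TimeBinScheme:
    return TimeBinScheme([
        TimeBin("T0", 3.0, 2.0, 1),
        TimeBin("T1", 2.0, 1.0, 2),
        TimeBin("T2", 1.0, 0.01, 3),
    ])


@pytest.fixture(scope="session")
def fig1_world(toy_scheme) -> pd.DataFrame:
    """The worked toy configuration used throughout the docs.

    Focal locality A (lon 0, lat 40) has 4 occurrences in bin T1, exactly
    one of which is a first occurrence; locality B sits exactly 400 km due
    north with 3 occurrences in T1; locality C exactly 350 km due north
    with 5 occurrences in the prior bin T0.  Additional far-field (lon 90)
    occurrences give the non-first species earlier records without
    touching any weighted count near A.
    """
    rows = []
    lat_a = 40.0
    # far-field earlier records for the non-first species
    for sp in ["a2", "a3", "a4", "b1", "b2", "b3"]:
        rows.append((sp, "FAR", 90.0, 40.0, "T0"))
    for sp in ["c1", "c2", "c3", "c4", "c5"]:
        rows.append((sp, "C", 0.0, lat_a + km_north(350.0), "T0"))
    for sp in ["a_new", "a2", "a3", "a4"]:
        rows.append((sp, "A", 0.0, lat_a, "T1"))
    for sp in ["b1", "b2", "b3"]:
        rows.append((sp, "B", 0.0, lat_a + km_north(400.0), "T1"))
    raw = pd.DataFrame(rows, columns=["species", "locality", "lon", "lat", "bin"])
    raw["order"] = "Artiodactyla"
    raw["hypsodonty"] = np.nan
    raw["lophs"] = np.nan
    return normalize_occurrences(raw, toy_scheme)


@pytest.fixture(scope="session")
def small_world():
    """One default synthetic world plus its normalised table and FAD/LAD."""
    world = generate_world(WorldConfig(seed=42))
    occ = normalize_occurrences(world.occurrences_raw, world.scheme)
    ranges = global_fad_lad(occ)
    return world, occ, ranges
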