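"""Occurrence-table ingestion and normalisation.

The atomic record is one species observed at one locality in one time bin
("occurrence").  Input is a flat CSV with columns

    species, locality, lon, lat, bin, order, hypsodonty, lophs

where ``hypsodonty`` is one of the categories bra/mes/hyp/hys (or empty) and
``lophs`` an integer 0..3 (or empty).  Normalisation encodes hypsodonty on
the ordinal 1..3 scale (bra=1, mes=2, hyp=hys=3), caps loph counts at 2,
deduplicates (species, locality, bin) and resolves bin names against a
:class:`~fossilhotspots.bins.TimeBinScheme`.

First/last appearance data (FAD/LAD) are always determined on the *global*
(unfiltered) table; regional filtering only selects which occurrences enter
the spatial analyses.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .bins import TimeBinScheme

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("species", "locality", "lon", "lat", "bin")

HYPSODONTY_CODES = {"bra": 1, "mes": 2, "hyp": 3, "hys": 3}

#: Large plant-eating orders whose dental traits enter ecometric estimation.
HERBIVORE_ORDERS = frozenset(
    {"Perissodactyla", "Artiodactyla", "Primates", "Proboscidea", "Hyracoidea"}
)

_OPEN_NOMENCLATURE = re.compile(r"(?:\bsp\.|\bindet\.|\bcf\.)", re.IGNORECASE)


def encode_hypsodonty(raw) -> float:
    """Map a hypsodonty category to its ordinal value (1..3); NaN if missing.

    bra -> 1, mes -> 2, hyp -> 3, hys -> 3.  Unknown categories are treated
    as missing (and logged by the table-level reader).
    """
    if raw is None or pd.isna(raw):
        return np.nan
    return float(HYPSODONTY_CODES.get(str(raw).strip().lower(), np.nan))


def cap_lophs(raw) -> float:
    """Cap a longitudinal loph count at 2; NaN for missing or out-of-range."""
    if raw is None or pd.isna(raw):
        return np.nan
    try:
        v = float(raw)
    except (TypeError, ValueError):
        return np.nan
    if v < 0 or v > 3:
        return np.nan
    return min(v, 2.0)


def read_occurrence_csv(
    path: str | Path,
    bin_scheme: TimeBinScheme,
    drop_open_nomenclature: bool = True,
) -> pd.DataFrame:
    """Read and normalise a NOW-style occurrence CSV.

    Rows with an unresolvable bin name or missing coordinates are dropped
    (count logged); duplicate (species, locality, bin) rows collapse to one.
    ``drop_open_nomenclature`` removes taxonomically indeterminate names
    containing "sp.", "indet." or "cf.".

    Returns a DataFrame with columns species, locality, lon, lat, bin,
    bin_ordinal, order, hyp, lop, in_region.
    """
    df = pd.read_csv(path, dtype={"species": str, "locality": str, "bin": str},
                     float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence CSV is missing required columns: {missing}")
    for optional in ("order", "hypsodonty", "lophs"):
        if optional not in df.columns:
            df[optional] = np.nan
    return normalize_occurrences(
        df, bin_scheme, drop_open_nomenclature=drop_open_nomenclature
    )


def normalize_occurrences(
    df: pd.DataFrame,
    bin_scheme: TimeBinScheme,
    drop_open_nomenclature: bool = True,
) -> pd.DataFrame:
    """Normalise an in-memory raw occurrence table (see read_occurrence_csv)."""
    n0 = len(df)
    df = df.copy()

    bad_coord = df["lon"].isna() | df["lat"].isna()
    if bad_coord.any():
        logger.info("dropping %d rows with missing coordinates", int(bad_coord.sum()))
        df = df[~bad_coord]

    resolvable = df["bin"].isin(bin_scheme.names)
    if (~resolvable).any():
        logger.info("dropping %d rows with unresolvable bin", int((~resolvable).sum()))
        df = df[resolvable]

    if drop_open_nomenclature:
        indeterminate = df["species"].astype(str).str.contains(_OPEN_NOMENCLATURE)
        if indeterminate.any():
            logger.info(
                "dropping %d open-nomenclature rows", int(indeterminate.sum())
            )
            df = df[~indeterminate]

    before = len(df)
    df = df.drop_duplicates(subset=["species", "locality", "bin"])
    if len(df) < before:
        logger.info("collapsed %d duplicate (species, locality, bin) rows",
                    before - len(df))

    if df.empty:
        raise ValueError(f"no occurrences left after filtering ({n0} raw rows)")

    out = pd.DataFrame(
        {
            "species": df["species"].astype(str),
            "locality": df["locality"].astype(str),
            "lon": df["lon"].astype(float),
            "lat": df["lat"].astype(float),
            "bin": df["bin"].astype(str),
            "bin_ordinal": df["bin"].map(bin_scheme.ordinal).astype(int),
            "order": df["order"].astype("string"),
            "hyp": df["hypsodonty"].map(encode_hypsodonty).astype(float),
            "lop": df["lophs"].map(cap_lophs).astype(float),
            "in_region": True,
        }
    ).reset_index(drop=True)
    return out


def filter_region(
    occurrences: pd.DataFrame,
    lon_min: float = -25.0,
    lon_max: float = 40.0,
    lat_min: float = 35.0,
) -> pd.DataFrame:
    """Restrict to the study window: lon_min <= lon <= lon_max and lat > lat_min.

    Longitude endpoints are inclusive; the latitude bound is strict
    ("latitude above" the bound).  Idempotent.
    """
    for v in (lon_min, lon_max, lat_min):
        if not np.isfinite(v):
            raise ValueError("region bounds must be finite")
    keep = (
        (occurrences["lon"] >= lon_min)
        & (occurrences["lon"] <= lon_max)
        & (occurrences["lat"] > lat_min)
    )
    out = occurrences[keep].copy()
    out["in_region"] = True
    if out.empty:
        logger.info("region filter left no occurrences")
    return out.reset_index(drop=True)


def global_fad_lad(global_occurrences: pd.DataFrame) -> pd.DataFrame:
    """Per-species global first/last appearance bins.

    Computed on the *global* table.  Every occurrence whose bin equals its
    species' FAD bin is a first occurrence (multiplicity preserved);
    symmetrically for last occurrences.

    Returns a DataFrame indexed by species with columns fad_ordinal,
    lad_ordinal, fad_bin, lad_bin.
    """
    g = global_occurrences.groupby("species")["bin_ordinal"]
    ranges = pd.DataFrame({"fad_ordinal": g.min(), "lad_ordinal": g.max()})
    ord_to_name = (
        global_occurrences.drop_duplicates("bin_ordinal")
        .set_index("bin_ordinal")["bin"]
    )
    ranges["fad_bin"] = ranges["fad_ordinal"].map(ord_to_name)
    ranges["lad_bin"] = ranges["lad_ordinal"].map(ord_to_name)
    return ranges


def flag_event_occurrences(
    occurrences: pd.DataFrame, ranges: pd.DataFrame
) -> pd.DataFrame:
    """Add boolean is_first / is_last columns against global FAD/LAD."""
    out = occurrences.copy()
    fad = out["species"].map(ranges["fad_ordinal"])
    lad = out["species"].map(ranges["lad_ordinal"])
    out["is_first"] = (out["bin_ordinal"] == fad).fillna(False).astype(bool)
    out["is_last"] = (out["bin_ordinal"] == lad).fillna(False).astype(bool)
    return out
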