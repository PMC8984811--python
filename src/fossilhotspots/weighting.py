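"""Great-circle distances and linear-decay spatial weighting.

Every spatial aggregation in the pipeline counts occurrences around a focal
point with weight ``max(0, 1 - d/R)``, where ``d`` is the great-circle
(haversine) distance to the focal point and ``R`` the aggregation radius
(default 500 km; 100 km is the standard sensitivity setting).  An occurrence
at the focal point itself therefore counts 1, one at 400 km with R = 500
counts 0.2, and anything at or beyond R counts 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088

DEFAULT_RADIUS_KM = 500.0


@dataclass(frozen=True)
class FocalPoint:
    lon: float
    lat: float
    radius_km: float = DEFAULT_RADIUS_KM

    def __post_init__(self) -> None:
        if not self.radius_km > 0:
            raise ValueError("radius_km must be positive")


@dataclass(frozen=True)
class WeightedCount:
    """A distance-weighted occurrence count.

    ``value`` is the sum of weights; ``n_contributing`` the number of raw
    occurrences with positive weight.
    """

    value: float
    n_contributing: int


def great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine distance in km on a sphere of radius 6371.0088 km.

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if d.ndim == 0:
        return float(d)
    return d


def decay_weight(distance_km, radius_km, kernel: str = "linear"):
    """Spatial weight of an occurrence at the given distance.

    linear (default): max(0, 1 - d/R).  exponential: exp(-d/R), offered as
    an alternative kernel; linear is what all the statistics here use.
    """
    d = np.asarray(distance_km, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance_km must be non-negative")
    if not radius_km > 0:
        raise ValueError("radius_km must be positive")
    if kernel == "linear":
        w = np.maximum(0.0, 1.0 - d / radius_km)
    elif kernel == "exponential":
        w = np.exp(-d / radius_km)
    else:
        raise ValueError(f"unknown weight kernel {kernel!r}")
    if w.ndim == 0:
        return float(w)
    return w


def weighted_occurrence_count(
    focal: FocalPoint,
    occurrences: pd.DataFrame,
    bin_name: str | None = None,
    predicate: pd.Series | None = None,
    kernel: str = "linear",
) -> WeightedCount:
    """Distance-weighted count of occurrences around a focal point.

    ``bin_name`` restricts to one time bin; ``predicate`` is an optional
    boolean mask aligned with ``occurrences`` selecting e.g. first
    occurrences or a single species.
    """
    mask = np.ones(len(occurrences), dtype=bool)
    if bin_name is not None:
        mask &= (occurrences["bin"] == bin_name).to_numpy()
    if predicate is not None:
        mask &= np.asarray(predicate, dtype=bool)
    sub = occurrences.loc[mask]
    if sub.empty:
        return WeightedCount(0.0, 0)
    d = great_circle_km(focal.lon, focal.lat,
                        sub["lon"].to_numpy(), sub["lat"].to_numpy())
    w = decay_weight(d, focal.radius_km, kernel=kernel)
    pos = w > 0
    return WeightedCount(float(np.sum(w[pos])), int(np.count_nonzero(pos)))


def weight_matrix(
    focal_lons: np.ndarray,
    focal_lats: np.ndarray,
    occ_lons: np.ndarray,
    occ_lats: np.ndarray,
    radius_km: float,
    kernel: str = "linear",
) -> np.ndarray:
    """(n_focal, n_occurrence) matrix of decay weights; the workhorse used by
    the detectors to aggregate many focal points at once."""
    d = great_circle_km(
        np.asarray(focal_lons)[:, None],
        np.asarray(focal_lats)[:, None],
        np.asarray(occ_lons)[None, :],
        np.asarray(occ_lats)[None, :],
    )
    return decay_weight(d, radius_km, kernel=kernel)


def make_grid(
    lon_min: float,
    lon_max: float,
    lat_min: float,
    lat_max: float,
    spacing_deg: float = 1.0,
) -> pd.DataFrame:
    """Regular lon/lat lattice of focal points over a bounding box."""
    if spacing_deg <= 0:
        raise ValueError("spacing_deg must be positive")
    lons = np.arange(lon_min, lon_max + 1e-9, spacing_deg)
    lats = np.arange(lat_min, lat_max + 1e-9, spacing_deg)
    gl, gt = np.meshgrid(lons, lats)
    return pd.DataFrame({"lon": gl.ravel(), "lat": gt.ravel()})
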