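"""Species longevity, geographic range size and hotspot-membership contrasts.

Longevity is the full observed span: older bound of the first-appearance
bin minus younger bound of the last-appearance bin, so a single-bin species
carries its bin's full duration.  Per-bin geographic range follows a
three-tier rule: one location -> 0 km^2; two locations -> great-circle
distance x 10 km (a 10 km wide rectangle between them); three or more ->
area of the planar convex hull after projecting the points with a Lambert
azimuthal equal-area projection centred on their centroid (collinear point
sets degrade to the two-point rule on the farthest pair).

Species are then compared between those that have at least one first (or
last) occurrence inside a flagged hotspot cell of the matching bin and
those that do not.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from .bins import TimeBinScheme
from .data import flag_event_occurrences
from .weighting import EARTH_RADIUS_KM, great_circle_km


def species_longevity(
    fad_bin: str,
    lad_bin: str,
    scheme: TimeBinScheme,
    convention: str = "full_span",
) -> float:
    """Observed species duration in Myr.

    full_span (default): older bound of the FAD bin minus younger bound of
    the LAD bin.  midpoint: distance between bin midpoints (zero for
    single-bin species).
    """
    fad, lad = scheme[fad_bin], scheme[lad_bin]
    if fad.ordinal > lad.ordinal:
        raise ValueError("FAD bin is younger than LAD bin")
    if convention == "full_span":
        return fad.older_bound - lad.younger_bound
    if convention == "midpoint":
        return fad.midpoint_ma - lad.midpoint_ma
    raise ValueError(f"unknown longevity convention {convention!r}")


def _azimuthal_equal_area_km(lons: np.ndarray, lats: np.ndarray
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Project points to planar km, Lambert azimuthal equal-area about the
    centroid; areas on the plane equal areas on the sphere."""
    lam = np.radians(lons)
    phi = np.radians(lats)
    lam0, phi0 = lam.mean(), phi.mean()
    cosc = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    k = np.sqrt(2.0 / np.clip(1.0 + cosc, 1e-12, None))
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_KM * k * (np.cos(phi0) * np.sin(phi)
                               - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0))
    return x, y


def _farthest_pair_km(lons: np.ndarray, lats: np.ndarray) -> float:
    d = great_circle_km(lons[:, None], lats[:, None],
                        lons[None, :], lats[None, :])
    return float(np.max(d))


def per_bin_range_area(lons, lats) -> float:
    """Geographic range area (km^2) of one species' locations in one bin."""
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    if lons.size == 0:
        raise ValueError("need at least one location")
    pts = np.unique(np.column_stack([lons, lats]), axis=0)
    if len(pts) == 1:
        return 0.0
    if len(pts) == 2:
        return great_circle_km(pts[0, 0], pts[0, 1], pts[1, 0], pts[1, 1]) * 10.0
    x, y = _azimuthal_equal_area_km(pts[:, 0], pts[:, 1])
    hull = MultiPoint(list(zip(x, y))).convex_hull
    if hull.geom_type != "Polygon" or hull.area <= 0.0:
        # collinear: fall back to the two-point rectangle on the farthest pair
        return _farthest_pair_km(pts[:, 0], pts[:, 1]) * 10.0
    return float(hull.area)


def _nearest_node_klass(
    occ: pd.DataFrame, cells: pd.DataFrame
) -> np.ndarray:
    """For each occurrence, the klass of the nearest grid node in its bin."""
    labels = np.array(["none"] * len(occ), dtype=object)
    for bname, cg in cells.groupby("bin"):
        mask = (occ["bin"] == bname).to_numpy()
        if not mask.any():
            continue
        nl = cg["lon"].to_numpy()
        nt = cg["lat"].to_numpy()
        ol = occ.loc[mask, "lon"].to_numpy()
        ot = occ.loc[mask, "lat"].to_numpy()
        d2 = (nl[None, :] - ol[:, None]) ** 2 + (nt[None, :] - ot[:, None]) ** 2
        labels[mask] = cg["klass"].to_numpy()[np.argmin(d2, axis=1)]
    return labels


def hotspot_member_species(
    occurrences: pd.DataFrame,
    ranges: pd.DataFrame,
    cells: pd.DataFrame,
    event: str = "first",
) -> set[str]:
    """Species with at least one first (last) occurrence whose nearest grid
    node is classified "hotspot" in the matching bin."""
    occ = flag_event_occurrences(occurrences, ranges)
    flag = "is_first" if event == "first" else "is_last"
    ev = occ[occ[flag]].reset_index(drop=True)
    if ev.empty or cells.empty:
        return set()
    labels = _nearest_node_klass(ev, cells)
    return set(ev.loc[labels == "hotspot", "species"])


def species_summaries(
    occurrences: pd.DataFrame,
    ranges: pd.DataFrame,
    scheme: TimeBinScheme,
    origination_cells: pd.DataFrame | None = None,
    extinction_cells: pd.DataFrame | None = None,
    longevity_convention: str = "full_span",
) -> pd.DataFrame:
    """One row per species: FAD/LAD, longevity, mean per-bin range area and
    hotspot memberships.

    Only species whose global FAD and LAD both fall strictly inside the
    scheme (not its first or last bin) are marked ``interior`` — those are
    the ones whose full life is observable; mean area averages over the
    bins where the species actually occurs.
    """
    orig_members = (hotspot_member_species(occurrences, ranges,
                                           origination_cells, "first")
                    if origination_cells is not None else set())
    ext_members = (hotspot_member_species(occurrences, ranges,
                                          extinction_cells, "last")
                   if extinction_cells is not None else set())
    first_ord = scheme.ordinal(scheme.names[0])
    last_ord = scheme.ordinal(scheme.names[-1])
    out = []
    for sp, g in occurrences.groupby("species"):
        if sp not in ranges.index:
            continue
        r = ranges.loc[sp]
        areas = {
            bname: per_bin_range_area(bg["lon"].to_numpy(), bg["lat"].to_numpy())
            for bname, bg in g.groupby("bin")
        }
        out.append({
            "species": sp,
            "fad_bin": r["fad_bin"],
            "lad_bin": r["lad_bin"],
            "longevity_myr": species_longevity(r["fad_bin"], r["lad_bin"],
                                               scheme, longevity_convention),
            "mean_area_km2": float(np.mean(list(areas.values()))),
            "n_bins_present": len(areas),
            "single_bin": r["fad_ordinal"] == r["lad_ordinal"],
            "interior": (first_ord < r["fad_ordinal"])
                        and (r["lad_ordinal"] < last_ord),
            "origination_hotspot_member": sp in orig_members,
            "extinction_hotspot_member": sp in ext_members,
        })
    return pd.DataFrame(out).set_index("species")


def hotspot_species_comparison(
    summaries: pd.DataFrame,
    membership: str = "origination_hotspot_member",
    exclude_single_bin: bool = False,
    interior_only: bool = True,
) -> pd.DataFrame:
    """Group-mean longevity and range area for hotspot vs non-hotspot species.

    ``interior_only`` restricts to species whose whole observed life falls
    inside the analysis window, mirroring how average lifespans are usually
    reported.  An empty group yields NaN means with n = 0.
    """
    df = summaries
    if interior_only:
        df = df[df["interior"]]
    if exclude_single_bin:
        df = df[~df["single_bin"]]
    out = []
    for group, sel in (("hotspot", df[membership]),
                       ("non-hotspot", ~df[membership])):
        g = df[sel]
        out.append({
            "group": group,
            "n_species": int(len(g)),
            "mean_longevity_myr": float(g["longevity_myr"].mean())
            if len(g) else float("nan"),
            "mean_area_km2": float(g["mean_area_km2"].mean())
            if len(g) else float("nan"),
        })
    return pd.DataFrame(out)
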