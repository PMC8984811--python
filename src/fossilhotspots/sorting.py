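"""Species-sorting hotspots: exceptional immigration and local extinction.

Sorting is faunal change carried by species that exist elsewhere globally:
a species disappearing from a focal area while persisting globally is a
local extinction; one newly appearing in the area after existing elsewhere
is an immigration.  For each focal point and pair of adjacent bins the
species lists inside the radius are compared after pruning species that
globally originate in the later bin or globally die out in the earlier bin
(those are true origination/extinction, not sorting).

A two-covariate logistic model on the pooled candidate table supplies each
candidate's event probability; the exceedance test for the observed event
count at a node is the exact Poisson-binomial upper tail, computed by
dynamic programming (the plain binomial is recovered when probabilities
are equal).

The default model covariates are the *area-total* weighted occurrence
counts of the focal area in the two bins (its sampling intensities).  The
per-species weighted sums are also tabulated, but they cannot serve as
covariates: a candidate's weighted sum in the "after" bin is zero exactly
when the event fires, so a logistic model on them is perfectly separated
and its MLE diverges.  With area totals every candidate at a node shares
one probability and the node-level test reduces to a plain binomial tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bins import TimeBinScheme
from .events import (ALPHA_DEFAULT, BETA_DEFAULT, EventModel, fit_event_model)
from .weighting import DEFAULT_RADIUS_KM, great_circle_km, decay_weight

DIRECTIONS = ("local_extinction", "immigration")


@dataclass(frozen=True)
class SortingTransition:
    """Adjacent bin pair (unit1 older, unit2 younger) around a focal bin."""

    unit1: str
    unit2: str
    focal_bin: str


def transitions(scheme: TimeBinScheme, direction: str) -> list[SortingTransition]:
    """Bin pairs analysed for a direction.

    Focal bins are those with both an older and a younger neighbour.  For
    local extinction the pair is (focal, next); for immigration it is
    (previous, focal).
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    out = []
    for name in scheme.names[1:-1]:
        if direction == "local_extinction":
            out.append(SortingTransition(name, scheme.next(name).name, name))
        else:
            out.append(SortingTransition(scheme.previous(name).name, name, name))
    return out


def focal_species_lists(
    occurrences: pd.DataFrame,
    ranges: pd.DataFrame,
    focal_lon: float,
    focal_lat: float,
    radius_km: float,
    bin1: str,
    bin2: str,
    scheme: TimeBinScheme,
) -> tuple[set[str], set[str]]:
    """Species present within the radius in each of two adjacent bins,
    pruned to species globally extant in both bins.

    Pruning removes species whose global FAD is bin2 or global LAD is bin1
    from *both* lists, leaving only candidates for sorting events.
    """
    o1, o2 = scheme.ordinal(bin1), scheme.ordinal(bin2)
    if o2 != o1 + 1:
        raise ValueError(f"bins {bin1!r}, {bin2!r} are not adjacent in the scheme")
    lists = []
    for bname in (bin1, bin2):
        sub = occurrences[occurrences["bin"] == bname]
        if sub.empty:
            lists.append(set())
            continue
        d = great_circle_km(focal_lon, focal_lat,
                            sub["lon"].to_numpy(), sub["lat"].to_numpy())
        lists.append(set(sub.loc[d < radius_km, "species"]))
    s1, s2 = lists
    pruned = {
        sp for sp in (s1 | s2)
        if ranges.loc[sp, "fad_ordinal"] == o2 or ranges.loc[sp, "lad_ordinal"] == o1
    }
    return s1 - pruned, s2 - pruned


def _area_weighted_total(
    occurrences: pd.DataFrame,
    bin_name: str,
    focal_lon: float,
    focal_lat: float,
    radius_km: float,
) -> float:
    """Weighted count of all occurrences around the focal point in one bin."""
    sub = occurrences[occurrences["bin"] == bin_name]
    if sub.empty:
        return 0.0
    d = great_circle_km(focal_lon, focal_lat,
                        sub["lon"].to_numpy(), sub["lat"].to_numpy())
    return float(decay_weight(d, radius_km).sum())


def _species_weighted_sums(
    occurrences: pd.DataFrame,
    species: list[str],
    bin_name: str,
    focal_lon: float,
    focal_lat: float,
    radius_km: float,
) -> dict[str, float]:
    """Per-species sum of decay weights within the focal area in one bin."""
    sub = occurrences[(occurrences["bin"] == bin_name)
                      & occurrences["species"].isin(species)]
    if sub.empty:
        return {sp: 0.0 for sp in species}
    d = great_circle_km(focal_lon, focal_lat,
                        sub["lon"].to_numpy(), sub["lat"].to_numpy())
    w = decay_weight(d, radius_km)
    sums = pd.Series(w, index=sub["species"].to_numpy()).groupby(level=0).sum()
    return {sp: float(sums.get(sp, 0.0)) for sp in species}


def build_sorting_rows(
    occurrences: pd.DataFrame,
    ranges: pd.DataFrame,
    grid: pd.DataFrame,
    scheme: TimeBinScheme,
    radius_km: float = DEFAULT_RADIUS_KM,
    direction: str = "local_extinction",
) -> pd.DataFrame:
    """Pooled candidate table over all grid nodes and transitions.

    local_extinction: one row per species in the (pruned) unit1 list,
    event=1 iff absent from the unit2 list.  immigration: one row per
    species in the unit2 list, event=1 iff absent from unit1.

    w_unit1/w_unit2 are the species' own weighted occurrence sums in the
    focal area (diagnostic; the unit2 sum is 0 exactly when a
    local-extinction event fires); x_unit1/x_unit2 are the area-total
    weighted counts over all occurrences, the default model covariates.

    Columns: node_id, lon, lat, bin (focal), species, w_unit1, w_unit2,
    x_unit1, x_unit2, y.
    """
    rows: list[dict] = []
    for tr in transitions(scheme, direction):
        for node_id, g in enumerate(grid.itertuples(index=False)):
            s1, s2 = focal_species_lists(occurrences, ranges, g.lon, g.lat,
                                         radius_km, tr.unit1, tr.unit2, scheme)
            listed, other = (s1, s2) if direction == "local_extinction" else (s2, s1)
            if not listed:
                continue
            cand = sorted(listed)
            w1 = _species_weighted_sums(occurrences, cand, tr.unit1,
                                        g.lon, g.lat, radius_km)
            w2 = _species_weighted_sums(occurrences, cand, tr.unit2,
                                        g.lon, g.lat, radius_km)
            x1 = _area_weighted_total(occurrences, tr.unit1, g.lon, g.lat,
                                      radius_km)
            x2 = _area_weighted_total(occurrences, tr.unit2, g.lon, g.lat,
                                      radius_km)
            for sp in cand:
                rows.append({
                    "node_id": node_id, "lon": g.lon, "lat": g.lat,
                    "bin": tr.focal_bin, "species": sp,
                    "w_unit1": w1[sp], "w_unit2": w2[sp],
                    "x_unit1": x1, "x_unit2": x2,
                    "y": int(sp not in other),
                })
    return pd.DataFrame(rows, columns=["node_id", "lon", "lat", "bin", "species",
                                       "w_unit1", "w_unit2", "x_unit1",
                                       "x_unit2", "y"])


def poisson_binomial_tail(probabilities, k: int) -> float:
    """P(sum of independent Bernoulli(p_i) >= k), exactly, by DP.

    Equals the binomial upper tail when all p_i are equal.
    """
    ps = np.asarray(probabilities, dtype=float)
    if ps.size and (np.any(ps <= 0.0) or np.any(ps >= 1.0)):
        raise ValueError("all probabilities must lie strictly in (0, 1)")
    if k < 0 or k > ps.size:
        raise ValueError(f"need 0 <= k <= {ps.size}, got k={k}")
    if k == 0:
        return 1.0
    # pmf[j] = P(count == j) after folding in each Bernoulli
    pmf = np.zeros(ps.size + 1)
    pmf[0] = 1.0
    for i, p in enumerate(ps):
        pmf[1:i + 2] = pmf[1:i + 2] * (1.0 - p) + pmf[:i + 1] * p
        pmf[0] *= 1.0 - p
    return float(np.sum(pmf[k:]))


def fit_sorting_model(rows: pd.DataFrame,
                      covariates: str = "area") -> EventModel:
    """Logistic fit on the pooled candidate table (intercept + two weights).

    covariates="area" (default) uses the focal area's total weighted
    sampling intensities in the two bins; "species" uses the candidate's
    own weighted sums, which for local extinction are perfectly separated
    (the fit will fail with a diagnostic) and are offered only to probe
    that behaviour.
    """
    cols = {"area": ("x_unit1", "x_unit2"),
            "species": ("w_unit1", "w_unit2")}[covariates]
    renamed = rows.rename(columns={cols[0]: "w_earlier", cols[1]: "w_later"})
    return fit_event_model(renamed[["w_earlier", "w_later", "y"]])


def detect_sorting_hotspots(
    occurrences: pd.DataFrame,
    ranges: pd.DataFrame,
    scheme: TimeBinScheme,
    grid: pd.DataFrame,
    radius_km: float = DEFAULT_RADIUS_KM,
    direction: str = "local_extinction",
    alpha: float = ALPHA_DEFAULT,
    beta: float = BETA_DEFAULT,
    model: EventModel | None = None,
    min_support: float = 1.0,
    covariates: str = "area",
) -> pd.DataFrame:
    """Per grid node, per transition: Poisson-binomial exceedance of the
    observed sorting-event count.

    Nodes need at least ``min_support`` weighted occurrences in the focal,
    preceding and subsequent bins to be supported; others are reported as
    klass="unsupported".
    """
    rows = build_sorting_rows(occurrences, ranges, grid, scheme,
                              radius_km=radius_km, direction=direction)
    if model is None:
        model = fit_sorting_model(rows, covariates=covariates)
    ccols = {"area": ("x_unit1", "x_unit2"),
             "species": ("w_unit1", "w_unit2")}[covariates]

    # weighted total occurrences per node per bin, for the support rule
    glon = grid["lon"].to_numpy(dtype=float)
    glat = grid["lat"].to_numpy(dtype=float)
    support: dict[str, np.ndarray] = {}
    for bname in scheme.names:
        sub = occurrences[occurrences["bin"] == bname]
        if sub.empty:
            support[bname] = np.zeros(len(grid))
        else:
            d = great_circle_km(glon[:, None], glat[:, None],
                                sub["lon"].to_numpy()[None, :],
                                sub["lat"].to_numpy()[None, :])
            support[bname] = decay_weight(d, radius_km).sum(axis=1)

    out = []
    for tr in transitions(scheme, direction):
        prev_bin = scheme.previous(tr.focal_bin).name
        next_bin = scheme.next(tr.focal_bin).name
        node_support = np.minimum.reduce([support[tr.focal_bin],
                                          support[prev_bin], support[next_bin]])
        sub = rows[rows["bin"] == tr.focal_bin]
        by_node = dict(tuple(sub.groupby("node_id"))) if not sub.empty else {}
        for node_id in range(len(grid)):
            supported = node_support[node_id] >= min_support
            cand = by_node.get(node_id)
            if cand is None or cand.empty:
                out.append({"lon": glon[node_id], "lat": glat[node_id],
                            "bin": tr.focal_bin, "direction": direction,
                            "n_candidates": 0, "k_events": 0,
                            "tail_prob": 1.0,
                            "klass": "unsupported" if not supported else "neutral"})
                continue
            ps = model.predict(cand[ccols[0]].to_numpy(),
                               cand[ccols[1]].to_numpy())
            k = int(cand["y"].sum())
            tail = poisson_binomial_tail(ps, k)
            if not supported:
                klass = "unsupported"
            elif tail < alpha:
                klass = "hotspot"
            elif tail > beta:
                klass = "stable"
            else:
                klass = "neutral"
            out.append({"lon": glon[node_id], "lat": glat[node_id],
                        "bin": tr.focal_bin, "direction": direction,
                        "n_candidates": len(cand), "k_events": k,
                        "tail_prob": tail, "klass": klass})
    return pd.DataFrame(out)
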