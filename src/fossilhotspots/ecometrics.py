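"""Dental ecometrics: community trait means and NPP transfer function.

Mean hypsodonty (HYP, ordinal 1..3) and mean loph count (LOP, 0..2) of the
large plant-eating mammal community — Perissodactyla, Artiodactyla,
Primates, Proboscidea and Hyracoidea — summarise how abrasive/arid the
local vegetation was.  Means are distance-weighted over occurrences around
each grid node with the same linear-decay kernel as the hotspot detectors,
and a configurable linear transfer function maps (HYP, LOP) to estimated
net primary productivity in g C m^-2 yr^-1.  The transfer-function
coefficients are configuration (they come from published calibrations on
modern communities and are not hard-coded here); predictions are clipped
below at zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import HERBIVORE_ORDERS
from .weighting import DEFAULT_RADIUS_KM, weight_matrix

MIN_TRAIT_SUPPORT = 2.0


@dataclass(frozen=True)
class NppModelConfig:
    """Linear transfer function NPP = intercept + a*HYP + b*LOP + c*HYP*LOP."""

    intercept: float
    hyp_coef: float
    lop_coef: float
    interaction_coef: float = 0.0
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        for v in (self.intercept, self.hyp_coef, self.lop_coef,
                  self.interaction_coef):
            if not np.isfinite(v):
                raise ValueError("NPP model coefficients must be finite")

    @classmethod
    def from_json(cls, path: str | Path) -> "NppModelConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def estimate_npp(mean_hyp: float, mean_lop: float,
                 model: NppModelConfig | None) -> float:
    """Evaluate the transfer function; clipped below at 0; NaN passes through."""
    if model is None:
        raise ValueError(
            "no NPP transfer function configured: supply an NppModelConfig "
            "with published calibration coefficients"
        )
    if np.isnan(mean_hyp) or np.isnan(mean_lop):
        return float("nan")
    raw = (model.intercept + model.hyp_coef * mean_hyp
           + model.lop_coef * mean_lop
           + model.interaction_coef * mean_hyp * mean_lop)
    return max(0.0, float(raw))


def grid_trait_means(
    occurrences: pd.DataFrame,
    grid: pd.DataFrame,
    bin_name: str,
    radius_km: float = DEFAULT_RADIUS_KM,
    orders: frozenset[str] = HERBIVORE_ORDERS,
    min_support: float = MIN_TRAIT_SUPPORT,
    kernel: str = "linear",
) -> pd.DataFrame:
    """Distance-weighted community trait means per grid node for one bin.

    Only occurrences of the allowed orders enter; an occurrence missing one
    trait is excluded from that trait's mean only.  Means are reported when
    the weighted count of trait-bearing occurrences reaches ``min_support``
    (default 2), else NaN.

    Returns columns lon, lat, bin, mean_hyp, mean_lop, weighted_support.
    """
    sub = occurrences[
        (occurrences["bin"] == bin_name)
        & occurrences["order"].isin(orders)
        & (occurrences["hyp"].notna() | occurrences["lop"].notna())
    ]
    glon = grid["lon"].to_numpy(dtype=float)
    glat = grid["lat"].to_numpy(dtype=float)
    res = pd.DataFrame({"lon": glon, "lat": glat, "bin": bin_name})
    if sub.empty:
        res["mean_hyp"] = np.nan
        res["mean_lop"] = np.nan
        res["weighted_support"] = 0.0
        return res
    w = weight_matrix(glon, glat, sub["lon"].to_numpy(), sub["lat"].to_numpy(),
                      radius_km, kernel=kernel)
    means, supports = {}, {}
    for trait in ("hyp", "lop"):
        vals = sub[trait].to_numpy(dtype=float)
        has = np.isfinite(vals)
        wt = w[:, has]
        denom = wt.sum(axis=1)
        num = wt @ vals[has]
        with np.errstate(invalid="ignore", divide="ignore"):
            m = num / denom
        m[denom < min_support] = np.nan
        means[trait], supports[trait] = m, denom
    res["mean_hyp"] = means["hyp"]
    res["mean_lop"] = means["lop"]
    # support reported for the scarcer trait: both means must rest on it
    res["weighted_support"] = np.minimum(supports["hyp"], supports["lop"])
    return res


def trait_grid(
    occurrences: pd.DataFrame,
    grid: pd.DataFrame,
    bins: list[str],
    radius_km: float = DEFAULT_RADIUS_KM,
    npp_model: NppModelConfig | None = None,
    orders: frozenset[str] = HERBIVORE_ORDERS,
    min_support: float = MIN_TRAIT_SUPPORT,
) -> pd.DataFrame:
    """Trait means (and NPP if a transfer function is given) for many bins."""
    parts = []
    for bname in bins:
        part = grid_trait_means(occurrences, grid, bname, radius_km=radius_km,
                                orders=orders, min_support=min_support)
        if npp_model is not None:
            part["npp"] = [
                estimate_npp(h, l, npp_model)
                for h, l in zip(part["mean_hyp"], part["mean_lop"])
            ]
        else:
            part["npp"] = np.nan
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def _five_number(x: np.ndarray) -> dict[str, float]:
    if x.size == 0:
        return {k: float("nan") for k in ("min", "q1", "median", "q3", "max")}
    q = np.percentile(x, [0, 25, 50, 75, 100])
    return {"min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4]}


def hotspot_environment_summary(
    trait_grid_df: pd.DataFrame,
    hotspot_grid: pd.DataFrame,
    hotspot_label: str = "hotspot",
) -> pd.DataFrame:
    """Per-bin five-number NPP summaries for hotspot vs non-hotspot cells.

    Cells must share the lattice and bins between the two tables; only
    cells with a defined NPP (trait support met) enter.  Unsupported
    detector cells are excluded from both groups.
    """
    merged = trait_grid_df.merge(hotspot_grid, on=["lon", "lat", "bin"],
                                 how="inner")
    merged = merged[np.isfinite(merged["npp"])
                    & (merged["klass"] != "unsupported")]
    out = []
    for bname, g in merged.groupby("bin", sort=False):
        hot = g[g["klass"] == hotspot_label]["npp"].to_numpy()
        non = g[g["klass"] != hotspot_label]["npp"].to_numpy()
        for group, vals in (("hotspot", hot), ("non-hotspot", non)):
            row = {"bin": bname, "group": group, "n_cells": int(vals.size)}
            row.update(_five_number(vals))
            out.append(row)
    return pd.DataFrame(out)
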