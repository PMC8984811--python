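"""Origination / extinction hotspot detection.

The idea: how many first (or last) occurrences a place shows should be
judged against how intensively that place and its surroundings were sampled
in the two time bins spanning the transition.  A logistic regression is fit
on one row per occurrence, with the two distance-weighted sampling
intensities as covariates and "is this occurrence a first (last)
occurrence" as the target.  At a grid node the model then gives a
per-occurrence event probability, and a binomial tail probability asks how
surprising the node's weighted event count is given its weighted total.

For origination the transition is (previous bin -> focal bin) and the focal
bin is the later one; bins without an older neighbour, and the terminal bin
of the scheme, are excluded (their first occurrences are boundary
artefacts).  For extinction the transition is (focal bin -> next bin) and
the focal bin is the earlier one; only bins without a younger neighbour are
excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special

from .bins import TimeBinScheme
from .data import flag_event_occurrences
from .weighting import DEFAULT_RADIUS_KM, great_circle_km, weight_matrix

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05
BETA_DEFAULT = 0.95
MIN_WEIGHTED_SUPPORT = 1.0


@dataclass(frozen=True)
class EventModel:
    """Fitted two-covariate logistic model for per-occurrence event probability."""

    intercept: float
    beta_earlier: float
    beta_later: float
    converged: bool
    n_rows: int

    def predict(self, w_earlier, w_later):
        """P(event) = sigmoid(intercept + b1*w_earlier + b2*w_later)."""
        eta = (self.intercept
               + self.beta_earlier * np.asarray(w_earlier, dtype=float)
               + self.beta_later * np.asarray(w_later, dtype=float))
        return special.expit(eta)


def eligible_bins(scheme: TimeBinScheme, event: str) -> list[str]:
    """Focal bins entering the analysis for the given event direction."""
    names = scheme.names
    if event == "first":
        return names[1:-1]
    if event == "last":
        return names[:-1]
    raise ValueError(f"event must be 'first' or 'last', got {event!r}")


def _transition_bins(scheme: TimeBinScheme, focal: str, event: str) -> tuple[str, str]:
    """(earlier, later) bin names of the transition around a focal bin."""
    if event == "first":
        prev = scheme.previous(focal)
        assert prev is not None
        return prev.name, focal
    nxt = scheme.next(focal)
    assert nxt is not None
    return focal, nxt.name


def build_event_rows(
    occurrences: pd.DataFrame,
    ranges: pd.DataFrame,
    scheme: TimeBinScheme,
    event: str = "first",
    radius_km: float = DEFAULT_RADIUS_KM,
    kernel: str = "linear",
) -> pd.DataFrame:
    """One regression row per in-scope occurrence.

    For every locality in every eligible focal bin, the two covariates are
    the distance-weighted counts of *all* occurrences around that locality
    in the earlier and later bin of the transition; the target is 1 iff the
    occurrence is a first (last) occurrence per the global FAD/LAD table.

    Returns columns locality, bin, lon, lat, w_earlier, w_later, y.
    """
    occ = flag_event_occurrences(occurrences, ranges)
    flag = "is_first" if event == "first" else "is_last"
    chunks: list[pd.DataFrame] = []
    for focal_bin in eligible_bins(scheme, event):
        earlier, later = _transition_bins(scheme, focal_bin, event)
        focal_occ = occ[occ["bin"] == focal_bin]
        if focal_occ.empty:
            continue
        locs = (focal_occ.groupby("locality")
                .agg(lon=("lon", "first"), lat=("lat", "first"))
                .reset_index())
        cov = {}
        for label, bname in (("w_earlier", earlier), ("w_later", later)):
            sub = occ[occ["bin"] == bname]
            if sub.empty:
                cov[label] = np.zeros(len(locs))
            else:
                w = weight_matrix(locs["lon"].to_numpy(), locs["lat"].to_numpy(),
                                  sub["lon"].to_numpy(), sub["lat"].to_numpy(),
                                  radius_km, kernel=kernel)
                cov[label] = w.sum(axis=1)
        locs["w_earlier"] = cov["w_earlier"]
        locs["w_later"] = cov["w_later"]
        merged = focal_occ.merge(locs, on="locality", suffixes=("", "_loc"))
        chunks.append(pd.DataFrame({
            "locality": merged["locality"],
            "bin": focal_bin,
            "lon": merged["lon_loc"],
            "lat": merged["lat_loc"],
            "w_earlier": merged["w_earlier"],
            "w_later": merged["w_later"],
            "y": merged[flag].astype(int),
        }))
    if not chunks:
        return pd.DataFrame(
            columns=["locality", "bin", "lon", "lat", "w_earlier", "w_later", "y"]
        )
    return pd.concat(chunks, ignore_index=True)


def fit_event_model(rows: pd.DataFrame) -> EventModel:
    """Maximum-likelihood logistic fit with intercept on the pooled row table."""
    if rows.empty:
        raise ValueError("cannot fit event model: no regression rows")
    y = rows["y"].to_numpy(dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("single-class targets: every row has y = "
                         f"{int(classes[0])}; the logistic model is undefined")
    X = sm.add_constant(rows[["w_earlier", "w_later"]].to_numpy(dtype=float))
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise ValueError(f"logistic fit failed (possible complete separation): {exc}")
    params = res.params
    converged = bool(res.mle_retvals.get("converged", False))
    if not np.all(np.isfinite(params)) or (
            not converged and np.max(np.abs(params)) > 100.0):
        raise ValueError(
            "complete (or quasi-complete) separation: a covariate predicts "
            "the target perfectly and the coefficient estimate diverges")
    return EventModel(
        intercept=float(params[0]),
        beta_earlier=float(params[1]),
        beta_later=float(params[2]),
        converged=converged,
        n_rows=len(rows),
    )


def binomial_tail(k: float, n: float, p: float, rounding: bool = False) -> float:
    """Upper-tail probability P(X >= k) for X ~ Binomial(n, p).

    Extended to real-valued (weighted) k and n through the regularised
    incomplete beta function I_p(k, n-k+1); for integer inputs this equals
    the exact binomial survival sum.  k = 0 returns 1.  ``rounding`` instead
    rounds k and n to nearest-even integers first.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must be in (0, 1), got {p}")
    if k < 0 or n <= 0 or k > n + 1e-9:
        raise ValueError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    if rounding:
        k, n = float(np.round(k)), float(np.round(n))
        k = min(k, n)
    if k <= 0:
        return 1.0
    return float(special.betainc(k, n - k + 1.0, p))


def classify_cell(
    tail_prob_first: float,
    tail_prob_last: float,
    alpha: float = ALPHA_DEFAULT,
    beta: float = BETA_DEFAULT,
) -> str:
    """Combined origination/extinction class of one supported cell.

    origination-hotspot / extinction-hotspot if only that direction's tail
    is below alpha, turnover if both are, stable if both exceed beta, else
    neutral.
    """
    for t in (tail_prob_first, tail_prob_last):
        if not (0.0 <= t <= 1.0):
            raise ValueError("tail probabilities must lie in [0, 1]")
    first_hot = tail_prob_first < alpha
    last_hot = tail_prob_last < alpha
    if first_hot and last_hot:
        return "turnover"
    if first_hot:
        return "origination-hotspot"
    if last_hot:
        return "extinction-hotspot"
    if tail_prob_first > beta and tail_prob_last > beta:
        return "stable"
    return "neutral"


def detect_hotspots(
    occurrences: pd.DataFrame,
    ranges: pd.DataFrame,
    scheme: TimeBinScheme,
    grid: pd.DataFrame,
    radius_km: float = DEFAULT_RADIUS_KM,
    event: str = "first",
    alpha: float = ALPHA_DEFAULT,
    beta: float = BETA_DEFAULT,
    kernel: str = "linear",
    min_support: float = MIN_WEIGHTED_SUPPORT,
    model: EventModel | None = None,
    rounding: bool = False,
) -> pd.DataFrame:
    """Per grid node, per eligible bin: weighted counts, event probability,
    binomial tail probability and hotspot class for one event direction.

    A node is supported in a bin when its weighted total occurrence count is
    at least ``min_support`` (default 1); unsupported nodes are reported
    with klass="unsupported".  ``min_distance_km`` gives the distance to the
    nearest raw occurrence of the focal bin so that remote-support cells can
    be masked downstream.
    """
    if model is None:
        rows = build_event_rows(occurrences, ranges, scheme, event=event,
                                radius_km=radius_km, kernel=kernel)
        model = fit_event_model(rows)
    occ = flag_event_occurrences(occurrences, ranges)
    flag = "is_first" if event == "first" else "is_last"
    glon = grid["lon"].to_numpy(dtype=float)
    glat = grid["lat"].to_numpy(dtype=float)
    out: list[pd.DataFrame] = []
    for focal_bin in eligible_bins(scheme, event):
        earlier, later = _transition_bins(scheme, focal_bin, event)
        focal_occ = occ[occ["bin"] == focal_bin]
        res = pd.DataFrame({"lon": glon, "lat": glat, "bin": focal_bin})
        if focal_occ.empty:
            continue
        w_focal = weight_matrix(glon, glat,
                                focal_occ["lon"].to_numpy(),
                                focal_occ["lat"].to_numpy(),
                                radius_km, kernel=kernel)
        n_weighted = w_focal.sum(axis=1)
        k_weighted = w_focal @ focal_occ[flag].to_numpy(dtype=float)
        cov = {}
        for label, bname in (("w_earlier", earlier), ("w_later", later)):
            sub = occ[occ["bin"] == bname]
            if sub.empty:
                cov[label] = np.zeros(len(res))
            else:
                w = weight_matrix(glon, glat, sub["lon"].to_numpy(),
                                  sub["lat"].to_numpy(), radius_km, kernel=kernel)
                cov[label] = w.sum(axis=1)
        # distance to nearest raw focal-bin occurrence, to flag remote support
        d = great_circle_km(glon[:, None], glat[:, None],
                            focal_occ["lon"].to_numpy()[None, :],
                            focal_occ["lat"].to_numpy()[None, :])
        res["min_distance_km"] = d.min(axis=1)
        res["n_weighted"] = n_weighted
        res["k_weighted"] = np.minimum(k_weighted, n_weighted)
        res["p_event"] = model.predict(cov["w_earlier"], cov["w_later"])
        supported = res["n_weighted"] >= min_support
        tails = np.ones(len(res))
        for i in np.flatnonzero(supported.to_numpy()):
            tails[i] = binomial_tail(res["k_weighted"].iat[i],
                                     res["n_weighted"].iat[i],
                                     res["p_event"].iat[i], rounding=rounding)
        res["tail_prob"] = tails
        klass = np.where(tails < alpha, "hotspot",
                         np.where(tails > beta, "stable", "neutral"))
        res["klass"] = np.where(supported, klass, "unsupported")
        out.append(res)
    if not out:
        return pd.DataFrame(columns=["lon", "lat", "bin", "min_distance_km",
                                     "n_weighted", "k_weighted", "p_event",
                                     "tail_prob", "klass"])
    return pd.concat(out, ignore_index=True)


def adjust_tails(cells: pd.DataFrame, alpha: float = ALPHA_DEFAULT,
                 beta: float = BETA_DEFAULT) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment of supported cells' tail probabilities.

    Off by default everywhere: the maps are exploratory and per-cell tails
    are what the classification thresholds were defined on.  Returns a copy
    with tail_prob replaced by BH-adjusted values and klass re-derived.
    """
    from statsmodels.stats.multitest import multipletests
    out = cells.copy()
    sup = out["klass"] != "unsupported"
    if sup.any():
        adj = multipletests(out.loc[sup, "tail_prob"].to_numpy(),
                            method="fdr_bh")[1]
        out.loc[sup, "tail_prob"] = adj
        out.loc[sup, "klass"] = np.where(
            adj < alpha, "hotspot", np.where(adj > beta, "stable", "neutral"))
    return out


def classify_cells(
    first_results: pd.DataFrame,
    last_results: pd.DataFrame,
    alpha: float = ALPHA_DEFAULT,
    beta: float = BETA_DEFAULT,
) -> pd.DataFrame:
    """Merge per-direction detector outputs into the four-way map classes.

    Cells present in only one direction's table (bin windows differ at the
    scheme edges) or unsupported in either direction are "unsupported".
    """
    merged = first_results.merge(
        last_results, on=["lon", "lat", "bin"], suffixes=("_first", "_last")
    )
    labels = []
    for r in merged.itertuples(index=False):
        if r.klass_first == "unsupported" or r.klass_last == "unsupported":
            labels.append("unsupported")
        else:
            labels.append(classify_cell(r.tail_prob_first, r.tail_prob_last,
                                        alpha=alpha, beta=beta))
    merged["klass"] = labels
    return merged[["lon", "lat", "bin", "tail_prob_first", "tail_prob_last",
                   "klass"]]
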