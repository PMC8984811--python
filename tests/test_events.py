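import math

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from fossilhotspots.bins import TimeBin, TimeBinScheme
from fossilhotspots.data import (flag_event_occurrences, global_fad_lad,
                                 normalize_occurrences)
from fossilhotspots.events import (
    binomial_tail,
    build_event_rows,
    classify_cell,
    classify_cells,
    detect_hotspots,
    eligible_bins,
    fit_event_model,
)
from fossilhotspots.weighting import EARTH_RADIUS_KM, great_circle_km, make_grid


class TestBuildEventRows:
    def test_toy_locality_rows(self, fig1_world, toy_scheme):
        """The focal locality contributes 4 rows with covariates (1.5, 4.6)
        and exactly one positive target."""
        ranges = global_fad_lad(fig1_world)
        rows = build_event_rows(fig1_world, ranges, toy_scheme, event="first",
                                radius_km=500.0)
        a = rows[rows["locality"] == "A"]
        assert len(a) == 4
        assert np.allclose(a["w_earlier"], 1.5, atol=1e-9)
        assert np.allclose(a["w_later"], 4.6, atol=1e-9)
        assert sorted(a["y"]) == [0, 0, 0, 1]

    def test_row_and_event_totals(self, small_world):
        """One row per in-scope occurrence; positive targets count the
        first occurrences."""
        world, occ, ranges = small_world
        rows = build_event_rows(occ, ranges, world.scheme, event="first",
                                radius_km=400.0)
        scope = occ[occ["bin"].isin(eligible_bins(world.scheme, "first"))]
        flagged = flag_event_occurrences(scope, ranges)
        assert len(rows) == len(scope)
        assert rows["y"].sum() == flagged["is_first"].sum()

    def test_extinction_window_includes_oldest_bin(self, toy_scheme):
        assert eligible_bins(toy_scheme, "first") == ["T1"]
        assert eligible_bins(toy_scheme, "last") == ["T0", "T1"]

    def test_empty_bin_contributes_no_rows(self, fig1_world, toy_scheme):
        ranges = global_fad_lad(fig1_world)
        rows = build_event_rows(fig1_world, ranges, toy_scheme, event="last",
                                radius_km=500.0)
        # T1 localities have no "next-bin" support but still produce rows;
        # no row may come from the terminal bin
        assert set(rows["bin"]) <= {"T0", "T1"}

    def test_matches_brute_force_enumeration(self, toy_scheme):
        """Hand enumeration over 2 localities x 2 occupied bins."""
        lat_off = math.degrees(200.0 / EARTH_RADIUS_KM)
        raw = pd.DataFrame(
            [("p", "L1", 0.0, 40.0, "T0"),
             ("q", "L1", 0.0, 40.0, "T1"),
             ("p", "L2", 0.0, 40.0 + lat_off, "T1"),
             ("r", "L2", 0.0, 40.0 + lat_off, "T1")],
            columns=["species", "locality", "lon", "lat", "bin"])
        raw["order"] = "Rodentia"; raw["hypsodonty"] = np.nan; raw["lophs"] = np.nan
        occ = normalize_occurrences(raw, toy_scheme)
        ranges = global_fad_lad(occ)
        rows = build_event_rows(occ, ranges, toy_scheme, event="first",
                                radius_km=500.0)
        w = 1.0 - 200.0 / 500.0  # weight between L1 and L2
        # L1 in T1: earlier = own p (1.0); later = own q + L2 pair * w
        l1 = rows[rows["locality"] == "L1"]
        assert len(l1) == 1 and l1["y"].iat[0] == 1  # q first appears in T1
        assert l1["w_earlier"].iat[0] == pytest.approx(1.0)
        assert l1["w_later"].iat[0] == pytest.approx(1.0 + 2 * w)
        # L2 in T1: earlier = L1's p at 200 km; later = own 2 + L1's q * w
        l2 = rows[rows["locality"] == "L2"]
        assert len(l2) == 2
        assert np.allclose(l2["w_earlier"], w)
        assert np.allclose(l2["w_later"], 2.0 + w)
        # p re-occurs (not first), r is new
        assert sorted(l2["y"]) == [0, 1]


class TestFitEventModel:
    def test_parameter_recovery_on_simulated_data(self):
        rng = np.random.default_rng(11)
        n = 5000
        x1 = rng.uniform(0, 10, n)
        x2 = rng.uniform(0, 10, n)
        truth = (-1.0, 0.3, 0.1)
        p = special.expit(truth[0] + truth[1] * x1 + truth[2] * x2)
        y = rng.random(n) < p
        rows = pd.DataFrame({"w_earlier": x1, "w_later": x2, "y": y.astype(int)})
        model = fit_event_model(rows)
        assert model.converged
        import statsmodels.api as sm
        ref = sm.Logit(rows["y"], sm.add_constant(rows[["w_earlier", "w_later"]])
                       ).fit(disp=0)
        est = [model.intercept, model.beta_earlier, model.beta_later]
        for e, t, se in zip(est, truth, ref.bse):
            assert abs(e - t) < 3 * se

    def test_single_class_targets_rejected(self):
        rows = pd.DataFrame({"w_earlier": [1, 2], "w_later": [1, 2], "y": [0, 0]})
        with pytest.raises(ValueError, match="single-class"):
            fit_event_model(rows)

    def test_duplicating_rows_leaves_estimates_unchanged(self):
        rng = np.random.default_rng(5)
        rows = pd.DataFrame({
            "w_earlier": rng.uniform(0, 5, 400),
            "w_later": rng.uniform(0, 5, 400),
            "y": rng.integers(0, 2, 400),
        })
        m1 = fit_event_model(rows)
        m2 = fit_event_model(pd.concat([rows, rows], ignore_index=True))
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-6)
        assert m1.beta_earlier == pytest.approx(m2.beta_earlier, abs=1e-6)
        assert m1.beta_later == pytest.approx(m2.beta_later, abs=1e-6)


class TestBinomialTail:
    def test_all_successes(self):
        assert binomial_tail(4, 4, 0.5) == pytest.approx(0.0625, abs=1e-12)

    def test_zero_events(self):
        assert binomial_tail(0, 7.3, 0.42) == 1.0

    def test_at_least_one_of_three(self):
        assert binomial_tail(1, 3, 0.2) == pytest.approx(1 - 0.8 ** 3, abs=1e-12)

    def test_integer_inputs_match_survival_sum(self):
        for n in (1, 4, 11):
            for k in range(1, n + 1):
                for p in (0.1, 0.5, 0.83):
                    exact = sum(math.comb(n, j) * p**j * (1 - p)**(n - j)
                                for j in range(k, n + 1))
                    assert binomial_tail(k, n, p) == pytest.approx(
                        exact, abs=1e-12)

    def test_monotone_in_p_and_k(self):
        assert binomial_tail(3, 10, 0.4) > binomial_tail(3, 10, 0.2)
        assert binomial_tail(2, 10, 0.3) > binomial_tail(4, 10, 0.3)
        # weighted (non-integer) inputs interpolate the same ordering
        assert binomial_tail(2.5, 10.2, 0.3) > binomial_tail(3.5, 10.2, 0.3)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            binomial_tail(5, 4, 0.5)
        with pytest.raises(ValueError):
            binomial_tail(1, 4, 1.0)

    def test_rounding_mode(self):
        assert binomial_tail(3.4, 9.7, 0.3, rounding=True) == \
            binomial_tail(3, 10, 0.3)


class TestClassification:
    @pytest.mark.parametrize("tf,tl,expected", [
        (0.04, 0.50, "origination-hotspot"),
        (0.50, 0.04, "extinction-hotspot"),
        (0.04, 0.04, "turnover"),
        (0.96, 0.97, "stable"),
        (0.50, 0.50, "neutral"),
        (0.04, 0.96, "origination-hotspot"),
    ])
    def test_threshold_classes(self, tf, tl, expected):
        assert classify_cell(tf, tl) == expected

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            classify_cell(1.2, 0.5)


class TestDetectHotspots:
    def test_no_events_after_first_bin_flags_nothing(self, toy_scheme):
        """A world whose species all appear in the oldest bin has no
        origination signal anywhere later."""
        rng = np.random.default_rng(3)
        rows = []
        for i in range(30):
            lon, lat = rng.uniform(0, 10), rng.uniform(40, 50)
            rows.append((f"s{i}", f"L{i}", lon, lat, "T0"))
            rows.append((f"s{i}", f"M{i}", lon, lat, "T1"))
            rows.append((f"s{i}", f"N{i}", lon, lat, "T2"))
        raw = pd.DataFrame(rows, columns=["species", "locality", "lon", "lat",
                                          "bin"])
        raw["order"] = "Rodentia"; raw["hypsodonty"] = np.nan; raw["lophs"] = np.nan
        occ = normalize_occurrences(raw, toy_scheme)
        ranges = global_fad_lad(occ)
        grid = make_grid(0, 10, 40, 50, 5.0)
        with pytest.raises(ValueError, match="single-class"):
            # no first occurrence in the eligible window: nothing to model
            detect_hotspots(occ, ranges, toy_scheme, grid, 500.0, "first")

    def test_injected_cluster_is_flagged(self, small_world):
        from fossilhotspots.synthetic import (HotspotSpec, WorldConfig,
                                              generate_world)
        from fossilhotspots.data import normalize_occurrences
        hs = HotspotSpec(5.0, 46.0, 600.0, 3, "first", 0.5)
        world = generate_world(WorldConfig(seed=2, hotspots=[hs],
                                           background_first_frac=0.05))
        occ = normalize_occurrences(world.occurrences_raw, world.scheme)
        ranges = global_fad_lad(occ)
        grid = make_grid(-10, 25, 38, 55, 5.0)
        cells = detect_hotspots(occ, ranges, world.scheme, grid,
                                radius_km=400.0, event="first")
        focal = cells[cells["bin"] == "B4"]
        d = great_circle_km(focal["lon"].to_numpy(), focal["lat"].to_numpy(),
                            5.0, 46.0)
        assert (focal["klass"].to_numpy()[d < 600] == "hotspot").any()
        # bookkeeping invariants hold everywhere
        assert (cells["k_weighted"] <= cells["n_weighted"] + 1e-9).all()
        assert cells["tail_prob"].between(0, 1).all()

    def test_unsupported_cells_labelled(self, fig1_world, toy_scheme):
        ranges = global_fad_lad(fig1_world)
        grid = pd.DataFrame({"lon": [0.0, 150.0], "lat": [40.0, 0.0]})
        cells = detect_hotspots(fig1_world, ranges, toy_scheme, grid,
                                radius_km=500.0, event="first")
        far = cells[(cells["lon"] == 150.0)]
        assert (far["klass"] == "unsupported").all()

    def test_combined_classification_joins_directions(self, small_world):
        world, occ, ranges = small_world
        grid = make_grid(-10, 25, 38, 55, 10.0)
        first = detect_hotspots(occ, ranges, world.scheme, grid, 400.0, "first")
        last = detect_hotspots(occ, ranges, world.scheme, grid, 400.0, "last")
        combined = classify_cells(first, last)
        # only bins present in both windows survive the join
        assert set(combined["bin"]) == set(world.scheme.names[1:-1])
        assert set(combined["klass"]) <= {
            "origination-hotspot", "extinction-hotspot", "turnover",
            "stable", "neutral", "unsupported"}


def test_bh_adjustment_is_monotone_and_conservative(small_world):
    """Benjamini-Hochberg adjusted tails never fall below the raw tails and
    never flag a cell the raw classification did not."""
    from fossilhotspots.events import adjust_tails, detect_hotspots
    world, occ, ranges = small_world
    grid = make_grid(-10, 25, 38, 55, 10.0)
    cells = detect_hotspots(occ, ranges, world.scheme, grid, 400.0, "first")
    adj = adjust_tails(cells)
    sup = cells["klass"] != "unsupported"
    assert (adj.loc[sup, "tail_prob"].to_numpy()
            >= cells.loc[sup, "tail_prob"].to_numpy() - 1e-12).all()
    assert ((adj["klass"] == "hotspot") <= (cells["klass"] == "hotspot")).all()
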