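"""Drought-index chain: watershed tracing, anomalies, indicators, FHD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hydroshift as hs
from hydroshift.drought import (BasinGraph, aggregate_market, compute_anomalies,
                                delineate_watershed, drought_indicator,
                                market_mean_anomaly, rolling_anomaly,
                                watershed_runoff)
from hydroshift.errors import ValidationError
from hydroshift.months import month_range


def graph_from(downstream, cells=None):
    cells = cells or {b: np.array([0]) for b in downstream}
    return BasinGraph(downstream=downstream, cells=cells)


class TestDelineation:
    def test_isolated_basin_is_its_own_watershed(self):
        g = graph_from({"A": None})
        assert delineate_watershed(g, "A") == {"A"}

    def test_chain_traces_all_upstream(self):
        g = graph_from({"A": "B", "B": "C", "C": None})
        assert delineate_watershed(g, "C") == {"A", "B", "C"}
        assert delineate_watershed(g, "B") == {"A", "B"}
        assert delineate_watershed(g, "A") == {"A"}

    def test_tree_excludes_downstream(self):
        g = graph_from({"A": "C", "B": "C", "C": "D", "D": None})
        assert delineate_watershed(g, "C") == {"A", "B", "C"}

    def test_unknown_outlet_raises(self):
        g = graph_from({"A": None})
        with pytest.raises(KeyError):
            delineate_watershed(g, "Z")

    def test_cycle_rejected_at_construction(self):
        with pytest.raises(ValidationError, match="cycle"):
            graph_from({"A": "B", "B": "A"})

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_transitive_closure_oracle(self, seed):
        """BFS tracing equals networkx reachability on random forests."""
        import networkx as nx
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 200))
        ids = [f"b{k}" for k in range(n)]
        downstream = {}
        for k in range(n):
            # only point to lower indices => acyclic by construction
            j = int(rng.integers(-1, k)) if k else -1
            downstream[ids[k]] = None if j < 0 else ids[j]
        g = graph_from(downstream)
        dg = nx.DiGraph([(b, d) for b, d in downstream.items() if d])
        dg.add_nodes_from(ids)
        outlet = ids[int(rng.integers(n))]
        expected = nx.ancestors(dg, outlet) | {outlet}
        assert delineate_watershed(g, outlet) == expected


class TestWatershedRunoff:
    def grid(self, values):
        values = np.asarray(values, dtype=float)
        n_m, n_cells = values.shape
        months = month_range("2000-01", "2000-0%d" % n_m if n_m < 10 else "2000-12")
        from hydroshift.grids import make_grid
        return make_grid(values.reshape(n_m, 1, n_cells), months[:n_m],
                         [0.5], np.arange(n_cells) + 0.5)

    def test_uniform_grid_gives_constant_series(self):
        g = self.grid([[2.0, 2.0, 2.0]] * 3)
        graph = BasinGraph(downstream={"A": None}, cells={"A": np.array([0, 1, 2])})
        series = watershed_runoff(g, graph, {"A"})
        assert (series == 2.0).all()

    def test_two_cell_mean(self):
        g = self.grid([[1.0, 3.0]])
        graph = BasinGraph(downstream={"A": None, "B": None},
                           cells={"A": np.array([0]), "B": np.array([1])})
        assert watershed_runoff(g, graph, {"A", "B"}).iloc[0] == 2.0

    def test_adding_basin_at_mean_leaves_series_unchanged(self):
        g = self.grid([[1.0, 3.0, 2.0]])
        graph = BasinGraph(downstream={"A": None, "B": None, "C": None},
                           cells={"A": np.array([0]), "B": np.array([1]),
                                  "C": np.array([2])})
        before = watershed_runoff(g, graph, {"A", "B"})
        after = watershed_runoff(g, graph, {"A", "B", "C"})
        assert np.allclose(before.values, after.values)

    def test_empty_basin_set_rejected(self):
        g = self.grid([[1.0]])
        graph = BasinGraph(downstream={"A": None}, cells={"A": np.array([0])})
        with pytest.raises(ValidationError):
            watershed_runoff(g, graph, set())


class TestAnomalies:
    def test_constant_series_zero_anomalies(self):
        months = month_range("2000-01", "2004-12")
        s = pd.Series(1.7, index=months)
        ws = compute_anomalies(s, (2000, 2004))
        assert (ws.anomaly == 0).all()

    def test_repeated_seasonal_cycle_absorbed(self):
        months = month_range("2000-01", "2004-12")
        cyc = np.tile(1.0 + 0.5 * np.sin(2 * np.pi * np.arange(12) / 12), 5)
        ws = compute_anomalies(pd.Series(cyc, index=months), (2000, 2004))
        assert np.allclose(ws.anomaly.values, 0.0)

    def test_single_spike_splits_by_reference_share(self):
        """+0.2 in one reference month of 20 years: that month keeps
        0.2*(19/20); the same calendar month of other years gets -0.2/20."""
        months = month_range("2000-01", "2019-12")
        vals = np.ones(len(months))
        spike_idx = months.index("2007-06")
        vals[spike_idx] += 0.2
        ws = compute_anomalies(pd.Series(vals, index=months), (2000, 2019))
        assert ws.anomaly["2007-06"] == pytest.approx(0.2 * 19 / 20)
        assert ws.anomaly["2011-06"] == pytest.approx(-0.2 / 20)
        assert ws.anomaly["2011-07"] == pytest.approx(0.0, abs=1e-15)

    def test_climatology_zero_mean_property(self, small_world):
        """Per calendar month, reference-period anomalies average to zero."""
        w = small_world
        series = hs.drought.watershed_series_by_plant(
            w.runoff, w.basins, w.hydro_plants, w.config.reference_period)
        for ws in series.values():
            cal = ws.anomaly.index.str[5:7].astype(int)
            scale = np.abs(ws.runoff.values).max()
            for cm in range(1, 13):
                mean = ws.anomaly[cal == cm].mean()
                assert abs(mean) <= 1e-9 * scale

    def test_missing_reference_rejected(self):
        months = month_range("2000-01", "2000-12")
        with pytest.raises(ValidationError):
            compute_anomalies(pd.Series(1.0, index=months), (2010, 2012))


class TestRollingAndIndicator:
    def test_window_one_is_identity(self):
        s = pd.Series([1.0, -2.0, 3.0], index=month_range("2000-01", "2000-03"))
        assert rolling_anomaly(s, 1).equals(s)

    def test_trailing_three_month_mean(self):
        s = pd.Series([0.0, 0.0, 3.0], index=month_range("2000-01", "2000-03"))
        rolled = rolling_anomaly(s, 3)
        assert np.isnan(rolled.iloc[0]) and np.isnan(rolled.iloc[1])
        assert rolled.iloc[2] == pytest.approx(1.0)

    def test_nonstandard_window_warns(self):
        s = pd.Series(np.zeros(10), index=month_range("2000-01", "2000-10"))
        with pytest.warns(UserWarning, match="non-standard"):
            rolling_anomaly(s, 4)
        with pytest.raises(ValidationError):
            rolling_anomaly(s, 0)

    def test_indicator_definitions(self):
        idx = month_range("2000-01", "2000-03")
        rolled = pd.Series([0.5, -0.1, 0.0], index=idx)
        neg = drought_indicator(rolled, "negative")
        assert list(neg) == [0.0, 1.0, 0.0]  # exactly zero is not drought

    def test_severe_threshold_is_one_sd(self):
        idx = month_range("2000-01", "2000-01")
        rolled = pd.Series([-0.5 * 2.0], index=idx)  # half an sd below normal
        assert drought_indicator(rolled, "severe", sd=2.0).iloc[0] == 0.0
        assert drought_indicator(rolled, "negative").iloc[0] == 1.0

    def test_severe_requires_positive_sd(self):
        rolled = pd.Series([-1.0], index=month_range("2000-01", "2000-01"))
        with pytest.raises(ValidationError):
            drought_indicator(rolled, "severe", sd=0.0)

    def test_missing_propagates(self):
        rolled = pd.Series([np.nan, -1.0], index=month_range("2000-01", "2000-02"))
        out = drought_indicator(rolled, "negative")
        assert np.isnan(out.iloc[0]) and out.iloc[1] == 1.0


def plants_df(rows):
    return pd.DataFrame(rows, columns=["plant_id", "market", "capacity_mw"])


class TestMarketAggregation:
    def test_all_in_drought_gives_one(self):
        plants = plants_df([("p1", "A", 10.0), ("p2", "A", 90.0)])
        ind = pd.DataFrame(1.0, index=["p1", "p2"], columns=["2000-01"])
        out = aggregate_market(ind, plants)
        assert out.loc["A", "2000-01"] == 1.0

    def test_capacity_vs_arithmetic_weighting(self):
        plants = plants_df([("p1", "A", 100.0), ("p2", "A", 300.0)])
        ind = pd.DataFrame({"2000-01": [0.0, 1.0]}, index=["p1", "p2"])
        assert aggregate_market(ind, plants, "capacity").loc["A", "2000-01"] \
            == pytest.approx(0.75)
        assert aggregate_market(ind, plants, "arithmetic").loc["A", "2000-01"] \
            == pytest.approx(0.5)

    def test_market_without_hydro_is_missing(self):
        plants = plants_df([("p1", "A", 100.0)])
        ind = pd.DataFrame({"2000-01": [1.0]}, index=["p1"])
        out = aggregate_market(ind, plants, markets=["A", "B"])
        assert out.loc["A", "2000-01"] == 1.0
        assert np.isnan(out.loc["B", "2000-01"])

    def test_negative_capacity_rejected(self):
        plants = plants_df([("p1", "A", -5.0)])
        ind = pd.DataFrame({"2000-01": [1.0]}, index=["p1"])
        with pytest.raises(ValidationError):
            aggregate_market(ind, plants)

    def test_merged_markets_via_market_map(self):
        plants = plants_df([("p1", "A", 100.0), ("p2", "B", 100.0)])
        ind = pd.DataFrame({"2000-01": [1.0, 0.0]}, index=["p1", "p2"])
        merged = aggregate_market(ind, plants, market_map={"A": "AB", "B": "AB"})
        assert merged.loc["AB", "2000-01"] == pytest.approx(0.5)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_fhd_bounds_and_monotonicity(self, seed):
        """FHD stays in [0,1] and never decreases when more plants are
        flagged as in drought."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 8))
        plants = plants_df([(f"p{k}", "A", float(rng.uniform(1, 500)))
                            for k in range(n)])
        flags = rng.integers(0, 2, size=n).astype(float)
        ind = pd.DataFrame({"2000-01": flags}, index=plants["plant_id"])
        fhd = aggregate_market(ind, plants).loc["A", "2000-01"]
        assert 0.0 <= fhd <= 1.0
        k = int(rng.integers(n))
        more = flags.copy()
        more[k] = 1.0
        ind2 = pd.DataFrame({"2000-01": more}, index=plants["plant_id"])
        assert aggregate_market(ind2, plants).loc["A", "2000-01"] >= fhd - 1e-12

    def test_mean_anomaly_offsetting_and_weights(self):
        plants = plants_df([("p1", "A", 100.0), ("p2", "A", 100.0)])
        anom = pd.DataFrame({"2000-01": [1.0, -1.0]}, index=["p1", "p2"])
        assert market_mean_anomaly(anom, plants).loc["A", "2000-01"] \
            == pytest.approx(0.0)
        plants2 = plants_df([("p1", "A", 1.0), ("p2", "A", 3.0)])
        anom2 = pd.DataFrame({"2000-01": [0.0, -2.0]}, index=["p1", "p2"])
        assert market_mean_anomaly(anom2, plants2).loc["A", "2000-01"] \
            == pytest.approx(-1.5)
        single = plants_df([("p1", "A", 10.0)])
        anom3 = pd.DataFrame({"2000-01": [-0.7]}, index=["p1"])
        assert market_mean_anomaly(anom3, single).loc["A", "2000-01"] \
            == pytest.approx(-0.7)


def test_severe_never_exceeds_negative_indicator(small_world):
    """Pointwise, severe drought implies (ordinary) drought."""
    w = small_world
    table = w.truth.fhd
    ok = table["fhd_severe"] <= table["fhd"] + 1e-12
    assert ok[table["fhd"].notna()].all()
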