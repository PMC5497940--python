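"""Pressure layer construction, SPI gapfilling and matrix aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oceanhealth import (
    EngineConfig,
    GapfillError,
    aggregate_pressures,
    aggregate_resilience,
    anomaly_pressure,
    count_anomalous_weeks,
    fishing_pressure,
    oa_pressure,
    slr_pressure,
    spi_layer,
)


def _base(cells, value):
    return pd.DataFrame({"cell_id": cells["cell_id"], "value": value})


class TestOceanAcidification:
    def test_printed_equation(self, cells_one_region):
        # (3.0 - 2.0) / (3.0 - 1.0) = 0.5
        base = _base(cells_one_region, 3.0)
        annual = pd.DataFrame({"cell_id": [1, 2, 3], "year": 2016, "value": 2.0})
        out = oa_pressure(base, annual, cells_one_region)
        assert out["value"].iloc[0] == pytest.approx(0.5)

    def test_undersaturated_cells_at_maximum_pressure(self, cells_one_region):
        base = _base(cells_one_region, 3.0)
        annual = pd.DataFrame({"cell_id": [1, 2, 3], "year": 2016, "value": 0.9})
        out = oa_pressure(base, annual, cells_one_region)
        assert out["value"].iloc[0] == pytest.approx(1.0)

    def test_improved_saturation_is_zero_pressure(self, cells_one_region):
        base = _base(cells_one_region, 3.0)
        annual = pd.DataFrame({"cell_id": [1, 2, 3], "year": 2016, "value": 3.5})
        out = oa_pressure(base, annual, cells_one_region)
        assert out["value"].iloc[0] == pytest.approx(0.0)

    def test_indeterminate_baseline_excluded(self, cells_one_region):
        base = _base(cells_one_region, [0.9, 3.0, 3.0])
        annual = pd.DataFrame({"cell_id": [1, 2, 3], "year": 2016, "value": [2.0, 2.0, 2.0]})
        out = oa_pressure(base, annual, cells_one_region)
        assert out["value"].iloc[0] == pytest.approx(0.5)  # only cells 2,3 count

    @given(st.floats(min_value=1.01, max_value=5.0), st.floats(min_value=0.1, max_value=5.0),
           st.floats(min_value=0.1, max_value=5.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_declining_saturation(self, base_v, y1, y2):
        cells = pd.DataFrame({"cell_id": [1], "region_id": [1], "area_km2": [1.0], "coastal_flag": [True]})
        base = pd.DataFrame({"cell_id": [1], "value": [base_v]})
        lo, hi = sorted([y1, y2])
        p_hi = oa_pressure(base, pd.DataFrame({"cell_id": [1], "year": [1], "value": [lo]}), cells)
        p_lo = oa_pressure(base, pd.DataFrame({"cell_id": [1], "year": [1], "value": [hi]}), cells)
        assert p_hi["value"].iloc[0] >= p_lo["value"].iloc[0] - 1e-12
        assert 0.0 <= p_hi["value"].iloc[0] <= 1.0


class TestSeaLevelRise:
    def _monthly(self, cells, yearly_values):
        rows = []
        for year, v in yearly_values.items():
            for m in range(1, 13):
                rows.append(pd.DataFrame({"cell_id": cells["cell_id"], "year": year, "month": m, "value": v}))
        return pd.concat(rows, ignore_index=True)

    def test_falling_seas_are_zero_pressure(self, cells_one_region):
        monthly = self._monthly(cells_one_region, {y: -5.0 for y in range(2011, 2016)})
        out = slr_pressure(monthly, cells_one_region)
        assert (out["value"] == 0.0).all()

    def test_reference_maximum_scores_one(self, cells_one_region):
        monthly = self._monthly(cells_one_region, {2011: 2.0, 2012: 2.0, 2013: 2.0, 2014: 2.0, 2015: 8.0})
        out = slr_pressure(monthly, cells_one_region)
        assert out[out["year"] == 2015]["value"].iloc[0] == pytest.approx(1.0)

    def test_half_reference_scores_half(self, cells_one_region):
        monthly = self._monthly(cells_one_region, {2011: 4.0, 2012: 4.0, 2013: 4.0, 2014: 4.0, 2015: 8.0})
        out = slr_pressure(monthly, cells_one_region)
        assert out[out["year"] == 2011]["value"].iloc[0] == pytest.approx(0.5)

    def test_only_coastal_cells_used(self):
        cells = pd.DataFrame(
            {"cell_id": [1, 2], "region_id": [1, 1], "area_km2": [1.0, 100.0],
             "coastal_flag": [True, False]}
        )
        rows = []
        for m in range(1, 13):
            rows.append(pd.DataFrame({"cell_id": [1, 2], "year": 2015, "month": m, "value": [4.0, 400.0]}))
        out = slr_pressure(pd.concat(rows, ignore_index=True), cells)
        # the huge offshore cell is ignored: coastal cell is its own reference
        assert out["value"].iloc[0] == pytest.approx(1.0)


def _weekly(cells, n_years=6, base=10.0, spikes=None, start_year=2010):
    """Flat weekly series with optional (cell, year, week) spikes."""
    rows = []
    rng = np.random.default_rng(0)
    for cid in cells["cell_id"]:
        for i in range(n_years):
            year = start_year + i
            vals = np.full(52, base) + rng.normal(0, 0.5, 52)
            rows.append(pd.DataFrame({"cell_id": cid, "year": year, "week": np.arange(1, 53), "value": vals}))
    df = pd.concat(rows, ignore_index=True)
    if spikes:
        for cid, year, week in spikes:
            df.loc[(df.cell_id == cid) & (df.year == year) & (df.week == week), "value"] += 100.0
    return df


class TestAnomalyPressure:
    def test_constant_series_has_no_anomalies(self, cells_one_region):
        rows = []
        for cid in cells_one_region["cell_id"]:
            for year in range(2010, 2016):
                rows.append(pd.DataFrame({"cell_id": cid, "year": year, "week": np.arange(1, 53), "value": 7.0}))
        weekly = pd.concat(rows, ignore_index=True)
        counts = count_anomalous_weeks(weekly)
        assert (counts["count"] == 0).all()
        out = anomaly_pressure(weekly, cells_one_region)
        assert (out["value"] == 0.0).all()

    def test_yearly_count_capped_at_52(self, cells_one_region):
        # one year entirely anomalous: exactly 52 events, no more
        weekly = _weekly(cells_one_region, spikes=[(1, 2015, w) for w in range(1, 53)])
        counts = count_anomalous_weeks(weekly)
        c = counts[(counts.cell_id == 1) & (counts.year == 2015)]["count"].iloc[0]
        assert c == 52

    def test_reference_cell_scores_one(self, cells_one_region):
        weekly = _weekly(cells_one_region, spikes=[(1, 2015, w) for w in range(1, 11)])
        out = anomaly_pressure(weekly, cells_one_region)
        # cell 1's own 5-year sum is the q99.99 reference; its region mean is
        # diluted by quiet cells but bounded by 1
        assert out["value"].max() <= 1.0

    def test_adding_anomalous_week_never_decreases_pressure(self, cells_one_region):
        base_spikes = [(1, 2014, 1), (1, 2015, 2)]
        w1 = _weekly(cells_one_region, spikes=base_spikes)
        w2 = _weekly(cells_one_region, spikes=base_spikes + [(1, 2015, 30)])
        p1 = anomaly_pressure(w1, cells_one_region)
        p2 = anomaly_pressure(w2, cells_one_region)
        y = p1["year"].max()
        v1 = p1[p1.year == y]["value"].iloc[0]
        v2 = p2[p2.year == y]["value"].iloc[0]
        # same reference regime: more anomalous weeks, at least as much pressure
        assert v2 >= v1 - 1e-12


class TestFishingPressure:
    def _inputs(self, cells, catch=(10.0, 10.0, 10.0), npp=(1.0, 1.0, 1.0), split=0.5):
        years = [2015, 2016]
        ind = pd.concat(
            [pd.DataFrame({"cell_id": cells["cell_id"], "year": y, "value": catch}) for y in years],
            ignore_index=True,
        )
        art = ind.copy()
        npp_df = pd.DataFrame({"cell_id": cells["cell_id"], "value": npp})
        gear = pd.DataFrame({"region_id": [1, 1], "year": years, "value": split})
        return ind, art, npp_df, gear

    def test_zero_catch_means_zero_pressure(self, cells_one_region):
        ind, art, npp, gear = self._inputs(cells_one_region, catch=(0.0, 0.0, 0.0))
        out = fishing_pressure(ind, art, npp, gear, cells_one_region)
        for layer in ("fp_com_hb", "fp_com_lb", "fp_art_lb"):
            assert (out[layer]["value"] == 0.0).all()

    def test_full_high_bycatch_split_zeroes_low_layer(self, cells_one_region):
        ind, art, npp, gear = self._inputs(cells_one_region, split=1.0)
        out = fishing_pressure(ind, art, npp, gear, cells_one_region)
        assert (out["fp_com_lb"]["value"] == 0.0).all()
        assert (out["fp_com_hb"]["value"] > 0.0).any()

    def test_productivity_standardisation_ratio(self, cells_one_region):
        # same catch, doubled NPP -> half the standardized pressure
        ind, art, npp, gear = self._inputs(cells_one_region, npp=(1.0, 2.0, 1.0))
        out = fishing_pressure(ind, art, npp, gear, cells_one_region)
        # compare via cell-level before region aggregation is hidden; use two
        # single-cell regions instead
        cells2 = pd.DataFrame(
            {"cell_id": [1, 2], "region_id": [1, 2], "area_km2": [1.0, 1.0],
             "coastal_flag": [True, True]}
        )
        ind2 = pd.DataFrame({"cell_id": [1, 2], "year": 2016, "value": [10.0, 10.0]})
        npp2 = pd.DataFrame({"cell_id": [1, 2], "value": [1.0, 2.0]})
        gear2 = pd.DataFrame({"region_id": [1, 2], "year": 2016, "value": [0.5, 0.5]})
        out2 = fishing_pressure(ind2, ind2, npp2, gear2, cells2)
        vals = out2["fp_art_lb"].set_index("region_id")["value"]
        # small deviation from exactly 1/2 comes from quantile interpolation
        # in the empirical rescaling reference
        assert vals[2] == pytest.approx(vals[1] / 2.0, rel=1e-3)

    def test_missing_npp_cell_excluded(self, cells_one_region):
        ind, art, _, gear = self._inputs(cells_one_region)
        npp = pd.DataFrame({"cell_id": [1, 2], "value": [1.0, 1.0]})  # cell 3 missing
        out = fishing_pressure(ind, art, npp, gear, cells_one_region)
        assert not out["fp_art_lb"].empty


def _regions_df(n=5, uninhabited=()):
    return pd.DataFrame(
        {"region_id": range(1, n + 1), "name": [f"r{i}" for i in range(n)],
         "eez_area_km2": 1.0, "inhabited": [i + 1 not in uninhabited for i in range(n)],
         "un_georegion": ["Africa", "Asia", "Europe", "Oceania", "Americas"][:n]}
    )


def _components(values_by_region, year=2016):
    rows = []
    for rid, vals in values_by_region.items():
        for k, v in enumerate(vals):
            if v is None:
                continue
            d, c = divmod(k, 4)
            rows.append({"region_id": rid, "year": year, "category": f"comp_{d+1}_{c+1}", "value": v})
    return pd.DataFrame(rows)


class TestSpiLayer:
    def _wgi(self, n=5):
        return pd.DataFrame({"region_id": range(1, n + 1), "year": 2016, "value": 0.5})

    def test_nested_means(self):
        comps = _components({rid: [60.0] * 12 for rid in range(1, 6)})
        out = spi_layer(comps, self._wgi(), _regions_df())
        assert np.allclose(out["spi"], 60.0)
        assert np.allclose(out["pressure"], 0.4)
        assert np.allclose(out["resilience"], 0.6)

    def test_no_missing_data_is_identity(self):
        rng = np.random.default_rng(1)
        vals = {rid: list(rng.uniform(20, 90, 12)) for rid in range(1, 6)}
        comps = _components(vals)
        out = spi_layer(comps, self._wgi(), _regions_df()).set_index("region_id")
        for rid in range(1, 6):
            arr = np.array(vals[rid]).reshape(3, 4)
            assert out.loc[rid, "spi"] == pytest.approx(arr.mean(axis=1).mean())

    def test_linear_components_imputed_exactly(self):
        # every component is affine in a common signal: imputation is exact
        signal = {1: 30.0, 2: 45.0, 3: 60.0, 4: 75.0, 5: 90.0}
        slopes = np.linspace(0.5, 1.5, 12)
        inters = np.linspace(-5, 5, 12)
        vals = {rid: [inters[k] + slopes[k] * s for k in range(12)] for rid, s in signal.items()}
        truth = vals[3][7]
        vals[3][7] = None  # blank one component
        comps = _components(vals)
        out = spi_layer(comps, self._wgi(), _regions_df()).set_index("region_id")
        expected_spi = np.array([inters[k] + slopes[k] * 60.0 for k in range(12)]).reshape(3, 4).mean(axis=1).mean()
        assert out.loc[3, "spi"] == pytest.approx(expected_spi, abs=1e-6)

    def test_uninhabited_regions_receive_no_score(self):
        comps = _components({rid: [60.0] * 12 for rid in range(1, 5)})
        out = spi_layer(comps, self._wgi(), _regions_df(uninhabited=(5,)))
        assert 5 not in set(out["region_id"])

    def test_fully_missing_region_predicted_from_governance(self):
        vals = {rid: [60.0] * 12 for rid in range(1, 5)}
        comps = _components(vals)  # region 5 entirely absent
        wgi = self._wgi()
        out = spi_layer(comps, wgi, _regions_df()).set_index("region_id")
        assert 5 in out.index
        assert 0 <= out.loc[5, "spi"] <= 100

    def test_underdetermined_gapfill_raises(self):
        comps = _components({1: [60.0] * 11 + [None], 2: [50.0] * 12})
        with pytest.raises(GapfillError):
            spi_layer(comps, self._wgi(2), _regions_df(2))


def _layer(value_by_region, year=2016):
    return pd.DataFrame(
        {"region_id": list(value_by_region), "year": year, "value": list(value_by_region.values())}
    )


class TestAggregation:
    def _pm(self, rows):
        return pd.DataFrame(rows, columns=["goal_id", "layer_id", "weight", "category"])

    def _rm(self, rows):
        return pd.DataFrame(rows, columns=["goal_id", "layer_id", "rtype", "addresses_category"])

    def test_all_zero_layers_give_zero_pressure(self, cfg):
        pm = self._pm([("G", "a", 3, "pollution"), ("G", "s", 1, "social")])
        layers = {"a": _layer({1: 0.0}), "s": _layer({1: 0.0})}
        out = aggregate_pressures(layers, pm, cfg)
        assert out["pressure"].iloc[0] == pytest.approx(0.0)

    def test_all_one_layers_give_one(self, cfg):
        pm = self._pm([("G", "a", 3, "pollution"), ("G", "b", 1, "climate change"),
                       ("G", "s", 1, "social")])
        layers = {k: _layer({1: 1.0}) for k in "abs"}
        out = aggregate_pressures(layers, pm, cfg)
        assert out["pressure"].iloc[0] == pytest.approx(1.0)

    def test_gamma_combination(self, cfg):
        # one ecological category at 0.4, social at 0.8, gamma 0.5 -> 0.6
        pm = self._pm([("G", "a", 2, "pollution"), ("G", "s", 1, "social")])
        layers = {"a": _layer({1: 0.4}), "s": _layer({1: 0.8})}
        out = aggregate_pressures(layers, pm, cfg)
        assert out["pressure"].iloc[0] == pytest.approx(0.6)

    def test_rank_weighted_mean_within_category(self, cfg):
        pm = self._pm([("G", "a", 3, "pollution"), ("G", "b", 1, "pollution")])
        layers = {"a": _layer({1: 1.0}), "b": _layer({1: 0.0})}
        out = aggregate_pressures(layers, pm, cfg)
        assert out["pressure"].iloc[0] == pytest.approx(0.75)

    def test_permutation_and_duplication_invariance(self, cfg):
        pm1 = self._pm([("G", "a", 2, "pollution"), ("G", "b", 1, "climate change")])
        pm2 = self._pm([("G", "b", 1, "climate change"), ("G", "a", 2, "pollution")])
        layers = {"a": _layer({1: 0.3}), "b": _layer({1: 0.7})}
        v1 = aggregate_pressures(layers, pm1, cfg)["pressure"].iloc[0]
        v2 = aggregate_pressures(layers, pm2, cfg)["pressure"].iloc[0]
        assert v1 == pytest.approx(v2)
        # duplicating an identical layer within its category changes nothing
        pm3 = self._pm([("G", "a", 2, "pollution"), ("G", "a2", 2, "pollution"),
                        ("G", "b", 1, "climate change")])
        layers3 = {**layers, "a2": _layer({1: 0.3})}
        v3 = aggregate_pressures(layers3, pm3, cfg)["pressure"].iloc[0]
        assert v3 == pytest.approx(v1)

    def test_uninhabited_region_drops_social_pressure(self, cfg):
        pm = self._pm([("G", "a", 2, "pollution"), ("G", "s", 1, "social")])
        layers = {"a": _layer({1: 0.4, 2: 0.4}), "s": _layer({1: 0.8, 2: 0.8})}
        regions = _regions_df(2, uninhabited=(2,))
        out = aggregate_pressures(layers, pm, cfg, regions).set_index("region_id")
        assert out.loc[1, "pressure"] == pytest.approx(0.6)
        assert out.loc[2, "pressure"] == pytest.approx(0.4)

    def test_resilience_all_ones(self, cfg):
        rm = self._rm([("G", "ra", "regulatory", "pollution"),
                       ("G", "e", "ecological", None), ("G", "s", "social", None)])
        layers = {k: _layer({1: 1.0}) for k in ("ra", "e", "s")}
        out = aggregate_resilience(layers, rm, cfg)
        assert out["resilience"].iloc[0] == pytest.approx(1.0)

    def test_resilience_mean_of_components(self, cfg):
        rm = self._rm([("G", "ra", "regulatory", "pollution"),
                       ("G", "e", "ecological", None), ("G", "s", "social", None)])
        layers = {"ra": _layer({1: 0.6}), "e": _layer({1: 0.6}), "s": _layer({1: 0.6})}
        out = aggregate_resilience(layers, rm, cfg)
        assert out["resilience"].iloc[0] == pytest.approx(0.6)

    def test_duplicate_regulatory_layer_value_leaves_r_unchanged(self, cfg):
        rm1 = self._rm([("G", "ra", "regulatory", "pollution"),
                        ("G", "e", "ecological", None)])
        rm2 = self._rm([("G", "ra", "regulatory", "pollution"),
                        ("G", "rb", "regulatory", "pollution"),
                        ("G", "e", "ecological", None)])
        layers = {"ra": _layer({1: 0.5}), "rb": _layer({1: 0.5}), "e": _layer({1: 0.9})}
        v1 = aggregate_resilience(layers, rm1, cfg)["resilience"].iloc[0]
        v2 = aggregate_resilience(layers, rm2, cfg)["resilience"].iloc[0]
        assert v1 == pytest.approx(v2)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_pressure_bounded_for_arbitrary_layers(self, cfg, vals):
        pm = self._pm([("G", "a", 3, "pollution"), ("G", "b", 2, "fishing pressure"),
                       ("G", "s", 1, "social")])
        layers = {k: _layer({1: v}) for k, v in zip("abs", vals)}
        out = aggregate_pressures(layers, pm, cfg)
        assert 0.0 <= out["pressure"].iloc[0] <= 1.0
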