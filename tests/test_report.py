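import json

import numpy as np
import pandas as pd
import pytest

import spataft as sp
from conftest import plain_dataset
from test_compare import crafted_samples


def samples_with(beta_draws, intercept=None, s_draws=None, spec=None,
                 state_labels=("0",)):
    beta_draws = np.atleast_2d(np.asarray(beta_draws, dtype=float))
    D = beta_draws.shape[0]
    s = np.zeros((D, len(state_labels))) if s_draws is None \
        else np.asarray(s_draws, dtype=float)
    return sp.PosteriorSamples(
        intercept=np.zeros(D) if intercept is None else np.asarray(intercept),
        beta=beta_draws, log_shape=np.zeros(D),
        u=np.empty((D, 0)), s=s, tau_u=np.ones(D), tau_s=np.ones(D),
        pointwise_loglik=np.zeros((D, 1)),
        coef_labels=tuple(f"b{j}" for j in range(beta_draws.shape[1])),
        state_labels=tuple(state_labels), acceptance={},
        spec=spec or sp.ModelSpec(), seed=0)


class TestFixedEffectsTable:
    def test_constant_draws_reproduce_reported_rounding(self):
        samples = samples_with(np.full((50, 1), 0.343))
        table = sp.fixed_effects_table(samples)
        row = table.iloc[1]
        assert row["mean"] == pytest.approx(0.343)
        assert round(row["time_ratio"], 2) == 1.41

    def test_zero_draws(self):
        table = sp.fixed_effects_table(samples_with(np.zeros((20, 1))))
        row = table.iloc[1]
        assert row["time_ratio"] == 1.0
        assert row["ci_low"] == row["ci_high"] == 0.0

    def test_symmetric_draws_give_unit_ratio(self):
        draws = np.concatenate([np.full(30, 0.7), np.full(30, -0.7)])
        table = sp.fixed_effects_table(samples_with(draws[:, None]))
        assert table.iloc[1]["mean"] == pytest.approx(0.0)
        assert table.iloc[1]["time_ratio"] == pytest.approx(1.0)

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            sp.fixed_effects_table(samples_with(np.zeros((5, 2))),
                                   labels=("only_one",))

    def test_csv_round_trip_preserves_precision(self, tmp_path):
        rng = np.random.default_rng(0)
        table = sp.fixed_effects_table(
            samples_with(rng.normal(size=(100, 3))))
        path = tmp_path / "fe.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        for col in ("mean", "sd", "ci_low", "ci_high"):
            assert back[col].to_numpy() == pytest.approx(
                table[col].to_numpy(), rel=1e-12)


class TestStatusCrosstab:
    def build_counts_dataset(self, levels, censored_counts, event_counts):
        vals, times, events = [], [], []
        for lv, c, e in zip(levels, censored_counts, event_counts):
            vals += [lv] * (c + e)
            times += [20.0] * c + [10.0] * e
            events += [0] * c + [1] * e
        return plain_dataset(times, events,
                             factors={"fac": (tuple(levels), vals)})

    def test_survey_table_percentages(self):
        # printed survey counts: female/male heads among censored
        ds = self.build_counts_dataset(("female", "male"),
                                       (30085, 6085), (81541, 9834))
        table = sp.status_crosstab(ds, "fac")
        female = table.loc[table.level == "female"].iloc[0]
        assert female["censored"] == 30085
        assert female["censored_pct"] == pytest.approx(83.18, abs=0.005)
        assert female["event_pct"] == pytest.approx(89.24, abs=0.005)

    def test_wealth_event_column_share(self):
        counts = (27204, 23769, 19433, 13868, 7101)
        ds = self.build_counts_dataset(
            ("poorest", "poorer", "middle", "richer", "richest"),
            (0, 0, 0, 0, 1), counts)
        table = sp.status_crosstab(ds, "fac")
        richest = table.loc[table.level == "richest"].iloc[0]
        assert richest["event_pct"] == pytest.approx(7.77, abs=0.005)

    def test_single_level_factor_is_100_percent(self):
        ds = self.build_counts_dataset(("only",), (3,), (5,))
        table = sp.status_crosstab(ds, "fac")
        assert table["censored_pct"].iloc[0] == 100.0
        assert table["event_pct"].iloc[0] == 100.0

    def test_columns_sum_to_status_totals(self, sim_small):
        _, dataset, _ = sim_small
        table = sp.status_crosstab(dataset, "x1")
        assert table["censored"].sum() == int((dataset.events == 0).sum())
        assert table["event"].sum() == int(dataset.events.sum())
        assert table["censored_pct"].sum() == pytest.approx(100.0)

    def test_unknown_factor_rejected(self, sim_small):
        _, dataset, _ = sim_small
        with pytest.raises(KeyError):
            sp.status_crosstab(dataset, "nope")


class TestSpatialEffects:
    def test_zero_draws_all_unit_ratio_near_null(self):
        g = sp.make_lattice_graph(2, 2)
        samples = samples_with(np.zeros((10, 1)),
                               s_draws=np.zeros((10, 4)),
                               state_labels=g.labels)
        table = sp.bin_spatial_effects(
            sp.spatial_effect_table(samples, g))
        assert np.all(table["time_ratio"] == 1.0)
        assert set(table["bin_label"]) == {"near-null"}

    def test_constant_effect_exponentiates(self):
        g = sp.AdjacencyGraph(("a", "b"), ((0, 1, 1.0),))
        s = np.tile([0.2, -0.2], (15, 1))
        samples = samples_with(np.zeros((15, 1)), s_draws=s,
                               state_labels=g.labels)
        table = sp.spatial_effect_table(samples, g)
        assert table.loc[table.state == "a", "time_ratio"].iloc[0] == \
            pytest.approx(np.exp(0.2))

    def test_component_zero_sum_of_posterior_means(self, fitted_small):
        cfg, *_, samples = fitted_small
        table = sp.spatial_effect_table(samples, cfg.graph)
        assert table["mean"].sum() == pytest.approx(0.0, abs=1e-9)

    def test_requires_icar_spec(self):
        g = sp.AdjacencyGraph(("a",), ())
        samples = samples_with(
            np.zeros((5, 1)),
            spec=sp.ModelSpec(include_icar=False), state_labels=g.labels)
        with pytest.raises(ValueError, match="no ICAR"):
            sp.spatial_effect_table(samples, g)


class TestBinning:
    def test_direct_lookup_with_break_ties_upward(self):
        table = pd.DataFrame({
            "state": list("abcdef"),
            "mean": np.zeros(6),
            "time_ratio": [0.5, 0.9, 1.0, 1.2, 1.9, 0.95]})
        out = sp.bin_spatial_effects(table, breaks=(0.8, 0.95, 1.05, 1.24))
        assert out["bin"].tolist() == [1, 2, 3, 4, 5, 3]  # 0.95 -> upper

    def test_non_monotone_breaks_rejected(self):
        table = pd.DataFrame({"state": ["a"], "mean": [0.0],
                              "time_ratio": [1.0]})
        with pytest.raises(ValueError, match="increasing"):
            sp.bin_spatial_effects(table, breaks=(1.1, 0.9))

    def test_label_count_checked(self):
        table = pd.DataFrame({"state": ["a"], "mean": [0.0],
                              "time_ratio": [1.0]})
        with pytest.raises(ValueError, match="labels"):
            sp.bin_spatial_effects(table, breaks=(0.9, 1.1),
                                   labels=("lo", "hi"))


def square(x0, y0):
    return [[[x0, y0], [x0 + 1, y0], [x0 + 1, y0 + 1], [x0, y0 + 1],
             [x0, y0]]]


def toy_geojson(names):
    return {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature",
             "properties": {"name": nm},
             "geometry": {"type": "Polygon",
                          "coordinates": square(i, 0)}}
            for i, nm in enumerate(names)]}


class TestChoropleth:
    def make_table(self, states):
        return sp.bin_spatial_effects(pd.DataFrame({
            "state": states,
            "mean": np.linspace(-0.3, 0.3, len(states)),
            "time_ratio": np.exp(np.linspace(-0.3, 0.3, len(states)))}))

    def test_complete_join(self, tmp_path):
        names = ["n1", "n2", "n3", "n4"]
        out = tmp_path / "joined.geojson"
        summary = sp.export_choropleth(
            self.make_table(names), toy_geojson(names), "name", out,
            tmp_path / "map.png")
        assert summary == {"matched": 4, "unmatched_features": 0}
        joined = json.loads(out.read_text())
        assert all("time_ratio" in f["properties"]
                   for f in joined["features"])
        assert (tmp_path / "map.png").exists()

    def test_case_and_whitespace_normalised(self, tmp_path):
        summary = sp.export_choropleth(
            self.make_table(["State One"]), toy_geojson(["  state   one "]),
            "name", tmp_path / "j.geojson")
        assert summary["matched"] == 1

    def test_misspelled_state_named(self, tmp_path):
        with pytest.raises(KeyError, match="n9"):
            sp.export_choropleth(
                self.make_table(["n1", "n9"]), toy_geojson(["n1", "n2"]),
                "name", tmp_path / "j.geojson")

    def test_rerun_is_byte_identical(self, tmp_path):
        names = ["a", "b", "c"]
        p1, p2 = tmp_path / "a.geojson", tmp_path / "b.geojson"
        sp.export_choropleth(self.make_table(names), toy_geojson(names),
                             "name", p1)
        sp.export_choropleth(self.make_table(names), toy_geojson(names),
                             "name", p2)
        assert p1.read_bytes() == p2.read_bytes()
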