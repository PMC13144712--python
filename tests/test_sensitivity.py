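import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from woodfrog.sensitivity import (
    CATEGORIES, EmergenceSimulator, MicroclimateSensitivitySimulator,
    ParameterSpec, category_attribution, default_parameter_table,
    inflate_trait_ranges, microclimate_sensitivity, oat_design, read_plan,
    read_parameter_table, run_oat, write_parameter_table, write_plan,
)


def _specs(n=5, category="behavior"):
    return [ParameterSpec(f"x{i}", category, 0.0, 1.0, 2.0, f"traits.x{i}")
            for i in range(n)]


class TestOatDesign:
    def test_two_p_plus_one_runs(self):
        plan = oat_design(_specs(5))
        assert len(plan) == 11
        assert (plan["level"] == "baseline").sum() == 1

    def test_degenerate_span_contributes_no_runs(self):
        specs = _specs(3) + [ParameterSpec("fixed", "behavior", 1, 1, 1,
                                           "traits.fixed")]
        assert len(oat_design(specs)) == 7

    def test_plan_round_trips_through_csv(self, tmp_path):
        plan = oat_design(_specs(4))
        path = tmp_path / "plan.csv"
        write_plan(plan, path)
        pd.testing.assert_frame_equal(read_plan(path), plan)

    def test_duplicate_names_rejected(self):
        specs = _specs(2) + [ParameterSpec("x0", "behavior", 0, 1, 2, "traits.x0")]
        with pytest.raises(ValueError, match="duplicate"):
            oat_design(specs)

    def test_parameter_table_round_trip(self, tmp_path):
        table = default_parameter_table()
        path = tmp_path / "params.csv"
        write_parameter_table(table, path)
        back = read_parameter_table(path)
        assert back == table


class TestRunOat:
    def test_linear_response_importance_equals_span(self):
        specs = [ParameterSpec("x", "behavior", 0.0, 1.0, 2.0, "traits.x")]
        plan = oat_design(specs)
        results = run_oat(plan, lambda ov: 100.0 + 5.0 * ov.get("x", 1.0), specs)
        assert results[0].importance == pytest.approx(10.0)

    def test_non_monotone_response_uses_range_of_means(self):
        specs = [ParameterSpec("x", "behavior", 0.0, 1.0, 2.0, "traits.x")]
        plan = oat_design(specs)
        response = {0.0: 100.0, 1.0: 90.0, 2.0: 100.0}
        results = run_oat(plan, lambda ov: response[ov.get("x", 1.0)], specs)
        assert results[0].importance == pytest.approx(10.0)

    def test_zero_span_parameter_has_zero_importance(self):
        specs = [ParameterSpec("x", "behavior", 1.0, 1.0, 1.0, "traits.x")]
        plan = oat_design(specs)
        results = run_oat(plan, lambda ov: 100.0, specs)
        assert results[0].importance == 0.0

    def test_baseline_executed_exactly_once(self):
        specs = _specs(6)
        plan = oat_design(specs)
        calls = {"baseline": 0, "total": 0}

        def sim(overrides):
            calls["total"] += 1
            if not overrides:
                calls["baseline"] += 1
            return 100.0 + sum(overrides.values())

        run_oat(plan, sim, specs)
        assert calls["baseline"] == 1
        assert calls["total"] == 2 * len(specs) + 1

    def test_equals_naive_three_runs_per_parameter(self):
        specs = _specs(4)
        plan = oat_design(specs)

        def sim(overrides):
            return 100.0 + sum(v ** 2 for v in overrides.values())

        shared = run_oat(plan, sim, specs)
        for p in shared:
            lo = sim({p.parameter: 0.0})
            mid = sim({})
            hi = sim({p.parameter: 2.0})
            naive = max(lo, mid, hi) - min(lo, mid, hi)
            assert p.importance == pytest.approx(naive)

    def test_all_runs_missing_is_flagged_not_zero(self):
        specs = [ParameterSpec("x", "behavior", 0.0, 1.0, 2.0, "traits.x")]
        plan = oat_design(specs)
        results = run_oat(plan, lambda ov: float("nan"), specs)
        assert results[0].undefined
        assert np.isnan(results[0].importance)


class TestAttribution:
    @staticmethod
    def _result(name, cat, importance):
        from woodfrog.sensitivity import SensitivityResult
        return SensitivityResult(name, cat, 0, 0, 0, importance)

    def test_normalization_arithmetic(self):
        res = [self._result("a", "meteorology", 30.0),
               self._result("b", "geography", 20.0),
               self._result("c", "behavior", 10.0)]
        table = category_attribution(res).set_index("category")["share_pct"]
        assert table["meteorology"] == pytest.approx(50.0)
        assert table["geography"] == pytest.approx(100 / 3)
        assert table["behavior"] == pytest.approx(100 / 6)

    def test_single_nonzero_parameter_takes_all(self):
        res = [self._result("a", "morphology", 5.0),
               self._result("b", "physiology", 0.0)]
        table = category_attribution(res).set_index("category")["share_pct"]
        assert table["morphology"] == 100.0

    def test_zero_total_importance_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            category_attribution([self._result("a", "behavior", 0.0)])

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.001, 100), min_size=1, max_size=10))
    def test_shares_always_sum_to_100(self, importances):
        res = [self._result(f"p{i}", CATEGORIES[i % 5], v)
               for i, v in enumerate(importances)]
        assert category_attribution(res)["share_pct"].sum() == pytest.approx(100.0)

    def test_known_driver_recovery(self):
        """A rigged simulator where only one parameter matters gives it
        100% of the attribution and everyone else exactly 0."""
        specs = [ParameterSpec("driver", "meteorology", -1.0, 0.0, 1.0, "traits.a"),
                 ParameterSpec("inert1", "behavior", 0.0, 1.0, 2.0, "traits.b"),
                 ParameterSpec("inert2", "morphology", 5.0, 6.0, 7.0, "traits.c")]
        plan = oat_design(specs)
        results = run_oat(plan, lambda ov: 100.0 + 4.0 * ov.get("driver", 0.0), specs)
        table = category_attribution(results).set_index("category")
        assert table.loc["meteorology", "share_pct"] == 100.0
        assert table.loc["behavior", "share_pct"] == 0.0
        assert table.loc["morphology", "share_pct"] == 0.0


class TestInflation:
    def test_explicit_override_for_consecutive_hours(self):
        specs = [ParameterSpec("favorable_consecutive_hours", "behavior",
                               1, 12, 24, "traits.favorable_consecutive_hours",
                               inflatable=True, lower_bound=1)]
        out = inflate_trait_ranges(specs,
                                   {"favorable_consecutive_hours": (1, 96)})
        assert (out[0].min, out[0].max) == (1.0, 96.0)
        assert out[0].mean == 12

    def test_factor_one_is_identity(self):
        specs = default_parameter_table()
        assert inflate_trait_ranges(specs, 1.0) == specs

    def test_mass_widening_arithmetic_with_clipping(self):
        specs = [ParameterSpec("mass", "morphology", 7.6, 11.6, 15.6,
                               "traits.mass", inflatable=True, lower_bound=0.5)]
        out = inflate_trait_ranges(specs, 2.0)
        assert out[0].min == pytest.approx(3.6)
        assert out[0].max == pytest.approx(19.6)
        clipped = inflate_trait_ranges(specs, 5.0)
        assert clipped[0].min == 0.5  # physical bound

    def test_non_inflatable_untouched(self):
        specs = [ParameterSpec("elevation", "geography", 136, 236, 336,
                               "site.elevation", inflatable=False)]
        assert inflate_trait_ranges(specs, 3.0) == specs


class TestMicroclimateSensitivity:
    @staticmethod
    def _fake_sim(gains):
        """Microclimate responses linear in the overrides."""
        def sim(overrides):
            x = sum(overrides.values())
            return {k: g * x for k, g in gains.items()}
        return sim

    def test_additive_temperature_offset_passes_through(self):
        specs = [ParameterSpec("air_temp_offset", "meteorology", -1.0, 0.0, 1.0,
                               "weather.temp_offset")]
        gains = {"air_min": 1.0, "air_max": 1.0, "soil_min": 1.0, "soil_max": 1.0}
        table = microclimate_sensitivity(specs, self._fake_sim(gains))
        for key in gains:
            assert table[f"importance_{key}"].iloc[0] == pytest.approx(2.0)

    def test_zero_span_parameter_all_zero(self):
        specs = [ParameterSpec("fixed", "geography", 2.0, 2.0, 2.0,
                               "site.elevation")]
        table = microclimate_sensitivity(specs, self._fake_sim(
            {k: 1.0 for k in MicroclimateSensitivitySimulator.RESPONSES}))
        assert (table.filter(like="importance_").iloc[0] == 0.0).all()

    def test_endogenous_parameters_rejected(self):
        specs = [ParameterSpec("mass", "morphology", 7.6, 11.6, 15.6, "traits.mass")]
        with pytest.raises(ValueError, match="endogenous"):
            microclimate_sensitivity(specs, self._fake_sim({}))

    def test_canopy_acts_more_on_warm_tail(self, small_weather, small_ponds):
        """Real microclimate: canopy damping removes daytime warmth, so
        air-temperature maxima are more canopy-sensitive than minima."""
        specs = [ParameterSpec("canopy_cover", "geography", 0.0, 0.45, 0.9,
                               "site.canopy_cover")]
        pond = next(small_ponds.itertuples(index=False))
        sim = MicroclimateSensitivitySimulator(small_weather, pond, specs)
        table = microclimate_sensitivity(specs, sim)
        assert table["importance_air_max"].iloc[0] > table["importance_air_min"].iloc[0]


class TestEmergenceSimulator:
    def test_real_oat_recovers_exogenous_dominance(self, small_weather, small_ponds):
        """On the default synthetic configuration the combined exogenous
        (meteorology + geography) share exceeds the combined morphology +
        physiology share — the study's qualitative headline."""
        specs = default_parameter_table()
        pond = next(small_ponds.iloc[[2]].itertuples(index=False))
        sim = EmergenceSimulator(small_weather, pond, specs)
        plan = oat_design(specs)
        results = run_oat(plan, sim, specs)
        assert sim.n_calls == 2 * len(specs) + 1
        shares = category_attribution(results).set_index("category")["share_pct"]
        exo = shares["meteorology"] + shares["geography"]
        endo_passive = shares["morphology"] + shares["physiology"]
        assert exo > endo_passive

    def test_temperature_offset_binding_shifts_forcing(self, small_weather,
                                                       small_ponds):
        specs = [ParameterSpec("air_temp_offset", "meteorology", -2.0, 0.0, 2.0,
                               "weather.temp_offset")]
        pond = next(small_ponds.itertuples(index=False))
        sim = EmergenceSimulator(small_weather, pond, specs)
        warm = sim({"air_temp_offset": 2.0})
        base = sim({})
        assert warm <= base  # warming never delays mean emergence
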