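import numpy as np
import pytest

from ohca_survival import (
    DecayParams,
    Municipality,
    build_scenario_table,
    compute_gains,
    scenario_survival,
    sensitivity_over_r,
    to_percent,
)

# Printed scenario table: percent survival per municipality for shifts
# 0/1/5/10 min (source mixes truncation and rounding; compared at +-0.1 pp).
PUBLISHED_TABLE = {
    "Bergen": [47.7, 51.2, 68.5, 98.5],
    "Tokke": [29.9, 32.2, 43.0, 61.9],
    "Lurøy": [9.2, 9.9, 13.3, 19.1],
    "Sørfold": [19.4, 20.8, 27.8, 40.0],
}


class TestScenarioTable:
    def test_reproduces_published_values(self, norwegian_cohort, default_params):
        table = build_scenario_table(norwegian_cohort, default_params, [1, 5, 10])
        for _, row in table.data.iterrows():
            expected = PUBLISHED_TABLE[row["municipality"]]
            got = [100 * row[c] for c in table.survival_columns()]
            assert got == pytest.approx(expected, abs=0.1)

    def test_empty_cohort_gives_empty_table(self, default_params):
        table = build_scenario_table([], default_params, [1, 5, 10])
        assert len(table.data) == 0
        assert table.survival_columns() == [
            "survival_0", "survival_1", "survival_5", "survival_10"]

    def test_duplicate_names_rejected(self, default_params):
        cohort = [Municipality("A", "x", 10.0), Municipality("A", "y", 12.0)]
        with pytest.raises(ValueError, match="duplicate"):
            build_scenario_table(cohort, default_params)

    def test_negative_delta_rejected(self, norwegian_cohort, default_params):
        with pytest.raises(ValueError):
            build_scenario_table(norwegian_cohort, default_params, [-1.0])

    def test_rows_match_direct_scenario_calls(self, norwegian_cohort, default_params):
        table = build_scenario_table(norwegian_cohort, default_params, [2.5, 7.0])
        for m in norwegian_cohort:
            row = table.data.set_index("municipality").loc[m.name]
            assert row["survival_2p5"] == scenario_survival(m, default_params, 2.5).survival
            assert row["survival_7"] == scenario_survival(m, default_params, 7.0).survival

    def test_survival_monotone_within_and_across_rows(self, norwegian_cohort,
                                                      default_params):
        table = build_scenario_table(norwegian_cohort, default_params, [1, 5, 10])
        vals = table.data[table.survival_columns()].to_numpy()
        # non-decreasing across increasing shift within each row
        assert np.all(np.diff(vals, axis=1) >= 0)
        # decreasing in response time at fixed shift
        order = table.data["response_min"].to_numpy().argsort()
        assert np.all(np.diff(vals[order], axis=0) < 0)

    def test_percent_frame_rendering(self, norwegian_cohort, default_params):
        table = build_scenario_table(norwegian_cohort, default_params, [5])
        rendered = table.to_percent_frame().set_index("municipality")
        assert rendered.loc["Bergen", "survival_5"] == "68.6%"
        assert rendered.loc["Tokke", "survival_0"] == "30.0%"


class TestGains:
    def test_tokke_five_minute_gain_exceeds_13_pp(self, norwegian_cohort,
                                                  default_params):
        table = build_scenario_table(norwegian_cohort, default_params, [1, 5, 10])
        gains = compute_gains(table).set_index("municipality")
        assert gains.loc["Tokke", "gain_pp_5"] > 13.0
        assert gains.loc["Tokke", "gain_pp_5"] == pytest.approx(13.1, abs=0.1)

    def test_bergen_five_minute_gain(self, norwegian_cohort, default_params):
        # difference of the two closed-form values, computed independently
        expected = 100 * (0.93 ** 5.2 - 0.93 ** 10.2)
        table = build_scenario_table(norwegian_cohort, default_params, [5])
        gains = compute_gains(table).set_index("municipality")
        assert gains.loc["Bergen", "gain_pp_5"] == pytest.approx(expected, abs=1e-12)
        assert to_percent(0.93 ** 5.2) - to_percent(0.93 ** 10.2) == pytest.approx(
            20.9, abs=0.05)

    def test_zero_shift_gain_is_zero(self, norwegian_cohort, default_params):
        table = build_scenario_table(norwegian_cohort, default_params, [0.0, 5.0])
        gains = compute_gains(table)
        assert np.all(gains["gain_pp_0"] == 0.0)

    def test_gains_equal_direct_differences(self, norwegian_cohort, default_params):
        table = build_scenario_table(norwegian_cohort, default_params, [1, 5, 10])
        gains = compute_gains(table).set_index("municipality")
        for m in norwegian_cohort:
            for d in (1, 5, 10):
                direct = scenario_survival(m, default_params, d).gain_pp
                assert gains.loc[m.name, f"gain_pp_{d}"] == pytest.approx(
                    direct, abs=1e-12)


class TestSensitivity:
    def test_slice_at_default_rate_matches_table(self, norwegian_cohort,
                                                 default_params):
        grid = sensitivity_over_r(norwegian_cohort, [0.05, 0.07, 0.12], [1, 5, 10])
        table = build_scenario_table(norwegian_cohort, default_params, [1, 5, 10])
        slice_ = grid.data[grid.data["r"] == 0.07]
        for m in norwegian_cohort:
            row = table.data.set_index("municipality").loc[m.name]
            sub = slice_[slice_["municipality"] == m.name].set_index("delta_min")
            assert sub.loc[0.0, "survival"] == row["survival_0"]
            for d in (1.0, 5.0, 10.0):
                assert sub.loc[d, "survival"] == row[f"survival_{d:g}"]

    def test_survival_decreasing_in_rate(self, norwegian_cohort):
        grid = sensitivity_over_r(norwegian_cohort, [0.05, 0.07, 0.09, 0.12], [0.0])
        for m in norwegian_cohort:
            sub = grid.data[
                (grid.data["municipality"] == m.name) & (grid.data["delta_min"] == 0.0)
            ].sort_values("r")
            assert np.all(np.diff(sub["survival"].to_numpy()) < 0)

    def test_low_rate_matches_loop_oracle(self, norwegian_cohort):
        grid = sensitivity_over_r(norwegian_cohort, [0.05], [0.0])
        bergen = grid.data[
            (grid.data["municipality"] == "Bergen") & (grid.data["delta_min"] == 0.0)
        ]["survival"].iloc[0]
        # brute-force product over 10 whole minutes, then fractional remainder
        prod = 1.0
        for _ in range(10):
            prod *= 0.95
        prod *= 0.95 ** 0.2
        assert bergen == pytest.approx(prod, abs=1e-12)

    def test_zero_rate_gives_s0_everywhere(self, norwegian_cohort):
        grid = sensitivity_over_r(norwegian_cohort, [0.0], [1, 5, 10])
        assert np.all(grid.data["survival"] == 1.0)

    def test_rate_outside_unit_interval_rejected(self, norwegian_cohort):
        with pytest.raises(ValueError):
            sensitivity_over_r(norwegian_cohort, [1.0], [1])
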