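"""Exploratory statistics: time charts, percent-of-max, ranks, spikes, correlation."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiexplorer import (
    StudyStore,
    ValidationError,
    compare_points,
    flag_spikes,
    percent_of_max,
    rainfall_correlation,
    rank_chart,
    time_chart,
)
from epiexplorer.synthetic import CASE_STUDY_SERIES, default_months

from conftest import make_fc_store


def pearson_oracle(x, y):
    """From-scratch Pearson r, independent of the library implementation."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


class TestTimeChart:
    def test_m13_series_is_single_july_spike(self, m13_store):
        ts = time_chart(m13_store, "M13", "fc_count")
        assert ts.value_at("2017-07") == 35_800_000
        assert all(v == 0 for m, v in ts.entries if m != "2017-07")
        assert len(ts) == 15

    def test_m13_july_water_score_is_series_max(self, m13_store):
        ts = time_chart(m13_store, "M13", "water")
        assert ts.value_at("2017-07") == max(ts.values) == 5

    def test_entries_strictly_ascending(self, s17_store):
        ts = time_chart(s17_store, "S17", "fc_count")
        assert list(ts.months) == sorted(ts.months)
        # missing months are omitted, not zero-filled
        assert "2017-10" not in ts.months and len(ts) == 7

    def test_point_without_records_gives_empty_series(self):
        store = make_fc_store({})
        assert len(time_chart(store, "X1", "fc_count")) == 0

    def test_unknown_variable_lists_valid_names(self, m13_store):
        with pytest.raises(ValidationError, match="fc_count.*mud"):
            time_chart(m13_store, "M13", "coliform")


class TestPercentOfMax:
    def test_worked_example_20_of_100(self):
        store = make_fc_store({"2017-01": 100, "2017-02": 20, "2017-03": 55})
        assert percent_of_max(store, "X1", "2017-02") == 20.0

    def test_maximum_month_is_100(self):
        store = make_fc_store({"2017-01": 100, "2017-02": 20})
        assert percent_of_max(store, "X1", "2017-01") == 100.0

    def test_m13_december_is_zero(self, m13_store):
        assert percent_of_max(m13_store, "M13", "2017-12") == 0.0

    def test_all_zero_history_is_zero_by_convention(self):
        store = make_fc_store({"2017-01": 0, "2017-02": 0})
        assert percent_of_max(store, "X1", "2017-02") == 0.0

    def test_missing_period_errors(self, s17_store):
        with pytest.raises(ValidationError, match="2017-10"):
            percent_of_max(s17_store, "S17", "2017-10")

    @given(
        st.lists(st.floats(0, 1e8, allow_nan=False), min_size=2, max_size=12),
        st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_always_within_0_100_and_100_at_argmax(self, values, data):
        months = default_months("2016-10", "2017-12")[: len(values)]
        store = make_fc_store(dict(zip(months, values)))
        period = data.draw(st.sampled_from(months))
        pct = percent_of_max(store, "X1", period)
        assert 0.0 <= pct <= 100.0
        if values and max(values) > 0:
            argmax_month = months[values.index(max(values))]
            assert percent_of_max(store, "X1", argmax_month) == 100.0


class TestRankChart:
    def _store(self, values):
        store = StudyStore()
        for i, v in enumerate(values):
            sub = make_fc_store({"2017-07": v}, point_id=f"M{i+1}",
                                lon=-72.337 + i * 1e-3)
            store.add_water_point(sub.get_point(f"M{i+1}"))
            store.add_epi_sample(sub.query_samples(f"M{i+1}")[0])
        return store

    def test_descending_dense_ranks(self):
        table = rank_chart(self._store([10, 300, 42]), "fc_count", "2017-07")
        assert [(r, pid) for r, pid, _ in table.rows] == [(1, "M2"), (2, "M3"), (3, "M1")]
        values = [v for _, _, v in table.rows]
        assert values == sorted(values, reverse=True)

    def test_ties_ordered_by_point_id(self):
        table = rank_chart(self._store([7, 7, 99]), "fc_count", "2017-07")
        assert [(r, pid) for r, pid, _ in table.rows] == [(1, "M3"), (2, "M1"), (3, "M2")]

    def test_single_point_scope(self):
        table = rank_chart(self._store([5]), "fc_count", "2017-07", scope=["M1"])
        assert table.rows == ((1, "M1", 5.0),)

    def test_m13_ranks_first_in_july(self, m13_store):
        table = rank_chart(m13_store, "fc_count", "2017-07", scope="M")
        assert table.rows[0][:2] == (1, "M13")

    def test_points_without_observation_listed_separately(self, p1_store, default_study):
        table = rank_chart(p1_store, "fc_count", "2017-10", scope="all")
        assert table.missing == ()
        # synthetic store observes every month, so nothing is missing there
        full = rank_chart(default_study, "fc_count", "2017-03")
        assert set(p for _, p, _ in full.rows) | set(full.missing) == {
            p.point_id for p in default_study.water_points
        }

    def test_empty_scope_errors(self, m13_store):
        with pytest.raises(ValidationError, match="scope"):
            rank_chart(m13_store, "fc_count", "2017-07", scope="Q")

    @given(st.permutations(["M1", "M2", "M3", "M4"]))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_scope_order_and_rank1_is_max(self, order):
        store = self._store([3, 141, 59, 26])
        table = rank_chart(store, "fc_count", "2017-07", scope=list(order))
        baseline = rank_chart(store, "fc_count", "2017-07", scope="all")
        assert table.rows == baseline.rows
        assert table.rows[0][2] == max(v for _, _, v in table.rows)


class TestFlagSpikes:
    @pytest.mark.parametrize(
        "fixture_name, point_id, expected",
        [
            ("s17_store", "S17", ("2017-05", "2017-06", "2017-07")),
            ("m13_store", "M13", ("2017-07",)),
            ("p1_store", "P1", ("2017-05", "2017-06")),
        ],
    )
    def test_case_study_flags(self, request, fixture_name, point_id, expected):
        store = request.getfixturevalue(fixture_name)
        report = flag_spikes(store, point_id)
        assert report.flagged == expected

    def test_matches_brute_force_rule_on_s17(self, s17_store):
        """Hand-applied rule: v > 100 * (1 + median of the other months)."""
        from statistics import median
        series = sorted(CASE_STUDY_SERIES["S17"].items())
        expected = tuple(
            m for i, (m, v) in enumerate(series)
            if v > 100 * (1 + median([x for j, (_, x) in enumerate(series) if j != i]))
        )
        assert flag_spikes(s17_store, "S17").flagged == expected

    def test_constant_series_unflagged(self):
        store = make_fc_store({"2017-01": 9, "2017-02": 9, "2017-03": 9})
        assert flag_spikes(store, "X1").flagged == ()

    def test_requires_three_observations(self):
        store = make_fc_store({"2017-01": 0, "2017-02": 1})
        with pytest.raises(ValidationError, match="at least 3"):
            flag_spikes(store, "X1")

    def test_injected_value_is_recovered(self):
        """Adding a value above threshold to random series flags exactly it."""
        rng = random.Random(42)
        months = default_months("2016-10", "2017-12")
        for _ in range(100):
            n = rng.randint(5, 15)
            base = [rng.choice([0, 0, 0, rng.randint(1, 50)]) for _ in range(n)]
            series = dict(zip(months, base))
            target = rng.choice(months[:n])
            from statistics import median
            others = [v for m, v in series.items() if m != target]
            series[target] = 100 * (1 + median(others)) + rng.randint(1, 10**6)
            store = make_fc_store(series)
            assert target in flag_spikes(store, "X1").flagged


class TestComparePoints:
    def test_m1_vs_m13_in_july(self, m13_store):
        paired = compare_points(m13_store, "M1", "M13", "fc_count")
        by_month = {m: (a, b) for m, a, b in paired.entries}
        assert by_month["2017-07"] == (0.0, 35_800_000.0)
        assert len(paired.entries) == 15

    def test_self_comparison_pairs_identical_values(self, s17_store):
        paired = compare_points(s17_store, "S17", "S17", "fc_count")
        assert all(a == b for _, a, b in paired.entries)

    def test_disjoint_months_empty(self):
        store = make_fc_store({"2017-01": 5})
        other = make_fc_store({"2017-02": 5}, point_id="X2", lon=-72.30)
        store.add_water_point(other.get_point("X2"))
        store.add_epi_sample(other.query_samples("X2")[0])
        assert compare_points(store, "X1", "X2", "fc_count").entries == ()


class TestRainfallCorrelation:
    months = default_months("2016-10", "2017-09")

    def test_perfectly_proportional_series(self):
        rain = {m: 10.0 * (i + 1) for i, m in enumerate(self.months)}
        fc = {m: 2.0 * v for m, v in rain.items()}
        result = rainfall_correlation(fc, rain)
        assert result.r == pytest.approx(1.0, abs=1e-12)
        assert result.n == 12

    def test_agrees_with_formula_oracle_on_random_series(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(3, 20))
            months = default_months("2015-01", "2017-12")[:n]
            x = rng.uniform(0, 1e6, n)
            y = rng.uniform(0, 500, n)
            got = rainfall_correlation(dict(zip(months, x)), dict(zip(months, y)))
            assert got.r == pytest.approx(pearson_oracle(list(x), list(y)), abs=1e-12)

    def test_outlier_injection_drops_r_and_exclusion_restores_it(self):
        rng = np.random.default_rng(5)
        rain = {m: float(rng.uniform(20, 300)) for m in self.months}
        fc = {m: 50.0 + 2.0 * v + float(rng.normal(0, 10)) for m, v in rain.items()}
        clean = rainfall_correlation(fc, rain)
        # a single extreme contamination event in the driest month
        outlier_month = min(rain, key=rain.get)
        fc[outlier_month] = 1e6
        with_outlier = rainfall_correlation(fc, rain)
        excluded = rainfall_correlation(fc, rain, exclude=[outlier_month])
        assert with_outlier.r < clean.r
        assert excluded.r > with_outlier.r
        assert excluded.excluded == (outlier_month,)
        assert excluded.n == with_outlier.n - 1

    def test_constant_rainfall_errors(self):
        rain = {m: 100.0 for m in self.months}
        fc = {m: float(i) for i, m in enumerate(self.months)}
        with pytest.raises(ValidationError, match="variance"):
            rainfall_correlation(fc, rain)

    def test_fewer_than_three_pairs_errors(self):
        with pytest.raises(ValidationError, match=">= 3"):
            rainfall_correlation({"2017-01": 1, "2017-02": 2}, {"2017-01": 5, "2017-02": 9})

    def test_negative_rain_rejected(self):
        rain = {m: -1.0 for m in self.months}
        with pytest.raises(ValidationError, match="rain"):
            rainfall_correlation({m: 1.0 for m in self.months}, rain)
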