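"""Data model, CSV ingest, monthly aggregation and holdout splitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import entrocast as ec


def _write(tmp_path, text, name="s.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadSeries:
    def test_slash_dates_and_values(self, tmp_path):
        p = _write(tmp_path, "date,value\n2015/1/22,58.2\n2015/1/23,64.4\n2015/1/24,73.6\n")
        s = ec.read_series(p)
        assert len(s) == 3
        assert s.values[0] == 58.2
        assert s.dates[0] == pd.Timestamp("2015-01-22")

    def test_single_row(self, tmp_path):
        p = _write(tmp_path, "date,value\n2020-05-01,10.0\n")
        s = ec.read_series(p)
        assert len(s) == 1 and s.values.mean() == 10.0

    def test_zero_value_rejected_with_row(self, tmp_path):
        p = _write(tmp_path, "date,value\n2020-05-01,3.0\n2020-05-02,0.0\n")
        with pytest.raises(ValueError, match="row 1"):
            ec.read_series(p)

    def test_non_numeric_rejected(self, tmp_path):
        p = _write(tmp_path, "date,value\n2020-05-01,abc\n")
        with pytest.raises(ValueError, match="non-numeric"):
            ec.read_series(p)

    def test_duplicate_date_rejected(self, tmp_path):
        p = _write(tmp_path, "date,value\n2020-05-01,3.0\n2020-05-01,4.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            ec.read_series(p)

    def test_calendar_gap_policy(self, tmp_path):
        p = _write(tmp_path, "date,value\n2020-05-01,3.0\n2020-05-03,4.0\n")
        with pytest.raises(ValueError, match="gap"):
            ec.read_series(p)
        s = ec.read_series(p, allow_gaps=True)
        assert len(s) == 2

    def test_unsorted_rows_are_sorted(self, tmp_path):
        p = _write(tmp_path, "date,value\n2020-05-02,4.0\n2020-05-01,3.0\n")
        s = ec.read_series(p)
        assert list(s.values) == [3.0, 4.0]


@given(
    st.lists(
        st.floats(min_value=0.01, max_value=1e6, allow_nan=False), min_size=1, max_size=40
    )
)
def test_write_read_roundtrip_full_precision(tmp_path_factory, values):
    """read ∘ write is the identity on values to full stored precision."""
    tmp = tmp_path_factory.mktemp("rt")
    s = ec.DailySeries.from_values(values)
    ec.write_series(s, tmp / "s.csv")
    back = ec.read_series(tmp / "s.csv")
    assert np.array_equal(back.values, s.values)
    assert (back.dates == s.dates).all()


class TestMonthlyMeans:
    def test_constant_month(self):
        s = ec.DailySeries.from_values([10.0] * 31, start="2021-01-01")
        assert ec.monthly_means(s) == [ec.MonthlySummary(2021, 1, 10.0, 31)]

    def test_two_months_brute_force(self):
        # Jan 30/31 = {10, 20}, Feb 1 = {30}
        s = ec.DailySeries.from_values([10.0, 20.0, 30.0], start="2021-01-30")
        assert ec.monthly_means(s) == [
            ec.MonthlySummary(2021, 1, 15.0, 2),
            ec.MonthlySummary(2021, 2, 30.0, 1),
        ]

    def test_single_day(self):
        s = ec.DailySeries.from_values([42.0])
        (m,) = ec.monthly_means(s)
        assert m.mean_value == 42.0 and m.n_days == 1

    def test_constant_series_constant_every_month(self):
        s = ec.DailySeries.from_values([7.5] * 90, start="2021-01-01")
        assert all(m.mean_value == 7.5 for m in ec.monthly_means(s))


class TestSplitHoldout:
    def test_three_one(self):
        s = ec.DailySeries.from_values([1.0, 2.0, 3.0])
        train, test = ec.split_holdout(s, 1)
        assert list(train.values) == [1.0, 2.0] and list(test.values) == [3.0]

    @pytest.mark.parametrize("n_holdout", [0, 5, 6])
    def test_invalid_holdout(self, n_holdout):
        s = ec.DailySeries.from_values([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError):
            ec.split_holdout(s, n_holdout)

    @given(st.integers(min_value=11, max_value=60), st.integers(min_value=1, max_value=10))
    def test_concatenation_restores_input(self, n, h):
        rng = np.random.default_rng(n)
        s = ec.DailySeries.from_values(rng.uniform(1, 100, n))
        train, test = ec.split_holdout(s, h)
        assert len(train) + len(test) == n
        assert np.array_equal(np.r_[train.values, test.values], s.values)


class TestInvariants:
    def test_positivity_enforced(self):
        with pytest.raises(ValueError, match="non-positive"):
            ec.DailySeries.from_values([1.0, -3.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ec.DailySeries.from_values([])

    def test_non_increasing_dates_rejected(self):
        dates = pd.DatetimeIndex(["2020-01-02", "2020-01-01"])
        with pytest.raises(ValueError, match="increasing"):
            ec.DailySeries(dates, np.array([1.0, 2.0]))
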