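"""Market shares, practice quintiles and switch-away rates."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import statincost as sc

from _helpers import make_rec


def initiations(practice_counts, month="2010-01", focal="simvastatin", other="atorvastatin"):
    """practice_counts: {practice: (n_focal, n_other)} -> first-episode records."""
    records = []
    i = 0
    for practice, (nf, no) in practice_counts.items():
        for _ in range(nf):
            records.append(
                make_rec(patient=f"p{i}", practice=practice, month=month, statin=focal)
            )
            i += 1
        for _ in range(no):
            records.append(
                make_rec(patient=f"p{i}", practice=practice, month=month, statin=other)
            )
            i += 1
    return records


class TestMarketShares:
    def test_degenerate_distribution(self):
        records = [make_rec(patient=f"p{i}", statin="simvastatin") for i in range(10)]
        series = sc.market_shares(records)
        assert series.share("simvastatin", sc.month("2010-01")) == 1.0
        assert series.share("atorvastatin", sc.month("2010-01")) == 0.0

    def test_direct_count(self):
        records = [make_rec(patient=f"p{i}", statin="simvastatin") for i in range(3)]
        records.append(make_rec(patient="p9", statin="atorvastatin"))
        series = sc.market_shares(records)
        assert series.share("simvastatin", sc.month("2010-01")) == pytest.approx(0.75)
        assert series.share("atorvastatin", sc.month("2010-01")) == pytest.approx(0.25)

    def test_no_initiations_marked_empty(self):
        records = [make_rec(patient=f"p{i}", first=False) for i in range(4)]
        series = sc.market_shares(records)
        assert series.empty_periods == [sc.month("2010-01")]

    def test_quarterly_granularity_pools_months(self):
        records = [
            make_rec(patient="a", month="2010-01", statin="simvastatin"),
            make_rec(patient="b", month="2010-03", statin="atorvastatin"),
        ]
        series = sc.market_shares(records, granularity="quarter")
        assert series.share("simvastatin", sc.quarter("2010Q1")) == pytest.approx(0.5)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        choices=st.lists(st.integers(0, 4), min_size=1, max_size=30),
        months=st.lists(st.integers(0, 5), min_size=1, max_size=30),
    )
    def test_shares_sum_to_one_per_nonempty_period(self, choices, months):
        statins = list(sc.Statin)
        records = [
            make_rec(
                patient=f"p{i}",
                month=f"2010-{1 + m % 6:02d}",
                statin=statins[c],
            )
            for i, (c, m) in enumerate(zip(choices, months))
        ]
        series = sc.market_shares(records)
        sums = series.shares.dropna(how="all").sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestDynamicQuintiles:
    def test_one_practice_per_quintile(self):
        counts = {f"g{i}": (k, 10 - k) for i, k in enumerate([1, 3, 5, 7, 9])}
        qs = sc.quintile_means_dynamic(initiations(counts), "simvastatin")
        row = qs.means.iloc[0]
        assert list(row[[f"q{i}" for i in range(1, 6)]]) == pytest.approx(
            [0.1, 0.3, 0.5, 0.7, 0.9]
        )

    def test_hand_partition_of_ten_practices(self):
        counts = {f"g{i:02d}": (k, 10 - k) for i, k in enumerate(range(10))}
        qs = sc.quintile_means_dynamic(initiations(counts), "simvastatin")
        row = qs.means.iloc[0]
        assert row["q1"] == pytest.approx(0.05)
        assert row["q5"] == pytest.approx(0.85)

    def test_symmetry_all_practices_equal(self):
        counts = {f"g{i}": (6, 4) for i in range(5)}
        qs = sc.quintile_means_dynamic(initiations(counts), "simvastatin")
        assert np.allclose(qs.means.iloc[0].values, 0.6)

    def test_group_means_monotone_within_period(self):
        rng = np.random.default_rng(5)
        counts = {f"g{i:02d}": (int(rng.integers(0, 11)), 10) for i in range(17)}
        qs = sc.quintile_means_dynamic(initiations(counts), "simvastatin")
        row = qs.means.iloc[0].values
        assert np.all(np.diff(row) >= -1e-12)

    def test_underpopulated_period_skipped(self):
        counts = {"g1": (1, 1), "g2": (1, 1)}
        qs = sc.quintile_means_dynamic(initiations(counts), "simvastatin")
        assert qs.means.empty


class TestFixedQuintiles:
    def test_coincides_with_dynamic_at_baseline(self):
        counts = {f"g{i:02d}": (k, 10 - k) for i, k in enumerate(range(10))}
        records = initiations(counts, month="2003-07")
        dyn = sc.quintile_means_dynamic(records, "simvastatin")
        fixed = sc.quintile_means_fixed(records, "simvastatin", "2003Q3")
        assert np.allclose(
            dyn.means.loc[sc.month("2003-07")].values,
            fixed.means.loc[sc.month("2003-07")].values,
        )

    def test_membership_stays_fixed(self):
        counts = {f"g{i:02d}": (k, 10 - k) for i, k in enumerate(range(10))}
        later = {f"g{i:02d}": (10, 0) if i == 0 else (k, 10 - k) for i, k in enumerate(range(10))}
        records = initiations(counts, month="2003-07") + initiations(later, month="2003-10")
        fixed = sc.quintile_means_fixed(records, "simvastatin", "2003Q3")
        first, second = fixed.means.iloc[0], fixed.means.iloc[1]
        # the bottom-baseline practice g00 jumping to share 1.0 moves only q1
        assert second["q1"] > first["q1"]
        assert np.allclose(second[["q2", "q3", "q4", "q5"]], first[["q2", "q3", "q4", "q5"]])

    def test_two_period_hand_oracle(self):
        counts = {f"g{i:02d}": (k, 10 - k) for i, k in enumerate(range(10))}
        flipped = {f"g{i:02d}": (10 - k, k) for i, k in enumerate(range(10))}
        records = initiations(counts, month="2003-07") + initiations(flipped, month="2003-11")
        fixed = sc.quintile_means_fixed(records, "simvastatin", "2003Q3")
        second = fixed.means.loc[sc.month("2003-11")]
        # baseline groups {g00,g01},...,{g08,g09}; flipped shares 1.0..0.1
        assert second["q1"] == pytest.approx((1.0 + 0.9) / 2)
        assert second["q5"] == pytest.approx((0.2 + 0.1) / 2)

    def test_underpopulated_baseline_is_an_error(self):
        records = initiations({"g1": (5, 5)}, month="2003-07")
        with pytest.raises(sc.StatinCostError, match="baseline"):
            sc.quintile_means_fixed(records, "simvastatin", "2003Q3")


class TestSwitchAway:
    def seq(self, patient, statin_months):
        return [
            make_rec(patient=patient, month=m, statin=s, first=(i == 0))
            for i, (m, s) in enumerate(statin_months)
        ]

    def test_single_event_census(self):
        records = self.seq(
            "p1",
            [("2010-01", "atorvastatin"), ("2010-02", "simvastatin"), ("2010-04", "atorvastatin")],
        )
        assert sc.switch_away_rate(records, "simvastatin", 4) == 100.0

    def test_never_prescribed_again_counts_in_denominator_only(self):
        records = self.seq("p1", [("2010-01", "atorvastatin"), ("2010-02", "simvastatin")])
        assert sc.switch_away_rate(records, "simvastatin", 4) == 0.0

    def test_switch_back_outside_window_not_counted(self):
        records = self.seq(
            "p1",
            [("2010-01", "atorvastatin"), ("2010-02", "simvastatin"), ("2010-09", "atorvastatin")],
        )
        assert sc.switch_away_rate(records, "simvastatin", 4) == 0.0
        assert sc.switch_away_rate(records, "simvastatin", 12) == 100.0

    def test_ten_patient_hand_count(self):
        records = []
        for i in range(10):
            base = [("2010-01", "atorvastatin"), ("2010-02", "simvastatin")]
            if i < 3:
                base.append(("2010-05", "rosuvastatin"))  # inside 4-month window
            else:
                base.append(("2010-12", "simvastatin"))
            records += self.seq(f"p{i}", base)
        assert sc.switch_away_rate(records, "simvastatin", 4) == pytest.approx(30.0)

    def test_no_switches_is_undefined(self):
        records = self.seq("p1", [("2010-01", "simvastatin"), ("2010-02", "simvastatin")])
        assert sc.switch_away_rate(records, "simvastatin", 4) is None
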