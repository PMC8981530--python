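"""Episode costing and the two counterfactual savings scenarios."""
import numpy as np
import pytest

import statincost as sc

from _helpers import eq_rows, make_rec, price_cells_for_table, random_small_fixture
from _oracle import oracle_scenarios


def toy_prices(unit_costs, years=range(2009, 2016)):
    """unit_costs: {(statin, strength): GBP/tablet} replicated across years."""
    cells = []
    for (statin, strength), uc in unit_costs.items():
        for year in years:
            cells.append(sc.PriceCell(year, sc.Statin.parse(statin), strength, 1000.0, uc * 1000.0))
    return cells


class TestEpisodeCost:
    def test_hand_oracle(self, flat_deflators):
        prices = toy_prices({("simvastatin", 20.0): 0.50})
        rec = make_rec(tablets=28, days=28)
        assert sc.episode_cost(rec, 28, prices, flat_deflators) == pytest.approx(14.0)

    def test_cap_none_equals_cap_days_supplied(self, flat_deflators):
        prices = toy_prices({("simvastatin", 20.0): 0.37})
        rec = make_rec(tablets=56, days=42)
        assert sc.episode_cost(rec, None, prices, flat_deflators) == pytest.approx(
            sc.episode_cost(rec, 42, prices, flat_deflators)
        )

    def test_cap_prorates_by_day_fraction(self, flat_deflators):
        prices = toy_prices({("simvastatin", 20.0): 0.50})
        rec = make_rec(tablets=56, days=56)
        capped = sc.episode_cost(rec, 28, prices, flat_deflators)
        uncapped = sc.episode_cost(rec, None, prices, flat_deflators)
        assert capped == pytest.approx(uncapped / 2)

    def test_missing_price_identifies_statin_and_year(self, flat_deflators):
        prices = toy_prices({("simvastatin", 20.0): 0.50})
        rec = make_rec(statin="rosuvastatin", strength=10, month="2013-01")
        with pytest.raises(sc.MissingPriceError, match="rosuvastatin.*2013"):
            sc.episode_cost(rec, 28, prices, flat_deflators)

    def test_deflation_applied(self):
        prices = toy_prices({("simvastatin", 20.0): 0.50})
        deflators = sc.DeflatorSeries({2010: 80.0, 2018: 100.0})
        rec = make_rec(tablets=28, days=28)
        assert sc.episode_cost(rec, 28, prices, deflators) == pytest.approx(14.0 * 100 / 80)


class TestHypotheticalEpisodeCost:
    def test_record_on_comparator_is_fixed_point(self, toy_table, flat_deflators):
        prices = toy_prices({("simvastatin", 20.0): 0.10})
        rec = make_rec(statin="simvastatin", strength=20, month="2010-06")
        actual = sc.episode_cost(rec, 28, prices, flat_deflators)
        hyp = sc.hypothetical_episode_cost(
            rec, 28, prices, toy_table, sc.ComparatorPolicy(), flat_deflators
        )
        assert hyp == actual

    def test_pre_cutover_substitution_toy_oracle(self, toy_table, flat_deflators):
        # atorvastatin 10 mg (medium) in 2010 -> simvastatin 20 mg;
        # £1.00/tab vs £0.10/tab, 28 capped tablets: £28 vs £2.80
        prices = toy_prices({("atorvastatin", 10.0): 1.00, ("simvastatin", 20.0): 0.10})
        rec = make_rec(statin="atorvastatin", strength=10, month="2010-06")
        actual = sc.episode_cost(rec, 28, prices, flat_deflators)
        hyp = sc.hypothetical_episode_cost(
            rec, 28, prices, toy_table, sc.ComparatorPolicy(), flat_deflators
        )
        assert actual == pytest.approx(28.0)
        assert hyp == pytest.approx(2.80)

    def test_post_cutover_substitutes_to_atorvastatin(self, flat_deflators):
        table = sc.EquivalenceTable.default()
        # rosuvastatin 10 mg (43%, high) -> atorvastatin 20 mg (43%, high)
        prices = toy_prices({("rosuvastatin", 10.0): 0.80, ("atorvastatin", 20.0): 0.05})
        rec = make_rec(statin="rosuvastatin", strength=10, month="2015-03")
        hyp = sc.hypothetical_episode_cost(
            rec, 28, prices, table, sc.ComparatorPolicy(), flat_deflators
        )
        assert hyp == pytest.approx(28 * 0.05)


class TestScenarios:
    def test_three_record_enumeration_oracle(self, flat_deflators):
        table = sc.EquivalenceTable.default()
        rng = np.random.default_rng(0)
        cells = price_cells_for_table(table, range(2010, 2014), rng)
        records = [
            make_rec(patient="a", statin="atorvastatin", strength=20, month="2010-02"),
            make_rec(patient="b", statin="rosuvastatin", strength=10, month="2012-07"),
            make_rec(patient="c", statin="simvastatin", strength=40, month="2011-11"),
        ]
        expected = oracle_scenarios(records, cells, eq_rows(table), flat_deflators.index)
        rows = sc.scenario_first_episode(records, cells, table, deflators=flat_deflators)
        for row in rows:
            if row.year is None or row.year not in expected["first"]:
                continue
            n, a, h = expected["first"][row.year]
            assert row.n_patients == n
            assert row.actual_cost == pytest.approx(a, rel=1e-12)
            assert row.hypothetical_cost == pytest.approx(h, rel=1e-12)

    def test_all_patients_two_patient_oracle(self, flat_deflators):
        table = sc.EquivalenceTable.default()
        rng = np.random.default_rng(1)
        cells = price_cells_for_table(table, range(2011, 2014), rng)
        records = [
            make_rec(patient="a", statin="atorvastatin", strength=20, month="2011-12"),
            make_rec(patient="a", statin="atorvastatin", strength=20, month="2012-01", first=False),
            make_rec(patient="a", statin="atorvastatin", strength=20, month="2012-06", first=False),
            make_rec(patient="b", statin="pravastatin", strength=40, month="2013-02"),
            make_rec(patient="b", statin="pravastatin", strength=40, month="2013-03", first=False),
        ]
        expected = oracle_scenarios(records, cells, eq_rows(table), flat_deflators.index)
        rows = sc.scenario_all_patients(records, cells, table, deflators=flat_deflators)
        by_year = {r.year: r for r in rows if r.year is not None}
        for year, (n, a, h) in expected["all"].items():
            assert by_year[year].n_patients == n
            assert by_year[year].actual_cost == pytest.approx(a, rel=1e-12)
            assert by_year[year].hypothetical_cost == pytest.approx(h, rel=1e-12)

    def test_comparator_cohort_has_zero_savings(self, flat_deflators):
        table = sc.EquivalenceTable.default()
        cells = price_cells_for_table(table, range(2010, 2015), np.random.default_rng(2))
        records = [
            make_rec(patient=f"p{i}", statin=str(sc.comparator_for(m)), strength=20,
                     month=m, first=(i % 2 == 0))
            for i, m in enumerate(["2010-01", "2011-06", "2012-04", "2012-05", "2014-09"])
        ]
        for rows in (
            sc.scenario_first_episode(records, cells, table, deflators=flat_deflators),
            sc.scenario_all_patients(records, cells, table, deflators=flat_deflators),
        ):
            for row in rows:
                assert row.savings_abs == pytest.approx(0.0, abs=1e-12)

    def test_doubling_tablets_doubles_everything(self, flat_deflators):
        rng = np.random.default_rng(3)
        records, cells, table, deflators = random_small_fixture(rng)
        doubled = [
            sc.PrescriptionRecord(
                r.patient_id, r.practice_id, r.issue_month, r.statin, r.strength_mg,
                r.tablets * 2, r.days_supplied, r.first_episode,
            )
            for r in records
        ]
        base = sc.scenario_first_episode(records, cells, table, deflators=deflators)
        twice = sc.scenario_first_episode(doubled, cells, table, deflators=deflators)
        for b, t in zip(base, twice):
            assert t.actual_cost == pytest.approx(2 * b.actual_cost)
            assert t.hypothetical_cost == pytest.approx(2 * b.hypothetical_cost)
            assert t.savings_abs == pytest.approx(2 * b.savings_abs)

    def test_nesting_all_patients_reproduces_first_episode(self, flat_deflators):
        rng = np.random.default_rng(4)
        records, cells, table, deflators = random_small_fixture(rng)
        restricted = [r for r in records if r.first_episode and r.days_supplied <= 28]
        if not restricted:
            restricted = [make_rec(statin="atorvastatin", strength=20, days=28)]
        first = sc.scenario_first_episode(restricted, cells, table, deflators=deflators)
        allp = sc.scenario_all_patients(restricted, cells, table, deflators=deflators)
        for f, a in zip(first, allp):
            assert f.year == a.year
            assert f.actual_cost == pytest.approx(a.actual_cost, rel=1e-12)
            assert f.hypothetical_cost == pytest.approx(a.hypothetical_cost, rel=1e-12)

    def test_raising_comparator_price_weakly_decreases_savings(self, toy_table, flat_deflators):
        records = [make_rec(statin="atorvastatin", strength=10, month="2010-06")]
        for uc_sim, uc_sim_hi in [(0.10, 0.50), (0.50, 2.00)]:
            lo = toy_prices({("atorvastatin", 10.0): 1.0, ("simvastatin", 20.0): uc_sim})
            hi = toy_prices({("atorvastatin", 10.0): 1.0, ("simvastatin", 20.0): uc_sim_hi})
            s_lo = sc.scenario_first_episode(records, lo, toy_table, deflators=flat_deflators)
            s_hi = sc.scenario_first_episode(records, hi, toy_table, deflators=flat_deflators)
            assert s_hi[-1].savings_abs <= s_lo[-1].savings_abs

    def test_year_with_no_first_episodes_has_zero_row(self, flat_deflators):
        table = sc.EquivalenceTable.default()
        cells = price_cells_for_table(table, range(2010, 2013), np.random.default_rng(5))
        records = [
            make_rec(patient="a", month="2010-03"),
            make_rec(patient="a", month="2011-03", first=False),
            make_rec(patient="b", month="2012-03"),
        ]
        rows = {r.year: r for r in sc.scenario_first_episode(records, cells, table, deflators=flat_deflators)}
        assert rows[2011].n_patients == 0
        assert rows[2011].actual_cost == 0
        assert rows[2011].savings_pct is None

    def test_scale_multiplies_counts_and_money(self, flat_deflators):
        table = sc.EquivalenceTable.default()
        cells = price_cells_for_table(table, range(2010, 2011), np.random.default_rng(6))
        records = [make_rec(patient="a", month="2010-03", statin="atorvastatin", strength=20)]
        base = sc.scenario_first_episode(records, cells, table, deflators=flat_deflators)
        scaled = sc.scenario_first_episode(records, cells, table, deflators=flat_deflators, scale=1000.0)
        assert scaled[0].n_patients == pytest.approx(1000 * base[0].n_patients)
        assert scaled[0].actual_cost == pytest.approx(1000 * base[0].actual_cost)
        assert scaled[0].savings_pct == pytest.approx(base[0].savings_pct)


class TestScaleToNational:
    def test_identity_and_hand_ratio(self):
        assert sc.scale_to_national(400, 40000, 40000) == pytest.approx(400)
        assert sc.scale_to_national(400, 4_000_000, 40_000) == pytest.approx(40_000)

    def test_zero_sample_basis_errors(self):
        with pytest.raises(sc.StatinCostError):
            sc.scale_to_national(400, 4_000_000, 0)


def test_savings_row_enforces_conservation():
    with pytest.raises(sc.StatinCostError):
        sc.SavingsRow(2010, 1, 100.0, 50.0, 10.0, 10.0)
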