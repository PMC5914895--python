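import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialcea.config import AnalysisConfig
from trialcea.cost_engine import (
    CapitalAsset,
    CostItem,
    CostLedger,
    LedgerError,
    MissingCPIError,
    MoneyAmount,
    UnknownExchangeRateError,
    aggregate,
    allocate,
    annuity_factor,
    convert_currency,
    equivalent_annual_cost,
    grand_total,
    inflate_to_base_year,
    load_ledger,
    to_base,
    unit_cost,
    write_ledger_csv,
)


def _usd(value, year=2015):
    return MoneyAmount(value, "USD", year)


class TestMoneyAmount:
    def test_rejects_negative_value(self):
        with pytest.raises(LedgerError, match=">= 0"):
            MoneyAmount(-1.0, "USD", 2015)

    def test_rejects_implausible_year(self):
        with pytest.raises(LedgerError, match="plausible range"):
            MoneyAmount(1.0, "USD", 1850)


class TestConvertCurrency:
    def test_identity_when_already_base(self):
        amt = _usd(100.0)
        assert convert_currency(amt, {}, "USD") == amt

    def test_unit_ratio(self):
        amt = MoneyAmount(3700.0, "UGX", 2014)
        out = convert_currency(amt, {"UGX": {2014: 3700.0}}, "USD")
        assert out.value == pytest.approx(1.0)
        assert out.currency == "USD"
        assert out.year == 2014  # year preserved; inflation is separate

    def test_missing_rate_names_currency_and_year(self):
        with pytest.raises(UnknownExchangeRateError, match="UGX in 2013"):
            convert_currency(MoneyAmount(1.0, "UGX", 2013), {"UGX": {2014: 3700.0}}, "USD")


class TestInflate:
    def test_identity_at_base_year(self):
        amt = _usd(100.0, 2015)
        assert inflate_to_base_year(amt, {2015: 100.0}, 2015) == amt

    def test_ratio(self):
        out = inflate_to_base_year(_usd(100.0, 2013), {2013: 100.0, 2015: 110.0}, 2015)
        assert out.value == pytest.approx(110.0)
        assert out.year == 2015

    def test_derived_ratio(self):
        # 250 * 115 / 92 = 312.50, by hand
        out = inflate_to_base_year(_usd(250.0, 2013), {2013: 92.0, 2015: 115.0}, 2015)
        assert out.value == pytest.approx(312.50)

    def test_missing_cpi_names_year(self):
        with pytest.raises(MissingCPIError, match="2013"):
            inflate_to_base_year(_usd(1.0, 2013), {2015: 100.0}, 2015)


def test_convert_then_inflate_composite():
    # 5550 UGX at 3700 UGX/USD, then CPI factor 1.10: 5550/3700*1.10 = 1.65
    config = AnalysisConfig(
        base_year=2015,
        base_currency="USD",
        discount_rate=0.0,
        horizon_years=1.0,
        exchange_rates={"UGX": {2014: 3700.0}},
        cpi={2014: 100.0, 2015: 110.0},
    )
    out = to_base(MoneyAmount(5550.0, "UGX", 2014), config)
    assert out.value == pytest.approx(1.65)
    assert (out.currency, out.year) == ("USD", 2015)


class TestAnnuityFactor:
    def test_zero_rate_limit(self):
        assert annuity_factor(0.0, 7) == 7.0

    def test_single_year_full_rate(self):
        assert annuity_factor(1.0, 1) == pytest.approx(0.5)

    def test_against_brute_force_sum(self):
        # oracle: direct summation of discount factors
        for rate in (0.0926, 0.03, 0.2):
            for n in (1, 5, 7, 30):
                oracle = sum((1.0 + rate) ** -t for t in range(1, n + 1))
                assert annuity_factor(rate, n) == pytest.approx(oracle, rel=1e-12)

    def test_frozen_value(self):
        # brute-force sum of the 7 factors at 9.26%, frozen
        assert annuity_factor(0.0926, 7) == pytest.approx(4.9893433220, rel=1e-9)

    def test_rejects_horizon_below_one(self):
        with pytest.raises(ValueError, match=">= 1"):
            annuity_factor(0.1, 0)


class TestEquivalentAnnualCost:
    def test_straight_line_when_undiscounted(self):
        asset = CapitalAsset(_usd(700.0), useful_life_years=7)
        assert equivalent_annual_cost(asset) == pytest.approx(100.0)

    def test_full_resale_identity(self):
        # resale_fraction = 1 reduces analytically to P * r
        asset = CapitalAsset(
            _usd(446_940.0), 7, resale_fraction=1.0, discount_rate=0.0926
        )
        assert equivalent_annual_cost(asset) == pytest.approx(41_386.644, abs=1e-6)

    def test_no_resale_frozen_value(self):
        # oracle: NPV brute force — the annual charge A solving
        # sum_t A (1+r)^-t = P is P / annuity_factor
        asset = CapitalAsset(_usd(1000.0), 7, resale_fraction=0.0, discount_rate=0.0926)
        eac = equivalent_annual_cost(asset)
        npv = sum(eac * 1.0926**-t for t in range(1, 8))
        assert npv == pytest.approx(1000.0, rel=1e-12)
        assert eac == pytest.approx(200.4272, abs=1e-3)

    @given(
        p=st.floats(1.0, 1e7),
        r=st.floats(0.001, 0.5),
        n=st.integers(1, 40),
        s1=st.floats(0.0, 1.5),
        s2=st.floats(0.0, 1.5),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_decreasing_in_resale_increasing_in_principal(
        self, p, r, n, s1, s2
    ):
        lo, hi = sorted((s1, s2))
        eac_lo = equivalent_annual_cost(
            CapitalAsset(_usd(p), n, resale_fraction=lo, discount_rate=r)
        )
        eac_hi = equivalent_annual_cost(
            CapitalAsset(_usd(p), n, resale_fraction=hi, discount_rate=r)
        )
        assert eac_hi <= eac_lo + 1e-9
        # increasing in principal (EAC is positive only while resale <= 1)
        if lo <= 1.0:
            bigger = equivalent_annual_cost(
                CapitalAsset(_usd(2 * p), n, resale_fraction=lo, discount_rate=r)
            )
            assert bigger >= eac_lo - 1e-9


class TestAllocate:
    def test_full_and_zero(self):
        base = dict(
            label="x",
            phase="implementation",
            category="staff",
            cost_basis="economic",
            amount=_usd(100.0),
        )
        assert allocate(CostItem(allocation_fraction=1.0, **base)) == 100.0
        assert allocate(CostItem(allocation_fraction=0.0, **base)) == 0.0

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(LedgerError, match=r"\[0, 1\]"):
            CostItem(
                label="x",
                phase="implementation",
                category="staff",
                cost_basis="economic",
                amount=_usd(1.0),
                allocation_fraction=1.5,
            )


class TestAggregate:
    def test_single_item_is_hundred_percent(self, usd_config):
        ledger = CostLedger(
            items=(
                CostItem(
                    "x", "implementation", "staff", "economic", _usd(42.0), 1.0
                ),
            )
        )
        table = aggregate(ledger, usd_config, "category")
        assert list(table.percent) == [100.0]

    def test_phase_and_category_totals_agree(self, simple_ledger, usd_config):
        by_phase = aggregate(simple_ledger, usd_config, "phase")
        by_cat = aggregate(simple_ledger, usd_config, "category")
        assert by_phase.total.sum() == pytest.approx(by_cat.total.sum())
        assert by_phase.total.sum() == pytest.approx(1000.0)

    def test_published_margin_percents(self, usd_config):
        # category totals 156,441 / 69,164 / 171,628 -> 397,233 and 39/17/43
        items = tuple(
            CostItem(c, "implementation", c, "economic", _usd(v), 1.0)
            for c, v in [
                ("staff", 156_441.0),
                ("capital", 69_164.0),
                ("recurrent", 171_628.0),
            ]
        )
        table = aggregate(CostLedger(items=items), usd_config, "category")
        assert table.total.sum() == pytest.approx(397_233.0)
        assert list(table.percent) == [39.0, 17.0, 43.0]

    def test_phase_split_percents(self, usd_config):
        items = (
            CostItem("a", "start_up", "staff", "economic", _usd(117_949.0), 1.0),
            CostItem("b", "implementation", "staff", "economic", _usd(279_284.0), 1.0),
        )
        table = aggregate(CostLedger(items=items), usd_config, "phase")
        assert list(table.percent) == [30.0, 70.0]

    def test_capital_asset_charged_as_eac_times_horizon(self, usd_config):
        asset = CapitalAsset(
            _usd(446_940.0), 7, resale_fraction=1.0, discount_rate=0.0926,
            phase="development",
        )
        ledger = CostLedger(
            items=(
                CostItem("a", "implementation", "staff", "economic", _usd(100.0), 1.0),
            ),
            capital_assets=(asset,),
        )
        total = grand_total(ledger, usd_config)
        assert total == pytest.approx(100.0 + 41_386.644 * 1.5, rel=1e-9)

    def test_me_phase_excluded_by_default(self, usd_config):
        items = (
            CostItem("a", "implementation", "staff", "economic", _usd(100.0), 1.0),
            CostItem("m", "monitoring_evaluation", "staff", "economic", _usd(50.0), 1.0),
        )
        ledger = CostLedger(items=items)
        assert grand_total(ledger, usd_config) == pytest.approx(100.0)
        assert grand_total(ledger, usd_config, include_me=True) == pytest.approx(150.0)

    def test_empty_ledger_errors(self, usd_config):
        with pytest.raises(LedgerError, match="empty ledger"):
            aggregate(CostLedger(items=()), usd_config)


class TestUnitCost:
    def test_published_per_school_value(self):
        assert unit_cost(157_343.0, 21) == pytest.approx(7_492.5238, abs=1e-3)

    def test_identity_denominator(self):
        assert unit_cost(42.0, 1) == 42.0

    def test_direct_per_pupil_division(self):
        assert unit_cost(157_343.0, 9_000) == pytest.approx(17.4826, abs=1e-4)

    def test_zero_denominator_guard(self):
        with pytest.raises(ZeroDivisionError):
            unit_cost(1.0, 0)


class TestCsvRoundTrip:
    def test_round_trip(self, tmp_path, usd_config):
        ledger = CostLedger(
            items=(
                CostItem(
                    "fuel",
                    "implementation",
                    "recurrent",
                    "financial",
                    MoneyAmount(2586.9, "UGX", 2013),
                    0.5,
                ),
            ),
            capital_assets=(
                CapitalAsset(_usd(1000.0), 5, 0.25, 0.0926, "laptop", "start_up"),
            ),
        )
        path = tmp_path / "ledger.csv"
        write_ledger_csv(ledger, path)
        back = load_ledger(path, discount_rate=0.0926)
        assert back.items == ledger.items
        assert back.capital_assets == ledger.capital_assets
        assert grand_total(back, usd_config) == pytest.approx(
            grand_total(ledger, usd_config)
        )

    def test_zero_value_row_rejected_with_row_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "label,phase,category,cost_basis,value,currency,year,"
            "allocation_fraction,is_capital,useful_life_years,resale_fraction\n"
            "ok,implementation,staff,economic,10,USD,2015,1.0,,,\n"
            "bad,implementation,staff,economic,0,USD,2015,1.0,,,\n"
        )
        with pytest.raises(LedgerError, match="row 3"):
            load_ledger(path)

    def test_missing_category_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "label,phase,category,cost_basis,value,currency,year,"
            "allocation_fraction,is_capital,useful_life_years,resale_fraction\n"
            "bad,implementation,,economic,10,USD,2015,1.0,,,\n"
        )
        with pytest.raises(LedgerError, match="row 2"):
            load_ledger(path)
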