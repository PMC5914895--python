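import numpy as np
import pytest

from trialcea.config import AnalysisConfig
from trialcea.cost_engine import CostItem, CostLedger, MoneyAmount


@pytest.fixture
def usd_config() -> AnalysisConfig:
    return AnalysisConfig(
        base_year=2015,
        base_currency="USD",
        discount_rate=0.0926,
        horizon_years=1.5,
        exchange_rates={"UGX": {2013: 2586.9, 2014: 2599.8}},
        cpi={2013: 98.29, 2014: 99.88, 2015: 100.0},
    )


@pytest.fixture
def simple_ledger() -> CostLedger:
    """Three USD-2015 items, one per category, known totals."""

    def item(label, phase, category, value, frac=1.0):
        return CostItem(
            label=label,
            phase=phase,
            category=category,
            cost_basis="economic",
            amount=MoneyAmount(value, "USD", 2015),
            allocation_fraction=frac,
        )

    return CostLedger(
        items=(
            item("salaries", "implementation", "staff", 600.0),
            item("laptops", "start_up", "capital", 250.0),
            item("fuel", "implementation", "recurrent", 150.0),
        ),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
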