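"""Analysis configuration: base year/currency, discount rate, horizon,
exchange-rate and CPI tables.

Rate and CPI tables are user-supplied inputs, never bundled constants —
the series used by any particular study are part of its data, not of this
package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = ["AnalysisConfig", "load_config"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Immutable bundle of every analysis-wide parameter.

    Parameters
    ----------
    base_year :
        Calendar year all money is expressed in after inflation.
    base_currency :
        ISO-4217 code all money is converted to.
    discount_rate :
        Annual effective rate used to annualize capital.
    horizon_years :
        Analysis horizon in years (e.g. 1.5 for an 18-month trial).
    exchange_rates :
        ``{currency: {year: units-per-base}}``; the base currency itself
        never needs an entry.
    cpi :
        ``{year: index}`` consumer-price series for the base currency.
    denominators :
        Optional named counts for unit costs (e.g. schools, pupils).
    """

    base_year: int
    base_currency: str
    discount_rate: float
    horizon_years: float
    exchange_rates: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    cpi: Mapping[int, float] = field(default_factory=dict)
    denominators: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.horizon_years <= 0:
            raise ValueError(f"horizon_years must be > 0, got {self.horizon_years}")
        if self.discount_rate < 0:
            raise ValueError(f"discount_rate must be >= 0, got {self.discount_rate}")


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a JSON file.

    JSON object keys mirror the dataclass fields; year keys inside
    ``exchange_rates`` and ``cpi`` may be strings (JSON has no int keys)
    and are coerced to ``int``.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    rates = {
        cur: {int(y): float(r) for y, r in table.items()}
        for cur, table in raw.get("exchange_rates", {}).items()
    }
    cpi = {int(y): float(v) for y, v in raw.get("cpi", {}).items()}
    return AnalysisConfig(
        base_year=int(raw["base_year"]),
        base_currency=str(raw["base_currency"]),
        discount_rate=float(raw["discount_rate"]),
        horizon_years=float(raw["horizon_years"]),
        exchange_rates=rates,
        cpi=cpi,
        denominators={k: float(v) for k, v in raw.get("denominators", {}).items()},
    )
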