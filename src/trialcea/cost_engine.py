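"""Ingredients-based costing engine.

Turns a raw multi-currency, multi-year cost ledger into base-year economic
costs by phase and category, with capital annualization (equivalent annual
cost), shared-cost allocation, and unit costs.

Conventions, applied in this fixed order for every ledger line:

1. convert to the base currency at the expenditure year's average rate;
2. inflate to base-year prices with the CPI series;
3. multiply by the allocation fraction;
4. for capital lines, replace the outlay by its equivalent annual cost
   charged for ``horizon_years``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd

from trialcea._rounding import round_half_up
from trialcea.config import AnalysisConfig

__all__ = [
    "PHASES",
    "CATEGORIES",
    "COST_BASES",
    "MoneyAmount",
    "CostItem",
    "CapitalAsset",
    "CostLedger",
    "LedgerError",
    "UnknownExchangeRateError",
    "MissingCPIError",
    "convert_currency",
    "inflate_to_base_year",
    "to_base",
    "annuity_factor",
    "equivalent_annual_cost",
    "allocate",
    "item_contribution",
    "aggregate",
    "grand_total",
    "unit_cost",
    "load_ledger",
    "write_ledger_csv",
]

PHASES = ("development", "start_up", "implementation", "monitoring_evaluation")
CATEGORIES = ("staff", "capital", "recurrent")
COST_BASES = ("financial", "economic")

#: plausible expenditure-year window enforced on every MoneyAmount
YEAR_RANGE = (2000, 2030)


class LedgerError(ValueError):
    """Any structural problem with a ledger or one of its lines."""


class UnknownExchangeRateError(LedgerError):
    def __init__(self, currency: str, year: int):
        self.currency, self.year = currency, year
        super().__init__(f"unknown exchange rate for {currency} in {year}")


class MissingCPIError(LedgerError):
    def __init__(self, year: int):
        self.year = year
        super().__init__(f"no CPI entry for year {year}")


@dataclass(frozen=True)
class MoneyAmount:
    """A non-negative amount of money tagged with currency and year."""

    value: float
    currency: str
    year: int

    def __post_init__(self) -> None:
        if self.value < 0:
            raise LedgerError(f"money value must be >= 0, got {self.value}")
        if not YEAR_RANGE[0] <= self.year <= YEAR_RANGE[1]:
            raise LedgerError(
                f"year {self.year} outside plausible range {YEAR_RANGE}"
            )


@dataclass(frozen=True)
class CostItem:
    """One ledger line.

    ``allocation_fraction`` is the share of the expenditure attributable
    to the intervention (shared staff, overheads and capital are charged
    pro rata by proportion of use).
    """

    label: str
    phase: str
    category: str
    cost_basis: str
    amount: MoneyAmount
    allocation_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise LedgerError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        if self.category not in CATEGORIES:
            raise LedgerError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        if self.cost_basis not in COST_BASES:
            raise LedgerError(
                f"unknown cost_basis {self.cost_basis!r}; expected one of {COST_BASES}"
            )
        if not 0.0 <= self.allocation_fraction <= 1.0:
            raise LedgerError(
                f"allocation_fraction must be in [0, 1], got {self.allocation_fraction}"
            )


@dataclass(frozen=True)
class CapitalAsset:
    """A capital outlay annualized over its useful life.

    ``resale_fraction`` is the share of the principal recovered at end of
    life; values above 1 are permitted only so that sensitivity sweeps can
    explore them.
    """

    principal: MoneyAmount
    useful_life_years: int
    resale_fraction: float = 0.0
    discount_rate: float = 0.0
    label: str = ""
    phase: str = "start_up"
    category: str = "capital"
    cost_basis: str = "economic"
    allocation_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.useful_life_years < 1:
            raise LedgerError(
                f"useful_life_years must be >= 1, got {self.useful_life_years}"
            )
        if self.discount_rate < 0:
            raise LedgerError(f"discount_rate must be >= 0, got {self.discount_rate}")
        if self.resale_fraction < 0:
            raise LedgerError(
                f"resale_fraction must be >= 0, got {self.resale_fraction}"
            )
        if self.phase not in PHASES or self.category not in CATEGORIES:
            raise LedgerError(f"invalid phase/category on asset {self.label!r}")


@dataclass(frozen=True)
class CostLedger:
    """An ordered collection of cost items and capital assets."""

    items: tuple[CostItem, ...]
    capital_assets: tuple[CapitalAsset, ...] = ()
    base_year: int = 2015
    base_currency: str = "USD"
    horizon_years: float = 1.5

    def __post_init__(self) -> None:
        if self.horizon_years <= 0:
            raise LedgerError(f"horizon_years must be > 0, got {self.horizon_years}")


# ---------------------------------------------------------------------------
# money normalisation


def convert_currency(
    amount: MoneyAmount,
    rate_table: Mapping[str, Mapping[int, float]],
    base_currency: str,
) -> MoneyAmount:
    """Convert ``amount`` to the base currency at its expenditure year's rate.

    ``rate_table`` maps ``currency -> year -> units-per-base``. Amounts
    already in the base currency pass through unchanged. The year is
    preserved (inflation is a separate step).
    """
    if amount.currency == base_currency:
        return amount
    try:
        rate = rate_table[amount.currency][amount.year]
    except KeyError:
        raise UnknownExchangeRateError(amount.currency, amount.year) from None
    return MoneyAmount(amount.value / rate, base_currency, amount.year)


def inflate_to_base_year(
    amount: MoneyAmount, cpi_table: Mapping[int, float], base_year: int
) -> MoneyAmount:
    """Re-express ``amount`` (already in base currency) at base-year prices."""
    if amount.year == base_year:
        return amount
    for year in (amount.year, base_year):
        if year not in cpi_table:
            raise MissingCPIError(year)
    factor = cpi_table[base_year] / cpi_table[amount.year]
    return MoneyAmount(amount.value * factor, amount.currency, base_year)


def to_base(amount: MoneyAmount, config: AnalysisConfig) -> MoneyAmount:
    """Convert then inflate — the pipeline's pinned order."""
    converted = convert_currency(amount, config.exchange_rates, config.base_currency)
    return inflate_to_base_year(converted, config.cpi, config.base_year)


# ---------------------------------------------------------------------------
# capital annualization


def annuity_factor(rate: float, n: int | float) -> float:
    """Present value of 1 unit per year for ``n`` years at ``rate``.

    Equals ``sum((1 + rate) ** -t for t in 1..n)``; ``n`` for a zero rate.
    """
    if n < 1:
        raise ValueError(f"annuity horizon must be >= 1 year, got {n}")
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if rate == 0:
        return float(n)
    return (1.0 - (1.0 + rate) ** -n) / rate


def equivalent_annual_cost(asset: CapitalAsset) -> float:
    """Constant annual charge equivalent to a capital outlay.

    EAC = (P − S·(1+r)^−n) / annuity_factor(r, n) with S the discounted
    resale value ``resale_fraction × P``. When the asset is fully
    resaleable (``resale_fraction = 1``) this reduces analytically to
    ``P · r``: holding the asset costs only the interest on its value.
    """
    p = asset.principal.value
    r = asset.discount_rate
    n = asset.useful_life_years
    salvage = asset.resale_fraction * p
    if r == 0:
        return (p - salvage) / n
    return (p - salvage * (1.0 + r) ** -n) / annuity_factor(r, n)


# ---------------------------------------------------------------------------
# allocation and aggregation


def allocate(item: CostItem) -> float:
    """Share of an item's value attributable to the intervention.

    Precondition: ``item.amount`` has already been converted and inflated
    to the base year (see :func:`to_base`).
    """
    return item.amount.value * item.allocation_fraction


def item_contribution(item: CostItem, config: AnalysisConfig) -> float:
    """Full per-line pipeline: convert, inflate, allocate."""
    return to_base(item.amount, config).value * item.allocation_fraction


def _asset_contribution(asset: CapitalAsset, config: AnalysisConfig) -> float:
    """Capital line: normalise the principal, annualize, charge the horizon."""
    principal = to_base(asset.principal, config)
    normalised = replace(asset, principal=principal)
    return (
        equivalent_annual_cost(normalised)
        * config.horizon_years
        * asset.allocation_fraction
    )


def _in_scope(phase: str, include_me: bool) -> bool:
    return include_me or phase != "monitoring_evaluation"


def aggregate(
    ledger: CostLedger,
    config: AnalysisConfig,
    group_by: Literal["phase", "category"] = "phase",
    include_me: bool = False,
) -> pd.DataFrame:
    """Total base-year cost per phase or per category.

    Capital assets enter as equivalent annual cost × ``horizon_years``.
    Monitoring & evaluation lines are excluded unless ``include_me``.

    Returns a DataFrame with columns ``group``, ``total`` (full
    precision) and ``percent`` (share of the in-scope grand total,
    rounded half-up to an integer, for reporting).
    """
    if group_by not in ("phase", "category"):
        raise ValueError(f"group_by must be 'phase' or 'category', got {group_by!r}")
    totals: dict[str, float] = {}
    n_lines = 0
    for item in ledger.items:
        if not _in_scope(item.phase, include_me):
            continue
        key = item.phase if group_by == "phase" else item.category
        totals[key] = totals.get(key, 0.0) + item_contribution(item, config)
        n_lines += 1
    for asset in ledger.capital_assets:
        if not _in_scope(asset.phase, include_me):
            continue
        key = asset.phase if group_by == "phase" else asset.category
        totals[key] = totals.get(key, 0.0) + _asset_contribution(asset, config)
        n_lines += 1
    if n_lines == 0:
        raise LedgerError("empty ledger: no in-scope cost lines to aggregate")
    grand = sum(totals.values())
    order = PHASES if group_by == "phase" else CATEGORIES
    rows = [
        {
            "group": g,
            "total": totals[g],
            "percent": round_half_up(100.0 * totals[g] / grand) if grand else 0.0,
        }
        for g in order
        if g in totals
    ]
    return pd.DataFrame(rows, columns=["group", "total", "percent"])


def grand_total(
    ledger: CostLedger, config: AnalysisConfig, include_me: bool = False
) -> float:
    """In-scope grand total (same scope rules as :func:`aggregate`)."""
    return float(aggregate(ledger, config, "phase", include_me)["total"].sum())


def unit_cost(total: float, denominator: float, label: str = "") -> float:
    """``total / denominator`` at full precision.

    Reports round the result half-up to the nearest whole currency unit;
    this function does not.
    """
    if denominator <= 0:
        raise ZeroDivisionError(
            f"unit cost {label or 'denominator'!s} requires a positive denominator, "
            f"got {denominator}"
        )
    return total / denominator


# ---------------------------------------------------------------------------
# CSV interface

LEDGER_COLUMNS = [
    "label",
    "phase",
    "category",
    "cost_basis",
    "value",
    "currency",
    "year",
    "allocation_fraction",
    "is_capital",
    "useful_life_years",
    "resale_fraction",
]


def load_ledger(
    path: str | Path,
    base_year: int = 2015,
    base_currency: str = "USD",
    horizon_years: float = 1.5,
    discount_rate: float = 0.0,
) -> CostLedger:
    """Read a ledger CSV (UTF-8, header required).

    Degenerate rows — zero/blank value, missing phase or category — are
    rejected with row-numbered errors rather than silently dropped.
    Capital rows (``is_capital`` truthy) become :class:`CapitalAsset`
    entries annualized at ``discount_rate``.
    """
    items: list[CostItem] = []
    assets: list[CapitalAsset] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "value" not in reader.fieldnames:
            raise LedgerError(f"{path}: missing header row with a 'value' column")
        for lineno, row in enumerate(reader, start=2):
            try:
                value = float(row["value"] or "nan")
                if not value > 0:
                    raise LedgerError(f"non-positive or missing value {row['value']!r}")
                amount = MoneyAmount(value, row["currency"].strip(), int(row["year"]))
                common = dict(
                    label=row["label"],
                    phase=row["phase"].strip(),
                    category=row["category"].strip(),
                    cost_basis=row["cost_basis"].strip(),
                    allocation_fraction=float(row["allocation_fraction"] or 1.0),
                )
                if str(row.get("is_capital", "")).strip().lower() in ("1", "true", "yes"):
                    assets.append(
                        CapitalAsset(
                            principal=amount,
                            useful_life_years=int(row["useful_life_years"]),
                            resale_fraction=float(row["resale_fraction"] or 0.0),
                            discount_rate=discount_rate,
                            **common,
                        )
                    )
                else:
                    items.append(CostItem(amount=amount, **common))
            except (LedgerError, KeyError, ValueError) as exc:
                raise LedgerError(f"{path}, row {lineno}: {exc}") from exc
    return CostLedger(
        items=tuple(items),
        capital_assets=tuple(assets),
        base_year=base_year,
        base_currency=base_currency,
        horizon_years=horizon_years,
    )


def write_ledger_csv(ledger: CostLedger, path: str | Path) -> None:
    """Write a ledger in the CSV dialect :func:`load_ledger` consumes."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LEDGER_COLUMNS)
        for it in ledger.items:
            writer.writerow(
                [
                    it.label,
                    it.phase,
                    it.category,
                    it.cost_basis,
                    repr(float(it.amount.value)),
                    it.amount.currency,
                    it.amount.year,
                    repr(float(it.allocation_fraction)),
                    "",
                    "",
                    "",
                ]
            )
        for a in ledger.capital_assets:
            writer.writerow(
                [
                    a.label,
                    a.phase,
                    a.category,
                    a.cost_basis,
                    repr(float(a.principal.value)),
                    a.principal.currency,
                    a.principal.year,
                    repr(float(a.allocation_fraction)),
                    "true",
                    a.useful_life_years,
                    repr(float(a.resale_fraction)),
                ]
            )
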