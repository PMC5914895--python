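"""Cost-effectiveness ratios and univariate (tornado) sensitivity analysis.

The comparator is do-nothing: zero incremental cost, zero cases averted.
The ratio is therefore a simple quotient of programme cost over cases
averted, undefined when nothing is averted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from trialcea._rounding import round_half_up
from trialcea.effect_engine import CaseCounts

__all__ = [
    "CEAResult",
    "SensitivityRow",
    "NotCostEffectiveError",
    "UnknownParameterError",
    "cost_effectiveness",
    "tornado",
]

#: tolerance for the bracketing invariant (guards float noise only)
_BRACKET_TOL = 1e-9


class NotCostEffectiveError(ValueError):
    """Raised when zero or negative cases are averted vs do-nothing."""

    def __init__(self, averted: float):
        self.averted = averted
        super().__init__(
            f"not cost-effective vs do-nothing: {averted:g} cases averted, "
            "cost-per-case ratio undefined"
        )


class UnknownParameterError(KeyError):
    def __init__(self, name: str, valid: Sequence[str]):
        super().__init__(
            f"unknown sensitivity parameter {name!r}; valid names: {sorted(valid)}"
        )


@dataclass(frozen=True)
class CEAResult:
    """Cost-effectiveness summary for one pipeline run.

    Ratios are stored at full precision; :meth:`rounded` gives the
    report-style half-up whole-dollar view.
    """

    total_cost: float
    annual_cost: float
    averted_cases: float
    cost_per_case_total: float
    cost_per_case_annual: float
    unit_costs: Mapping[str, float] = field(default_factory=dict)

    def rounded(self) -> dict[str, float]:
        out = {
            "total_cost": round_half_up(self.total_cost),
            "annual_cost": round_half_up(self.annual_cost),
            "averted_cases": round_half_up(self.averted_cases),
            "cost_per_case_total": round_half_up(self.cost_per_case_total),
            "cost_per_case_annual": round_half_up(self.cost_per_case_annual),
        }
        out.update({k: round_half_up(v) for k, v in self.unit_costs.items()})
        return out


@dataclass(frozen=True)
class SensitivityRow:
    """One univariate perturbation: results at the low and high parameter
    values around the untouched base case."""

    parameter: str
    perturbation: str
    low_result: float
    base_result: float
    high_result: float
    result_kind: str = "total_cost"

    def __post_init__(self) -> None:
        lo = min(self.low_result, self.high_result) - _BRACKET_TOL
        hi = max(self.low_result, self.high_result) + _BRACKET_TOL
        if not lo <= self.base_result <= hi:
            raise ValueError(
                f"sensitivity row {self.parameter!r} does not bracket the base: "
                f"base {self.base_result} outside [{lo}, {hi}]"
            )


def cost_effectiveness(
    total_cost: float,
    annual_cost: float,
    counts: CaseCounts,
    unit_costs: Mapping[str, float] | None = None,
) -> CEAResult:
    """Cost per case averted against a do-nothing comparator."""
    if counts.averted_cases <= 0:
        raise NotCostEffectiveError(counts.averted_cases)
    return CEAResult(
        total_cost=total_cost,
        annual_cost=annual_cost,
        averted_cases=counts.averted_cases,
        cost_per_case_total=total_cost / counts.averted_cases,
        cost_per_case_annual=annual_cost / counts.averted_cases,
        unit_costs=dict(unit_costs or {}),
    )


def tornado(
    base_config: Mapping[str, float],
    perturbations: Sequence[tuple[str, float, float]],
    pipeline: Callable[[Mapping[str, float]], float],
    result_kind: str = "total_cost",
) -> list[SensitivityRow]:
    """Univariate sensitivity analysis.

    For each ``(parameter, low, high)`` the *entire* pipeline is re-run
    with exactly that one parameter replaced — outputs are never scaled
    post hoc, so interactions (e.g. with capital annualization) are
    honoured. An empty perturbation list returns no rows and leaves the
    base result as the single source of truth.
    """
    base_config = dict(base_config)
    base_result = float(pipeline(base_config))
    rows: list[SensitivityRow] = []
    for name, low, high in perturbations:
        if name not in base_config:
            raise UnknownParameterError(name, list(base_config))
        cfg_low = {**base_config, name: low}
        cfg_high = {**base_config, name: high}
        rows.append(
            SensitivityRow(
                parameter=name,
                perturbation=f"{low:g} .. {high:g} (base {base_config[name]:g})",
                low_result=float(pipeline(cfg_low)),
                base_result=base_result,
                high_result=float(pipeline(cfg_high)),
                result_kind=result_kind,
            )
        )
    return rows
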