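"""Result bundles, deterministic report rendering, and the built-in
worked example.

Every headline number in a bundle carries a provenance string naming the
operation chain that produced it, so any printed figure can be traced
back to its inputs. Reports round money half-up to whole dollars and
percents to integers; JSON keeps full precision alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from trialcea._rounding import round_half_up
from trialcea.cea_engine import SensitivityRow, cost_effectiveness, tornado
from trialcea.cost_engine import (
    CapitalAsset,
    MoneyAmount,
    aggregate,
    equivalent_annual_cost,
    unit_cost,
)
from trialcea.effect_engine import counterfactual_cases
from trialcea.synthetic_data import simulate_ledger

__all__ = [
    "ReportBundle",
    "render_report",
    "run_paper_fixture",
    "teacher_time_midpoint",
    "percent_share",
    "FIXTURE",
]


def teacher_time_midpoint(low: float, high: float) -> float:
    """Average economic cost of teacher time: midpoint of salary-derived
    bounds (the only aggregation the underlying range supports)."""
    return (low + high) / 2.0


def percent_share(part: float, whole: float) -> float:
    """Integer percent (half-up) of ``part`` in ``whole``."""
    if whole <= 0:
        raise ZeroDivisionError("percent share requires a positive denominator")
    return round_half_up(100.0 * part / whole)


@dataclass(frozen=True)
class ReportBundle:
    """Everything a rendered report needs: cost table, sensitivity tables,
    headline figures, and per-figure provenance strings."""

    table1: pd.DataFrame  # columns: group, total, percent (phases then categories)
    table2: tuple[SensitivityRow, ...]  # sensitivity of total cost
    table3: tuple[SensitivityRow, ...]  # sensitivity of cost per case
    headline: Mapping[str, float]
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [k for k in self.headline if k not in self.provenance]
        if missing:
            raise ValueError(f"headline values without provenance: {missing}")


# ---------------------------------------------------------------------------
# rendering


def _fmt_money(x: float) -> str:
    return f"{round_half_up(x):,.0f}"


def _table1_text(table1: pd.DataFrame) -> str:
    lines = ["Costs by phase and category", "-" * 44]
    total = table1[table1.kind == "phase"]["total"].sum()
    lines.append(f"{'Total':<28}{_fmt_money(total):>12}")
    for _, row in table1.iterrows():
        pct = f"{row.percent:.0f}" if pd.notna(row.percent) else ""
        lines.append(f"{row.group:<28}{_fmt_money(row.total):>12}{pct:>4}")
    return "\n".join(lines)


def _sensitivity_text(title: str, rows: Sequence[SensitivityRow]) -> str:
    if not rows:
        return f"{title}\n(no sensitivity rows supplied)"
    lines = [title, "-" * 60]
    for r in rows:
        lo = min(r.low_result, r.high_result)
        hi = max(r.low_result, r.high_result)
        lines.append(
            f"{r.parameter:<32}{_fmt_money(lo):>12}{_fmt_money(hi):>12}"
        )
    return "\n".join(lines)


def _rows_frame(rows: Sequence[SensitivityRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "perturbation": r.perturbation,
                "low_result": round_half_up(r.low_result),
                "base_result": round_half_up(r.base_result),
                "high_result": round_half_up(r.high_result),
                "result_kind": r.result_kind,
            }
            for r in rows
        ],
        columns=[
            "parameter",
            "perturbation",
            "low_result",
            "base_result",
            "high_result",
            "result_kind",
        ],
    )


def render_report(
    bundle: ReportBundle, fmt: str, out_dir: str | Path
) -> list[Path]:
    """Write the bundle as ``csv``, ``text`` or ``json`` files.

    Deterministic: identical bundles yield byte-identical files.
    Returns the list of files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt == "csv":
        t1 = bundle.table1.copy()
        t1["total"] = t1["total"].map(round_half_up)
        paths = {
            "table1_costs.csv": t1,
            "table2_total_cost_sensitivity.csv": _rows_frame(bundle.table2),
            "table3_cost_per_case_sensitivity.csv": _rows_frame(bundle.table3),
            "headline.csv": pd.DataFrame(
                [
                    {
                        "label": k,
                        "value": round_half_up(v)
                        if "percent" not in k
                        else v,
                        "provenance": bundle.provenance.get(k, ""),
                    }
                    for k, v in bundle.headline.items()
                ]
            ),
        }
        for name, frame in paths.items():
            p = out / name
            frame.to_csv(p, index=False)
            written.append(p)
    elif fmt == "text":
        blocks = [
            _table1_text(bundle.table1),
            _sensitivity_text("Sensitivity of total cost", bundle.table2),
            _sensitivity_text("Sensitivity of cost per case averted", bundle.table3),
            "Headline figures",
            "-" * 44,
        ]
        for k, v in bundle.headline.items():
            blocks.append(f"{k:<36}{round_half_up(v):>12,.0f}")
        p = out / "report.txt"
        p.write_text("\n".join(blocks) + "\n", encoding="utf-8")
        written.append(p)
    elif fmt == "json":
        payload = {
            "table1": bundle.table1.to_dict(orient="records"),
            "table2": _rows_frame(bundle.table2).to_dict(orient="records"),
            "table3": _rows_frame(bundle.table3).to_dict(orient="records"),
            "headline": {k: round_half_up(v) for k, v in bundle.headline.items()},
            "headline_full_precision": dict(bundle.headline),
            "provenance": dict(bundle.provenance),
        }
        p = out / "report.json"
        p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", "utf-8")
        written.append(p)
    else:
        raise ValueError(f"unknown report format {fmt!r}; use csv, text or json")
    return written


# ---------------------------------------------------------------------------
# built-in worked example
#
# All inputs below are published summary figures for an 18-month, 21-school
# school-violence-prevention programme: phase/category cost totals
# (excluding monitoring & evaluation), the programme-level counterfactual
# prevalences, the annualization conventions for the one-off design
# investment, and the teacher-salary-derived time-cost bounds. They are
# *inputs*; every reported figure is recomputed from them at run time.

FIXTURE: dict[str, object] = {
    "category_totals": {"staff": 156_441.0, "capital": 69_164.0, "recurrent": 171_628.0},
    "phase_totals": {"start_up": 117_949.0, "implementation": 279_284.0},
    "annual_implementation_cost": 157_343.0,
    "n_schools": 21,
    "n_pupils": 9_000,
    "expected_prevalence": 0.49,
    "observed_prevalence": 0.31,
    "dev_principal": 446_940.0,
    "dev_staff_cost": 244_251.0,
    "dev_resale_fraction": 1.0,
    "dev_useful_life_years": 7,
    "discount_rate": 0.0926,
    "horizon_years": 1.5,
    "total_cost_incl_me": 449_845.0,
    "staff_cost_incl_me": 211_439.0,
    "teacher_time_low": 1_589.0,
    "teacher_time_high": 2_781.0,
    "averted_ci": (720.0, 2_430.0),
}


def _dev_asset(principal: float, resale: float, f: Mapping[str, object]) -> CapitalAsset:
    return CapitalAsset(
        principal=MoneyAmount(principal, "USD", 2012),
        useful_life_years=int(f["dev_useful_life_years"]),
        resale_fraction=resale,
        discount_rate=float(f["discount_rate"]),
        label="programme design and development",
        phase="development",
        category="capital",
    )


def _fixture_cost_pipeline(
    other_cost: float, horizon: float
) -> "callable":
    """Total-cost pipeline over the tornado parameter dict.

    Parameters: ``dev_principal`` and ``dev_resale_fraction``. The
    development investment is annualized (equivalent annual cost) and
    charged for the horizon on top of the fixed running costs.
    """

    def pipeline(params: Mapping[str, float]) -> float:
        asset = _dev_asset(
            params["dev_principal"], params["dev_resale_fraction"], FIXTURE
        )
        return other_cost + equivalent_annual_cost(asset) * horizon

    return pipeline


def run_paper_fixture(seed: int = 0) -> ReportBundle:
    """Recompute the worked example's headline figures from first
    principles: a synthetic ledger reproducing the published cost margins
    is aggregated, counterfactual cases are derived from the published
    prevalences, and ratios, unit costs and sensitivity rows follow.
    """
    f = FIXTURE
    horizon = float(f["horizon_years"])

    # cost side: ledger realising the published phase/category margins
    ledger, config = simulate_ledger(
        {
            "category_totals": f["category_totals"],
            "phase_totals": f["phase_totals"],
            "n_capital_assets": 0,
        },
        seed=seed,
        horizon_years=horizon,
        discount_rate=float(f["discount_rate"]),
    )
    by_phase = aggregate(ledger, config, "phase")
    by_category = aggregate(ledger, config, "category")
    total_cost = float(by_phase["total"].sum())

    # effect side
    counts = counterfactual_cases(
        int(f["n_pupils"]),
        float(f["expected_prevalence"]),
        float(f["observed_prevalence"]),
    )

    annual_cost = float(f["annual_implementation_cost"])
    per_school = unit_cost(annual_cost, int(f["n_schools"]), "per school")
    cea = cost_effectiveness(
        total_cost, annual_cost, counts, unit_costs={"per_school_annual": per_school}
    )

    # sensitivity: development principal +-50%, resale fraction +-50%,
    # cases averted at its interval bounds; full pipeline re-run each time
    dev_p = float(f["dev_principal"])
    resale = float(f["dev_resale_fraction"])
    dev_eac_charge = (
        equivalent_annual_cost(_dev_asset(dev_p, resale, f)) * horizon
    )
    other_cost = total_cost - dev_eac_charge
    cost_pipeline = _fixture_cost_pipeline(other_cost, horizon)
    cost_params = {"dev_principal": dev_p, "dev_resale_fraction": resale}
    table2 = tornado(
        cost_params,
        [
            ("dev_principal", 0.5 * dev_p, 1.5 * dev_p),
            ("dev_resale_fraction", 0.5 * resale, 1.5 * resale),
        ],
        cost_pipeline,
        result_kind="total_cost",
    )

    ci_low, ci_high = (float(v) for v in f["averted_ci"])
    ratio_params = {**cost_params, "averted_cases": float(counts.averted_cases)}

    def ratio_pipeline(params: Mapping[str, float]) -> float:
        return cost_pipeline(params) / params["averted_cases"]

    table3 = tornado(
        ratio_params,
        [
            ("dev_principal", 0.5 * dev_p, 1.5 * dev_p),
            ("dev_resale_fraction", 0.5 * resale, 1.5 * resale),
            ("averted_cases", ci_high, ci_low),  # more averted -> cheaper per case
        ],
        ratio_pipeline,
        result_kind="cost_per_case",
    )

    table1 = pd.concat(
        [by_phase.assign(kind="phase"), by_category.assign(kind="category")],
        ignore_index=True,
    )

    headline = {
        "total_cost_excl_me": total_cost,
        "expected_cases": counts.expected_cases,
        "observed_cases": counts.observed_cases,
        "averted_cases": counts.averted_cases,
        "cost_per_case_total": cea.cost_per_case_total,
        "cost_per_case_annual": cea.cost_per_case_annual,
        "annual_cost_per_school": per_school,
        "implementation_percent": float(
            by_phase.loc[by_phase.group == "implementation", "percent"].iloc[0]
        ),
        "recurrent_percent": float(
            by_category.loc[by_category.group == "recurrent", "percent"].iloc[0]
        ),
        "staff_percent_incl_me": percent_share(
            float(f["staff_cost_incl_me"]), float(f["total_cost_incl_me"])
        ),
        "dev_staff_percent": percent_share(
            float(f["dev_staff_cost"]), float(f["dev_principal"])
        ),
        "teacher_time_cost": teacher_time_midpoint(
            float(f["teacher_time_low"]), float(f["teacher_time_high"])
        ),
    }
    provenance = {
        "total_cost_excl_me": "aggregate(simulated ledger at published margins, by phase).sum",
        "expected_cases": "counterfactual_cases(n_pupils, expected_prevalence, observed_prevalence).expected",
        "observed_cases": "counterfactual_cases(...).observed",
        "averted_cases": "counterfactual_cases(...).expected - observed",
        "cost_per_case_total": "cost_effectiveness(total_cost_excl_me, ...).cost_per_case_total",
        "cost_per_case_annual": "cost_effectiveness(..., annual_implementation_cost).cost_per_case_annual",
        "annual_cost_per_school": "unit_cost(annual_implementation_cost, n_schools)",
        "implementation_percent": "aggregate(by phase).percent[implementation]",
        "recurrent_percent": "aggregate(by category).percent[recurrent]",
        "staff_percent_incl_me": "percent_share(staff_cost_incl_me, total_cost_incl_me)",
        "dev_staff_percent": "percent_share(dev_staff_cost, dev_principal)",
        "teacher_time_cost": "teacher_time_midpoint(teacher_time_low, teacher_time_high)",
    }
    return ReportBundle(
        table1=table1,
        table2=tuple(table2),
        table3=tuple(table3),
        headline=headline,
        provenance=provenance,
    )
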