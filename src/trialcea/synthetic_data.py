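"""Simulators with known ground truth for every pipeline stage.

Trial outcomes use a beta-binomial construction: cluster prevalences are
beta-distributed with mean equal to the arm prevalence and a variance
implied by the intracluster correlation, and pupil outcomes are Bernoulli
given their cluster's prevalence. Beta-binomial (rather than logit-normal)
clustering is used because the mean/ICC relation is closed-form, so
desk-scale checks are exact.

All randomness flows from a single integer seed. Each component draws
from its own numbered substream (``default_rng([seed, k])``), so adding a
component never perturbs the draws of earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from trialcea.config import AnalysisConfig
from trialcea.cost_engine import (
    CATEGORIES,
    CapitalAsset,
    CostItem,
    CostLedger,
    MoneyAmount,
    annuity_factor,
)
from trialcea.effect_engine import PupilRecord

__all__ = [
    "TrialDesign",
    "simulate_trial",
    "simulate_ledger",
    "InfeasibleProfileError",
]

# substream indices (append-only; never renumber)
_STREAM_CLUSTER_PREV = 0
_STREAM_OUTCOMES = 1
_STREAM_COVARIATES = 2
_STREAM_LEDGER = 3


class InfeasibleProfileError(ValueError):
    """Requested ledger profile cannot be realised (margin mismatch)."""


@dataclass(frozen=True)
class TrialDesign:
    """Two-arm cluster-trial generating parameters.

    ``risk_difference`` is protective: the intervention-arm prevalence is
    ``control_prevalence - risk_difference``.
    """

    n_clusters_per_arm: int
    pupils_per_cluster: int | Sequence[int]
    control_prevalence: float
    risk_difference: float
    icc: float = 0.0
    covariate_effects: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters_per_arm < 1:
            raise ValueError("need at least one cluster per arm")
        if not 0.0 < self.control_prevalence < 1.0:
            raise ValueError("control_prevalence must be in (0, 1)")
        if not 0.0 < self.control_prevalence - self.risk_difference < 1.0:
            raise ValueError(
                "intervention prevalence (control_prevalence - risk_difference) "
                "must lie in (0, 1)"
            )
        if not 0.0 <= self.icc < 1.0:
            raise ValueError("icc must be in [0, 1)")

    def cluster_sizes(self) -> list[int]:
        if isinstance(self.pupils_per_cluster, int):
            return [self.pupils_per_cluster] * (2 * self.n_clusters_per_arm)
        sizes = list(self.pupils_per_cluster)
        if len(sizes) != 2 * self.n_clusters_per_arm:
            raise ValueError(
                f"pupils_per_cluster list must have {2 * self.n_clusters_per_arm} "
                f"entries, got {len(sizes)}"
            )
        return sizes


def _beta_params(mean: float, icc: float) -> tuple[float, float]:
    # icc = 1 / (a + b + 1) for a Beta(a, b) cluster-prevalence law
    s = 1.0 / icc - 1.0
    a, b = mean * s, (1.0 - mean) * s
    # degenerate shapes (numerically ~0) would concentrate all mass at 0/1
    if a <= 1e-6 or b <= 1e-6:
        raise ValueError(
            f"icc {icc} too large for arm prevalence {mean}: "
            f"beta parameters ({a:g}, {b:g}) must be positive"
        )
    return a, b


def simulate_trial(design: TrialDesign) -> list[PupilRecord]:
    """Generate pupil records for a two-arm cluster trial.

    Identical seeds give byte-identical output. Control clusters are
    named ``c01..``, intervention clusters ``i01..``.
    """
    rng_prev = np.random.default_rng([design.seed, _STREAM_CLUSTER_PREV])
    rng_out = np.random.default_rng([design.seed, _STREAM_OUTCOMES])
    rng_cov = np.random.default_rng([design.seed, _STREAM_COVARIATES])

    sizes = design.cluster_sizes()
    effects = (
        np.asarray(design.covariate_effects, dtype=float)
        if design.covariate_effects is not None
        else None
    )
    p_int = design.control_prevalence - design.risk_difference

    records: list[PupilRecord] = []
    width = len(str(design.n_clusters_per_arm))
    for k, (arm, prefix, mean) in enumerate(
        [("control", "c", design.control_prevalence), ("intervention", "i", p_int)]
    ):
        for j in range(design.n_clusters_per_arm):
            if design.icc == 0.0:
                p_cluster = mean
            else:
                a, b = _beta_params(mean, design.icc)
                p_cluster = float(rng_prev.beta(a, b))
            n = sizes[k * design.n_clusters_per_arm + j]
            school = f"{prefix}{j + 1:0{width}d}"
            if effects is None:
                outcomes = rng_out.binomial(1, p_cluster, size=n)
                for y in outcomes:
                    records.append(PupilRecord(school, arm, int(y)))
            else:
                school_term = rng_cov.standard_normal(len(effects))
                for _ in range(n):
                    z = school_term + rng_cov.standard_normal(len(effects))
                    p = float(np.clip(p_cluster + effects @ z, 0.01, 0.99))
                    y = int(rng_out.binomial(1, p))
                    records.append(PupilRecord(school, arm, y, tuple(z)))
    return records


# ---------------------------------------------------------------------------
# ledger simulation

# fixture exchange-rate (units per USD) and CPI series covering the
# expenditure years the simulator draws from
_RATE_YEARS = (2012, 2013, 2014)
_UGX_RATES = {2012: 2504.6, 2013: 2586.9, 2014: 2599.8}
_GBP_RATES = {2012: 0.6308, 2013: 0.6395, 2014: 0.6072}
_CPI = {2012: 96.87, 2013: 98.29, 2014: 99.88, 2015: 100.0}


def _synthetic_config(horizon_years: float, discount_rate: float) -> AnalysisConfig:
    return AnalysisConfig(
        base_year=2015,
        base_currency="USD",
        discount_rate=discount_rate,
        horizon_years=horizon_years,
        exchange_rates={"UGX": dict(_UGX_RATES), "GBP": dict(_GBP_RATES)},
        cpi=dict(_CPI),
    )


def _raw_value(target_usd2015: float, currency: str, year: int) -> float:
    """Invert convert→inflate so the normalised value hits the target."""
    if currency == "USD":
        rate = 1.0
    elif currency == "UGX":
        rate = _UGX_RATES[year]
    else:
        rate = _GBP_RATES[year]
    inflate = _CPI[2015] / _CPI[year]
    return target_usd2015 * rate / inflate


def simulate_ledger(
    profile: Mapping[str, object],
    seed: int = 0,
    horizon_years: float = 1.5,
    discount_rate: float = 0.0926,
) -> tuple[CostLedger, AnalysisConfig]:
    """Build a multi-currency ledger whose normalised totals are known.

    ``profile`` keys:

    - ``category_totals``: mapping category -> base-year total (required);
    - ``phase_totals``: mapping phase -> total (optional; defaults to an
      even start-up/implementation split). Must sum to the same grand
      total as the categories;
    - ``n_capital_assets``: how many capital lines to carve out of the
      ``capital`` category (default 1 when that category is positive).

    Line amounts are constructed by inverting the convert→inflate
    pipeline, so aggregation reproduces the requested totals to well
    within one currency unit. Capital lines are sized so that their
    equivalent annual cost times ``horizon_years`` contributes exactly
    their carved share.
    """
    rng = np.random.default_rng([seed, _STREAM_LEDGER])

    cat_totals = {c: float(v) for c, v in dict(profile["category_totals"]).items()}
    for c in cat_totals:
        if c not in CATEGORIES:
            raise InfeasibleProfileError(f"unknown category {c!r}")
        if cat_totals[c] < 0:
            raise InfeasibleProfileError(f"negative total for category {c!r}")
    grand = sum(cat_totals.values())

    if "phase_totals" in profile and profile["phase_totals"] is not None:
        phase_totals = {p: float(v) for p, v in dict(profile["phase_totals"]).items()}
        if abs(sum(phase_totals.values()) - grand) > 1e-6 * max(1.0, grand):
            raise InfeasibleProfileError(
                f"phase totals sum to {sum(phase_totals.values()):.6f} but "
                f"category totals sum to {grand:.6f}"
            )
    else:
        phase_totals = {"start_up": 0.5 * grand, "implementation": 0.5 * grand}

    config = _synthetic_config(horizon_years, discount_rate)
    if grand == 0.0:
        return (
            CostLedger((), (), 2015, "USD", horizon_years),
            config,
        )

    n_cap = int(profile.get("n_capital_assets", 1 if cat_totals.get("capital") else 0))

    items: list[CostItem] = []
    assets: list[CapitalAsset] = []
    currencies = ("USD", "UGX", "GBP")
    phases = [p for p, v in phase_totals.items() if v > 0]

    for category, cat_total in cat_totals.items():
        if cat_total <= 0:
            continue
        # proportional fitting: cell(phase, category) = row * col / grand
        for phase in phases:
            cell = phase_totals[phase] * cat_total / grand
            if cell <= 0:
                continue
            carve_capital = category == "capital" and n_cap > 0
            n_plain = int(rng.integers(1, 4))
            weights = rng.dirichlet(np.ones(n_plain + (n_cap if carve_capital else 0)))
            targets = weights * cell
            for i, target in enumerate(targets):
                currency = currencies[int(rng.integers(len(currencies)))]
                year = int(rng.choice(_RATE_YEARS))
                frac = float(rng.choice([0.5, 0.8, 1.0]))
                if carve_capital and i >= n_plain:
                    # principal such that EAC * horizon * frac == target
                    life = int(rng.integers(3, 9))
                    resale = float(rng.choice([0.0, 0.25, 0.5]))
                    r = discount_rate
                    eac_per_unit = (1.0 - resale * (1.0 + r) ** -life) / annuity_factor(
                        r, life
                    )
                    principal = target / (horizon_years * eac_per_unit * frac)
                    assets.append(
                        CapitalAsset(
                            principal=MoneyAmount(
                                _raw_value(principal, currency, year), currency, year
                            ),
                            useful_life_years=life,
                            resale_fraction=resale,
                            discount_rate=r,
                            label=f"{phase}/{category} asset {i}",
                            phase=phase,
                            category=category,
                            allocation_fraction=frac,
                        )
                    )
                else:
                    items.append(
                        CostItem(
                            label=f"{phase}/{category} item {i}",
                            phase=phase,
                            category=category,
                            cost_basis="economic",
                            amount=MoneyAmount(
                                _raw_value(target / frac, currency, year),
                                currency,
                                year,
                            ),
                            allocation_fraction=frac,
                        )
                    )
            # capital is carved once, in the first phase that has a cell
            if carve_capital:
                n_cap = 0
    ledger = CostLedger(
        items=tuple(items),
        capital_assets=tuple(assets),
        base_year=2015,
        base_currency="USD",
        horizon_years=horizon_years,
    )
    return ledger, config
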