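"""Cluster-adjusted risk-difference estimation and cases-averted arithmetic.

The effect model is an identity-link regression of the binary outcome on
the arm indicator (plus optional covariates), so the arm coefficient is an
absolute risk difference. Variance comes from a cluster-robust sandwich
with schools as clusters:

    V = (X'X)^-1 ( sum_g X_g' e_g e_g' X_g ) (X'X)^-1 * G/(G-1)

where G is the number of clusters. An identity-link binomial GLM is tried
first; if IRLS fails to converge or produces fitted probabilities outside
[0, 1], the estimator falls back to an ordinary linear-probability fit
(flagged in the output) — same mean function, same sandwich.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

from trialcea._rounding import round_half_up

__all__ = [
    "ARMS",
    "PupilRecord",
    "EffectEstimate",
    "CaseCounts",
    "EffectDataError",
    "fit_risk_difference",
    "counterfactual_cases",
    "averted_bounds",
    "load_pupils",
    "write_pupils_csv",
]

ARMS = ("control", "intervention")


class EffectDataError(ValueError):
    """Trial data unusable for estimation (single arm, empty cluster, ...)."""


@dataclass(frozen=True)
class PupilRecord:
    """One pupil: cluster label, arm, binary outcome, optional covariates."""

    school_id: str
    arm: str
    outcome: int
    covariates: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise EffectDataError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.outcome not in (0, 1):
            raise EffectDataError(f"outcome must be 0 or 1, got {self.outcome!r}")


@dataclass(frozen=True)
class EffectEstimate:
    """Adjusted risk difference (control minus intervention; positive =
    protective) with cluster-robust SE and normal-approximation CI."""

    risk_difference: float
    se: float
    ci_low: float
    ci_high: float
    n_clusters: int
    adjusted: bool
    converged: bool = True
    fallback_used: bool = False
    ci_multiplier: float = 1.96

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be non-negative")
        if not self.ci_low <= self.risk_difference <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass(frozen=True)
class CaseCounts:
    """Expected vs observed case counts and the cases averted between them.

    Counts are rounded half-up to whole cases; ``averted_cases`` is the
    difference of the rounded counts so the identity
    ``averted = expected - observed`` holds exactly on reported numbers.
    """

    n_pupils: int
    expected_prevalence: float
    observed_prevalence: float
    expected_cases: float
    observed_cases: float
    averted_cases: float
    averted_low: float = float("nan")
    averted_high: float = float("nan")


def _design_matrix(
    records: Sequence[PupilRecord], adjust: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    y = np.array([r.outcome for r in records], dtype=float)
    treat = np.array([1.0 if r.arm == "intervention" else 0.0 for r in records])
    cols = [np.ones(len(records)), treat]
    if adjust and records[0].covariates:
        cov = np.array([r.covariates for r in records], dtype=float)
        cols.extend(cov.T)
    X = np.column_stack(cols)
    clusters = np.array([r.school_id for r in records])
    return y, X, clusters


def _validate(records: Sequence[PupilRecord]) -> None:
    if not records:
        raise EffectDataError("no records supplied")
    arm_of: dict[str, str] = {}
    for r in records:
        prev = arm_of.setdefault(r.school_id, r.arm)
        if prev != r.arm:
            raise EffectDataError(
                f"cluster {r.school_id!r} appears in both arms; "
                "cluster randomization requires one arm per school"
            )
    per_arm = {a: sum(1 for v in arm_of.values() if v == a) for a in ARMS}
    for arm, g in per_arm.items():
        if g < 2:
            raise EffectDataError(
                f"need >= 2 clusters per arm; arm {arm!r} has {g}"
            )
    outcomes = {r.outcome for r in records}
    if outcomes != {0, 1}:
        raise EffectDataError(
            f"both outcome levels must be present, saw only {sorted(outcomes)}"
        )


def _cluster_sandwich(
    X: np.ndarray, resid: np.ndarray, clusters: np.ndarray
) -> np.ndarray:
    """(X'X)^-1 meat (X'X)^-1 scaled by G/(G-1)."""
    bread = np.linalg.inv(X.T @ X)
    meat = np.zeros((X.shape[1], X.shape[1]))
    labels = np.unique(clusters)
    for g in labels:
        idx = clusters == g
        s = X[idx].T @ resid[idx]  # cluster score, shape (k,)
        meat += np.outer(s, s)
    G = len(labels)
    return bread @ meat @ bread * (G / (G - 1))


def fit_risk_difference(
    records: Sequence[PupilRecord],
    adjust: bool = False,
    ci_multiplier: float = 1.96,
) -> EffectEstimate:
    """Estimate the control-minus-intervention risk difference.

    With clusters of size one the sandwich reduces to an HC-type robust
    variance. With no covariates and no clustering structure the point
    estimate is exactly the difference in sample proportions.
    """
    records = list(records)
    _validate(records)
    y, X, clusters = _design_matrix(records, adjust)

    converged = True
    fallback = False
    beta = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(y, X, family=sm.families.Binomial(sm.families.links.Identity()))
            res = glm.fit(maxiter=100)
        mu = res.fittedvalues
        if res.converged and np.all((mu > 0.0) & (mu < 1.0)):
            beta = np.asarray(res.params)
        else:
            converged = bool(res.converged)
    except (ValueError, np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        converged = False
    if beta is None:
        # linear-probability fallback: same mean function, OLS solution
        fallback = True
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)

    resid = y - X @ beta
    V = _cluster_sandwich(X, resid, clusters)
    # arm coded 1 = intervention, so RD (control minus intervention) = -beta[1]
    rd = float(-beta[1])
    se = float(np.sqrt(V[1, 1]))
    return EffectEstimate(
        risk_difference=rd,
        se=se,
        ci_low=rd - ci_multiplier * se,
        ci_high=rd + ci_multiplier * se,
        n_clusters=len(np.unique(clusters)),
        adjusted=adjust,
        converged=converged,
        fallback_used=fallback,
        ci_multiplier=ci_multiplier,
    )


def counterfactual_cases(
    n_pupils: int, expected_prevalence: float, observed_prevalence: float
) -> CaseCounts:
    """Cases expected without the intervention, cases observed, cases averted.

    ``observed > expected`` yields a negative averted count with a
    warning (evidence of harm), not an error.
    """
    for name, p in (
        ("expected_prevalence", expected_prevalence),
        ("observed_prevalence", observed_prevalence),
    ):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    if n_pupils <= 0:
        raise ValueError(f"n_pupils must be positive, got {n_pupils}")
    expected = round_half_up(n_pupils * expected_prevalence)
    observed = round_half_up(n_pupils * observed_prevalence)
    averted = expected - observed
    if averted < 0:
        warnings.warn(
            f"observed cases ({observed:.0f}) exceed expected ({expected:.0f}): "
            "negative cases averted indicates harm",
            stacklevel=2,
        )
    return CaseCounts(
        n_pupils=n_pupils,
        expected_prevalence=expected_prevalence,
        observed_prevalence=observed_prevalence,
        expected_cases=expected,
        observed_cases=observed,
        averted_cases=averted,
    )


def averted_bounds(n_pupils: int, effect: EffectEstimate) -> tuple[float, float]:
    """Cases-averted bounds from the risk-difference CI, rounded half-up."""
    if not (np.isfinite(effect.ci_low) and np.isfinite(effect.ci_high)):
        raise ValueError("effect estimate must have a finite CI")
    low = round_half_up(n_pupils * effect.ci_low)
    high = round_half_up(n_pupils * effect.ci_high)
    return low, high


# ---------------------------------------------------------------------------
# CSV interface


def load_pupils(path: str | Path) -> list[PupilRecord]:
    """Read pupil records: school_id, arm, outcome, then covariate columns."""
    out: list[PupilRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:3] != ["school_id", "arm", "outcome"]:
            raise EffectDataError(
                f"{path}: expected columns school_id,arm,outcome,..., got {header[:3]}"
            )
        for row in reader:
            out.append(
                PupilRecord(
                    school_id=row[0],
                    arm=row[1],
                    outcome=int(row[2]),
                    covariates=tuple(float(v) for v in row[3:]),
                )
            )
    return out


def write_pupils_csv(records: Iterable[PupilRecord], path: str | Path) -> None:
    records = list(records)
    n_cov = len(records[0].covariates) if records else 0
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["school_id", "arm", "outcome"] + [f"x{i + 1}" for i in range(n_cov)]
        )
        for r in records:
            writer.writerow(
                [r.school_id, r.arm, r.outcome] + [repr(v) for v in r.covariates]
            )
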