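"""Waitlist prognosis of ascites: Kaplan-Meier, log-rank and Cox models.

Quantifies the effect of ascites grade on the 90-day primary outcome
(death or delisting for sickness), optionally adjusted for an allocation
score.  Estimation is delegated to lifelines (product-limit estimator,
K-group log-rank, Cox partial likelihood with Efron tie handling — waitlist
times are day-granular and heavily tied); this module fixes the
conventions and returns plain result containers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .records import PrimaryOutcome


class PrognosisError(ValueError):
    pass


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate on (0, 90]: starts at S(0)=1, non-increasing."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each time
    at_risk: np.ndarray        # risk-set size just before each time

    def at(self, t: float) -> float:
        """S(t); beyond the last observed time the last value is carried."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class HazardEstimate:
    term: str
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float


def _unpack(outcomes: Sequence[PrimaryOutcome]) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray([o.time for o in outcomes], dtype=float)
    e = np.asarray([o.event for o in outcomes], dtype=bool)
    return t, e


def kaplan_meier(outcomes: Sequence[PrimaryOutcome]) -> SurvivalCurve:
    """Product-limit survival estimate; ties at a time drop simultaneously."""
    if len(outcomes) == 0:
        raise PrognosisError("kaplan_meier requires at least one outcome")
    t, e = _unpack(outcomes)
    kmf = KaplanMeierFitter().fit(t, event_observed=e)
    table = kmf.event_table
    times = table.index.to_numpy(dtype=float)
    keep = times > 0
    surv = kmf.survival_function_["KM_estimate"].to_numpy()[keep]
    return SurvivalCurve(times=times[keep], survival=surv,
                         at_risk=table["at_risk"].to_numpy()[keep])


def logrank(groups: Mapping[str, Sequence[PrimaryOutcome]]):
    """K-group log-rank test; returns (chi-square, df, p-value)."""
    if len(groups) < 2:
        raise PrognosisError("logrank requires at least two groups")
    labels, times, events = [], [], []
    for name, outs in groups.items():
        if len(outs) == 0:
            raise PrognosisError(f"logrank group {name!r} is empty")
        t, e = _unpack(outs)
        times.append(t)
        events.append(e)
        labels.append(np.repeat(name, len(outs)))
    res = multivariate_logrank_test(np.concatenate(times),
                                    np.concatenate(labels),
                                    np.concatenate(events))
    return float(res.test_statistic), int(res.degrees_of_freedom), float(res.p_value)


def cox_fit(outcomes: Sequence[PrimaryOutcome], covariates: pd.DataFrame,
            alpha: float = 0.05) -> list[HazardEstimate]:
    """Multivariable Cox proportional-hazards fit (Efron ties, Wald CIs).

    ``covariates`` is one numeric column per term, aligned with
    ``outcomes``.  Raises :class:`PrognosisError` naming the offending term
    on rank deficiency or non-convergence.
    """
    t, e = _unpack(outcomes)
    if len(covariates) != len(t):
        raise PrognosisError("covariates and outcomes must be aligned")
    if not e.any():
        raise PrognosisError("cox_fit requires at least one event")
    df = covariates.reset_index(drop=True).astype(float).copy()
    degenerate = [c for c in df.columns if df[c].nunique() < 2]
    if degenerate:
        raise PrognosisError(f"constant covariate column(s): {degenerate}")
    df["time"] = t
    df["event"] = e.astype(int)
    cph = CoxPHFitter(alpha=alpha)
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError/ValueError
        raise PrognosisError(f"Cox fit failed: {exc}") from exc
    summary = cph.summary
    out = []
    for term, row in summary.iterrows():
        out.append(HazardEstimate(
            term=str(term),
            hazard_ratio=float(np.exp(row["coef"])),
            ci_lower=float(np.exp(row["coef lower 95%"])),
            ci_upper=float(np.exp(row["coef upper 95%"])),
            p_value=float(row["p"]),
        ))
    return out


def ascites_cox(frame: pd.DataFrame, score_col: str) -> list[HazardEstimate]:
    """Cox model of the primary outcome on ascites grade indicators plus one
    adjusting score, on a scored cohort frame."""
    outcomes = [PrimaryOutcome(time=float(t), event=bool(ev))
                for t, ev in zip(frame["time"], frame["event"])]
    cov = pd.DataFrame({
        "ascites_mild": (frame["ascites"] == "mild").astype(float).to_numpy(),
        "ascites_moderate_severe":
            (frame["ascites"] == "moderate_severe").astype(float).to_numpy(),
        score_col: frame[score_col].to_numpy(dtype=float),
    })
    return cox_fit(outcomes, cov)
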