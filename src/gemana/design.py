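"""Discrimination-based sample size for comparing two prognostic models.

The design question: how many waitlist candidates are needed to show, with
given power, that an established allocation score and a candidate
replacement differ in discrimination on a right-censored time-to-event
outcome?  Discrimination is measured by the Royston-Sauerbrei D statistic
(the log-hazard separation between prognostic halves of the cohort), which
is obtainable from Harrell's c through a published cubic approximation.

The implemented calculation works on the event scale: with ``SE_ref`` the
standard error of the established model's D in the reference validation
cohort, the per-event variance of the D difference is taken as
``(pi^2 / 2) * SE_ref^2 / (1 - censoring)``, giving

    events = (z_{1-a/2} + z_{1-b})^2 * sigma^2 / (D_a - D_b)^2
    n      = ceil(events / outcome_prevalence)
    events_required = floor(n * outcome_prevalence)

Every intermediate is recorded in the method trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm


class DesignError(ValueError):
    pass


def c_to_D(c: float) -> float:
    """Convert Harrell's c to the Royston-Sauerbrei D statistic.

    Published cubic approximation ``D = 5.50 (c - 0.5) + 10.26 (c - 0.5)^3``,
    monotone increasing with D(0.5) = 0.  Only the non-negative
    discrimination branch c in [0.5, 1) is supported.
    """
    if not 0.5 <= c < 1.0:
        raise DesignError(f"c = {c!r} outside [0.5, 1): negative or perfect "
                          "discrimination unsupported")
    x = c - 0.5
    return 5.50 * x + 10.26 * x ** 3


@dataclass(frozen=True)
class SampleSizeInputs:
    """Design assumptions for comparing two correlated models' D values.

    ``D_a``/``se_D_a`` belong to the established (reference) model whose
    reference-cohort uncertainty drives the variance term; ``D_b`` is the
    candidate model's expected D.
    """

    D_a: float
    se_D_a: float
    D_b: float
    se_D_b: float
    power: float = 0.90
    alpha: float = 0.05
    censoring_prop: float = 0.50
    outcome_prev: float = 0.055

    def __post_init__(self) -> None:
        if not (math.isfinite(self.D_a) and math.isfinite(self.D_b)):
            raise DesignError("D values must be finite")
        if self.se_D_a <= 0 or self.se_D_b <= 0:
            raise DesignError("standard errors must be > 0")
        for name in ("power", "alpha", "censoring_prop", "outcome_prev"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise DesignError(f"{name} must lie in (0, 1)")


@dataclass(frozen=True)
class SampleSizeResult:
    n_required: int | None
    events_required: int | None
    status: str                 # "ok" or "undetectable_difference"
    trace: dict


def sample_size_compare_D(inputs: SampleSizeInputs) -> SampleSizeResult:
    """Minimum cohort size to distinguish two models' D values.

    Two-sided test at ``alpha`` with the requested power; equal D values are
    undetectable at any finite n and are reported as an explicit status
    rather than an exception.
    """
    delta = inputs.D_a - inputs.D_b
    z_alpha = float(norm.ppf(1.0 - inputs.alpha / 2.0))
    z_power = float(norm.ppf(inputs.power))
    sigma2 = (math.pi ** 2 / 2.0) * inputs.se_D_a ** 2 / (1.0 - inputs.censoring_prop)
    trace = {
        "delta_D": delta,
        "z_alpha_two_sided": z_alpha,
        "z_power": z_power,
        "per_event_variance": sigma2,
        "censoring_prop": inputs.censoring_prop,
        "outcome_prev": inputs.outcome_prev,
    }
    if delta == 0.0:
        return SampleSizeResult(None, None, "undetectable_difference",
                                trace | {"events_raw": math.inf})
    events_raw = (z_alpha + z_power) ** 2 * sigma2 / delta ** 2
    n = math.ceil(events_raw / inputs.outcome_prev)
    events = math.floor(n * inputs.outcome_prev)
    trace["events_raw"] = events_raw
    return SampleSizeResult(n_required=n, events_required=events,
                            status="ok", trace=trace)
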