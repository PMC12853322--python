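"""Validation of allocation scores on the right-censored 90-day outcome.

Implements the evaluation battery used to compare the score family:

* Harrell's concordance for right-censored data, with a U-statistic
  ("structural components") standard error — no resampling;
* a one-shot nonparametric test for the difference of two correlated
  c-indices computed on the same patients (paired influence components);
* the inverse-probability-of-censoring-weighted (IPCW) Brier score at
  90 days, with predicted probabilities from a univariable
  proportional-hazards mapping of each score;
* the Greenwood-Nam-D'Agostino (GND) chi-square calibration test over
  deciles of predicted risk, with sparse-decile merging;
* survival-adapted decision-curve analysis (net benefit vs threshold);
* integer-point reclassification matrices between two scores.

Pair-usability convention for the concordance machinery: a pair is usable
when the shorter time belongs to an event; equal-time pairs are unusable
unless both are events with tied scores (counted 0.5).  The same kernel
feeds the c estimate, its variance, and the paired comparison, so the two
statistics are internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

HORIZON = 90.0


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Fast product-limit helpers (cross-checked against the prognosis module)
# ---------------------------------------------------------------------------

def km_event_prob(times, events, horizon: float = HORIZON):
    """Product-limit event probability by ``horizon`` and its Greenwood
    variance.  Returns ``(1 - S(horizon), var)``."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq, first = np.unique(t, return_index=True)
    n = len(t)
    at_risk = n - first
    d = np.add.reduceat(e.astype(int), first)
    mask = (uniq <= horizon) & (d > 0)
    at_risk, d = at_risk[mask], d[mask]
    if len(d) == 0:
        return 0.0, 0.0
    frac = d / at_risk
    s = float(np.prod(1.0 - frac))
    denom = at_risk * (at_risk - d)
    with np.errstate(divide="ignore"):
        gw = np.where(denom > 0, d / denom, np.inf)
    var = s * s * float(np.sum(gw))
    if not np.isfinite(var):
        var = np.nan
    return 1.0 - s, var


def censoring_survival_at(times, events, at, strictly_before: bool = True):
    """P(censoring time > ``at``) by the product-limit estimator with the
    censoring indicator as the event (evaluated just before ``at`` when
    ``strictly_before``)."""
    t = np.asarray(times, dtype=float)
    c = ~np.asarray(events, dtype=bool)
    order = np.argsort(t, kind="stable")
    t, c = t[order], c[order]
    uniq, first = np.unique(t, return_index=True)
    n = len(t)
    at_risk = n - first
    d = np.add.reduceat(c.astype(int), first)
    keep = uniq < at if strictly_before else uniq <= at
    keep &= d > 0
    if not keep.any():
        return 1.0
    return float(np.prod(1.0 - d[keep] / at_risk[keep]))


# ---------------------------------------------------------------------------
# Harrell's c and the one-shot correlated comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceResult:
    c: float
    se: float
    ci_lower: float
    ci_upper: float
    n_usable_pairs: int


def _pair_components(scores, times, events, chunk: int = 512):
    """Per-patient sums of the concordance and usability kernels.

    Returns ``(u, w)`` where ``u[i] = sum_j conc(i, j)`` and
    ``w[i] = sum_j usable(i, j)`` over all ordered pairs ``j != i``.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    n = len(s)
    if not (len(t) == len(e) == n):
        raise EvaluationError("scores and outcomes must be aligned")
    u = np.zeros(n)
    w = np.zeros(n)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        dt_lt = t[sl, None] < t[None, :]
        dt_gt = t[sl, None] > t[None, :]
        dt_eq = ~dt_lt & ~dt_gt
        s_gt = s[sl, None] > s[None, :]
        s_lt = s[sl, None] < s[None, :]
        s_eq = ~s_gt & ~s_lt
        ei = e[sl, None]
        ej = e[None, :]
        case_i_first = dt_lt & ei               # i fails first, usable
        case_j_first = dt_gt & ej               # j fails first, usable
        case_tied = dt_eq & ei & ej & s_eq      # tied-time double event, tied score
        usable = case_i_first | case_j_first | case_tied
        conc = (case_i_first * (s_gt + 0.5 * s_eq)
                + case_j_first * (s_lt + 0.5 * s_eq)
                + case_tied * 0.5)
        idx = np.arange(sl.start, sl.stop)
        conc[np.arange(len(idx)), idx] = 0.0    # exclude the diagonal
        usable[np.arange(len(idx)), idx] = False
        u[sl] = conc.sum(axis=1)
        w[sl] = usable.sum(axis=1)
    return u, w


def _c_and_influence(scores, times, events):
    u, w = _pair_components(scores, times, events)
    n = len(u)
    total_w = w.sum()
    if total_w == 0:
        raise EvaluationError("no usable pairs under right-censoring")
    c = float(u.sum() / total_w)
    w_bar = total_w / (n * (n - 1))             # mean pair usability
    q = (u - c * w) / ((n - 1) * w_bar)         # influence components, sum 0
    return c, q, int(round(total_w / 2)), n


def harrell_c(scores, times, events, alpha: float = 0.05) -> ConcordanceResult:
    """Harrell's c for right-censored outcomes with a one-shot SE.

    ``c = (concordant + 0.5 * score-ties) / usable`` over usable pairs; the
    variance is the degree-2 U-statistic estimate ``4 * var(q_i) / n`` from
    the per-patient influence components ``q_i``.
    """
    c, q, n_pairs, n = _c_and_influence(scores, times, events)
    var = 4.0 * float(np.sum(q * q)) / (n * (n - 1))
    se = float(np.sqrt(max(var, 0.0)))
    z = norm.ppf(1 - alpha / 2)
    return ConcordanceResult(
        c=c, se=se,
        ci_lower=float(max(0.0, c - z * se)),
        ci_upper=float(min(1.0, c + z * se)),
        n_usable_pairs=n_pairs)


@dataclass(frozen=True)
class CComparison:
    c_a: float
    c_b: float
    difference: float
    variance: float
    z: float
    p_value: float


def compare_c_one_shot(scores_a, scores_b, times, events) -> CComparison:
    """Test the difference of two correlated c-indices without resampling.

    Both scores are evaluated on the same patients; the variance of the
    difference comes from the paired per-patient influence components, so
    the correlation between the two estimates is accounted for.  Identical
    score vectors (degenerate variance) report difference 0 with p = 1.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape:
        raise EvaluationError("score vectors must be aligned")
    if np.array_equal(sa, sb):
        ca, _, _, _ = _c_and_influence(sa, times, events)
        return CComparison(ca, ca, 0.0, 0.0, 0.0, 1.0)
    ca, qa, _, n = _c_and_influence(sa, times, events)
    cb, qb, _, _ = _c_and_influence(sb, times, events)
    d = qa - qb
    var = 4.0 * float(np.sum(d * d)) / (n * (n - 1))
    diff = ca - cb
    if var <= 0.0:
        return CComparison(ca, cb, 0.0, 0.0, 0.0, 1.0)
    z = diff / np.sqrt(var)
    return CComparison(ca, cb, float(diff), float(var), float(z),
                       float(2.0 * norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# Predicted 90-day risk and the IPCW Brier score
# ---------------------------------------------------------------------------

def cox_predicted_risk(score, times, events, horizon: float = HORIZON):
    """Map a raw score to a predicted event probability by ``horizon`` via a
    univariable proportional-hazards fit on the same data (the minimal
    monotone mapping from score to probability)."""
    from lifelines import CoxPHFitter

    df = pd.DataFrame({"score": np.asarray(score, dtype=float),
                       "time": np.asarray(times, dtype=float),
                       "event": np.asarray(events, dtype=bool).astype(int)})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    base = cph.baseline_survival_["baseline survival"]
    usable = base.index.to_numpy(dtype=float) <= horizon
    s0 = float(base.to_numpy()[usable][-1]) if usable.any() else 1.0
    partial = cph.predict_partial_hazard(df).to_numpy(dtype=float)
    return 1.0 - s0 ** partial


def ipcw_brier(predicted_risk, times, events, horizon: float = HORIZON) -> float:
    """IPCW mean squared error of predicted event probabilities at ``horizon``.

    Events before the horizon contribute ``(1 - p)^2 / G(T-)``; subjects
    under observation at the horizon contribute ``p^2 / G(horizon-)``;
    earlier censorings contribute zero (their information is carried by the
    weights).  ``G`` is the product-limit estimate of censoring survival.
    """
    p = np.asarray(predicted_risk, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    n = len(p)
    is_event = e & (t <= horizon)
    at_horizon = ~e & (t >= horizon)
    contrib = np.zeros(n)
    g_horizon = censoring_survival_at(t, e, horizon, strictly_before=True)
    if g_horizon <= 0.0:
        raise EvaluationError("censoring-weight denominator is zero at the horizon")
    for ti in np.unique(t[is_event]):
        g = censoring_survival_at(t, e, ti, strictly_before=True)
        if g <= 0.0:
            raise EvaluationError(f"censoring-weight denominator is zero at t={ti}")
        sel = is_event & (t == ti)
        contrib[sel] = (1.0 - p[sel]) ** 2 / g
    contrib[at_horizon] = p[at_horizon] ** 2 / g_horizon
    return float(contrib.sum() / n)


def brier_90d(score, times, events, horizon: float = HORIZON,
              predicted_is_risk: bool = False) -> float:
    """Overall accuracy of a score at 90 days: lower is better.

    By default the raw score is turned into a predicted probability via
    :func:`cox_predicted_risk`; pass ``predicted_is_risk=True`` when the
    first argument already holds probabilities.
    """
    risk = np.asarray(score, dtype=float) if predicted_is_risk \
        else cox_predicted_risk(score, times, events, horizon)
    return ipcw_brier(risk, times, events, horizon)


# ---------------------------------------------------------------------------
# Greenwood-Nam-D'Agostino calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationBins:
    """GND goodness-of-fit over (possibly merged) risk deciles.

    ``bin_of_decile`` maps each original decile index to its final bin, so
    the merge trace reconstructs the pre-merge partition.
    """

    predicted_mean: np.ndarray
    observed_prob: np.ndarray
    expected_events: np.ndarray
    counts: np.ndarray
    chi2: float
    df: int
    p_value: float
    status: str                     # "ok" or "not_assessable"
    merge_trace: tuple[str, ...]
    bin_of_decile: tuple[int, ...]


def gnd_calibration(predicted_risk, times, events, n_bins: int = 10,
                    min_expected: float = 2.0, horizon: float = HORIZON,
                    df_convention: str = "bins") -> CalibrationBins:
    """GND chi-square calibration test over deciles of predicted risk.

    The cohort is cut at predicted-risk quantiles; per bin the observed
    90-day event probability is the product-limit estimate and its variance
    the Greenwood estimate.  Bins with fewer than ``min_expected`` expected
    events (or with no observed events, whose variance is undefined) are
    merged into the adjacent bin with more expected events, ties toward the
    centre, until every bin qualifies.  ``chi2 = sum (obs - pred)^2 / var``.

    ``df_convention``: with ``"bins"`` (default) the reference distribution
    has one degree of freedom per final bin — appropriate here because the
    predicted risks are externally supplied, not estimated on the validation
    data, so each bin contributes a full chi-square df under the null.
    ``"bins_minus_1"`` gives the Hosmer-Lemeshow-analogy convention common
    in registry reports (slightly anticonservative for external risks).
    """
    if df_convention not in ("bins", "bins_minus_1"):
        raise EvaluationError(f"unknown df_convention {df_convention!r}")
    p = np.asarray(predicted_risk, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise EvaluationError("predicted risks must lie in [0, 1]")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)

    edges = np.unique(np.quantile(p, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 3:
        return CalibrationBins(np.array([np.mean(p)]),
                               np.array([km_event_prob(t, e, horizon)[0]]),
                               np.array([p.sum()]), np.array([len(p)]),
                               np.nan, 0, np.nan, "not_assessable",
                               ("degenerate risk distribution",), (0,) * 1)
    decile = np.clip(np.searchsorted(edges, p, side="right") - 1,
                     0, len(edges) - 2)
    n_deciles = len(edges) - 1

    bins: list[list[int]] = [[k] for k in range(n_deciles)]
    trace: list[str] = []

    def members(b):
        return np.isin(decile, b)

    def stats(b):
        sel = members(b)
        obs, var = km_event_prob(t[sel], e[sel], horizon)
        return p[sel].sum(), obs, var, int(sel.sum())

    while True:
        info = [stats(b) for b in bins]
        bad = [k for k, (exp, _, var, _) in enumerate(info)
               if exp < min_expected or var == 0.0 or not np.isfinite(var)]
        if not bad or len(bins) == 1:
            break
        k = min(bad, key=lambda i: info[i][0])   # sparsest bin first
        neighbours = [j for j in (k - 1, k + 1) if 0 <= j < len(bins)]
        centre = (len(bins) - 1) / 2.0
        j = max(neighbours,
                key=lambda m: (info[m][0], -abs(m - centre)))
        lo, hi = sorted((k, j))
        trace.append(f"merged bin {hi} into bin {lo}")
        bins[lo] = bins[lo] + bins[hi]
        del bins[hi]

    info = [stats(b) for b in bins]
    if len(bins) < 2 or any(i[2] == 0.0 or not np.isfinite(i[2]) for i in info):
        status, chi2, df, pval = "not_assessable", np.nan, 0, np.nan
    else:
        status = "ok"
        chi2 = 0.0
        for b, (exp, obs, var, cnt) in zip(bins, info):
            sel = members(b)
            pred_mean = p[sel].mean()
            chi2 += (obs - pred_mean) ** 2 / var
        df = len(bins) if df_convention == "bins" else len(bins) - 1
        pval = float(chi2_dist.sf(chi2, df))

    bin_of_decile = np.empty(n_deciles, dtype=int)
    for k, b in enumerate(bins):
        bin_of_decile[b] = k
    return CalibrationBins(
        predicted_mean=np.array([p[members(b)].mean() for b in bins]),
        observed_prob=np.array([i[1] for i in info]),
        expected_events=np.array([i[0] for i in info]),
        counts=np.array([i[3] for i in info]),
        chi2=float(chi2) if status == "ok" else np.nan,
        df=df, p_value=pval, status=status,
        merge_trace=tuple(trace), bin_of_decile=tuple(bin_of_decile.tolist()))


# ---------------------------------------------------------------------------
# Decision curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray       # model curve
    treat_all: np.ndarray
    treat_none: np.ndarray        # identically zero
    empty_thresholds: tuple[float, ...]   # thresholds with nobody above


def decision_curve(predicted_risk, times, events,
                   thresholds=None, horizon: float = HORIZON) -> DecisionCurve:
    """Survival-adapted net benefit against the threshold probability.

    ``NB(th) = P(risk >= th, event by horizon) - P(risk >= th, event-free)
    * th / (1 - th)`` with event probabilities from the product-limit
    estimator within the treated (risk >= th) subset.
    """
    p = np.asarray(predicted_risk, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    th = np.asarray(thresholds if thresholds is not None
                    else np.arange(0.01, 0.51, 0.01), dtype=float)
    if np.any((th <= 0) | (th >= 1)):
        raise EvaluationError("thresholds must lie in (0, 1)")
    overall_p, _ = km_event_prob(t, e, horizon)
    odds = th / (1.0 - th)
    treat_all = overall_p - (1.0 - overall_p) * odds
    nb = np.zeros_like(th)
    empty = []
    for i, cut in enumerate(th):
        sel = p >= cut
        if not sel.any():
            empty.append(float(cut))
            continue
        p_sub, _ = km_event_prob(t[sel], e[sel], horizon)
        frac = sel.mean()
        nb[i] = frac * (p_sub - (1.0 - p_sub) * odds[i])
    return DecisionCurve(thresholds=th, net_benefit=nb, treat_all=treat_all,
                         treat_none=np.zeros_like(th),
                         empty_thresholds=tuple(empty))


# ---------------------------------------------------------------------------
# Integer-point reclassification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReclassificationSummary:
    """Cross-tabulation of two integer scores plus shift-group outcomes.

    ``matrix`` holds row-normalised percentages (rows: model A value,
    columns: model B value, each row sums to 100).  ``groups`` reports per
    shift group (downgraded / unchanged / upgraded by the sign of B - A)
    the cohort percentage, primary-outcome percentage and transplant
    percentage.
    """

    matrix: pd.DataFrame
    counts: pd.DataFrame
    groups: pd.DataFrame


def reclassify(int_scores_a, int_scores_b, events, transplanted) -> ReclassificationSummary:
    a = np.asarray(int_scores_a, dtype=int)
    b = np.asarray(int_scores_b, dtype=int)
    ev = np.asarray(events, dtype=bool)
    tx = np.asarray(transplanted, dtype=bool)
    if not (len(a) == len(b) == len(ev) == len(tx)):
        raise EvaluationError("reclassification inputs must be aligned")
    counts = pd.crosstab(pd.Series(a, name="model_a"),
                         pd.Series(b, name="model_b"))
    matrix = counts.div(counts.sum(axis=1), axis=0) * 100.0
    shift = np.sign(b - a)
    rows = []
    for name, code in (("downgraded", -1), ("unchanged", 0), ("upgraded", 1)):
        sel = shift == code
        n = int(sel.sum())
        rows.append({
            "group": name,
            "n": n,
            "percent": 100.0 * n / len(a),
            "primary_outcome_pct": 100.0 * ev[sel].mean() if n else np.nan,
            "transplanted_pct": 100.0 * tx[sel].mean() if n else np.nan,
        })
    return ReclassificationSummary(matrix=matrix, counts=counts,
                                   groups=pd.DataFrame(rows).set_index("group"))


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-score discrimination/accuracy plus pairwise tests, calibration,
    decision curves and the ascites reclassification summary."""

    n: int
    concordance: dict[str, ConcordanceResult]
    brier: dict[str, float]
    comparisons: dict[tuple[str, str], CComparison]
    calibration: dict[str, CalibrationBins]
    decision_curves: dict[str, DecisionCurve]
    reclassification: ReclassificationSummary | None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "concordance": {k: vars(v) | {} for k, v in self.concordance.items()},
            "brier": dict(self.brier),
            "comparisons": {f"{a} vs {b}": {
                "difference": c.difference, "variance": c.variance,
                "z": c.z, "p_value": c.p_value}
                for (a, b), c in self.comparisons.items()},
            "calibration": {k: {
                "chi2": v.chi2, "df": v.df, "p_value": v.p_value,
                "status": v.status,
                "predicted_mean": v.predicted_mean.tolist(),
                "observed_prob": v.observed_prob.tolist()}
                for k, v in self.calibration.items()},
            "reclassification": None if self.reclassification is None else [
                {k: (None if isinstance(v, float) and np.isnan(v) else v)
                 for k, v in row.items()}
                for row in self.reclassification.groups.reset_index().to_dict("records")],
        }


def evaluate_scores(frame: pd.DataFrame,
                    score_cols: Sequence[str] = ("gema_na_cont",
                                                 "gema_na_no_ascites_cont",
                                                 "meld_na_cont", "meld3_cont"),
                    calibration_cols: Sequence[str] | None = None,
                    reclassify_cols: tuple[str, str] | None =
                        ("gema_na_int", "gema_na_no_ascites_int"),
                    thresholds=None) -> EvaluationReport:
    """Run the full evaluation battery on a scored cohort frame.

    Rows with a missing value in any requested score column are dropped
    (complete-case, as registries exclude patients whose albumin is
    unavailable from every cross-model comparison).
    """
    needed = [c for c in score_cols if c in frame.columns]
    df = frame.dropna(subset=needed)
    t = df["time"].to_numpy(dtype=float)
    e = df["event"].to_numpy(dtype=bool)

    concordance = {}
    brier = {}
    risks = {}
    for col in needed:
        s = df[col].to_numpy(dtype=float)
        concordance[col] = harrell_c(s, t, e)
        risks[col] = cox_predicted_risk(s, t, e)
        brier[col] = ipcw_brier(risks[col], t, e)

    comparisons = {}
    for i, a in enumerate(needed):
        for b in needed[i + 1:]:
            comparisons[(a, b)] = compare_c_one_shot(
                df[a].to_numpy(dtype=float), df[b].to_numpy(dtype=float), t, e)

    calibration = {col: gnd_calibration(risks[col], t, e)
                   for col in (calibration_cols or needed)}
    curves = {col: decision_curve(risks[col], t, e, thresholds)
              for col in needed}

    recl = None
    if reclassify_cols and all(c in df.columns for c in reclassify_cols):
        recl = reclassify(df[reclassify_cols[0]], df[reclassify_cols[1]],
                          e, df["disposition"].to_numpy() == "transplanted")
    return EvaluationReport(n=len(df), concordance=concordance, brier=brier,
                            comparisons=comparisons, calibration=calibration,
                            decision_curves=curves, reclassification=recl)
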