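"""Liver-allocation scores: RFH-GFR, GEMA, GEMA-Na and the MELD family.

The GEMA family replaces serum creatinine with the Royal Free Hospital
glomerular filtration rate (RFH-GFR), a cirrhosis-specific GFR estimator.
In its original form the RFH-GFR carries a multiplicative penalty of 0.92
for moderate-severe ascites (an 8% reduction); the "without ascites"
iteration of GEMA-Na simply fixes that factor at 1 for everyone while
keeping every other coefficient unchanged.  Because the GFR enters GEMA
through -8.306 * ln(RFH-GFR), toggling ascites shifts the continuous score
by at most 8.306 * ln(1/0.92) ~= 0.693 points.

All functions accept scalars or numpy arrays and are vectorised; the
record-level API (:func:`score_panel`) wraps them for a single
:class:`~gemana.records.PatientRecord`.

Unit convention: records store creatinine/urea/bilirubin in mg/dL; the
RFH-GFR equation is evaluated with creatinine in umol/L and urea in mmol/L
(the conversion happens here).  With the registry-mean inputs this yields
GFR values in the printed 66-72 mL/min range; evaluating the equation on
mg/dL inputs would give values ~25x too large.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import (
    CREATININE_MGDL_PER_UMOLL,
    UREA_MGDL_TO_MMOLL,
    AscitesGrade,
    PatientRecord,
    Sex,
)

#: Multiplier applied to RFH-GFR in the presence of moderate-severe ascites.
ASCITES_GFR_FACTOR = 0.92

#: RFH-GFR coefficients (creatinine in umol/L, urea in mmol/L).
_RFH = dict(const=45.9, creatinine=-0.836, urea=-0.229, inr=-0.113,
            age=-0.129, sodium=0.972, male_factor=1.236)

#: GEMA linear-in-logs coefficients.
_GEMA = dict(bilirubin=3.777, inr=7.883, gfr=-8.306, const=31.932)

#: Integer allocation points are ranked on this scale.
SCORE_MIN, SCORE_MAX = 6, 40

#: Sodium clamp for the MELD-Na-style correction term.
SODIUM_CLAMP = (125.0, 140.0)


def compute_rfh_gfr(creatinine_mgdl, urea_mgdl, inr, age, sodium,
                    male, moderate_severe_ascites=False, *,
                    include_ascites: bool = True):
    """Royal Free Hospital GFR estimate in mL/min.

    ``male`` and ``moderate_severe_ascites`` are booleans (or arrays).
    With ``include_ascites=False`` the ascites penalty is suppressed for
    everyone (the "without ascites" configuration).
    """
    creat = np.asarray(creatinine_mgdl, dtype=float) * CREATININE_MGDL_PER_UMOLL
    urea = np.asarray(urea_mgdl, dtype=float) * UREA_MGDL_TO_MMOLL
    inr = np.asarray(inr, dtype=float)
    age = np.asarray(age, dtype=float)
    sodium = np.asarray(sodium, dtype=float)
    if np.any(creat <= 0) or np.any(urea <= 0) or np.any(inr <= 0) \
            or np.any(age <= 0) or np.any(sodium <= 0):
        raise ValueError("RFH-GFR inputs must be strictly positive")
    gfr = (_RFH["const"]
           * creat ** _RFH["creatinine"]
           * urea ** _RFH["urea"]
           * inr ** _RFH["inr"]
           * age ** _RFH["age"]
           * sodium ** _RFH["sodium"])
    gfr = gfr * np.where(np.asarray(male, dtype=bool), _RFH["male_factor"], 1.0)
    if include_ascites:
        gfr = gfr * np.where(np.asarray(moderate_severe_ascites, dtype=bool),
                             ASCITES_GFR_FACTOR, 1.0)
    return gfr if gfr.ndim else float(gfr)


def compute_gema(bilirubin_mgdl, inr, rfh_gfr):
    """Continuous GEMA score from bilirubin, INR and a precomputed RFH-GFR.

    Bilirubin and INR are floored at 1.0 before the logarithm (MELD-family
    convention; the negative-log region would otherwise reward coagulopathy
    values below the healthy reference).
    """
    bili = np.maximum(np.asarray(bilirubin_mgdl, dtype=float), 1.0)
    inr = np.maximum(np.asarray(inr, dtype=float), 1.0)
    gfr = np.asarray(rfh_gfr, dtype=float)
    if np.any(gfr <= 0):
        raise ValueError("RFH-GFR must be strictly positive")
    out = (_GEMA["bilirubin"] * np.log(bili)
           + _GEMA["inr"] * np.log(inr)
           + _GEMA["gfr"] * np.log(gfr)
           + _GEMA["const"])
    return out if out.ndim else float(out)


def apply_sodium_adjustment(base, sodium, clamp=SODIUM_CLAMP):
    """Sodium correction shared by GEMA-Na and MELD-Na.

    ``base - Na' - 0.025 * base * (140 - Na') + 140`` with sodium clamped to
    ``clamp`` (default [125, 140]); the identity at Na' = 140.
    """
    base = np.asarray(base, dtype=float)
    na = np.clip(np.asarray(sodium, dtype=float), clamp[0], clamp[1])
    out = base - na - 0.025 * base * (140.0 - na) + 140.0
    return out if out.ndim else float(out)


def compute_gema_na(bilirubin_mgdl, inr, rfh_gfr, sodium):
    """Continuous GEMA-Na from raw inputs (vectorised form)."""
    return apply_sodium_adjustment(compute_gema(bilirubin_mgdl, inr, rfh_gfr),
                                   sodium)


def compute_meld(bilirubin_mgdl, inr, creatinine_mgdl):
    """Classic (pre-2016) continuous MELD.

    ``3.78 ln(bili) + 11.2 ln(INR) + 9.57 ln(creat) + 6.43`` with floors of
    1.0 on all three inputs and creatinine capped at 4.0 mg/dL.
    """
    bili = np.maximum(np.asarray(bilirubin_mgdl, dtype=float), 1.0)
    inr = np.maximum(np.asarray(inr, dtype=float), 1.0)
    creat = np.clip(np.asarray(creatinine_mgdl, dtype=float), 1.0, 4.0)
    out = 3.78 * np.log(bili) + 11.2 * np.log(inr) + 9.57 * np.log(creat) + 6.43
    return out if out.ndim else float(out)


def compute_meld_na(bilirubin_mgdl, inr, creatinine_mgdl, sodium):
    """MELD-Na: MELD with the sodium correction on the [125, 140] clamp."""
    return apply_sodium_adjustment(
        compute_meld(bilirubin_mgdl, inr, creatinine_mgdl), sodium)


def compute_meld3(bilirubin_mgdl, inr, creatinine_mgdl, sodium, albumin_gdl,
                  female):
    """Continuous MELD 3.0.

    Adds sex and albumin (with interactions) to the MELD-Na inputs; floors
    of 1.0 on bilirubin/INR/creatinine, creatinine capped at 3.0 mg/dL,
    sodium clamped to [125, 137] and albumin to [1.5, 3.5] g/dL.
    """
    bili = np.maximum(np.asarray(bilirubin_mgdl, dtype=float), 1.0)
    inr = np.maximum(np.asarray(inr, dtype=float), 1.0)
    creat = np.clip(np.asarray(creatinine_mgdl, dtype=float), 1.0, 3.0)
    na = np.clip(np.asarray(sodium, dtype=float), 125.0, 137.0)
    alb = np.clip(np.asarray(albumin_gdl, dtype=float), 1.5, 3.5)
    fem = np.asarray(female, dtype=bool)
    ln_bili = np.log(bili)
    ln_creat = np.log(creat)
    out = (1.33 * fem
           + 4.56 * ln_bili
           + 0.82 * (137.0 - na)
           - 0.24 * (137.0 - na) * ln_bili
           + 9.09 * np.log(inr)
           + 11.14 * ln_creat
           + 1.85 * (3.5 - alb)
           - 1.83 * (3.5 - alb) * ln_creat
           + 6.0)
    return out if out.ndim else float(out)


def integer_points(continuous):
    """Allocation points: round half-up to the nearest integer, then clamp
    to the 6-40 ranking scale."""
    x = np.floor(np.asarray(continuous, dtype=float) + 0.5)
    x = np.clip(x, SCORE_MIN, SCORE_MAX)
    out = x.astype(int)
    return out if out.ndim else int(out)


@dataclass(frozen=True)
class ScorePanel:
    """Continuous and integer (6-40) values of every score for one patient.

    MELD 3.0 fields are ``None`` when albumin is unavailable; such patients
    are excluded from MELD 3.0 analyses only.
    """

    rfh_gfr: float
    rfh_gfr_no_ascites: float
    gema_na_cont: float
    gema_na_no_ascites_cont: float
    meld_cont: float
    meld_na_cont: float
    meld3_cont: float | None
    gema_na_int: int
    gema_na_no_ascites_int: int
    meld_int: int
    meld_na_int: int
    meld3_int: int | None


def score_panel(rec: PatientRecord) -> ScorePanel:
    """Compute every score for one validated record."""
    male = rec.sex is Sex.MALE
    ms = rec.ascites is AscitesGrade.MODERATE_SEVERE
    gfr = compute_rfh_gfr(rec.creatinine, rec.urea, rec.inr, rec.age,
                          rec.sodium, male, ms, include_ascites=True)
    gfr_no = compute_rfh_gfr(rec.creatinine, rec.urea, rec.inr, rec.age,
                             rec.sodium, male, ms, include_ascites=False)
    gema_na = apply_sodium_adjustment(
        compute_gema(rec.bilirubin, rec.inr, gfr), rec.sodium)
    gema_na_no = apply_sodium_adjustment(
        compute_gema(rec.bilirubin, rec.inr, gfr_no), rec.sodium)
    meld = compute_meld(rec.bilirubin, rec.inr, rec.creatinine)
    meld_na = compute_meld_na(rec.bilirubin, rec.inr, rec.creatinine, rec.sodium)
    if rec.has_albumin:
        meld3 = compute_meld3(rec.bilirubin, rec.inr, rec.creatinine,
                              rec.sodium, rec.albumin, not male)
        meld3_int = integer_points(meld3)
    else:
        meld3, meld3_int = None, None
    return ScorePanel(
        rfh_gfr=gfr, rfh_gfr_no_ascites=gfr_no,
        gema_na_cont=gema_na, gema_na_no_ascites_cont=gema_na_no,
        meld_cont=meld, meld_na_cont=meld_na, meld3_cont=meld3,
        gema_na_int=integer_points(gema_na),
        gema_na_no_ascites_int=integer_points(gema_na_no),
        meld_int=integer_points(meld),
        meld_na_int=integer_points(meld_na),
        meld3_int=meld3_int,
    )


SCORE_COLUMNS = (
    "rfh_gfr", "rfh_gfr_no_ascites",
    "gema_na_cont", "gema_na_no_ascites_cont",
    "meld_cont", "meld_na_cont", "meld3_cont",
    "gema_na_int", "gema_na_no_ascites_int",
    "meld_int", "meld_na_int", "meld3_int",
)


def score_frame(frame):
    """Append every score to a cohort DataFrame in canonical columns.

    Returns a copy with the :data:`SCORE_COLUMNS` added.  MELD 3.0 columns
    are NaN where albumin is missing.
    """
    import pandas as pd

    df = frame.copy()
    male = df["sex"].to_numpy() == "male"
    ms = df["ascites"].to_numpy() == AscitesGrade.MODERATE_SEVERE.value
    creat = df["creatinine_mgdl"].to_numpy(dtype=float)
    urea = df["urea_mgdl"].to_numpy(dtype=float)
    bili = df["bilirubin_mgdl"].to_numpy(dtype=float)
    inr = df["inr"].to_numpy(dtype=float)
    age = df["age"].to_numpy(dtype=float)
    na = df["sodium_mmoll"].to_numpy(dtype=float)
    alb = df["albumin_gdl"].to_numpy(dtype=float) if "albumin_gdl" in df else np.full(len(df), np.nan)

    gfr = compute_rfh_gfr(creat, urea, inr, age, na, male, ms, include_ascites=True)
    gfr_no = compute_rfh_gfr(creat, urea, inr, age, na, male, ms, include_ascites=False)
    gema_na = apply_sodium_adjustment(compute_gema(bili, inr, gfr), na)
    gema_na_no = apply_sodium_adjustment(compute_gema(bili, inr, gfr_no), na)
    meld = compute_meld(bili, inr, creat)
    meld_na = apply_sodium_adjustment(meld, na)
    with np.errstate(invalid="ignore"):
        meld3 = np.where(np.isnan(alb), np.nan,
                         compute_meld3(bili, inr, creat, na,
                                       np.where(np.isnan(alb), 3.5, alb), ~male))

    df["rfh_gfr"] = gfr
    df["rfh_gfr_no_ascites"] = gfr_no
    df["gema_na_cont"] = gema_na
    df["gema_na_no_ascites_cont"] = gema_na_no
    df["meld_cont"] = meld
    df["meld_na_cont"] = meld_na
    df["meld3_cont"] = meld3
    df["gema_na_int"] = integer_points(gema_na)
    df["gema_na_no_ascites_int"] = integer_points(gema_na_no)
    df["meld_int"] = integer_points(meld)
    df["meld_na_int"] = integer_points(meld_na)
    meld3_pts = np.clip(np.floor(np.nan_to_num(meld3) + 0.5), SCORE_MIN, SCORE_MAX)
    df["meld3_int"] = pd.array(np.where(np.isnan(meld3), np.nan, meld3_pts),
                               dtype="Int64")
    return df
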