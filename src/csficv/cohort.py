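"""Patient-level cohort handling: outcome classification, covariate coding,
simplified multiple imputation and group description.

The malignant-edema outcome is a composite of clinical and imaging criteria:
a patient is classified ``malignant_edema`` if decompressive surgery or death
occurred within one week and was attributed to edema, or if the clinical triad
(decreased consciousness, unilateral dilated pupil, severe deficit) coincided
with a midline shift strictly greater than 5 mm.  Deaths within a week with no
attributable cause form a third category, ``death_unknown``, which is excluded
before any modelling.

Covariates are coded in the direction conventional for this prediction model:
risk increases with *younger* age, *lower* ASPECTS, *lower* collateral score
and *lower* CSF/ICV ratio, so those predictors are sign-inverted (affine
transforms of the raw values).  Reperfusion is dichotomized on the eTICI scale
at 2B50; if digital subtraction angiography was available in one plane only,
the highest grade that can be assigned is 2A.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CodingError,
    DegenerateComparisonError,
    ImputationError,
    InvalidRateError,
    ValidationError,
)

# Outcome categories
MALIGNANT_EDEMA = "malignant_edema"
NO_MALIGNANT_EDEMA = "no_malignant_edema"
DEATH_UNKNOWN = "death_unknown"
OUTCOME_CATEGORIES = (MALIGNANT_EDEMA, NO_MALIGNANT_EDEMA, DEATH_UNKNOWN)

# eTICI reperfusion grades, ordered; >= 2B50 counts as successful reperfusion.
ETICI_GRADES = ("0", "1", "2A", "2B50", "2B67", "2C", "3")
ETICI_SUCCESS_MIN = "2B50"
MIDLINE_SHIFT_THRESHOLD_MM = 5.0

# Centering constants for the coded predictors.  Centering only moves the
# intercept; slopes are fixed by the per-unit definitions below.
AGE_REF_YR = 68.0
NIHSS_REF = 16.0
ASPECTS_REF = 9.0
COLLATERAL_REF = 2.0
OTG_REF_MIN = 210.0
CSF_ICV_REF_PCT = 14.0

BASIC_PREDICTORS = [
    "age_dec",       # per 10 years younger
    "nihss",         # per point higher
    "aspects_inv",   # per point lower
    "ica_occl",      # 0/1
    "collat_inv",    # per point lower, ordinal 0-3
    "otg_h",         # onset-to-groin per 60 min
    "unsucc_reperf", # 0/1
]
EXTENDED_PREDICTORS = BASIC_PREDICTORS + ["csf_icv_inv"]  # per percent lower

#: Column dictionary for cohort CSV files.
COLUMN_DICTIONARY = {
    "patient_id": "integer row identifier",
    "age_yr": "age in years",
    "nihss": "baseline NIHSS, points",
    "aspects": "ASPECTS, points 0-10",
    "ica_occlusion": "1 if occlusion of the intracranial ICA, 0 for M1/M2/A1/A2",
    "collateral_score": "CTA collateral filling grade, ordinal 0-3",
    "otg_minutes": "time from symptom onset to groin puncture, minutes",
    "etici": "eTICI reperfusion grade on DSA: one of " + "/".join(ETICI_GRADES),
    "dsa_one_plane": "1 if DSA available in a single plane (caps eTICI at 2A)",
    "reperfusion_success": "1 if effective eTICI >= 2B50",
    "csf_icv_pct": "CSF volume / intracranial volume, percent",
    "surgery_7d": "1 if decompressive surgery within 7 days",
    "death_7d": "1 if death within 7 days",
    "edema_attributed": "1 if surgery/death clinically attributed to malignant edema",
    "clinical_triad": "1 if decreased consciousness + dilated pupil + severe deficit",
    "midline_shift_mm": "midline shift on follow-up NCCT, mm",
    "mrs_90d": "modified Rankin Scale at 90 days, 0-6",
    "outcome": "one of " + "/".join(OUTCOME_CATEGORIES),
}


def _as_bool(value) -> bool:
    if pd.isna(value):
        return False
    return bool(value)


def classify_edema(record: Mapping) -> str:
    """Assign the three-level outcome category to one patient record.

    Rule: malignant edema iff (surgery within 7 d OR death within 7 d, with
    the event attributed to edema) OR (clinical triad AND midline shift
    > 5 mm, strict).  Death within 7 d with no attributable cause is
    ``death_unknown``; everything else is ``no_malignant_edema``.
    """
    surgery = _as_bool(record.get("surgery_7d"))
    death = _as_bool(record.get("death_7d"))
    attributed = _as_bool(record.get("edema_attributed"))
    triad = _as_bool(record.get("clinical_triad"))
    shift = record.get("midline_shift_mm", np.nan)
    shift = float(shift) if not pd.isna(shift) else np.nan

    if attributed and not (surgery or death):
        raise ValidationError(
            "edema_attributed is set without decompressive surgery or death"
        )
    if not np.isnan(shift) and shift < 0:
        raise ValidationError(f"negative midline shift: {shift} mm")

    if (surgery or death) and attributed:
        return MALIGNANT_EDEMA
    if triad and not np.isnan(shift) and shift > MIDLINE_SHIFT_THRESHOLD_MM:
        return MALIGNANT_EDEMA
    if death:
        return DEATH_UNKNOWN
    return NO_MALIGNANT_EDEMA


def classify_edema_table(table: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`classify_edema` over a cohort table."""
    return pd.Series(
        [classify_edema(row) for row in table.to_dict("records")],
        index=table.index,
        name="outcome",
    )


def effective_etici(grade: str, one_plane: bool = False) -> str:
    """eTICI grade after applying the one-plane DSA cap (highest possible 2A)."""
    if grade not in ETICI_GRADES:
        raise CodingError(f"unknown eTICI grade {grade!r}; expected one of {ETICI_GRADES}")
    if one_plane and ETICI_GRADES.index(grade) > ETICI_GRADES.index("2A"):
        return "2A"
    return grade


def is_successful_reperfusion(grade: str, one_plane: bool = False) -> bool:
    eff = effective_etici(grade, one_plane)
    return ETICI_GRADES.index(eff) >= ETICI_GRADES.index(ETICI_SUCCESS_MIN)


def code_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Build the coded model frame (one column per predictor, plus outcome).

    All codings are affine transforms of the raw columns; missing raw values
    propagate to missing coded values.  The outcome column ``outcome_event``
    is 1 for malignant edema, 0 for no malignant edema and NaN for
    death-with-unknown-cause (excluded before modelling).
    """
    out = pd.DataFrame(index=table.index)
    out["age_dec"] = (AGE_REF_YR - table["age_yr"]) / 10.0
    out["nihss"] = table["nihss"] - NIHSS_REF
    out["aspects_inv"] = ASPECTS_REF - table["aspects"]
    out["ica_occl"] = table["ica_occlusion"].astype(float)
    out["collat_inv"] = COLLATERAL_REF - table["collateral_score"]
    out["otg_h"] = (table["otg_minutes"] - OTG_REF_MIN) / 60.0

    if "reperfusion_success" in table.columns:
        success = table["reperfusion_success"].astype(float)
    else:
        one_plane = table.get("dsa_one_plane", pd.Series(False, index=table.index))
        success = pd.Series(
            [
                np.nan
                if pd.isna(g)
                else float(is_successful_reperfusion(str(g), _as_bool(p)))
                for g, p in zip(table["etici"], one_plane)
            ],
            index=table.index,
        )
    out["unsucc_reperf"] = 1.0 - success

    if "csf_icv_pct" in table.columns:
        out["csf_icv_inv"] = CSF_ICV_REF_PCT - table["csf_icv_pct"]

    if "outcome" in table.columns:
        out["outcome_event"] = table["outcome"].map(
            {MALIGNANT_EDEMA: 1.0, NO_MALIGNANT_EDEMA: 0.0, DEATH_UNKNOWN: np.nan}
        )
    return out


def exclude_death_unknown(table: pd.DataFrame) -> pd.DataFrame:
    """Drop patients who died of unknown cause (pre-modelling exclusion)."""
    return table.loc[table["outcome"] != DEATH_UNKNOWN].copy()


# ---------------------------------------------------------------------------
# Simplified multiple imputation (chained equations)
# ---------------------------------------------------------------------------

# column -> kind; only these raw columns are imputable.
IMPUTABLE_COLUMNS = {
    "age_yr": "continuous",
    "nihss": "continuous",
    "aspects": "ordinal10",
    "ica_occlusion": "binary",
    "collateral_score": "ordinal3",
    "otg_minutes": "continuous",
    "reperfusion_success": "binary",
    "csf_icv_pct": "continuous",
}


def _design(frame: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    X = frame[list(cols)].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(frame)), X])


def _draw_continuous(rng, X_obs, y_obs, X_mis):
    beta, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ beta
    dof = max(len(y_obs) - X_obs.shape[1], 1)
    sigma = float(np.sqrt(resid @ resid / dof))
    return X_mis @ beta + rng.normal(0.0, sigma, size=len(X_mis))


def _draw_binary(rng, X_obs, y_obs, X_mis):
    # small ridge keeps the working fit finite under separation
    from .models import _irls

    try:
        beta, *_ = _irls(X_obs, y_obs, ridge=1e-4, tol=1e-6, max_iter=50, check_separation=False)
        p = 1.0 / (1.0 + np.exp(-(X_mis @ beta)))
    except Exception:
        p = np.full(len(X_mis), float(np.mean(y_obs)))
    return (rng.random(len(X_mis)) < p).astype(float)


def impute_missing(
    table: pd.DataFrame,
    m: int = 5,
    seed: int = 0,
    n_cycles: int = 10,
) -> list[pd.DataFrame]:
    """Return ``m`` completed copies of ``table`` (chained-equation imputation).

    Continuous variables are imputed by linear regression with normal
    residual draws, binary variables by logistic regression with Bernoulli
    draws; the ordinal collateral score and ASPECTS are imputed linearly and
    rounded/clipped back onto their scales.  The outcome (which must be
    complete) is included as a predictor in every imputation model.
    """
    if m < 1:
        raise InvalidRateError(f"m must be >= 1, got {m}")
    if "outcome" in table.columns and table["outcome"].isna().any():
        raise ImputationError("outcome must be complete before imputation")

    cols = [c for c in IMPUTABLE_COLUMNS if c in table.columns]
    missing_cols = [c for c in cols if table[c].isna().any()]
    for c in missing_cols:
        if table[c].isna().all():
            raise ImputationError(f"column {c!r} is 100% missing; cannot impute")
    if not missing_cols:
        return [table.copy() for _ in range(m)]

    work_base = table[cols].astype(float).copy()
    if "outcome" in table.columns:
        work_base["_event"] = table["outcome"].map(
            {MALIGNANT_EDEMA: 1.0, NO_MALIGNANT_EDEMA: 0.0, DEATH_UNKNOWN: 0.5}
        )

    completed = []
    root = np.random.SeedSequence(seed)
    for child in root.spawn(m):
        rng = np.random.default_rng(child)
        work = work_base.copy()
        # initial fill: random draws from the observed marginal
        for c in missing_cols:
            obs = work[c].dropna().to_numpy()
            idx = work.index[work[c].isna()]
            work.loc[idx, c] = rng.choice(obs, size=len(idx), replace=True)

        for _ in range(n_cycles):
            for c in missing_cols:
                others = [x for x in work.columns if x != c]
                mis_idx = table.index[table[c].isna()]
                obs_idx = table.index[table[c].notna()]
                X_obs = _design(work.loc[obs_idx], others)
                X_mis = _design(work.loc[mis_idx], others)
                y_obs = table.loc[obs_idx, c].to_numpy(dtype=float)
                kind = IMPUTABLE_COLUMNS[c]
                if kind == "binary":
                    draw = _draw_binary(rng, X_obs, y_obs, X_mis)
                else:
                    draw = _draw_continuous(rng, X_obs, y_obs, X_mis)
                    if kind == "ordinal3":
                        draw = np.clip(np.round(draw), 0, 3)
                    elif kind == "ordinal10":
                        draw = np.clip(np.round(draw), 0, 10)
                work.loc[mis_idx, c] = draw

        full = table.copy()
        for c in missing_cols:
            full[c] = work[c]
        completed.append(full)
    return completed


# ---------------------------------------------------------------------------
# Group description
# ---------------------------------------------------------------------------

#: variable -> test family used by summarize_groups
SUMMARY_VARIABLES = {
    "age_yr": "continuous",
    "otg_minutes": "continuous",
    "csf_icv_pct": "continuous",
    "nihss": "ordinal",
    "aspects": "ordinal",
    "collateral_score": "ordinal",
    "mrs_90d": "ordinal",
    "ica_occlusion": "categorical",
    "reperfusion_success": "categorical",
}


def _fmt_mean_sd(x: np.ndarray) -> str:
    return f"{np.mean(x):.1f} ± {np.std(x, ddof=1):.1f}"


def _fmt_median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:g} [{q1:g}-{q3:g}]"


def summarize_groups(
    table: pd.DataFrame,
    variables: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Compare the malignant-edema and no-edema groups variable by variable.

    Continuous near-normal variables get mean±SD and a two-sample t test,
    ordinal/skewed ones median [IQR] and Mann-Whitney U, categorical ones
    counts and chi-square (Fisher's exact for sparse 2x2 tables).
    """
    variables = dict(variables or SUMMARY_VARIABLES)
    df = exclude_death_unknown(table)
    groups = [g for g in (MALIGNANT_EDEMA, NO_MALIGNANT_EDEMA) if (df["outcome"] == g).any()]
    if len(groups) < 2:
        raise DegenerateComparisonError("need both outcome groups to compare")

    rows = []
    g1 = df.loc[df["outcome"] == MALIGNANT_EDEMA]
    g0 = df.loc[df["outcome"] == NO_MALIGNANT_EDEMA]
    for var, kind in variables.items():
        if var not in df.columns:
            continue
        a = g1[var].dropna().to_numpy(dtype=float)
        b = g0[var].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            continue
        if kind == "continuous":
            stat, p = stats.ttest_ind(a, b, equal_var=False)
            s1, s0, test = _fmt_mean_sd(a), _fmt_mean_sd(b), "t"
        elif kind == "ordinal":
            if np.array_equal(np.unique(a), np.unique(b)) and np.array_equal(a, b):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            s1, s0, test = _fmt_median_iqr(a), _fmt_median_iqr(b), "mann-whitney"
        elif kind == "categorical":
            tab = pd.crosstab(df["outcome"], df[var])
            if tab.shape == (2, 2) and (tab.to_numpy() < 5).any():
                stat, p = stats.fisher_exact(tab.to_numpy())
                test = "fisher"
            else:
                stat, p, *_ = stats.chi2_contingency(tab.to_numpy())
                test = "chi2"
            s1 = f"{int(np.sum(a)):d}/{len(a)}"
            s0 = f"{int(np.sum(b)):d}/{len(b)}"
        else:
            raise ValueError(f"unknown variable kind {kind!r}")
        rows.append(
            {
                "variable": var,
                "edema": s1,
                "no_edema": s0,
                "test": test,
                "statistic": float(stat),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("variable")
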