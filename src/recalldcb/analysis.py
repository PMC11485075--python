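"""Longitudinal decline analysis and diagnostic evaluation.

Given a participant table carrying baseline predictors (the
recall-ability biomarkers N_avg/R_avg/M_avg and the traditional
immediate/delayed error scores) and CDR at baseline and 36 months, this
module fits the three regressions of the longitudinal design — linear
CDR-at-36-months (optionally on the square-root scale), proportional
odds over the ordered CDR stages, and logistic regression on the
decline indicator (CDR increase >= 0.5) — and evaluates M as a
screening classifier: confusion counts at a threshold (positive call =
M below threshold, i.e. low recall ability), NPV/PPV/sensitivity/
specificity, and the ROC curve with its midrank AUC.

Covariates follow the design throughout: years of education, sex, PHS
and age enter every model; baseline CDR enters the CDR-level models but
not the decline model (it is already part of the change score).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "DiagnosticMetrics",
    "BIOMARKER_PREDICTORS",
    "DEFAULT_THRESHOLD",
    "build_records",
    "linear_cdr_regression",
    "ordinal_cdr_regression",
    "logistic_decline_regression",
    "classify_decline",
    "diagnostics_from_counts",
    "roc_auc",
    "youden_threshold",
    "implied_cdr_difference",
]

BIOMARKER_PREDICTORS = ("M_avg", "N_avg", "R_avg", "immediate_recall",
                        "delayed_recall")
DEFAULT_THRESHOLD = 0.58
_CDR_STAGES = (0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class ConfusionCounts:
    """Decline-classification counts at one threshold."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        for name in ("hits", "misses", "false_alarms", "correct_rejections"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.hits + self.misses + self.false_alarms + self.correct_rejections


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Screening metrics; a metric whose denominator is zero is None."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    auc: float | None = None

    def rounded(self, ndigits: int = 2) -> dict:
        return {
            k: (None if v is None else round(v, ndigits))
            for k, v in self.__dict__.items()
        }


def implied_cdr_difference(coefficient: float, m_difference: float) -> float:
    """Outcome difference implied by a fitted coefficient over a
    cross-sectional difference in M (e.g. -2.38 x 0.2 ~ -0.5 CDR)."""
    return coefficient * m_difference


# ---------------------------------------------------------------------------
# Record assembly
# ---------------------------------------------------------------------------

def build_records(
    participants_df: pd.DataFrame,
    dcb_df: pd.DataFrame | None = None,
    scores_df: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge covariates, fitted biomarkers and traditional scores into
    one analysis table, adding the binary decline indicator
    (``cdr_36m - cdr_baseline >= 0.5``).  Incomplete rows are dropped
    with a logged count (complete-case analysis)."""
    records = participants_df.copy()
    if dcb_df is not None:
        cols = ["participant_id"] + [
            c for c in ("N_avg", "R_avg", "M_avg") if c in dcb_df.columns
        ]
        records = records.merge(dcb_df[cols], on="participant_id", how="left")
    if scores_df is not None:
        records = records.merge(scores_df, on="participant_id", how="left")
    records["decline"] = (
        (records["cdr_36m"] - records["cdr_baseline"]) >= 0.5
    ).astype(int)
    analysis_cols = [c for c in records.columns if c != "participant_id"]
    complete = records.dropna(subset=analysis_cols)
    n_dropped = len(records) - len(complete)
    if n_dropped:
        logger.info("build_records: dropped %d incomplete record(s)", n_dropped)
    return complete.reset_index(drop=True)


def _design(
    records: pd.DataFrame,
    predictors: Sequence[str],
    covariates: Sequence[str],
) -> pd.DataFrame:
    for col in list(predictors):
        if col not in records.columns:
            raise ValueError(f"predictor {col!r} missing from records")
    X = pd.DataFrame(index=records.index)
    for col in list(predictors) + [c for c in covariates if c != "sex"]:
        X[col] = records[col].astype(float)
    if "sex" in covariates:
        X["sex_male"] = (
            records["sex"].astype(str).str.upper().str.startswith("M")
        ).astype(float)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy()])
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        zero_var = [c for c in X.columns if X[c].nunique() <= 1]
        offending = zero_var or list(X.columns)
        raise ValueError(
            f"rank-deficient design (rank {rank} < {arr.shape[1]}); "
            f"offending columns: {offending}"
        )


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------

def linear_cdr_regression(
    records: pd.DataFrame,
    predictors: Sequence[str] = ("M_avg",),
    transform: str = "none",
) -> pd.DataFrame:
    """CDR at 36 months on baseline predictors plus covariates.

    ``transform='sqrt'`` fits the square-root of the outcome (a
    variance-stabilizing option when residuals are skewed).  Returns a
    coefficient table (coef, se, 95% CI, t, p) indexed by term.
    """
    if len(records) < 20:
        raise ValueError("need at least 20 records for the linear model")
    if transform not in ("none", "sqrt"):
        raise ValueError(f"unknown transform {transform!r}")
    y = records["cdr_36m"].astype(float)
    if transform == "sqrt":
        y = np.sqrt(y)
    X = _design(records, predictors,
                ("education", "sex", "phs", "age", "cdr_baseline"))
    _check_rank(X)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    ci = fit.conf_int(alpha=0.05)
    return pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "ci_lower": ci[0],
            "ci_upper": ci[1],
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )


@dataclass
class OrdinalFit:
    """Proportional-odds fit summary over the ordered CDR stages."""

    params: pd.DataFrame
    model_chi2: float
    df: int
    p_value: float
    nagelkerke_r2: float
    n: int


def ordinal_cdr_regression(
    records: pd.DataFrame,
    predictors: Sequence[str] = ("M_avg",),
) -> OrdinalFit:
    """Proportional-odds (cumulative logit) model of CDR at 36 months.

    Stages absent from the data are collapsed away (with a warning), as
    a cumulative model cannot estimate thresholds for empty categories.
    Reports per-term coefficient, SE, Wald statistic and p, the model
    likelihood-ratio chi-square against the thresholds-only null, and
    Nagelkerke's pseudo-R².
    """
    y_raw = records["cdr_36m"].astype(float)
    present = sorted(y_raw.unique())
    if len(present) < 2:
        raise ValueError("outcome has a single category; ordinal model undefined")
    absent = sorted(set(_CDR_STAGES) - set(present))
    if absent:
        warnings.warn(
            f"CDR stages {absent} absent from the data; categories collapsed",
            UserWarning, stacklevel=2,
        )
    y = pd.Categorical(y_raw, categories=present, ordered=True)
    X = _design(records, predictors,
                ("education", "sex", "phs", "age", "cdr_baseline"))
    _check_rank(X)
    model = OrderedModel(y, X, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(method="bfgs", maxiter=500, disp=0)
    k = X.shape[1]
    coefs = fit.params[:k]
    ses = fit.bse[:k]
    wald = (coefs / ses) ** 2
    from scipy.stats import chi2 as chi2_dist

    counts = pd.Series(y).value_counts()
    ll0 = float((counts * np.log(counts / counts.sum())).sum())
    chi2 = 2.0 * (fit.llf - ll0)
    n = len(records)
    r2_cs = 1.0 - np.exp(2.0 * (ll0 - fit.llf) / n)
    r2_max = 1.0 - np.exp(2.0 * ll0 / n)
    params = pd.DataFrame(
        {"coef": coefs, "se": ses, "wald": wald,
         "p": chi2_dist.sf(wald, 1)},
        index=X.columns,
    )
    return OrdinalFit(
        params=params,
        model_chi2=float(chi2),
        df=k,
        p_value=float(chi2_dist.sf(chi2, k)),
        nagelkerke_r2=float(r2_cs / r2_max),
        n=n,
    )


@dataclass
class LogisticFit:
    """Decline-model fit: coefficients plus AIC with/without each predictor."""

    params: pd.DataFrame
    aic: float
    aic_without: dict
    separation: bool
    n: int

    @property
    def llf(self) -> float:
        return -(self.aic - 2 * (len(self.params))) / 2.0


def logistic_decline_regression(
    records: pd.DataFrame,
    predictors: Sequence[str] = ("M_avg",),
) -> LogisticFit:
    """Maximum-likelihood logistic regression of decline on baseline
    predictors plus education, sex, PHS and age (baseline CDR excluded:
    it is part of the change score defining the outcome).

    Reports unstandardized and standardized (per-SD) coefficients, Wald
    statistics, the model AIC, and the AIC of the model refit without
    each focal predictor.  Complete separation triggers a ridge-penalized
    fallback fit and a warning.
    """
    y = records["decline"].astype(int)
    if y.nunique() < 2:
        raise ValueError("both outcome classes must be present")
    covariates = ("education", "sex", "phs", "age")
    X = _design(records, predictors, covariates)
    _check_rank(X)

    def _fit(cols):
        Xc = sm.add_constant(X[cols])
        model = sm.Logit(y, Xc)
        separation = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = model.fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", True) or np.any(
                np.abs(fit.params) > 50
            ):
                raise PerfectSeparationError("suspected separation")
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separation = True
            warnings.warn(
                "separation detected in the logistic model; "
                "refit with a small ridge penalty", UserWarning, stacklevel=3,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = model.fit_regularized(
                    alpha=1.0, L1_wt=0.0, disp=0, maxiter=500
                )
        return fit, separation

    all_cols = list(X.columns)
    fit, separation = _fit(all_cols)
    sds = X.std(ddof=1)
    from scipy.stats import chi2 as chi2_dist

    coef = fit.params
    se = fit.bse
    wald = (coef / se) ** 2
    params = pd.DataFrame(
        {
            "coef": coef,
            "se": se,
            "coef_std": coef * pd.concat(
                [pd.Series({"const": np.nan}), sds]
            ),
            "wald": wald,
            "p": chi2_dist.sf(wald, 1),
        }
    )
    aic_without = {}
    for pred in predictors:
        reduced = [c for c in all_cols if c != pred]
        fit_r, _ = _fit(reduced)
        aic_without[pred] = float(fit_r.aic)
    return LogisticFit(
        params=params,
        aic=float(fit.aic),
        aic_without=aic_without,
        separation=separation,
        n=len(records),
    )


# ---------------------------------------------------------------------------
# Classification and diagnostics
# ---------------------------------------------------------------------------

def classify_decline(
    records: pd.DataFrame,
    m_threshold: float = DEFAULT_THRESHOLD,
    score: str = "M_avg",
) -> ConfusionCounts:
    """Confusion counts for the screening rule "predict decline iff the
    recall-ability score falls below the threshold" (strict <)."""
    if records[score].isna().any():
        raise ValueError(f"{score} missing for some records")
    predicted = records[score].to_numpy() < m_threshold
    observed = records["decline"].to_numpy().astype(bool)
    return ConfusionCounts(
        hits=int(np.sum(predicted & observed)),
        misses=int(np.sum(~predicted & observed)),
        false_alarms=int(np.sum(predicted & ~observed)),
        correct_rejections=int(np.sum(~predicted & ~observed)),
    )


def diagnostics_from_counts(counts: ConfusionCounts) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV and NPV from confusion counts;
    a ratio with a zero denominator is reported as None, never NaN."""

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    return DiagnosticMetrics(
        sensitivity=ratio(counts.hits, counts.hits + counts.misses),
        specificity=ratio(counts.correct_rejections,
                          counts.correct_rejections + counts.false_alarms),
        ppv=ratio(counts.hits, counts.hits + counts.false_alarms),
        npv=ratio(counts.correct_rejections,
                  counts.correct_rejections + counts.misses),
    )


def roc_auc(
    records: pd.DataFrame,
    score: str = "M_avg",
    outcome: str = "decline",
    lower_is_positive: bool = True,
) -> tuple:
    """AUC by the midrank (Mann-Whitney) statistic plus ROC points.

    With ``lower_is_positive`` (the biomarker convention: low recall
    ability signals risk) the risk score is the negated biomarker.
    Ties are handled by midranks, which makes the statistic identical
    to the trapezoidal area under the empirical ROC curve.  Returns
    ``(auc, roc_df)`` where ``roc_df`` has columns fpr/tpr/threshold.
    """
    y = records[outcome].to_numpy().astype(bool)
    if y.all() or not y.any():
        raise ValueError("both outcome classes are required for a ROC curve")
    risk = records[score].to_numpy().astype(float)
    if lower_is_positive:
        risk = -risk
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = rankdata(risk)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-risk, kind="mergesort")
    y_sorted = y[order]
    risk_sorted = risk[order]
    distinct = np.r_[np.diff(risk_sorted) != 0, True]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(~y_sorted)[distinct]
    roc = pd.DataFrame(
        {
            "fpr": np.r_[0.0, fp / n_neg],
            "tpr": np.r_[0.0, tp / n_pos],
            "threshold": np.r_[np.inf, risk_sorted[distinct]],
        }
    )
    return float(auc), roc


def youden_threshold(
    records: pd.DataFrame,
    score: str = "M_avg",
    outcome: str = "decline",
) -> float:
    """Threshold on the biomarker scale maximizing Youden's J
    (sensitivity + specificity - 1) for the rule "positive iff score <
    threshold".  Candidate cuts are midpoints between adjacent distinct
    scores (plus one above the maximum), so the strict inequality never
    splits a tie group."""
    y = records[outcome].to_numpy().astype(bool)
    if y.all() or not y.any():
        raise ValueError("both outcome classes are required")
    values = records[score].to_numpy().astype(float)
    u = np.unique(values)
    candidates = np.r_[(u[:-1] + u[1:]) / 2.0, u[-1] + 1.0]
    pos_sorted = np.sort(values[y])
    neg_sorted = np.sort(values[~y])
    tpr = np.searchsorted(pos_sorted, candidates) / len(pos_sorted)
    fpr = np.searchsorted(neg_sorted, candidates) / len(neg_sorted)
    return float(candidates[np.argmax(tpr - fpr)])
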