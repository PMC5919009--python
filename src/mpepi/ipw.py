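"""Inverse-probability weighting for tumor-data selection bias.

Among cases, tumor mutation data may be missing for reasons related to
observed clinical covariates (stage, site, age and year of diagnosis,
cohort, sex).  A logistic availability model yields fitted probabilities
p_i; the subtype analyses are then refit with weights 1 for controls,
1/p_i for cases with tumor data, and 0 for cases without, which removes
selection bias acting through the modeled covariates.  A balance check
refits the availability model weighted by 1/p_i (available) and
1/(1 - p_i) (unavailable): under a correct model all covariate
coefficients are null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from ._utils import DegenerateDataError, DomainError, EstimationError, SeparationError
from .matched import ConditionalLogisticRegression, MatchedDesign, clogit_fit
from .simulate import UNAVAILABLE

#: covariates the emulated study used to model tumor-data availability
DEFAULT_AVAILABILITY_COVARIATES = (
    "tumor_stage",
    "tumor_site",
    "age_at_diagnosis",
    "year_of_diagnosis",
    "cohort",
    "sex",
)


def _design(frame: pd.DataFrame, covariates) -> pd.DataFrame:
    parts = []
    for c in covariates:
        col = frame[c]
        if col.dtype.kind in "fiub":
            parts.append(col.astype(float).to_frame())
        else:
            parts.append(
                pd.get_dummies(col.astype(str), prefix=c, drop_first=True).astype(float)
            )
    X = pd.concat(parts, axis=1)
    for name in X.columns:
        if np.ptp(X[name].to_numpy()) == 0:
            raise EstimationError(f"covariate term {name!r} is constant; inestimable")
    return X


class AvailabilityModel(BaseEstimator):
    """Logistic model for tumor-data availability among cases.

    fit(cases) expects a case-level frame with an availability indicator
    (by default derived from the subtype column: UNAVAILABLE means no tumor
    data).  Cases with missing model covariates are excluded and counted.

    Attributes
    ----------
    coefficients_ : pd.Series           (including "const")
    fitted_probs_ : pd.Series           indexed like the retained cases
    pvalues_ : pd.Series
    n_excluded_ : int                   cases dropped for missing covariates
    """

    def __init__(self, covariates=DEFAULT_AVAILABILITY_COVARIATES):
        self.covariates = covariates

    def fit(self, cases: pd.DataFrame, y=None):
        cases = cases.copy()
        if y is None:
            avail = (cases["subtype"] != UNAVAILABLE).astype(int)
        else:
            avail = pd.Series(np.asarray(y).astype(int), index=cases.index)
        complete = cases[list(self.covariates)].notna().all(axis=1)
        self.n_excluded_ = int((~complete).sum())
        cases, avail = cases[complete], avail[complete]
        if avail.nunique() < 2:
            raise DegenerateDataError(
                "availability is degenerate (all cases available or none)"
            )
        X = sm.add_constant(_design(cases, self.covariates))
        try:
            res = sm.Logit(avail.to_numpy(), X.to_numpy()).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises on perfect separation
            raise SeparationError(str(exc)) from exc
        if not res.mle_retvals.get("converged", True):
            raise EstimationError("availability model did not converge")
        self.exog_names_ = list(X.columns)
        self.coefficients_ = pd.Series(res.params, index=self.exog_names_)
        self.bse_ = pd.Series(res.bse, index=self.exog_names_)
        self.pvalues_ = pd.Series(res.pvalues, index=self.exog_names_)
        self.fitted_probs_ = pd.Series(res.predict(X.to_numpy()), index=cases.index)
        self.case_index_ = cases.index
        self.availability_ = avail
        return self


def fit_availability_model(
    cases: pd.DataFrame, covariates=DEFAULT_AVAILABILITY_COVARIATES
) -> AvailabilityModel:
    return AvailabilityModel(covariates=covariates).fit(cases)


@dataclass
class WeightAssignment:
    """Subject-level IPW weights with exclusion bookkeeping."""

    weights: pd.Series
    n_zero_weight_cases: int
    n_excluded_missing_covariates: int


def compute_weights(model: AvailabilityModel, subjects: pd.DataFrame) -> WeightAssignment:
    """1 for controls, 1/p_i for cases with tumor data, 0 otherwise.

    Cases excluded from the availability fit (missing model covariates)
    also receive weight 0 and are counted separately.
    """
    w = pd.Series(1.0, index=subjects.index)
    cases = subjects[subjects["is_case"]]
    w[cases.index] = 0.0
    probs = model.fitted_probs_.reindex(cases.index)
    available = (cases["subtype"] != UNAVAILABLE) & probs.notna()
    if (probs[available] <= 0).any():
        raise DomainError("fitted availability probability of 0 gives undefined weight")
    w[cases.index[available]] = 1.0 / probs[available]
    n_zero = int((w[cases.index] == 0).sum())
    return WeightAssignment(
        weights=w,
        n_zero_weight_cases=n_zero,
        n_excluded_missing_covariates=model.n_excluded_,
    )


def weighted_clogit(
    design: MatchedDesign,
    weights: WeightAssignment | pd.Series,
    cov_type: str = "observed",
) -> ConditionalLogisticRegression:
    """IPW conditional logistic regression (set weight = its case's weight)."""
    w = weights.weights if isinstance(weights, WeightAssignment) else weights
    return clogit_fit(design, sample_weight=w, cov_type=cov_type)


@dataclass
class BalanceReport:
    """Weighted availability-model refit used as a covariate-balance check."""

    coefficients: pd.Series
    pvalues: pd.Series
    level: float
    passed: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coefficient": self.coefficients, "p_value": self.pvalues}
        )


def balance_check(
    model: AvailabilityModel, cases: pd.DataFrame, level: float = 0.2
) -> BalanceReport:
    """Refit availability weighted by 1/p_i (available) or 1/(1-p_i) (not).

    Balance holds when every covariate coefficient is statistically null
    (p > ``level``) in the weighted refit.
    """
    idx = model.case_index_
    probs = model.fitted_probs_
    avail = model.availability_.astype(bool)
    if ((probs <= 0) | (probs >= 1)).any():
        raise DomainError("fitted probabilities of exactly 0 or 1 give undefined weights")
    w = np.where(avail, 1.0 / probs, 1.0 / (1.0 - probs))
    X = sm.add_constant(_design(cases.loc[idx], model.covariates))
    res = sm.GLM(
        avail.astype(float).to_numpy(),
        X.to_numpy(),
        family=sm.families.Binomial(),
        freq_weights=w,
    ).fit()
    coefs = pd.Series(res.params, index=X.columns)
    pvals = pd.Series(res.pvalues, index=X.columns)
    cov_p = pvals.drop("const")
    return BalanceReport(
        coefficients=coefs,
        pvalues=pvals,
        level=level,
        passed=bool((cov_p > level).all()),
    )


@dataclass
class IpwComparison:
    """Paired complete-case vs IPW log-ORs with summary discrepancies."""

    table: pd.DataFrame
    mean_abs_diff: float
    max_abs_diff: float
    slope: float
    intercept: float


def compare_complete_case_vs_ipw(
    results_cc: pd.DataFrame, results_ipw: pd.DataFrame
) -> IpwComparison:
    """Pair log-ORs by (exposure, subtype) and summarize their differences.

    Both inputs are tables as produced by ``SubtypeFitResult.to_frame``.
    A least-squares line through the pairs accompanies the identity line
    for display.
    """
    key = ["exposure", "subtype"]
    a = results_cc.set_index(key)["log_OR"]
    b = results_ipw.set_index(key)["log_OR"]
    if set(a.index) != set(b.index):
        raise ValueError("complete-case and IPW results cover different exposures")
    b = b.reindex(a.index)
    diff = (b - a).to_numpy()
    if len(a) >= 2 and np.ptp(a.to_numpy()) > 0:
        slope, intercept = np.polyfit(a.to_numpy(), b.to_numpy(), 1)
    else:
        slope, intercept = np.nan, np.nan
    table = pd.DataFrame(
        {
            "log_OR_complete_case": a,
            "log_OR_ipw": b,
            "difference": b - a,
        }
    ).reset_index()
    return IpwComparison(
        table=table,
        mean_abs_diff=float(np.mean(np.abs(diff))),
        max_abs_diff=float(np.max(np.abs(diff))),
        slope=float(slope),
        intercept=float(intercept),
    )
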