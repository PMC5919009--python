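"""Case-case replication: multinomial logistic regression of tumor subtype
on exposure and ratios of odds ratios (RORs).

With wild-type tumors as the reference category, the exponentiated
per-allele slope for a mutated subtype is the ROR: the factor by which the
subtype-vs-wild-type odds change per variant allele.  Asymptotically this
equals the ratio of the subtype-specific case-control odds ratios, which
is what the consistency check below quantifies.  Heterogeneity of subtype
composition with respect to the exposure is tested by a likelihood-ratio
test of both slopes against zero (2 df, primary) or of slope equality
(1 df, alternative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from ._utils import EstimationError
from .matched import SubtypeFitResult

_Z95 = 1.959963984540054


@dataclass
class CaseOnlyDesign:
    """Cases with complete subtype labels and one exposure column."""

    data: pd.DataFrame
    exposure: str = "genotype"
    subtype_col: str = "subtype"
    reference: str = "WT"

    def frame(self) -> pd.DataFrame:
        df = self.data[[self.subtype_col, self.exposure]].dropna()
        return df


@dataclass
class RorEstimate:
    subtype: str
    log_ror: float
    se: float
    ror: float
    ci95: tuple[float, float]
    n: int


@dataclass
class RorResult:
    """Per-subtype RORs (reference fixed at 1) and the heterogeneity LRT."""

    exposure: str
    reference: str
    n_reference: int
    per_subtype: dict[str, RorEstimate]
    lrt: tuple[float, int, float]  # primary 2-df test: both slopes = 0
    lrt_equal_slopes: tuple[float, int, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subtype": self.reference,
                "n": self.n_reference,
                "ROR": 1.0,
                "CI_low": np.nan,
                "CI_high": np.nan,
                "P": self.lrt[2],
            }
        ]
        for s, e in self.per_subtype.items():
            rows.append(
                {
                    "subtype": s,
                    "n": e.n,
                    "ROR": e.ror,
                    "CI_low": e.ci95[0],
                    "CI_high": e.ci95[1],
                    "P": self.lrt[2],
                }
            )
        return pd.DataFrame(rows)


class CaseCaseMultinomial(BaseEstimator):
    """Baseline-category multinomial logit of subtype on one exposure.

    Attributes
    ----------
    ror_ : dict subtype -> RorEstimate
    llf_, llnull_ : fitted and intercept-only log-likelihoods
    lrt_ : (statistic, df, p) for the 2-df test of both slopes = 0
    """

    def __init__(self, reference: str = "WT", subtype_order: Sequence[str] = ("KRAS", "BRAF")):
        self.reference = reference
        self.subtype_order = subtype_order

    def fit(self, X, y=None):
        if isinstance(X, CaseOnlyDesign):
            df = X.frame()
            exposure, subtype = df[X.exposure].to_numpy(float), df[X.subtype_col]
            self.reference = X.reference
        else:
            exposure = np.asarray(X, dtype=float).ravel()
            subtype = pd.Series(np.asarray(y, dtype=object))
        levels = [self.reference] + [
            s for s in self.subtype_order if (subtype == s).any()
        ]
        extra = sorted(set(subtype) - set(levels))
        levels += extra
        if len(levels) < 2 or not (subtype == self.reference).any():
            raise EstimationError("need the reference level plus at least one subtype")
        if np.ptp(exposure) == 0:
            raise EstimationError("exposure does not vary among cases")
        codes = pd.Categorical(subtype, categories=levels).codes
        Xd = sm.add_constant(exposure)
        model = sm.MNLogit(codes, Xd)
        res = model.fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True):
            raise EstimationError("multinomial fit did not converge")
        null = sm.MNLogit(codes, np.ones((len(codes), 1))).fit(disp=0)
        self.llf_ = float(res.llf)
        self.llnull_ = float(null.llf)
        k = len(levels) - 1
        stat = max(0.0, 2.0 * (self.llf_ - self.llnull_))
        self.lrt_ = (float(stat), k, float(stats.chi2.sf(stat, k)))

        self.ror_ = {}
        params = np.asarray(res.params)  # shape (2, k): rows const, slope
        bse = np.asarray(res.bse)
        for j, s in enumerate(levels[1:]):
            b, se = float(params[1, j]), float(bse[1, j])
            self.ror_[s] = RorEstimate(
                subtype=s,
                log_ror=b,
                se=se,
                ror=float(np.exp(b)),
                ci95=(float(np.exp(b - _Z95 * se)), float(np.exp(b + _Z95 * se))),
                n=int((subtype == s).sum()),
            )
        self.n_reference_ = int((subtype == self.reference).sum())
        self._codes = codes
        self._exposure = exposure
        self._k = k
        return self

    def lrt_equal_slopes(self) -> tuple[float, int, float]:
        """Alternative 1-df-per-extra-slope test: slopes equal across subtypes."""
        codes, x, k = self._codes, self._exposure, self._k
        if k < 2:
            raise EstimationError("equal-slopes test needs at least two subtypes")

        def negll(theta):
            intercepts, slope = theta[:k], theta[k]
            eta = np.column_stack(
                [np.zeros_like(x)] + [intercepts[j] + slope * x for j in range(k)]
            )
            eta -= eta.max(axis=1, keepdims=True)
            logp = eta - np.log(np.exp(eta).sum(axis=1, keepdims=True))
            return -float(logp[np.arange(len(codes)), codes].sum())

        res = optimize.minimize(negll, np.zeros(k + 1), method="BFGS")
        ll_eq = -float(res.fun)
        stat = max(0.0, 2.0 * (self.llf_ - ll_eq))
        dof = k - 1
        return (float(stat), dof, float(stats.chi2.sf(stat, dof)))


def multinomial_fit(design: CaseOnlyDesign) -> CaseCaseMultinomial:
    return CaseCaseMultinomial(reference=design.reference).fit(design)


def ror_result(design: CaseOnlyDesign, equal_slopes: bool = True) -> RorResult:
    fit = multinomial_fit(design)
    eq = None
    if equal_slopes and fit._k >= 2:
        eq = fit.lrt_equal_slopes()
    return RorResult(
        exposure=design.exposure,
        reference=design.reference,
        n_reference=fit.n_reference_,
        per_subtype=fit.ror_,
        lrt=fit.lrt_,
        lrt_equal_slopes=eq,
    )


def case_case_heterogeneity_lrt(design: CaseOnlyDesign) -> tuple[float, int, float]:
    """Primary LRT: both subtype slopes jointly zero (chi-square, df = #slopes)."""
    return multinomial_fit(design).lrt_


@dataclass
class ConsistencyReport:
    """Case-control OR ratios next to the case-case RORs for one exposure."""

    table: pd.DataFrame
    comparable: bool


def consistency_with_case_control(
    cc_fit: SubtypeFitResult, ror: RorResult
) -> ConsistencyReport:
    """Compare OR_subtype / OR_reference with the case-case ROR per subtype.

    Under a shared generating mechanism the two agree asymptotically; the
    table reports the log-scale difference and its joint standard error.
    """
    rows = []
    comparable = True
    ref = ror.reference
    ref_est = cc_fit.per_subtype.get(ref)
    for s, e in ror.per_subtype.items():
        cc_est = cc_fit.per_subtype.get(s)
        if cc_est is None or ref_est is None:
            rows.append({"subtype": s, "comparable": False})
            comparable = False
            continue
        log_or_ratio = cc_est.log_or - ref_est.log_or
        se_ratio = float(np.hypot(cc_est.se, ref_est.se))
        diff = log_or_ratio - e.log_ror
        joint_se = float(np.hypot(se_ratio, e.se))
        rows.append(
            {
                "subtype": s,
                "log_or_ratio_case_control": log_or_ratio,
                "log_ror_case_case": e.log_ror,
                "difference": diff,
                "joint_se": joint_se,
                "comparable": True,
            }
        )
    return ConsistencyReport(table=pd.DataFrame(rows), comparable=comparable)
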