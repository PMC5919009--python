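"""Conditional logistic regression over matched sets and subtype-specific
odds ratios with heterogeneity testing.

The likelihood conditions on one case per matched set, eliminating the
set-level nuisance parameters that absorb the matching factors:

    l(beta) = sum_s w_s [ eta_case(s) - log sum_{i in s} exp(eta_i) ]

with eta the linear predictor and w_s an optional per-set weight (used by
the inverse-probability-weighted sensitivity analysis).  The maximizer is
found by damped Newton iterations with observed-information standard
errors; at beta = 0 the log-likelihood has the closed form
sum_s w_s log(1/m_s) for set sizes m_s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._utils import DomainError, EstimationError, SeparationError

#: default regression adjustments: biomarker models add lifestyle covariates,
#: SNP models rely on the matched-set conditioning alone
DEFAULT_BIOMARKER_ADJUST = (
    "bmi",
    "smoking",
    "alcohol",
    "neopterin",
    "recreational_pa",
    "occupational_pa",
)


class ConditionalLogisticRegression(BaseEstimator):
    """Maximum conditional likelihood for matched case-control sets.

    Parameters
    ----------
    max_iter, tol : Newton iteration controls; convergence when the
        gradient infinity-norm drops below ``tol``.
    max_halvings : step halvings allowed per iteration on likelihood decrease.
    cov_type : {'observed', 'robust'}
        Observed-information SEs (default) or a sandwich estimator over
        set-level score contributions (relevant under weighting).

    Attributes
    ----------
    coef_, bse_, cov_, llf_, llnull_, converged_, n_iter_
    """

    def __init__(
        self,
        max_iter: int = 100,
        tol: float = 1e-8,
        max_halvings: int = 30,
        cov_type: str = "observed",
        max_abs_coef: float = 15.0,
    ):
        self.max_iter = max_iter
        self.tol = tol
        self.max_halvings = max_halvings
        self.cov_type = cov_type
        self.max_abs_coef = max_abs_coef

    def fit(self, X, y, groups, sample_weight=None, start=None, feature_names=None):
        if isinstance(X, pd.DataFrame):
            feature_names = feature_names or list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y).astype(bool)
        groups = np.asarray(groups)
        n, p = X.shape
        self.feature_names_ = feature_names or [f"x{j}" for j in range(p)]

        order = np.argsort(groups, kind="stable")
        X, y, groups = X[order], y[order], groups[order]
        _, starts, counts = np.unique(groups, return_index=True, return_counts=True)
        if not np.all(np.add.reduceat(y.astype(int), starts) == 1):
            raise ValueError("every matched set must contain exactly one case")
        if sample_weight is None:
            w = np.ones(len(starts))
        else:
            sw = np.asarray(sample_weight, dtype=float)[order]
            if (sw < 0).any():
                raise DomainError("weights must be nonnegative")
            w = sw[y]  # the case's weight carries the set, per the IPW rule
        keep = w > 0
        # informative sets: exposure must vary within at least one set
        within_var = np.zeros(p)
        for j in range(p):
            col = X[:, j]
            mx = np.maximum.reduceat(col, starts)
            mn = np.minimum.reduceat(col, starts)
            within_var[j] = np.max((mx - mn)[keep]) if keep.any() else 0.0
        if not keep.any() or (within_var == 0).all():
            raise EstimationError("no informative matched sets")

        case_pos = np.flatnonzero(y)  # one per set, aligned with sorted sets

        beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
        ll, grad, hess = self._llk(beta, X, y, starts, w, case_pos)
        self.llnull_ = float(np.sum(w * np.log(1.0 / counts)))
        n_iter = 0
        converged = False
        for n_iter in range(1, self.max_iter + 1):
            if np.max(np.abs(grad)) < self.tol:
                converged = True
                break
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
            scale = 1.0
            for _ in range(self.max_halvings + 1):
                cand = beta + scale * step
                ll_new, g_new, h_new = self._llk(cand, X, y, starts, w, case_pos)
                if ll_new >= ll - 1e-12:
                    break
                scale *= 0.5
            else:
                break
            beta, ll, grad, hess = cand, ll_new, g_new, h_new
            if np.max(np.abs(beta)) > self.max_abs_coef:
                j = int(np.argmax(np.abs(beta)))
                raise SeparationError(self.feature_names_[j])
        else:
            if np.max(np.abs(grad)) < self.tol:
                converged = True
        if not converged and np.max(np.abs(grad)) < self.tol:
            converged = True
        if not converged:
            raise EstimationError(
                f"conditional logit did not converge in {self.max_iter} iterations"
            )

        info = -hess
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            raise EstimationError("singular information matrix")
        if self.cov_type == "robust":
            scores = self._set_scores(beta, X, starts, w, case_pos)
            meat = scores.T @ scores
            cov = cov @ meat @ cov
        self.coef_ = beta
        self.cov_ = cov
        self.bse_ = np.sqrt(np.diag(cov))
        self.llf_ = float(ll)
        self.n_iter_ = n_iter
        self.converged_ = True
        return self

    @staticmethod
    def _segments(eta, starts):
        # per-set logsumexp, softmax probabilities
        seg_max = np.maximum.reduceat(eta, starts)
        rep = np.repeat(seg_max, np.diff(np.append(starts, len(eta))))
        ex = np.exp(eta - rep)
        denom = np.add.reduceat(ex, starts)
        probs = ex / np.repeat(denom, np.diff(np.append(starts, len(eta))))
        lse = seg_max + np.log(denom)
        return probs, lse

    def _llk(self, beta, X, y, starts, w, case_pos):
        eta = X @ beta
        probs, lse = self._segments(eta, starts)
        ll = float(np.sum(w * (eta[case_pos] - lse)))
        wp = probs * np.repeat(w, np.diff(np.append(starts, len(eta))))
        mean_x = np.empty((len(starts), X.shape[1]))
        grad = np.zeros(X.shape[1])
        for j in range(X.shape[1]):
            mean_x[:, j] = np.add.reduceat(wp * X[:, j], starts)
        grad = (w[:, None] * X[case_pos]).sum(axis=0) - mean_x.sum(axis=0)
        # Hessian: -sum_s w_s (E_s[xx'] - E_s[x]E_s[x]')
        p = X.shape[1]
        exx = np.zeros((p, p))
        for j in range(p):
            for k in range(j, p):
                v = np.add.reduceat(wp * X[:, j] * X[:, k], starts).sum()
                exx[j, k] = exx[k, j] = v
        w_safe = np.where(w > 0, w, 1.0)  # zero-weight sets contribute nothing
        mu = mean_x / w_safe[:, None]
        emm = (w[:, None, None] * mu[:, :, None] * mu[:, None, :]).sum(axis=0)
        hess = -(exx - emm)
        return ll, grad, hess

    def _set_scores(self, beta, X, starts, w, case_pos):
        eta = X @ beta
        probs, _ = self._segments(eta, starts)
        p = X.shape[1]
        mu = np.empty((len(starts), p))
        for j in range(p):
            mu[:, j] = np.add.reduceat(probs * X[:, j], starts)
        return w[:, None] * (X[case_pos] - mu)

    def wald_ci(self, level: float = 0.95) -> np.ndarray:
        z = stats.norm.ppf(0.5 + level / 2)
        return np.column_stack([self.coef_ - z * self.bse_, self.coef_ + z * self.bse_])


@dataclass
class MatchedDesign:
    """A matched case-control analysis specification over a subject table."""

    data: pd.DataFrame
    exposure: str
    covariates: Sequence[str] = ()
    set_col: str = "set_id"
    case_col: str = "is_case"
    subtype_col: str = "subtype"

    def frame(self) -> pd.DataFrame:
        cols = [self.set_col, self.case_col, self.subtype_col, self.exposure, *self.covariates]
        cols = [c for c in dict.fromkeys(cols) if c in self.data.columns]
        return self.data[cols].dropna(subset=[self.exposure, *self.covariates])

    def design_matrix(self, df: pd.DataFrame) -> pd.DataFrame:
        """Numeric design: exposure first, categorical covariates dummy-coded."""
        parts = [df[[self.exposure]].astype(float)]
        for c in self.covariates:
            col = df[c]
            if col.dtype.kind in "fiub":
                parts.append(col.astype(float).to_frame())
            else:
                parts.append(pd.get_dummies(col.astype(str), prefix=c, drop_first=True).astype(float))
        return pd.concat(parts, axis=1)


def _drop_incomplete_sets(df: pd.DataFrame, design: MatchedDesign) -> pd.DataFrame:
    """Keep only sets that still have one case and at least one control."""
    g = df.groupby(design.set_col)[design.case_col]
    ok = g.transform("sum").eq(1) & g.transform("size").gt(1)
    return df[ok]


def clogit_fit(
    design: MatchedDesign,
    start=None,
    sample_weight=None,
    cov_type: str = "observed",
) -> ConditionalLogisticRegression:
    """Fit the conditional logistic model of a :class:`MatchedDesign`."""
    df = _drop_incomplete_sets(design.frame(), design)
    Xd = design.design_matrix(df)
    est = ConditionalLogisticRegression(cov_type=cov_type)
    sw = None
    if sample_weight is not None:
        sw = np.asarray(pd.Series(sample_weight).reindex(df.index).to_numpy(), dtype=float)
    est.fit(
        Xd,
        df[design.case_col].to_numpy(),
        df[design.set_col].to_numpy(),
        sample_weight=sw,
        start=start,
        feature_names=list(Xd.columns),
    )
    return est


@dataclass
class SubtypeEstimate:
    subtype: str
    log_or: float
    se: float
    odds_ratio: float
    ci95: tuple[float, float]
    n_cases: int
    n_controls: int


@dataclass
class SubtypeFitResult:
    """Per-subtype odds ratios plus the heterogeneity likelihood-ratio test."""

    exposure: str
    per_subtype: dict[str, SubtypeEstimate]
    lrt_het: tuple[float, int, float] | None = None  # (statistic, df, p)
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, e in self.per_subtype.items():
            rows.append(
                {
                    "exposure": self.exposure,
                    "subtype": s,
                    "n_cases": e.n_cases,
                    "n_controls": e.n_controls,
                    "OR": e.odds_ratio,
                    "CI_low": e.ci95[0],
                    "CI_high": e.ci95[1],
                    "log_OR": e.log_or,
                    "SE": e.se,
                    "P_het": self.lrt_het[2] if self.lrt_het else np.nan,
                }
            )
        return pd.DataFrame(rows)


_Z95 = 1.959963984540054


def subtype_specific_fit(
    design: MatchedDesign,
    subtypes: Sequence[str] = ("KRAS", "BRAF", "WT"),
    sample_weight=None,
    cov_type: str = "observed",
    heterogeneity: bool = True,
    shared_nuisance: bool = False,
) -> SubtypeFitResult:
    """Subtype-specific ORs: one conditional logit per subtype's sets.

    Sets whose case lacks a subtype label (tumor data unavailable) are
    excluded; each case's matched controls travel with it.  When
    ``heterogeneity`` is set, a likelihood-ratio test compares
    subtype-specific exposure coefficients against a common coefficient
    (nuisance covariates stay subtype-specific in both models unless
    ``shared_nuisance``).
    """
    df = _drop_incomplete_sets(design.frame(), design)
    sub_per_set = (
        df.loc[df[design.case_col], [design.set_col, design.subtype_col]]
        .set_index(design.set_col)[design.subtype_col]
    )
    per_subtype: dict[str, SubtypeEstimate] = {}
    warnings: list[str] = []
    fits: dict[str, ConditionalLogisticRegression] = {}
    for s in subtypes:
        sets_s = sub_per_set.index[sub_per_set == s]
        sub = df[df[design.set_col].isin(sets_s)]
        if sub.empty or not sub[design.case_col].any():
            warnings.append(f"subtype {s!r} has no informative sets; omitted")
            continue
        d_s = MatchedDesign(
            data=sub,
            exposure=design.exposure,
            covariates=design.covariates,
            set_col=design.set_col,
            case_col=design.case_col,
            subtype_col=design.subtype_col,
        )
        fit = clogit_fit(d_s, sample_weight=sample_weight, cov_type=cov_type)
        b, se = float(fit.coef_[0]), float(fit.bse_[0])
        per_subtype[s] = SubtypeEstimate(
            subtype=s,
            log_or=b,
            se=se,
            odds_ratio=float(np.exp(b)),
            ci95=(float(np.exp(b - _Z95 * se)), float(np.exp(b + _Z95 * se))),
            n_cases=int(sub[design.case_col].sum()),
            n_controls=int((~sub[design.case_col]).sum()),
        )
        fits[s] = fit

    lrt = None
    if heterogeneity and len(fits) >= 2:
        lrt = _heterogeneity_lrt_from_design(
            design, df, sub_per_set, list(fits), fits,
            sample_weight=sample_weight, shared_nuisance=shared_nuisance,
        )
    return SubtypeFitResult(
        exposure=design.exposure, per_subtype=per_subtype, lrt_het=lrt, warnings=warnings
    )


def _joint_design_matrix(
    design: MatchedDesign,
    df: pd.DataFrame,
    sub_per_set: pd.Series,
    subtypes: Sequence[str],
    split_exposure: bool,
    shared_nuisance: bool,
) -> pd.DataFrame:
    """Stacked design over all subtype sets with optional per-subtype columns."""
    base = design.design_matrix(df)
    set_sub = df[design.set_col].map(sub_per_set)
    parts = {}
    if split_exposure:
        for s in subtypes:
            ind = (set_sub == s).astype(float).to_numpy()
            parts[f"{design.exposure}:{s}"] = base[design.exposure].to_numpy() * ind
    else:
        parts[design.exposure] = base[design.exposure].to_numpy()
    nuisance = [c for c in base.columns if c != design.exposure]
    for c in nuisance:
        if shared_nuisance:
            parts[c] = base[c].to_numpy()
        else:
            for s in subtypes:
                ind = (set_sub == s).astype(float).to_numpy()
                parts[f"{c}:{s}"] = base[c].to_numpy() * ind
    return pd.DataFrame(parts, index=df.index)


def _heterogeneity_lrt_from_design(
    design, df, sub_per_set, subtypes, fits, sample_weight=None, shared_nuisance=False
) -> tuple[float, int, float]:
    keep_sets = sub_per_set.index[sub_per_set.isin(subtypes)]
    sub = df[df[design.set_col].isin(keep_sets)]
    if shared_nuisance:
        X_full = _joint_design_matrix(design, sub, sub_per_set, subtypes, True, True)
        ll_full = _fit_joint(design, sub, X_full, sample_weight).llf_
    else:
        # full model with subtype-specific exposure AND nuisance terms is
        # likelihood-equivalent to the separate per-subtype fits
        ll_full = float(sum(f.llf_ for f in fits.values()))
    X_red = _joint_design_matrix(design, sub, sub_per_set, subtypes, False, shared_nuisance)
    ll_red = _fit_joint(design, sub, X_red, sample_weight).llf_
    stat = max(0.0, 2.0 * (ll_full - ll_red))
    dof = len(subtypes) - 1
    pval = float(stats.chi2.sf(stat, dof))
    return (float(stat), dof, pval)


def _fit_joint(design, df, Xd, sample_weight):
    est = ConditionalLogisticRegression()
    sw = None
    if sample_weight is not None:
        sw = np.asarray(pd.Series(sample_weight).reindex(df.index).to_numpy(), dtype=float)
    est.fit(
        Xd,
        df[design.case_col].to_numpy(),
        df[design.set_col].to_numpy(),
        sample_weight=sw,
        feature_names=list(Xd.columns),
    )
    return est


def heterogeneity_lrt(
    design: MatchedDesign,
    subtypes: Sequence[str] = ("KRAS", "BRAF", "WT"),
    sample_weight=None,
    shared_nuisance: bool = False,
) -> tuple[float, int, float]:
    """LRT of subtype-varying vs subtype-constant exposure association.

    Statistic 2(l_full - l_reduced) ~ chi-square with (#subtypes - 1) df.
    """
    df = _drop_incomplete_sets(design.frame(), design)
    sub_per_set = (
        df.loc[df[design.case_col], [design.set_col, design.subtype_col]]
        .set_index(design.set_col)[design.subtype_col]
    )
    present = [s for s in subtypes if (sub_per_set == s).any()]
    if len(present) < 2:
        raise EstimationError("heterogeneity test needs at least two subtypes with sets")
    fits = {}
    for s in present:
        sets_s = sub_per_set.index[sub_per_set == s]
        d_s = MatchedDesign(
            data=df[df[design.set_col].isin(sets_s)],
            exposure=design.exposure,
            covariates=design.covariates,
            set_col=design.set_col,
            case_col=design.case_col,
            subtype_col=design.subtype_col,
        )
        fits[s] = clogit_fit(d_s, sample_weight=sample_weight)
    return _heterogeneity_lrt_from_design(
        design, df, sub_per_set, present, fits,
        sample_weight=sample_weight, shared_nuisance=shared_nuisance,
    )


def cochran_q(estimates: Sequence[tuple[float, float]]) -> tuple[float, int, float]:
    """Cochran's Q over (log-OR, SE) pairs: fixed-effect homogeneity test."""
    if len(estimates) < 2:
        raise ValueError("need at least two estimates")
    beta = np.array([b for b, _ in estimates], dtype=float)
    se = np.array([s for _, s in estimates], dtype=float)
    if (se <= 0).any():
        raise DomainError("standard errors must be positive")
    w = se**-2
    pooled = float(np.sum(w * beta) / np.sum(w))
    q = float(np.sum(w * (beta - pooled) ** 2))
    dof = len(estimates) - 1
    return q, dof, float(stats.chi2.sf(q, dof))


def snp_metabolite_association(
    genotype, metabolite
) -> tuple[float, float, float]:
    """Percent change in metabolite concentration per variant allele.

    Ordinary least squares of log-concentration on allele count; returns
    (percent change per allele, SE of the log-slope, two-sided Wald p).
    """
    import statsmodels.api as sm

    g = np.asarray(genotype, dtype=float)
    conc = np.asarray(metabolite, dtype=float)
    ok = ~(np.isnan(g) | np.isnan(conc))
    g, conc = g[ok], conc[ok]
    if (conc <= 0).any():
        raise DomainError("concentrations must be positive")
    if np.ptp(g) == 0:
        raise EstimationError("genotype is constant; slope inestimable")
    res = sm.OLS(np.log(conc), sm.add_constant(g)).fit()
    slope = float(res.params[1])
    return 100.0 * (np.exp(slope) - 1.0), float(res.bse[1]), float(res.pvalues[1])
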