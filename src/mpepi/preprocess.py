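"""Analysis-variable derivation for the discrete (network) and regression stages.

Continuous exposures are discretized into tertiles with cut-offs taken
from the control distribution (inverse-ECDF quantiles, right-closed bins),
or standardized per control log-SD for the "OR per 1 SD" contrast.  SNPs
are carried per-allele for regression and dominant-coded (any variant
allele) for the network stage.  Self-reported lifestyle covariates get an
explicit "missing" category; biomarker/SNP missingness is handled by
complete-case exclusion with exact bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import DegenerateDataError, DomainError
from .simulate import CONTROL, UNAVAILABLE, Cohort

MISSING_LABEL = "missing"
OUTCOME_COL = "outcome"
OUTCOME_LEVELS = ("control", "KRAS", "BRAF", "WT")


class ControlQuantileDiscretizer(TransformerMixin, BaseEstimator):
    """Discretize a continuous variable at control-based quantile cut-offs.

    Parameters
    ----------
    n_bins : int
        3 for tertiles (default), 4 for quartiles.

    The fit sample is the control subsample only.  Cut-offs are inverse-ECDF
    empirical quantiles; a value equal to an upper cut-off stays in the lower
    group (right-closed bins).  Applied to its own fit sample the rule yields
    groups as equal as ties permit.
    """

    def __init__(self, n_bins: int = 3):
        self.n_bins = n_bins

    def fit(self, X, y=None):
        values = np.asarray(X, dtype=float).ravel()
        values = values[~np.isnan(values)]
        if values.size < self.n_bins:
            raise DegenerateDataError(
                f"need at least {self.n_bins} non-missing control values"
            )
        qs = np.arange(1, self.n_bins) / self.n_bins
        cuts = np.quantile(values, qs, method="inverted_cdf")
        if np.unique(cuts).size != cuts.size:
            raise DegenerateDataError(
                "control distribution too concentrated to discretize"
            )
        self.cutpoints_ = np.asarray(cuts, dtype=float)
        self.n_values_ = int(values.size)
        return self

    def transform(self, X):
        values = np.asarray(X, dtype=float).ravel()
        codes = np.searchsorted(self.cutpoints_, values, side="left").astype(float)
        codes[np.isnan(values)] = np.nan
        return codes

    def labels(self) -> list[str]:
        prefix = "T" if self.n_bins == 3 else "Q"
        return [f"{prefix}{i + 1}" for i in range(self.n_bins)]


class LogSDScaler(TransformerMixin, BaseEstimator):
    """Standardize concentrations per 1 SD of the control log-distribution.

    One unit of the transformed scale is the "per 1 SD" contrast of the
    biomarker odds ratios.
    """

    def fit(self, X, y=None):
        values = np.asarray(X, dtype=float).ravel()
        values = values[~np.isnan(values)]
        if (values <= 0).any():
            raise DomainError("concentrations must be positive")
        logs = np.log(values)
        sd = float(np.std(logs, ddof=1)) if logs.size > 1 else 0.0
        if not sd > 0:
            raise DegenerateDataError("zero spread in control log-values")
        self.mean_ = float(np.mean(logs))
        self.scale_ = sd
        return self

    def transform(self, X):
        values = np.asarray(X, dtype=float)
        out = np.full(values.shape, np.nan)
        ok = ~np.isnan(values)
        if (values[ok] <= 0).any():
            raise DomainError("concentrations must be positive")
        out[ok] = (np.log(values[ok]) - self.mean_) / self.scale_
        return out

    def inverse_transform(self, Z):
        z = np.asarray(Z, dtype=float)
        return np.exp(z * self.scale_ + self.mean_)


@dataclass
class DiscretizationRule:
    """A fitted control-based cut-off rule for one variable."""

    variable: str
    cutpoints: tuple[float, ...]
    labels: tuple[str, ...]
    source: str = "controls"

    def apply(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        codes = np.searchsorted(np.asarray(self.cutpoints), v, side="left")
        out = np.empty(v.shape, dtype=object)
        ok = ~np.isnan(v)
        out[ok] = np.asarray(self.labels, dtype=object)[codes[ok]]
        out[~ok] = None
        return out


def fit_tertile_rule(values_controls, variable: str = "x") -> DiscretizationRule:
    disc = ControlQuantileDiscretizer(n_bins=3).fit(values_controls)
    return DiscretizationRule(
        variable=variable,
        cutpoints=tuple(float(c) for c in disc.cutpoints_),
        labels=tuple(disc.labels()),
    )


def fit_quartile_rule(values_controls, variable: str = "x") -> DiscretizationRule:
    disc = ControlQuantileDiscretizer(n_bins=4).fit(values_controls)
    return DiscretizationRule(
        variable=variable,
        cutpoints=tuple(float(c) for c in disc.cutpoints_),
        labels=tuple(disc.labels()),
    )


def standardize_per_sd(values, controls) -> np.ndarray:
    """(log value - control log-mean) / control log-SD."""
    return LogSDScaler().fit(controls).transform(values)


def encode_genotype(allele_count, mode: str = "additive"):
    """Per-allele ('additive') or any-variant ('dominant') genotype encoding."""
    counts = np.asarray(allele_count, dtype=float)
    ok = ~np.isnan(counts)
    if not np.isin(counts[ok], (0.0, 1.0, 2.0)).all():
        raise DomainError("allele counts must be in {0, 1, 2}")
    if mode == "additive":
        return counts
    if mode == "dominant":
        out = np.where(counts >= 1, 1.0, 0.0)
        out[~ok] = np.nan
        return out
    raise ValueError(f"unknown genotype encoding {mode!r}")


def compute_egfr_cockcroft_gault(
    age, weight_kg, creatinine, sex, creatinine_unit: str = "mg/dl"
) -> np.ndarray:
    """Cockcroft-Gault creatinine clearance in mL/min.

    (140 - age) * weight / (72 * creatinine[mg/dL]), times 0.85 for women.
    ``creatinine_unit`` may be 'mg/dl' or 'umol/l' (divided by 88.4).
    """
    age = np.asarray(age, dtype=float)
    weight = np.asarray(weight_kg, dtype=float)
    crea = np.asarray(creatinine, dtype=float)
    if (age <= 0).any() or (weight <= 0).any() or (crea <= 0).any():
        raise DomainError("age, weight and creatinine must be positive")
    if creatinine_unit.lower() in ("umol/l", "µmol/l"):
        crea = crea / 88.4
    elif creatinine_unit.lower() != "mg/dl":
        raise ValueError(f"unknown creatinine unit {creatinine_unit!r}")
    egfr = (140.0 - age) * weight / (72.0 * crea)
    female = np.asarray(sex) == "female"
    return np.where(female, 0.85 * egfr, egfr)


def assign_missing_category(values: pd.Series, label: str = MISSING_LABEL) -> pd.Series:
    """Replace missing markers in a categorical covariate by an explicit level."""
    out = values.astype(object).copy()
    mask = pd.isna(out)
    out[mask] = label
    return out


def bmi_band(bmi) -> np.ndarray:
    """BMI in the bands <25, [25, 30), >=30 kg/m^2."""
    b = np.asarray(bmi, dtype=float)
    out = np.empty(b.shape, dtype=object)
    out[b < 25] = "lt_25"
    out[(b >= 25) & (b < 30)] = "25_30"
    out[b >= 30] = "ge_30"
    out[np.isnan(b)] = None
    return out


@dataclass
class DiscreteDataset:
    """Fully categorical complete-case table for network learning.

    ``data`` has one row per retained subject; every column is a string
    category and ``outcome`` is the 4-level node (control/KRAS/BRAF/WT).
    """

    data: pd.DataFrame
    rules: dict[str, DiscretizationRule]
    n_dropped_cases: int
    n_dropped_controls: int
    n_unavailable_sets: int
    outcome: str = OUTCOME_COL

    def variables(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("subject_id", "set_id")]

    def write(self, table_path: str | Path, rules_path: str | Path | None = None) -> None:
        self.data.to_csv(table_path, sep="\t", index=False)
        if rules_path is not None:
            save_rules(self.rules, rules_path)


def save_rules(rules: Mapping[str, DiscretizationRule], path: str | Path) -> None:
    payload = {
        name: {
            "variable": r.variable,
            "cutpoints": list(r.cutpoints),
            "labels": list(r.labels),
            "source": r.source,
        }
        for name, r in rules.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_rules(path: str | Path) -> dict[str, DiscretizationRule]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return {
        name: DiscretizationRule(
            variable=d["variable"],
            cutpoints=tuple(d["cutpoints"]),
            labels=tuple(d["labels"]),
            source=d.get("source", "controls"),
        )
        for name, d in payload.items()
    }


def build_discrete_dataset(
    cohort: Cohort,
    rules: Mapping[str, DiscretizationRule] | None = None,
    quantile_source: str = "controls",
) -> DiscreteDataset:
    """Assemble the categorical table consumed by network learning.

    Biomarkers (and neopterin, eGFR) become control-based tertiles, age a
    control-based quartile group, SNPs dominant dichotomies, lifestyle
    covariates explicit categories with a "missing" level, and the outcome
    the 4-level node.  Sets whose case lacks tumor data are dropped first;
    then any subject with a missing biomarker or SNP is excluded
    (complete-case), with exact drop counts reported.
    """
    df = cohort.data
    bio = cohort.biomarker_names()
    snps = cohort.snp_names()

    unavailable_sets = set(df.loc[df["subtype"] == UNAVAILABLE, "set_id"])
    kept = df[~df["set_id"].isin(unavailable_sets)].copy()

    exposures = bio + snps
    incomplete = kept[exposures].isna().any(axis=1)
    n_dropped_cases = int((incomplete & kept["is_case"]).sum())
    n_dropped_controls = int((incomplete & ~kept["is_case"]).sum())
    kept = kept[~incomplete].copy()

    controls = kept[~kept["is_case"]]
    if quantile_source == "pooled":
        fit_frame = kept
    elif quantile_source == "controls":
        fit_frame = controls
    else:
        raise ValueError(f"unknown quantile_source {quantile_source!r}")

    egfr = compute_egfr_cockcroft_gault(
        kept["age_at_sampling"], kept["weight_kg"], kept["creatinine"], kept["sex"]
    )
    kept = kept.assign(egfr=egfr)
    fit_egfr = kept.loc[fit_frame.index, "egfr"]

    if rules is None:
        rules = {}
        for name in bio:
            rules[name] = fit_tertile_rule(fit_frame[name], variable=name)
        rules["neopterin"] = fit_tertile_rule(fit_frame["neopterin"], variable="neopterin")
        rules["egfr"] = fit_tertile_rule(fit_egfr, variable="egfr")
        rules["age_at_sampling"] = fit_quartile_rule(
            fit_frame["age_at_sampling"], variable="age_at_sampling"
        )
    rules = dict(rules)

    out = pd.DataFrame(
        {"subject_id": kept["subject_id"], "set_id": kept["set_id"]},
        index=kept.index,
    )
    for name in bio:
        out[name] = rules[name].apply(kept[name])
    for name in snps:
        out[name] = np.where(encode_genotype(kept[name], "dominant") >= 1, "variant", "common")
    out["sex"] = kept["sex"]
    out["cohort"] = kept["cohort"]
    out["fasting"] = kept["fasting"]
    out["age_group"] = rules["age_at_sampling"].apply(kept["age_at_sampling"])
    out["bmi_band"] = bmi_band(kept["bmi"])
    out["smoking"] = assign_missing_category(kept["smoking"])
    out["alcohol"] = assign_missing_category(kept["alcohol"])
    out["recreational_pa"] = assign_missing_category(kept["recreational_pa"])
    out["occupational_pa"] = assign_missing_category(kept["occupational_pa"])
    out["neopterin"] = rules["neopterin"].apply(kept["neopterin"])
    out["egfr"] = rules["egfr"].apply(kept["egfr"])
    subtype = kept["subtype"].astype(object)
    out[OUTCOME_COL] = np.where(subtype == CONTROL, "control", subtype)

    return DiscreteDataset(
        data=out.reset_index(drop=True),
        rules=rules,
        n_dropped_cases=n_dropped_cases,
        n_dropped_controls=n_dropped_controls,
        n_unavailable_sets=len(unavailable_sets),
    )
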