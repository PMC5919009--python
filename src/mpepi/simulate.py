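"""Synthetic matched case-control cohorts with molecular tumor subtypes.

The generator emulates a nested case-control study in which each incident
case is matched to a fixed number of controls on sex, age (within a small
caliper), cohort and fasting status.  Cases carry one of three mutually
exclusive tumor subtypes (KRAS-mutated, BRAF-mutated, wild-type); tumor
mutation data may be unavailable for a covariate-dependent fraction of
cases.  Exposures are a panel of correlated log-normal plasma biomarkers
and Hardy-Weinberg SNP genotypes with configurable subtype-specific
log-odds effects, so every downstream estimator can be tested against a
known ground truth.

Case status is generated by a within-set conditional logit: given the
set's subtype, each member becomes the case with probability proportional
to exp(sum of subtype-specific effects times its exposures).  This is
exactly the model the conditional-likelihood estimators assume, so
parameter recovery is unbiased by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._utils import ConfigurationError, child_seed, stream_rng

SUBTYPES = ("KRAS", "BRAF", "WT")
UNAVAILABLE = "UNAVAILABLE"
CONTROL = "NONE"

#: default biomarker panel: (name, mean of log-concentration, SD of log-concentration)
DEFAULT_BIOMARKERS: tuple[tuple[str, float, float], ...] = (
    ("folate", 2.30, 0.45),
    ("vitamin_b6", 3.55, 0.50),
    ("vitamin_b2", 2.56, 0.60),
    ("vitamin_b12", 5.80, 0.35),
    ("homocysteine", 2.25, 0.30),
    ("cystathionine", -1.61, 0.50),
    ("cysteine", 5.63, 0.12),
    ("glycine", 5.48, 0.20),
    ("serine", 4.70, 0.18),
    ("methionine", 3.22, 0.20),
    ("choline", 2.20, 0.20),
    ("betaine", 3.55, 0.30),
    ("dmg", 1.39, 0.30),
    ("sarcosine", 0.34, 0.35),
)

#: default SNP panel: (name, minor-allele frequency)
DEFAULT_SNPS: tuple[tuple[str, float], ...] = (
    ("rs1021737", 0.31),
    ("rs3733890", 0.30),
    ("rs234706", 0.31),
    ("cbs_844ins68", 0.08),
    ("rs70991108", 0.43),
    ("rs2071010", 0.12),
    ("rs2236225", 0.44),
    ("rs1801131", 0.31),
    ("rs1801133", 0.33),
    ("rs1805087", 0.19),
    ("rs1532268", 0.45),
    ("rs1801394", 0.47),
    ("rs1979277", 0.30),
    ("rs1051266", 0.44),
    ("rs1801198", 0.44),
    ("rs9606756", 0.11),
    ("rs34489327", 0.29),
)

# Table-2-patterned default truth: per-allele log-OR for (KRAS, BRAF, WT)
DEFAULT_EFFECTS: dict[str, tuple[float, float, float]] = {
    "rs1021737": (float(np.log(0.72)), float(np.log(1.56)), float(np.log(0.94))),
}


def _exchangeable_corr(p: int, rho: float = 0.25) -> np.ndarray:
    return np.full((p, p), rho) + (1.0 - rho) * np.eye(p)


@dataclass
class SimulationConfig:
    """Study-design quantities for one simulated cohort.

    Defaults mirror the emulated study: 1:2 matching, subtype mix
    (0.26, 0.24, 0.50), 14 correlated log-normal biomarkers, 17
    Hardy-Weinberg SNPs, a 7% per-allele effect of the designated SNP on
    its metabolite, and ~0.3% missingness per exposure.
    """

    n_cases: int = 488
    controls_per_case: int = 2
    subtype_probs: tuple[float, float, float] = (0.26, 0.24, 0.50)
    biomarker_spec: Sequence[tuple[str, float, float]] = DEFAULT_BIOMARKERS
    biomarker_corr: np.ndarray | None = None  # defaults to exchangeable 0.25
    snp_spec: Sequence[tuple[str, float]] = DEFAULT_SNPS
    effect_spec: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    snp_metabolite_effect: tuple[str, str, float] = ("rs1021737", "cystathionine", 1.07)
    site_snp_effect: float = 0.0  # per-allele log-odds shift toward right-sided tumors
    availability_spec: Mapping[str, float] | None = None
    missingness_rate: float = 0.003
    age_caliper: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.subtype_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any():
            raise ConfigurationError("subtype_probs must be three nonnegative values")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ConfigurationError("subtype_probs must sum to 1 within 1e-12")
        if self.controls_per_case < 1:
            raise ConfigurationError("controls_per_case must be >= 1")
        if self.n_cases < 1:
            raise ConfigurationError("n_cases must be positive")
        if not (0.0 <= self.missingness_rate <= 0.03):
            raise ConfigurationError("missingness_rate must lie in [0, 0.03]")
        for name, maf in self.snp_spec:
            if not (0.0 <= maf <= 0.5):
                raise ConfigurationError(f"MAF of {name!r} outside [0, 0.5]")
        corr = self.corr_matrix()
        if corr.shape != (len(self.biomarker_spec),) * 2:
            raise ConfigurationError("correlation matrix shape mismatch")
        if len(self.biomarker_spec) > 0:
            if not np.allclose(corr, corr.T):
                raise ConfigurationError("correlation matrix must be symmetric")
            if np.linalg.eigvalsh(corr).min() <= 0:
                raise ConfigurationError("correlation matrix must be positive definite")
        known = self.exposure_names()
        for name in self.effect_spec:
            if name not in known:
                raise ConfigurationError(f"effect_spec references unknown exposure {name!r}")

    def corr_matrix(self) -> np.ndarray:
        if self.biomarker_corr is None:
            return _exchangeable_corr(len(self.biomarker_spec))
        return np.asarray(self.biomarker_corr, dtype=float)

    def biomarker_names(self) -> list[str]:
        return [name for name, _, _ in self.biomarker_spec]

    def snp_names(self) -> list[str]:
        return [name for name, _ in self.snp_spec]

    def exposure_names(self) -> list[str]:
        return self.biomarker_names() + self.snp_names()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["biomarker_spec"] = [[b[0], float(b[1]), float(b[2])] for b in self.biomarker_spec]
        d["snp_spec"] = [[s[0], float(s[1])] for s in self.snp_spec]
        d["effect_spec"] = {k: [float(x) for x in v] for k, v in self.effect_spec.items()}
        sm = self.snp_metabolite_effect
        d["snp_metabolite_effect"] = [sm[0], sm[1], float(sm[2])]
        if self.biomarker_corr is not None:
            d["biomarker_corr"] = np.asarray(self.biomarker_corr, dtype=float).tolist()
        d["subtype_probs"] = [float(p) for p in self.subtype_probs]
        if self.availability_spec is not None:
            d["availability_spec"] = {k: float(v) for k, v in self.availability_spec.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "biomarker_spec" in d:
            d["biomarker_spec"] = [tuple(b) for b in d["biomarker_spec"]]
        if "snp_spec" in d:
            d["snp_spec"] = [tuple(s) for s in d["snp_spec"]]
        if "effect_spec" in d:
            d["effect_spec"] = {k: tuple(v) for k, v in d["effect_spec"].items()}
        if "snp_metabolite_effect" in d:
            d["snp_metabolite_effect"] = tuple(d["snp_metabolite_effect"])
        if d.get("biomarker_corr") is not None:
            d["biomarker_corr"] = np.asarray(d["biomarker_corr"], dtype=float)
        if "subtype_probs" in d:
            d["subtype_probs"] = tuple(d["subtype_probs"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class Cohort:
    """A simulated cohort: one row per subject plus the generating truth."""

    data: pd.DataFrame
    config: SimulationConfig
    truth: Mapping[str, tuple[float, float, float]]

    @property
    def cases(self) -> pd.DataFrame:
        return self.data[self.data["is_case"]]

    @property
    def controls(self) -> pd.DataFrame:
        return self.data[~self.data["is_case"]]

    def biomarker_names(self) -> list[str]:
        return self.config.biomarker_names()

    def snp_names(self) -> list[str]:
        return self.config.snp_names()

    def write(self, table_path: str | Path, config_path: str | Path | None = None) -> None:
        """Write the subject table (TSV) and a sidecar config echo (YAML)."""
        self.data.to_csv(table_path, sep="\t", index=False)
        if config_path is not None:
            self.config.to_yaml(config_path)

    @classmethod
    def read(cls, table_path: str | Path, config_path: str | Path) -> "Cohort":
        config = SimulationConfig.from_yaml(config_path)
        data = pd.read_csv(table_path, sep="\t")
        return cls(data=data, config=config, truth=dict(config.effect_spec))


def _availability_probs(cases: pd.DataFrame, spec: Mapping[str, float]) -> np.ndarray:
    """expit(linear predictor) of tumor-data availability on case covariates."""
    from scipy.special import expit

    lp = np.full(len(cases), float(spec.get("intercept", 0.0)))
    covariate_frame = _availability_covariate_frame(cases)
    for name, coef in spec.items():
        if name == "intercept":
            continue
        if name not in covariate_frame.columns:
            raise ConfigurationError(
                f"availability_spec references unknown covariate {name!r}"
            )
        lp += float(coef) * covariate_frame[name].to_numpy(dtype=float)
    return expit(lp)


def _availability_covariate_frame(cases: pd.DataFrame) -> pd.DataFrame:
    """Numeric encodings of the case covariates the availability model may use."""
    f = pd.DataFrame(index=cases.index)
    f["age_at_sampling"] = cases["age_at_sampling"]
    f["age_at_diagnosis"] = cases["age_at_diagnosis"]
    f["sex_female"] = (cases["sex"] == "female").astype(float)
    f["cohort_msp"] = (cases["cohort"] == "MSP").astype(float)
    f["stage_iii_iv"] = (cases["tumor_stage"] == "III_IV").astype(float)
    f["site_right"] = (cases["tumor_site"] == "right_colon").astype(float)
    f["site_rectum"] = (cases["tumor_site"] == "rectum").astype(float)
    f["year_2002_2006"] = (cases["year_of_diagnosis"] == "2002_2006").astype(float)
    f["year_ge_2006"] = (cases["year_of_diagnosis"] == "ge_2006").astype(float)
    return f


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> Cohort:
    """Generate a matched case-control cohort under ``config``.

    Returns a :class:`Cohort` whose sets each contain exactly one case and
    ``controls_per_case`` controls, matched exactly on sex, cohort and
    fasting and within ``age_caliper`` years on age.
    """
    master = config.seed if seed is None else seed
    n_sets = config.n_cases
    m = 1 + config.controls_per_case
    n = n_sets * m

    match_rng = stream_rng(master, "matching")
    bio_rng = stream_rng(master, "biomarkers")
    snp_rng = stream_rng(master, "genotypes")
    out_rng = stream_rng(master, "outcome")
    clin_rng = stream_rng(master, "clinical")
    miss_rng = stream_rng(master, "missingness")

    # --- set-level matching variables -------------------------------------
    cohort_lab = np.where(match_rng.random(n_sets) < 0.78, "VIP", "MSP")
    sex = np.where(
        cohort_lab == "MSP", "female",
        np.where(match_rng.random(n_sets) < 0.5, "female", "male"),
    )
    fasting = np.empty(n_sets, dtype=object)
    vip = cohort_lab == "VIP"
    fasting[vip] = match_rng.choice(
        ["ge_8h", "4_8h", "lt_4h"], size=int(vip.sum()), p=[0.77, 0.13, 0.10]
    )
    fasting[~vip] = match_rng.choice(
        ["lt_4h", "4_8h", "ge_8h"], size=int((~vip).sum()), p=[0.96, 0.03, 0.01]
    )
    set_age = np.clip(match_rng.normal(60.0, 7.0, n_sets), 35.0, 75.0)

    rep = np.repeat  # member-level expansion
    set_id = rep(np.arange(n_sets), m)
    member = np.tile(np.arange(m), n_sets)
    age = rep(set_age, m) + match_rng.uniform(
        -config.age_caliper / 2, config.age_caliper / 2, n
    )
    sex_m = rep(sex, m)
    cohort_m = rep(cohort_lab, m)
    fasting_m = rep(fasting, m)

    # --- anthropometry, kidney function inputs, lifestyle -----------------
    female = sex_m == "female"
    height = np.where(
        female, clin_rng.normal(1.65, 0.06, n), clin_rng.normal(1.78, 0.07, n)
    )
    bmi = np.clip(clin_rng.normal(25.8, 3.8, n), 17.0, 45.0)
    weight = bmi * height**2
    creatinine = np.exp(
        np.where(
            female,
            clin_rng.normal(np.log(0.78), 0.13, n),
            clin_rng.normal(np.log(0.95), 0.13, n),
        )
    )
    neopterin = np.exp(clin_rng.normal(np.log(9.5), 0.25, n))
    smoking = clin_rng.choice(["never", "current", "ex"], size=n, p=[0.62, 0.20, 0.18])
    alcohol = clin_rng.choice(
        ["zero", "below_median", "above_median"], size=n, p=[0.12, 0.44, 0.44]
    )
    recreational_pa = clin_rng.choice(
        ["1", "2", "3", "4", "5"], size=n, p=[0.40, 0.26, 0.18, 0.08, 0.08]
    )
    occupational_pa = clin_rng.choice(
        ["1", "2", "3", "4", "5"], size=n, p=[0.20, 0.18, 0.28, 0.27, 0.07]
    )

    # --- exposures --------------------------------------------------------
    p_bio = len(config.biomarker_spec)
    if p_bio:
        chol = np.linalg.cholesky(config.corr_matrix())
        z = bio_rng.standard_normal((n, p_bio)) @ chol.T
        mus = np.array([mu for _, mu, _ in config.biomarker_spec])
        sds = np.array([sd for _, _, sd in config.biomarker_spec])
        log_conc = mus + sds * z
    else:
        z = np.empty((n, 0))
        log_conc = np.empty((n, 0))

    genotypes = {
        name: snp_rng.binomial(2, maf, size=n) for name, maf in config.snp_spec
    }

    snp_name, metab_name, ratio = config.snp_metabolite_effect
    bio_names = config.biomarker_names()
    if snp_name in genotypes and metab_name in bio_names:
        j = bio_names.index(metab_name)
        log_conc[:, j] = log_conc[:, j] + np.log(ratio) * genotypes[snp_name]

    # --- outcome: subtype per set, case chosen by within-set logit --------
    subtype_idx = out_rng.choice(3, size=n_sets, p=np.asarray(config.subtype_probs))
    eta = np.zeros((n, 3))
    for name, betas in config.effect_spec.items():
        if name in genotypes:
            x = genotypes[name].astype(float)
        else:
            j = bio_names.index(name)
            # per-1-generating-SD contrast on the log scale
            x = (log_conc[:, j] - config.biomarker_spec[j][1]) / config.biomarker_spec[j][2]
        eta += np.outer(x, np.asarray(betas, dtype=float))
    eta_s = eta[np.arange(n), rep(subtype_idx, m)].reshape(n_sets, m)
    eta_s = eta_s - eta_s.max(axis=1, keepdims=True)
    probs = np.exp(eta_s)
    probs /= probs.sum(axis=1, keepdims=True)
    cum = probs.cumsum(axis=1)
    u = out_rng.random(n_sets)
    case_member = (u[:, None] > cum).sum(axis=1)
    is_case = member == rep(case_member, m)

    subtype_true = np.full(n, CONTROL, dtype=object)
    subtype_true[is_case] = np.array(SUBTYPES, dtype=object)[subtype_idx]

    # --- case-only clinical tumor variables -------------------------------
    followup = clin_rng.uniform(2.0, 15.0, n)
    age_dx = age + followup
    year_dx = clin_rng.choice(
        ["lt_2002", "2002_2006", "ge_2006"], size=n, p=[0.25, 0.35, 0.40]
    )
    stage = clin_rng.choice(["I_II", "III_IV"], size=n, p=[0.55, 0.45])
    # site multinomial logit; the designated SNP may shift the right-colon odds
    g_site = genotypes.get(snp_name, np.zeros(n)).astype(float)
    u_site = np.column_stack(
        [
            np.log(0.33) + config.site_snp_effect * g_site,
            np.full(n, np.log(0.33)),
            np.full(n, np.log(0.34)),
        ]
    )
    u_site = u_site - u_site.max(axis=1, keepdims=True)
    p_site = np.exp(u_site)
    p_site /= p_site.sum(axis=1, keepdims=True)
    site_draw = (clin_rng.random(n)[:, None] > p_site.cumsum(axis=1)).sum(axis=1)
    site = np.array(["right_colon", "left_colon", "rectum"], dtype=object)[site_draw]

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(n)],
            "set_id": set_id,
            "is_case": is_case,
            "subtype": subtype_true.copy(),
            "subtype_true": subtype_true,
            "sex": sex_m,
            "age_at_sampling": age,
            "cohort": cohort_m,
            "fasting": fasting_m,
            "smoking": smoking,
            "alcohol": alcohol,
            "recreational_pa": recreational_pa,
            "occupational_pa": occupational_pa,
            "bmi": bmi,
            "weight_kg": weight,
            "creatinine": creatinine,
            "neopterin": neopterin,
            "age_at_diagnosis": np.where(is_case, age_dx, np.nan),
            "year_of_diagnosis": np.where(is_case, year_dx, None),
            "tumor_stage": np.where(is_case, stage, None),
            "tumor_site": np.where(is_case, site, None),
        }
    )
    for j, name in enumerate(bio_names):
        df[name] = np.exp(log_conc[:, j])
    for name in config.snp_names():
        df[name] = genotypes[name].astype(float)

    # --- MCAR missingness on the exposure panel ---------------------------
    if config.missingness_rate > 0:
        for name in config.exposure_names():
            mask = miss_rng.random(n) < config.missingness_rate
            df.loc[mask, name] = np.nan

    cohort = Cohort(data=df, config=config, truth=dict(config.effect_spec))
    if config.availability_spec is not None:
        cohort = impose_tumor_unavailability(
            cohort, config.availability_spec, seed=child_seed(master, "availability")
        )
    return cohort


def impose_tumor_unavailability(
    cohort: Cohort, availability_spec: Mapping[str, float], seed: int
) -> Cohort:
    """Replace case subtypes by UNAVAILABLE with probability 1 - expit(lp).

    The linear predictor ``lp`` is evaluated on each case's covariates per
    ``availability_spec`` (name -> coefficient, plus "intercept").  The true
    subtype is retained in the ``subtype_true`` column for recovery testing.
    """
    df = cohort.data.copy()
    cases = df[df["is_case"]]
    probs = _availability_probs(cases, availability_spec)
    rng = np.random.default_rng(seed)
    unavailable = rng.random(len(cases)) > probs
    df.loc[cases.index[unavailable], "subtype"] = UNAVAILABLE
    return Cohort(data=df, config=cohort.config, truth=cohort.truth)


def simulate_case_only(
    n_cases: int,
    maf: float,
    slopes: tuple[float, float],
    base_probs: tuple[float, float, float] = (0.26, 0.24, 0.50),
    seed: int = 0,
) -> pd.DataFrame:
    """Case-only data from a baseline-category multinomial logit.

    Genotypes are Hardy-Weinberg with minor-allele frequency ``maf``;
    subtype odds vs wild-type change by exp(slope) per allele, with
    ``slopes`` ordered (KRAS, BRAF).  Used to test case-case ratio-of-odds
    -ratio recovery against a known truth.
    """
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, maf, size=n_cases)
    pk, pb, pw = base_probs
    logits = np.column_stack(
        [
            np.log(pk / pw) + slopes[0] * g,
            np.log(pb / pw) + slopes[1] * g,
            np.zeros(n_cases),
        ]
    )
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    draw = (rng.random(n_cases)[:, None] > p.cumsum(axis=1)).sum(axis=1)
    subtype = np.array(["KRAS", "BRAF", "WT"], dtype=object)[draw]
    return pd.DataFrame({"subtype": subtype, "genotype": g.astype(float)})
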