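"""Conditional-logistic contracts: closed-form null likelihood, separation,
grid-search and statsmodels oracles, subtype-specific recovery, the
heterogeneity LRT, Cochran's Q, and the SNP-metabolite association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mpepi import (
    ConditionalLogisticRegression,
    MatchedDesign,
    SimulationConfig,
    clogit_fit,
    cochran_q,
    heterogeneity_lrt,
    simulate_cohort,
    snp_metabolite_association,
    subtype_specific_fit,
)
from mpepi._utils import DomainError, EstimationError, SeparationError


def simple_sets(rng, n_sets=100, m=3, beta=0.0):
    """Matched sets with a single standard-normal exposure and known beta."""
    x = rng.standard_normal((n_sets, m))
    eta = beta * x
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    case = (rng.random(n_sets)[:, None] > p.cumsum(axis=1)).sum(axis=1)
    rows = {
        "set_id": np.repeat(np.arange(n_sets), m),
        "is_case": (np.tile(np.arange(m), n_sets) == np.repeat(case, m)),
        "x": x.ravel(),
        "subtype": "WT",
    }
    df = pd.DataFrame(rows)
    df.loc[~df["is_case"], "subtype"] = "NONE"
    return df


def grid_search_mle(df, grid=np.arange(-2.0, 2.0001, 1e-4)):
    """Brute-force maximizer of the 1-parameter conditional likelihood."""
    wide_x = df.pivot_table(index="set_id", columns=df.groupby("set_id").cumcount(), values="x")
    x = wide_x.to_numpy()
    case_x = df.loc[df["is_case"]].set_index("set_id")["x"].reindex(wide_x.index).to_numpy()
    eta = x[None, :, :] * grid[:, None, None]
    lse = stats.logsumexp = None
    from scipy.special import logsumexp

    ll = (case_x[None, :] * grid[:, None]).sum(axis=1) - logsumexp(eta, axis=2).sum(axis=1)
    return grid[np.argmax(ll)]


class TestConditionalLogit:
    def test_null_log_likelihood_closed_form(self, rng):
        df = simple_sets(rng, n_sets=100, m=3)
        est = ConditionalLogisticRegression(max_iter=0)
        with pytest.raises(EstimationError):
            est.fit(df[["x"]], df["is_case"], df["set_id"])
        fitted = clogit_fit(MatchedDesign(data=df, exposure="x"))
        assert fitted.llnull_ == pytest.approx(100 * np.log(1 / 3), abs=1e-10)
        assert fitted.llnull_ == pytest.approx(-109.861, abs=5e-4)

    def test_single_set_binary_separation(self):
        df = pd.DataFrame(
            {
                "set_id": [0, 0],
                "is_case": [True, False],
                "x": [1.0, 0.0],
                "subtype": ["WT", "NONE"],
            }
        )
        with pytest.raises(SeparationError):
            clogit_fit(MatchedDesign(data=df, exposure="x"))

    def test_mle_matches_grid_search_oracle(self, rng):
        df = simple_sets(rng, n_sets=200, m=3, beta=0.5)
        fit = clogit_fit(MatchedDesign(data=df, exposure="x"))
        brute = grid_search_mle(df)
        assert fit.coef_[0] == pytest.approx(brute, abs=1e-4)
        assert abs(fit.coef_[0] - 0.5) < 3 * fit.bse_[0]

    def test_matches_statsmodels_conditional_logit(self, rng):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        df = simple_sets(rng, n_sets=150, m=3, beta=0.3)
        df["z"] = rng.standard_normal(len(df))
        fit = clogit_fit(MatchedDesign(data=df, exposure="x", covariates=("z",)))
        ref = ConditionalLogit(
            df["is_case"].astype(int), df[["x", "z"]], groups=df["set_id"]
        ).fit(disp=0)
        assert np.allclose(fit.coef_, ref.params, atol=1e-4)
        assert np.allclose(fit.bse_, ref.bse, atol=1e-4)

    def test_invariant_to_member_order_and_set_labels(self, rng):
        df = simple_sets(rng, n_sets=80, m=3, beta=0.4)
        fit1 = clogit_fit(MatchedDesign(data=df, exposure="x"))
        shuffled = df.sample(frac=1.0, random_state=1)
        shuffled["set_id"] = shuffled["set_id"].map(lambda s: f"set-{s}")
        fit2 = clogit_fit(MatchedDesign(data=shuffled, exposure="x"))
        assert fit1.coef_[0] == pytest.approx(fit2.coef_[0], abs=1e-10)
        assert fit1.llf_ == pytest.approx(fit2.llf_, abs=1e-10)

    def test_requires_exactly_one_case_per_set(self, rng):
        df = simple_sets(rng, n_sets=10, m=3)
        df.loc[df.index[1], "is_case"] = True  # second case in set 0
        with pytest.raises(ValueError):
            ConditionalLogisticRegression().fit(
                df[["x"]], df["is_case"], df["set_id"]
            )
        # the design-level entry point instead drops the malformed set
        fit = clogit_fit(MatchedDesign(data=df, exposure="x"))
        assert fit.llnull_ == pytest.approx(9 * np.log(1 / 3))


class TestSubtypeSpecificFit:
    def test_recovers_generating_log_odds_ratios(self):
        truth = {"rs1021737": (np.log(0.72), np.log(1.56), 0.0)}
        cfg = SimulationConfig(
            n_cases=1500, effect_spec=truth, missingness_rate=0.0, seed=404
        )
        cohort = simulate_cohort(cfg)
        res = subtype_specific_fit(MatchedDesign(data=cohort.data, exposure="rs1021737"))
        for s, target in zip(("KRAS", "BRAF", "WT"), truth["rs1021737"]):
            est = res.per_subtype[s]
            assert abs(est.log_or - target) < 3 * est.se

    def test_subtype_case_counts_partition_cases(self, effect_cohort):
        res = subtype_specific_fit(
            MatchedDesign(data=effect_cohort.data, exposure="rs1021737")
        )
        total_cases = sum(e.n_cases for e in res.per_subtype.values())
        assert total_cases == int(effect_cohort.data["is_case"].sum())

    def test_ci_is_exp_of_wald_interval(self, effect_cohort):
        res = subtype_specific_fit(
            MatchedDesign(data=effect_cohort.data, exposure="rs1021737"),
            heterogeneity=False,
        )
        for est in res.per_subtype.values():
            lo = np.exp(est.log_or - 1.959963984540054 * est.se)
            hi = np.exp(est.log_or + 1.959963984540054 * est.se)
            assert est.ci95 == pytest.approx((lo, hi), rel=1e-12)

    def test_null_cis_cover_one(self, null_cohort):
        res = subtype_specific_fit(
            MatchedDesign(data=null_cohort.data, exposure="rs1801133"),
            heterogeneity=False,
        )
        # single draw: all three intervals should cover the null OR of 1
        for est in res.per_subtype.values():
            assert est.ci95[0] < 1.0 < est.ci95[1]


class TestHeterogeneityLrt:
    def test_statistic_nonnegative_and_df(self, effect_cohort):
        res = subtype_specific_fit(
            MatchedDesign(data=effect_cohort.data, exposure="rs1021737")
        )
        stat, df, p = res.lrt_het
        assert stat >= 0 and df == 2 and 0 <= p <= 1

    def test_detects_opposite_effects(self):
        truth = {"rs1801133": (np.log(1.5), -np.log(1.5), 0.0)}
        rejections = 0
        for seed in range(5):
            cfg = SimulationConfig(
                n_cases=1200, effect_spec=truth, missingness_rate=0.0, seed=500 + seed
            )
            cohort = simulate_cohort(cfg)
            stat, df, p = heterogeneity_lrt(
                MatchedDesign(data=cohort.data, exposure="rs1801133")
            )
            rejections += p < 0.05
        assert rejections >= 4

    def test_single_subtype_rejected(self, rng):
        df = simple_sets(rng, n_sets=60, m=3, beta=0.2)
        with pytest.raises(EstimationError):
            heterogeneity_lrt(MatchedDesign(data=df, exposure="x"))

    def test_full_model_equals_sum_of_per_subtype_fits(self, effect_cohort):
        # with subtype-specific nuisance terms, the joint full model factorizes
        res = subtype_specific_fit(
            MatchedDesign(data=effect_cohort.data, exposure="rs1021737"),
            shared_nuisance=False,
        )
        stat_a = res.lrt_het[0]
        stat_b = heterogeneity_lrt(
            MatchedDesign(data=effect_cohort.data, exposure="rs1021737")
        )[0]
        assert stat_a == pytest.approx(stat_b, abs=1e-6)


class TestCochranQ:
    def test_identical_estimates_give_zero(self):
        q, df, p = cochran_q([(0.4, 0.1), (0.4, 0.1)])
        assert q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        q, df, p = cochran_q([(0.0, 1.0), (2.0, 1.0)])
        assert q == pytest.approx(2.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(0.1573, abs=5e-5)

    def test_null_p_values_uniform(self, rng):
        pvals = []
        for _ in range(400):
            betas = rng.normal(0.3, 0.2, size=4)
            ests = [(b + rng.normal(0, 0.2), 0.2) for b in [betas.mean()] * 4]
            pvals.append(cochran_q(ests)[2])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_nonpositive_se_rejected(self):
        with pytest.raises(DomainError):
            cochran_q([(0.1, 0.0), (0.2, 0.1)])


class TestSnpMetabolite:
    def test_recovers_seven_percent_effect(self):
        cfg = SimulationConfig(n_cases=4000, effect_spec={}, missingness_rate=0.0, seed=606)
        df = simulate_cohort(cfg).data
        pct, se, p = snp_metabolite_association(df["rs1021737"], df["cystathionine"])
        assert abs(np.log1p(pct / 100) - np.log(1.07)) < 3 * se
        assert p < 0.05

    def test_scale_invariance(self, rng):
        g = rng.integers(0, 3, 500).astype(float)
        conc = np.exp(rng.standard_normal(500) + 0.05 * g)
        pct1, _, _ = snp_metabolite_association(g, conc)
        pct2, _, _ = snp_metabolite_association(g, conc * 37.5)
        assert pct1 == pytest.approx(pct2, rel=1e-10)

    def test_constant_genotype_rejected(self, rng):
        with pytest.raises(EstimationError):
            snp_metabolite_association(np.ones(50), np.exp(rng.standard_normal(50)))
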