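"""Network-learning contracts: closed-form local scores, decomposability,
hill-climb optimality against exhaustive DAG enumeration, bootstrap edge
confidences, and the L1 mixture threshold."""

from itertools import product

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mpepi import (
    HillClimbBayesNet,
    bootstrap_average,
    estimate_threshold,
    hill_climb,
    local_aic_score,
    outcome_edge_ranking,
)


def enumerate_best_score(df: pd.DataFrame) -> float:
    """Exhaustive oracle: maximum AIC score over all DAGs on three nodes."""
    names = list(df.columns)
    assert len(names) == 3
    pairs = [(0, 1), (0, 2), (1, 2)]
    best = -np.inf
    n_dags = 0
    for arrows in product((0, 1, 2), repeat=3):  # absent / forward / backward
        g = nx.DiGraph()
        g.add_nodes_from(names)
        for (i, j), a in zip(pairs, arrows):
            if a == 1:
                g.add_edge(names[i], names[j])
            elif a == 2:
                g.add_edge(names[j], names[i])
        if not nx.is_directed_acyclic_graph(g):
            continue
        n_dags += 1
        best = max(
            best,
            sum(local_aic_score(df, v, list(g.predecessors(v))) for v in names),
        )
    assert n_dags == 25
    return best


class TestLocalScore:
    def test_binary_no_parents_closed_form(self):
        df = pd.DataFrame({"x": ["a"] * 7 + ["b"] * 3})
        expected = 7 * np.log(0.7) + 3 * np.log(0.3) - 1
        assert local_aic_score(df, "x") == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(-7.1086, abs=5e-4)

    def test_deterministic_copy_child_gain(self):
        rng = np.random.default_rng(4)
        parent = rng.integers(0, 2, 100)
        df = pd.DataFrame({"p": parent.astype(str), "c": parent.astype(str)})
        n1 = int(parent.sum())
        n0 = 100 - n1
        # with the parent: perfect prediction, log-lik 0, penalty (2-1)*2
        # without: multinomial MLE log-lik, penalty (2-1)*1
        ll0 = n0 * np.log(n0 / 100) + n1 * np.log(n1 / 100)
        gain = (0.0 - 2.0) - (ll0 - 1.0)
        with_p = local_aic_score(df, "c", ["p"])
        without = local_aic_score(df, "c")
        assert with_p - without == pytest.approx(gain, abs=1e-9)

    def test_child_in_parents_rejected(self):
        df = pd.DataFrame({"x": ["a", "b"]})
        with pytest.raises(ValueError):
            local_aic_score(df, "x", ["x"])

    def test_full_vs_observed_penalty(self):
        # a parent level never realized jointly: observed q < full q
        df = pd.DataFrame(
            {"p": ["a"] * 5 + ["b"] * 5 + ["c"] * 5, "c": ["x", "y"] * 7 + ["x"]}
        )
        sub = df[df["p"] != "c"].reset_index(drop=True)
        sub["p"] = pd.Categorical(sub["p"], categories=["a", "b", "c"])
        obs = local_aic_score(sub, "c", ["p"], penalty_configs="observed")
        full = local_aic_score(sub, "c", ["p"], penalty_configs="full")
        assert full == pytest.approx(obs - 1.0)


class TestHillClimb:
    def test_single_variable_empty_graph(self):
        df = pd.DataFrame({"x": ["a", "b", "a", "b"]})
        net = hill_climb(df)
        assert net.dag.number_of_edges() == 0
        assert net.score == pytest.approx(local_aic_score(df, "x"))

    def test_score_decomposability(self, null_cohort):
        from mpepi import build_discrete_dataset

        data = build_discrete_dataset(null_cohort).data[
            ["rs1021737", "folate", "sex", "outcome"]
        ]
        net = hill_climb(data)
        assert net.score == pytest.approx(sum(net.per_node_scores.values()), abs=1e-9)
        assert nx.is_directed_acyclic_graph(net.dag)

    def test_independent_variables_empty_at_chi2_rate(self, rng):
        # an arc is added iff the LR gain exceeds the 1-parameter penalty,
        # i.e. with asymptotic probability P(chi2_1 > 2) ~ 0.157 under
        # independence; check the empirical rate against that closed form
        reps = 200
        empty = 0
        for _ in range(reps):
            df = pd.DataFrame(
                {
                    "a": rng.integers(0, 2, 500).astype(str),
                    "b": rng.integers(0, 2, 500).astype(str),
                }
            )
            empty += hill_climb(df).dag.number_of_edges() == 0
        from scipy import stats

        p_empty = stats.chi2.sf(2.0, 1)  # P(add) per pair
        expected = reps * (1 - p_empty)
        sd = np.sqrt(reps * p_empty * (1 - p_empty))
        assert abs(empty - expected) < 3 * sd

    def test_chain_matches_enumeration_oracle(self, rng):
        n = 2000
        a = rng.integers(0, 2, n)
        b = (a + (rng.random(n) < 0.1)) % 2
        c = (b + (rng.random(n) < 0.1)) % 2
        df = pd.DataFrame({"A": a, "B": b, "C": c}).astype(str)
        assert hill_climb(df).score == pytest.approx(enumerate_best_score(df), abs=1e-9)

    def test_estimator_api(self):
        df = pd.DataFrame({"x": ["a", "b"] * 10, "y": ["a", "b"] * 10})
        est = HillClimbBayesNet().fit(df)
        assert hasattr(est, "dag_") and hasattr(est, "score_")
        assert est.get_params()["penalty_configs"] == "observed"


class TestBootstrapAverage:
    def test_deterministic_dependence_confidence_one(self, rng):
        x = rng.integers(0, 2, 400)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.integers(0, 2, 400)}).astype(str)
        avg = bootstrap_average(df, n_bootstrap=25, seed=5)
        assert avg.edge_confidence[("a", "b")] == 1.0
        assert avg.edge_confidence.get(("a", "c"), 0.0) <= 0.2

    def test_single_replicate_confidences_zero_or_one(self, rng):
        df = pd.DataFrame(
            {"a": rng.integers(0, 2, 200), "b": rng.integers(0, 3, 200)}
        ).astype(str)
        avg = bootstrap_average(df, n_bootstrap=1, seed=6)
        assert all(c in (0.0, 1.0) for c in avg.edge_confidence.values())

    def test_confidences_are_exact_counts(self, rng):
        x = rng.integers(0, 2, 300)
        y = (x + (rng.random(300) < 0.4)) % 2
        df = pd.DataFrame({"a": x, "b": y}).astype(str)
        nb = 40
        avg = bootstrap_average(df, n_bootstrap=nb, seed=7)
        for c in avg.edge_confidence.values():
            assert (c * nb) == pytest.approx(round(c * nb), abs=1e-12)

    def test_bit_reproducible_under_seed(self, rng):
        df = pd.DataFrame(
            {
                "a": rng.integers(0, 2, 200),
                "b": rng.integers(0, 2, 200),
                "c": rng.integers(0, 2, 200),
            }
        ).astype(str)
        a = bootstrap_average(df, n_bootstrap=30, seed=11)
        b = bootstrap_average(df, n_bootstrap=30, seed=11)
        assert a.edge_confidence == b.edge_confidence
        assert a.threshold == b.threshold

    def test_invalid_bootstrap_count(self):
        df = pd.DataFrame({"a": ["x", "y"]})
        with pytest.raises(Exception):
            bootstrap_average(df, n_bootstrap=0, seed=1)


class TestThreshold:
    def test_perfectly_separated_mixture(self):
        conf = [0.0] * 7 + [1.0] * 3
        thr = estimate_threshold(conf)
        assert all(c > thr for c in conf if c == 1.0)
        assert all(c <= thr for c in conf if c == 0.0)

    def test_single_atom_all_or_none(self):
        thr = estimate_threshold([0.5] * 8)
        assert thr <= 0.5

    def test_beta_mixture_recovers_high_mode(self, rng):
        agree = 0
        for _ in range(100):
            low = rng.beta(1, 20, 25)
            high = rng.beta(20, 1, 25)
            conf = np.concatenate([low, high])
            thr = estimate_threshold(conf)
            included = conf > thr
            agree += included[25:].all() and not included[:25].any()
        assert agree >= 90

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_threshold([])


class TestOutcomeRanking:
    def test_causally_linked_exposure_ranks_first(self, rng):
        hits = 0
        for rep in range(20):
            n = 600
            g = rng.integers(0, 2, n)
            outcome = (g + (rng.random(n) < 0.15)) % 2
            noise1 = rng.integers(0, 2, n)
            noise2 = rng.integers(0, 3, n)
            df = pd.DataFrame(
                {"snp": g, "noise1": noise1, "noise2": noise2, "outcome": outcome}
            ).astype(str)
            avg = bootstrap_average(df, n_bootstrap=20, seed=rep)
            ranking = outcome_edge_ranking(avg, "outcome")
            hits += ranking[0][0] == "snp"
        assert hits >= 18

    def test_null_outcome_few_exposures_included_at_study_scale(self):
        # with no exposure-outcome effects, the overwhelming majority of
        # exposures must stay below the estimated inclusion threshold in a
        # study-sized cohort (the threshold lands near 0.5, anchored by the
        # genuine biomarker-biomarker structure)
        from mpepi import SimulationConfig, build_discrete_dataset, simulate_cohort

        for seed in (1, 2):
            cfg = SimulationConfig(
                n_cases=450, effect_spec={}, missingness_rate=0.0, seed=seed
            )
            cohort = simulate_cohort(cfg)
            data = build_discrete_dataset(cohort).data.drop(
                columns=["subject_id", "set_id"]
            )
            avg = bootstrap_average(data, n_bootstrap=40, seed=seed)
            ranking = outcome_edge_ranking(avg, "outcome")
            exposures = set(cfg.exposure_names())
            included = [v for v, c in ranking if v in exposures and c > avg.threshold]
            assert len(included) <= 3  # <= ~10% of the 31 exposures

    def test_alphabetical_tie_break_and_length(self):
        from mpepi.bayesnet import AveragedNetwork

        avg = AveragedNetwork(
            nodes=("b", "a", "outcome"),
            edge_confidence={("a", "outcome"): 0.4, ("b", "outcome"): 0.4},
            direction_confidence={},
            threshold=0.5,
            n_bootstrap=10,
        )
        ranking = outcome_edge_ranking(avg, "outcome")
        assert ranking == [("a", 0.4), ("b", 0.4)]
        with pytest.raises(ValueError):
            outcome_edge_ranking(avg, "nope")
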