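"""Discrete Bayesian-network screening: hill-climbing on an AIC score with
bootstrap model averaging.

The score of a DAG decomposes over nodes; each node contributes its
multinomial log-likelihood given its parent configuration minus the number
of free parameters (r - 1) * q, where r is the number of child levels and
q the number of parent configurations (observed configurations by default).
The greedy search starts from the empty graph and applies single-arc
additions, deletions and reversals while the total score strictly improves,
with a deterministic lexicographic tie-break so runs are reproducible.

Edge support is quantified by nonparametric bootstrap: the fraction of
resampled datasets whose learned network contains an arc between two
variables in either direction ("edge confidence").  The inclusion threshold
is estimated by fitting a two-point {0, 1} mixture to the empirical
confidence distribution in L1 distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import ConfigurationError

_MOVE_RANK = {"add": 0, "delete": 1, "reverse": 2}
_EPS = 1e-10


def _encode(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Integer-code a categorical table; returns (codes, cardinalities, names).

    Columns with a declared CategoricalDtype keep their full level set (so
    unobserved levels still count toward the 'full' parameter penalty);
    other columns use their observed values.
    """
    names = list(data.columns)
    cols = []
    cards = []
    for c in names:
        col = data[c]
        if isinstance(col.dtype, pd.CategoricalDtype):
            codes = col.cat.codes.to_numpy()
            card = len(col.cat.categories)
        else:
            codes, uniques = pd.factorize(col, sort=True)
            card = len(uniques)
        if (codes < 0).any():
            raise ValueError(f"missing values in variable {c!r}; complete-case required")
        cols.append(codes.astype(np.int64))
        cards.append(card)
    return np.column_stack(cols), np.asarray(cards, dtype=np.int64), names


def _local_score(
    X: np.ndarray,
    cards: np.ndarray,
    child: int,
    parents: tuple[int, ...],
    penalty_configs: str,
) -> float:
    r = int(cards[child])
    y = X[:, child]
    if parents:
        q_full = 1
        idx = np.zeros(X.shape[0], dtype=np.int64)
        for p in parents:
            idx = idx * int(cards[p]) + X[:, p]
            q_full *= int(cards[p])
        if q_full <= 262_144:  # direct contingency table
            counts = np.bincount(idx * r + y, minlength=q_full * r).reshape(q_full, r)
            nj = counts.sum(axis=1)
            occupied = nj > 0
            counts, nj = counts[occupied], nj[occupied]
            q_obs = int(occupied.sum())
        else:  # sparse parent-configuration space
            uniq, inv = np.unique(idx, return_inverse=True)
            q_obs = uniq.size
            counts = np.bincount(inv * r + y, minlength=q_obs * r).reshape(q_obs, r)
            nj = counts.sum(axis=1)
    else:
        counts = np.bincount(y, minlength=r)[None, :]
        nj = counts.sum(axis=1)
        q_obs = q_full = 1
    pos = counts > 0
    ll = float(
        np.sum(counts[pos] * np.log(counts[pos] / np.broadcast_to(nj[:, None], counts.shape)[pos]))
    )
    q = q_full if penalty_configs == "full" else q_obs
    return ll - (r - 1) * q


def local_aic_score(
    data: pd.DataFrame,
    child: str,
    parents: Iterable[str] = (),
    penalty_configs: str = "observed",
) -> float:
    """AIC-type local score of ``child`` given ``parents`` (higher is better)."""
    parents = list(parents)
    if child in parents:
        raise ValueError("parents must exclude the child")
    X, cards, names = _encode(data)
    idx = {n: i for i, n in enumerate(names)}
    return _local_score(
        X, cards, idx[child], tuple(sorted(idx[p] for p in parents)), penalty_configs
    )


@dataclass
class ScoredNetwork:
    """A DAG with its decomposed AIC score."""

    dag: nx.DiGraph
    score: float
    per_node_scores: dict[str, float]


class HillClimbBayesNet(BaseEstimator):
    """Greedy DAG search maximizing the decomposable AIC score.

    Parameters
    ----------
    penalty_configs : {'observed', 'full'}
        Whether the parameter count uses parent configurations observed in
        the data (default) or the full Cartesian product.
    max_iter : int
        Safety cap on accepted moves.

    Attributes
    ----------
    dag_ : networkx.DiGraph
        The learned acyclic graph.
    score_ : float
        Total network score (sum of local scores).
    per_node_scores_ : dict
        Local score per node.
    """

    def __init__(self, penalty_configs: str = "observed", max_iter: int = 10_000):
        self.penalty_configs = penalty_configs
        self.max_iter = max_iter

    def fit(self, X: pd.DataFrame, y=None):
        codes, cards, names = _encode(X)
        parents, node_scores, n_moves = _hill_climb_codes(
            codes, cards, self.penalty_configs, self.max_iter
        )
        p = len(names)

        dag = nx.DiGraph()
        dag.add_nodes_from(names)
        for v in range(p):
            for u in parents[v]:
                dag.add_edge(names[u], names[v])
        assert nx.is_directed_acyclic_graph(dag)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.dag_ = dag
        self.per_node_scores_ = {names[i]: float(node_scores[i]) for i in range(p)}
        self.score_ = float(sum(node_scores))
        self.n_moves_ = n_moves
        return self


def _better(cand, best) -> bool:
    # larger delta wins; exact ties resolved by the lexicographic move key
    if cand[0] != best[0]:
        return cand[0] > best[0]
    return cand[1] < best[1]


def _hill_climb_codes(
    codes: np.ndarray, cards: np.ndarray, penalty_configs: str, max_iter: int
) -> tuple[list[set[int]], list[float], int]:
    """Greedy search on integer-coded data; returns (parent sets, scores, moves).

    Add/delete deltas are cached per directed pair and refreshed only for
    the node(s) whose parent set a move changed, so each iteration costs
    O(p) local-score evaluations after the initial O(p^2) sweep.
    """
    p = codes.shape[1]
    parents: list[set[int]] = [set() for _ in range(p)]
    children: list[set[int]] = [set() for _ in range(p)]
    cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def score(child: int, par: set[int]) -> float:
        key = (child, tuple(sorted(par)))
        if key not in cache:
            cache[key] = _local_score(codes, cards, child, key[1], penalty_configs)
        return cache[key]

    def creates_cycle(u: int, v: int) -> bool:
        # would adding u -> v create a path v -> ... -> u?
        stack = [v]
        seen = set()
        while stack:
            node = stack.pop()
            if node == u:
                return True
            if node in seen:
                continue
            seen.add(node)
            stack.extend(children[node])
        return False

    node_scores = [score(i, parents[i]) for i in range(p)]
    # delta of adding u->v (u not a parent of v) / deleting u->v (u a parent)
    add_delta: dict[tuple[int, int], float] = {}
    del_delta: dict[tuple[int, int], float] = {}

    def refresh(v: int) -> None:
        pv = parents[v]
        base = node_scores[v]
        for u in range(p):
            if u == v:
                continue
            if u in pv:
                del_delta[(u, v)] = score(v, pv - {u}) - base
                add_delta.pop((u, v), None)
            else:
                add_delta[(u, v)] = score(v, pv | {u}) - base
                del_delta.pop((u, v), None)

    for v in range(p):
        refresh(v)

    n_moves = 0
    while n_moves < max_iter:
        best = None  # (delta, tie_key, move)
        for (u, v), delta in add_delta.items():
            if delta <= _EPS or v in parents[u]:
                continue
            cand = (delta, (v, u, _MOVE_RANK["add"]), ("add", u, v))
            if (best is None or _better(cand, best)) and not creates_cycle(u, v):
                best = cand
        for (u, v), delta in del_delta.items():
            if delta > _EPS:
                cand = (delta, (v, u, _MOVE_RANK["delete"]), ("delete", u, v))
                if best is None or _better(cand, best):
                    best = cand
            rdelta = delta + add_delta[(v, u)]
            if rdelta > _EPS:
                cand = (rdelta, (v, u, _MOVE_RANK["reverse"]), ("reverse", u, v))
                if best is None or _better(cand, best):
                    # legality: with u->v removed, v->u must not close a cycle
                    children[u].discard(v)
                    ok = not creates_cycle(v, u)
                    children[u].add(v)
                    if ok:
                        best = cand
        if best is None:
            break
        _, _, (kind, u, v) = best
        if kind == "add":
            parents[v].add(u)
            children[u].add(v)
        elif kind == "delete":
            parents[v].discard(u)
            children[u].discard(v)
        else:
            parents[v].discard(u)
            children[u].discard(v)
            parents[u].add(v)
            children[v].add(u)
            node_scores[u] = score(u, parents[u])
            refresh(u)
        node_scores[v] = score(v, parents[v])
        refresh(v)
        n_moves += 1
    return parents, node_scores, n_moves


def hill_climb(data: pd.DataFrame, seed: int | None = None) -> ScoredNetwork:
    """Learn a DAG by greedy search from the empty graph.

    The search is deterministic (lexicographic tie-break); ``seed`` is
    accepted for interface symmetry with the bootstrap stage and unused.
    """
    est = HillClimbBayesNet().fit(data)
    return ScoredNetwork(dag=est.dag_, score=est.score_, per_node_scores=est.per_node_scores_)


def estimate_threshold(confidences: Sequence[float]) -> float:
    """Significance threshold for edge confidences via an L1 mixture fit.

    The ideal confidence distribution puts mass t at 0 (noise edges) and
    1 - t at 1 (true edges).  The mixing weight t is chosen to minimize the
    L1 distance between the ideal step CDF and the empirical CDF of the
    observed confidences; the returned threshold is the empirical t-quantile
    of the confidences.  On exact ties the smallest minimizer is used, which
    yields all-or-none inclusion for a degenerate single-atom input.
    """
    conf = np.sort(np.asarray(list(confidences), dtype=float))
    if conf.size == 0:
        raise ValueError("need at least one confidence value")
    k = conf.size
    # segment representation of the empirical CDF on [0, 1]
    grid = np.concatenate(([0.0], conf, [1.0]))
    heights = np.concatenate((np.arange(k + 1) / k, [1.0]))
    lengths = np.diff(grid)
    pos = lengths > 0
    levels = heights[:-1][pos]
    weights = lengths[pos]
    # L1(t) = sum w |level - t| is minimized at a weighted median of levels
    order = np.argsort(levels, kind="stable")
    levels, weights = levels[order], weights[order]
    cum = np.cumsum(weights)
    t_hat = float(levels[np.searchsorted(cum, cum[-1] / 2.0)])
    if t_hat >= 1.0:
        return float(conf[-1])
    return float(np.quantile(conf, t_hat, method="inverted_cdf"))


@dataclass
class AveragedNetwork:
    """Bootstrap-averaged network: edge confidences and the inclusion rule."""

    nodes: tuple[str, ...]
    edge_confidence: dict[tuple[str, str], float]  # unordered pairs, key sorted
    direction_confidence: dict[tuple[str, str], float]  # ordered (parent, child)
    threshold: float
    n_bootstrap: int

    @property
    def included_edges(self) -> set[tuple[str, str]]:
        return {e for e, c in self.edge_confidence.items() if c > self.threshold}

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), c in self.edge_confidence.items():
            if c > self.threshold:
                g.add_edge(a, b, confidence=c)
        return g

    def to_edge_list(self) -> pd.DataFrame:
        rows = []
        for (a, b), c in sorted(self.edge_confidence.items()):
            rows.append(
                {
                    "var1": a,
                    "var2": b,
                    "confidence": c,
                    "direction_confidence_var1_to_var2": self.direction_confidence.get((a, b), 0.0),
                    "direction_confidence_var2_to_var1": self.direction_confidence.get((b, a), 0.0),
                    "included": c > self.threshold,
                }
            )
        return pd.DataFrame(rows, columns=[
            "var1", "var2", "confidence",
            "direction_confidence_var1_to_var2",
            "direction_confidence_var2_to_var1", "included",
        ])

    def to_dot(self) -> str:
        lines = ["graph averaged_network {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for (a, b), c in sorted(self.edge_confidence.items()):
            if c > self.threshold:
                lines.append(f'  "{a}" -- "{b}" [label="{c:.3f}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"


class BootstrapAveragedNetwork(BaseEstimator):
    """Bootstrap model averaging of hill-climbed networks.

    Parameters
    ----------
    n_bootstrap : int
        Number of nonparametric resamples (the study design used 1000).
    resample : {'rows', 'sets'}
        Resample individual rows (default; the network stage treats the data
        as a flat table) or whole matched sets via a set-id column.
    set_col : str
        Column naming the matched set when ``resample='sets'``.
    random_state : int
        Seed; the full run is bit-reproducible given this value.

    Attributes
    ----------
    edge_confidence_, direction_confidence_, threshold_, included_edges_,
    averaged_ : the fitted :class:`AveragedNetwork`.
    """

    def __init__(
        self,
        n_bootstrap: int = 1000,
        resample: str = "rows",
        set_col: str = "set_id",
        random_state: int = 0,
        penalty_configs: str = "observed",
    ):
        self.n_bootstrap = n_bootstrap
        self.resample = resample
        self.set_col = set_col
        self.random_state = random_state
        self.penalty_configs = penalty_configs

    def fit(self, X: pd.DataFrame, y=None):
        if self.n_bootstrap < 1:
            raise ConfigurationError("n_bootstrap must be >= 1")
        if self.resample == "sets":
            sets = X[self.set_col]
            groups = {s: idx.to_numpy() for s, idx in X.groupby(sets, sort=True).groups.items()}
            set_ids = list(groups)
            data = X.drop(columns=[self.set_col])
        elif self.resample == "rows":
            data = X.drop(columns=[self.set_col], errors="ignore")
        else:
            raise ConfigurationError(f"unknown resample unit {self.resample!r}")

        rng = np.random.default_rng(self.random_state)
        codes, cards, names = _encode(data.reset_index(drop=True))
        if self.resample == "sets":
            positions = {s: np.flatnonzero(sets.to_numpy() == s) for s in set_ids}
        n = codes.shape[0]
        edge_counts: dict[tuple[str, str], int] = {}
        dir_counts: dict[tuple[str, str], int] = {}
        for _ in range(self.n_bootstrap):
            if self.resample == "rows":
                take = rng.integers(0, n, n)
            else:
                chosen = rng.integers(0, len(set_ids), len(set_ids))
                take = np.concatenate([positions[set_ids[c]] for c in chosen])
            parents, _, _ = _hill_climb_codes(
                codes[take], cards, self.penalty_configs, 10_000
            )
            for v, pv in enumerate(parents):
                for u in pv:
                    a, b = names[u], names[v]
                    key = (a, b) if a <= b else (b, a)
                    edge_counts[key] = edge_counts.get(key, 0) + 1
                    dir_counts[(a, b)] = dir_counts.get((a, b), 0) + 1

        nb = self.n_bootstrap
        self.edge_confidence_ = {k: c / nb for k, c in sorted(edge_counts.items())}
        self.direction_confidence_ = {k: c / nb for k, c in sorted(dir_counts.items())}
        confs = list(self.edge_confidence_.values())
        self.threshold_ = estimate_threshold(confs) if confs else 0.0
        self.averaged_ = AveragedNetwork(
            nodes=tuple(names),
            edge_confidence=self.edge_confidence_,
            direction_confidence=self.direction_confidence_,
            threshold=self.threshold_,
            n_bootstrap=nb,
        )
        self.included_edges_ = self.averaged_.included_edges
        return self


def bootstrap_average(
    data: pd.DataFrame,
    n_bootstrap: int = 1000,
    seed: int = 0,
    resample: str = "rows",
) -> AveragedNetwork:
    """Bootstrap-averaged network of ``data`` (complete-case categorical table)."""
    est = BootstrapAveragedNetwork(
        n_bootstrap=n_bootstrap, random_state=seed, resample=resample
    ).fit(data)
    return est.averaged_


def outcome_edge_ranking(
    avg: AveragedNetwork, outcome: str
) -> list[tuple[str, float]]:
    """Exposures ranked by edge confidence with the outcome node.

    Descending confidence; ties broken alphabetically.
    """
    if outcome not in avg.nodes:
        raise ValueError(f"unknown outcome node {outcome!r}")
    conf = {}
    for node in avg.nodes:
        if node == outcome:
            continue
        key = (node, outcome) if node <= outcome else (outcome, node)
        conf[node] = avg.edge_confidence.get(key, 0.0)
    return sorted(conf.items(), key=lambda kv: (-kv[1], kv[0]))
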