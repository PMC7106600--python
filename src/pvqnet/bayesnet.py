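"""Discrete Bayesian-network engine.

A network is a DAG over named discrete variables plus one conditional
probability table (CPT) per node; the joint distribution factorizes as the
product of each variable given its parents.  This module provides:

* score-based structure search (greedy hill-climbing and tabu search) under
  expert arc constraints -- a whitelist of arcs that must be present (the
  clinician's initial graph) and a blacklist of arcs that must never appear;
* decomposable network scores (BIC and BDeu);
* Bayesian CPT estimation (Dirichlet posterior means);
* exact inference by variable elimination;
* CPDAG (Markov-equivalence class) utilities used to compare learned and
  ground-truth structures.

Constraint-based structure algorithms (Grow-Shrink, the IAMB family, MMPC)
are registered by name for configuration compatibility but intentionally
unsupported; the score-based searches are the ones exercised here.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln


class ConstraintError(ValueError):
    """Whitelist/blacklist sets are inconsistent."""


class StateDomainError(ValueError):
    """Data contains a value outside a variable's declared state set."""


class InconsistentEvidenceError(ValueError):
    """Evidence has probability zero under the network."""


class UnsupportedAlgorithmError(ValueError):
    """A registered but unimplemented structure-search algorithm was requested."""


# ---------------------------------------------------------------------------
# Graph
# ---------------------------------------------------------------------------

@dataclass
class DAG:
    """Directed acyclic graph over named discrete variables."""

    nodes: dict[str, tuple]               # name -> ordered state set
    arcs: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.nodes = {k: tuple(v) for k, v in self.nodes.items()}
        self.arcs = set(map(tuple, self.arcs))
        for u, v in self.arcs:
            if u == v:
                raise ValueError(f"self-arc {u}->{v}")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"arc {u}->{v} references unknown node")

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(u for u, v in self.arcs if v == node))

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(v for u, v in self.arcs if u == node))

    def copy(self) -> "DAG":
        return DAG(dict(self.nodes), set(self.arcs))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        return g


def check_acyclic(dag: DAG) -> bool:
    """True iff a topological ordering exists."""
    return nx.is_directed_acyclic_graph(dag.to_networkx())


def topological_order(dag: DAG) -> list[str]:
    return list(nx.lexicographical_topological_sort(dag.to_networkx()))


@dataclass
class ArcConstraints:
    """Expert structure knowledge: mandatory and forbidden arcs."""

    whitelist: set[tuple[str, str]] = field(default_factory=set)
    blacklist: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.whitelist = set(map(tuple, self.whitelist))
        self.blacklist = set(map(tuple, self.blacklist))

    def validate(self, nodes: Iterable[str]) -> None:
        nodes = set(nodes)
        overlap = self.whitelist & self.blacklist
        if overlap:
            raise ConstraintError(f"arcs both white- and blacklisted: {sorted(overlap)}")
        for u, v in self.whitelist | self.blacklist:
            if u == v:
                raise ConstraintError(f"self-arc constraint {u}->{v}")
            if u not in nodes or v not in nodes:
                raise ConstraintError(f"constraint arc {u}->{v} references unknown node")
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(self.whitelist)
        if not nx.is_directed_acyclic_graph(g):
            raise ConstraintError("whitelist alone is cyclic")

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {"whitelist": sorted(map(list, self.whitelist)),
               "blacklist": sorted(map(list, self.blacklist))}
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ArcConstraints":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(whitelist={tuple(a) for a in d.get("whitelist", [])},
                   blacklist={tuple(a) for a in d.get("blacklist", [])})


# ---------------------------------------------------------------------------
# Data encoding
# ---------------------------------------------------------------------------

class DiscreteData:
    """Integer-coded view of a discrete data table with declared state sets.

    Declared states (not the observed values) define each variable's
    cardinality, so a state unseen in a training fold still has a CPT entry.
    """

    def __init__(self, frame: pd.DataFrame, states: Mapping[str, Sequence]):
        if len(frame) == 0:
            raise ValueError("empty data table")
        self.states = {k: tuple(v) for k, v in states.items()}
        self.n = len(frame)
        self.codes: dict[str, np.ndarray] = {}
        self.card: dict[str, int] = {}
        for col, sts in self.states.items():
            if col not in frame.columns:
                raise StateDomainError(f"data is missing variable {col!r}")
            cat = pd.Categorical(frame[col], categories=list(sts))
            codes = np.asarray(cat.codes, dtype=np.int64)
            if (codes < 0).any():
                bad = frame[col][codes < 0].iloc[0]
                raise StateDomainError(f"value {bad!r} of {col!r} outside declared states {sts}")
            self.codes[col] = codes
            self.card[col] = len(sts)

    def subset(self, mask: np.ndarray) -> "DiscreteData":
        out = object.__new__(DiscreteData)
        out.states = self.states
        out.codes = {k: v[mask] for k, v in self.codes.items()}
        out.n = int(next(iter(out.codes.values())).size) if out.codes else 0
        if out.n == 0:
            raise ValueError("empty data subset")
        out.card = self.card
        return out

    def joint_index(self, cols: Sequence[str]) -> tuple[np.ndarray, int]:
        """Mixed-radix row index over ``cols`` (last column varies fastest)."""
        idx = np.zeros(self.n, dtype=np.int64)
        size = 1
        for col in cols:
            idx = idx * self.card[col] + self.codes[col]
            size *= self.card[col]
        return idx, size


def _as_data(data, states: Mapping[str, Sequence] | None) -> DiscreteData:
    if isinstance(data, DiscreteData):
        return data
    if states is None:
        raise ValueError("states must be given when passing a raw DataFrame")
    return DiscreteData(data, states)


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreSpec:
    """Decomposable network score: penalized likelihood (bic) or Bayesian
    Dirichlet equivalent uniform (bdeu) with the given equivalent sample size."""

    family: str = "bic"
    equivalent_sample_size: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("bic", "bdeu"):
            raise ValueError(f"unknown score family {self.family!r}")
        if self.equivalent_sample_size <= 0:
            raise ValueError("equivalent_sample_size must be positive")


def local_score(node: str, parents: Sequence[str], data, spec: ScoreSpec = ScoreSpec(),
                states: Mapping[str, Sequence] | None = None) -> float:
    """Score contribution of one node given a candidate parent set."""
    d = _as_data(data, states)
    parents = tuple(sorted(parents))
    r = d.card[node]
    pa_idx, q = d.joint_index(parents)
    counts = np.bincount(pa_idx * r + d.codes[node], minlength=q * r).reshape(q, r)
    n_j = counts.sum(axis=1)
    if spec.family == "bic":
        nz = counts > 0
        ll = float(np.sum(counts[nz] * np.log(counts[nz] / n_j[:, None].repeat(r, 1)[nz])))
        penalty = 0.5 * math.log(d.n) * q * (r - 1)
        return ll - penalty
    a_jk = spec.equivalent_sample_size / (q * r)
    a_j = spec.equivalent_sample_size / q
    return float(
        np.sum(gammaln(a_j) - gammaln(a_j + n_j))
        + np.sum(gammaln(a_jk + counts) - gammaln(a_jk))
    )


def score_network(dag: DAG, data, spec: ScoreSpec = ScoreSpec(),
                  states: Mapping[str, Sequence] | None = None) -> float:
    """Decomposable total score: sum of local scores over nodes."""
    d = _as_data(data, states if states is not None else dag.nodes)
    return sum(local_score(n, dag.parents(n), d, spec) for n in dag.nodes)


# ---------------------------------------------------------------------------
# Structure search
# ---------------------------------------------------------------------------

_MOVE_RANK = {"add": 0, "delete": 1, "reverse": 2}
_EPS = 1e-10


class _Searcher:
    """Shared machinery for hill-climbing and tabu search."""

    def __init__(self, data, constraints: ArcConstraints | None, spec: ScoreSpec,
                 states: Mapping[str, Sequence] | None):
        if states is None and not isinstance(data, DiscreteData):
            raise ValueError("states required with a raw DataFrame")
        self.data = _as_data(data, states)
        self.spec = spec
        self.nodes = sorted(self.data.states)
        self.constraints = constraints or ArcConstraints()
        self.constraints.validate(self.nodes)
        self.parents: dict[str, set[str]] = {n: set() for n in self.nodes}
        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(self.nodes)
        for u, v in sorted(self.constraints.whitelist):
            self.graph.add_edge(u, v)
            self.parents[v].add(u)
        self._cache: dict[tuple[str, frozenset], float] = {}
        self.score = sum(self._ls(n, self.parents[n]) for n in self.nodes)

    def _ls(self, node: str, parents: set[str] | frozenset) -> float:
        key = (node, frozenset(parents))
        if key not in self._cache:
            self._cache[key] = local_score(node, tuple(parents), self.data, self.spec)
        return self._cache[key]

    def legal_moves(self):
        """Yield (key, move, delta) in deterministic lexicographic order."""
        wl, bl = self.constraints.whitelist, self.constraints.blacklist
        arcs = set(self.graph.edges)
        moves = []
        for u in self.nodes:
            for v in self.nodes:
                if u == v:
                    continue
                if (u, v) not in arcs:
                    if (u, v) not in bl and not nx.has_path(self.graph, v, u):
                        moves.append(((v, u, _MOVE_RANK["add"]), ("add", u, v)))
                else:
                    if (u, v) not in wl:
                        moves.append(((v, u, _MOVE_RANK["delete"]), ("delete", u, v)))
                        if (v, u) not in bl:
                            self.graph.remove_edge(u, v)
                            ok = not nx.has_path(self.graph, u, v)
                            self.graph.add_edge(u, v)
                            if ok:
                                moves.append(((v, u, _MOVE_RANK["reverse"]), ("reverse", u, v)))
        for key, move in sorted(moves, key=lambda t: t[0]):
            yield key, move, self._delta(move)

    def _delta(self, move) -> float:
        kind, u, v = move
        if kind == "add":
            return self._ls(v, self.parents[v] | {u}) - self._ls(v, self.parents[v])
        if kind == "delete":
            return self._ls(v, self.parents[v] - {u}) - self._ls(v, self.parents[v])
        return (
            self._ls(v, self.parents[v] - {u}) - self._ls(v, self.parents[v])
            + self._ls(u, self.parents[u] | {v}) - self._ls(u, self.parents[u])
        )

    def apply(self, move) -> None:
        kind, u, v = move
        if kind == "add":
            self.graph.add_edge(u, v)
            self.parents[v].add(u)
        elif kind == "delete":
            self.graph.remove_edge(u, v)
            self.parents[v].discard(u)
        else:
            self.graph.remove_edge(u, v)
            self.parents[v].discard(u)
            self.graph.add_edge(v, u)
            self.parents[u].add(v)
        self.score = sum(self._ls(n, self.parents[n]) for n in self.nodes)

    def dag(self) -> DAG:
        return DAG(dict(self.data.states), set(self.graph.edges))


def _inverse(move):
    kind, u, v = move
    if kind == "add":
        return ("delete", u, v)
    if kind == "delete":
        return ("add", u, v)
    return ("reverse", v, u)


def hill_climb(data, constraints: ArcConstraints | None = None,
               spec: ScoreSpec = ScoreSpec(), max_iter: int = 200,
               states: Mapping[str, Sequence] | None = None) -> DAG:
    """Greedy single-move ascent from the whitelist graph to a local optimum.

    At each step the best score-increasing arc addition/deletion/reversal that
    keeps the graph acyclic and respects the constraints is applied; ties are
    broken lexicographically so the search is deterministic.
    """
    s = _Searcher(data, constraints, spec, states)
    for _ in range(max_iter):
        best = None
        for key, move, delta in s.legal_moves():
            if delta > _EPS and (best is None or delta > best[0] + _EPS):
                best = (delta, key, move)
        if best is None:
            break
        s.apply(best[2])
    return s.dag()


def tabu_search(data, constraints: ArcConstraints | None = None,
                spec: ScoreSpec = ScoreSpec(), tabu_length: int = 10,
                max_iter: int = 200, max_tabu_escapes: int = 10,
                states: Mapping[str, Sequence] | None = None) -> DAG:
    """Hill-climbing that escapes local optima via a FIFO tabu list.

    At a local optimum the best non-improving move whose inverse is not on the
    tabu list is accepted (up to ``max_tabu_escapes`` times); the best-scoring
    DAG visited is returned, so the result never scores below the plain
    hill-climbing optimum for the same inputs.
    """
    if tabu_length < 1:
        raise ValueError("tabu_length must be >= 1")
    s = _Searcher(data, constraints, spec, states)
    tabu: deque = deque(maxlen=tabu_length)
    best_score = s.score
    best_arcs = set(s.graph.edges)
    escapes = 0
    for _ in range(max_iter):
        best = None
        for key, move, delta in s.legal_moves():
            if move in tabu:
                continue
            if best is None or delta > best[0] + _EPS:
                best = (delta, key, move)
        if best is None:
            break
        if best[0] <= _EPS:
            if escapes >= max_tabu_escapes:
                break
            escapes += 1
        tabu.append(_inverse(best[2]))
        s.apply(best[2])
        if s.score > best_score + _EPS:
            best_score = s.score
            best_arcs = set(s.graph.edges)
    return DAG(dict(s.data.states), best_arcs)


#: Algorithm registry: search algorithms selectable by configuration name.
SUPPORTED_ALGORITHMS = {"hill_climbing": hill_climb, "tabu": tabu_search}
#: Constraint-based algorithms tried during the original calibration but out
#: of scope here; requesting one raises UnsupportedAlgorithmError.
UNSUPPORTED_ALGORITHMS = ("grow_shrink", "iamb", "fast_iamb", "inter_iamb", "mmpc")


def get_algorithm(name: str):
    if name in SUPPORTED_ALGORITHMS:
        return SUPPORTED_ALGORITHMS[name]
    if name in UNSUPPORTED_ALGORITHMS:
        raise UnsupportedAlgorithmError(
            f"algorithm {name!r} is registered but not implemented; "
            f"supported: {sorted(SUPPORTED_ALGORITHMS)}"
        )
    raise ValueError(f"unknown algorithm {name!r}")


# ---------------------------------------------------------------------------
# Parameters and inference
# ---------------------------------------------------------------------------

@dataclass
class CPT:
    """Conditional distribution of ``child`` for every parent configuration.

    ``table`` has one axis per parent (in ``parents`` order) plus a trailing
    axis over child states; every slice along the last axis sums to one.
    """

    child: str
    parents: tuple[str, ...]
    states: dict[str, tuple]
    table: np.ndarray

    def __post_init__(self) -> None:
        self.parents = tuple(self.parents)
        expected = tuple(len(self.states[p]) for p in self.parents) + (len(self.states[self.child]),)
        self.table = np.asarray(self.table, dtype=float).reshape(expected)
        # canonical parent order (sorted) so tables from different sources
        # are directly comparable
        order = tuple(sorted(self.parents))
        if order != self.parents:
            perm = [self.parents.index(p) for p in order] + [len(self.parents)]
            self.table = np.ascontiguousarray(np.transpose(self.table, perm))
            self.parents = order
        if np.any(self.table < 0):
            raise ValueError(f"negative probability in CPT of {self.child}")
        if not np.allclose(self.table.sum(axis=-1), 1.0, atol=1e-9):
            raise ValueError(f"CPT rows of {self.child} do not sum to 1")

    @property
    def rows(self) -> np.ndarray:
        """(q, r) view: one row per parent configuration."""
        r = len(self.states[self.child])
        return self.table.reshape(-1, r)

    def row(self, assignment: Mapping[str, object]) -> np.ndarray:
        idx = tuple(self.states[p].index(assignment[p]) for p in self.parents)
        return self.table[idx]


@dataclass
class BayesianNetwork:
    dag: DAG
    cpts: dict[str, CPT]

    def __post_init__(self) -> None:
        for node in self.dag.nodes:
            cpt = self.cpts.get(node)
            if cpt is None:
                raise ValueError(f"missing CPT for node {node}")
            if tuple(sorted(cpt.parents)) != self.dag.parents(node):
                raise ValueError(f"CPT parents of {node} disagree with the DAG")

    @property
    def states(self) -> dict[str, tuple]:
        return self.dag.nodes

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "nodes": {k: list(v) for k, v in self.dag.nodes.items()},
            "arcs": sorted(map(list, self.dag.arcs)),
            "cpts": {
                n: {"parents": list(c.parents), "table": c.rows.tolist()}
                for n, c in self.cpts.items()
            },
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BayesianNetwork":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        nodes = {k: tuple(v) for k, v in d["nodes"].items()}
        dag = DAG(nodes, {tuple(a) for a in d["arcs"]})
        cpts = {
            n: CPT(child=n, parents=tuple(c["parents"]), states=nodes,
                   table=np.asarray(c["table"], dtype=float))
            for n, c in d["cpts"].items()
        }
        return cls(dag, cpts)


def fit_cpts(dag: DAG, data, equivalent_sample_size: float = 1.0,
             states: Mapping[str, Sequence] | None = None) -> BayesianNetwork:
    """Dirichlet posterior-mean CPT estimation ("Bayesian method").

    With a uniform prior of total weight ``equivalent_sample_size`` spread over
    the joint child x parent table, each row is
    ``(n_jk + ess/(r q)) / (n_j + ess/q)``; a configuration with no data falls
    back to the uniform prior mean.
    """
    if not check_acyclic(dag):
        raise ValueError("dag contains a cycle")
    if equivalent_sample_size <= 0:
        raise ValueError("equivalent_sample_size must be positive")
    d = _as_data(data, states if states is not None else dag.nodes)
    cpts = {}
    for node in dag.nodes:
        parents = dag.parents(node)
        r = d.card[node]
        pa_idx, q = d.joint_index(parents)
        counts = np.bincount(pa_idx * r + d.codes[node], minlength=q * r).reshape(q, r)
        alpha = equivalent_sample_size / (q * r)
        table = (counts + alpha) / (counts.sum(axis=1, keepdims=True) + alpha * r)
        cpts[node] = CPT(child=node, parents=parents, states=dict(dag.nodes), table=table)
    return BayesianNetwork(dag.copy(), cpts)


def max_cpt_error(bn_a: BayesianNetwork, bn_b: BayesianNetwork) -> float:
    """Largest absolute CPT-entry difference between two same-structure nets."""
    if set(bn_a.dag.nodes) != set(bn_b.dag.nodes) or bn_a.dag.arcs != bn_b.dag.arcs:
        raise ValueError("networks must share nodes and arcs")
    err = 0.0
    for node in bn_a.dag.nodes:
        err = max(err, float(np.abs(bn_a.cpts[node].table - bn_b.cpts[node].table).max()))
    return err


def joint_probability(bn: BayesianNetwork, assignment: Mapping[str, object]) -> float:
    """Probability of one full assignment: product of per-node CPT entries."""
    missing = set(bn.dag.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment missing nodes {sorted(missing)}; use posterior() instead")
    p = 1.0
    for node, cpt in bn.cpts.items():
        row = cpt.row(assignment)
        p *= row[bn.states[node].index(assignment[node])]
    return float(p)


class _Factor:
    __slots__ = ("vars", "table")

    def __init__(self, vars: tuple[str, ...], table: np.ndarray):
        self.vars = vars
        self.table = table

    def multiply(self, other: "_Factor") -> "_Factor":
        out_vars = self.vars + tuple(v for v in other.vars if v not in self.vars)
        a = self.table.reshape(self.table.shape + (1,) * (len(out_vars) - len(self.vars)))
        # transpose other's axes into out order, padding absent axes with 1
        present = [v for v in out_vars if v in other.vars]
        bt = other.table.transpose([other.vars.index(v) for v in present])
        b = bt.reshape([bt.shape[present.index(v)] if v in present else 1 for v in out_vars])
        return _Factor(out_vars, a * b)

    def marginalize(self, var: str) -> "_Factor":
        i = self.vars.index(var)
        return _Factor(self.vars[:i] + self.vars[i + 1:], self.table.sum(axis=i))


def _evidence_sliced_factors(bn: BayesianNetwork, evidence: Mapping[str, object]):
    factors = []
    for node, cpt in bn.cpts.items():
        vars = cpt.parents + (node,)
        table = cpt.table
        keep = []
        for i, v in enumerate(vars):
            if v in evidence:
                sts = bn.states[v]
                if evidence[v] not in sts:
                    raise StateDomainError(f"evidence {v}={evidence[v]!r} not in states {sts}")
                table = np.take(table, sts.index(evidence[v]), axis=len(keep))
            else:
                keep.append(v)
        factors.append(_Factor(tuple(keep), np.asarray(table, dtype=float)))
    return factors


def posterior(bn: BayesianNetwork, target: str, evidence: Mapping[str, object] | None = None
              ) -> dict:
    """Exact conditional distribution of ``target`` by variable elimination.

    Elimination follows a min-degree heuristic on the factor interaction
    graph.  Raises :class:`InconsistentEvidenceError` if the evidence has zero
    probability.
    """
    evidence = dict(evidence or {})
    if target in evidence:
        raise ValueError(f"target {target!r} is part of the evidence")
    if target not in bn.dag.nodes:
        raise ValueError(f"unknown target {target!r}")
    factors = _evidence_sliced_factors(bn, evidence)
    to_eliminate = set(bn.dag.nodes) - set(evidence) - {target}
    while to_eliminate:
        # min-degree: eliminate the variable appearing with the fewest
        # distinct neighbors across current factors; ties lexicographic.
        neighbors = {v: set() for v in to_eliminate}
        for f in factors:
            for v in f.vars:
                if v in neighbors:
                    neighbors[v] |= set(f.vars) - {v}
        var = min(to_eliminate, key=lambda v: (len(neighbors[v]), v))
        related = [f for f in factors if var in f.vars]
        factors = [f for f in factors if var not in f.vars]
        prod = related[0]
        for f in related[1:]:
            prod = prod.multiply(f)
        factors.append(prod.marginalize(var))
        to_eliminate.discard(var)
    result = _Factor((), np.array(1.0))
    for f in factors:
        result = result.multiply(f)
    table = result.table
    if result.vars != (target,):
        table = np.moveaxis(table, result.vars.index(target), 0).reshape(len(bn.states[target]))
    total = float(table.sum())
    if total <= 0:
        raise InconsistentEvidenceError(f"evidence {evidence} has zero probability")
    dist = table / total
    return {s: float(p) for s, p in zip(bn.states[target], dist)}


def predict_risk(bn: BayesianNetwork, evidence: Mapping[str, object],
                 threshold: float = 0.5, sb_node: str = "sb_group",
                 positive: str = "with_sb") -> tuple[float, str]:
    """Posterior probability of the SB-positive state and the thresholded label."""
    if sb_node not in bn.dag.nodes:
        raise ValueError(f"network has no node {sb_node!r}")
    evidence = {k: v for k, v in evidence.items() if k in bn.dag.nodes and k != sb_node}
    dist = posterior(bn, sb_node, evidence)
    p = dist[positive]
    negative = next(s for s in bn.states[sb_node] if s != positive)
    return p, (positive if p >= threshold else negative)


# ---------------------------------------------------------------------------
# Equivalence classes
# ---------------------------------------------------------------------------

def cpdag(dag: DAG) -> tuple[frozenset, frozenset]:
    """Completed partially directed graph of ``dag``'s equivalence class.

    Returns ``(directed, undirected)``: compelled arcs as ordered pairs and
    reversible edges as frozenset pairs.  Orientation starts from the
    v-structures and closes under the Meek rules.
    """
    adj: dict[str, set[str]] = {n: set() for n in dag.nodes}
    for u, v in dag.arcs:
        adj[u].add(v)
        adj[v].add(u)
    directed: set[tuple[str, str]] = set()
    for z in dag.nodes:
        pa = dag.parents(z)
        for x, y in combinations(pa, 2):
            if x not in adj[y]:
                directed.add((x, z))
                directed.add((y, z))
    undirected = {frozenset((u, v)) for u, v in dag.arcs
                  if (u, v) not in directed}

    def orient(u, v):
        directed.add((u, v))
        undirected.discard(frozenset((u, v)))

    changed = True
    while changed:
        changed = False
        for e in list(undirected):
            a, b = sorted(e)
            for u, v in ((a, b), (b, a)):
                # R1: x -> u, u - v, x and v non-adjacent  =>  u -> v
                if any((x, u) in directed and v not in adj[x] and x != v
                       for x in adj[u]):
                    orient(u, v)
                    changed = True
                    break
                # R2: u -> x -> v with u - v  =>  u -> v
                if any((u, x) in directed and (x, v) in directed for x in adj[u] & adj[v]):
                    orient(u, v)
                    changed = True
                    break
                # R3: u - x, u - y, x -> v, y -> v, x,y non-adjacent  =>  u -> v
                spouses = [x for x in adj[u] & adj[v]
                           if frozenset((u, x)) in undirected and (x, v) in directed]
                if any(x not in adj[y] for x, y in combinations(spouses, 2)):
                    orient(u, v)
                    changed = True
                    break
            if changed:
                break
    return frozenset(directed), frozenset(undirected)


def shd(cpdag_a: tuple[frozenset, frozenset], cpdag_b: tuple[frozenset, frozenset]) -> int:
    """Structural Hamming distance between two CPDAGs.

    Each node pair contributes 1 when its edge type (absent, undirected, or
    either direction) differs between the two graphs.
    """
    def edge_types(c):
        directed, undirected = c
        types: dict[frozenset, object] = {}
        for u, v in directed:
            types[frozenset((u, v))] = (u, v)
        for e in undirected:
            types[e] = "undirected"
        return types

    ta, tb = edge_types(cpdag_a), edge_types(cpdag_b)
    pairs = set(ta) | set(tb)
    return sum(1 for e in pairs if ta.get(e) != tb.get(e))
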