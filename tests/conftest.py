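"""Shared fixtures and independent oracle helpers."""

from itertools import product

import pytest
from hypothesis import settings

from pvqnet import questionnaire_io as qio
from pvqnet import synthetic_data as sd

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def truth_network():
    return sd.default_truth_network()


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-record strong-signal cohort (fast to generate, both groups)."""
    return sd.generate_cohort(sd.GeneratorConfig(n=120, seed=7))


def make_record(i: int = 0, **overrides) -> qio.PatientRecord:
    base = dict(
        patient_id=f"P{i:03d}",
        oq_items={3: 1, 8: 0, 13: 3, 24: 2, 31: 4},
        deq_items={3: 4, 16: 2, 19: 5, 48: 3, 56: 6, 62: 1},
        rfl_items={k: 1 + (k % 6) for k in qio.RFL_ITEMS},
        diagnosis="major_depressive",
        children="1",
        gender="woman",
        age_band="28-38",
        schooling="university",
        cohabitation="family",
        marital_status="single",
        occupation="employed",
        sb_status="none",
    )
    base.update(overrides)
    return qio.PatientRecord(**base)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately brute-force, separate from the library's
# code paths)
# ---------------------------------------------------------------------------

def enumerate_joint(bn):
    """Full joint distribution as {assignment tuple: probability}, computed
    by explicit products of CPT lookups over every assignment."""
    nodes = sorted(bn.dag.nodes)
    table = {}
    for combo in product(*(bn.states[v] for v in nodes)):
        a = dict(zip(nodes, combo))
        p = 1.0
        for v in nodes:
            cpt = bn.cpts[v]
            row = cpt.row(a)
            p *= row[bn.states[v].index(a[v])]
        table[combo] = p
    return nodes, table


def brute_posterior(bn, target, evidence):
    """Posterior by summing the enumerated joint."""
    nodes, joint = enumerate_joint(bn)
    idx = {v: i for i, v in enumerate(nodes)}
    totals = {s: 0.0 for s in bn.states[target]}
    for combo, p in joint.items():
        if all(combo[idx[v]] == s for v, s in evidence.items()):
            totals[combo[idx[target]]] += p
    z = sum(totals.values())
    return {s: t / z for s, t in totals.items()}


def dfs_has_cycle(nodes, arcs) -> bool:
    """Back-edge DFS cycle detector."""
    color = {n: 0 for n in nodes}
    adj = {n: [] for n in nodes}
    for u, v in arcs:
        adj[u].append(v)

    def visit(u):
        color[u] = 1
        for w in adj[u]:
            if color[w] == 1:
                return True
            if color[w] == 0 and visit(w):
                return True
        color[u] = 2
        return False

    return any(color[n] == 0 and visit(n) for n in nodes)


def all_dags_3(names=("A", "B", "C")):
    """All 25 DAGs on three labelled nodes, as arc sets."""
    pairs = [(names[0], names[1]), (names[0], names[2]), (names[1], names[2])]
    dags = []
    for choice in product((0, 1, 2), repeat=3):   # absent / forward / backward
        arcs = set()
        for (u, v), c in zip(pairs, choice):
            if c == 1:
                arcs.add((u, v))
            elif c == 2:
                arcs.add((v, u))
        if not dfs_has_cycle(names, arcs):
            dags.append(frozenset(arcs))
    return dags


def skeleton_vstructs(nodes, arcs):
    """Equivalence-class key: (skeleton, v-structures)."""
    skel = frozenset(frozenset(e) for e in arcs)
    adj = {n: set() for n in nodes}
    parents = {n: set() for n in nodes}
    for u, v in arcs:
        adj[u].add(v)
        adj[v].add(u)
        parents[v].add(u)
    vs = set()
    for z in nodes:
        for x in parents[z]:
            for y in parents[z]:
                if x < y and x not in adj[y]:
                    vs.add((x, z, y))
    return skel, frozenset(vs)
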