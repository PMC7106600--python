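"""Synthetic cohorts with a known ground-truth network.

The study's real cohort is controlled-access, so every pipeline stage is
exercised on generated data engineered to share its statistical signature:

* ~650 patients, with/without-SB groups close to balanced;
* highly inter-correlated RFL and OQ item blocks (one latent factor each,
  plus a strong ordinal "level" separation that the composite discretizer
  can recover);
* weakly correlated DEQ items with a two-factor structure whose loadings
  default to the published component coefficients;
* sociodemographic marginals taken from the validation sample's tables.

Generation runs feature-first: discrete feature states (including the SB
label) are drawn from a ground-truth Bayesian network by ancestral sampling,
then item answers are rendered from those states through latent factors and
Likert thresholds.  Because the rendering is (noisily) invertible by the
feature pipeline, composite/PCA/structure/parameter recovery are all
testable against known truth.

The default truth network is deliberately illustrative -- the published
expert graph is only available as a figure -- and uses the topology
``age_band -> {deq_quadrant, rfl_level}``, ``{deq_quadrant, rfl_level,
oq_level} -> sb_group -> oq8``.  The suicidal-ideation item (oq8) is modeled
as a symptom (child) of the SB state, which also keeps every CPT row well
supplied with data at realistic sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from . import questionnaire_io as qio
from .bayesnet import CPT, DAG, BayesianNetwork, check_acyclic, topological_order
from .features import QUADRANTS

_SB_STATES = (qio.WITHOUT_SB, qio.WITH_SB)

#: Published DEQ component coefficients (unit-norm, orthogonal columns;
#: rows follow the DEQ item order 3, 16, 19, 48, 56, 62).
DEQ_LOADINGS = np.array([
    [-0.277, 0.515],
    [0.464, 0.286],
    [0.357, 0.471],
    [-0.509, 0.234],
    [0.184, 0.555],
    [-0.537, 0.262],
])

#: Validation-sample age-band shares (study coding, 14-19 .. 60+).
AGE_MARGINAL = (0.1169, 0.1831, 0.1892, 0.1923, 0.2246, 0.0938)

DEMOGRAPHIC_MARGINALS: dict[str, dict[str, float]] = {
    "gender": {"woman": 0.7954, "man": 0.2046, "other": 0.0},
    "diagnosis": {
        "major_depressive": 0.4338, "bipolar": 0.1615, "moderate_depressive": 0.0831,
        "mild_depressive": 0.0185, "adjustment": 0.1077, "anxiety": 0.1154,
        "mixed_episode": 0.0231, "other": 0.0462, "dysthymia": 0.0108,
    },
    # only aggregate summaries are published for the remaining fields; these
    # shares are chosen to match the published aggregates (e.g. 48.3% with
    # higher education, mean 1.44 children)
    "children": {"0": 0.35, "1": 0.18, "2": 0.22, "3": 0.13, "4": 0.07, "5+": 0.05},
    "schooling": {"basic": 0.20, "secondary": 0.3169, "technical": 0.22, "university": 0.2631},
    "cohabitation": {"alone": 0.1031, "friends": 0.02, "couple": 0.1292, "family": 0.7477},
    "marital_status": {"single": 0.4169, "married": 0.3662, "separated": 0.10,
                       "widow": 0.0692, "free_union": 0.0477},
    "occupation": {"employed": 0.5062, "student": 0.2185, "unemployed": 0.06,
                   "housewife": 0.1954, "retired/not_working": 0.0199},
}

#: Attempt-severity mix among SB-positive patients (validation-sample shares).
SEVERITY_PROBS = {"ideation": 0.5215, "attempt_low_severity": 0.2362,
                  "attempt_high_severity": 0.2423}


def default_truth_network(signal: bool = True) -> BayesianNetwork:
    """Illustrative ground-truth network over the derived feature variables.

    With ``signal=False`` the SB node is cut loose from everything (its CPT
    rows are all 0.5 and oq8 no longer depends on it) -- the chance-level
    configuration used for leakage checks.
    """
    states = {
        "age_band": qio.AGE_BANDS_STUDY,
        "deq_quadrant": QUADRANTS,
        "rfl_level": (1, 2, 3),
        "oq_level": (1, 2, 3),
        "sb_group": _SB_STATES,
        "oq8": (0, 1, 2, 3, 4),
    }
    arcs = {
        ("age_band", "deq_quadrant"),
        ("age_band", "rfl_level"),
        ("deq_quadrant", "sb_group"),
        ("rfl_level", "sb_group"),
        ("oq_level", "sb_group"),
        ("sb_group", "oq8"),
    }
    dag = DAG(states, arcs)

    age_p = np.array(AGE_MARGINAL) / np.sum(AGE_MARGINAL)

    # Mild age tilts make the age arcs detectable at large n; each tilt is
    # centered under the age marginal so the quadrant and RFL-level marginals
    # stay exactly uniform (the quantile discretizer bins into equal shares,
    # so a tilted marginal would cut bin edges inside a level cluster).
    quad_tilt = np.array([0.07, 0.04, 0.01, -0.02, -0.04, -0.06])
    quad_tilt = quad_tilt - quad_tilt @ age_p
    quad_rows = np.stack([
        [0.25 - t, 0.25, 0.25 + t, 0.25] for t in quad_tilt
    ])
    rfl_tilt = np.array([-0.06, -0.03, 0.0, 0.02, 0.04, 0.06])
    rfl_tilt = rfl_tilt - rfl_tilt @ age_p
    rfl_rows = np.stack([
        [1 / 3 - t, 1 / 3, 1 / 3 + t] for t in rfl_tilt
    ])

    oq_p = np.array([1 / 3, 1 / 3, 1 / 3])

    # SB risk: distress (oq) raises it, reasons for living (rfl) protect.
    # When the two balance, the self-esteem digit of the DEQ quadrant decides
    # with a softer 0.85/0.15 signal; otherwise the signal is a strong
    # 0.95/0.05.  All rows stay well away from 0 and 1 so parameter recovery
    # is well conditioned, and none sits at 0.5, so the Bayes decision is
    # unambiguous in every configuration.
    sb_rows = []
    for quad, rfl, oq in product(QUADRANTS, (1, 2, 3), (1, 2, 3)):
        s = (oq - 2) - (rfl - 2)
        if s > 0:
            p = 0.95
        elif s < 0:
            p = 0.05
        else:
            p = 0.85 if quad[0] == "1" else 0.15
        if not signal:
            p = 0.5
        sb_rows.append([1 - p, p])
    sb_rows = np.array(sb_rows)

    oq8_rows = np.array([
        [0.45, 0.30, 0.15, 0.07, 0.03],   # without SB
        [0.03, 0.07, 0.15, 0.30, 0.45],   # with SB
    ])
    if not signal:
        oq8_rows = np.array([[0.35, 0.25, 0.2, 0.12, 0.08]] * 2)

    cpts = {
        "age_band": CPT("age_band", (), states, age_p),
        "deq_quadrant": CPT("deq_quadrant", ("age_band",), states, quad_rows),
        "rfl_level": CPT("rfl_level", ("age_band",), states, rfl_rows),
        "oq_level": CPT("oq_level", (), states, oq_p),
        "sb_group": CPT("sb_group", ("deq_quadrant", "rfl_level", "oq_level"),
                        states, sb_rows),
        "oq8": CPT("oq8", ("sb_group",), states, oq8_rows),
    }
    return BayesianNetwork(dag, cpts)


def sample_network(bn: BayesianNetwork, n: int,
                   seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Ancestral sampling: draw ``n`` joint assignments in topological order."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes: dict[str, np.ndarray] = {}
    for node in topological_order(bn.dag):
        cpt = bn.cpts[node]
        r = len(bn.states[node])
        if not cpt.parents:
            probs = np.broadcast_to(cpt.table.reshape(1, r), (n, r))
        else:
            idx = np.zeros(n, dtype=np.int64)
            for p in cpt.parents:
                idx = idx * len(bn.states[p]) + codes[p]
            probs = cpt.rows[idx]
        u = rng.random(n)
        codes[node] = (u[:, None] > probs.cumsum(axis=1)).sum(axis=1)
    return pd.DataFrame({
        node: [bn.states[node][c] for c in codes[node]] for node in bn.dag.nodes
    })


def likertize(value, thresholds: Sequence[float], minimum: int = 1):
    """Map latent value(s) to an ordinal answer: minimum + #thresholds below."""
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    level = np.searchsorted(thresholds, value, side="left") + minimum
    if np.isscalar(value) or np.ndim(value) == 0:
        return int(level)
    return level.astype(int)


def _halfnormal_scale(gap: float, sigma: float) -> float:
    """Scale s so that sign * (gap + |N(0, s)|) has variance sigma**2."""
    c = math.sqrt(2 / math.pi)
    disc = gap * gap * c * c - gap * gap + sigma * sigma
    if disc <= 0:
        raise ValueError(f"gap {gap} too large for component sd {sigma}")
    return -gap * c + math.sqrt(disc)


@dataclass
class GeneratorConfig:
    """Study conditions for cohort generation.

    Defaults emulate the validation sample: n=650, near-balanced SB groups,
    strong within-block item correlations for OQ/RFL, weak DEQ inter-item
    correlations carrying a two-component structure with the published
    loadings, and published demographic marginals.
    """

    n: int = 650
    seed: int = 0
    truth_network: BayesianNetwork = field(default_factory=default_truth_network)
    # OQ / RFL rendering: level-dependent latent mean + one shared factor
    oq_factor_loading: float = 0.5
    rfl_factor_loading: float = 0.5
    oq_level_means: tuple[float, ...] = (-2.8, 0.0, 2.8)
    rfl_level_means: tuple[float, ...] = (-2.8, 0.0, 2.8)
    oq_within_scale: float = 0.55
    rfl_within_scale: float = 0.55
    oq_thresholds: tuple[float, ...] = (-2.1, -0.7, 0.7, 2.1)
    rfl_thresholds: tuple[float, ...] = (-2.25, -1.2, 0.0, 1.2, 2.25)
    # DEQ rendering: two latent components with a sign gap per quadrant digit
    deq_loadings: np.ndarray = field(default_factory=lambda: DEQ_LOADINGS.copy())
    deq_component_sds: tuple[float, float] = (1.452, 1.131)
    deq_gaps: tuple[float, float] = (1.3, 0.9)
    deq_noise_sd: float = 0.95
    deq_thresholds: tuple[float, ...] = (-1.5, -0.9, -0.3, 0.3, 0.9, 1.5)
    demographic_marginals: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEMOGRAPHIC_MARGINALS.items()})
    severity_probs: dict = field(default_factory=lambda: dict(SEVERITY_PROBS))

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        for name in ("oq_thresholds", "rfl_thresholds", "deq_thresholds"):
            t = np.asarray(getattr(self, name))
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        for fld, marg in self.demographic_marginals.items():
            total = sum(marg.values())
            # published percentages are rounded; allow rounding slack
            if abs(total - 1.0) > 1e-3:
                raise ValueError(f"{fld} marginals sum to {total}, not 1")
            if any(p < 0 for p in marg.values()):
                raise ValueError(f"{fld} has a negative probability")
        if abs(sum(self.severity_probs.values()) - 1.0) > 1e-6:
            raise ValueError("severity probabilities must sum to 1")
        for loading in (self.oq_factor_loading, self.rfl_factor_loading):
            if not 0 < loading < 1:
                raise ValueError("factor loadings must lie in (0, 1)")
        if not check_acyclic(self.truth_network.dag):
            raise ValueError("truth network is cyclic")
        for gap, sd in zip(self.deq_gaps, self.deq_component_sds):
            _halfnormal_scale(gap, sd)  # raises if infeasible


@dataclass
class SyntheticCohort:
    """Generated records plus the per-record ground truth behind them."""

    records: list[qio.PatientRecord]
    truth: pd.DataFrame
    config: GeneratorConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.records])


def _render_block(rng: np.random.Generator, level_means: Sequence[float],
                  levels: np.ndarray, n_items: int, loading: float,
                  scale: float, thresholds: Sequence[float], minimum: int
                  ) -> np.ndarray:
    """Items = level mean + scale * (loading*shared + sqrt(1-l^2)*noise)."""
    n = levels.size
    mu = np.asarray(level_means)[levels - 1]
    shared = rng.standard_normal(n)
    noise = rng.standard_normal((n, n_items))
    latent = mu[:, None] + scale * (loading * shared[:, None]
                                    + math.sqrt(1 - loading**2) * noise)
    return likertize(latent, thresholds, minimum=minimum)


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Draw a full item-level cohort; reproducible given ``config.seed``."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    feats = sample_network(config.truth_network, n, rng)
    oq_levels = feats["oq_level"].to_numpy().astype(int)
    rfl_levels = feats["rfl_level"].to_numpy().astype(int)
    quadrants = feats["deq_quadrant"].to_numpy()

    # OQ: rendered on the scored 0..4 scale, then converted to printed answer
    # positions (items 13/24/31 print a reversed 4..0 scale).
    oq_scored = _render_block(rng, config.oq_level_means, oq_levels, 4,
                              config.oq_factor_loading, config.oq_within_scale,
                              config.oq_thresholds, minimum=0)
    oq_scored = np.clip(oq_scored, 0, 4)
    rfl_answers = _render_block(rng, config.rfl_level_means, rfl_levels,
                                len(qio.RFL_ITEMS), config.rfl_factor_loading,
                                config.rfl_within_scale, config.rfl_thresholds,
                                minimum=1)
    rfl_answers = np.clip(rfl_answers, 1, 6)

    # DEQ: component scores with a sign gap per quadrant digit, published
    # loading directions, independent item noise.
    sds = config.deq_component_sds
    gaps = config.deq_gaps
    scales = [_halfnormal_scale(g, s) for g, s in zip(gaps, sds)]
    digit1 = np.array([1 if q[0] == "1" else -1 for q in quadrants])
    digit2 = np.array([1 if q[1] == "1" else -1 for q in quadrants])
    t1 = digit1 * (gaps[0] + np.abs(rng.standard_normal(n)) * scales[0])
    t2 = digit2 * (gaps[1] + np.abs(rng.standard_normal(n)) * scales[1])
    deq_latent = (np.column_stack([t1, t2]) @ np.asarray(config.deq_loadings).T
                  + config.deq_noise_sd * rng.standard_normal((n, 6)))
    deq_answers = np.clip(likertize(deq_latent, config.deq_thresholds, minimum=1), 1, 7)

    demo: dict[str, np.ndarray] = {}
    for fld, marg in config.demographic_marginals.items():
        cats = list(marg)
        probs = np.array([marg[c] for c in cats], dtype=float)
        demo[fld] = rng.choice(np.array(cats, dtype=object), size=n, p=probs / probs.sum())

    severities = list(config.severity_probs)
    sev_p = np.array([config.severity_probs[s] for s in severities])
    sev_draw = rng.choice(np.array(severities, dtype=object), size=n, p=sev_p / sev_p.sum())
    sb = feats["sb_group"].to_numpy()
    sb_status = np.where(sb == qio.WITH_SB, sev_draw, "none")

    oq8 = feats["oq8"].to_numpy().astype(int)
    width = len(str(n))
    records = []
    for i in range(n):
        oq_items = {}
        for j, item in enumerate(qio.OQ_ITEMS):
            if item == 8:
                oq_items[item] = int(oq8[i])
            else:
                pos = (3, 13, 24, 31).index(item)
                scored = int(oq_scored[i, pos])
                oq_items[item] = 4 - scored if item in (13, 24, 31) else scored
        records.append(qio.PatientRecord(
            patient_id=f"S{i:0{width}d}",
            oq_items=oq_items,
            deq_items={item: int(deq_answers[i, j]) for j, item in enumerate(qio.DEQ_ITEMS)},
            rfl_items={item: int(rfl_answers[i, j]) for j, item in enumerate(qio.RFL_ITEMS)},
            diagnosis=str(demo["diagnosis"][i]),
            children=str(demo["children"][i]),
            gender=str(demo["gender"][i]),
            age_band=str(feats["age_band"].iloc[i]),
            schooling=str(demo["schooling"][i]),
            cohabitation=str(demo["cohabitation"][i]),
            marital_status=str(demo["marital_status"][i]),
            occupation=str(demo["occupation"][i]),
            sb_status=str(sb_status[i]),
        ))
        records[-1].validate(age_bands=qio.AGE_BANDS_STUDY)

    truth = feats.copy()
    truth["pc1_true"] = t1
    truth["pc2_true"] = t2
    sb_cpt = config.truth_network.cpts["sb_group"]
    truth["sb_probability"] = [
        float(sb_cpt.row(feats.iloc[i].to_dict())[_SB_STATES.index(qio.WITH_SB)])
        for i in range(n)
    ]
    return SyntheticCohort(records=records, truth=truth, config=config)


def bayes_balanced_accuracy(bn: BayesianNetwork, sb_node: str = "sb_group",
                            evidence_nodes: Sequence[str] | None = None,
                            positive: str = qio.WITH_SB) -> float:
    """Balanced accuracy of the Bayes-optimal classifier, by enumeration.

    The classifier observes ``evidence_nodes`` (default: every non-SB node)
    and predicts the SB state with the larger posterior.
    """
    from .bayesnet import joint_probability

    if evidence_nodes is None:
        evidence_nodes = [v for v in bn.dag.nodes if v != sb_node]
    hidden = [v for v in bn.dag.nodes if v != sb_node and v not in evidence_nodes]
    states = bn.states
    neg = next(s for s in states[sb_node] if s != positive)
    correct = {positive: 0.0, neg: 0.0}
    mass = {positive: 0.0, neg: 0.0}
    for combo in product(*(states[v] for v in evidence_nodes)):
        assignment = dict(zip(evidence_nodes, combo))
        p_pos = p_neg = 0.0
        for hcombo in product(*(states[v] for v in hidden)):
            full = {**assignment, **dict(zip(hidden, hcombo))}
            p_pos += joint_probability(bn, {**full, sb_node: positive})
            p_neg += joint_probability(bn, {**full, sb_node: neg})
        pred = positive if p_pos >= p_neg else neg
        mass[positive] += p_pos
        mass[neg] += p_neg
        correct[pred] += p_pos if pred == positive else p_neg
    sens = correct[positive] / mass[positive]
    spec = correct[neg] / mass[neg]
    return 0.5 * (sens + spec)


def random_network(n_nodes: int, seed: int = 0, max_card: int = 3,
                   edge_prob: float = 0.4, alpha: float = 1.0) -> BayesianNetwork:
    """A random DAG with Dirichlet-drawn CPTs, for inference stress tests.

    Node order is the topological order; each earlier->later arc is included
    independently with ``edge_prob``.  Smaller ``alpha`` gives more extreme
    rows.
    """
    rng = np.random.default_rng(seed)
    names = [f"v{i}" for i in range(n_nodes)]
    cards = rng.integers(2, max_card + 1, size=n_nodes)
    states = {names[i]: tuple(f"s{j}" for j in range(cards[i])) for i in range(n_nodes)}
    arcs = {(names[i], names[j])
            for i in range(n_nodes) for j in range(i + 1, n_nodes)
            if rng.random() < edge_prob}
    dag = DAG(states, arcs)
    cpts = {}
    for i, name in enumerate(names):
        parents = dag.parents(name)
        q = int(np.prod([len(states[p]) for p in parents])) if parents else 1
        rows = rng.dirichlet(np.full(cards[i], alpha), size=q)
        cpts[name] = CPT(name, parents, states, rows)
    return BayesianNetwork(dag, cpts)


def null_config(n: int = 650, seed: int = 0) -> GeneratorConfig:
    """Chance-level conditions: the SB label is independent of everything."""
    return GeneratorConfig(n=n, seed=seed, truth_network=default_truth_network(signal=False))
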