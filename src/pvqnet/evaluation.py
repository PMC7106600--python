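"""Cross-validated evaluation of the full screening pipeline.

Every fold refits the complete chain -- composite scoring, DEQ PCA, quantile
discretizers, structure search, CPT estimation -- on the training cases only,
then predicts the held-out cases, so no fitted quantity ever sees the case it
predicts.  Leave-one-out CV aggregates all N single-case predictions into one
confusion matrix; repeated stratified 10-fold CV yields an accuracy
distribution.  The metric set mirrors the standard caret-style report
(sensitivity .. balanced accuracy) with ``with_sb`` as the positive class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import questionnaire_io as qio
from .bayesnet import (ArcConstraints, DiscreteData, ScoreSpec, fit_cpts,
                       get_algorithm, posterior, UnsupportedAlgorithmError)
from .features import feature_states, fit_deq_pca, score_oq, score_rfl

#: Network variables used by the shipped synthetic study configuration.
STUDY_VARIABLES = ("age_band", "deq_quadrant", "rfl_level", "oq_level",
                   "oq8", "rfl25", "sb_group")


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.fn, self.tn):
            if v < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricSet:
    """The eleven confusion-matrix summaries of the standard fit report."""

    sensitivity: float
    specificity: float
    pos_pred_value: float
    neg_pred_value: float
    precision: float
    recall: float
    f1: float
    prevalence: float
    detection_rate: float
    detection_prevalence: float
    balanced_accuracy: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} is undefined (zero denominator); reporting NaN",
                      stacklevel=3)
        return math.nan
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Compute the metric set; undefined ratios come back as NaN + warning."""
    n = cm.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    sens = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    spec = _ratio(cm.tn, cm.tn + cm.fp, "specificity")
    ppv = _ratio(cm.tp, cm.tp + cm.fp, "pos_pred_value")
    npv = _ratio(cm.tn, cm.tn + cm.fn, "neg_pred_value")
    f1 = _ratio(2 * ppv * sens, ppv + sens, "f1") if not (math.isnan(ppv) or math.isnan(sens)) else math.nan
    return MetricSet(
        sensitivity=sens,
        specificity=spec,
        pos_pred_value=ppv,
        neg_pred_value=npv,
        precision=ppv,
        recall=sens,
        f1=f1,
        prevalence=(cm.tp + cm.fn) / n,
        detection_rate=cm.tp / n,
        detection_prevalence=(cm.tp + cm.fp) / n,
        balanced_accuracy=0.5 * (sens + spec),
    )


def default_constraints(variables: Sequence[str] = STUDY_VARIABLES) -> ArcConstraints:
    """Illustrative expert constraints: demographics exogenous, trait/state
    variables feed the SB node, and the SB label never causes a demographic
    or trait variable.  (The originally published expert graph exists only as
    a figure; this default is the package's own, editable stand-in.)"""
    variables = tuple(variables)
    whitelist = {(v, "sb_group") for v in ("deq_quadrant", "rfl_level", "oq_level")
                 if v in variables}
    blacklist = set()
    for v in variables:
        if v not in ("age_band",):
            blacklist.add((v, "age_band"))
    for v in ("age_band", "deq_quadrant", "rfl_level", "gender", "diagnosis",
              "children", "schooling", "cohabitation", "marital_status", "occupation"):
        if v in variables:
            blacklist.add(("sb_group", v))
    blacklist -= whitelist
    return ArcConstraints(whitelist=whitelist, blacklist=blacklist)


@dataclass
class PipelineConfig:
    """Everything the CV pipeline needs to be re-fit from scratch on a fold."""

    variables: tuple[str, ...] = STUDY_VARIABLES
    constraints: ArcConstraints | None = None
    score: ScoreSpec = field(default_factory=ScoreSpec)
    algorithm: str = "tabu"
    k: int = 3
    ess: float = 1.0
    threshold: float = 0.5
    refit_structure: bool = True
    age_bands: str = "study"
    sb_node: str = "sb_group"

    def resolved_constraints(self) -> ArcConstraints:
        if self.constraints is not None:
            return self.constraints
        return default_constraints(self.variables)


class _PipelineData:
    """Per-record raw material, precomputed once per cohort.

    Only the fold-dependent steps (PCA, discretizer edges, network) are redone
    per fold; per-record item composites do not depend on other records.
    """

    def __init__(self, records: Sequence[qio.PatientRecord], config: PipelineConfig):
        self.config = config
        self.n = len(records)
        self.ids = [r.patient_id for r in records]
        self.oq_mean = np.array([score_oq(r.oq_items)[0] for r in records])
        self.oq8 = np.array([r.oq_items[8] for r in records], dtype=np.int64)
        self.rfl_mean = np.array([score_rfl(r.rfl_items)[0] for r in records])
        self.rfl25 = np.array([r.rfl_items[25] for r in records], dtype=np.int64)
        self.deq = np.array([[r.deq_items[i] for i in qio.DEQ_ITEMS] for r in records],
                            dtype=float)
        self.states = feature_states(k=config.k, age_bands=config.age_bands)
        self.y = np.array([qio.derive_sb_group(r) for r in records])
        self.y_code = (self.y == qio.WITH_SB).astype(np.int64)
        self.fixed_codes: dict[str, np.ndarray] = {}
        for var in config.variables:
            if var in ("deq_quadrant", "oq_level", "rfl_level", "sb_group"):
                continue
            if var == "oq8":
                self.fixed_codes[var] = self.oq8
            elif var == "rfl25":
                self.fixed_codes[var] = self.rfl25 - 1
            else:
                sts = list(self.states[var])
                cat = pd.Categorical([getattr(r, var) for r in records], categories=sts)
                codes = np.asarray(cat.codes, dtype=np.int64)
                if (codes < 0).any():
                    raise ValueError(f"record value outside declared states for {var}")
                self.fixed_codes[var] = codes

    def fold_codes(self, train: np.ndarray) -> dict[str, np.ndarray]:
        """Codes for ALL records using transforms fitted on ``train`` only."""
        cfg = self.config
        codes = dict(self.fixed_codes)
        if "deq_quadrant" in cfg.variables:
            pca = fit_deq_pca(self.deq[train])
            z = (self.deq - pca.means) / pca.sds
            scores = z @ pca.loadings
            codes["deq_quadrant"] = (2 * (scores[:, 0] >= 0) + (scores[:, 1] >= 0)).astype(np.int64)
        if "oq_level" in cfg.variables:
            edges = np.quantile(self.oq_mean[train], np.arange(1, cfg.k) / cfg.k)
            codes["oq_level"] = np.searchsorted(edges, self.oq_mean, side="right")
        if "rfl_level" in cfg.variables:
            edges = np.quantile(self.rfl_mean[train], np.arange(1, cfg.k) / cfg.k)
            codes["rfl_level"] = np.searchsorted(edges, self.rfl_mean, side="right")
        codes["sb_group"] = self.y_code
        return codes

    def data_for(self, codes: dict[str, np.ndarray], rows: np.ndarray) -> DiscreteData:
        d = object.__new__(DiscreteData)
        d.states = {v: tuple(self.states[v]) for v in self.config.variables}
        d.codes = {v: codes[v][rows] for v in self.config.variables}
        d.n = int(rows.sum() if rows.dtype == bool else len(rows))
        d.card = {v: len(d.states[v]) for v in self.config.variables}
        return d

    def evidence_for(self, codes: dict[str, np.ndarray], i: int) -> dict:
        ev = {}
        for var in self.config.variables:
            if var == self.config.sb_node:
                continue
            ev[var] = self.states[var][codes[var][i]]
        return ev


def _fit_fold(pdat: _PipelineData, codes: dict, train: np.ndarray,
              fixed_arcs: set | None = None):
    cfg = pdat.config
    data = pdat.data_for(codes, train)
    if fixed_arcs is None:
        search = get_algorithm(cfg.algorithm)
        dag = search(data, constraints=cfg.resolved_constraints(), spec=cfg.score)
    else:
        from .bayesnet import DAG
        dag = DAG({v: tuple(pdat.states[v]) for v in cfg.variables}, set(fixed_arcs))
    return fit_cpts(dag, data, equivalent_sample_size=cfg.ess)


def _learn_full_structure(pdat: _PipelineData) -> set:
    all_rows = np.ones(pdat.n, dtype=bool)
    codes = pdat.fold_codes(all_rows)
    data = pdat.data_for(codes, all_rows)
    search = get_algorithm(pdat.config.algorithm)
    dag = search(data, constraints=pdat.config.resolved_constraints(),
                 spec=pdat.config.score)
    return set(dag.arcs)


def _confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    pos = qio.WITH_SB
    return ConfusionMatrix(
        tp=int(np.sum((y_pred == pos) & (y_true == pos))),
        fp=int(np.sum((y_pred == pos) & (y_true != pos))),
        fn=int(np.sum((y_pred != pos) & (y_true == pos))),
        tn=int(np.sum((y_pred != pos) & (y_true != pos))),
    )


def loocv(records: Sequence[qio.PatientRecord],
          config: PipelineConfig | None = None) -> tuple[MetricSet, pd.DataFrame]:
    """Leave-one-out CV: train on N-1 cases, predict the held-out case.

    Returns the pooled metric set and a per-case prediction frame
    (patient_id, true group, posterior risk, predicted group).
    """
    config = config or PipelineConfig()
    n = len(records)
    if n < 10:
        raise ValueError("LOOCV needs at least 10 cases")
    pdat = _PipelineData(records, config)
    if len(set(pdat.y)) < 2:
        raise ValueError("both SB groups must be present")
    fixed_arcs = None if config.refit_structure else _learn_full_structure(pdat)
    probs = np.full(n, np.nan)
    preds = np.empty(n, dtype=object)
    errors = np.empty(n, dtype=object)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        if len(set(pdat.y[train])) < 2:
            errors[i] = "training fold contains a single class"
            preds[i] = None
            continue
        codes = pdat.fold_codes(train)
        bn = _fit_fold(pdat, codes, train, fixed_arcs)
        dist = posterior(bn, config.sb_node, pdat.evidence_for(codes, i))
        p = dist[qio.WITH_SB]
        probs[i] = p
        preds[i] = qio.WITH_SB if p >= config.threshold else qio.WITHOUT_SB
        errors[i] = None
    ok = np.array([p is not None for p in preds])
    cm = _confusion_from_predictions(pdat.y[ok], np.array([p for p in preds[ok]]))
    frame = pd.DataFrame({
        "patient_id": pdat.ids,
        "sb_group": pdat.y,
        "risk_probability": probs,
        "predicted": preds,
        "error": errors,
    })
    return metrics(cm), frame


def _fold_assignments(y_code: np.ndarray, k: int, repeats: int, seed: int
                      ) -> list[np.ndarray]:
    """Stratified fold labels per repeat, reproducible given the seed."""
    assignments = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=(seed + r) % (2**31))
        folds = np.empty(y_code.size, dtype=np.int64)
        for f, (_, test_idx) in enumerate(skf.split(np.zeros_like(y_code), y_code)):
            folds[test_idx] = f
        assignments.append(folds)
    return assignments


def _kfold_accuracy(pdat: _PipelineData, folds: np.ndarray,
                    fixed_arcs: set | None) -> float:
    cfg = pdat.config
    y_pred = np.empty(pdat.n, dtype=object)
    for f in np.unique(folds):
        train = folds != f
        codes = pdat.fold_codes(train)
        bn = _fit_fold(pdat, codes, train, fixed_arcs)
        for i in np.flatnonzero(~train):
            dist = posterior(bn, cfg.sb_node, pdat.evidence_for(codes, i))
            p = dist[qio.WITH_SB]
            y_pred[i] = qio.WITH_SB if p >= cfg.threshold else qio.WITHOUT_SB
    cm = _confusion_from_predictions(pdat.y, np.array(list(y_pred)))
    return (cm.tp + cm.tn) / cm.n


def repeated_kfold(records: Sequence[qio.PatientRecord], k: int = 10,
                   repeats: int = 100, seed: int = 0,
                   config: PipelineConfig | None = None) -> dict:
    """Repeated stratified k-fold CV; per-repeat accuracy is pooled over folds."""
    config = config or PipelineConfig()
    if k > len(records):
        raise ValueError(f"k={k} exceeds cohort size {len(records)}")
    pdat = _PipelineData(records, config)
    if len(set(pdat.y)) < 2:
        raise ValueError("both SB groups must be present")
    fixed_arcs = None if config.refit_structure else _learn_full_structure(pdat)
    per_repeat = [
        _kfold_accuracy(pdat, folds, fixed_arcs)
        for folds in _fold_assignments(pdat.y_code, k, repeats, seed)
    ]
    arr = np.asarray(per_repeat)
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if repeats > 1 else 0.0,
        "per_repeat": [float(a) for a in arr],
        "k": k,
        "repeats": repeats,
        "seed": seed,
    }


def select_algorithm(records: Sequence[qio.PatientRecord],
                     algorithms: Sequence[str],
                     config: PipelineConfig | None = None,
                     k: int = 10, repeats: int = 10, seed: int = 0) -> dict:
    """Rank structure-search algorithms by CV classification error.

    All algorithms are evaluated on the same fold assignments; ranking is by
    mean error, ties broken by error variance.  Unsupported algorithm names
    are reported, never silently dropped.
    """
    config = config or PipelineConfig()
    base = _PipelineData(records, config)
    assignments = _fold_assignments(base.y_code, k, repeats, seed)
    results: dict[str, dict] = {}
    unsupported: list[str] = []
    for name in algorithms:
        try:
            get_algorithm(name)
        except UnsupportedAlgorithmError:
            unsupported.append(name)
            continue
        cfg = replace(config, algorithm=name)
        pdat = _PipelineData(records, cfg)
        fixed = None if cfg.refit_structure else _learn_full_structure(pdat)
        errs = np.array([1.0 - _kfold_accuracy(pdat, folds, fixed)
                         for folds in assignments])
        results[name] = {
            "mean_error": float(errs.mean()),
            "error_variance": float(errs.var(ddof=1)) if repeats > 1 else 0.0,
            "per_repeat_error": [float(e) for e in errs],
        }
    if not results:
        raise ValueError(f"no supported algorithm among {list(algorithms)}")
    ranking = sorted(results, key=lambda a: (results[a]["mean_error"],
                                             results[a]["error_variance"], a))
    return {"ranking": ranking, "results": results, "unsupported": unsupported,
            "k": k, "repeats": repeats, "seed": seed}
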