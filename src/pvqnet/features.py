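"""Item scoring, DEQ principal components and discretization.

The network operates on a small set of derived discrete variables rather than
the raw 25 answers:

* ``oq_mean`` -- mean of the four general OQ items after reverse-keying the
  positively worded ones (higher = more distress), with the suicidal-ideation
  item (OQ 8) kept as its own ordinal variable;
* ``rfl_mean`` -- mean of 13 reasons-for-living items (higher = more
  protective), with RFL 25 ("I'm too stable to kill myself") kept separate;
* two principal components of the six standardized DEQ items ("low
  self-esteem" and "interpersonal sensitivity") summarized as a sign quadrant;
* quantile-discretized levels of the two continuous composites.

All transforms are fitted on training data only and serialize to JSON so that
scoring is reproducible across processes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import questionnaire_io as qio
from .questionnaire_io import PatientRecord, derive_sb_group

#: OQ items whose printed scale runs 4..0: happiness/satisfaction wording,
#: reversed so that higher always means more distress.
OQ_REVERSED = frozenset({13, 24, 31})
#: Items entering the OQ composite (OQ 8 deliberately excluded).
OQ_COMPOSITE_ITEMS = (3, 13, 24, 31)
#: RFL item kept out of the composite.
RFL_SEPARATE = 25
RFL_COMPOSITE_ITEMS = tuple(i for i in qio.RFL_ITEMS if i != RFL_SEPARATE)

QUADRANTS = ("00", "01", "10", "11")
#: Index (within the DEQ item order) of item 19, whose loading is positive in
#: both retained components; used to fix the sign of each component.
_SIGN_ANCHOR = qio.DEQ_ITEMS.index(19)


class ScoringError(ValueError):
    """An item answer is missing or out of range at scoring time."""


class DegenerateInputError(ValueError):
    """Input without enough variation to fit a transform."""


def _check_items(items: Mapping[int, int], declared: Sequence[int],
                 lo: int, hi: int, label: str) -> None:
    for i in declared:
        if i not in items:
            raise ScoringError(f"missing {label} item {i}")
        v = items[i]
        if not lo <= v <= hi:
            raise ScoringError(f"{label} item {i} answer {v!r} outside {lo}..{hi}")


def score_oq(oq_items: Mapping[int, int]) -> tuple[float, int]:
    """Score the OQ block: (composite mean on 0..4, OQ8 answer unchanged).

    Items 13/24/31 are reverse-keyed (score = 4 - answer position); item 3 is
    scored as answered.  Higher scores mean more frequent distress.
    """
    _check_items(oq_items, qio.OQ_ITEMS, *qio.OQ_RANGE, label="oq")
    scored = [
        (4 - oq_items[i]) if i in OQ_REVERSED else oq_items[i]
        for i in OQ_COMPOSITE_ITEMS
    ]
    return float(np.mean(scored)), int(oq_items[8])


def score_rfl(rfl_items: Mapping[int, int]) -> tuple[float, int]:
    """Score the RFL block: (mean of the 13 composite items, RFL25 unchanged)."""
    _check_items(rfl_items, qio.RFL_ITEMS, *qio.RFL_RANGE, label="rfl")
    vals = [rfl_items[i] for i in RFL_COMPOSITE_ITEMS]
    return float(np.mean(vals)), int(rfl_items[RFL_SEPARATE])


@dataclass
class PCAModel:
    """Two retained principal components of the standardized DEQ items.

    ``loadings`` holds one unit-norm column per component; each component is
    oriented so the loading of DEQ item 19 is non-negative, which matches the
    construct direction of both published components without touching data.
    """

    item_order: tuple[int, ...]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray        # (n_items, 2)
    variance_proportions: np.ndarray  # (2,), eigenvalue / n_items

    def to_dict(self) -> dict:
        return {
            "item_order": list(self.item_order),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "variance_proportions": self.variance_proportions.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCAModel":
        return cls(
            item_order=tuple(d["item_order"]),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            variance_proportions=np.asarray(d["variance_proportions"], dtype=float),
        )


def fit_deq_pca(X: np.ndarray, item_order: Sequence[int] = qio.DEQ_ITEMS) -> PCAModel:
    """Correlation-matrix PCA of DEQ responses, retaining two components.

    Columns are standardized by the training mean and sd (ddof=1); components
    are right singular vectors of the standardized matrix, i.e. eigenvectors
    of the 6x6 correlation matrix ordered by decreasing eigenvalue.  Exactly
    two components are retained regardless of explained variance.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < p + 1:
        raise DegenerateInputError(f"need at least {p + 1} rows to fit PCA, got {n}")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        bad = [item_order[i] for i in np.flatnonzero(sds <= 0)]
        raise DegenerateInputError(f"constant DEQ column(s): items {bad}")
    Z = (X - means) / sds
    # SVD of the standardized matrix; eigenvalues of the correlation matrix
    # are s^2/(n-1).
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = s**2 / (n - 1)
    loadings = vt[:2].T.copy()
    for c in range(2):
        anchor = loadings[_SIGN_ANCHOR, c]
        if anchor < 0 or (anchor == 0 and loadings[np.argmax(np.abs(loadings[:, c])), c] < 0):
            loadings[:, c] = -loadings[:, c]
    return PCAModel(
        item_order=tuple(item_order),
        means=means,
        sds=sds,
        loadings=loadings,
        variance_proportions=eigvals[:2] / p,
    )


def project_deq(model: PCAModel, deq_items: Mapping[int, int]) -> tuple[float, float]:
    """Project one response vector onto the two retained components."""
    _check_items(deq_items, model.item_order, *qio.DEQ_RANGE, label="deq")
    x = np.array([deq_items[i] for i in model.item_order], dtype=float)
    z = (x - model.means) / model.sds
    s1, s2 = z @ model.loadings
    return float(s1), float(s2)


def assign_quadrant(pc1_score: float, pc2_score: float, threshold: float = 0.0) -> str:
    """Two-digit quadrant code: digit = 1 iff the score is >= threshold.

    ``10``/``11`` therefore read "low self-esteem" (high component-1 score) and
    the second digit "high interpersonal sensitivity".  The boundary goes to
    the high side.
    """
    if not (np.isfinite(pc1_score) and np.isfinite(pc2_score)):
        raise ValueError("quadrant scores must be finite")
    return f"{int(pc1_score >= threshold)}{int(pc2_score >= threshold)}"


def fit_discretizer(values: Iterable[float], k: int) -> np.ndarray:
    """Empirical-quantile bin edges (k-1 interior edges) for k ordinal levels."""
    values = np.asarray(list(values), dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.unique(values).size < k:
        raise DegenerateInputError(
            f"need at least {k} distinct values to fit {k} bins, got {np.unique(values).size}"
        )
    return np.quantile(values, np.arange(1, k) / k)


def apply_discretizer(edges: np.ndarray, value: float | np.ndarray) -> int | np.ndarray:
    """Map value(s) to levels 1..k; intervals are left-closed, ends clamp."""
    edges = np.asarray(edges, dtype=float)
    level = np.searchsorted(edges, value, side="right") + 1
    if np.isscalar(value) or np.ndim(value) == 0:
        return int(level)
    return level.astype(int)


@dataclass
class FeatureTransforms:
    """All fitted state needed to turn raw records into network features."""

    pca: PCAModel
    oq_edges: np.ndarray
    rfl_edges: np.ndarray
    k: int = 3
    quadrant_threshold: float = 0.0
    oq_reversed: tuple[int, ...] = tuple(sorted(OQ_REVERSED))

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "pca": self.pca.to_dict(),
            "oq_edges": np.asarray(self.oq_edges).tolist(),
            "rfl_edges": np.asarray(self.rfl_edges).tolist(),
            "k": self.k,
            "quadrant_threshold": self.quadrant_threshold,
            "oq_reversed": list(self.oq_reversed),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FeatureTransforms":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            pca=PCAModel.from_dict(d["pca"]),
            oq_edges=np.asarray(d["oq_edges"], dtype=float),
            rfl_edges=np.asarray(d["rfl_edges"], dtype=float),
            k=int(d["k"]),
            quadrant_threshold=float(d["quadrant_threshold"]),
            oq_reversed=tuple(d["oq_reversed"]),
        )


def fit_transforms(records: Sequence[PatientRecord], k: int = 3,
                   quadrant_threshold: float = 0.0) -> FeatureTransforms:
    """Fit PCA and both composite discretizers on a training cohort."""
    deq = np.array([[r.deq_items[i] for i in qio.DEQ_ITEMS] for r in records], dtype=float)
    pca = fit_deq_pca(deq)
    oq_means = [score_oq(r.oq_items)[0] for r in records]
    rfl_means = [score_rfl(r.rfl_items)[0] for r in records]
    return FeatureTransforms(
        pca=pca,
        oq_edges=fit_discretizer(oq_means, k),
        rfl_edges=fit_discretizer(rfl_means, k),
        k=k,
        quadrant_threshold=quadrant_threshold,
    )


#: Discrete feature columns (with their state sets) that can enter the network.
def feature_states(k: int = 3, age_bands: str | Sequence[str] = "instrument") -> dict[str, tuple]:
    bands = qio.resolve_age_bands(age_bands)
    return {
        "oq_level": tuple(range(1, k + 1)),
        "oq8": tuple(range(0, 5)),
        "rfl_level": tuple(range(1, k + 1)),
        "rfl25": tuple(range(1, 7)),
        "deq_quadrant": QUADRANTS,
        "diagnosis": qio.DIAGNOSES,
        "children": qio.CHILDREN,
        "gender": qio.GENDERS,
        "age_band": bands,
        "schooling": qio.SCHOOLING,
        "cohabitation": qio.COHABITATION,
        "marital_status": qio.MARITAL_STATUS,
        "occupation": qio.OCCUPATIONS,
        "sb_group": (qio.WITHOUT_SB, qio.WITH_SB),
    }


def build_feature_table(records: Sequence[PatientRecord],
                        transforms: FeatureTransforms) -> pd.DataFrame:
    """One feature row per record; deterministic given the fitted transforms."""
    rows = []
    for rec in records:
        try:
            oq_mean, oq8 = score_oq(rec.oq_items)
            rfl_mean, rfl25 = score_rfl(rec.rfl_items)
            s1, s2 = project_deq(transforms.pca, rec.deq_items)
        except ScoringError as exc:
            raise ScoringError(f"{rec.patient_id}: {exc}") from exc
        row = {
            "patient_id": rec.patient_id,
            "oq_mean": oq_mean,
            "oq8": oq8,
            "rfl_mean": rfl_mean,
            "rfl25": rfl25,
            "pc1_score": s1,
            "pc2_score": s2,
            "deq_quadrant": assign_quadrant(s1, s2, transforms.quadrant_threshold),
            "oq_level": apply_discretizer(transforms.oq_edges, oq_mean),
            "rfl_level": apply_discretizer(transforms.rfl_edges, rfl_mean),
        }
        for fld in qio.DEMOGRAPHIC_FIELDS:
            row[fld] = getattr(rec, fld)
        row["sb_group"] = derive_sb_group(rec)
        rows.append(row)
    return pd.DataFrame(rows)
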