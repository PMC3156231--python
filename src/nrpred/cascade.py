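"""Two-level prediction cascade and its evaluation protocol.

Level 1 decides whether a query protein is a nuclear receptor (NR) or not
(NONNR); queries identified as NR continue to level 2, which assigns one of
the subfamilies.  Evaluation follows the jackknife (leave-one-out) protocol
with per-class accuracy, one-vs-rest Matthews correlation coefficients and
confusion quadrants, plus a 2-D grid search over the FKNN parameters (K, m)
that maximizes the overall jackknife success rate.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import fknn
from .descriptors import PropertyScale, load_property_scales
from .errors import LeakageError, ParameterError
from .fknn import FknnParams, ReferenceSet, _decide, _profiles
from .fusion import FusionWeights, featurize, featurize_records, mode_columns
from .sequence_io import PredictionResult, ProteinRecord

logger = logging.getLogger(__name__)

NR_CLASS = "NR"
NONNR_CLASS = "NONNR"
_SUBFAMILY = re.compile(r"^NR\d+$")

MODEL_FORMAT_VERSION = 1


def level1_label(label: str) -> str:
    """Collapse a subfamily tag to the binary NR / NONNR attribute."""
    if label == NONNR_CLASS:
        return NONNR_CLASS
    if _SUBFAMILY.match(label or ""):
        return NR_CLASS
    raise ParameterError(f"unrecognized class label {label!r}")


# ---------------------------------------------------------------------------
# evaluation report


@dataclass(frozen=True)
class ConfusionQuadrants:
    """One-vs-rest confusion counts for a single class."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def mcc(q: ConfusionQuadrants) -> float:
    """Matthews correlation coefficient of one confusion table.

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); by convention 0
    when any marginal factor is zero (flagged in the evaluation report).
    """
    tp, fp, tn, fn = (float(v) for v in (q.TP, q.FP, q.TN, q.FN))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


@dataclass
class EvaluationReport:
    """Per-class and overall accuracy, per-class MCC, confusion quadrants."""

    classes: list[str]
    per_class_n: dict[str, int]
    per_class_accuracy: dict[str, Optional[float]]
    per_class_mcc: dict[str, Optional[float]]
    overall_accuracy: float
    quadrants: dict[str, ConfusionQuadrants]
    degenerate_mcc: list[str]
    not_applicable: list[str]
    n_evaluated: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.classes:
            q = self.quadrants[c]
            rows.append(
                {
                    "class": c,
                    "n": self.per_class_n[c],
                    "accuracy": self.per_class_accuracy[c],
                    "TP": q.TP,
                    "FP": q.FP,
                    "TN": q.TN,
                    "FN": q.FN,
                    "MCC": self.per_class_mcc[c],
                }
            )
        rows.append(
            {
                "class": "overall",
                "n": self.n_evaluated,
                "accuracy": self.overall_accuracy,
                "TP": None,
                "FP": None,
                "TN": None,
                "FN": None,
                "MCC": None,
            }
        )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "overall_accuracy": self.overall_accuracy,
            "n_evaluated": self.n_evaluated,
            "classes": {
                c: {
                    "n": self.per_class_n[c],
                    "accuracy": self.per_class_accuracy[c],
                    "mcc": self.per_class_mcc[c],
                    "quadrants": vars(self.quadrants[c]),
                }
                for c in self.classes
            },
            "degenerate_mcc": self.degenerate_mcc,
            "not_applicable": self.not_applicable,
        }
        return json.dumps(payload, indent=2)


def build_report(
    true_idx: np.ndarray, pred_idx: np.ndarray, classes: Sequence[str]
) -> EvaluationReport:
    """Assemble an :class:`EvaluationReport` from class-index arrays."""
    true_idx = np.asarray(true_idx)
    pred_idx = np.asarray(pred_idx)
    n = true_idx.size
    per_n: dict[str, int] = {}
    per_acc: dict[str, Optional[float]] = {}
    per_mcc: dict[str, Optional[float]] = {}
    quadrants: dict[str, ConfusionQuadrants] = {}
    degenerate: list[str] = []
    not_applicable: list[str] = []
    for i, c in enumerate(classes):
        is_true = true_idx == i
        is_pred = pred_idx == i
        q = ConfusionQuadrants(
            TP=int(np.sum(is_true & is_pred)),
            FP=int(np.sum(~is_true & is_pred)),
            TN=int(np.sum(~is_true & ~is_pred)),
            FN=int(np.sum(is_true & ~is_pred)),
        )
        quadrants[c] = q
        per_n[c] = int(is_true.sum())
        if per_n[c] == 0:
            not_applicable.append(c)
            per_acc[c] = None
            per_mcc[c] = None
            continue
        per_acc[c] = float(q.TP / per_n[c])
        value = mcc(q)
        denom = (q.TP + q.FP) * (q.TP + q.FN) * (q.TN + q.FP) * (q.TN + q.FN)
        if denom == 0:
            degenerate.append(c)
        per_mcc[c] = float(value)
    return EvaluationReport(
        classes=list(classes),
        per_class_n=per_n,
        per_class_accuracy=per_acc,
        per_class_mcc=per_mcc,
        overall_accuracy=float(np.mean(true_idx == pred_idx)),
        quadrants=quadrants,
        degenerate_mcc=degenerate,
        not_applicable=not_applicable,
        n_evaluated=int(n),
    )


# ---------------------------------------------------------------------------
# jackknife and grid search


def _loo_neighbor_tables(X: np.ndarray, k_max: int):
    """Leave-one-out neighbor distances/indices, each row excluding itself."""
    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")[:, :k_max]
    dists = np.take_along_axis(D, order, axis=1)
    return dists, order


def _loo_predict(
    dists: np.ndarray,
    order: np.ndarray,
    label_indices: np.ndarray,
    n_classes: int,
    params: FknnParams,
) -> np.ndarray:
    nbr = label_indices[order[:, : params.K]]
    prof = _profiles(dists[:, : params.K], nbr, n_classes, params.m)
    return _decide(prof, nbr[:, 0])


def jackknife(ref: ReferenceSet, params: FknnParams) -> EvaluationReport:
    """Leave-one-out evaluation: each sample predicted with itself removed."""
    if params.K >= ref.n:
        raise ParameterError(
            f"K={params.K} must be < reference size {ref.n} for the jackknife"
        )
    dists, order = _loo_neighbor_tables(ref.X, params.K)
    pred = _loo_predict(dists, order, ref.label_indices, len(ref.classes), params)
    return build_report(ref.label_indices, pred, ref.classes)


@dataclass(frozen=True)
class GridSearchResult:
    """Jackknife accuracy surface over (K, m) and the best grid point."""

    grid: dict[tuple[int, float], float]
    best: tuple[int, float]
    best_accuracy: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"K": k, "m": m, "accuracy": acc} for (k, m), acc in self.grid.items()
        ]
        return pd.DataFrame(rows)


def grid_search(
    ref: ReferenceSet,
    K_values: Sequence[int],
    m_values: Sequence[float],
) -> GridSearchResult:
    """Jackknife the reference set at every (K, m); ties resolve to the
    smallest K, then the smallest m."""
    K_values = sorted(set(int(k) for k in K_values))
    m_values = sorted(set(float(m) for m in m_values))
    if not K_values or not m_values:
        raise ParameterError("K and m grids must be non-empty")
    if K_values[0] < 1 or any(k >= ref.n for k in K_values):
        raise ParameterError(
            f"all K must be in [1, {ref.n - 1}] for a reference of size {ref.n}"
        )
    if m_values[0] <= 1:
        raise ParameterError("all m must be > 1")
    dists, order = _loo_neighbor_tables(ref.X, max(K_values))
    grid: dict[tuple[int, float], float] = {}
    best = None
    best_acc = -1.0
    for K in K_values:
        for m in m_values:
            params = FknnParams(K=K, m=m)
            pred = _loo_predict(
                dists, order, ref.label_indices, len(ref.classes), params
            )
            acc = float(np.mean(pred == ref.label_indices))
            grid[(K, m)] = acc
            if acc > best_acc:
                best, best_acc = (K, m), acc
    return GridSearchResult(grid=grid, best=best, best_accuracy=best_acc)


# ---------------------------------------------------------------------------
# the two-level cascade


@dataclass
class CascadeModel:
    """Level-1 (NR vs NONNR) and level-2 (subfamily) reference sets with
    their FKNN parameters, sharing one feature configuration."""

    level1: ReferenceSet
    level2: ReferenceSet
    params1: FknnParams
    params2: FknnParams
    weights: FusionWeights
    scales: tuple[PropertyScale, ...]


def train_cascade(
    records: Sequence[ProteinRecord],
    params1: FknnParams = FknnParams(),
    params2: FknnParams = FknnParams(),
    weights: FusionWeights = FusionWeights(),
    scales: Optional[Sequence[PropertyScale]] = None,
) -> CascadeModel:
    """Build both reference sets from validated, labeled records.

    The level-2 reference contains exactly the NR-labeled proteins of the
    level-1 NR class, with their subfamily tags.
    """
    if scales is None:
        scales = load_property_scales()
    scales = tuple(scales)
    labels = [r.label for r in records]
    if any(l is None for l in labels):
        raise ParameterError("training records must all carry class labels")
    X = featurize_records(records, weights, scales)
    l1 = [level1_label(l) for l in labels]
    ids = [r.identifier for r in records]
    seqs = [r.sequence for r in records]
    level1 = ReferenceSet(
        X, l1, classes=[NR_CLASS, NONNR_CLASS], identifiers=ids, sequences=seqs
    )
    nr_mask = np.array([l == NR_CLASS for l in l1])
    level2 = ReferenceSet(
        X[nr_mask],
        [l for l, keep in zip(labels, nr_mask) if keep],
        identifiers=[i for i, keep in zip(ids, nr_mask) if keep],
        sequences=[s for s, keep in zip(seqs, nr_mask) if keep],
    )
    return CascadeModel(level1, level2, params1, params2, weights, scales)


def predict_two_level(model: CascadeModel, query: ProteinRecord) -> PredictionResult:
    """Route one validated query through both levels of the cascade."""
    vec = featurize(query, model.weights, model.scales).values
    label1, mem1 = fknn.predict(vec, model.level1, model.params1)
    if label1 == NONNR_CLASS:
        return PredictionResult(query.identifier, label1, mem1)
    label2, mem2 = fknn.predict(vec, model.level2, model.params2)
    return PredictionResult(query.identifier, label1, mem1, label2, mem2)


def predict_two_level_batch(
    model: CascadeModel, queries: Sequence[ProteinRecord]
) -> list[PredictionResult]:
    """Batch prediction; per-record failures are logged and skipped."""
    results: list[PredictionResult] = []
    for rec in queries:
        try:
            results.append(predict_two_level(model, rec))
        except Exception as exc:  # noqa: BLE001 — batch must continue
            logger.warning("prediction failed for %s: %s", rec.identifier, exc)
    return results


def two_level_jackknife(
    records: Sequence[ProteinRecord],
    params1: FknnParams = FknnParams(),
    params2: FknnParams = FknnParams(),
    weights: FusionWeights = FusionWeights(),
    scales: Optional[Sequence[PropertyScale]] = None,
) -> EvaluationReport:
    """Leave-one-out evaluation of the full cascade.

    Each sample is routed through level 1 (and, when identified as NR,
    level 2) with itself removed from every reference set it appears in.
    The report is over the final labels: the subfamilies plus NONNR.
    """
    if scales is None:
        scales = load_property_scales()
    labels = [r.label for r in records]
    if any(l is None for l in labels):
        raise ParameterError("records must all carry class labels")
    X = featurize_records(records, weights, scales)
    n = len(records)
    l1_idx = np.array(
        [0 if level1_label(l) == NR_CLASS else 1 for l in labels], dtype=np.intp
    )

    # level 1, leave-one-out over the combined set
    d1, o1 = _loo_neighbor_tables(X, params1.K)
    pred1 = _loo_predict(d1, o1, l1_idx, 2, params1)

    # level 2 reference: the NR-labeled samples
    nr_rows = np.nonzero(l1_idx == 0)[0]
    if nr_rows.size < 2:
        raise ParameterError("need at least 2 NR-labeled records for level 2")
    sub_labels = [labels[i] for i in nr_rows]
    sub_classes = list(dict.fromkeys(sub_labels))
    sub_index = {c: i for i, c in enumerate(sub_classes)}
    sub_idx = np.array([sub_index[l] for l in sub_labels], dtype=np.intp)
    X2 = X[nr_rows]

    # NR members: leave-one-out within the subfamily reference
    d2, o2 = _loo_neighbor_tables(X2, params2.K)
    pred2_nr = _loo_predict(d2, o2, sub_idx, len(sub_classes), params2)

    # non-NR samples mistaken for NR at level 1: full subfamily reference
    ref2 = ReferenceSet(X2, sub_labels, classes=sub_classes)
    final_classes = sub_classes + [NONNR_CLASS]
    nonnr_final = len(final_classes) - 1
    true_final = np.array(
        [sub_index.get(l, nonnr_final) for l in labels], dtype=np.intp
    )
    pred_final = np.full(n, nonnr_final, dtype=np.intp)
    nr_pos = {row: j for j, row in enumerate(nr_rows)}
    routed = np.nonzero(pred1 == 0)[0]
    outside = [i for i in routed if i not in nr_pos]
    if outside:
        dec, _ = fknn.predict_batch(X[outside], ref2, params2)
        for i, d in zip(outside, dec):
            pred_final[i] = d
    for i in routed:
        if i in nr_pos:
            pred_final[i] = pred2_nr[nr_pos[i]]
    return build_report(true_final, pred_final, final_classes)


def independent_test(
    model: CascadeModel, test: Sequence[ProteinRecord], level: int
) -> EvaluationReport:
    """Evaluate labeled test records against a trained cascade level.

    Refuses to run if any test identifier or exact sequence occurs in the
    model's reference sets (leakage).  Level 1 scores NR vs NONNR over all
    records; level 2 scores the subfamily assignment over the NR-labeled
    records only.  Classes absent from the test set are reported as not
    applicable.
    """
    if level not in (1, 2):
        raise ParameterError(f"level must be 1 or 2, got {level}")
    labels = [r.label for r in test]
    if any(l is None for l in labels):
        raise ParameterError("test records must all carry class labels")
    train_ids = set(model.level1.identifiers or [])
    train_seqs = set(model.level1.sequences or [])
    bad_ids = sorted({r.identifier for r in test} & train_ids)
    bad_seqs = sorted(
        {r.identifier for r in test if r.sequence in train_seqs} - set(bad_ids)
    )
    if bad_ids or bad_seqs:
        raise LeakageError(
            "test records overlap the training reference set "
            f"(identifiers: {bad_ids}; identical sequences: {bad_seqs})"
        )
    if level == 1:
        ref = model.level1
        params = model.params1
        eval_records = list(test)
        true = [level1_label(l) for l in labels]
    else:
        ref = model.level2
        params = model.params2
        eval_records = [r for r in test if level1_label(r.label) == NR_CLASS]
        if not eval_records:
            raise ParameterError("no NR-labeled records in the test set")
        true = [r.label for r in eval_records]
    X = featurize_records(eval_records, model.weights, model.scales)
    pred_idx, _ = fknn.predict_batch(X, ref, params)
    classes = list(ref.classes)
    index = {c: i for i, c in enumerate(classes)}
    extra = [l for l in true if l not in index]
    for l in dict.fromkeys(extra):
        index[l] = len(classes)
        classes.append(l)
    true_idx = np.array([index[l] for l in true], dtype=np.intp)
    return build_report(true_idx, pred_idx, classes)


def feature_ablation(
    records: Sequence[ProteinRecord],
    modes: Sequence[str],
    K_values: Sequence[int],
    m_values: Sequence[float],
    weights: FusionWeights = FusionWeights(),
    scales: Optional[Sequence[PropertyScale]] = None,
) -> pd.DataFrame:
    """Best jackknife accuracy per descriptor subset, (K, m) re-optimized
    per mode by grid search.  Returns a table with columns mode, n_features,
    K, m, accuracy."""
    if scales is None:
        scales = load_property_scales()
    labels = [r.label for r in records]
    if any(l is None for l in labels):
        raise ParameterError("records must all carry class labels")
    X = featurize_records(records, weights, scales)
    rows = []
    for mode in modes:
        cols = mode_columns(mode)  # raises ParameterError on unknown mode
        ref = ReferenceSet(X[:, cols], list(labels))
        result = grid_search(ref, K_values, m_values)
        rows.append(
            {
                "mode": mode,
                "n_features": int(cols.size),
                "K": result.best[0],
                "m": result.best[1],
                "accuracy": result.best_accuracy,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model serialization


def save_model(model: CascadeModel, path) -> None:
    """Write a cascade model as a single self-describing .npz archive."""
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "params1": {"K": model.params1.K, "m": model.params1.m},
        "params2": {"K": model.params2.K, "m": model.params2.m},
        "weights": {
            "w_dc": model.weights.w_dc,
            "w_cf": model.weights.w_cf,
            "w_fsc": model.weights.w_fsc,
        },
        "classes1": model.level1.classes,
        "classes2": model.level2.classes,
        "scales": {
            s.name: {a: s.raw_values[a] for a in sorted(s.raw_values)}
            for s in model.scales
        },
        "scale_order": [s.name for s in model.scales],
    }
    np.savez(
        path,
        meta=np.array(json.dumps(meta)),
        X1=model.level1.X,
        labels1=np.array(model.level1.labels),
        ids1=np.array(model.level1.identifiers or []),
        seqs1=np.array(model.level1.sequences or []),
        X2=model.level2.X,
        labels2=np.array(model.level2.labels),
        ids2=np.array(model.level2.identifiers or []),
        seqs2=np.array(model.level2.sequences or []),
    )


def load_model(path) -> CascadeModel:
    """Read a cascade model written by :func:`save_model`."""
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        if meta.get("format_version") != MODEL_FORMAT_VERSION:
            raise ParameterError(
                f"unsupported model format version {meta.get('format_version')!r}"
            )
        scales = tuple(
            PropertyScale(name, meta["scales"][name]) for name in meta["scale_order"]
        )
        level1 = ReferenceSet(
            archive["X1"],
            [str(l) for l in archive["labels1"]],
            classes=list(meta["classes1"]),
            identifiers=[str(i) for i in archive["ids1"]],
            sequences=[str(s) for s in archive["seqs1"]],
        )
        level2 = ReferenceSet(
            archive["X2"],
            [str(l) for l in archive["labels2"]],
            classes=list(meta["classes2"]),
            identifiers=[str(i) for i in archive["ids2"]],
            sequences=[str(s) for s in archive["seqs2"]],
        )
        return CascadeModel(
            level1,
            level2,
            FknnParams(**meta["params1"]),
            FknnParams(**meta["params2"]),
            FusionWeights(**meta["weights"]),
            scales,
        )
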