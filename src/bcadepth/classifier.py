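"""Linear-SVM voxel classification with recursive feature elimination.

Training voxels (tumor = positive class, wall = negative class) are
z-score normalized per column and fed to a linear-kernel SVM (libsvm via
scikit-learn, C default 1.0).  Feature selection is SVM-RFE: refit, drop
the ``step`` columns with the smallest absolute weight, repeat; the subset
size is chosen by the peak of the stratified fivefold cross-validated
accuracy over a grid of candidate sizes (smallest size on ties).

Class probabilities come from a Platt sigmoid p = 1/(1+exp(A f + B)) fitted
on the training decision values f.  Segmentation thresholds the probability
map at 0.5 ("hard boundary", followed by largest-connected-component and
hole-filling postprocessing); voxels with 0.1 <= p <= 0.9 form the "soft
boundary", the mixed tumor/wall interface zone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import Mask

__all__ = ["SVMModel", "RFEResult", "ProbabilityMap", "SegmentationResult",
           "SVMRFE", "train_svm", "rfe_rank", "select_optimal",
           "predict_probability", "probability_map", "hard_segment",
           "soft_boundary", "dice"]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _platt_fit(f: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit the Platt sigmoid p = 1/(1+exp(A f + B)) by regularized MLE.

    Targets are smoothed as in Platt (1999): t+ = (N+ + 1)/(N+ + 2),
    t- = 1/(N- + 2).
    """
    y = np.asarray(y).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    t = np.where(y, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(ab):
        a, b = ab
        z = a * f + b
        # -sum [ t*log(p) + (1-t)*log(1-p) ],  p = sigmoid(-z)
        return float(np.sum(t * np.logaddexp(0.0, z)
                            + (1 - t) * np.logaddexp(0.0, -z)))

    b0 = np.log((n_neg + 1.0) / (n_pos + 1.0))
    res = optimize.minimize(nll, x0=np.array([-1.0, b0]), method="BFGS")
    return float(res.x[0]), float(res.x[1])


@dataclass
class SVMModel:
    """A fitted, Platt-calibrated linear SVM over named feature columns."""

    pipeline: Pipeline
    columns: list
    platt_a: float
    platt_b: float

    @property
    def weights(self) -> np.ndarray:
        """Weight vector in normalized feature space."""
        return self.pipeline.named_steps["svc"].coef_[0].copy()

    def _check_columns(self, X):
        if isinstance(X, pd.DataFrame):
            if list(X.columns) != list(self.columns):
                missing = [c for c in self.columns if c not in X.columns]
                extra = [c for c in X.columns if c not in self.columns]
                raise ValueError(
                    f"feature columns do not match the model: missing "
                    f"{missing[:5]}, unexpected {extra[:5]}")
            return X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.columns):
            raise ValueError(
                f"expected {len(self.columns)} feature columns, got {X.shape[1]}")
        return X

    def decision_function(self, X) -> np.ndarray:
        return self.pipeline.decision_function(self._check_columns(X))

    def predict_proba(self, X) -> np.ndarray:
        """P(tumor) per row, in [0, 1]."""
        f = self.decision_function(X)
        z = self.platt_a * f + self.platt_b
        return 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)

    def to_json(self) -> str:
        scaler = self.pipeline.named_steps["scale"]
        svc = self.pipeline.named_steps["svc"]
        # linear decision function recovered as w.x + b in scaled space
        w = svc.coef_[0]
        payload = {
            "columns": [c.item() if hasattr(c, "item") else c
                        for c in self.columns],
            "scale_mean": scaler.mean_.tolist(),
            "scale_std": scaler.scale_.tolist(),
            "w": w.tolist(),
            "b": float(svc.intercept_[0]),
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
            "C": float(svc.C),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "_LinearSVMModel":
        d = json.loads(text)
        return _LinearSVMModel(
            columns=d["columns"],
            mean=np.asarray(d["scale_mean"]), std=np.asarray(d["scale_std"]),
            w=np.asarray(d["w"]), b=float(d["b"]),
            platt_a=float(d["platt_a"]), platt_b=float(d["platt_b"]))


@dataclass
class _LinearSVMModel:
    """Deserialized linear model (decision function + Platt sigmoid)."""

    columns: list
    mean: np.ndarray
    std: np.ndarray
    w: np.ndarray
    b: float
    platt_a: float
    platt_b: float

    _check_columns = SVMModel._check_columns

    def decision_function(self, X) -> np.ndarray:
        X = self._check_columns(X)
        return ((X - self.mean) / self.std) @ self.w + self.b

    predict_proba = SVMModel.predict_proba
    predict = SVMModel.predict


def _as_xy(X, y):
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else \
        list(range(np.asarray(X).shape[1]))
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else \
        np.asarray(X, dtype=float)
    ya = np.asarray(y).astype(int).ravel()
    if Xa.shape[0] != ya.shape[0]:
        raise ValueError("X and y length mismatch")
    if not np.isfinite(Xa).all():
        raise ValueError("X contains non-finite values")
    if len(np.unique(ya)) < 2:
        raise ValueError("training labels contain a single class")
    return Xa, ya, cols


def _svm_pipeline(C: float) -> Pipeline:
    return Pipeline([("scale", StandardScaler()),
                     ("svc", SVC(kernel="linear", C=C))])


def train_svm(X, y, C: float = 1.0) -> SVMModel:
    """Fit the z-score + linear-SVM pipeline and its Platt calibration."""
    Xa, ya, cols = _as_xy(X, y)
    pipe = _svm_pipeline(C)
    pipe.fit(Xa, ya)
    f = pipe.decision_function(Xa)
    a, b = _platt_fit(f, ya)
    return SVMModel(pipe, cols, a, b)


def rfe_rank(X, y, step: int = 1, C: float = 1.0) -> np.ndarray:
    """SVM-RFE ranking: refit, eliminate the ``step`` columns with the
    smallest |w|, repeat until one survives.  Best column first.

    Ties on |w| are broken by eliminating the highest column index.
    """
    Xa, ya, _ = _as_xy(X, y)
    n = Xa.shape[1]
    if n < 2:
        raise ValueError("need at least 2 feature columns")
    if step < 1 or step >= n:
        raise ValueError(f"step must be in [1, n_columns), got {step}")
    cols = np.arange(n)
    eliminated = []
    while len(cols) > 1:
        pipe = _svm_pipeline(C)
        pipe.fit(Xa[:, cols], ya)
        w = np.abs(pipe.named_steps["svc"].coef_[0])
        # sort worst-first: smallest |w|; ties -> highest column index first
        order = np.lexsort((-cols, w))
        k = min(step, len(cols) - 1)
        drop = order[:k]
        eliminated.extend(cols[drop].tolist())
        cols = np.delete(cols, drop)
    ranking = np.array(list(cols) + eliminated[::-1], dtype=int)
    return ranking


@dataclass
class RFEResult:
    """Ranking plus the cross-validated subset-size selection."""

    ranking: np.ndarray
    grid: list
    cv_accuracy_curve: np.ndarray
    optimal_n: int
    optimal_columns: list
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    model: SVMModel


def _training_metrics(model, Xa, ya):
    p = model.predict_proba(Xa)
    pred = (p >= 0.5).astype(int)
    pos, neg = ya == 1, ya == 0
    sens = float((pred[pos] == 1).mean()) if pos.any() else float("nan")
    spec = float((pred[neg] == 0).mean()) if neg.any() else float("nan")
    acc = float((pred == ya).mean())
    auc = float(roc_auc_score(ya, model.decision_function(Xa)))
    return sens, spec, acc, auc


def select_optimal(X, y, ranking, folds: int = 5, grid=None, C: float = 1.0,
                   seed: int = 0) -> RFEResult:
    """Choose the subset size by peak mean k-fold CV accuracy.

    ``grid`` is the list of candidate sizes N (default: a geometric grid up
    to the column count); the optimal N is the smallest argmax.  Also
    reports training sensitivity/specificity/accuracy/AUC of the final
    model fitted on the optimal columns.
    """
    Xa, ya, cols = _as_xy(X, y)
    ranking = np.asarray(ranking, dtype=int)
    n = Xa.shape[1]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if grid is None:
        grid = np.unique(np.round(np.geomspace(1, n, num=min(n, 15)))
                         .astype(int)).tolist()
    grid = sorted(int(g) for g in grid)
    if grid[0] < 1 or grid[-1] > n:
        raise ValueError(f"grid must lie within [1, {n}]")
    class_counts = np.bincount(ya)
    if class_counts.min() < folds:
        raise ValueError("too few samples per class for stratified folding")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Xa, ya))
    curve = np.empty(len(grid))
    for gi, N in enumerate(grid):
        sub = ranking[:N]
        accs = []
        for tr, te in splits:
            pipe = _svm_pipeline(C)
            pipe.fit(Xa[np.ix_(tr, sub)], ya[tr])
            accs.append((pipe.predict(Xa[np.ix_(te, sub)]) == ya[te]).mean())
        curve[gi] = np.mean(accs)
    best = int(np.argmax(curve))  # first (=smallest N) on exact ties
    optimal_n = grid[best]
    sub = ranking[:optimal_n]
    sub_cols = [cols[i] for i in sub]
    Xsub = pd.DataFrame(Xa[:, sub], columns=sub_cols) \
        if isinstance(X, pd.DataFrame) else Xa[:, sub]
    model = train_svm(Xsub, ya, C=C)
    sens, spec, acc, auc = _training_metrics(model, Xa[:, sub], ya)
    return RFEResult(ranking, grid, curve, optimal_n, sub_cols,
                     sens, spec, acc, auc, model)


class SVMRFE(BaseEstimator):
    """sklearn-style selector+classifier wrapping SVM-RFE.

    ``fit`` computes the RFE ranking, the CV accuracy curve over ``grid``
    and the final Platt-calibrated model on the optimal subset; exposes
    ``ranking_``, ``cv_scores_``, ``n_features_``, ``support_``,
    ``result_``.  ``transform`` selects the optimal columns;
    ``predict``/``predict_proba`` delegate to the fitted model.
    """

    def __init__(self, C: float = 1.0, step: int = 1, folds: int = 5,
                 grid=None, seed: int = 0):
        self.C = C
        self.step = step
        self.folds = folds
        self.grid = grid
        self.seed = seed

    def fit(self, X, y):
        ranking = rfe_rank(X, y, step=self.step, C=self.C)
        res = select_optimal(X, y, ranking, folds=self.folds, grid=self.grid,
                             C=self.C, seed=self.seed)
        self.result_ = res
        self.ranking_ = res.ranking
        self.cv_scores_ = res.cv_accuracy_curve
        self.n_features_ = res.optimal_n
        n = np.asarray(X).shape[1] if not isinstance(X, pd.DataFrame) \
            else X.shape[1]
        self.support_ = np.zeros(n, dtype=bool)
        self.support_[res.ranking[:res.optimal_n]] = True
        self.model_ = res.model
        return self

    def transform(self, X):
        sub = self.result_.ranking[:self.n_features_]
        if isinstance(X, pd.DataFrame):
            return X.iloc[:, sub]
        return np.asarray(X)[:, sub]

    def predict(self, X):
        return self.model_.predict(self.transform(X))

    def predict_proba(self, X):
        p = self.model_.predict_proba(self.transform(X))
        return np.column_stack([1 - p, p])


@dataclass
class ProbabilityMap:
    """Per-voxel P(tumor) over a candidate-region domain."""

    prob: np.ndarray          # 3D float array, 0 outside domain
    domain: Mask

    def __post_init__(self):
        if self.prob.shape != self.domain.data.shape:
            raise ValueError("probability array and domain shape mismatch")
        dom = self.domain.bool()
        p = self.prob[dom]
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")


def predict_probability(model, X_candidate) -> np.ndarray:
    """Calibrated P(tumor) per candidate voxel (columns must match)."""
    return model.predict_proba(X_candidate)


def probability_map(model, X_candidate: pd.DataFrame, domain: Mask) -> ProbabilityMap:
    """Scatter per-voxel probabilities back onto the candidate grid."""
    p = predict_probability(model, X_candidate)
    vox = np.asarray(X_candidate.index.to_frame().to_numpy(), dtype=int)
    grid = np.zeros(domain.data.shape)
    grid[vox[:, 0], vox[:, 1], vox[:, 2]] = p
    return ProbabilityMap(grid, domain)


def hard_segment(prob: ProbabilityMap, threshold: float = 0.5) -> Mask:
    """Hard boundary: p >= threshold, keep the largest 26-connected
    component, fill enclosed holes."""
    binary = (prob.prob >= threshold) & prob.domain.bool()
    if not binary.any():
        warnings.warn("hard segmentation is empty at this threshold")
        return Mask.from_bool(binary, prob.domain)
    labels, n = ndimage.label(binary, structure=_STRUCT26)
    if n > 1:
        sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
        binary = labels == (1 + int(np.argmax(sizes)))
    binary = ndimage.binary_fill_holes(binary)
    return Mask.from_bool(binary, prob.domain)


def soft_boundary(prob: ProbabilityMap, lo: float = 0.1, hi: float = 0.9) -> Mask:
    """Soft boundary: candidate voxels with lo <= p <= hi (inclusive)."""
    if not (0 <= lo < hi <= 1):
        raise ValueError(f"need 0 <= lo < hi <= 1, got ({lo}, {hi})")
    sel = (prob.prob >= lo) & (prob.prob <= hi) & prob.domain.bool()
    return Mask.from_bool(sel, prob.domain)


def dice(a: Mask, b: Mask) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); 1.0 if both masks are empty."""
    am = a.bool() if isinstance(a, Mask) else np.asarray(a, dtype=bool)
    bm = b.bool() if isinstance(b, Mask) else np.asarray(b, dtype=bool)
    if am.shape != bm.shape:
        raise ValueError(f"mask shapes differ: {am.shape} vs {bm.shape}")
    denom = am.sum() + bm.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (am & bm).sum() / denom)
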