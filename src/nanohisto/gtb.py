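"""Gradient tree boosting for small-n, wide-p biomarker regression.

An additive ensemble of binary regression trees trained on squared-error
residuals: the base prediction is the training-outcome mean, and each
successive tree is a variance-reduction regression tree fit to the current
residuals, its contribution shrunk by the learning rate.  The learner is
deliberately written for the regime it is used in here -- a dozen or two
animals, 23 partially missing histology features -- and therefore:

* splits are found by exhaustive search over every feature and every
  midpoint between consecutive distinct observed values (no histograms,
  no subsampling), making the fit fully deterministic;
* exact ties in variance reduction -- common at tiny nodes, where many
  features induce the same partition -- are resolved toward the feature
  whose observed values correlate most strongly with the tree's current
  residuals (then lowest index, lowest threshold).  Breaking ties by raw
  column position instead would let the leftmost column of the table absorb
  every tied split and so turn occurrence-based importance into an artifact
  of panel ordering;
* missing values are handled sparsity-aware: they are excluded from the
  threshold statistics and routed to whichever child minimizes the split's
  squared error, a default direction stored in the node and reused at
  prediction time;
* feature importance is occurrence-based: the share of internal nodes in
  the ensemble that split on a feature, reported as mean +/- SD across the
  leave-one-out fold ensembles.

Model selection uses leave-one-out cross-validation, appropriate for the
very small sample sizes of in vivo accumulation studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .scoring import ValidationError

_EPS = 1e-12


@dataclass(frozen=True)
class GTBConfig:
    """Boosting hyperparameters (defaults follow the study setup:
    ten trees of depth up to eight)."""

    n_trees: int = 10
    max_depth: int = 8
    learning_rate: float = 0.3
    min_leaf: int = 1
    seed: int = 0  # reserved; the fit itself is deterministic

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.max_depth < 1 or self.min_leaf < 1:
            raise ValidationError("n_trees, max_depth and min_leaf must be >= 1")
        if not 0 < self.learning_rate <= 1:
            raise ValidationError("learning_rate must lie in (0,1]")


@dataclass
class TreeNode:
    """Internal node (feature/threshold/default direction) or leaf (value)."""

    feature: Optional[int] = None
    threshold: float = 0.0
    default_left: bool = True
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    value: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"value": self.value}
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "default_left": self.default_left,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "value" in d and "feature" not in d:
            return cls(value=d["value"])
        return cls(
            feature=d["feature"], threshold=d["threshold"],
            default_left=d["default_left"],
            left=cls.from_dict(d["left"]), right=cls.from_dict(d["right"]),
        )


@dataclass
class GTBModel:
    base_prediction: float
    trees: list[TreeNode]
    config: GTBConfig
    feature_names: list[str]

    def to_json(self, path=None) -> str:
        payload = {
            "base_prediction": self.base_prediction,
            "config": {
                "n_trees": self.config.n_trees,
                "max_depth": self.config.max_depth,
                "learning_rate": self.config.learning_rate,
                "min_leaf": self.config.min_leaf,
                "seed": self.config.seed,
            },
            "feature_names": list(self.feature_names),
            "trees": [t.to_dict() for t in self.trees],
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "GTBModel":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            base_prediction=d["base_prediction"],
            trees=[TreeNode.from_dict(t) for t in d["trees"]],
            config=GTBConfig(**d["config"]),
            feature_names=list(d["feature_names"]),
        )


@dataclass
class LOOResult:
    measured: np.ndarray
    predicted: np.ndarray
    r_squared: float
    fold_models: list[GTBModel]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"measured": self.measured,
                             "predicted": self.predicted})


@dataclass
class ImportanceReport:
    """Mean and SD over fold ensembles of each feature's split share."""

    feature_names: list[str]
    mean_importance: np.ndarray
    sd_importance: np.ndarray
    ranking: list[str]
    no_splits: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.feature_names,
             "mean_importance": self.mean_importance,
             "sd_importance": self.sd_importance}
        ).sort_values("mean_importance", ascending=False, kind="stable",
                      ignore_index=True)


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------

def _sse(total: float, sq_total: float, n: int) -> float:
    return sq_total - (total * total / n) if n > 0 else 0.0


def _best_split_for_feature(x: np.ndarray, r: np.ndarray, min_leaf: int):
    """Best (sse, threshold, default_left) for one feature, or None.

    Missing values are excluded from threshold statistics; for every
    candidate threshold both default directions are scored and the lower
    post-split squared error wins (ties default left).
    """
    miss = np.isnan(x)
    xo, ro = x[~miss], r[~miss]
    if len(xo) < 2:
        return None
    order = np.argsort(xo, kind="stable")
    xs, rs = xo[order], ro[order]
    cuts = np.nonzero(np.diff(xs) > 0)[0]  # split after position i
    if len(cuts) == 0:
        return None

    csum = np.cumsum(rs)
    csq = np.cumsum(rs * rs)
    total, sq_total, n_obs = csum[-1], csq[-1], len(rs)
    rm = r[miss]
    m_sum, m_sq, m_n = rm.sum(), np.sum(rm * rm), len(rm)

    nl = cuts + 1
    nr = n_obs - nl
    sl, ql = csum[cuts], csq[cuts]
    sr, qr = total - sl, sq_total - ql

    # default left: missing rows join the left child; default right: the right
    with np.errstate(invalid="ignore", divide="ignore"):
        left_dl = (ql + m_sq) - (sl + m_sum) ** 2 / (nl + m_n)
        right_dl = qr - sr ** 2 / nr
        left_dr = ql - sl ** 2 / nl
        right_dr = (qr + m_sq) - (sr + m_sum) ** 2 / (nr + m_n)
    sse_dl = left_dl + right_dl
    sse_dr = left_dr + right_dr

    valid_dl = (nl + m_n >= min_leaf) & (nr >= min_leaf)
    valid_dr = (nl >= min_leaf) & (nr + m_n >= min_leaf)
    sse_dl = np.where(valid_dl, sse_dl, np.inf)
    sse_dr = np.where(valid_dr, sse_dr, np.inf)

    default_left = sse_dl <= sse_dr
    sse = np.where(default_left, sse_dl, sse_dr)
    if not np.any(np.isfinite(sse)):
        return None
    best = int(np.argmin(sse))  # argmin keeps the first (lowest threshold) tie
    thr = (xs[cuts[best]] + xs[cuts[best] + 1]) / 2.0
    return float(sse[best]), float(thr), bool(default_left[best])


def _residual_priorities(X: np.ndarray, r: np.ndarray) -> np.ndarray:
    """|Pearson correlation| of each feature with the residuals, over the
    feature's observed rows; the tie-break order for equal-loss splits."""
    p = np.zeros(X.shape[1])
    for f in range(X.shape[1]):
        x = X[:, f]
        obs = ~np.isnan(x)
        if obs.sum() < 2:
            continue
        xo, ro = x[obs], r[obs]
        if np.ptp(xo) == 0 or np.ptp(ro) == 0:
            continue
        p[f] = abs(float(np.corrcoef(xo, ro)[0, 1]))
    return p


def _build_tree(X: np.ndarray, r: np.ndarray, rows: np.ndarray,
                depth: int, cfg: GTBConfig,
                priority: np.ndarray) -> TreeNode:
    rr = r[rows]
    node_value = float(rr.mean())
    if depth >= cfg.max_depth or len(rows) < 2 * cfg.min_leaf or len(rows) < 2:
        return TreeNode(value=node_value)

    parent_sse = float(np.sum((rr - node_value) ** 2))
    best = None  # (sse, feature, threshold, default_left)
    for f in range(X.shape[1]):
        cand = _best_split_for_feature(X[rows, f], rr, cfg.min_leaf)
        if cand is None:
            continue
        sse, thr, dl = cand
        if best is None or sse < best[0] - _EPS:
            best = (sse, f, thr, dl)
        elif sse <= best[0] + _EPS and priority[f] > priority[best[1]] + _EPS:
            # equal loss: credit the feature most associated with the
            # residuals (keeps importance invariant to column order)
            best = (sse, f, thr, dl)
    if best is None or best[0] >= parent_sse - _EPS:
        return TreeNode(value=node_value)

    _, f, thr, dl = best
    xf = X[rows, f]
    miss = np.isnan(xf)
    goes_left = np.where(miss, dl, xf < thr)
    left_rows = rows[goes_left]
    right_rows = rows[~goes_left]
    if len(left_rows) == 0 or len(right_rows) == 0:
        return TreeNode(value=node_value)
    return TreeNode(
        feature=f, threshold=thr, default_left=dl,
        left=_build_tree(X, r, left_rows, depth + 1, cfg, priority),
        right=_build_tree(X, r, right_rows, depth + 1, cfg, priority),
    )


def _tree_predict_row(node: TreeNode, row: np.ndarray) -> float:
    while not node.is_leaf:
        x = row[node.feature]
        if np.isnan(x):
            node = node.left if node.default_left else node.right
        else:
            node = node.left if x < node.threshold else node.right
    return node.value


def _tree_predict(node: TreeNode, X: np.ndarray) -> np.ndarray:
    return np.array([_tree_predict_row(node, X[i]) for i in range(len(X))])


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("X must be 2-D")
    return arr, [f"f{i}" for i in range(arr.shape[1])]


def fit(X, y, cfg: GTBConfig = GTBConfig()) -> GTBModel:
    """Train a squared-error boosted ensemble on (possibly missing) features."""
    Xm, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    if yv.ndim != 1 or len(yv) != len(Xm):
        raise ValidationError("y must align with X rows")
    if np.any(np.isnan(yv)):
        raise ValidationError("outcome vector must not contain missing values")
    if len(yv) < 2:
        raise ValidationError("need >= 2 samples")

    base = float(yv.mean())
    pred = np.full(len(yv), base)
    trees: list[TreeNode] = []
    rows = np.arange(len(yv))
    for _ in range(cfg.n_trees):
        resid = yv - pred
        priority = _residual_priorities(Xm, resid)
        tree = _build_tree(Xm, resid, rows, 0, cfg, priority)
        trees.append(tree)
        pred = pred + cfg.learning_rate * _tree_predict(tree, Xm)
    return GTBModel(base_prediction=base, trees=trees, config=cfg,
                    feature_names=names)


def predict(model: GTBModel, X) -> np.ndarray:
    """Ensemble prediction; missing features follow stored default directions."""
    if isinstance(X, pd.DataFrame):
        X = X.rename(columns=str)
        missing = set(model.feature_names) - set(X.columns)
        if missing:
            raise ValidationError(f"feature columns absent: {sorted(missing)}")
        Xm = X[model.feature_names].to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[None, :]
        if Xm.shape[1] != len(model.feature_names):
            raise ValidationError("feature layout does not match the model")
    pred = np.full(len(Xm), model.base_prediction)
    lr = model.config.learning_rate
    for tree in model.trees:
        pred = pred + lr * _tree_predict(tree, Xm)
    return pred


def training_mse_path(X, y, cfg: GTBConfig = GTBConfig()) -> np.ndarray:
    """Training MSE after 0, 1, ..., n_trees trees (non-increasing)."""
    model = fit(X, y, cfg)
    Xm, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    pred = np.full(len(yv), model.base_prediction)
    path = [float(np.mean((yv - pred) ** 2))]
    for tree in model.trees:
        pred = pred + cfg.learning_rate * _tree_predict(tree, Xm)
        path.append(float(np.mean((yv - pred) ** 2)))
    return np.asarray(path)


def r_squared(measured, predicted, method: str = "pearson") -> float:
    """Agreement between measured and predicted outcomes.

    ``pearson`` (default) is the squared Pearson correlation, matching an
    R2 read off a predicted-vs-measured scatter with a fitted line;
    ``determination`` is 1 - SS_res/SS_tot (can be negative for a predictor
    worse than the mean).
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.ndim != 1 or len(m) < 2:
        raise ValidationError("need two aligned vectors of length >= 2")
    if np.ptp(m) == 0:
        raise ValidationError("measured vector is constant; R2 undefined")
    if method == "pearson":
        if np.ptp(p) == 0:
            return 0.0
        return float(np.corrcoef(m, p)[0, 1] ** 2)
    if method == "determination":
        ss_res = float(np.sum((m - p) ** 2))
        ss_tot = float(np.sum((m - m.mean()) ** 2))
        return 1.0 - ss_res / ss_tot
    raise ValidationError(f"unknown method {method!r}")


def loo_cv(X, y, cfg: GTBConfig = GTBConfig()) -> LOOResult:
    """Leave-one-out cross-validation: each sample predicted by a model
    trained on all the others."""
    Xm, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    if n < 3:
        raise ValidationError("leave-one-out needs >= 3 samples")
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(Xm, columns=names)
    preds = np.empty(n)
    fold_models = []
    for i in range(n):
        keep = np.arange(n) != i
        model = fit(Xdf.iloc[keep], yv[keep], cfg)
        preds[i] = predict(model, Xdf.iloc[[i]])[0]
        fold_models.append(model)
    r2 = r_squared(yv, preds, method="pearson")
    return LOOResult(measured=yv, predicted=preds, r_squared=r2,
                     fold_models=fold_models)


def _count_splits(node: TreeNode, counts: np.ndarray) -> None:
    if node.is_leaf:
        return
    counts[node.feature] += 1
    _count_splits(node.left, counts)
    _count_splits(node.right, counts)


def feature_importance(fold_models: Sequence[GTBModel]) -> ImportanceReport:
    """Occurrence-based importance: per fold, a feature's share of the
    ensemble's internal nodes; mean and SD taken across folds."""
    if not fold_models:
        raise ValidationError("need >= 1 model")
    names = fold_models[0].feature_names
    shares = np.zeros((len(fold_models), len(names)))
    any_split = False
    for k, model in enumerate(fold_models):
        counts = np.zeros(len(names))
        for tree in model.trees:
            _count_splits(tree, counts)
        total = counts.sum()
        if total > 0:
            shares[k] = counts / total
            any_split = True
    mean = shares.mean(axis=0)
    sd = shares.std(axis=0)  # population SD over folds
    order = np.argsort(-mean, kind="stable")
    return ImportanceReport(
        feature_names=list(names), mean_importance=mean, sd_importance=sd,
        ranking=[names[i] for i in order], no_splits=not any_split,
    )
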