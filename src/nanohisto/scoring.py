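"""Ordinal biomarker scoring and classification of nanomedicine accumulation.

Pathologists grade tumour blood-vessel (CD31) and tumour-associated-macrophage
(TAM, F4/80 or CD68) density on an ordinal 1-4 rubric (1 absent, 2 low,
3 intermediate, 4 high).  The product of the two grades (range 1-16) is used
as a single stratification score: tumours with a product score at or above a
fixed cutoff (default 6) are predicted to accumulate nanomedicines well.
This module implements the rubric binning, the product score, consensus
aggregation over observers and sections, cutoff classification with confusion
statistics, and ROC/AUROC evaluation of the score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

MARKERS = ("vessel", "TAM")

#: Product scores at or above this value predict high accumulation.
DEFAULT_CUTOFF = 6


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ObserverScoreMatrix:
    """Long-format ordinal scores: one row per (model, observer, section, marker).

    ``scores`` columns: ``model``, ``observer``, ``section``, ``marker``,
    ``score``; every score is an integer in {1, 2, 3, 4} and ``marker`` is
    ``vessel`` or ``TAM``.
    """

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"model", "observer", "section", "marker", "score"}
        missing = required - set(self.scores.columns)
        if missing:
            raise ValidationError(f"score matrix missing columns: {sorted(missing)}")
        s = self.scores["score"]
        if len(s) == 0:
            raise ValidationError("score matrix is empty")
        if not np.all(np.equal(np.mod(s, 1), 0)) or s.min() < 1 or s.max() > 4:
            raise ValidationError("scores must be integers in {1,2,3,4}")
        bad = set(self.scores["marker"]) - set(MARKERS)
        if bad:
            raise ValidationError(f"unknown markers: {sorted(bad)}")

    @property
    def models(self) -> list[str]:
        return list(dict.fromkeys(self.scores["model"]))

    def select(self, model_id: str, marker: str) -> np.ndarray:
        """All (observer, section) scores for one model and marker."""
        df = self.scores
        sel = df[(df["model"] == model_id) & (df["marker"] == marker)]["score"]
        if len(sel) == 0:
            raise KeyError(f"no scores for model={model_id!r}, marker={marker!r}")
        return sel.to_numpy(dtype=int)

    def to_csv(self, path) -> None:
        self.scores.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ObserverScoreMatrix":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class ProductScoreRecord:
    """Consensus vessel and TAM grades for one tumour model and their product."""

    model_id: str
    vessel_score: int
    tam_score: int
    product: int

    def __post_init__(self) -> None:
        if self.product != self.vessel_score * self.tam_score:
            raise ValidationError("product must equal vessel_score * tam_score")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


@dataclass
class ROCResult:
    """Threshold sweep over product scores with trapezoidal AUROC.

    ``thresholds`` is descending; an item is called positive when its score is
    >= the threshold, so the curve runs from (0, 0) (threshold above every
    score) to (1, 1) (threshold at the minimum score).
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float
    n_pos: int = 0
    n_neg: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def density_to_ordinal(value: float, bin_edges) -> int:
    """Map a continuous density to the 1-4 rubric using three ascending edges.

    Bins are left-closed: a value exactly on an edge takes the higher grade.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.shape != (3,) or not np.all(np.diff(edges) > 0):
        raise ValidationError("bin_edges must be three strictly ascending reals")
    return int(1 + np.searchsorted(edges, value, side="right"))


def quartile_bin_edges(reference_values) -> np.ndarray:
    """Derive rubric bin edges from a reference density distribution.

    The three quartiles (Q1, Q2, Q3) of the reference sample become the
    edges, so grading a density against its own cohort assigns roughly a
    quarter of samples to each of the four ordinal levels.
    """
    vals = np.asarray(reference_values, dtype=float)
    if len(vals) < 4:
        raise ValidationError("need >= 4 reference values for quartile edges")
    edges = np.quantile(vals, [0.25, 0.5, 0.75])
    if not np.all(np.diff(edges) > 0):
        raise ValidationError("reference distribution too discrete for "
                              "strictly ascending quartile edges")
    return edges


def product_score(vessel_score: int, tam_score: int) -> int:
    """Vessel grade x TAM grade, range 1-16."""
    for s in (vessel_score, tam_score):
        if not (isinstance(s, (int, np.integer)) and 1 <= s <= 4):
            raise ValidationError(f"ordinal score out of range: {s!r}")
    return int(vessel_score) * int(tam_score)


def consensus(scores: ObserverScoreMatrix, model_id: str, marker: str) -> int:
    """Median observer-section score; half-integer medians round down."""
    vals = scores.select(model_id, marker)
    return int(math.floor(np.median(vals)))


def classify(product: int, cutoff: int = DEFAULT_CUTOFF) -> str:
    """Predict accumulation class from a product score (inclusive cutoff)."""
    if not 1 <= product <= 16:
        raise ValidationError(f"product score out of range: {product}")
    return "predicted_high" if product >= cutoff else "predicted_low"


def product_scores(scores: ObserverScoreMatrix,
                   cutoff: int = DEFAULT_CUTOFF) -> list[ProductScoreRecord]:
    """Consensus product score per model, in the matrix's model order."""
    records = []
    for m in scores.models:
        v = consensus(scores, m, "vessel")
        t = consensus(scores, m, "TAM")
        records.append(ProductScoreRecord(m, v, t, product_score(v, t)))
    return records


def confusion(predictions, truth_classes) -> ConfusionMatrix:
    """Count tp/tn/fp/fn with high accumulation as the positive class.

    ``predictions`` holds ``predicted_high``/``predicted_low`` and
    ``truth_classes`` holds ``high``/``low``, aligned element-wise.
    """
    preds = list(predictions)
    truth = list(truth_classes)
    if len(preds) != len(truth):
        raise ValidationError("predictions and truth differ in length")
    if not preds:
        raise ValidationError("empty inputs")
    tp = tn = fp = fn = 0
    for p, t in zip(preds, truth):
        pred_high = p == "predicted_high"
        is_high = t == "high"
        if pred_high and is_high:
            tp += 1
        elif pred_high and not is_high:
            fp += 1
        elif not pred_high and is_high:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def roc(scores, labels) -> ROCResult:
    """ROC curve from item-level scores and binary truth labels.

    Sweeps thresholds over the distinct score values in descending order
    (positive call: score >= threshold).  The trapezoidal area under the
    resulting curve equals the Mann-Whitney statistic U/(n_pos*n_neg), with
    tied pos/neg scores contributing 1/2.

    ``labels`` may be ``high``/``low`` strings or truthy/falsy values.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(
        [x == "high" if isinstance(x, str) else bool(x) for x in labels]
    )
    if s.shape != lab.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D")
    n_pos = int(lab.sum())
    n_neg = int(len(lab) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present for a ROC curve")

    distinct = np.unique(s)[::-1]
    thresholds = np.concatenate(([distinct[0] + 1.0], distinct))
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        called = s >= t
        tpr[i] = np.sum(called & lab) / n_pos
        fpr[i] = np.sum(called & ~lab) / n_neg
    auroc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr,
                     auroc=auroc, n_pos=n_pos, n_neg=n_neg)


def score_vs_accumulation(product_score_means, accumulation_means,
                          group_names=None):
    """Relate per-group mean product scores to mean tumour accumulation.

    Returns ``(table, fit)`` where ``table`` pairs the group means (with a
    ``true_negative_candidate`` flag on the lowest-scoring group when it also
    accumulates least) and ``fit`` is the ordinary-least-squares
    (slope, intercept, r_squared) from :func:`nanohisto.histoquant.linear_fit`.
    """
    from .histoquant import linear_fit  # local import to avoid cycle at import time

    x = np.asarray(product_score_means, dtype=float)
    y = np.asarray(accumulation_means, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("need >= 3 aligned group means")
    names = list(group_names) if group_names is not None else [
        f"group{i}" for i in range(len(x))
    ]
    flags = [False] * len(x)
    lowest = int(np.argmin(x))
    if lowest == int(np.argmin(y)):
        flags[lowest] = True
    table = pd.DataFrame(
        {"group": names, "product_score": x, "accumulation": y,
         "true_negative_candidate": flags}
    )
    fit = linear_fit(x, y)
    return table, fit
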