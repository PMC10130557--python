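"""Kin-pair classification from (phi, k0, k2) kinship statistics.

Three classifiers over the same three-dimensional feature space:

* nearest-center (Euclidean) assignment to the canonical expectations
  POP=(0.25,0,0), FSP=(0.25,0.25,0.25), 2nd degree=(0.125,0.5,0),
  3rd degree=(0.063,0.75,0), unrelated=(0,1,0);
* the Manichaikul degree intervals: degree d if
  phi in (2^-(d+3/2), 2^-(d+1/2)), with pairs at degree 1 split into
  parent-offspring when k0 < 2^(-9/2) ~ 0.044, full siblings otherwise;
* a linear support-vector machine trained on simulated kinship statistics
  with pedigree-truth labels.

Third-degree calls exist only as classifier output and are mapped to U for
scoring.  ``evaluate`` builds one-vs-rest confusion counts per class and
the macro precision/recall/F1 summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.multiclass import OneVsOneClassifier
from sklearn.svm import LinearSVC

from .pedigree import KIN_LABELS

log = logging.getLogger(__name__)

__all__ = ["EUCLIDEAN_CENTERS", "classify_euclidean", "classify_manichaikul",
           "train_svm", "SvmModel", "evaluate", "MetricsTable",
           "POP_K0_CUTOFF"]

# canonical (phi, k0, k2) expectations per kin class
EUCLIDEAN_CENTERS: dict[str, tuple[float, float, float]] = {
    "POP": (0.25, 0.0, 0.0),
    "FSP": (0.25, 0.25, 0.25),
    "DEG2": (0.125, 0.5, 0.0),
    "DEG3": (0.063, 0.75, 0.0),
    "U": (0.0, 1.0, 0.0),
}
# tie-break and degree precedence: closer degree wins
_PRECEDENCE = ["POP", "FSP", "DEG2", "DEG3", "U"]

POP_K0_CUTOFF = 2.0 ** (-9.0 / 2.0)   # ~0.044


def _features(triples) -> np.ndarray:
    if isinstance(triples, pd.DataFrame):
        X = triples[["phi", "k0", "k2"]].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(triples, dtype=float))
    if X.shape[1] != 3:
        raise ValueError("expected (phi, k0, k2) triples")
    return X


def classify_euclidean(triples, collapse_deg3: bool = True) -> np.ndarray:
    """Nearest canonical center in (phi, k0, k2); DEG3 mapped to U.

    Equidistant centers resolve to the closer degree (POP > FSP > DEG2 >
    DEG3 > U).  Always assigns a label to finite input.
    """
    X = _features(triples)
    centers = np.array([EUCLIDEAN_CENTERS[k] for k in _PRECEDENCE])
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    best = np.argmin(d2, axis=1)  # argmin takes first == highest precedence
    labels = np.array(_PRECEDENCE, dtype=object)[best]
    if collapse_deg3:
        labels[labels == "DEG3"] = "U"
    return labels


def classify_manichaikul(triples, collapse_deg3: bool = True) -> np.ndarray:
    """Degree intervals on phi with the k0 parent-offspring split.

    Degree d covers phi in (2^-(d+3/2), 2^-(d+1/2)); boundary values join
    the lower (more related) degree, and phi above the first-degree upper
    bound is treated as first degree.  Below the third-degree lower bound
    is unrelated.
    """
    X = _features(triples)
    phi, k0 = X[:, 0], X[:, 1]
    b = lambda e: 2.0 ** e
    labels = np.full(phi.shape[0], "U", dtype=object)
    deg1 = phi >= b(-5 / 2)
    deg2 = (phi >= b(-7 / 2)) & ~deg1
    deg3 = (phi >= b(-9 / 2)) & ~deg1 & ~deg2
    labels[deg1 & (k0 < POP_K0_CUTOFF)] = "POP"
    labels[deg1 & (k0 >= POP_K0_CUTOFF)] = "FSP"
    labels[deg2] = "DEG2"
    labels[deg3] = "DEG3"
    if collapse_deg3:
        labels[labels == "DEG3"] = "U"
    return labels


@dataclass
class SvmModel:
    """Fitted linear-kernel multiclass SVM over (phi, k0, k2)."""

    estimator: OneVsOneClassifier
    classes: list[str]
    seed: int
    n_points: int
    training_meta: dict = field(default_factory=dict)

    def predict(self, triples) -> np.ndarray:
        X = _features(triples)
        return self.estimator.predict(X).astype(object)


def train_svm(triples, labels, seed: int = 0, C: float = 1.0,
              training_meta: dict | None = None) -> SvmModel:
    """Train the linear SVM on labelled kinship statistics.

    Linear kernel, C=1, no class weighting, unscaled features (the three
    statistics are already commensurate).  Multiclass handling is
    one-vs-one voting (the libsvm convention), with each binary problem
    solved by liblinear in the primal so that training is deterministic
    and scales to millions of points.
    """
    X = _features(triples)
    y = np.asarray(labels, dtype=object)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain at least two classes")
    est = OneVsOneClassifier(LinearSVC(C=C, dual=False, random_state=seed))
    est.fit(X, y)
    return SvmModel(estimator=est, classes=[str(c) for c in est.classes_],
                    seed=seed, n_points=X.shape[0],
                    training_meta=dict(training_meta or {}))


@dataclass
class MetricsTable:
    """One-vs-rest confusion counts and summary metrics."""

    per_class: pd.DataFrame    # index class; TP FP FN TN precision recall specificity
    confusion: pd.DataFrame    # truth x predicted counts
    precision_macro: float
    recall_macro: float
    f1_macro: float

    @property
    def n_pairs(self) -> int:
        return int(self.confusion.to_numpy().sum())


def evaluate(pred, truth, classes=None) -> MetricsTable:
    """Score predictions against truth labels.

    ``classes`` defaults to the kin classes present in the truth vector (in
    POP/FSP/DEG2/U order); classes absent from both vectors are excluded
    from the macro averages and logged.  Per-class precision and recall
    default to 0 when undefined (no predicted / no true members).
    """
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    all_labels = [c for c in KIN_LABELS if c in set(pred) | set(truth)]
    extra = sorted((set(pred) | set(truth)) - set(all_labels))
    all_labels += [c for c in extra if c not in all_labels]
    if classes is None:
        classes = [c for c in all_labels if c in set(truth)]
        dropped = [c for c in all_labels if c not in classes]
        if dropped:
            log.info("evaluate: classes %s absent from truth, excluded "
                     "from macro averages", dropped)
    conf = pd.crosstab(pd.Series(truth, name="truth"),
                       pd.Series(pred, name="pred")).reindex(
        index=all_labels, columns=all_labels, fill_value=0)
    total = conf.to_numpy().sum()
    rows = {}
    for c in classes:
        tp = conf.loc[c, c]
        fp = conf[c].sum() - tp
        fn = conf.loc[c].sum() - tp
        tn = total - tp - fp - fn
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        rows[c] = dict(TP=tp, FP=fp, FN=fn, TN=tn, precision=prec,
                       recall=rec, specificity=spec)
    per_class = pd.DataFrame(rows).T
    p_macro = float(per_class["precision"].mean()) if len(per_class) else 0.0
    r_macro = float(per_class["recall"].mean()) if len(per_class) else 0.0
    f1 = (2 * p_macro * r_macro / (p_macro + r_macro)
          if (p_macro + r_macro) > 0 else 0.0)
    return MetricsTable(per_class=per_class, confusion=conf,
                        precision_macro=p_macro, recall_macro=r_macro,
                        f1_macro=f1)
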