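"""ROC curves, AUC, operating points, and likelihood-ratio tables.

Every metric consumes a :class:`~famliab.fh_model.RiskClassifier`, so
family-history, SNP-grid, and combined models are all scored identically.
Items tied in risk are merged before ROC construction, which makes the
trapezoid rule handle ties as single line segments; points between ROC
vertices are reached by deterministic linear interpolation (the randomized
classifier that realizes any convex combination of vertices).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from famliab.fh_model import RiskClassifier


@dataclass
class RocCurve:
    """ROC vertices (1 - specificity, sensitivity), anchored at (0,0) and (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self):
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)

    @property
    def vertices(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])


@dataclass
class OperatingPoint:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


@dataclass
class LrTable:
    """Likelihood ratio and population mass of each classifier item."""

    lr: np.ndarray
    prob: np.ndarray

    def __post_init__(self):
        self.lr = np.asarray(self.lr, dtype=float)
        self.prob = np.asarray(self.prob, dtype=float)


def roc(classifier: RiskClassifier) -> RocCurve:
    """ROC vertices: cumulative case/control masses over items sorted by risk.

    With items sorted in non-increasing risk order, vertex k is
    (sum of the top-k control masses, sum of the top-k case masses).
    """
    clf = classifier.merged()
    order = np.argsort(-clf.risk, kind="stable")
    tpr = np.concatenate([[0.0], np.cumsum(clf.p_case[order])])
    fpr = np.concatenate([[0.0], np.cumsum(clf.p_control[order])])
    tpr[-1] = 1.0
    fpr[-1] = 1.0
    return RocCurve(fpr=fpr, tpr=tpr)


def auc(obj) -> float:
    """Trapezoidal area under the ROC curve.

    Equals P(random case scores above random control) + 0.5 P(tie).
    Accepts a :class:`RocCurve` or a :class:`RiskClassifier`.
    """
    curve = obj if isinstance(obj, RocCurve) else roc(obj)
    return float(np.trapezoid(curve.tpr, curve.fpr))


def operating_point(classifier: RiskClassifier, sensitivity: float) -> OperatingPoint:
    """Specificity, PPV, and NPV of the (randomized) rule achieving a target sensitivity.

    The target sensitivity is realized by linear interpolation between the
    two adjacent ROC vertices. PPV and NPV follow from Bayes' rule at the
    prior f: PPV = sens*f / (sens*f + fpr*(1-f)) and
    NPV = spec*(1-f) / (spec*(1-f) + (1-sens)*f). At sensitivity 0 the PPV
    is reported as the limiting value along the ROC (the top item's risk).
    """
    if not 0.0 <= sensitivity <= 1.0:
        raise ValueError("target sensitivity must be in [0, 1]")
    curve = roc(classifier)
    f = classifier.prior
    tpr, fpr = curve.tpr, curve.fpr
    k = int(np.searchsorted(tpr, sensitivity, side="left"))
    if k == 0:
        fp = 0.0
    else:
        t0, t1 = tpr[k - 1], tpr[k]
        lam = 0.0 if t1 == t0 else (sensitivity - t0) / (t1 - t0)
        fp = fpr[k - 1] + lam * (fpr[k] - fpr[k - 1])
    spec = 1.0 - fp
    pos = sensitivity * f + fp * (1.0 - f)
    if pos > 0:
        ppv = sensitivity * f / pos
    else:
        ppv = float(np.max(classifier.risk))  # limit along the ROC from the origin
    neg = spec * (1.0 - f) + (1.0 - sensitivity) * f
    npv = spec * (1.0 - f) / neg if neg > 0 else 1.0 - f
    return OperatingPoint(sensitivity=sensitivity, specificity=spec, ppv=ppv, npv=npv)


def lr_table(classifier: RiskClassifier) -> LrTable:
    """Likelihood ratio of each item: post-test odds over pre-test odds.

    LR_j = [r_j / (1 - r_j)] / [f / (1 - f)]; a risk of exactly 1 maps to
    +inf and a risk of 0 to 0. The control-weighted mean of LR is 1.
    """
    clf = classifier.merged()
    f = clf.prior
    pre_odds = f / (1.0 - f)
    with np.errstate(divide="ignore"):
        post_odds = np.where(clf.risk < 1.0, clf.risk / (1.0 - clf.risk), np.inf)
        lr = post_odds / pre_odds
    return LrTable(lr=lr, prob=clf.pop_prob)


def extreme_lr_fraction(table: LrTable, x: float) -> float:
    """Population fraction whose odds move at least x-fold in either direction.

    Sums the population mass of items with LR >= x or LR <= 1/x.
    """
    if x < 1.0:
        raise ValueError("the fold-change threshold x must be at least 1")
    sel = (table.lr >= x) | (table.lr <= 1.0 / x)
    return float(table.prob[sel].sum())
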