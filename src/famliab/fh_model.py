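"""Complete and restricted family-history risk classifiers.

A *complete* family-history model assigns each relatives' disease-status
pattern its exact conditional risk P(index affected | pattern). A
*restricted* model first condenses the pattern through a summary function
(by default the Gail-style thresholded count — 0, 1, or >1 — of affected
first-degree relatives) and assigns each equivalence class its pooled risk.
Both reduce to a :class:`RiskClassifier`: a finite set of
(risk, P(item | case), P(item | control)) triples, the common currency for
all downstream ROC/AUC/PPV/NPV/likelihood-ratio metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from famliab.liability_core import PatternDistribution
from famliab.pedigree import Pedigree

_SUM_TOL = 1e-6
_RISK_TIE_TOL = 1e-12


@dataclass
class RiskClassifier:
    """Finite risk-prediction model over discrete items.

    ``p_case[j] = P(item j | case)`` and ``p_control[j] = P(item j | control)``
    each sum to 1; ``prior`` is the pre-test disease probability f. The
    consistency identities ``p_case_j = r_j P(item_j) / f`` and
    ``p_control_j = (1 - r_j) P(item_j) / (1 - f)`` hold by construction.
    """

    risk: np.ndarray
    p_case: np.ndarray
    p_control: np.ndarray
    prior: float
    labels: list | None = field(default=None, repr=False)

    def __post_init__(self):
        self.risk = np.asarray(self.risk, dtype=float)
        self.p_case = np.asarray(self.p_case, dtype=float)
        self.p_control = np.asarray(self.p_control, dtype=float)
        if not (len(self.risk) == len(self.p_case) == len(self.p_control)):
            raise ValueError("risk, p_case, p_control must have equal lengths")
        for name, arr in (("p_case", self.p_case), ("p_control", self.p_control)):
            s = arr.sum()
            if abs(s - 1.0) > 1e-4:
                raise ValueError(f"{name} sums to {s}, expected 1")
        if np.any((self.risk < -1e-12) | (self.risk > 1 + 1e-12)):
            raise ValueError("risks must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.risk)

    @property
    def pop_prob(self) -> np.ndarray:
        """Population probability of each item."""
        return self.prior * self.p_case + (1.0 - self.prior) * self.p_control

    @property
    def mean_risk(self) -> float:
        return float(self.pop_prob @ self.risk)

    def merged(self, tol: float = _RISK_TIE_TOL) -> "RiskClassifier":
        """Merge items whose risks agree within ``tol`` into single items."""
        order = np.argsort(-self.risk, kind="stable")
        r = self.risk[order]
        groups = np.concatenate([[0], np.cumsum(np.abs(np.diff(r)) > tol)])
        m = groups[-1] + 1
        risk = np.zeros(m)
        pc = np.zeros(m)
        pk = np.zeros(m)
        np.add.at(pc, groups, self.p_case[order])
        np.add.at(pk, groups, self.p_control[order])
        pop = np.zeros(m)
        np.add.at(pop, groups, self.pop_prob[order])
        np.add.at(risk, groups, self.risk[order] * self.pop_prob[order])
        with np.errstate(invalid="ignore"):
            risk = np.where(pop > 0, risk / np.maximum(pop, 1e-300), r[np.searchsorted(groups, np.arange(m))])
        return RiskClassifier(risk=risk, p_case=pc, p_control=pk, prior=self.prior)


def classifier_from_items(risk, pop_prob, prior: float | None = None, labels=None) -> RiskClassifier:
    """Build a classifier from per-item risks and population masses.

    When ``prior`` is omitted it is the realized mean risk, which makes the
    case/control weights and likelihood-ratio identities hold exactly.
    """
    risk = np.asarray(risk, dtype=float)
    pop = np.asarray(pop_prob, dtype=float)
    f = float(pop @ risk)
    if prior is None:
        prior = f
    # normalize by the realized case/control masses so both columns sum to 1
    p_case = risk * pop / max(f, 1e-300)
    p_control = (1.0 - risk) * pop / max(1.0 - f, 1e-300)
    return RiskClassifier(risk=risk, p_case=p_case, p_control=p_control, prior=prior, labels=labels)


class SummaryFunction:
    """Total mapping from relatives' status vectors to a finite category set."""

    def __init__(self, fn, categories, name: str = "summary"):
        self._fn = fn
        self.categories = list(categories)
        self.name = name

    def __call__(self, rel_pattern) -> object:
        return self._fn(np.asarray(rel_pattern))

    def apply(self, rel_patterns: np.ndarray) -> np.ndarray:
        """Category index (into ``categories``) for each row of patterns."""
        lookup = {c: i for i, c in enumerate(self.categories)}
        out = np.empty(len(rel_patterns), dtype=int)
        for i, pat in enumerate(rel_patterns):
            cat = self._fn(pat)
            if cat not in lookup:
                raise ValueError(f"summary produced unknown category {cat!r}")
            out[i] = lookup[cat]
        return out


def first_degree_summary(ped: Pedigree, max_count: int = 2) -> SummaryFunction:
    """Gail-style summary: thresholded count of affected first-degree relatives.

    First-degree relatives (parents, full siblings, children of the index)
    are identified from the pedigree links; the count is capped at
    ``max_count`` (default 2, i.e. categories 0, 1, >1).
    """
    fd = np.array(ped.first_degree_positions(), dtype=int) - 1  # relative-bit positions

    def count(rel_pattern: np.ndarray) -> int:
        if len(fd) == 0:
            return 0
        return int(min(rel_pattern[fd].sum(), max_count))

    return SummaryFunction(count, categories=list(range(max_count + 1)),
                           name=f"affected-first-degree(0..{max_count}+)")


def complete_classifier(dist: PatternDistribution) -> RiskClassifier:
    """Complete family-history model: one item per relatives' pattern."""
    return classifier_from_items(
        risk=dist.index_risk,
        pop_prob=dist.rel_probs,
        labels=[tuple(int(b) for b in p) for p in dist.rel_patterns],
    )


def restricted_classifier(
    dist: PatternDistribution,
    ped: Pedigree | None = None,
    summary: SummaryFunction | None = None,
) -> RiskClassifier:
    """Restricted family-history model over summary-statistic classes.

    Class risk is the pattern-probability-weighted average of the member
    patterns' risks: P(index affected | S(pattern) = c). Empty classes are
    dropped with a warning.
    """
    ped = ped if ped is not None else dist.pedigree
    if summary is None:
        summary = first_degree_summary(ped)
    cats = summary.apply(dist.rel_patterns)
    m = len(summary.categories)
    mass = np.zeros(m)
    joint_aff = np.zeros(m)
    np.add.at(mass, cats, dist.rel_probs)
    np.add.at(joint_aff, cats, dist.rel_probs * dist.index_risk)
    keep = mass > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} empty summary class(es): "
            f"{[summary.categories[i] for i in np.flatnonzero(~keep)]}",
            stacklevel=2,
        )
    risk = joint_aff[keep] / mass[keep]
    return classifier_from_items(
        risk=risk,
        pop_prob=mass[keep] / mass[keep].sum(),
        labels=[summary.categories[i] for i in np.flatnonzero(keep)],
    )
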