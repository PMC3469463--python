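"""Forward Monte-Carlo simulation of family liabilities and disease statuses.

This module is the empirical oracle for the analytic machinery: it draws
genetic vectors from N(0, h2 * A), a shared-environment component common to
the family, independent residuals, and the index's measured genetic
liability, then thresholds at T. Every closed-form quantity in the package
(pattern probabilities, AUCs, likelihood-ratio and PPV tables) has an
estimator here that should agree within Monte-Carlo error.

Randomness uses a counter-based Philox stream keyed by a single integer
seed; all variates for one replicate occupy a contiguous block, so the
first N replicates are identical regardless of how many are requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from famliab.classifier_metrics import OperatingPoint
from famliab.fh_model import RiskClassifier, SummaryFunction, classifier_from_items
from famliab.liability_core import DiseaseSpec, PatternDistribution
from famliab.pedigree import Pedigree


@dataclass
class SimConfig:
    spec: DiseaseSpec
    ped: Pedigree
    n_replicates: int
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")


@dataclass
class SimResult:
    """Simulated families: arrays of shape (n_replicates, n) in pedigree order."""

    spec: DiseaseSpec
    ped: Pedigree
    genetic: np.ndarray
    shared: np.ndarray
    env: np.ndarray
    measured_g: np.ndarray
    liability: np.ndarray
    status: np.ndarray

    @property
    def n_replicates(self) -> int:
        return self.status.shape[0]

    @property
    def index_status(self) -> np.ndarray:
        return self.status[:, 0]

    def rel_pattern_index(self) -> np.ndarray:
        """Relatives' pattern as an integer (relative i -> bit i) per replicate."""
        n = self.status.shape[1]
        if n == 1:
            return np.zeros(self.n_replicates, dtype=np.int64)
        bits = self.status[:, 1:].astype(np.int64)
        return bits @ (1 << np.arange(n - 1))

    def pattern_index(self) -> np.ndarray:
        """Full pattern as an integer (index individual = bit 0) per replicate."""
        bits = self.status.astype(np.int64)
        return bits @ (1 << np.arange(self.status.shape[1]))

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per (replicate, individual)."""
        n_rep, n = self.status.shape
        rep = np.repeat(np.arange(n_rep), n)
        ind = np.tile(np.array(self.ped.ids), n_rep)
        return pd.DataFrame(
            {
                "replicate": rep,
                "individual": ind,
                "g": self.genetic.ravel(),
                "shared": np.repeat(self.shared, n),
                "e": self.env.ravel(),
                "measured_g": np.where(
                    np.tile(np.arange(n), n_rep) == 0,
                    np.repeat(self.measured_g, n),
                    np.nan,
                ),
                "liability": self.liability.ravel(),
                "status": self.status.ravel().astype(int),
            }
        )


def _factor(cov: np.ndarray) -> np.ndarray:
    """Symmetric factor L with L L' = cov; eigenvalue clipping for near-singular cov."""
    w, U = np.linalg.eigh(cov)
    if w.min() < -1e-10:
        raise np.linalg.LinAlgError(f"covariance has eigenvalue {w.min():.3e} < 0")
    return U * np.sqrt(np.clip(w, 0.0, None))


def simulate_families(
    cfg: SimConfig | None = None,
    *,
    spec: DiseaseSpec | None = None,
    ped: Pedigree | None = None,
    n_replicates: int | None = None,
    seed: int = 0,
) -> SimResult:
    """Draw families under the liability-threshold model.

    Per replicate: genetic vector ~ N(0, h2 * A), shared component
    ~ N(0, c2) common to all members, residuals ~ N(0, 1 - h2 - c2) i.i.d.,
    and the index's measured liability g_m = (v / h2) * g_index +
    N(0, v - v^2 / h2). Disease status is liability >= T.
    """
    if cfg is None:
        cfg = SimConfig(spec=spec, ped=ped, n_replicates=n_replicates, seed=seed)
    spec, ped = cfg.spec, cfg.ped
    n = ped.n
    N = cfg.n_replicates
    rng = np.random.Generator(np.random.Philox(cfg.seed))
    # one contiguous block of 2n + 2 variates per replicate (prefix-stable)
    z = rng.standard_normal((N, 2 * n + 2))
    z_gen, z_shared, z_env, z_meas = z[:, :n], z[:, n], z[:, n + 1 : 2 * n + 1], z[:, 2 * n + 1]
    A = ped.relationship_matrix()
    L = _factor(spec.h2 * A)
    genetic = z_gen @ L.T
    shared = np.sqrt(spec.c2) * z_shared
    env = np.sqrt(max(1.0 - spec.h2 - spec.c2, 0.0)) * z_env
    liability = genetic + shared[:, None] + env
    v = spec.v
    if v > 0 and spec.h2 > 0:
        measured_g = (v / spec.h2) * genetic[:, 0] + np.sqrt(max(v - v**2 / spec.h2, 0.0)) * z_meas
    else:
        measured_g = np.zeros(N)
    status = liability >= spec.threshold
    return SimResult(
        spec=spec,
        ped=ped,
        genetic=genetic,
        shared=shared,
        env=env,
        measured_g=measured_g,
        liability=liability,
        status=status,
    )


# ---------------------------------------------------------------------------
# empirical estimators
# ---------------------------------------------------------------------------


def empirical_auc(status: np.ndarray, scores: np.ndarray) -> float:
    """Rank-statistic (Mann-Whitney) AUC with midrank tie correction."""
    status = np.asarray(status, dtype=bool)
    n_case = int(status.sum())
    n_ctrl = len(status) - n_case
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("empirical AUC needs at least one case and one control")
    ranks = rankdata(scores)
    return float((ranks[status].sum() - n_case * (n_case + 1) / 2) / (n_case * n_ctrl))


def pattern_frequencies(sim: SimResult) -> np.ndarray:
    """Empirical frequency of each of the 2^n full disease-status patterns."""
    idx = sim.pattern_index()
    return np.bincount(idx, minlength=1 << sim.status.shape[1]) / sim.n_replicates


def _scores(sim: SimResult, scorer: str, dist: PatternDistribution | None,
            summary: SummaryFunction | None) -> np.ndarray:
    if scorer == "snp":
        return sim.measured_g
    if scorer == "liability":
        return sim.liability[:, 0]
    if dist is None:
        raise ValueError(f"scorer {scorer!r} needs the analytic pattern distribution")
    rel_idx = sim.rel_pattern_index()
    if scorer == "complete":
        return dist.index_risk[rel_idx]
    if scorer == "restricted":
        if summary is None:
            from famliab.fh_model import first_degree_summary

            summary = first_degree_summary(sim.ped)
        cats = summary.apply(dist.rel_patterns)
        mass = np.zeros(len(summary.categories))
        aff = np.zeros(len(summary.categories))
        np.add.at(mass, cats, dist.rel_probs)
        np.add.at(aff, cats, dist.rel_probs * dist.index_risk)
        class_risk = np.where(mass > 0, aff / np.maximum(mass, 1e-300), dist.spec.f)
        return class_risk[cats[rel_idx]]
    raise ValueError(f"unknown scorer {scorer!r}")


def empirical_classifier(status: np.ndarray, scores: np.ndarray, prior: float,
                         bins: int = 50) -> RiskClassifier:
    """Group replicates by score and estimate an empirical risk classifier.

    Discrete score sets (at most ``bins`` distinct values) become one item
    per value; continuous scores are quantile-binned.
    """
    uniq = np.unique(scores)
    if len(uniq) <= bins:
        grp = np.searchsorted(uniq, scores)
        m = len(uniq)
    else:
        edges = np.quantile(scores, np.linspace(0, 1, bins + 1)[1:-1])
        grp = np.searchsorted(edges, scores)
        m = bins
    count = np.bincount(grp, minlength=m).astype(float)
    aff = np.bincount(grp, weights=np.asarray(status, dtype=float), minlength=m)
    keep = count > 0
    risk = aff[keep] / count[keep]
    mass = count[keep] / count.sum()
    return classifier_from_items(risk=risk, pop_prob=mass, prior=prior)


def empirical_metrics(
    sim: SimResult,
    scorer: str = "complete",
    dist: PatternDistribution | None = None,
    summary: SummaryFunction | None = None,
    sensitivities=(0.05, 0.1, 0.25, 0.5, 0.75, 0.9),
    bins: int = 50,
) -> dict:
    """Empirical AUC, likelihood-ratio histogram, and PPV table for a scorer.

    ``scorer`` is one of ``complete``, ``restricted``, ``snp``, or
    ``liability``; the family-history scorers map each simulated relatives'
    pattern to its analytic risk from ``dist``.
    """
    from famliab.classifier_metrics import lr_table, operating_point

    scores = _scores(sim, scorer, dist, summary)
    status = sim.index_status
    a = empirical_auc(status, scores)
    clf = empirical_classifier(status, scores, prior=float(status.mean()), bins=bins)
    table = lr_table(clf)
    ops: list[OperatingPoint] = [operating_point(clf, s) for s in sensitivities]
    return {
        "auc": a,
        "lr": list(zip(table.lr.tolist(), table.prob.tolist())),
        "operating_points": [
            {"sens": o.sensitivity, "spec": o.specificity, "ppv": o.ppv, "npv": o.npv}
            for o in ops
        ],
    }
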