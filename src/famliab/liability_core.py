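"""Joint liability distributions over pedigrees and pattern probabilities.

Under the liability-threshold model each family member carries a latent
liability l_i = g_i + s + e_i with additive genetic component g (covariance
h2 * A across the family), an optional shared-environment component s of
variance c2 common to all members, and an independent residual. Disease
occurs when l_i >= T = Phi^-1(1 - f). The probability of any disease-status
pattern is a rectangle probability of the joint multivariate normal, which
we evaluate with scipy's quasi-Monte-Carlo MVN integrator under a fixed
integration seed so results are reproducible run to run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.stats import multivariate_normal, norm

from famliab.pedigree import DEFAULT_PATTERN_CAP, Pedigree

#: Absolute tolerance requested from the MVN integrator.
DEFAULT_ABS_TOL = 1e-6
#: Fixed seed for the quasi-Monte-Carlo MVN rule (reproducibility contract).
DEFAULT_QMC_SEED = 20120905
#: Pattern probabilities below this are treated as degenerate.
DEGENERATE_PROB = 1e-12


@dataclass(frozen=True)
class DiseaseSpec:
    """Scalar parameters of one disease under the liability-threshold model.

    Parameters
    ----------
    f:
        Lifetime morbid risk — the probability that an individual develops
        the disease at some point in life. Strictly inside (0, 1).
    h2:
        Heritability of liability (additive genetic fraction of liability
        variance), in [0, 1].
    c2:
        Shared-environment fraction of liability variance, common to all
        family members; an upper-bound construction. Default 0.
    pi:
        Proportion of the heritability explained by known SNP associations;
        v = pi * h2 is the variance of the measured genetic component.
    """

    f: float
    h2: float
    c2: float = 0.0
    pi: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.f < 1.0:
            raise ValueError(f"lifetime risk f must be in (0, 1), got {self.f}")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"heritability h2 must be in [0, 1], got {self.h2}")
        if not 0.0 <= self.c2 < 1.0:
            raise ValueError(f"shared-environment c2 must be in [0, 1), got {self.c2}")
        if self.h2 + self.c2 > 1.0 + 1e-12:
            raise ValueError(f"h2 + c2 must not exceed 1, got {self.h2 + self.c2}")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError(f"proportion explained pi must be in [0, 1], got {self.pi}")

    @property
    def threshold(self) -> float:
        """Liability threshold T = Phi^-1(1 - f)."""
        return liability_threshold(self.f)

    @property
    def v(self) -> float:
        """Variance of the measured genetic component, v = pi * h2."""
        return self.pi * self.h2

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "DiseaseSpec":
        known = {k: float(mapping[k]) for k in ("f", "h2", "c2", "pi") if k in mapping}
        if "f" not in known or "h2" not in known:
            raise ValueError("disease spec requires at least keys 'f' and 'h2'")
        return cls(**known)


def liability_threshold(f: float) -> float:
    """Threshold T = Phi^-1(1 - f) on the standard-normal liability scale."""
    if not 0.0 < f < 1.0:
        raise ValueError(f"lifetime risk f must be strictly inside (0, 1), got {f}")
    return float(norm.ppf(1.0 - f))


@dataclass
class LiabilityJoint:
    """Multivariate normal over total liabilities of a pedigree."""

    mean: np.ndarray
    cov: np.ndarray
    threshold: float

    @property
    def n(self) -> int:
        return len(self.mean)


def assemble_covariance(spec: DiseaseSpec, A: np.ndarray) -> LiabilityJoint:
    """Liability covariance h2*A + c2*J + (1 - h2 - c2)*I for one pedigree.

    J is the all-ones matrix (rank-one shared-environment block). For a
    non-inbred pedigree the diagonal is exactly 1. Raises if the result is
    not positive semidefinite within tolerance.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    cov = spec.h2 * A + spec.c2 * np.ones((n, n)) + (1.0 - spec.h2 - spec.c2) * np.eye(n)
    min_eig = float(np.linalg.eigvalsh(cov)[0])
    if min_eig < -1e-8:
        raise np.linalg.LinAlgError(
            f"liability covariance is not positive semidefinite "
            f"(smallest eigenvalue {min_eig:.3e})"
        )
    return LiabilityJoint(mean=np.zeros(n), cov=cov, threshold=spec.threshold)


# ---------------------------------------------------------------------------
# MVN rectangle machinery
# ---------------------------------------------------------------------------


def _below_threshold_cdf(
    mean: np.ndarray,
    cov: np.ndarray,
    threshold: float,
    subset: np.ndarray,
    abs_tol: float,
    qmc_seed: int,
) -> float:
    """P(l_i < T for all i in ``subset``) — marginalize by dropping coordinates."""
    k = len(subset)
    if k == 0:
        return 1.0
    if k == 1:
        i = subset[0]
        sd = np.sqrt(cov[i, i])
        return float(norm.cdf((threshold - mean[i]) / sd))
    sub_mean = mean[subset]
    sub_cov = cov[np.ix_(subset, subset)]
    return float(
        multivariate_normal.cdf(
            np.full(k, threshold),
            mean=sub_mean,
            cov=sub_cov,
            abseps=abs_tol,
            releps=0.0,
            rng=np.random.default_rng(qmc_seed),
        )
    )


def joint_pattern_probs(
    mean: np.ndarray,
    cov: np.ndarray,
    threshold: float,
    abs_tol: float = DEFAULT_ABS_TOL,
    qmc_seed: int = DEFAULT_QMC_SEED,
) -> np.ndarray:
    """Probabilities of all 2^n disease-status patterns of a joint normal.

    Pattern k has individual i affected (l_i >= T) iff bit i of k is set.
    One MVN cdf is evaluated per subset of individuals (all coordinates
    constrained below T; the rest marginalized out), and the exact pattern
    probabilities follow by a signed superset Moebius transform — the
    inclusion-exclusion shared across all patterns. Tiny negative values
    from cancellation are clipped to 0.
    """
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    n = len(mean)
    size = 1 << n
    q = np.empty(size)
    for mask in range(size):
        subset = np.flatnonzero([(mask >> i) & 1 for i in range(n)])
        q[mask] = _below_threshold_cdf(mean, cov, threshold, subset, abs_tol, qmc_seed)
    # G[U] = sum over supersets W of U of (-1)^{|W \ U|} q[W]
    G = q.copy()
    for b in range(n):
        bit = 1 << b
        for mask in range(size):
            if not mask & bit:
                G[mask] -= G[mask | bit]
    probs = np.empty(size)
    full = size - 1
    for a in range(size):
        probs[a] = G[full ^ a]
    np.clip(probs, 0.0, None, out=probs)
    return probs


def orthant_probability(
    joint: LiabilityJoint,
    pattern,
    abs_tol: float = DEFAULT_ABS_TOL,
    qmc_seed: int = DEFAULT_QMC_SEED,
) -> float:
    """P(l_i >= T for affected i, l_i < T for unaffected i) for one pattern.

    Inclusion-exclusion over subsets of the affected set, each term a
    below-threshold cdf of the corresponding coordinate subset.
    """
    pattern = np.asarray(pattern, dtype=int)
    if len(pattern) != joint.n:
        raise ValueError("pattern length does not match joint dimension")
    unaffected = np.flatnonzero(pattern == 0)
    affected = np.flatnonzero(pattern != 0)
    total = 0.0
    for mask in range(1 << len(affected)):
        chosen = affected[[bool((mask >> i) & 1) for i in range(len(affected))]]
        subset = np.sort(np.concatenate([unaffected, chosen])).astype(int)
        sign = -1.0 if bin(mask).count("1") % 2 else 1.0
        total += sign * _below_threshold_cdf(
            joint.mean, joint.cov, joint.threshold, subset, abs_tol, qmc_seed
        )
    return float(max(total, 0.0))


# ---------------------------------------------------------------------------
# Pattern distribution over a pedigree
# ---------------------------------------------------------------------------


@dataclass
class PatternDistribution:
    """Joint distribution over the 2^n disease-status patterns of a pedigree.

    ``patterns[k]`` is the status vector for pattern index k (index
    individual = bit 0), ``probs[k]`` its probability. ``rel_patterns`` are
    the 2^(n-1) relative-only patterns; ``index_risk[j]`` is the
    conditional risk P(index affected | relatives show pattern j).
    """

    spec: DiseaseSpec
    pedigree: Pedigree
    patterns: np.ndarray
    probs: np.ndarray
    rel_patterns: np.ndarray = field(repr=False, default=None)
    rel_probs: np.ndarray = field(repr=False, default=None)
    index_risk: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.patterns.shape[1]


def pattern_distribution(
    spec: DiseaseSpec,
    ped: Pedigree,
    abs_tol: float = DEFAULT_ABS_TOL,
    qmc_seed: int = DEFAULT_QMC_SEED,
    cap: int = DEFAULT_PATTERN_CAP,
) -> PatternDistribution:
    """Exact joint distribution over disease-status patterns of a pedigree.

    Evaluates all multivariate-normal orthant probabilities under the
    family liability covariance and derives, for every relatives-only
    pattern, the conditional risk of the index individual. Relative
    patterns with probability below ``DEGENERATE_PROB`` keep the prior risk
    f (with a warning) so classifier bookkeeping stays total.
    """
    patterns = ped.enumerate_patterns(cap=cap)
    joint = assemble_covariance(spec, ped.relationship_matrix())
    probs = joint_pattern_probs(joint.mean, joint.cov, joint.threshold, abs_tol, qmc_seed)
    return _distribution_from_probs(spec, ped, patterns, probs)


def _distribution_from_probs(
    spec: DiseaseSpec,
    ped: Pedigree,
    patterns: np.ndarray,
    probs: np.ndarray,
) -> PatternDistribution:
    n = patterns.shape[1]
    half = 1 << max(n - 1, 0)
    if n == 1:
        rel_patterns = np.zeros((1, 0), dtype=np.uint8)
        rel_probs = np.array([1.0])
        index_risk = np.array([probs[1] / max(probs.sum(), DEGENERATE_PROB)])
    else:
        # index is bit 0: probs[2j] = P(rel=j, index unaffected), probs[2j+1] affected
        rel_patterns = patterns[::2, 1:]
        p0 = probs[0::2]
        p1 = probs[1::2]
        rel_probs = p0 + p1
        index_risk = np.full(half, spec.f)
        ok = rel_probs > DEGENERATE_PROB
        index_risk[ok] = p1[ok] / rel_probs[ok]
        if not ok.all():
            warnings.warn(
                f"{int((~ok).sum())} degenerate relative pattern(s) with probability "
                f"< {DEGENERATE_PROB:g}; their index risk is set to the prior f",
                stacklevel=2,
            )
    return PatternDistribution(
        spec=spec,
        pedigree=ped,
        patterns=patterns,
        probs=probs,
        rel_patterns=rel_patterns,
        rel_probs=rel_probs,
        index_risk=index_risk,
    )
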