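"""Closed-form accuracy of SNP-based risk models on the liability scale.

The measured genetic liability g of the index individual carries a fraction
pi of the heritability, Var(g) = v = pi * h2, and Cov(g, l) = v where l is
the total liability. Selection theory gives the exact first two moments of
g among cases (l >= T) and controls; treating both conditional
distributions as normal (the standard approximation in this literature)
yields closed forms for the AUC, the parametric ROC curve, the posterior
risk r(g), likelihood-ratio tail fractions, and the inverse map from a
target AUC back to the "equivalent" proportion of heritability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from famliab.classifier_metrics import RocCurve
from famliab.liability_core import DiseaseSpec


@dataclass(frozen=True)
class CaseControlMoments:
    """Mean and variance of the measured genetic component g by outcome group."""

    mu_case: float
    var_case: float
    mu_control: float
    var_control: float
    degenerate: bool = False


def case_control_moments(spec: DiseaseSpec) -> CaseControlMoments:
    """Truncated-normal moments of g among cases and controls.

    With T = Phi^-1(1 - f), selection intensities i_case = phi(T)/f and
    i_control = -phi(T)/(1 - f), and v = pi * h2:

        mu  = v * i
        var = v * (1 - v * i * (i - T))

    for each group. These are exact moments of g = v*l + independent noise
    conditioned on the threshold event; only the normal shape of the
    conditional law is an approximation downstream.
    """
    v = spec.v
    if v == 0.0:
        return CaseControlMoments(0.0, 0.0, 0.0, 0.0, degenerate=True)
    T = spec.threshold
    phi_T = norm.pdf(T)
    i_case = phi_T / spec.f
    i_ctrl = -phi_T / (1.0 - spec.f)
    return CaseControlMoments(
        mu_case=v * i_case,
        var_case=v * (1.0 - v * i_case * (i_case - T)),
        mu_control=v * i_ctrl,
        var_control=v * (1.0 - v * i_ctrl * (i_ctrl - T)),
    )


def snp_auc(spec: DiseaseSpec) -> float:
    """AUC = Phi((mu_case - mu_control) / sqrt(var_case + var_control)).

    The tail probability of the difference of the two (approximately)
    normal group distributions of g. Returns 0.5 when pi = 0.
    """
    m = case_control_moments(spec)
    if m.degenerate:
        return 0.5
    return float(norm.cdf((m.mu_case - m.mu_control) / np.sqrt(m.var_case + m.var_control)))


def snp_roc(spec: DiseaseSpec, thresholds: np.ndarray | None = None) -> RocCurve:
    """Parametric ROC: sweep the decision threshold t over the g scale.

    sensitivity(t) = 1 - Phi((t - mu_case)/sd_case),
    1 - specificity(t) = 1 - Phi((t - mu_control)/sd_control).
    """
    m = case_control_moments(spec)
    if m.degenerate:
        return RocCurve(fpr=np.array([0.0, 1.0]), tpr=np.array([0.0, 1.0]))
    sd_case = np.sqrt(m.var_case)
    sd_ctrl = np.sqrt(m.var_control)
    if thresholds is None:
        lo = min(m.mu_control - 8.5 * sd_ctrl, m.mu_case - 8.5 * sd_case)
        hi = max(m.mu_control + 8.5 * sd_ctrl, m.mu_case + 8.5 * sd_case)
        thresholds = np.linspace(lo, hi, 4097)
    t = np.sort(np.asarray(thresholds, dtype=float))[::-1]
    tpr = 1.0 - norm.cdf((t - m.mu_case) / sd_case)
    fpr = 1.0 - norm.cdf((t - m.mu_control) / sd_ctrl)
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    return RocCurve(fpr=fpr, tpr=tpr)


def risk_given_g(spec: DiseaseSpec, g) -> np.ndarray | float:
    """Posterior disease risk given measured genetic liability g.

    r(g) = 1 - Phi((T - g) / sqrt(1 - v)); the residual liability l - g has
    variance 1 - v. Degenerate limits: v = 0 gives the prior f for all g,
    v = 1 gives a step function at T.
    """
    g = np.asarray(g, dtype=float)
    v = spec.v
    T = spec.threshold
    if v >= 1.0:
        out = np.where(g >= T, 1.0, 0.0)
    elif v == 0.0:
        out = np.full_like(g, spec.f)
    else:
        out = 1.0 - norm.cdf((T - g) / np.sqrt(1.0 - v))
    return out if out.ndim else float(out)


def likelihood_ratio_given_g(spec: DiseaseSpec, g) -> np.ndarray | float:
    """LR(g) = [r(g) (1 - f)] / [(1 - r(g)) f] — post- over pre-test odds."""
    r = np.asarray(risk_given_g(spec, g), dtype=float)
    f = spec.f
    with np.errstate(divide="ignore"):
        out = np.where(r < 1.0, r * (1.0 - f) / (np.maximum(1.0 - r, 1e-300) * f), np.inf)
    return out if out.ndim else float(out)


def extreme_lr_fraction_continuous(spec: DiseaseSpec, x: float) -> float:
    """Population fraction assigned at least x-fold increased or decreased odds.

    LR(g) is strictly increasing in g, so the set {LR >= x or LR <= 1/x}
    is two tails of g ~ N(0, v). The boundaries are found by bracketed
    root-finding; if a fold change is unattainable, that tail contributes 0.
    """
    if x < 1.0:
        raise ValueError("the fold-change threshold x must be at least 1")
    v = spec.v
    if v <= 0.0:
        return 1.0 if x == 1.0 else 0.0
    sd = np.sqrt(v)

    def log_lr(g: float) -> float:
        lr = likelihood_ratio_given_g(spec, g)
        return np.log(lr) if np.isfinite(lr) and lr > 0 else (np.inf if lr > 1 else -np.inf)

    def solve(target: float) -> float | None:
        lo, hi = -12.0 * sd, 12.0 * sd
        for _ in range(8):  # LR is monotone; expand bracket on failure
            if log_lr(lo) <= target <= log_lr(hi):
                return brentq(lambda g: log_lr(g) - target, lo, hi, xtol=1e-12)
            lo *= 2.0
            hi *= 2.0
        return None

    frac = 0.0
    g_hi = solve(np.log(x))
    if g_hi is not None:
        frac += 1.0 - norm.cdf(g_hi / sd)
    g_lo = solve(-np.log(x))
    if g_lo is not None:
        frac += norm.cdf(g_lo / sd)
    return float(min(frac, 1.0))


def fraction_above_risk(spec: DiseaseSpec, risk_threshold: float) -> float:
    """Population fraction whose posterior risk r(g) exceeds a threshold.

    r(g) is increasing in g, so this is the upper tail of g ~ N(0, v)
    beyond g* = T - sqrt(1 - v) * Phi^-1(1 - r*).
    """
    if not 0.0 < risk_threshold < 1.0:
        raise ValueError("risk threshold must be in (0, 1)")
    v = spec.v
    if v <= 0.0:
        return 1.0 if spec.f > risk_threshold else 0.0
    g_star = spec.threshold - np.sqrt(max(1.0 - v, 0.0)) * norm.ppf(1.0 - risk_threshold)
    return float(1.0 - norm.cdf(g_star / np.sqrt(v)))


def max_snp_auc(f: float, h2: float) -> float:
    """Ceiling AUC of a genetic model explaining all heritability (pi = 1)."""
    return snp_auc(DiseaseSpec(f=f, h2=h2, pi=1.0))


def equivalent_pi(f: float, h2: float, auc_target: float, tol: float = 1e-8) -> float:
    """Proportion of heritability a SNP model must explain to reach a target AUC.

    Inverts the strictly increasing map pi -> AUC by bracketed root-finding
    on [0, 1]. A target of 0.5 maps to 0; a target above the pi = 1 ceiling
    raises with the maximum attainable AUC in the message.
    """
    if not 0.5 <= auc_target < 1.0:
        raise ValueError(f"target AUC must be in [0.5, 1), got {auc_target}")
    if auc_target == 0.5:
        return 0.0
    ceiling = max_snp_auc(f, h2)
    if auc_target > ceiling + 1e-12:
        raise ValueError(
            f"target AUC {auc_target} exceeds the maximum attainable "
            f"{ceiling:.6f} at pi = 1 for f={f}, h2={h2}"
        )
    if auc_target >= ceiling:
        return 1.0
    return float(
        brentq(
            lambda pi: snp_auc(DiseaseSpec(f=f, h2=h2, pi=pi)) - auc_target,
            0.0,
            1.0,
            xtol=tol,
        )
    )
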