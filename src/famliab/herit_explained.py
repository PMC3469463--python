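"""Proportion of heritability explained by a list of SNP associations.

Starting from curated (frequency, allelic odds ratio, p-value, sample-size)
records, the pipeline (i) greedily selects an approximately independent set
of genome-wide-significant associations under a pairwise r-squared cap,
(ii) shrinks reported odds ratios for winner's-curse bias by inverting the
expectation of a significance-truncated normal z-score, (iii) converts each
association to the variance it explains on the unit liability scale via
genotype-specific liability thresholds (the So/Risch construction), and
(iv) sums the per-SNP variances and divides by h2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from famliab.liability_core import DiseaseSpec

#: Genome-wide significance threshold for European-ancestry studies.
DEFAULT_ALPHA = 5e-8
#: Pairwise r-squared cap ensuring approximate independence of markers.
DEFAULT_R2_MAX = 0.005


@dataclass(frozen=True)
class SnpAssociation:
    """One variant's association record.

    ``risk_allele_freq`` is the population frequency of the risk allele,
    ``allelic_or`` the multiplicative per-allele odds ratio (genotype odds
    1 : R : R^2), and ``se_log_or``, when absent, is back-computed from the
    two-sided p-value as |log R| / Phi^-1(1 - p/2).
    """

    id: str
    risk_allele_freq: float
    allelic_or: float
    p_value: float
    n_cases: float
    n_controls: float
    risk_allele: str | None = None
    se_log_or: float | None = None

    def __post_init__(self):
        if not 0.0 < self.risk_allele_freq < 1.0:
            raise ValueError(f"{self.id}: risk allele frequency must be in (0, 1)")
        if self.allelic_or <= 0.0:
            raise ValueError(f"{self.id}: odds ratio must be positive")
        if min(self.n_cases, self.n_controls) <= 0:
            raise ValueError(f"{self.id}: case/control counts must be positive")

    @property
    def effective_n(self) -> float:
        """Harmonic mean of the case and control counts (study power ranking)."""
        return 2.0 / (1.0 / self.n_cases + 1.0 / self.n_controls)

    @property
    def log_or(self) -> float:
        return float(np.log(self.allelic_or))

    def se(self) -> float:
        if self.se_log_or is not None:
            return float(self.se_log_or)
        z = norm.ppf(1.0 - self.p_value / 2.0)
        if z <= 0:
            raise ValueError(f"{self.id}: cannot derive a standard error from p={self.p_value}")
        return abs(self.log_or) / z


@dataclass
class VarianceExplainedReport:
    """Per-SNP and total liability-scale variance explained, and pi = V / h2."""

    snp_ids: list[str]
    variance_raw: np.ndarray
    variance_corrected: np.ndarray
    total_raw: float
    total_corrected: float
    pi_raw: float
    pi_corrected: float
    corrected: bool = True
    clipped: bool = field(default=False, repr=False)

    @property
    def pi(self) -> float:
        return self.pi_corrected if self.corrected else self.pi_raw

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.snp_ids,
                "variance_raw": self.variance_raw,
                "variance_corrected": self.variance_corrected,
            }
        )


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


def greedy_select(
    assocs: list[SnpAssociation],
    r2: pd.DataFrame | None = None,
    r2_max: float = DEFAULT_R2_MAX,
    alpha: float = DEFAULT_ALPHA,
) -> list[SnpAssociation]:
    """Greedy selection of approximately independent significant associations.

    Associations with p > alpha are dropped; the rest are ordered by
    effective sample size (descending, ties by smaller p-value) and
    accepted greedily when their r-squared with every previously accepted
    marker is at most ``r2_max``. ``r2`` is a square symmetric DataFrame
    indexed by variant id; a missing entry is treated as 1 (conservative
    exclusion) with a warning. With no r2 matrix all markers are treated
    as mutually independent.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    candidates = [a for a in assocs if a.p_value <= alpha]
    candidates.sort(key=lambda a: (-a.effective_n, a.p_value))
    if r2 is None:
        return candidates
    selected: list[SnpAssociation] = []
    warned = False
    for cand in candidates:
        ok = True
        for acc in selected:
            try:
                rho = float(r2.loc[cand.id, acc.id])
            except KeyError:
                rho = np.nan
            if np.isnan(rho):
                if not warned:
                    warnings.warn(
                        f"missing r2 entry for pair ({cand.id}, {acc.id}); "
                        "treating missing linkage values as 1 (conservative exclusion)",
                        stacklevel=2,
                    )
                    warned = True
                rho = 1.0
            if rho > r2_max:
                ok = False
                break
        if ok:
            selected.append(cand)
    return selected


# ---------------------------------------------------------------------------
# winner's-curse correction
# ---------------------------------------------------------------------------


def winners_curse_correct(
    log_or: float,
    se: float,
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Shrink a reported log odds ratio for significance-conditioned bias.

    Model: the observed z = b/s is drawn from N(mu, 1) truncated to
    |z| > c, c = Phi^-1(1 - alpha/2). The corrected estimate solves

        mu + [phi(c - mu) - phi(c + mu)] / [Phi(mu - c) + Phi(-mu - c)] = b/s

    for mu by bracketed root-finding and returns mu * s. Requires the
    association to be genome-wide significant (|z| >= c). The correction is
    odd-symmetric and strictly shrinks toward zero.
    """
    if se <= 0:
        raise ValueError("standard error must be positive")
    c = norm.ppf(1.0 - alpha / 2.0)
    z = log_or / se
    if abs(z) < c * (1.0 - 1e-12):  # tolerate round-off at the boundary
        raise ValueError(
            f"association is not significant at alpha={alpha:g} "
            f"(|z| = {abs(z):.3f} < {c:.3f}); correction undefined"
        )
    sign = 1.0 if z >= 0 else -1.0
    z_abs = abs(z)

    def expected_z(mu: float) -> float:
        denom = norm.cdf(mu - c) + norm.cdf(-mu - c)
        return mu + (norm.pdf(c - mu) - norm.pdf(c + mu)) / denom

    # expected_z is increasing in mu with expected_z(0) = 0 and
    # expected_z(mu) > mu, so the root lies in (0, z_abs]
    lo, hi = 0.0, z_abs
    if expected_z(hi) < z_abs:  # numerically flat tail; no shrinkage possible
        return log_or
    mu = brentq(lambda m: expected_z(m) - z_abs, lo, hi, xtol=1e-12)
    return float(sign * mu * se)


# ---------------------------------------------------------------------------
# per-SNP variance explained
# ---------------------------------------------------------------------------


def _genotype_risks(p: float, R: float, f: float) -> tuple[np.ndarray, np.ndarray]:
    """HWE genotype frequencies and genotype-specific lifetime risks.

    Genotype odds are o0 * R^j for j risk alleles; the baseline odds o0 is
    solved so the population risk averages to f.
    """
    q = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    Rj = np.array([1.0, R, R**2])

    def mean_risk(log_o0: float) -> float:
        o = np.exp(log_o0) * Rj
        return float(q @ (o / (1.0 + o))) - f

    base = np.log(f / (1.0 - f))
    lo, hi = base - 2 * abs(np.log(R)) - 60.0, base + 2 * abs(np.log(R)) + 60.0
    log_o0 = brentq(mean_risk, lo, hi, xtol=1e-14)
    o = np.exp(log_o0) * Rj
    fj = o / (1.0 + o)
    if np.any((fj <= 0.0) | (fj >= 1.0)):
        raise ValueError(
            f"genotype risks outside (0, 1); odds ratio {R} and frequency {p} "
            f"are incompatible with lifetime risk {f}"
        )
    return q, fj


def snp_variance_explained(assoc_or_params, spec: DiseaseSpec) -> float:
    """Liability-scale variance explained by one biallelic association.

    Each genotype class j gets its own liability threshold
    T_j = Phi^-1(1 - f_j) against a unit-variance residual; the genotype's
    mean liability shift is m_j = T - T_j. The between-genotype variance
    V = Var(m_J) of the shifts, against the unit residual, explains
    V / (1 + V) of total liability variance after rescaling to a
    unit-variance total scale.
    """
    if isinstance(assoc_or_params, SnpAssociation):
        p, R = assoc_or_params.risk_allele_freq, assoc_or_params.allelic_or
    else:
        p, R = assoc_or_params
    if R == 1.0:
        return 0.0
    q, fj = _genotype_risks(p, R, spec.f)
    T = spec.threshold
    m = T - norm.ppf(1.0 - fj)
    V = float(q @ m**2 - (q @ m) ** 2)
    return V / (1.0 + V)


def total_pi(
    assocs: list[SnpAssociation],
    spec: DiseaseSpec,
    corrected: bool = True,
    alpha: float = DEFAULT_ALPHA,
) -> VarianceExplainedReport:
    """Sum per-SNP liability variances (independence assumed) and divide by h2.

    Reports both raw and winner's-curse-corrected totals; ``corrected``
    selects which one ``report.pi`` exposes. A pi above 1 is clipped with a
    prominent warning.
    """
    if spec.h2 <= 0:
        raise ValueError("total_pi requires a positive heritability")
    ids, raw, corr = [], [], []
    for a in assocs:
        ids.append(a.id)
        raw.append(snp_variance_explained(a, spec))
        b_corr = winners_curse_correct(a.log_or, a.se(), alpha=alpha)
        corr.append(snp_variance_explained((a.risk_allele_freq, float(np.exp(b_corr))), spec))
    raw = np.asarray(raw)
    corr = np.asarray(corr)
    v_raw, v_corr = float(raw.sum()), float(corr.sum())
    pi_raw, pi_corr = v_raw / spec.h2, v_corr / spec.h2
    clipped = False
    if max(pi_raw, pi_corr) > 1.0:
        warnings.warn(
            f"estimated proportion of heritability explained exceeds 1 "
            f"(raw {pi_raw:.3f}, corrected {pi_corr:.3f}); clipping to 1 — "
            "the association list is likely not independent",
            stacklevel=2,
        )
        clipped = True
        pi_raw, pi_corr = min(pi_raw, 1.0), min(pi_corr, 1.0)
    return VarianceExplainedReport(
        snp_ids=ids,
        variance_raw=raw,
        variance_corrected=corr,
        total_raw=v_raw,
        total_corrected=v_corr,
        pi_raw=pi_raw,
        pi_corrected=pi_corr,
        corrected=corrected,
        clipped=clipped,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["id", "risk_allele", "freq", "OR", "pval", "n_cases", "n_controls"]


def load_associations(path) -> list[SnpAssociation]:
    """Read a TSV of associations: id, risk_allele, freq, OR, pval, n_cases, n_controls[, se]."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"association table is missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SnpAssociation(
                id=str(row["id"]),
                risk_allele=str(row["risk_allele"]),
                risk_allele_freq=float(row["freq"]),
                allelic_or=float(row["OR"]),
                p_value=float(row["pval"]),
                n_cases=float(row["n_cases"]),
                n_controls=float(row["n_controls"]),
                se_log_or=float(row["se"]) if "se" in df.columns and pd.notna(row["se"]) else None,
            )
        )
    return out


def load_r2_matrix(path) -> pd.DataFrame:
    """Read a square r-squared TSV with variant ids as both header and index."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError("r2 matrix must be square with matching row/column ids")
    return df
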