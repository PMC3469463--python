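import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from famliab import (
    DiseaseSpec,
    SnpAssociation,
    greedy_select,
    load_associations,
    load_r2_matrix,
    snp_variance_explained,
    total_pi,
    winners_curse_correct,
)
from famliab.herit_explained import DEFAULT_ALPHA, _genotype_risks

SPEC = DiseaseSpec(f=0.05, h2=0.5)


def assoc(id, freq=0.3, orr=1.2, pval=1e-9, nca=5000, nco=5000, se=None):
    return SnpAssociation(
        id=id, risk_allele_freq=freq, allelic_or=orr, p_value=pval,
        n_cases=nca, n_controls=nco, se_log_or=se,
    )


class TestGreedySelect:
    def test_independent_snps_all_kept(self):
        assocs = [assoc(f"s{i}") for i in range(4)]
        r2 = pd.DataFrame(np.eye(4) * 0.0, index=[a.id for a in assocs],
                          columns=[a.id for a in assocs])
        assert len(greedy_select(assocs, r2)) == 4

    def test_nonsignificant_dropped(self):
        kept = greedy_select([assoc("a"), assoc("b", pval=1e-4)])
        assert [a.id for a in kept] == ["a"]

    def test_correlated_pair_keeps_better_powered(self):
        a = assoc("big", nca=20000, nco=20000)
        b = assoc("small", nca=1000, nco=1000)
        ids = ["big", "small"]
        r2 = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=ids, columns=ids)
        kept = greedy_select([b, a], r2)
        assert [x.id for x in kept] == ["big"]

    def test_missing_r2_is_conservative(self):
        a, b = assoc("a", nca=9000, nco=9000), assoc("b")
        r2 = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        with pytest.warns(UserWarning, match="missing r2"):
            kept = greedy_select([a, b], r2)
        assert [x.id for x in kept] == ["a"]

    def test_matches_brute_force_re_execution(self):
        rng = np.random.default_rng(2)
        ids = [f"s{i}" for i in range(5)]
        assocs = [
            assoc(i, nca=int(rng.integers(500, 20000)), nco=int(rng.integers(500, 20000)),
                  pval=float(10 ** -rng.uniform(8, 20)))
            for i in ids
        ]
        m = rng.uniform(0, 0.02, (5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        r2 = pd.DataFrame(m, index=ids, columns=ids)
        kept = {a.id for a in greedy_select(assocs, r2, r2_max=0.005)}
        # independent re-execution of the published rule
        ordered = sorted(assocs, key=lambda a: (-a.effective_n, a.p_value))
        expected = []
        for cand in ordered:
            if all(r2.loc[cand.id, acc] <= 0.005 for acc in expected):
                expected.append(cand.id)
        assert kept == set(expected)


class TestWinnersCurse:
    def test_negligible_for_overwhelming_significance(self):
        b, s = 3.0, 0.1  # z = 30
        corrected = winners_curse_correct(b, s)
        assert abs(corrected - b) < 1e-3 * abs(b)

    def test_strict_shrinkage_at_the_boundary(self):
        s = 0.05
        c = norm.ppf(1 - DEFAULT_ALPHA / 2)
        b = c * s  # exactly genome-wide significant
        corrected = winners_curse_correct(b, s)
        assert 0.0 <= corrected < b

    def test_odd_symmetry(self):
        b, s = 0.32, 0.05
        assert winners_curse_correct(-b, s) == pytest.approx(
            -winners_curse_correct(b, s), abs=1e-12
        )

    def test_nonsignificant_rejected(self):
        with pytest.raises(ValueError, match="not significant"):
            winners_curse_correct(0.1, 0.05)

    def test_reduces_bias_in_simulation(self):
        """In the winner's-curse regime — a true effect below the discovery
        threshold, observed only when it fluctuates past it — the corrected
        estimate is closer to the truth on average than the raw one."""
        rng = np.random.default_rng(7)
        s = 0.1
        c = norm.ppf(1 - DEFAULT_ALPHA / 2)
        beta = 0.45  # z_true = 4.5, below the threshold c ~ 5.45
        raws, corrs = [], []
        while len(raws) < 10_000:
            b = rng.normal(beta, s, size=4000)
            sig = np.abs(b / s) >= c
            for bi in b[sig]:
                raws.append(bi)
                corrs.append(winners_curse_correct(float(bi), s))
        raw_bias = np.mean(raws) - beta
        corr_bias = np.mean(corrs) - beta
        assert abs(corr_bias) < abs(raw_bias)
        assert raw_bias > 0  # selection inflates


class TestVarianceExplained:
    def test_null_effect_explains_nothing(self):
        assert snp_variance_explained(assoc("x", orr=1.0), SPEC) == 0.0

    def test_allele_label_invariance(self):
        v1 = snp_variance_explained(assoc("x", freq=0.3, orr=1.4), SPEC)
        v2 = snp_variance_explained(assoc("x", freq=0.7, orr=1 / 1.4), SPEC)
        assert v1 == pytest.approx(v2, rel=1e-9)

    def test_monotone_in_odds_ratio(self):
        vs = [snp_variance_explained(assoc("x", orr=r), SPEC) for r in (1.05, 1.2, 1.5, 2.0)]
        assert all(a < b for a, b in zip(vs, vs[1:]))

    def test_small_effect_closed_form(self):
        """First-order theory: V ~ 2p(1-p) [beta f(1-f) / phi(T)]^2."""
        p, R = 0.4, 1.04
        beta = np.log(R)
        f, T = SPEC.f, SPEC.threshold
        approx = 2 * p * (1 - p) * (beta * f * (1 - f) / norm.pdf(T)) ** 2
        v = snp_variance_explained(assoc("x", freq=p, orr=R), SPEC)
        assert v == pytest.approx(approx / (1 + approx), rel=0.05)

    def test_genotype_risks_average_to_prevalence(self):
        q, fj = _genotype_risks(0.25, 1.5, SPEC.f)
        assert float(q @ fj) == pytest.approx(SPEC.f, abs=1e-10)
        # multiplicative odds: middle genotype odds are the geometric mean
        odds = fj / (1 - fj)
        assert odds[1] ** 2 == pytest.approx(odds[0] * odds[2], rel=1e-8)

    def test_simulation_oracle(self):
        """Genotype-attributable liability variance in a forward simulation."""
        p, R = 0.3, 1.6
        q, fj = _genotype_risks(p, R, SPEC.f)
        T = SPEC.threshold
        m = T - norm.ppf(1 - fj)  # genotype liability shifts against unit residual
        rng = np.random.default_rng(123)
        n = 1_000_000
        geno = rng.binomial(2, p, size=n)
        shifts = m[geno]
        status = shifts + rng.standard_normal(n) >= T
        # prevalence calibration
        assert abs(status.mean() - SPEC.f) <= 3 * np.sqrt(SPEC.f * (1 - SPEC.f) / n)
        # variance of the genotype shifts, rescaled to total variance 1 + V
        dev = (shifts - shifts.mean()) ** 2
        V_emp = dev.mean()
        se = dev.std(ddof=1) / np.sqrt(n)
        V_th = snp_variance_explained(assoc("x", freq=p, orr=R), SPEC)
        assert abs(V_emp / (1 + V_emp) - V_th) <= 3 * se

    def test_incompatible_parameters_raise(self):
        with pytest.raises(ValueError, match="odds ratio"):
            SnpAssociation(id="bad", risk_allele_freq=0.5, allelic_or=-2.0,
                           p_value=1e-9, n_cases=100, n_controls=100)


class TestTotalPi:
    def test_empty_list(self):
        report = total_pi([], SPEC)
        assert report.pi_raw == 0.0 and report.pi_corrected == 0.0

    def test_duplicated_snp_doubles(self):
        a = assoc("x", orr=1.3)
        one = total_pi([a], SPEC)
        two = total_pi([a, a], SPEC)
        assert two.total_raw == pytest.approx(2 * one.total_raw)

    def test_correction_shrinks_borderline_list(self):
        rng = np.random.default_rng(5)
        assocs = [
            assoc(f"s{i}", freq=float(rng.uniform(0.1, 0.9)),
                  orr=float(np.exp(rng.uniform(0.28, 0.35))),
                  se=0.05, pval=1e-8)
            for i in range(6)
        ]
        report = total_pi(assocs, SPEC)
        assert report.total_corrected < report.total_raw
        assert 0 <= report.pi_corrected <= report.pi_raw

    def test_overflow_clipped_with_warning(self):
        assocs = [assoc(f"s{i}", orr=3.0, se=0.01) for i in range(40)]
        with pytest.warns(UserWarning, match="clipping"):
            report = total_pi(assocs, DiseaseSpec(f=0.05, h2=0.05))
        assert report.pi_raw == 1.0 and report.clipped


class TestIO:
    def test_association_table_roundtrip(self, tmp_path):
        path = tmp_path / "assoc.tsv"
        path.write_text(
            "id\trisk_allele\tfreq\tOR\tpval\tn_cases\tn_controls\tse\n"
            "rs1\tA\t0.3\t1.25\t1e-10\t5000\t8000\t0.02\n"
            "rs2\tG\t0.6\t1.10\t2e-9\t4000\t4000\t\n"
        )
        assocs = load_associations(path)
        assert [a.id for a in assocs] == ["rs1", "rs2"]
        assert assocs[0].se() == 0.02
        assert assocs[1].se() == pytest.approx(
            abs(np.log(1.10)) / norm.ppf(1 - 2e-9 / 2)
        )

    def test_r2_matrix_roundtrip(self, tmp_path):
        path = tmp_path / "ld.tsv"
        path.write_text("\trs1\trs2\nrs1\t1.0\t0.2\nrs2\t0.2\t1.0\n")
        r2 = load_r2_matrix(path)
        assert r2.loc["rs1", "rs2"] == 0.2
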