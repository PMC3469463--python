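import numpy as np
import pytest
from scipy.stats import norm

from famliab import (
    DiseaseSpec,
    Individual,
    Pedigree,
    case_control_moments,
    equivalent_pi,
    extreme_lr_fraction_continuous,
    risk_given_g,
    snp_auc,
    snp_roc,
)
from famliab.simulate import SimConfig, empirical_auc, simulate_families
from famliab.snp_model import fraction_above_risk, likelihood_ratio_given_g, max_snp_auc

from conftest import auc_se

SPECS = [
    DiseaseSpec(f=0.402, h2=0.49, pi=0.069),
    DiseaseSpec(f=0.132, h2=0.79, pi=0.100),
    DiseaseSpec(f=0.018, h2=0.87, pi=0.045),
    DiseaseSpec(f=0.005, h2=0.56, pi=0.135),
]


def quadrature_moments(spec, n_grid=200_001, width=40.0):
    """Oracle: integrate the exact (non-normal) conditional density of g."""
    v = spec.v
    sd = np.sqrt(v)
    g = np.linspace(-width * sd, width * sd, n_grid)
    dens = norm.pdf(g, scale=sd)
    p_case_given_g = 1.0 - norm.cdf((spec.threshold - g) / np.sqrt(1.0 - v))
    w_case = dens * p_case_given_g
    w_ctrl = dens * (1.0 - p_case_given_g)
    out = []
    for w in (w_case, w_ctrl):
        total = np.trapezoid(w, g)
        mu = np.trapezoid(w * g, g) / total
        var = np.trapezoid(w * (g - mu) ** 2, g) / total
        out.append((mu, var))
    return out


class TestMoments:
    def test_symmetric_disease(self):
        spec = DiseaseSpec(f=0.5, h2=0.6, pi=0.5)
        m = case_control_moments(spec)
        expected = spec.v * norm.pdf(0.0) / 0.5
        assert m.mu_case == pytest.approx(expected)
        assert m.mu_control == pytest.approx(-expected)
        assert m.var_case == pytest.approx(m.var_control)

    @pytest.mark.parametrize("spec", SPECS, ids=lambda s: f"f{s.f}")
    def test_matches_quadrature_oracle(self, spec):
        m = case_control_moments(spec)
        (mu_c, var_c), (mu_k, var_k) = quadrature_moments(spec)
        assert m.mu_case == pytest.approx(mu_c, abs=1e-6)
        assert m.var_case == pytest.approx(var_c, abs=1e-6)
        assert m.mu_control == pytest.approx(mu_k, abs=1e-6)
        assert m.var_control == pytest.approx(var_k, abs=1e-6)

    def test_degenerate_when_nothing_measured(self):
        m = case_control_moments(DiseaseSpec(f=0.1, h2=0.8, pi=0.0))
        assert m.degenerate and m.mu_case == 0.0


class TestSnpAuc:
    def test_no_information_is_half(self):
        assert snp_auc(DiseaseSpec(f=0.1, h2=0.8, pi=0.0)) == 0.5

    def test_strictly_increasing_in_pi(self):
        aucs = [snp_auc(DiseaseSpec(f=0.1, h2=0.8, pi=p)) for p in np.linspace(0.05, 1, 12)]
        assert all(a < b for a, b in zip(aucs, aucs[1:]))

    def test_ceiling_grows_as_disease_rarefies(self):
        ceilings = [max_snp_auc(f, 0.6) for f in (0.4, 0.2, 0.1, 0.02, 0.005)]
        assert all(a < b for a, b in zip(ceilings, ceilings[1:]))

    def test_monte_carlo_oracle(self):
        """Empirical rank AUC of simulated measured liabilities matches closed form."""
        spec = DiseaseSpec(f=0.402, h2=0.49, pi=0.069)
        one = Pedigree([Individual("x", is_index=True)])
        sim = simulate_families(SimConfig(spec=spec, ped=one, n_replicates=500_000, seed=9))
        a_emp = empirical_auc(sim.index_status, sim.measured_g)
        a_th = snp_auc(spec)
        n_case = int(sim.index_status.sum())
        assert abs(a_emp - a_th) <= 3 * auc_se(a_th, n_case, len(sim.index_status) - n_case)


class TestSnpRoc:
    @pytest.mark.parametrize("spec", SPECS[:2], ids=lambda s: f"f{s.f}")
    def test_area_consistent_with_auc(self, spec):
        curve = snp_roc(spec)
        area = np.trapezoid(curve.tpr, curve.fpr)
        assert area == pytest.approx(snp_auc(spec), abs=1e-4)

    def test_endpoints_and_dominance(self):
        curve = snp_roc(DiseaseSpec(f=0.1, h2=0.8, pi=0.3))
        assert curve.fpr[0] == 0.0 and curve.tpr[-1] == 1.0
        assert np.all(curve.tpr >= curve.fpr - 1e-12)


class TestRiskGivenG:
    def test_zero_information_returns_prior(self):
        spec = DiseaseSpec(f=0.13, h2=0.5, pi=0.0)
        assert risk_given_g(spec, 1.7) == pytest.approx(0.13)

    def test_averages_to_prevalence(self):
        spec = DiseaseSpec(f=0.05, h2=0.7, pi=0.4)
        sd = np.sqrt(spec.v)
        g = np.linspace(-10 * sd, 10 * sd, 40_001)
        mean_risk = np.trapezoid(risk_given_g(spec, g) * norm.pdf(g, scale=sd), g)
        assert mean_risk == pytest.approx(spec.f, abs=1e-7)

    def test_monotone_in_g(self):
        spec = DiseaseSpec(f=0.05, h2=0.7, pi=0.4)
        g = np.linspace(-1, 1, 101)
        r = risk_given_g(spec, g)
        assert np.all(np.diff(r) > 0)

    def test_full_information_step(self):
        spec = DiseaseSpec(f=0.05, h2=1.0, pi=1.0)
        T = spec.threshold
        assert risk_given_g(spec, T + 0.01) == 1.0
        assert risk_given_g(spec, T - 0.01) == 0.0


class TestLikelihoodRatio:
    def test_control_expectation_is_one(self):
        spec = DiseaseSpec(f=0.05, h2=0.7, pi=0.4)
        sd = np.sqrt(spec.v)
        g = np.linspace(-10 * sd, 10 * sd, 40_001)
        dens_ctrl = norm.pdf(g, scale=sd) * (1 - risk_given_g(spec, g)) / (1 - spec.f)
        mean_lr = np.trapezoid(likelihood_ratio_given_g(spec, g) * dens_ctrl, g)
        assert mean_lr == pytest.approx(1.0, abs=1e-6)

    def test_threshold_one_includes_everyone(self):
        spec = DiseaseSpec(f=0.05, h2=0.7, pi=0.4)
        assert extreme_lr_fraction_continuous(spec, 1.0) == pytest.approx(1.0)

    def test_fraction_shrinks_with_threshold(self):
        spec = DiseaseSpec(f=0.005, h2=0.56, pi=0.135)
        fracs = [extreme_lr_fraction_continuous(spec, x) for x in (2, 5, 10, 50)]
        assert all(a > b for a, b in zip(fracs, fracs[1:]))

    def test_monte_carlo_tail_fraction(self):
        spec = DiseaseSpec(f=0.005, h2=0.56, pi=0.135)
        rng = np.random.default_rng(17)
        g = rng.normal(0.0, np.sqrt(spec.v), size=400_000)
        lr = likelihood_ratio_given_g(spec, g)
        emp = np.mean((lr >= 5) | (lr <= 0.2))
        th = extreme_lr_fraction_continuous(spec, 5.0)
        assert abs(emp - th) <= 3 * np.sqrt(th * (1 - th) / len(g))


class TestFractionAboveRisk:
    def test_tail_shrinks_with_threshold(self):
        spec = DiseaseSpec(f=0.1, h2=0.8, pi=0.5)
        assert fraction_above_risk(spec, 0.2) > fraction_above_risk(spec, 0.5)

    def test_matches_direct_formula(self):
        spec = DiseaseSpec(f=0.005, h2=0.56, pi=1.0)
        # r(g) > 1/2 iff g > T, so the fraction is the tail of N(0, v) past T
        expected = 1 - norm.cdf(spec.threshold / np.sqrt(spec.v))
        assert fraction_above_risk(spec, 0.5) == pytest.approx(expected, rel=1e-9)


class TestEquivalentPi:
    def test_half_auc_needs_nothing(self):
        assert equivalent_pi(0.402, 0.49, 0.5) == 0.0

    @pytest.mark.parametrize("pi", [0.05, 0.2, 0.6, 0.95])
    def test_round_trip(self, pi):
        spec = DiseaseSpec(f=0.1, h2=0.7, pi=pi)
        assert equivalent_pi(0.1, 0.7, snp_auc(spec)) == pytest.approx(pi, abs=1e-6)

    def test_unattainable_target_reports_ceiling(self):
        with pytest.raises(ValueError, match="maximum attainable"):
            equivalent_pi(0.402, 0.49, 0.99)
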