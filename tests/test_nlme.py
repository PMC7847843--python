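"""Estimation engine: likelihood oracles, EBEs, information criteria, CWRES."""

import numpy as np
import pytest

from gcvpk.data import DoseEvent, Observation, PKDataset, Subject
from gcvpk.nlme import (
    _BatchData,
    _prepare,
    aic,
    base_model_spec,
    bic,
    ebe,
    ebes,
    fit,
    foce_ofv,
    individual_neg2ll,
)


def _single_subject_dataset(obs, cl=5.0, vd=10.0, rate_for_f4=None, n_doses=1):
    subject = Subject("s1", wt=12.0, height=90.0, age=2.5, sex="M", scr=26.0, egfr=120.0)
    amount = rate_for_f4 if rate_for_f4 is not None else 60.0
    doses = [DoseEvent(i * 12.0, amount, 1.0) for i in range(n_doses)]
    return PKDataset(subjects=[subject], doses={"s1": doses},
                     observations={"s1": obs})


@pytest.fixture(scope="module")
def small_fit(small_dataset, final_spec):
    ds, _ = small_dataset
    return fit(ds, final_spec, seed=0, n_restarts=0, n_polish=2)


class TestIndividualLikelihood:
    def test_proportional_error_density_term(self):
        # dose sized so the prediction at end of infusion is exactly 4.0,
        # then the -2LL data term for y=4.4 under 8.23% proportional error
        # matches the hand-evaluated Gaussian density
        cl, vd = 5.0, 10.0
        ke = cl / vd
        amount = 4.0 * cl / (1.0 - np.exp(-ke * 1.0))
        ds = _single_subject_dataset([Observation(1.0, 4.4)], rate_for_f4=amount)
        sd = _prepare(ds, "censored")[0]
        got = individual_neg2ll(np.zeros(2), sd, cl, vd, np.zeros(2), 0.0823, 0.0)
        s = 0.0823 * 4.0
        expected = np.log(2 * np.pi) + 2 * np.log(s) + (0.4 / s) ** 2
        assert got == pytest.approx(expected, abs=1e-10)
        assert got == pytest.approx(1.0920, abs=2e-4)

    def test_perfect_fit_leaves_only_log_variance(self):
        cl, vd = 5.0, 10.0
        amount = 4.0 * cl / (1.0 - np.exp(-cl / vd))
        ds = _single_subject_dataset([Observation(1.0, 4.0)], rate_for_f4=amount)
        sd = _prepare(ds, "censored")[0]
        got = individual_neg2ll(np.zeros(2), sd, cl, vd, np.zeros(2), 0.0823, 0.0)
        assert got == pytest.approx(np.log(2 * np.pi) + 2 * np.log(0.0823 * 4.0),
                                    abs=1e-10)

    def test_prior_term_at_zero_is_log_determinant(self):
        ds = _single_subject_dataset([])
        sd = _prepare(ds, "censored")[0]
        omega2 = np.array([0.04, 0.25])
        got = individual_neg2ll(np.zeros(2), sd, 5.0, 10.0, omega2, 0.1, 0.0)
        assert got == pytest.approx(
            2 * np.log(2 * np.pi) + np.log(0.04) + np.log(0.25), abs=1e-12
        )


class TestFoceObjective:
    def test_zero_iiv_equals_exact_neg2ll(self, small_dataset, final_spec):
        """With omega = 0 the FOCE objective is the exact fixed-effect -2LL."""
        ds, man = small_dataset
        theta = dict(theta_cl=5.23, theta_vd=11.35, theta1=0.8, theta2=0.92,
                     theta3=1.02)
        got = foce_ofv(ds, final_spec, theta, (0.0, 0.0), (0.0823, 0.0))
        exact = 0.0
        for sd in _prepare(ds, "censored"):
            exact += individual_neg2ll(np.zeros(2), sd,
                                       final_spec.cl(theta, sd.subject),
                                       final_spec.vd(theta, sd.subject),
                                       np.zeros(2), 0.0823, 0.0)
        assert got == pytest.approx(exact, abs=1e-8)

    def test_matches_quadrature_marginal_for_small_iiv(self):
        """Laplace equals brute-force integration when the integrand is
        effectively Gaussian (tiny random-effect variance, data generated
        near the typical profile)."""
        obs = [Observation(1.0, 4.75), Observation(3.0, 1.72), Observation(6.5, 0.30)]
        ds = _single_subject_dataset(obs)
        spec = base_model_spec()
        theta = dict(theta_cl=5.0, theta_vd=10.0)
        omega = (0.001, 0.001)
        got = foce_ofv(ds, spec, theta, omega, (0.1, 0.0))
        sd = _prepare(ds, "censored")[0]

        def joint_density(e0, e1):
            g = individual_neg2ll(np.array([e0, e1]), sd, 5.0, 10.0,
                                  np.array(omega) ** 2, 0.1, 0.0)
            return np.exp(-0.5 * g)

        grid = np.linspace(-5 * 0.001, 5 * 0.001, 201)
        vals = np.array([[joint_density(a, b) for b in grid] for a in grid])
        integral = np.trapezoid(np.trapezoid(vals, grid, axis=1), grid)
        assert got == pytest.approx(-2.0 * np.log(integral), abs=1e-4)

    def test_close_to_quadrature_marginal_for_moderate_iiv(self):
        """At realistic variability the conditional approximation tracks the
        exact marginal to a fraction of a likelihood unit."""
        obs = [Observation(1.0, 4.75), Observation(3.0, 1.72), Observation(6.5, 0.30)]
        ds = _single_subject_dataset(obs)
        spec = base_model_spec()
        theta = dict(theta_cl=5.0, theta_vd=10.0)
        omega = (0.15, 0.4)
        got = foce_ofv(ds, spec, theta, omega, (0.1, 0.0))
        sd = _prepare(ds, "censored")[0]
        g0, g1 = np.linspace(-0.9, 0.9, 121), np.linspace(-2.4, 2.4, 161)
        vals = np.array([
            [np.exp(-0.5 * individual_neg2ll(np.array([a, b]), sd, 5.0, 10.0,
                                             np.array(omega) ** 2, 0.1, 0.0))
             for b in g1] for a in g0
        ])
        integral = np.trapezoid(np.trapezoid(vals, g1, axis=1), g0)
        assert got == pytest.approx(-2.0 * np.log(integral), abs=0.5)

    def test_nested_model_dominance(self, small_dataset, small_fit, final_spec):
        """A richer nested model cannot fit worse than its reduction."""
        ds, _ = small_dataset
        base = fit(ds, base_model_spec(), seed=0, n_restarts=0, n_polish=1)
        assert small_fit.ofv <= base.ofv + 1e-6

    def test_censored_records_lower_the_likelihood_little_when_consistent(self,
                                                                          final_spec):
        # a below-LLOQ record whose prediction is also tiny adds ~0 cost
        subject = Subject("s1", 12.0, 90.0, 2.5, "M", 26.0, 120.0)
        doses = [DoseEvent(0.0, 60.0, 1.0)]
        obs = [Observation(1.0, 4.2), Observation(11.9, 0.02, below_loq=True)]
        ds = PKDataset([subject], {"s1": doses}, {"s1": obs})
        theta = dict(theta_cl=5.23, theta_vd=11.35, theta1=0.8, theta2=0.92,
                     theta3=1.02)
        with_cens = foce_ofv(ds, final_spec, theta, (0.0, 0.0), (0.0823, 0.0))
        ds2 = PKDataset([subject], {"s1": doses}, {"s1": obs[:1]})
        without = foce_ofv(ds2, final_spec, theta, (0.0, 0.0), (0.0823, 0.0))
        assert 0 <= with_cens - without < 0.1


class TestEmpiricalBayes:
    def test_no_observations_gives_prior_mode(self):
        ds = _single_subject_dataset([])
        spec = base_model_spec()
        got = ebe(ds, spec, dict(theta_cl=5.0, theta_vd=10.0), (0.2, 0.4),
                  (0.1, 0.0), "s1")
        assert np.allclose(got, 0.0)

    def test_vanishing_iiv_shrinks_to_zero(self):
        ds = _single_subject_dataset([Observation(1.0, 6.0)])
        spec = base_model_spec()
        got = ebe(ds, spec, dict(theta_cl=5.0, theta_vd=10.0), (1e-8, 1e-8),
                  (0.1, 0.0), "s1")
        assert np.max(np.abs(got)) < 1e-4

    def test_rich_data_recovers_true_effects(self):
        """50 low-noise observations pin the subject's (eta_CL, eta_Vd)."""
        rng = np.random.default_rng(3)
        eta_true = np.array([0.2, -0.1])
        cl, vd = 5.0 * np.exp(eta_true[0]), 10.0 * np.exp(eta_true[1])
        subject = Subject("s1", 12.0, 90.0, 2.5, "M", 26.0, 120.0)
        doses = [DoseEvent(i * 12.0, 60.0, 1.0) for i in range(10)]
        from gcvpk.pk import superpose

        times = np.sort(rng.uniform(0.5, 118.0, size=50))
        f = superpose(times, cl, vd, np.arange(10) * 12.0, np.full(10, 60.0),
                      np.full(10, 1.0))
        obs = [Observation(float(t), float(y * (1 + rng.normal(0, 0.02))))
               for t, y in zip(times, f)]
        ds = PKDataset([subject], {"s1": doses}, {"s1": obs})
        got = ebe(ds, base_model_spec(), dict(theta_cl=5.0, theta_vd=10.0),
                  (0.3, 0.5), (0.02, 0.0), "s1")
        assert np.allclose(got, eta_true, atol=0.02)

    def test_all_subjects_get_estimates(self, small_dataset, final_spec):
        ds, _ = small_dataset
        theta = dict(theta_cl=5.23, theta_vd=11.35, theta1=0.8, theta2=0.92,
                     theta3=1.02)
        e = ebes(ds, final_spec, theta, (0.129, 0.6578), (0.0823, 0.0))
        assert len(e) == 30
        assert all(np.all(np.isfinite(v)) for v in e.values())


class TestInformationCriteria:
    # printed (OFV, AIC, BIC) triples of the seven candidate clearance
    # models with n_obs = 138; n_par back-derived from the AIC-OFV gap
    TRIPLES = [
        (311.74, 323.74, 341.31, 6),
        (298.25, 308.25, 322.89, 5),
        (312.02, 324.02, 341.58, 6),
        (306.98, 320.98, 341.47, 7),
        (332.86, 350.86, 377.20, 9),
        (298.85, 316.85, 343.19, 9),
        (309.25, 327.25, 353.59, 9),
    ]

    @pytest.mark.parametrize("ofv,aic_val,bic_val,n_par", TRIPLES)
    def test_aic_bic_identities(self, ofv, aic_val, bic_val, n_par):
        # printed tables carry two decimals: agree to that precision
        assert aic(ofv, n_par) == pytest.approx(aic_val, abs=0.01)
        assert bic(ofv, n_par, 138) == pytest.approx(bic_val, abs=0.01)

    def test_fit_result_consistency(self, small_fit):
        assert small_fit.aic == pytest.approx(small_fit.ofv + 2 * small_fit.n_par)
        assert small_fit.bic == pytest.approx(
            small_fit.ofv + np.log(small_fit.n_obs) * small_fit.n_par
        )
        assert small_fit.n_par == 8  # 5 fixed effects + 2 omegas + sigma


class TestFit:
    def test_recovers_generating_parameters_loosely(self, small_fit):
        # 30 subjects / 80 sparse samples: typical values recovered within
        # the sampling noise of such a design
        assert small_fit.theta["theta_cl"] == pytest.approx(5.23, rel=0.2)
        assert small_fit.theta["theta_vd"] == pytest.approx(11.35, rel=0.35)
        assert small_fit.converged

    def test_residual_table_complete(self, small_fit, small_dataset):
        ds, _ = small_dataset
        n_quant = sum(1 for obs in ds.observations.values()
                      for o in obs if not o.below_loq)
        assert len(small_fit.residual_table) == n_quant
        assert small_fit.residual_table["CWRES"].notna().all()

    def test_standard_errors_reported(self, small_dataset, final_spec):
        ds, _ = small_dataset
        res = fit(ds, final_spec, seed=0, compute_se=True, n_restarts=0,
                  n_polish=1)
        assert res.se_pct is not None
        finite = [v for v in res.se_pct.values() if np.isfinite(v)]
        assert len(finite) >= 6 and all(v > 0 for v in finite)

    def test_no_iiv_signal_shrinks_omega(self, final_spec):
        """Identical noise-free subjects leave nothing for the random
        effects to explain: omega estimates collapse toward zero."""
        from gcvpk.pk import superpose

        subjects, doses, observations = [], {}, {}
        dose_t = np.arange(6) * 12.0
        for i in range(12):
            s = Subject(f"c{i}", 12.0, 90.0, 2.5, "M", 26.0, 120.0)
            subjects.append(s)
            doses[s.id] = [DoseEvent(float(t), 60.0, 1.0) for t in dose_t]
            f = superpose(np.array([1.0, 30.0]), 5.23, 11.35, dose_t,
                          np.full(6, 60.0), np.full(6, 1.0))
            observations[s.id] = [Observation(1.0, float(f[0])),
                                  Observation(30.0, float(f[1]))]
        ds = PKDataset(subjects, doses, observations)
        res = fit(ds, base_model_spec(), seed=0, n_restarts=0, n_polish=1)
        assert res.omega["omega_cl"] < 0.05
        assert res.omega["omega_vd"] < 0.05


class TestCwres:
    def test_approximately_standard_normal_under_true_model(self, small_fit):
        cw = small_fit.residual_table["CWRES"].to_numpy()
        assert np.mean(np.abs(cw) <= 3.0) >= 0.95
        assert abs(cw.mean()) < 0.35
        assert 0.5 < cw.std() < 1.6

    def test_reduces_to_scaled_residual_without_iiv(self, final_spec):
        subject = Subject("s1", 12.0, 90.0, 2.5, "M", 26.0, 120.0)
        doses = [DoseEvent(0.0, 60.0, 1.0)]
        obs = [Observation(1.0, 4.4)]
        ds = PKDataset([subject], {"s1": doses}, {"s1": obs})
        from gcvpk.nlme import _cwres_subject

        sd = _prepare(ds, "censored")[0]
        theta = dict(theta_cl=5.23, theta_vd=11.35, theta1=0.8, theta2=0.92,
                     theta3=1.02)
        cl = final_spec.cl(theta, subject)
        vd = final_spec.vd(theta, subject)
        got = _cwres_subject(sd, cl, vd, np.zeros(2), np.zeros(2), (0.0, 0.3))
        from gcvpk.nlme import _conc

        f = _conc(sd, sd.t, cl, vd)[0]
        assert got[0] == pytest.approx((4.4 - f) / 0.3, abs=1e-10)
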