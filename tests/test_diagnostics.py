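"""Bootstrap, VPC and NPDE validation machinery."""

import numpy as np
import pytest
from scipy import stats

import gcvpk.diagnostics as diag
from gcvpk.diagnostics import bootstrap, bootstrap_bias, npde, vpc
from gcvpk.nlme import fit

TRUTH = dict(theta_cl=5.23, theta_vd=11.35, theta1=0.80, theta2=0.92, theta3=1.02)
OMEGA = (0.129, 0.6578)
SIGMA = (0.0823, 0.0)


class TestBootstrapBias:
    # every printed bootstrap row: (estimate, median, published bias %)
    PUBLISHED_ROWS = [
        (11.35, 11.26, -0.79),
        (5.23, 5.17, -1.15),
        (0.80, 0.79, -1.25),
        (0.92, 0.97, 5.43),
        (1.02, 0.98, -3.92),
        (65.78, 63.79, -3.03),
        (12.90, 13.11, 1.63),
        (8.23, 8.37, 1.70),
    ]

    @pytest.mark.parametrize("estimate,median,bias", PUBLISHED_ROWS)
    def test_formula_reproduces_published_column(self, estimate, median, bias):
        assert bootstrap_bias(median, estimate) == pytest.approx(bias, abs=0.01)

    def test_zero_estimate_rejected(self):
        with pytest.raises(ZeroDivisionError):
            bootstrap_bias(1.0, 0.0)


class TestBootstrap:
    def test_degenerate_resampler_gives_zero_bias(self, small_dataset, final_spec,
                                                  monkeypatch):
        """If every replicate is the original dataset the interval collapses."""
        ds, _ = small_dataset
        ref = fit(ds, final_spec, seed=0, n_restarts=0, n_polish=1)
        monkeypatch.setattr(diag, "_resample", lambda dataset, rng: dataset)
        res = bootstrap(ds, final_spec, ref, n_replicates=3, seed=1,
                        n_restarts=0, n_polish=0, maxiter=60)
        row = res.table.loc["theta_cl"]
        assert row["p2.5"] == pytest.approx(row["p97.5"], rel=1e-6)
        assert abs(row["bias_pct"]) < 1.0  # refit noise only

    def test_estimates_inside_percentile_interval(self, small_dataset, final_spec):
        ds, _ = small_dataset
        ref = fit(ds, final_spec, seed=0, n_restarts=0, n_polish=1)
        res = bootstrap(ds, final_spec, ref, n_replicates=12, seed=2,
                        n_restarts=0, n_polish=0, maxiter=60)
        assert res.n_converged >= 10
        for name in ("theta_cl", "theta_vd"):
            row = res.table.loc[name]
            assert row["p2.5"] <= row["estimate"] <= row["p97.5"]
            assert row["p2.5"] <= row["median"] <= row["p97.5"]

    def test_resampler_preserves_cohort_size(self, small_dataset):
        ds, _ = small_dataset
        rng = np.random.default_rng(5)
        bs = diag._resample(ds, rng)
        assert bs.n_subjects == ds.n_subjects
        # with-replacement draw: some subject repeated with high probability
        wts = sorted(s.wt for s in bs.subjects)
        assert len(set(wts)) < len(wts)


class TestVpc:
    def test_calibrated_under_true_model(self, small_dataset, final_spec):
        ds, _ = small_dataset
        res = vpc(ds, final_spec, TRUTH, OMEGA, SIGMA, n_sim=400, seed=1)
        # data were generated from this very model: the large majority of
        # observed percentile points sit inside their 95% bands
        assert res.coverage >= 0.85
        s = res.summary
        assert (s["sim_lo"] <= s["sim_hi"]).all()

    def test_single_simulation_collapses_bands(self, small_dataset, final_spec):
        ds, _ = small_dataset
        res = vpc(ds, final_spec, TRUTH, OMEGA, SIGMA, n_sim=1, seed=1)
        assert np.allclose(res.summary["sim_lo"], res.summary["sim_hi"])

    def test_bands_widen_with_residual_error(self, small_dataset, final_spec):
        ds, _ = small_dataset
        narrow = vpc(ds, final_spec, TRUTH, OMEGA, (0.05, 0.0), n_sim=200, seed=3)
        wide = vpc(ds, final_spec, TRUTH, OMEGA, (0.30, 0.0), n_sim=200, seed=3)
        w_n = (narrow.summary["sim_hi"] - narrow.summary["sim_lo"]).median()
        w_w = (wide.summary["sim_hi"] - wide.summary["sim_lo"]).median()
        assert w_w > w_n

    def test_inflated_error_widens_percentile_spread(self, small_dataset,
                                                     final_spec):
        """A model simulating inflated variability spreads its outer
        percentile curves far beyond what the observed data need."""
        ds, _ = small_dataset
        good = vpc(ds, final_spec, TRUTH, OMEGA, SIGMA, n_sim=300, seed=4)
        bad = vpc(ds, final_spec, TRUTH, (OMEGA[0], OMEGA[1] * 2.0),
                  (SIGMA[0] * 3.0, 0.0), n_sim=300, seed=4)

        def outer_spread(res):
            s = res.summary.pivot(index="bin", columns="percentile",
                                  values="sim_median")
            return s[97.5] - s[2.5]

        # widening is strongest where volume variability acts (early bins)
        assert outer_spread(bad).iloc[0] > 1.5 * outer_spread(good).iloc[0]
        assert (outer_spread(bad) > outer_spread(good)).all()
        # and the observed percentiles sit no better than under the truth
        assert bad.coverage <= good.coverage

    def test_small_bins_merge(self, small_dataset, final_spec):
        ds, _ = small_dataset
        res = vpc(ds, final_spec, TRUTH, OMEGA, SIGMA, n_sim=50, seed=5,
                  n_bins=40, min_bin_size=5)
        counts = res.summary.groupby("bin")["n"].first()
        assert (counts >= 5).all()


class TestNpde:
    def test_calibrated_under_true_model(self, small_dataset, final_spec):
        ds, _ = small_dataset
        res = npde(ds, final_spec, TRUTH, OMEGA, SIGMA, n_sim=1000, seed=1)
        v = res.values
        assert abs(v.mean()) < 0.25
        assert abs(v.var(ddof=1) - 1.0) < 0.35
        for p in (res.p_wilcoxon, res.p_variance, res.p_shapiro, res.p_global):
            assert p > 0.05

    def test_biased_clearance_detected(self, small_dataset, final_spec):
        """Simulating with +50% clearance shifts predictions low, so the
        location test must reject."""
        ds, _ = small_dataset
        biased = dict(TRUTH, theta_cl=TRUTH["theta_cl"] * 1.5)
        res = npde(ds, final_spec, biased, OMEGA, SIGMA, n_sim=500, seed=2)
        assert res.p_wilcoxon < 0.01
        assert abs(res.values.mean()) > 0.3

    def test_single_observation_reduces_to_rank_statistic(self, final_spec):
        from gcvpk.data import DoseEvent, Observation, PKDataset, Subject

        s = Subject("u", 12.0, 90.0, 2.5, "M", 26.0, 120.0)
        ds = PKDataset([s], {"u": [DoseEvent(0.0, 60.0, 1.0)]},
                       {"u": [Observation(2.0, 3.0)]})
        res = npde(ds, final_spec, TRUTH, OMEGA, SIGMA, n_sim=400, seed=3)
        # recompute the plain inverse-normal rank statistic independently
        rng = np.random.default_rng(3)
        from gcvpk.nlme import _conc, _prepare

        sd = _prepare(ds)[0]
        etas = rng.normal(0.0, 1.0, size=(400, 2)) * np.asarray(OMEGA)
        cl_t = final_spec.cl(TRUTH, s)
        vd_t = final_spec.vd(TRUTH, s)
        sims = np.array([
            _conc(sd, sd.t, cl_t * np.exp(e[0]), vd_t * np.exp(e[1]))[0]
            for e in etas
        ])
        sims = sims * (1 + SIGMA[0] * rng.normal(size=(400, 1))[:, 0])
        pde = np.clip((sims < 3.0).mean(), 1 / 800, 1 - 1 / 800)
        assert res.values[0] == pytest.approx(stats.norm.ppf(pde), abs=0.35)

    def test_global_is_bonferroni_of_components(self, small_dataset, final_spec):
        ds, _ = small_dataset
        res = npde(ds, final_spec, TRUTH, OMEGA, SIGMA, n_sim=300, seed=4)
        expected = min(1.0, 3.0 * min(res.p_wilcoxon, res.p_variance, res.p_shapiro))
        assert res.p_global == pytest.approx(expected)


class TestPlots:
    def test_figures_build(self, small_dataset, final_spec, tmp_path):
        from gcvpk import plots

        ds, _ = small_dataset
        v = vpc(ds, final_spec, TRUTH, OMEGA, SIGMA, n_sim=50, seed=9)
        r = npde(ds, final_spec, TRUTH, OMEGA, SIGMA, n_sim=100, seed=9)
        f = fit(ds, final_spec, seed=0, n_restarts=0, n_polish=0, maxiter=30)
        for name, fig in (("vpc", plots.plot_vpc(v)), ("npde", plots.plot_npde(r)),
                          ("gof", plots.plot_gof(f))):
            fig.savefig(tmp_path / f"{name}.png", dpi=60)
            assert (tmp_path / f"{name}.png").stat().st_size > 0
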