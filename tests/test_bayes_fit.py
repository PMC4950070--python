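import warnings

import numpy as np
import pytest

import surrometa as sm
from surrometa.bayes_fit import (
    ModelSpec,
    PosteriorFit,
    _Layout,
    _make_log_prob,
    brma_spec,
    fit_model,
    predict_final_outcome,
    surrogacy_report,
    trma_scm_spec,
    trma_ucm_spec,
)
from surrometa.study_effects import EffectRow

QUICK = dict(iterations=16_000, burn_in=6_000)


def _fit_quiet(data, spec):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_model(data, spec)


@pytest.fixture(scope="module")
def scm_fit(rrms):
    return _fit_quiet(rrms, trma_scm_spec(seed=101, iterations=40_000, burn_in=14_000))


class TestPerDrawInvariants:
    def test_implied_T_positive_definite(self, scm_fit):
        sub = scm_fit.T[:: max(1, scm_fit.n_draws // 500)]
        assert np.all(np.linalg.eigvalsh(sub)[:, 0] > 0)
        assert np.all(scm_fit.psi2 > 0)

    def test_pooled_effect_identities(self, scm_fit):
        """beta_2 = lambda_20 + lambda_21 beta_1, and the final-outcome analogue."""
        d = scm_fit._param_draws()
        assert np.allclose(d["beta1"], d["eta1"])
        assert np.allclose(d["beta2"], d["lambda20"] + d["lambda21"] * d["beta1"])
        assert np.allclose(d["beta3"], d["lambda30"] + d["lambda32"] * d["beta2"])

    def test_summary_shape(self, scm_fit):
        s = scm_fit.summary()
        assert {"lambda21", "lambda32", "psi2_2", "tau1", "rho_b23"} <= set(s.index)


class TestDegenerateAndRecovery:
    def test_univariate_matches_conditional_closed_form(self, rng):
        """With one outcome the fit is a normal-normal random-effects model.

        Conditional on each retained tau draw, the pooled-mean posterior
        is inverse-variance weighting (with the vague normal prior), so
        the posterior mean of beta equals the average of those
        closed-form means over the tau draws.
        """
        true_mu, tau = -0.4, 0.25
        sig = rng.uniform(0.1, 0.3, 10)
        y = true_mu + rng.standard_normal(10) * np.sqrt(tau**2 + sig**2)
        data = [
            EffectRow(f"s{i}", [y[i]], [sig[i]], np.eye(1)) for i in range(10)
        ]
        spec = ModelSpec(name="uni", outcomes=(0,), seed=3, **QUICK)
        fit = _fit_quiet(data, spec)
        w = 1.0 / (sig[None, :] ** 2 + fit.tau[:, 0:1] ** 2)  # (M, S)
        prior_prec = 1.0 / spec.prior_mean_var
        cond_mean = (w @ y) / (w.sum(axis=1) + prior_prec)
        assert fit.beta[:, 0].mean() == pytest.approx(cond_mean.mean(), abs=0.01)

    def test_no_heterogeneity_recovery(self, rng):
        """tau ~ 0 truth with precise studies: tau posterior small, beta recovered."""
        beta_true = np.array([-0.3, -0.25])
        sig = 0.05
        rows = []
        for i in range(12):
            y = beta_true + sig * rng.standard_normal(2)
            rows.append(EffectRow(f"s{i}", y, [sig, sig], np.eye(2)))
        spec = ModelSpec(name="biv", outcomes=(0, 1), seed=5, **QUICK)
        fit = _fit_quiet(rows, spec)
        assert np.median(fit.tau[:, 0]) < 0.1
        mc_se = sig / np.sqrt(12)
        assert fit.beta[:, 0].mean() == pytest.approx(beta_true[0], abs=3 * mc_se + 0.02)

    def test_scm_parameter_recovery(self):
        scenario = sm.SimScenario(structure="sequential", family="normal", n_studies=40, seed=7)
        ds = sm.simulate_dataset(scenario)
        fit = _fit_quiet(ds.rows, trma_scm_spec(seed=8, **QUICK))
        # generative slopes are rho*tau_j/tau_k = 0.8
        lo, hi = fit.credible_interval("lambda32")
        assert lo < 0.8 < hi
        # eta1 estimates the mean of the realised first-outcome true effects
        lo, hi = fit.credible_interval("eta1")
        assert lo < ds.true_effects[:, 0].mean() < hi


class TestValidation:
    def test_too_few_studies(self, rrms):
        with pytest.raises(ValueError, match="3 studies"):
            fit_model(rrms[:2], trma_scm_spec(**QUICK))

    def test_all_missing_outcome_column(self, rrms):
        rows = [r.mask_outcome(2) for r in rrms]
        with pytest.raises(ValueError, match="missing in every study"):
            fit_model(rows, trma_scm_spec(**QUICK))

    def test_iterations_must_exceed_burn_in(self):
        with pytest.raises(ValueError, match="exceed"):
            ModelSpec(iterations=100, burn_in=200)


def test_prior_predictive_rho_uniform_scm():
    """With no data the sequential-model correlation priors are recovered.

    The sequential chain is positive definite for any |rho| < 1, so the
    marginal prior of each modelled correlation stays uniform(-1, 1).
    """
    layout = _Layout(3, "sequential")
    spec = trma_scm_spec(seed=9)
    log_prob = _make_log_prob(layout, [], spec)
    import emcee

    rng = np.random.default_rng(11)
    nwalk, dim = 30, layout.dim
    p0 = 0.5 * rng.standard_normal((nwalk, dim))
    sampler = emcee.EnsembleSampler(nwalk, dim, log_prob, vectorize=True)
    sampler.random_state = np.random.RandomState(12).get_state()
    sampler.run_mcmc(p0, 1500)
    rho = np.tanh(sampler.get_chain()[500:, :, 2 * 3 :].reshape(-1, 2))
    # correlated MCMC draws: check uniform(-1,1) moments rather than a KS test
    for k in range(2):
        assert abs(rho[:, k].mean()) < 0.05
        assert rho[:, k].var() == pytest.approx(1 / 3, abs=0.04)
        assert (np.abs(rho[:, k]) > 0.5).mean() == pytest.approx(0.5, abs=0.05)


class TestPrediction:
    @staticmethod
    def _fixed_fit(T, beta, n_copies=200_000):
        n = T.shape[0]
        layout = _Layout(n, "unstructured")
        return PosteriorFit(
            spec=ModelSpec(name="fixed", outcomes=tuple(range(n))),
            outcomes=np.arange(n),
            parents=layout.parents,
            edges=layout.edges,
            means=np.tile(beta, (n_copies, 1)),
            tau=np.tile(np.sqrt(np.diag(T)), (n_copies, 1)),
            rho_edges=np.zeros((n_copies, len(layout.edges))),
            T=np.tile(T, (n_copies, 1, 1)),
            psi2=np.ones((n_copies, n)),
            slopes=np.zeros((n_copies, len(layout.edges))),
            beta=np.tile(beta, (n_copies, 1)),
        )

    def test_matches_analytic_conditional_normal(self, rng):
        """Fixed parameters, zero within-correlation: exact conditioning."""
        T = np.array([[0.25, 0.1, 0.08], [0.1, 0.25, 0.12], [0.08, 0.12, 0.25]])
        beta = np.array([-0.3, -0.24, -0.19])
        fit = self._fixed_fit(T, beta)
        y = np.array([-0.6, -0.5, np.nan])
        sig = np.array([0.15, 0.1, np.nan])
        row = EffectRow("new", y, sig, np.eye(3))
        pred = predict_final_outcome(fit, row, sigma_final=0.2, rng=rng)
        C = T[:2, :2] + np.diag(sig[:2] ** 2)
        k = np.linalg.solve(C, T[:2, 2])
        mean = beta[2] + k @ (y[:2] - beta[:2])
        var = T[2, 2] - k @ T[:2, 2]
        assert pred.true_draws.mean() == pytest.approx(mean, abs=0.005)
        assert pred.true_draws.var() == pytest.approx(var, rel=0.03)
        assert pred.est_draws.var() == pytest.approx(var + 0.04, rel=0.03)

    def test_no_information_transfer(self, rng):
        """Surrogates at the pooled means with zero correlation: centre = beta3."""
        T = np.diag([0.25, 0.25, 0.25])
        beta = np.array([-0.3, -0.24, -0.19])
        fit = self._fixed_fit(T, beta)
        row = EffectRow("new", [beta[0], beta[1], np.nan], [0.1, 0.1, np.nan], np.eye(3))
        pred = predict_final_outcome(fit, row, sigma_final=0.1, rng=rng)
        assert pred.true_draws.mean() == pytest.approx(beta[2], abs=0.005)

    def test_no_surrogate_errors(self, scm_fit):
        row = EffectRow("empty", [np.nan] * 3, [np.nan] * 3, np.eye(3))
        with pytest.raises(ValueError, match="no observed surrogate"):
            predict_final_outcome(scm_fit, row)

    def test_rrms_polman_prediction(self, rrms, scm_fit):
        """Masked-final prediction for the largest trial lands near the
        published predicted odds ratio (~0.58 with interval ~(0.33, 1.03))."""
        i = [r.study_id for r in rrms].index("Polman")
        masked = [r if k != i else r.mask_outcome(2) for k, r in enumerate(rrms)]
        fit = _fit_quiet(masked, trma_scm_spec(seed=31, iterations=40_000, burn_in=14_000))
        pred = predict_final_outcome(
            fit, masked[i], sigma_final=float(rrms[i].sigma[2]),
            rng=np.random.default_rng(1),
        )
        e = pred.exp_estimate
        assert e["median"] == pytest.approx(0.58, abs=0.07)
        assert e["lo"] == pytest.approx(0.33, abs=0.08)
        assert e["hi"] == pytest.approx(1.03, abs=0.20)


class TestBorrowingOfStrength:
    def test_trivariate_tightens_final_pooled_effect(self, rrms, scm_fit):
        uni = _fit_quiet(
            rrms, ModelSpec(name="uni3", outcomes=(2,), seed=17, **QUICK)
        )
        sd_tri = scm_fit.beta[:, 2].std()
        sd_uni = uni.beta[:, 0].std()
        assert sd_tri <= sd_uni * 1.02


class TestSurrogacyReport:
    def test_rrms_scm_verdicts(self, scm_fit):
        rep = surrogacy_report(scm_fit)
        t = rep.table.set_index("parameter")
        assert t.loc["lambda32", "satisfied"]  # relapse -> progression slope non-zero
        assert t.loc["lambda30", "satisfied"]  # intercept consistent with zero
        assert t.loc["psi2_3", "mean"] < 0.1

    def test_null_slope_contains_zero(self):
        """Data generated with no surrogate-final association."""
        rng = np.random.default_rng(23)
        rows = []
        for i in range(20):
            mu = np.array([-0.3 + 0.5 * rng.standard_normal(), 0.5 * rng.standard_normal()])
            sig = np.array([0.15, 0.15])
            rows.append(EffectRow(f"s{i}", mu + sig * rng.standard_normal(2), sig, np.eye(2)))
        fit = _fit_quiet(rows, ModelSpec(name="biv", outcomes=(0, 1), seed=29, **QUICK))
        rep = surrogacy_report(fit).table.set_index("parameter")
        assert not rep.loc["lambda21", "satisfied"]

    def test_perfect_surrogate_recovery(self):
        """psi^2 = 0, lambda_0 = 0 truth: posterior conditional variance near 0."""
        rng = np.random.default_rng(37)
        rows = []
        for i in range(20):
            mu1 = -0.3 + 0.5 * rng.standard_normal()
            mu = np.array([mu1, 0.8 * mu1])
            sig = np.array([0.1, 0.1])
            rows.append(EffectRow(f"s{i}", mu + sig * rng.standard_normal(2), sig, np.eye(2)))
        fit = _fit_quiet(rows, ModelSpec(name="biv", outcomes=(0, 1), seed=41, **QUICK))
        assert np.median(fit.psi2[:, 1]) < 0.05
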