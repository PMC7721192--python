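import numpy as np
import pytest

from tagmove import (
    MovementConfig,
    StudyFrame,
    TagDataset,
    TagReturnModel,
    compute_dic,
    compute_psis_loo,
    compute_waic,
    gelman_rubin,
    run_mcmc,
)
from tagmove.age_key import log_lik_age_sample
from tagmove.movement import log_prior_movement
from tagmove.tag_data import AgeLengthSample, ReportingRates


class TestGelmanRubin:
    def test_iid_chains_converge_to_one(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal((4, 10_000, 3))
        rhat = gelman_rubin(draws)
        assert (rhat < 1.05).all()

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal((2, 500, 1))
        draws[1] += 10.0
        assert gelman_rubin(draws)[0] > 1.1

    def test_constant_parameter_undefined(self):
        rng = np.random.default_rng(2)
        draws = rng.standard_normal((2, 100, 2))
        draws[:, :, 1] = 3.14
        rhat = gelman_rubin(draws)
        assert np.isfinite(rhat[0])
        assert np.isnan(rhat[1])

    def test_needs_multiple_chains(self):
        with pytest.raises(ValueError, match="chains"):
            gelman_rubin(np.zeros((1, 100, 2)))

    def test_agrees_with_arviz(self):
        import arviz as az

        rng = np.random.default_rng(3)
        draws = np.cumsum(rng.standard_normal((3, 2000, 2)), axis=1) * 0.01
        draws += rng.standard_normal((3, 2000, 2))
        ours = gelman_rubin(draws)
        # arviz uses rank-normalised split-rhat; agreement is approximate
        theirs = np.array([
            float(az.rhat(az.convert_to_dataset(draws[:, :, i]))["x"])
            for i in range(2)
        ])
        np.testing.assert_allclose(ours, theirs, atol=0.05)


class TestDIC:
    def test_point_mass_posterior_has_no_penalty(self):
        ll = np.tile(np.log([0.2, 0.5]), (50, 1))
        dev = -2 * np.log([0.2, 0.5]).sum()
        res = compute_dic(ll, dev)
        assert res.pd_dic == pytest.approx(0.0, abs=1e-12)
        assert res.dic == pytest.approx(dev, abs=1e-12)

    def test_gaussian_mean_effective_parameters(self):
        """Known-variance normal mean with flat prior: pd -> 1."""
        rng = np.random.default_rng(4)
        n, sigma = 40, 1.0
        y = rng.normal(0.7, sigma, n)
        ybar = y.mean()
        mu_draws = rng.normal(ybar, sigma / np.sqrt(n), 40_000)
        ll = -0.5 * np.log(2 * np.pi) - 0.5 * (y[None, :] - mu_draws[:, None]) ** 2
        dev_hat = float(-2 * (-0.5 * np.log(2 * np.pi)
                              - 0.5 * (y - mu_draws.mean()) ** 2).sum())
        res = compute_dic(ll, dev_hat)
        assert res.pd_dic == pytest.approx(1.0, abs=0.05)

    def test_translation_by_constant(self):
        rng = np.random.default_rng(5)
        ll = rng.uniform(-3, -1, (200, 10))
        dev = 50.0
        base = compute_dic(ll, dev)
        shifted = compute_dic(ll - 0.5, dev + 2 * 0.5 * 10)
        assert shifted.dic == pytest.approx(base.dic + 10.0, abs=1e-9)


class TestWAIC:
    def test_degenerate_posterior(self):
        ll = np.tile(np.log([0.2, 0.5]), (10, 1))
        res = compute_waic(ll)
        assert res.pd_waic == pytest.approx(0.0, abs=1e-12)
        assert res.waic == pytest.approx(-2 * np.log([0.2, 0.5]).sum(), abs=1e-9)

    def test_two_draw_hand_case(self):
        ll = np.log([[0.2], [0.4]])
        res = compute_waic(ll)
        assert res.lppd == pytest.approx(np.log(0.3), abs=1e-12)
        assert res.pd_waic == pytest.approx(np.var(np.log([0.2, 0.4]), ddof=1),
                                            abs=1e-12)
        assert res.waic == pytest.approx(-2 * (res.lppd - res.pd_waic), abs=1e-12)

    def test_observation_order_invariance(self):
        rng = np.random.default_rng(6)
        ll = rng.uniform(-4, -1, (100, 12))
        perm = rng.permutation(12)
        assert compute_waic(ll).waic == pytest.approx(
            compute_waic(ll[:, perm]).waic, abs=1e-10
        )

    def test_needs_two_draws(self):
        with pytest.raises(ValueError, match="two"):
            compute_waic(np.array([[-1.0, -2.0]]))


class TestPSISLOO:
    def test_parameter_free_model_reduces_to_log_density(self):
        # identical draws: importance weights are constant
        p = np.array([0.2, 0.5, 0.1])
        ll = np.tile(np.log(p), (100, 1))
        res = compute_psis_loo(ll)
        assert res.loo == pytest.approx(-2 * np.log(p).sum(), abs=1e-9)

    def test_close_to_waic_for_large_data(self):
        rng = np.random.default_rng(7)
        n = 200
        y = rng.normal(0.0, 1.0, n)
        mu = rng.normal(y.mean(), 1 / np.sqrt(n), 4000)
        ll = -0.5 * np.log(2 * np.pi) - 0.5 * (y[None, :] - mu[:, None]) ** 2
        loo = compute_psis_loo(ll).loo
        waic = compute_waic(ll).waic
        assert abs(loo - waic) < 1.0

    def test_matches_arviz_loo(self):
        import arviz as az

        rng = np.random.default_rng(8)
        y = rng.normal(0, 1, 30)
        mu = rng.normal(y.mean(), 1 / np.sqrt(30), (4, 800))
        ll = (-0.5 * np.log(2 * np.pi)
              - 0.5 * (y[None, None, :] - mu[:, :, None]) ** 2)
        ours = compute_psis_loo(ll.reshape(-1, 30))
        idata = az.from_dict(log_likelihood={"y": ll})
        theirs = az.loo(idata, pointwise=False, scale="deviance", reff=1.0)
        assert ours.loo == pytest.approx(float(theirs.elpd_loo), rel=1e-3)


def _tiny_setup(seed=0, releases=400):
    """2 regions x 2 years x 2 ages, single length class."""
    frame = StudyFrame((2000, 2001), ("A", "B"), 2, ("L",))
    rng = np.random.default_rng(seed)
    rel = np.zeros((2, 2, 1), dtype=int)
    rel[0, 0, 0] = releases
    rel[0, 1, 0] = releases
    rec = np.zeros((2, 2, 1, 2, 2), dtype=int)
    rec[0, 0, 0, 0, 0] = max(releases // 40, 1)
    rec[0, 0, 0, 1, 1] = max(releases // 80, 1)
    rec[0, 1, 0, 0, 1] = max(releases // 50, 1)
    ds = TagDataset(frame=frame, releases=rel, recoveries=rec)
    reporting = ReportingRates(frame=frame, lam=np.full((2, 2), 0.5))
    sample = AgeLengthSample(frame=frame, n=np.array([[30, 20]]))
    return frame, ds, reporting, sample


class TestLogPosterior:
    def test_recomposition_from_module_terms(self):
        """log posterior = movement prior + kappa prior + Jacobian - NLL + age term."""
        frame, ds, reporting, sample = _tiny_setup()
        model = TagReturnModel(ds, reporting, sample, MovementConfig("C"))
        rng = np.random.default_rng(9)
        natural = model.sample_prior(rng)
        x = model.space.pack(natural)
        got, pw = model.log_posterior(x)

        from tagmove.likelihood import negative_log_likelihood

        fate = model.fate_probabilities(natural)
        nll = negative_log_likelihood(ds, fate).nll
        expected = (
            log_prior_movement(model.movement_params(natural), model.config)
            - natural["g_kappa"].sum()
            + model.space.log_jacobian(x)
            - nll
            + log_lik_age_sample(model.kappa_of(natural), sample)
        )
        assert got == pytest.approx(expected, rel=1e-12)
        assert -pw.sum() == pytest.approx(nll, rel=1e-12)

    def test_out_of_support_natural_values_unreachable(self):
        frame, ds, reporting, sample = _tiny_setup()
        model = TagReturnModel(ds, reporting, sample, MovementConfig("C"))
        natural = model.sample_prior(np.random.default_rng(0))
        natural["M"] = 3.0  # outside the (0.2, 2) prior support
        with pytest.raises(ValueError, match="strictly"):
            model.space.pack(natural)

    def test_prior_only_when_no_data(self):
        frame, ds0, reporting, _ = _tiny_setup()
        empty = TagDataset(
            frame=frame,
            releases=np.zeros((2, 2, 1), dtype=int),
            recoveries=np.zeros((2, 2, 1, 2, 2), dtype=int),
        )
        model = TagReturnModel(empty, reporting, None, MovementConfig("C"))
        natural = model.sample_prior(np.random.default_rng(1))
        x = model.space.pack(natural)
        got, _ = model.log_posterior(x)
        expected = model.log_prior(natural) + model.space.log_jacobian(x)
        assert got == pytest.approx(expected, rel=1e-12)


class TestRunMCMC:
    def test_same_seed_identical_draws(self):
        frame, ds, reporting, sample = _tiny_setup()
        kwargs = dict(n_chains=2, n_iter=150, thin=2, seed=5)
        r1 = run_mcmc(ds, reporting, sample, MovementConfig("C"), **kwargs)
        r2 = run_mcmc(ds, reporting, sample, MovementConfig("C"), **kwargs)
        np.testing.assert_array_equal(r1.draws, r2.draws)
        np.testing.assert_array_equal(r1.pointwise, r2.pointwise)

    def test_seed_required(self):
        frame, ds, reporting, sample = _tiny_setup()
        with pytest.raises(ValueError, match="seed"):
            run_mcmc(ds, reporting, sample, MovementConfig("C"), n_iter=10)

    def test_kappa_marginal_matches_conjugate_oracle(self):
        """With no tagging data the kappa posterior is Dirichlet(1 + n)."""
        frame = StudyFrame((2000, 2001), ("A",), 3, ("L",))
        ds = TagDataset(
            frame=frame,
            releases=np.zeros((2, 1, 1), dtype=int),
            recoveries=np.zeros((2, 1, 1, 2, 1), dtype=int),
        )
        reporting = ReportingRates(frame=frame, lam=np.full((2, 1), 0.5))
        sample = AgeLengthSample(frame=frame, n=np.array([[12, 6, 2]]))
        run = run_mcmc(ds, reporting, sample, MovementConfig("C"),
                       n_chains=3, n_iter=4000, thin=4, seed=11)
        names = run.param_names
        idx = [i for i, n in enumerate(names) if n.startswith("g_kappa")]
        g = run.stacked()[:, idx]
        kappa_draws = g / g.sum(axis=1, keepdims=True)
        conc = 1.0 + np.array([12, 6, 2])
        expected = conc / conc.sum()
        import arviz as az

        for j in range(3):
            d = kappa_draws[:, j].reshape(run.natural.shape[0], -1)
            ess = max(float(az.ess(az.convert_to_dataset(d))["x"]), 10.0)
            se = d.std(ddof=1) / np.sqrt(ess)
            assert abs(kappa_draws[:, j].mean() - expected[j]) < 3 * se + 0.01

    def test_posterior_tracks_empirical_recovery_rate(self):
        """1 region, lam=1: the recovery-cell probability is identified."""
        from tagmove import MovementParams, TruthSpec, simulate_study

        frame = StudyFrame((2000,), ("A",), 2, ("L",))
        truth = TruthSpec(
            frame=frame,
            movement_config=MovementConfig("C"),
            movement=MovementParams(gamma=np.array([[1.0]])),
            M=0.5, F=np.array([[0.4]]), eta=(1.0, 5.0, 2.0, 0.1),
            lam=np.array([[1.0]]),
            kappa=np.array([[0.5, 0.5]]),
            releases=np.array([[[40_000]]]),
            age_sample_size=np.array([2000]),
        )
        ds, sample = simulate_study(truth, 21)
        emp = ds.total_recoveries / ds.total_releases
        run = run_mcmc(ds, truth.reporting(), sample, MovementConfig("C"),
                       n_chains=2, n_iter=1200, thin=4, seed=13)
        pr_draws = []
        flat = run.stacked("transformed")[::10]
        for x in flat:
            fate = run.model.fate_probabilities(run.model.space.unpack(x))
            pr_draws.append(fate.pr_recap[0, 0, 0, 0, 0])
        pr_draws = np.asarray(pr_draws)
        se_emp = np.sqrt(emp * (1 - emp) / ds.total_releases)
        assert abs(np.median(pr_draws) - emp) < 4 * se_emp + pr_draws.std()
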