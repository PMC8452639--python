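"""Variational Laplace: evidence, recovery, comparison, prior chaining."""

import numpy as np
import pytest

from spectraldcm import cmc, inversion as inv, priors, synth
from spectraldcm.ephys import TraceRecording


def linear_evidence(y, X, prior, noise_sd):
    """Closed-form log marginal likelihood of y = X lam + N(0, noise_sd^2)."""
    n = y.size
    C = noise_sd**2 * np.eye(n) + X @ prior.cov @ X.T
    r = y - X @ prior.mean
    _, logdet = np.linalg.slogdet(2 * np.pi * C)
    return -0.5 * (logdet + r @ np.linalg.solve(C, r))


class TestDataFeatures:
    def test_psd_on_grid_passes_through(self, coarse_settings):
        grid = coarse_settings.freqs
        vals = np.exp(-grid / 20.0)
        psd = cmc.SpectralDensity(freqs=grid, values=vals)
        np.testing.assert_allclose(
            inv.data_features(psd, coarse_settings), np.log(vals)
        )

    def test_white_noise_trace_is_flat(self):
        settings = inv.FitSettings(freq_range=(1, 100), freq_step=0.5)
        x = np.random.default_rng(0).standard_normal(200_000)
        feats = inv.data_features(TraceRecording(x, 1000.0), settings)
        expected = np.log(2.0 / 1000.0)  # one-sided PSD of unit white noise
        assert np.max(np.abs(feats - expected)) < 0.3

    def test_split_halves_agree(self):
        settings = inv.FitSettings(freq_range=(2, 80), freq_step=1.0)
        tr = cmc.simulate_timeseries(cmc.CMCParameters(), 120.0, 1000.0, seed=8)
        half = tr.samples.size // 2
        f1 = inv.data_features(TraceRecording(tr.samples[:half], 1000.0), settings)
        f2 = inv.data_features(TraceRecording(tr.samples[half:], 1000.0), settings)
        assert np.mean(np.abs(f1 - f2)) < 0.25

    def test_range_above_nyquist_rejected(self):
        settings = inv.FitSettings(freq_range=(1, 300), freq_step=1.0)
        with pytest.raises(ValueError):
            inv.data_features(TraceRecording(np.zeros(10_000), 500.0), settings)

    def test_psd_not_covering_range_rejected(self, coarse_settings):
        psd = cmc.SpectralDensity(
            freqs=np.arange(10.0, 50.0), values=np.ones(40)
        )
        with pytest.raises(ValueError):
            inv.data_features(psd, coarse_settings)


class TestVariationalLaplace:
    def test_linear_gaussian_free_energy_matches_closed_form(self):
        rng = np.random.default_rng(1)
        n, d = 40, 5
        X = rng.standard_normal((n, d))
        prior = inv.ParameterDensity(rng.standard_normal(d) * 0.3, 0.5 * np.eye(d))
        noise_sd = 0.2
        lam_true = prior.mean + rng.standard_normal(d) * 0.4
        y = X @ lam_true + rng.normal(0, noise_sd, n)
        settings = inv.FitSettings(
            max_iter=64, f_tolerance=1e-6,
            fix_noise_logprec=np.log(1 / noise_sd**2),
        )
        res = inv.variational_laplace(y, lambda lam: X @ lam, prior, settings)
        assert res.free_energy == pytest.approx(
            linear_evidence(y, X, prior, noise_sd), abs=1e-3
        )
        # exact Gaussian posterior
        Pi0 = np.linalg.inv(prior.cov)
        Sig = np.linalg.inv(X.T @ X / noise_sd**2 + Pi0)
        mu = Sig @ (X.T @ y / noise_sd**2 + Pi0 @ prior.mean)
        np.testing.assert_allclose(res.posterior.mean, mu, atol=1e-8)
        np.testing.assert_allclose(res.posterior.cov, Sig, atol=1e-10)

    def test_trajectory_monotone_on_accepted_steps(self, coarse_settings):
        base = cmc.CMCParameters()
        psd = synth.generate_state_psd_data(
            synth.default_state_params(), 0.1, coarse_settings.freqs, seed=2
        )[1]
        model = inv.SpectralCMC(
            inv.data_features(psd, coarse_settings), base,
            settings=coarse_settings,
        )
        res = model.fit()
        assert np.all(np.diff(res.f_trajectory) >= -1e-9)
        assert res.free_energy == res.f_trajectory[-1]

    def test_truth_at_prior_mean_stays_near_prior_mean(self, coarse_settings):
        base = cmc.CMCParameters()
        noiseless = cmc.predict_psd(base, coarse_settings.freqs)
        model = inv.SpectralCMC(
            np.log(noiseless.values), base, settings=coarse_settings
        )
        res = model.fit()
        z = np.abs(res.params - 0.0) / res.bse
        assert np.all(z < 1.0)

    def test_non_psd_prior_covariance_rejected(self):
        with pytest.raises(ValueError):
            inv.ParameterDensity(np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_feature_grid_mismatch_rejected(self, coarse_settings):
        with pytest.raises(ValueError):
            inv.SpectralCMC(np.zeros(7), settings=coarse_settings)

    def test_summary_and_conf_int_surface(self, coarse_settings):
        base = cmc.CMCParameters()
        psd = synth.generate_state_psd_data(
            synth.default_state_params(), 0.1, coarse_settings.freqs, seed=3
        )[0]
        res = inv.SpectralCMC.from_psd(
            psd, base_params=base, settings=coarse_settings
        ).fit()
        text = res.summary()
        assert "free energy" in text and "gamma10" in text
        ci = res.conf_int(0.05)
        assert ci.shape == (18, 2)
        assert np.all(ci[:, 0] < ci[:, 1])
        fitted = res.fitted_params
        assert np.all(fitted.tau > 0)


class TestFreeEnergyComponents:
    def test_complexity_zero_when_posterior_equals_prior(self):
        # a forward map insensitive to lambda leaves the posterior at the prior
        prior = inv.default_prior(3)
        y = np.zeros(10)
        settings = inv.FitSettings(max_iter=16, fix_noise_logprec=0.0)
        res = inv.variational_laplace(
            y, lambda lam: np.zeros(10), prior, settings
        )
        acc, cmp_ = inv.free_energy_components(res)
        assert cmp_ == pytest.approx(0.0, abs=1e-9)
        assert res.free_energy == pytest.approx(acc, abs=1e-9)

    def test_wider_prior_reduces_complexity(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 4))
        y = X @ np.full(4, 0.5) + rng.normal(0, 0.1, 30)
        settings = inv.FitSettings(max_iter=64, f_tolerance=1e-6,
                                   fix_noise_logprec=np.log(100.0))
        cmps = []
        for scale in (1.0, 4.0):
            prior = inv.ParameterDensity(np.zeros(4), scale * 0.0625 * np.eye(4))
            res = inv.variational_laplace(y, lambda lam: X @ lam, prior, settings)
            cmps.append(res.complexity)
        assert cmps[1] < cmps[0]
        assert all(c >= 0 for c in cmps)

    def test_noisier_features_reduce_accuracy(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 4))
        prior = inv.default_prior(4)
        settings = inv.FitSettings(max_iter=64, f_tolerance=1e-6,
                                   fix_noise_logprec=np.log(100.0))
        y_clean = X @ np.full(4, 0.2)
        accs = []
        for noise in (0.0, 0.5):
            y = y_clean + rng.normal(0, noise, 30) if noise else y_clean
            res = inv.variational_laplace(y, lambda lam: X @ lam, prior, settings)
            accs.append(res.accuracy)
        assert accs[1] < accs[0]


class TestCompareModels:
    def test_equal_evidence_gives_uniform_probabilities(self):
        out = inv.compare_models([3.0, 3.0, 3.0])
        np.testing.assert_allclose(out["posterior_prob"], 1 / 3)

    def test_delta_f_of_3_9_gives_098_probability(self):
        out = inv.compare_models([0.0, 3.9], ["null", "winner"])
        expected = 1.0 / (1.0 + np.exp(-3.9))
        assert out.loc["winner", "posterior_prob"] == pytest.approx(
            expected, abs=1e-6
        )
        assert out.loc["winner", "posterior_prob"] == pytest.approx(0.980, abs=5e-4)

    def test_shift_invariance(self):
        a = inv.compare_models([1.0, 2.5, 0.3])
        b = inv.compare_models([101.0, 102.5, 100.3])
        np.testing.assert_allclose(
            a["posterior_prob"], b["posterior_prob"], rtol=1e-12
        )
        assert a["posterior_prob"].sum() == pytest.approx(1.0)

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            inv.compare_models([1.0])


class TestEmpiricalPriors:
    def test_posterior_mean_equal_prior_gives_base(self):
        base = inv.default_prior(4)
        post = inv.ParameterDensity(base.mean.copy(), 0.01 * np.eye(4))
        out = inv.empirical_prior_from(post, base)
        np.testing.assert_allclose(out.mean, base.mean)
        np.testing.assert_allclose(out.cov, base.cov)

    def test_means_chained_covariance_reset(self):
        base = inv.default_prior(4)
        post = inv.ParameterDensity(np.array([1.0, -1, 2, 0.5]), 0.01 * np.eye(4))
        out = inv.empirical_prior_from(post, base)
        np.testing.assert_allclose(out.mean, post.mean)
        np.testing.assert_allclose(out.cov, base.cov)  # never the posterior's

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            inv.empirical_prior_from(inv.default_prior(3), inv.default_prior(4))

    def test_chaining_moves_means_towards_data_optimum(self):
        # repeated fit->prior chaining on fixed data approaches the ML point
        rng = np.random.default_rng(6)
        X = rng.standard_normal((50, 3))
        lam_star = np.array([0.8, -0.6, 0.4])
        y = X @ lam_star
        base = inv.default_prior(3)
        settings = inv.FitSettings(max_iter=64, f_tolerance=1e-6,
                                   fix_noise_logprec=np.log(25.0))
        prior = base
        dists = []
        for _ in range(3):
            res = inv.variational_laplace(y, lambda lam: X @ lam, prior, settings)
            dists.append(np.linalg.norm(res.posterior.mean - lam_star))
            prior = inv.empirical_prior_from(res.posterior, base)
        assert dists[1] < dists[0] and dists[2] < dists[1]


class TestConditionSequence:
    def test_null_only_space_uses_plain_empirical_priors(self, coarse_settings):
        base = cmc.CMCParameters()
        psds = synth.generate_state_psd_data(
            synth.default_state_params(base), 0.05, coarse_settings.freqs, seed=4
        )
        feats = [inv.data_features(p, coarse_settings) for p in psds]
        null_space = priors.ModelSpace(
            (priors.ModelSpec((), "both", is_null=True),)
        )
        seq = inv.fit_condition_sequence(
            *feats, null_space, coarse_settings, base,
            shifts={"gamma": -0.2, "tau": -0.3, "sigma": 0.4},
        )
        assert seq.winning_spec.is_null
        assert len(seq.f_table) == 1
        # stage-2 prior for the null model is exactly the stage-1 empirical
        # prior: its fit must start shrunk around the control posterior mean
        np.testing.assert_allclose(
            seq.interictal.raw.prior.mean, seq.control.posterior.mean
        )

    def test_f_table_has_one_row_per_model(self, coarse_settings):
        base = cmc.CMCParameters()
        psds = synth.generate_state_psd_data(
            synth.default_state_params(base), 0.05, coarse_settings.freqs, seed=5
        )
        feats = [inv.data_features(p, coarse_settings) for p in psds]
        space = priors.ModelSpace(
            (
                priors.ModelSpec((), "both", is_null=True),
                priors.ModelSpec(("gamma", "sigma"), "deep"),
                priors.ModelSpec(("gamma", "tau", "sigma"), "both"),
            )
        )
        seq = inv.fit_condition_sequence(
            *feats, space, coarse_settings, base,
            shifts=priors.shifts_from_contrast(
                priors.MicroscaleContrast(0.8, 0.7, 1.47)
            ),
        )
        assert len(seq.f_table) == 3
        assert set(seq.f_table.index) == {s.name for s in space}


class TestOccamProperty:
    def test_larger_model_not_strongly_favoured_on_null_data(self, coarse_settings):
        """Data generated from the null (control) circuit: the richer
        microscale-informed models never beat the null by more than 3 nats
        in most runs (the KL penalty enforces Occam's razor)."""
        base = cmc.CMCParameters()
        shifts = {"gamma": np.log(0.8), "tau": np.log(0.7), "sigma": np.log(1.47)}
        space = priors.ModelSpace(
            (
                priors.ModelSpec((), "both", is_null=True),
                priors.ModelSpec(("gamma", "tau", "sigma"), "both"),
            )
        )
        wins = 0
        n_runs = 5
        for seed in range(n_runs):
            psds = synth.generate_state_psd_data(
                [base, base, base], 0.05, coarse_settings.freqs, seed=seed
            )
            feats = [inv.data_features(p, coarse_settings) for p in psds]
            seq = inv.fit_condition_sequence(
                *feats, space, coarse_settings, base, shifts
            )
            f = seq.f_table["free_energy"]
            if f["gamma+tau+sigma_x_both"] - f["null"] <= 3.0:
                wins += 1
        assert wins >= 0.9 * n_runs
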