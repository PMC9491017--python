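"""Gaussian-process emulation: fitting, prediction, posterior sampling, CV.

The independent oracle here is a from-scratch Cholesky GP (textbook
formulas, own Matérn implementation) evaluated at the fitted hyperparameters.
"""

import numpy as np
import pytest
from types import SimpleNamespace

import heartgsa as hg
from heartgsa.emulator import GPEConfig, _fit_core, posterior_covariance


# ---------------------------------------------------------------- oracle ----
def matern52(xa: np.ndarray, xb: np.ndarray, ell: np.ndarray, s2: float) -> np.ndarray:
    d = np.sqrt(
        np.maximum(
            ((xa[:, None, :] - xb[None, :, :]) / ell[None, None, :]) ** 2, 0.0
        ).sum(-1)
    )
    r = np.sqrt(5.0) * d
    return s2 * (1.0 + r + r**2 / 3.0) * np.exp(-r)


def cholesky_gp_oracle(x, y, xs, ell, s2, noise):
    """Textbook GP posterior (mean, variance incl. noise) via Cholesky."""
    k = matern52(x, x, ell, s2) + noise * np.eye(len(x))
    ks = matern52(xs, x, ell, s2)
    kss = s2 * np.ones(len(xs)) + noise
    L = np.linalg.cholesky(k)
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, y))
    mu = ks @ alpha
    v = np.linalg.solve(L, ks.T)
    var = kss - np.sum(v**2, axis=0)
    return mu, var


@pytest.fixture()
def linear_problem():
    rng = np.random.default_rng(42)
    x = rng.random((30, 2))
    y = 3.0 * x[:, 0] + 0.5
    return x, y


class TestFit:
    def test_noiseless_linear_target(self, linear_problem):
        x, y = linear_problem
        model = hg.fit_gpe(x, y, GPEConfig(seed=0))
        xs = np.random.default_rng(1).random((20, 2))
        mu, _ = hg.predict(model, xs)
        assert np.allclose(mu, 3.0 * xs[:, 0] + 0.5, rtol=1e-3, atol=1e-3)
        assert model.cv_mean > 0.999

    def test_constant_target_rejected(self):
        x = np.random.default_rng(0).random((20, 2))
        with pytest.raises(ValueError, match="constant"):
            hg.fit_gpe(x, np.ones(20))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="training points"):
            hg.fit_gpe(np.random.random((3, 2)), np.arange(3.0), run_cv=False)

    def test_interpolation_at_training_points(self):
        rng = np.random.default_rng(3)
        x = rng.random((25, 2))
        y = np.sin(3 * x[:, 0]) + x[:, 1] ** 2
        model = hg.fit_gpe(x, y, GPEConfig(noise_floor=1e-10, seed=0), run_cv=False)
        mu, _ = hg.predict(model, x)
        assert np.allclose(mu, y, atol=1e-5)

    def test_standardization_round_trip(self):
        """Affinely transformed copies of the data give identical native-unit
        predictions."""
        rng = np.random.default_rng(5)
        x = rng.random((30, 2))
        y = np.sin(3 * x[:, 0]) + 0.3 * x[:, 1]
        xs = rng.random((10, 2))
        cfg = GPEConfig(seed=0, optimize=False)  # fixed kernel isolates the transforms
        m1 = hg.fit_gpe(x, y, cfg, run_cv=False)
        a, b, c, d = 12.0, -3.0, 7.0, 2.5
        m2 = hg.fit_gpe(a * x + b, c * y + d, cfg, run_cv=False)
        mu1, _ = hg.predict(m1, xs)
        mu2, _ = hg.predict(m2, a * xs + b)
        assert np.allclose(c * mu1 + d, mu2, rtol=1e-8, atol=1e-8)


class TestPredict:
    def test_matches_cholesky_oracle(self):
        """Posterior mean/variance agree with the from-scratch GP at the
        fitted hyperparameters to 1e-8."""
        rng = np.random.default_rng(7)
        x = rng.random((40, 2))
        y = np.sin(4 * x[:, 0]) * np.cos(3 * x[:, 1]) + 1e-3 * rng.standard_normal(40)
        cfg = GPEConfig(mean_function="constant", noise_floor=1e-8, seed=0)
        model = _fit_core(x, y, cfg, None)
        hp = model.hyperparameters
        ell = np.asarray(hp["lengthscales"])
        x_std = model._xt(x)
        resid = model.gpr.y_train_
        mu_o, var_o = cholesky_gp_oracle(
            x_std, resid, model._xt(x), ell, hp["signal_variance"], hp["noise_variance"]
        )
        mu_o = (model._mean(model._xt(x)) + mu_o) * model.y_std + model.y_mean
        var_o = var_o * model.y_std**2
        mu, var = hg.predict(model, x)
        scale = np.abs(y).max()
        assert np.allclose(mu, mu_o, atol=1e-8 * scale)
        assert np.allclose(var, var_o, atol=1e-8 * model.y_std**2)

    def test_prior_reversion_far_from_data(self):
        rng = np.random.default_rng(11)
        x = rng.random((20, 1)) * 0.1  # cluster near 0
        y = np.sin(20 * x[:, 0])
        cfg = GPEConfig(mean_function="constant", seed=0)
        model = _fit_core(x, y, cfg, None)
        _, var_near = hg.predict(model, np.array([[0.05]]))
        _, var_far = hg.predict(model, np.array([[50.0]]))
        hp = model.hyperparameters
        assert var_far > var_near
        assert var_far[0] == pytest.approx(
            (hp["signal_variance"] + hp["noise_variance"]) * model.y_std**2, rel=0.05
        )

    def test_variance_monotone_along_ray(self):
        rng = np.random.default_rng(13)
        x = rng.random((25, 2))
        y = x[:, 0] + x[:, 1]
        model = _fit_core(x, y, GPEConfig(seed=0), None)
        ray = np.array([[1.0 + s, 1.0 + s] for s in np.linspace(0, 5, 8)])
        _, var = hg.predict(model, ray)
        assert np.all(np.diff(var) >= -1e-12)


class TestSamplePosterior:
    @pytest.fixture()
    def model(self):
        rng = np.random.default_rng(17)
        x = rng.random((30, 2))
        y = np.sin(3 * x[:, 0]) + 0.5 * x[:, 1]
        return _fit_core(x, y, GPEConfig(noise_floor=1e-10, seed=0), None)

    def test_sample_mean_approaches_predictive_mean(self, model):
        xs = np.random.default_rng(19).random((5, 2))
        draws = hg.sample_posterior(model, xs, 4000, seed=0, method="exact")
        mu, var = hg.predict(model, xs)
        se = np.sqrt(var / 4000)
        assert np.all(np.abs(draws.mean(axis=0) - mu) < 3 * np.maximum(se, 1e-12) + 1e-9)

    def test_near_zero_noise_draws_hit_training_values(self, model):
        xs = model.gpr.X_train_[:5]
        # invert the standardization to query in native units
        x_native = xs * model.x_range + model.x_min
        draws = hg.sample_posterior(model, x_native, 50, seed=1, method="exact")
        mu, _ = hg.predict(model, x_native)
        assert np.allclose(draws, mu[None, :], atol=1e-5)

    def test_draw_covariance_matches_predictive_covariance(self, model):
        xs = np.array([[0.2, 0.3], [0.5, 0.6], [0.8, 0.1]])
        draws = hg.sample_posterior(model, xs, 10000, seed=2, method="exact")
        _, cov = posterior_covariance(model, xs)
        emp = np.cov(draws.T)
        scale = np.abs(np.diag(cov)).max()
        assert np.allclose(emp, cov, atol=5 * scale / np.sqrt(10000) + 0.05 * scale)

    def test_pathwise_route_consistent_with_exact(self, model):
        """RFF + Matheron draws agree with the exact posterior in mean."""
        xs = np.random.default_rng(23).random((50, 2))
        draws = hg.sample_posterior(model, xs, 400, seed=3, method="rff")
        mu, var = hg.predict(model, xs)
        sd = np.sqrt(var)
        err = np.abs(draws.mean(axis=0) - mu)
        assert np.all(err < 0.2 * np.ptp(mu) * np.ones_like(mu) + 5 * sd / np.sqrt(400))

    def test_invalid_draw_count(self, model):
        with pytest.raises(ValueError):
            hg.sample_posterior(model, np.zeros((2, 2)), 0, seed=0)


class TestCrossValidate:
    def test_linear_target_high_score(self, linear_problem):
        x, y = linear_problem
        _, mean = hg.cross_validate(x, y, GPEConfig(seed=0))
        assert mean > 0.99

    def test_pure_noise_target_low_score(self):
        rng = np.random.default_rng(29)
        x = rng.random((60, 3))
        y = rng.standard_normal(60)
        _, mean = hg.cross_validate(x, y, GPEConfig(seed=0))
        assert mean < 0.2

    def test_fold_boundary(self):
        rng = np.random.default_rng(31)
        x = rng.random((12, 1))
        y = np.sin(5 * x[:, 0])
        scores, _ = hg.cross_validate(x, y, GPEConfig(mean_function="constant", seed=0), k=6)
        assert len(scores) == 6

    def test_smooth_2d_target_60_lhs_points(self):
        """Mean 5-fold CV R² > 0.99 on a smooth 2D response over a 60-point
        Latin hypercube design."""
        space = hg.space_from_baselines({"a": 1.0, "b": 1.0})
        d = hg.latin_hypercube(space, 60, seed=0)
        x = d.values.to_numpy()
        y = np.sin(2 * x[:, 0]) + (x[:, 1] - 1.0) ** 2
        _, mean = hg.cross_validate(x, y, GPEConfig(seed=0), k=5, space=space)
        assert mean > 0.99


class TestSerialization:
    def test_save_gpe_json_round_trips_metadata(self, tmp_path, linear_problem):
        import json

        x, y = linear_problem
        model = hg.fit_gpe(x, y, GPEConfig(seed=0), feature_name="toy")
        path = tmp_path / "gpe.json"
        from heartgsa.emulator import save_gpe

        save_gpe(model, path)
        payload = json.loads(path.read_text())
        assert payload["feature"] == "toy"
        assert payload["n_train"] == 30
        assert len(payload["hyperparameters"]["lengthscales"]) == 2
        assert payload["cv_mean"] == pytest.approx(model.cv_mean)


class TestScreening:
    def test_partition_by_threshold(self):
        models = {
            "a": SimpleNamespace(cv_mean=0.9),
            "b": SimpleNamespace(cv_mean=0.4),
        }
        kept, excluded = hg.screen_emulators(models)
        assert kept == ["a"] and excluded == ["b"]

    def test_exact_threshold_excluded(self):
        models = {"edge": SimpleNamespace(cv_mean=0.5)}
        kept, excluded = hg.screen_emulators(models, threshold=0.5)
        assert kept == [] and excluded == ["edge"]

    def test_empty_set(self):
        assert hg.screen_emulators({}) == ([], [])
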