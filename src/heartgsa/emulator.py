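"""Univariate Gaussian-process emulation of simulator output features.

Each scalar feature gets its own emulator: a deterministic mean function
(constant or linear in the standardized inputs) plus a zero-mean Gaussian
process with a stationary Matérn covariance and i.i.d. Gaussian observation
noise.  Inputs are mapped to the unit cube (log10 first for log-scale
parameters), outputs are z-scored; hyperparameters are found by multi-start
maximization of the log marginal likelihood.  Accuracy is scored by k-fold
cross-validated R² in native units, and emulators whose mean CV R² does not
exceed 0.5 are screened out of the sensitivity analysis.

Posterior sampling offers two routes: exact joint draws via a Cholesky
factorization of the predictive covariance (with escalating jitter), and a
scalable pathwise approximation for large point sets that combines random
Fourier features of the Matérn spectrum with the Matheron update rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold

from .design import ParameterSpace

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GPEConfig:
    nu: float = 2.5  # Matérn smoothness
    mean_function: str = "linear"  # constant | linear
    noise_floor: float = 1e-8  # lower bound on the noise variance (z-scored units)
    restarts: int = 5  # multi-start optimizations of the marginal likelihood
    standardize_x: bool = True
    standardize_y: bool = True
    optimize: bool = True  # False freezes the kernel at its initial values
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nu not in (1.5, 2.5):
            raise ValueError("nu must be 1.5 or 2.5")
        if self.mean_function not in ("constant", "linear"):
            raise ValueError("mean_function must be 'constant' or 'linear'")
        if not self.noise_floor > 0:
            raise ValueError("noise_floor must be positive")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class TrainedGPE:
    """A fitted emulator with its transforms and cross-validation scores."""

    gpr: GaussianProcessRegressor
    beta: np.ndarray  # mean-function coefficients on [1, x_std]
    x_min: np.ndarray
    x_range: np.ndarray
    log_mask: np.ndarray
    y_mean: float
    y_std: float
    config: GPEConfig
    space: ParameterSpace | None = None
    cv_scores: list[float] = field(default_factory=list)
    feature_name: str = ""

    @property
    def cv_mean(self) -> float:
        defined = [s for s in self.cv_scores if np.isfinite(s)]
        return float(np.mean(defined)) if defined else float("nan")

    @property
    def hyperparameters(self) -> dict[str, object]:
        k = self.gpr.kernel_
        return {
            "signal_variance": float(k.k1.k1.constant_value),
            "lengthscales": np.atleast_1d(k.k1.k2.length_scale).tolist(),
            "noise_variance": float(k.k2.noise_level),
            "mean_coefficients": self.beta.tolist(),
        }

    # ---- transforms -------------------------------------------------
    def _xt(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        xt = x.copy()
        xt[:, self.log_mask] = np.log10(xt[:, self.log_mask])
        return (xt - self.x_min) / self.x_range

    def _mean(self, x_std: np.ndarray) -> np.ndarray:
        phi = np.hstack([np.ones((x_std.shape[0], 1)), x_std]) if self.beta.size > 1 else np.ones(
            (x_std.shape[0], 1)
        )
        return phi @ self.beta


def _build_transform(
    x: np.ndarray, cfg: GPEConfig, space: ParameterSpace | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = x.shape[1]
    if space is not None:
        log_mask = np.array([p.scale == "log10" for p in space.parameters])
        lo = np.array(
            [np.log10(p.lower) if p.scale == "log10" else p.lower for p in space.parameters]
        )
        hi = np.array(
            [np.log10(p.upper) if p.scale == "log10" else p.upper for p in space.parameters]
        )
        return lo, hi - lo, log_mask
    log_mask = np.zeros(d, dtype=bool)
    if not cfg.standardize_x:
        return np.zeros(d), np.ones(d), log_mask
    lo, hi = x.min(axis=0), x.max(axis=0)
    rng = np.where(hi > lo, hi - lo, 1.0)
    return lo, rng, log_mask


def _fit_core(
    x: np.ndarray, y: np.ndarray, cfg: GPEConfig, space: ParameterSpace | None
) -> TrainedGPE:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, d = x.shape
    if n < d + 2:
        raise ValueError(f"need at least D+2={d+2} training points, got {n}")
    if not np.all(np.isfinite(y)):
        raise ValueError("training targets must be finite (drop unconverged runs first)")
    if np.ptp(y) == 0.0:
        raise ValueError(
            "training target is constant; exclude this feature (R² undefined)"
        )

    x_min, x_range, log_mask = _build_transform(x, cfg, space)
    xt = x.copy()
    xt[:, log_mask] = np.log10(xt[:, log_mask])
    x_std = (xt - x_min) / x_range

    y_mean = float(np.mean(y)) if cfg.standardize_y else 0.0
    y_std = float(np.std(y)) if cfg.standardize_y else 1.0
    y_std = y_std if y_std > 0 else 1.0
    yz = (y - y_mean) / y_std

    if cfg.mean_function == "linear":
        phi = np.hstack([np.ones((n, 1)), x_std])
    else:
        phi = np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(phi, yz, rcond=None)
    resid = yz - phi @ beta

    kernel = (
        ConstantKernel(1.0, (1e-4, 1e4))
        * Matern(length_scale=np.full(d, 0.5), length_scale_bounds=(1e-2, 1e2), nu=cfg.nu)
        + WhiteKernel(noise_level=max(1e-6, cfg.noise_floor), noise_level_bounds=(cfg.noise_floor, 1e2))
    )
    gpr = GaussianProcessRegressor(
        kernel=kernel,
        alpha=1e-12,
        normalize_y=False,
        optimizer="fmin_l_bfgs_b" if cfg.optimize else None,
        n_restarts_optimizer=cfg.restarts - 1 if cfg.optimize else 0,
        random_state=cfg.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign convergence chatter from L-BFGS
        gpr.fit(x_std, resid)
    return TrainedGPE(
        gpr=gpr,
        beta=beta,
        x_min=x_min,
        x_range=x_range,
        log_mask=log_mask,
        y_mean=y_mean,
        y_std=y_std,
        config=cfg,
        space=space,
    )


def fit_gpe(
    x: np.ndarray,
    y: np.ndarray,
    cfg: GPEConfig | None = None,
    space: ParameterSpace | None = None,
    k_folds: int = 5,
    feature_name: str = "",
    run_cv: bool = True,
) -> TrainedGPE:
    """Fit an emulator on a training design and score it by k-fold CV.

    The returned model carries its input/output transforms, so predictions
    are in native units.
    """
    cfg = cfg or GPEConfig()
    model = _fit_core(x, y, cfg, space)
    model.feature_name = feature_name
    if run_cv:
        scores, _ = cross_validate(x, y, cfg, k=k_folds, seed=cfg.seed, space=space)
        model.cv_scores = scores
    return model


def predict(model: TrainedGPE, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior predictive mean and variance (native units) at query points.

    Points outside the training space are allowed but logged.  The variance
    includes the fitted observation-noise level.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if model.space is not None:
        outside = ~model.space.contains(x)
        if outside.any():
            log.info("%d query points lie outside the parameter space", int(outside.sum()))
    x_std = model._xt(x)
    mu_gp, sd = model.gpr.predict(x_std, return_std=True)
    mu = (model._mean(x_std) + mu_gp) * model.y_std + model.y_mean
    var = np.maximum(sd, 0.0) ** 2 * model.y_std**2
    return mu, var


def posterior_covariance(model: TrainedGPE, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Joint predictive mean and covariance (native units) at query points."""
    x_std = model._xt(np.atleast_2d(np.asarray(x, dtype=float)))
    mu_gp, cov = model.gpr.predict(x_std, return_cov=True)
    mu = (model._mean(x_std) + mu_gp) * model.y_std + model.y_mean
    return mu, cov * model.y_std**2


def sample_posterior(
    model: TrainedGPE,
    x: np.ndarray,
    n_draws: int,
    seed: int,
    method: str = "auto",
    n_fourier: int = 1024,
) -> np.ndarray:
    """Joint posterior draws at query points; shape (n_draws, n_points).

    ``method='exact'`` factorizes the full predictive covariance (jitter
    escalated 1e-10 → 1e-6 before giving up); ``method='rff'`` uses Matérn
    random Fourier features with a Matheron update, which scales to the large
    pick-freeze point sets of the sensitivity stage.  ``'auto'`` switches to
    the pathwise route above 2000 points.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if method == "auto":
        method = "rff" if x.shape[0] > 2000 else "exact"
    rng = np.random.default_rng(seed)
    if method == "exact":
        mu, cov = posterior_covariance(model, x)
        n = cov.shape[0]
        scale = max(np.max(np.diag(cov)), 1e-30)
        chol = None
        for jitter in (0.0, 1e-10, 1e-8, 1e-6):
            try:
                chol = cholesky(cov + jitter * scale * np.eye(n), lower=True)
                break
            except np.linalg.LinAlgError:
                continue
        if chol is None:
            raise np.linalg.LinAlgError(
                "posterior covariance not positive definite after jitter escalation"
            )
        z = rng.standard_normal((n_draws, n))
        return mu[None, :] + z @ chol.T
    if method == "rff":
        return _sample_pathwise(model, x, n_draws, rng, n_fourier)
    raise ValueError("method must be 'auto', 'exact' or 'rff'")


def _sample_pathwise(
    model: TrainedGPE, x: np.ndarray, n_draws: int, rng: np.random.Generator, n_fourier: int
) -> np.ndarray:
    """Approximate joint posterior draws via Matérn random Fourier features
    plus the Matheron pathwise update.

    A Matérn-ν prior draw is f(x) = √(2σ²/F)·Σ w_f cos(ω_f·x + b_f) with
    frequencies ω ~ Student-t(2ν)/ℓ; conditioning on the training data uses
    f*|y = f_prior(x*) + K*ₘ(Kₘₘ+σₙ²I)⁻¹(y − f_prior(X) − ε), ε ~ N(0, σₙ²I).
    """
    hp = model.hyperparameters
    sigma2 = hp["signal_variance"]
    noise = hp["noise_variance"]
    ell = np.asarray(hp["lengthscales"], dtype=float)
    nu = model.config.nu
    x_std = model._xt(x)
    xt_train = model.gpr.X_train_
    y_train = model.gpr.y_train_  # residuals after the mean function
    d = x_std.shape[1]
    if ell.size == 1:
        ell = np.full(d, float(ell))

    # training-kernel factorization (small m×m)
    k_mm = model.gpr.kernel_(xt_train)
    cf = cho_factor(k_mm + 1e-12 * np.eye(k_mm.shape[0]), lower=True)
    k_star = model.gpr.kernel_(x_std, xt_train)  # white kernel is 0 off-diagonal

    draws = np.empty((n_draws, x_std.shape[0]))
    m = xt_train.shape[0]
    for j in range(n_draws):
        z = rng.standard_normal((n_fourier, d))
        u = rng.chisquare(2.0 * nu, size=(n_fourier, 1))
        omega = z * np.sqrt(2.0 * nu / u) / ell[None, :]
        b = rng.uniform(0.0, 2.0 * np.pi, size=n_fourier)
        w = rng.standard_normal(n_fourier)
        amp = np.sqrt(2.0 * sigma2 / n_fourier)

        def prior(pts: np.ndarray) -> np.ndarray:
            return amp * (np.cos(pts @ omega.T + b[None, :]) @ w)

        eps = rng.standard_normal(m) * np.sqrt(noise)
        alpha = cho_solve(cf, y_train - prior(xt_train) - eps)
        f_star = prior(x_std) + k_star @ alpha
        draws[j] = f_star
    mean_fn = model._mean(x_std)
    return (draws + mean_fn[None, :]) * model.y_std + model.y_mean


def save_gpe(model: TrainedGPE, path) -> None:
    """Serialize a trained emulator to versioned JSON: hyperparameters,
    transforms, CV scores and a digest of the training data."""
    import hashlib
    import json
    from pathlib import Path

    data = np.ascontiguousarray(
        np.hstack([model.gpr.X_train_, model.gpr.y_train_.reshape(-1, 1)])
    )
    payload = {
        "format_version": 1,
        "feature": model.feature_name,
        "config": {
            "nu": model.config.nu,
            "mean_function": model.config.mean_function,
            "noise_floor": model.config.noise_floor,
            "restarts": model.config.restarts,
            "seed": model.config.seed,
        },
        "hyperparameters": model.hyperparameters,
        "transforms": {
            "x_min": model.x_min.tolist(),
            "x_range": model.x_range.tolist(),
            "log_mask": model.log_mask.tolist(),
            "y_mean": model.y_mean,
            "y_std": model.y_std,
        },
        "cv_scores": model.cv_scores,
        "cv_mean": model.cv_mean,
        "training_data_sha256": hashlib.sha256(data.tobytes()).hexdigest(),
        "n_train": int(model.gpr.X_train_.shape[0]),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def cross_validate(
    x: np.ndarray,
    y: np.ndarray,
    cfg: GPEConfig | None = None,
    k: int = 5,
    seed: int = 0,
    space: ParameterSpace | None = None,
) -> tuple[list[float], float]:
    """Seeded k-fold CV; per-fold R² in native units plus their mean.

    A fold whose held-out truth is constant has no defined R²; it is recorded
    as NaN, the mean is taken over defined folds, and a warning is logged.
    """
    cfg = cfg or GPEConfig()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < 2 * k:
        raise ValueError(f"need at least 2k={2*k} points for {k}-fold CV")
    scores: list[float] = []
    for train_idx, test_idx in KFold(n_splits=k, shuffle=True, random_state=seed).split(x):
        model = _fit_core(x[train_idx], y[train_idx], cfg, space)
        mu, _ = predict(model, x[test_idx])
        if np.ptp(y[test_idx]) == 0.0:
            log.warning("CV fold with constant truth: R² undefined, recorded as NaN")
            scores.append(float("nan"))
        else:
            scores.append(float(r2_score(y[test_idx], mu)))
    defined = [s for s in scores if np.isfinite(s)]
    return scores, float(np.mean(defined)) if defined else float("nan")


def screen_emulators(
    models: Mapping[str, TrainedGPE], threshold: float = 0.5
) -> tuple[list[str], list[str]]:
    """Partition emulators by mean CV R² strictly above the threshold.

    Excluded names are logged with their scores, mirroring the screening of
    poorly emulated features before index calculation.
    """
    kept, excluded = [], []
    for name, model in models.items():
        if model.cv_mean > threshold:
            kept.append(name)
        else:
            excluded.append(name)
            log.info("emulator '%s' excluded: mean CV R² = %.3f <= %.2f", name, model.cv_mean, threshold)
    return kept, excluded
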