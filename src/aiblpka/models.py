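"""Regression models mapping keto-enol bond lengths to pKa.

The workhorse is a single-bond ordinary least-squares line, of which the
published C-O model

    pKa = 93.381 * r(C-O) - 127.71

is the canonical instance (:func:`published_co_model`).  Multi-feature
alternatives — partial least squares, epsilon-insensitive support vector
regression (linear and RBF kernels), random-forest regression, and a
Gaussian process with a squared-exponential ARD kernel — are provided for
comparison.  PLS/SVR/RFR are fitted through scikit-learn behind a uniform
predictor interface; the Gaussian process (kernel, marginal likelihood,
gradient, restarts) is implemented here from first principles.

Multi-feature methods operate on z-scored features (train-set mean/s.d.):
raw bond-length differences are of order 0.01 Å, which would make RBF-type
kernel hyperparameters of order unity meaningless.  Single-bond OLS uses
raw angstroms so its slope/intercept are directly comparable with the
published equation.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.svm import SVR

from .errors import DegenerateFitError, NumericalError
from .geometry import BOND_ROMAN

__all__ = [
    "LinearBondModel",
    "FittedRegressor",
    "GPRModel",
    "METHODS",
    "fit_ols_single",
    "predict_linear",
    "published_co_model",
    "fit_ols_multi",
    "fit_pls",
    "fit_svr",
    "fit_rfr",
    "kernel_se_ard",
    "log_marginal_likelihood",
    "fit_gpr",
]

METHODS = ("OLS", "PLS", "SVR_linear", "SVR_rbf", "RFR", "GPR_rbf")

#: SVR dual-problem tolerance, frozen for cross-run determinism.
SVR_TOL = 1e-6


# ---------------------------------------------------------------------------
# single-bond linear models


@dataclass
class LinearBondModel:
    """Affine pKa model on one bond length: pKa = slope * r + intercept."""

    bond: str
    slope: float
    intercept: float
    r2_train: float
    fitted_n: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.bond not in BOND_ROMAN:
            raise ValueError(f"bond must be one of {BOND_ROMAN}")
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("non-finite coefficients")
        if self.slope == 0.0 and not self.degenerate:
            raise ValueError("zero slope only allowed on a degenerate fit")

    def predict(self, lengths) -> np.ndarray:
        r = np.atleast_1d(np.asarray(lengths, dtype=float))
        return self.slope * r + self.intercept

    def to_json(self) -> str:
        return json.dumps({
            "kind": "linear_bond", "bond": self.bond, "slope": self.slope,
            "intercept": self.intercept, "r2_train": self.r2_train,
            "fitted_n": self.fitted_n, "degenerate": self.degenerate,
        }, indent=2)


def fit_ols_single(lengths, pkas, bond: str) -> LinearBondModel:
    """Least-squares line of pKa on one bond length (raw Å)."""
    x = np.asarray(lengths, dtype=float)
    y = np.asarray(pkas, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("lengths and pkas must be matching 1-D sequences")
    if x.size < 3:
        raise ValueError("need at least 3 points for a single-bond fit")
    if np.ptp(x) == 0.0:
        raise DegenerateFitError("zero variance in bond length")
    res = stats.linregress(x, y)
    if res.slope == 0.0 or np.ptp(y) == 0.0:
        return LinearBondModel(bond, 0.0, float(np.mean(y)), 0.0, x.size,
                               degenerate=True)
    return LinearBondModel(bond, float(res.slope), float(res.intercept),
                           float(res.rvalue ** 2), x.size)


def predict_linear(model: LinearBondModel, length: float) -> float:
    """Evaluate an affine bond model; warns (never errors) on extrapolation
    outside the plausible (0.5, 3.0) Å window."""
    if not (0.5 < length < 3.0):
        warnings.warn(f"bond length {length} Å outside (0.5, 3.0): extrapolating",
                      stacklevel=2)
    return float(model.slope * length + model.intercept)


def published_co_model() -> LinearBondModel:
    """The published single-bond C-O model, pKa = 93.381 r(CO) - 127.71,
    fitted on the 47 retained training compounds."""
    return LinearBondModel(bond="ii", slope=93.381, intercept=-127.71,
                           r2_train=0.72, fitted_n=47)


# ---------------------------------------------------------------------------
# multi-feature predictors (scikit-learn backed)


@dataclass
class FittedRegressor:
    """Uniform wrapper: a fitted estimator plus its standardisation constants."""

    method: str
    estimator: object
    hyperparams: dict
    x_mean: np.ndarray
    x_sd: np.ndarray
    n_train: int
    train_checksum: str

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self.x_mean) / self.x_sd
        return np.asarray(self.estimator.predict(Z)).ravel()

    def to_json(self) -> str:
        payload = {
            "kind": "sklearn", "method": self.method,
            "hyperparams": self.hyperparams,
            "x_mean": self.x_mean.tolist(), "x_sd": self.x_sd.tolist(),
            "n_train": self.n_train, "train_checksum": self.train_checksum,
        }
        est = self.estimator
        if hasattr(est, "coef_") and hasattr(est, "intercept_"):
            payload["coef"] = np.asarray(est.coef_).ravel().tolist()
            payload["intercept"] = np.asarray(est.intercept_).ravel().tolist()
        return json.dumps(payload, indent=2)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X - mean) / sd, mean, sd


def _checksum(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X, dtype=float).tobytes())
    h.update(np.ascontiguousarray(y, dtype=float).tobytes())
    return h.hexdigest()[:16]


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on sample count")
    return X, y


def fit_ols_multi(X, y) -> FittedRegressor:
    """Multiple linear regression on standardized features."""
    X, y = _as_xy(X, y)
    Z, mean, sd = _standardize(X)
    est = LinearRegression().fit(Z, y)
    return FittedRegressor("OLS", est, {}, mean, sd, y.size, _checksum(X, y))


def fit_pls(X, y, n_latent: int) -> FittedRegressor:
    """PLS1 regression with ``n_latent`` latent variables."""
    X, y = _as_xy(X, y)
    if n_latent > X.shape[1]:
        raise ValueError(f"n_latent={n_latent} exceeds {X.shape[1]} features")
    if y.size < n_latent + 2:
        raise ValueError("too few samples for the requested latent dimension")
    Z, mean, sd = _standardize(X)
    est = PLSRegression(n_components=n_latent, scale=False).fit(Z, y)
    return FittedRegressor("PLS", est, {"n_latent": n_latent},
                           mean, sd, y.size, _checksum(X, y))


def fit_svr(X, y, kernel: str, C: float = 1000.0, epsilon: float = 0.1,
            gamma: float | None = None) -> FittedRegressor:
    """Epsilon-insensitive SVR on standardized features."""
    if kernel not in ("linear", "rbf"):
        raise ValueError(f"invalid kernel {kernel!r} (linear or rbf)")
    if C <= 0 or epsilon < 0:
        raise ValueError("require C > 0 and epsilon >= 0")
    if kernel == "rbf" and gamma is None:
        raise ValueError("gamma is required with the rbf kernel")
    X, y = _as_xy(X, y)
    Z, mean, sd = _standardize(X)
    hp = {"C": C, "epsilon": epsilon}
    if kernel == "rbf":
        hp["gamma"] = gamma
    est = SVR(kernel=kernel, tol=SVR_TOL, **hp).fit(Z, y)
    return FittedRegressor(f"SVR_{kernel}", est, hp, mean, sd, y.size,
                           _checksum(X, y))


def fit_rfr(X, y, n_estimators: int = 25, max_depth: int | None = 6,
            seed: int = 0, bootstrap: bool = True) -> FittedRegressor:
    """Random-forest regression; prediction is the mean over trees.

    ``bootstrap=False`` fits every tree on the full sample (useful for
    checking that an unconstrained tree memorises its training points).
    """
    if n_estimators < 1:
        raise ValueError("n_estimators must be >= 1")
    X, y = _as_xy(X, y)
    Z, mean, sd = _standardize(X)
    est = RandomForestRegressor(n_estimators=n_estimators, max_depth=max_depth,
                                random_state=seed, bootstrap=bootstrap).fit(Z, y)
    return FittedRegressor("RFR", est,
                           {"n_estimators": n_estimators, "max_depth": max_depth},
                           mean, sd, y.size, _checksum(X, y))


# ---------------------------------------------------------------------------
# Gaussian process with SE-ARD kernel, from first principles


def kernel_se_ard(x, x_prime, log_lengthscales) -> float:
    """Squared-exponential ARD correlation between two points.

        k(x, x') = exp(-1/2 sum_d (x_d - x'_d)^2 / l_d^2),  l_d = exp(log_l_d)

    Each dimension has its own length scale (automatic relevance
    determination); the signal variance is kept as a separate multiplier.
    """
    x = np.asarray(x, dtype=float).ravel()
    xp = np.asarray(x_prime, dtype=float).ravel()
    ll = np.asarray(log_lengthscales, dtype=float).ravel()
    if not (x.size == xp.size == ll.size):
        raise ValueError("x, x_prime and log_lengthscales must share a dimension")
    d = (x - xp) / np.exp(ll)
    return float(np.exp(-0.5 * np.dot(d, d)))


def _gram(X: np.ndarray, log_ls: np.ndarray) -> np.ndarray:
    Z = X / np.exp(log_ls)
    sq = np.sum((Z[:, None, :] - Z[None, :, :]) ** 2, axis=-1)
    return np.exp(-0.5 * sq)


def _cross(Xa: np.ndarray, Xb: np.ndarray, log_ls: np.ndarray) -> np.ndarray:
    Za, Zb = Xa / np.exp(log_ls), Xb / np.exp(log_ls)
    sq = np.sum((Za[:, None, :] - Zb[None, :, :]) ** 2, axis=-1)
    return np.exp(-0.5 * sq)


def log_marginal_likelihood(X, y, log_lengthscales, kernel_variance: float,
                            jitter: float = 1e-10) -> float:
    """Gaussian-process log marginal likelihood via Cholesky factorisation.

        log p(y) = -1/2 y^T K^-1 y - 1/2 log|K| - n/2 log 2 pi,
        K = s2 * SE-ARD gram + jitter I
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    ll = np.asarray(log_lengthscales, dtype=float).ravel()
    K = kernel_variance * _gram(X, ll) + jitter * np.eye(y.size)
    cf = linalg.cho_factor(K, lower=True)
    alpha = linalg.cho_solve(cf, y)
    return float(-0.5 * y @ alpha - np.sum(np.log(np.diag(cf[0])))
                 - 0.5 * y.size * np.log(2.0 * np.pi))


@dataclass
class GPRModel:
    """A fitted zero-mean GP posterior with SE-ARD kernel.

    Hyperparameters live in optimizer (log) space; ``noise_jitter`` is a
    fixed numerical stabiliser, not a learned noise variance.
    """

    log_lengthscales: np.ndarray
    kernel_variance: float
    noise_jitter: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    X_train: np.ndarray          # standardized
    y_mean: float
    y_train: np.ndarray          # centered
    alpha: np.ndarray = field(repr=False, default=None)
    restarts: int = 1
    log_likelihood: float = np.nan

    def predict(self, X) -> np.ndarray:
        """Posterior mean at new inputs (raw Å scale)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self.x_mean) / self.x_sd
        Ks = self.kernel_variance * _cross(Z, self.X_train, self.log_lengthscales)
        return Ks @ self.alpha + self.y_mean

    def to_json(self) -> str:
        return json.dumps({
            "kind": "gpr", "log_lengthscales": self.log_lengthscales.tolist(),
            "kernel_variance": self.kernel_variance,
            "noise_jitter": self.noise_jitter,
            "x_mean": self.x_mean.tolist(), "x_sd": self.x_sd.tolist(),
            "X_train": self.X_train.tolist(), "y_mean": self.y_mean,
            "y_train": self.y_train.tolist(), "restarts": self.restarts,
            "log_likelihood": self.log_likelihood,
        }, indent=2)


def _neg_lml_and_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                      jitter: float) -> tuple[float, np.ndarray]:
    # theta = [log kernel_variance, log_lengthscale_1..d]
    log_var, log_ls = theta[0], theta[1:]
    var = np.exp(log_var)
    n = y.size
    G = _gram(X, log_ls)
    K = var * G + jitter * np.eye(n)
    cf = linalg.cho_factor(K, lower=True)
    alpha = linalg.cho_solve(cf, y)
    lml = (-0.5 * y @ alpha - np.sum(np.log(np.diag(cf[0])))
           - 0.5 * n * np.log(2.0 * np.pi))
    Kinv = linalg.cho_solve(cf, np.eye(n))
    W = np.outer(alpha, alpha) - Kinv          # d lml/dK = W/2
    grad = np.empty_like(theta)
    grad[0] = 0.5 * np.sum(W * (var * G))
    ls = np.exp(log_ls)
    for d in range(log_ls.size):
        sq_d = (X[:, None, d] - X[None, :, d]) ** 2 / ls[d] ** 2
        grad[d + 1] = 0.5 * np.sum(W * (var * G * sq_d))
    return -lml, -grad


def fit_gpr(X, y, restarts: int = 100, seed: int = 0,
            jitter: float = 1e-10) -> GPRModel:
    """Maximise the GP log marginal likelihood over log length scales and
    signal variance, keeping the best of ``restarts`` seeded random
    initialisations (the first start is at the origin of log space).

    Gradient-based optimisation (L-BFGS-B on the analytic gradient); inputs
    are z-scored and targets centered internally.  The search box is
    bounded — log variance in [-6, 6], log length scales in [-13, 13] — so
    the noise-free likelihood cannot drift to the flat infinite-variance
    ridge where the posterior solve loses precision.  The Cholesky jitter
    escalates tenfold up to 1e-4 before a numerical error is raised.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    X, y = _as_xy(X, y)
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    Z, x_mean, x_sd = _standardize(X)
    y_mean = float(y.mean())
    yc = y - y_mean
    d = Z.shape[1]
    rng = np.random.default_rng(seed)
    starts = [np.zeros(1 + d)] + [rng.normal(0.0, 1.0, size=1 + d)
                                  for _ in range(restarts - 1)]
    bounds = [(-6.0, 6.0)] + [(-13.0, 13.0)] * d
    best = None
    for theta0 in starts:
        jit = jitter
        while True:
            try:
                res = optimize.minimize(
                    _neg_lml_and_grad, theta0, args=(Z, yc, jit),
                    jac=True, method="L-BFGS-B", bounds=bounds)
                break
            except linalg.LinAlgError:
                jit *= 10.0
                if jit > 1e-4:
                    raise NumericalError(
                        "kernel matrix not positive definite even at jitter 1e-4; "
                        f"theta0={theta0}") from None
        if np.isfinite(res.fun) and (best is None or res.fun < best[0]):
            best = (res.fun, res.x, jit)
    if best is None:
        raise NumericalError("all optimizer restarts failed")
    _, theta, _ = best
    log_var, log_ls = float(theta[0]), theta[1:]
    var = float(np.exp(log_var))
    # jitter escalation serves optimisation robustness only; the posterior
    # uses the smallest jitter at which the final kernel factorises
    jit = jitter
    while True:
        K = var * _gram(Z, log_ls) + jit * np.eye(yc.size)
        try:
            cf = linalg.cho_factor(K, lower=True)
            break
        except linalg.LinAlgError:
            jit *= 10.0
            if jit > 1e-4:
                raise NumericalError(
                    "final kernel matrix not positive definite at jitter 1e-4"
                ) from None
    alpha = linalg.cho_solve(cf, yc)
    return GPRModel(
        log_lengthscales=log_ls, kernel_variance=var, noise_jitter=jit,
        x_mean=x_mean, x_sd=x_sd, X_train=Z, y_mean=y_mean, y_train=yc,
        alpha=alpha, restarts=restarts,
        log_likelihood=float(log_marginal_likelihood(Z, yc, log_ls, var, jit)),
    )
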