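"""Bayesian size-weight regression for harvested corals.

The central model is the two-parameter power law

    W = a · D^b

linking maximum colony diameter D (cm) to drained wet weight W (g), fitted
per species by posterior sampling under either a gaussian likelihood
(W_i ~ N(a·D_i^b, σ)) or a lognormal one (log W_i ~ N(log a + b·log D_i, σ)).
Linear (μ = a + b·D) and exponential (μ = a·e^{bD}) mean functions are
provided as the alternative families screened during model selection.

An exponent b = 3 corresponds to isometric growth (mass scaling with the
cube of a linear dimension); b < 3 indicates allometry, with weight
accumulating more slowly than volume as colonies broaden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .datatypes import SpecimenRecord
from .mcmc import PosteriorDraws, hdi, sample_posterior

__all__ = [
    "PowerLawParams", "PriorSpec", "FitSummary", "SizeWeightRegressor",
    "predict_weight", "fit_loglog_oracle", "fit_posterior", "summarise_fit",
]

FAMILIES = ("power", "linear", "exponential")
LIKELIHOODS = ("gaussian", "lognormal")

RHAT_CONVERGED = 1.01
RHAT_FAILED = 1.05


class InsufficientDataError(ValueError):
    """Too few observations to identify the model."""


class DegenerateDesignError(ValueError):
    """Fewer than two distinct diameters: the slope is unidentifiable."""


@dataclass(frozen=True)
class PowerLawParams:
    """Point values of the power-law constants.

    ``a`` is the scaling constant (g·cm⁻ᵇ, the weight of a 1 cm colony),
    ``b`` the dimensionless exponent, ``sigma`` the residual scale (g under
    the gaussian likelihood, log-g under the lognormal one).
    """

    a: float
    b: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.sigma > 0):
            raise ValueError(f"PowerLawParams must be positive, got {self}")


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative default priors, fully overridable.

    On the sampling scale: log a ~ N(log_a_mu, log_a_sd²);
    b ~ N(b_mu, b_sd²) truncated to (0, ∞) for the power family (centred on
    isometry, b = 3); σ ~ half-Normal(sigma_scale), with ``sigma_scale``
    defaulting to the observed response SD on the fitting scale.
    """

    log_a_mu: float = 0.0
    log_a_sd: float = 2.0
    b_mu: float = 3.0
    b_sd: float = 1.0
    sigma_scale: float | None = None


def predict_weight(params: PowerLawParams, diameter_cm: float | np.ndarray) -> float | np.ndarray:
    """Evaluate W = a·D^b; strictly increasing in D for b > 0."""
    d = np.asarray(diameter_cm, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be > 0")
    out = params.a * d**params.b
    return float(out) if np.isscalar(diameter_cm) or out.ndim == 0 else out


def _extract_xy(records: Sequence[SpecimenRecord]) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([r.max_diameter_cm for r in records], dtype=float)
    y = np.array([r.weight_g for r in records], dtype=float)
    return x, y


def _loglog_ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Raw least squares of log W on log D: (log a, b, residual sd)."""
    if np.unique(x).size < 2:
        raise DegenerateDesignError("need >= 2 distinct diameters")
    if np.any(y <= 0) or np.any(x <= 0):
        raise ValueError("weights and diameters must be > 0")
    lx, ly = np.log(x), np.log(y)
    b, loga = np.polyfit(lx, ly, 1)
    resid = ly - (loga + b * lx)
    dof = max(x.size - 2, 1)
    sigma = float(np.sqrt(resid @ resid / dof))
    return float(loga), float(b), max(sigma, 1e-12)


def fit_loglog_oracle(records: Sequence[SpecimenRecord] | None = None,
                      *, x: np.ndarray | None = None,
                      y: np.ndarray | None = None) -> PowerLawParams:
    """Closed-form log-log least squares: log W = log a + b·log D.

    Exact on noiseless power-law data; used as the independent point-estimate
    oracle for the Bayesian fitter.
    """
    if records is not None:
        x, y = _extract_xy(records)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    loga, b, sigma = _loglog_ols(x, y)
    return PowerLawParams(a=float(np.exp(loga)), b=b, sigma=sigma)


# ---------------------------------------------------------------------------
# mean functions and likelihoods (vectorised over a block of parameter rows)

def _mean_fn(family: str, theta_nat: np.ndarray, x: np.ndarray) -> np.ndarray:
    """μ(D) for a (C, 3) block of natural-scale parameters -> (C, n)."""
    a = theta_nat[:, 0:1]
    b = theta_nat[:, 1:2]
    lx = np.log(x)[None, :]
    with np.errstate(over="ignore", invalid="ignore"):
        if family == "power":
            return a * np.exp(b * lx)
        if family == "linear":
            return a + b * x[None, :]
        if family == "exponential":
            return a * np.exp(b * x[None, :])
    raise ValueError(f"unknown family {family!r}")


def _loglik_rows(family: str, likelihood: str, theta_nat: np.ndarray,
                 x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pointwise log likelihood, shape (C, n); -inf rows where unsupported."""
    mu = _mean_fn(family, theta_nat, x)
    sigma = theta_nat[:, 2:3]
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        if likelihood == "gaussian":
            ll = (-0.5 * np.log(2 * np.pi) - np.log(sigma)
                  - 0.5 * ((y[None, :] - mu) / sigma) ** 2)
        elif likelihood == "lognormal":
            # density of W itself (Jacobian -log y), so elpd is comparable
            # across likelihoods
            logmu = np.log(mu)
            ll = (-0.5 * np.log(2 * np.pi) - np.log(sigma)
                  - 0.5 * ((np.log(y)[None, :] - logmu) / sigma) ** 2
                  - np.log(y)[None, :])
        else:
            raise ValueError(f"unknown likelihood {likelihood!r}")
    return np.where(np.isfinite(ll), ll, -np.inf)


def _natural(family: str, theta: np.ndarray) -> np.ndarray:
    """Sampling scale -> natural scale.  Power/exponential sample log a."""
    out = theta.copy()
    if family in ("power", "exponential"):
        out[..., 0] = np.exp(theta[..., 0])
    out[..., 2] = np.exp(theta[..., 2])
    return out


def _default_priors(family: str, x: np.ndarray, y: np.ndarray,
                    likelihood: str, priors: PriorSpec) -> dict:
    """Resolve prior hyperparameters on the sampling scale."""
    resp = np.log(y) if (likelihood == "lognormal" and y.size) else y
    sd_y = float(np.std(resp)) if resp.size > 1 else 1.0
    sd_y = sd_y if sd_y > 0 else 1.0
    sigma_scale = priors.sigma_scale if priors.sigma_scale is not None else sd_y
    if family == "power":
        return {"m": np.array([priors.log_a_mu, priors.b_mu]),
                "s": np.array([priors.log_a_sd, priors.b_sd]),
                "b_positive": True, "sigma_scale": sigma_scale}
    sd_x = float(np.std(x)) if x.size > 1 else 1.0
    sd_x = sd_x if sd_x > 0 else 1.0
    if family == "linear":
        mean_y = float(np.mean(resp)) if resp.size else 0.0
        return {"m": np.array([mean_y, 0.0]),
                "s": np.array([5.0 * sd_y, 5.0 * sd_y / sd_x]),
                "b_positive": False, "sigma_scale": sigma_scale}
    if family == "exponential":
        return {"m": np.array([priors.log_a_mu, 0.0]),
                "s": np.array([priors.log_a_sd, 1.0 / sd_x]),
                "b_positive": False, "sigma_scale": sigma_scale}
    raise ValueError(f"unknown family {family!r}")


def _log_prior(family: str, theta: np.ndarray, hyper: dict) -> np.ndarray:
    m, s = hyper["m"], hyper["s"]
    lp = -0.5 * np.sum(((theta[:, :2] - m) / s) ** 2, axis=1)
    if hyper["b_positive"]:
        lp = np.where(theta[:, 1] > 0, lp, -np.inf)
    # half-normal on sigma, sampled as log sigma (+ Jacobian log sigma)
    log_sigma = theta[:, 2]
    sigma = np.exp(log_sigma)
    lp = lp - 0.5 * (sigma / hyper["sigma_scale"]) ** 2 + log_sigma
    return lp


def pointwise_loglik(draws: PosteriorDraws, x: np.ndarray, y: np.ndarray,
                     family: str = "power", likelihood: str = "gaussian") -> np.ndarray:
    """Pointwise log likelihood over all pooled draws, shape (S, n)."""
    theta = draws.flat()
    return _loglik_rows(family, likelihood, theta, np.asarray(x, float), np.asarray(y, float))


# ---------------------------------------------------------------------------

@dataclass
class FitSummary:
    """Posterior summaries in the reporting format used for size-weight fits:
    per-parameter mean ± SE (posterior SD), 95% HDI, convergence diagnostics,
    and Bayesian R²."""

    params: dict[str, dict[str, float]]
    bayes_r2: float
    n_obs: int
    converged: bool
    likelihood: str = "gaussian"
    family: str = "power"

    def to_dict(self) -> dict:
        return {
            "params": self.params, "bayes_r2": self.bayes_r2, "n_obs": self.n_obs,
            "converged": self.converged, "likelihood": self.likelihood,
            "family": self.family,
        }


def summarise_fit(draws: PosteriorDraws,
                  records: Sequence[SpecimenRecord] | None = None,
                  *, x: np.ndarray | None = None, y: np.ndarray | None = None,
                  family: str = "power", likelihood: str = "gaussian",
                  hdi_mass: float = 0.95) -> FitSummary:
    """Summarise posterior draws against the data they were fitted to.

    Bayesian R² follows the residual-variance decomposition
    R²_s = Var_i(μ_i^{(s)}) / (Var_i(μ_i^{(s)}) + σ_s²), averaged over draws;
    under the lognormal likelihood both terms are on the log scale.
    """
    if draws.n_draws == 0:
        raise ValueError("empty draws")
    if records is not None:
        x, y = _extract_xy(records)
    diag = draws.diagnostics()
    params: dict[str, dict[str, float]] = {}
    for name in draws.param_names:
        samp = draws.flat(name)
        lo, hi = hdi(samp, hdi_mass)
        params[name] = {
            "mean": float(np.mean(samp)), "se": float(np.std(samp, ddof=1)),
            "median": float(np.median(samp)), "hdi_low": lo, "hdi_high": hi,
            "rhat": diag[name]["rhat"], "ess": diag[name]["ess"],
        }
    converged = all(v["rhat"] < RHAT_CONVERGED for v in params.values())

    r2 = float("nan")
    if x is not None and len(np.asarray(x)) > 1:
        theta = draws.flat()
        mu = _mean_fn(family, theta, np.asarray(x, float))
        if likelihood == "lognormal":
            with np.errstate(invalid="ignore", divide="ignore"):
                mu = np.log(mu)
        var_fit = np.nanvar(mu, axis=1)
        sigma2 = theta[:, 2] ** 2
        r2 = float(np.mean(var_fit / (var_fit + sigma2)))

    return FitSummary(params=params, bayes_r2=r2, n_obs=0 if x is None else len(np.asarray(x)),
                      converged=converged, likelihood=likelihood, family=family)


class SizeWeightRegressor(RegressorMixin, BaseEstimator):
    """Bayesian size-weight model with a power, linear or exponential mean.

    Parameters
    ----------
    family : {"power", "linear", "exponential"}
        Mean function: a·D^b, a + b·D, or a·e^{bD}.
    likelihood : {"gaussian", "lognormal"}
        Observation model: W ~ N(μ, σ), or log W ~ N(log μ, σ).
    priors : PriorSpec, optional
        Prior hyperparameters (defaults are weakly informative; the power
        exponent prior is centred on isometry, b = 3).
    n_chains, n_iter : int
        Chains and total iterations per chain (first half is warm-up).
    random_state : int, optional
        Seed; fits are reproducible given the same seed and data.

    Attributes
    ----------
    draws_ : PosteriorDraws
        Natural-scale posterior draws of (a, b, sigma).
    params_ : PowerLawParams or tuple
        Posterior-mean point parameters (PowerLawParams for the power family).
    summary_ : FitSummary
        Posterior means, SEs, 95% HDIs, R̂/ESS and Bayesian R².
    converged_ : bool
        True when all split-R̂ < 1.01; an R̂ ≥ 1.05 additionally raises a
        ConvergenceWarning (flagged, never silent).

    Examples
    --------
    >>> reg = SizeWeightRegressor(likelihood="lognormal", random_state=0)
    >>> reg.fit(diameters_cm.reshape(-1, 1), weights_g)   # doctest: +SKIP
    >>> reg.predict([[10.0]])                             # doctest: +SKIP
    """

    PARAM_NAMES = ("a", "b", "sigma")

    def __init__(self, family: str = "power", likelihood: str = "gaussian",
                 priors: PriorSpec | None = None, n_chains: int = 4,
                 n_iter: int = 5000, n_warmup: int | None = None,
                 random_state: int | None = None):
        self.family = family
        self.likelihood = likelihood
        self.priors = priors
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.n_warmup = n_warmup
        self.random_state = random_state

    # -- internal -----------------------------------------------------------
    def _validate_inputs(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single diameter column")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        if X.shape != y.shape:
            raise ValueError("X and y lengths differ")
        if np.any(X <= 0):
            raise ValueError("diameters must be > 0")
        if np.any(y <= 0):
            raise ValueError("weights must be > 0")
        return X, y

    def _init_point(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Family-specific least-squares starting point on the sampling scale."""
        if self.family == "power":
            loga, b, sigma_ln = _loglog_ols(x, y)
            b = max(b, 1e-3)  # the exponent prior is truncated to (0, inf)
            if self.likelihood == "gaussian":
                resid = y - np.exp(loga) * x**b
                sigma = max(float(np.std(resid)), 1e-6)
            else:
                sigma = sigma_ln
            return np.array([loga, b, np.log(sigma)])
        if self.family == "linear":
            b, a = np.polyfit(x, y, 1)
            mu = a + b * x
            if self.likelihood == "lognormal" and mu.min() <= 0:
                # shift the intercept so the mean stays positive everywhere
                a += 1e-3 * float(np.mean(y)) - mu.min()
                mu = a + b * x
            resid = (y - mu if self.likelihood == "gaussian"
                     else np.log(y) - np.log(mu))
            return np.array([a, b, np.log(max(float(np.std(resid)), 1e-6))])
        # exponential: log-linear in D
        b, loga = np.polyfit(x, np.log(y), 1)
        mu = np.exp(loga + b * x)
        resid = y - mu if self.likelihood == "gaussian" else np.log(y) - np.log(mu)
        return np.array([loga, b, np.log(max(float(np.std(resid)), 1e-6))])

    # -- sklearn API --------------------------------------------------------
    def fit(self, X, y):
        """Sample the posterior of (a, b, σ) for diameters X (cm) and weights y (g)."""
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.likelihood not in LIKELIHOODS:
            raise ValueError(f"likelihood must be one of {LIKELIHOODS}")
        x, y = self._validate_inputs(X, y)
        if 0 < x.size < 3:
            raise InsufficientDataError(f"need >= 3 observations, got {x.size}")
        priors = self.priors or PriorSpec()
        hyper = _default_priors(self.family, x, y, self.likelihood, priors)
        if x.size == 0 and priors.sigma_scale is None:
            raise ValueError("prior-predictive mode requires an explicit sigma_scale")

        family, likelihood = self.family, self.likelihood

        def log_post(theta: np.ndarray) -> np.ndarray:
            lp = _log_prior(family, theta, hyper)
            if x.size:
                ok = np.isfinite(lp)
                if np.any(ok):
                    nat = _natural(family, theta[ok])
                    lp_ok = _loglik_rows(family, likelihood, nat, x, y).sum(axis=1)
                    lp[ok] = lp[ok] + lp_ok
            return lp

        if x.size:
            x0 = self._init_point(x, y)
        else:
            x0 = np.array([hyper["m"][0], max(hyper["m"][1], 0.5),
                           np.log(hyper["sigma_scale"] * 0.8)])
        init_scales = np.array([0.05, 0.05, 0.05]) if x.size else np.array([1.0, 0.5, 0.5])

        draws = sample_posterior(
            log_post, x0, param_names=self.PARAM_NAMES,
            n_chains=self.n_chains, n_iter=self.n_iter, n_warmup=self.n_warmup,
            seed=self.random_state, init_scales=init_scales,
            transform=lambda t: _natural(family, t),
        )
        self.draws_ = draws
        self.X_, self.y_ = x, y
        self.summary_ = summarise_fit(draws, x=x, y=y, family=family,
                                      likelihood=likelihood)
        self.converged_ = self.summary_.converged
        worst = max(v["rhat"] for v in self.summary_.params.values())
        if worst >= RHAT_FAILED:
            warnings.warn(
                f"size-weight fit did not converge (max rhat {worst:.3f})",
                category=UserWarning, stacklevel=2)
        means = {n: self.summary_.params[n]["mean"] for n in self.PARAM_NAMES}
        if family == "power":
            self.params_ = PowerLawParams(means["a"], means["b"], means["sigma"])
        else:
            self.params_ = (means["a"], means["b"], means["sigma"])
        return self

    def predict(self, X):
        """Plug-in prediction at the posterior-mean parameters."""
        if not hasattr(self, "draws_"):
            raise RuntimeError("regressor is not fitted")
        X = np.asarray(X, dtype=float)
        x = X[:, 0] if X.ndim == 2 else X
        if isinstance(self.params_, PowerLawParams):
            theta = np.array([[self.params_.a, self.params_.b, self.params_.sigma]])
        else:
            theta = np.array([list(self.params_)])
        return _mean_fn(self.family, theta, x)[0]

    def loglik_matrix(self) -> np.ndarray:
        """Pointwise log likelihood of the training data, shape (S, n)."""
        return pointwise_loglik(self.draws_, self.X_, self.y_,
                                family=self.family, likelihood=self.likelihood)


def fit_posterior(records: Sequence[SpecimenRecord], likelihood: str = "gaussian",
                  priors: PriorSpec | None = None, *, family: str = "power",
                  n_chains: int = 4, n_iter: int = 5000,
                  seed: int | None = None) -> PosteriorDraws:
    """Functional wrapper over :class:`SizeWeightRegressor`.

    An empty record list with an explicit ``priors.sigma_scale`` runs in
    prior-predictive mode (the "posterior" is the prior).
    """
    x, y = _extract_xy(records) if records else (np.array([]), np.array([]))
    reg = SizeWeightRegressor(family=family, likelihood=likelihood, priors=priors,
                              n_chains=n_chains, n_iter=n_iter, random_state=seed)
    reg.fit(x, y)
    return reg.draws_
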