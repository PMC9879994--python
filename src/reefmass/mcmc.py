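"""Posterior sampling utilities.

The sampler is an adaptive random-walk Metropolis on an unconstrained
parameterisation, run as several independent chains vectorised through
numpy.  The proposal covariance is estimated from pooled warm-up history
and each chain's step scale is tuned toward an acceptance rate of ~0.3
during warm-up only, so the kept draws form a valid Markov chain.
Convergence is monitored with split-R̂ and effective sample size (arviz).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = ["PosteriorDraws", "sample_posterior", "hdi", "eti"]

_TARGET_ACCEPT = 0.3


@dataclass
class PosteriorDraws:
    """Post-warm-up draws from ``n_chains`` independent chains.

    ``array`` has shape (chains, iterations, parameters), on the natural
    (constrained) scale of the model parameters.
    """

    param_names: tuple[str, ...]
    array: np.ndarray
    seed: int | None = None
    sampler_settings: dict = field(default_factory=dict)
    accept_rate: float = float("nan")

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, dtype=float)
        if self.array.ndim != 3:
            raise ValueError("draws array must be (chains, iterations, parameters)")
        if self.array.shape[0] < 2:
            raise ValueError("at least 2 chains are required")
        if self.array.shape[2] != len(self.param_names):
            raise ValueError("parameter-name count does not match draw array")

    @property
    def n_chains(self) -> int:
        return self.array.shape[0]

    @property
    def n_draws(self) -> int:
        return self.array.shape[0] * self.array.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (chains, iterations)."""
        return self.array[:, :, self.param_names.index(name)]

    def flat(self, name: str | None = None) -> np.ndarray:
        """All chains pooled: (draws, parameters), or (draws,) for one name."""
        if name is not None:
            return self.get(name).reshape(-1)
        return self.array.reshape(-1, self.array.shape[2])

    def to_arviz(self):
        import arviz as az

        return az.from_dict({n: self.get(n) for n in self.param_names})

    def diagnostics(self) -> dict[str, dict[str, float]]:
        """Split-R̂ and bulk effective sample size per parameter."""
        import arviz as az

        idata = self.to_arviz()
        rhat = az.rhat(idata)
        ess = az.ess(idata)
        return {
            n: {"rhat": float(rhat[n].values), "ess": float(ess[n].values)}
            for n in self.param_names
        }


def sample_posterior(
    log_post: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    *,
    param_names: Sequence[str],
    n_chains: int = 4,
    n_iter: int = 5000,
    n_warmup: int | None = None,
    seed: int | None = None,
    init_jitter: float = 0.1,
    init_scales: np.ndarray | None = None,
    transform: Callable[[np.ndarray], np.ndarray] | None = None,
) -> PosteriorDraws:
    """Draw from a posterior with adaptive random-walk Metropolis.

    Parameters
    ----------
    log_post : callable
        Vectorised log posterior density: maps a (chains, p) parameter block
        to (chains,) log densities (``-inf`` outside the support).
    x0 : ndarray, shape (p,)
        Starting point on the sampling (unconstrained) scale; each chain is
        initialised at ``x0`` plus Gaussian jitter of scale ``init_jitter``.
    n_iter : int
        Total iterations per chain; the first ``n_warmup`` (default half)
        are used for adaptation and discarded.
    transform : callable, optional
        Maps sampled coordinates to the natural parameter scale for storage
        (e.g. exponentiating log-parameters).  Identity when omitted.

    Returns
    -------
    PosteriorDraws
        ``(n_chains, n_iter - n_warmup, p)`` draws on the natural scale.
    """
    rng = np.random.default_rng(seed)
    x0 = np.asarray(x0, dtype=float)
    p = x0.size
    if n_warmup is None:
        n_warmup = n_iter // 2
    if init_scales is None:
        init_scales = np.full(p, 0.1)

    state = x0[None, :] + init_jitter * rng.standard_normal((n_chains, p))
    lp = log_post(state)
    if not np.all(np.isfinite(lp)):
        # pull non-finite chains back to the (assumed finite) centre
        bad = ~np.isfinite(lp)
        state[bad] = x0
        lp = log_post(state)
        if not np.all(np.isfinite(lp)):
            raise ValueError("log posterior not finite at the initial point")

    chol = np.diag(init_scales)
    log_scale = np.zeros(n_chains)
    history: list[np.ndarray] = []
    kept = np.empty((n_chains, n_iter - n_warmup, p))
    n_accept = 0
    adapt_every = 200

    for t in range(n_iter):
        z = rng.standard_normal((n_chains, p))
        prop = state + np.exp(log_scale)[:, None] * (z @ chol.T)
        lp_prop = log_post(prop)
        log_u = np.log(rng.random(n_chains))
        accept = log_u < (lp_prop - lp)
        state = np.where(accept[:, None], prop, state)
        lp = np.where(accept, lp_prop, lp)

        if t < n_warmup:
            # Robbins-Monro step-size tuning plus pooled covariance updates
            log_scale += (accept.astype(float) - _TARGET_ACCEPT) / np.sqrt(1.0 + t / 10.0)
            history.append(state.copy())
            if (t + 1) % adapt_every == 0 and t > adapt_every:
                pool = np.concatenate(history[len(history) // 2:], axis=0)
                cov = np.cov(pool, rowvar=False).reshape(p, p)
                cov += 1e-10 * np.eye(p)
                try:
                    chol = np.linalg.cholesky((2.38**2 / p) * cov)
                except np.linalg.LinAlgError:
                    pass
        else:
            kept[:, t - n_warmup, :] = state
            n_accept += int(accept.sum())

    natural = transform(kept) if transform is not None else kept
    return PosteriorDraws(
        param_names=tuple(param_names),
        array=natural,
        seed=seed,
        sampler_settings={"n_chains": n_chains, "n_iter": n_iter, "n_warmup": n_warmup},
        accept_rate=n_accept / max(1, n_chains * (n_iter - n_warmup)),
    )


def hdi(samples: Sequence[float] | np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Highest-density interval of a posterior sample.

    The shortest contiguous interval containing ``ceil(mass * n)`` of the
    sorted samples; width ties resolve to the smallest lower bound.

    Requires at least 10 samples and ``0 < mass < 1``.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 10:
        raise ValueError(f"hdi requires at least 10 samples, got {n}")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie strictly between 0 and 1")
    k = int(np.ceil(mass * n))
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: smallest lower bound
    return float(x[i]), float(x[i + k - 1])


def eti(samples: Sequence[float] | np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval (quantile-based alternative to hdi)."""
    x = np.asarray(samples, dtype=float).ravel()
    alpha = (1.0 - mass) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def mc_se(draws: "PosteriorDraws", name: str) -> float:
    """Monte-Carlo standard error of the posterior mean of one parameter."""
    import arviz as az

    x = draws.get(name)
    ess = float(az.ess(az.from_dict({name: x}))[name].values)
    return float(np.std(x) / np.sqrt(max(ess, 1.0)))


def summarise_param(
    samples: np.ndarray, mass: float = 0.95
) -> Mapping[str, float]:
    lo, hi = hdi(samples, mass)
    return {
        "mean": float(np.mean(samples)),
        "sd": float(np.std(samples, ddof=1)),
        "median": float(np.median(samples)),
        "hdi_low": lo,
        "hdi_high": hi,
    }
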