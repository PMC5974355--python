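"""Posterior sampling and uncertainty-propagation machinery.

Every model in this package is either (a) a small regression fitted by
Markov-chain Monte Carlo, or (b) a deterministic transformation of
independent prior draws (plain Monte Carlo — equivalent to MCMC for such
maps, and faster).  This module provides the shared pieces: prior
specifications, a seeded multi-chain random-walk Metropolis sampler,
rank-normalised split R-hat convergence diagnostics and posterior
summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

__all__ = [
    "PriorSpec",
    "ChainConfig",
    "PosteriorDraws",
    "gamma_prior",
    "sample_prior",
    "run_chains",
    "rhat",
    "summarize",
]


# ---------------------------------------------------------------------------
# Prior specifications
# ---------------------------------------------------------------------------

_FAMILIES = ("normal", "gamma", "uniform", "fixed")


@dataclass(frozen=True)
class PriorSpec:
    """A univariate prior: normal, gamma, uniform or a point mass.

    Parameters
    ----------
    family:
        One of ``"normal"`` (params ``mean, sd``), ``"gamma"``
        (``shape, rate``), ``"uniform"`` (``lower, upper``) or ``"fixed"``
        (``value`` — a degenerate point mass, used for inputs held constant).
    params:
        Family parameters, in the order above.
    bounds:
        Optional truncation interval ``(lo, hi)``; sampling is from the
        distribution restricted (and renormalised) to this interval.
    """

    family: str
    params: tuple[float, ...]
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown prior family {self.family!r}; expected one of {_FAMILIES}"
            )
        p = self.params
        if self.family == "normal":
            if len(p) != 2 or p[1] <= 0:
                raise ValueError("normal prior needs (mean, sd) with sd > 0")
        elif self.family == "gamma":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ValueError("gamma prior needs (shape, rate), both > 0")
        elif self.family == "uniform":
            if len(p) != 2 or not p[0] < p[1]:
                raise ValueError("uniform prior needs (lower, upper) with lower < upper")
        else:  # fixed
            if len(p) != 1:
                raise ValueError("fixed prior needs a single (value,)")
        if self.bounds is not None and not self.bounds[0] < self.bounds[1]:
            raise ValueError("truncation bounds must satisfy lo < hi")

    # -- analytic helpers ---------------------------------------------------

    def _frozen(self):
        if self.family == "normal":
            return stats.norm(loc=self.params[0], scale=self.params[1])
        if self.family == "gamma":
            return stats.gamma(a=self.params[0], scale=1.0 / self.params[1])
        if self.family == "uniform":
            lo, hi = self.params
            return stats.uniform(loc=lo, scale=hi - lo)
        raise AssertionError("fixed priors have no scipy counterpart")

    def mean(self) -> float:
        """Analytic mean (of the truncated distribution when bounded)."""
        if self.family == "fixed":
            return self.params[0]
        dist = self._frozen()
        if self.bounds is None:
            return float(dist.mean())
        lo, hi = self.bounds
        # numerical mean of the truncated density
        grid = np.linspace(dist.ppf(1e-9), dist.ppf(1 - 1e-9), 20001)
        grid = grid[(grid >= lo) & (grid <= hi)]
        w = dist.pdf(grid)
        return float(np.sum(grid * w) / np.sum(w))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` values (inverse-CDF through the truncated CDF)."""
        if self.family == "fixed":
            return np.full(n, self.params[0])
        dist = self._frozen()
        u = rng.random(n)
        if self.bounds is None:
            return np.asarray(dist.ppf(u))
        lo, hi = self.bounds
        a, b = dist.cdf(lo), dist.cdf(hi)
        if b <= a:
            raise ValueError("truncation interval has zero prior mass")
        return np.asarray(dist.ppf(a + u * (b - a)))


def gamma_prior(mean: float, sd: float | None = None, rule: str = "moment") -> PriorSpec:
    """Build a gamma prior from a mean (and SD) under one of two rules.

    ``rule="moment"`` matches both moments: shape = mean²/sd², rate = mean/sd².
    ``rule="literal"`` uses the observed mean as the shape with rate = 1
    (which forces variance = mean); kept as a configurable alternative
    because some field workflows specify gamma priors exactly this way.
    """
    if mean <= 0:
        raise ValueError("gamma prior mean must be positive")
    if rule == "literal":
        return PriorSpec("gamma", (mean, 1.0))
    if rule == "moment":
        if sd is None or sd <= 0:
            raise ValueError("moment-matched gamma prior needs sd > 0")
        return PriorSpec("gamma", (mean**2 / sd**2, mean / sd**2))
    raise ValueError(f"unknown gamma prior rule {rule!r}")


def sample_prior(spec: PriorSpec, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` values from a prior specification, seeded."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n < 1:
        raise ValueError("n must be >= 1")
    return spec.sample(n, rng)


# ---------------------------------------------------------------------------
# Chain configuration and posterior container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run configuration.

    Defaults mirror the full production setting (3 chains of 150,000
    samples, 50,000 burn-in, no thinning); :meth:`reduced` gives the
    cheaper setting used throughout the test-suite.
    """

    n_chains: int = 3
    n_samples: int = 150_000
    n_burnin: int = 50_000
    thinning: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 for convergence checking")
        if not self.n_samples > self.n_burnin >= 0:
            raise ValueError("need n_samples > n_burnin >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @classmethod
    def reduced(cls, seed: int = 0) -> "ChainConfig":
        return cls(n_chains=3, n_samples=20_000, n_burnin=5_000, seed=seed)


@dataclass
class PosteriorDraws:
    """Post-burn-in draws per parameter, with split R-hat attached.

    ``draws`` maps parameter name to a (chains, draws) array.
    """

    draws: dict[str, np.ndarray]
    rhats: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.draws.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite draws for parameter {name!r}")
        if not self.rhats:
            self.rhats = {
                name: rhat(arr) if arr.ndim == 2 and arr.shape[0] >= 2 else float("nan")
                for name, arr in self.draws.items()
            }

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated into one flat vector."""
        return np.asarray(self.draws[name]).reshape(-1)

    @property
    def parameters(self) -> list[str]:
        return list(self.draws)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.draws:
            s = summarize(self.pooled(name))
            s["parameter"] = name
            s["rhat"] = self.rhats.get(name, float("nan"))
            rows.append(s)
        return pd.DataFrame(rows)[["parameter", "mean", "sd", "lo95", "hi95", "rhat"]]

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------


def _split_rhat_raw(x: np.ndarray) -> float:
    """Gelman–Rubin potential scale reduction on split chains.

    Each chain is split in half; with m split chains of length n,
    W = mean within-chain variance, B = n · var(chain means),
    var⁺ = (n−1)/n · W + B/n and R̂ = sqrt(var⁺ / W).
    """
    m, n = x.shape
    half = n // 2
    splits = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    chain_means = splits.mean(axis=1)
    chain_vars = splits.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = half * chain_means.var(ddof=1)
    if w == 0.0:
        # degenerate: every split chain is constant
        return 1.0 if b == 0.0 else float("inf")
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def rhat(draws: np.ndarray, rank_normalize: bool = True) -> float:
    """Split-R̂ convergence diagnostic for a (chains, draws) array.

    By default the draws are rank-normalised first (ranks mapped through
    the standard-normal quantile function with the (r − 3/8)/(N + 1/4)
    offset), i.e. the bulk variant of the rank-normalised split-R̂; the
    plain split statistic is available with ``rank_normalize=False``.
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("rhat needs a (chains, draws) array with >= 2 chains")
    if x.shape[1] < 10:
        raise ValueError("rhat needs >= 10 draws per chain")
    if np.ptp(x) == 0.0:
        return 1.0  # all chains frozen at one value: nothing to diagnose
    if rank_normalize:
        r = stats.rankdata(x.reshape(-1)).reshape(x.shape)
        z = ndtri((r - 3.0 / 8.0) / (x.size + 1.0 / 4.0))
        return _split_rhat_raw(z)
    return _split_rhat_raw(x)


def summarize(draws: np.ndarray) -> dict[str, float]:
    """Mean, SD and central 95% credible interval of pooled draws."""
    x = np.asarray(draws, dtype=float).reshape(-1)
    if x.size == 0:
        raise ValueError("cannot summarise empty draws")
    lo, hi = np.percentile(x, [2.5, 97.5])
    return {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        "lo95": float(lo),
        "hi95": float(hi),
    }


# ---------------------------------------------------------------------------
# Random-walk Metropolis, vectorised over chains
# ---------------------------------------------------------------------------


@dataclass
class MetropolisModel:
    """A target for :func:`run_chains`.

    ``log_posterior`` maps a (chains, n_params) array to a (chains,) array
    of log densities (−inf outside the support); ``initializer`` maps
    (rng, n_chains) to overdispersed starting points; ``names`` labels the
    raw parameter axes; ``transforms`` optionally adds derived parameters
    (name → function of the raw (chains, draws, p) array).
    """

    log_posterior: Callable[[np.ndarray], np.ndarray]
    initializer: Callable[[np.ndarray, int], np.ndarray]
    names: list[str]
    transforms: Mapping[str, Callable[[np.ndarray], np.ndarray]] | None = None


def run_chains(model: MetropolisModel, config: ChainConfig) -> PosteriorDraws:
    """Sample the model with adaptive random-walk Metropolis.

    Proposals are independent Gaussians per parameter; the per-parameter
    scales adapt toward a 0.234 acceptance rate during burn-in and are
    frozen afterwards (so the post-burn-in kernel is valid Metropolis).
    All chains advance in lock-step as rows of one array, which keeps the
    whole run a few seconds even at the full production configuration.
    """
    rng = np.random.default_rng(config.seed)
    p = len(model.names)
    theta = np.atleast_2d(np.asarray(model.initializer(rng, config.n_chains), float))
    if theta.shape != (config.n_chains, p):
        raise ValueError(
            f"initializer returned shape {theta.shape}, expected {(config.n_chains, p)}"
        )
    logp = np.asarray(model.log_posterior(theta), dtype=float)
    if not np.all(np.isfinite(logp)):
        bad = theta[~np.isfinite(logp)]
        raise ValueError(f"log-posterior not finite at initial points: {bad!r}")

    scales = np.full((config.n_chains, p), 0.1)
    kept = np.empty((config.n_chains, config.n_samples - config.n_burnin, p))
    target_accept = 0.234

    for step in range(config.n_samples):
        # update one parameter block at a time (Metropolis-within-Gibbs)
        for j in range(p):
            prop = theta.copy()
            prop[:, j] += scales[:, j] * rng.standard_normal(config.n_chains)
            logp_prop = np.asarray(model.log_posterior(prop), dtype=float)
            with np.errstate(invalid="ignore"):
                accept = np.log(rng.random(config.n_chains)) < (logp_prop - logp)
            accept &= np.isfinite(logp_prop)
            theta[accept] = prop[accept]
            logp[accept] = logp_prop[accept]
            if step < config.n_burnin:
                # Robbins–Monro adaptation, frozen after burn-in
                gain = 2.0 / (1.0 + 0.02 * step) ** 0.6
                scales[:, j] *= np.exp(gain * 0.1 * (accept.astype(float) - target_accept))
                np.clip(scales[:, j], 1e-8, 1e4, out=scales[:, j])
        if step >= config.n_burnin:
            kept[:, step - config.n_burnin, :] = theta

    kept = kept[:, :: config.thinning, :]
    draws: dict[str, np.ndarray] = {
        name: kept[:, :, j] for j, name in enumerate(model.names)
    }
    if model.transforms:
        for name, fn in model.transforms.items():
            draws[name] = np.asarray(fn(kept))
    return PosteriorDraws(draws=draws)


def propagate(draws: np.ndarray, g: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
    """Push draws through a deterministic map (no re-sampling).

    Trivial by construction, but kept as an explicit named operation so the
    propagation contract — summarising g(draws) is *the* way uncertainty
    moves through the budget equations — has a single home.
    """
    return np.asarray(g(np.asarray(draws)))
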