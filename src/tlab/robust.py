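"""Robust Bayesian parameter estimation with a t-distribution likelihood.

Bayesian analogues of one-sample and independent-samples t-tests: the data
(participant-level change scores or mean endorsements) are described by a
t-distribution with location mu, scale sigma, and normality nu, so that a few
heavy-tailed observations inflate nu's posterior rather than distorting mu.
The one-group model estimates (mu, sigma, nu) against a comparison value;
the two-group model estimates (mu1, mu2, sigma1, sigma2) with a single
shared normality parameter.

Priors are the conventional vague defaults for this model family:

* mu   ~ Normal(mean(D), 100 * sd(D))            (essentially flat)
* sigma ~ Uniform(sd(D) / 1000, 1000 * sd(D))
* nu - 1 ~ Exponential(mean 29), putting credibility on both nearly normal
  (nu > 30) and heavy-tailed (nu < 30) regimes.

Sampling is Metropolis-within-Gibbs with per-parameter Gaussian random walks
on transformed scales (log sigma, log(nu - 1)), adaptive proposal scales
during burn-in (frozen afterwards).  The sampler is vectorized over an
optional batch axis so that Monte-Carlo studies (many datasets, one chain
each) run as a single set of array operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import arviz as az
import numpy as np
from scipy.special import gammaln
from scipy.stats import gaussian_kde

__all__ = [
    "ObservationSet",
    "RobustModelSpec",
    "SamplerConfig",
    "PosteriorSummary",
    "SamplerDivergenceError",
    "fit",
    "fit_batch",
    "effect_size_draws",
    "hdi",
    "posterior_mode",
]


class SamplerDivergenceError(RuntimeError):
    """The chain mixed too poorly to summarize (effective sample size below floor)."""


@dataclass(frozen=True)
class ObservationSet:
    """Real-valued scores, optionally split into two groups.

    For two-group data pass ``groups`` (any two labels); group order follows
    first appearance, defining which group is mu1.
    """

    values: np.ndarray
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if not np.all(np.isfinite(values)):
            raise ValueError("observations must be finite")
        if self.groups is not None:
            groups = np.asarray(self.groups)
            if groups.shape != values.shape:
                raise ValueError("groups must align with values")
            object.__setattr__(self, "groups", groups)
            labels = self.group_labels()
            if len(labels) != 2:
                raise ValueError(f"two-group data needs exactly 2 labels, got {labels}")
            split = self.split()
        else:
            split = [values]
        for arr in split:
            if arr.size < 2:
                raise ValueError("need at least two observations per group")
            if arr.std(ddof=1) <= 0:
                raise ValueError("sample standard deviation must be positive")

    def group_labels(self) -> list:
        assert self.groups is not None
        return list(dict.fromkeys(self.groups.tolist()))

    def split(self) -> list[np.ndarray]:
        if self.groups is None:
            return [self.values]
        return [self.values[self.groups == g] for g in self.group_labels()]


@dataclass(frozen=True)
class RobustModelSpec:
    """Model kind, comparison value and prior hyperparameters.

    nu_rate is the rate of the exponential prior on nu - 1; the default
    1/29 gives the prior mean 30 for nu.  nu_floor > 1 truncates the
    normality parameter from below (useful to pin the likelihood to the
    near-normal regime); effect_size_convention records the two-group
    denominator, which is a package convention rather than a universal
    standard.
    """

    kind: str = "one_group"  # "one_group" | "two_group"
    comparison_value: float = 0.0
    mu_prior_sd_factor: float = 100.0
    sigma_prior_range: tuple[float, float] = (1e-3, 1e3)  # x sample sd
    nu_rate: float = 1.0 / 29.0
    nu_floor: float = 1.0
    effect_size_convention: str = "pooled_rms_sd"

    def __post_init__(self) -> None:
        if self.kind not in ("one_group", "two_group"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        lo, hi = self.sigma_prior_range
        if not (0 < lo < hi):
            raise ValueError("sigma prior bounds must be positive and ordered")
        if self.nu_rate <= 0:
            raise ValueError("nu_rate must be positive")
        if self.nu_floor < 1.0:
            raise ValueError("nu_floor must be at least 1")


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC chain settings: ``steps`` recorded draws after ``burn_in``."""

    steps: int = 100_000
    burn_in: int = 10_000
    thinning: int = 1
    seed: int = 0
    ess_warn: float = 1_000.0
    ess_floor: float = 50.0

    def __post_init__(self) -> None:
        if self.steps < 1_000:
            raise ValueError("steps must be at least 1,000")
        if self.burn_in < 0 or self.thinning < 1:
            raise ValueError("invalid burn_in or thinning")


REDUCED_SAMPLER = SamplerConfig(steps=10_000, burn_in=2_000)


@dataclass
class PosteriorSummary:
    """Posterior draws plus derived quantities and point/interval summaries."""

    draws: dict[str, np.ndarray]
    ess: dict[str, float]
    spec: RobustModelSpec
    n_obs: tuple[int, ...]

    def mean(self, param: str) -> float:
        return float(np.mean(self.draws[param]))

    def mode(self, param: str) -> float:
        return posterior_mode(self.draws[param])

    def hdi(self, param: str, mass: float = 0.95) -> tuple[float, float]:
        return hdi(self.draws[param], mass)

    def summary(self) -> dict[str, dict[str, float]]:
        """JSON-ready summary: per parameter {mean, mode, hdi_low, hdi_high, ess}."""
        out: dict[str, dict[str, float]] = {}
        for param, d in self.draws.items():
            lo, hi = hdi(d, 0.95)
            out[param] = {
                "mean": float(np.mean(d)),
                "mode": posterior_mode(d),
                "hdi_low": lo,
                "hdi_high": hi,
                "ess": self.ess.get(param, float("nan")),
            }
        return out


# ---------------------------------------------------------------------------
# Log-posterior (vectorized over a leading batch axis)
# ---------------------------------------------------------------------------

def _t_loglik(data: np.ndarray, mu: np.ndarray, sigma: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Summed t log-density per batch row; data (B, n), parameters (B,)."""
    n = data.shape[1]
    z = (data - mu[:, None]) / sigma[:, None]
    const = gammaln((nu + 1.0) / 2.0) - gammaln(nu / 2.0) - 0.5 * np.log(nu * np.pi)
    return n * const - n * np.log(sigma) - (nu + 1.0) / 2.0 * np.sum(
        np.log1p(z * z / nu[:, None]), axis=1
    )


class _Posterior:
    """Unnormalized log posterior over transformed parameters.

    One-group theta columns: (mu, log sigma, log(nu - nu_floor)).
    Two-group theta columns: (mu1, mu2, log sigma1, log sigma2, log(nu - nu_floor)).
    The uniform sigma prior and exponential nu prior act on the natural
    scale; Jacobians for the log transforms are included.
    """

    def __init__(self, groups: Sequence[np.ndarray], spec: RobustModelSpec):
        self.groups = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
        self.spec = spec
        pooled = np.concatenate([g for g in self.groups], axis=1)
        self.mu0 = pooled.mean(axis=1)
        sd = pooled.std(axis=1, ddof=1)
        if np.any(sd <= 0):
            raise ValueError("sample standard deviation must be positive")
        self.mu_sd = spec.mu_prior_sd_factor * sd
        self.sig_lo = spec.sigma_prior_range[0] * sd
        self.sig_hi = spec.sigma_prior_range[1] * sd
        self.n_groups = len(self.groups)
        self.n_params = 2 * self.n_groups + 1

    def initial_theta(self) -> np.ndarray:
        cols = []
        for g in self.groups:
            cols.append(g.mean(axis=1))
        for g in self.groups:
            cols.append(np.log(g.std(axis=1, ddof=1)))
        batch = self.groups[0].shape[0]
        cols.append(np.full(batch, np.log(10.0)))
        return np.column_stack(cols)

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        k = self.n_groups
        mus = theta[:, :k]
        log_sigmas = theta[:, k : 2 * k]
        sigmas = np.exp(log_sigmas)
        nu = self.spec.nu_floor + np.exp(theta[:, 2 * k])
        lp = np.zeros(theta.shape[0])
        for j, g in enumerate(self.groups):
            lp += _t_loglik(g, mus[:, j], sigmas[:, j], nu)
            lp += -0.5 * ((mus[:, j] - self.mu0) / self.mu_sd) ** 2
            lp += log_sigmas[:, j]  # Jacobian; uniform sigma prior is flat
        lp += theta[:, 2 * k] - self.spec.nu_rate * (nu - 1.0)  # Jacobian + exp prior
        out_of_bounds = np.any(
            (sigmas < self.sig_lo[:, None]) | (sigmas > self.sig_hi[:, None]), axis=1
        )
        return np.where(out_of_bounds | ~np.isfinite(lp), -np.inf, lp)


def _metropolis_within_gibbs(
    posterior: _Posterior, sampler: SamplerConfig, rng: np.random.Generator
) -> np.ndarray:
    """Adaptive component-wise random-walk sampler; returns (batch, kept, P)."""
    theta = posterior.initial_theta()
    batch, n_params = theta.shape
    lp = posterior(theta)
    step = np.full((batch, n_params), 0.5)
    accepted = np.zeros((batch, n_params))
    adapt_window = 50
    total = sampler.burn_in + sampler.steps
    kept = np.empty((batch, (sampler.steps + sampler.thinning - 1) // sampler.thinning, n_params))
    k_idx = 0
    for it in range(total):
        for p in range(n_params):
            prop = theta.copy()
            prop[:, p] += step[:, p] * rng.standard_normal(batch)
            lp_prop = posterior(prop)
            accept = np.log(rng.random(batch)) < lp_prop - lp
            theta[accept] = prop[accept]
            lp = np.where(accept, lp_prop, lp)
            accepted[:, p] += accept
        if it < sampler.burn_in and (it + 1) % adapt_window == 0:
            rate = accepted / adapt_window
            step *= np.exp(rate - 0.44)  # target univariate RW acceptance
            accepted[:] = 0.0
        if it >= sampler.burn_in:
            offset = it - sampler.burn_in
            if offset % sampler.thinning == 0:
                kept[:, k_idx, :] = theta
                k_idx += 1
    return kept[:, :k_idx, :]


def _summarize_chain(
    chain: np.ndarray,
    spec: RobustModelSpec,
    sampler: SamplerConfig,
    labels: Sequence[str],
    n_obs: tuple[int, ...],
) -> PosteriorSummary:
    k = (chain.shape[1] - 1) // 2
    draws: dict[str, np.ndarray] = {}
    for j in range(k):
        draws[labels[j]] = chain[:, j]
    for j in range(k):
        draws[labels[k + j]] = np.exp(chain[:, k + j])
    nu = spec.nu_floor + np.exp(chain[:, 2 * k])
    draws["nu"] = nu
    draws["log10_nu"] = np.log10(nu)
    if spec.kind == "one_group":
        draws["effect_size"] = (draws["mu"] - spec.comparison_value) / draws["sigma"]
    else:
        draws["mu_diff"] = draws["mu1"] - draws["mu2"]
        draws["sigma_diff"] = draws["sigma1"] - draws["sigma2"]
        draws["effect_size"] = draws["mu_diff"] / np.sqrt(
            (draws["sigma1"] ** 2 + draws["sigma2"] ** 2) / 2.0
        )
    mu_key = "mu" if spec.kind == "one_group" else "mu1"
    ess = {key: float(az.ess(np.asarray(d))) for key, d in draws.items()}
    if ess[mu_key] < sampler.ess_floor:
        raise SamplerDivergenceError(
            f"effective sample size for {mu_key} is {ess[mu_key]:.0f}, "
            f"below the hard floor {sampler.ess_floor:.0f}; the chain did not mix"
        )
    if ess[mu_key] < sampler.ess_warn:
        warnings.warn(
            f"effective sample size for {mu_key} is {ess[mu_key]:.0f} (< {sampler.ess_warn:.0f}); "
            "consider a longer chain",
            RuntimeWarning,
            stacklevel=3,
        )
    return PosteriorSummary(draws=draws, ess=ess, spec=spec, n_obs=n_obs)


def fit(
    observations: ObservationSet,
    spec: RobustModelSpec | None = None,
    sampler: SamplerConfig | None = None,
) -> PosteriorSummary:
    """Sample the posterior of the robust model for one dataset.

    One-group draws are keyed ``mu, sigma, nu, log10_nu, effect_size``;
    two-group fits add per-group parameters plus ``mu_diff, sigma_diff``.
    Raises :class:`SamplerDivergenceError` when mixing is pathological.
    """
    spec = spec or RobustModelSpec()
    sampler = sampler or SamplerConfig()
    groups = observations.split()
    if spec.kind == "two_group":
        if len(groups) != 2:
            raise ValueError("two_group model requires grouped observations")
        labels = ["mu1", "mu2", "sigma1", "sigma2"]
    else:
        if len(groups) != 1:
            raise ValueError("one_group model cannot use grouped observations")
        labels = ["mu", "sigma"]
    posterior = _Posterior([g[None, :] for g in groups], spec)
    rng = np.random.default_rng(sampler.seed)
    chain = _metropolis_within_gibbs(posterior, sampler, rng)[0]
    return _summarize_chain(chain, spec, sampler, labels, tuple(g.size for g in groups))


def fit_batch(
    datasets: np.ndarray,
    spec: RobustModelSpec | None = None,
    sampler: SamplerConfig | None = None,
    datasets2: np.ndarray | None = None,
) -> list[PosteriorSummary]:
    """Fit many datasets at once with one vectorized set of chains.

    ``datasets`` is (B, n); for two-group fits pass the second group as
    ``datasets2`` (B, n2).  Each dataset gets an independent chain (shared
    proposal schedule, per-chain adaptation), equivalent to calling
    :func:`fit` per row but an order of magnitude faster for Monte-Carlo
    recovery studies.
    """
    spec = spec or RobustModelSpec()
    sampler = sampler or REDUCED_SAMPLER
    datasets = np.atleast_2d(np.asarray(datasets, dtype=float))
    if spec.kind == "two_group":
        if datasets2 is None:
            raise ValueError("two_group batch fit requires datasets2")
        groups = [datasets, np.atleast_2d(np.asarray(datasets2, dtype=float))]
        labels = ["mu1", "mu2", "sigma1", "sigma2"]
    else:
        groups = [datasets]
        labels = ["mu", "sigma"]
    posterior = _Posterior(groups, spec)
    rng = np.random.default_rng(sampler.seed)
    chains = _metropolis_within_gibbs(posterior, sampler, rng)
    n_obs = tuple(g.shape[1] for g in groups)
    return [
        _summarize_chain(chains[b], spec, sampler, labels, n_obs)
        for b in range(chains.shape[0])
    ]


def effect_size_draws(summary: PosteriorSummary, spec: RobustModelSpec | None = None) -> np.ndarray:
    """Standardized-effect draws: (mu - c) / sigma, or the two-group analogue.

    The two-group denominator sqrt((sigma1^2 + sigma2^2) / 2) is this
    package's convention (recorded in ``RobustModelSpec.effect_size_convention``);
    with equal group scales it reduces to (mu1 - mu2) / sigma.
    """
    spec = spec or summary.spec
    if spec.kind == "one_group":
        return (summary.draws["mu"] - spec.comparison_value) / summary.draws["sigma"]
    return (summary.draws["mu1"] - summary.draws["mu2"]) / np.sqrt(
        (summary.draws["sigma1"] ** 2 + summary.draws["sigma2"] ** 2) / 2.0
    )


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Highest density interval: the shortest interval holding ``mass`` of the draws.

    Computed as the narrowest window over ceil(mass * n) sorted draws, with
    ties broken toward the lowest start index.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 100:
        raise ValueError("need at least 100 draws for a stable HDI")
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must lie in (0, 1)")
    sorted_draws = np.sort(draws)
    k = int(np.ceil(mass * draws.size))
    widths = sorted_draws[k - 1 :] - sorted_draws[: draws.size - k + 1]
    start = int(np.argmin(widths))  # first minimum = lowest start
    return float(sorted_draws[start]), float(sorted_draws[start + k - 1])


def posterior_mode(draws: np.ndarray, grid_points: int = 512) -> float:
    """Point summary: maximizer of a Gaussian KDE evaluated on a uniform grid.

    Matches the usual 'modal estimate' read off a smoothed posterior plot.
    Degenerate (constant) draw vectors return the constant.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 100:
        raise ValueError("need at least 100 draws for a mode estimate")
    lo, hi = draws.min(), draws.max()
    if hi - lo < 1e-12:
        return float(lo)
    kde = gaussian_kde(draws)
    grid = np.linspace(lo, hi, grid_points)
    return float(grid[int(np.argmax(kde(grid)))])
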