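"""Independent brute-force oracle for the robust t-model posterior.

Evaluates the unnormalized one-group posterior on a dense (mu, sigma, nu)
grid and integrates out (sigma, nu) to get the marginal posterior of mu.
Deliberately shares no code with the MCMC implementation beyond numpy/scipy
primitives.
"""

import numpy as np
from scipy.special import gammaln


def grid_mu_marginal(
    data: np.ndarray,
    nu_rate: float = 1.0 / 29.0,
    mu_sd_factor: float = 100.0,
    n_mu: int = 60,
    n_sigma: int = 60,
    n_nu: int = 20,
):
    """Return (mu_grid, normalized marginal posterior weights of mu)."""
    data = np.asarray(data, dtype=float)
    n = data.size
    xbar, sd = data.mean(), data.std(ddof=1)
    mu = np.linspace(xbar - 6 * sd / np.sqrt(n), xbar + 6 * sd / np.sqrt(n), n_mu)
    sigma = np.geomspace(sd / 4, sd * 4, n_sigma)
    nu = np.geomspace(1.05, 150.0, n_nu)

    M, S = np.meshgrid(mu, sigma, indexing="ij")
    z2 = ((data[None, None, :] - M[..., None]) / S[..., None]) ** 2
    logpost = np.empty((n_mu, n_sigma, n_nu))
    for k, v in enumerate(nu):  # slice over nu to bound memory
        loglik = (
            n * (gammaln((v + 1) / 2) - gammaln(v / 2) - 0.5 * np.log(v * np.pi))
            - n * np.log(S)
            - (v + 1) / 2 * np.log1p(z2 / v).sum(axis=-1)
        )
        logpost[:, :, k] = loglik - nu_rate * (v - 1)
    logpost += (-0.5 * ((M - xbar) / (mu_sd_factor * sd)) ** 2)[..., None]
    logpost -= logpost.max()
    post = np.exp(logpost)
    # trapezoid weights in sigma and nu (log-spaced grids)
    w_sigma = np.gradient(sigma)
    w_nu = np.gradient(nu)
    marginal = np.einsum("msv,s,v->m", post, w_sigma, w_nu)
    return mu, marginal / marginal.sum()


def central_mass_interval(grid: np.ndarray, weights: np.ndarray, mass: float = 0.95):
    """Equal-tail interval holding ``mass`` of a discrete distribution."""
    cdf = np.cumsum(weights)
    lo = grid[np.searchsorted(cdf, (1 - mass) / 2)]
    hi = grid[np.searchsorted(cdf, 1 - (1 - mass) / 2)]
    return float(lo), float(hi)
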