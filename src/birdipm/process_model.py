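"""Population process and count observation model.

The stratum population index n_{m,t} is the sum of survivors s_{m,t} and
recruits g_{m,t}.  Year-to-year transitions use truncated-Gaussian
approximations of the underlying binomial (survival) and Poisson
(recruitment) processes, matching their first two moments:

    s_t ~ Normal[0,inf)( n_{t-1} * phi_{t-1},  n_{t-1} * phi_{t-1} * (1 - phi_{t-1}) )
    g_t ~ Normal[0,inf)( n_{t-1} * gamma_{t-1}, n_{t-1} * gamma_{t-1} )

with recruitment decomposed as gamma = RI * iota (productivity index times
a latent first-year-survival/immigration multiplier).  Working with a
continuous index lets count and capture-recapture data collected on
different site sets be joined at a common regional scale.

Counts are overdispersed Poisson around the index:

    y_{i,t} ~ Poisson(exp(log n_{m,t} + omega_i + eta * novice + eps_{i,t}))

with a route-x-observer random effect omega, a fixed novice (start-up-year)
effect eta and a per-cell overdispersion effect eps.  The route-level
abundance index applies the lognormal mean correction

    N_{m,t} = w_m * exp(log n_{m,t} + sigma_omega^2 / 2 + sigma_eps^2 / 2)

and trends are geometric means of realized growth rates N_{t+1}/N_t,
reported as percent per year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "count_loglik",
    "truncnorm_logpdf",
    "survivor_logdensity",
    "recruit_logdensity",
    "survival_linpred",
    "abundance_index",
    "realized_growth",
    "trend",
    "composite_abundance",
    "composite_trend",
    "InitialStatePrior",
    "initial_state_prior",
    "tv_binomial",
    "tv_poisson",
]


def count_loglik(y, log_n, omega=0.0, eta=0.0, novice=0, eps=0.0):
    """Poisson log-pmf of a count with log-mean ``log_n + omega + eta*novice + eps``."""
    y = np.asarray(y)
    lp = np.asarray(log_n + omega + eta * np.asarray(novice) + eps, dtype=float)
    if not np.isfinite(lp).all():
        raise ValueError("non-finite linear predictor in count model")
    return y * lp - np.exp(lp) - special.gammaln(y + 1.0)


def truncnorm_logpdf(x, mean, var):
    """Log-density of Normal(mean, var) truncated to [0, inf).

    Includes the normalizing constant P(X >= 0); -inf below the truncation
    point.  ``var`` must be positive.
    """
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    var = np.asarray(var, dtype=float)
    if np.any(var <= 0):
        raise ValueError("truncated-normal variance must be positive")
    sd = np.sqrt(var)
    out = (
        -0.5 * np.log(2.0 * np.pi)
        - np.log(sd)
        - 0.5 * ((x - mean) / sd) ** 2
        - special.log_ndtr(mean / sd)  # log P(X >= 0)
    )
    return np.where(x < 0, -np.inf, out)


def survivor_logdensity(s, n_prev, phi):
    """Truncated-Gaussian approximation of Binomial(n_prev, phi) survivors."""
    n_prev = np.asarray(n_prev, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(n_prev <= 0):
        raise ValueError("previous population index must be positive")
    if np.any((phi <= 0) | (phi >= 1)):
        raise ValueError("survival probability must lie in (0, 1)")
    mean = n_prev * phi
    return truncnorm_logpdf(s, mean, mean * (1.0 - phi))


def recruit_logdensity(g, n_prev, gamma):
    """Truncated-Gaussian approximation of Poisson(n_prev * gamma) recruits."""
    n_prev = np.asarray(n_prev, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if np.any(n_prev <= 0):
        raise ValueError("previous population index must be positive")
    if np.any(gamma <= 0):
        raise ValueError("recruitment rate must be positive")
    mean = n_prev * gamma
    return truncnorm_logpdf(g, mean, mean)


def survival_linpred(phi0, beta_cmd, cmd, beta_tw, tw, nu):
    """Adult apparent survival from the logit-linear covariate model.

    logit(phi) = logit(phi0) + beta_cmd * cmd + beta_tw * tw + nu
    """
    return special.expit(special.logit(phi0) + beta_cmd * cmd + beta_tw * tw + nu)


def abundance_index(n, sigma_omega, sigma_eps, w=1.0):
    """Route-level abundance index with the lognormal mean correction.

    N = w * exp(log n + sigma_omega^2/2 + sigma_eps^2/2): the expected count
    on an encounter route, marginal over the observer and overdispersion
    effects, scaled by the proportion w of routes with encounters.
    """
    n = np.asarray(n, dtype=float)
    return w * np.exp(np.log(n) + 0.5 * sigma_omega**2 + 0.5 * sigma_eps**2)


def realized_growth(n_series):
    """Annual realized growth rates N_{t+1} / N_t."""
    n = np.asarray(n_series, dtype=float)
    if np.any(n <= 0):
        raise ValueError("abundance series must be positive")
    return n[..., 1:] / n[..., :-1]


def trend(n_series):
    """Percent-per-year trend: 100 * (geometric mean growth - 1).

    Computed in log space over the last axis; scale-invariant in the
    series.  Needs at least two years.
    """
    lam = realized_growth(n_series)
    if lam.shape[-1] < 1:
        raise ValueError("need at least two years for a trend")
    return 100.0 * (np.exp(np.mean(np.log(lam), axis=-1)) - 1.0)


def composite_abundance(n_by_stratum, area_weights):
    """Area-weighted composite abundance series sum_m a_m * N_{m,t}."""
    n = np.atleast_2d(np.asarray(n_by_stratum, dtype=float))
    a = np.asarray(area_weights, dtype=float)
    if abs(a.sum() - 1.0) > 1e-8:
        raise ValueError("area weights must sum to 1")
    return np.tensordot(a, n, axes=(0, 0))


def composite_trend(n_by_stratum, area_weights):
    """Trend of the area-weighted composite abundance series (%/year)."""
    return trend(composite_abundance(n_by_stratum, area_weights))


@dataclass
class InitialStatePrior:
    """Weakly informative truncated-Normal[0, inf) priors for s_1 and g_1.

    Each component is centred at half the stratum's mean first-year count
    with sd ten times that mean, so the data dominate while the prior keeps
    the initial split between survivors and recruits proper.
    """

    mean: float
    sd: float

    def logpdf(self, x):
        return truncnorm_logpdf(x, self.mean, self.sd**2)

    def sample(self, rng: np.random.Generator, size=None):
        a = -self.mean / self.sd
        return stats.truncnorm.rvs(
            a, np.inf, loc=self.mean, scale=self.sd, size=size, random_state=rng
        )


def initial_state_prior(y_first_years) -> InitialStatePrior:
    """Prior for each of s_1, g_1 from the stratum's first-year counts.

    Mean = half the mean first-year count, sd = 10 x the mean count; with
    all-zero (or no) first-year counts, falls back to mean 1, sd 10.
    """
    y = np.asarray(y_first_years, dtype=float)
    if y.size == 0 or y.mean() == 0:
        return InitialStatePrior(mean=1.0, sd=10.0)
    m = float(y.mean())
    return InitialStatePrior(mean=0.5 * m, sd=10.0 * m)


# ---------------------------------------------------------------------------
# Quality of the Gaussian approximation
# ---------------------------------------------------------------------------


def _truncnorm_bin_masses(mean, var, k):
    sd = np.sqrt(var)
    tn = stats.truncnorm(-mean / sd, np.inf, loc=mean, scale=sd)
    upper = tn.cdf(k + 0.5)
    lower = tn.cdf(np.maximum(k - 0.5, 0.0))
    return upper - lower


def tv_binomial(n: int, phi: float) -> float:
    """Total variation distance between the truncated-Gaussian survivor
    approximation and the exact Binomial(n, phi), compared on integer bins.

    TV = (1/2) sum_k |approx mass of bin k - binomial pmf(k)| where bin k
    is [k - 1/2, k + 1/2) intersected with [0, inf); mass beyond n + 1/2 is
    charged to the distance.
    """
    k = np.arange(n + 1)
    approx = _truncnorm_bin_masses(n * phi, n * phi * (1 - phi), k)
    tail = 1.0 - approx.sum()  # truncated-normal mass outside [0, n + 1/2)
    pmf = stats.binom.pmf(k, n, phi)
    return 0.5 * (np.abs(approx - pmf).sum() + abs(tail))


def tv_poisson(lam: float) -> float:
    """Total variation between the truncated-Gaussian recruit approximation
    (mean = variance = lam) and the exact Poisson(lam) on integer bins."""
    kmax = int(lam + 12 * np.sqrt(lam) + 20)
    k = np.arange(kmax + 1)
    approx = _truncnorm_bin_masses(lam, lam, k)
    tail = 1.0 - approx.sum()
    pmf = stats.poisson.pmf(k, lam)
    return 0.5 * (np.abs(approx - pmf).sum() + abs(tail))
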