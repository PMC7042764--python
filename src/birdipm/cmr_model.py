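"""Transient Cormack-Jolly-Seber likelihood and the age-ratio productivity model.

Adult capture histories are modelled conditional on first capture.  A newly
marked bird is a resident with probability pi (residency state R); a
transient (R = 0) has zero probability of recapture after the marking
year.  Conditional on residency, the alive state z follows the usual CJS
absorbing-death chain with apparent survival phi_t and recapture
probability p.  Rather than sampling R and z, both are marginalized out in
closed form: for a constant within-individual p the resident likelihood of
a history with first capture f, last capture l, ncap recaptures and nmiss
intervening misses is

    prod_{t=f}^{l-1} phi_t * p^ncap * (1-p)^nmiss * chi_l

with chi_t = P(never seen after t | alive at t) from the backward recursion
chi_t = (1 - phi_t) + phi_t (1 - p) chi_{t+1}.  The transient branch
contributes (1 - pi) only to histories with no recaptures.

The within-season residency observation r (scored in the marking year) has
P(r = 1 | R = 1) = rho and P(r = 1 | R = 0) = 0, so an observed resident
zeroes the transient branch.

Productivity is a binomial model for the number of hatch-year birds among
aged captures at a station-year, with a logit-linear predictor in centred
log effort, winter drought, spring temperature and year/station random
effects.  The derived reproductive index RI is the expected hatch-year
proportion at reference effort and average station.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "cjs_marginal_loglik",
    "residency_obs_loglik",
    "transient_cjs_joint_loglik",
    "productivity_loglik",
    "productivity_linpred",
    "reproductive_index",
    "HistoryClasses",
    "compress_histories",
    "chi_recursion",
    "class_logliks",
]


def cjs_marginal_loglik(history, pi, phi_seq, p_seq) -> float:
    """Log-likelihood of one capture history, marginal over residency and death.

    ``history`` is the 0/1 detection vector from the marking occasion
    (history[0] must be 1); ``phi_seq`` are the survival probabilities for
    the K-1 intervals after marking and ``p_seq`` the recapture
    probabilities for occasions 2..K.  The alive state is marginalized by a
    forward recursion with absorbing death; the residency state by the
    two-branch mixture (1 - pi) * [no recaptures] + pi * L_CJS.
    """
    h = np.asarray(history, dtype=int)
    phi = np.asarray(phi_seq, dtype=float)
    p = np.asarray(p_seq, dtype=float)
    if h.size == 0 or h[0] != 1:
        raise ValueError("history must start with the marking capture (1)")
    if phi.shape != (h.size - 1,) or p.shape != (h.size - 1,):
        raise ValueError(
            f"need {h.size - 1} survival and recapture probabilities for a "
            f"history of length {h.size}"
        )
    a_alive, a_dead = 1.0, 0.0
    for k in range(1, h.size):
        if h[k]:
            a_alive, a_dead = a_alive * phi[k - 1] * p[k - 1], 0.0
        else:
            a_alive, a_dead = (
                a_alive * phi[k - 1] * (1.0 - p[k - 1]),
                a_dead + a_alive * (1.0 - phi[k - 1]),
            )
    l_cjs = a_alive + a_dead
    recaptured = h[1:].any()
    lik = pi * l_cjs if recaptured else (1.0 - pi) + pi * l_cjs
    if lik <= 0.0:
        if recaptured and pi < 1e-12:
            warnings.warn("recapture observed but residency probability ~ 0")
        return -np.inf
    return float(np.log(lik))


def residency_obs_loglik(r, pi, rho):
    """Log-likelihood of the marking-year residency observation, marginal over R.

    P(r = 1) = pi * rho (transients are never observed as residents);
    P(r = 0) = 1 - pi * rho.
    """
    r = np.asarray(r)
    q = pi * rho
    with np.errstate(divide="ignore"):
        return np.where(r == 1, np.log(q), np.log1p(-q))


def transient_cjs_joint_loglik(history, r, pi, rho, phi_seq, p_seq) -> float:
    """Joint log-likelihood of (capture history, residency observation).

    The two observations are not independent - they share the latent
    residency state - so the mixture is taken once:

    L = (1 - pi) * 1{r = 0} * 1{no recaptures}
        + pi * rho^r (1 - rho)^(1-r) * L_CJS(history | resident)
    """
    h = np.asarray(history, dtype=int)
    phi = np.asarray(phi_seq, dtype=float)
    p = np.asarray(p_seq, dtype=float)
    if h.size == 0 or h[0] != 1:
        raise ValueError("history must start with the marking capture (1)")
    a_alive, a_dead = 1.0, 0.0
    for k in range(1, h.size):
        if h[k]:
            a_alive, a_dead = a_alive * phi[k - 1] * p[k - 1], 0.0
        else:
            a_alive, a_dead = (
                a_alive * phi[k - 1] * (1.0 - p[k - 1]),
                a_dead + a_alive * (1.0 - phi[k - 1]),
            )
    l_res = (a_alive + a_dead) * (rho if r else 1.0 - rho)
    recaptured = bool(h[1:].any())
    lik = pi * l_res
    if not recaptured and not r:
        lik += 1.0 - pi
    if lik <= 0.0:
        return -np.inf
    return float(np.log(lik))


# ---------------------------------------------------------------------------
# Vectorized likelihood over compressed history classes
# ---------------------------------------------------------------------------


@dataclass
class HistoryClasses:
    """Sufficient statistics of capture histories for constant-p likelihoods.

    With time-varying survival but a recapture probability constant within
    an individual, the CJS likelihood depends on a history only through
    (first, last, ncap, nmiss): marking occasion, last detection occasion,
    number of recaptures, and number of missed occasions between first and
    last.  ``station`` and ``r`` are carried so station-level recapture
    effects and the residency observation can be attached.
    """

    first: np.ndarray
    last: np.ndarray
    ncap: np.ndarray
    nmiss: np.ndarray
    r: np.ndarray
    station: np.ndarray


def compress_histories(detections: np.ndarray, first_idx: np.ndarray,
                       r: np.ndarray, station_idx: np.ndarray) -> HistoryClasses:
    """Reduce 0/1 detection matrices to the sufficient statistics above."""
    det = np.asarray(detections, dtype=int)
    n, _ = det.shape
    last = first_idx.copy()
    ncap = np.zeros(n, dtype=int)
    for j in range(n):
        after = det[j, first_idx[j] + 1 :]
        ncap[j] = after.sum()
        if ncap[j]:
            last[j] = first_idx[j] + 1 + np.max(np.nonzero(after)[0])
    nmiss = (last - first_idx) - ncap
    return HistoryClasses(
        first=first_idx.astype(int),
        last=last.astype(int),
        ncap=ncap,
        nmiss=nmiss,
        r=np.asarray(r, dtype=int),
        station=np.asarray(station_idx, dtype=int),
    )


def chi_recursion(phi_t: np.ndarray, p) -> np.ndarray:
    """chi_t = P(never detected after occasion t | alive at t).

    ``phi_t`` has length T-1 (intervals); ``p`` may be a scalar or an array
    of quadrature values, in which case the result has shape
    (len(p), T).
    """
    phi = np.asarray(phi_t, dtype=float)
    p = np.atleast_1d(np.asarray(p, dtype=float))
    T = phi.size + 1
    chi = np.empty((p.size, T))
    chi[:, -1] = 1.0
    for t in range(T - 2, -1, -1):
        chi[:, t] = (1.0 - phi[t]) + phi[t] * (1.0 - p) * chi[:, t + 1]
    return chi


def class_logliks(cls: HistoryClasses, phi_t: np.ndarray, pi_t: np.ndarray,
                  rho: float, p) -> np.ndarray:
    """Per-individual joint log-likelihoods, vectorized over p values.

    Returns an array of shape (len(p), n_individuals): the joint
    (history, r) log-likelihood of each individual at each candidate
    recapture probability (e.g. Gauss-Hermite nodes of a station effect).
    Cross-checked in the test suite against the per-history forward
    recursion.
    """
    phi = np.asarray(phi_t, dtype=float)
    pi = np.asarray(pi_t, dtype=float)
    p = np.atleast_1d(np.asarray(p, dtype=float))
    chi = chi_recursion(phi, p)  # (K, T)
    cumlogphi = np.concatenate([[0.0], np.cumsum(np.log(phi))])  # (T,)
    # resident-branch likelihood, shape (K, n)
    log_surv = cumlogphi[cls.last] - cumlogphi[cls.first]
    with np.errstate(divide="ignore"):
        logp, log1mp = np.log(p), np.log1p(-p)
    l_res = np.exp(
        log_surv[None, :]
        + cls.ncap[None, :] * logp[:, None]
        + cls.nmiss[None, :] * log1mp[:, None]
        + np.log(chi[:, cls.last])
    )
    l_res *= np.where(cls.r == 1, rho, 1.0 - rho)[None, :]
    pi_f = pi[cls.first]
    lik = pi_f[None, :] * l_res
    transient_ok = (cls.ncap == 0) & (cls.r == 0)
    lik += np.where(transient_ok, 1.0 - pi_f, 0.0)[None, :]
    with np.errstate(divide="ignore"):
        return np.log(lik)


# ---------------------------------------------------------------------------
# Productivity (age-ratio) model
# ---------------------------------------------------------------------------


def productivity_loglik(n_hy, n_total, linpred):
    """Binomial log-pmf of hatch-year captures out of aged captures.

    Success probability is logit^-1(linpred); empty cells (n_total = 0)
    contribute exactly 0.
    """
    n_hy = np.asarray(n_hy)
    n_total = np.asarray(n_total)
    if np.any(n_hy > n_total):
        raise ValueError("more hatch-year captures than total captures")
    prob = special.expit(np.asarray(linpred, dtype=float))
    ll = stats.binom.logpmf(n_hy, n_total, prob)
    return np.where(n_total == 0, 0.0, ll)


def productivity_linpred(alpha0, alpha_ef=0.0, log_effort_centered=0.0,
                         alpha_cmd=0.0, cmd=0.0, alpha_temp=0.0, temp=0.0,
                         yr=0.0, sta=0.0):
    """Logit-scale linear predictor of the hatch-year proportion."""
    return (
        alpha0
        + alpha_ef * log_effort_centered
        + alpha_cmd * cmd
        + alpha_temp * temp
        + yr
        + sta
    )


def reproductive_index(alpha0, alpha_cmd=0.0, cmd=0.0, alpha_temp=0.0,
                       temp=0.0, yr=0.0):
    """Reproductive index RI: expected hatch-year proportion at reference effort.

    The effort term is at its centred zero and the station effect at 0, so
    RI reflects climate and year variation in productivity only.
    """
    return special.expit(alpha0 + alpha_cmd * cmd + alpha_temp * temp + yr)
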