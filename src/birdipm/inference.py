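"""Joint posterior assembly, MCMC sampling, convergence checks and summaries.

The joint likelihood is the product of three independent components sharing
vital-rate parameters: the state-space count model (observation x process),
the transient CJS model for capture histories, and the binomial age-ratio
productivity model.  Priors follow the weakly informative scheme of
hierarchical count/CMR models in this literature: Uniform(0,1) on
probability-scale intercepts, Normal(0, variance 1000) on regression
coefficients, Uniform(0,10) on sd hyperparameters, and a truncated
Normal(1, sd 10) on [0, inf) for the first-year-survival/immigration
multiplier iota (an sd of 0.1 is selectable for sensitivity runs).

Sampling strategy.  All random effects are parameterized non-centred
(standard-normal raw effects scaled by their sd hyperparameter).
Structural parameters, year effects and the latent stratum population
states are updated in correlated blocks by an adaptive random-walk
Metropolis sampler (Haario-style empirical-covariance proposals, scale
tuned to a target acceptance rate during warm-up, frozen afterwards).
Unit-level random effects - the route x observer effect omega, the
per-cell overdispersion eps, and the station effects of the recapture and
productivity models - are conditionally independent across units given
everything else, so they are updated by vectorized single-site Metropolis
moves with per-unit acceptance, which costs one pass over the data per
sweep.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from . import cmr_model, process_model
from .data_io import ModelDataset
from .ltre import GrowthSeries

__all__ = [
    "PriorSpec",
    "MCMCSettings",
    "ParameterLayout",
    "JointModel",
    "PosteriorDraws",
    "build_joint_model",
    "sample_posterior",
    "convergence_check",
    "summarize",
    "derive_quantities",
    "fit_dataset",
]


def _log_expit(x):
    return special.log_expit(x)


@dataclass
class PriorSpec:
    """Hyperparameters of the weakly informative prior scheme.

    ``coef_sd`` is the sd of the Normal prior on regression coefficients
    (variance 1000 by default); ``sigma_upper`` the upper bound of the
    Uniform prior on sd hyperparameters; ``iota_mean``/``iota_sd`` the
    moments of the truncated-Normal prior on iota.
    """

    coef_sd: float = np.sqrt(1000.0)
    sigma_upper: float = 10.0
    iota_mean: float = 1.0
    iota_sd: float = 10.0


@dataclass
class MCMCSettings:
    """Chain geometry.  ``draws`` is the total retained across chains.

    The ``paper`` preset carries the Gibbs-run lengths conventional for
    full-scale fits of this model family (4 chains, adapt 40k, burn-in
    20k, 80k retained, thin 4); the ``reduced`` preset is sized for
    desk-scale synthetic data.
    """

    chains: int = 4
    adapt: int = 40_000
    burnin: int = 20_000
    draws: int = 80_000
    thin: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("chains", "adapt", "burnin", "draws", "thin"):
            if getattr(self, name) < 1:
                raise ValueError(f"MCMC setting {name} must be a positive integer")

    @classmethod
    def paper(cls, seed: int = 0) -> "MCMCSettings":
        return cls(seed=seed)

    @classmethod
    def reduced(cls, seed: int = 0, chains: int = 2, adapt: int = 3500,
                burnin: int = 1200, draws: int = 5000, thin: int = 1) -> "MCMCSettings":
        return cls(chains=chains, adapt=adapt, burnin=burnin, draws=draws,
                   thin=thin, seed=seed)

    @property
    def draws_per_chain(self) -> int:
        return self.draws // self.chains


# ---------------------------------------------------------------------------
# Parameter layout
# ---------------------------------------------------------------------------

GLOBAL_PARAMS = [
    ("eta", 1),
    ("log_sigma_omega", 1),
    ("log_sigma_eps", 1),
    ("alpha_ef", 1),
    ("log_sigma_sta", 1),
    ("log_sigma_p", 1),
]

# raw (standard-normal) random-effect vectors with data-dependent sizes
UNIT_PARAMS = ("omega_raw", "eps_raw", "sta_p_raw", "sta_prod_raw")


def _stratum_params(T: int):
    return [
        ("logit_phi0", 1),
        ("beta_cmd", 1),
        ("beta_tw", 1),
        ("nu", T - 1),          # raw year effects, scaled by sigma_nu
        ("log_sigma_nu", 1),
        ("logit_pi0", 1),
        ("pi_yr", T),           # raw year effects, scaled by sigma_pi
        ("log_sigma_pi", 1),
        ("logit_p0", 1),
        ("logit_rho", 1),
        ("alpha0", 1),
        ("alpha_cmd", 1),
        ("alpha_temp", 1),
        ("yr", T),              # raw year effects, scaled by sigma_yr
        ("log_sigma_yr", 1),
        ("log_iota", T - 1),
        ("log_s", T),
        ("log_g", T),
    ]


class ParameterLayout:
    """Maps named (possibly per-stratum) parameters to a flat vector.

    ``unit_sizes`` gives, per stratum, the sizes of the data-dependent raw
    random-effect vectors (route x observer units, count cells, CMR
    stations, productivity stations).
    """

    def __init__(self, M: int, T: int, strata=None, unit_sizes: dict | None = None):
        self.M, self.T = M, T
        self.strata = list(strata) if strata is not None else list(range(M))
        unit_sizes = unit_sizes or {name: [0] * M for name in UNIT_PARAMS}
        self.slices: dict = {}
        pos = 0
        for name, size in GLOBAL_PARAMS:
            self.slices[(name, None)] = slice(pos, pos + size)
            pos += size
        for m in range(M):
            for name, size in _stratum_params(T):
                self.slices[(name, m)] = slice(pos, pos + size)
                pos += size
            for name in UNIT_PARAMS:
                size = unit_sizes[name][m]
                self.slices[(name, m)] = slice(pos, pos + size)
                pos += size
        self.dim = pos

    def sl(self, name: str, m=None) -> slice:
        return self.slices[(name, m)]

    def get(self, theta: np.ndarray, name: str, m=None) -> np.ndarray:
        return theta[..., self.slices[(name, m)]]

    def scalar_names(self) -> list[str]:
        out = [""] * self.dim
        for (name, m), sl in self.slices.items():
            label = name if m is None else f"{name}[{self.strata[m]}]"
            size = sl.stop - sl.start
            for k in range(size):
                out[sl.start + k] = label if size == 1 else f"{label}[{k}]"
        return out


# ---------------------------------------------------------------------------
# Preprocessed data blocks
# ---------------------------------------------------------------------------


@dataclass
class _CountBlock:
    """Count cells of one stratum, sorted by route x observer unit."""

    y: np.ndarray
    lgam: np.ndarray
    year: np.ndarray
    novice: np.ndarray
    unit: np.ndarray            # local unit index per cell
    unit_starts: np.ndarray     # reduceat boundaries of the sorted unit runs
    n_units: int


@dataclass
class _CJSBlock:
    """Unique history classes of one stratum, sorted by station."""

    cls: cmr_model.HistoryClasses
    mult: np.ndarray
    station_starts: np.ndarray
    n_stations: int


@dataclass
class _ProdBlock:
    """Age-ratio cells of one stratum with captures, sorted by station."""

    n_hy: np.ndarray
    n_tot: np.ndarray
    logc: np.ndarray
    clogeff: np.ndarray
    year: np.ndarray
    station: np.ndarray
    station_starts: np.ndarray
    n_stations: int


class JointModel:
    """Preprocessed data plus the joint log-posterior and its components.

    Likelihood components are evaluated per stratum so the sampler can
    cache and update them independently; ``*_cell_logliks`` expose the
    per-unit terms the vectorized random-effect updates need.
    """

    COMPONENTS = ("counts", "cjs", "prod", "state")

    def __init__(self, dataset: ModelDataset, priors: PriorSpec | None = None,
                 include_likelihood: bool = True):
        self.priors = priors or PriorSpec()
        self.include_likelihood = include_likelihood
        self.strata = dataset.strata
        self.years = np.asarray(dataset.years)
        self.M, self.T = dataset.n_strata, dataset.n_years
        self.route_weights = dataset.route_weights
        self.area_weights = dataset.area_weights

        sindex, yindex = dataset.stratum_index, dataset.year_index

        # --- covariates: z-scored within stratum, sd recorded ------------
        self.cov_sd = {}
        self.cov_z = {}
        for name in ("cmd", "tw", "temp"):
            arr = dataset.covariates.values(name, self.strata, self.years)
            mu = arr.mean(axis=1, keepdims=True)
            sd = arr.std(axis=1, keepdims=True)
            if np.any(sd == 0):
                raise ValueError(f"covariate {name!r} constant within a stratum")
            self.cov_z[name] = (arr - mu) / sd
            self.cov_sd[name] = sd[:, 0]

        # --- counts -------------------------------------------------------
        rec = dataset.counts.records
        self.count_blocks: list[_CountBlock] = []
        self.init_priors = []
        for m, s in enumerate(self.strata):
            sub = rec[rec["stratum"] == s].sort_values("route_observer", kind="stable")
            unit_labels = sub["route_observer"].to_numpy()
            uniq, unit_idx = np.unique(unit_labels, return_inverse=True)
            _, starts = np.unique(unit_idx, return_index=True)
            y = sub["count"].to_numpy(dtype=float)
            self.count_blocks.append(
                _CountBlock(
                    y=y,
                    lgam=special.gammaln(y + 1.0),
                    year=sub["year"].map(yindex).to_numpy(),
                    novice=sub["novice"].to_numpy(dtype=float),
                    unit=unit_idx,
                    unit_starts=np.sort(starts),
                    n_units=len(uniq),
                )
            )
            first = sub.loc[sub["year"] == self.years[0], "count"]
            self.init_priors.append(process_model.initial_state_prior(first.to_numpy()))

        # --- capture histories --------------------------------------------
        cap = dataset.captures
        self.cjs_blocks: list[_CJSBlock | None] = []
        for m, s in enumerate(self.strata):
            mask = (cap.individuals["stratum"] == s).to_numpy()
            if not mask.any():
                self.cjs_blocks.append(None)
                continue
            ind = cap.individuals.loc[mask]
            det = cap.detections[mask]
            stations = {k: i for i, k in enumerate(sorted(ind["station"].unique()))}
            first_idx = np.searchsorted(cap.years, ind["first_year"].to_numpy())
            offset = int(np.searchsorted(self.years, cap.years[0]))
            cls = cmr_model.compress_histories(
                det,
                first_idx,
                ind["resident_observed"].to_numpy(),
                ind["station"].map(stations).to_numpy(),
            )
            key = np.stack([cls.station, cls.first, cls.last, cls.ncap, cls.nmiss, cls.r])
            uniq, counts = np.unique(key.T, axis=0, return_counts=True)
            agg = cmr_model.HistoryClasses(
                first=uniq[:, 1] + offset,
                last=uniq[:, 2] + offset,
                ncap=uniq[:, 3],
                nmiss=uniq[:, 4],
                r=uniq[:, 5],
                station=uniq[:, 0],
            )
            _, sta_starts = np.unique(agg.station, return_index=True)
            self.cjs_blocks.append(
                _CJSBlock(cls=agg, mult=counts.astype(float),
                          station_starts=np.sort(sta_starts),
                          n_stations=len(stations))
            )

        # --- age-specific captures ----------------------------------------
        ages = dataset.ages.rows
        with_caps = ages[(ages["n_hy"] + ages["n_adult"]) > 0]
        self.log_effort_center = (
            float(np.log(with_caps["effort_net_hours"]).mean()) if len(with_caps) else 0.0
        )
        self.prod_blocks: list[_ProdBlock | None] = []
        for m, s in enumerate(self.strata):
            sub = with_caps[with_caps["stratum"] == s].sort_values("station", kind="stable")
            if not len(sub):
                self.prod_blocks.append(None)
                continue
            _, sta_idx = np.unique(sub["station"].to_numpy(), return_inverse=True)
            _, sta_starts = np.unique(sta_idx, return_index=True)
            n_hy = sub["n_hy"].to_numpy(dtype=float)
            n_tot = (sub["n_hy"] + sub["n_adult"]).to_numpy(dtype=float)
            self.prod_blocks.append(
                _ProdBlock(
                    n_hy=n_hy,
                    n_tot=n_tot,
                    logc=(
                        special.gammaln(n_tot + 1)
                        - special.gammaln(n_hy + 1)
                        - special.gammaln(n_tot - n_hy + 1)
                    ),
                    clogeff=np.log(sub["effort_net_hours"].to_numpy()) - self.log_effort_center,
                    year=sub["year"].map(yindex).to_numpy(),
                    station=sta_idx,
                    station_starts=np.sort(sta_starts),
                    n_stations=int(sta_idx.max()) + 1,
                )
            )

        unit_sizes = {
            "omega_raw": [b.n_units for b in self.count_blocks],
            "eps_raw": [b.y.size for b in self.count_blocks],
            "sta_p_raw": [b.n_stations if b else 0 for b in self.cjs_blocks],
            "sta_prod_raw": [b.n_stations if b else 0 for b in self.prod_blocks],
        }
        self.layout = ParameterLayout(self.M, self.T, self.strata, unit_sizes)

    # -- parameter transforms ----------------------------------------------
    def phi_intervals(self, theta, m) -> np.ndarray:
        """Apparent survival per interval t -> t+1 (length T-1).

        The winter drought / migration tailwind of the interval ending at
        breeding season t+1 are the values labelled t+1.
        """
        L = self.layout
        sd = np.exp(L.get(theta, "log_sigma_nu", m)[0])
        lin = (
            L.get(theta, "logit_phi0", m)
            + L.get(theta, "beta_cmd", m) * self.cov_z["cmd"][m, 1:]
            + L.get(theta, "beta_tw", m) * self.cov_z["tw"][m, 1:]
            + sd * L.get(theta, "nu", m)
        )
        return np.clip(special.expit(lin), 1e-12, 1 - 1e-12)

    def ri_years(self, theta, m) -> np.ndarray:
        """Reproductive index per breeding season (length T)."""
        L = self.layout
        sd = np.exp(L.get(theta, "log_sigma_yr", m)[0])
        lin = (
            L.get(theta, "alpha0", m)
            + L.get(theta, "alpha_cmd", m) * self.cov_z["cmd"][m]
            + L.get(theta, "alpha_temp", m) * self.cov_z["temp"][m]
            + sd * L.get(theta, "yr", m)
        )
        return special.expit(lin)

    def pi_years(self, theta, m) -> np.ndarray:
        L = self.layout
        sd = np.exp(L.get(theta, "log_sigma_pi", m)[0])
        lin = L.get(theta, "logit_pi0", m) + sd * L.get(theta, "pi_yr", m)
        return np.clip(special.expit(lin), 1e-12, 1 - 1e-12)

    def station_p(self, theta, m) -> np.ndarray:
        """Station-specific recapture probabilities."""
        L = self.layout
        sd = np.exp(L.get(theta, "log_sigma_p", None)[0])
        lin = L.get(theta, "logit_p0", m)[0] + sd * L.get(theta, "sta_p_raw", m)
        return np.clip(special.expit(lin), 1e-12, 1 - 1e-12)

    # -- likelihood components ----------------------------------------------
    def count_cell_logliks(self, theta, m, omega_raw=None, eps_raw=None) -> np.ndarray:
        """Per-cell Poisson log-likelihoods given the observation effects."""
        blk = self.count_blocks[m]
        L = self.layout
        if omega_raw is None:
            omega_raw = L.get(theta, "omega_raw", m)
        if eps_raw is None:
            eps_raw = L.get(theta, "eps_raw", m)
        s = np.exp(L.get(theta, "log_s", m))
        g = np.exp(L.get(theta, "log_g", m))
        log_n = np.log(s + g)
        eta = L.get(theta, "eta", None)[0]
        sw = np.exp(L.get(theta, "log_sigma_omega", None)[0])
        se = np.exp(L.get(theta, "log_sigma_eps", None)[0])
        a = (
            log_n[blk.year]
            + sw * omega_raw[blk.unit]
            + eta * blk.novice
            + se * eps_raw
        )
        with np.errstate(over="ignore", invalid="ignore"):
            ll = blk.y * a - np.exp(a) - blk.lgam
        return ll

    def component_counts(self, theta, m) -> float:
        if not self.include_likelihood:
            return 0.0
        blk = self.count_blocks[m]
        if blk is None or blk.y.size == 0:
            return 0.0
        total = self.count_cell_logliks(theta, m).sum()
        return float(total) if np.isfinite(total) else -np.inf

    def cjs_class_logliks(self, theta, m, sta_p_raw=None) -> np.ndarray:
        """Multiplicity-weighted log-likelihood per unique history class."""
        blk = self.cjs_blocks[m]
        L = self.layout
        phi = self.phi_intervals(theta, m)
        pi = self.pi_years(theta, m)
        rho = float(np.clip(special.expit(L.get(theta, "logit_rho", m)[0]), 1e-12, 1 - 1e-12))
        if sta_p_raw is None:
            sta_p_raw = L.get(theta, "sta_p_raw", m)
        sd = np.exp(L.get(theta, "log_sigma_p", None)[0])
        p_sta = np.clip(
            special.expit(L.get(theta, "logit_p0", m)[0] + sd * sta_p_raw),
            1e-12, 1 - 1e-12,
        )
        cls = blk.cls
        chi = cmr_model.chi_recursion(phi, p_sta)  # (n_sta, T)
        cumlogphi = np.concatenate([[0.0], np.cumsum(np.log(phi))])
        p_cls = p_sta[cls.station]
        log_surv = cumlogphi[cls.last] - cumlogphi[cls.first]
        l_res = np.exp(
            log_surv
            + cls.ncap * np.log(p_cls)
            + cls.nmiss * np.log1p(-p_cls)
            + np.log(chi[cls.station, cls.last])
        )
        l_res = l_res * np.where(cls.r == 1, rho, 1.0 - rho)
        pi_f = pi[cls.first]
        lik = pi_f * l_res
        lik = lik + np.where((cls.ncap == 0) & (cls.r == 0), 1.0 - pi_f, 0.0)
        with np.errstate(divide="ignore"):
            return blk.mult * np.log(lik)

    def component_cjs(self, theta, m) -> float:
        blk = self.cjs_blocks[m]
        if not self.include_likelihood or blk is None:
            return 0.0
        total = self.cjs_class_logliks(theta, m).sum()
        return float(total) if np.isfinite(total) else -np.inf

    def prod_cell_logliks(self, theta, m, sta_prod_raw=None) -> np.ndarray:
        """Per station-year binomial log-likelihoods of the age ratio."""
        blk = self.prod_blocks[m]
        L = self.layout
        if sta_prod_raw is None:
            sta_prod_raw = L.get(theta, "sta_prod_raw", m)
        sd_yr = np.exp(L.get(theta, "log_sigma_yr", m)[0])
        ss = np.exp(L.get(theta, "log_sigma_sta", None)[0])
        b = (
            L.get(theta, "alpha0", m)[0]
            + L.get(theta, "alpha_ef", None)[0] * blk.clogeff
            + L.get(theta, "alpha_cmd", m)[0] * self.cov_z["cmd"][m][blk.year]
            + L.get(theta, "alpha_temp", m)[0] * self.cov_z["temp"][m][blk.year]
            + sd_yr * L.get(theta, "yr", m)[blk.year]
            + ss * sta_prod_raw[blk.station]
        )
        return (
            blk.n_hy * _log_expit(b)
            + (blk.n_tot - blk.n_hy) * _log_expit(-b)
            + blk.logc
        )

    def component_prod(self, theta, m) -> float:
        blk = self.prod_blocks[m]
        if not self.include_likelihood or blk is None:
            return 0.0
        total = self.prod_cell_logliks(theta, m).sum()
        return float(total) if np.isfinite(total) else -np.inf

    def component_state(self, theta, m) -> float:
        """Process-model transitions, initial-state prior and log-scale Jacobians."""
        L = self.layout
        log_s = L.get(theta, "log_s", m)
        log_g = L.get(theta, "log_g", m)
        s, g = np.exp(log_s), np.exp(log_g)
        n = s + g
        phi = self.phi_intervals(theta, m)
        ri = self.ri_years(theta, m)
        iota = np.exp(L.get(theta, "log_iota", m))
        gamma = np.clip(ri[:-1] * iota, 1e-12, None)
        ll = process_model.survivor_logdensity(s[1:], n[:-1], phi).sum()
        ll += process_model.recruit_logdensity(g[1:], n[:-1], gamma).sum()
        prior = self.init_priors[m]
        ll += float(prior.logpdf(s[0]) + prior.logpdf(g[0]))
        ll += float(log_s.sum() + log_g.sum())  # d s / d log s Jacobians
        return float(ll) if np.isfinite(ll) else -np.inf

    # -- priors ---------------------------------------------------------------
    def log_prior(self, theta) -> float:
        L, pr = self.layout, self.priors
        total = 0.0
        # coefficients and novice effect ~ Normal(0, coef_sd^2)
        coef = [L.get(theta, "eta", None), L.get(theta, "alpha_ef", None)]
        for m in range(self.M):
            for name in ("beta_cmd", "beta_tw", "alpha_cmd", "alpha_temp"):
                coef.append(L.get(theta, name, m))
        coef = np.concatenate(coef)
        total += float(np.sum(-0.5 * (coef / pr.coef_sd) ** 2) - coef.size * np.log(pr.coef_sd))
        # uniform(0,1) intercepts on the probability scale -> logistic on logits
        logits = []
        for m in range(self.M):
            for name in ("logit_phi0", "logit_pi0", "logit_p0", "logit_rho", "alpha0"):
                logits.append(L.get(theta, name, m))
        logits = np.concatenate(logits)
        total += float(np.sum(_log_expit(logits) + _log_expit(-logits)))
        # sd hyperparameters ~ U(0, upper), sampled on the log scale
        log_sigmas = [L.get(theta, "log_sigma_omega", None),
                      L.get(theta, "log_sigma_eps", None),
                      L.get(theta, "log_sigma_sta", None),
                      L.get(theta, "log_sigma_p", None)]
        for m in range(self.M):
            for name in ("log_sigma_nu", "log_sigma_pi", "log_sigma_yr"):
                log_sigmas.append(L.get(theta, name, m))
        log_sigmas = np.concatenate(log_sigmas)
        if np.any(np.exp(log_sigmas) >= pr.sigma_upper):
            return -np.inf
        total += float(np.sum(log_sigmas) - log_sigmas.size * np.log(pr.sigma_upper))
        # standard-normal raw random effects (non-centred parameterization)
        raw = []
        for m in range(self.M):
            for name in ("nu", "pi_yr", "yr") + UNIT_PARAMS:
                raw.append(L.get(theta, name, m))
        raw = np.concatenate(raw)
        total += float(np.sum(-0.5 * raw**2) - 0.5 * raw.size * np.log(2 * np.pi))
        # iota ~ truncated Normal(iota_mean, iota_sd) on [0, inf), log-scale Jacobian
        for m in range(self.M):
            log_iota = L.get(theta, "log_iota", m)
            iota = np.exp(log_iota)
            total += float(
                process_model.truncnorm_logpdf(iota, pr.iota_mean, pr.iota_sd**2).sum()
                + log_iota.sum()
            )
        return float(total) if np.isfinite(total) else -np.inf

    def component(self, name: str, theta, m) -> float:
        return getattr(self, f"component_{name}")(theta, m)

    def log_likelihood(self, theta) -> float:
        total = 0.0
        for m in range(self.M):
            for name in self.COMPONENTS:
                total += self.component(name, theta, m)
        return total

    def log_posterior(self, theta) -> float:
        lp = self.log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.log_likelihood(theta)

    # -- initialization -------------------------------------------------------
    def initial_point(self) -> np.ndarray:
        """Data-driven starting point: counts set the latent index scale."""
        L = self.layout
        theta = np.zeros(L.dim)
        theta[L.sl("log_sigma_omega")] = np.log(0.3)
        theta[L.sl("log_sigma_eps")] = np.log(0.2)
        theta[L.sl("log_sigma_sta")] = np.log(0.3)
        theta[L.sl("log_sigma_p")] = np.log(0.3)
        for m in range(self.M):
            blk = self.count_blocks[m]
            n_hat = np.full(self.T, 1.0)
            if blk.y.size:
                sums = np.bincount(blk.year, weights=blk.y, minlength=self.T)
                cnts = np.bincount(blk.year, minlength=self.T).astype(float)
                with np.errstate(invalid="ignore", divide="ignore"):
                    mean = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
                n_hat = pd.Series(mean).ffill().bfill().fillna(1.0).to_numpy()
                n_hat = np.maximum(n_hat, 0.5)
            theta[L.sl("log_s", m)] = np.log(0.5 * n_hat)
            theta[L.sl("log_g", m)] = np.log(0.5 * n_hat)
            theta[L.sl("logit_phi0", m)] = special.logit(0.5)
            theta[L.sl("log_sigma_nu", m)] = np.log(0.15)
            theta[L.sl("logit_pi0", m)] = special.logit(0.6)
            theta[L.sl("log_sigma_pi", m)] = np.log(0.2)
            theta[L.sl("logit_p0", m)] = special.logit(0.3)
            theta[L.sl("logit_rho", m)] = special.logit(0.7)
            blkp = self.prod_blocks[m]
            if blkp is not None and blkp.n_tot.sum() > 0:
                frac = np.clip(blkp.n_hy.sum() / blkp.n_tot.sum(), 0.02, 0.98)
            else:
                frac = 0.2
            theta[L.sl("alpha0", m)] = special.logit(frac)
            theta[L.sl("log_sigma_yr", m)] = np.log(0.25)
            theta[L.sl("log_iota", m)] = np.log(1.5)
        return theta


def build_joint_model(dataset: ModelDataset, priors: PriorSpec | None = None,
                      include_likelihood: bool = True) -> JointModel:
    """Assemble the joint log-posterior for an aligned dataset.

    With ``include_likelihood=False`` the three data likelihoods are
    dropped and the model reduces to its prior (the process-model
    transitions are retained as the prior over latent states), which is
    used for prior-predictive checks.
    """
    return JointModel(dataset, priors=priors, include_likelihood=include_likelihood)


# ---------------------------------------------------------------------------
# Adaptive blocked random-walk Metropolis
# ---------------------------------------------------------------------------


@dataclass
class _Block:
    name: str
    idx: np.ndarray
    comps: list  # list of (component name, stratum index)
    target: float = 0.234


class _BlockState:
    """Per-block adaptation state: running moments and proposal Cholesky."""

    def __init__(self, block: _Block, init_scales: np.ndarray):
        self.block = block
        d = block.idx.size
        self.d = d
        self.log_lambda = 0.0
        self.mean = np.zeros(d)
        self.m2 = np.zeros((d, d))
        self.count = 0
        self.chol = np.diag(init_scales)
        self.base = np.diag(init_scales**2)
        self.n_props = 0

    def propose(self, rng: np.random.Generator) -> np.ndarray:
        lam = np.exp(self.log_lambda)
        return lam * (self.chol @ rng.standard_normal(self.d))

    def update_moments(self, x: np.ndarray) -> None:
        self.count += 1
        delta = x - self.mean
        self.mean += delta / self.count
        self.m2 += np.outer(delta, x - self.mean)

    def refresh_chol(self) -> None:
        if self.count > max(2 * self.d, 20):
            cov = self.m2 / (self.count - 1)
            cov = (2.38**2 / self.d) * cov + 1e-8 * np.eye(self.d) + 1e-4 * self.base
            try:
                self.chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass

    def adapt_scale(self, accepted: bool) -> None:
        self.n_props += 1
        step = 1.0 / max(10.0, self.n_props**0.6)
        self.log_lambda += step * ((1.0 if accepted else 0.0) - self.block.target)
        self.log_lambda = float(np.clip(self.log_lambda, -4.0, 4.0))


def _make_blocks(model: JointModel) -> list[_Block]:
    L = model.layout

    def idx(*names_m):
        parts = [np.arange(L.sl(n, m).start, L.sl(n, m).stop) for n, m in names_m]
        return np.concatenate(parts)

    blocks = []
    for m in range(model.M):
        has_cjs = model.cjs_blocks[m] is not None and model.include_likelihood
        has_prod = model.prod_blocks[m] is not None and model.include_likelihood
        cjs = [("cjs", m)] if has_cjs else []
        prod = [("prod", m)] if has_prod else []
        blocks.append(_Block("states", idx(("log_s", m), ("log_g", m)),
                             [("counts", m), ("state", m)]))
        blocks.append(_Block(
            "survival",
            idx(("logit_phi0", m), ("beta_cmd", m), ("beta_tw", m), ("nu", m)),
            [("state", m)] + cjs,
        ))
        blocks.append(_Block("residency", idx(("logit_pi0", m), ("pi_yr", m)), cjs))
        blocks.append(_Block("recapture", idx(("logit_p0", m), ("logit_rho", m)),
                             cjs, target=0.35))
        blocks.append(_Block(
            "productivity",
            idx(("alpha0", m), ("alpha_cmd", m), ("alpha_temp", m), ("yr", m)),
            [("state", m)] + prod,
        ))
        blocks.append(_Block("iota", idx(("log_iota", m)), [("state", m)]))
        blocks.append(_Block(
            "hypers",
            idx(("log_sigma_nu", m), ("log_sigma_pi", m), ("log_sigma_yr", m)),
            [("state", m)] + cjs + prod, target=0.35,
        ))
    blocks.append(_Block(
        "obs_global",
        idx(("eta", None), ("log_sigma_omega", None), ("log_sigma_eps", None)),
        [("counts", m) for m in range(model.M)], target=0.35,
    ))
    blocks.append(_Block("prod_global", idx(("alpha_ef", None), ("log_sigma_sta", None)),
                         [("prod", m) for m in range(model.M)
                          if model.prod_blocks[m] is not None], target=0.35))
    blocks.append(_Block("cjs_global", idx(("log_sigma_p", None)),
                         [("cjs", m) for m in range(model.M)
                          if model.cjs_blocks[m] is not None], target=0.44))
    return blocks


class _VectorScale:
    """Per-coordinate Robbins-Monro scale adaptation for vectorized moves."""

    def __init__(self, size: int, init: float = 0.5, target: float = 0.44):
        self.log_s = np.full(size, np.log(init))
        self.target = target
        self.n = 0

    @property
    def scales(self) -> np.ndarray:
        return np.exp(self.log_s)

    def adapt(self, accepted: np.ndarray) -> None:
        self.n += 1
        step = 1.0 / max(10.0, self.n**0.6)
        self.log_s += step * (accepted.astype(float) - self.target)
        np.clip(self.log_s, -6.0, 3.0, out=self.log_s)


def _segment_sums(values: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.add.reduceat(values, starts)


class _ScalarScale:
    """Robbins-Monro adaptation of a single proposal scale."""

    def __init__(self, init: float = 0.3, target: float = 0.234):
        self.log_s = np.log(init)
        self.target = target
        self.n = 0

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_s))

    def adapt(self, accepted: bool) -> None:
        self.n += 1
        step = 1.0 / max(10.0, self.n**0.6)
        self.log_s = float(np.clip(
            self.log_s + step * (float(accepted) - self.target), -6.0, 3.0
        ))


def _split_swap_move(model, theta, rng, scale: float, cache, m) -> bool:
    """Random walk on the survivor/recruit split holding n = s + g fixed.

    The split s/n is only weakly identified (the transitions, not the
    counts, inform it), so moving it along the n-constant curve mixes the
    slow direction cheaply: the count likelihood is invariant and only the
    process-model component is re-evaluated.  The map (log s, log g) ->
    (log n, log-odds split) has unit Jacobian determinant, so a symmetric
    step in the split's log-odds is a symmetric proposal.
    """
    L = model.layout
    sl_s, sl_g = L.sl("log_s", m), L.sl("log_g", m)
    log_s, log_g = theta[sl_s], theta[sl_g]
    n = np.exp(log_s) + np.exp(log_g)
    la = log_s - log_g  # log-odds of the survivor share
    la_new = la + scale * rng.standard_normal(la.size)
    a_new = special.expit(la_new)
    prop = theta.copy()
    prop[sl_s] = np.log(a_new * n)
    prop[sl_g] = np.log((1.0 - a_new) * n)
    new_state = model.component_state(prop, m)
    if np.log(rng.uniform()) < new_state - cache[("state", m)]:
        theta[sl_s] = prop[sl_s]
        theta[sl_g] = prop[sl_g]
        cache[("state", m)] = new_state
        return True
    return False


def sample_posterior(model: JointModel, settings: MCMCSettings) -> PosteriorDraws:
    """Run the adaptive blocked Metropolis sampler.

    Proposal covariances and scales adapt during the adaptive + burn-in
    sweeps and are frozen for the retained draws, so the recorded chains
    target the exact posterior.  Reproducible given ``settings.seed``.
    """
    blocks = _make_blocks(model)
    L = model.layout
    init_scales_full = np.full(L.dim, 0.1)
    for m in range(model.M):
        init_scales_full[L.sl("log_s", m)] = 0.15
        init_scales_full[L.sl("log_g", m)] = 0.15
        init_scales_full[L.sl("log_iota", m)] = 0.2
    for name in ("log_sigma_omega", "log_sigma_eps", "log_sigma_sta", "log_sigma_p"):
        init_scales_full[L.sl(name)] = 0.2

    total_sweeps = settings.adapt + settings.burnin + settings.draws_per_chain * settings.thin
    keep_from = settings.adapt + settings.burnin
    out = np.empty((settings.chains, settings.draws_per_chain, L.dim))
    root = np.random.SeedSequence(settings.seed)
    chain_seeds = root.spawn(settings.chains)

    for c in range(settings.chains):
        rng = np.random.default_rng(chain_seeds[c])
        theta = model.initial_point()
        theta += 0.05 * init_scales_full * rng.standard_normal(L.dim) * (1 + c)
        states = [_BlockState(b, init_scales_full[b.idx]) for b in blocks]
        vec_scales = {}
        for m in range(model.M):
            for name in UNIT_PARAMS:
                size = L.sl(name, m).stop - L.sl(name, m).start
                if size:
                    vec_scales[(name, m)] = _VectorScale(size)
        swap_scales = [_ScalarScale() for _ in range(model.M)]
        cache = {
            (name, m): model.component(name, theta, m)
            for m in range(model.M)
            for name in model.COMPONENTS
        }
        prior_cur = model.log_prior(theta)
        if not np.isfinite(prior_cur):
            raise RuntimeError("initial point outside the prior support")
        kept = 0
        for sweep in range(total_sweeps):
            adapting = sweep < keep_from
            for b, st in zip(blocks, states):
                prop = theta.copy()
                prop[b.idx] += st.propose(rng)
                new_prior = model.log_prior(prop)
                accepted = False
                if np.isfinite(new_prior):
                    new_comps = {key: model.component(key[0], prop, key[1])
                                 for key in b.comps}
                    delta = new_prior - prior_cur
                    delta += sum(new_comps[k] - cache[k] for k in b.comps)
                    if np.log(rng.uniform()) < delta:
                        theta = prop
                        prior_cur = new_prior
                        cache.update(new_comps)
                        accepted = True
                if adapting:
                    st.adapt_scale(accepted)
                    st.update_moments(theta[b.idx])
                    if sweep >= 100 and sweep % 50 == 0:
                        st.refresh_chol()
            # vectorized unit-level random-effect updates
            if model.include_likelihood:
                prior_cur = _update_unit_effects(
                    model, theta, rng, vec_scales, cache, prior_cur, adapting
                )
            # survivor/recruit split moves along the n-constant direction
            for m in range(model.M):
                for _ in range(3):
                    ok = _split_swap_move(model, theta, rng,
                                          swap_scales[m].scale, cache, m)
                    if adapting:
                        swap_scales[m].adapt(ok)
            if sweep >= keep_from and (sweep - keep_from) % settings.thin == 0:
                if kept < settings.draws_per_chain:
                    out[c, kept] = theta
                    kept += 1
        if not np.isfinite(model.log_posterior(theta)):
            raise RuntimeError(f"chain {c} ended at a non-finite posterior point")

    manifest = {
        "seed": settings.seed,
        "chains": settings.chains,
        "adapt": settings.adapt,
        "burnin": settings.burnin,
        "draws": settings.draws,
        "thin": settings.thin,
        "dim": L.dim,
        "strata": list(model.strata),
        "years": [int(y) for y in model.years],
    }
    return PosteriorDraws(out, L, list(model.strata), model.years, manifest)


def _update_unit_effects(model, theta, rng, vec_scales, cache, prior_cur, adapting):
    """Vectorized Metropolis updates of the unit-level raw random effects.

    Each family (omega, eps, recapture-station, productivity-station) is
    conditionally independent across its units, so proposals for all units
    are evaluated in one vectorized pass and accepted per unit.  The prior
    contribution of a standard-normal raw effect x is -x^2/2.
    """
    L = model.layout
    for m in range(model.M):
        # --- per-cell overdispersion eps ---------------------------------
        sl = L.sl("eps_raw", m)
        if sl.stop > sl.start:
            vs = vec_scales[("eps_raw", m)]
            old = theta[sl].copy()
            new = old + vs.scales * rng.standard_normal(old.size)
            ll_old = model.count_cell_logliks(theta, m)
            ll_new = model.count_cell_logliks(theta, m, eps_raw=new)
            delta = (ll_new - ll_old) + 0.5 * (old**2 - new**2)
            acc = np.log(rng.uniform(size=old.size)) < delta
            theta[sl] = np.where(acc, new, old)
            prior_cur += float(0.5 * np.sum(old[acc] ** 2 - new[acc] ** 2))
            cache[("counts", m)] = float(np.where(acc, ll_new, ll_old).sum())
            if adapting:
                vs.adapt(acc)
        # --- route x observer effects omega ------------------------------
        sl = L.sl("omega_raw", m)
        if sl.stop > sl.start:
            blk = model.count_blocks[m]
            vs = vec_scales[("omega_raw", m)]
            old = theta[sl].copy()
            new = old + vs.scales * rng.standard_normal(old.size)
            ll_old = model.count_cell_logliks(theta, m)
            ll_new = model.count_cell_logliks(theta, m, omega_raw=new)
            d_unit = (
                _segment_sums(ll_new - ll_old, blk.unit_starts)
                + 0.5 * (old**2 - new**2)
            )
            acc = np.log(rng.uniform(size=old.size)) < d_unit
            theta[sl] = np.where(acc, new, old)
            prior_cur += float(0.5 * np.sum(old[acc] ** 2 - new[acc] ** 2))
            cell_acc = acc[blk.unit]
            cache[("counts", m)] = float(np.where(cell_acc, ll_new, ll_old).sum())
            if adapting:
                vs.adapt(acc)
        # --- productivity station effects --------------------------------
        sl = L.sl("sta_prod_raw", m)
        if sl.stop > sl.start:
            blk = model.prod_blocks[m]
            vs = vec_scales[("sta_prod_raw", m)]
            old = theta[sl].copy()
            new = old + vs.scales * rng.standard_normal(old.size)
            ll_old = model.prod_cell_logliks(theta, m)
            ll_new = model.prod_cell_logliks(theta, m, sta_prod_raw=new)
            d_sta = (
                _segment_sums(ll_new - ll_old, blk.station_starts)
                + 0.5 * (old**2 - new**2)
            )
            acc = np.log(rng.uniform(size=old.size)) < d_sta
            theta[sl] = np.where(acc, new, old)
            prior_cur += float(0.5 * np.sum(old[acc] ** 2 - new[acc] ** 2))
            cell_acc = acc[blk.station]
            cache[("prod", m)] = float(np.where(cell_acc, ll_new, ll_old).sum())
            if adapting:
                vs.adapt(acc)
        # --- recapture station effects ------------------------------------
        sl = L.sl("sta_p_raw", m)
        if sl.stop > sl.start:
            blk = model.cjs_blocks[m]
            vs = vec_scales[("sta_p_raw", m)]
            old = theta[sl].copy()
            new = old + vs.scales * rng.standard_normal(old.size)
            ll_old = model.cjs_class_logliks(theta, m)
            ll_new = model.cjs_class_logliks(theta, m, sta_p_raw=new)
            d_sta = (
                _segment_sums(ll_new - ll_old, blk.station_starts)
                + 0.5 * (old**2 - new**2)
            )
            acc = np.log(rng.uniform(size=old.size)) < d_sta
            theta[sl] = np.where(acc, new, old)
            prior_cur += float(0.5 * np.sum(old[acc] ** 2 - new[acc] ** 2))
            cls_acc = acc[blk.cls.station]
            cache[("cjs", m)] = float(np.where(cls_acc, ll_new, ll_old).sum())
            if adapting:
                vs.adapt(acc)
    return prior_cur


@dataclass
class PosteriorDraws:
    """Retained MCMC draws: array (chains, draws_per_chain, dim) plus labels."""

    array: np.ndarray
    layout: ParameterLayout
    strata: list
    years: np.ndarray
    manifest: dict = field(default_factory=dict)

    def get(self, name: str, m=None) -> np.ndarray:
        """Draws of one named parameter, shape (chains, draws, size)."""
        return self.array[..., self.layout.sl(name, m)]

    def flat(self, name: str, m=None) -> np.ndarray:
        """Draws pooled over chains, shape (chains*draws, size)."""
        x = self.get(name, m)
        return x.reshape(-1, x.shape[-1])

    @property
    def n_draws(self) -> int:
        return self.array.shape[0] * self.array.shape[1]

    def write_manifest(self, path) -> None:
        Path(path).write_text(json.dumps(self.manifest, indent=2, default=str))


# ---------------------------------------------------------------------------
# Convergence and summaries
# ---------------------------------------------------------------------------


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction for one scalar parameter.

    Each chain is halved, between- and within-half variances are compared:
    R-hat = sqrt(((n-1)/n * W + B/n) / W).
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 1:
        raise ValueError("need an array (chains, draws)")
    n = c.shape[1] // 2
    if n < 2:
        return np.nan
    halves = np.concatenate([c[:, :n], c[:, n : 2 * n]], axis=0)
    means = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else np.inf
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))




def convergence_check(draws: PosteriorDraws, threshold: float = 1.1,
                      include_unit_effects: bool = False) -> pd.DataFrame:
    """Per-parameter split R-hat; pass iff all monitored values < threshold.

    By default the structural parameters, year effects and latent states
    are monitored; the unit-level raw random effects can be included too.
    Parameters with numerically constant draws are skipped.  Requires at
    least 2 chains; the result's ``attrs['passed']`` carries the verdict.
    """
    arr = draws.array
    if arr.shape[0] < 2:
        raise ValueError("convergence check requires at least 2 chains")
    names = draws.layout.scalar_names()
    skip_prefixes = () if include_unit_effects else UNIT_PARAMS
    rows = []
    for k, name in enumerate(names):
        if name.startswith(skip_prefixes):
            continue
        x = arr[:, :, k]
        if np.ptp(x) < 1e-12:
            continue
        rows.append({"parameter": name, "rhat": split_rhat(x)})
    table = pd.DataFrame(rows)
    table.attrs["passed"] = bool((table["rhat"] < threshold).all()) if len(table) else True
    table.attrs["threshold"] = threshold
    return table


def derive_quantities(draws: PosteriorDraws, model: JointModel) -> dict:
    """Per-draw derived quantities: abundance indices, trends, vital-rate series.

    Returns arrays pooled over chains: ``N`` (draws, M, T) route-level
    abundance indices; ``composite_N`` (draws, T); ``trend`` (draws, M) and
    ``composite_trend`` (draws,), %/year; ``growth`` a per-stratum list of
    :class:`~birdipm.ltre.GrowthSeries` with a leading draw axis; and
    anomaly-scale coefficient draws under ``*_anom`` keys.
    """
    flat = draws.array.reshape(-1, draws.layout.dim)
    L = draws.layout
    n_draws = flat.shape[0]
    M, T = model.M, model.T
    sw = np.exp(flat[:, L.sl("log_sigma_omega")][:, 0])
    se = np.exp(flat[:, L.sl("log_sigma_eps")][:, 0])
    N = np.empty((n_draws, M, T))
    growth = []
    phi_all = np.empty((n_draws, M, T - 1))
    ri_all = np.empty((n_draws, M, T))
    iota_all = np.empty((n_draws, M, T - 1))
    for m in range(M):
        s = np.exp(flat[:, L.sl("log_s", m)])
        g = np.exp(flat[:, L.sl("log_g", m)])
        n = s + g
        N[:, m, :] = model.route_weights[m] * np.exp(
            np.log(n) + 0.5 * sw[:, None] ** 2 + 0.5 * se[:, None] ** 2
        )
        sd_nu = np.exp(flat[:, L.sl("log_sigma_nu", m)])
        lin = (
            flat[:, L.sl("logit_phi0", m)]
            + flat[:, L.sl("beta_cmd", m)] * model.cov_z["cmd"][m, 1:][None, :]
            + flat[:, L.sl("beta_tw", m)] * model.cov_z["tw"][m, 1:][None, :]
            + sd_nu * flat[:, L.sl("nu", m)]
        )
        phi_all[:, m, :] = special.expit(lin)
        sd_yr = np.exp(flat[:, L.sl("log_sigma_yr", m)])
        ri_all[:, m, :] = special.expit(
            flat[:, L.sl("alpha0", m)]
            + flat[:, L.sl("alpha_cmd", m)] * model.cov_z["cmd"][m][None, :]
            + flat[:, L.sl("alpha_temp", m)] * model.cov_z["temp"][m][None, :]
            + sd_yr * flat[:, L.sl("yr", m)]
        )
        iota_all[:, m, :] = np.exp(flat[:, L.sl("log_iota", m)])
        growth.append(
            GrowthSeries(
                phi=phi_all[:, m, :],
                ri=ri_all[:, m, :-1],
                iota=iota_all[:, m, :],
                realized=N[:, m, 1:] / N[:, m, :-1],
            )
        )
    trend = process_model.trend(N.transpose(1, 0, 2)).T  # (draws, M)
    composite_N = np.tensordot(model.area_weights, N, axes=(0, 1))
    composite_trend = process_model.trend(composite_N)
    anom = {}
    for coef, cov in (("beta_cmd", "cmd"), ("beta_tw", "tw"),
                      ("alpha_cmd", "cmd"), ("alpha_temp", "temp")):
        anom[f"{coef}_anom"] = np.stack(
            [flat[:, L.sl(coef, m)][:, 0] / model.cov_sd[cov][m] for m in range(M)],
            axis=1,
        )
    return {
        "N": N,
        "composite_N": composite_N,
        "trend": trend,
        "composite_trend": composite_trend,
        "phi": phi_all,
        "ri": ri_all,
        "iota": iota_all,
        "growth": growth,
        **anom,
    }


def _quants(x: np.ndarray) -> dict:
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)),
        "q2.5": float(np.quantile(x, 0.025)),
        "q50": float(np.quantile(x, 0.5)),
        "q97.5": float(np.quantile(x, 0.975)),
    }


def summarize(draws: PosteriorDraws, model: JointModel) -> pd.DataFrame:
    """Posterior summary table (mean, sd, 2.5/50/97.5 percentiles).

    Probability-scale intercepts, sd hyperparameters, anomaly-scale
    coefficients, per-stratum and composite trends, mean productivity and
    mean survival are all reported; one row per (parameter, stratum,
    year) with stratum/year blank for global quantities.
    """
    q = derive_quantities(draws, model)
    flat = draws.array.reshape(-1, draws.layout.dim)
    L = draws.layout
    rows = []

    def add(name, x, stratum="", year=""):
        rows.append({"parameter": name, "stratum": stratum, "year": year, **_quants(x)})

    add("eta", flat[:, L.sl("eta")][:, 0])
    add("alpha_ef", flat[:, L.sl("alpha_ef")][:, 0])
    for name in ("sigma_omega", "sigma_eps", "sigma_sta", "sigma_p"):
        add(name, np.exp(flat[:, L.sl(f"log_{name}")][:, 0]))
    add("composite_trend", q["composite_trend"])
    for m, s in enumerate(model.strata):
        add("phi0", special.expit(flat[:, L.sl("logit_phi0", m)][:, 0]), s)
        add("mean_phi", q["phi"][:, m, :].mean(axis=1), s)
        add("beta_cmd", flat[:, L.sl("beta_cmd", m)][:, 0], s)
        add("beta_cmd_anom", q["beta_cmd_anom"][:, m], s)
        add("beta_tw", flat[:, L.sl("beta_tw", m)][:, 0], s)
        add("beta_tw_anom", q["beta_tw_anom"][:, m], s)
        add("sigma_nu", np.exp(flat[:, L.sl("log_sigma_nu", m)][:, 0]), s)
        add("pi0", special.expit(flat[:, L.sl("logit_pi0", m)][:, 0]), s)
        add("p0", special.expit(flat[:, L.sl("logit_p0", m)][:, 0]), s)
        add("rho", special.expit(flat[:, L.sl("logit_rho", m)][:, 0]), s)
        add("ri0", special.expit(flat[:, L.sl("alpha0", m)][:, 0]), s)
        add("mean_ri", q["ri"][:, m, :].mean(axis=1), s)
        add("alpha_cmd", flat[:, L.sl("alpha_cmd", m)][:, 0], s)
        add("alpha_cmd_anom", q["alpha_cmd_anom"][:, m], s)
        add("alpha_temp", flat[:, L.sl("alpha_temp", m)][:, 0], s)
        add("alpha_temp_anom", q["alpha_temp_anom"][:, m], s)
        add("sigma_yr", np.exp(flat[:, L.sl("log_sigma_yr", m)][:, 0]), s)
        add("mean_iota", q["iota"][:, m, :].mean(axis=1), s)
        add("mean_gamma", (q["ri"][:, m, :-1] * q["iota"][:, m, :]).mean(axis=1), s)
        add("trend", q["trend"][:, m], s)
        for t, year in enumerate(model.years):
            add("N", q["N"][:, m, t], s, int(year))
    return pd.DataFrame(rows)


def fit_dataset(dataset: ModelDataset, settings: MCMCSettings | None = None,
                priors: PriorSpec | None = None):
    """Convenience wrapper: build the joint model and sample its posterior."""
    model = build_joint_model(dataset, priors=priors)
    draws = sample_posterior(model, settings or MCMCSettings.reduced())
    return model, draws
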