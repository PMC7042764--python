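"""Joint model assembly, MCMC sampler, convergence diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from birdipm import inference as inf
from birdipm import synthetic_data as sd
from birdipm.covariates import CovariateSeries
from birdipm.data_io import AgeCaptureTable, CaptureData, CountDataset, assemble_dataset


def _count_only_dataset(rng, n_units=80, T=2, lam=(6.0, 9.0)):
    """Pure Poisson counts, no observation effects, no CMR or age data."""
    years = np.arange(2000, 2000 + T)
    rows = []
    for i in range(n_units):
        for t, year in enumerate(years):
            rows.append(
                {
                    "route_observer": f"r{i:03d}_o1",
                    "route": f"r{i:03d}",
                    "stratum": "s1",
                    "year": int(year),
                    "count": int(rng.poisson(lam[t % len(lam)])),
                    "novice": 0,
                }
            )
    counts = CountDataset(pd.DataFrame(rows))
    captures = CaptureData(
        pd.DataFrame(columns=["individual", "station", "stratum", "first_year",
                              "resident_observed"]),
        np.zeros((0, T), dtype=int),
        years,
        pd.DataFrame(columns=["station", "stratum", "first_year_operated",
                              "last_year_operated", "years_operated"]),
    )
    ages = AgeCaptureTable(
        pd.DataFrame(columns=["station", "stratum", "year", "n_hy", "n_adult",
                              "effort_net_hours"])
    )
    cov = CovariateSeries(
        pd.DataFrame(
            {"stratum": "s1", "year": years,
             "cmd": rng.standard_normal(T), "tw": rng.standard_normal(T),
             "temp": rng.standard_normal(T)}
        )
    )
    return assemble_dataset(counts, captures, ages, cov)


class TestLayout:
    def test_slices_partition_the_vector(self, reduced_dataset):
        model = inf.build_joint_model(reduced_dataset)
        L = model.layout
        seen = np.zeros(L.dim, dtype=int)
        for sl in L.slices.values():
            seen[sl] += 1
        assert (seen == 1).all()
        assert len(L.scalar_names()) == L.dim

    def test_named_access_round_trip(self, reduced_dataset):
        model = inf.build_joint_model(reduced_dataset)
        L = model.layout
        theta = np.arange(L.dim, dtype=float)
        got = L.get(theta, "log_iota", 0)
        assert got.size == model.T - 1
        assert np.array_equal(got, theta[L.sl("log_iota", 0)])


class TestJointModel:
    def test_posterior_is_prior_plus_component_sum(self, reduced_dataset, rng):
        model = inf.build_joint_model(reduced_dataset)
        theta = model.initial_point() + 0.01 * rng.standard_normal(model.layout.dim)
        total = model.log_prior(theta) + sum(
            model.component(name, theta, m)
            for m in range(model.M)
            for name in model.COMPONENTS
        )
        assert model.log_posterior(theta) == pytest.approx(total)

    def test_removing_cmr_data_decouples_recapture_parameters(self, rng):
        ds = _count_only_dataset(rng)
        model = inf.build_joint_model(ds)
        theta = model.initial_point()
        base = model.log_likelihood(theta)
        bumped = theta.copy()
        bumped[model.layout.sl("logit_p0", 0)] += 1.3
        bumped[model.layout.sl("logit_rho", 0)] -= 0.7
        assert model.log_likelihood(bumped) == pytest.approx(base)

    def test_likelihood_invariant_to_record_order(self, reduced_sim, rng):
        ds1 = reduced_sim.assemble()
        shuffled = reduced_sim.counts.records.sample(frac=1.0, random_state=3)
        ds2 = assemble_dataset(
            CountDataset(shuffled), reduced_sim.captures, reduced_sim.ages,
            reduced_sim.covariates, reduced_sim.meta,
        )
        m1 = inf.build_joint_model(ds1)
        m2 = inf.build_joint_model(ds2)
        # at a point with all raw unit effects at zero the cell order is irrelevant
        theta = m1.initial_point()
        assert m1.log_posterior(theta) == pytest.approx(
            m2.log_posterior(m2.initial_point())
        )

    def test_out_of_support_point_is_rejected(self, reduced_dataset):
        model = inf.build_joint_model(reduced_dataset)
        theta = model.initial_point()
        theta[model.layout.sl("log_sigma_nu", 0)] = np.log(25.0)  # above U(0,10)
        assert model.log_posterior(theta) == -np.inf


class TestSplitRhat:
    def test_well_mixed_chains_near_one(self, rng):
        chains = rng.standard_normal((4, 1000))
        assert inf.split_rhat(chains) < 1.05

    def test_shifted_chains_flagged(self, rng):
        chains = rng.standard_normal((2, 500)) + np.array([[0.0], [3.0]])
        assert inf.split_rhat(chains) > 1.1

    def test_matches_reference_implementation(self, rng):
        arviz = pytest.importorskip("arviz")
        x = rng.standard_normal((4, 600)) + rng.normal(0, 0.2, (4, 1))
        ours = inf.split_rhat(x)
        ref = arviz.rhat(arviz.convert_to_dataset(x[:, :, None]),
                         method="split")["x"].values.item()
        assert ours == pytest.approx(ref, abs=1e-8)

    def test_single_chain_rejected(self, rng):
        draws = inf.PosteriorDraws(
            rng.standard_normal((1, 50, 4)), inf.ParameterLayout(0, 2), [], np.arange(2)
        )
        with pytest.raises(ValueError, match="2 chains"):
            inf.convergence_check(draws)


class TestSampler:
    def test_same_seed_reproduces_draws_exactly(self, rng):
        ds = _count_only_dataset(rng, n_units=25)
        model = inf.build_joint_model(ds)
        settings = inf.MCMCSettings.reduced(seed=5, chains=2, adapt=120,
                                            burnin=60, draws=80)
        a = inf.sample_posterior(model, settings)
        b = inf.sample_posterior(model, settings)
        assert np.array_equal(a.array, b.array)

    def test_conjugate_toy_recovers_poisson_mean(self, rng):
        # with flat effects the stratum index posterior is approximately the
        # Gamma(sum y + 1, n_units) conjugate posterior of a Poisson mean
        ds = _count_only_dataset(rng, n_units=80, T=2, lam=(6.0, 9.0))
        model = inf.build_joint_model(ds)
        settings = inf.MCMCSettings.reduced(seed=2, chains=2, adapt=1200,
                                            burnin=600, draws=2400)
        draws = inf.sample_posterior(model, settings)
        s = np.exp(draws.flat("log_s", 0))
        g = np.exp(draws.flat("log_g", 0))
        n_post = (s + g).mean(axis=0)
        rec = ds.counts.records
        for t, year in enumerate(ds.years):
            y = rec.loc[rec["year"] == year, "count"]
            gamma_mean = (y.sum() + 1) / len(y)
            assert n_post[t] == pytest.approx(gamma_mean, rel=0.05)

    def test_prior_predictive_marginals_match_priors(self, reduced_sim):
        # with the data likelihoods removed, MCMC over the full joint
        # (including latent trajectories) must return the bare priors for
        # phi0 ~ U(0,1) and iota ~ truncNormal(1, 10) marginals
        # a near-zero population keeps the process transitions from tightly
        # coupling the rates to the latent trajectories, so the prior
        # marginals can be explored quickly
        sc = sd.reduced_scenario(n_years=3, n_routes=(6,), n_stations=(3,),
                                 initial_population=(2,), route_scaling=(2.0,),
                                 new_marked_per_station_year=(2.0,),
                                 age_captures_per_station_year=(2.0,))
        ds = sd.simulate_dataset(sc, 3).assemble()
        model = inf.build_joint_model(ds, include_likelihood=False)
        settings = inf.MCMCSettings.reduced(seed=9, chains=2, adapt=3000,
                                            burnin=1000, draws=8000)
        draws = inf.sample_posterior(model, settings)
        from scipy.special import expit

        phi0 = expit(draws.flat("logit_phi0", 0)[:, 0])
        d_phi = stats.kstest(phi0, "uniform").statistic
        assert d_phi < 0.1
        iota = np.exp(draws.flat("log_iota", 0)[:, 0])
        a = (0 - 1.0) / 10.0
        d_iota = stats.kstest(iota, stats.truncnorm(a, np.inf, loc=1, scale=10).cdf).statistic
        assert d_iota < 0.1


class TestSummaries:
    def test_symmetric_draws_mean_equals_median(self):
        x = np.concatenate([np.linspace(-3, 3, 501)])
        q = inf._quants(x)
        assert q["mean"] == pytest.approx(q["q50"])

    def test_quantiles_match_sorted_positions(self, rng):
        x = rng.standard_normal(4001)
        q = inf._quants(x)
        assert q["q2.5"] == pytest.approx(np.sort(x)[int(0.025 * 4000)], abs=0.02)
        assert q["q97.5"] == pytest.approx(np.sort(x)[int(0.975 * 4000)], abs=0.02)

    def test_per_draw_trend_recomputed_from_abundance(self, reduced_dataset, rng):
        model = inf.build_joint_model(reduced_dataset)
        settings = inf.MCMCSettings.reduced(seed=4, chains=2, adapt=150,
                                            burnin=60, draws=100)
        draws = inf.sample_posterior(model, settings)
        q = inf.derive_quantities(draws, model)
        from birdipm.process_model import trend

        for k in (0, 10, -1):
            assert q["trend"][k, 0] == pytest.approx(trend(q["N"][k, 0, :]))
        lam = q["N"][:, 0, 1:] / q["N"][:, 0, :-1]
        assert np.allclose(q["growth"][0].realized, lam)
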