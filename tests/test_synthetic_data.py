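"""The synthetic-data generator: reproducibility, validity, moment checks."""

import warnings

import numpy as np
import pandas as pd
import pytest

from birdipm import synthetic_data as sd


class TestReproducibility:
    def test_same_seed_bitwise_identical(self):
        a = sd.simulate_dataset(sd.reduced_scenario(), 99)
        b = sd.simulate_dataset(sd.reduced_scenario(), 99)
        pd.testing.assert_frame_equal(a.counts.records, b.counts.records)
        assert np.array_equal(a.captures.detections, b.captures.detections)
        pd.testing.assert_frame_equal(a.ages.rows, b.ages.rows)
        assert np.array_equal(a.truth["n"], b.truth["n"])

    def test_different_seeds_differ(self):
        a = sd.simulate_dataset(sd.reduced_scenario(), 1)
        b = sd.simulate_dataset(sd.reduced_scenario(), 2)
        assert not np.array_equal(a.truth["n"], b.truth["n"])


class TestValidity:
    def test_generated_dataset_passes_all_validation(self, reduced_sim):
        ds = reduced_sim.assemble()  # raises on any invariant violation
        assert ds.n_strata == 1 and ds.n_years == 17

    def test_table1_dataset_passes_validation(self):
        sim = sd.simulate_dataset(sd.table1_scenario(), 5)
        ds = sim.assemble()
        assert ds.n_strata == 3
        routes = ds.summary["n_routes"]
        assert (routes["pnw"], routes["sne"], routes["cca"]) == (148, 58, 21)


class TestCovariates:
    def test_white_series_has_low_autocorrelation(self, rng):
        cov = sd.simulate_covariates(sd.reduced_scenario(), rng)
        x = cov.frame["cmd"].to_numpy()
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) < 0.45  # T=17 null sampling band

    def test_long_series_standard_moments(self, rng):
        sc = sd.reduced_scenario(n_years=10_000)
        cov = sd.simulate_covariates(sc, rng)
        x = cov.frame["temp"].to_numpy()
        assert abs(x.mean()) < 0.02 and abs(x.std() - 1.0) < 0.02

    def test_ar1_series_is_autocorrelated(self, rng):
        sc = sd.reduced_scenario(n_years=2_000, covariate_ar1=0.7)
        cov = sd.simulate_covariates(sc, rng)
        x = cov.frame["tw"].to_numpy()
        assert np.corrcoef(x[:-1], x[1:])[0, 1] == pytest.approx(0.7, abs=0.06)
        assert abs(x.std() - 1.0) < 0.1  # marginal variance preserved


class TestPopulation:
    def test_closed_population_is_constant(self, rng):
        sc = sd.reduced_scenario(
            phi0=(1 - 1e-12,), sigma_nu=(1e-9,), beta_cmd=(0.0,), beta_tw=(0.0,),
            ri0=(1e-12,), iota_mean=(1e-12,), iota_log_sd=(1e-9,),
            alpha_cmd=(0.0,), alpha_temp=(0.0,), sigma_yr=(1e-9,),
        )
        cov = sd.simulate_covariates(sc, rng)
        truth = sd.simulate_population(sc, cov, rng)
        assert np.all(truth["n"][0] == sc.initial_population[0])

    def test_certain_death_extinction_at_second_step(self, rng):
        sc = sd.reduced_scenario(
            phi0=(1e-12,), sigma_nu=(1e-9,), beta_cmd=(0.0,), beta_tw=(0.0,),
            ri0=(1e-12,), iota_mean=(1e-12,), iota_log_sd=(1e-9,),
            alpha_cmd=(0.0,), alpha_temp=(0.0,), sigma_yr=(1e-9,),
        )
        cov = sd.simulate_covariates(sc, rng)
        with pytest.warns(UserWarning, match="extinct"):
            truth = sd.simulate_population(sc, cov, rng)
        assert np.all(truth["n"][0][1:] == 0)

    def test_mean_growth_matches_vital_rates(self, rng):
        # many replicates at moderate n: realized growth ~ phi + RI * iota
        sc = sd.reduced_scenario(
            n_years=2, initial_population=(500,), sigma_nu=(1e-6,),
            sigma_yr=(1e-6,), iota_log_sd=(1e-6,),
            beta_cmd=(0.0,), beta_tw=(0.0,), alpha_cmd=(0.0,), alpha_temp=(0.0,),
        )
        lam_expected = sc.phi0[0] + sc.ri0[0] * sc.iota_mean[0]
        growths = []
        for _ in range(1000):
            cov = sd.simulate_covariates(sc, rng)
            truth = sd.simulate_population(sc, cov, rng)
            growths.append(truth["n"][0, 1] / truth["n"][0, 0])
        se = np.std(growths) / np.sqrt(len(growths))
        assert np.mean(growths) == pytest.approx(lam_expected, abs=4 * se + 1e-3)


class TestCounts:
    def test_no_observation_effects_is_plain_poisson(self, rng):
        sc = sd.reduced_scenario(sigma_omega=1e-9, sigma_eps=1e-9, eta=0.0,
                                 n_routes=(300,))
        cov = sd.simulate_covariates(sc, rng)
        truth = sd.simulate_population(sc, cov, rng)
        counts = sd.simulate_counts(truth, sc, rng)
        rec = counts.records
        disp = []
        for year, grp in rec.groupby("year"):
            if grp["count"].mean() > 0:
                disp.append(grp["count"].var() / grp["count"].mean())
        assert np.mean(disp) == pytest.approx(1.0, abs=0.15)

    def test_overdispersion_raises_variance(self, rng):
        sc = sd.reduced_scenario(sigma_omega=1e-9, sigma_eps=0.5, eta=0.0,
                                 n_routes=(300,))
        cov = sd.simulate_covariates(sc, rng)
        truth = sd.simulate_population(sc, cov, rng)
        counts = sd.simulate_counts(truth, sc, rng)
        rec = counts.records
        disp = [g["count"].var() / g["count"].mean()
                for _, g in rec.groupby("year") if g["count"].mean() > 0]
        assert np.mean(disp) > 1.5

    def test_mean_counts_track_scaled_population(self, reduced_sim):
        sc = reduced_sim.truth["scenario"]
        rec = reduced_sim.counts.records
        dens = reduced_sim.truth["n"][0] / sc.route_scaling[0]
        by_year = rec.groupby("year")["count"].mean().to_numpy()
        # correlation across 17 years between density and mean count
        assert np.corrcoef(dens, by_year)[0, 1] > 0.9

    def test_novice_years_exist_and_flags_valid(self, reduced_sim):
        rec = reduced_sim.counts.records
        assert rec["novice"].sum() > 40  # turnover happened beyond year one


class TestCaptureHistories:
    def test_deterministic_limit_every_year_recaptured(self, rng):
        sc = sd.reduced_scenario(
            pi0=(1 - 1e-12,), sigma_pi=(1e-9,), p0=(1 - 1e-12,), sigma_p_sta=1e-9,
            phi0=(1 - 1e-12,), sigma_nu=(1e-9,), beta_cmd=(0.0,), beta_tw=(0.0,),
            n_stations=(3,), new_marked_per_station_year=(2.0,),
        )
        cov = sd.simulate_covariates(sc, rng)
        truth = sd.simulate_population(sc, cov, rng)
        cap = sd.simulate_cmr(truth, sc, rng)
        first = np.argmax(cap.detections == 1, axis=1)
        for j in range(cap.n_individuals):
            assert cap.detections[j, first[j]:].all()

    def test_all_transients_are_never_recaptured(self, rng):
        sc = sd.reduced_scenario(pi0=(1e-12,), sigma_pi=(1e-9,),
                                 n_stations=(5,))
        cov = sd.simulate_covariates(sc, rng)
        truth = sd.simulate_population(sc, cov, rng)
        cap = sd.simulate_cmr(truth, sc, rng)
        first = np.argmax(cap.detections == 1, axis=1)
        for j in range(cap.n_individuals):
            assert cap.detections[j, first[j] + 1:].sum() == 0
        assert cap.individuals["resident_observed"].sum() == 0

    def test_magnitudes_match_monitoring_program_scale(self):
        # thousands of individuals, hundreds of recaptures per stratum
        sim = sd.simulate_dataset(sd.table1_scenario(), 11)
        ds = sim.assemble()
        inds = ds.summary["n_individuals"]
        recs = ds.summary["n_recaptures"]
        for stratum, expected in [("pnw", 3781), ("sne", 2595), ("cca", 4424)]:
            assert 0.5 * expected <= inds[stratum] <= 1.5 * expected
        for stratum, expected in [("pnw", 483), ("sne", 408), ("cca", 401)]:
            assert 0.5 * expected <= recs[stratum] <= 1.5 * expected


class TestAgeCaptures:
    def test_symmetric_model_gives_half_hatch_year(self, rng):
        sc = sd.reduced_scenario(
            ri0=(0.5,), alpha_ef=0.0, alpha_cmd=(0.0,), alpha_temp=(0.0,),
            sigma_yr=(1e-9,), sigma_sta=1e-9, n_stations=(40,),
            age_captures_per_station_year=(30.0,),
        )
        cov = sd.simulate_covariates(sc, rng)
        truth = sd.simulate_population(sc, cov, rng)
        ages = sd.simulate_age_captures(truth, sc, rng)
        frac = ages.rows["n_hy"].sum() / (ages.rows["n_hy"] + ages.rows["n_adult"]).sum()
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_temperature_effect_recovered_by_regression(self, rng):
        sc = sd.reduced_scenario(alpha_temp=(0.27,), sigma_yr=(1e-9,),
                                 sigma_sta=1e-9, alpha_ef=0.0,
                                 n_stations=(60,), age_captures_per_station_year=(40.0,))
        cov = sd.simulate_covariates(sc, rng)
        truth = sd.simulate_population(sc, cov, rng)
        ages = sd.simulate_age_captures(truth, sc, rng)
        merged = ages.rows.merge(cov.frame, on=["stratum", "year"])
        by_year = merged.groupby("temp").apply(
            lambda g: g["n_hy"].sum() / (g["n_hy"] + g["n_adult"]).sum(),
            include_groups=False,
        )
        slope = np.polyfit(by_year.index, np.log(by_year / (1 - by_year)), 1)[0]
        assert 0.1 < slope < 0.45

    def test_zero_capture_rate_boundary(self, rng):
        sc = sd.reduced_scenario(age_captures_per_station_year=(0.0,))
        cov = sd.simulate_covariates(sc, rng)
        truth = sd.simulate_population(sc, cov, rng)
        ages = sd.simulate_age_captures(truth, sc, rng)
        assert (ages.rows["n_hy"] + ages.rows["n_adult"]).sum() == 0
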