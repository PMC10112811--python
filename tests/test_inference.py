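"""Likelihood correctness, MCMC contracts, and parameter recovery."""

import math

import numpy as np
import pytest

import allospeed as ap
from allospeed import LocomotionMode
from allospeed.exceptions import ConfigurationError
from conftest import make_single_mode_config

TRUTH = {
    "v0[flying]": 30.54,
    "v0[running]": 0.28,
    "v0[swimming]": 0.39,
    "k_lambda": 0.033,
    "c": 0.27,
    "d": 0.24,
    "sigma": 0.3,
}


class TestPointwiseLogLikelihood:
    def test_on_curve_record_attains_gaussian_mode_density(self):
        spec = ap.ModelSpec()
        params = ap.reference_parameters(sigma=0.25)
        speed = ap.realised_speed(spec, 12.0, "running", params)
        record = ap.SpeedRecord("sp", 12.0, speed, "running")
        (ll,) = ap.pointwise_log_likelihood(spec, params, [record])
        assert ll == pytest.approx(-math.log(0.25 * math.sqrt(2 * math.pi)), abs=1e-12)

    def test_sum_matches_bruteforce_oracle(self):
        spec = ap.ModelSpec()
        params = ap.reference_parameters(sigma=0.3)
        records = ap.generate_dataset(ap.default_empirical_emulation(seed=8))[:100]
        total = ap.pointwise_log_likelihood(spec, params, records).sum()
        # independent oracle: per-record scalar arithmetic, no shared code path
        oracle = 0.0
        for r in records:
            m, v0, k, c, d = r.mass, params.v0_for(r.mode), 0.033, 0.27, 0.24
            f = (1.0 / k) * m**c / (m ** (c + d) + 1.0 / (v0 * k))
            z = (math.log10(r.speed) - math.log10(f)) / 0.3
            oracle += -0.5 * z * z - math.log(0.3) - 0.5 * math.log(2 * math.pi)
        assert total == pytest.approx(oracle, rel=1e-10)

    def test_doubling_sigma_shifts_density_analytically(self):
        spec = ap.ModelSpec()
        p1 = ap.reference_parameters(sigma=0.2)
        p2 = ap.reference_parameters(sigma=0.4)
        records = ap.generate_dataset(make_single_mode_config(n=20, seed=3))
        ll1 = ap.pointwise_log_likelihood(spec, p1, records)
        ll2 = ap.pointwise_log_likelihood(spec, p2, records)
        # r^2/(2 s^2) terms: ll2 - ll1 = -ln 2 + (3/4) r^2 / (2 s1^2)
        mu = np.array(
            [ap.log10_realised_speed(spec, r.mass, r.mode, p1) for r in records]
        )
        r2 = (np.log10([r.speed for r in records]) - mu) ** 2
        expected = -math.log(2) + 0.75 * r2 / (2 * 0.2**2)
        np.testing.assert_allclose(ll2 - ll1, expected, rtol=1e-10)


class TestFitContracts:
    def test_default_protocol_retains_9000_converged_draws(self, default_fit):
        assert default_fit.n_draws == 9000
        assert all(r <= 1.01 for r in default_fit.rhat.values())
        assert all(e > 1000 for e in default_fit.ess.values())
        assert default_fit.converged

    def test_posterior_covers_truth(self, default_fit):
        for name, true_value in TRUTH.items():
            lo, hi = default_fit.credible_interval(name, 0.9)
            assert lo < hi
            # sanity on the shared fit; the replicate-based coverage claim
            # lives in the acceptance suite
            assert lo * 0.5 < true_value < hi * 2

    def test_near_noise_free_recovery_within_one_percent(self, light_mcmc):
        config = ap.SimulationConfig(
            true_spec=ap.ModelSpec(),
            true_params=ap.reference_parameters(sigma=1e-6),
            n_per_mode={m: 100 for m in LocomotionMode},
            mass_range_log10={
                LocomotionMode.FLYING: (-10, 1.2),
                LocomotionMode.RUNNING: (-9, 4),
                LocomotionMode.SWIMMING: (-6, 5.15),
            },
            seed=5,
        )
        records = ap.generate_dataset(config)
        result = ap.fit(ap.ModelSpec(), records, mcmc=light_mcmc)
        means = result.means()
        for name, true_value in TRUTH.items():
            if name == "sigma":
                continue
            assert means[name] == pytest.approx(true_value, rel=0.01), name

    def test_empty_or_thin_mode_stratum_rejected(self):
        records = ap.generate_dataset(make_single_mode_config(n=10, seed=1))
        lone_flyer = ap.SpeedRecord("f", 0.1, 8.0, "flying")
        with pytest.raises(ConfigurationError, match="flying"):
            ap.fit(ap.ModelSpec(), records + [lone_flyer])
        with pytest.raises(ConfigurationError):
            ap.fit(ap.ModelSpec(), [])

    def test_record_order_does_not_change_posterior(self, light_mcmc):
        records = ap.generate_dataset(make_single_mode_config(n=120, seed=31))
        rng = np.random.default_rng(0)
        shuffled = list(records)
        rng.shuffle(shuffled)
        a = ap.fit(ap.ModelSpec(), records, mcmc=light_mcmc)
        b = ap.fit(ap.ModelSpec(), shuffled, mcmc=light_mcmc)
        # distributional equality within Monte-Carlo error
        for name in a.param_names:
            xa, xb = a.flat(name), b.flat(name)
            mcse = math.hypot(
                xa.std() / math.sqrt(a.ess[name]), xb.std() / math.sqrt(b.ess[name])
            )
            assert abs(xa.mean() - xb.mean()) < 4 * mcse, name

    def test_metabolic_fit_to_hump_data_misfits_systematically(
        self, default_dataset, light_mcmc
    ):
        # a power law through hump-shaped data: residuals positive at mid
        # masses, negative at the extremes
        spec = ap.ModelSpec(kind="metabolic")
        result = ap.fit(spec, default_dataset, mcmc=light_mcmc)
        params = result.parameter_set()
        resid = np.array(
            [
                np.log10(r.speed)
                - ap.log10_realised_speed(spec, r.mass, r.mode, params)
                for r in default_dataset
            ]
        )
        log_mass = np.array([np.log10(r.mass) for r in default_dataset])
        modes = np.array([r.mode.value for r in default_dataset])
        mid_means, extreme_means = [], []
        for mode in np.unique(modes):
            sel = modes == mode
            lo, hi = np.quantile(log_mass[sel], [1 / 3, 2 / 3])
            mid = sel & (log_mass >= lo) & (log_mass <= hi)
            ext = sel & ~((log_mass >= lo) & (log_mass <= hi))
            mid_means.append(resid[mid].mean())
            extreme_means.append(resid[ext].mean())
        assert np.mean(mid_means) > 0 > np.mean(extreme_means)


class TestPosteriorResult:
    def test_export_shapes(self, default_fit):
        frame = default_fit.to_dataframe()
        assert len(frame) == default_fit.n_draws
        assert set(default_fit.param_names) <= set(frame.columns)
        idata = default_fit.to_inference_data()
        assert "posterior" in idata.groups()
        assert idata.log_likelihood["log10_speed"].shape[-1] == default_fit.n_obs

    def test_parameter_set_roundtrip(self, default_fit):
        params = default_fit.parameter_set()
        v = ap.realised_speed(ap.ModelSpec(), 100.0, "running", params)
        assert 0.1 < v < 10.0


class TestCalibration:
    def test_simulation_based_calibration_ranks_uniform(self):
        """Reduced-replicate SBC: fitting data drawn from the prior keeps the
        rank of the truth uniform among posterior draws."""
        mode = LocomotionMode.RUNNING
        spec = ap.ModelSpec()
        mcmc = ap.McmcConfig(chains=2, warmup_iterations=800, sampling_iterations=800, seed=0)
        rng = np.random.default_rng(2024)
        n_reps, n_obs = 16, 30
        ranks = {name: [] for name in ["v0[running]", "k_lambda", "c", "d", "sigma"]}
        for rep in range(n_reps):
            truth = ap.ParameterSet(
                v0={mode: rng.gamma(1.0, 100.0)},
                k_lambda=rng.gamma(1.0, 1.0),
                c=abs(rng.normal(0, 1.0)),
                d=abs(rng.normal(0, 1.0)),
                sigma=abs(2.5 * rng.standard_cauchy()),
            )
            config = ap.SimulationConfig(
                true_spec=spec,
                true_params=truth,
                n_per_mode={mode: n_obs},
                mass_range_log10={mode: (-6.0, 4.0)},
                seed=int(rng.integers(2**31 - 1)),
            )
            records = ap.generate_dataset(config)
            result = ap.fit(
                spec,
                records,
                mcmc=ap.McmcConfig(
                    chains=2,
                    warmup_iterations=mcmc.warmup_iterations,
                    sampling_iterations=mcmc.sampling_iterations,
                    seed=rep,
                ),
            )
            true_by_name = {
                "v0[running]": truth.v0_for(mode),
                "k_lambda": truth.k_for(spec, ap.Realm.TERRESTRIAL),
                "c": truth.c_for(mode),
                "d": truth.d,
                "sigma": truth.sigma,
            }
            for name, true_value in true_by_name.items():
                draws = result.flat(name)[::16]  # thin against autocorrelation
                ranks[name].append((draws < true_value).mean())
        from scipy import stats

        for name, r in ranks.items():
            assert stats.kstest(r, "uniform").pvalue > 0.01, name
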