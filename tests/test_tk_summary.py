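"""Posterior summaries, derived kinetics, HK_AF, predicted-vs-observed."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from citpoptk.mcmc_engine import PosteriorSamples, SamplerConfig
from citpoptk.pop_likelihood import Subject, TrialDataset, default_limits
from citpoptk.synthetic_trial import (
    TrialDesign,
    central_params,
    default_population,
    generate_observations,
    generate_population,
)
from citpoptk.tk_model import TKParams, derive_rates
from citpoptk.tk_summary import (
    DEFAULT_TK_FACTOR,
    UnconvergedError,
    compute_hkaf,
    derived_tk_posterior,
    deterministic_simulation,
    gsd_auc_posterior,
    posterior_median_params,
    predicted_vs_observed,
    summarize_population,
)


def build_samples(draws_dict, n_chains=2):
    """PosteriorSamples from {name: (n_chains, n_draws) array}."""
    names = list(draws_dict)
    arrs = [np.asarray(draws_dict[n], float) for n in names]
    draws = np.stack(arrs, axis=-1)
    return PosteriorSamples(
        draws=draws,
        names=names,
        n_burn_stored=0,
        accept_rate=np.ones((draws.shape[0], draws.shape[2])),
        scales=np.ones(draws.shape[2]),
        scale_history=np.ones((draws.shape[0], 1, draws.shape[2])),
        config=SamplerConfig(n_chains=n_chains, n_iter=draws.shape[1]),
    )


def population_draws(rng, n=2000, mu_sd=0.1, subjects=(), theta_sd=0.1):
    """Synthetic population-level draws centred on the trial centrals."""
    centrals = np.log(central_params().as_array())
    lnvar_c = math.log(math.log(1.5) ** 2)
    out = {}
    for i, p in enumerate(TKParams.names):
        out[f"mu_{p}"] = centrals[i] + mu_sd * rng.standard_normal((2, n))
        out[f"lnvar_{p}"] = lnvar_c + 0.05 * rng.standard_normal((2, n))
    out["ln_err_gsd_blood"] = math.log(1.2) + 0.01 * rng.standard_normal((2, n))
    out["ln_err_gsd_urine"] = math.log(1.2) + 0.01 * rng.standard_normal((2, n))
    for sid in subjects:
        for i, p in enumerate(TKParams.names):
            out[f"ln_{p}[{sid}]"] = centrals[i] + theta_sd * rng.standard_normal(
                (2, n)
            )
    return out


class TestSummarizePopulation:
    def test_degenerate_draws_collapse_interval(self):
        rng = np.random.default_rng(0)
        draws = population_draws(rng, n=200, mu_sd=0.0)
        table = summarize_population(build_samples(draws))
        row = table.set_index("parameter").loc["Cl_tot"]
        assert row.GM_median == pytest.approx(0.04)
        assert row.GM_lo90 == pytest.approx(row.GM_hi90)

    def test_normal_draws_match_closed_form_quantiles(self):
        rng = np.random.default_rng(1)
        draws = population_draws(rng, n=25_000, mu_sd=0.1)
        for p in TKParams.names:
            draws[f"mu_{p}"] -= np.log(central_params().as_array())[
                TKParams.names.index(p)
            ]
        table = summarize_population(build_samples(draws))
        row = table.set_index("parameter").loc["Cl_tot"]
        se = 0.1 * math.sqrt(math.pi / (2 * 50_000))
        assert row.GM_median == pytest.approx(1.0, abs=3 * math.exp(se) - 3 + 0.01)
        assert row.GM_lo90 == pytest.approx(math.exp(-1.6449 * 0.1), rel=0.02)
        assert row.GM_hi90 == pytest.approx(math.exp(1.6449 * 0.1), rel=0.02)

    def test_one_row_per_population_parameter(self):
        rng = np.random.default_rng(2)
        table = summarize_population(build_samples(population_draws(rng, n=100)))
        assert list(table["parameter"]) == list(TKParams.names) + [
            "err_gsd_blood", "err_gsd_urine",
        ]

    def test_unconverged_draws_refused_without_force(self):
        rng = np.random.default_rng(3)
        draws = population_draws(rng, n=200)
        draws["mu_Cl_tot"][1] += 5.0  # chains disagree wildly
        samples = build_samples(draws)
        with pytest.raises(UnconvergedError, match="mu_Cl_tot"):
            summarize_population(samples)
        assert summarize_population(samples, force=True) is not None


class TestDerivedTKPosterior:
    def test_zero_variability_gives_unit_auc_gsd(self):
        rng = np.random.default_rng(4)
        draws = population_draws(rng, n=300, subjects=["S01", "S02", "S03"],
                                 theta_sd=0.0)
        table = derived_tk_posterior(build_samples(draws), dose_per_kg=1500.0)
        row = table.set_index("quantity").loc["AUC_inf"]
        assert row.GSD_median == pytest.approx(1.0)

    def test_half_life_is_ln2_over_elimination_rate(self):
        rng = np.random.default_rng(5)
        draws = population_draws(rng, n=300, subjects=["S01", "S02"],
                                 theta_sd=0.0)
        table = derived_tk_posterior(build_samples(draws)).set_index("quantity")
        k_el = derive_rates(central_params()).k_el
        assert table.loc["t_half"].GM_median == pytest.approx(
            math.log(2) / k_el, rel=1e-9
        )
        assert table.loc["k_el"].GM_median == pytest.approx(k_el, rel=1e-9)

    def test_auc_gsd_matches_lognormal_ratio_closed_form(self):
        # independent lognormal F and Cl across many subjects:
        # GSD_AUC -> exp(sqrt(ln^2 gF + ln^2 gCl))
        rng = np.random.default_rng(6)
        sids = [f"S{i:03d}" for i in range(400)]
        draws = population_draws(rng, n=30, subjects=sids, theta_sd=0.0)
        g_f, g_cl = 1.3, 1.4
        for sid in sids:
            draws[f"ln_F_gutabs[{sid}]"] += math.log(g_f) * rng.standard_normal()
            draws[f"ln_Cl_tot[{sid}]"] += math.log(g_cl) * rng.standard_normal()
        gsd = gsd_auc_posterior(build_samples(draws))
        expected = math.exp(
            math.sqrt(math.log(g_f) ** 2 + math.log(g_cl) ** 2)
        )
        assert gsd == pytest.approx(expected, rel=0.1)

    def test_population_method_uses_variance_draws(self):
        rng = np.random.default_rng(7)
        draws = population_draws(rng, n=500, subjects=["S01", "S02"])
        for p in ("F_gutabs", "Cl_tot"):
            draws[f"lnvar_{p}"][:] = math.log(math.log(1.5) ** 2)
        gsd = gsd_auc_posterior(build_samples(draws), method="population")
        expected = math.exp(math.sqrt(2) * math.log(1.5))
        assert gsd == pytest.approx(expected, rel=1e-6)

    def test_single_subject_gsd_undefined(self):
        rng = np.random.default_rng(8)
        draws = population_draws(rng, n=100, subjects=["S01"])
        with pytest.raises(ValueError, match="2 subjects"):
            derived_tk_posterior(build_samples(draws))


class TestComputeHkaf:
    def test_reported_adjustment_factor_from_auc_gsd(self):
        result = compute_hkaf(1.49)
        assert round(result.hk_af, 2) == pytest.approx(1.93, abs=0.005)
        assert result.hk_af == pytest.approx(1.49 ** norm.ppf(0.95), rel=1e-12)
        assert result.z == pytest.approx(1.6449, abs=5e-5)

    def test_no_variability_gives_unit_factor(self):
        assert compute_hkaf(1.0).hk_af == pytest.approx(1.0)

    def test_euler_gsd_arithmetic(self):
        result = compute_hkaf(math.e)
        assert result.hk_af == pytest.approx(math.e ** norm.ppf(0.95), rel=1e-12)
        assert result.hk_af == pytest.approx(5.1805, abs=5e-4)

    def test_default_factor_is_sqrt_ten(self):
        assert DEFAULT_TK_FACTOR == pytest.approx(math.sqrt(10.0))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_hkaf(0.9)
        with pytest.raises(ValueError):
            compute_hkaf(1.5, p=1.5)

    def test_strictly_increasing_in_gsd_and_percentile(self):
        grid = [1.0, 1.2, 1.5, 2.0, 3.0]
        values = [compute_hkaf(g).hk_af for g in grid]
        assert all(a < b for a, b in zip(values, values[1:]))
        p_grid = [0.8, 0.9, 0.95, 0.99]
        values_p = [compute_hkaf(1.5, p).hk_af for p in p_grid]
        assert all(a < b for a, b in zip(values_p, values_p[1:]))


class TestPredictedVsObserved:
    def make_selfconsistent_case(self):
        """Noiseless data generated from the exact posterior medians."""
        rng = np.random.default_rng(9)
        design = TrialDesign(n_subjects=2)
        pop = default_population(gsd=1.3)
        subjects, truth = generate_population(design, pop, seed=10)
        from citpoptk.pop_likelihood import MatrixLimits, QuantLimits

        wide = QuantLimits(
            blood=MatrixLimits(1e-12, 1e-11, 1e12),
            urine=MatrixLimits(1e-12, 1e-11, 1e12),
        )
        data = generate_observations(
            subjects, truth, design, limits=wide,
            err_gsd_blood=1.0 + 1e-12, err_gsd_urine=1.0 + 1e-12,
            seed=10, include_fecal=False,
        )
        draws = population_draws(rng, n=50, subjects=[], theta_sd=0.0)
        for sid, theta in truth.params.items():
            for i, p in enumerate(TKParams.names):
                draws[f"ln_{p}[{sid}]"] = np.full(
                    (2, 50), math.log(theta.as_array()[i])
                )
        return data, build_samples(draws)

    def test_noiseless_data_fall_on_identity_line(self):
        data, samples = self.make_selfconsistent_case()
        pairs, stats = predicted_vs_observed(samples, data)
        np.testing.assert_allclose(
            pairs["predicted"], pairs["observed"], rtol=1e-6
        )
        for _, row in stats.iterrows():
            assert row.slope == pytest.approx(1.0, rel=1e-6)
            assert row.r2_identity == pytest.approx(1.0, abs=1e-9)

    def test_censored_rows_excluded(self):
        data, samples = self.make_selfconsistent_case()
        pairs, _ = predicted_vs_observed(samples, data)
        n_quantified = sum(
            o.censor == "quantified" and o.matrix in ("blood", "urine")
            for o in data.observations
        )
        assert len(pairs) == n_quantified

    def test_subject_missing_from_draws_reported(self):
        data, samples = self.make_selfconsistent_case()
        extra = Subject("S99", bw=60.0, dose_per_kg=200.0)
        data2 = TrialDataset(
            data.subjects + [extra], data.observations, data.limits
        )
        with pytest.raises(KeyError, match="S99"):
            predicted_vs_observed(samples, data2)


class TestDeterministicSimulation:
    SUBJECTS = [Subject("S01", bw=70.0, dose_per_kg=200.0),
                Subject("S02", bw=60.0, dose_per_kg=200.0)]

    def test_initial_state_holds_only_gut_mass(self):
        trajs = deterministic_simulation(central_params(), self.SUBJECTS)
        for s in self.SUBJECTS:
            traj = trajs[s.subject_id]
            assert traj.times[0] == 0.0
            assert traj.A_gut[0] == pytest.approx(200.0 * s.bw)
            assert traj.C_cpt_out[0] == 0.0

    def test_terminal_urinary_recovery_is_pig_scaled_fraction(self):
        # F_gutabs * k_ufrac = 0.17 * 0.5 = 0.085 of the dose at infinite
        # time; at 48 h part of the dose is still in the body
        long_t = np.linspace(0.0, 2000.0, 501)
        trajs = deterministic_simulation(
            central_params(), self.SUBJECTS[:1], times=long_t
        )
        traj = trajs["S01"]
        terminal = traj.Q_u_out[-1] / (200.0 * 70.0)
        assert terminal == pytest.approx(0.085, rel=0.01)
        at_48h = traj.Q_u_out[np.searchsorted(long_t, 48.0)] / (200.0 * 70.0)
        assert at_48h < 0.085

    def test_matches_general_simulator(self):
        from citpoptk.tk_model import simulate_closed_form

        trajs = deterministic_simulation(central_params(), self.SUBJECTS[:1])
        ref = simulate_closed_form(
            central_params(), self.SUBJECTS[0].dose_event, trajs["S01"].times
        )
        np.testing.assert_allclose(trajs["S01"].C_cpt_out, ref.C_cpt_out)


class TestPosteriorMedianParams:
    def test_median_of_symmetric_draws_recovers_centre(self):
        rng = np.random.default_rng(12)
        draws = population_draws(rng, n=4001, subjects=["S01"], theta_sd=0.1)
        params = posterior_median_params(build_samples(draws))
        np.testing.assert_allclose(
            params["S01"].as_array(), central_params().as_array(), rtol=0.05
        )
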