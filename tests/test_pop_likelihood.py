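"""Hierarchical model: priors, individual level, censored likelihood."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from citpoptk.pop_likelihood import (
    ERR_LNGSD_BOUNDS,
    SIGMA2_LNVAR_BOUNDS,
    MatrixLimits,
    Observation,
    PopTKTarget,
    PopulationParams,
    PriorSpec,
    QuantLimits,
    Subject,
    TrialDataset,
    default_limits,
    default_priors,
    individual_log_density,
    initial_vector,
    log_posterior,
    log_prior,
    observation_log_likelihood,
)
from citpoptk.tk_model import TKParams


def make_pop(mu=None, sigma=0.4, err=1.2):
    if mu is None:
        mu = np.log([0.04, 0.9, 0.5, 0.17, 0.5, 0.04, 0.9])
    return PopulationParams(
        mu=np.asarray(mu, float),
        sigma=np.full(7, sigma),
        err_gsd_blood=err,
        err_gsd_urine=err,
    )


class TestLogPrior:
    def test_central_values_are_in_support(self):
        pop = make_pop()
        assert np.isfinite(log_prior(pop, default_priors()))

    def test_urinary_fraction_above_one_excluded(self):
        # GM of k_ufrac = e^0.5 > 1 violates the (0, 1) truncation
        mu = np.log([0.04, 0.9, 0.5, 0.17, 0.5, 0.04, 0.9])
        mu[TKParams.names.index("k_ufrac")] = 0.5
        assert log_prior(make_pop(mu), default_priors()) == -np.inf

    def test_mode_density_matches_numerical_truncation_mass(self):
        # at the prior modes the log-density is the sum of normal maxima
        # minus the log truncated masses; verify the masses by quadrature
        priors = default_priors()
        mu = np.array([s.mu_ln for s in priors])
        pop = make_pop(mu)
        expected = 0.0
        for spec in priors:
            expected += norm.logpdf(0.0) - math.log(spec.sigma_ln)
            lo, hi = spec.bounds
            if np.isfinite(lo) or np.isfinite(hi):
                mass, _ = quad(
                    lambda v, s=spec: norm.pdf(v, s.mu_ln, s.sigma_ln),
                    lo, hi,
                )
                expected -= math.log(mass)
        lo_v, hi_v = SIGMA2_LNVAR_BOUNDS
        expected += -7 * math.log(hi_v - lo_v)
        lo_e, hi_e = ERR_LNGSD_BOUNDS
        expected += -2 * math.log(hi_e - lo_e)
        assert log_prior(pop, priors) == pytest.approx(expected, rel=1e-9)

    def test_duplicate_and_missing_priors_rejected(self):
        priors = default_priors()
        with pytest.raises(ValueError, match="duplicate"):
            log_prior(make_pop(), priors + [priors[0]])
        with pytest.raises(ValueError, match="missing"):
            log_prior(make_pop(), priors[:-1])


class TestIndividualLogDensity:
    def test_maximized_at_population_geometric_mean(self):
        pop = make_pop()
        theta_mode = TKParams.from_array(np.exp(pop.mu))
        best = individual_log_density(theta_mode, pop)
        rng = np.random.default_rng(0)
        for _ in range(20):
            other = TKParams.from_array(
                np.exp(pop.mu + rng.uniform(-0.3, 0.3, size=7))
            )
            assert individual_log_density(other, pop) <= best

    def test_degenerate_population_rejects_off_mode_subjects(self):
        pop = make_pop(sigma=0.0)
        off = TKParams.from_array(np.exp(pop.mu) * 1.01)
        assert individual_log_density(off, pop) == -np.inf

    def test_out_of_support_gives_minus_infinity_not_error(self):
        pop = make_pop()
        # k_ufrac = 0.999 > e^-0.01: outside the individual-level support
        theta = TKParams.from_array(
            np.exp(pop.mu) * [1, 1, 0, 1, 1, 1, 1] + [0, 0, 0.999, 0, 0, 0, 0]
        )
        assert individual_log_density(theta, pop) == -np.inf

    def test_value_matches_hand_computed_sum(self):
        # three free parameters moved off-centre; others at the mode
        pop = make_pop(sigma=0.5)
        shift = np.zeros(7)
        shift[:3] = [0.2, -0.1, 0.05]
        theta = TKParams.from_array(np.exp(pop.mu + shift))
        expected = 0.0
        by_name = {s.name: s for s in default_priors()}
        for i, name in enumerate(TKParams.names):
            lo, hi = by_name[name].bounds
            z_mass = norm.cdf((hi - pop.mu[i]) / 0.5) - norm.cdf(
                (lo - pop.mu[i]) / 0.5
            )
            expected += norm.logpdf(pop.mu[i] + shift[i], pop.mu[i], 0.5)
            expected -= math.log(z_mass)
        assert individual_log_density(theta, pop) == pytest.approx(expected)


class TestObservationLikelihood:
    LIMS = default_limits()

    def test_quantified_at_median(self):
        pop = make_pop(err=1.3)
        obs = Observation("S01", "blood", 2.0, 0.8)
        lp = observation_log_likelihood(obs, 0.8, pop, self.LIMS)
        expected = -math.log(0.8 * math.log(1.3) * math.sqrt(2 * math.pi))
        assert lp == pytest.approx(expected)

    def test_below_lod_probability_approaches_one_for_huge_lod(self):
        pop = make_pop()
        lims = QuantLimits(
            blood=MatrixLimits(1e6, 2e6, 3e6), urine=self.LIMS.urine
        )
        obs = Observation("S01", "blood", 2.0, math.nan, "below_lod")
        assert observation_log_likelihood(obs, 0.05, pop, lims) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_branches_partition_outcome_space(self):
        pop = make_pop(err=1.4)
        pred = 0.04
        s = math.log(1.4)
        lims = self.LIMS.blood
        total = 0.0
        for censor in ("below_lod", "interval_lod_lloq", "above_uloq"):
            obs = Observation("S01", "blood", 2.0, math.nan, censor)
            total += math.exp(
                observation_log_likelihood(obs, pred, pop, self.LIMS)
            )
        # remaining mass: a quantified value inside [LLOQ, ULOQ]
        z = lambda v: (math.log(v) - math.log(pred)) / s
        total += norm.cdf(z(lims.uloq)) - norm.cdf(z(lims.lloq))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_zero_prediction_floored_not_crashing(self):
        pop = make_pop()
        obs = Observation("S01", "blood", 0.0, 0.06)
        lp = observation_log_likelihood(obs, 0.0, pop, self.LIMS)
        assert np.isfinite(lp) and lp < -100  # wildly unlikely, but finite

    def test_fecal_rows_have_no_error_model(self):
        pop = make_pop()
        obs = Observation("S01", "feces", 12.0, 0.2)
        with pytest.raises(ValueError, match="feces"):
            observation_log_likelihood(obs, 0.2, pop, self.LIMS)


class TestLogPosterior:
    def subjects(self):
        return [Subject("S01", bw=70.0, dose_per_kg=200.0)]

    def test_no_data_reduces_to_prior_and_individual_terms(self):
        pop = make_pop()
        theta = TKParams.from_array(np.exp(pop.mu))
        data = TrialDataset(self.subjects(), [], default_limits())
        expected = log_prior(pop, default_priors()) + individual_log_density(
            theta, pop
        )
        assert log_posterior(pop, {"S01": theta}, data) == pytest.approx(expected)

    def test_single_observation_is_compositional(self):
        from citpoptk.tk_model import DoseEvent, simulate_closed_form

        pop = make_pop()
        theta = TKParams.from_array(np.exp(pop.mu))
        obs = Observation("S01", "blood", 4.0, 0.06)
        data = TrialDataset(self.subjects(), [obs], default_limits())
        pred = simulate_closed_form(
            theta, DoseEvent(200.0, 70.0), [4.0]
        ).C_cpt_out[0]
        expected = (
            log_prior(pop, default_priors())
            + individual_log_density(theta, pop)
            + observation_log_likelihood(obs, pred, pop, default_limits())
        )
        assert log_posterior(pop, {"S01": theta}, data) == pytest.approx(expected)

    def test_observation_beyond_horizon_rejected(self):
        obs = Observation("S01", "blood", 49.0, 0.06)
        with pytest.raises(ValueError, match="48"):
            TrialDataset(self.subjects(), [obs], default_limits())

    def test_unknown_subject_rejected(self):
        obs = Observation("S99", "blood", 4.0, 0.06)
        with pytest.raises(ValueError, match="S99"):
            TrialDataset(self.subjects(), [obs], default_limits())


class TestPosteriorDominance:
    def test_diffuse_population_level_leaves_map_to_the_data(self):
        # single subject, noiseless-ish data at a known clearance: with a
        # very diffuse population level the profile of the posterior in
        # ln Cl_tot must peak where the likelihood alone peaks
        from citpoptk.tk_model import DoseEvent, simulate_closed_form

        true_cl = 0.08
        theta_gen = TKParams.from_array(
            np.exp(np.log([true_cl, 0.9, 0.5, 0.17, 0.5, 0.04, 0.9]))
        )
        subj = Subject("S01", bw=70.0, dose_per_kg=200.0)
        times = [2.0, 6.0, 12.0, 24.0, 36.0, 48.0]
        traj = simulate_closed_form(theta_gen, subj.dose_event, times)
        wide = QuantLimits(
            blood=MatrixLimits(1e-12, 1e-11, 1e12),
            urine=MatrixLimits(1e-12, 1e-11, 1e12),
        )
        obs = [
            Observation("S01", "blood", t, float(c))
            for t, c in zip(times, traj.C_cpt_out)
        ]
        data = TrialDataset([subj], obs, wide)
        pop = make_pop(mu=np.log([0.04, 0.9, 0.5, 0.17, 0.5, 0.04, 0.9]),
                       sigma=5.0, err=1.2)

        grid = np.linspace(np.log(true_cl) - 0.7, np.log(true_cl) + 0.7, 141)

        def profile(include_pop_level):
            values = []
            for ln_cl in grid:
                theta = TKParams.from_array(
                    np.exp([ln_cl] + list(np.log(theta_gen.as_array()[1:])))
                )
                lik = 0.0
                pred = simulate_closed_form(theta, subj.dose_event, times)
                for o, c in zip(obs, pred.C_cpt_out):
                    lik += observation_log_likelihood(o, float(c), pop, wide)
                if include_pop_level:
                    lik += individual_log_density(theta, pop)
                values.append(lik)
            return grid[int(np.argmax(values))]

        map_with_pop = profile(True)
        map_lik_only = profile(False)
        assert map_with_pop == pytest.approx(map_lik_only, abs=grid[1] - grid[0])
        assert map_lik_only == pytest.approx(np.log(true_cl), abs=grid[1] - grid[0])


class TestFastTargetAgreesWithReference:
    def test_logp_equals_composed_reference_functions(self, small_trial):
        data, _ = small_trial
        target = PopTKTarget(data)
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = initial_vector(target, rng=rng, jitter=0.2)
            pop, thetas = target.unpack(x)
            assert target.logp(x) == pytest.approx(
                log_posterior(pop, thetas, data), rel=1e-10
            )

    def test_coordinate_density_differences_match_full_density(self, small_trial):
        data, _ = small_trial
        target = PopTKTarget(data)
        rng = np.random.default_rng(6)
        x = initial_vector(target, rng=rng)
        for i in range(0, target.dim, 5):
            x2 = x.copy()
            x2[i] += 0.04
            d_full = target.logp(x2) - target.logp(x)
            d_coord = target.coord_logp(x2, i) - target.coord_logp(x, i)
            assert d_coord == pytest.approx(d_full, abs=1e-8)

    def test_group_moves_preserve_density_bookkeeping(self, small_trial):
        # every move's partial logp must track the full logp difference
        data, _ = small_trial
        target = PopTKTarget(data)
        rng = np.random.default_rng(7)
        x = initial_vector(target, rng=rng)
        from citpoptk.mcmc_engine import GibbsMove

        for move in target.group_moves():
            if isinstance(move, GibbsMove):
                continue
            x_new, _ = move.propose(x, 0.05, rng)
            d_full = target.logp(x_new) - target.logp(x)
            d_move = move.logp(x_new) - move.logp(x)
            assert d_move == pytest.approx(d_full, abs=1e-8), move.name
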