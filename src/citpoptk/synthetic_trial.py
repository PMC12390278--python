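"""Synthetic oral-bolus trials with the structure the analysis assumes.

The generator emulates the design of the citrinin intervention study: 10
volunteers, a single aqueous bolus of 200 ng/kg bw before breakfast, a
fixed capillary-blood schedule (0, 15, 30 min and 1, 2, 4, 6, 8, 12, 24,
36, 48 h) and irregular urine voids with recorded volumes over 48 h.
Subjects' kinetic parameters are lognormal around the population
geometric means, the assay adds lognormal noise, and values outside the
validated quantification range are censored exactly as the real assay
would censor them.  The full ground truth (population draw, per-subject
parameters, noiseless outputs) is kept so that parameter recovery can be
tested end to end.

Also implements the metabolite (HO-CIT) urinary-mass estimator used for
the deterministic comparison: the cumulative CIT mass in urine times a
random HO-CIT/CIT ratio drawn from a normal distribution spanning 3-17,
truncated so the combined mass never exceeds the administered dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

from .tk_model import TKParams, simulate_closed_form
from .pop_likelihood import (
    Observation,
    PopulationParams,
    PriorSpec,
    QuantLimits,
    Subject,
    TrialDataset,
    default_limits,
    default_priors,
)

__all__ = [
    "TrialDesign",
    "GroundTruth",
    "PIG_SCALED_CENTRAL_GM",
    "central_params",
    "default_population",
    "generate_population",
    "generate_observations",
    "generate_trial",
    "estimate_hocit_urinary_mass",
    "HOCIT_RATIO_MEAN",
    "HOCIT_RATIO_SD",
    "HOCIT_RATIO_RANGE",
]

#: pig-scaled central geometric means, in TKParams order
PIG_SCALED_CENTRAL_GM = {
    "Cl_tot": 0.04,
    "V_dist": 0.90,
    "k_ufrac": 0.50,
    "F_gutabs": 0.17,
    "k_gutelim": 0.50,
    "Cl_met": 0.04,
    "V_distmet": 0.90,
}

#: HO-CIT/CIT urinary mass ratio: "normal distribution extending from 3
#: to 17", read as mean 10 with +-3 SD spanning the stated range.
HOCIT_RATIO_MEAN = 10.0
HOCIT_RATIO_SD = 7.0 / 3.0
HOCIT_RATIO_RANGE = (3.0, 17.0)


@dataclass(frozen=True)
class TrialDesign:
    """Study design parameters of the emulated trial."""

    n_subjects: int = 10
    dose_per_kg: float = 200.0
    blood_schedule: tuple[float, ...] = (
        0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 48.0,
    )
    horizon: float = 48.0
    first_void_range: tuple[float, float] = (1.0, 7.0)
    void_gap_range: tuple[float, float] = (3.0, 7.0)
    void_volume_range_mL: tuple[float, float] = (100.0, 400.0)
    bw_range_kg: tuple[float, float] = (55.0, 90.0)
    fecal_events_per_subject: int = 2
    fecal_dry_mass_g: float = 30.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        sched = self.blood_schedule
        if any(t < 0 or t > self.horizon for t in sched):
            raise ValueError("blood schedule must lie within [0, horizon]")
        if any(b < a for a, b in zip(sched, sched[1:])):
            raise ValueError("blood schedule must be sorted")


@dataclass
class GroundTruth:
    """Everything the generator drew, for recovery testing.

    ``noiseless`` maps subject id -> {"blood": (times, conc ng/mL),
    "urine": (times, cumulative ng)} and is filled by
    :func:`generate_observations`.
    """

    pop: PopulationParams
    params: dict[str, TKParams]
    noiseless: dict[str, dict] = field(default_factory=dict)


def central_params() -> TKParams:
    """The pig-scaled central parameter set as a TKParams."""
    return TKParams(**PIG_SCALED_CENTRAL_GM)


def default_population(gsd: float = 1.5, err_gsd: float = 1.2) -> PopulationParams:
    """Population at the pig-scaled central GMs with a common GSD."""
    mu = np.log([PIG_SCALED_CENTRAL_GM[n] for n in TKParams.names])
    sigma = np.full(len(TKParams.names), math.log(gsd))
    return PopulationParams(
        mu=mu, sigma=sigma, err_gsd_blood=err_gsd, err_gsd_urine=err_gsd
    )


def generate_population(
    design: TrialDesign,
    pop: PopulationParams,
    seed: int | np.random.Generator = 0,
    priors: list[PriorSpec] | None = None,
) -> tuple[list[Subject], GroundTruth]:
    """Draw subjects: body weights and truncated-lognormal parameters.

    Body weights are uniform on the design range.  Each subject's ln
    parameters are Normal(mu, sigma), redrawn while outside the
    truncation support (error after 1000 rejections per component).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    priors = priors if priors is not None else default_priors()
    by_name = {s.name: s for s in priors}
    # parameters without a prior entry draw untruncated
    bounds = [
        by_name[n].bounds if n in by_name else (-np.inf, np.inf)
        for n in TKParams.names
    ]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    # structural constraint: fractions stay inside (0, 1) regardless
    for frac in ("k_ufrac", "F_gutabs"):
        i = TKParams.names.index(frac)
        hi[i] = min(hi[i], -1e-9)

    subjects: list[Subject] = []
    params: dict[str, TKParams] = {}
    for j in range(design.n_subjects):
        sid = f"S{j + 1:02d}"
        bw = rng.uniform(*design.bw_range_kg)
        ln_theta = np.empty(len(TKParams.names))
        for p in range(len(TKParams.names)):
            for attempt in range(1000):
                draw = rng.normal(pop.mu[p], pop.sigma[p])
                if lo[p] <= draw <= hi[p]:
                    ln_theta[p] = draw
                    break
            else:
                raise RuntimeError(
                    f"1000 rejections drawing {TKParams.names[p]} inside "
                    f"[{lo[p]}, {hi[p]}]; truncation support too narrow"
                )
        subjects.append(Subject(sid, bw=bw, dose_per_kg=design.dose_per_kg))
        params[sid] = TKParams.from_array(np.exp(ln_theta))
    return subjects, GroundTruth(pop=pop, params=params)


def _censor_value(noisy: float, lims) -> tuple[float, str]:
    """Apply assay limits to a noisy measurement: (recorded value, flag)."""
    if noisy < lims.lod:
        return (math.nan, "below_lod")
    if noisy < lims.lloq:
        return (math.nan, "interval_lod_lloq")
    if noisy > lims.uloq:
        return (math.nan, "above_uloq")
    return (noisy, "quantified")


def generate_observations(
    subjects: list[Subject],
    truth: GroundTruth,
    design: TrialDesign,
    limits: QuantLimits | None = None,
    err_gsd_blood: float | None = None,
    err_gsd_urine: float | None = None,
    seed: int | np.random.Generator = 0,
    include_fecal: bool = True,
) -> TrialDataset:
    """Noisy, censored observations for every subject.

    Blood values are the noiseless concentrations at the schedule times
    times lognormal noise; the assay limits are applied to the noisy
    concentration.  Urine voids occur at random times (first void, then
    uniform gaps) with recorded volumes; the recorded value is the noisy
    cumulative mass, while the censor flag is assigned from the noisy
    void *concentration* (mass increment over void volume), which is
    what the assay actually measures against its limits.  Fecal events
    exercise the I/O path only and never enter the likelihood.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    limits = limits if limits is not None else default_limits()
    gb = err_gsd_blood if err_gsd_blood is not None else truth.pop.err_gsd_blood
    gu = err_gsd_urine if err_gsd_urine is not None else truth.pop.err_gsd_urine
    sb, su = math.log(gb), math.log(gu)

    observations: list[Observation] = []
    for subject in subjects:
        theta = truth.params[subject.subject_id]

        # urine void times: first void, then uniform gaps, all within horizon
        t = rng.uniform(*design.first_void_range)
        void_times = []
        while t <= design.horizon:
            void_times.append(t)
            t += rng.uniform(*design.void_gap_range)
        void_times = np.array(void_times)
        volumes = rng.uniform(*design.void_volume_range_mL, size=void_times.size)

        tb = np.array(design.blood_schedule)
        t_all = np.sort(np.concatenate([tb, void_times]))
        traj = simulate_closed_form(theta, subject.dose_event, t_all)
        c_blood = np.interp(tb, t_all, traj.C_cpt_out)
        q_urine = np.interp(void_times, t_all, traj.Q_u_out)
        q_fec = traj.Q_fec_out

        truth.noiseless[subject.subject_id] = {
            "blood": (tb, c_blood),
            "urine": (void_times, q_urine),
        }

        for t_i, c_i in zip(tb, c_blood):
            noisy = c_i * math.exp(sb * rng.standard_normal())
            value, flag = _censor_value(noisy, limits.blood)
            observations.append(
                Observation(subject.subject_id, "blood", float(t_i), value, flag)
            )

        q_prev = 0.0
        for k, (t_k, q_k, vol_k) in enumerate(zip(void_times, q_urine, volumes)):
            z = rng.standard_normal()
            noisy_cum = q_k * math.exp(su * z)
            noisy_conc = (q_k - q_prev) * math.exp(su * z) / vol_k
            _, flag = _censor_value(noisy_conc, limits.urine)
            value = noisy_cum if flag == "quantified" else math.nan
            observations.append(
                Observation(
                    subject.subject_id,
                    "urine",
                    float(t_k),
                    value,
                    flag,
                    void_volume=float(vol_k),
                )
            )
            q_prev = q_k

        if include_fecal and limits.feces is not None:
            # sparse fecal events: concentration of the fecal-mass increment
            # over a nominal dry mass; I/O exercise only
            times = np.sort(rng.uniform(6.0, design.horizon,
                                        size=design.fecal_events_per_subject))
            q_f = np.interp(times, t_all, q_fec)
            prev = 0.0
            for t_f, qf_k in zip(times, q_f):
                conc = (qf_k - prev) / design.fecal_dry_mass_g
                noisy = conc * math.exp(su * rng.standard_normal())
                value, flag = _censor_value(noisy, limits.feces)
                observations.append(
                    Observation(subject.subject_id, "feces", float(t_f), value, flag)
                )
                prev = qf_k

    return TrialDataset(
        subjects=list(subjects),
        observations=observations,
        limits=limits,
        horizon=design.horizon,
    )


def generate_trial(
    design: TrialDesign | None = None,
    pop: PopulationParams | None = None,
    seed: int = 0,
    limits: QuantLimits | None = None,
    include_fecal: bool = True,
    priors: list[PriorSpec] | None = None,
) -> tuple[TrialDataset, GroundTruth]:
    """One-call generator: population draw plus noisy observations.

    A single seed drives both stages through independent child streams.
    """
    design = design if design is not None else TrialDesign()
    pop = pop if pop is not None else default_population()
    ss = np.random.SeedSequence(seed)
    rng_pop, rng_obs = (np.random.default_rng(s) for s in ss.spawn(2))
    subjects, truth = generate_population(design, pop, seed=rng_pop, priors=priors)
    data = generate_observations(
        subjects, truth, design, limits=limits, seed=rng_obs,
        include_fecal=include_fecal,
    )
    return data, truth


def estimate_hocit_urinary_mass(
    cum_cit_mass_ng: float,
    dose_ng: float,
    seed: int | np.random.Generator = 0,
) -> float:
    """Estimated cumulative HO-CIT mass in urine over the trial window.

    Multiplies the subject's cumulative CIT urinary mass by a ratio
    drawn from Normal(10, 7/3) truncated to [3, 17], then truncates the
    result to the administered mass not recovered as CIT so that mass
    balance is preserved.
    """
    if not (0.0 <= cum_cit_mass_ng <= dose_ng):
        raise ValueError(
            f"cumulative CIT mass {cum_cit_mass_ng} must lie in [0, dose={dose_ng}]"
        )
    if cum_cit_mass_ng == 0.0:
        return 0.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = HOCIT_RATIO_RANGE
    a = (lo - HOCIT_RATIO_MEAN) / HOCIT_RATIO_SD
    b = (hi - HOCIT_RATIO_MEAN) / HOCIT_RATIO_SD
    # inverse-CDF draw from the truncated normal
    u = rng.uniform(ndtr(a), ndtr(b))
    ratio = HOCIT_RATIO_MEAN + HOCIT_RATIO_SD * float(ndtri(u))
    return min(ratio * cum_cit_mass_ng, dose_ng - cum_cit_mass_ng)
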