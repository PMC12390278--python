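"""Posterior post-processing and the human-variability adjustment factor.

Turns raw MCMC draws into the quantities a risk assessor uses: per
parameter, the posterior median and 90% CI of the population geometric
mean and geometric standard deviation; per draw and subject, the derived
kinetics (half-life, Tmax, Cmax, AUC to infinity); and the
chemical-specific adjustment factor for human toxicokinetic variability

    HK_AF = GSD_AUC ** Qnorm(0.95),

the factor needed to cover the 95th percentile of a lognormal AUC
distribution, compared against the default TK uncertainty factor
10**0.5 = 3.16.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .tk_model import TKParams, TrajectorySet, simulate_closed_form
from .pop_likelihood import Subject, TrialDataset
from .mcmc_engine import PosteriorSamples, convergence_report

__all__ = [
    "CSAFResult",
    "DEFAULT_TK_FACTOR",
    "UnconvergedError",
    "summarize_population",
    "derived_tk_posterior",
    "gsd_auc_posterior",
    "compute_hkaf",
    "posterior_median_params",
    "predicted_vs_observed",
    "deterministic_simulation",
]

#: default uncertainty factor for human TK variability, 10**(1/2)
DEFAULT_TK_FACTOR = 10.0 ** 0.5


class UnconvergedError(RuntimeError):
    """Raised when summaries are requested from an unconverged fit."""


def _require_converged(samples: PosteriorSamples, force: bool, threshold: float):
    report = convergence_report(samples, threshold=threshold)
    if not report.attrs["converged"] and not force:
        worst = report.loc[report["rhat"].idxmax()]
        raise UnconvergedError(
            f"max R-hat {report.attrs['max_rhat']:.3f} "
            f"({worst['parameter']}) exceeds {threshold}; "
            "pass force=True to summarize anyway"
        )
    return report


def summarize_population(
    samples: PosteriorSamples,
    force: bool = False,
    threshold: float = 1.2,
) -> pd.DataFrame:
    """Posterior GM and GSD summaries per population parameter.

    For each kinetic parameter the GM draw is ``exp(mu)`` and the GSD
    draw ``exp(sigma)``; the table reports the 5th/50th/95th percentiles
    of each over the pooled post-burn-in draws.  Refuses (unless
    ``force``) when any R-hat exceeds ``threshold``.
    """
    _require_converged(samples, force, threshold)
    rows = []
    for p in TKParams.names:
        gm = np.exp(samples.pooled(f"mu_{p}"))
        gsd = np.exp(np.sqrt(np.exp(samples.pooled(f"lnvar_{p}"))))
        lo, med, hi = np.percentile(gm, [5, 50, 95])
        glo, gmed, ghi = np.percentile(gsd, [5, 50, 95])
        rows.append(
            {
                "parameter": p,
                "GM_median": med, "GM_lo90": lo, "GM_hi90": hi,
                "GSD_median": gmed, "GSD_lo90": glo, "GSD_hi90": ghi,
            }
        )
    for m in ("blood", "urine"):
        g = np.exp(samples.pooled(f"ln_err_gsd_{m}"))
        lo, med, hi = np.percentile(g, [5, 50, 95])
        rows.append(
            {
                "parameter": f"err_gsd_{m}",
                "GM_median": np.nan, "GM_lo90": np.nan, "GM_hi90": np.nan,
                "GSD_median": med, "GSD_lo90": lo, "GSD_hi90": hi,
            }
        )
    return pd.DataFrame(rows)


def _subject_ids(samples: PosteriorSamples) -> list[str]:
    ids = []
    suffix = f"ln_{TKParams.names[0]}["
    for name in samples.names:
        if name.startswith(suffix):
            ids.append(name[len(suffix) : -1])
    return ids


def _subject_draws(samples: PosteriorSamples) -> tuple[list[str], np.ndarray]:
    """Pooled subject-level natural-scale draws, shape (n_draws, n_subj, 7)."""
    ids = _subject_ids(samples)
    if not ids:
        raise ValueError("no subject-level parameters found in the draws")
    flat = samples.pooled()
    out = np.empty((flat.shape[0], len(ids), len(TKParams.names)))
    for j, sid in enumerate(ids):
        for p_idx, p in enumerate(TKParams.names):
            out[:, j, p_idx] = flat[:, samples.index_of(f"ln_{p}[{sid}]")]
    return ids, np.exp(out)


def _derived_arrays(theta: np.ndarray, dose_per_kg: float) -> dict[str, np.ndarray]:
    """Vectorized derived kinetics; ``theta`` is (..., 7) natural scale."""
    cl, v, kuf, f, kge = (theta[..., i] for i in range(5))
    kel = cl / v
    kga = kge * f / (1.0 - f)
    lam = kga + kge
    tmax = np.log(lam / kel) / (lam - kel)
    amax = kga * dose_per_kg / (lam - kel) * (
        np.exp(-kel * tmax) - np.exp(-lam * tmax)
    )
    return {
        "AUC_inf": f * dose_per_kg / cl,
        "t_half": math.log(2.0) / kel,
        "k_el": kel,
        "Tmax": tmax,
        "Cmax": amax / (v * 1000.0),
    }


def derived_tk_posterior(
    samples: PosteriorSamples,
    dose_per_kg: float = 1500.0,
) -> pd.DataFrame:
    """Across-subject GM/GSD of derived kinetics, summarized over draws.

    Per posterior draw, each subject's AUC, half-life, Tmax and Cmax are
    computed from that subject's parameters; the within-draw geometric
    mean and geometric SD across subjects are then summarized by their
    posterior median and 90% CI.  ``dose_per_kg`` sets the reporting
    dose for the dose-dependent quantities.
    """
    ids, theta = _subject_draws(samples)
    if len(ids) < 2:
        raise ValueError(
            "across-subject GSD undefined with fewer than 2 subjects"
        )
    derived = _derived_arrays(theta, dose_per_kg)  # (n_draws, n_subj) each
    rows = []
    for name, values in derived.items():
        ln_v = np.log(values)
        gm = np.exp(ln_v.mean(axis=1))
        gsd = np.exp(ln_v.std(axis=1, ddof=1))
        lo, med, hi = np.percentile(gm, [5, 50, 95])
        glo, gmed, ghi = np.percentile(gsd, [5, 50, 95])
        rows.append(
            {
                "quantity": name,
                "GM_median": med, "GM_lo90": lo, "GM_hi90": hi,
                "GSD_median": gmed, "GSD_lo90": glo, "GSD_hi90": ghi,
            }
        )
    frame = pd.DataFrame(rows)
    frame.attrs["dose_per_kg"] = dose_per_kg
    frame.attrs["n_subjects"] = len(ids)
    return frame


def gsd_auc_posterior(
    samples: PosteriorSamples,
    method: str = "subjects",
) -> float:
    """Posterior median of the population geometric SD of AUC.

    ``method="subjects"`` (default) uses the within-draw across-subject
    GSD of the individual AUCs, matching how the trial summarizes the 10
    volunteers.  ``method="population"`` instead propagates the
    population-level GSDs of F_gutabs and Cl_tot through the lognormal
    ratio ``AUC = F * dose / Cl``.
    """
    if method == "subjects":
        _, theta = _subject_draws(samples)
        ln_auc = np.log(theta[..., 3] / theta[..., 0])  # dose factor cancels
        gsd = np.exp(ln_auc.std(axis=1, ddof=1))
        return float(np.median(gsd))
    if method == "population":
        s_f = np.sqrt(np.exp(samples.pooled("lnvar_F_gutabs")))
        s_cl = np.sqrt(np.exp(samples.pooled("lnvar_Cl_tot")))
        gsd = np.exp(np.sqrt(s_f**2 + s_cl**2))
        return float(np.median(gsd))
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class CSAFResult:
    """Chemical-specific adjustment factor for human TK variability."""

    gsd_auc: float
    percentile: float
    z: float
    hk_af: float
    default_factor: float
    is_below_default: bool


def compute_hkaf(gsd_auc: float, p: float = 0.95) -> CSAFResult:
    """HK_AF = GSD_AUC raised to the standard-normal quantile at ``p``.

    Raises for ``gsd_auc < 1`` (a geometric SD is >= 1 by construction).
    """
    if not (gsd_auc >= 1.0):
        raise ValueError(f"gsd_auc must be >= 1, got {gsd_auc!r}")
    if not (0.0 < p < 1.0):
        raise ValueError(f"percentile p must lie in (0, 1), got {p!r}")
    z = float(norm.ppf(p))
    hk_af = gsd_auc**z
    return CSAFResult(
        gsd_auc=gsd_auc,
        percentile=p,
        z=z,
        hk_af=hk_af,
        default_factor=DEFAULT_TK_FACTOR,
        is_below_default=hk_af <= DEFAULT_TK_FACTOR,
    )


def posterior_median_params(samples: PosteriorSamples) -> dict[str, TKParams]:
    """Per-subject parameters at the posterior median of the ln draws."""
    out = {}
    for sid in _subject_ids(samples):
        ln_med = np.array(
            [np.median(samples.pooled(f"ln_{p}[{sid}]")) for p in TKParams.names]
        )
        out[sid] = TKParams.from_array(np.exp(ln_med))
    return out


def predicted_vs_observed(
    samples: PosteriorSamples,
    data: TrialDataset,
    force: bool = False,
    threshold: float = 1.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair every quantified observation with its posterior prediction.

    Predictions come from each subject's posterior-median parameters.
    Returns the pair table and a per-matrix table with the concordance
    slope (least-squares through the origin) and the R-squared of the
    identity fit.  Censored observations are excluded.
    """
    _require_converged(samples, force, threshold)
    params = posterior_median_params(samples)
    for s in data.subjects:
        if s.subject_id not in params:
            raise KeyError(
                f"subject {s.subject_id!r} present in data but absent from draws"
            )
    rows = []
    for subject in data.subjects:
        theta = params[subject.subject_id]
        obs = sorted(
            (o for o in data.observations
             if o.subject_id == subject.subject_id
             and o.matrix in ("blood", "urine")
             and o.censor == "quantified"),
            key=lambda o: o.time,
        )
        if not obs:
            continue
        times = np.array([o.time for o in obs])
        order = np.argsort(times, kind="stable")
        traj = simulate_closed_form(theta, subject.dose_event, times[order])
        inv = np.empty_like(order)
        inv[order] = np.arange(order.size)
        for k, o in enumerate(obs):
            pred = (
                traj.C_cpt_out[inv[k]] if o.matrix == "blood"
                else traj.Q_u_out[inv[k]]
            )
            rows.append(
                {
                    "subject_id": o.subject_id,
                    "matrix": o.matrix,
                    "time_h": o.time,
                    "observed": o.value,
                    "predicted": float(pred),
                }
            )
    pairs = pd.DataFrame(rows)
    stats = []
    for matrix, grp in pairs.groupby("matrix"):
        x = grp["observed"].to_numpy()
        y = grp["predicted"].to_numpy()
        slope = float(np.sum(x * y) / np.sum(x * x))
        ss_res = float(np.sum((x - y) ** 2))
        ss_tot = float(np.sum((x - x.mean()) ** 2))
        stats.append(
            {
                "matrix": matrix,
                "n": len(grp),
                "slope": slope,
                "r2_identity": 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
            }
        )
    return pairs, pd.DataFrame(stats)


def deterministic_simulation(
    central: TKParams,
    subjects: list[Subject],
    times: np.ndarray | None = None,
    horizon: float = 48.0,
) -> dict[str, TrajectorySet]:
    """Forward simulation at fixed central parameters, per subject.

    No inter-individual variability and no noise: the pig-scaled
    counterpart of the population fit, at each subject's dose and body
    weight over the trial horizon.
    """
    if times is None:
        times = np.linspace(0.0, horizon, 481)
    return {
        s.subject_id: simulate_closed_form(central, s.dose_event, times)
        for s in subjects
    }
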