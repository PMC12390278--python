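"""Deterministic kinetics of the citrinin (CIT) parent + metabolite model.

The structural model has four fates for an oral bolus: from the gut lumen,
CIT is absorbed into a central (blood) compartment with rate ``k_gutabs``
or lost to feces with rate ``k_gutelim``.  From the central compartment it
is excreted in urine (rate ``k_u``) or metabolised to dihydrocitrinone
(HO-CIT, rate ``k_met``), which occupies its own central compartment and
is cleared into urine with rate ``k_umet``.  All transfers are first
order, so the system is a linear cascade with closed-form (Bateman-type)
solutions; an adaptive ODE integrator provides the same trajectories for
degenerate rate configurations and serves as an independent numerical
oracle.

Amounts are in ng, volumes in L per kg body weight, times in hours.
Blood concentrations are reported in ng/mL.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "TKParams",
    "RateSet",
    "DoseEvent",
    "TrajectorySet",
    "DerivedTK",
    "IntegrationError",
    "derive_rates",
    "simulate_closed_form",
    "simulate_ode",
    "derived_tk",
    "RATE_DEGENERACY_RTOL",
]

logger = logging.getLogger(__name__)

#: Two first-order rates are treated as numerically equal (and the closed
#: form as ill-conditioned) when their relative difference is below this.
RATE_DEGENERACY_RTOL = 1e-8


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails; carries the state reached."""

    def __init__(self, message: str, t_reached: float, state: np.ndarray):
        super().__init__(message)
        self.t_reached = t_reached
        self.state = state


@dataclass(frozen=True)
class TKParams:
    """One subject's kinetic parameters on the natural scale.

    Parameters
    ----------
    Cl_tot : float
        Total clearance of CIT, L/(h * kg bw).
    V_dist : float
        Volume of distribution of CIT, L/kg bw.
    k_ufrac : float
        Fraction of eliminated CIT going to urine (0 < k_ufrac < 1).
    F_gutabs : float
        Fraction of the gut dose absorbed (0 < F_gutabs < 1; the value 1
        is excluded because it would require an unbounded absorption
        rate).
    k_gutelim : float
        Gut elimination (fecal loss) rate constant, 1/h.
    Cl_met : float
        Clearance of HO-CIT, L/(h * kg bw).
    V_distmet : float
        Volume of distribution of HO-CIT, L/kg bw.
    """

    Cl_tot: float
    V_dist: float
    k_ufrac: float
    F_gutabs: float
    k_gutelim: float
    Cl_met: float
    V_distmet: float

    def __post_init__(self) -> None:
        for name in ("Cl_tot", "V_dist", "k_gutelim", "Cl_met", "V_distmet"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if not (0.0 < self.k_ufrac < 1.0):
            raise ValueError(
                f"k_ufrac must lie in (0, 1), got {self.k_ufrac!r}"
            )
        if not (0.0 < self.F_gutabs):
            raise ValueError(
                f"F_gutabs must be strictly positive, got {self.F_gutabs!r}"
            )
        if self.F_gutabs >= 1.0:
            raise ValueError(
                "F_gutabs must be < 1: F_gutabs = 1 implies an infinite "
                f"absorption rate k_gutabs (got {self.F_gutabs!r})"
            )

    #: canonical ordering of the sampled parameters
    names = (
        "Cl_tot",
        "V_dist",
        "k_ufrac",
        "F_gutabs",
        "k_gutelim",
        "Cl_met",
        "V_distmet",
    )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.names])

    @classmethod
    def from_array(cls, values: np.ndarray) -> "TKParams":
        return cls(**dict(zip(cls.names, map(float, values))))


@dataclass(frozen=True)
class RateSet:
    """First-order rate constants derived from :class:`TKParams` (1/h)."""

    k_el: float
    k_u: float
    k_met: float
    k_gutabs: float
    k_umet: float
    lambda_gut: float


@dataclass(frozen=True)
class DoseEvent:
    """A single oral bolus at time 0: dose in ng/kg bw, body weight in kg."""

    dose_per_kg: float
    bw: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if not (self.dose_per_kg > 0):
            raise ValueError(f"dose_per_kg must be > 0, got {self.dose_per_kg!r}")
        if not (self.bw > 0):
            raise ValueError(f"bw must be > 0, got {self.bw!r}")

    @property
    def total_ng(self) -> float:
        """Administered mass, ng."""
        return self.dose_per_kg * self.bw


@dataclass
class TrajectorySet:
    """Forward-simulated model outputs over a time grid.

    ``A_gut`` (ng) is the mass remaining in the gut lumen; ``C_cpt_out``
    and ``C_cpt_met_out`` (ng/mL) are the CIT and HO-CIT central
    concentrations; ``Q_u_out``, ``Q_fec_out`` and ``Q_u_met_out`` (ng)
    are cumulative masses in urine, feces, and urine-as-metabolite.
    """

    times: np.ndarray
    A_gut: np.ndarray
    C_cpt_out: np.ndarray
    Q_u_out: np.ndarray
    Q_fec_out: np.ndarray
    C_cpt_met_out: np.ndarray
    Q_u_met_out: np.ndarray
    # central amounts (ng), kept for mass-balance checks
    A_central: np.ndarray = field(default=None, repr=False)
    A_met: np.ndarray = field(default=None, repr=False)

    def mass_total(self) -> np.ndarray:
        """Sum over all compartments at each output time (ng)."""
        return (
            self.A_gut
            + self.A_central
            + self.A_met
            + self.Q_u_out
            + self.Q_fec_out
            + self.Q_u_met_out
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_h": self.times,
                "A_gut_ng": self.A_gut,
                "C_cpt_ngmL": self.C_cpt_out,
                "Q_u_ng": self.Q_u_out,
                "Q_fec_ng": self.Q_fec_out,
                "C_met_ngmL": self.C_cpt_met_out,
                "Q_umet_ng": self.Q_u_met_out,
            }
        )


@dataclass(frozen=True)
class DerivedTK:
    """Derived kinetic quantities for a single subject.

    ``AUC_inf`` is the blood AUC extrapolated to infinity for a
    kg-normalised dose, in ng*h/L.
    """

    t_half: float
    k_el: float
    Tmax: float
    Cmax: float
    AUC_inf: float


def derive_rates(p: TKParams) -> RateSet:
    """Map clearances/volumes/fractions to first-order rate constants.

    ``k_el = Cl_tot / V_dist`` splits into urinary (``k_u = k_ufrac *
    k_el``) and metabolic (``k_met = (1 - k_ufrac) * k_el``) routes;
    the absorbed fraction fixes ``k_gutabs = k_gutelim * F_gutabs /
    (1 - F_gutabs)`` so that ``k_gutabs / (k_gutabs + k_gutelim) =
    F_gutabs``; the metabolite clears with ``k_umet = Cl_met /
    V_distmet``.
    """
    k_el = p.Cl_tot / p.V_dist
    k_u = p.k_ufrac * k_el
    k_met = (1.0 - p.k_ufrac) * k_el
    k_gutabs = p.k_gutelim * p.F_gutabs / (1.0 - p.F_gutabs)
    k_umet = p.Cl_met / p.V_distmet
    return RateSet(
        k_el=k_el,
        k_u=k_u,
        k_met=k_met,
        k_gutabs=k_gutabs,
        k_umet=k_umet,
        lambda_gut=k_gutabs + p.k_gutelim,
    )


def _check_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted ascending")
    return t


def _rates_degenerate(r: RateSet) -> bool:
    rates = (r.k_el, r.lambda_gut, r.k_umet)
    for i in range(3):
        for j in range(i + 1, 3):
            a, b = rates[i], rates[j]
            if abs(a - b) < RATE_DEGENERACY_RTOL * max(abs(a), abs(b)):
                return True
    return False


def _expm1_frac(rate: float, t: np.ndarray) -> np.ndarray:
    """(1 - exp(-rate * t)) / rate, stable for all positive rates."""
    return -np.expm1(-rate * t) / rate


def simulate_closed_form(
    p: TKParams, d: DoseEvent, times
) -> TrajectorySet:
    """Exact linear-cascade solution of the model on a time grid.

    Falls back to :func:`simulate_ode` when any two of the cascade rates
    (k_el, lambda_gut, k_umet) coincide within :data:`RATE_DEGENERACY_RTOL`,
    where the Bateman denominators cancel catastrophically.
    """
    t = _check_times(times)
    r = derive_rates(p)
    if _rates_degenerate(r):
        logger.info(
            "degenerate rate configuration (k_el=%.6g, lambda_gut=%.6g, "
            "k_umet=%.6g); delegating to simulate_ode",
            r.k_el,
            r.lambda_gut,
            r.k_umet,
        )
        return simulate_ode(p, d, t)

    D = d.total_ng
    a, lam, m = r.k_el, r.lambda_gut, r.k_umet

    e_a = np.exp(-a * t)
    e_lam = np.exp(-lam * t)
    e_m = np.exp(-m * t)

    A_gut = D * e_lam
    coef = r.k_gutabs * D / (lam - a)
    A_c = coef * (e_a - e_lam)

    # running integral of the central amount
    I_c = coef * (_expm1_frac(a, t) - _expm1_frac(lam, t))
    Q_u = r.k_u * I_c
    Q_fec = (p.k_gutelim / lam) * D * -np.expm1(-lam * t)

    # metabolite: dA_met/dt = k_met * A_c - m * A_met
    A_met = r.k_met * coef * ((e_a - e_m) / (m - a) - (e_lam - e_m) / (m - lam))
    I_met = r.k_met * coef * (
        (_expm1_frac(a, t) - _expm1_frac(m, t)) / (m - a)
        - (_expm1_frac(lam, t) - _expm1_frac(m, t)) / (m - lam)
    )
    Q_umet = m * I_met

    return TrajectorySet(
        times=t,
        A_gut=A_gut,
        C_cpt_out=A_c / (p.V_dist * d.bw * 1000.0),
        Q_u_out=Q_u,
        Q_fec_out=Q_fec,
        C_cpt_met_out=A_met / (p.V_distmet * d.bw * 1000.0),
        Q_u_met_out=Q_umet,
        A_central=A_c,
        A_met=A_met,
    )


def simulate_ode(
    p: TKParams,
    d: DoseEvent,
    times,
    rtol: float = 1e-12,
    atol_frac: float = 1e-16,
) -> TrajectorySet:
    """Adaptive numerical integration of the same six-state system.

    State order: (A_gut, A_c, Q_u, Q_fec, A_met, Q_umet).  The absolute
    tolerance is ``atol_frac`` times the administered mass so accuracy is
    dose-scale invariant.
    """
    t = _check_times(times)
    r = derive_rates(p)
    D = d.total_ng

    def rhs(_t, y):
        A_gut, A_c, _Q_u, _Q_fec, A_met, _Q_umet = y
        return [
            -r.lambda_gut * A_gut,
            r.k_gutabs * A_gut - r.k_el * A_c,
            r.k_u * A_c,
            p.k_gutelim * A_gut,
            r.k_met * A_c - r.k_umet * A_met,
            r.k_umet * A_met,
        ]

    y0 = [D, 0.0, 0.0, 0.0, 0.0, 0.0]
    t_eval = t
    t_span = (0.0, float(t[-1]) if t[-1] > 0 else 1e-9)
    sol = solve_ivp(
        rhs,
        t_span,
        y0,
        method="DOP853",
        t_eval=t_eval if t[-1] > 0 else None,
        rtol=rtol,
        atol=atol_frac * D,
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed: {sol.message}",
            t_reached=float(sol.t[-1]) if sol.t.size else 0.0,
            state=sol.y[:, -1] if sol.y.size else np.array(y0),
        )
    if t[-1] > 0:
        y = sol.y
    else:  # all-zero time grid: initial condition everywhere
        y = np.tile(np.asarray(y0)[:, None], (1, t.size))

    A_gut, A_c, Q_u, Q_fec, A_met, Q_umet = (np.maximum(row, 0.0) for row in y)
    return TrajectorySet(
        times=t,
        A_gut=A_gut,
        C_cpt_out=A_c / (p.V_dist * d.bw * 1000.0),
        Q_u_out=Q_u,
        Q_fec_out=Q_fec,
        C_cpt_met_out=A_met / (p.V_distmet * d.bw * 1000.0),
        Q_u_met_out=Q_umet,
        A_central=A_c,
        A_met=A_met,
    )


def derived_tk(p: TKParams, dose_per_kg: float) -> DerivedTK:
    """Half-life, Tmax, Cmax and AUC to infinity for a kg-normalised dose.

    ``Cmax`` is evaluated per kg body weight (the dose enters per kg and
    volumes are per kg, so body weight cancels).
    """
    if not (dose_per_kg > 0):
        raise ValueError(f"dose_per_kg must be > 0, got {dose_per_kg!r}")
    r = derive_rates(p)
    a, lam = r.k_el, r.lambda_gut
    if abs(lam - a) < RATE_DEGENERACY_RTOL * max(lam, a):
        tmax = 1.0 / a  # L'Hopital limit of ln(lam/a)/(lam-a)
        amax_per_kg = r.k_gutabs * dose_per_kg * tmax * math.exp(-a * tmax)
    else:
        tmax = math.log(lam / a) / (lam - a)
        amax_per_kg = (
            r.k_gutabs
            * dose_per_kg
            / (lam - a)
            * (math.exp(-a * tmax) - math.exp(-lam * tmax))
        )
    cmax = amax_per_kg / (p.V_dist * 1000.0)  # ng/mL
    return DerivedTK(
        t_half=math.log(2.0) / r.k_el,
        k_el=r.k_el,
        Tmax=tmax,
        Cmax=cmax,
        AUC_inf=p.F_gutabs * dose_per_kg / p.Cl_tot,
    )
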