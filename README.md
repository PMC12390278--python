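# citpoptk

Population toxicokinetics of the mycotoxin **citrinin (CIT)** in
humans: a parent + metabolite compartmental model with first-order
oral absorption, a hierarchical Bayesian population fit with
censoring-aware lognormal likelihoods, a synthetic emulation of a
10-volunteer single-oral-bolus biomonitoring trial, and the
chemical-specific adjustment factor for human inter-individual TK
variability (HK_AF).

The package is for risk assessors and modellers who want to go from
sparse, heavily censored biomonitoring measurements (capillary blood
concentrations and per-void urinary masses over 48 h) to population
TK parameter distributions — and from those to the question whether
the default uncertainty factor for human TK variability,
10<sup>1/2</sup> = 3.16, is protective for this compound.

## The model

An oral bolus enters the gut, is absorbed (rate k<sub>gutabs</sub>)
or lost to feces (k<sub>gutelim</sub>); from the central compartment
CIT goes to urine (k<sub>u</sub>) or is oxidised to dihydrocitrinone
(HO-CIT, k<sub>met</sub>), which clears into urine (k<sub>umet</sub>).
Sampled parameters are Cl<sub>tot</sub>, V<sub>dist</sub>,
k<sub>ufrac</sub>, F<sub>gutabs</sub>, k<sub>gutelim</sub>,
Cl<sub>met</sub>, V<sub>distmet</sub>, with
k<sub>el</sub> = Cl<sub>tot</sub>/V<sub>dist</sub>. Each subject's
ln-parameters are Normal(μ, σ) around population geometric means with
pig-scaled allometric priors; measurements are lognormal around the
model prediction and censored at the assay's LOD/LLOQ/ULOQ. The
factor for human TK variability is

HK_AF = GSD<sub>AUC</sub><sup>Q<sub>norm</sub>(0.95)</sup>

where GSD<sub>AUC</sub> is the population geometric standard
deviation of the AUC extrapolated to infinity. See
[docs/methods.md](docs/methods.md) for the full account.

## Worked example

```python
from citpoptk import compute_hkaf, derived_tk
from citpoptk.synthetic_trial import central_params

res = compute_hkaf(1.49)   # population GSD of AUC from the 10-volunteer fit
print(f"HK_AF = {res.hk_af:.4f}  (default factor {res.default_factor:.2f})")

d = derived_tk(central_params(), 200.0)   # pig-scaled priors, trial dose
print(f"t_half = {d.t_half:.2f} h, Cmax = {d.Cmax:.4f} ng/mL")
```

prints

```
HK_AF = 1.9269  (default factor 3.16)
t_half = 15.60 h, Cmax = 0.0307 ng/mL
```

i.e. a 1.49-fold geometric SD in AUC implies that a factor of ~1.93
covers the 95th percentile of the population — comfortably below the
default 3.16 — and the pig-scaled parameters predict a blood peak of
only ~0.03 ng/mL at the 200 ng/kg bw trial dose, right at the assay's
detection limit, which is why the population fit must work largely
from censored observations.

## The analysis pipeline

Numbered drivers under `analysis/` run the whole study on a synthetic
trial and write their tables under `results/`:

```bash
python analysis/01_generate_trial.py      # 10 subjects, 120 blood + ~97 urine records
python analysis/02_deterministic_model.py # pig-scaled forward simulation per subject
python analysis/03_fit_poptk.py           # 4 chains x 2500 MCMC, R-hat report
python analysis/04_posterior_report.py    # parameter summaries, HK_AF, pred-vs-obs
python analysis/05_recovery.py            # 5-seed coverage experiment (~10 min)
```

At the default seed the fit reports `max R-hat = 1.034 (converged)`
and the report stage prints
`GSD_AUC = 1.260; HK_AF = 1.463 <= default factor 3.16`: the
synthetic population was generated with a parameter GSD of 1.5, and
the fitted across-subject AUC variability lands near it, again below
the default factor.

The same stages are available as a console script
(`citpoptk generate|simulate|fit|report|recover`) and as library
functions (`citpoptk.pipeline`).

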