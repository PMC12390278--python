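# Methods

## The compartmental model

Citrinin (CIT) is modelled as a linear first-order cascade. An oral
bolus `D = dose_per_kg * bw` (ng) enters the gut lumen, from which it
is either absorbed into a central blood compartment (rate `k_gutabs`,
1/h) or lost to feces (`k_gutelim`). From the central compartment CIT
is excreted in urine (`k_u`) or oxidised to dihydrocitrinone (HO-CIT,
`k_met`), which occupies its own central compartment and is cleared
into urine (`k_umet`). Volumes of distribution `V_dist` and
`V_distmet` (L/kg bw) convert amounts to blood concentrations.
Enterohepatic recirculation, multiple dosing and saturable kinetics
are out of scope.

The sampled (natural-scale) parameters per subject are
`Cl_tot` and `V_dist` (clearance and volume of CIT), `k_ufrac` (the
fraction of eliminated CIT going to urine), `F_gutabs` (the fraction
of the oral dose absorbed), `k_gutelim`, and `Cl_met`, `V_distmet` for
the metabolite. Rates derive as

    k_el    = Cl_tot / V_dist          k_u   = k_ufrac * k_el
    k_met   = (1 - k_ufrac) * k_el     k_umet = Cl_met / V_distmet
    k_gutabs = k_gutelim * F_gutabs / (1 - F_gutabs)

so that `k_gutabs / (k_gutabs + k_gutelim) = F_gutabs` exactly.
`F_gutabs = 1` is excluded (it would require an infinite absorption
rate); the prior support is open at 1. This clearance/volume
parameterization is used because the published posterior summaries
report exactly these quantities, and the printed elimination rate
equals the clearance-to-volume ratio to rounding; the redundant
rate-based prior set (a direct prior on the total elimination rate and
on the metabolite's urinary rate) is exposed as an alternative
(`rate_parameterization_priors`) but not wired into the default fit.

Because the system is a linear cascade, trajectories have closed
Bateman-type forms; these are used everywhere for speed. When any two
of the cascade rates (`k_el`, `lambda_gut = k_gutabs + k_gutelim`,
`k_umet`) coincide within a relative `1e-8`, the shared-denominator
terms cancel catastrophically and the simulator silently (but logged)
falls back to an adaptive Runge-Kutta integration (`DOP853`,
`rtol = 1e-12`, absolute tolerance `1e-16` of the administered mass).
The ODE route doubles as an independent numerical oracle: the test
suite checks agreement with the closed form to `1e-8` relative and
mass conservation at every output time. Notably, the pig-scaled
central values themselves are degenerate (`Cl_met/V_distmet =
Cl_tot/V_dist`), so deterministic simulations at the centrals run
through the ODE path.

Units: amounts ng, volumes L/kg bw, time h, concentrations ng/mL
(amount / (V * bw * 1000)). The AUC extrapolated to infinity is
`F_gutabs * dose_per_kg / Cl_tot` in ng·h/L for a kg-normalised dose.
(The published unit for AUC omits the time dimension; ng·h/L is used
here and the discrepancy noted.) Derived kinetics are `t_half =
ln 2 / k_el`, `Tmax = ln(lambda_gut/k_el) / (lambda_gut - k_el)`
(limit `1/k_el`), and `Cmax` evaluated at `Tmax`. Derived Tmax/Cmax
are reported for a configurable dose, 1500 ng/kg bw by default to
match the published summary tables (the trial itself used 200).

## The hierarchical population model

Each kinetic parameter `p` has a population geometric mean `exp(mu_p)`
and geometric SD `exp(sigma_p)`. Subjects' ln-parameters are
`Normal(mu_p, sigma_p)` truncated to the same support as the prior
(fractions to (0, 1); `k_ufrac` additionally bounded below at 0.01).
Priors on `mu_p` are normal on the ln scale, centred on allometrically
pig-scaled values (clearances 0.04 L/(h·kg), volumes 0.9 L/kg,
fractions 0.5 and 0.17, gut elimination 0.5 1/h) with ln-scale SD
1.15, truncated for the fraction parameters.

The population variances and residual errors have no published
hyperpriors; the package's choices are: `ln(sigma_p^2)` uniform on
`[ln(ln^2 1.05), ln(ln^2 3.16)]` (population GSD between 1.05 and
3.16 — from negligible variability to the default TK uncertainty
factor), and `ln(error GSD)` uniform on `[ln 1.01, ln 3.0]` per
matrix, bracketing the validated assay precision without fixing it.

### Observation model and censoring

Measured values are lognormal around the model prediction with a
per-matrix error GSD. Blood observations are central-compartment
concentrations at the scheduled times; urine observations are
cumulative excreted masses at void times (the quantity the trial's
excretion plots use). Values outside the assay's validated range
enter as censored probabilities: below the LOD, between LOD and LLOQ,
or above the ULOQ, each a lognormal tail/interval probability. These
are computed in log space (`log_ndtr` and a complementary-tail
interval form) because the naive CDF difference underflows exactly in
the regime this trial lives in — predictions far below the LOD.
Since urine limits are concentrations, censored urine voids are
compared on the concentration scale (predicted mass increment over
recorded void volume). A prediction of exactly zero (the pre-dose
sample) is floored at `1e-12 * LOD` before logs. HO-CIT and fecal
records never enter the likelihood: the trial produced no usable
measurements for them (no metabolite standard; no fecal masses), so
the metabolite posterior simply reflects its prior.

## Posterior sampling

The sampler is Metropolis-within-Gibbs on the flat ln-scale vector
(7 population means, 7 ln-variances, 2 ln-error-GSDs, 7 per subject):

1. a componentwise random-walk scan with per-coordinate scales adapted
   during burn-in (Robbins-Monro towards 0.44 acceptance, diminishing
   steps, frozen afterwards);
2. Metropolized-Gibbs sweeps for the hyperparameters: conditional on
   the subjects, each population mean has a conjugate normal full
   conditional and each variance a truncated inverse-gamma one; both
   are used as independence proposals with a Metropolis-Hastings
   correction for the truncation-normalizer factor the conjugate form
   ignores (acceptance near 1);
3. adaptive-covariance block moves (Haario-style, burn-in only): one
   7-dimensional block per subject and one 16-dimensional population
   block that carries every subject along as a fixed standardized
   residual (the non-centered/ancillary view of the hierarchy, with
   the appropriate Jacobian);
4. explicit ridge translations: with most blood samples censored, the
   data pin down only combinations of parameters — raising `Cl_tot`,
   `V_dist`, `F_gutabs` and lowering `k_ufrac` together preserves the
   elimination rate, blood amplitude, AUC and urinary recovery at
   once. Scalar moves along these directions (population-wide and per
   subject) let chains traverse the ridge instead of diffusing along
   it.

All moves leave the posterior invariant; adaptation happens during
burn-in only, so the post-burn-in chains are valid Markov chains.
Initialization follows the prior centrals (population GSD 1.5,
error GSD 1.2, subjects at the population means), jittered per chain
by ±0.1 on the ln scale. Draws are bitwise reproducible given the
seed (one child stream per chain).

Convergence uses the classic Gelman-Rubin potential scale reduction
on whole post-burn-in chains (the split variant is available behind a
flag), with the conventional value 1 for zero-variance chains and a
pass threshold of 1.2 over every population and individual parameter.
Summaries refuse to run on unconverged draws unless forced.

## The synthetic trial generator

The generator emulates the volunteer study the analysis was designed
for: 10 subjects, a single 200 ng/kg bw oral bolus at t = 0 (the
pre-dose sample is modelled as concentration zero under the
CIT-minimising diet), blood at 0, 0.25, 0.5, 1, 2, 4, 6, 8, 12, 24,
36, 48 h (120 records), urine voids with a first void 1-7 h post dose
and gaps uniform on 3-7 h (expected ~9.7 voids/subject, matching the
97 urine samples of the design), void volumes uniform on 100-400 mL,
body weights uniform on 55-90 kg (the real covariate table is not
reproduced here; body weight only scales absolute masses). Noise is
lognormal per measurement; censoring applies the validated limits to
what the assay actually measures (blood concentration; per-void urine
concentration). Two fecal events per subject are generated only to
exercise the file formats. The full ground truth (population draw,
subject parameters, noiseless curves) is retained for recovery tests.

What the generator does not emulate: diet-derived background
exposure, enterohepatic reabsorption steps in the excretion profile,
assay drift, hematocrit effects, or covariate structure — so a
passing recovery test demonstrates the estimator works under the
model's own assumptions, not that those assumptions hold in vivo.

The HO-CIT urinary-mass estimator multiplies a subject's cumulative
urinary CIT mass by a ratio drawn from Normal(10, 7/3) truncated to
[3, 17] (read as mean 10 with ±3 SD spanning the stated 3-17 range),
then truncates to the administered mass not recovered as CIT so mass
balance is preserved.

## The adjustment factor

Under the assumption that chronic effects track the AUC, the
chemical-specific adjustment factor for human TK variability is

    HK_AF = GSD_AUC ^ Qnorm(0.95)

the multiple of the population-median AUC that covers the 95th
percentile of a lognormal AUC distribution. `GSD_AUC` is taken, per
draw, as the across-subject geometric SD of the individual
`AUC_inf` values (posterior median reported), matching how the
10-subject trial is summarized; a population-parameter-based variant
(propagating the GSDs of `F_gutabs` and `Cl_tot` through the
lognormal ratio) is available via a flag. The result is compared
against the default human TK uncertainty factor `10^0.5 = 3.16`; at
the published `GSD_AUC = 1.49` the factor is 1.93, i.e. the default
is protective.

## Problem sizes and runtime choices

The fits run at 4 chains x 2,500 iterations with 50% burn-in
(~1.5-2 minutes each), the scale at which the convergence and
recovery experiments are run here; the recovery experiment uses five
independent seeds. The Monte-Carlo calibration of the censoring
branches uses 10^6 draws per configuration; oracle equivalence is
checked on 100 random parameter sets. Exact reproduction of the
original study's posterior numbers requires its raw volunteer data
and is out of scope; the synthetic-recovery properties above are the
package's evidence of correctness.

## Known limitations

- Identifiability at the pig-scaled truth is weak: most blood values
  fall below the LLOQ, so the posterior is wide along the ridge
  directions described above. The sampler handles this, but posterior
  CIs for `V_dist` and `F_gutabs` are broad by construction.
- The residual-error model (lognormal, per-matrix GSD) and the
  treatment of censored values are declared modelling choices; the
  original analysis did not document its versions of either.
- Between-occasion variability, covariate effects and correlated
  random effects are not modelled.
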