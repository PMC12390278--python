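#!/usr/bin/env python
"""Summarize the posterior: TK parameters, HK_AF, predicted vs observed.

Produces the population summary table (posterior median and 90% CI of
each parameter's geometric mean and geometric SD), the derived
kinetics (half-life, Tmax, Cmax, AUC to infinity; reported for a
1500 ng/kg bw dose), the predicted-vs-observed concordance per matrix,
and the chemical-specific adjustment factor for human TK variability
HK_AF = GSD_AUC^Qnorm(0.95), compared against the default uncertainty
factor 10^0.5 = 3.16.

Requires 01 and 03 to have run; writes to results/report/.
"""

from citpoptk.cli import main

if __name__ == "__main__":
    raise SystemExit(
        main([
            "report", "--seed", "1", "--data", "results/trial",
            "--draws", "results/fit/draws.csv", "--out", "results/report",
        ])
    )
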