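#!/usr/bin/env python
"""Deterministic forward simulation at the pig-scaled central values.

Simulates all six model outputs (gut mass, blood CIT, cumulative
urinary and fecal CIT, blood HO-CIT, cumulative urinary HO-CIT) for
every subject of the generated trial, with no inter-individual
variability and no noise. This is the pre-fit sanity view: the
pig-scaled parameters predict a terminal urinary recovery of
F_gutabs * k_ufrac = 8.5% of the dose, well below the ~20% reported in
human volunteers, which is precisely why the population fit updates
the priors.

Requires 01_generate_trial.py to have run (for the subject table);
writes per-subject trajectory tables to results/deterministic/.
"""

from citpoptk.cli import main

if __name__ == "__main__":
    raise SystemExit(
        main([
            "simulate", "--seed", "1", "--data", "results/trial",
            "--out", "results/deterministic",
        ])
    )
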