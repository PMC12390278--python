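"""Shared fixtures: small synthetic trials and the full-scale fits.

The full-scale fit fixture (10 subjects, 4 chains x 2500 iterations,
seeds 1-5) is expensive and session-scoped; the convergence and
parameter-recovery tests share it.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from citpoptk.config import RunConfig
from citpoptk.mcmc_engine import SamplerConfig, convergence_report
from citpoptk.pipeline import fit_dataset, generate_stage
from citpoptk.synthetic_trial import TrialDesign, default_population, generate_trial

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


RECOVERY_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def small_trial():
    """A 3-subject trial, cheap enough for likelihood unit tests."""
    design = TrialDesign(n_subjects=3)
    return generate_trial(design=design, seed=42)


@pytest.fixture(scope="session")
def smoke_fit(small_trial):
    """A short 2-chain fit of the 3-subject trial."""
    data, truth = small_trial
    cfg = RunConfig().with_seed(42)
    cfg = dataclasses.replace(
        cfg,
        sampler=SamplerConfig(n_chains=2, n_iter=400, seed=42),
    )
    samples, target = fit_dataset(data, cfg)
    return data, truth, samples, target


def run_full_scale_fit(seed: int):
    """One fit at the emulated trial's full design: 10 subjects,
    4 chains x 2500 iterations, 50% burn-in."""
    cfg = RunConfig().with_seed(seed)
    cfg = dataclasses.replace(
        cfg,
        sampler=dataclasses.replace(cfg.sampler, n_iter=2500, n_chains=4),
    )
    data, truth = generate_stage(cfg)
    samples, target = fit_dataset(data, cfg)
    return data, truth, samples


@pytest.fixture(scope="session")
def full_scale_fits():
    """Five independent synthetic trials fitted at full scale."""
    return {seed: run_full_scale_fit(seed) for seed in RECOVERY_SEEDS}
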