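"""Run configuration: a flat TOML file binding all pipeline settings.

Sections mirror the pipeline stages: ``[design]`` (trial design),
``[limits.blood]`` / ``[limits.urine]`` / ``[limits.feces]``
(quantification limits), ``[population]`` (generating GSDs for the
synthetic trial), ``[sampler]`` and ``[report]``.  Every field has a
default, so an empty file is a valid configuration.  The SHA-256 of the
canonical JSON form of the resolved configuration is stamped into every
output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .mcmc_engine import SamplerConfig
from .pop_likelihood import (
    MatrixLimits,
    PriorSpec,
    QuantLimits,
    default_limits,
    default_priors,
)
from .synthetic_trial import TrialDesign

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    design: TrialDesign = field(default_factory=TrialDesign)
    limits: QuantLimits = field(default_factory=default_limits)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    priors: list[PriorSpec] = field(default_factory=default_priors)
    population_gsd: float = 1.5
    err_gsd: float = 1.2
    reporting_dose_per_kg: float = 1500.0
    hkaf_percentile: float = 0.95
    seed: int = 0

    def with_seed(self, seed: int | None) -> "RunConfig":
        if seed is None:
            return self
        return dataclasses.replace(
            self, seed=seed, sampler=dataclasses.replace(self.sampler, seed=seed)
        )

    def to_dict(self) -> dict:
        return {
            "design": dataclasses.asdict(self.design),
            "priors": [dataclasses.asdict(p) for p in self.priors],
            "limits": {
                m: dataclasses.asdict(self.limits.for_matrix(m))
                for m in ("blood", "urine", "feces")
                if getattr(self.limits, m, None) is not None
            },
            "sampler": dataclasses.asdict(self.sampler),
            "population_gsd": self.population_gsd,
            "err_gsd": self.err_gsd,
            "reporting_dose_per_kg": self.reporting_dose_per_kg,
            "hkaf_percentile": self.hkaf_percentile,
            "seed": self.seed,
        }

    def sha256(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _build(cls, section: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - names
    if unknown:
        raise ValueError(
            f"invalid field {sorted(unknown)[0]!r} in config section [{context}]"
        )
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
    }
    return cls(**coerced)


def load_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    """Load a TOML configuration; missing sections fall back to defaults."""
    raw: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    known = {
        "design", "limits", "sampler", "priors", "population_gsd", "err_gsd",
        "reporting_dose_per_kg", "hkaf_percentile", "seed",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"invalid top-level config field {sorted(unknown)[0]!r}")

    design = _build(TrialDesign, raw.get("design", {}), "design")
    sampler = _build(SamplerConfig, raw.get("sampler", {}), "sampler")
    lim_raw = raw.get("limits", {})
    defaults = default_limits()
    limits = QuantLimits(
        blood=_build(MatrixLimits, lim_raw["blood"], "limits.blood")
        if "blood" in lim_raw else defaults.blood,
        urine=_build(MatrixLimits, lim_raw["urine"], "limits.urine")
        if "urine" in lim_raw else defaults.urine,
        feces=_build(MatrixLimits, lim_raw["feces"], "limits.feces")
        if "feces" in lim_raw else defaults.feces,
    )
    if "priors" in raw:
        priors = [
            _build(PriorSpec, {"name": name, **spec}, f"priors.{name}")
            for name, spec in raw["priors"].items()
        ]
    else:
        priors = default_priors()
    cfg = RunConfig(
        design=design,
        limits=limits,
        sampler=sampler,
        priors=priors,
        population_gsd=float(raw.get("population_gsd", 1.5)),
        err_gsd=float(raw.get("err_gsd", 1.2)),
        reporting_dose_per_kg=float(raw.get("reporting_dose_per_kg", 1500.0)),
        hkaf_percentile=float(raw.get("hkaf_percentile", 0.95)),
        seed=int(raw.get("seed", 0)),
    )
    return cfg.with_seed(seed)
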