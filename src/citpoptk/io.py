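"""CSV/JSON round-tripping for every table the pipeline produces.

All tables are comma-separated UTF-8 with a mandatory header row,
decimal point ".", and times in hours as decimals.  Each file starts
with a single comment line carrying the global seed and the SHA-256 of
the run configuration, so any output can be traced to the run that
produced it; readers skip comment lines.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .pop_likelihood import (
    MatrixLimits,
    Observation,
    QuantLimits,
    Subject,
    TrialDataset,
)
from .mcmc_engine import PosteriorSamples, SamplerConfig

__all__ = [
    "write_table",
    "read_table",
    "write_subjects",
    "read_subjects",
    "write_observations",
    "read_observations",
    "read_dataset",
    "write_dataset",
    "write_draws",
    "read_draws",
    "write_run_meta",
    "read_run_meta",
]

OBS_COLUMNS = ["subject_id", "matrix", "time_h", "value", "censor", "void_volume_mL"]
SUBJ_COLUMNS = ["subject_id", "bw_kg", "dose_ng_per_kg"]


def _header_line(seed: int | None, config_sha: str | None) -> str:
    return f"# seed={seed if seed is not None else 'NA'} config_sha256={config_sha or 'NA'}\n"


def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config_sha: str | None = None,
) -> Path:
    """Write a DataFrame as CSV with the provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_line(seed, config_sha))
        frame.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_subjects(subjects: list[Subject], path, seed=None, config_sha=None) -> Path:
    frame = pd.DataFrame(
        [
            {"subject_id": s.subject_id, "bw_kg": s.bw, "dose_ng_per_kg": s.dose_per_kg}
            for s in subjects
        ],
        columns=SUBJ_COLUMNS,
    )
    return write_table(frame, path, seed, config_sha)


def read_subjects(path) -> list[Subject]:
    frame = read_table(path)
    return [
        Subject(str(r.subject_id), bw=float(r.bw_kg), dose_per_kg=float(r.dose_ng_per_kg))
        for r in frame.itertuples()
    ]


def write_observations(
    observations: list[Observation], path, seed=None, config_sha=None
) -> Path:
    frame = pd.DataFrame(
        [
            {
                "subject_id": o.subject_id,
                "matrix": o.matrix,
                "time_h": o.time,
                "value": o.value,
                "censor": o.censor,
                "void_volume_mL": o.void_volume if o.void_volume is not None else np.nan,
            }
            for o in observations
        ],
        columns=OBS_COLUMNS,
    )
    return write_table(frame, path, seed, config_sha)


def read_observations(path) -> list[Observation]:
    frame = read_table(path)
    out = []
    for r in frame.itertuples():
        vol = None if pd.isna(r.void_volume_mL) else float(r.void_volume_mL)
        value = math.nan if pd.isna(r.value) else float(r.value)
        out.append(
            Observation(
                str(r.subject_id), str(r.matrix), float(r.time_h), value,
                str(r.censor), void_volume=vol,
            )
        )
    return out


def write_dataset(
    data: TrialDataset, out_dir: str | Path, seed=None, config_sha=None
) -> dict[str, Path]:
    out_dir = Path(out_dir)
    paths = {
        "subjects": write_subjects(
            data.subjects, out_dir / "subjects.csv", seed, config_sha
        ),
        "observations": write_observations(
            data.observations, out_dir / "observations.csv", seed, config_sha
        ),
    }
    limits = {
        m: vars(data.limits.for_matrix(m))
        for m in ("blood", "urine", "feces")
        if getattr(data.limits, m, None) is not None
    }
    meta_path = out_dir / "limits.json"
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump({"horizon_h": data.horizon, "limits": limits}, fh, indent=1)
    paths["limits"] = meta_path
    return paths


def read_dataset(in_dir: str | Path) -> TrialDataset:
    in_dir = Path(in_dir)
    with open(in_dir / "limits.json", encoding="utf-8") as fh:
        meta = json.load(fh)
    lims = {m: MatrixLimits(**v) for m, v in meta["limits"].items()}
    limits = QuantLimits(
        blood=lims["blood"], urine=lims["urine"], feces=lims.get("feces")
    )
    return TrialDataset(
        subjects=read_subjects(in_dir / "subjects.csv"),
        observations=read_observations(in_dir / "observations.csv"),
        limits=limits,
        horizon=float(meta.get("horizon_h", 48.0)),
    )


def write_draws(samples: PosteriorSamples, path, seed=None, config_sha=None) -> Path:
    return write_table(samples.to_long_frame(), path, seed, config_sha)


def read_draws(path, n_burn_stored: int, config: SamplerConfig | None = None) -> PosteriorSamples:
    frame = read_table(path)
    if frame.empty:
        raise ValueError(f"draws file {path} holds no samples")
    return PosteriorSamples.from_long_frame(frame, n_burn_stored, config)


def write_run_meta(path, meta: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, default=str)
    return path


def read_run_meta(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
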