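"""Configuration, CSV/JSON file I/O and run provenance.

CSV dialect: comma-separated, dot decimal, UTF-8, header row with
unit-suffixed column names.  Every JSON report carries a provenance block
(config hash, seed, package version) but no timestamps, so re-running a
command with the same configuration reproduces byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .engine import ConcentrationTimeProfile, DosingRegimen

PROFILE_COLUMNS = ["time_h", "conc_ng_per_mL", "individual_id", "percentile_tag"]


class RunConfig(BaseModel):
    """Schema-validated run configuration for the CLI."""

    compound_file: Optional[str] = None
    physiology_preset: str = "european_adult"
    dose_mg: float = Field(default=10.0, ge=0)
    n_doses: int = Field(default=1, ge=1)
    interval_h: float = Field(default=12.0, gt=0)
    duration_h: float = Field(default=72.0, gt=0)
    impairment: Optional[str] = None
    age: Optional[float] = None
    n_individuals: int = Field(default=6, ge=1)
    seed: int = 0
    output_dir: str = "."

    def regimen(self) -> DosingRegimen:
        return DosingRegimen(
            dose_mg=self.dose_mg, n_doses=self.n_doses,
            interval_h=self.interval_h, duration_h=self.duration_h,
        )


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig(**yaml.safe_load(fh))


def config_hash(params: dict) -> str:
    canonical = json.dumps(params, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def provenance_block(params: dict, seed: int) -> dict:
    return {"config_hash": config_hash(params), "seed": seed, "version": __version__}


def write_json_report(path, payload: dict, params: dict, seed: int) -> None:
    payload = dict(payload)
    payload["provenance"] = provenance_block(params, seed)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_profile_csv(path, profile: ConcentrationTimeProfile, percentile_tag: str = "") -> None:
    df = pd.DataFrame(
        {
            "time_h": profile.times_h,
            "conc_ng_per_mL": profile.conc_ng_per_ml,
            "individual_id": profile.individual_id,
            "percentile_tag": percentile_tag,
        }
    )
    df.to_csv(path, index=False)


def read_profile_csv(path, regimen: Optional[DosingRegimen] = None) -> ConcentrationTimeProfile:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"time_h", "conc_ng_per_mL"} - set(df.columns)
    if missing:
        raise ValueError(
            f"malformed profile CSV {path}: missing columns {sorted(missing)} "
            f"(expected unit-suffixed header {PROFILE_COLUMNS[:2]})"
        )
    ids = df["individual_id"].unique() if "individual_id" in df.columns else ["reference"]
    return ConcentrationTimeProfile(
        np.asarray(df["time_h"], dtype=float),
        np.asarray(df["conc_ng_per_mL"], dtype=float),
        regimen,
        str(ids[0]),
    )
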