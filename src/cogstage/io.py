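"""File formats and run configuration.

Single long-format visits CSV (one row per participant-visit), per-scan PET
CSV, and a per-test norm-model CSV.  UTF-8, "." decimal, empty string =
missing.  Unparseable cells become missing values (with a logged count);
range violations on bounded scales are hard errors.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .norms import DEFAULT_BATTERY, NormModel
from .simulate import SimConfig
from .staging import FlagThresholds

__all__ = [
    "VisitRecord",
    "FormatError",
    "RunConfig",
    "read_visits",
    "write_visits",
    "read_pet",
    "write_pet",
    "read_norm_model",
    "write_norm_model",
    "load_run_config",
    "config_hash",
    "get_logger",
]

log = logging.getLogger("cogstage")


def get_logger(logfile: str | Path | None = None) -> logging.Logger:
    """Logger to stderr and optionally a file, shared by all stages."""
    if not log.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        log.addHandler(h)
        log.setLevel(logging.INFO)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
        log.addHandler(fh)
    return log


class FormatError(ValueError):
    """Malformed input table."""


MANDATORY_COLUMNS = ("participant_id", "visit_index", "age", "sex", "wrat3_std")

RATING_COLUMNS = (
    "cdr_global",
    "qdrs_global",
    "iadl",
    "iqcode",
    "self_memory_problem",
    "self_memory_likert",
)


@dataclass
class VisitRecord:
    """One participant-visit: demographics, raw scores, ratings."""

    participant_id: str
    visit_index: int
    age: float
    sex: int
    wrat3_std: float
    raw_scores: dict[str, float] = field(default_factory=dict)
    cdr_global: float = float("nan")
    qdrs_global: float = float("nan")
    iadl: float = float("nan")
    iqcode: float = float("nan")
    self_memory_problem: str | None = None
    self_memory_likert: float = float("nan")
    latent_state: str | None = None

    def get(self, key: str, default=None):
        if key in self.raw_scores:
            return self.raw_scores[key]
        return getattr(self, key, default)


def _validate_visits(df: pd.DataFrame) -> None:
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory columns: {', '.join(missing)}")
    checks = [
        ("iadl", 0, 16),
        ("iqcode", 16, 80),
        ("self_memory_likert", 1, 7),
        ("visit_index", 1, np.inf),
    ]
    for col, lo, hi in checks:
        if col not in df.columns:
            continue
        v = pd.to_numeric(df[col], errors="coerce")
        bad = v.notna() & ((v < lo) | (v > hi))
        if bad.any():
            raise FormatError(
                f"column {col!r}: {int(bad.sum())} value(s) outside [{lo}, {hi}]"
            )
    for pid, grp in df.groupby("participant_id", sort=False):
        vi = grp["visit_index"].to_numpy(float)
        ages = grp["age"].to_numpy(float)
        if not (np.diff(vi) > 0).all() or not (np.diff(ages) > 0).all():
            raise FormatError(
                f"participant {pid}: visit_index and age must strictly increase"
            )


def read_visits(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format visits CSV."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    if df.empty:
        log.warning("visits file %s has an empty data section", path)
        return df
    numeric = [c for c in df.columns if c not in ("participant_id", "self_memory_problem", "latent_state")]
    n_bad = 0
    for c in numeric:
        coerced = pd.to_numeric(df[c], errors="coerce")
        n_bad += int((coerced.isna() & df[c].notna()).sum())
        df[c] = coerced
    if n_bad:
        log.warning("%d unparseable cell(s) set to missing", n_bad)
    _validate_visits(df)
    return df


def write_visits(df: pd.DataFrame, path: str | Path) -> None:
    cols = list(MANDATORY_COLUMNS)
    cols += [t for t in DEFAULT_BATTERY if t in df.columns]
    cols += [c for c in RATING_COLUMNS if c in df.columns]
    if "latent_state" in df.columns:
        cols.append("latent_state")
    df.to_csv(path, index=False, columns=cols)


PET_COLUMNS = ("participant_id", "scan_age", "global_pib_dvr")


def read_pet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in PET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory PET columns: {', '.join(missing)}")
    for c in df.columns:
        if c.startswith(("global_", "suvr_", "scan_")):
            df[c] = pd.to_numeric(df[c], errors="coerce")
            if (df[c].dropna() <= 0).any():
                raise FormatError(f"column {c!r}: values must be positive")
    return df


def write_pet(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_norm_model(model: NormModel, path: str | Path) -> None:
    model.to_frame().to_csv(path, index=False)


def read_norm_model(path: str | Path) -> NormModel:
    return NormModel.from_frame(pd.read_csv(path))


@dataclass
class RunConfig:
    """Validation-run configuration: paths, thresholds, analysis toggles."""

    out_dir: str = "cogstage_out"
    visits_path: str | None = None
    pet_path: str | None = None
    norms_path: str | None = None
    seed: int = 20210
    alpha: float = 0.05
    fdr_q: float = 0.05
    run_concurrent: bool = True
    run_change: bool = True
    run_progression: bool = True
    run_biomarker: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: FlagThresholds = field(default_factory=FlagThresholds)

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.fdr_q < 1):
            raise ValueError("alpha and fdr_q must lie in (0, 1)")


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration mirroring RunConfig field names."""
    raw: Mapping = yaml.safe_load(Path(path).read_text()) or {}
    sim_kwargs = dict(raw.pop("sim", {}) or {})
    if "transition_matrix" in sim_kwargs:
        sim_kwargs["transition_matrix"] = np.asarray(sim_kwargs["transition_matrix"], float)
    thr_kwargs = dict(raw.pop("thresholds", {}) or {})
    known = {f.name for f in dc_fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    if sim_kwargs:
        cfg.sim = SimConfig(**sim_kwargs)
    if thr_kwargs:
        cfg.thresholds = FlagThresholds(**thr_kwargs)
    if "seed" in raw or "seed" not in sim_kwargs:
        cfg.sim.seed = cfg.seed
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full configuration, stamped on outputs."""
    parts = []
    for f in dc_fields(RunConfig):
        if f.name == "out_dir":  # output location does not change the science
            continue
        v = getattr(cfg, f.name)
        if f.name == "sim":
            v = {k: (np.asarray(val).tolist() if k == "transition_matrix" else val)
                 for k, val in v.__dict__.items()}
        elif f.name == "thresholds":
            v = v.__dict__
        parts.append(f"{f.name}={v!r}")
    return hashlib.sha256("|".join(parts).encode()).hexdigest()[:12]
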