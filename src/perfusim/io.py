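"""File formats: batch-record CSV schema, parameter JSON, run configs.

The batch-record CSV is the portable exchange format for measured perfusion
runs: one row per sample, units fixed in the column names so they cannot
drift silently.

Mandatory columns::

    time_d, xv_e6_per_ml, viability, bleed_ml_d, feed_ml_d,
    temp_c, ph, volume_ml

Optional columns: ``titer_norm`` (normalized product concentration) and
``diameter_um`` (mean cell diameter).  Unknown columns are preserved as
annotations.
"""

from __future__ import annotations

import dataclasses
import glob as _glob
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .kinetics import KineticParams, QuadraticEffect

__all__ = [
    "BatchRecord",
    "MANDATORY_COLUMNS",
    "read_batch_record",
    "read_batch_records",
    "write_batch_record",
    "params_to_dict",
    "params_from_dict",
    "save_params",
    "load_params",
    "load_config",
]

MANDATORY_COLUMNS = (
    "time_d",
    "xv_e6_per_ml",
    "viability",
    "bleed_ml_d",
    "feed_ml_d",
    "temp_c",
    "ph",
    "volume_ml",
)


@dataclass
class BatchRecord:
    """Measured time series of one perfusion run."""

    batch_id: str
    time_d: np.ndarray
    xv: np.ndarray
    viability: np.ndarray
    bleed_ml_d: np.ndarray
    feed_ml_d: np.ndarray
    temp_c: np.ndarray
    ph: np.ndarray
    volume_ml: float
    titer_norm: np.ndarray | None = None
    diameter_um: np.ndarray | None = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "time_d", "xv", "viability", "bleed_ml_d", "feed_ml_d",
            "temp_c", "ph",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        n = self.time_d.size
        for name in ("xv", "viability", "bleed_ml_d", "feed_ml_d",
                     "temp_c", "ph"):
            if np.asarray(getattr(self, name)).size != n:
                raise ValueError(f"column {name} has wrong length")
        if np.any(np.diff(self.time_d) <= 0):
            raise ValueError(
                f"batch {self.batch_id}: sample times must be increasing"
            )
        bad = np.flatnonzero(
            (self.viability <= 0) | (self.viability > 1.0)
        )
        if bad.size:
            raise ValueError(
                f"batch {self.batch_id}: viability outside (0, 1] at "
                f"rows {bad.tolist()}"
            )
        neg = np.flatnonzero(
            (self.xv < 0) | (self.bleed_ml_d < 0) | (self.feed_ml_d < 0)
        )
        if neg.size:
            raise ValueError(
                f"batch {self.batch_id}: negative density or flow at "
                f"rows {neg.tolist()}"
            )
        if self.volume_ml <= 0:
            raise ValueError("volume_ml must be positive")

    def to_frame(self) -> pd.DataFrame:
        data = {
            "time_d": self.time_d,
            "xv_e6_per_ml": self.xv,
            "viability": self.viability,
            "bleed_ml_d": self.bleed_ml_d,
            "feed_ml_d": self.feed_ml_d,
            "temp_c": self.temp_c,
            "ph": self.ph,
            "volume_ml": np.full(self.time_d.size, self.volume_ml),
        }
        if self.titer_norm is not None:
            data["titer_norm"] = self.titer_norm
        if self.diameter_um is not None:
            data["diameter_um"] = self.diameter_um
        for key, value in self.annotations.items():
            data[key] = value
        return pd.DataFrame(data)


def read_batch_record(path: str) -> BatchRecord:
    """Load and validate one batch-record CSV."""
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    known = set(MANDATORY_COLUMNS) | {"titer_norm", "diameter_um"}
    annotations = {
        c: df[c].to_numpy() for c in df.columns if c not in known
    }
    return BatchRecord(
        batch_id=os.path.splitext(os.path.basename(path))[0],
        time_d=df["time_d"].to_numpy(),
        xv=df["xv_e6_per_ml"].to_numpy(),
        viability=df["viability"].to_numpy(),
        bleed_ml_d=df["bleed_ml_d"].to_numpy(),
        feed_ml_d=df["feed_ml_d"].to_numpy(),
        temp_c=df["temp_c"].to_numpy(),
        ph=df["ph"].to_numpy(),
        volume_ml=float(df["volume_ml"].iloc[0]),
        titer_norm=(
            df["titer_norm"].to_numpy() if "titer_norm" in df else None
        ),
        diameter_um=(
            df["diameter_um"].to_numpy() if "diameter_um" in df else None
        ),
        annotations=annotations,
    )


def read_batch_records(path_or_glob) -> list[BatchRecord]:
    """Load one file, a glob pattern, or a list of paths."""
    if isinstance(path_or_glob, (list, tuple)):
        paths = list(path_or_glob)
    else:
        paths = sorted(_glob.glob(str(path_or_glob))) or [str(path_or_glob)]
    return [read_batch_record(p) for p in paths]


def write_batch_record(record: BatchRecord, path: str) -> None:
    record.to_frame().to_csv(path, index=False)


# --------------------------------------------------------------------------
# kinetic parameter JSON
# --------------------------------------------------------------------------

def params_to_dict(p: KineticParams) -> dict:
    d = {
        name: float(np.asarray(getattr(p, name)))
        for name in ("mu_max", "kd", "kt", "kl", "K_I_phib", "kls", "kbh")
    }
    d["quad_effects"] = [
        {
            "input_name": q.input_name,
            "target": q.target,
            "theta": float(np.asarray(q.theta)),
            "scale_c": q.scale_c,
            "parameterization": q.parameterization,
        }
        for q in p.quad_effects
    ]
    return d


def params_from_dict(d: dict) -> KineticParams:
    quads = tuple(
        QuadraticEffect(**q) for q in d.get("quad_effects", [])
    )
    kwargs = {
        k: d[k]
        for k in ("mu_max", "kd", "kt", "kl", "K_I_phib", "kls", "kbh")
        if k in d
    }
    p = KineticParams(quad_effects=quads, **kwargs)
    p.validate()
    return p


def save_params(p: KineticParams, path: str, **extra) -> None:
    payload = params_to_dict(p)
    payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_params(path: str) -> KineticParams:
    with open(path) as fh:
        return params_from_dict(json.load(fh))


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

_KNOWN_SECTIONS = {
    "paths", "model", "recipe", "controller", "pso", "mlp",
    "optimizer", "noise", "seed", "log_level",
}


def load_config(path: str) -> dict:
    """Read a YAML run config and reject unknown top-level sections."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(cfg) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(f"{path}: unknown config section(s) {sorted(unknown)}")
    return cfg


def dump_resolved_config(cfg: dict, path: str) -> None:
    """Write the fully resolved config next to a run's outputs."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
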