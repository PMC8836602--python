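"""Configuration, file formats and run manifests.

All artifacts are plain text: YAML for configuration and manifests, TSV
(6-decimal fixed point) for numeric tables, JSON for summaries.  Every
output file carries a header naming the producing version and the
configuration hash, so a run can be re-traced from its artifacts.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .environments import PKA, REFERENCE_GAS_TARGETS
from .free_energy import FEPFrame, FreeEnergyProfile

__all__ = [
    "ConfigError",
    "PipelineConfig",
    "read_config",
    "config_hash",
    "RunManifest",
    "write_frames_tsv",
    "read_frames_tsv",
    "write_profile_tsv",
    "write_json",
    "write_table_tsv",
]

logger = logging.getLogger(__name__)

_VALID_SUBSTRATES = ("HIS", "NMH")
_VALID_ENVIRONMENTS = ("gas", "water", "enzyme")


class ConfigError(ValueError):
    """Configuration schema violation, with the offending key path."""


_SCHEDULE_DEFAULTS = {
    "n_windows": 51,
    "steps_per_window": 20_000,
    "equilibration_fraction": 0.1,
    "timestep_fs": 0.5,
    "friction_per_ps": 1.0,
    "sample_stride": 10,
}
_REPLICA_DEFAULTS = {"n_replicas": 10, "relaxation_steps": 2_000}
_CALIBRATION_DEFAULTS = {"tol": 0.1, "max_iter": 12, "seed": None}


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration with defaults filled in."""

    substrates: list[str]
    environments: list[str]
    temperature: float = 300.0
    ph: float = 7.4
    pka: dict = dataclasses.field(default_factory=lambda: dict(PKA))
    seed: int = 1
    restraint_k: float = 0.5
    schedule: dict = dataclasses.field(default_factory=lambda: dict(_SCHEDULE_DEFAULTS))
    replicas: dict = dataclasses.field(default_factory=lambda: dict(_REPLICA_DEFAULTS))
    calibration: dict = dataclasses.field(default_factory=lambda: dict(_CALIBRATION_DEFAULTS))
    reference_targets: dict = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in REFERENCE_GAS_TARGETS.items()}
    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _check_keys(d: dict, allowed: set, path: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) at {path}: {sorted(unknown)}")


def _merge_section(raw: dict, defaults: dict, path: str) -> dict:
    _check_keys(raw, set(defaults), path)
    out = dict(defaults)
    out.update(raw)
    return out


def validate_config(raw: dict) -> PipelineConfig:
    """Validate a raw config mapping; fill defaults; reject unknown keys."""
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    allowed = {
        "substrates",
        "environments",
        "temperature",
        "ph",
        "pka",
        "seed",
        "restraint_k",
        "schedule",
        "replicas",
        "calibration",
        "reference_targets",
    }
    _check_keys(raw, allowed, "<root>")
    subs = raw.get("substrates", list(_VALID_SUBSTRATES))
    if isinstance(subs, str):
        subs = [subs]
    for s in subs:
        if s not in _VALID_SUBSTRATES:
            raise ConfigError(f"substrates: unknown substrate {s!r}")
    envs = raw.get("environments", list(_VALID_ENVIRONMENTS))
    if isinstance(envs, str):
        envs = [envs]
    for e in envs:
        if e not in _VALID_ENVIRONMENTS:
            raise ConfigError(f"environments: unknown environment {e!r}")

    pka = dict(PKA)
    pka.update(raw.get("pka") or {})
    corrected = any(e in ("water", "enzyme") for e in envs)
    if corrected:
        for s in subs:
            if pka.get(s) is None:
                raise ConfigError(f"pka.{s}: required for corrected (water/enzyme) runs")

    refs = {k: dict(v) for k, v in REFERENCE_GAS_TARGETS.items()}
    for s, tgt in (raw.get("reference_targets") or {}).items():
        if s not in _VALID_SUBSTRATES:
            raise ConfigError(f"reference_targets.{s}: unknown substrate")
        _check_keys(tgt, {"dg_act", "dg_rxn"}, f"reference_targets.{s}")
        refs[s].update(tgt)

    cfg = PipelineConfig(
        substrates=list(subs),
        environments=list(envs),
        temperature=float(raw.get("temperature", 300.0)),
        ph=float(raw.get("ph", 7.4)),
        pka=pka,
        seed=int(raw.get("seed", 1)),
        restraint_k=float(raw.get("restraint_k", 0.5)),
        schedule=_merge_section(raw.get("schedule") or {}, _SCHEDULE_DEFAULTS, "schedule"),
        replicas=_merge_section(raw.get("replicas") or {}, _REPLICA_DEFAULTS, "replicas"),
        calibration=_merge_section(
            raw.get("calibration") or {}, _CALIBRATION_DEFAULTS, "calibration"
        ),
        reference_targets=refs,
    )
    if cfg.temperature <= 0:
        raise ConfigError("temperature: must be > 0")
    if cfg.restraint_k < 0:
        raise ConfigError("restraint_k: must be >= 0")
    return cfg


def read_config(path: str | Path) -> PipelineConfig:
    """Read and validate a YAML pipeline configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    cfg = validate_config(raw)
    logger.info("configuration %s validated; effective values: %s", path, cfg.to_dict())
    return cfg


def config_hash(cfg: PipelineConfig) -> str:
    """Short stable hash of the effective configuration."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclasses.dataclass
class RunManifest:
    """Everything needed to bit-reproduce a run."""

    config: dict
    config_hash: str
    base_seed: int
    environment_tag: str | None = None
    substrate_tag: str | None = None
    version: str = __version__
    created_utc: str = dataclasses.field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _header(cfg_hash: str) -> str:
    return f"# maoevb {__version__} config={cfg_hash}\n"


FRAME_COLUMNS = ["replica", "lambda", "step", "eps1", "eps2", "emap", "eg"]


def write_frames_tsv(frames: list[FEPFrame], path: str | Path, cfg_hash: str, stride: int = 10) -> None:
    """Energy frames as TSV: replica, lambda, step, eps1, eps2, emap, eg."""
    parts = []
    for f in frames:
        n = f.n_samples
        parts.append(
            pd.DataFrame(
                {
                    "replica": np.full(n, f.replica_id, dtype=int),
                    "lambda": np.full(n, f.lam),
                    "step": np.arange(n) * stride,
                    "eps1": f.eps1,
                    "eps2": f.eps2,
                    "emap": f.emap,
                    "eg": f.eg,
                }
            )
        )
    table = pd.concat(parts, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(_header(cfg_hash))
        table.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_frames_tsv(path: str | Path, h12=None) -> list[FEPFrame]:
    """Read frames back; schema violations name the offending line."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed energy TSV {path}: {err}") from None
    missing = [c for c in FRAME_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"energy TSV {path} lacks column(s) {missing}")
    bad = table[FRAME_COLUMNS].isna().any(axis=1)
    if bad.any():
        # +3 = 1-based, header line and comment line
        line = int(bad.idxmax()) + 3
        raise ValueError(f"energy TSV {path}: incomplete record at line {line}")
    frames = []
    for (rep, lam), grp in table.groupby(["replica", "lambda"], sort=True):
        frames.append(
            FEPFrame(
                lam=float(lam),
                eps1=grp["eps1"].to_numpy(),
                eps2=grp["eps2"].to_numpy(),
                emap=grp["emap"].to_numpy(),
                eg=grp["eg"].to_numpy(),
                replica_id=int(rep),
                emap_atol=2e-6,  # 6-decimal TSV rounding
            )
        )
    return frames


def write_profile_tsv(profile: FreeEnergyProfile, path: str | Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg_hash))
        profile.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6f")


def write_table_tsv(table: pd.DataFrame, path: str | Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg_hash))
        table.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def write_json(obj: dict, path: str | Path, cfg_hash: str) -> None:
    payload = {"_meta": {"version": __version__, "config": cfg_hash}}
    payload.update(obj)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n")
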