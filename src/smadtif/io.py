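"""Artifact writers and run-configuration handling.

Every artifact directory gets a manifest (config hash, package version,
timestamp) sufficient to rerun the computation.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import yaml

from . import __version__
from .simulate import Trajectory


def write_trajectory(traj: Trajectory, out_dir, stem: str = "trajectory",
                     tidy: bool = True) -> Path:
    """Write a trajectory as wide CSV (and tidy CSV when requested) plus a
    JSON metadata sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wide = out / f"{stem}_wide.csv"
    traj.to_frame(tidy=False).to_csv(wide, index=False)
    if tidy:
        traj.to_frame(tidy=True).to_csv(out / f"{stem}_tidy.csv", index=False)
    meta = {
        "protocol": {k: v for k, v in vars(traj.protocol).items()},
        "diagnostics": traj.diagnostics,
        "species": traj.species,
        "package_version": __version__,
    }
    if traj.system is not None:
        meta["variant"] = {
            "mechanism": traj.system.variant.mechanism.value,
            "ligand_depletion": traj.system.variant.ligand_depletion,
            "fam_included": traj.system.variant.fam_included,
        }
    (out / f"{stem}_meta.json").write_text(json.dumps(meta, indent=2,
                                                      default=str))
    return wide


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir, config: dict, artifacts: list[str]) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "artifacts": artifacts,
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def load_config(path) -> dict:
    """Load a run configuration (YAML mapping); unknown top-level keys are
    rejected by the CLI against its per-command schema."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a mapping")
    return cfg
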