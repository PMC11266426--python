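"""Replicate orchestration: config-driven runs producing CSV/JSON tables.

A run is described by a single YAML config. Inputs are either a synthetic
spec (``simulate``) or file paths (``inputs``: a GRO/PDB topology plus one
frame-table per replicate). Enabled analyses each write a tidy CSV whose
header carries the manifest hash; the manifest (JSON) records every
parameter verbatim, so re-running from the manifest reproduces the tables
byte for byte (timestamps are deliberately not recorded).

Exit-code convention of the CLI wrapper: 0 success, 2 config error,
3 data error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import conformation, contacts, fields
from .core import Trajectory
from .io import read_frame_table, read_gro, read_pdb
from .lipids import PHOSPHOLIPID_CLASSES, classify_lipids
from .synthetic import ContactWindow, HeightFieldSpec, SyntheticSpec, script_trajectory

logger = logging.getLogger("barmem")

__all__ = ["RunConfig", "ConfigError", "DataError", "run"]

_FLOAT_FMT = "%.8g"


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Missing or unreadable input data (CLI exit code 3)."""


_KNOWN_ANALYSES = ("occupancy", "profile", "density2d", "angle")
_KNOWN_TOP_KEYS = {"seed", "output_dir", "log_level", "simulate", "inputs", "analyses"}


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "barmem_out"
    log_level: str = "INFO"
    simulate: Optional[dict] = None
    inputs: Optional[dict] = None
    analyses: Dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "barmem_out")),
            log_level=str(raw.get("log_level", "INFO")),
            simulate=raw.get("simulate"),
            inputs=raw.get("inputs"),
            analyses=raw.get("analyses") or {},
        )
        if (cfg.simulate is None) == (cfg.inputs is None):
            raise ConfigError("config needs exactly one of 'simulate' or 'inputs'")
        bad = set(cfg.analyses) - set(_KNOWN_ANALYSES)
        if bad:
            raise ConfigError(f"unknown analysis key(s): {sorted(bad)}")
        if not cfg.analyses:
            raise ConfigError("no analyses enabled")
        return cfg

    def canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)

    def manifest_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def _spec_from_config(sim: dict, seed: int) -> SyntheticSpec:
    sim = dict(sim)
    hf = sim.pop("height_field", None)
    if hf is not None:
        sim["height_field"] = HeightFieldSpec(**hf)
    sched = sim.pop("contact_schedule", None)
    if sched is not None:
        sim["contact_schedule"] = [ContactWindow(**w) for w in sched]
    ramp = sim.pop("angle_ramp", None)
    if ramp is not None:
        sim["angle_ramp"] = tuple(ramp)
    try:
        return SyntheticSpec(seed=seed, **sim)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid simulate block: {exc}") from exc


def _load_trajectories(inputs: dict) -> List[Trajectory]:
    top_path = inputs.get("topology")
    traj_paths = inputs.get("trajectories") or []
    if not top_path or not traj_paths:
        raise ConfigError("'inputs' needs 'topology' and a non-empty 'trajectories' list")
    top_path = Path(top_path)
    if not top_path.exists():
        raise DataError(f"topology file not found: {top_path}")
    topology = read_pdb(top_path) if top_path.suffix.lower() == ".pdb" else read_gro(top_path)
    trajs = []
    for p in traj_paths:
        p = Path(p)
        if not p.exists():
            raise DataError(f"trajectory file not found: {p}")
        trajs.append(read_frame_table(p, topology))
    return trajs


def _write_table(df: pd.DataFrame, path: Path, manifest_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# manifest_sha256: {manifest_hash}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def run(config: RunConfig, base_dir: Optional[Path] = None) -> Path:
    """Execute a configured run; returns the output directory.

    Deterministic given config + seed. A failure in one analysis aborts
    the run with an exception after earlier outputs were written; the
    manifest is written last, so its presence marks a complete run.
    """
    out = Path(base_dir or ".") / config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    h = config.manifest_hash()

    if config.simulate is not None:
        spec = _spec_from_config(config.simulate, config.seed)
        records = script_trajectory(spec)
        trajs = [r.trajectory for r in records]
    else:
        trajs = _load_trajectories(config.inputs)
    inventory = classify_lipids(trajs[0].topology)

    for name, params in config.analyses.items():
        params = dict(params or {})
        logger.info("running analysis %s on %d replicate(s)", name, len(trajs))
        if name == "occupancy":
            cutoff = float(params.pop("cutoff", 0.4))
            classes = params.pop("classes", list(PHOSPHOLIPID_CLASSES))
            convention = params.pop("run_convention", "k")
            _reject_extra(name, params)
            rows = []
            cp = contacts.ContactParams(cutoff=cutoff)
            for cls in classes:
                if len(inventory.lipids_of_class(cls)) == 0:
                    continue
                profiles = [
                    contacts.occupancy_profile(
                        contacts.contact_series(t, cp, cls, inventory), run_convention=convention
                    )
                    for t in trajs
                ]
                agg = contacts.aggregate_occupancy(profiles)
                for i, (chain, resseq) in enumerate(agg.residue_keys):
                    row = {"chain": chain, "resseq": resseq, "lipid_class": cls,
                           "mean": agg.mean[i], "sd": agg.sd[i]}
                    for r, p in enumerate(profiles):
                        row[f"occupancy_rep{r}"] = p.values[i]
                    rows.append(row)
            _write_table(pd.DataFrame(rows), out / "occupancy.csv", h)
        elif name == "profile":
            kw = {k: params[k] for k in ("leaflet", "bin_nm", "sample_every_ps",
                                         "leaflet_method", "selection") if k in params}
            _reject_extra(name, {k: v for k, v in params.items() if k not in kw})
            profiles = [fields.height_profile(t, inventory, **kw) for t in trajs]
            agg = fields.aggregate_height_profiles(profiles)
            kappa = fields.curvature_estimate(agg)
            df = pd.DataFrame(
                {
                    "bin_center_nm": agg.bin_centers,
                    "mean_z_nm": agg.mean_z,
                    "sd_nm": agg.sd,
                    "n": agg.counts,
                    "missing": agg.missing.astype(int),
                    "curvature_per_nm": kappa,
                }
            )
            _write_table(df, out / "height_profile.csv", h)
        elif name == "density2d":
            cls = params.pop("lipid_class", "POPC")
            kw = {k: params.pop(k) for k in ("window_ps", "bin_nm", "alignment") if k in params}
            _reject_extra(name, params)
            maps = [fields.density_map_2d(t, cls, inventory, **kw) for t in trajs]
            grid = np.mean([m.grid for m in maps], axis=0)
            ref = maps[0]
            np.savetxt(out / "density2d.csv", grid, delimiter=",", fmt=_FLOAT_FMT,
                       header=f"manifest_sha256: {h}")
            meta = {
                "lipid_class": cls,
                "x_edges_nm": ref.x_edges.tolist(),
                "y_edges_nm": ref.y_edges.tolist(),
                "window_ps": list(ref.window_ps),
                "alignment": ref.alignment,
                "n_replicates": len(maps),
                "manifest_sha256": h,
            }
            (out / "density2d.json").write_text(json.dumps(meta, indent=1))
        elif name == "angle":
            groups = conformation.AngleGroups(**params) if params else conformation.AngleGroups()
            series = [conformation.angle_series(t, groups) for t in trajs]
            agg = conformation.aggregate_angle_series(series)
            df = pd.DataFrame({"time_ps": agg.times, "mean_deg": agg.mean, "sd_deg": agg.sd})
            for r, s in enumerate(series):
                df[f"angle_deg_rep{r}"] = s.angles
            _write_table(df, out / "angle.csv", h)
    manifest = {
        "config": json.loads(config.canonical_json()),
        "manifest_sha256": h,
        "n_replicates": len(trajs),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def _reject_extra(name: str, params: dict) -> None:
    if params:
        raise ConfigError(f"analysis {name!r}: unknown parameter(s) {sorted(params)}")
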