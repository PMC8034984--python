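"""End-to-end study orchestration: model -> trajectories -> ISFs -> report.

``run_study`` reproduces the full analysis chain at desk scale for a
configurable model and engine: it builds (or loads) the rigid model,
estimates its diffusion tensor, generates one trajectory per seed, computes
the four ISF components, extracts effective diffusion coefficients, and
writes a decoupling report plus a provenance manifest.  Every output is a
plain-text format (XYZ/JSON/CSV) except trajectories (NPZ), and a run
re-executed from its emitted config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bd_engine import run_bd
from .diffusion_analysis import (
    average_replicates,
    compare_decoupling,
    dtrans_theoretical,
    extract_deff,
    normalize_by_D0,
)
from .dpd_engine import DPDParams, run_dpd
from .rigid_model import (
    coarse_grain_pdb,
    estimate_diffusion_tensor,
    load_model,
    make_spherical_shell,
    make_synthetic_mab,
    save_model,
)
from .scattering import compute_all_isfs, make_lag_grid
from .traj_tools import msd
from .trajectory import save_trajectory

__all__ = ["RunConfig", "run_study", "build_model_from_config"]


@dataclass
class RunConfig:
    """Serializable configuration of a full study run."""

    model: dict = field(default_factory=lambda: {"type": "synthetic_mab", "seed": 1})
    engine: str = "bd"
    engine_params: dict = field(default_factory=dict)
    seeds: list = field(default_factory=lambda: [101, 102, 103])
    Q_grid: list = field(default_factory=lambda: (np.arange(1, 21) * 0.01).tolist())
    lag_max: float = 40.0
    n_lags: int = 18
    origin_stride: int = 50
    fit_window: list = field(default_factory=lambda: [0.0, 40.0])
    reduced_time_cap: float = 0.25
    Q_ref: float = None   # default: smallest Q in the grid
    outdir: str = "study_out"

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def build_model_from_config(spec: dict):
    """Instantiate a rigid model from a config dict (synthetic, shell or PDB)."""
    kind = spec.get("type", "synthetic_mab")
    kwargs = {k: v for k, v in spec.items() if k not in ("type", "path", "scheme")}
    if kind == "synthetic_mab":
        if "lobe_radii" in kwargs:
            kwargs["lobe_radii"] = tuple(kwargs["lobe_radii"])
        return make_synthetic_mab(**kwargs)
    if kind == "spherical_shell":
        return make_spherical_shell(**kwargs)
    if kind == "pdb":
        return coarse_grain_pdb(Path(spec["path"]).read_text(),
                                scheme=spec.get("scheme", "centroid"))
    if kind == "xyz":
        return load_model(spec["path"])
    raise ValueError(f"unknown model type {spec.get('type')!r}")


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_study(config: RunConfig) -> Path:
    """Execute the full pipeline described by ``config``; returns the outdir.

    Emits: model.xyz/.json, tensor.json, traj_<seed>.npz, isf_<seed>.csv,
    msd_<seed>.csv, deff.csv, decoupling.json/.csv, config.yaml and
    manifest.json.  Partial failures leave completed stages on disk with the
    manifest marking the failure point.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_digest": config.digest(), "version": __version__,
                "stages": {}, "failed_stage": None}
    (out / "config.yaml").write_text(config.to_yaml())

    def record(stage, files):
        manifest["stages"][stage] = {
            str(f.name): _file_digest(f) for f in files
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    try:
        stage = "model"
        model = build_model_from_config(config.model)
        save_model(model, out / "model.xyz")
        tensor = estimate_diffusion_tensor(model)
        (out / "tensor.json").write_text(tensor.to_json())
        record(stage, [out / "model.xyz", out / "model.json", out / "tensor.json"])

        stage = "trajectories"
        trajs = []
        files = []
        for seed in config.seeds:
            if config.engine == "bd":
                ep = dict(config.engine_params)
                dt = ep.pop("dt", 0.25)
                n_steps = ep.pop("n_steps", 20000)
                traj = run_bd(model, tensor, dt=dt, n_steps=n_steps, seed=seed, **ep)
            elif config.engine == "dpd":
                ep = dict(config.engine_params)
                n_steps = ep.pop("n_steps", 2000)
                snap = ep.pop("snapshot_every", 10)
                equil = ep.pop("equil_steps", 200)
                aprc = ep.pop("angstrom_per_rc", 10.0)
                params = DPDParams(seed=seed, **ep)
                traj = run_dpd(model, params, n_steps, snapshot_every=snap,
                               equil_steps=equil, angstrom_per_rc=aprc)
            else:
                raise ValueError(f"unknown engine {config.engine!r}")
            f = out / f"traj_{seed}.npz"
            save_trajectory(traj, f)
            trajs.append(traj)
            files.append(f)
        record(stage, files)

        stage = "isf"
        lag_grid = make_lag_grid(trajs[0].dt, min(config.lag_max,
                                 trajs[0].times[-1] * 0.5), config.n_lags)
        files = []
        all_isfs = []
        for seed, traj in zip(config.seeds, trajs):
            isfs = compute_all_isfs(traj, model, np.asarray(config.Q_grid),
                                    lag_grid, config.origin_stride)
            all_isfs.append(isfs)
            f = out / f"isf_{seed}.csv"
            import pandas as pd

            pd.concat([c.to_dataframe() for c in isfs.values()]).to_csv(f, index=False)
            files.append(f)
            fm = out / f"msd_{seed}.csv"
            msd(traj, origin_stride=config.origin_stride, log_lags=40).to_dataframe().to_csv(fm, index=False)
            files.append(fm)
        record(stage, files)

        stage = "deff"
        per = {k: [] for k in ("total", "com", "rot", "trans")}
        for isfs in all_isfs:
            for k in per:
                per[k].append(extract_deff(isfs[k], tuple(config.fit_window),
                                           D0_guess=tensor.D0,
                                           reduced_time_cap=config.reduced_time_cap))
        avg = {k: average_replicates(v) for k, v in per.items()}
        q_ref = config.Q_ref if config.Q_ref is not None else min(config.Q_grid)
        norm, D0 = normalize_by_D0(avg, Q_ref=q_ref, source="trans")
        import pandas as pd

        rows = []
        for k, c in avg.items():
            for i, q in enumerate(c.Q_grid):
                rows.append({"component": k, "Q": q, "Deff": c.values[i],
                             "Deff_over_D0": c.values[i] / D0,
                             "spread": c.spread[i]})
        pd.DataFrame(rows).to_csv(out / "deff.csv", index=False)
        record(stage, [out / "deff.csv"])

        stage = "decoupling"
        report = compare_decoupling(avg["total"], avg["com"], avg["rot"],
                                    avg["trans"], isfs=all_isfs[0], D0=D0)
        d = report.to_dict()
        d["dtrans_theoretical"] = dtrans_theoretical(
            model, tensor, np.asarray(config.Q_grid)).tolist()
        (out / "decoupling.json").write_text(json.dumps(d, indent=1))
        report.to_dataframe().to_csv(out / "decoupling.csv", index=False)
        record(stage, [out / "decoupling.json", out / "decoupling.csv"])
    except Exception:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise
    return out
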