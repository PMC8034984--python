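"""Rigid-body trajectory container and on-disk formats (HDF5 / NPZ / XYZ)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._quat import quats_to_matrices

__all__ = ["Trajectory", "save_trajectory", "load_trajectory"]


@dataclass
class Trajectory:
    """Time series of rigid-body center-of-mass position and orientation.

    ``com_positions`` are unwrapped lab-frame coordinates (length units);
    ``orientations`` are unit quaternions (w, x, y, z) mapping body to lab.
    ``velocities`` is optional (used by the inertial Langevin engine).
    """

    times: np.ndarray
    com_positions: np.ndarray
    orientations: np.ndarray
    engine: str = "external"
    length_unit: str = "A"
    time_unit: str = "ns"
    seed: int | None = None
    velocities: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.com_positions = np.asarray(self.com_positions, dtype=np.float64)
        self.orientations = np.asarray(self.orientations, dtype=np.float64)
        n = self.times.shape[0]
        if self.com_positions.shape != (n, 3) or self.orientations.shape != (n, 4):
            raise ValueError("inconsistent trajectory array shapes")
        if n > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12 * abs(dt[0])):
                raise ValueError("times must be uniformly spaced")
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("orientations must be unit quaternions")

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    @property
    def dt(self) -> float:
        if self.n_frames < 2:
            raise ValueError("trajectory has fewer than 2 frames")
        return float(self.times[1] - self.times[0])

    def rotation_matrices(self) -> np.ndarray:
        """(n, 3, 3) body-to-lab rotation matrices."""
        return quats_to_matrices(self.orientations)

    def bead_positions(self, model, frame: int) -> np.ndarray:
        """Reconstruct lab-frame bead positions of `model` at one frame."""
        R = quats_to_matrices(self.orientations[frame])
        return self.com_positions[frame] + model.positions @ R.T


def save_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as HDF5 (.h5/.hdf5) or NPZ (anything else)."""
    path = Path(path)
    meta = json.dumps(
        {
            "engine": traj.engine,
            "length_unit": traj.length_unit,
            "time_unit": traj.time_unit,
            "seed": traj.seed,
            "metadata": traj.metadata,
        }
    )
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=traj.times)
            f.create_dataset("com", data=traj.com_positions)
            f.create_dataset("quat", data=traj.orientations)
            if traj.velocities is not None:
                f.create_dataset("vel", data=traj.velocities)
            f.attrs["params"] = meta
    else:
        arrays = dict(time=traj.times, com=traj.com_positions, quat=traj.orientations,
                      params=np.bytes_(meta))
        if traj.velocities is not None:
            arrays["vel"] = traj.velocities
        np.savez(path, **arrays)


def load_trajectory(path) -> Trajectory:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["params"])
            vel = f["vel"][:] if "vel" in f else None
            traj = Trajectory(
                times=f["time"][:], com_positions=f["com"][:], orientations=f["quat"][:],
                velocities=vel, **_meta_kwargs(meta),
            )
        return traj
    with np.load(path) as data:
        meta = json.loads(bytes(data["params"]).decode())
        vel = data["vel"] if "vel" in data else None
        return Trajectory(
            times=data["time"], com_positions=data["com"], orientations=data["quat"],
            velocities=vel, **_meta_kwargs(meta),
        )


def _meta_kwargs(meta: dict) -> dict:
    return dict(
        engine=meta.get("engine", "external"),
        length_unit=meta.get("length_unit", "A"),
        time_unit=meta.get("time_unit", "ns"),
        seed=meta.get("seed"),
        metadata=meta.get("metadata", {}),
    )


def export_xyz(traj: Trajectory, model, path, stride: int = 1) -> None:
    """Write reconstructed bead positions as a multi-frame XYZ file."""
    path = Path(path)
    Rs = traj.rotation_matrices()
    with open(path, "w") as f:
        for k in range(0, traj.n_frames, stride):
            pos = traj.com_positions[k] + model.positions @ Rs[k].T
            f.write(f"{model.n_beads}\nt={traj.times[k]:.6g}\n")
            for p in pos:
                f.write(f"C {p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")
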