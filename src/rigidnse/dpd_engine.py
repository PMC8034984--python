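"""Dissipative particle dynamics fluid with an embedded rigid body.

Pairwise forces follow the standard DPD form: a soft conservative repulsion
F^C = a (1 - r/r_c) rhat, a dissipative force F^D = -gamma w_D(r)(rhat.v_ij)
rhat and a random force F^R = sigma w_R(r) xi rhat / sqrt(dt), with
w_D = w_R^2 = (1 - r/r_c)^2 and sigma^2 = 2 gamma kBT (fluctuation-
dissipation pairing).  The energy scale is kBT = 1 and parameters default to
the water-compressibility convention (a = 25, rho = 3, gamma = 4.5).

The rigid body is a set of DPD interaction sites of the same type as the
fluid, moved as one unit: bead forces are accumulated into a net force and a
torque about the center of mass, and the COM position, linear momentum,
orientation quaternion and angular momentum are integrated with the modified
velocity-Verlet scheme (lambda = 0.5).  Pair randomness is counter-based
(a splitmix64 hash of seed, step and the ordered particle pair), so a run is
bitwise reproducible regardless of traversal order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from ._quat import quat_from_rotvec, quat_mult, quat_normalize, quats_to_matrices
from .rigid_model import RigidBodyModel
from .trajectory import Trajectory

__all__ = ["DPDParams", "DPDState", "pair_forces", "step", "run_dpd",
           "kinetic_temperature"]

_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)


@dataclass
class DPDParams:
    """DPD fluid and integration parameters (reduced units, r_c = kBT = 1)."""

    a: float = 25.0
    gamma_dpd: float = 4.5
    r_c: float = 1.0
    rho: float = 3.0
    box: tuple = (10.0, 10.0, 10.0)
    dt: float = 0.01
    kBT: float = 1.0
    lambda_: float = 0.5
    seed: int = 0
    v_cap: float = 100.0
    sigma_rand: float = None

    def __post_init__(self):
        if self.dt <= 0 or self.r_c <= 0 or self.rho <= 0 or self.kBT <= 0:
            raise ValueError("dt, r_c, rho and kBT must be positive")
        fd = np.sqrt(2.0 * self.gamma_dpd * self.kBT)
        if self.sigma_rand is None:
            self.sigma_rand = fd
        elif not np.isclose(self.sigma_rand, fd, rtol=1e-10):
            raise ValueError(
                "sigma_rand^2 must equal 2 gamma_dpd kBT (fluctuation-dissipation)"
            )
        self.box = tuple(float(b) for b in self.box)
        if any(b <= 0 for b in self.box):
            raise ValueError("box edges must be positive")

    def to_dict(self) -> dict:
        return {
            "a": self.a, "gamma_dpd": self.gamma_dpd, "r_c": self.r_c,
            "rho": self.rho, "box": list(self.box), "dt": self.dt,
            "kBT": self.kBT, "lambda_": self.lambda_, "seed": self.seed,
        }


@dataclass
class DPDState:
    """Instantaneous state of the fluid and the (optional) rigid body."""

    fluid_pos: np.ndarray
    fluid_vel: np.ndarray
    body_X: np.ndarray = None          # (Nb,3) body-frame bead coords, r_c units
    body_com: np.ndarray = None
    body_quat: np.ndarray = None
    body_vel: np.ndarray = None        # COM velocity
    body_angmom: np.ndarray = None     # lab-frame angular momentum about COM
    bead_mass: float = 1.0
    time: float = 0.0
    step_index: int = 0
    forces: np.ndarray = None          # cached forces from the last evaluation

    @property
    def n_fluid(self) -> int:
        return self.fluid_pos.shape[0]

    @property
    def n_body(self) -> int:
        return 0 if self.body_X is None else self.body_X.shape[0]

    def body_R(self) -> np.ndarray:
        return quats_to_matrices(self.body_quat)

    def body_inertia_body(self) -> np.ndarray:
        X = self.body_X
        return self.bead_mass * ((X**2).sum() * np.eye(3) - X.T @ X)

    def all_positions(self) -> np.ndarray:
        if self.n_body == 0:
            return self.fluid_pos
        beads = self.body_com + self.body_X @ self.body_R().T
        return np.vstack([self.fluid_pos, beads])

    def all_velocities(self) -> np.ndarray:
        if self.n_body == 0:
            return self.fluid_vel
        R = self.body_R()
        I_lab = R @ self.body_inertia_body() @ R.T
        omega = np.linalg.solve(I_lab, self.body_angmom)
        arms = self.body_X @ R.T
        bead_v = self.body_vel + np.cross(omega, arms)
        return np.vstack([self.fluid_vel, bead_v])


# ---------------------------------------------------------------------------
# Force kernel
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _splitmix64(z):
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & _MASK
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & _MASK
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & _MASK
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _pair_xi(seed, step_idx, i, j):
    """Symmetric uniform random number with zero mean and unit variance."""
    lo = min(i, j)
    hi = max(i, j)
    key = _splitmix64(np.uint64(seed) ^ _splitmix64(np.uint64(step_idx)))
    key = _splitmix64(key ^ (np.uint64(lo) << np.uint64(21)) ^ np.uint64(hi))
    u = key / 1.8446744073709552e19  # 2^64
    return np.sqrt(12.0) * (u - 0.5)


@njit(cache=True, inline="always")
def _accumulate_pair(pos, vel, i, j, box, a, gamma, sigma, rc, inv_sqrt_dt,
                     seed, step_idx, forces):
    dx = pos[i, 0] - pos[j, 0]
    dy = pos[i, 1] - pos[j, 1]
    dz = pos[i, 2] - pos[j, 2]
    dx -= box[0] * np.rint(dx / box[0])
    dy -= box[1] * np.rint(dy / box[1])
    dz -= box[2] * np.rint(dz / box[2])
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= rc * rc or r2 == 0.0:
        return
    r = np.sqrt(r2)
    w = 1.0 - r / rc
    ex, ey, ez = dx / r, dy / r, dz / r
    dvx = vel[i, 0] - vel[j, 0]
    dvy = vel[i, 1] - vel[j, 1]
    dvz = vel[i, 2] - vel[j, 2]
    rv = ex * dvx + ey * dvy + ez * dvz
    xi = _pair_xi(seed, step_idx, i, j)
    f = a * w - gamma * w * w * rv + sigma * w * xi * inv_sqrt_dt
    forces[i, 0] += f * ex
    forces[i, 1] += f * ey
    forces[i, 2] += f * ez
    forces[j, 0] -= f * ex
    forces[j, 1] -= f * ey
    forces[j, 2] -= f * ez


@njit(cache=True)
def _dpd_forces(pos, vel, n_fluid, box, a, gamma, sigma, rc, inv_sqrt_dt,
                seed, step_idx):
    N = pos.shape[0]
    forces = np.zeros((N, 3))
    ncx = max(1, int(box[0] / rc))
    ncy = max(1, int(box[1] / rc))
    ncz = max(1, int(box[2] / rc))
    use_cells = ncx >= 3 and ncy >= 3 and ncz >= 3
    if not use_cells:
        for i in range(N):
            for j in range(i + 1, N):
                if i >= n_fluid and j >= n_fluid:
                    continue  # rigid body: no internal pair forces
                _accumulate_pair(pos, vel, i, j, box, a, gamma, sigma, rc,
                                 inv_sqrt_dt, seed, step_idx, forces)
        return forces

    ncell = ncx * ncy * ncz
    head = np.full(ncell, -1, dtype=np.int64)
    nxt = np.empty(N, dtype=np.int64)
    cx = np.empty(N, dtype=np.int64)
    cy = np.empty(N, dtype=np.int64)
    cz = np.empty(N, dtype=np.int64)
    for i in range(N):
        cx[i] = int(pos[i, 0] / box[0] * ncx) % ncx
        cy[i] = int(pos[i, 1] / box[1] * ncy) % ncy
        cz[i] = int(pos[i, 2] / box[2] * ncz) % ncz
        c = (cx[i] * ncy + cy[i]) * ncz + cz[i]
        nxt[i] = head[c]
        head[c] = i
    for i in range(N):
        # same-cell pairs: follow the linked list downstream of i
        j = nxt[i]
        while j >= 0:
            if not (i >= n_fluid and j >= n_fluid):
                _accumulate_pair(pos, vel, i, j, box, a, gamma, sigma, rc,
                                 inv_sqrt_dt, seed, step_idx, forces)
            j = nxt[j]
        # half of the 26 neighbour cells to visit each cell pair once
        for n in range(13):
            ox = _NEIGH[n, 0]
            oy = _NEIGH[n, 1]
            oz = _NEIGH[n, 2]
            c = (((cx[i] + ox) % ncx) * ncy + (cy[i] + oy) % ncy) * ncz \
                + (cz[i] + oz) % ncz
            j = head[c]
            while j >= 0:
                if not (i >= n_fluid and j >= n_fluid):
                    _accumulate_pair(pos, vel, i, j, box, a, gamma, sigma, rc,
                                     inv_sqrt_dt, seed, step_idx, forces)
                j = nxt[j]
    return forces


_NEIGH = np.array(
    [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
        (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ],
    dtype=np.int64,
)


def pair_forces(state: DPDState, params: DPDParams) -> np.ndarray:
    """Total DPD pair forces on every particle (fluid first, body beads last)."""
    # wrap into the primary box so cell binning is valid for unwrapped bodies
    pos = np.mod(state.all_positions(), np.asarray(params.box))
    vel = state.all_velocities()
    return _dpd_forces(
        pos, vel, state.n_fluid, np.asarray(params.box), params.a,
        params.gamma_dpd, params.sigma_rand, params.r_c,
        1.0 / np.sqrt(params.dt), params.seed, state.step_index,
    )


def kinetic_temperature(state: DPDState) -> float:
    """Instantaneous fluid kinetic temperature <m v^2>/3 per particle."""
    v2 = (state.fluid_vel**2).sum(axis=1)
    return float(v2.mean() / 3.0)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def _rotate_quat(q, rotvec):
    dq = np.empty(4)
    quat_from_rotvec(np.ascontiguousarray(rotvec), dq)
    out = np.empty(4)
    quat_mult(np.ascontiguousarray(q), dq, out)
    quat_normalize(out)
    return out


def step(state: DPDState, params: DPDParams) -> DPDState:
    """One modified velocity-Verlet DPD step (Groot-Warren, lambda = 0.5)."""
    dt, lam = params.dt, params.lambda_
    box = np.asarray(params.box)
    nf, nb = state.n_fluid, state.n_body

    if state.forces is None:
        f = pair_forces(state, params)
    else:
        f = state.forces
    ff = f[:nf]

    # positions
    new_fluid_pos = np.mod(state.fluid_pos + dt * state.fluid_vel
                           + 0.5 * dt * dt * ff, box)
    fluid_v_tilde = state.fluid_vel + lam * dt * ff

    if nb > 0:
        fb = f[nf:]
        R = state.body_R()
        arms = state.body_X @ R.T
        F = fb.sum(axis=0)
        tau = np.cross(arms, fb).sum(axis=0)
        M = state.bead_mass * nb
        I_lab = R @ state.body_inertia_body() @ R.T
        omega = np.linalg.solve(I_lab, state.body_angmom)
        new_com = state.body_com + dt * state.body_vel + 0.5 * dt * dt * F / M
        new_quat = _rotate_quat(state.body_quat, omega * dt)
        vel_tilde = state.body_vel + lam * dt * F / M
        angmom_tilde = state.body_angmom + lam * dt * tau
        mid = replace(
            state, fluid_pos=new_fluid_pos, fluid_vel=fluid_v_tilde,
            body_com=new_com, body_quat=new_quat, body_vel=vel_tilde,
            body_angmom=angmom_tilde, step_index=state.step_index + 1,
            forces=None,
        )
    else:
        mid = replace(
            state, fluid_pos=new_fluid_pos, fluid_vel=fluid_v_tilde,
            step_index=state.step_index + 1, forces=None,
        )

    f_new = pair_forces(mid, params)
    new_fluid_vel = state.fluid_vel + 0.5 * dt * (ff + f_new[:nf])
    if np.any(np.abs(new_fluid_vel) > params.v_cap):
        raise RuntimeError(
            f"velocity blow-up at step {state.step_index}: "
            f"max |v| = {np.abs(new_fluid_vel).max():.3g} > cap {params.v_cap}"
        )

    if nb > 0:
        fb_new = f_new[nf:]
        Rn = mid.body_R()
        arms_n = mid.body_X @ Rn.T
        F_new = fb_new.sum(axis=0)
        tau_new = np.cross(arms_n, fb_new).sum(axis=0)
        new_vel = state.body_vel + 0.5 * dt * (F + F_new) / M
        new_angmom = state.body_angmom + 0.5 * dt * (tau + tau_new)
        return replace(
            mid, fluid_vel=new_fluid_vel, body_vel=new_vel,
            body_angmom=new_angmom, time=state.time + dt, forces=f_new,
        )
    return replace(mid, fluid_vel=new_fluid_vel, time=state.time + dt,
                   forces=f_new)


def init_state(
    params: DPDParams,
    model: RigidBodyModel | None = None,
    angstrom_per_rc: float = 10.0,
    mass_scale: float = 1.0,
    seed: int | None = None,
) -> DPDState:
    """Random fluid at density rho with an optional centered rigid body."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    box = np.asarray(params.box)
    n_fluid = int(round(params.rho * box.prod()))
    pos = rng.uniform(0.0, 1.0, size=(n_fluid, 3)) * box
    vel = rng.standard_normal((n_fluid, 3)) * np.sqrt(params.kBT)
    vel -= vel.mean(axis=0)

    if model is None or model.n_beads == 0:
        return DPDState(fluid_pos=pos, fluid_vel=vel)

    X = model.positions / angstrom_per_rc
    diameter = 0.0
    if model.n_beads > 1:
        diameter = model.diameter() / angstrom_per_rc
    if diameter > min(params.box) / 2.0:
        raise ValueError(
            f"body diameter {diameter:.2f} r_c exceeds half the smallest box "
            f"edge ({min(params.box) / 2:.2f} r_c): minimum-image violation"
        )
    return DPDState(
        fluid_pos=pos, fluid_vel=vel, body_X=X, body_com=box / 2.0,
        body_quat=np.array([1.0, 0.0, 0.0, 0.0]), body_vel=np.zeros(3),
        body_angmom=np.zeros(3), bead_mass=mass_scale,
    )


def run_dpd(
    model: RigidBodyModel | None,
    params: DPDParams,
    n_steps: int,
    snapshot_every: int = 10,
    equil_steps: int = 0,
    angstrom_per_rc: float = 10.0,
    mass_scale: float = 1.0,
) -> Trajectory:
    """Run DPD and return the rigid-body (or tracer-free) trajectory.

    Equilibration steps are run first and excluded from the output.  Times
    and lengths are in DPD units; the COM is unwrapped for MSD analysis.
    """
    if n_steps < 0 or equil_steps < 0:
        raise ValueError("step counts must be non-negative")
    state = init_state(params, model, angstrom_per_rc, mass_scale)
    for _ in range(equil_steps):
        state = step(state, params)

    has_body = state.n_body > 0
    unwrapped = state.body_com.copy() if has_body else np.zeros(3)
    prev = unwrapped.copy()
    box = np.asarray(params.box)

    n_snap = n_steps // max(snapshot_every, 1) + 1
    times = np.empty(n_snap)
    com = np.empty((n_snap, 3))
    quat = np.empty((n_snap, 4))
    temps = []
    times[0] = 0.0
    com[0] = unwrapped
    quat[0] = state.body_quat if has_body else (1.0, 0.0, 0.0, 0.0)
    isnap = 1
    for s in range(n_steps):
        state = step(state, params)
        if has_body:
            d = state.body_com - prev
            d -= box * np.rint(d / box)
            unwrapped += d
            prev = state.body_com.copy()
        if (s + 1) % max(snapshot_every, 1) == 0:
            times[isnap] = (s + 1) * params.dt  # production time, equilibration excluded
            com[isnap] = unwrapped
            quat[isnap] = state.body_quat if has_body else (1.0, 0.0, 0.0, 0.0)
            temps.append(kinetic_temperature(state))
            isnap += 1
    return Trajectory(
        times=times, com_positions=com, orientations=quat, engine="dpd",
        length_unit="r_c", time_unit="dpd", seed=params.seed,
        metadata={
            "params": params.to_dict(),
            "angstrom_per_rc": angstrom_per_rc,
            "mass_scale": mass_scale,
            "equil_steps": equil_steps,
            "mean_kinetic_temperature": float(np.mean(temps)) if temps else None,
        },
    )
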