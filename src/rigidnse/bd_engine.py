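"""Overdamped rigid-body Brownian dynamics and an inertial Langevin reference.

``run_bd`` is the fast trajectory generator: it propagates a rigid body whose
6x6 diffusion tensor is fixed in the body frame, so translational mobility is
shape-coupled — the mechanism that makes the center-of-mass, translational and
total effective diffusion coefficients differ for anisotropic particles.
Each step draws a 6-vector Gaussian displacement with covariance 2 D dt in the
current body frame; the translational part is rotated to the lab frame and the
rotational part is applied through the quaternion exponential map.

``run_langevin_point`` integrates a free underdamped point particle with the
exact Ornstein-Uhlenbeck propagator; it exists to exercise the momentum-
relaxation-time fit of the mean-square displacement.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._quat import quat_from_rotvec, quat_mult, quat_normalize, quat_to_matrix
from .rigid_model import DiffusionTensor, RigidBodyModel
from .trajectory import Trajectory

__all__ = ["run_bd", "run_langevin_point"]

#: Hard cap on the RMS angular step, rad; beyond this the exponential-map
#: composition of rotational increments is no longer a faithful discretization.
MAX_ROT_STEP_RMS = 0.2


@njit(cache=True)
def _bd_loop(L, normals, snap_every, out_com, out_quat):
    q = np.empty(4)
    q[0] = 1.0
    q[1] = q[2] = q[3] = 0.0
    pos = np.zeros(3)
    R = np.empty((3, 3))
    d = np.empty(6)
    rotvec = np.empty(3)
    dq = np.empty(4)
    qn = np.empty(4)
    out_com[0] = pos
    out_quat[0] = q
    isnap = 1
    n_steps = normals.shape[0]
    for s in range(n_steps):
        for i in range(6):
            acc = 0.0
            for j in range(6):
                acc += L[i, j] * normals[s, j]
            d[i] = acc
        quat_to_matrix(q, R)
        for i in range(3):
            pos[i] += R[i, 0] * d[0] + R[i, 1] * d[1] + R[i, 2] * d[2]
            rotvec[i] = d[3 + i]
        quat_from_rotvec(rotvec, dq)
        quat_mult(q, dq, qn)  # body-frame increment composes on the right
        quat_normalize(qn)
        for i in range(4):
            q[i] = qn[i]
        if (s + 1) % snap_every == 0:
            out_com[isnap] = pos
            out_quat[isnap] = q
            isnap += 1


def run_bd(
    model: RigidBodyModel,
    D: DiffusionTensor,
    dt: float,
    n_steps: int,
    seed: int = 0,
    snapshot_every: int = 1,
    time_unit: str = "ns",
) -> Trajectory:
    """Generate an overdamped rigid-body Brownian trajectory.

    Parameters
    ----------
    model : RigidBodyModel
        Only used for metadata; the body enters through ``D``.
    D : DiffusionTensor
        Body-frame diffusion tensor (Å² or rad² per time unit).
    dt : float
        Timestep; must keep the RMS rotational step below 0.2 rad.
    n_steps, seed, snapshot_every
        Number of steps, RNG seed, snapshot stride.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    rot_rms = np.sqrt(2.0 * np.trace(D.rr) * dt)
    if rot_rms >= MAX_ROT_STEP_RMS:
        raise ValueError(
            f"rotational step RMS {rot_rms:.3g} rad exceeds {MAX_ROT_STEP_RMS}; "
            "reduce dt"
        )
    C = 2.0 * dt * D.as_matrix()
    # PSD square root via eigen-decomposition (tolerates semi-definite blocks)
    w, V = np.linalg.eigh(C)
    L = V * np.sqrt(np.clip(w, 0.0, None))

    n_snap = n_steps // max(snapshot_every, 1) + 1
    com = np.empty((n_snap, 3))
    quat = np.empty((n_snap, 4))
    if n_steps == 0:
        com[0] = 0.0
        quat[0] = (1.0, 0.0, 0.0, 0.0)
    else:
        rng = np.random.default_rng(seed)
        normals = rng.standard_normal((n_steps, 6))
        _bd_loop(np.ascontiguousarray(L), normals, max(snapshot_every, 1), com, quat)
    times = np.arange(n_snap) * dt * max(snapshot_every, 1)
    return Trajectory(
        times=times,
        com_positions=com,
        orientations=quat,
        engine="bd",
        time_unit=time_unit,
        seed=seed,
        metadata={
            "dt": dt,
            "n_steps": n_steps,
            "snapshot_every": snapshot_every,
            "D0": D.D0,
            "Dr": D.Dr,
            "tensor": D.as_matrix().tolist(),
            "tau_B": 0.0,  # overdamped: no momentum relaxation scale
            "model_label": model.label,
        },
    )


def run_langevin_point(
    mass: float,
    gamma: float,
    kBT: float,
    dt: float,
    n_steps: int,
    seed: int = 0,
    v0=None,
) -> Trajectory:
    """Free underdamped Langevin particle via the exact OU propagator.

    m dv/dt = -gamma v + noise, with noise spectral density g = 2 gamma kBT
    per dimension.  Position and velocity are advanced jointly with their
    exact Gaussian transition kernel, so results are unbiased at any dt.
    The momentum relaxation time is tau_B = m/gamma.

    ``v0`` may be a 3-vector, a scalar initial speed (random direction), or
    None to draw a Maxwell-Boltzmann velocity.
    """
    if mass <= 0 or gamma < 0 or kBT < 0 or dt <= 0 or n_steps < 0:
        raise ValueError("invalid Langevin parameters")
    if gamma > 0 and dt > mass / gamma / 10.0:
        raise ValueError("dt must be < tau_B/10 to resolve the ballistic regime")
    rng = np.random.default_rng(seed)
    if v0 is None:
        v = rng.standard_normal(3) * np.sqrt(kBT / mass)
    elif np.isscalar(v0):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        v = float(v0) * u
    else:
        v = np.asarray(v0, dtype=np.float64).copy()

    x = np.zeros(3)
    pos = np.empty((n_steps + 1, 3))
    vel = np.empty((n_steps + 1, 3))
    pos[0], vel[0] = x, v

    if gamma == 0:
        # ballistic limit: no friction implies no thermal noise (g = 2 gamma kBT)
        for s in range(n_steps):
            x = x + v * dt
            pos[s + 1], vel[s + 1] = x, v
    else:
        tau = mass / gamma
        c = np.exp(-dt / tau)
        drift = -tau * np.expm1(-dt / tau)  # tau (1 - e^{-dt/tau})
        kT_m = kBT / mass
        svv2 = kT_m * (1.0 - c * c)
        sxx2 = kT_m * tau * tau * (2.0 * dt / tau - 3.0 + 4.0 * c - c * c)
        sxv = kT_m * tau * (1.0 - c) ** 2
        svv = np.sqrt(max(svv2, 0.0))
        if svv > 0:
            a_xv = sxv / svv
            b_x = np.sqrt(max(sxx2 - a_xv * a_xv, 0.0))
        else:
            a_xv, b_x = 0.0, 0.0
        n1 = rng.standard_normal((n_steps, 3))
        n2 = rng.standard_normal((n_steps, 3))
        for s in range(n_steps):
            x = x + v * drift + a_xv * n1[s] + b_x * n2[s]
            v = c * v + svv * n1[s]
            pos[s + 1], vel[s + 1] = x, v

    quat = np.zeros((n_steps + 1, 4))
    quat[:, 0] = 1.0
    return Trajectory(
        times=np.arange(n_steps + 1) * dt,
        com_positions=pos,
        orientations=quat,
        engine="langevin",
        seed=seed,
        velocities=vel,
        metadata={
            "mass": mass,
            "gamma": gamma,
            "kBT": kBT,
            "dt": dt,
            "tau_B": (mass / gamma) if gamma > 0 else np.inf,
        },
    )
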