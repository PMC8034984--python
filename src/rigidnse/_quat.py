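"""Unit-quaternion helpers shared by the engines and the scattering kernels.

Convention: q = (w, x, y, z), scalar first; q maps body-frame vectors to the
lab frame, v_lab = R(q) v_body.  All functions are plain ufunc-style numpy code
so they can be called from numba-jitted loops via their scalar counterparts.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def quat_mult(p, q, out):
    """Hamilton product out = p * q (scalar-first)."""
    pw, px, py, pz = p[0], p[1], p[2], p[3]
    qw, qx, qy, qz = q[0], q[1], q[2], q[3]
    out[0] = pw * qw - px * qx - py * qy - pz * qz
    out[1] = pw * qx + px * qw + py * qz - pz * qy
    out[2] = pw * qy - px * qz + py * qw + pz * qx
    out[3] = pw * qz + px * qy - py * qx + pz * qw


@njit(cache=True, inline="always")
def quat_normalize(q):
    n = np.sqrt(q[0] * q[0] + q[1] * q[1] + q[2] * q[2] + q[3] * q[3])
    q[0] /= n
    q[1] /= n
    q[2] /= n
    q[3] /= n


@njit(cache=True, inline="always")
def quat_from_rotvec(v, out):
    """Quaternion for a rotation of |v| radians about v/|v| (exponential map)."""
    theta = np.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
    half = 0.5 * theta
    if theta < 1e-12:
        # second-order small-angle expansion keeps the map smooth at zero
        c = 1.0 - half * half / 2.0
        s = 0.5 * (1.0 - half * half / 6.0)
    else:
        c = np.cos(half)
        s = np.sin(half) / theta
    out[0] = c
    out[1] = s * v[0]
    out[2] = s * v[1]
    out[3] = s * v[2]


@njit(cache=True, inline="always")
def quat_to_matrix(q, R):
    """Rotation matrix of a unit quaternion; R v_body = v_lab."""
    w, x, y, z = q[0], q[1], q[2], q[3]
    R[0, 0] = 1.0 - 2.0 * (y * y + z * z)
    R[0, 1] = 2.0 * (x * y - z * w)
    R[0, 2] = 2.0 * (x * z + y * w)
    R[1, 0] = 2.0 * (x * y + z * w)
    R[1, 1] = 1.0 - 2.0 * (x * x + z * z)
    R[1, 2] = 2.0 * (y * z - x * w)
    R[2, 0] = 2.0 * (x * z - y * w)
    R[2, 1] = 2.0 * (y * z + x * w)
    R[2, 2] = 1.0 - 2.0 * (x * x + y * y)


def quats_to_matrices(quats: np.ndarray) -> np.ndarray:
    """Vectorized quaternion -> rotation-matrix conversion, (n,4) -> (n,3,3)."""
    q = np.asarray(quats, dtype=np.float64)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    R = np.empty((q.shape[0], 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - z * w)
    R[:, 0, 2] = 2 * (x * z + y * w)
    R[:, 1, 0] = 2 * (x * y + z * w)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - x * w)
    R[:, 2, 0] = 2 * (x * z - y * w)
    R[:, 2, 1] = 2 * (y * z + x * w)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R[0] if single else R
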