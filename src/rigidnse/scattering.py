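"""Normalized coherent intermediate scattering functions of a rigid body.

For a single rigid particle the coherent ISF, angularly averaged over the
wavevector direction, reduces to the double sum

    I(Q, t) = sum_{m,n} b_m b_n sinc(Q r_mn(t)),   r_mn(t) = |r_m(t0) - r_n(t0+t)|,

evaluated between a time origin t0 and a lagged frame, averaged over strided
origins and normalized by its lag-0 (static) value.  Four components are
computed from the same (COM, quaternion) trajectory:

* total — beads reconstructed with both translation and rotation;
* com   — center of mass only, <sinc(Q |dr_c(t)|)>;
* rot   — COM removed, rotation only (equals the intra-particle ISF of a
          rigid body);
* trans — structure-weighted translation: the orientation is frozen at the
          origin so the double sum weights the COM displacement by the
          form-factor amplitude, the trajectory estimator of the
          shape-weighted translational diffusion Dtrans(Q).

Because the body is rigid, cross-time pair distances depend only on the
relative rotation A = R(t0)^T R(t0+t) and the body-frame displacement
b = R(t0)^T dr_c, which is what the numba kernel consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .rigid_model import RigidBodyModel
from .trajectory import Trajectory

__all__ = ["ISFCurve", "isf_total", "isf_com", "isf_rot", "isf_trans_weighted",
           "isf_from_beads", "compute_all_isfs", "make_lag_grid", "tau_c"]


@dataclass
class ISFCurve:
    """Normalized coherent ISF on a (Q, lag) grid for one motion component."""

    component: str
    Q_grid: np.ndarray
    lag_grid: np.ndarray
    values: np.ndarray          # (nQ, nlag), values[:, lag==0] == 1
    n_origins: np.ndarray       # per lag
    reduced_time: np.ndarray = None   # optional D0 Q^2 t axis, (nQ, nlag)
    stderr: np.ndarray = None   # (nQ, nlag) origin-scatter standard errors
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.Q_grid = np.atleast_1d(np.asarray(self.Q_grid, dtype=np.float64))
        self.lag_grid = np.atleast_1d(np.asarray(self.lag_grid, dtype=np.float64))
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.Q_grid), len(self.lag_grid)):
            raise ValueError("values must have shape (nQ, n_lags)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ISF contains non-finite values")

    def with_reduced_time(self, D0: float) -> "ISFCurve":
        self.reduced_time = D0 * self.Q_grid[:, None] ** 2 * self.lag_grid[None, :]
        return self

    def to_dataframe(self):
        import pandas as pd

        nQ, nl = self.values.shape
        return pd.DataFrame(
            {
                "component": self.component,
                "Q": np.repeat(self.Q_grid, nl),
                "lag": np.tile(self.lag_grid, nQ),
                "value": self.values.ravel(),
                "n_origins": np.tile(self.n_origins, nQ),
            }
        )


def tau_c(diameter: float, D0: float) -> float:
    """Characteristic diffusion time sigma^2/(6 D0): the time to diffuse one
    particle diameter."""
    return diameter**2 / (6.0 * D0)


def make_lag_grid(dt: float, t_max: float, n: int = 20, t_min: float = None):
    """Log-spaced lag times that are exact multiples of the frame spacing."""
    t_min = dt if t_min is None else max(t_min, dt)
    lags = np.unique(np.round(np.geomspace(t_min / dt, t_max / dt, n)).astype(int))
    return lags[lags >= 1] * dt


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _isf_accumulate(X, w, A, bvec, lag_idx, Q, out, outsq, counts):
    """Accumulate sum_mn w_m w_n sinc(Q |x_m - A_k x_n - b_k|) per lag bin.

    ``outsq`` collects squared per-configuration sums for origin-scatter
    standard errors.
    """
    ncfg = A.shape[0]
    N = X.shape[0]
    nQ = Q.shape[0]
    Y = np.empty((N, 3))
    tmp = np.empty(nQ)
    for k in range(ncfg):
        for n in range(N):
            Y[n, 0] = A[k, 0, 0] * X[n, 0] + A[k, 0, 1] * X[n, 1] + A[k, 0, 2] * X[n, 2] + bvec[k, 0]
            Y[n, 1] = A[k, 1, 0] * X[n, 0] + A[k, 1, 1] * X[n, 1] + A[k, 1, 2] * X[n, 2] + bvec[k, 1]
            Y[n, 2] = A[k, 2, 0] * X[n, 0] + A[k, 2, 1] * X[n, 1] + A[k, 2, 2] * X[n, 2] + bvec[k, 2]
        l = lag_idx[k]
        for iq in range(nQ):
            tmp[iq] = 0.0
        for m in range(N):
            xm0, xm1, xm2 = X[m, 0], X[m, 1], X[m, 2]
            wm = w[m]
            for n in range(N):
                dx = xm0 - Y[n, 0]
                dy = xm1 - Y[n, 1]
                dz = xm2 - Y[n, 2]
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                ww = wm * w[n]
                if r < 1e-12:
                    for iq in range(nQ):
                        tmp[iq] += ww
                else:
                    for iq in range(nQ):
                        qr = Q[iq] * r
                        if qr < 1e-12:
                            tmp[iq] += ww
                        else:
                            tmp[iq] += ww * np.sin(qr) / qr
        for iq in range(nQ):
            out[l, iq] += tmp[iq]
            outsq[l, iq] += tmp[iq] * tmp[iq]
        counts[l] += 1


@njit(cache=True, fastmath=True)
def _isf_accumulate_harmonic(X, w, A, bvec, lag_idx, dq, kvals, out, outsq, counts):
    """As _isf_accumulate for Q = k*dq: sin(k theta) by Chebyshev recurrence.

    kvals maps output columns to integer harmonics; sin((k+1)t) =
    2 cos(t) sin(kt) - sin((k-1)t) makes a 20-point Q grid cost little more
    than a single sine per pair.
    """
    ncfg = A.shape[0]
    N = X.shape[0]
    nQ = kvals.shape[0]
    kmax = int(kvals[-1])
    col = np.full(kmax + 1, -1, dtype=np.int64)
    for i in range(nQ):
        col[kvals[i]] = i
    Y = np.empty((N, 3))
    tmp = np.empty(nQ)
    for k in range(ncfg):
        for n in range(N):
            Y[n, 0] = A[k, 0, 0] * X[n, 0] + A[k, 0, 1] * X[n, 1] + A[k, 0, 2] * X[n, 2] + bvec[k, 0]
            Y[n, 1] = A[k, 1, 0] * X[n, 0] + A[k, 1, 1] * X[n, 1] + A[k, 1, 2] * X[n, 2] + bvec[k, 1]
            Y[n, 2] = A[k, 2, 0] * X[n, 0] + A[k, 2, 1] * X[n, 1] + A[k, 2, 2] * X[n, 2] + bvec[k, 2]
        l = lag_idx[k]
        for iq in range(nQ):
            tmp[iq] = 0.0
        for m in range(N):
            xm0, xm1, xm2 = X[m, 0], X[m, 1], X[m, 2]
            wm = w[m]
            for n in range(N):
                dx = xm0 - Y[n, 0]
                dy = xm1 - Y[n, 1]
                dz = xm2 - Y[n, 2]
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                ww = wm * w[n]
                theta = dq * r
                if theta < 1e-12:
                    for iq in range(nQ):
                        tmp[iq] += ww
                    continue
                s_prev = 0.0
                s = np.sin(theta)
                c2 = 2.0 * np.cos(theta)
                winv = ww / theta
                for kk in range(1, kmax + 1):
                    ic = col[kk]
                    if ic >= 0:
                        tmp[ic] += winv * s / kk
                    s_next = c2 * s - s_prev
                    s_prev = s
                    s = s_next
        for iq in range(nQ):
            out[l, iq] += tmp[iq]
            outsq[l, iq] += tmp[iq] * tmp[iq]
        counts[l] += 1


@njit(cache=True, fastmath=True)
def _isf_beads_accumulate(P0, Pt, w, Q, out):
    """Double sum between two explicit bead frames, one (Q,) result row."""
    N = P0.shape[0]
    nQ = Q.shape[0]
    for m in range(N):
        for n in range(N):
            dx = P0[m, 0] - Pt[n, 0]
            dy = P0[m, 1] - Pt[n, 1]
            dz = P0[m, 2] - Pt[n, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            ww = w[m] * w[n]
            for iq in range(nQ):
                qr = Q[iq] * r
                if qr < 1e-12:
                    out[iq] += ww
                else:
                    out[iq] += ww * np.sin(qr) / qr


# ---------------------------------------------------------------------------
# Shared plumbing
# ---------------------------------------------------------------------------

def _prepare(traj: Trajectory, lag_grid, origin_stride):
    dt = traj.dt
    lag_frames = np.unique(np.round(np.asarray(lag_grid, dtype=float) / dt).astype(int))
    lag_frames = lag_frames[lag_frames >= 0]
    if np.any(lag_frames >= traj.n_frames):
        warnings.warn("dropping lags beyond the trajectory length")
        lag_frames = lag_frames[lag_frames < traj.n_frames]
    if 0 not in lag_frames:
        lag_frames = np.concatenate([[0], lag_frames])
    max_lag = int(lag_frames.max())
    origins = np.arange(0, traj.n_frames - max_lag, max(origin_stride, 1))
    if len(origins) == 0:
        raise ValueError("no valid time origins: trajectory shorter than max lag")
    return lag_frames, origins, dt


def _harmonic_indices(Q: np.ndarray):
    """Integer harmonics k with Q = k*dq if the grid is commensurate, else None.

    Sorted positive grids whose values are integer multiples (up to 4096) of
    their smallest spacing qualify for the fast recurrence kernel.
    """
    Q = np.asarray(Q, dtype=np.float64)
    if len(Q) == 0 or np.any(Q <= 0) or np.any(np.diff(Q) <= 0):
        return None
    dq = Q[0] if len(Q) == 1 else min(Q[0], np.diff(Q).min())
    if dq <= 0:
        return None
    k = Q / dq
    kr = np.round(k).astype(np.int64)
    if np.any(kr < 1) or kr[-1] > 4096 or not np.allclose(k, kr, rtol=0, atol=1e-8):
        return None
    return kr


def _static_sum(model: RigidBodyModel, Q: np.ndarray) -> np.ndarray:
    """Lag-0 normalizer sum_mn b_m b_n sinc(Q r_mn) = P(Q) (sum b)^2."""
    from .rigid_model import form_factor

    return form_factor(model, Q) * model.scattering_lengths.sum() ** 2


def _run_rigid_kernel(model, traj, Q, lag_frames, origins, mode):
    """mode: 'total' (A=rel rot, b=disp), 'rot' (b=0), 'trans' (A=I)."""
    Q = np.atleast_1d(np.asarray(Q, dtype=np.float64))
    Rs = traj.rotation_matrices()
    com = traj.com_positions
    nlag = len(lag_frames)
    # configs for all (origin, lag>0) combinations
    cfg_A, cfg_b, cfg_lag = [], [], []
    for il, l in enumerate(lag_frames):
        if l == 0:
            continue
        R0 = Rs[origins]
        Rt = Rs[origins + l]
        dc = com[origins + l] - com[origins]
        b_body = np.einsum("kba,kb->ka", R0, dc)  # R0^T dc
        if mode == "total":
            A = np.einsum("kba,kbc->kac", R0, Rt)  # R0^T Rt
        elif mode == "rot":
            A = np.einsum("kba,kbc->kac", R0, Rt)
            b_body = np.zeros_like(b_body)
        elif mode == "trans":
            A = np.broadcast_to(np.eye(3), (len(origins), 3, 3)).copy()
        else:
            raise ValueError(mode)
        cfg_A.append(A)
        cfg_b.append(b_body)
        cfg_lag.append(np.full(len(origins), il, dtype=np.int64))
    out = np.zeros((nlag, len(Q)))
    outsq = np.zeros((nlag, len(Q)))
    counts = np.zeros(nlag, dtype=np.int64)
    if cfg_A:
        X = np.ascontiguousarray(model.positions)
        w = np.ascontiguousarray(model.scattering_lengths)
        Acat = np.ascontiguousarray(np.concatenate(cfg_A))
        bcat = np.ascontiguousarray(np.concatenate(cfg_b))
        lcat = np.concatenate(cfg_lag)
        kvals = _harmonic_indices(Q)
        if kvals is not None:
            _isf_accumulate_harmonic(X, w, Acat, bcat, lcat, Q[0] / kvals[0],
                                     kvals, out, outsq, counts)
        else:
            _isf_accumulate(X, w, Acat, bcat, lcat, Q, out, outsq, counts)
    # lag 0: static double sum, identical at every origin
    s0 = _static_sum(model, Q)
    out[lag_frames == 0] = s0 * len(origins)
    outsq[lag_frames == 0] = s0**2 * len(origins)
    counts[lag_frames == 0] = len(origins)
    nc = counts[:, None].astype(np.float64)
    mean = out / nc
    var = np.maximum(outsq / nc - mean**2, 0.0)
    sem = np.sqrt(var / nc)
    values = (mean / s0[None, :]).T  # (nQ, nlag)
    stderr = (sem / s0[None, :]).T
    return values, stderr, counts


# ---------------------------------------------------------------------------
# Public components
# ---------------------------------------------------------------------------

def isf_total(traj: Trajectory, model: RigidBodyModel, Q_grid, lag_grid,
              origin_stride: int = 10) -> ISFCurve:
    """Normalized total coherent ISF from the rigid-body trajectory."""
    lag_frames, origins, dt = _prepare(traj, lag_grid, origin_stride)
    values, stderr, counts = _run_rigid_kernel(model, traj, Q_grid, lag_frames,
                                               origins, "total")
    return ISFCurve("total", np.atleast_1d(np.asarray(Q_grid, dtype=float)),
                    lag_frames * dt, values, counts, stderr=stderr,
                    metadata={"origin_stride": origin_stride})


def isf_rot(traj: Trajectory, model: RigidBodyModel, Q_grid, lag_grid,
            origin_stride: int = 10) -> ISFCurve:
    """Normalized rotational (COM-removed intra-particle) coherent ISF."""
    lag_frames, origins, dt = _prepare(traj, lag_grid, origin_stride)
    values, stderr, counts = _run_rigid_kernel(model, traj, Q_grid, lag_frames,
                                               origins, "rot")
    return ISFCurve("rot", np.atleast_1d(np.asarray(Q_grid, dtype=float)),
                    lag_frames * dt, values, counts, stderr=stderr,
                    metadata={"origin_stride": origin_stride})


def isf_trans_weighted(traj: Trajectory, model: RigidBodyModel, Q_grid, lag_grid,
                       origin_stride: int = 10) -> ISFCurve:
    """Structure-weighted translational ISF (orientation frozen at the origin)."""
    lag_frames, origins, dt = _prepare(traj, lag_grid, origin_stride)
    values, stderr, counts = _run_rigid_kernel(model, traj, Q_grid, lag_frames,
                                               origins, "trans")
    return ISFCurve("trans", np.atleast_1d(np.asarray(Q_grid, dtype=float)),
                    lag_frames * dt, values, counts, stderr=stderr,
                    metadata={"origin_stride": origin_stride})


def isf_com(traj, Q_grid, lag_grid, origin_stride: int = 10) -> ISFCurve:
    """Center-of-mass coherent ISF, <sinc(Q |dr_c(t)|)> over origins.

    ``traj`` may be a Trajectory or an (n, 3) COM track (unit frame spacing).
    """
    if isinstance(traj, Trajectory):
        com = traj.com_positions
        dt = traj.dt
        nf = traj.n_frames
    else:
        com = np.asarray(traj, dtype=np.float64)
        dt = 1.0
        nf = com.shape[0]
    Q = np.atleast_1d(np.asarray(Q_grid, dtype=np.float64))
    lag_frames = np.unique(np.round(np.asarray(lag_grid, dtype=float) / dt).astype(int))
    lag_frames = lag_frames[lag_frames >= 0]
    if np.any(lag_frames >= nf):
        warnings.warn("dropping lags beyond the trajectory length")
        lag_frames = lag_frames[lag_frames < nf]
    if 0 not in lag_frames:
        lag_frames = np.concatenate([[0], lag_frames])
    max_lag = int(lag_frames.max())
    origins = np.arange(0, nf - max_lag, max(origin_stride, 1))
    if len(origins) == 0:
        raise ValueError("no valid time origins")
    values = np.empty((len(Q), len(lag_frames)))
    stderr = np.zeros((len(Q), len(lag_frames)))
    counts = np.empty(len(lag_frames), dtype=np.int64)
    for il, l in enumerate(lag_frames):
        if l == 0:
            values[:, il] = 1.0
            counts[il] = len(origins)
            continue
        d = np.linalg.norm(com[origins + l] - com[origins], axis=1)
        qd = Q[:, None] * d[None, :]
        samples = np.where(qd < 1e-12, 1.0, np.sin(qd) / np.where(qd == 0, 1, qd))
        values[:, il] = samples.mean(axis=1)
        stderr[:, il] = samples.std(axis=1) / np.sqrt(samples.shape[1])
        counts[il] = len(origins)
    return ISFCurve("com", Q, lag_frames * dt, values, counts, stderr=stderr,
                    metadata={"origin_stride": origin_stride})


def isf_from_beads(bead_track, Q_grid, lag_frames, origin_stride: int = 1,
                   scattering_lengths=None, dt: float = 1.0) -> ISFCurve:
    """Coherent ISF from an explicit bead trajectory (n_frames, N, 3).

    Brute-force cross-frame double sum; intended for small systems,
    externally produced trajectories and oracle checks.
    """
    beads = np.asarray(bead_track, dtype=np.float64)
    nf, N, _ = beads.shape
    Q = np.atleast_1d(np.asarray(Q_grid, dtype=np.float64))
    w = np.ones(N) if scattering_lengths is None else np.asarray(scattering_lengths, float)
    lag_frames = np.unique(np.asarray(lag_frames, dtype=int))
    lag_frames = lag_frames[(lag_frames >= 0) & (lag_frames < nf)]
    if 0 not in lag_frames:
        lag_frames = np.concatenate([[0], lag_frames])
    max_lag = int(lag_frames.max())
    origins = np.arange(0, nf - max_lag, max(origin_stride, 1))
    out = np.zeros((len(lag_frames), len(Q)))
    counts = np.zeros(len(lag_frames), dtype=np.int64)
    for il, l in enumerate(lag_frames):
        for t0 in origins:
            _isf_beads_accumulate(beads[t0], beads[t0 + l], w, Q, out[il])
            counts[il] += 1
    mean = out / counts[:, None]
    values = (mean / mean[lag_frames == 0][0][None, :]).T
    return ISFCurve("total", Q, lag_frames * dt, values, counts)


def compute_all_isfs(traj: Trajectory, model: RigidBodyModel, Q_grid, lag_grid,
                     origin_stride: int = 10) -> dict:
    """Total, COM, rotational and translation-weighted ISFs as a dict."""
    return {
        "total": isf_total(traj, model, Q_grid, lag_grid, origin_stride),
        "com": isf_com(traj, Q_grid, lag_grid, origin_stride),
        "rot": isf_rot(traj, model, Q_grid, lag_grid, origin_stride),
        "trans": isf_trans_weighted(traj, model, Q_grid, lag_grid, origin_stride),
    }
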