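"""Trajectory decomposition, mean-square displacement and the Langevin fit.

The rigid-body trajectory splits exactly into a center-of-mass track and a
COM-removed ("rotational") bead cloud, r_i(t) = r_c(t) + r_i,rot(t).  The
center-of-mass MSD, fitted to the free-particle Langevin form, yields the
momentum relaxation time tau_B = m/gamma that separates ballistic from
diffusive motion; effective-diffusion fits of ISFs must start above tau_B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .trajectory import Trajectory

__all__ = ["MSDCurve", "MSDFit", "decompose", "msd", "langevin_msd_model",
           "fit_langevin_msd"]


@dataclass
class MSDCurve:
    lag_times: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"lag_time": self.lag_times, "msd": self.values, "n_pairs": self.n_pairs}
        )


@dataclass
class MSDFit:
    """Free-particle Langevin MSD fit result.

    MSD(t) = tau_B^2 (1-e^{-t/tau_B})^2 (nu0^2 - 3 g/(2 m gamma))
             + (3 g / gamma^2) [t - tau_B (1 - e^{-t/tau_B})],   g = 2 gamma kBT,

    the 3-D Ornstein-Uhlenbeck result for a particle with initial speed nu0.
    The long-time diffusivity is D = kBT/gamma per dimension (slope 6 kBT/gamma).
    """

    tau_B: float
    gamma: float
    nu0: float
    g: float
    kBT: float
    mass: float
    cov: np.ndarray
    fit_window: tuple

    @property
    def D_long(self) -> float:
        """Long-time diffusion coefficient per dimension, kBT/gamma."""
        return self.kBT / self.gamma


def decompose(obj, model=None):
    """Split bead trajectories into COM and COM-removed (rotational) parts.

    Parameters
    ----------
    obj : (n_frames, N, 3) array or Trajectory
        Bead positions per frame, or a rigid-body trajectory (requires
        ``model`` to reconstruct the beads).
    model : RigidBodyModel, optional
        Needed when ``obj`` is a Trajectory; its masses weight the COM.

    Returns
    -------
    com_track : (n_frames, 3)
    rot_track : (n_frames, N, 3) with the COM removed per frame
    """
    if isinstance(obj, Trajectory):
        if model is None:
            raise ValueError("a model is required to reconstruct bead positions")
        Rs = obj.rotation_matrices()
        beads = obj.com_positions[:, None, :] + np.einsum(
            "fab,nb->fna", Rs, model.positions
        )
        weights = model.masses / model.masses.sum()
    else:
        beads = np.asarray(obj, dtype=np.float64)
        if beads.ndim != 3 or beads.shape[2] != 3:
            raise ValueError("bead trajectory must be (n_frames, N, 3)")
        weights = np.full(beads.shape[1], 1.0 / beads.shape[1])
    com = np.einsum("fnc,n->fc", beads, weights)
    return com, beads - com[:, None, :]


def msd(com_track, origin_stride: int = 10, lags=None, log_lags: int = None):
    """Multi-time-origin mean-square displacement of a COM track.

    ``com_track`` is an (n, 3) array or a Trajectory (its COM is used, with
    lag times in trajectory units).  ``lags`` are integer frame lags; if None,
    every lag (or ``log_lags`` log-spaced lags) is used.
    """
    if isinstance(com_track, Trajectory):
        dt = com_track.dt
        r = com_track.com_positions
    else:
        r = np.asarray(com_track, dtype=np.float64)
        dt = 1.0
    n = r.shape[0]
    if n < 2:
        raise ValueError("need at least 2 frames")
    if lags is None:
        if log_lags is not None:
            lags = np.unique(
                np.round(np.geomspace(1, n - 1, log_lags)).astype(int)
            )
        else:
            lags = np.arange(1, n)
    lags = np.asarray(lags, dtype=int)
    lags = lags[(lags >= 0) & (lags < n)]
    lag_times = np.empty(len(lags) + 1)
    vals = np.empty(len(lags) + 1)
    npairs = np.empty(len(lags) + 1, dtype=int)
    lag_times[0], vals[0], npairs[0] = 0.0, 0.0, n
    stride = max(origin_stride, 1)
    for k, l in enumerate(lags, start=1):
        if l == 0:
            lag_times[k], vals[k], npairs[k] = 0.0, 0.0, n
            continue
        origins = np.arange(0, n - l, stride)
        d = r[origins + l] - r[origins]
        vals[k] = np.mean((d * d).sum(axis=1))
        lag_times[k] = l * dt
        npairs[k] = len(origins)
    order = np.argsort(lag_times)
    keep = np.concatenate([[True], np.diff(lag_times[order]) > 0])
    order = order[keep]
    return MSDCurve(lag_times[order], vals[order], npairs[order])


def langevin_msd_model(t, tau_B, gamma, nu0, kBT=1.0):
    """3-D free-particle Langevin MSD with g = 2 gamma kBT and m = gamma tau_B."""
    t = np.asarray(t, dtype=np.float64)
    m = gamma * tau_B
    g = 2.0 * gamma * kBT
    e = np.exp(-t / tau_B)
    ballistic = tau_B**2 * (1.0 - e) ** 2 * (nu0**2 - 3.0 * g / (2.0 * m * gamma))
    diffusive = (3.0 * g / gamma**2) * (t - tau_B * (1.0 - e))
    return ballistic + diffusive


def fit_langevin_msd(msd_curve: MSDCurve, mass: float = None, kBT: float = 1.0,
                     fit_window: tuple = None, stationary: bool = True) -> MSDFit:
    """Fit an MSD curve to the free-particle Langevin form.

    Requires the curve to resolve both the ballistic (t << tau_B) and
    diffusive (t >> tau_B) regimes; a curve with no ballistic signature
    (pure diffusion) makes tau_B unidentifiable and raises.

    ``stationary=True`` (default) ties nu0^2 = 3 kBT/m, the thermal value.
    This is the correct form for multi-time-origin MSD curves, where each
    origin starts from an equilibrium velocity, and it removes a genuine
    near-degeneracy of the 3-parameter form on such data: with nu0 free,
    the model reproduces a stationary curve through third order in t with
    either tau_B or 2 tau_B.  Set it False only for single-origin tracks
    launched with a known initial speed.
    """
    t = msd_curve.lag_times
    y = msd_curve.values
    pos = t > 0
    t, y = t[pos], y[pos]
    if fit_window is not None:
        m_ = (t >= fit_window[0]) & (t <= fit_window[1])
        t, y = t[m_], y[m_]
    if len(t) < 4:
        raise ValueError("too few MSD points for a 3-parameter fit")
    if t.max() / t.min() < 30:
        warnings.warn("MSD window spans < 1.5 decades; tau_B may be ill-determined")

    # initial guesses: long-time slope -> gamma; short-time curvature -> nu0
    slope_long = (y[-1] - y[len(y) // 2]) / (t[-1] - t[len(t) // 2])
    gamma0 = max(6.0 * kBT / max(slope_long, 1e-300), 1e-12)
    nu0_0 = np.sqrt(max(y[0], 1e-300)) / t[0]
    tau0 = max(slope_long / max(nu0_0**2, 1e-300), t[0])

    # relative weighting equalizes ballistic and diffusive decades; the extra
    # sqrt(t) factor models the loss of independent origin pairs at long lags,
    # which otherwise lets the noisiest points dominate the fit
    sigma = np.maximum(y, y.max() * 1e-12) * np.sqrt(t / t.min())
    try:
        if stationary:
            def f(tt, log_tau, log_gamma):
                tau_, gamma_ = np.exp(log_tau), np.exp(log_gamma)
                nu_ = np.sqrt(3.0 * kBT / (gamma_ * tau_))  # thermal speed
                return langevin_msd_model(tt, tau_, gamma_, nu_, kBT)

            popt, pcov = curve_fit(f, t, y, p0=[np.log(tau0), np.log(gamma0)],
                                   sigma=sigma, maxfev=20000)
            tau_B, gamma = np.exp(popt[0]), np.exp(popt[1])
            nu0 = np.sqrt(3.0 * kBT / (gamma * tau_B))
        else:
            def f(tt, log_tau, log_gamma, nu0_):
                return langevin_msd_model(tt, np.exp(log_tau), np.exp(log_gamma),
                                          nu0_, kBT)

            popt, pcov = curve_fit(f, t, y,
                                   p0=[np.log(tau0), np.log(gamma0), nu0_0],
                                   sigma=sigma, maxfev=20000)
            tau_B, gamma, nu0 = np.exp(popt[0]), np.exp(popt[1]), abs(popt[2])
    except RuntimeError as exc:
        raise RuntimeError(f"Langevin MSD fit did not converge: {exc}") from exc
    if not np.isfinite(tau_B) or tau_B <= 0:
        raise RuntimeError("fitted tau_B is not positive")
    if tau_B < 1.5 * t.min():
        raise RuntimeError(
            f"fitted tau_B = {tau_B:.3g} is below the time resolution "
            f"({t.min():.3g}): no resolvable ballistic regime (pure diffusion?)"
        )
    resid = f(t, *popt) / y - 1.0
    if np.sqrt(np.mean(resid**2)) > 0.5:
        raise RuntimeError(
            f"Langevin MSD fit rejected: RMS relative residual "
            f"{np.sqrt(np.mean(resid ** 2)):.2f}"
        )
    return MSDFit(
        tau_B=float(tau_B), gamma=float(gamma), nu0=float(nu0),
        g=2.0 * gamma * kBT, kBT=kBT,
        mass=float(mass) if mass is not None else float(gamma * tau_B),
        cov=pcov, fit_window=(float(t.min()), float(t.max())),
    )
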