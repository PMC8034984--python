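"""Optional matplotlib views of Deff curves and ISF overlays."""

from __future__ import annotations

import numpy as np


def plot_deff_curves(curves: dict, D0: float = None, ax=None):
    """Deff(Q) (or Deff/D0 if D0 given) per component, with replicate spread."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    norm = D0 if D0 else 1.0
    for name, c in curves.items():
        ax.errorbar(c.Q_grid, c.values / norm, yerr=c.spread / norm,
                    marker="o", ms=3, capsize=2, label=name)
    ax.set_xlabel(r"$Q$ ($\mathrm{\AA}^{-1}$)")
    ax.set_ylabel(r"$D_{\rm eff}/D_0$" if D0 else r"$D_{\rm eff}$")
    ax.legend(fontsize=8)
    return ax


def plot_isf_reduced_time(isf, D0: float, ax=None, **kwargs):
    """ISF curves against the reduced time D0 Q^2 t (master-curve axis)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for iq, q in enumerate(isf.Q_grid):
        x = D0 * q * q * isf.lag_grid
        ax.plot(x, isf.values[iq], marker=".", ms=3,
                label=f"Q={q:g}", **kwargs)
    x = np.linspace(0, ax.get_xlim()[1], 100)
    ax.plot(x, np.exp(-x), "k--", lw=1, label=r"$e^{-D_0Q^2t}$")
    ax.set_xlabel(r"$D_0 Q^2 t$")
    ax.set_ylabel(r"$I(Q,t)/I(Q,0)$")
    ax.legend(fontsize=7)
    return ax
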