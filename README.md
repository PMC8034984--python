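# rigidnse

Coherent intermediate scattering functions and short-time diffusion of rigid
coarse-grained proteins, from dissipative-particle-dynamics (DPD) or
rigid-body Brownian-dynamics trajectories.

## The problem

Neutron spin echo (NSE) measures the normalized coherent intermediate
scattering function I(Q,t)/I(Q,0) of proteins in solution at
Q ≈ 0.01–0.2 Å⁻¹ and nanosecond–microsecond times.  For a rigid particle
this signal mixes center-of-mass (COM) translation and rotation; standard
analyses *decouple* them,

    I(Q,t)/I(Q,0) ≈ I_com(Q,t) · I_rot(Q,t)
    ⇒  D_total(Q) ≈ D_com + D_rot(Q)            (COM + rotation sum)
    or D_total(Q) ≈ D_trans(Q) + D_rot(Q),       (structure-weighted sum)

with D_trans(Q) = ⟨|F(Qq̂)|² (q̂·D_tt·q̂)⟩_q̂ / P(Q).  For anisotropic
particles such as a Y-shaped monoclonal antibody (~10 nm across), these
approximations carry errors that matter whenever a small NSE signal change
is attributed to internal protein motion.  This package quantifies those
errors: it simulates the Brownian motion of a rigid bead model exactly,
computes the total / COM / rotational / translation-weighted coherent ISFs
from the same trajectory, extracts the short-time effective diffusion
coefficients D_eff(Q) = −(1/Q²) d ln I/dt, and reports the relative error
of each decoupling approximation as a function of Q.

It is intended for scattering and biophysics groups who analyse NSE (or
other coherent quasi-elastic) data with rigid-body reference models.

## What is inside

| module | contents |
| --- | --- |
| `rigid_model` | bead models from PDB (1 bead/residue) or synthetic (Y-shaped antibody, spherical shell); Debye form factor; Rotne–Prager–Yamakawa / Kirkwood diffusion tensors |
| `dpd_engine` | DPD fluid with an embedded rigid body (conservative + dissipative + random forces, fluctuation–dissipation paired, momentum conserving) |
| `bd_engine` | fast overdamped rigid-body Brownian dynamics with a body-frame anisotropic 6×6 tensor; exact inertial Langevin reference particle |
| `traj_tools` | trajectory decomposition, multi-origin MSD, Langevin MSD fit (momentum relaxation time τ_B) |
| `scattering` | the four coherent ISF components via the orientationally averaged double sum, with origin-scatter error bars |
| `diffusion_analysis` | D_eff(Q) extraction, the D_trans(Q) sphere quadrature, D₀ normalization, decoupling reports |
| `reporting` / `cli` | end-to-end `run-study` pipeline with provenance manifest; `rigidnse` command-line tool |

## Worked example

```python
import numpy as np
import rigidnse as rn

# a Y-shaped antibody-like rigid body, ~90 A across, 300 beads
model = rn.make_synthetic_mab(seed=1)
D = rn.estimate_diffusion_tensor(model)      # bead-model hydrodynamics
print(f"D0 = {D.D0:.2f} A^2/ns, Dr = {D.Dr:.2e} rad^2/ns")

# one 5 us Brownian trajectory and its ISF components
traj = rn.run_bd(model, D, dt=0.25, n_steps=20_000, seed=101)
Q = 0.01 * np.arange(1, 21)                  # 0.01 ... 0.2 1/A
lags = rn.make_lag_grid(0.25, 40.0, 18)      # log-spaced, <= 40 ns
isfs = rn.compute_all_isfs(traj, model, Q, lags, origin_stride=80)

# short-time effective diffusion coefficients and the decoupling errors
deff = {k: rn.extract_deff(v, (0.25, 40.0), D0_guess=D.D0)
        for k, v in isfs.items()}
rep = rn.compare_decoupling(deff["total"], deff["com"], deff["rot"],
                            deff["trans"], D0=D.D0)
e17, q17 = rep.max_error("com_rot")
e19, q19 = rep.max_error("trans_rot")
print(f"max (Dcom+Drot-Dtot)/Dtot  = {e17:+.1%} at Q = {q17:.2f} 1/A")
print(f"max (Dtrans+Drot-Dtot)/Dtot = {e19:+.1%} at Q = {q19:.2f} 1/A")
```

Output from this exact script:

```
D0 = 5.30 A^2/ns, Dr = 1.88e-03 rad^2/ns
max (Dcom+Drot-Dtot)/Dtot  = +5.2% at Q = 0.08 1/A
max (Dtrans+Drot-Dtot)/Dtot = -0.5% at Q = 0.20 1/A
```

Reading: the model free-diffuses at 5.3 Å²/ns and rotates at 1.9·10⁻³
rad²/ns.  Adding the bare COM coefficient to the rotational one
*overestimates* the measured total D_eff — here by 5% on a single short
trajectory, peaking near Q ≈ 2π/diameter where the scattering is most
sensitive to shape; using the structure-weighted translational coefficient
instead reduces the error to below 1%, inside the single-trajectory noise.
Averaging 3 seeds and longer runs (as `run-study` and the acceptance
script do) tightens the COM+rotation error to ≈ +2.5%.

The same pipeline runs from the shell:

```bash
rigidnse build-model --out model.xyz              # synthetic antibody
rigidnse simulate-bd --model model.xyz --out traj.npz --n-steps 20000 --seed 1
rigidnse compute-isf --traj traj.npz --model model.xyz --out isf.csv
rigidnse run-study --outdir study_out             # full 3-seed study
```

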