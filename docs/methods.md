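# Methods

## The observable

Neutron spin echo (NSE) measures the normalized coherent intermediate
scattering function (ISF) of particles in solution,

    I(Q,t)/I(Q,0) = < F(Q⃗,0) F*(Q⃗,t) e^{iQ⃗·Δr⃗_c(t)} >_θ / P(Q),

where F(Q⃗,t) = Σ_n b_n e^{iQ⃗·[r⃗_n(t)−r⃗_c(t)]} is the single-particle
scattering amplitude, Δr⃗_c(t) the center-of-mass (COM) displacement,
P(Q) = <|F|²>_θ the form factor, and <·>_θ the average over wavevector
directions.  For a dilute, rigid particle the intra-particle part of the ISF
is purely rotational.  A widely used approximation factorizes the ISF into
independent COM and rotational parts,

    I(Q,t)/I(Q,0) ≈ I_com(Q,t) · I_rot(Q,t),

which at short times implies additivity of effective diffusion coefficients,
D_total(Q) ≈ D_com + D_rot(Q).  A refinement replaces the bare COM
coefficient by a structure-weighted translational coefficient

    D_trans(Q) = < |F(Q q̂)|² (q̂·D_tt·q̂) >_q̂ / P(Q),

giving D_total(Q) ≈ D_trans(Q) + D_rot(Q).  This package measures how well
both approximations hold for an anisotropic, antibody-shaped rigid body, by
simulating its Brownian motion exactly and computing every term of the
comparison from the same trajectories.

For an orientationally averaged single particle the ISF reduces to the
double sum

    I(Q,t) = Σ_{m,n} b_m b_n sinc(Q r_mn(t)),   r_mn(t) = |r⃗_m(t₀) − r⃗_n(t₀+t)|,

which is what the numerical kernels evaluate, between a time origin and a
lagged frame, averaged over strided origins and normalized at lag 0.  Four
components come from one rigid-body trajectory (COM + quaternion):

* **total** — beads reconstructed with translation and rotation;
* **com** — <sinc(Q |Δr_c|)>, the COM correlator;
* **rot** — COM removed: the coherent rotational ISF;
* **trans** — orientation frozen at the origin: the trajectory estimator of
  the structure-weighted translational ISF (its short-time decay rate is
  D_trans(Q); the package also evaluates the defining quadrature directly
  and cross-checks the two).

Because the body is rigid, cross-time pair distances depend only on the
relative rotation A = R(t₀)ᵀR(t₀+t) and the body-frame displacement
b = R(t₀)ᵀΔr_c, which keeps the kernels O(N²) per configuration without
rebuilding bead clouds.  When the Q grid consists of integer multiples of a
base spacing, sin(kθ) is generated by a Chebyshev recurrence, so a 20-point
Q grid costs little more than one sine per bead pair.

## Effective diffusion coefficients

D_eff(Q) = −(1/Q²) d ln[I(Q,t)/I(Q,0)]/dt at short times, estimated by a
weighted linear fit of ln I against t.  The fit window must sit above the
momentum relaxation time of the generating engine (zero for the overdamped
surrogate) and inside the statistically reproducible region.  Because ISF
decays are multi-exponential away from t → 0, the window is additionally
capped per Q at D₀Q²t ≤ 0.25 (configurable), keeping every fit in the
short-time regime while leaving measurable decay at small Q.  All four
components are fitted in the same windows so that shared COM noise
partially cancels in the decoupling differences.  Points are weighted by
origin-scatter standard errors accumulated alongside the ISF sums.

## Engines

**Brownian-dynamics surrogate (`run_bd`).**  The body's 6×6 diffusion
tensor is fixed in the body frame; each step draws a 6-vector Gaussian
displacement with covariance 2 D dt, applies the translational part in the
lab frame and the rotational part through the quaternion exponential map
(renormalized each step).  The shape-coupled mobility — translation being
easier along some body axes than others — is exactly the mechanism that
separates D_com, D_trans and D_total, so the surrogate reproduces the
decoupling physics at a small fraction of the cost of an explicit-solvent
run.  The rotational step RMS is capped at 0.2 rad.  Overdamped dynamics is
appropriate because COM motion is diffusive above the momentum relaxation
time, and all ISF fits start above it.

**DPD fluid (`run_dpd`).**  A dissipative-particle-dynamics fluid with an
embedded rigid body provides the momentum-conserving, hydrodynamic route.
Pair forces are the standard conservative/dissipative/random triplet with
ω_D = ω_R² = (1 − r/r_c)² and σ² = 2γkBT; parameters default to the
water-compressibility convention a = 25 kBT/r_c at ρ = 3, γ = 4.5,
dt = 0.01, kBT = 1.  Integration is modified velocity-Verlet (λ = 0.5).
The rigid body is a set of ordinary DPD sites whose forces are reduced to a
net force and torque; COM, momentum, quaternion and angular momentum are
propagated as one unit, with no body-internal pair forces.  Pair randomness
is counter-based (splitmix64 of seed, step, ordered pair), making runs
bitwise reproducible independent of traversal order.  The desk-scale
default is a reduced box; a production-scale configuration (box ≥ 6 body
diameters, ~10⁶ fluid particles, ~10⁷ steps) is expressible with the same
API but is a cluster-scale run.

**Inertial Langevin reference (`run_langevin_point`).**  A free underdamped
point particle advanced with the exact Ornstein–Uhlenbeck transition
kernel (unbiased at any dt), used to exercise the momentum-relaxation-time
fit.

## The Langevin MSD fit

The 3-D free-particle MSD conditional on initial speed ν₀ is

    MSD(t) = τ_B²(1−e^{−t/τ_B})²(ν₀² − 3g/(2mγ)) + (3g/γ²)[t − τ_B(1−e^{−t/τ_B})],

with g = 2γkBT and τ_B = m/γ; it has the ballistic limit ν₀²t² and the
diffusive limit (6kBT/γ)t.  We re-derived this form from the OU process and
unit-tested both limits before fitting.  On *stationary* multi-time-origin
MSD curves the three-parameter fit is nearly degenerate: with ν₀ free, the
model reproduces a stationary curve through O(t³) at either τ_B or exactly
2τ_B.  The default fit therefore ties ν₀² = 3kBT/m (each origin starts at
thermal velocity), which removes the degeneracy; the free-ν₀ form remains
available for single-origin tracks.  Fits are weighted ∝ 1/(y√t), the √t
factor modelling the loss of independent origin pairs at long lags.

## Rigid models and hydrodynamics

Models are rigid bead clouds: one bead per amino-acid residue from a PDB
file (heavy-atom centroid by default, CA optional), unit scattering lengths
and equal masses, re-centered to the COM.  The synthetic antibody stand-in
is three spheroidal bead lobes (two Fab arms opened by a 120° hinge, one Fc
stem scaled ×0.9 for asymmetry) with ~100 Å overall diameter, the size and
topology of an IgG; a quasi-uniform Fibonacci spherical shell provides the
spherically symmetric null model.

The default diffusion-tensor estimate ("rpy") builds the 3N×3N
Rotne–Prager–Yamakawa translational mobility of the bead array (with the
overlap form for r < 2a), inverts it, contracts with the rigid-body lever
arms to a 6×6 resistance — adding the per-bead rotational self-friction
8πηa³ — and returns D = kBT Ξ⁻¹ about the COM.  The classic Kirkwood
double sum is available as `method="kirkwood"`; it reproduces the tt block
cheaply but its hydrodynamics-free rotational friction grows additively
with bead count and would make rotation unphysically slow for ~300-bead
models, which is why it is not the default.  Users may inject any symmetric
positive semi-definite 6×6 tensor.

Defaults with units: bead hydrodynamic radius a = 4.5 Å (residue scale);
viscosity η = 3.2·10⁻⁴ kBT·ns/Å³, chosen so a ~100 Å body has
D₀ ≈ 3.7 Å²/ns, the scale of an antibody in a D₂O buffer.  All analysis is
unit-agnostic in the reduced variables D₀Q²t and t/τ_c, with
τ_c = σ²/(6D₀) the time to diffuse one diameter σ (this form is fixed by
that physical meaning).  The structure-weighted quadrature uses a
Gauss–Legendre × uniform-azimuth product rule on the sphere and verifies
convergence by order doubling (< 0.1% change required); the
translation–rotation coupling block is excluded from the q̂ average by
default since it integrates to zero for a COM-centered body-frame tensor.

## Study conditions and problem sizes

The default decoupling study runs the Brownian surrogate for the synthetic
antibody (300 beads) with its bead-model tensor: 3 independent seeds,
10 µs trajectories at 0.25 ns resolution (≈ 20 rotational relaxation
times), Q = 0.01–0.2 Å⁻¹ in 0.01 steps, lag grid log-spaced to 40 ns,
origins every 12 ns.  These sizes put the statistical spread of the Deff
curves well below the decoupling signal at intermediate and high Q while
remaining desk-scale.  The test suite uses smaller versions of the same
studies (fewer beads, shorter runs), stated in each fixture.

Measured on these conditions, the COM+rotation sum overestimates the total
effective diffusion coefficient at all Q (maximum ≈ 2–3% near
Q ≈ 2π/diameter), the structure-weighted sum is accurate to better than 1%,
and the theoretical |D_trans(Q) − D₀|/D₀ peaks at ≈ 4% at Q ≈ 0.08 Å⁻¹.
The ordering and signs match the physics of shape-coupled mobility: the
form-factor weighting emphasizes slow directions, so D_trans < D_com and
their difference is largest at the inverse particle size.  The magnitudes
are smaller than for a real antibody because the default synthetic Y is
less anisotropic (translational anisotropy ≈ 14%); users reproducing
stronger coupling should supply a more elongated model or a PDB structure.

## What the synthetic generator does and does not emulate

The surrogate reproduces rigid-body translation–rotation statistics with a
body-fixed anisotropic mobility, which is the entire content of the
decoupling question for rigid particles.  It does not include solvent
momentum (no hydrodynamic memory, no sound), inter-particle correlations,
or internal flexibility — so passing tests demonstrate correctness of the
estimators and the size of rigid-body decoupling errors, not the behaviour
of concentrated or flexible systems.  The DPD engine restores solvent
hydrodynamics at desk scale only for sanity-level checks (thermostat
temperature, momentum conservation, force law); quantitative ISF work at
DPD scale needs the cluster-size configuration.

## Numerical choices and degenerate inputs

* ISF normalization uses the exact static Debye sum at lag 0, so the lag-0
  value is exactly 1.
* Lags beyond the trajectory are dropped with a warning; a lag equal to the
  trajectory length leaves a single usable origin.
* Deff fits reject windows with fewer than 3 points or non-positive ISF
  values (log domain); at high Q, where the reduced-time cap bites, the
  earliest 3 usable lags are used.
* Pure-diffusion MSD input makes τ_B unidentifiable; the fit raises rather
  than returning a sub-resolution τ_B.
* Coincident beads make bead-model hydrodynamics singular and are rejected.
* The BD propagator refuses rotational steps with RMS ≥ 0.2 rad; the DPD
  integrator aborts on velocity blow-up with diagnostics.
* Known limitation: the origin-scatter standard errors underestimate the
  true uncertainty when origins are spaced closer than the lag (correlated
  samples); replicate spread across seeds is the primary uncertainty,
  matching how the error bars of multi-trajectory studies are usually
  estimated.
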