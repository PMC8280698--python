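# Methods

## Dynamics

Nuclei follow classical trajectories on the active adiabatic surface
(velocity Verlet); the electronic coefficients obey

    i dC_n/dt = eps_n C_n - i sum_k (Rdot . d_nk) C_k + i xi_n,

integrated with fixed-step RK4 on `n_substeps` substeps per nuclear step
(default 20), with eps_n and the velocity–NACV projections linearly
interpolated between the nuclear grid points. Adiabatic quantities come
from diagonalizing the analytic diabatic matrix: gradients from the
Hellmann–Feynman diagonal of U^T (dH) U, NACVs from its off-diagonal
divided by the gap, eigenvector signs aligned with the previous step so the
couplings are continuous along a trajectory. Exact degeneracies raise an
error rather than return an arbitrary NACV; trajectories never land on one
in practice. All internal quantities are in Hartree atomic units (hbar = 1,
bohr, electron masses); femtoseconds appear only in output tables.

Hops are decided once per nuclear step, after the electronic update, from
the fewest-switches probability

    zeta_ak = max(0, 2 dt (Rdot . d_ak) Re rho_ak / rho_aa),

with cumulative-window selection over states in ascending index against a
single uniform draw (a hop to state n requires
sum_{k<n} zeta < r <= sum_{k<=n} zeta, strictly above the lower edge).
Accepted hops conserve total energy through one of three velocity
adjustments: uniform (isotropic) scaling `kappa = sqrt(1 - dE/KE)`;
adjustment along the NACV, `V -> V + gamma d/M` with gamma the
smaller-magnitude real root of `(sum d^2/2M) gamma^2 + (V.d) gamma + dE = 0`
(computed with the numerically stable root pair); or NACV with isotropic
fallback when the NACV adjustment is frustrated. Energetically forbidden
hops are rejected; the frustrated-hop policy either keeps the momentum
(default — the literature has not settled the question) or reverses it.

Each trajectory owns a Philox stream keyed by (base seed, trajectory
index), one hop draw per step plus the scheme's draws, so any run replays
bitwise and any single trajectory can be re-derived in isolation. The
two-state electronic kernel is numba-compiled when numba is importable;
a pure-numpy path with identical arithmetic is used otherwise and for
more than two states.

## Decoherence corrections

**SHXF.** The correction term is

    xi_n = sum_nu (Q_nu / M_nu) (f_n,nu - sum_l |C_l|^2 f_l,nu) C_n,

with quantum momentum `Q = (R - sum_k |C_k|^2 R_k^aux) / (2 sigma^2)` —
the leading-order -grad|chi|/|chi| of an equal-width Gaussian mixture
centered on the auxiliary positions. The sum over `l` runs over the live
states (active plus alive auxiliaries) with renormalized populations, which
makes the term exactly norm-neutral: it redistributes population toward
the state whose accumulated force aligns with Q, in operation the active
one. An auxiliary trajectory is spawned on a nonactive surface when its
population first exceeds `spawn_threshold` (default 1e-4; the choice only
needs to be small), at the current position, along the parent's velocity,
with kinetic energy KE_parent + eps_active - eps_n (the potential-energy
difference distributed isotropically over the coordinates). Auxiliaries
advance by their own velocity, with the speed refreshed each step from
energy conservation on their surface; a classically forbidden auxiliary
freezes at zero velocity (and is counted in the run diagnostics) rather
than dying, so its accumulated force stays defined. The accumulated force
f_k integrates -grad eps_k along the surface-k surrogate as per-step
momentum changes on top of the launch momentum, so f_k is the current
momentum — the phase gradient — of the surface-k component; the real
trajectory stands in for the active surface. Without the launch-momentum
offset the correction misses the dominant part of the inter-surface
momentum difference on models whose surfaces are asymptotically parallel
and decoheres far too slowly. On an accepted hop the real trajectory takes
over the target surface, its auxiliary is deleted, and a fresh auxiliary is
respawned for the formerly active state. sigma defaults to the
ground-state width of the initial nuclear wavepacket (a per-run scalar
override is honored), following the width-of-the-ground-state protocol.

**SHEDC.** After the coherent update, nonactive amplitudes are damped by
exp(-dt/tau_n) with `tau_n = (hbar/|eps_n - eps_a|)(1 + alpha/T)`,
T the total nuclear kinetic energy and alpha = 0.1 Hartree by convention;
the active amplitude is rescaled (phase untouched) so the populations sum
to one. A zero gap means no damping for that pair; T = 0 skips the step.
The damping acts on coefficients, matching the widely used codes.

**A-FSSH.** Per nonactive state, displacement moments obey
d(dR_n)/dt = dP_n/M and d(dP_n)/dt = dF_n with dF_n = F_n - F_a, stepped
velocity-Verlet-consistently with the nuclear integrator and zeroed at
trajectory start, on hops, and on collapse/reset events. The collapse rate
is `(dF_n . dR_n - 2|(eps_n - eps_a)(d_an . dR_n)|)/(2 hbar)`, the reset
rate its negated growth term (the simplified augmented-FSSH pair; the
exact expression used is echoed into run metadata). Each nonactive state
draws independent collapse and reset uniforms every nuclear step
(dt_c = nuclear dt); a collapse zeroes C_n and boosts the active amplitude
magnitude so the norm stays one.

All three schemes are pure per-step transformations behind one plugin
interface and preserve the electronic norm to 1e-10 in full runs.

## Model systems

Literature parameterizations of the three standard 1D scattering models
(masses 2000 a.u.):

| model | diabats | coupling |
|---|---|---|
| `single_crossing` | V11 = ±A(1-exp(∓Bx)), V22 = -V11; A=0.01, B=1.6 | C exp(-Dx^2); C=0.005, D=1 |
| `dual_crossing` | V11 = 0; V22 = -A exp(-Bx^2)+E0; A=0.1, B=0.28, E0=0.05 | C exp(-Dx^2); C=0.015, D=0.06 |
| `recrossing` | V11 = A = 6e-4, V22 = -A | B exp(Cx) (x<0), B(2-exp(-Cx)) (x>0); B=0.1, C=0.9 |
| `sharp_crossing` | V11 = ax, V22 = -ax; a = 0.005 | c exp(-x^2/2w^2); c = 0.03, w = 0.07 |

`sharp_crossing` is an in-house fixture emulating a strongly sloped,
localized crossing: the coupling window (~0.15 bohr) is traversed in
~15 a.u. of time at the study momentum, of the order of one coarse nuclear
step, and its strength was chosen so the passage is genuinely intermediate
(exact upper-adiabat transfer ~0.70 at k0 = 20) — weak enough coupling
would make the transfer saturate near 1 and hide the time-step
sensitivity the fixture exists to exhibit.

## Study conditions

Initial conditions are Wigner-sampled from the ground state of the
harmonic fit to the initial Gaussian: R ~ N(x0, sigma^2),
P ~ N(k0, 1/(4 sigma^2)), with sigma = 10/k0 (momentum spread k0/20, the
conventional scattering choice); the oracle propagates the identical
Gaussian, so the two calculations share their initial density exactly.
Ensembles start on the lower adiabat with C = delta. Single crossing:
x0 = -6, k0 in {8.5, 15, 25} (at 8.5 the upper channel is closed:
frustrated hops and a temporarily trapped upper-state component), runs end
when all trajectories pass |x| = 10 outgoing or at t_max = 8000/3500/2000
a.u.; n = 2000. Recrossing: x0 = -13, k0 = 10, t_max = 8000, n = 1000.
Nuclear dt = 1.0 a.u. (the coupling regions span well over 100 a.u. of
travel on the smooth models), 20 electronic substeps. Oracle: 3072-point
grid on [-60, 60], dt_q = 0.5 (halving dt_q and dx moves final populations
by < 1e-6). The time-step scan uses dt = 0.5/0.25/0.1 fs at n = 500 and
flags a run as not converged when a coarser dt deviates from the finest by
more than three combined binomial standard errors. These sizes keep the
full validation suite at desk scale (minutes on one CPU); they are stated
here so every reported number is reproducible.

## What the synthetic setup does and does not show

The models are 1D, two-state, with analytic surfaces; the Wigner sampling
is temperature-zero and harmonic. Passing tests demonstrate the
correctness of the algorithms (integrators, hopping, energy bookkeeping,
the decoherence operators) and their qualitative physics (restored
internal consistency, coherence decay, dt sensitivity at sharp crossings)
against an exact reference — something ab initio applications cannot do.
They do not probe multi-dimensional conical-intersection topology,
anharmonic sampling, or electronic-structure noise.

Two documented behaviors of the corrections themselves show up clearly and
are left as findings, not failures of implementation:

* **SHEDC in the slow-passage regime.** At the medium momentum the
  single-crossing passage time (~270 a.u.) is comparable to the SHEDC time
  constant inside the coupling region, so damping acts *during* the
  transfer and shifts the final populations by ~0.1 from exact — the known
  overdamping pathology (the corrected schemes overshooting the reference
  transfer is also what the molecular comparisons report). At low and high
  momentum SHEDC agrees with the oracle to ~0.02.
* **A-FSSH on parallel surfaces.** Its moments are driven purely by BO
  force differences, which vanish on asymptotically parallel surfaces, so
  after the packet components separate the collapse rate goes to zero and
  residual coherence survives indefinitely on the single-crossing model.
  SHXF (whose accumulated-force difference retains the launch-momentum
  offset) and SHEDC (which damps on any finite gap) do decohere there.
  This is the state-pairwise/parallel-surface blind spot discussed as an
  open problem for surface hopping generally.

## Numerical choices and degenerate inputs

RK4 norm drift with xi = 0 is monitored every step; drift above 1e-6
aborts an uncorrected run with a "reduce dt" diagnostic (corrected schemes
renormalize roundoff-level drift). Negative fewest-switches probabilities
are clamped to zero; a vanishing active population (rho_aa < 1e-12) yields
zero hop probability with a warning rather than a division. The NACV
quadratic uses the stable root pair (q = -(b + sign(b) sqrt(disc))/2) and
picks the smaller-|gamma| root; b = 0 breaks the tie toward the negative
root. Eigenvector sign fixing falls back to "first nonzero component
positive" when no previous frame exists. Total energy is audited per
trajectory: drift relative to the last hop and the energy jump across each
accepted hop are recorded and tested (< 1e-6 and < 1e-10 Hartree at the
study settings).

## Limitations

Beyond the physics limitations above: the oracle is restricted to 1D
(the hopping code is dimension-agnostic but oracle-based validation is
not); wavefunction-overlap/local-diabatization couplings and the
cumulative hopping scheme are not implemented (explicit NACVs are used in
the electronic equation); Ehrenfest, coupled-trajectory (CT-MQC) and
multiple-spawning methods are out of scope.
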