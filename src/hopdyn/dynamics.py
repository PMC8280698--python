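"""Fewest-switches surface hopping: nuclear + electronic propagation.

One nuclear step of the algorithm, per trajectory:

1. velocity-Verlet on the active Born–Oppenheimer surface;
2. RK4 integration of the coupled electronic coefficients on ``n_substeps``
   substeps, with energies and velocity-NACV couplings linearly interpolated
   across the nuclear step and the decoherence scheme's rate term included;
3. the scheme's post-step transform (damping / stochastic collapse);
4. fewest-switches hop decision, zeta_ak = max(0, 2 dt (V.d_ak) Re rho_ak /
   rho_aa), with cumulative-window target selection against one uniform draw;
5. on an accepted hop, velocity adjustment (isotropic, along the NACV, or
   NACV with isotropic fallback) conserving total energy; frustrated hops
   keep or reverse the velocity according to policy.

The runner is vectorized over the ensemble; a single trajectory is an
ensemble of one.  Every random draw comes from the trajectory's own
counter-derived stream, so runs replay bitwise for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .decoherence import (DecoherenceParams, StepContext, TwoStateXFRate,
                          make_scheme)
from .models import AdiabaticPoint, ModelSystem, adiabatic_point
from .sampling import trajectory_rng

try:                                    # optional compiled kernels
    from . import _kernels
except ImportError:                     # pragma: no cover - numba missing
    _kernels = None

__all__ = [
    "IntegrationError", "TrajectoryState", "SHConfig", "EnsembleRecord",
    "TrajectoryRecord", "nuclear_step", "electronic_step", "hop_probability",
    "attempt_hop", "rescale_isotropic", "rescale_nacv", "rescale_dispatch",
    "run_ensemble", "run_trajectory",
]

AU_TIME_FS = 0.02418884326586  # 1 a.u. of time in femtoseconds

# hop-log branch codes
BRANCH_ISO = 0
BRANCH_NACV = 1
BRANCH_NACV_ISO_FALLBACK = 2
BRANCH_FRUSTRATED = 3
BRANCH_FRUSTRATED_ZERO_NACV = 4

HOP_LOG_DTYPE = np.dtype([
    ("step", np.int64), ("t", np.float64), ("traj", np.int64),
    ("from_state", np.int16), ("to_state", np.int16),
    ("accepted", np.bool_), ("branch", np.int8),
    ("energy_jump", np.float64),
])


class IntegrationError(RuntimeError):
    """Electronic norm drift beyond tolerance — the time step is too large."""


@dataclass
class TrajectoryState:
    """Phase-space point of one trajectory plus its electronic coefficients."""

    R: np.ndarray
    V: np.ndarray
    active: int
    C: np.ndarray
    t: float = 0.0
    adiab: Optional[AdiabaticPoint] = None


@dataclass(frozen=True)
class SHConfig:
    """Run parameters for a surface-hopping propagation.

    dt and t_max in a.u. of time; ``rescale`` in {iso, nacv, nacv+iso};
    ``frustrated`` in {keep, reverse}; ``exit_position`` optionally stops the
    whole ensemble once every trajectory sits beyond |R| with outgoing
    velocity (1D scattering runs).
    """

    dt: float
    t_max: float
    n_substeps: int = 20
    rescale: str = "iso"
    frustrated: str = "keep"
    decoherence: Optional[DecoherenceParams] = None
    initial_state: int = 0
    seed: int = 0
    record_every: int = 1
    exit_position: Optional[float] = None
    norm_tol: float = 1e-6

    def __post_init__(self):
        if self.dt <= 0 or self.t_max <= 0:
            raise ValueError("dt and t_max must be positive")
        if self.n_substeps < 1:
            raise ValueError("n_substeps must be >= 1")
        if self.rescale not in ("iso", "nacv", "nacv+iso"):
            raise ValueError(f"unknown rescale mode {self.rescale!r}")
        if self.frustrated not in ("keep", "reverse"):
            raise ValueError(f"unknown frustrated-hop policy {self.frustrated!r}")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


# --------------------------------------------------------------------------
# Elementary operations
# --------------------------------------------------------------------------

def nuclear_step(state: TrajectoryState, model: ModelSystem, dt: float
                 ) -> TrajectoryState:
    """One velocity-Verlet step on the active surface (single trajectory)."""
    adiab = state.adiab or adiabatic_point(model, state.R)
    m = model.masses
    F = -adiab.gradients[state.active]
    V_half = state.V + 0.5 * dt * F / m
    R_new = state.R + dt * V_half
    adiab_new = adiabatic_point(model, R_new, prev=adiab)
    F_new = -adiab_new.gradients[state.active]
    V_new = V_half + 0.5 * dt * F_new / m
    return TrajectoryState(R=R_new, V=V_new, active=state.active,
                           C=state.C, t=state.t + dt, adiab=adiab_new)


def _coupling(V, nacv):
    """kappa_nk = sum_nu V_nu d_nk,nu for batched V (N,d), nacv (N,n,n,d)."""
    return np.einsum("td,tnkd->tnk", V, nacv)


def electronic_step(C, energies, couplings, dt, n_substeps, xi=None):
    """RK4 integration of i dC_n/dt = eps_n C_n - i sum_k kappa_nk C_k + i xi_n.

    ``energies`` = (e_start, e_end) and ``couplings`` = (kappa_start,
    kappa_end) are linearly interpolated across the nuclear step; ``xi``,
    when given, is a callable C -> real rates lam with dC_n/dt += lam_n C_n
    (the decoherence term, held geometrically fixed over the step).  Shapes
    are batched: C (N, n), e (N, n), kappa (N, n, n).  With xi = None the
    propagation is norm-conserving to integrator accuracy.
    """
    C = np.asarray(C, dtype=complex)
    squeeze = C.ndim == 1
    if squeeze:
        C = C[None]
        energies = (np.atleast_2d(energies[0]), np.atleast_2d(energies[1]))
        couplings = (couplings[0][None], couplings[1][None])
    e0, e1 = energies
    k0, k1 = couplings
    n = C.shape[1]
    if n == 2:
        kap0 = np.ascontiguousarray(k0[:, 0, 1])
        kap1 = np.ascontiguousarray(k1[:, 0, 1])
        if _kernels is not None and (xi is None or
                                     isinstance(xi, TwoStateXFRate)):
            args = (np.ascontiguousarray(C),
                    np.ascontiguousarray(e0[:, 0]),
                    np.ascontiguousarray(e1[:, 0] - e0[:, 0]),
                    np.ascontiguousarray(e0[:, 1]),
                    np.ascontiguousarray(e1[:, 1] - e0[:, 1]),
                    kap0, kap1 - kap0)
            if xi is None:
                out = _kernels.rk4_two_state(*args, dt, n_substeps)
            else:
                out = _kernels.rk4_two_state_xf(
                    *args, np.ascontiguousarray(xi.g),
                    np.ascontiguousarray(xi.live[:, 0]),
                    np.ascontiguousarray(xi.live[:, 1]), dt, n_substeps)
        else:
            out = _rk4_two_state(C, e0, e1, kap0, kap1, dt, n_substeps, xi)
    else:
        out = _rk4_general(C, e0, e1, k0, k1, dt, n_substeps, xi)
    return out[0] if squeeze else out


def _rk4_two_state(C, e0, e1, kap0, kap1, dt, nsub, xi=None):
    """Specialized two-state RK4 kernel (kappa_01 = -kappa_10 = kap)."""
    h = dt / nsub
    c0 = C[:, 0].copy()
    c1 = C[:, 1].copy()
    de0 = e1[:, 0] - e0[:, 0]
    de1 = e1[:, 1] - e0[:, 1]
    dk = kap1 - kap0
    # interpolation nodes at substep boundaries and midpoints
    s = np.arange(2 * nsub + 1) / (2 * nsub)
    ea = e0[:, 0] + s[:, None] * de0
    eb = e0[:, 1] + s[:, None] * de1
    kk = kap0 + s[:, None] * dk

    def deriv(x0, x1, j):
        d0 = -1j * (ea[j] * x0) - kk[j] * x1
        d1 = -1j * (eb[j] * x1) + kk[j] * x0
        if xi is not None:
            lam = xi(np.stack([x0, x1], axis=1))
            d0 = d0 + lam[:, 0] * x0
            d1 = d1 + lam[:, 1] * x1
        return d0, d1

    for j in range(nsub):
        a0, a1 = deriv(c0, c1, 2 * j)
        b0, b1 = deriv(c0 + 0.5 * h * a0, c1 + 0.5 * h * a1, 2 * j + 1)
        g0, g1 = deriv(c0 + 0.5 * h * b0, c1 + 0.5 * h * b1, 2 * j + 1)
        d0, d1 = deriv(c0 + h * g0, c1 + h * g1, 2 * j + 2)
        c0 = c0 + (h / 6.0) * (a0 + 2 * b0 + 2 * g0 + d0)
        c1 = c1 + (h / 6.0) * (a1 + 2 * b1 + 2 * g1 + d1)
    return np.stack([c0, c1], axis=1)


def _rk4_general(C, e0, e1, k0, k1, dt, nsub, xi=None):
    h = dt / nsub
    de = e1 - e0
    dk = k1 - k0

    def deriv(c, s):
        e = e0 + s * de
        k = k0 + s * dk
        d = -1j * e * c - np.einsum("tnk,tk->tn", k, c)
        if xi is not None:
            d = d + xi(c) * c
        return d

    c = C.copy()
    for j in range(nsub):
        s0, sm, s1 = j / nsub, (j + 0.5) / nsub, (j + 1) / nsub
        a = deriv(c, s0)
        b = deriv(c + 0.5 * h * a, sm)
        g = deriv(c + 0.5 * h * b, sm)
        d = deriv(c + h * g, s1)
        c = c + (h / 6.0) * (a + 2 * b + 2 * g + d)
    return c


def hop_probability(C, active, kappa, dt):
    """Fewest-switches hop probabilities zeta_ak out of the active state.

    zeta_ak = max(0, 2 dt kappa_ak Re(rho_ak) / rho_aa) with
    rho_ak = C_a C_k*; the active entry is zero.  Batched shapes: C (N, n),
    active (N,), kappa (N, n, n) -> zeta (N, n).  A vanishing active
    population (rho_aa < 1e-12) yields zero probabilities.
    """
    C = np.asarray(C, dtype=complex)
    squeeze = C.ndim == 1
    if squeeze:
        C = C[None]
        active = np.atleast_1d(active)
        kappa = kappa[None]
    N, n = C.shape
    idx = np.arange(N)
    Ca = C[idx, active]
    rho_aa = np.abs(Ca) ** 2
    coh = np.real(Ca[:, None] * np.conj(C))       # Re rho_ak
    kap_a = kappa[idx, active]                    # kappa_ak
    safe = rho_aa > 1e-12
    zeta = 2.0 * dt * kap_a * coh / np.where(safe, rho_aa, 1.0)[:, None]
    zeta = np.where(safe[:, None], zeta, 0.0)
    zeta[idx, active] = 0.0
    np.clip(zeta, 0.0, None, out=zeta)
    return zeta[0] if squeeze else zeta


def attempt_hop(zeta, r):
    """Cumulative-window target selection: hop to the first state n with
    sum_{k<=n} zeta_k >= r > sum_{k<n} zeta_k; -1 (no hop) if r exceeds the
    total.  States are ordered by index.  Batched: zeta (N, n), r (N,)."""
    zeta = np.atleast_2d(np.asarray(zeta, dtype=float))
    squeeze = np.ndim(r) == 0
    r = np.atleast_1d(np.asarray(r, dtype=float))
    cum = np.cumsum(zeta, axis=1)
    prev = cum - zeta
    hit = (prev < r[:, None]) & (r[:, None] <= cum)
    target = np.where(hit.any(axis=1), np.argmax(hit, axis=1), -1)
    return int(target[0]) if squeeze else target


def rescale_isotropic(V, masses, dE):
    """Uniform velocity scaling conserving total energy across a hop.

    kappa = sqrt(1 - dE/KE) applied to every velocity when KE >= dE
    (dE = eps_target - eps_current); otherwise the hop is frustrated and V
    is returned untouched.  Returns (V_new, accepted).
    """
    V = np.asarray(V, dtype=float)
    masses = np.asarray(masses, dtype=float)
    KE = 0.5 * float(np.sum(masses * V * V))
    if KE <= 0.0:
        # no direction to scale along; reject unless the hop is isoenergetic
        return V, dE == 0.0
    if KE < dE:
        return V, False
    return V * math.sqrt(1.0 - dE / KE), True


def rescale_nacv(V, masses, d, dE):
    """Velocity adjustment along the NACV: V_nu -> V_nu + gamma d_nu / M_nu.

    gamma is the smaller-|gamma| real root of
    (sum d^2/2M) gamma^2 + (sum V.d) gamma + dE = 0 (total-energy
    conservation across the hop).  No real root, or a zero coupling vector,
    frustrates the hop.  Returns (V_new, accepted, reason) with reason in
    {"ok", "no-root", "zero-nacv"}.
    """
    V = np.asarray(V, dtype=float)
    masses = np.asarray(masses, dtype=float)
    d = np.asarray(d, dtype=float)
    a = float(np.sum(d * d / (2.0 * masses)))
    if a <= 0.0:
        return V, False, "zero-nacv"
    b = float(np.sum(V * d))
    disc = b * b - 4.0 * a * dE
    if disc < 0.0:
        return V, False, "no-root"
    sq = math.sqrt(disc)
    # numerically stable pair; the smaller-|gamma| root is c/q
    if b >= 0.0:
        q = -0.5 * (b + sq)
    else:
        q = -0.5 * (b - sq)
    if q != 0.0:
        g_small, g_big = dE / q, q / a
    else:                                     # b == 0: symmetric roots
        g_small = g_big = sq / (2.0 * a)
        g_small = -g_small if abs(-g_small) < abs(g_small) else g_small
    gamma = g_small if abs(g_small) <= abs(g_big) else g_big
    return V + gamma * d / masses, True, "ok"


def rescale_dispatch(mode, V, masses, d, dE):
    """Apply the configured velocity-adjustment mode.

    Returns (V_new, accepted, branch code).  ``nacv+iso`` retries the
    frustrated NACV adjustment isotropically.
    """
    if mode == "iso":
        Vn, ok = rescale_isotropic(V, masses, dE)
        return Vn, ok, BRANCH_ISO if ok else BRANCH_FRUSTRATED
    Vn, ok, reason = rescale_nacv(V, masses, d, dE)
    if ok:
        return Vn, True, BRANCH_NACV
    if mode == "nacv":
        return V, False, (BRANCH_FRUSTRATED_ZERO_NACV if reason == "zero-nacv"
                          else BRANCH_FRUSTRATED)
    Vn, ok = rescale_isotropic(V, masses, dE)
    return Vn, ok, BRANCH_NACV_ISO_FALLBACK if ok else BRANCH_FRUSTRATED


# --------------------------------------------------------------------------
# Records
# --------------------------------------------------------------------------

@dataclass
class TrajectoryRecord:
    """Sampled time series of one trajectory plus its hop log."""

    t: np.ndarray
    R: np.ndarray
    V: np.ndarray
    active: np.ndarray
    pops: np.ndarray
    energies: np.ndarray
    e_total: np.ndarray
    hop_log: np.ndarray
    n_accepted: int
    n_frustrated: int
    max_energy_drift: float
    max_hop_energy_jump: float
    max_norm_drift: float
    rng_draws: int


@dataclass
class EnsembleRecord:
    """Sampled time series of a whole ensemble on a common time grid.

    Arrays are (n_rec, n_traj, ...); ``hop_log`` is a structured array over
    all trajectories.  Per-trajectory views come from :meth:`trajectory`.
    """

    t: np.ndarray
    R: np.ndarray
    V: np.ndarray
    active: np.ndarray
    pops: np.ndarray
    energies: np.ndarray
    e_total: np.ndarray
    hop_log: np.ndarray
    n_accepted: np.ndarray
    n_frustrated: np.ndarray
    max_energy_drift: np.ndarray
    max_hop_energy_jump: np.ndarray
    max_norm_drift: float
    rng_draws_per_traj: int
    scheme_metadata: dict = field(default_factory=dict)

    @property
    def n_traj(self) -> int:
        return self.R.shape[1]

    @property
    def n_states(self) -> int:
        return self.pops.shape[2]

    def trajectory(self, j: int) -> TrajectoryRecord:
        log = self.hop_log[self.hop_log["traj"] == j]
        return TrajectoryRecord(
            t=self.t, R=self.R[:, j], V=self.V[:, j], active=self.active[:, j],
            pops=self.pops[:, j], energies=self.energies[:, j],
            e_total=self.e_total[:, j], hop_log=log,
            n_accepted=int(self.n_accepted[j]),
            n_frustrated=int(self.n_frustrated[j]),
            max_energy_drift=float(self.max_energy_drift[j]),
            max_hop_energy_jump=float(self.max_hop_energy_jump[j]),
            max_norm_drift=self.max_norm_drift,
            rng_draws=self.rng_draws_per_traj)


# --------------------------------------------------------------------------
# Ensemble runner
# --------------------------------------------------------------------------

_RNG_CHUNK = 1024  # steps of uniforms buffered per refill


def run_ensemble(model: ModelSystem, R0: np.ndarray, P0: np.ndarray,
                 config: SHConfig, C0: Optional[np.ndarray] = None,
                 active0: Optional[np.ndarray] = None) -> EnsembleRecord:
    """Propagate an ensemble of surface-hopping trajectories.

    R0, P0: initial positions/momenta, shape (n_traj, n_dof).  All
    trajectories start on ``config.initial_state`` with C = delta unless
    C0/active0 are given.  Deterministic for a fixed ``config.seed``.
    """
    R = np.array(R0, dtype=float)
    if R.ndim == 1:
        R = R[:, None]
    V = np.array(P0, dtype=float)
    if V.ndim == 1:
        V = V[:, None]
    V = V / model.masses
    N, ndof = R.shape
    n = model.n_states
    m = model.masses
    dt = config.dt

    active = (np.full(N, config.initial_state, dtype=np.int64)
              if active0 is None else np.array(active0, dtype=np.int64))
    if C0 is None:
        C = np.zeros((N, n), dtype=complex)
        C[np.arange(N), active] = 1.0
    else:
        C = np.array(C0, dtype=complex)

    adiab = adiabatic_point(model, R)
    scheme = make_scheme(config.decoherence, model)
    scheme.setup(N, n, ndof)
    draws = 1 + scheme.draws_per_step

    rngs = [trajectory_rng(config.seed, j) for j in range(N)]
    table = np.empty((_RNG_CHUNK, N, draws))

    def refill():
        for j in range(N):
            table[:, j, :] = rngs[j].random((_RNG_CHUNK, draws))

    n_steps = int(math.ceil(config.t_max / dt))
    n_rec = n_steps // config.record_every + 2
    rec_t = np.empty(n_rec)
    rec_R = np.empty((n_rec, N, ndof))
    rec_V = np.empty((n_rec, N, ndof))
    rec_active = np.empty((n_rec, N), dtype=np.int16)
    rec_pops = np.empty((n_rec, N, n))
    rec_e = np.empty((n_rec, N, n))
    rec_etot = np.empty((n_rec, N))
    hop_entries: list[tuple] = []

    idx = np.arange(N)
    n_accepted = np.zeros(N, dtype=np.int64)
    n_frustrated = np.zeros(N, dtype=np.int64)
    drift_max = np.zeros(N)
    hop_jump_max = np.zeros(N)
    norm_drift_max = 0.0

    def total_energy():
        ke = 0.5 * np.einsum("td,d,td->t", V, m, V)
        return ke + adiab.energies[idx, active]

    E_ref = total_energy()

    rec_i = 0

    def record(step):
        nonlocal rec_i
        rec_t[rec_i] = step * dt
        rec_R[rec_i] = R
        rec_V[rec_i] = V
        rec_active[rec_i] = active
        rec_pops[rec_i] = np.abs(C) ** 2
        rec_e[rec_i] = adiab.energies
        rec_etot[rec_i] = total_energy()
        rec_i += 1

    record(0)
    steps_done = 0

    for step in range(1, n_steps + 1):
        ti = (step - 1) % _RNG_CHUNK
        if ti == 0:
            refill()
        u = table[ti]

        R_start, V_start, adiab_start = R, V, adiab

        # --- nuclear velocity-Verlet on the active surface
        F = -adiab.gradients[idx, active]
        V_half = V + (0.5 * dt) * F / m
        R = R + dt * V_half
        adiab = adiabatic_point(model, R, prev=adiab_start)
        F_new = -adiab.gradients[idx, active]
        V = V_half + (0.5 * dt) * F_new / m

        ctx = StepContext(model=model, masses=m, dt=dt, R_start=R_start,
                          V_start=V_start, R=R, V=V, C=C, active=active,
                          adiab_start=adiab_start, adiab_end=adiab)

        # --- electronic propagation with the scheme's rate term
        lam = scheme.electronic_rate(ctx)
        kap0 = _coupling(V_start, adiab_start.nacv)
        kap1 = _coupling(V, adiab.nacv)
        C = electronic_step(C, (adiab_start.energies, adiab.energies),
                            (kap0, kap1), dt, config.n_substeps, xi=lam)
        norm = np.einsum("tn,tn->t", C.real, C.real) + np.einsum(
            "tn,tn->t", C.imag, C.imag)
        drift = float(np.max(np.abs(norm - 1.0)))
        norm_drift_max = max(norm_drift_max, drift)
        if drift > config.norm_tol:
            if config.decoherence is None or \
                    config.decoherence.scheme == "none":
                raise IntegrationError(
                    f"electronic norm drift {drift:.2e} at step {step}; "
                    "reduce dt or increase n_substeps")
            C = C / np.sqrt(norm)[:, None]   # corrected schemes: clip roundoff

        ctx.C = C
        C = scheme.after_electronic(ctx, u[:, 1:])
        ctx.C = C

        # --- fewest-switches hop decision
        zeta = hop_probability(C, active, kap1, dt)
        target = attempt_hop(zeta, u[:, 0])
        hoppers = np.nonzero((target >= 0) & (target != active))[0]
        E_now = total_energy()

        for j in hoppers:
            old = int(active[j])
            new = int(target[j])
            dE = float(adiab.energies[j, new] - adiab.energies[j, old])
            Vj, ok, branch = rescale_dispatch(
                config.rescale, V[j], m, adiab.nacv[j, old, new], dE)
            if ok:
                e_before = E_now[j]
                V[j] = Vj
                active[j] = new
                ke = 0.5 * float(np.sum(m * Vj * Vj))
                e_after = ke + adiab.energies[j, new]
                jump = abs(e_after - e_before)
                hop_jump_max[j] = max(hop_jump_max[j], jump)
                n_accepted[j] += 1
                E_ref[j] = e_after
                scheme.on_hop(ctx, j, old, new)
                hop_entries.append((step, step * dt, j, old, new, True,
                                    branch, jump))
            else:
                n_frustrated[j] += 1
                if config.frustrated == "reverse":
                    V[j] = -V[j]
                    E_ref[j] = E_now[j]
                hop_entries.append((step, step * dt, j, old, new, False,
                                    branch, 0.0))

        # --- energy audit between hops
        E_now = total_energy()
        np.maximum(drift_max, np.abs(E_now - E_ref), out=drift_max)

        steps_done = step
        if step % config.record_every == 0 or step == n_steps:
            record(step)
        if config.exit_position is not None:
            out = np.abs(R).max(axis=1) > config.exit_position
            outgoing = np.einsum("td,td->t", R, V) > 0
            if np.all(out & outgoing):
                if step % config.record_every != 0 and step != n_steps:
                    record(step)
                break

    hop_log = np.array(hop_entries, dtype=HOP_LOG_DTYPE) if hop_entries \
        else np.empty(0, dtype=HOP_LOG_DTYPE)
    meta = scheme.metadata()
    return EnsembleRecord(
        t=rec_t[:rec_i].copy(), R=rec_R[:rec_i].copy(), V=rec_V[:rec_i].copy(),
        active=rec_active[:rec_i].copy(), pops=rec_pops[:rec_i].copy(),
        energies=rec_e[:rec_i].copy(), e_total=rec_etot[:rec_i].copy(),
        hop_log=hop_log, n_accepted=n_accepted, n_frustrated=n_frustrated,
        max_energy_drift=drift_max, max_hop_energy_jump=hop_jump_max,
        max_norm_drift=norm_drift_max,
        rng_draws_per_traj=steps_done * draws, scheme_metadata=meta)


def run_trajectory(model: ModelSystem, state0: TrajectoryState,
                   config: SHConfig) -> TrajectoryRecord:
    """Propagate a single trajectory (an ensemble of one)."""
    R0 = np.atleast_1d(state0.R)[None, :]
    P0 = (np.atleast_1d(state0.V) * model.masses)[None, :]
    C0 = None if state0.C is None else np.asarray(state0.C)[None, :]
    rec = run_ensemble(model, R0, P0, config, C0=C0,
                       active0=np.array([state0.active]))
    return rec.trajectory(0)
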