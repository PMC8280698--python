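"""Decoherence corrections for surface hopping: SHXF, SHEDC, A-FSSH.

Fewest-switches surface hopping propagates fully coherent electronic
coefficients while the nuclei commit to a single active surface, which leaves
the ensemble overcoherent and breaks internal consistency.  The three
corrections here restore decoherence per trajectory in qualitatively
different ways:

* **SHXF** adds an extra term to the electronic equation built from the
  nuclear quantum momentum and accumulated force differences, with the
  quantum momentum evaluated from cheap auxiliary trajectories spawned on
  populated nonactive surfaces:

      dC_n/dt |_xf = sum_nu (Q_nu / M_nu) (f_n,nu - sum_l |C_l|^2 f_l,nu) C_n

  where Q = (R - sum_k |C_k|^2 R_k^aux) / (2 sigma^2) and
  f_k = -int grad eps_k dt' is measured as the momentum change of the
  (auxiliary) trajectory on surface k.  The term redistributes population
  without changing the norm, pushing coefficients toward the state whose
  accumulated force is aligned with Q — in practice, the active state.

* **SHEDC** exponentially damps nonactive amplitudes at a rate set by the
  energy gap and nuclear kinetic energy, tau_n = (hbar/|eps_n - eps_a|)
  (1 + alpha/T), with alpha = 0.1 Hartree by convention, then rescales the
  active amplitude so the total population stays 1.

* **A-FSSH** propagates position/momentum moments of the nuclear wavepacket
  on nonactive surfaces and stochastically collapses amplitudes at a rate
  built from how fast the surfaces drive those moments apart.  The collapse
  rate used here is the simplified one of the augmented-FSSH literature,

      1/tau_n = [ dF_n . dR_n - 2 |(eps_n - eps_a)(d_an . dR_n)| ] / 2

  with a companion reset rate -(dF_n . dR_n)/2 that zeroes the moments when
  the surfaces converge again (recorded in run metadata).

All schemes implement a per-step plugin contract used by
:mod:`hopdyn.dynamics` and preserve the total electronic norm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .models import ModelSystem, adiabatic_energies

__all__ = [
    "DecoherenceParams", "DecoherenceScheme", "NoDecoherence",
    "SHXF", "SHEDC", "AFSSH", "make_scheme",
    "quantum_momentum", "shxf_xi", "edc_apply",
    "afssh_step_moments", "afssh_rate", "afssh_collapse",
]

AFSSH_RATE_EXPRESSION = ("1/tau_n = (dF_n.dR_n - 2*|(eps_n-eps_a)*(d_an.dR_n)|)/2; "
                         "reset: 1/tau_n_reset = -(dF_n.dR_n)/2 (hbar = 1)")


@dataclass(frozen=True)
class DecoherenceParams:
    """Scheme tag plus the parameters the chosen scheme reads.

    sigma: SHXF Gaussian width (bohr), scalar or per-DOF; spawn_threshold:
    SHXF population cutoff for launching an auxiliary trajectory; alpha:
    SHEDC energy constant (Hartree, conventionally 0.1).
    """

    scheme: str = "none"
    sigma: float | np.ndarray | None = None
    spawn_threshold: float = 1e-4
    alpha: float = 0.1

    def __post_init__(self):
        if self.scheme not in ("none", "shxf", "edc", "afssh"):
            raise ValueError(f"unknown decoherence scheme {self.scheme!r}")
        if self.scheme == "shxf":
            if self.sigma is None or np.any(np.asarray(self.sigma) <= 0):
                raise ValueError("SHXF requires sigma > 0")
        if not (0.0 < self.spawn_threshold < 0.5):
            raise ValueError("spawn_threshold must lie in (0, 0.5)")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


# --------------------------------------------------------------------------
# Pure per-step building blocks (also the unit-testable operations)
# --------------------------------------------------------------------------

def quantum_momentum(R, aux_positions, populations, sigma):
    """Quantum momentum from population-weighted auxiliary positions.

    Q_nu = (R_nu - sum_k p_k R^aux_k,nu) / (2 sigma_nu^2), the leading-order
    -grad|chi|/|chi| of an equal-width Gaussian mixture evaluated at R.
    The active state's "auxiliary" position is R itself; ``populations``
    must sum to 1 over the states represented in ``aux_positions``.

    Shapes: R (..., ndof), aux_positions (..., nstates, ndof),
    populations (..., nstates) -> Q (..., ndof).
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    mean = np.einsum("...k,...kd->...d", populations, aux_positions)
    return (np.asarray(R, dtype=float) - mean) / (2.0 * sigma ** 2)


def shxf_xi(C, Q, f, masses, live=None):
    """SHXF decoherence contribution: rates lambda_n and xi_n = lambda_n C_n.

    lambda_n = sum_nu Q_nu (f_n,nu - fbar_nu) / M_nu with fbar the
    population-weighted mean accumulated force over live states.  By
    construction sum_n d|C_n|^2/dt from xi alone vanishes, so the term
    redistributes population without creating it; it is identically zero
    when a single state carries all population or when all accumulated
    forces coincide.

    Shapes: C (..., n), Q (..., ndof), f (..., n, ndof), masses (ndof,).
    ``live`` optionally masks states without auxiliary data (their rate is 0).
    """
    C = np.asarray(C)
    pops = np.abs(C) ** 2
    if live is not None:
        pops = np.where(live, pops, 0.0)
    tot = pops.sum(axis=-1, keepdims=True)
    ptil = pops / np.where(tot > 0, tot, 1.0)
    fbar = np.einsum("...k,...kd->...d", ptil, f)
    lam = np.einsum("...d,...nd->...n", Q / np.asarray(masses, dtype=float),
                    f - fbar[..., None, :])
    if live is not None:
        lam = np.where(live, lam, 0.0)
    return lam, lam * C


def edc_apply(C, active, energies, T, alpha, dt):
    """Energy-based decoherence damping of one coefficient vector.

    C_n -> C_n exp(-dt/tau_n), tau_n = (1/|eps_n - eps_a|)(1 + alpha/T) for
    n != a; the active amplitude is then rescaled (phase untouched) so that
    sum |C|^2 = 1.  Zero gap means no damping for that pair; T <= 0 leaves
    C unchanged.
    """
    C = np.array(C, dtype=complex)
    if T <= 0:
        return C
    gap = np.abs(np.asarray(energies, dtype=float) - energies[active])
    with np.errstate(divide="ignore"):
        rate = gap / (1.0 + alpha / T)      # 1/tau_n
    fac = np.exp(-dt * rate)
    fac[active] = 1.0
    C *= fac
    rest = np.sum(np.abs(C) ** 2) - np.abs(C[active]) ** 2
    target = max(1.0 - rest, 0.0)
    mag = np.abs(C[active])
    if mag > 0:
        C[active] *= np.sqrt(target) / mag
    else:
        C[active] = np.sqrt(target)
    return C


def afssh_step_moments(dR, dP, dF_start, dF_end, masses, dt):
    """Advance A-FSSH displacement moments one velocity-Verlet step.

    d(dR)/dt = dP/M and d(dP)/dt = dF_n, with dF_n = F_n - F_a the BO force
    difference; the discretization mirrors the nuclear integrator.  The
    active state's force difference is zero, so its moments stay zero.
    """
    masses = np.asarray(masses, dtype=float)
    dP_half = dP + 0.5 * dt * dF_start
    dR_new = dR + dt * dP_half / masses
    dP_new = dP_half + 0.5 * dt * dF_end
    return dR_new, dP_new


def afssh_rate(dR, dF, gap, d_an, hbar=1.0):
    """Collapse and reset rates per nonactive state.

    Growth term (dF_n . dR_n)/(2 hbar) minus the nonadiabatic-coupling term
    2 |gap_n (d_an . dR_n)| / (2 hbar); the reset rate is minus the growth
    term.  Both vanish when the moments are zero; the growth term vanishes
    when dF is perpendicular to dR.

    Shapes: dR, dF, d_an (..., n, ndof); gap (..., n).
    """
    growth = np.einsum("...nd,...nd->...n", dF, dR) / (2.0 * hbar)
    coupling = np.abs(gap * np.einsum("...nd,...nd->...n", d_an, dR)) / hbar
    return growth - coupling, -growth


def afssh_collapse(C, active, rates, reset_rates, dt_c, u_collapse, u_reset):
    """Stochastic collapse/reset decision for one coefficient vector.

    Per nonactive state n: if dt_c * rate_n exceeds the uniform draw, C_n is
    collapsed to 0 and the active amplitude magnitude is increased so the
    total population stays 1.  A reset event (dt_c * reset_rate_n above its
    own draw) zeroes that state's moments without touching C.  Returns
    (C, collapsed_mask, reset_mask).  Nonpositive rates never fire.
    """
    C = np.array(C, dtype=complex)
    n = C.shape[-1]
    p_col = np.clip(dt_c * np.asarray(rates, dtype=float), 0.0, 1.0)
    p_res = np.clip(dt_c * np.asarray(reset_rates, dtype=float), 0.0, 1.0)
    nonactive = np.arange(n) != active
    collapsed = (np.asarray(u_collapse) < p_col) & nonactive
    reset = (np.asarray(u_reset) < p_res) & nonactive
    if collapsed.any():
        transferred = np.sum(np.abs(C[collapsed]) ** 2)
        C[collapsed] = 0.0
        mag = np.abs(C[active])
        target = mag ** 2 + transferred
        if mag > 0:
            C[active] *= np.sqrt(target) / mag
        else:
            C[active] = np.sqrt(target)
    return C, collapsed, reset


# --------------------------------------------------------------------------
# Plugin contract
# --------------------------------------------------------------------------

class TwoStateXFRate:
    """Two-state SHXF rate in projected form.

    With g_i = sum_nu (Q_nu/M_nu)(f_0,nu - f_1,nu) and live-state normalized
    populations p~, the rates are lam_0 = p~_1 g and lam_1 = -p~_0 g.  The
    object is callable (C -> lam) for the generic integrator and exposes
    (g, live) for the compiled two-state kernel.
    """

    __slots__ = ("g", "live")

    def __init__(self, g: np.ndarray, live: np.ndarray):
        self.g = g
        self.live = live

    def __call__(self, C):
        w = self.live * (np.abs(C) ** 2)
        tot = w.sum(axis=1)
        safe = np.where(tot > 0, tot, 1.0)
        lam0 = (w[:, 1] / safe) * self.g * self.live[:, 0]
        lam1 = -(w[:, 0] / safe) * self.g * self.live[:, 1]
        return np.stack([lam0, lam1], axis=1)


class StepContext:
    """Quantities a scheme may read during one nuclear step (set by the runner).

    Attributes are ensemble-shaped: R/V (N, ndof), C (N, n) complex, active
    (N,) int, adiab_start/adiab_end batched AdiabaticPoints, dt, masses,
    model; V_start/R_start are the values before the Verlet update.
    """

    __slots__ = ("model", "masses", "dt", "R_start", "V_start", "R", "V",
                 "C", "active", "adiab_start", "adiab_end")

    def __init__(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)


class DecoherenceScheme:
    """Per-step plugin: an electronic-rate hook plus a post-step transform."""

    #: uniform draws consumed per trajectory per nuclear step
    draws_per_step = 0

    def setup(self, n_traj: int, n_states: int, n_dof: int):
        pass

    def electronic_rate(self, ctx: StepContext) -> Optional[Callable]:
        """Return lam(C) -> (N, n) real rates entering the coherent RK4, or None."""
        return None

    def after_electronic(self, ctx: StepContext, uniforms: np.ndarray) -> np.ndarray:
        """Transform coefficients after the coherent update; returns new C."""
        return ctx.C

    def on_hop(self, ctx: StepContext, traj: int, old: int, new: int):
        pass

    def metadata(self) -> dict:
        return {"scheme": "none"}


class NoDecoherence(DecoherenceScheme):
    """Pure fewest-switches surface hopping (xi = 0)."""


class SHEDC(DecoherenceScheme):
    """Energy-based decoherence: exponential damping of nonactive amplitudes."""

    def __init__(self, params: DecoherenceParams):
        self.alpha = params.alpha

    def after_electronic(self, ctx, uniforms):
        C = ctx.C
        n = C.shape[1]
        idx = np.arange(C.shape[0])
        T = 0.5 * np.einsum("td,d,td->t", ctx.V, ctx.masses, ctx.V)
        e = ctx.adiab_end.energies
        e_a = e[idx, ctx.active]
        gap = np.abs(e - e_a[:, None])
        ok = T > 0
        rate = np.where(ok[:, None], gap / (1.0 + self.alpha / np.where(ok, T, 1.0)[:, None]), 0.0)
        fac = np.exp(-ctx.dt * rate)
        fac[idx, ctx.active] = 1.0
        C = C * fac
        pops = np.abs(C) ** 2
        rest = pops.sum(axis=1) - pops[idx, ctx.active]
        target = np.clip(1.0 - rest, 0.0, None)
        mag = np.abs(C[idx, ctx.active])
        scale = np.where(mag > 0, np.sqrt(target) / np.where(mag > 0, mag, 1.0), 0.0)
        C[idx, ctx.active] = np.where(mag > 0, C[idx, ctx.active] * scale,
                                      np.sqrt(target).astype(complex))
        return C

    def metadata(self):
        return {"scheme": "edc", "alpha": self.alpha,
                "tau": "(hbar/|eps_n-eps_a|)(1+alpha/T)"}


class AFSSH(DecoherenceScheme):
    """Augmented FSSH: moment propagation with stochastic collapse/reset."""

    def __init__(self, params: DecoherenceParams):
        self.params = params
        self.n_collapses = 0
        self.n_resets = 0

    def setup(self, n_traj, n_states, n_dof):
        self.n_states = n_states
        self.dR = np.zeros((n_traj, n_states, n_dof))
        self.dP = np.zeros((n_traj, n_states, n_dof))
        self.draws_per_step = 2 * n_states

    def _force_diff(self, adiab, active):
        idx = np.arange(active.shape[0])
        grads = adiab.gradients
        return -(grads - grads[idx, active][:, None, :])

    def after_electronic(self, ctx, uniforms):
        idx = np.arange(ctx.C.shape[0])
        dF0 = self._force_diff(ctx.adiab_start, ctx.active)
        dF1 = self._force_diff(ctx.adiab_end, ctx.active)
        self.dR, self.dP = afssh_step_moments(self.dR, self.dP, dF0, dF1,
                                              ctx.masses, ctx.dt)
        # keep the (identically zero) active-state moments exact
        self.dR[idx, ctx.active] = 0.0
        self.dP[idx, ctx.active] = 0.0

        e = ctx.adiab_end.energies
        gap = e - e[idx, ctx.active][:, None]
        d_an = ctx.adiab_end.nacv[idx, ctx.active]      # (N, n, ndof)
        rate, reset_rate = afssh_rate(self.dR, dF1, gap, d_an)

        n = self.n_states
        u_col = uniforms[:, :n]
        u_res = uniforms[:, n:2 * n]
        nonactive = np.arange(n)[None, :] != ctx.active[:, None]
        collapsed = (u_col < np.clip(ctx.dt * rate, 0.0, 1.0)) & nonactive
        reset = (u_res < np.clip(ctx.dt * reset_rate, 0.0, 1.0)) & nonactive

        C = ctx.C.copy()
        if collapsed.any():
            pops = np.abs(C) ** 2
            transferred = np.where(collapsed, pops, 0.0).sum(axis=1)
            C[collapsed] = 0.0
            mag = np.abs(C[idx, ctx.active])
            target = mag ** 2 + transferred
            boost = np.where(mag > 0, np.sqrt(target) / np.where(mag > 0, mag, 1.0), 0.0)
            C[idx, ctx.active] = np.where(mag > 0, C[idx, ctx.active] * boost,
                                          np.sqrt(target).astype(complex))
            self.dR[collapsed] = 0.0
            self.dP[collapsed] = 0.0
            self.n_collapses += int(collapsed.sum())
        if reset.any():
            self.dR[reset] = 0.0
            self.dP[reset] = 0.0
            self.n_resets += int(reset.sum())
        return C

    def on_hop(self, ctx, traj, old, new):
        self.dR[traj] = 0.0
        self.dP[traj] = 0.0

    def metadata(self):
        return {"scheme": "afssh", "rate_expression": AFSSH_RATE_EXPRESSION,
                "dt_c": "nuclear dt", "n_collapses": self.n_collapses,
                "n_resets": self.n_resets}


class SHXF(DecoherenceScheme):
    """Exact-factorization decoherence via auxiliary trajectories.

    An auxiliary trajectory is spawned on a nonactive surface when its
    population first exceeds ``spawn_threshold``, launched along the parent
    velocity with kinetic energy KE + eps_active - eps_n (the potential-energy
    difference isotropically distributed over the coordinates), and advanced
    by its own velocity with the speed refreshed from energy conservation on
    its surface.  Classically forbidden auxiliaries freeze (zero velocity)
    rather than die, and are counted in ``n_frozen``.  Accumulated forces are
    measured as momentum changes per step on top of the launch momentum, so
    f_k carries the full phase gradient (current momentum) of the surface-k
    component; the real trajectory stands in for the active surface.
    """

    def __init__(self, params: DecoherenceParams, model: ModelSystem):
        self.params = params
        self.model = model
        self.sigma = np.broadcast_to(
            np.atleast_1d(np.asarray(params.sigma, dtype=float)),
            (model.n_dof,)).copy()
        self.n_frozen = 0
        self.n_spawned = 0

    def setup(self, n_traj, n_states, n_dof):
        self.aux_R = np.zeros((n_traj, n_states, n_dof))
        self.aux_V = np.zeros((n_traj, n_states, n_dof))
        self.aux_E = np.zeros((n_traj, n_states))
        self.f = np.zeros((n_traj, n_states, n_dof))
        self.alive = np.zeros((n_traj, n_states), dtype=bool)

    def _kinetic(self, V):
        return 0.5 * np.einsum("...d,d,...d->...", V, self.model.masses, V)

    def electronic_rate(self, ctx):
        m = self.model.masses
        N, n = ctx.C.shape
        idx = np.arange(N)
        dt = ctx.dt
        pops = np.abs(ctx.C) ** 2
        e_end = ctx.adiab_end.energies
        had_aux = self.alive.any(axis=1)

        # 1. advance live auxiliaries and accumulate their forces
        live_rows, live_states = np.nonzero(self.alive)
        if live_rows.size:
            v_old = self.aux_V[live_rows, live_states]
            r_new = self.aux_R[live_rows, live_states] + v_old * dt
            self.aux_R[live_rows, live_states] = r_new
            e_aux = adiabatic_energies(self.model, r_new)[np.arange(live_rows.size),
                                                          live_states]
            ke_new = self.aux_E[live_rows, live_states] - e_aux
            ke_old = 0.5 * np.einsum("kd,d,kd->k", v_old, m, v_old)
            v_new = np.zeros_like(v_old)
            moving = (ke_new > 0)
            rescalable = moving & (ke_old > 0)
            v_new[rescalable] = (v_old[rescalable]
                                 * np.sqrt(ke_new[rescalable] / ke_old[rescalable])[:, None])
            # frozen auxiliaries that become allowed again restart along the
            # parent's current direction
            thaw = moving & (ke_old <= 0)
            if thaw.any():
                vp = ctx.V[live_rows[thaw]]
                kp = 0.5 * np.einsum("kd,d,kd->k", vp, m, vp)
                ok = kp > 0
                scale = np.zeros_like(kp)
                scale[ok] = np.sqrt(ke_new[thaw][ok] / kp[ok])
                v_new[thaw] = vp * scale[:, None]
            self.n_frozen += int(np.sum(~moving))
            self.aux_V[live_rows, live_states] = v_new
            self.f[live_rows, live_states] += m * (v_new - v_old)

        # 2. the real trajectory is the active-surface surrogate: its
        #    accumulated force integrates to the current momentum
        self.f[idx, ctx.active] = ctx.V * m

        # 3. kill auxiliaries whose population fell below threshold
        dead = self.alive & (pops < self.params.spawn_threshold)
        if dead.any():
            self.alive[dead] = False
            self.aux_V[dead] = 0.0
            self.f[dead] = 0.0

        # 4. spawn auxiliaries for newly populated nonactive states
        nonactive = np.arange(n)[None, :] != ctx.active[:, None]
        need = nonactive & ~self.alive & (pops >= self.params.spawn_threshold)
        if need.any():
            rows, states = np.nonzero(need)
            ke_parent = self._kinetic(ctx.V)[rows]
            e_a = e_end[rows, ctx.active[rows]]
            e_n = e_end[rows, states]
            ke_aux = ke_parent + e_a - e_n
            v = np.zeros((rows.size, self.model.n_dof))
            ok = (ke_aux > 0) & (ke_parent > 0)
            v[ok] = ctx.V[rows[ok]] * np.sqrt(ke_aux[ok] / ke_parent[ok])[:, None]
            self.n_frozen += int(np.sum(ke_aux <= 0))
            self.n_spawned += int(rows.size)
            self.aux_R[rows, states] = ctx.R[rows]
            self.aux_V[rows, states] = v
            self.aux_E[rows, states] = e_n + np.clip(ke_aux, 0.0, None)
            self.alive[rows, states] = True
            # launch momentum: the newborn component's phase-gradient offset
            self.f[rows, states] = v * m

        # 5. quantum momentum and the rate entering the electronic equation
        decohering = self.alive.any(axis=1)
        if not decohering.any():
            return None
        live = self.alive | (np.arange(n)[None, :] == ctx.active[:, None])
        X = np.where(self.alive[..., None], self.aux_R, ctx.R[:, None, :])
        f = self.f
        sigma = self.sigma
        masses = m
        R = ctx.R
        act_mask = decohering

        if n == 2:
            # Q evaluated with the step-start populations; for two states the
            # rate reduces to a single projection per trajectory (see
            # TwoStateXFRate), with the population factors applied per RK4
            # stage inside the integrator.
            w = np.where(live, pops, 0.0)
            tot = w.sum(axis=1, keepdims=True)
            ptil = w / np.where(tot > 0, tot, 1.0)
            Q = (R - np.einsum("tk,tkd->td", ptil, X)) / (2.0 * sigma ** 2)
            g = np.einsum("td,td->t", Q / masses, f[:, 0] - f[:, 1])
            g = np.where(act_mask, g, 0.0)
            return TwoStateXFRate(g, live.astype(float))

        def lam_fn(C):
            pops = np.abs(C) ** 2
            w = np.where(live, pops, 0.0)
            tot = w.sum(axis=1, keepdims=True)
            ptil = w / np.where(tot > 0, tot, 1.0)
            Q = (R - np.einsum("tk,tkd->td", ptil, X)) / (2.0 * sigma ** 2)
            fbar = np.einsum("tk,tkd->td", ptil, f)
            lam = np.einsum("td,tnd->tn", Q / masses, f - fbar[:, None, :])
            lam = np.where(live, lam, 0.0)
            return np.where(act_mask[:, None], lam, 0.0)

        return lam_fn

    def on_hop(self, ctx, traj, old, new):
        m = self.model.masses
        # real trajectory takes over the new active surface
        self.alive[traj, new] = False
        self.aux_V[traj, new] = 0.0
        # respawn an auxiliary for the previously active state at R
        e = ctx.adiab_end.energies[traj]
        ke_parent = 0.5 * float(np.einsum("d,d,d->", ctx.V[traj], m, ctx.V[traj]))
        ke_aux = ke_parent + e[new] - e[old]
        if ke_aux > 0 and ke_parent > 0:
            v = ctx.V[traj] * np.sqrt(ke_aux / ke_parent)
        else:
            v = np.zeros(self.model.n_dof)
            self.n_frozen += 1
        self.aux_R[traj, old] = ctx.R[traj]
        self.aux_V[traj, old] = v
        self.aux_E[traj, old] = e[old] + max(ke_aux, 0.0)
        self.alive[traj, old] = True
        self.f[traj, old] = v * m
        self.n_spawned += 1

    def metadata(self):
        return {"scheme": "shxf", "sigma": self.sigma.tolist(),
                "spawn_threshold": self.params.spawn_threshold,
                "n_spawned": self.n_spawned, "n_frozen_aux_steps": self.n_frozen}


def make_scheme(params: Optional[DecoherenceParams], model: ModelSystem
                ) -> DecoherenceScheme:
    """Instantiate the scheme a run configuration asks for."""
    if params is None or params.scheme == "none":
        return NoDecoherence()
    if params.scheme == "shxf":
        return SHXF(params, model)
    if params.scheme == "edc":
        return SHEDC(params)
    if params.scheme == "afssh":
        return AFSSH(params)
    raise ValueError(f"unknown decoherence scheme {params.scheme!r}")
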