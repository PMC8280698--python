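"""Analytic model Hamiltonians and their adiabatic quantities.

A :class:`ModelSystem` supplies a symmetric diabatic potential matrix and its
position derivatives; everything the dynamics needs on the adiabatic side —
Born–Oppenheimer energies, Hellmann–Feynman gradients and nonadiabatic
coupling vectors (NACVs) — is obtained by diagonalization through
:func:`adiabatic_point`.  All quantities are in Hartree atomic units
(hbar = 1, positions in bohr, masses in electron masses).

The built-in catalogue contains the three standard one-dimensional scattering
models (single avoided crossing, dual avoided crossing, extended coupling
with reflection) in their usual literature parameterization, plus an in-house
sloped sharp-crossing model whose narrow, steep crossing region makes the
hopping dynamics sensitive to the nuclear time step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "ConicalIntersectionError",
    "ModelSystem",
    "AdiabaticPoint",
    "adiabatize",
    "adiabatic_point",
    "builtin_models",
    "get_model",
]

#: Gap (Hartree) below which two adiabatic surfaces are treated as degenerate.
DEGENERACY_TOL = 1e-12


class ConicalIntersectionError(ValueError):
    """Raised when adiabatic surfaces are degenerate at an evaluation point.

    The NACV d_nk = (U^T dH U)_nk / (eps_k - eps_n) is undefined there.
    """


@dataclass(frozen=True)
class ModelSystem:
    """Analytic diabatic model: potential matrix, gradients and masses.

    ``diabatic(R)`` maps positions of shape (..., n_dof) to symmetric real
    matrices of shape (..., n_states, n_states); ``diabatic_gradient(R)``
    returns shape (..., n_dof, n_states, n_states).
    """

    label: str
    n_states: int
    n_dof: int
    masses: np.ndarray
    diabatic: Callable[[np.ndarray], np.ndarray]
    diabatic_gradient: Callable[[np.ndarray], np.ndarray]
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        m = np.atleast_1d(np.asarray(self.masses, dtype=float))
        if m.shape != (self.n_dof,):
            raise ValueError(f"masses must have shape ({self.n_dof},), got {m.shape}")
        if np.any(m <= 0):
            raise ValueError("masses must be strictly positive")
        object.__setattr__(self, "masses", m)


@dataclass
class AdiabaticPoint:
    """Adiabatic data at one position (or a batch of positions).

    energies: (..., n) ascending; gradients: (..., n, n_dof);
    nacv: (..., n, n, n_dof) with d_nk = -d_kn; eigvecs: (..., n, n)
    orthonormal columns with a continuity-fixed sign.
    """

    energies: np.ndarray
    gradients: np.ndarray
    nacv: np.ndarray
    eigvecs: np.ndarray


def _eigh_2state(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form eigendecomposition of batched symmetric 2x2 matrices.

    Much faster than np.linalg.eigh for the per-step ensemble workload.
    """
    a = H[..., 0, 0]
    b = H[..., 1, 1]
    c = H[..., 0, 1]
    mean = 0.5 * (a + b)
    h = 0.5 * (a - b)
    r = np.hypot(h, c)
    energies = np.stack([mean - r, mean + r], axis=-1)

    # Eigenvector of the lower state; branch avoids catastrophic cancellation.
    use_a = h >= 0.0
    v0 = np.where(use_a, c, h - r)
    v1 = np.where(use_a, -(h + r), c)
    norm = np.hypot(v0, v1)
    # Degenerate (r == 0) points: any orthonormal pair works; pick identity.
    safe = norm > 0.0
    v0 = np.where(safe, v0, 1.0)
    v1 = np.where(safe, v1, 0.0)
    norm = np.where(safe, norm, 1.0)
    v0 = v0 / norm
    v1 = v1 / norm
    U = np.empty(H.shape, dtype=float)
    U[..., 0, 0] = v0
    U[..., 1, 0] = v1
    # Orthogonal complement for the upper state.
    U[..., 0, 1] = -v1
    U[..., 1, 1] = v0
    return energies, U


def _fix_phase(U: np.ndarray, prev: Optional[np.ndarray]) -> np.ndarray:
    """Choose eigenvector signs for continuity.

    Against ``prev`` when given (maximize per-column overlap), otherwise make
    the first nonzero component of each column positive.
    """
    if prev is not None:
        overlap = np.einsum("...ik,...ik->...k", prev, U)
        sign = np.where(overlap < 0.0, -1.0, 1.0)
    else:
        n = U.shape[-1]
        # first component with |.| above a tiny floor, per column
        sign = np.ones(U.shape[:-2] + (n,))
        for k in range(n):
            col = U[..., :, k]
            idx = np.argmax(np.abs(col) > 1e-12, axis=-1)
            lead = np.take_along_axis(col, idx[..., None], axis=-1)[..., 0]
            sign[..., k] = np.where(lead < 0.0, -1.0, 1.0)
    return U * sign[..., None, :]


def adiabatize(H: np.ndarray, prev_eigvecs: Optional[np.ndarray] = None,
               symmetry_tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Diagonalize symmetric H -> (energies ascending, sign-fixed eigvecs).

    Accepts a single matrix or a batch (..., n, n).  Raises ``ValueError``
    for non-symmetric input.
    """
    H = np.asarray(H, dtype=float)
    if H.shape[-1] != H.shape[-2]:
        raise ValueError("H must be square")
    if not np.allclose(H, np.swapaxes(H, -1, -2), atol=symmetry_tol):
        raise ValueError("diabatic matrix must be symmetric")
    if H.shape[-1] == 2:
        energies, U = _eigh_2state(H)
    else:
        energies, U = np.linalg.eigh(H)
    return energies, _fix_phase(U, prev_eigvecs)


def adiabatic_point(model: ModelSystem, R: np.ndarray,
                    prev: Optional[AdiabaticPoint] = None) -> AdiabaticPoint:
    """Evaluate energies, gradients and NACVs of ``model`` at position(s) R.

    Gradients come from the Hellmann–Feynman diagonal (U^T dH U)_nn and the
    NACV from the off-diagonal d_nk = (U^T dH U)_nk / (eps_k - eps_n), with
    eigenvector signs aligned to ``prev`` for continuity along a path.
    """
    R = np.asarray(R, dtype=float)
    squeeze = R.ndim == 1
    Rb = R[None, :] if squeeze else R

    H = model.diabatic(Rb)
    prev_U = None if prev is None else (prev.eigvecs[None] if prev.eigvecs.ndim == 2
                                        else prev.eigvecs)
    energies, U = adiabatize(H, prev_U)

    gap = energies[..., 1:] - energies[..., :-1]
    if np.any(gap < DEGENERACY_TOL):
        raise ConicalIntersectionError(
            "degenerate adiabatic surfaces at evaluation point; NACV undefined")

    dH = model.diabatic_gradient(Rb)               # (..., ndof, n, n)
    G = np.einsum("...in,...dij,...jk->...dnk", U, dH, U)  # (..., ndof, n, n)

    n = model.n_states
    idx = np.arange(n)
    gradients = np.moveaxis(G[..., idx, idx], -2, -1)       # (..., n, ndof)

    de = energies[..., None, :] - energies[..., :, None]     # eps_k - eps_n
    de_safe = np.where(np.abs(de) < DEGENERACY_TOL, 1.0, de)
    nacv = np.moveaxis(G, -3, -1) / de_safe[..., None]       # (..., n, n, ndof)
    nacv[..., idx, idx, :] = 0.0
    # enforce d_nk = -d_kn exactly (roundoff from the einsum would otherwise
    # leave ulp-level asymmetry)
    for a in range(n):
        for b in range(a + 1, n):
            nacv[..., b, a, :] = -nacv[..., a, b, :]

    if squeeze:
        return AdiabaticPoint(energies[0], gradients[0], nacv[0], U[0])
    return AdiabaticPoint(energies, gradients, nacv, U)


def adiabatic_energies(model: ModelSystem, R: np.ndarray) -> np.ndarray:
    """Eigenvalues only (cheap path used for auxiliary-trajectory energies)."""
    H = model.diabatic(np.asarray(R, dtype=float))
    if model.n_states == 2:
        e, _ = _eigh_2state(H)
        return e
    return np.linalg.eigvalsh(H)


# --------------------------------------------------------------------------
# Built-in model catalogue
# --------------------------------------------------------------------------

def _model_1d(label, V, dV, mass, params):
    """Wrap scalar-position matrix functions into a 1-DOF ModelSystem."""

    def diabatic(R):
        x = np.asarray(R, dtype=float)[..., 0]
        return V(x)

    def diabatic_gradient(R):
        x = np.asarray(R, dtype=float)[..., 0]
        return dV(x)[..., None, :, :]

    return ModelSystem(label=label, n_states=2, n_dof=1,
                       masses=np.array([mass]), diabatic=diabatic,
                       diabatic_gradient=diabatic_gradient, params=params)


def single_avoided_crossing(A=0.01, B=1.6, C=0.005, D=1.0, mass=2000.0):
    """Tully model I: a single avoided crossing at the origin.

    V11 is odd about the origin, the coupling even; a single nonadiabatic
    passage, the analogue of the one-event photodynamics regime.
    """

    def V(x):
        v11 = np.where(x >= 0, A * (1 - np.exp(-B * np.clip(x, 0, None))),
                       -A * (1 - np.exp(B * np.clip(x, None, 0))))
        v12 = C * np.exp(-D * x * x)
        out = np.empty(x.shape + (2, 2))
        out[..., 0, 0] = v11
        out[..., 1, 1] = -v11
        out[..., 0, 1] = out[..., 1, 0] = v12
        return out

    def dV(x):
        dv11 = A * B * np.exp(-B * np.abs(x))
        dv12 = -2 * D * x * C * np.exp(-D * x * x)
        out = np.empty(x.shape + (2, 2))
        out[..., 0, 0] = dv11
        out[..., 1, 1] = -dv11
        out[..., 0, 1] = out[..., 1, 0] = dv12
        return out

    return _model_1d("single_crossing", V, dV, mass,
                     dict(A=A, B=B, C=C, D=D, mass=mass))


def dual_avoided_crossing(A=0.10, B=0.28, E0=0.05, C=0.015, D=0.06, mass=2000.0):
    """Tully model II: two avoided crossings (Stueckelberg interference)."""

    def V(x):
        out = np.empty(x.shape + (2, 2))
        out[..., 0, 0] = np.zeros_like(x)
        out[..., 1, 1] = -A * np.exp(-B * x * x) + E0
        out[..., 0, 1] = out[..., 1, 0] = C * np.exp(-D * x * x)
        return out

    def dV(x):
        out = np.empty(x.shape + (2, 2))
        out[..., 0, 0] = np.zeros_like(x)
        out[..., 1, 1] = 2 * A * B * x * np.exp(-B * x * x)
        out[..., 0, 1] = out[..., 1, 0] = -2 * C * D * x * np.exp(-D * x * x)
        return out

    return _model_1d("dual_crossing", V, dV, mass,
                     dict(A=A, B=B, E0=E0, C=C, D=D, mass=mass))


def extended_coupling(A=6e-4, B=0.10, C=0.90, mass=2000.0):
    """Tully model III: extended coupling with reflection.

    The upper adiabat reflects moderate-energy wavepackets back through the
    coupling region, so trajectories recross it — the classic testbed for
    overcoherence and internal-consistency failure.
    """

    def V(x):
        v12 = np.where(x < 0, B * np.exp(C * np.clip(x, None, 0)),
                       B * (2 - np.exp(-C * np.clip(x, 0, None))))
        out = np.empty(x.shape + (2, 2))
        out[..., 0, 0] = np.full_like(x, A)
        out[..., 1, 1] = np.full_like(x, -A)
        out[..., 0, 1] = out[..., 1, 0] = v12
        return out

    def dV(x):
        dv12 = B * C * np.exp(-C * np.abs(x))
        out = np.zeros(x.shape + (2, 2))
        out[..., 0, 1] = out[..., 1, 0] = dv12
        return out

    return _model_1d("recrossing", V, dV, mass,
                     dict(A=A, B=B, C=C, mass=mass))


def sharp_sloped_crossing(slope=0.005, C=0.03, w=0.07, mass=2000.0):
    """Sloped crossing with a very narrow coupling region.

    Two steeply sloped linear diabats cross at the origin under a Gaussian
    coupling of width ``w`` (bohr).  A trajectory traverses the nonadiabatic
    region in a few atomic time units, so coarse nuclear time steps can miss
    it entirely — the sharp-conical-intersection pathology.
    """

    def V(x):
        out = np.empty(x.shape + (2, 2))
        out[..., 0, 0] = slope * x
        out[..., 1, 1] = -slope * x
        out[..., 0, 1] = out[..., 1, 0] = C * np.exp(-x * x / (2 * w * w))
        return out

    def dV(x):
        out = np.empty(x.shape + (2, 2))
        out[..., 0, 0] = np.full_like(x, slope)
        out[..., 1, 1] = np.full_like(x, -slope)
        out[..., 0, 1] = out[..., 1, 0] = -(x / (w * w)) * C * np.exp(-x * x / (2 * w * w))
        return out

    return _model_1d("sharp_crossing", V, dV, mass,
                     dict(slope=slope, C=C, w=w, mass=mass))


_CATALOGUE: dict[str, Callable[..., ModelSystem]] = {
    "single_crossing": single_avoided_crossing,
    "dual_crossing": dual_avoided_crossing,
    "recrossing": extended_coupling,
    "sharp_crossing": sharp_sloped_crossing,
}


def builtin_models() -> dict[str, Callable[..., ModelSystem]]:
    """Catalogue of named model factories (name -> factory(**params))."""
    return dict(_CATALOGUE)


def get_model(name: str, **params) -> ModelSystem:
    """Instantiate a catalogue model by name, overriding default parameters."""
    try:
        factory = _CATALOGUE[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(_CATALOGUE)}") from None
    return factory(**params)
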