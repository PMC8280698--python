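"""Wigner sampling of harmonic ground states and per-trajectory RNG streams.

Initial nuclear conditions are drawn from the Wigner distribution of the
ground vibrational state of uncoupled harmonic oscillators: per mode,
R ~ N(R0, 1/(2 m omega)) and P ~ N(0, m omega / 2) — temperature zero only.
The same ground state fixes the SHXF Gaussian width sigma = sqrt(1/(2 m omega)).

Each trajectory owns a counter-derived Philox stream so that runs are
reproducible and trajectories are independent of ensemble size; "several
repeats of the same initial condition" are realized as identical (R, P)
with distinct hopping streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HarmonicSpec", "wigner_sample", "sigma_from_ground_state",
           "trajectory_rng", "spec_for_gaussian"]


@dataclass(frozen=True)
class HarmonicSpec:
    """Uncoupled harmonic modes: frequencies, masses (a.u.) and center (bohr)."""

    frequencies: np.ndarray
    masses: np.ndarray
    center: np.ndarray

    def __post_init__(self):
        w = np.atleast_1d(np.asarray(self.frequencies, dtype=float))
        m = np.atleast_1d(np.asarray(self.masses, dtype=float))
        c = np.atleast_1d(np.asarray(self.center, dtype=float))
        if not (w.shape == m.shape == c.shape):
            raise ValueError("frequencies, masses and center must share a shape")
        if np.any(w <= 0) or np.any(m <= 0):
            raise ValueError("frequencies and masses must be strictly positive")
        object.__setattr__(self, "frequencies", w)
        object.__setattr__(self, "masses", m)
        object.__setattr__(self, "center", c)

    @property
    def n_modes(self) -> int:
        return self.frequencies.size


def spec_for_gaussian(center, sigma_x, mass) -> HarmonicSpec:
    """Harmonic spec whose ground state has position width ``sigma_x``.

    Convenience for matching a Gaussian wavepacket of variance sigma_x**2:
    omega = 1 / (2 m sigma_x**2).
    """
    sigma_x = np.atleast_1d(np.asarray(sigma_x, dtype=float))
    mass = np.atleast_1d(np.asarray(mass, dtype=float))
    omega = 1.0 / (2.0 * mass * sigma_x ** 2)
    return HarmonicSpec(frequencies=omega, masses=mass,
                        center=np.atleast_1d(np.asarray(center, dtype=float)))


def wigner_sample(spec: HarmonicSpec, n: int, seed, momenta: str = "sampled"
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` (R, P) pairs from the ground-state Wigner distribution.

    Returns arrays of shape (n, n_modes).  ``momenta='zero'`` samples only
    geometries and sets all momenta to zero (the geometry-only protocol
    sometimes used for stiff systems).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if momenta not in ("sampled", "zero"):
        raise ValueError("momenta must be 'sampled' or 'zero'")
    rng = np.random.default_rng(seed)
    sig_r = np.sqrt(1.0 / (2.0 * spec.masses * spec.frequencies))
    R = spec.center + sig_r * rng.standard_normal((n, spec.n_modes))
    if momenta == "zero":
        P = np.zeros((n, spec.n_modes))
    else:
        sig_p = np.sqrt(spec.masses * spec.frequencies / 2.0)
        P = sig_p * rng.standard_normal((n, spec.n_modes))
    return R, P


def sigma_from_ground_state(spec: HarmonicSpec, override=None) -> np.ndarray:
    """SHXF Gaussian width per mode: sigma = sqrt(1/(2 m omega)) (bohr).

    This is the position-space standard deviation of |chi|^2 for the ground
    state.  A scalar ``override`` (the single per-molecule value used in
    practice) is honored verbatim and broadcast to all modes.
    """
    if override is not None:
        return np.full(spec.n_modes, float(override))
    return np.sqrt(1.0 / (2.0 * spec.masses * spec.frequencies))


def trajectory_rng(base_seed: int, traj_index: int, repeat: int = 0) -> np.random.Generator:
    """Counter-derived, independent stream for one trajectory.

    The stream is a Philox generator keyed by (base_seed, traj_index, repeat)
    through a SeedSequence, so any trajectory can be replayed in isolation.
    """
    ss = np.random.SeedSequence((int(base_seed), int(traj_index), int(repeat)))
    return np.random.Generator(np.random.Philox(ss))
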