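"""Ensemble diagnostics, configuration handling and result I/O.

Two electronic populations coexist in surface hopping: the fraction of
trajectories on each surface, Pi_k(t), and the ensemble mean of the
coefficient populations, rho_kk(t) = <|C_k|^2>.  Internal consistency —
their agreement — is the central diagnostic of a decoherence correction,
together with the decoherence indicator, the ensemble mean of the pairwise
coherence rho_nn rho_kk (bounded by 1/4 per state pair and zero for a fully
decohered ensemble).

Run configurations are YAML mappings; results go out as CSV (summary, hop
log) and JSON (full config echo, seeds, scheme parameters).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import dynamics as dyn
from .decoherence import DecoherenceParams
from .models import ModelSystem, get_model
from .sampling import sigma_from_ground_state, spec_for_gaussian, wigner_sample

__all__ = [
    "EnsembleResult", "ConfigError", "aggregate", "internal_consistency_error",
    "decoherence_indicator", "read_config", "validate_config",
    "run_from_config", "write_results", "convergence_harness",
    "ConvergenceReport",
]

log = logging.getLogger("hopdyn")

AU_TIME_FS = dyn.AU_TIME_FS


@dataclass
class EnsembleResult:
    """Aggregated ensemble populations and diagnostics on one time grid."""

    t: np.ndarray                 # a.u.
    Pi: np.ndarray                # (n_rec, n_states) fraction of trajectories
    rho: np.ndarray               # (n_rec, n_states) mean |C_k|^2
    indicator: np.ndarray         # (n_rec,) mean pairwise coherence
    n_traj: int
    Pi_se: np.ndarray             # binomial standard error of Pi
    rho_se: np.ndarray            # sample standard error of rho
    energy_drift: np.ndarray      # (n_rec,) max_j |E_j(t) - E_j(0)|
    n_accepted: int = 0
    n_frustrated: int = 0
    max_energy_drift: float = 0.0
    max_hop_energy_jump: float = 0.0
    max_norm_drift: float = 0.0
    scheme_metadata: dict = field(default_factory=dict)

    @property
    def t_fs(self) -> np.ndarray:
        return self.t * AU_TIME_FS

    @property
    def n_states(self) -> int:
        return self.Pi.shape[1]


def decoherence_indicator(pops: np.ndarray) -> np.ndarray:
    """Ensemble-mean pairwise coherence sum_{n<k} <rho_nn rho_kk>.

    ``pops``: per-trajectory populations, shape (n_rec, n_traj, n_states)
    (or (n_traj, n_states) for a single time).  Bounded by 0.25 per state
    pair; zero when every trajectory is concentrated on one state.
    """
    pops = np.asarray(pops, dtype=float)
    n = pops.shape[-1]
    out = 0.0
    for a in range(n):
        for b in range(a + 1, n):
            out = out + pops[..., a] * pops[..., b]
    return np.mean(out, axis=-1)


def _from_arrays(t, active, pops, e_total, n_states):
    n_traj = active.shape[1]
    Pi = np.stack([(active == k).mean(axis=1) for k in range(n_states)], axis=1)
    rho = pops.mean(axis=1)
    rho_se = pops.std(axis=1, ddof=1) / np.sqrt(n_traj) if n_traj > 1 \
        else np.zeros_like(rho)
    Pi_se = np.sqrt(Pi * (1.0 - Pi) / n_traj)
    ind = decoherence_indicator(pops)
    drift = np.abs(e_total - e_total[0][None, :]).max(axis=1)
    return Pi, rho, Pi_se, rho_se, ind, drift


def aggregate(records) -> EnsembleResult:
    """Build an :class:`EnsembleResult` from trajectory records.

    Accepts an :class:`~hopdyn.dynamics.EnsembleRecord` or any sequence of
    :class:`~hopdyn.dynamics.TrajectoryRecord` sharing one time grid
    (mixed grids raise).  Aggregation is order-independent.
    """
    if isinstance(records, dyn.EnsembleRecord):
        rec = records
        n = rec.n_states
        Pi, rho, Pi_se, rho_se, ind, drift = _from_arrays(
            rec.t, rec.active, rec.pops, rec.e_total, n)
        return EnsembleResult(
            t=rec.t, Pi=Pi, rho=rho, indicator=ind, n_traj=rec.n_traj,
            Pi_se=Pi_se, rho_se=rho_se, energy_drift=drift,
            n_accepted=int(rec.n_accepted.sum()),
            n_frustrated=int(rec.n_frustrated.sum()),
            max_energy_drift=float(rec.max_energy_drift.max()),
            max_hop_energy_jump=float(rec.max_hop_energy_jump.max()),
            max_norm_drift=float(rec.max_norm_drift),
            scheme_metadata=dict(rec.scheme_metadata))

    records = list(records)
    if not records:
        raise ValueError("no records to aggregate")
    t = records[0].t
    for r in records[1:]:
        if r.t.shape != t.shape or not np.allclose(r.t, t):
            raise ValueError("trajectory records do not share a time grid")
    active = np.stack([r.active for r in records], axis=1)
    pops = np.stack([r.pops for r in records], axis=1)
    e_total = np.stack([r.e_total for r in records], axis=1)
    n = pops.shape[2]
    Pi, rho, Pi_se, rho_se, ind, drift = _from_arrays(t, active, pops, e_total, n)
    return EnsembleResult(
        t=t, Pi=Pi, rho=rho, indicator=ind, n_traj=len(records),
        Pi_se=Pi_se, rho_se=rho_se, energy_drift=drift,
        n_accepted=sum(r.n_accepted for r in records),
        n_frustrated=sum(r.n_frustrated for r in records),
        max_energy_drift=max(r.max_energy_drift for r in records),
        max_hop_energy_jump=max(r.max_hop_energy_jump for r in records),
        max_norm_drift=max(r.max_norm_drift for r in records))


def internal_consistency_error(result: EnsembleResult):
    """|Pi_k - rho_kk| per time and state, and its max over both.

    Returns (max_error, series) with series of shape (n_rec, n_states).
    """
    series = np.abs(result.Pi - result.rho)
    return float(series.max()), series


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

class ConfigError(ValueError):
    """Schema violation in a run configuration, reported with its key path."""


_DEFAULTS = {
    "dynamics": {"n_substeps": 20, "rescale": "iso", "frustrated": "keep",
                 "record_every": 1, "exit_position": None, "initial_state": 0},
    "initial": {"momenta": "sampled"},
    "decoherence": {"scheme": "none", "spawn_threshold": 1e-4, "alpha": 0.1,
                    "sigma": None},
    "seed": 0,
}


def _require(cfg, path, typ=None):
    node = cfg
    seen = []
    for key in path.split("."):
        seen.append(key)
        if not isinstance(node, dict) or key not in node:
            raise ConfigError(f"missing required config key: {'.'.join(seen)}")
        node = node[key]
    if typ is not None and not isinstance(node, typ):
        raise ConfigError(f"config key {path} must be of type {typ}")
    return node


def validate_config(cfg: dict) -> dict:
    """Validate a run configuration and fill in defaults (returns a copy)."""
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    _require(cfg, "model.name", str)
    for key in ("dynamics.dt", "dynamics.t_max", "initial.center",
                "initial.momentum", "initial.sigma"):
        _require(cfg, key, (int, float))
    _require(cfg, "initial.samples", int)

    out = json.loads(json.dumps(cfg))  # deep copy, also checks serializability
    out.setdefault("model", {}).setdefault("params", {})
    for section, defaults in _DEFAULTS.items():
        if isinstance(defaults, dict):
            node = out.setdefault(section, {})
            for k, v in defaults.items():
                node.setdefault(k, v)
        else:
            out.setdefault(section, defaults)

    dec = out["decoherence"]
    if dec["scheme"] not in ("none", "shxf", "edc", "afssh"):
        raise ConfigError("decoherence.scheme must be one of "
                          "none/shxf/edc/afssh")
    if dec["scheme"] == "shxf" and dec["sigma"] is None:
        # ground-state-width protocol: sigma of the initial nuclear density
        dec["sigma"] = float(out["initial"]["sigma"])
    if out["initial"]["momenta"] not in ("sampled", "zero"):
        raise ConfigError("initial.momenta must be 'sampled' or 'zero'")
    return out


def read_config(path) -> dict:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg)


def _build(cfg, ntraj=None, seed=None):
    cfg = validate_config(cfg)
    if ntraj is not None:
        cfg["initial"]["samples"] = int(ntraj)
    if seed is not None:
        cfg["seed"] = int(seed)
    model = get_model(cfg["model"]["name"], **cfg["model"]["params"])
    ini = cfg["initial"]
    spec = spec_for_gaussian(ini["center"], ini["sigma"], model.masses)
    ic_seed = np.random.SeedSequence((int(cfg["seed"]), 0x1C))
    R0, P0 = wigner_sample(spec, ini["samples"], ic_seed,
                           momenta=ini["momenta"])
    P0 = P0 + float(ini["momentum"])
    d = cfg["dynamics"]
    dec = cfg["decoherence"]
    params = None if dec["scheme"] == "none" else DecoherenceParams(
        scheme=dec["scheme"], sigma=dec["sigma"],
        spawn_threshold=dec["spawn_threshold"], alpha=dec["alpha"])
    shc = dyn.SHConfig(dt=float(d["dt"]), t_max=float(d["t_max"]),
                       n_substeps=int(d["n_substeps"]), rescale=d["rescale"],
                       frustrated=d["frustrated"], decoherence=params,
                       initial_state=int(d["initial_state"]),
                       seed=int(cfg["seed"]),
                       record_every=int(d["record_every"]),
                       exit_position=d["exit_position"])
    return cfg, model, R0, P0, shc


def run_from_config(cfg: dict, ntraj: Optional[int] = None,
                    seed: Optional[int] = None):
    """Run a full ensemble from a configuration mapping.

    Returns (EnsembleResult, EnsembleRecord, resolved config).
    """
    cfg, model, R0, P0, shc = _build(cfg, ntraj=ntraj, seed=seed)
    log.info("run: model=%s n=%d dt=%g scheme=%s seed=%d",
             model.label, R0.shape[0], shc.dt,
             cfg["decoherence"]["scheme"], shc.seed)
    record = dyn.run_ensemble(model, R0, P0, shc)
    result = aggregate(record)
    if result.n_frustrated:
        log.warning("%d frustrated hops", result.n_frustrated)
    if result.max_norm_drift > 1e-8:
        log.warning("electronic norm drift %.2e", result.max_norm_drift)
    return result, record, cfg


# --------------------------------------------------------------------------
# Result output
# --------------------------------------------------------------------------

def summary_frame(result: EnsembleResult) -> pd.DataFrame:
    """Summary table: t_au, t_fs, Pi_k..., rho_k..., indicator, energy_drift."""
    cols = {"t_au": result.t, "t_fs": result.t_fs}
    for k in range(result.n_states):
        cols[f"Pi_{k}"] = result.Pi[:, k]
    for k in range(result.n_states):
        cols[f"rho_{k}"] = result.rho[:, k]
    cols["indicator"] = result.indicator
    cols["energy_drift"] = result.energy_drift
    return pd.DataFrame(cols)


def write_results(outdir, result: EnsembleResult, config: dict,
                  record: Optional[dyn.EnsembleRecord] = None):
    """Persist a run: summary.csv, hops.csv, metadata.json (+records.npz)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary_frame(result).to_csv(outdir / "summary.csv", index=False)
    meta = {
        "config": config,
        "n_traj": result.n_traj,
        "n_accepted_hops": result.n_accepted,
        "n_frustrated_hops": result.n_frustrated,
        "max_energy_drift": result.max_energy_drift,
        "max_hop_energy_jump": result.max_hop_energy_jump,
        "max_norm_drift": result.max_norm_drift,
        "scheme": result.scheme_metadata,
    }
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))
    if record is not None:
        pd.DataFrame(record.hop_log).to_csv(outdir / "hops.csv", index=False)
        np.savez_compressed(
            outdir / "records.npz", t=record.t, R=record.R, V=record.V,
            active=record.active, pops=record.pops, energies=record.energies,
            e_total=record.e_total)
    log.info("results written to %s", outdir)
    return outdir


# --------------------------------------------------------------------------
# Convergence harness
# --------------------------------------------------------------------------

@dataclass
class ConvergenceReport:
    """Final-population convergence across time steps and ensemble sizes."""

    table: pd.DataFrame          # dt, n, Pi_k..., se_k...
    state: int
    converged: bool              # coarse dt agree with finest within 3 sigma
    non_monotone: bool           # Pi(dt) not monotone beyond combined error

    def __str__(self):
        flag = "converged" if self.converged else "NOT converged"
        return f"ConvergenceReport(state={self.state}, {flag})\n" + \
            self.table.to_string(index=False)


def convergence_harness(cfg: dict, dt_list: Sequence[float],
                        n_list: Optional[Sequence[int]] = None,
                        state: int = 1, seed: Optional[int] = None
                        ) -> ConvergenceReport:
    """Scan the nuclear time step (and ensemble size) and flag non-convergence.

    Runs the configured ensemble at every (dt, n), tabulating the final
    Pi_k with its binomial standard error.  The run is flagged not
    converged when any coarser dt differs from the finest dt by more than
    3x the combined Monte-Carlo error; non-monotone behavior of Pi(dt)
    beyond that error is flagged separately (the sharp-crossing pathology).
    """
    if len(dt_list) < 2:
        raise ValueError("need at least two dt values")
    cfg = validate_config(cfg)
    if n_list is None:
        n_list = [cfg["initial"]["samples"]]
    rows = []
    for dt in dt_list:
        for ntraj in n_list:
            c = json.loads(json.dumps(cfg))
            c["dynamics"]["dt"] = float(dt)
            res, _, _ = run_from_config(c, ntraj=ntraj, seed=seed)
            row = {"dt": float(dt), "n": ntraj}
            for k in range(res.n_states):
                row[f"Pi_{k}"] = res.Pi[-1, k]
                # floor of half a count avoids zero error bars at Pi = 0 or 1
                row[f"se_{k}"] = max(res.Pi_se[-1, k], 0.5 / res.n_traj)
            rows.append(row)
    table = pd.DataFrame(rows)

    n_max = max(n_list)
    sub = table[table["n"] == n_max].sort_values("dt").reset_index(drop=True)
    p = sub[f"Pi_{state}"].to_numpy()
    se = sub[f"se_{state}"].to_numpy()
    ref_p, ref_se = p[0], se[0]          # finest dt
    err = np.sqrt(se ** 2 + ref_se ** 2)
    converged = bool(np.all(np.abs(p - ref_p) <= 3.0 * err))
    diffs = np.diff(p)
    tol = 3.0 * np.sqrt(se[1:] ** 2 + se[:-1] ** 2)
    signif = np.abs(diffs) > tol
    non_monotone = bool(np.any(signif & (diffs > 0)) and
                        np.any(signif & (diffs < 0)))
    return ConvergenceReport(table=table, state=state, converged=converged,
                             non_monotone=non_monotone)
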