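"""Langevin dynamics (BAOAB splitting) and temperature replica exchange.

The friction sub-step is an exact Ornstein-Uhlenbeck solve, so velocities are
thermostatted exactly; positions carry the usual O(dt²) splitting error.
Replica exchange proposes neighbour swaps at fixed intervals with alternating
even/odd pairing and Metropolis acceptance min(1, exp(Δβ ΔE)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels, units
from .energy import _kernel_args, total_energy_forces
from .system import System

_SEED_MAX = 2**31 - 1


@dataclass
class LangevinParams:
    timestep: float = 0.3        # reduced time units (≈14.7 fs at 0.3)
    temperature: float = 300.0   # K
    friction: float = 0.843      # inverse reduced time units
    seed: int = 0
    n_steps: int = 10000
    save_interval: int = 100

    def __post_init__(self):
        if self.timestep <= 0 or self.friction <= 0:
            raise ValueError("timestep and friction must be positive")
        if self.save_interval <= 0 or self.n_steps < self.save_interval:
            raise ValueError("save_interval must divide the run into ≥1 chunk")


@dataclass
class ReplicaSchedule:
    temperatures: tuple = tuple(300.0 + 10.0 * i for i in range(10))
    exchange_interval: int = 1000
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        if len(t) < 2:
            raise ValueError("need at least 2 replicas")
        if not (np.diff(t) > 0).all():
            raise ValueError("temperatures must be strictly increasing")
        self.temperatures = tuple(float(x) for x in t)


@dataclass
class Trajectory:
    """Equally spaced coordinate frames plus run metadata."""

    frames: np.ndarray                 # (F, N, 3)
    step_ids: np.ndarray               # (F,)
    potential_energies: np.ndarray = None
    kinetic_energies: np.ndarray = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.step_ids = np.asarray(self.step_ids, dtype=np.int64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, n_beads, 3)")
        if len(self.frames) != len(self.step_ids):
            raise ValueError("frames and step_ids length mismatch")
        if len(self.step_ids) > 1:
            gaps = np.diff(self.step_ids)
            if not (gaps == gaps[0]).all():
                raise ValueError("frames must be equally spaced in steps")
        if not np.isfinite(self.frames).all():
            raise ValueError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]


class EnergyDivergence(RuntimeError):
    """Raised when the potential energy leaves the stable range; carries the
    trajectory up to the last stable frame."""

    def __init__(self, message, trajectory):
        super().__init__(message)
        self.trajectory = trajectory


def minimize_energy(system: System, coords=None, max_steps=500,
                    max_displacement=0.2, tol=1.0):
    """Damped steepest descent to relax steric strain in built structures.

    Displacements are capped at ``max_displacement`` Å per step; stops when
    the largest force component drops below ``tol`` kcal/mol/Å.
    """
    pos = np.array(system.coords0 if coords is None else coords, dtype=float)
    for _ in range(max_steps):
        _, forces = total_energy_forces(pos, system)
        fmax = np.abs(forces).max()
        if fmax < tol:
            break
        step = min(max_displacement / fmax, 0.02)
        pos += step * forces
    return pos


def _maxwell_boltzmann(rng, masses, temperature):
    scale = np.sqrt(units.KB * temperature / masses)[:, None]
    return rng.normal(size=(len(masses), 3)) * scale


def run_langevin(system: System, params: LangevinParams,
                 initial_coords=None, initial_velocities=None,
                 energy_threshold=1e10) -> Trajectory:
    """Propagate the system; identical seed ⇒ identical trajectory."""
    rng = np.random.default_rng(params.seed)
    pos = np.array(system.coords0 if initial_coords is None else initial_coords,
                   dtype=float)
    e0, _ = total_energy_forces(pos, system)
    if not np.isfinite(e0.total):
        raise ValueError("non-finite initial energy")
    vel = (np.array(initial_velocities, dtype=float)
           if initial_velocities is not None
           else _maxwell_boltzmann(rng, system.masses, params.temperature))
    args = _kernel_args(system)
    e_go = np.zeros(max(len(system.contact_sets), 1))
    kbt = units.KB * params.temperature
    n_chunks = params.n_steps // params.save_interval
    frames = np.empty((n_chunks, system.n_beads, 3))
    steps = np.empty(n_chunks, dtype=np.int64)
    pots = np.empty(n_chunks)
    kins = np.empty(n_chunks)
    for c in range(n_chunks):
        seed = int(rng.integers(_SEED_MAX))
        pot = _kernels.baoab_chunk(pos, vel, system.masses,
                                   params.save_interval, params.timestep,
                                   params.friction, kbt, seed, e_go=e_go,
                                   **args)
        if not np.isfinite(pot) or abs(pot) > energy_threshold:
            traj = Trajectory(frames[:c], steps[:c], pots[:c], kins[:c],
                              _run_metadata(params))
            raise EnergyDivergence(
                f"potential energy diverged ({pot:.3g}) at step "
                f"{(c + 1) * params.save_interval}", traj)
        frames[c] = pos
        steps[c] = (c + 1) * params.save_interval
        pots[c] = pot
        kins[c] = 0.5 * float(np.sum(system.masses[:, None] * vel**2))
    return Trajectory(frames, steps, pots, kins, _run_metadata(params))


def _run_metadata(params, **extra):
    from . import __version__

    md = {"params": {"timestep": params.timestep,
                     "temperature": params.temperature,
                     "friction": params.friction,
                     "seed": params.seed,
                     "n_steps": params.n_steps,
                     "save_interval": params.save_interval},
          "code_version": __version__}
    md.update(extra)
    return md


@dataclass
class ExchangeAttempt:
    step: int
    temp_pair: tuple      # (lower temperature index, upper)
    delta: float          # Δβ ΔE for the proposed swap
    accepted: bool


@dataclass
class ExchangeLog:
    """Swap attempts plus the replica↔temperature mapping over time.

    ``replica_at_temp[k, t]`` is the replica id occupying temperature rung
    ``t`` after the k-th exchange round (row 0 = initial mapping).
    """

    attempts: list = field(default_factory=list)
    replica_at_temp: np.ndarray = None

    def acceptance_rate(self, temp_pair=None) -> float:
        sel = [a for a in self.attempts
               if temp_pair is None or a.temp_pair == tuple(temp_pair)]
        if not sel:
            return float("nan")
        return sum(a.accepted for a in sel) / len(sel)

    def metropolis_expectation(self, temp_pair) -> float:
        """Mean min(1, exp(Δ)) over the logged proposals for one pair."""
        sel = [a for a in self.attempts if a.temp_pair == tuple(temp_pair)]
        if not sel:
            return float("nan")
        return float(np.mean([min(1.0, np.exp(a.delta)) for a in sel]))

    def replica_trace(self, replica: int) -> np.ndarray:
        """Temperature rung occupied by one replica after each round."""
        hits = np.argwhere(self.replica_at_temp == replica)
        return hits[np.argsort(hits[:, 0]), 1]


@dataclass
class REMDResult:
    """Per-temperature continuous trajectories plus the exchange log; the
    per-replica continuous paths are recoverable via ``replica_frames``."""

    trajectories: list           # Trajectory per temperature rung
    exchange_log: ExchangeLog
    schedule: ReplicaSchedule

    def energies(self, temp_index) -> np.ndarray:
        return self.trajectories[temp_index].potential_energies

    def replica_frames(self, replica: int) -> np.ndarray:
        """Reconstruct the coordinate frames visited by one replica."""
        mapping = self.exchange_log.replica_at_temp
        frames = []
        n_rounds = mapping.shape[0] - 1
        per_round = self.trajectories[0].n_frames // max(n_rounds, 1)
        for rnd in range(n_rounds):
            t = int(np.argwhere(mapping[rnd] == replica)[0, 0])
            sl = self.trajectories[t].frames[rnd * per_round:(rnd + 1) * per_round]
            frames.append(sl)
        return np.concatenate(frames) if frames else np.zeros((0, 0, 3))


def run_remd(system: System, schedule: ReplicaSchedule,
             params: LangevinParams, initial_coords=None) -> REMDResult:
    """Temperature replica exchange.

    All replicas start from the same coordinates (or ``initial_coords`` per
    replica).  Exchanges are proposed every ``schedule.exchange_interval``
    steps between neighbouring rungs, alternating even/odd pairs; a swap
    exchanges configurations (and rescales velocities by sqrt(T_new/T_old)).
    """
    temps = np.asarray(schedule.temperatures)
    n_rep = len(temps)
    if schedule.exchange_interval % params.save_interval != 0:
        raise ValueError("save_interval must divide exchange_interval")
    if params.n_steps % schedule.exchange_interval != 0:
        raise ValueError("exchange_interval must divide n_steps")
    master = np.random.default_rng(schedule.seed)
    rep_rngs = [np.random.default_rng(int(master.integers(_SEED_MAX)))
                for _ in range(n_rep)]
    swap_rng = np.random.default_rng(int(master.integers(_SEED_MAX)))

    if initial_coords is None:
        pos = [np.array(system.coords0) for _ in range(n_rep)]
    elif np.asarray(initial_coords).ndim == 2:
        pos = [np.array(initial_coords, dtype=float) for _ in range(n_rep)]
    else:
        pos = [np.array(c, dtype=float) for c in initial_coords]
    vel = [_maxwell_boltzmann(rep_rngs[t], system.masses, temps[t])
           for t in range(n_rep)]

    args = _kernel_args(system)
    e_go = np.zeros(max(len(system.contact_sets), 1))
    n_rounds = params.n_steps // schedule.exchange_interval
    saves_per_round = schedule.exchange_interval // params.save_interval
    n_frames = n_rounds * saves_per_round
    frames = np.empty((n_rep, n_frames, system.n_beads, 3))
    pots = np.empty((n_rep, n_frames))
    kins = np.empty((n_rep, n_frames))
    mapping = np.empty((n_rounds + 1, n_rep), dtype=np.int64)
    mapping[0] = np.arange(n_rep)
    replica_of_temp = np.arange(n_rep)
    attempts = []

    cur_pot = np.empty(n_rep)
    for rnd in range(n_rounds):
        for t in range(n_rep):
            kbt = units.KB * temps[t]
            for s in range(saves_per_round):
                seed = int(rep_rngs[t].integers(_SEED_MAX))
                pot = _kernels.baoab_chunk(pos[t], vel[t], system.masses,
                                           params.save_interval,
                                           params.timestep, params.friction,
                                           kbt, seed, e_go=e_go, **args)
                if not np.isfinite(pot):
                    raise EnergyDivergence(
                        f"replica at {temps[t]:.0f} K diverged",
                        Trajectory(frames[t, :rnd * saves_per_round],
                                   np.arange(rnd * saves_per_round) + 1,
                                   metadata=_run_metadata(params)))
                f = rnd * saves_per_round + s
                frames[t, f] = pos[t]
                pots[t, f] = pot
                kins[t, f] = 0.5 * float(np.sum(system.masses[:, None]
                                                * vel[t]**2))
            cur_pot[t] = pot
        # alternate even/odd neighbour pairs
        first = 0 if rnd % 2 == 0 else 1
        step_now = (rnd + 1) * schedule.exchange_interval
        for lo in range(first, n_rep - 1, 2):
            hi = lo + 1
            beta_lo = 1.0 / (units.KB * temps[lo])
            beta_hi = 1.0 / (units.KB * temps[hi])
            delta = (beta_lo - beta_hi) * (cur_pot[lo] - cur_pot[hi])
            accept = delta >= 0 or swap_rng.random() < np.exp(delta)
            attempts.append(ExchangeAttempt(step_now, (lo, hi), float(delta),
                                            bool(accept)))
            if accept:
                pos[lo], pos[hi] = pos[hi], pos[lo]
                scale_up = np.sqrt(temps[hi] / temps[lo])
                vel[lo], vel[hi] = vel[hi] / scale_up, vel[lo] * scale_up
                cur_pot[lo], cur_pot[hi] = cur_pot[hi], cur_pot[lo]
                replica_of_temp[[lo, hi]] = replica_of_temp[[hi, lo]]
        mapping[rnd + 1] = replica_of_temp

    trajs = []
    step_ids = (np.arange(n_frames) + 1) * params.save_interval
    for t in range(n_rep):
        md = _run_metadata(params, temperature=float(temps[t]),
                           remd_seed=schedule.seed)
        trajs.append(Trajectory(frames[t], step_ids, pots[t], kins[t], md))
    log = ExchangeLog(attempts, mapping)
    return REMDResult(trajs, log, schedule)


def free_energy_vs_reference(result: REMDResult, ref_index=0):
    """Dimensionless free-energy differences f_t − f_ref between temperature
    rungs by exponential averaging of the sampled potential energies:
    f_t − f_ref = −ln⟨exp(−(β_t − β_ref) E)⟩_ref.

    Returns (estimates, standard errors) arrays over rungs; errors by block
    averaging over 10 blocks.
    """
    temps = np.asarray(result.schedule.temperatures)
    betas = 1.0 / (units.KB * temps)
    e_ref = result.energies(ref_index)
    out = np.zeros(len(temps))
    err = np.zeros(len(temps))
    for t in range(len(temps)):
        if t == ref_index:
            continue
        db = betas[t] - betas[ref_index]
        w = -db * e_ref
        shift = w.max()
        blocks = np.array_split(w, 10)
        vals = [-(np.log(np.mean(np.exp(b - shift))) + shift) for b in blocks]
        out[t] = -(np.log(np.mean(np.exp(w - shift))) + shift)
        err[t] = np.std(vals, ddof=1) / np.sqrt(len(vals))
    return out, err
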