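"""Replica folding-and-quench protocol.

Each replica starts from a fresh self-avoiding random coil below the folding
transition temperature, folds at ``T_fold`` for a chain-length-dependent
time, then is equilibrated for ``t_q = t_fold / 3`` at each of two quench
temperatures ``T1 > T2`` to freeze the structure for analysis. The set of
final quenched conformations of all replicas is the ensemble Gamma on which
fitness and order statistics are computed.

The folding-time estimate grows as ``n^3 * exp(f(n)) * dt_f`` with chain
length ``n``, where ``dt_f`` ~ 10 ps is the timescale of positional
exchanges on the surface of a folding nucleus. The ``literal`` variant uses
``f(n) = n`` and is impractically long beyond toy chains; the default
``sqrt_exponent`` variant uses ``f(n) = sqrt(n)``; ``fixed`` uses a
user-supplied cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import (ChainState, ThermostatParams, integrate,
                       maxwell_boltzmann_velocities, replica_rng)
from .energetics import ContactTable, PotentialParams
from .errors import GenerationError, IntegrationError, InvalidInputError

__all__ = ["FoldingSchedule", "ReplicaEnsemble", "folding_time",
           "random_coil", "fold_ensemble"]

DEFAULT_N_REPLICAS = 127

# integration-stage tags feeding the per-replica RNG streams
_STAGE_COIL, _STAGE_FOLD, _STAGE_Q1, _STAGE_Q2 = 0, 1, 2, 3


@dataclass(frozen=True)
class FoldingSchedule:
    """Temperatures and durations of the fold/quench protocol (ps, K)."""

    t_fold: float
    dt_f: float = 10.0
    T_fold: float = 302.15
    T1: float = 218.2
    T2: float = 134.3
    T_f_estimate: float = 1.25 * 302.15

    def __post_init__(self):
        if self.t_fold <= 0 or self.dt_f <= 0:
            raise InvalidInputError("times must be positive")
        if not (self.T2 < self.T1 < self.T_fold):
            raise InvalidInputError("need T2 < T1 < T_fold")
        if not self.T_fold < self.T_f_estimate:
            raise InvalidInputError("T_fold must lie below T_f_estimate")

    @property
    def t_q(self) -> float:
        """Equilibration time per quench stage, t_fold / 3."""
        return self.t_fold / 3.0

    @classmethod
    def for_length(cls, n_res: int, variant: str = "sqrt_exponent",
                   dt_f: float = 10.0, cap: float | None = None,
                   **kwargs) -> "FoldingSchedule":
        t = folding_time(n_res, dt_f=dt_f, variant=variant, fixed=cap)
        if cap is not None:
            t = min(t, cap)
        return cls(t_fold=t, dt_f=dt_f, **kwargs)


@dataclass
class ReplicaEnsemble:
    """Quenched conformations of independently folded replicas (Gamma)."""

    members: list
    seeds: list
    schedule: FoldingSchedule
    sequence: str
    failed: list = field(default_factory=list)

    def __post_init__(self):
        n = len(self.sequence)
        for m in self.members:
            if m.shape != (n, 3):
                raise InvalidInputError("inconsistent member chain length")

    def __len__(self) -> int:
        return len(self.members)

    def coords(self) -> np.ndarray:
        """Members stacked as an (n_replicas, n_res, 3) array."""
        return np.asarray(self.members, dtype=float)


def folding_time(n_res: int, dt_f: float = 10.0,
                 variant: str = "sqrt_exponent",
                 fixed: float | None = None) -> float:
    """Folding duration in ps for a chain of ``n_res`` monomers."""
    if n_res < 2:
        raise InvalidInputError("need at least 2 monomers")
    if variant == "literal":
        return n_res ** 3 * float(np.exp(n_res)) * dt_f
    if variant == "sqrt_exponent":
        return n_res ** 3 * float(np.exp(np.sqrt(n_res))) * dt_f
    if variant == "fixed":
        if fixed is None or fixed <= 0:
            raise InvalidInputError("fixed variant needs a positive duration")
        return float(fixed)
    raise InvalidInputError(f"unknown folding-time variant {variant!r}")


def random_coil(n_res: int, params: PotentialParams,
                rng: np.random.Generator | int,
                min_sep_factor: float = 0.8,
                max_retries: int = 200) -> np.ndarray:
    """Self-avoiding random coil with exact bond lengths.

    Consecutive monomers sit exactly ``l`` apart; every non-consecutive pair
    is at least ``min_sep_factor * l`` apart. Grown monomer by monomer with
    bounded restarts.
    """
    if n_res < 2:
        raise InvalidInputError("need at least 2 monomers")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    min_sep = min_sep_factor * params.l
    for _ in range(max_retries):
        pos = np.zeros((n_res, 3))
        ok = True
        for i in range(1, n_res):
            placed = False
            for _attempt in range(60):
                v = rng.normal(size=3)
                v *= params.l / np.linalg.norm(v)
                cand = pos[i - 1] + v
                if i < 2 or np.all(
                        np.linalg.norm(pos[:i - 1] - cand, axis=1) >= min_sep):
                    pos[i] = cand
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return pos
    raise GenerationError(f"failed to grow a {n_res}-mer coil after "
                          f"{max_retries} restarts")


def _fold_one(seq: str, schedule: FoldingSchedule, table: ContactTable,
              params: PotentialParams, thermostat: ThermostatParams,
              base_seed: int, replica_index: int) -> np.ndarray:
    """Fold and quench a single replica; returns its final conformation."""
    n = len(seq)
    coil = random_coil(n, params, replica_rng(base_seed, replica_index,
                                              _STAGE_COIL))
    stages = [(_STAGE_FOLD, schedule.T_fold, schedule.t_fold),
              (_STAGE_Q1, schedule.T1, schedule.t_q),
              (_STAGE_Q2, schedule.T2, schedule.t_q)]
    pos = coil
    for stage, T, duration in stages:
        rng = replica_rng(base_seed, replica_index, stage)
        bath = thermostat.with_temperature(T)
        vel = maxwell_boltzmann_velocities(n, bath, params, rng)
        state = ChainState(pos, vel, rng)
        n_steps = int(round(duration / thermostat.dt))
        state = integrate(state, seq, table, bath, n_steps, params=params)
        pos = state.positions
    return pos


def fold_ensemble(seq: str, schedule: FoldingSchedule, table: ContactTable,
                  base_seed: int,
                  n_replicas: int = DEFAULT_N_REPLICAS,
                  params: PotentialParams = PotentialParams(),
                  thermostat: ThermostatParams = ThermostatParams()
                  ) -> ReplicaEnsemble:
    """Fold ``n_replicas`` independent replicas of one sequence.

    Replica streams are keyed by (base_seed, replica_index, stage), so the
    result is independent of execution order. A replica whose integration
    blows up is recorded in ``failed`` (with its final coil left out of the
    returned members) rather than aborting the ensemble.
    """
    if n_replicas < 1:
        raise InvalidInputError("n_replicas must be >= 1")
    members, seeds, failed = [], [], []
    for rep in range(n_replicas):
        try:
            pos = _fold_one(seq, schedule, table, params, thermostat,
                            base_seed, rep)
        except IntegrationError:
            failed.append(rep)
            continue
        members.append(pos)
        seeds.append(rep)
    return ReplicaEnsemble(members=members, seeds=seeds, schedule=schedule,
                           sequence=seq, failed=failed)
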