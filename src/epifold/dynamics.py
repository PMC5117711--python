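"""Langevin dynamics of the monomer chain.

The chain moves in an implicit solvent: each monomer feels the systematic
force from the chain potentials, a friction drag ``-m*gamma*v`` and the
matching thermal noise at the bath temperature. Propagation uses the BAOAB
splitting (velocity half-kick, drift, exact Ornstein-Uhlenbeck update,
drift, half-kick), which reduces exactly to velocity Verlet when the
friction vanishes and samples the configurational Boltzmann distribution
with O(dt^2) accuracy at finite friction.

Internally everything runs in reduced units: lengths in Angstroms, times in
ps and energies in k_B*T0, so the reduced Boltzmann constant is 1 and a
bath at absolute temperature T enters as T/T0. The printed monomer mass
(grams) is converted once into k_B*T0 * ps^2 / A^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .energetics import PotentialParams, ContactTable, pair_strength_matrix
from .errors import IntegrationError, InvalidInputError

#: Boltzmann constant, J/K.
K_B = 1.380649e-23

__all__ = ["ThermostatParams", "ChainState", "forces", "integrate",
           "kinetic_temperature", "maxwell_boltzmann_velocities",
           "reduced_mass", "replica_rng"]

# magnitude cap applied to the pair force when two nonbonded monomers
# coincide (the analytic direction is undefined at r = 0)
_FORCE_CAP = 1.0e4


@dataclass(frozen=True)
class ThermostatParams:
    """Langevin bath parameters.

    Attributes
    ----------
    mass : float
        Monomer mass in grams.
    gamma : float
        Friction coefficient in 1/ps.
    dt : float
        Integration time step in ps.
    T : float
        Bath temperature in Kelvin.
    """

    mass: float = 1.66e-22
    gamma: float = 10.0
    dt: float = 0.01
    T: float = 302.15

    def __post_init__(self):
        for name in ("mass", "gamma", "dt", "T"):
            if getattr(self, name) < 0 or (name != "gamma"
                                           and getattr(self, name) <= 0):
                raise InvalidInputError(f"{name} must be positive")

    def with_temperature(self, T: float) -> "ThermostatParams":
        return replace(self, T=T)


@dataclass
class ChainState:
    """Positions (A), velocities (A/ps) and the RNG stream of one replica."""

    positions: np.ndarray
    velocities: np.ndarray
    rng: np.random.Generator | None = None

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        if self.positions.shape != self.velocities.shape:
            raise InvalidInputError("positions/velocities shape mismatch")
        if not (np.isfinite(self.positions).all()
                and np.isfinite(self.velocities).all()):
            raise InvalidInputError("non-finite state")


def reduced_mass(thermostat: ThermostatParams,
                 params: PotentialParams) -> float:
    """Monomer mass in reduced units (k_B*T0 * ps^2 / A^2)."""
    e0 = K_B * params.T0                      # J per k_B*T0
    m_kg = thermostat.mass * 1e-3
    # 1 A/ps = 1e2 m/s, so m v^2 [J] = m_kg * 1e4 * v_red^2
    return m_kg * 1e4 / e0


def replica_rng(base_seed: int, replica_index: int,
                stage: int) -> np.random.Generator:
    """Independent, reproducible RNG stream for (seed, replica, stage)."""
    ss = np.random.SeedSequence([int(base_seed), int(replica_index),
                                 int(stage)])
    return np.random.Generator(np.random.PCG64(ss))


@njit(cache=True)
def _pair_force_scalar(r, epsp, l, alpha, eps_core):
    """dU/dr of the cross-chain potential at distance r."""
    x = np.exp(-alpha * (r - l))
    dmu = 2.0 * alpha * x * (1.0 - x)
    if r <= l:
        du = eps_core * dmu
        if epsp > 0.0:
            du += -alpha * epsp * x
    else:
        if epsp <= 0.0:
            du = -epsp * dmu
        else:
            du = -alpha * epsp * x
    return du


@njit(cache=True)
def _forces_kernel(pos, epsp, l, kappa, alpha, eps_core, fout):
    n = pos.shape[0]
    n_capped = 0
    for i in range(n):
        for k in range(3):
            fout[i, k] = 0.0
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > 1e-12:
            c = kappa * (r - l) / r
            fout[i, 0] += c * dx
            fout[i, 1] += c * dy
            fout[i, 2] += c * dz
            fout[i + 1, 0] -= c * dx
            fout[i + 1, 1] -= c * dy
            fout[i + 1, 2] -= c * dz
    for i in range(n - 2):
        for j in range(i + 2, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < 1e-9:
                # coincident monomers: deterministic capped push along x
                n_capped += 1
                fout[i, 0] -= _FORCE_CAP
                fout[j, 0] += _FORCE_CAP
                continue
            du = _pair_force_scalar(r, epsp[i, j], l, alpha, eps_core)
            if du > _FORCE_CAP:
                du = _FORCE_CAP
                n_capped += 1
            elif du < -_FORCE_CAP:
                du = -_FORCE_CAP
                n_capped += 1
            c = du / r
            fout[i, 0] += c * dx
            fout[i, 1] += c * dy
            fout[i, 2] += c * dz
            fout[j, 0] -= c * dx
            fout[j, 1] -= c * dy
            fout[j, 2] -= c * dz
    return n_capped


@njit(cache=True)
def _baoab_kernel(pos, vel, epsp, l, kappa, alpha, eps_core,
                  m, dt, c1, c2, sigma_v, noise, f):
    """Propagate len(noise) BAOAB steps in place; return failing step or -1."""
    n = pos.shape[0]
    n_steps = noise.shape[0]
    half = 0.5 * dt
    _forces_kernel(pos, epsp, l, kappa, alpha, eps_core, f)
    for s in range(n_steps):
        for i in range(n):
            for k in range(3):
                vel[i, k] += half * f[i, k] / m
                pos[i, k] += half * vel[i, k]
        for i in range(n):
            for k in range(3):
                vel[i, k] = c1 * vel[i, k] + c2 * sigma_v * noise[s, i, k]
                pos[i, k] += half * vel[i, k]
        _forces_kernel(pos, epsp, l, kappa, alpha, eps_core, f)
        for i in range(n):
            for k in range(3):
                vel[i, k] += half * f[i, k] / m
        ok = True
        for i in range(n):
            for k in range(3):
                if not np.isfinite(pos[i, k]):
                    ok = False
        if not ok:
            return s
    return -1


def forces(conf: np.ndarray, seq: str, table: ContactTable,
           params: PotentialParams = PotentialParams()) -> np.ndarray:
    """Analytic per-monomer forces (negative gradient of the total energy).

    Pairwise contributions obey Newton's third law, so the net force is the
    zero vector. Coincident nonbonded monomers trigger a capped deterministic
    push and a warning rather than a singular force.
    """
    pos = np.ascontiguousarray(conf, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] != len(seq):
        raise InvalidInputError("conformation/sequence mismatch")
    epsp = np.ascontiguousarray(pair_strength_matrix(seq, table))
    f = np.empty_like(pos)
    n_capped = _forces_kernel(pos, epsp, params.l, params.kappa, params.alpha,
                              params.eps_core, f)
    if n_capped:
        warnings.warn(f"capped {n_capped} singular/near-singular pair forces",
                      RuntimeWarning, stacklevel=2)
    return f


def maxwell_boltzmann_velocities(n_res: int, thermostat: ThermostatParams,
                                 params: PotentialParams,
                                 rng: np.random.Generator) -> np.ndarray:
    """Velocities drawn from the Maxwell-Boltzmann distribution at T."""
    m = reduced_mass(thermostat, params)
    kT = thermostat.T / params.T0
    return rng.normal(0.0, np.sqrt(kT / m), size=(n_res, 3))


def integrate(state: ChainState, seq: str, table: ContactTable,
              thermostat: ThermostatParams,
              n_steps: int,
              seed: int | None = None,
              params: PotentialParams = PotentialParams(),
              _chunk: int = 20000) -> ChainState:
    """Propagate ``n_steps`` Langevin steps at the bath temperature.

    The same seed (or RNG state) and inputs give a bit-identical trajectory.
    Raises :class:`IntegrationError` naming the step index if any coordinate
    becomes non-finite.
    """
    if n_steps < 0:
        raise InvalidInputError("n_steps must be >= 0")
    rng = np.random.default_rng(seed) if seed is not None else state.rng
    if rng is None and n_steps > 0 and thermostat.gamma > 0:
        raise InvalidInputError("an RNG seed or state is required")
    pos = state.positions.copy()
    vel = state.velocities.copy()
    if n_steps == 0:
        return ChainState(pos, vel, rng)
    epsp = np.ascontiguousarray(pair_strength_matrix(seq, table))
    m = reduced_mass(thermostat, params)
    kT = thermostat.T / params.T0
    c1 = np.exp(-thermostat.gamma * thermostat.dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    sigma_v = np.sqrt(kT / m)
    f = np.empty_like(pos)
    done = 0
    while done < n_steps:
        chunk = min(_chunk, n_steps - done)
        if rng is not None:
            noise = rng.standard_normal((chunk, pos.shape[0], 3))
        else:
            noise = np.zeros((chunk, pos.shape[0], 3))
        fail = _baoab_kernel(pos, vel, epsp, params.l, params.kappa,
                             params.alpha, params.eps_core, m, thermostat.dt,
                             c1, c2, sigma_v, noise, f)
        if fail >= 0:
            raise IntegrationError(done + fail)
        done += chunk
    return ChainState(pos, vel, rng)


def kinetic_temperature(state: ChainState, thermostat: ThermostatParams,
                        params: PotentialParams = PotentialParams()) -> float:
    """Instantaneous kinetic temperature 2*KE/(3*N*k_B), in Kelvin."""
    n = state.positions.shape[0]
    if n < 1:
        raise InvalidInputError("need at least one monomer")
    m = reduced_mass(thermostat, params)
    ke = 0.5 * m * float(np.sum(state.velocities ** 2))
    return 2.0 * ke / (3.0 * n) * params.T0
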