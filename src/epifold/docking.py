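"""Shell-sweep docking of a single-monomer ligand and the activity test.

The folded replica is enclosed in a spherical shell of ~10^4 evenly
distributed points centred on the monomer centroid. At each point the
ligand energy is the sum of unit Morse attractions to the binding-site
monomers and the repulsive Morse core from all other monomers. The shell
radius is reduced step by step until it lies inside the folded structure,
and the minimum-energy point over the whole sweep is the docked pose.

A docked replica is *active* when every pairwise distance within the
binding complex (site monomers plus ligand) is within the tolerance
(default 1 Angstrom, inclusive) of the corresponding distance in a
pre-defined target state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .energetics import PotentialParams
from .errors import (CannotBuildTargetError, DockingError, InvalidInputError,
                     InvalidTargetError)

__all__ = ["BindingSite", "TargetState", "Pose", "sphere_points", "dock",
           "is_active", "make_target", "complex_distances"]

DEFAULT_SHELL_POINTS = 10_000
DEFAULT_SWEEP_STEP = 0.25


@dataclass(frozen=True)
class BindingSite:
    """Monomer indices forming the binding site; the ligand is one monomer."""

    site_indices: tuple
    ligand_count: int = 1

    def __post_init__(self):
        idx = tuple(int(i) for i in self.site_indices)
        object.__setattr__(self, "site_indices", idx)
        if len(set(idx)) != len(idx) or not idx:
            raise InvalidInputError("site indices must be unique, nonempty")
        if any(i < 0 for i in idx):
            raise InvalidInputError("site indices must be non-negative")
        if self.ligand_count != 1:
            raise InvalidInputError("only single-monomer ligands supported")


@dataclass(frozen=True)
class TargetState:
    """Reference pairwise distances of the binding complex.

    ``pair_distances`` maps frozen index pairs to distances in Angstroms;
    the ligand is keyed as ``"L"``. For k site monomers the complex has
    C(k+1, 2) pairs.
    """

    pair_distances: dict
    tolerance: float = 1.0

    def __post_init__(self):
        if self.tolerance <= 0:
            raise InvalidInputError("tolerance must be positive")
        if any(d <= 0 for d in self.pair_distances.values()):
            raise InvalidInputError("target distances must be positive")


@dataclass(frozen=True)
class Pose:
    """Docked ligand position, its energy and the shell radius of origin."""

    ligand_position: np.ndarray
    energy: float
    shell_radius: float

    def __post_init__(self):
        if not np.isfinite(self.energy):
            raise InvalidInputError("pose energy must be finite")


def sphere_points(n: int = DEFAULT_SHELL_POINTS) -> np.ndarray:
    """``n`` near-uniform unit vectors by the generalized-spiral (Fibonacci)
    construction."""
    if n < 4:
        raise InvalidInputError("need at least 4 points")
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _shell_energies(points: np.ndarray, conf: np.ndarray,
                    site_mask: np.ndarray, params: PotentialParams
                    ) -> np.ndarray:
    """Ligand energy at each candidate point (vectorised over points)."""
    d = np.linalg.norm(points[:, None, :] - conf[None, :, :], axis=2)
    x = np.exp(-params.alpha * (d - params.l))
    mu = x * x - 2.0 * x
    att = np.sum(mu[:, site_mask], axis=1)
    # repulsive core = excluded-volume part of the pair potential,
    # mu(r) + 1 = (1 - x)^2 for r <= l and 0 beyond: non-negative, so
    # burying the ligand among non-site monomers is never rewarded
    xs = x[:, ~site_mask]
    core = np.where(d[:, ~site_mask] <= params.l, (1.0 - xs) ** 2, 0.0)
    return att + np.sum(core, axis=1)


def dock(conf: np.ndarray, site: BindingSite,
         sweep: float = DEFAULT_SWEEP_STEP,
         n_shell_points: int = DEFAULT_SHELL_POINTS,
         params: PotentialParams = PotentialParams()) -> Pose:
    """Global minimum-energy ligand pose over the radial shell sweep.

    Shells are centred on the monomer centroid and swept from
    ``max(centroid distance) + 2l`` down to ``min(centroid distance)`` in
    steps of ``sweep``.
    """
    conf = np.asarray(conf, float)
    if conf.ndim != 2 or conf.shape[1] != 3:
        raise InvalidInputError("conformation must be (n, 3)")
    if max(site.site_indices) >= conf.shape[0]:
        raise InvalidInputError("site index outside chain")
    if sweep <= 0:
        raise InvalidInputError("sweep step must be positive")
    center = conf.mean(axis=0)
    rads = np.linalg.norm(conf - center, axis=1)
    r_max = float(rads.max() + 2.0 * params.l)
    r_min = float(rads.min())
    radii = np.arange(r_max, r_min - 1e-9, -sweep)
    if radii.size == 0:
        raise DockingError("empty shell sweep range")
    unit = sphere_points(n_shell_points)
    site_mask = np.zeros(conf.shape[0], dtype=bool)
    site_mask[list(site.site_indices)] = True
    best = None
    for r in radii:
        pts = center + r * unit
        e = _shell_energies(pts, conf, site_mask, params)
        k = int(np.argmin(e))
        if best is None or e[k] < best[1]:
            best = (pts[k].copy(), float(e[k]), float(r))
    return Pose(ligand_position=best[0], energy=best[1], shell_radius=best[2])


def complex_distances(conf: np.ndarray, site: BindingSite,
                      ligand_position: np.ndarray) -> dict:
    """All pairwise distances within the binding complex, ligand keyed 'L'."""
    conf = np.asarray(conf, float)
    labels = list(site.site_indices) + ["L"]
    coords = {i: conf[i] for i in site.site_indices}
    coords["L"] = np.asarray(ligand_position, float)
    return {frozenset((a, b)): float(np.linalg.norm(coords[a] - coords[b]))
            for a, b in combinations(labels, 2)}


def is_active(conf: np.ndarray, site: BindingSite, pose: Pose,
              target: TargetState) -> bool:
    """True iff every complex pair distance is within tolerance (inclusive)
    of the target."""
    dists = complex_distances(conf, site, pose.ligand_position)
    for pair, d in dists.items():
        if pair not in target.pair_distances:
            raise InvalidTargetError(f"target missing pair {sorted(pair, key=str)}")
        if abs(d - target.pair_distances[pair]) > target.tolerance:
            return False
    return True


def make_target(ens, site: BindingSite, seed_target: TargetState,
                sweep: float = DEFAULT_SWEEP_STEP,
                n_shell_points: int = DEFAULT_SHELL_POINTS,
                params: PotentialParams = PotentialParams(),
                tolerance: float | None = None) -> TargetState:
    """Average target state over replicas active under a provisional target.

    Docks every ensemble member, keeps those active with respect to
    ``seed_target`` and averages their complex pair distances. Raises when
    no replica qualifies.
    """
    members = ens.members if hasattr(ens, "members") else list(ens)
    sums: dict = {}
    n_active = 0
    for conf in members:
        pose = dock(conf, site, sweep=sweep, n_shell_points=n_shell_points,
                    params=params)
        if is_active(conf, site, pose, seed_target):
            n_active += 1
            for pair, d in complex_distances(conf, site,
                                             pose.ligand_position).items():
                sums[pair] = sums.get(pair, 0.0) + d
    if n_active == 0:
        raise CannotBuildTargetError("no replica active under the "
                                     "provisional target")
    return TargetState(
        pair_distances={p: s / n_active for p, s in sums.items()},
        tolerance=tolerance if tolerance is not None else seed_target.tolerance)
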