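"""Small deterministic test systems exercising the full pipeline.

Three kinds:

``minimal-folder``
    A 12-mer with a strongly hydrophobic core that collapses reliably
    under a short, capped folding schedule. Its binding-site target is
    built at fixture-creation time by folding a calibration ensemble with
    seeds derived from the fixture seed, docking the reference fold and
    averaging over the provisionally active replicas — so the fixture is
    fully self-contained and reproducible from the seed alone.

``planted-epistasis``
    A sequence plus a mock activity protocol in which fitness is 1 only
    when two designated sites are jointly non-wildtype: by construction
    the single mutants are lethal-neutral and the double mutant rescues,
    planting strong positive epistasis at that pair.

``docking-toy``
    A frozen 8-mer coil and a one-monomer binding site for comparing the
    shell-sweep docking against an exhaustive dense-grid search.

These run in seconds to minutes; they emulate folding funnels and binding
geometry, not the size, diversity or evolutionary history of real
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .docking import BindingSite, TargetState, complex_distances, dock, \
    make_target
from .dynamics import ThermostatParams
from .energetics import ContactTable, PotentialParams, default_contact_table
from .errors import InvalidInputError
from .fitness import FoldDockProtocol
from .folding import FoldingSchedule, fold_ensemble, random_coil
from .structure import order_profile, select_reference

__all__ = ["FixtureSystem", "make_fixture", "PlantedEpistasisProtocol",
           "SHIPPED_SEED"]

#: default fixture seed used by the regression-pinned invariants
SHIPPED_SEED = 7

# minimal-folder operating point: 12-mer, capped schedule, reduced shells
_FOLDER_SEQ = "KSKGLLLGKSKS"
_FOLDER_SITE = (4, 5, 6)
_FOLDER_T_FOLD = 240.0
_FOLDER_N_REPLICAS = 16
_FOLDER_SHELL_POINTS = 1024
_FOLDER_SWEEP = 0.25


@dataclass
class FixtureSystem:
    """A ready-to-run small system."""

    kind: str
    sequence: str
    site: BindingSite | None
    target: TargetState | None
    schedule: FoldingSchedule | None
    n_replicas: int
    base_seed: int
    table: ContactTable | None = None
    params: PotentialParams = field(default_factory=PotentialParams)
    thermostat: ThermostatParams = field(default_factory=ThermostatParams)
    planted_pair: tuple | None = None
    conformation: np.ndarray | None = None
    sweep: float = _FOLDER_SWEEP
    n_shell_points: int = _FOLDER_SHELL_POINTS

    def protocol(self) -> FoldDockProtocol:
        if self.site is None or self.target is None:
            raise InvalidInputError(f"{self.kind} fixture has no protocol")
        return FoldDockProtocol(
            schedule=self.schedule, table=self.table, site=self.site,
            target=self.target, n_replicas=self.n_replicas,
            params=self.params, thermostat=self.thermostat,
            sweep=self.sweep, n_shell_points=self.n_shell_points)


class PlantedEpistasisProtocol:
    """Mock activity protocol with epistasis planted at one site pair.

    Fitness is 1 when both planted sites differ from the wildtype residues
    and 0 otherwise, so single mutants at the pair change nothing and the
    double mutant jumps to full fitness (epsilon = +1 at the planted pair).
    """

    def __init__(self, wildtype: str, pair: tuple, n_replicas: int = 16):
        self.wildtype = wildtype
        self.pair = pair
        self.n_replicas = n_replicas

    def replica_activity(self, seq: str, base_seed: int) -> np.ndarray:
        i, j = self.pair
        on = seq[i] != self.wildtype[i] and seq[j] != self.wildtype[j]
        return np.full(self.n_replicas, on, dtype=bool)


def _folder_schedule() -> FoldingSchedule:
    return FoldingSchedule(t_fold=_FOLDER_T_FOLD)


def _build_folder_target(seed: int, table: ContactTable,
                         params: PotentialParams,
                         thermostat: ThermostatParams) -> TargetState:
    """Fold a calibration ensemble and average the active complex geometry."""
    site = BindingSite(_FOLDER_SITE)
    schedule = _folder_schedule()
    calib_seed = int(np.random.SeedSequence([seed, 0xF1D]).generate_state(1)[0]
                     % (2 ** 31))
    ens = fold_ensemble(_FOLDER_SEQ, schedule, table, calib_seed,
                        n_replicas=_FOLDER_N_REPLICAS, params=params,
                        thermostat=thermostat)
    ref = order_profile(select_reference(ens))
    pose = dock(ref.x_star, site, sweep=_FOLDER_SWEEP,
                n_shell_points=_FOLDER_SHELL_POINTS, params=params)
    provisional = TargetState(
        pair_distances=complex_distances(ref.x_star, site,
                                         pose.ligand_position),
        tolerance=1.0)
    return make_target(ens, site, provisional, sweep=_FOLDER_SWEEP,
                       n_shell_points=_FOLDER_SHELL_POINTS, params=params)


def make_fixture(kind: str, seed: int = SHIPPED_SEED) -> FixtureSystem:
    """Build one of the deterministic test systems."""
    params = PotentialParams()
    thermostat = ThermostatParams()
    if kind == "minimal-folder":
        table = default_contact_table(params)
        target = _build_folder_target(seed, table, params, thermostat)
        return FixtureSystem(
            kind=kind, sequence=_FOLDER_SEQ, site=BindingSite(_FOLDER_SITE),
            target=target, schedule=_folder_schedule(),
            n_replicas=_FOLDER_N_REPLICAS, base_seed=seed, table=table,
            params=params, thermostat=thermostat)
    if kind == "planted-epistasis":
        seq = "AWDKTGELVRIS"
        return FixtureSystem(
            kind=kind, sequence=seq, site=None, target=None, schedule=None,
            n_replicas=16, base_seed=seed, planted_pair=(2, 9))
    if kind == "docking-toy":
        seq = "KWKKLKKV"
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, 0xD0C]))
        conf = random_coil(len(seq), params, rng)
        return FixtureSystem(
            kind=kind, sequence=seq, site=BindingSite((1,)), target=None,
            schedule=None, n_replicas=1, base_seed=seed,
            conformation=conf, params=params)
    raise InvalidInputError(f"unknown fixture kind {kind!r}")
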