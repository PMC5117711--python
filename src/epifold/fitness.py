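"""Fitness measurement, mutation proposal and a simple selection loop.

Fitness of a sequence is the fraction of active replicas, ``P = N*/N``:
the sequence is folded into an ensemble of independent replicas, the ligand
is docked onto each and a replica counts as active when its binding complex
matches the target geometry within tolerance.

Mutations are constrained to amino-acid exchanges that are reachable under
the genetic code: the default exchange matrix counts, for each ordered
amino-acid pair, the number of codon pairs that differ by a single
nucleotide substitution; a substitution is proposable when that row-
normalised probability is positive. A Dayhoff-style 20x20 count table can
be supplied instead as a whitespace-delimited file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import stats

from .docking import (BindingSite, TargetState, dock, is_active,
                      DEFAULT_SHELL_POINTS, DEFAULT_SWEEP_STEP)
from .dynamics import ThermostatParams
from .energetics import (AA_INDEX, AMINO_ACIDS, ContactTable, PotentialParams)
from .errors import FormatError, InvalidInputError, NoMoveError
from .folding import DEFAULT_N_REPLICAS, FoldingSchedule, fold_ensemble

log = logging.getLogger(__name__)

__all__ = ["FitnessMeasurement", "ExchangeMatrix", "MutationSpec",
           "FoldDockProtocol", "fitness", "fitness_error",
           "propose_mutation", "evolve", "genetic_code_exchange_matrix",
           "load_exchange_matrix", "apply_mutation"]


@dataclass(frozen=True)
class FitnessMeasurement:
    """Active-replica count and the fitness fraction P = N*/N."""

    n_active: int
    n_replicas: int
    seed: int

    def __post_init__(self):
        if not 0 <= self.n_active <= self.n_replicas:
            raise InvalidInputError("need 0 <= n_active <= n_replicas")

    @property
    def P(self) -> float:
        return self.n_active / self.n_replicas

    @property
    def P_exact(self) -> Fraction:
        return Fraction(self.n_active, self.n_replicas)


@dataclass(frozen=True)
class ExchangeMatrix:
    """Amino-acid transition counts and row-normalised probabilities."""

    counts: np.ndarray
    alphabet: str = AMINO_ACIDS

    def __post_init__(self):
        c = np.asarray(self.counts, float)
        if c.shape != (20, 20) or np.any(c < 0):
            raise FormatError("counts must be a non-negative 20x20 matrix")
        object.__setattr__(self, "counts", c)

    @property
    def probs(self) -> np.ndarray:
        row = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(row > 0, self.counts / row, 0.0)
        return p

    def allowed_targets(self, from_aa: str) -> list[str]:
        """Amino acids nu != mu with p(mu, nu) > 0."""
        i = AA_INDEX[from_aa]
        p = self.probs[i]
        return [aa for j, aa in enumerate(self.alphabet)
                if j != i and p[j] > 0]


@dataclass(frozen=True)
class MutationSpec:
    """A single-site substitution."""

    site: int
    from_aa: str
    to_aa: str

    def __post_init__(self):
        if self.from_aa == self.to_aa:
            raise InvalidInputError("mutation must change the residue")


_STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def genetic_code_exchange_matrix() -> ExchangeMatrix:
    """Counts of single-nucleotide codon substitutions per amino-acid pair."""
    counts = np.zeros((20, 20))
    bases = "ACGT"
    for codon, aa in _STANDARD_CODE.items():
        for pos in range(3):
            for b in bases:
                if b == codon[pos]:
                    continue
                mutated = codon[:pos] + b + codon[pos + 1:]
                aa2 = _STANDARD_CODE.get(mutated)
                if aa2 is not None:
                    counts[AA_INDEX[aa], AA_INDEX[aa2]] += 1
    return ExchangeMatrix(counts=counts)


def load_exchange_matrix(path: str | Path) -> ExchangeMatrix:
    """Read a whitespace-delimited 20x20 count table with residue headers."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0].split()
    if sorted(header) != sorted(AMINO_ACIDS):
        raise FormatError("header must list the 20 canonical amino acids")
    counts = np.zeros((20, 20))
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != 21:
            raise FormatError("each row needs a residue code plus 20 counts")
        i = AA_INDEX[parts[0]]
        for col, val in zip(header, parts[1:]):
            counts[i, AA_INDEX[col]] = float(val)
    return ExchangeMatrix(counts=counts)


@dataclass(frozen=True)
class FoldDockProtocol:
    """The full fold-then-dock activity protocol behind P = N*/N."""

    schedule: FoldingSchedule
    table: ContactTable
    site: BindingSite
    target: TargetState
    n_replicas: int = DEFAULT_N_REPLICAS
    params: PotentialParams = PotentialParams()
    thermostat: ThermostatParams = ThermostatParams()
    sweep: float = DEFAULT_SWEEP_STEP
    n_shell_points: int = DEFAULT_SHELL_POINTS

    def replica_activity(self, seq: str, base_seed: int) -> np.ndarray:
        """Per-replica activity flags; failed replicas count inactive."""
        ens = fold_ensemble(seq, self.schedule, self.table, base_seed,
                            n_replicas=self.n_replicas, params=self.params,
                            thermostat=self.thermostat)
        if ens.failed:
            log.warning("%d replica(s) failed integration; counted inactive",
                        len(ens.failed))
        flags = np.zeros(self.n_replicas, dtype=bool)
        for rep, conf in zip(ens.seeds, ens.members):
            try:
                pose = dock(conf, self.site, sweep=self.sweep,
                            n_shell_points=self.n_shell_points,
                            params=self.params)
            except Exception:
                log.warning("docking failed for replica %d", rep)
                continue
            flags[rep] = is_active(conf, self.site, pose, self.target)
        return flags


def fitness(seq: str, protocol, base_seed: int) -> FitnessMeasurement:
    """Measure P = N*/N for one sequence under an activity protocol.

    ``protocol`` is anything exposing ``replica_activity(seq, base_seed)``;
    the fold-and-dock implementation is :class:`FoldDockProtocol`, and tests
    substitute mocks.
    """
    flags = np.asarray(protocol.replica_activity(seq, base_seed), dtype=bool)
    return FitnessMeasurement(n_active=int(flags.sum()),
                              n_replicas=flags.size, seed=base_seed)


def fitness_error(measurements) -> tuple[float, float]:
    """Mean and width of a set of fitness measurements.

    Reports the Gaussian-fit width (MLE, equal to the population SD) and
    checks it against the sample SD; the Gaussian width is returned.
    """
    p = np.asarray([getattr(m, "P", m) for m in measurements], float)
    if p.size < 10:
        raise InvalidInputError("need at least 10 measurements")
    mean, sigma = stats.norm.fit(p)
    return float(mean), float(sigma)


def propose_mutation(seq: str, site: int, xmat: ExchangeMatrix,
                     rng: np.random.Generator | int,
                     weighted: bool = False) -> MutationSpec:
    """Sample a genetic-code-compatible substitution at one site.

    By default the target residue is uniform over the allowed set
    (exchanges with positive probability); ``weighted=True`` samples
    proportionally to the exchange probabilities instead.
    """
    if not 0 <= site < len(seq):
        raise InvalidInputError("site outside sequence")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    from_aa = seq[site]
    allowed = xmat.allowed_targets(from_aa)
    if not allowed:
        raise NoMoveError(f"no allowed substitution for {from_aa}")
    if weighted:
        i = AA_INDEX[from_aa]
        w = np.array([xmat.probs[i, AA_INDEX[a]] for a in allowed])
        to_aa = rng.choice(allowed, p=w / w.sum())
    else:
        to_aa = allowed[rng.integers(len(allowed))]
    return MutationSpec(site=site, from_aa=from_aa, to_aa=str(to_aa))


def apply_mutation(seq: str, *mutations: MutationSpec) -> str:
    """Apply one or more substitutions to a sequence."""
    chars = list(seq)
    for m in mutations:
        if chars[m.site] != m.from_aa:
            raise InvalidInputError(
                f"site {m.site} holds {chars[m.site]}, not {m.from_aa}")
        chars[m.site] = m.to_aa
    return "".join(chars)


def threshold_rule(p_min: float):
    """Acceptance rule: accept when the mutant fitness is at least p_min."""
    def rule(p_old: float, p_new: float) -> bool:
        return p_new >= p_min
    return rule


def evolve(seq: str, steps: int, protocol, xmat: ExchangeMatrix,
           base_seed: int, rule=None) -> list[str]:
    """Single-lineage hill-walk: propose, measure, accept.

    Each step mutates a random site; the pluggable ``rule(P_old, P_new)``
    decides acceptance (default: accept when the mutant P >= the current P).
    Returns the trajectory of sequences, starting with the input.
    """
    if rule is None:
        def rule(p_old, p_new):
            return p_new >= p_old
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, 0xE70]))
    traj = [seq]
    current = seq
    p_cur = fitness(current, protocol, base_seed).P
    for step in range(steps):
        site = int(rng.integers(len(current)))
        try:
            mut = propose_mutation(current, site, xmat, rng)
        except NoMoveError:
            traj.append(current)
            continue
        cand = apply_mutation(current, mut)
        p_new = fitness(cand, protocol, base_seed + 1 + step).P
        if rule(p_cur, p_new):
            current, p_cur = cand, p_new
        traj.append(current)
    return traj
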