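"""Pair potentials and the sequence-dependent contact-energy table.

The chain is a string of point monomers. Consecutive monomers are linked by
a harmonic bond of equilibrium length ``l``; non-adjacent monomers interact
through potentials assembled from the unit Morse function

    mu(r) = exp(-2*alpha*(r - l)) - 2*exp(-alpha*(r - l))

whose attractive minimum sits at ``r = l``. Each cross-chain potential has
an excluded-volume core of strength ``eps_core`` and a sequence-dependent
tail of signed strength ``eps_prime``; negative ``eps_prime`` is attractive
(a well of depth ``|eps_prime|`` at ``r = l``), positive is repulsive. The
per-pair strengths come from an empirical residue-residue contact-energy
matrix (Miyazawa-Jernigan statistical potentials rescaled with threonine as
the reference solvent) normalised by the mean absolute contact energy.

All energies are carried in reduced units of ``k_B * T0``; distances in
Angstroms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import DegenerateTableError, FormatError, InvalidInputError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

__all__ = [
    "AMINO_ACIDS",
    "AA_INDEX",
    "PotentialParams",
    "ContactTable",
    "bond_energy",
    "morse_unit",
    "nonbonded_energy",
    "build_contact_table",
    "load_contact_energies",
    "default_contact_table",
    "total_energy",
    "sequence_to_indices",
]


@dataclass(frozen=True)
class PotentialParams:
    """Parameters of the chain potentials.

    Attributes
    ----------
    l : float
        Equilibrium bond length in Angstroms.
    kappa : float
        Bond stiffness in k_B*T0 per Angstrom^2.
    alpha : float
        Morse range parameter in 1/Angstrom.
    eps_core : float
        Excluded-volume strength in k_B*T0.
    T0 : float
        Reference temperature in Kelvin (sets the energy unit).
    """

    l: float = 3.8
    kappa: float = 11.0
    alpha: float = 2.1
    eps_core: float = 2.0
    T0: float = 302.15

    def __post_init__(self):
        for name in ("l", "kappa", "alpha", "eps_core", "T0"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ContactTable:
    """Residue-residue interaction strengths.

    ``E`` is the 20x20 threonine-rescaled contact-energy matrix, ``E_o`` the
    mean absolute energy over the upper triangle (diagonal included) and
    ``eps_prime = eps_core * E / E_o`` the signed strengths used by the
    cross-chain potentials.
    """

    E: np.ndarray
    E_o: float
    eps_prime: np.ndarray
    alphabet: str = AMINO_ACIDS

    def strength(self, aa_i: str, aa_j: str) -> float:
        """Signed interaction strength eps_prime for a residue pair."""
        return float(self.eps_prime[AA_INDEX[aa_i], AA_INDEX[aa_j]])


def bond_energy(r, params: PotentialParams = PotentialParams()):
    """Harmonic bond energy kappa/2 * (r - l)^2.

    ``r`` may be a scalar or array of non-negative distances (Angstroms).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise InvalidInputError("distance must be non-negative")
    out = 0.5 * params.kappa * (r - params.l) ** 2
    return out if out.ndim else float(out)


def morse_unit(r, params: PotentialParams = PotentialParams()):
    """Unit Morse potential with minimum -1 at r = l."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise InvalidInputError("distance must be non-negative")
    x = np.exp(-params.alpha * (r - params.l))
    out = x * x - 2.0 * x
    return out if out.ndim else float(out)


def nonbonded_energy(r, eps_prime_value: float,
                     params: PotentialParams = PotentialParams()):
    """Cross-chain pair potential for a residue pair of strength eps_prime.

    For attractive pairs (eps_prime <= 0) the potential is a repulsive Morse
    core joined at r = l to a well of depth |eps_prime|; for repulsive pairs
    (eps_prime >= 0) the core is joined to a decaying exponential tail of
    amplitude eps_prime. The two branches agree when eps_prime = 0, the value
    at r = l is exactly eps_prime, and the potential vanishes as r -> inf.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise InvalidInputError("distance must be non-negative")
    eps = params.eps_core
    x = np.exp(-params.alpha * (r - params.l))
    mu = x * x - 2.0 * x
    inner = r <= params.l  # theta(0) = 1 on the r <= l component
    if eps_prime_value <= 0:
        out = np.where(inner, eps * mu + eps + eps_prime_value,
                       -eps_prime_value * mu)
    else:
        out = np.where(inner, eps * mu + eps + eps_prime_value * x,
                       eps_prime_value * x)
    return out if out.ndim else float(out)


def load_contact_energies(path: str | Path | None = None) -> np.ndarray:
    """Read a whitespace-delimited 20x20 contact-energy table.

    The file carries a header row and column of 1-letter amino-acid codes;
    any row/column order covering the 20 canonical residues is accepted and
    the matrix is returned in ``AMINO_ACIDS`` order.
    """
    if path is None:
        ref = resources.files("epifold") / "data" / "mj_contact_energies.tsv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split()
    if len(header) != 20 or sorted(header) != sorted(AMINO_ACIDS):
        raise FormatError("header must list the 20 canonical amino acids")
    raw = np.full((20, 20), np.nan)
    seen = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != 21:
            raise FormatError(f"expected 21 fields per row, got {len(parts)}")
        aa = parts[0]
        if aa not in AA_INDEX:
            raise FormatError(f"unknown amino-acid code {aa!r}")
        seen.append(aa)
        i = AA_INDEX[aa]
        for col, val in zip(header, parts[1:]):
            raw[i, AA_INDEX[col]] = float(val)
    if sorted(seen) != sorted(AMINO_ACIDS):
        raise FormatError("table must contain one row per amino acid")
    return raw


def build_contact_table(raw_energies: np.ndarray,
                        params: PotentialParams = PotentialParams()
                        ) -> ContactTable:
    """Build the interaction table from raw contact energies.

    Applies the threonine-reference-solvent rescaling
    ``E'_ij = E_ij - E_iT - E_jT + E_TT``, computes the normalisation
    ``E_o = <|E'_ij|>`` over the upper triangle (diagonal included) and the
    signed strengths ``eps_prime = eps_core * E' / E_o``.
    """
    raw = np.asarray(raw_energies, dtype=float)
    if raw.shape != (20, 20):
        raise FormatError(f"contact matrix must be 20x20, got {raw.shape}")
    if not np.allclose(raw, raw.T, atol=1e-9):
        raise FormatError("contact matrix must be symmetric")
    t = AA_INDEX["T"]
    rescaled = raw - raw[:, [t]] - raw[[t], :] + raw[t, t]
    iu = np.triu_indices(20)
    E_o = float(np.mean(np.abs(rescaled[iu])))
    if E_o <= 0:
        raise DegenerateTableError("rescaled contact table is identically zero")
    eps_prime = params.eps_core * rescaled / E_o
    return ContactTable(E=rescaled, E_o=E_o, eps_prime=eps_prime)


def default_contact_table(params: PotentialParams = PotentialParams()
                          ) -> ContactTable:
    """The bundled threonine-rescaled Miyazawa-Jernigan table."""
    return build_contact_table(load_contact_energies(), params)


def sequence_to_indices(seq: str) -> np.ndarray:
    """Map a 1-letter sequence to integer residue indices."""
    try:
        return np.array([AA_INDEX[aa] for aa in seq], dtype=np.int64)
    except KeyError as exc:
        raise InvalidInputError(f"unknown amino-acid code {exc.args[0]!r}")


def pair_strength_matrix(seq: str, table: ContactTable) -> np.ndarray:
    """Per-pair eps_prime matrix for a sequence (n_res x n_res)."""
    idx = sequence_to_indices(seq)
    return table.eps_prime[np.ix_(idx, idx)]


def total_energy(conf: np.ndarray, seq: str, table: ContactTable,
                 params: PotentialParams = PotentialParams()) -> float:
    """Potential energy of a conformation: bonds plus all |i-j| >= 2 pairs."""
    conf = np.asarray(conf, dtype=float)
    if conf.ndim != 2 or conf.shape[1] != 3:
        raise InvalidInputError("conformation must be an (n, 3) array")
    n = conf.shape[0]
    if n != len(seq):
        raise InvalidInputError("conformation and sequence lengths differ")
    if n < 2:
        raise InvalidInputError("need at least 2 monomers")
    bond_r = np.linalg.norm(np.diff(conf, axis=0), axis=1)
    energy = float(np.sum(bond_energy(bond_r, params)))
    epsp = pair_strength_matrix(seq, table)
    for i in range(n - 2):
        d = np.linalg.norm(conf[i + 2:] - conf[i], axis=1)
        for k, r in enumerate(d):
            energy += nonbonded_energy(float(r), float(epsp[i, i + 2 + k]),
                                       params)
    return energy
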