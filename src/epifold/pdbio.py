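"""Multi-model PDB persistence for replica ensembles.

Ensembles are stored as CA-only multi-model PDB files: one MODEL per
conformation, residues named by the sequence, 1-based numbering, a single
chain. On write, the reference fold x* is MODEL 1 and the remaining models
are sorted by decreasing alignment quality to x*. A docked ligand can be
appended as a HETATM record in its own chain. A YAML sidecar
(``<path>.meta.yaml``) carries the sequence, per-replica seeds and the
folding schedule so a written ensemble round-trips losslessly.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb
import yaml

from .docking import Pose
from .errors import FormatError
from .folding import FoldingSchedule, ReplicaEnsemble
from .structure import ReferenceFold, align

__all__ = ["read_ensemble", "write_ensemble", "write_pose"]

_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}
_ONE = {v: k for k, v in _THREE.items()}


def _template(sequence: str) -> struc.AtomArray:
    n = len(sequence)
    arr = struc.AtomArray(n)
    arr.chain_id = np.full(n, "A")
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.array([_THREE[aa] for aa in sequence])
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def _validate_pdb_text(path: Path) -> None:
    """Pre-parse check so format errors can cite line numbers."""
    counts: list[int] = []
    current = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            current = 0
        elif rec == "ENDMDL":
            counts.append(current or 0)
            current = None
        elif rec == "ATOM":
            if line[12:16].strip() != "CA":
                raise FormatError(
                    f"line {lineno}: expected CA-only records, got "
                    f"{line[12:16].strip()!r}")
            if current is None:
                current = 0
            current += 1
    if current:
        counts.append(current)
    if not counts:
        raise FormatError("no ATOM records found")
    if len(set(counts)) != 1:
        raise FormatError(f"models have inconsistent atom counts: {counts}")


def write_ensemble(ens: ReplicaEnsemble, ref: ReferenceFold | None,
                   path: str | Path) -> None:
    """Write an ensemble as multi-model CA-only PDB plus a YAML sidecar.

    With a reference fold, x* is the first model and members follow in
    order of decreasing alignment quality (increasing core RMS to x*);
    without one, members are written in replica order.
    """
    path = Path(path)
    if ref is not None:
        order = np.argsort([align(m, ref.x_star).rms_matched
                            for m in ens.members], kind="stable")
        models = [np.asarray(ref.x_star, float)]
        models += [np.asarray(ens.members[i], float) for i in order]
        member_order = [int(i) for i in order]
    else:
        models = [np.asarray(m, float) for m in ens.members]
        member_order = list(range(len(ens.members)))
    stack = struc.stack([_template(ens.sequence)] * len(models))
    stack.coord = np.asarray(models)
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))
    meta = {
        "sequence": ens.sequence,
        "seeds": [int(s) for s in ens.seeds],
        "failed": [int(s) for s in ens.failed],
        "member_order": member_order,
        "has_reference_model": ref is not None,
        "schedule": asdict(ens.schedule) if ens.schedule else None,
    }
    Path(str(path) + ".meta.yaml").write_text(yaml.safe_dump(meta))


def read_ensemble(path: str | Path) -> tuple[ReplicaEnsemble, np.ndarray | None]:
    """Read a multi-model CA-only PDB written by :func:`write_ensemble`.

    Returns (ensemble, x_star) where x_star is the first model when the
    sidecar marks it as a reference fold, else None. Coordinates round-trip
    at PDB precision (0.001 A).
    """
    path = Path(path)
    _validate_pdb_text(path)
    f = pdb.PDBFile.read(str(path))
    stack = pdb.get_structure(f)
    arr0 = stack[0]
    ca = arr0.atom_name == "CA"
    try:
        sequence = "".join(_ONE[rn] for rn in arr0.res_name[ca])
    except KeyError as exc:
        raise FormatError(f"unknown residue name {exc.args[0]!r}")
    coords = [np.asarray(stack[i].coord[ca], float)
              for i in range(stack.stack_depth())]
    meta_path = Path(str(path) + ".meta.yaml")
    schedule, seeds, failed, x_star = None, None, [], None
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text())
        if meta.get("schedule"):
            schedule = FoldingSchedule(**meta["schedule"])
        seeds = meta.get("seeds")
        failed = meta.get("failed", [])
        if meta.get("has_reference_model"):
            x_star = coords[0]
            coords = coords[1:]
    if seeds is None:
        seeds = list(range(len(coords)))
    ens = ReplicaEnsemble(members=coords, seeds=seeds, schedule=schedule,
                          sequence=sequence, failed=failed)
    return ens, x_star


def write_pose(conf: np.ndarray, sequence: str, pose: Pose,
               path: str | Path) -> None:
    """Write a conformation with its docked ligand (HETATM, chain L)."""
    n = len(sequence)
    arr = struc.AtomArray(n + 1)
    arr.chain_id = np.array(["A"] * n + ["L"])
    arr.res_id = np.append(np.arange(1, n + 1), 1)
    arr.res_name = np.array([_THREE[aa] for aa in sequence] + ["LIG"])
    arr.atom_name = np.array(["CA"] * n + ["C1"])
    arr.element = np.full(n + 1, "C")
    arr.hetero = np.array([False] * n + [True])
    arr.coord = np.vstack([np.asarray(conf, float),
                           np.asarray(pose.ligand_position, float)])
    f = pdb.PDBFile()
    f.set_structure(arr)
    f.write(str(Path(path)))
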