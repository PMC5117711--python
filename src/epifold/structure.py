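"""Ensemble alignment, reference-fold selection and order profiling.

The folded ensemble of a sequence is summarised by a reference structure
``x*`` (one of the ensemble members) together with the subset of the
floor(3N/4) members closest to it after structural alignment — the dominant
energy basin. Alignment is an iterative core superposition: structures are
superposed by least squares (improper rotations allowed, so mirror folds
match their enantiomers), the floor(2n/3) closest index pairs are
re-selected, and the procedure repeats until the matched set stabilises.

Order is measured Lindemann-style: a monomer is *ordered* when its
root-mean-square fluctuation about ``x*`` across the basin members is below
a set fraction of the bond length. A sequence is viable when the ordered
nucleus has at least 15 monomers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import AlignmentDegenerateError, InvalidInputError
from .folding import ReplicaEnsemble

__all__ = ["AlignmentResult", "ReferenceFold", "align", "superpose",
           "select_reference", "order_profile", "MIN_ORDERED_VIABLE"]

#: minimum ordered-nucleus size for a viable sequence
MIN_ORDERED_VIABLE = 15

_MAX_ALIGN_ITER = 50


@dataclass(frozen=True)
class AlignmentResult:
    """Rigid (possibly improper) transform of mobile onto target."""

    rotation: np.ndarray       # 3x3 orthogonal, det +-1
    translation: np.ndarray    # 3-vector, Angstroms
    matched: np.ndarray        # indices of the closest matched pairs
    rms_matched: float         # RMS distance over matched pairs (A)
    rms_all: float             # RMS distance over all pairs (A)

    def apply(self, conf: np.ndarray) -> np.ndarray:
        return conf @ self.rotation.T + self.translation


@dataclass(frozen=True)
class ReferenceFold:
    """Reference structure x*, basin subset and per-monomer order."""

    x_star: np.ndarray
    member_ids: np.ndarray
    aligned_members: np.ndarray        # (n_members, n_res, 3), aligned to x*
    score: float                       # mean rms_matched over the subset
    rmsf: np.ndarray | None = None
    ordered_mask: np.ndarray | None = None
    lindemann_c: float | None = None

    @property
    def n_ordered(self) -> int:
        if self.ordered_mask is None:
            raise InvalidInputError("order profile not computed")
        return int(np.sum(self.ordered_mask))

    def is_viable(self, min_ordered: int = MIN_ORDERED_VIABLE) -> bool:
        return self.n_ordered >= min_ordered


def superpose(mobile: np.ndarray, target: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares superposition transform over the full orthogonal group.

    Returns (rotation, translation) minimising ||R m + t - target|| with
    R allowed to be improper (reflections permitted). Raises when the mobile
    points are collinear (the in-plane orientation is then undetermined).
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, s, vt = np.linalg.svd(h)
    # two (near-)zero singular values: points essentially collinear
    if s[0] > 0 and s[1] <= 1e-9 * s[0]:
        raise AlignmentDegenerateError("point set is collinear")
    rot = vt.T @ u.T
    return rot, tc - rot @ mc


def align(mobile: np.ndarray, target: np.ndarray,
          match_fraction: float = 2.0 / 3.0) -> AlignmentResult:
    """Iterative-core structural alignment of two equal-length chains.

    Superposes on the current matched index set, re-selects the
    floor(match_fraction * n) index pairs with smallest post-transform
    distance, and repeats until the matched set recurs (max 50 iterations,
    oscillations broken by keeping the lowest-RMS iterate).
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[0] < 3:
        raise InvalidInputError("need two equal-length chains of >= 3 points")
    n = mobile.shape[0]
    k = max(3, int(np.floor(match_fraction * n)))
    matched = np.arange(n)
    best = None
    seen = set()
    for _ in range(_MAX_ALIGN_ITER):
        rot, trans = superpose(mobile[matched], target[matched])
        moved = mobile @ rot.T + trans
        d = np.linalg.norm(moved - target, axis=1)
        new_matched = np.sort(np.argsort(d, kind="stable")[:k])
        res = AlignmentResult(
            rotation=rot, translation=trans, matched=new_matched,
            rms_matched=float(np.sqrt(np.mean(d[new_matched] ** 2))),
            rms_all=float(np.sqrt(np.mean(d ** 2))))
        if best is None or res.rms_matched < best.rms_matched:
            best = res
        key = new_matched.tobytes()
        if key in seen:
            break
        seen.add(key)
        matched = new_matched
    return best


def select_reference(ens: ReplicaEnsemble | list,
                     subset_fraction: float = 0.75) -> ReferenceFold:
    """Pick x* and the basin subset minimising the mean aligned distance.

    Every ensemble member is tried as the candidate reference; all members
    are aligned to it, the floor(subset_fraction * N) members with smallest
    core RMS are kept, and the candidate with the smallest mean core RMS
    wins (ties to the lowest member index).
    """
    members = ens.members if isinstance(ens, ReplicaEnsemble) else list(ens)
    n_mem = len(members)
    if n_mem == 0:
        raise InvalidInputError("empty ensemble")
    k = int(np.floor(subset_fraction * n_mem))
    if k < 1:
        raise InvalidInputError("fewer members than subset size")
    best = None
    for cand_idx, cand in enumerate(members):
        results = [align(m, cand) for m in members]
        rms = np.array([r.rms_matched for r in results])
        order = np.argsort(rms, kind="stable")[:k]
        score = float(np.mean(rms[order]))
        if best is None or score < best[0]:
            subset = np.sort(order)
            aligned = np.stack([results[i].apply(members[i]) for i in subset])
            best = (score, cand_idx, subset, aligned)
    score, cand_idx, subset, aligned = best
    return ReferenceFold(x_star=np.asarray(members[cand_idx], float),
                         member_ids=subset, aligned_members=aligned,
                         score=score)


def order_profile(ref: ReferenceFold, lindemann_c: float = 0.25,
                  bond_length: float = 3.8) -> ReferenceFold:
    """Per-monomer RMSF about x* and the Lindemann ordered mask.

    ``rmsf_j = sqrt(mean_mu |x_j^mu - x_j*|^2)`` over the aligned basin
    members; monomer j is ordered when ``rmsf_j < lindemann_c * bond_length``.
    """
    dev = ref.aligned_members - ref.x_star[None, :, :]
    rmsf = np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))
    mask = rmsf < lindemann_c * bond_length
    return replace(ref, rmsf=rmsf, ordered_mask=mask, lindemann_c=lindemann_c)
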