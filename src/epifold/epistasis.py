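"""Pair-mutation scanning and the epistasis statistic.

For a pair of mutations, fitness changes are measured relative to the
un-mutated sequence, ``dP_nu = P_nu - P_0``, and epistasis is the deviation
of the double mutant from additivity:

    epsilon = dP12 - dP1 - dP2

Positive epsilon means the double mutant is less deleterious than the sum
of the single mutants; negative means more. Records carry the inter-site
distance R measured in the reference fold of the un-mutated sequence;
residues interact directly when R < 1.5 * l (5.7 A at the default bond
length), so records beyond that range are long-range epistasis.

Because each P is a finite-replica fraction, a single measurement carries
an error dP; treating the three measurements as independent propagates to
sqrt(2)*dP on dP1 + dP2 and sqrt(3)*dP on epsilon (a literal linear mode,
2*dP and 3*dP, is selectable). The lambda-filter keeps pairs whose double
mutant — or both singles — are no more deleterious than a cutoff lambda,
i.e. mutants with a chance of fixing in evolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, SummaryError
from .fitness import (ExchangeMatrix, MutationSpec, apply_mutation, fitness,
                      genetic_code_exchange_matrix, propose_mutation)

log = logging.getLogger(__name__)

__all__ = ["EpistasisRecord", "ErrorModel", "DistributionSummary", "epsilon",
           "pair_scan", "lambda_filter", "site_distance", "summarize",
           "records_to_frame", "frame_to_records"]

#: contact threshold in units of the bond length
CONTACT_FACTOR = 1.5


def epsilon(dP12: float, dP1: float, dP2: float) -> float:
    """Epistasis of a mutation pair: dP12 - dP1 - dP2."""
    for v in (dP12, dP1, dP2):
        if not -1.0 <= v <= 1.0:
            raise InvalidInputError("fitness changes must lie in [-1, 1]")
    return dP12 - dP1 - dP2


@dataclass(frozen=True)
class EpistasisRecord:
    """One sampled pair mutation and its fitness changes."""

    sites: tuple
    mutations: tuple
    dP1: float
    dP2: float
    dP12: float
    R: float

    def __post_init__(self):
        i, j = self.sites
        if i == j:
            raise InvalidInputError("sites must differ")
        if self.R < 0:
            raise InvalidInputError("distance must be non-negative")

    @property
    def eps(self) -> float:
        return self.dP12 - self.dP1 - self.dP2


@dataclass(frozen=True)
class ErrorModel:
    """Propagated measurement errors for the epistasis statistic.

    ``mode='quadrature'`` (independent errors): dSum = sqrt(2)*dP,
    dEps = sqrt(3)*dP. ``mode='linear'``: 2*dP and 3*dP.
    """

    dP: float
    mode: str = "quadrature"
    sig_mult: float = 3.0

    def __post_init__(self):
        if self.mode not in ("quadrature", "linear"):
            raise InvalidInputError("mode must be 'quadrature' or 'linear'")
        if self.dP < 0:
            raise InvalidInputError("dP must be non-negative")

    @property
    def dSum(self) -> float:
        return float((np.sqrt(2.0) if self.mode == "quadrature" else 2.0)
                     * self.dP)

    @property
    def dEps(self) -> float:
        return float((np.sqrt(3.0) if self.mode == "quadrature" else 3.0)
                     * self.dP)


@dataclass(frozen=True)
class DistributionSummary:
    """Gaussian-fit summary of a filtered epsilon (or P) distribution."""

    values: np.ndarray
    sigma: float
    mean: float
    n: int
    lam: float
    significant_fraction: float | None = None


def site_distance(ref, i: int, j: int,
                  bond_length: float = 3.8) -> tuple[float, bool]:
    """Distance between two monomers in the reference fold x*.

    Returns (R, in_contact) with in_contact = (R < 1.5 * bond_length),
    strict inequality.
    """
    x = ref.x_star if hasattr(ref, "x_star") else np.asarray(ref, float)
    n = x.shape[0]
    if i == j:
        raise InvalidInputError("sites must differ")
    if not (0 <= i < n and 0 <= j < n):
        raise InvalidInputError("site outside chain")
    r = float(np.linalg.norm(x[i] - x[j]))
    return r, r < CONTACT_FACTOR * bond_length


def _uniform_pair_sampler(rng: np.random.Generator, n_res: int) -> tuple:
    i, j = rng.choice(n_res, size=2, replace=False)
    return (int(min(i, j)), int(max(i, j)))


def pair_scan(seq: str, n_pairs: int, fitness_protocol, ref,
              base_seed: int,
              xmat: ExchangeMatrix | None = None,
              site_sampler=None,
              p0: float | None = None) -> list[EpistasisRecord]:
    """Scan random pair mutations and record their epistasis.

    For each sampled site pair a substitution is proposed at each site; the
    two single mutants and the double mutant are measured under
    ``fitness_protocol`` and the record stores the fitness changes, the
    epistasis and the inter-site distance R in the reference fold of the
    un-mutated sequence. ``p0`` may supply a pre-measured base fitness.
    Per-record failures are logged and skipped.
    """
    if n_pairs < 0:
        raise InvalidInputError("n_pairs must be >= 0")
    xmat = xmat if xmat is not None else genetic_code_exchange_matrix()
    sampler = site_sampler if site_sampler is not None else _uniform_pair_sampler
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, 0x5CA7]))
    if p0 is None:
        p0 = fitness(seq, fitness_protocol, base_seed).P
    records = []
    n_failed = 0
    for k in range(n_pairs):
        try:
            i, j = sampler(rng, len(seq))
            m1 = propose_mutation(seq, i, xmat, rng)
            m2 = propose_mutation(seq, j, xmat, rng)
            seed_k = base_seed + 1 + 3 * k
            p1 = fitness(apply_mutation(seq, m1), fitness_protocol, seed_k).P
            p2 = fitness(apply_mutation(seq, m2), fitness_protocol,
                         seed_k + 1).P
            p12 = fitness(apply_mutation(seq, m1, m2), fitness_protocol,
                          seed_k + 2).P
            r, _ = site_distance(ref, i, j)
            records.append(EpistasisRecord(
                sites=(i, j), mutations=(m1, m2),
                dP1=p1 - p0, dP2=p2 - p0, dP12=p12 - p0, R=r))
        except Exception as exc:  # per-record failure policy
            n_failed += 1
            log.warning("pair %d skipped: %s", k, exc)
    if n_failed:
        log.warning("%d of %d pair records failed and were skipped",
                    n_failed, n_pairs)
    return records


def lambda_filter(records, lam: float = -0.2):
    """Keep records with dP12 >= lam, or dP1 >= lam and dP2 >= lam."""
    return [r for r in records
            if r.dP12 >= lam or (r.dP1 >= lam and r.dP2 >= lam)]


def summarize(records, lam: float = -0.2,
              error_model: ErrorModel | None = None) -> DistributionSummary:
    """Gaussian-fit width of the filtered epsilon distribution.

    Also reports the fraction of filtered records whose |epsilon| exceeds
    ``sig_mult * dEps`` when an error model is given.
    """
    kept = lambda_filter(records, lam)
    if len(kept) < 2:
        raise SummaryError("need at least 2 filtered records")
    eps = np.array([r.eps for r in kept])
    mean, sigma = stats.norm.fit(eps)
    sig_frac = None
    if error_model is not None:
        thresh = error_model.sig_mult * error_model.dEps
        sig_frac = float(np.mean(np.abs(eps) > thresh))
    return DistributionSummary(values=eps, sigma=float(sigma),
                               mean=float(mean), n=len(kept), lam=lam,
                               significant_fraction=sig_frac)


def records_to_frame(records) -> pd.DataFrame:
    """Records as a flat table (one row per pair), ready for TSV export."""
    rows = []
    for r in records:
        m1, m2 = r.mutations
        rows.append({
            "site1": r.sites[0], "site2": r.sites[1],
            "mut1": f"{m1.from_aa}{m1.site + 1}{m1.to_aa}",
            "mut2": f"{m2.from_aa}{m2.site + 1}{m2.to_aa}",
            "dP1": r.dP1, "dP2": r.dP2, "dP12": r.dP12,
            "eps": r.eps, "R": r.R,
            "in_contact": r.R < CONTACT_FACTOR * 3.8,
        })
    cols = ["site1", "site2", "mut1", "mut2", "dP1", "dP2", "dP12",
            "eps", "R", "in_contact"]
    return pd.DataFrame(rows, columns=cols)


def frame_to_records(df: pd.DataFrame) -> list[EpistasisRecord]:
    """Rebuild records from a table written by :func:`records_to_frame`."""
    out = []
    for _, row in df.iterrows():
        def parse(tag):
            return MutationSpec(site=int(tag[1:-1]) - 1, from_aa=tag[0],
                                to_aa=tag[-1])
        out.append(EpistasisRecord(
            sites=(int(row.site1), int(row.site2)),
            mutations=(parse(row.mut1), parse(row.mut2)),
            dP1=float(row.dP1), dP2=float(row.dP2), dP12=float(row.dP12),
            R=float(row.R)))
    return out
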