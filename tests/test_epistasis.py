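"""The epistasis statistic, filters, distances and summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from epifold.epistasis import (EpistasisRecord, ErrorModel, epsilon,
                               frame_to_records, lambda_filter, pair_scan,
                               records_to_frame, site_distance, summarize)
from epifold.errors import InvalidInputError, SummaryError
from epifold.fitness import MutationSpec
from epifold.fixtures import PlantedEpistasisProtocol, make_fixture


def _record(dP1, dP2, dP12, sites=(0, 5), R=8.0):
    m1 = MutationSpec(site=sites[0], from_aa="A", to_aa="G")
    m2 = MutationSpec(site=sites[1], from_aa="L", to_aa="V")
    return EpistasisRecord(sites=sites, mutations=(m1, m2), dP1=dP1,
                           dP2=dP2, dP12=dP12, R=R)


class TestEpsilon:
    @pytest.mark.parametrize("dP12, dP1, dP2, expected", [
        (-0.13, -0.61, -0.29, 0.77),
        (-0.04, 0.0, -0.24, 0.2),
        (-0.47, -0.17, 0.02, -0.32),
        (-0.22, -0.11, 0.0, -0.11),
        (-0.43, -0.07, -0.10, -0.26),
    ])
    def test_worked_examples(self, dP12, dP1, dP2, expected):
        assert epsilon(dP12, dP1, dP2) == pytest.approx(expected, abs=1e-9)

    def test_additive_mutations_have_no_epistasis(self):
        assert epsilon(-0.5, -0.2, -0.3) == pytest.approx(0.0)

    @given(st.floats(-0.5, 0.5), st.floats(-0.5, 0.5), st.floats(-0.5, 0.5))
    def test_symmetric_under_mutation_relabelling(self, d12, d1, d2):
        # subtraction order differs, so allow one ulp-scale rounding step
        assert epsilon(d12, d1, d2) == pytest.approx(epsilon(d12, d2, d1),
                                                     abs=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            epsilon(1.5, 0.0, 0.0)

    def test_record_identity_is_exact(self):
        r = _record(-0.61, -0.29, -0.13)
        assert r.eps == r.dP12 - r.dP1 - r.dP2


class TestLambdaFilter:
    def test_permissive_cutoff_keeps_everything(self):
        recs = [_record(-0.9, -0.9, -0.9), _record(0.0, 0.0, 0.0)]
        assert len(lambda_filter(recs, lam=-1.0)) == 2

    def test_uniformly_deleterious_record_excluded(self):
        assert lambda_filter([_record(-0.5, -0.5, -0.5)], lam=-0.2) == []

    def test_double_mutant_branch_keeps_record(self):
        # both singles below lambda but the double above it
        recs = lambda_filter([_record(-0.61, -0.29, -0.13)], lam=-0.2)
        assert len(recs) == 1

    @given(st.lists(st.tuples(st.floats(-1, 1), st.floats(-1, 1),
                              st.floats(-1, 1)), max_size=30),
           st.floats(-1, 0.5), st.floats(-1, 0.5))
    def test_monotone_in_lambda(self, triples, lam_a, lam_b):
        lo, hi = min(lam_a, lam_b), max(lam_a, lam_b)
        recs = [_record(*t) for t in triples]
        kept_hi = {id(r) for r in lambda_filter(recs, hi)}
        kept_lo = {id(r) for r in lambda_filter(recs, lo)}
        assert kept_hi <= kept_lo


class TestSiteDistance:
    def test_bonded_neighbours_in_contact(self, params, rng):
        from epifold.folding import random_coil
        x = random_coil(10, params, rng)
        r, contact = site_distance(x, 3, 4)
        assert r == pytest.approx(params.l, abs=1e-9)
        assert contact

    def test_contact_threshold_is_strict(self):
        x = np.array([[0.0, 0, 0], [5.7, 0, 0], [11.4, 0, 0]])
        r, contact = site_distance(x, 0, 1)
        assert r == pytest.approx(5.7)
        assert not contact  # boundary excluded

    def test_same_site_rejected(self):
        with pytest.raises(InvalidInputError):
            site_distance(np.zeros((4, 3)), 2, 2)

    def test_matches_coordinate_arithmetic(self, rng):
        x = rng.normal(size=(8, 3))
        r, _ = site_distance(x, 1, 6)
        assert r == pytest.approx(np.sqrt(np.sum((x[1] - x[6]) ** 2)))


class AdditiveProtocol:
    """Mock fitness: independent per-site penalties, hence zero epistasis."""

    def __init__(self, wildtype, n=100):
        self.wt, self.n = wildtype, n

    def replica_activity(self, seq, base_seed):
        n_mut = sum(a != b for a, b in zip(seq, self.wt))
        n_active = max(0, self.n - 10 * n_mut)
        flags = np.zeros(self.n, dtype=bool)
        flags[:n_active] = True
        return flags


class TestPairScan:
    def test_zero_pairs_gives_empty_list(self, rng):
        ref = np.zeros((12, 3))
        out = pair_scan("AWDKTGELVRIS", 0, AdditiveProtocol("AWDKTGELVRIS"),
                        np.arange(36.0).reshape(12, 3), base_seed=1)
        assert out == []

    def test_additive_fitness_has_zero_epistasis(self):
        seq = "AWDKTGELVRIS"
        ref = np.arange(36.0).reshape(12, 3)
        recs = pair_scan(seq, 12, AdditiveProtocol(seq), ref, base_seed=2)
        assert len(recs) == 12
        assert all(r.eps == pytest.approx(0.0, abs=1e-12) for r in recs)

    def test_planted_epistasis_recovered(self):
        fx = make_fixture("planted-epistasis", 7)
        proto = PlantedEpistasisProtocol(fx.sequence, fx.planted_pair,
                                         fx.n_replicas)
        ref = np.arange(len(fx.sequence) * 3.0).reshape(-1, 3)
        recs = pair_scan(fx.sequence, 1, proto, ref, base_seed=3,
                         site_sampler=lambda rng, n: fx.planted_pair)
        assert len(recs) == 1
        assert recs[0].eps > 0.2
        assert recs[0].dP1 == recs[0].dP2 == 0.0


class TestErrorModel:
    def test_quadrature_factors(self):
        em = ErrorModel(dP=0.037)
        assert em.dSum == pytest.approx(np.sqrt(2) * 0.037)
        assert em.dEps == pytest.approx(np.sqrt(3) * 0.037)

    def test_linear_mode(self):
        em = ErrorModel(dP=0.037, mode="linear")
        assert em.dSum == pytest.approx(2 * 0.037)
        assert em.dEps == pytest.approx(3 * 0.037)

    def test_monte_carlo_propagation_matches_quadrature(self, rng):
        # independent binomial errors on P0, P1, P2, P12 propagated through
        # the statistic: eps involves P12 - P1 - P2 + P0... with dP per
        # measurement the quadrature estimate sqrt(3)*dP applies to the
        # three mutant measurements (P0 averaged to negligible error)
        dP = 0.037
        n_mc = 200_000
        p1 = rng.normal(0.6, dP, n_mc)
        p2 = rng.normal(0.7, dP, n_mc)
        p12 = rng.normal(0.5, dP, n_mc)
        eps_draws = (p12 - 0.8) - (p1 - 0.8) - (p2 - 0.8)
        em = ErrorModel(dP=dP)
        assert np.std(eps_draws) == pytest.approx(em.dEps, rel=0.02)


class TestSummarize:
    def test_gaussian_width_recovered(self, rng):
        recs = [_record(0.0, 0.0, float(np.clip(e, -1, 1)))
                for e in rng.normal(0.0, 0.14, 1500)]
        s = summarize(recs, lam=-0.2)
        se = 0.14 / np.sqrt(2 * (s.n - 1))
        assert abs(s.sigma - 0.14) < 4 * se

    def test_zero_epistasis_zero_width(self):
        recs = [_record(0.0, 0.0, 0.0) for _ in range(10)]
        s = summarize(recs, lam=-0.2, error_model=ErrorModel(dP=0.037))
        assert s.sigma == 0.0
        assert s.significant_fraction == 0.0

    def test_width_defined_for_any_feasible_lambda(self, rng):
        recs = [_record(*np.clip(rng.normal(0, 0.2, 3), -1, 1))
                for _ in range(200)]
        for lam in (-1.0, -0.5, -0.2, -0.05):
            s = summarize(recs, lam=lam)
            assert np.isfinite(s.sigma)

    def test_too_few_records_raise(self):
        with pytest.raises(SummaryError):
            summarize([_record(0, 0, 0)], lam=-0.2)


def test_record_table_round_trip(rng):
    recs = [_record(-0.2, 0.1, -0.3), _record(0.0, 0.0, 0.5, sites=(1, 7))]
    df = records_to_frame(recs)
    back = frame_to_records(df)
    for a, b in zip(recs, back):
        assert a.sites == b.sites
        assert a.eps == pytest.approx(b.eps)
        assert a.R == pytest.approx(b.R)
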