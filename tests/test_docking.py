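"""Shell-sweep docking and the binding-site activity test."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from epifold.docking import (BindingSite, Pose, TargetState,
                             complex_distances, dock, is_active, make_target,
                             sphere_points)
from epifold.energetics import PotentialParams
from epifold.errors import (CannotBuildTargetError, InvalidInputError,
                            InvalidTargetError)


def _ligand_energy(point, conf, site_idx, params):
    """Independent scalar oracle for the docking energy at one point."""
    e = 0.0
    site = set(site_idx)
    for i, mono in enumerate(conf):
        r = np.linalg.norm(point - mono)
        x = np.exp(-params.alpha * (r - params.l))
        if i in site:
            e += x * x - 2.0 * x
        elif r <= params.l:
            e += (1.0 - x) ** 2
    return e


class TestSpherePoints:
    def test_counts_and_unit_norm(self):
        pts = sphere_points(500)
        assert pts.shape == (500, 3)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_centroid_near_origin(self):
        pts = sphere_points(10_000)
        assert np.linalg.norm(pts.mean(axis=0)) < 0.01

    def test_nearest_neighbour_spacing_uniform(self):
        n = 10_000
        pts = sphere_points(n)
        d, _ = cKDTree(pts).query(pts, k=2)
        nn = d[:, 1]
        ideal = np.sqrt(4 * np.pi / n)
        assert nn.min() > ideal / 2
        assert nn.max() < ideal * 2

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidInputError):
            sphere_points(3)


class TestDock:
    def test_matches_pointwise_oracle(self, docking_toy, params):
        # the returned energy equals the independent oracle evaluated at
        # the returned position, and is the sweep minimum
        fx = docking_toy
        pose = dock(fx.conformation, fx.site, sweep=0.5, n_shell_points=256,
                    params=params)
        oracle = _ligand_energy(pose.ligand_position, fx.conformation,
                                fx.site.site_indices, params)
        assert pose.energy == pytest.approx(oracle, abs=1e-9)

    def test_minimum_over_sampled_shell_points(self, docking_toy, params):
        fx = docking_toy
        pose = dock(fx.conformation, fx.site, sweep=0.5, n_shell_points=256,
                    params=params)
        center = fx.conformation.mean(axis=0)
        rads = np.linalg.norm(fx.conformation - center, axis=1)
        unit = sphere_points(256)
        for r in np.arange(rads.max() + 2 * params.l, rads.min(), -0.5):
            es = [_ligand_energy(center + r * u, fx.conformation,
                                 fx.site.site_indices, params) for u in unit]
            assert pose.energy <= min(es) + 1e-9

    def test_isolated_site_monomer_binds_at_bond_length(self, params):
        # chain with one site monomer far from the rest: the ligand must
        # sit at the Morse minimum distance from it
        conf = np.vstack([np.outer(np.arange(5.0), [3.8, 0, 0]),
                          [[40.0, 0.0, 0.0]]])
        pose = dock(conf, BindingSite((5,)), sweep=0.1,
                    n_shell_points=20_000, params=params)
        d = np.linalg.norm(pose.ligand_position - conf[5])
        assert d == pytest.approx(params.l, abs=0.15)

    def test_matches_exhaustive_grid_search(self, docking_toy, params):
        # brute-force dense-grid oracle over the bounding box
        fx = docking_toy
        conf = fx.conformation
        lo = conf.min(axis=0) - 1.5 * params.l
        hi = conf.max(axis=0) + 1.5 * params.l
        step = 0.35
        axes = [np.arange(a, b + step, step) for a, b in zip(lo, hi)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        d = np.linalg.norm(pts[:, None, :] - conf[None, :, :], axis=2)
        x = np.exp(-params.alpha * (d - params.l))
        mu = x * x - 2 * x
        site_mask = np.zeros(conf.shape[0], bool)
        site_mask[list(fx.site.site_indices)] = True
        e = (mu[:, site_mask].sum(axis=1)
             + np.where(d[:, ~site_mask] <= params.l,
                        (1 - x[:, ~site_mask]) ** 2, 0.0).sum(axis=1))
        e_grid = e.min()
        pose = dock(conf, fx.site, sweep=0.2, n_shell_points=10_000,
                    params=params)
        assert abs(pose.energy - e_grid) < 0.25  # grid/shell resolution
        # the site is one monomer, so the optimum is a sphere around it:
        # compare the binding distance rather than the (degenerate) position
        grid_best = pts[np.argmin(e)]
        mono = conf[fx.site.site_indices[0]]
        d_pose = np.linalg.norm(pose.ligand_position - mono)
        d_grid = np.linalg.norm(grid_best - mono)
        assert abs(d_pose - d_grid) < 0.5

    def test_energy_invariant_under_rigid_motion(self, docking_toy, params,
                                                 rng):
        fx = docking_toy
        pose = dock(fx.conformation, fx.site, sweep=0.25,
                    n_shell_points=4096, params=params)
        rot = Rotation.random(random_state=rng).as_matrix()
        moved = fx.conformation @ rot.T + np.array([5.0, -3.0, 11.0])
        pose2 = dock(moved, fx.site, sweep=0.25, n_shell_points=4096,
                     params=params)
        assert pose2.energy == pytest.approx(pose.energy, abs=0.05)

    def test_finer_sweep_never_worse(self, docking_toy, params):
        fx = docking_toy
        coarse = dock(fx.conformation, fx.site, sweep=1.0,
                      n_shell_points=1024, params=params)
        fine = dock(fx.conformation, fx.site, sweep=0.25,
                    n_shell_points=1024, params=params)
        assert fine.energy <= coarse.energy + 1e-9


class TestActivity:
    @pytest.fixture()
    def complex_setup(self, docking_toy, params):
        fx = docking_toy
        pose = dock(fx.conformation, fx.site, sweep=0.25,
                    n_shell_points=2048, params=params)
        target = TargetState(complex_distances(fx.conformation, fx.site,
                                               pose.ligand_position))
        return fx, pose, target

    def test_identical_geometry_is_active(self, complex_setup):
        fx, pose, target = complex_setup
        assert is_active(fx.conformation, fx.site, pose, target)

    def test_perturbed_pair_is_inactive(self, complex_setup):
        fx, pose, target = complex_setup
        key = next(iter(target.pair_distances))
        shifted = dict(target.pair_distances)
        shifted[key] += 1.5
        assert not is_active(fx.conformation, fx.site, pose,
                             TargetState(shifted))

    def test_boundary_deviation_is_active(self):
        # deviation of exactly 1.0 A (float-exact): tolerance is inclusive
        conf = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        site = BindingSite((0,))
        pose = Pose(ligand_position=np.array([3.0, 0.0, 0.0]), energy=-1.0,
                    shell_radius=3.0)
        on_edge = TargetState({frozenset((0, "L")): 4.0,
                               frozenset((0, 1)): 10.0,
                               frozenset((1, "L")): 7.0})
        assert is_active(conf, site, pose, on_edge)
        past_edge = TargetState({frozenset((0, "L")): 4.5,
                                 frozenset((0, 1)): 10.0,
                                 frozenset((1, "L")): 7.0})
        assert not is_active(conf, site, pose, past_edge)

    def test_missing_pair_rejected(self, complex_setup):
        fx, pose, target = complex_setup
        partial = dict(target.pair_distances)
        partial.pop(next(iter(partial)))
        with pytest.raises(InvalidTargetError):
            is_active(fx.conformation, fx.site, pose, TargetState(partial))


class TestMakeTarget:
    def _tight_ensemble(self, conf, n, scale, rng):
        class Ens:
            members = [conf + rng.normal(scale=scale, size=conf.shape)
                       for _ in range(n)]
        return Ens()

    def test_identical_replicas_reproduce_geometry(self, docking_toy,
                                                   params, rng):
        fx = docking_toy
        ens = self._tight_ensemble(fx.conformation, 4, 0.0, rng)
        pose = dock(fx.conformation, fx.site, sweep=0.25,
                    n_shell_points=2048, params=params)
        seed = TargetState(complex_distances(fx.conformation, fx.site,
                                             pose.ligand_position))
        target = make_target(ens, fx.site, seed, sweep=0.25,
                             n_shell_points=2048, params=params)
        for pair, d in target.pair_distances.items():
            assert d == pytest.approx(seed.pair_distances[pair], abs=1e-9)

    def test_fixed_point_on_tight_ensemble(self, docking_toy, params, rng):
        fx = docking_toy
        ens = self._tight_ensemble(fx.conformation, 6, 0.02, rng)
        pose = dock(fx.conformation, fx.site, sweep=0.25,
                    n_shell_points=2048, params=params)
        seed = TargetState(complex_distances(fx.conformation, fx.site,
                                             pose.ligand_position))
        t1 = make_target(ens, fx.site, seed, sweep=0.25,
                         n_shell_points=2048, params=params)
        t2 = make_target(ens, fx.site, t1, sweep=0.25,
                         n_shell_points=2048, params=params)
        for pair in t1.pair_distances:
            assert abs(t1.pair_distances[pair]
                       - t2.pair_distances[pair]) < 0.01

    def test_averages_only_active_group(self, params, rng):
        # two replica groups; the seed target admits only the first, so the
        # averaged target must reproduce that group's geometry
        conf_a = np.vstack([np.outer(np.arange(4.0), [3.8, 0, 0]),
                            [[20.0, 0.0, 0.0]]])
        conf_b = conf_a.copy()
        conf_b[4] = [60.0, 0.0, 0.0]

        class Ens:
            members = [conf_a, conf_a.copy(), conf_b]
        site = BindingSite((4,))
        pose = dock(conf_a, site, sweep=0.25, n_shell_points=2048,
                    params=params)
        seed = TargetState(complex_distances(conf_a, site,
                                             pose.ligand_position))
        target = make_target(Ens(), site, seed, sweep=0.25,
                             n_shell_points=2048, params=params)
        for pair, d in target.pair_distances.items():
            assert d == pytest.approx(seed.pair_distances[pair], abs=0.3)

    def test_no_active_replica_raises(self, docking_toy, params, rng):
        fx = docking_toy
        ens = self._tight_ensemble(fx.conformation, 3, 0.0, rng)
        bogus = TargetState({p: d + 50.0 for p, d in complex_distances(
            fx.conformation, fx.site, np.zeros(3)).items()})
        with pytest.raises(CannotBuildTargetError):
            make_target(ens, fx.site, bogus, sweep=0.5,
                        n_shell_points=512, params=params)
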