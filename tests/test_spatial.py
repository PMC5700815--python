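"""Vesicle-pool classification, shell densities and spot colocalization."""

import numpy as np
import pytest
from scipy import optimize

import ihcexo as ix
from ihcexo.spatial import Ellipsoid, SynapseScene, SpotField, default_geometry
from helpers_geometry import brute_force_surface_distance, brute_force_classify


class TestSurfaceDistance:
    def test_matches_parametric_oracle(self, rng):
        ell = Ellipsoid(center=[10.0, -20.0, 100.0], semiaxes=[110.0, 190.0, 140.0])
        pts = rng.uniform(-400, 400, size=(25, 3)) + ell.center
        fast = ell.surface_distance(pts)
        slow = np.array([brute_force_surface_distance(ell, p) for p in pts])
        assert np.allclose(fast, slow, atol=1e-3)

    def test_sphere_distance_is_radial(self, rng):
        ell = Ellipsoid(center=np.zeros(3), semiaxes=[150.0, 150.0, 150.0])
        pts = rng.normal(0, 200, size=(20, 3))
        d = ell.surface_distance(pts)
        expected = np.abs(np.linalg.norm(pts, axis=1) - 150.0)
        assert np.allclose(d, expected, rtol=1e-8, atol=1e-8)


class TestClassifyPools:
    def test_rule_examples(self):
        geo = default_geometry()
        # 30 nm above membrane, 50 nm lateral of AZ center -> RRP
        # far from ribbon (>80), 100 nm above membrane, within 350 -> OP
        ves = np.array([[50.0, 0.0, 30.0], [0.0, 380.0, 100.0]])
        scene = SynapseScene(vesicles=ves, **geo)
        labels = ix.classify_pools(scene).labels
        assert labels[0] == "RRP"
        d_rib = scene.ribbon_distance()[1]
        assert 80.0 < d_rib <= 350.0 and labels[1] == "OP"

    def test_generated_scene_counts_recovered_exactly(self):
        scene = ix.generate_scene(pool_counts=(14, 42, 33), seed=5)
        counts = ix.classify_pools(scene).counts
        assert (counts["RRP"], counts["RAP"], counts["OP"]) == (14, 42, 33)

    def test_agrees_with_brute_force_oracle(self):
        scene = ix.generate_scene(pool_counts=(20, 60, 60), seed=11)
        fast = ix.classify_pools(scene).labels
        slow = brute_force_classify(scene)
        assert np.array_equal(fast, slow)

    def test_empty_scene_allowed(self):
        scene = SynapseScene(vesicles=np.empty((0, 3)), **default_geometry())
        counts = ix.classify_pools(scene).counts
        assert counts == {"RRP": 0, "RAP": 0, "OP": 0, "none": 0}

    def test_rigid_motion_invariance(self, rng):
        scene = ix.generate_scene(pool_counts=(10, 30, 30), seed=3)
        # random rotation + translation applied to every geometric element
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        shift = np.array([500.0, -300.0, 250.0])
        moved = SynapseScene(
            vesicles=scene.vesicles @ Q.T + shift,
            ribbon=Ellipsoid(center=Q @ scene.ribbon.center + shift,
                             semiaxes=scene.ribbon.semiaxes,
                             rotation=Q @ scene.ribbon.rotation),
            az_center=Q @ scene.az_center + shift,
            membrane_point=Q @ scene.membrane_point + shift,
            membrane_normal=Q @ scene.membrane_normal,
        )
        c0 = ix.classify_pools(scene).counts
        c1 = ix.classify_pools(moved).counts
        assert c0 == c1
        d0 = ix.pool_distances(scene, ix.classify_pools(scene))
        d1 = ix.pool_distances(moved, ix.classify_pools(moved))
        assert d0 == pytest.approx(d1, rel=1e-9)


class TestPoolDistances:
    def test_uniform_rrp_distance(self):
        geo = default_geometry()
        ves = np.array([[x, 0.0, 27.8] for x in (-40.0, 0.0, 40.0)])
        scene = SynapseScene(vesicles=ves, **geo)
        assignment = ix.classify_pools(scene)
        d_rrp, _ = ix.pool_distances(scene, assignment)
        assert d_rrp == pytest.approx(27.8)

    def test_rap_distance_centered_on_target(self):
        """RAP vesicles drawn around 46.6 nm from the ribbon average back."""
        rng = np.random.default_rng(8)
        geo = default_geometry()
        rib = geo["ribbon"]
        pts = []
        while len(pts) < 60:
            p = rng.uniform(rib.center - rib.semiaxes - 80,
                            rib.center + rib.semiaxes + 80)
            if rib.contains(p[None, :])[0] or p[2] <= 40.0:
                continue
            d = rib.surface_distance(p[None, :])[0]
            target = np.clip(rng.normal(46.6, 5.0), 5.0, 79.0)
            if abs(d - target) < 8.0:
                pts.append(p)
        scene = SynapseScene(vesicles=np.array(pts), **geo)
        assignment = ix.classify_pools(scene)
        _, d_rap = ix.pool_distances(scene, assignment)
        assert d_rap == pytest.approx(46.6, abs=4.0)

    def test_single_vesicle_mean_is_its_distance(self):
        geo = default_geometry()
        scene = SynapseScene(vesicles=np.array([[0.0, 0.0, 33.0]]), **geo)
        d_rrp, d_rap = ix.pool_distances(scene, ix.classify_pools(scene))
        assert d_rrp == pytest.approx(33.0)
        assert np.isnan(d_rap)


class TestShellDensities:
    def test_spherical_shell_volume_within_3_percent(self):
        r = 150.0
        geo = {
            "ribbon": Ellipsoid(center=np.zeros(3), semiaxes=[r, r, r]),
            "az_center": np.array([0.0, 0.0, -2000.0]),
            "membrane_point": np.array([0.0, 0.0, -2000.0]),
            "membrane_normal": np.array([0.0, 0.0, 1.0]),
        }
        # a single vesicle in the shell turns density into 1/volume
        scene = SynapseScene(vesicles=np.array([[0.0, 0.0, r + 40.0]]), **geo)
        dens = ix.shell_densities(scene, [0.0, 80.0], voxel=5.0)
        analytic = 4.0 / 3.0 * np.pi * ((r + 80.0) ** 3 - r**3) * 1e-9  # µm³
        assert dens[(0.0, 80.0)] == pytest.approx(1.0 / analytic, rel=0.03)

    def test_no_vesicles_zero_density(self):
        geo = default_geometry()
        scene = SynapseScene(vesicles=np.empty((0, 3)), **geo)
        dens = ix.shell_densities(scene, [0.0, 80.0, 350.0], voxel=10.0)
        assert all(v == 0.0 for v in dens.values())

    def test_halving_scale_multiplies_density_by_8(self):
        scene = ix.generate_scene(pool_counts=(0, 20, 20), seed=2)
        dens1 = ix.shell_densities(scene, [0.0, 80.0, 350.0], voxel=5.0)
        half = SynapseScene(
            vesicles=scene.vesicles / 2.0,
            ribbon=Ellipsoid(center=scene.ribbon.center / 2.0,
                             semiaxes=scene.ribbon.semiaxes / 2.0),
            az_center=scene.az_center / 2.0,
            membrane_point=scene.membrane_point / 2.0,
            membrane_normal=scene.membrane_normal,
        )
        dens2 = ix.shell_densities(half, [0.0, 40.0, 175.0], voxel=2.5)
        for (e1, e2) in zip(dens1.values(), dens2.values()):
            assert e2 == pytest.approx(8.0 * e1, rel=0.01)


class TestColocalization:
    def test_identical_fields_have_zero_cross_distances(self):
        pts = np.random.default_rng(0).uniform(0, 1000, size=(30, 2))
        res = ix.nn_colocalization(SpotField(pts, "a"), SpotField(pts, "b"))
        assert np.all(res.d_ab == 0)

    def test_lattice_self_distance_mode_equals_pitch(self, rng):
        pitch = 285.0
        gx, gy = np.meshgrid(np.arange(10) * pitch, np.arange(10) * pitch)
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        grid = grid + rng.normal(0, 3.0, grid.shape)
        res = ix.nn_colocalization(SpotField(grid, "a"), SpotField(grid, "b"),
                                   mode_bin=30.0)
        assert res.mode_bb == pytest.approx(pitch, abs=30.0)

    def test_printed_mode_ratio(self):
        assert round(285.0 / 124.0, 1) == 2.3

    def test_ks_statistic_matches_ecdf_oracle(self, rng):
        a = rng.normal(120, 30, 200)
        b = rng.normal(280, 60, 150)
        res_scipy = ix.amplitude_cdf_compare(a, b)  # same KS routine surface
        # brute-force two-sample KS from the empirical CDFs
        grid = np.sort(np.concatenate([a, b]))
        ecdf = lambda s, x: np.searchsorted(np.sort(s), x, side="right") / s.size
        brute = np.max(np.abs(ecdf(a, grid) - ecdf(b, grid)))
        assert res_scipy[0] == pytest.approx(brute, abs=1e-12)

    def test_full_colocalization_with_tiny_jitter(self):
        a, b = ix.generate_spots(n_b=100, coloc_fraction=1.0, jitter_sd=1e-6, seed=4)
        res = ix.nn_colocalization(a, b)
        assert np.max(res.d_ab) < 1e-4

    def test_null_spots_indistinguishable(self):
        """Without colocalization, a->b and b->b distances look alike."""
        rejections = 0
        n_seeds = 40
        for seed in range(n_seeds):
            a, b = ix.generate_spots(n_b=150, coloc_fraction=0.0, jitter_sd=50.0,
                                     seed=seed)
            res = ix.nn_colocalization(a, b)
            rejections += res.p_value < 0.01
        assert rejections / n_seeds <= 0.05

    def test_too_few_spots_rejected(self):
        with pytest.raises(ValueError):
            ix.nn_colocalization(SpotField(np.zeros((1, 2)), "a"),
                                 SpotField(np.zeros((5, 2)), "b"))
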