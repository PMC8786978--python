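import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from invadosim import ecm
from invadosim.params import AdhesionParams, EcmParams, KBT

from conftest import central_gradient

BOX = (15000.0, 15000.0, 15000.0)


@pytest.fixture(scope="module")
def net():
    return ecm.generate_network(BOX, 3000.0, 41.0, seed=2)


class TestGenerator:
    def test_deterministic_under_seed(self):
        a = ecm.generate_network(BOX, 3000.0, 41.0, seed=5)
        b = ecm.generate_network(BOX, 3000.0, 41.0, seed=5)
        assert np.array_equal(a.nodes, b.nodes)
        assert np.array_equal(a.segments, b.segments)

    def test_pore_size_within_15_percent(self, net):
        assert abs(net.pore_size - 3000.0) <= 0.15 * 3000.0

    def test_connected_giant_component(self, net):
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components
        n = net.n_nodes
        adj = coo_matrix((np.ones(len(net.segments)),
                          (net.segments[:, 0], net.segments[:, 1])),
                         shape=(n, n))
        _, labels = connected_components(adj, directed=False)
        assert np.bincount(labels).max() / n >= 0.9

    def test_rejects_bad_requests(self):
        with pytest.raises(ValueError):
            ecm.generate_network(BOX, -1.0, 41.0, seed=1)
        with pytest.raises(ValueError):
            ecm.generate_network((2000.0,) * 3, 3000.0, 41.0, seed=1)

    def test_rest_lengths_positive_and_stress_free(self, net):
        assert np.all(net.rest_length > 0)
        assert np.abs(ecm.fiber_forces(net)).max() < 1e-6


class TestFiberMechanics:
    def test_single_fiber_stretch_tension(self):
        """1 % axial stretch of one element: T = (A E / L0) dL."""
        p = EcmParams()
        nodes = np.array([[0.0, 0, 0], [500.0, 0, 0]])
        net1 = ecm.EcmFiberNetwork(
            nodes=nodes, segments=np.array([[0, 1]]),
            rest_length=np.array([500.0]), fiber_id=np.array([0]),
            intact=np.array([True]), triples=np.empty((0, 3), dtype=int),
            triple_seg=np.empty((0, 2), dtype=int),
            box=np.array(BOX), params=p)
        net1.nodes[1, 0] = 505.0
        f = ecm.fiber_forces(net1)
        expect = p.area * p.youngs / 500.0 * 5.0
        assert np.linalg.norm(f[0]) == pytest.approx(expect, rel=1e-9)
        assert np.allclose(f[0], -f[1])

    def test_force_is_energy_gradient(self, net, rng):
        x = net.nodes + rng.normal(0.0, 20.0, net.nodes.shape)
        f = ecm.fiber_forces(net, x)
        sub = rng.choice(net.n_nodes, size=6, replace=False)

        def e_of(xfull):
            return ecm.fiber_energy(net, xfull)

        h = 1e-3
        for i in sub:
            for k in range(3):
                xp = x.copy(); xm = x.copy()
                xp[i, k] += h; xm[i, k] -= h
                g = -(e_of(xp) - e_of(xm)) / (2 * h)
                assert f[i, k] == pytest.approx(g, rel=1e-5, abs=1e-6)

    def test_degraded_segments_exert_nothing(self, net, rng):
        x = net.nodes + rng.normal(0.0, 20.0, net.nodes.shape)
        f_all = ecm.fiber_forces(net, x)
        saved = net.intact.copy()
        try:
            net.intact[:] = False
            assert np.abs(ecm.fiber_forces(net, x)).max() == 0.0
        finally:
            net.intact[:] = saved
        assert np.abs(f_all).max() > 0


class TestBondKinetics:
    def test_off_rate_at_rest_length(self):
        p = AdhesionParams()
        assert ecm.bond_off_rate(p.lam, p) == pytest.approx(p.k_off0)

    def test_slip_bond_monotone(self):
        p = AdhesionParams()
        ks = [ecm.bond_off_rate(L, p) for L in np.linspace(30, 60, 10)]
        assert all(b > a for a, b in zip(ks, ks[1:]))

    def test_equilibrium_matches_closed_form(self):
        p = AdhesionParams()
        fc = ecm.FocalComplex(0, 0, n_b=0.0, n_tot=p.n_tot)
        L = 33.0
        for _ in range(4000):          # 20 s of kinetics
            ecm.bond_kinetics_step(fc, L, 5e-3, p)
        k_on = ecm.bond_on_rate(L, p)
        k_off = ecm.bond_off_rate(L, p)
        expect = p.n_tot * k_on / (k_on + k_off)
        assert fc.n_b == pytest.approx(expect, rel=1e-3)

    def test_bounds_respected(self):
        p = AdhesionParams()
        fc = ecm.FocalComplex(0, 0, n_b=49.0, n_tot=50)
        for _ in range(100):
            ecm.bond_kinetics_step(fc, 30.0, 0.5, p)
            assert 0.0 <= fc.n_b <= 50.0

    def test_negative_length_faults(self):
        with pytest.raises(ValueError):
            ecm.bond_off_rate(-1.0)
        with pytest.raises(ValueError):
            ecm.bond_on_rate(-1.0)


class TestFocalComplexForce:
    def test_zero_at_rest(self):
        fc = ecm.FocalComplex(0, 0, n_b=10.0)
        f_ci, f_fib, L = ecm.focal_complex_force(
            fc, np.zeros(3), np.array([30.0, 0, 0]))
        assert np.allclose(f_ci, 0.0, atol=1e-9)

    def test_100pN_example_and_reaction(self):
        """10 bonds stretched to 40 nm at 1 pN/nm pull with 100 pN."""
        fc = ecm.FocalComplex(0, 0, n_b=10.0)
        f_ci, f_fib, _ = ecm.focal_complex_force(
            fc, np.zeros(3), np.array([40.0, 0, 0]))
        assert np.linalg.norm(f_ci) == pytest.approx(100.0, rel=1e-9)
        assert np.allclose(f_ci + f_fib, 0.0, atol=1e-12)


class TestExclusionAndDegradation:
    def test_no_interpenetration_no_force(self):
        surf = np.array([[0.0, 0, 0], [100.0, 0, 0], [0, 100.0, 0]])
        normals = np.tile([0.0, 0, 1.0], (3, 1))
        pts = np.array([[10.0, 10.0, 50.0]])
        fp, fs, n = ecm.volume_exclusion_forces(surf, normals, pts, 10.0)
        assert n == 0 and np.abs(fp).max() == 0.0

    def test_penetration_100pN_and_reaction(self):
        """A point 10 nm inside at 0.01 N/m penalty feels 100 pN."""
        surf = np.array([[0.0, 0.0, 0.0]])
        normals = np.array([[0.0, 0.0, 1.0]])
        pts = np.array([[0.0, 0.0, -10.0]])
        fp, fs, n = ecm.volume_exclusion_forces(surf, normals, pts, 10.0)
        assert n == 1
        assert fp[0, 2] == pytest.approx(100.0)
        assert np.allclose(fp[0] + fs[0], 0.0, atol=1e-12)

    def test_degradation_irreversible_and_localized(self, net):
        saved = net.intact.copy()
        try:
            mid = net.segment_midpoints()[0]

            def phi6(pts):
                d = np.linalg.norm(pts - mid, axis=1)
                return np.where(d < 800.0, 0.0, 1.0)

            gone1 = ecm.degrade_segments(net, phi6, 0.2)
            assert gone1 >= 1
            n_deg = int((~net.intact).sum())
            # re-running with pristine phi6 cannot resurrect anything
            ecm.degrade_segments(net, lambda p: np.ones(len(p)), 0.2)
            assert int((~net.intact).sum()) == n_deg
        finally:
            net.intact[:] = saved

    def test_carve_cavity_clears_cell_volume(self):
        """Fully interior segments are removed; crossing segments are
        clipped so every node ends on or outside the cavity sphere and
        the clipped elements stay stress-free."""
        n = ecm.generate_network(BOX, 3000.0, 41.0, seed=9)
        center = np.array(BOX) / 2
        rcut = 3000.0 + 50.0
        removed = ecm.carve_cavity(n, center, 3000.0)
        assert removed > 0
        d0 = np.linalg.norm(n.nodes[n.segments[:, 0]] - center, axis=1)
        d1 = np.linalg.norm(n.nodes[n.segments[:, 1]] - center, axis=1)
        assert np.all(np.minimum(d0, d1) >= rcut - 1e-6)
        assert np.abs(ecm.fiber_forces(n)).max() < 1e-6


class TestStretchTest:
    def test_bulk_modulus_scale_and_monotonicity(self):
        """The measured modulus is linear in the fibril modulus and
        increases with fiber density (smaller pores)."""
        p_soft = EcmParams(youngs=100.0)
        net1 = ecm.generate_network(BOX, 3000.0, 41.0, 3, p_soft)
        r1 = ecm.bulk_modulus_stretch_test(net1, strains=(0.01, 0.02))
        p_stiff = EcmParams(youngs=200.0)
        net2 = ecm.generate_network(BOX, 3000.0, 41.0, 3, p_stiff)
        r2 = ecm.bulk_modulus_stretch_test(net2, strains=(0.01, 0.02))
        assert r2["bulk_modulus_pa"] == pytest.approx(
            2 * r1["bulk_modulus_pa"], rel=1e-2)
        assert r1["bulk_modulus_pa"] > 0

    def test_rejects_nonpositive_strain(self, net):
        with pytest.raises(ValueError):
            ecm.bulk_modulus_stretch_test(net, strains=(0.0, 0.01))


def test_point_segment_closest():
    a, b = np.zeros(3), np.array([100.0, 0, 0])
    t, d = ecm.point_segment_closest(np.array([30.0, 40.0, 0]), a, b)
    assert t == pytest.approx(0.3)
    assert d == pytest.approx(40.0)
    t, d = ecm.point_segment_closest(np.array([-50.0, 0, 0]), a, b)
    assert t == 0.0 and d == pytest.approx(50.0)
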