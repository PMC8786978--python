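import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from invadosim import actin as act
from invadosim.params import ActinParams

from conftest import central_gradient

P = ActinParams()


def straight_filament(n=6, L0=150.0, jitter=0.0, rng=None):
    x = np.zeros((n, 3))
    x[:, 0] = np.arange(n) * L0
    if jitter and rng is not None:
        x = x + rng.normal(0.0, jitter, x.shape)
    return act.ActinFilament(fid=0, x=x, L0=np.full(n - 1, L0))


class TestSimpleLaws:
    def test_initial_stiffness_is_0_46_N_per_m(self):
        k = act.effective_segment_stiffness(150.0, P)
        assert round(k / 1e3, 2) == 0.46      # pN/nm -> N/m

    def test_cross_section_38_48(self):
        assert round(P.area, 2) == 38.48

    def test_stiffness_halves_with_doubled_length(self):
        k150 = act.effective_segment_stiffness(150.0, P)
        k300 = act.effective_segment_stiffness(300.0, P)
        assert k300 == pytest.approx(k150 / 2)
        assert round(k300 / 1e3, 3) == 0.231

    def test_growth_rate_law(self):
        assert act.load_dependent_growth_rate(0.0, 1, P) == \
            pytest.approx(50.0)
        assert act.load_dependent_growth_rate(20.0, 1, P) == \
            pytest.approx(50.0 / math.e)
        v1 = act.load_dependent_growth_rate(35.0, 1, P)
        v2 = act.load_dependent_growth_rate(35.0, 2, P)
        assert v2 > v1
        with pytest.raises(ValueError):
            act.load_dependent_growth_rate(10.0, 0, P)

    def test_capping_probability(self):
        assert act.capping_probability(0.3, 0.01) == \
            pytest.approx(1 - math.exp(-0.003))

    def test_ratchet_force_values(self):
        n = np.array([0.0, 0.0, 1.0])
        # equal speeds: log(1) = 0
        f = act.ratchet_force(n, np.array([0, 0, 50.0]), np.zeros(3),
                              True, P)
        assert np.allclose(f, 0.0)
        # v0/e: one decade of log -> F_p
        f = act.ratchet_force(n, np.array([0, 0, 50.0 / math.e]),
                              np.zeros(3), True, P)
        assert np.linalg.norm(f) == pytest.approx(20.0, rel=1e-9)
        # phase gate
        f = act.ratchet_force(n, np.zeros(3), np.zeros(3), False, P)
        assert np.allclose(f, 0.0)
        # clamp at zero relative speed
        f = act.ratchet_force(n, np.zeros(3), np.zeros(3), True, P)
        assert np.linalg.norm(f) == pytest.approx(P.f_ratchet_max)


class TestElasticForces:
    def test_straight_rest_filament_zero_force(self):
        f = straight_filament()
        forces = act.filament_elastic_forces(f.x, f.L0, P)
        assert np.abs(forces).max() < 1e-6

    def test_stretched_segment_tension_6_9_nN(self):
        """165 nm on a 150-nm rest segment at 0.46 N/m -> 6.9 nN."""
        f = straight_filament(n=2)
        f.x[1, 0] = 165.0
        forces = act.filament_elastic_forces(f.x, f.L0, P)
        assert np.linalg.norm(forces[0]) == pytest.approx(6927.2, rel=1e-3)
        assert np.allclose(forces[0], -forces[1])

    def test_matches_energy_gradient(self, rng):
        f = straight_filament(n=6, jitter=8.0, rng=rng)
        forces = act.filament_elastic_forces(f.x, f.L0, P)
        g = central_gradient(lambda x: act.filament_energy(x, f.L0, P),
                            f.x)
        assert np.abs(forces - g).max() / np.abs(g).max() < 1e-6

    def test_single_node_accessor(self, rng):
        f = straight_filament(n=5, jitter=5.0, rng=rng)
        assert np.allclose(act.filament_elastic_force(f, 2, P),
                           act.filament_elastic_forces(f.x, f.L0, P)[2])
        with pytest.raises(IndexError):
            act.filament_elastic_force(f, 9, P)


class TestBranchForces:
    def _branch_points(self, rng=None):
        p1 = np.array([0.0, 0.0, 0.0])
        p2 = np.array([150.0, 0.0, 0.0])
        d = np.array([math.cos(math.radians(62)),
                      math.sin(math.radians(62)), 0.35])
        d /= np.linalg.norm(d)
        q1 = p1 + 33.0 * np.array([0.2, 0.6, 0.77])
        q2 = q1 + 140.0 * d
        pts = [p1, p2, q1, q2]
        if rng is not None:
            pts = [p + rng.normal(0.0, 6.0, 3) for p in pts]
        return pts

    def test_equilibrium_geometry_zero(self):
        """70-degree branch at 30-nm Arp2/3 length: no restoring force
        from spring or branch angle."""
        p1 = np.zeros(3)
        p2 = np.array([150.0, 0.0, 0.0])
        perp = np.array([0.0, 0.0, 1.0])
        d = (math.cos(math.radians(70)) * np.array([1.0, 0, 0])
             + math.sin(math.radians(70)) * perp)
        q1 = p1 + 30.0 * d
        q2 = q1 + 140.0 * d
        out = act.branch_forces(p1, p2, q1, q2, P)
        for f in out[:4]:
            assert np.abs(f).max() < 1e-6

    def test_arp_spring_100pN_example(self):
        """Arp2/3 link stretched to 40 nm at 0.01 N/m -> 100 pN."""
        params = ActinParams(kappa_br_ang=0.0, kappa_br_dihed=0.0)
        p1 = np.zeros(3)
        p2 = np.array([150.0, 0.0, 0.0])
        q1 = np.array([0.0, 40.0, 0.0])
        q2 = q1 + np.array([50.0, 120.0, 0.0])
        fp1, _, fq1, _, _ = act.branch_forces(p1, p2, q1, q2, params)
        assert np.linalg.norm(fp1) == pytest.approx(100.0, rel=1e-9)
        assert np.allclose(fp1, -fq1)

    def test_matches_energy_gradient(self, rng):
        pts = self._branch_points(rng)
        out = act.branch_forces(*pts, P)
        assert not out[4]

        def e_of(flat):
            return act.branch_energy(flat[0], flat[1], flat[2],
                                     flat[3], P)

        g = central_gradient(lambda x: e_of(x), np.asarray(pts))
        f = np.asarray(out[:4])
        assert np.abs(f - g).max() / np.abs(g).max() < 1e-6

    def test_forces_sum_to_zero(self, rng):
        out = act.branch_forces(*self._branch_points(rng), P)
        assert np.allclose(np.sum(out[:4], axis=0), 0.0, atol=1e-8)

    def test_collinear_daughter_flags_degenerate(self):
        p1 = np.zeros(3)
        p2 = np.array([150.0, 0.0, 0.0])
        d = np.array([0.5, 0.7, 0.51])
        d /= np.linalg.norm(d)
        q1 = p1 + 30.0 * d
        q2 = q1 + 100.0 * d        # w parallel to v: dihedral undefined
        assert act.branch_forces(p1, p2, q1, q2, P)[4]


class TestGrowthAndTurnover:
    def test_free_growth_rates(self):
        f = straight_filament()
        act.update_rest_lengths(f, True, 1.0, params=P)
        assert f.L0[-1] == pytest.approx(170.0)
        assert f.L0[0] == pytest.approx(140.0)

    def test_capped_blocks_barbed_growth(self):
        f = straight_filament()
        f.capped = True
        act.update_rest_lengths(f, True, 1.0, params=P)
        assert f.L0[-1] == pytest.approx(150.0)
        assert f.L0[0] == pytest.approx(140.0)   # shrink continues

    def test_nonprotrusive_blocks_growth(self):
        f = straight_filament()
        act.update_rest_lengths(f, False, 1.0, params=P)
        assert f.L0[-1] == pytest.approx(150.0)
        assert f.L0[0] == pytest.approx(140.0)

    def test_net_rate_is_10_nm_per_s(self):
        f = straight_filament(n=8)
        c0 = f.contour_rest()
        for _ in range(10):
            act.update_rest_lengths(f, True, 0.5, params=P)
        assert f.contour_rest() - c0 == pytest.approx(10.0 * 5.0)

    def test_barbed_split_at_300(self):
        f = straight_filament(n=3)
        f.L0[-1] = 295.0
        act.update_rest_lengths(f, True, 1.0, params=P)
        assert f.n_nodes == 4
        assert f.L0[-1] == pytest.approx(157.5)

    def test_deleted_when_fully_depolymerized(self):
        f = straight_filament(n=2, L0=12.0)
        alive = True
        for _ in range(10):
            alive = act.update_rest_lengths(f, False, 1.0, params=P)
            if not alive:
                break
        assert not alive

    def test_dt_must_be_positive(self):
        with pytest.raises(ValueError):
            act.update_rest_lengths(straight_filament(), True, 0.0,
                                    params=P)


class TestSevering:
    def test_900nm_gives_three_pieces(self):
        f = straight_filament(n=7)          # 6 x 150 = 900 nm
        pieces = act.sever_filament(f, 300.0)
        assert len(pieces) == 3
        for p in pieces:
            assert p.contour_rest() == pytest.approx(300.0)

    def test_short_filament_unchanged(self):
        f = straight_filament(n=2, L0=250.0)
        assert act.sever_filament(f, 300.0) == [f]

    def test_contour_conserved(self, rng):
        f = straight_filament(n=6, jitter=10.0, rng=rng)
        f.L0 = np.array([150.0, 120.0, 180.0, 160.0, 140.0])  # 750 nm
        pieces = act.sever_filament(f, 300.0)
        total = sum(p.contour_rest() for p in pieces)
        assert total == pytest.approx(750.0)
        assert all(np.all(p.L0 <= 300.0 + 1e-9) for p in pieces)

    def test_buckling_criterion(self):
        f = straight_filament(n=5)
        assert not act.is_buckled(f, P)
        # fold it
        f.x[3:, 0] = f.x[3:, 0] - 2 * (f.x[3:, 0] - f.x[2, 0])
        assert act.is_buckled(f, P)


@settings(derandomize=True, max_examples=40)
@given(L0=st.floats(min_value=150.0, max_value=300.0))
def test_stiffness_inverse_proportionality(L0):
    k = act.effective_segment_stiffness(L0, P)
    assert k * L0 == pytest.approx(P.area * P.youngs, rel=1e-12)
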