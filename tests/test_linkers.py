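import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from invadosim import actin as act
from invadosim import linkers as lk
from invadosim.params import LinkerParams

P = LinkerParams()


def two_filaments(angle_deg=5.0, offset=60.0):
    """A pair of nearly parallel 3-segment filaments."""
    x1 = np.zeros((4, 3))
    x1[:, 0] = np.arange(4) * 150.0
    a = math.radians(angle_deg)
    d = np.array([math.cos(a), math.sin(a), 0.0])
    x2 = np.array([0.0, offset, 0.0]) + np.outer(np.arange(4) * 150.0, d)
    f1 = act.ActinFilament(fid=0, x=x1, L0=np.full(3, 150.0))
    f2 = act.ActinFilament(fid=1, x=x2, L0=np.full(3, 150.0))
    return {0: f1, 1: f2}


class TestBindingPosition:
    def test_endpoints_and_interpolation(self):
        fils = two_filaments()
        ep = lk.Endpoint(0, 1, 0.0)
        assert np.allclose(lk.binding_position(fils, ep), fils[0].x[1])
        ep.frac = 1.0
        assert np.allclose(lk.binding_position(fils, ep), fils[0].x[2])
        ep = lk.Endpoint(0, 0, 0.25)
        assert np.allclose(lk.binding_position(fils, ep),
                           [37.5, 0.0, 0.0])


class TestLinkerForce:
    def make(self, kind, rest, fils, beta=0.5):
        return lk.LinkerOrMotor(
            kind, lk.Endpoint(0, 1, 0.5), lk.Endpoint(1, 1, beta),
            rest=rest, kappa=P.kappa)

    def test_zero_at_rest_length(self):
        fils = two_filaments(0.0, offset=50.0)
        link = self.make("alpha_actinin", 50.0, fils)
        contribs, tension = lk.linker_force(link, fils)
        assert tension == pytest.approx(0.0, abs=1e-9)
        for _, _, f in contribs:
            assert np.allclose(f, 0.0, atol=1e-9)

    def test_alpha_actinin_200pN_lever_weights(self):
        """70-nm extension of a 50-nm alpha-actinin at 0.01 N/m gives a
        200-pN connector, split (1-a, a) on the host segment nodes."""
        fils = two_filaments(0.0, offset=70.0)
        link = lk.LinkerOrMotor(
            "alpha_actinin", lk.Endpoint(0, 1, 0.3),
            lk.Endpoint(1, 1, 0.3), rest=50.0, kappa=P.kappa)
        contribs, tension = lk.linker_force(link, fils)
        assert tension == pytest.approx(200.0, rel=1e-9)
        mags = {(fid, node): np.linalg.norm(f)
                for fid, node, f in contribs}
        assert mags[(0, 1)] == pytest.approx(0.7 * 200.0)
        assert mags[(0, 2)] == pytest.approx(0.3 * 200.0)

    def test_action_reaction_across_filaments(self, rng):
        fils = two_filaments(12.0, offset=80.0)
        for f in fils.values():
            f.x = f.x + rng.normal(0.0, 10.0, f.x.shape)
        link = self.make("filamin", 150.0, fils, beta=0.8)
        contribs, _ = lk.linker_force(link, fils)
        tot = {0: np.zeros(3), 1: np.zeros(3)}
        for fid, _, f in contribs:
            tot[fid] += f
        assert np.allclose(tot[0] + tot[1], 0.0, atol=1e-9)

    def test_myosin_500pN(self):
        """Bipolar myosin at 350 nm (rest 300) carries 500 pN."""
        fils = two_filaments(0.0, offset=350.0)
        link = self.make("myosin", 300.0, fils)
        _, tension = lk.linker_force(link, fils)
        assert tension == pytest.approx(500.0, rel=1e-9)

    def test_inactive_motor_exerts_nothing(self):
        fils = two_filaments(0.0, offset=350.0)
        link = self.make("myosin", 300.0, fils)
        assert not link.active("protrusive")
        assert link.active("retractile")
        link2 = self.make("fascin", 40.0, fils)
        assert link2.active("protrusive")


class TestHillLaw:
    def test_endpoints(self):
        assert lk.hill_sliding_velocity(0.0, P) == pytest.approx(160.0)
        assert lk.hill_sliding_velocity(P.f_stall, P) == 0.0
        assert lk.hill_sliding_velocity(2 * P.f_stall, P) == 0.0

    def test_half_stall(self):
        v = lk.hill_sliding_velocity(620.0, P)
        assert v == pytest.approx(160.0 * 0.5 / (1 + 4.761 * 0.5),
                                  rel=1e-3)

    def test_monotone_decreasing(self):
        vs = [lk.hill_sliding_velocity(f, P)
              for f in np.linspace(0, P.f_stall, 20)]
        assert all(a >= b for a, b in zip(vs, vs[1:]))

    def test_negative_load_rejected(self):
        with pytest.raises(ValueError):
            lk.hill_sliding_velocity(-1.0, P)


class TestSliding:
    def test_alpha_update_example(self):
        """alpha* = alpha + v dt / |segment| on a 150-nm segment."""
        fils = two_filaments(0.0)
        ep = lk.Endpoint(0, 0, 0.5)
        lk.advance_endpoint(ep, fils, 160.0, 0.01)
        assert ep.frac == pytest.approx(0.5 + 160.0 * 0.01 / 150.0)

    def test_zero_velocity_no_motion(self):
        fils = two_filaments()
        ep = lk.Endpoint(0, 0, 0.37)
        lk.advance_endpoint(ep, fils, 0.0, 1.0)
        assert ep.frac == 0.37

    def test_hop_and_clamp_at_barbed_end(self):
        fils = two_filaments(0.0)
        ep = lk.Endpoint(0, 0, 0.9)
        lk.advance_endpoint(ep, fils, 150.0, 1.0)   # 150 nm of travel
        assert ep.seg == 1
        lk.advance_endpoint(ep, fils, 150.0, 10.0)  # way past the end
        assert ep.seg == 2 and ep.frac == 1.0

    def test_repeated_sliding_monotone_to_clamp(self):
        fils = two_filaments(0.0, offset=300.0)
        motor = lk.LinkerOrMotor(
            "myosin", lk.Endpoint(0, 0, 0.1), lk.Endpoint(1, 0, 0.2),
            rest=300.0, kappa=P.kappa)
        prev = (motor.a.seg, motor.a.frac)
        for _ in range(200):
            lk.advance_sliding(motor, fils, 0.05, P)
            cur = (motor.a.seg, motor.a.frac)
            assert cur >= prev
            prev = cur
        assert motor.a.seg == 2 and motor.a.frac == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=60)
    @given(alpha=st.floats(0.0, 0.95), v=st.floats(0.0, 100.0),
           dt=st.floats(1e-4, 0.05))
    def test_geometric_identity_of_alpha_update(self, alpha, v, dt):
        """The closed-form alpha* equals the geometric recomputation
        |x* - x_j| / |x_{j+1} - x_j| for within-segment sliding."""
        fils = two_filaments(0.0)
        seg_len = 150.0
        expected = alpha + v * dt / seg_len
        if expected > 1.0:
            return
        ep = lk.Endpoint(0, 0, alpha)
        xs = lk.binding_position(fils, ep)
        t_hat = np.array([1.0, 0.0, 0.0])
        x_star = xs + v * dt * t_hat
        geometric = np.linalg.norm(x_star - fils[0].x[0]) / seg_len
        lk.advance_endpoint(ep, fils, v, dt)
        assert ep.frac == pytest.approx(geometric, abs=1e-12)
        assert ep.frac == pytest.approx(expected, abs=1e-12)


class TestPlacement:
    def _place(self, fils, phase="protrusive", ko=None, seed=0,
               polarity=(0.0, 0.0, 1.0), center=(0.0, -3000.0, 0.0)):
        rng = np.random.default_rng(seed)
        links = []
        for _ in range(30):     # 30 control seconds of attempts
            links = lk.place_and_turnover(
                fils, links, phase, 0.0, 1.0, rng,
                np.asarray(center, dtype=float),
                np.asarray(polarity, dtype=float), P, ko=ko or set())
        return links

    def test_parallel_pair_gets_fascin(self):
        fils = two_filaments(5.0, offset=45.0)
        links = self._place(fils, polarity=(0.0, 1.0, 0.0))
        assert any(l.kind == "fascin" for l in links)

    def test_80_degree_pair_no_fascin(self):
        fils = two_filaments(80.0, offset=45.0)
        links = self._place(fils, polarity=(0.0, 1.0, 0.0))
        assert not any(l.kind == "fascin" for l in links)

    def test_outside_cone_no_leading_edge_linkers(self):
        fils = two_filaments(5.0, offset=45.0)
        # polarity opposite to the filament position vector
        links = self._place(fils, polarity=(0.0, -1.0, 0.0))
        assert not any(l.kind in ("fascin", "filamin") for l in links)

    def test_knockout_suppresses_species(self):
        fils = two_filaments(5.0, offset=45.0)
        links = self._place(fils, ko={"fascin", "filamin"},
                            polarity=(0.0, 1.0, 0.0))
        assert not any(l.kind in ("fascin", "filamin") for l in links)

    def test_turnover_removes_old_links(self):
        fils = two_filaments(5.0, offset=45.0)
        rng = np.random.default_rng(0)
        old = lk.LinkerOrMotor(
            "fascin", lk.Endpoint(0, 0, 0.5), lk.Endpoint(1, 0, 0.5),
            rest=40.0, kappa=P.kappa, birth=0.0, turnover=60.0)
        out = lk.place_and_turnover(fils, [old], "protrusive", 61.0,
                                    1.0, rng, np.zeros(3),
                                    np.array([0, 0, 1.0]), P)
        assert old not in out

    def test_motors_only_placed_during_retraction(self):
        fils = two_filaments(5.0, offset=45.0)
        fils[0].pattern = "perinuclear"
        fils[1].pattern = "perinuclear"
        prot = self._place(fils, phase="protrusive")
        retr = self._place(fils, phase="retractile")
        assert not any(l.kind == "myosin" for l in prot)
        assert any(l.kind in ("myosin", "alpha_actinin") for l in retr)
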