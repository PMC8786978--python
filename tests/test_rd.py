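import math

import numpy as np
import pytest

from invadosim import rd
from invadosim.params import RdParams

BOX = (8000.0, 8000.0, 8000.0)


def quiet_params(**kw):
    """All rates off unless specified."""
    base = dict(k_on_12=0.0, k_on_23=0.0, k_on_34=0.0, k_off_4=0.0,
                k_decay_1=0.0, k_decay_3=0.0, k_decay_5=0.0, k_deg_6=0.0,
                d_phi1=0.0, d_phi2=0.0, d_phi5=0.0)
    base.update(kw)
    return RdParams(**base)


class TestStepping:
    def test_empty_field_stays_empty(self):
        f = rd.make_field(BOX)
        rd.rd_step(f, 1e-3, "retractile", None)
        assert f.conc.max() == 0.0

    def test_stability_bound_enforced(self):
        f = rd.make_field(BOX, RdParams())
        with pytest.raises(ValueError):
            rd.rd_step(f, 10.0 * f.stability_limit(), "retractile", None)

    def test_exponential_decay_oracle(self):
        """phi3 with only decay: matches exp(-k t) within 1e-3."""
        k = 0.5
        f = rd.make_field(BOX, quiet_params(k_decay_3=k))
        f.conc[2][:] = 2.0
        dt = 1e-3 / k
        t = 0.0
        while t < 2.0 - 1e-12:
            rd.rd_step(f, dt, "retractile", None)
            t += dt
        expect = 2.0 * math.exp(-k * 2.0)
        assert abs(f.conc[2][3, 3, 3] - expect) / expect < 1e-3

    def test_binding_pair_conserves_totals(self, rng):
        """phi2 + phi3 <-> phi4 only: (phi2+phi4) and (phi3+phi4) are
        stoichiometric invariants."""
        f = rd.make_field((4000.0,) * 3,
                          quiet_params(k_on_23=0.4, k_off_4=0.2))
        for s in (1, 2):
            f.conc[s] = rng.random(f.shape)
        m24 = f.total_mass("phi2") + f.total_mass("phi4")
        m34 = f.total_mass("phi3") + f.total_mass("phi4")
        for _ in range(500):
            rd.rd_step(f, 2e-3, "retractile", None)
        assert f.total_mass("phi2") + f.total_mass("phi4") == \
            pytest.approx(m24, rel=1e-6)
        assert f.total_mass("phi3") + f.total_mass("phi4") == \
            pytest.approx(m34, rel=1e-6)

    def test_pure_diffusion_conserves_mass_zero_flux(self):
        f = rd.make_field(BOX, quiet_params(d_phi1=5.0e6))
        f.conc[0][7, 7, 7] = 5.0
        m0 = f.total_mass("phi1")
        for _ in range(300):
            rd.rd_step(f, 0.9 * f.stability_limit(), "retractile", None)
        assert f.total_mass("phi1") == pytest.approx(m0, rel=1e-10)
        assert f.conc[0].min() >= 0.0

    def test_nonnegativity_and_phi6_monotone(self, rng):
        f = rd.make_field((4000.0,) * 3, RdParams())
        for s in range(6):
            f.conc[s] = rng.random(f.shape)
        phi6_prev = f.conc[5].copy()
        for _ in range(200):
            rd.rd_step(f, 0.9 * f.stability_limit(), "protrusive",
                       np.array([[1, 1, 1]]))
            assert f.conc.min() >= 0.0
            assert np.all(f.conc[5] <= phi6_prev + 1e-12)
            phi6_prev = f.conc[5].copy()

    def test_immobile_species_do_not_transport(self):
        """phi3, phi4, phi6 have no diffusion term."""
        f = rd.make_field(BOX, quiet_params())
        for s in (2, 3, 5):
            f.conc[s][4, 4, 4] = 1.0
        for _ in range(100):
            rd.rd_step(f, 1e-2, "retractile", None)
        for s in (2, 3, 5):
            assert f.conc[s][4, 4, 4] == 1.0
            assert f.conc[s].sum() == 1.0


class TestSources:
    def test_secretion_only_protrusive_and_at_tips(self):
        tips = np.array([[2, 2, 2]])
        f = rd.make_field(BOX, RdParams())
        rd.rd_step(f, 1e-3, "retractile", tips)
        assert f.total_mass("phi3") == 0.0
        rd.rd_step(f, 1e-3, "protrusive", tips)
        assert f.conc[2][2, 2, 2] > 0.0
        assert f.conc[2].sum() == pytest.approx(f.conc[2][2, 2, 2])

    def test_mt1mmp_knockout_silences_sources(self):
        tips = np.array([[2, 2, 2]])
        f = rd.make_field(BOX, RdParams())
        for _ in range(50):
            rd.rd_step(f, 1e-3, "protrusive", tips, mt1mmp_on=False)
        assert f.conc.max() == 0.0

    def test_ligand_feedback_scales_with_phi5(self):
        p = RdParams(ligand_feedback=True)
        f = rd.make_field(BOX, p)
        tips = np.array([[2, 2, 2], [5, 5, 5]])
        f.conc[4][2, 2, 2] = 1.0
        f.conc[4][5, 5, 5] = 3.0
        rd.rd_step(f, 1e-3, "protrusive", tips)
        assert f.conc[2][5, 5, 5] == pytest.approx(
            3 * f.conc[2][2, 2, 2], rel=1e-9)

    def test_tip_nodes_cluster_at_polarity_cap(self, rng):
        f = rd.make_field(BOX)
        u = rng.normal(size=(200, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        ci = 2000.0 * u + 4000.0
        nodes = rd.tip_source_nodes(f, ci, np.array([0.0, 0.0, 1.0]))
        assert len(nodes)
        assert nodes[:, 2].min() >= f.shape[2] // 2
        empty = rd.tip_source_nodes(f, ci, np.array([0.0, 0.0, 1.0]),
                                    cap_fraction=0.0)
        assert len(empty) == 0


class TestSampling:
    def test_nodal_and_midpoint_values(self):
        f = rd.make_field((4000.0,) * 3)
        f.conc[0][0, 0, 0] = 1.0
        f.conc[0][1, 0, 0] = 3.0
        node = f.origin + np.array([0.5, 0.5, 0.5]) * f.h
        assert rd.sample_field(f, node, "phi1") == pytest.approx(1.0)
        mid = f.origin + np.array([1.0, 0.5, 0.5]) * f.h
        assert rd.sample_field(f, mid, "phi1") == pytest.approx(2.0)

    def test_uniform_field_everywhere_uniform(self, rng):
        f = rd.make_field((4000.0,) * 3)
        f.conc[3][:] = 0.7
        pts = rng.random((20, 3)) * 4000.0
        vals = rd.sample_field(f, pts)
        assert np.allclose(vals[:, 3], 0.7)

    def test_out_of_box_clamps(self):
        f = rd.make_field((4000.0,) * 3)
        f.conc[0][:] = 1.5
        assert rd.sample_field(f, np.array([-500.0, 200.0, 9000.0]),
                               "phi1") == pytest.approx(1.5)
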