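"""Coupled time integration and the three-phase motion controller.

Every structure (five cell surfaces, branched actin network, ECM fibers)
obeys an overdamped Kelvin-Voigt force balance: the nodal velocity is
the assembled force divided by the summed dashpot coefficients, plus a
lagged "dissipated force" carrying the neighbours' previous-step
velocities.  The explicit quotients are advanced inside a step-doubling
controller: a full step is compared against two half steps and accepted
when the Richardson error estimate, relative to a characteristic length
(the cell radius scale), is below tolerance.

The phase controller cycles protrusive -> retractile -> severing.  Phase
boundaries trigger the discrete biology: forced capping of tip
filaments and motor activation entering retraction, fragmentation of
buckled filaments entering severing, and uncapping plus renewed MT1-MMP
secretion when protrusion resumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import actin as act
from . import ecm as ecm_mod
from . import linkers as lk
from . import membranes as mem
from . import rd as rd_mod
from .params import Params

PHASES = ("protrusive", "retractile", "severing")


@dataclass
class PhaseSchedule:
    protrusive: float = 240.0
    retractile: float = 60.0
    severing: float = 20.0
    phase: str = "protrusive"
    clock: float = 0.0           # time inside the current phase
    cycle: int = 0

    def __post_init__(self):
        if min(self.protrusive, self.retractile, self.severing) <= 0:
            raise ValueError("phase durations must be positive")

    @property
    def period(self) -> float:
        return self.protrusive + self.retractile + self.severing

    def duration(self, phase: str) -> float:
        return getattr(self, phase)

    def phase_at(self, t: float) -> str:
        s = t % self.period
        if s < self.protrusive:
            return "protrusive"
        if s < self.protrusive + self.retractile:
            return "retractile"
        return "severing"

    def time_to_boundary(self) -> float:
        return self.duration(self.phase) - self.clock

    def advance(self, dt: float) -> list:
        """Move the phase clock; returns the transitions crossed, each as
        (old_phase, new_phase)."""
        events = []
        remaining = dt
        while remaining >= self.time_to_boundary() - 1e-12:
            remaining -= self.time_to_boundary()
            old = self.phase
            idx = PHASES.index(old)
            new = PHASES[(idx + 1) % 3]
            if new == "protrusive":
                self.cycle += 1
            self.phase = new
            self.clock = 0.0
            events.append((old, new))
        self.clock += remaining
        return events


@dataclass
class SimulationState:
    params: Params
    cell: mem.LayeredCellMesh
    schedule: PhaseSchedule
    rng: np.random.Generator
    polarity: np.ndarray
    filaments: dict = field(default_factory=dict)
    branches: list = field(default_factory=list)   # (mfid, mnode, dfid)
    links: list = field(default_factory=list)
    net: ecm_mod.EcmFiberNetwork | None = None
    rd: rd_mod.RdField | None = None
    fcs: list = field(default_factory=list)
    t: float = 0.0
    next_fid: int = 0
    ko: set = field(default_factory=set)
    max_filaments: int = 2000
    k_nucleate: float | None = None     # override of params.actin value
    events: list = field(default_factory=list)
    ratchet_reaction: bool = True
    f_ext_act: np.ndarray | None = None  # test/probe hook

    # integration caches (built by prepare())
    def __post_init__(self):
        self._prev_v = {}
        self._act = None
        self._excl_cache = None
        self._tip_nodes = None
        self._vg_cache = {}
        self._dt = self.params.integrator.dt_init
        self._degenerate_branches = 0
        self._last_forces = None

    # ------------------------------------------------------------ actin
    def sync_actin(self) -> None:
        """Rebuild the concatenated actin arrays after topology changes.

        Filament ``x`` members become views into one packed (N, 3)
        array so the vectorized force kernel and the per-filament API
        always agree.
        """
        fids = sorted(self.filaments)
        xs, L0s, segs, triples, tL0 = [], [], [], [], []
        slices = {}
        base = 0
        for fid in fids:
            f = self.filaments[fid]
            n = f.n_nodes
            xs.append(np.asarray(f.x, dtype=float))
            L0s.append(np.asarray(f.L0, dtype=float))
            for k in range(n - 1):
                segs.append((base + k, base + k + 1))
            for k in range(n - 2):
                triples.append((base + k, base + k + 1, base + k + 2))
                tL0.append(f.L0[k])
            slices[fid] = (base, base + n)
            base += n
        X = np.vstack(xs) if xs else np.empty((0, 3))
        L0 = np.concatenate(L0s) if L0s else np.empty(0)
        self._act = {
            "X": X, "L0": L0,
            "seg": np.asarray(segs, dtype=int).reshape(-1, 2),
            "tri": np.asarray(triples, dtype=int).reshape(-1, 3),
            "triL0_idx": None, "slices": slices,
        }
        # per-filament views into the packed arrays
        off = 0
        seg_off = 0
        for fid in fids:
            f = self.filaments[fid]
            n = f.n_nodes
            f.x = X[off:off + n]
            f.L0 = L0[seg_off:seg_off + n - 1]
            off += n
            seg_off += n - 1
        # triple rest lengths are the first segment of each triple
        tri = self._act["tri"]
        if len(tri):
            seg_map = {tuple(s): i for i, s in
                       enumerate(map(tuple, self._act["seg"]))}
            self._act["triL0_idx"] = np.array(
                [seg_map[(a, b)] for a, b, _ in tri], dtype=int)
        else:
            self._act["triL0_idx"] = np.empty(0, dtype=int)
        self.f_ext_act = None if self.f_ext_act is None or \
            len(self.f_ext_act) != len(X) else self.f_ext_act
        self._prev_v["act"] = _resize_prev(self._prev_v.get("act"), X)
        self._rebuild_aux()

    def _rebuild_aux(self) -> None:
        """Index arrays for the batched branch/linker/contact kernels."""
        live = self.filaments
        rows = []
        for mfid, mnode, dfid in self.branches:
            if mfid in live and dfid in live and \
                    mnode < live[mfid].n_nodes - 1 and \
                    live[dfid].n_nodes >= 2:
                rows.append((self.global_node(mfid, mnode),
                             self.global_node(mfid, mnode + 1),
                             self.global_node(dfid, 0),
                             self.global_node(dfid, 1)))
        self._br = np.asarray(rows, dtype=int).reshape(-1, 4)
        self._rebuild_link_arrays()
        adh, rat = [], []
        for fid, f in live.items():
            gb = self.global_node(fid, f.n_nodes - 1)
            if f.adhesion is None:
                continue
            # capping blocks polymerization, not the cortex tether:
            # capped-but-adhered tip filaments stay coupled, which is
            # how retractile contraction reaches the membrane
            if f.state in (act.ADHESION, act.CAPPED):
                adh.append((gb, f.adhesion))
            elif f.state == act.RATCHET:
                rat.append((gb, f.adhesion))
        self._adh = np.asarray(adh, dtype=int).reshape(-1, 2)
        self._rat = np.asarray(rat, dtype=int).reshape(-1, 2)

    def _rebuild_link_arrays(self) -> None:
        """Pack live crosslinkers/motors for the vectorized kernel.

        Group 0: filament-filament; group 1: filament-PAL tethers.
        Rebuilt whenever topology changes and after motor sliding.
        """
        n_pal = self.cell.pal.n_nodes
        ff, fp = [], []
        for link in self.links:
            if link.stale:
                continue
            if not (lk.endpoint_alive(self.filaments, link.a, n_pal)
                    and lk.endpoint_alive(self.filaments, link.b,
                                          n_pal)):
                link.stale = True
                continue
            motor = link.kind in ("alpha_actinin", "myosin")
            a0 = self.global_node(link.a.fid, link.a.seg)
            if link.b.fid == -1:
                fp.append((link, a0, link.a.frac, link.b.pal_node,
                           link.rest, link.kappa, motor))
            else:
                b0 = self.global_node(link.b.fid, link.b.seg)
                ff.append((link, a0, link.a.frac, b0, link.b.frac,
                           link.rest, link.kappa, motor))
        self._lk_ff = {
            "links": [r[0] for r in ff],
            "a0": np.array([r[1] for r in ff], dtype=int),
            "fa": np.array([r[2] for r in ff]),
            "b0": np.array([r[3] for r in ff], dtype=int),
            "fb": np.array([r[4] for r in ff]),
            "rest": np.array([r[5] for r in ff]),
            "kappa": np.array([r[6] for r in ff]),
            "motor": np.array([r[7] for r in ff], dtype=bool),
        }
        self._lk_fp = {
            "links": [r[0] for r in fp],
            "a0": np.array([r[1] for r in fp], dtype=int),
            "fa": np.array([r[2] for r in fp]),
            "pal": np.array([r[3] for r in fp], dtype=int),
            "rest": np.array([r[4] for r in fp]),
            "kappa": np.array([r[5] for r in fp]),
            "motor": np.array([r[6] for r in fp], dtype=bool),
        }

    def global_node(self, fid: int, j: int) -> int:
        a, b = self._act["slices"][fid]
        return a + j

    def add_filament(self, fil: act.ActinFilament) -> int:
        fid = self.next_fid
        fil.fid = fid
        self.next_fid += 1
        self.filaments[fid] = fil
        return fid

    # ------------------------------------------------------- geometry
    def cell_center(self) -> np.ndarray:
        return self.cell.nms.x.mean(axis=0)

    def nucleus_centroid(self) -> np.ndarray:
        return self.cell.nms.x.mean(axis=0)

    def tip_cap_indices(self, fraction: float | None = None) -> np.ndarray:
        fr = fraction if fraction is not None \
            else self.params.rd.tip_cap_fraction
        proj = self.cell.ci.x @ self.polarity
        n_cap = max(1, int(round(fr * len(proj))))
        return np.argsort(proj)[-n_cap:]

    def tip_position(self) -> np.ndarray:
        proj = self.cell.ci.x @ self.polarity
        return self.cell.ci.x[int(np.argmax(proj))].copy()


def _resize_prev(prev, like):
    out = np.zeros_like(like)
    if prev is not None:
        n = min(len(prev), len(out))
        out[:n] = prev[:n]
    return out


def _neighbor_sum(edges: np.ndarray, v: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, 3))
    if len(edges):
        np.add.at(out, edges[:, 0], v[edges[:, 1]])
        np.add.at(out, edges[:, 1], v[edges[:, 0]])
    return out


# ===================================================== force assembly

def _actin_internal_forces(state: SimulationState, X: np.ndarray):
    """Vectorized stretch + bend over the packed filament arrays."""
    p = state.params.actin
    a = state._act
    f = np.zeros_like(X)
    seg, L0 = a["seg"], a["L0"]
    if len(seg) == 0:
        return f
    d = X[seg[:, 1]] - X[seg[:, 0]]
    L = np.maximum(np.linalg.norm(d, axis=1), 1e-12)
    unit = d / L[:, None]
    kap = p.area * p.youngs / np.maximum(L0, p.seg_kappa_floor)
    t = (kap * (L - L0))[:, None] * unit
    np.add.at(f, seg[:, 0], t)
    np.add.at(f, seg[:, 1], -t)
    tri = a["tri"]
    if len(tri):
        u = X[tri[:, 1]] - X[tri[:, 0]]
        v = X[tri[:, 2]] - X[tri[:, 1]]
        lu = np.maximum(np.linalg.norm(u, axis=1), 1e-12)
        lv = np.maximum(np.linalg.norm(v, axis=1), 1e-12)
        uh, vh = u / lu[:, None], v / lv[:, None]
        c = np.einsum("ij,ij->i", uh, vh)
        ccl = np.clip(c, -1 + 1e-12, 1 - 1e-12)
        th = np.arccos(ccl)
        L0b = L0[a["triL0_idx"]]
        coef = p.bend_modulus * th / (L0b * np.sqrt(1 - ccl**2))
        dca = -(vh - ccl[:, None] * uh) / lu[:, None]
        dcc = (uh - ccl[:, None] * vh) / lv[:, None]
        np.add.at(f, tri[:, 0], coef[:, None] * dca)
        np.add.at(f, tri[:, 1], coef[:, None] * (-dca - dcc))
        np.add.at(f, tri[:, 2], coef[:, None] * dcc)
    return f


def _cross_rows(a, b):
    out = np.empty(np.broadcast(a, b).shape)
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def _branch_forces_batch(state: SimulationState, X: np.ndarray,
                         FA: np.ndarray) -> None:
    """Vectorized Arp2/3 + branch-angle + dihedral forces.

    Same mathematics as :func:`invadosim.actin.branch_forces` (the
    per-branch reference checked against finite differences), applied to
    all branches at once.
    """
    br = state._br
    if not len(br):
        return
    p = state.params.actin
    eps = 1e-12
    p1, p2, q1, q2 = X[br[:, 0]], X[br[:, 1]], X[br[:, 2]], X[br[:, 3]]
    lam0 = p.lambda_arp
    w = p1 - q1
    larp = np.maximum(np.linalg.norm(w, axis=1), eps)
    g = (p.kappa_arp * (larp - lam0) / larp)[:, None] * w
    np.add.at(FA, br[:, 0], -g)
    np.add.at(FA, br[:, 2], g)

    u = p2 - p1
    v = q2 - q1
    lu = np.maximum(np.linalg.norm(u, axis=1), eps)
    lv = np.maximum(np.linalg.norm(v, axis=1), eps)
    uh, vh = u / lu[:, None], v / lv[:, None]
    c = np.einsum("ij,ij->i", uh, vh)
    ccl = np.clip(c, -1 + eps, 1 - eps)
    phi = np.arccos(ccl)
    coef = (p.kappa_br_ang * (phi - p.branch_angle0)
            / (lam0 * np.sqrt(1.0 - ccl**2)))[:, None]
    dc_p2 = (vh - ccl[:, None] * uh) / lu[:, None]
    dc_q2 = (uh - ccl[:, None] * vh) / lv[:, None]
    np.add.at(FA, br[:, 0], -coef * dc_p2)
    np.add.at(FA, br[:, 1], coef * dc_p2)
    np.add.at(FA, br[:, 2], -coef * dc_q2)
    np.add.at(FA, br[:, 3], coef * dc_q2)

    m1 = _cross_rows(w, u)
    m2 = _cross_rows(w, v)
    n1 = np.linalg.norm(m1, axis=1)
    n2 = np.linalg.norm(m2, axis=1)
    ok = (n1 > act._SIN_MIN * larp * lu) & (n2 > act._SIN_MIN * larp * lv)
    state._degenerate_branches += int(np.count_nonzero(~ok))
    if np.any(ok):
        n1s = np.where(ok, n1, 1.0)
        n2s = np.where(ok, n2, 1.0)
        m1h = m1 / n1s[:, None]
        m2h = m2 / n2s[:, None]
        cd = np.clip(np.einsum("ij,ij->i", m1h, m2h), -1 + eps, 1 - eps)
        psi = np.arccos(cd)
        coefd = np.where(ok, p.kappa_br_dihed * psi
                         / (lam0 * np.sqrt(1.0 - cd**2)), 0.0)[:, None]
        g1 = (m2h - cd[:, None] * m1h) / n1s[:, None]
        g2 = (m1h - cd[:, None] * m2h) / n2s[:, None]
        dc_p1 = _cross_rows(u + w, g1) + _cross_rows(v, g2)
        dc_p2d = -_cross_rows(w, g1)
        dc_q2d = -_cross_rows(w, g2)
        dc_q1 = -(dc_p1 + dc_p2d + dc_q2d)
        np.add.at(FA, br[:, 0], coefd * dc_p1)
        np.add.at(FA, br[:, 1], coefd * dc_p2d)
        np.add.at(FA, br[:, 2], coefd * dc_q1)
        np.add.at(FA, br[:, 3], coefd * dc_q2d)


def _linker_forces_batch(state: SimulationState, X: np.ndarray,
                         pal: np.ndarray, phase: str, FA: np.ndarray,
                         Fpal: np.ndarray,
                         record_tension: bool = False) -> None:
    """Vectorized crosslinker/motor spring forces (lever-distributed)."""
    retract = phase == "retractile"
    ff = state._lk_ff
    if len(ff["a0"]):
        on = ~ff["motor"] | retract
        xa = (1 - ff["fa"])[:, None] * X[ff["a0"]] \
            + ff["fa"][:, None] * X[ff["a0"] + 1]
        xb = (1 - ff["fb"])[:, None] * X[ff["b0"]] \
            + ff["fb"][:, None] * X[ff["b0"] + 1]
        d = xb - xa
        L = np.maximum(np.linalg.norm(d, axis=1), 1e-12)
        fmag = np.where(on, ff["kappa"] * (L - ff["rest"]), 0.0)
        fv = (fmag / L)[:, None] * d
        np.add.at(FA, ff["a0"], (1 - ff["fa"])[:, None] * fv)
        np.add.at(FA, ff["a0"] + 1, ff["fa"][:, None] * fv)
        np.add.at(FA, ff["b0"], -(1 - ff["fb"])[:, None] * fv)
        np.add.at(FA, ff["b0"] + 1, -ff["fb"][:, None] * fv)
        if record_tension:
            for link, t in zip(ff["links"], np.abs(fmag)):
                link.tension = float(t)
    fp = state._lk_fp
    if len(fp["a0"]):
        on = ~fp["motor"] | retract
        xa = (1 - fp["fa"])[:, None] * X[fp["a0"]] \
            + fp["fa"][:, None] * X[fp["a0"] + 1]
        xb = pal[fp["pal"]]
        d = xb - xa
        L = np.maximum(np.linalg.norm(d, axis=1), 1e-12)
        fmag = np.where(on, fp["kappa"] * (L - fp["rest"]), 0.0)
        fv = (fmag / L)[:, None] * d
        np.add.at(FA, fp["a0"], (1 - fp["fa"])[:, None] * fv)
        np.add.at(FA, fp["a0"] + 1, fp["fa"][:, None] * fv)
        np.add.at(Fpal, fp["pal"], -fv)
        if record_tension:
            for link, t in zip(fp["links"], np.abs(fmag)):
                link.tension = float(t)


def assemble_forces(state: SimulationState, pos: dict) -> dict:
    """All force terms of the coupled model at the given positions.

    ``pos`` maps 'ci','ct','cc','pal','nms','act','ecm' to coordinate
    arrays.  Returns force arrays of the same shapes.  Also refreshes
    per-linker tensions (used by the Hill law next step).
    """
    prm = state.params
    cell = state.cell
    protrusive = state.schedule.phase == "protrusive"
    layers = {"ci": cell.ci, "ct": cell.ct, "cc": cell.cc,
              "pal": cell.pal, "nms": cell.nms}
    saved = {k: m.x for k, m in layers.items()}
    for k, m in layers.items():
        m.x = pos[k]
    try:
        F = {k: mem.elastic_forces(m) for k, m in layers.items()}
        f_ci, f_ct, f_cc = mem.transduce_and_cortex_forces(cell)
        F["ci"] += f_ci
        F["ct"] += f_ct
        F["cc"] += f_cc
        f_pal, f_nms = mem.nuclear_membrane_link_forces(cell)
        F["pal"] += f_pal
        F["nms"] += f_nms

        X = pos["act"]
        FA = _actin_internal_forces(state, X)
        if state.f_ext_act is not None:
            FA += state.f_ext_act

        # branch (Arp2/3 + angular + dihedral) forces, batched
        _branch_forces_batch(state, X, FA)

        # crosslinker / motor forces, batched
        phase = state.schedule.phase
        _linker_forces_batch(state, X, pos["pal"], phase, FA, F["pal"])

        # barbed-end adhesion springs to the cortex + ratchet forces.
        # Contact is measured radially (barbed-end radius against the
        # local cortex radius): the surface is much finer than its node
        # spacing, so a nearest-node distance would never register.
        normals = mem.node_normals(cell.ci)
        cc_center = pos["cc"].mean(axis=0)
        cc_rad = np.linalg.norm(pos["cc"] - cc_center, axis=1)
        adh = state._adh
        if len(adh):
            rel = X[adh[:, 0]] - cc_center
            rb = np.maximum(np.linalg.norm(rel, axis=1), 1e-9)
            e = cc_rad[adh[:, 1]] - rb        # >0: below the cortex
            fa = (prm.actin.kappa_adhesion * e / rb)[:, None] * rel
            np.add.at(FA, adh[:, 0], fa)
            np.add.at(F["cc"], adh[:, 1], -fa)
        rat = state._rat
        if len(rat) and protrusive:
            ap = prm.actin
            v_prev_act = state._prev_v.get("act")
            v_prev_cc = state._prev_v.get("cc")
            vb = v_prev_act[rat[:, 0]] if v_prev_act is not None and \
                len(v_prev_act) == len(X) else np.zeros((len(rat), 3))
            va = v_prev_cc[rat[:, 1]] if v_prev_cc is not None \
                else np.zeros((len(rat), 3))
            nr = normals[rat[:, 1]]
            s = np.abs(np.einsum("ij,ij->i", nr, vb - va))
            mag = np.where(s < 1e-12, ap.f_ratchet_max,
                           np.clip(ap.f_ratchet
                                   * np.log(ap.v0 / np.maximum(s, 1e-12)),
                                   0.0, ap.f_ratchet_max))
            fr = mag[:, None] * nr
            np.add.at(F["cc"], rat[:, 1], fr)
            if state.ratchet_reaction:
                np.add.at(FA, rat[:, 0], -fr)

        F["act"] = FA

        # ECM fiber elasticity + focal complexes + volume exclusion
        if state.net is not None:
            FE = ecm_mod.fiber_forces(state.net, pos["ecm"])
            for fc in state.fcs:
                i, j = state.net.segments[fc.seg]
                anchor = (1.0 - fc.frac) * pos["ecm"][i] \
                    + fc.frac * pos["ecm"][j]
                fci, ffib, _ = ecm_mod.focal_complex_force(
                    fc, pos["ci"][fc.ci_node], anchor, prm.adhesion)
                F["ci"][fc.ci_node] += fci
                FE[i] += (1.0 - fc.frac) * ffib
                FE[j] += fc.frac * ffib
            cache = state._excl_cache
            if cache is not None:
                seg_rows, fr = cache
                i, j = (state.net.segments[seg_rows, 0],
                        state.net.segments[seg_rows, 1])
                pts = (1 - fr)[:, None] * pos["ecm"][i] \
                    + fr[:, None] * pos["ecm"][j]
                fp, fs, _ = ecm_mod.volume_exclusion_forces(
                    pos["ci"], normals, pts,
                    prm.ecm.kappa_exclusion, keep_outside=True)
                np.add.at(FE, i, (1 - fr)[:, None] * fp)
                np.add.at(FE, j, fr[:, None] * fp)
                F["ci"] += fs
            F["ecm"] = FE
        else:
            F["ecm"] = np.zeros_like(pos["ecm"])

        # keep actin inside the cortex and outside the nucleus; a radial
        # penalty (direction from the cell/nucleus centre, magnitude set
        # by the nearest surface node's radius) stays smooth where a
        # nearest-normal scheme would jump across surface Voronoi cells
        if len(X):
            fp, fs, idx = _radial_confinement(
                pos["cc"], X, prm.ecm.kappa_exclusion, inside=True)
            F["act"] += fp
            np.add.at(F["cc"], idx, fs)
            fp, fs, idx = _radial_confinement(
                pos["nms"], X, prm.ecm.kappa_exclusion, inside=False)
            F["act"] += fp
            np.add.at(F["nms"], idx, fs)
    finally:
        for k, m in layers.items():
            m.x = saved[k]
    return F


def _radial_confinement(surf_x: np.ndarray, points: np.ndarray,
                        kappa: float, inside: bool):
    """Penalty keeping points inside (or outside) a star-shaped surface.

    The violation depth compares each point's distance from the surface
    centroid with the radius of its nearest surface node; the force acts
    along the smooth radial direction, the equal-opposite reaction on
    that surface node.  Returns (f_points, f_on_nearest, nearest_idx).
    """
    center = surf_x.mean(axis=0)
    rel = points - center
    r = np.linalg.norm(rel, axis=1)
    rhat = rel / np.maximum(r, 1e-9)[:, None]
    tree = cKDTree(surf_x)
    _, idx = tree.query(points, workers=1)
    r_surf = np.linalg.norm(surf_x[idx] - center, axis=1)
    if inside:
        depth = np.maximum(r - r_surf, 0.0)
        f = -kappa * depth[:, None] * rhat
    else:
        depth = np.maximum(r_surf - r, 0.0)
        f = kappa * depth[:, None] * rhat
    return f, -f, idx


def total_elastic_energy(state: SimulationState) -> float:
    """Sum of every elastic energy term (diagnostics / relaxation tests)."""
    cell = state.cell
    h = sum(mem.elastic_energy(m) for m in cell.layers().values())
    for xa, xb, kap in ((cell.ci.x, cell.ct.x, cell.kappa_t),
                        (cell.ct.x, cell.cc.x, cell.kappa_c),
                        (cell.pal.x, cell.nms.x, cell.kappa_nuc)):
        L = np.linalg.norm(xb - xa, axis=1)
        h += 0.5 * kap * float(np.sum((L - cell.link_rest) ** 2))
    for f in state.filaments.values():
        h += act.filament_energy(f.x, f.L0, state.params.actin)
    for mfid, mnode, dfid in state.branches:
        if mfid in state.filaments and dfid in state.filaments:
            mf, df = state.filaments[mfid], state.filaments[dfid]
            if mnode < mf.n_nodes - 1:
                h += act.branch_energy(mf.x[mnode], mf.x[mnode + 1],
                                       df.x[0], df.x[1],
                                       state.params.actin)
    phase = state.schedule.phase
    for link in state.links:
        if link.active(phase) and \
                lk.endpoint_alive(state.filaments, link.a,
                                  len(cell.pal.x)) and \
                lk.endpoint_alive(state.filaments, link.b,
                                  len(cell.pal.x)):
            h += lk.linker_energy(link, state.filaments, cell.pal.x)
    if state.net is not None:
        h += ecm_mod.fiber_energy(state.net)
    return h


# ======================================================== integration

def _velocities(state: SimulationState, F: dict, prev: dict) -> dict:
    """Explicit overdamped quotients with lagged dissipated forces."""
    prm = state.params
    cell = state.cell
    mp = prm.membrane
    v = {}
    specs = {
        "ci": (cell.ci, mp.c_link, ("ct",)),
        "ct": (cell.ct, 2 * mp.c_link, ("ci", "cc")),
        "cc": (cell.cc, mp.c_link, ("ct",)),
        "pal": (cell.pal, mp.c_link, ("nms",)),
        "nms": (cell.nms, mp.c_link, ("pal",)),
    }
    for name, (mesh_, c_links, partners) in specs.items():
        deg = np.zeros(mesh_.n_nodes)
        np.add.at(deg, mesh_.edges[:, 0], 1.0)
        np.add.at(deg, mesh_.edges[:, 1], 1.0)
        denom = (mesh_.c_pair * deg + c_links + mesh_.c_ground)[:, None]
        lag = mesh_.c_pair * _neighbor_sum(mesh_.edges, prev[name],
                                           mesh_.n_nodes)
        for pname in partners:
            lag = lag + mp.c_link * prev[pname]
        v[name] = (F[name] + lag) / denom
    # actin
    a = state._act
    ap = prm.actin
    n = len(a["X"])
    deg = np.zeros(n)
    if len(a["seg"]):
        np.add.at(deg, a["seg"][:, 0], 1.0)
        np.add.at(deg, a["seg"][:, 1], 1.0)
    denom = (ap.c_pair * deg + ap.c_ground)[:, None]
    lag = ap.c_pair * _neighbor_sum(a["seg"], prev["act"], n)
    v["act"] = (F["act"] + lag) / np.maximum(denom, 1e-12)
    # ecm
    if state.net is not None:
        net = state.net
        ne = net.n_nodes
        dege = np.zeros(ne)
        np.add.at(dege, net.segments[:, 0], 1.0)
        np.add.at(dege, net.segments[:, 1], 1.0)
        ep = prm.ecm
        denome = (ep.c_pair * dege + ep.c_ground)[:, None]
        lage = ep.c_pair * _neighbor_sum(net.segments, prev["ecm"], ne)
        ve = (F["ecm"] + lage) / denome
        ve[net.boundary_mask()] = 0.0       # matrix anchored at the box
        v["ecm"] = ve
    else:
        v["ecm"] = np.zeros((0, 3))
    return v


def _positions(state: SimulationState) -> dict:
    cell = state.cell
    return {"ci": cell.ci.x, "ct": cell.ct.x, "cc": cell.cc.x,
            "pal": cell.pal.x, "nms": cell.nms.x,
            "act": state._act["X"],
            "ecm": state.net.nodes if state.net is not None
            else np.empty((0, 3))}


def step(state: SimulationState, dt_try: float | None = None) -> float:
    """One adaptive mechanical step; returns the accepted dt.

    A full explicit step is compared with two half steps; the step is
    accepted when the maximum nodal discrepancy, relative to the
    characteristic length, is below the tolerance, otherwise dt is
    halved (fault below dt_min).
    """
    ip = state.params.integrator
    dt = dt_try if dt_try is not None else state._dt
    if state._act is None:
        state.sync_actin()
    pos0 = {k: v.copy() for k, v in _positions(state).items()}
    prev = _ensure_prev(state, pos0)
    F0 = assemble_forces(state, pos0)
    v0 = _velocities(state, F0, prev)
    retried = False
    while True:
        x_full = {k: pos0[k] + dt * v0[k] for k in pos0}
        x_half = {k: pos0[k] + 0.5 * dt * v0[k] for k in pos0}
        # the lagged dissipated-force terms are frozen at the previous
        # accepted step on both trial paths, so the Richardson estimate
        # measures truncation error only
        F1 = assemble_forces(state, x_half)
        v1 = _velocities(state, F1, prev)
        x_two = {k: x_half[k] + 0.5 * dt * v1[k] for k in pos0}
        err = max((np.abs(x_full[k] - x_two[k]).max() if len(x_full[k])
                   else 0.0) for k in pos0)
        if err / ip.length_ref < ip.tol:
            break
        retried = True
        dt *= 0.5
        if dt < ip.dt_min:
            worst = max(pos0, key=lambda k:
                        np.abs(x_full[k] - x_two[k]).max()
                        if len(x_full[k]) else 0.0)
            raise RuntimeError(
                f"time step underflow at t = {state.t:.4f} s "
                f"(structure '{worst}')")
    _commit(state, x_two)
    state._prev_v = v1
    state.t += dt
    # grow the natural step; a step merely clipped to hit a control tick
    # or phase boundary must not shrink it
    base = dt if retried else max(dt, state._dt)
    state._dt = min(base * ip.grow_factor, ip.dt_max)
    # continuous polymerization of rest lengths
    _grow_rest_lengths(state, dt)
    # myosin sliding with the Hill law (retractile phase); the sensed
    # load is the motor tension at the step just completed
    if state.schedule.phase == "retractile":
        _update_link_tensions(state)
        slid = False
        for link in state.links:
            if link.kind == "myosin" and not link.stale:
                lk.advance_sliding(link, state.filaments, dt,
                                   state.params.linker)
                slid = True
        if slid:
            state._rebuild_link_arrays()
    # reaction-diffusion sub-steps
    if state.rd is not None:
        _rd_substep(state, dt)
    return dt


def _update_link_tensions(state: SimulationState) -> None:
    X = state._act["X"]
    pal = state.cell.pal.x
    ff, fp = state._lk_ff, state._lk_fp
    if len(ff["a0"]):
        xa = (1 - ff["fa"])[:, None] * X[ff["a0"]] \
            + ff["fa"][:, None] * X[ff["a0"] + 1]
        xb = (1 - ff["fb"])[:, None] * X[ff["b0"]] \
            + ff["fb"][:, None] * X[ff["b0"] + 1]
        L = np.linalg.norm(xb - xa, axis=1)
        for link, t in zip(ff["links"],
                           np.abs(ff["kappa"] * (L - ff["rest"]))):
            link.tension = float(t)
    if len(fp["a0"]):
        xa = (1 - fp["fa"])[:, None] * X[fp["a0"]] \
            + fp["fa"][:, None] * X[fp["a0"] + 1]
        L = np.linalg.norm(pal[fp["pal"]] - xa, axis=1)
        for link, t in zip(fp["links"],
                           np.abs(fp["kappa"] * (L - fp["rest"]))):
            link.tension = float(t)


def _ensure_prev(state, pos):
    prev = state._prev_v
    for k, x in pos.items():
        if k not in prev or len(prev[k]) != len(x):
            prev[k] = np.zeros_like(x)
    return prev


def _commit(state: SimulationState, x: dict) -> None:
    cell = state.cell
    cell.ci.x[:] = x["ci"]
    cell.ct.x[:] = x["ct"]
    cell.cc.x[:] = x["cc"]
    cell.pal.x[:] = x["pal"]
    cell.nms.x[:] = x["nms"]
    state._act["X"][:] = x["act"]
    if state.net is not None:
        state.net.nodes[:] = x["ecm"]


def _grow_rest_lengths(state: SimulationState, dt: float) -> None:
    p = state.params.actin
    protrusive = state.schedule.phase == "protrusive"
    for fid, f in state.filaments.items():
        if protrusive and not f.capped and f.state != act.CAPPED:
            vg = state._vg_cache.get(fid, p.v_growth)
            f.L0[-1] += vg * dt
        if f.n_nodes >= 2:
            f.L0[0] = max(f.L0[0] - p.v_shrink * dt, 0.5)


def _rd_substep(state: SimulationState, dt: float) -> None:
    f = state.rd
    lim = f.stability_limit()
    n_sub = max(1, int(math.ceil(dt / lim)))
    sub = dt / n_sub
    on = "mt1mmp" not in state.ko
    for _ in range(n_sub):
        rd_mod.rd_step(f, sub, state.schedule.phase, state._tip_nodes,
                       mt1mmp_on=on)


# ================================================== control & biology

def control_tick(state: SimulationState, interval: float) -> None:
    """Per-second housekeeping: state machine, nucleation, linker
    placement/turnover, adhesion bookkeeping, degradation, caches."""
    prm = state.params
    rng = state.rng
    phase = state.schedule.phase
    center = state.cell_center()

    _segment_maintenance(state)
    _state_machine(state, interval)
    if phase == "protrusive" and "arp23" not in state.ko:
        _nucleate(state, interval)
    state.links = lk.place_and_turnover(
        state.filaments, state.links, phase, state.t, interval, rng,
        center, state.polarity, prm.linker, pal_x=state.cell.pal.x,
        ko=state.ko)
    if state.net is not None:
        _focal_complex_tick(state, interval)
        _refresh_exclusion_cache(state)
        if state.rd is not None:
            # phi6 is the chemical state of the collagen material, so a
            # segment is probed at its original position: mechanical
            # displacement must not read neighbouring (or empty) grid
            # cells as "degradation"
            if getattr(state, "_phi6_probe", None) is None:
                state._phi6_probe = state.net.segment_midpoints().copy()
                state._phi6_baseline = rd_mod.sample_field(
                    state.rd, state._phi6_probe, "phi6")
            ecm_mod.degrade_segments(
                state.net,
                lambda pts: rd_mod.sample_field(state.rd, pts, "phi6"),
                prm.ecm.degrade_threshold, state._phi6_baseline,
                positions=state._phi6_probe)
    if state.rd is not None:
        state._tip_nodes = rd_mod.tip_source_nodes(
            state.rd, state.cell.ci.x, state.polarity)
    state.sync_actin()


def _segment_maintenance(state: SimulationState) -> None:
    """Split over-long barbed segments, merge vanishing pointed ones,
    delete depolymerized filaments."""
    p = state.params.actin
    dead = []
    for fid, f in state.filaments.items():
        changed = False
        if f.L0[-1] > p.seg_split:
            act._split_barbed(f)
            changed = True
        while f.n_nodes > 2 and f.L0[0] < p.seg_merge:
            f.L0 = np.concatenate([[f.L0[0] + f.L0[1]], f.L0[2:]])
            f.x = np.vstack([f.x[:1], f.x[2:]])
            changed = True
        if f.n_nodes <= 2 and f.L0[0] <= 30.0:
            dead.append(fid)
        if changed and f.adhesion is not None:
            pass  # adhesion references a CC node, unaffected by resize
    for fid in dead:
        del state.filaments[fid]
        state.events.append((state.t, "filament_depolymerized", fid))
    if dead:
        gone = set(dead)
        state.branches = [b for b in state.branches
                          if b[0] not in gone and b[2] not in gone]
        for link in state.links:
            if link.a.fid in gone or link.b.fid in gone:
                link.stale = True


def _state_machine(state: SimulationState, dt: float) -> None:
    p = state.params.actin
    cc_x = state.cell.cc.x
    tree = cKDTree(cc_x)
    center = cc_x.mean(axis=0)
    cc_rad = np.linalg.norm(cc_x - center, axis=1)

    def radial_gap(f):
        """Barbed-end depth below the local cortex surface (nm)."""
        k = f.adhesion
        if k is None:
            k = int(tree.query(f.barbed)[1])
        rb = float(np.linalg.norm(f.barbed - center))
        return cc_rad[k] - rb, k

    # count cortex-engaged filaments per node for the growth law
    n_f = {}
    for f in state.filaments.values():
        if f.state in (act.ADHESION, act.RATCHET) and \
                f.adhesion is not None:
            n_f[f.adhesion] = n_f.get(f.adhesion, 0) + 1
    state._vg_cache = {}
    for fid, f in state.filaments.items():
        if f.state == act.NUCLEATED:
            f.state = act.GROWTH
        elif f.state == act.UNCAPPED:
            f.state = act.GROWTH
            f.capped = False
        if f.state == act.GROWTH:
            gap, k = radial_gap(f)
            if abs(gap) < p.adhesion_gap:
                f.state = act.ADHESION
                f.adhesion = k
                state.events.append((state.t, "adhesion", fid))
        elif f.state == act.ADHESION:
            gap, _ = radial_gap(f)
            if p.kappa_adhesion * abs(gap) > p.adhesion_rupture:
                f.state = act.RATCHET   # detach -> immediate ratchet
                state.events.append((state.t, "detach", fid))
        elif f.state == act.CAPPED and f.adhesion is not None:
            # the cortex tether of a capped filament obeys the same
            # 20-pN rupture rule; once broken it does not re-form
            # until the filament regrows into contact
            gap, _ = radial_gap(f)
            if p.kappa_adhesion * abs(gap) > p.adhesion_rupture:
                f.adhesion = None
                state.events.append((state.t, "tether_rupture", fid))
        if f.state in (act.GROWTH, act.RATCHET) and not f.capped:
            if state.rng.random() < act.capping_probability(p.k_cap, dt):
                f.state = act.CAPPED
                f.capped = True
                state.events.append((state.t, "capped", fid))
        # load-dependent growth rate for cortex-engaged filaments
        if f.state in (act.ADHESION, act.RATCHET) and \
                f.adhesion is not None:
            gap, _ = radial_gap(f)
            fc = p.kappa_adhesion * abs(gap)
            nf = max(1, n_f.get(f.adhesion, 1))
            state._vg_cache[fid] = act.load_dependent_growth_rate(
                fc, nf, p)
        if f.state not in (act.ADHESION, act.RATCHET):
            if f.adhesion is not None and f.state != act.CAPPED:
                f.adhesion = None


def _nucleate(state: SimulationState, dt: float) -> None:
    p = state.params.actin
    kn = state.k_nucleate if state.k_nucleate is not None \
        else p.k_nucleate
    if len(state.filaments) >= state.max_filaments:
        return
    n_events = state.rng.poisson(kn * dt)
    n_events = min(n_events,
                   state.max_filaments - len(state.filaments))
    if n_events == 0:
        return
    center = state.cell_center()
    cc_center = state.cell.cc.x.mean(axis=0)
    r_cortex = float(np.mean(np.linalg.norm(state.cell.cc.x - cc_center,
                                            axis=1)))
    # Arp2/3 is activated at the membrane: eligible mother segments sit
    # in the leading-edge cone within a sub-cortical shell, which is
    # what densifies the branched network at the invadopodium tip
    shell = 300.0
    eligible = []
    for fid, f in state.filaments.items():
        for j in range(f.n_nodes - 1):
            mid = 0.5 * (f.x[j] + f.x[j + 1])
            if np.linalg.norm(mid - cc_center) < r_cortex - shell:
                continue
            if lk.in_leading_edge(mid, center, state.polarity,
                                  state.params.linker.cone_deg):
                eligible.append((fid, j))
    if not eligible:
        return
    for _ in range(n_events):
        mfid, j = eligible[state.rng.integers(len(eligible))]
        mf = state.filaments[mfid]
        t_hat = mf.x[j + 1] - mf.x[j]
        t_hat = t_hat / max(np.linalg.norm(t_hat), 1e-12)
        r = state.rng.normal(size=3)
        perp = r - np.dot(r, t_hat) * t_hat
        perp /= max(np.linalg.norm(perp), 1e-12)
        # of the two azimuthal choices, daughters growing toward the
        # membrane persist (the inward half never engages the cortex)
        r_hat = mf.x[j] - cc_center
        r_hat /= max(np.linalg.norm(r_hat), 1e-12)
        if np.dot(perp, r_hat) < 0:
            perp = -perp
        d_hat = (math.cos(p.branch_angle0) * t_hat
                 + math.sin(p.branch_angle0) * perp)
        q1 = mf.x[j] + p.lambda_arp * d_hat
        q2 = q1 + 100.0 * d_hat
        daughter = act.ActinFilament(
            fid=-1, x=np.vstack([q1, q2]), L0=np.array([100.0]),
            state=act.NUCLEATED, mother=(mfid, j),
            pattern="leading-edge")
        dfid = state.add_filament(daughter)
        state.branches.append((mfid, j, dfid))
        state.events.append((state.t, "nucleation", dfid))


def _focal_complex_tick(state: SimulationState, dt: float) -> None:
    """Bond kinetics and contact-based focal-complex turnover.

    A new complex opens where a membrane node comes within the capture
    distance of an intact fiber segment (closest-point contact, since
    fiber nodes are far sparser than the physical binding radius); the
    slip-bond kinetics then decide whether it engages or dies.
    """
    prm = state.params.adhesion
    net = state.net
    capture = 2.0 * prm.l_bind
    keep = []
    for fc in state.fcs:
        if not net.intact[fc.seg]:
            state.events.append((state.t, "fc_lost_degraded", fc.ci_node))
            continue
        d = np.linalg.norm(fc.anchor(net) - state.cell.ci.x[fc.ci_node])
        ecm_mod.bond_kinetics_step(fc, max(d, 1e-6), dt, prm)
        if fc.n_b < 1e-3 and d > 4 * prm.lam:
            continue
        keep.append(fc)
    state.fcs = keep
    existing = {fc.ci_node for fc in state.fcs}
    live = np.where(net.intact)[0]
    if not len(live):
        return
    mids = net.segment_midpoints()[live]
    tree = cKDTree(mids)
    half = 0.5 * net.params.seg_length
    groups = tree.query_ball_point(state.cell.ci.x,
                                   half + 3 * capture, workers=1)
    for ci_node, cand in enumerate(groups):
        if ci_node in existing or not cand:
            continue
        best = None
        p = state.cell.ci.x[ci_node]
        for c in cand:
            row = int(live[c])
            i, j = net.segments[row]
            t, d = ecm_mod.point_segment_closest(p, net.nodes[i],
                                                 net.nodes[j])
            if best is None or d < best[2]:
                best = (row, t, d)
        if best is not None and best[2] <= capture:
            state.fcs.append(ecm_mod.FocalComplex(
                ci_node=int(ci_node), seg=best[0], frac=best[1],
                n_b=1.0, n_tot=prm.n_tot))
            state.events.append((state.t, "fc_formed", int(ci_node)))


def _refresh_exclusion_cache(state: SimulationState) -> None:
    """Sub-sample intact fiber segments near the cell for exclusion.

    Fiber nodes are ~0.5 um apart while membrane features are smaller,
    so contact must be tested along the fiber line: each nearby intact
    segment contributes points every ~100 nm, with (segment row,
    fraction) kept so penalty reactions are lever-distributed back onto
    the segment nodes.
    """
    net = state.net
    center = state.cell_center()
    r_ci = np.max(np.linalg.norm(state.cell.ci.x - center, axis=1))
    mids = net.segment_midpoints()
    near = np.linalg.norm(mids - center, axis=1) < r_ci + 1500.0
    rows = np.where(near & net.intact)[0]
    if not len(rows):
        state._excl_cache = None
        return
    fracs = np.linspace(0.1, 0.9, 5)
    seg_rows = np.repeat(rows, len(fracs))
    f = np.tile(fracs, len(rows))
    state._excl_cache = (seg_rows, f)


def advance_phase(state: SimulationState, dt: float) -> list:
    """Advance the phase clock by ``dt`` and fire boundary events."""
    events = state.schedule.advance(dt)
    for old, new in events:
        state.events.append((state.t, "phase", f"{old}->{new}"))
        if old == "protrusive" and new == "retractile":
            _cap_tip_filaments(state)
        elif old == "retractile" and new == "severing":
            _sever_buckled(state)
        elif new == "protrusive":
            for f in state.filaments.values():
                if f.state == act.CAPPED:
                    f.state = act.UNCAPPED
                    f.capped = False
            state.events.append((state.t, "uncap_all", state.schedule.cycle))
    return events


def _cap_tip_filaments(state: SimulationState) -> None:
    cap_idx = state.tip_cap_indices()
    thresh = float(np.min(state.cell.ci.x[cap_idx] @ state.polarity)) \
        - 500.0
    n = 0
    for f in state.filaments.values():
        if float(f.barbed @ state.polarity) >= thresh and \
                f.state != act.CAPPED:
            f.state = act.CAPPED
            f.capped = True
            n += 1
    state.events.append((state.t, "cap_tip_filaments", n))


def _sever_buckled(state: SimulationState) -> None:
    p = state.params.actin
    to_sever = [fid for fid, f in state.filaments.items()
                if act.is_buckled(f, p)]
    for fid in to_sever:
        f = state.filaments.pop(fid)
        pieces = act.sever_filament(f)
        if len(pieces) == 1:
            state.filaments[fid] = f
            continue
        gone = {fid}
        state.branches = [b for b in state.branches
                          if b[0] not in gone and b[2] not in gone]
        for link in state.links:
            if link.a.fid == fid or link.b.fid == fid:
                link.stale = True
        for piece in pieces:
            state.add_filament(piece)
        state.events.append((state.t, "severed", (fid, len(pieces))))
    state.sync_actin()


def run(state: SimulationState, duration: float,
        sample_interval: float = 1.0, on_sample=None) -> None:
    """Advance the full model by ``duration`` seconds.

    The mechanical stepper is clipped so control ticks (every
    ``control_interval``) and phase boundaries are hit exactly; the
    optional ``on_sample(state)`` callback fires every
    ``sample_interval`` of simulated time.
    """
    ip = state.params.integrator
    t_end = state.t + duration
    next_control = state.t
    next_sample = state.t
    while state.t < t_end - 1e-9:
        if state.t >= next_control - 1e-9:
            control_tick(state, ip.control_interval)
            next_control = state.t + ip.control_interval
        if on_sample is not None and state.t >= next_sample - 1e-9:
            on_sample(state)
            next_sample = state.t + sample_interval
        dt_cap = min(next_control - state.t, t_end - state.t,
                     state.schedule.time_to_boundary())
        dt_cap = max(dt_cap, ip.dt_min)
        taken = step(state, min(state._dt, dt_cap))
        advance_phase(state, taken)
    if on_sample is not None:
        on_sample(state)
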