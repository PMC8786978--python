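"""Scenario configuration, in-silico experiments, trajectory analysis.

A scenario bundles phase durations, initial filament counts for the two
seeding patterns (radial leading-edge filaments spanning nucleus to
membrane, and perinuclear filaments encircling the nucleus), the ECM
geometry, knockout flags, and the RNG seed.  ``run_scenario`` executes
the full coupled model and returns a trajectory record (tip position,
nucleus centroid, traction and intracellular force at the tip, adhered
filament count) sampled at a fixed interval.

Knockouts: ``ko_alpha_actinin`` / ``ko_filamin`` / ``ko_fascin``
suppress placement of the species; ``ko_mt1mmp`` silences tip secretion
(no matrix degradation beyond what initial MMP-2 could do — here none);
``inhibit_arp23`` suppresses daughter-filament nucleation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import actin as act
from . import ecm as ecm_mod
from . import engine
from . import linkers as lk
from . import membranes as mem
from . import rd as rd_mod
from .params import Params, EcmParams

__all__ = [
    "ScenarioConfig", "TrajectoryRecord", "make_fixture", "run_scenario",
    "tip_position", "average_speed", "linear_fit_r2",
]


@dataclass
class ScenarioConfig:
    """Run configuration (YAML-serializable)."""

    protrusive: float = 240.0
    retractile: float = 60.0
    severing: float = 20.0
    n_pattern1: int = 500            # radial, leading-edge
    n_pattern2: int = 500            # perinuclear
    radius_cell: float = 5000.0      # nm
    radius_nucleus: float = 2000.0
    subdivision: int = 2
    box: tuple = (45000.0, 30000.0, 20000.0)
    pore_size: float = 3000.0
    total_time: float = 960.0
    sample_interval: float = 1.0
    seed: int = 0
    ko_alpha_actinin: bool = False
    ko_filamin: bool = False
    ko_fascin: bool = False
    ko_mt1mmp: bool = False
    inhibit_arp23: bool = False
    stiffness_interface: bool = False
    interface_offset: float = 10000.0   # nm from cell to the stiff side
    stiff_density_factor: float = 2.0
    k_nucleate: float | None = None     # None -> params default
    max_filaments: int = 2000

    def knockouts(self) -> set:
        ko = set()
        if self.ko_alpha_actinin:
            ko.add("alpha_actinin")
        if self.ko_filamin:
            ko.add("filamin")
        if self.ko_fascin:
            ko.add("fascin")
        if self.ko_mt1mmp:
            ko.add("mt1mmp")
        if self.inhibit_arp23:
            ko.add("arp23")
        return ko

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        if "box" in data:
            data["box"] = tuple(data["box"])
        return cls(**data)


@dataclass
class TrajectoryRecord:
    frame: pd.DataFrame

    @property
    def time(self):
        return self.frame["t"].to_numpy()

    def tip(self):
        return self.frame[["tip_x", "tip_y", "tip_z"]].to_numpy()

    def nucleus(self):
        return self.frame[["nuc_x", "nuc_y", "nuc_z"]].to_numpy()


# ---------------------------------------------------------- seeding

def _seed_filaments(state: engine.SimulationState, n1: int, n2: int,
                    rng) -> None:
    """The two initial actin patterns.

    Pattern 1: radial filaments, pointed end near the nuclear membrane
    and barbed end near the inner cellular membrane, tilted up to 20
    degrees off radial.  Pattern 2: filaments tangent to a perinuclear
    shell, pre-crosslinked pairwise by one bipolar myosin filament and
    one alpha-actinin each.
    """
    p = state.params.actin
    lp = state.params.linker
    center = state.cell_center()
    r_in = np.mean(np.linalg.norm(state.cell.nms.x - center, axis=1))
    r_out = np.mean(np.linalg.norm(state.cell.cc.x - center, axis=1))
    for _ in range(n1):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        w = rng.normal(size=3)
        w -= np.dot(w, u) * u
        w /= max(np.linalg.norm(w), 1e-12)
        tilt = math.radians(rng.uniform(0.0, 20.0))
        d = math.cos(tilt) * u + math.sin(tilt) * w
        start = center + (r_in + 100.0) * u
        length = max(r_out - r_in - 150.0, 2 * p.seg_rest_init)
        n_seg = max(1, int(length // p.seg_rest_init))
        pts = start + np.outer(
            np.arange(n_seg + 1) * p.seg_rest_init, d)
        fil = act.ActinFilament(
            fid=-1, x=pts, L0=np.full(n_seg, p.seg_rest_init),
            state=act.GROWTH, pattern="leading-edge")
        state.add_filament(fil)
    peri_fids = []
    shell = r_in + 120.0   # within alpha-actinin reach of the PAL
    for _ in range(n2):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        tang = np.cross(u, rng.normal(size=3))
        tang /= max(np.linalg.norm(tang), 1e-12)
        length = rng.uniform(600.0, 900.0)
        n_seg = max(2, int(length // p.seg_rest_init))
        mid = center + shell * u
        pts = mid + np.outer(
            (np.arange(n_seg + 1) - n_seg / 2) * p.seg_rest_init, tang)
        fil = act.ActinFilament(
            fid=-1, x=pts, L0=np.full(n_seg, p.seg_rest_init),
            state=act.GROWTH, pattern="perinuclear")
        fid = state.add_filament(fil)
        peri_fids.append(fid)
        # anchor each perinuclear filament to its nearest PAL node so
        # myosin contraction is transmitted to the nucleus
        if "alpha_actinin" not in state.ko:
            pal_x = state.cell.pal.x
            dmin = np.linalg.norm(pal_x - mid, axis=1)
            k = int(np.argmin(dmin))
            seg_mid = fil.n_nodes // 2
            seg_mid = min(seg_mid, fil.n_nodes - 2)
            state.links.append(lk.LinkerOrMotor(
                "alpha_actinin",
                lk.Endpoint(fid, seg_mid,
                            lk._closest_frac(fil, seg_mid, pal_x[k],
                                             rng)),
                lk.Endpoint(-1, 0, 0.0, pal_node=k),
                rest=lp.rest["alpha_actinin"], kappa=lp.kappa,
                birth=0.0, turnover=lp.turnover))
    # initial pairwise myosin + alpha-actinin crosslinks between
    # adjacent perinuclear filaments, bound at their closest approach
    # (random pairing would seed springs stretched by micrometres)
    unpaired = list(peri_fids)
    while len(unpaired) >= 2:
        a = unpaired.pop()
        fa = state.filaments[a]
        mids = {b: 0.5 * (state.filaments[b].x[0]
                          + state.filaments[b].x[-1])
                for b in unpaired}
        ma = 0.5 * (fa.x[0] + fa.x[-1])
        b = min(unpaired, key=lambda k: np.linalg.norm(mids[k] - ma))
        unpaired.remove(b)
        fb = state.filaments[b]
        d2 = np.sum((fa.x[:, None, :] - fb.x[None, :, :]) ** 2, axis=2)
        j1, j2 = np.unravel_index(int(np.argmin(d2)), d2.shape)
        s1 = min(j1, fa.n_nodes - 2)
        s2 = min(j2, fb.n_nodes - 2)
        for kind in ("myosin", "alpha_actinin"):
            if kind in state.ko:
                continue
            state.links.append(lk.LinkerOrMotor(
                kind,
                lk.Endpoint(a, s1, lk._closest_frac(fa, s1, fb.x[j2],
                                                    rng)),
                lk.Endpoint(b, s2, lk._closest_frac(fb, s2, fa.x[j1],
                                                    rng)),
                rest=lp.rest[kind], kappa=lp.kappa, birth=0.0,
                turnover=lp.turnover))


def _build_state(config: ScenarioConfig,
                 params: Params | None = None,
                 with_ecm: bool = True,
                 with_rd: bool = True) -> engine.SimulationState:
    params = params or Params()
    rng = np.random.default_rng(config.seed)
    box = np.asarray(config.box, dtype=float)
    center = box / 2.0
    cell = mem.build_spherical_cell(
        config.radius_cell, config.radius_nucleus, config.subdivision,
        params.membrane, params.actin, center=center)
    schedule = engine.PhaseSchedule(config.protrusive, config.retractile,
                                    config.severing)
    polarity = np.array([0.0, 0.0, 1.0])
    if config.stiffness_interface:
        polarity = np.array([1.0, 0.0, 0.0])  # toward the stiff side
    state = engine.SimulationState(
        params=params, cell=cell, schedule=schedule, rng=rng,
        polarity=polarity, ko=config.knockouts(),
        max_filaments=config.max_filaments,
        k_nucleate=config.k_nucleate)
    _seed_filaments(state, config.n_pattern1, config.n_pattern2, rng)
    if with_ecm:
        ep = dataclasses.replace(params.ecm, box=tuple(box),
                                 pore_size=config.pore_size)
        net = ecm_mod.generate_network(
            box, config.pore_size, ep.fiber_diameter,
            int(rng.integers(2**31 - 1)), ep)
        if config.stiffness_interface:
            _densify_stiff_side(net, center, polarity,
                                config.interface_offset,
                                config.stiff_density_factor)
        # margin 0: the matrix rests directly against the membrane, so
        # protrusion immediately works against (or through) fibers
        ecm_mod.carve_cavity(net, center, config.radius_cell,
                             margin=0.0)
        state.net = net
    if with_rd:
        rdp = params.rd
        if config.stiffness_interface and not rdp.ligand_feedback:
            rdp = dataclasses.replace(rdp, ligand_feedback=True)
        state.rd = rd_mod.make_field(box, rdp)
        if state.net is not None:
            pts = state.net.segment_midpoints()
            rd_mod.init_collagen(state.rd, pts, 1.0,
                                 ligand_too=rdp.ligand_feedback)
            if config.stiffness_interface:
                # ligand density mirrors the matrix density contrast
                axes = [np.arange(s) * rdp.h + rdp.h / 2
                        for s in state.rd.shape]
                gx = np.stack(np.meshgrid(*axes, indexing="ij"),
                              axis=-1)
                plane = float(np.dot(center, polarity)) \
                    + config.interface_offset
                side = (gx @ polarity) > plane
                state.rd.conc[4][side] *= config.stiff_density_factor
    state.sync_actin()
    return state


def _densify_stiff_side(net, center, polarity, offset, factor):
    """Stiffen fiber elements beyond the soft/stiff interface plane
    (the half-space the cell migrates toward); node geometry and rest
    lengths are untouched so the network stays unstressed at t = 0."""
    plane = float(np.dot(center, polarity)) + offset
    side = np.dot(net.segment_midpoints(), polarity) > plane
    net.stiffness_scale = np.where(side, factor, 1.0)


# --------------------------------------------------------- experiments

def make_fixture(scale: str = "tiny", seed: int = 0,
                 params: Params | None = None,
                 **overrides) -> engine.SimulationState:
    """Miniature simulation states for testing and quick exploration.

    ``tiny``: 20 filaments, subdivision-1 icosphere, 8 um ECM patch and
    coarse RD grid — full phase cycles in seconds.  ``small``: 200
    filaments, subdivision-2 surfaces, 12 um patch.  Both reproduce the
    two seeding patterns statistically (pattern-1 radial alignment,
    pattern-2 perinuclear shell).
    """
    presets = {
        "tiny": dict(n_pattern1=14, n_pattern2=6, radius_cell=2000.0,
                     radius_nucleus=800.0, subdivision=1,
                     box=(8000.0, 8000.0, 8000.0), pore_size=1200.0,
                     protrusive=20.0,
                     retractile=10.0, severing=5.0, total_time=105.0,
                     k_nucleate=8.0, max_filaments=120),
        "small": dict(n_pattern1=140, n_pattern2=60, radius_cell=3000.0,
                      radius_nucleus=1200.0, subdivision=2,
                      box=(12000.0, 12000.0, 12000.0), protrusive=60.0,
                      retractile=30.0, severing=10.0, total_time=300.0,
                      k_nucleate=5.0, max_filaments=400),
    }
    if scale not in presets:
        raise ValueError(f"unknown fixture scale {scale!r}")
    kw = presets[scale]
    kw.update(overrides)
    config = ScenarioConfig(seed=seed, **kw)
    return _build_state(config, params)


def run_scenario(config: ScenarioConfig,
                 params: Params | None = None) -> TrajectoryRecord:
    """Execute a scenario and collect the trajectory record."""
    state = _build_state(config, params)
    rows = []

    def sample(st: engine.SimulationState):
        tip_idx = st.tip_cap_indices()
        tip = st.tip_position()
        nuc = st.nucleus_centroid()
        # traction: summed focal-complex force over tip-cap CI nodes
        tr = np.zeros(3)
        for fc in st.fcs:
            if fc.ci_node in set(tip_idx.tolist()):
                fci, _, _ = ecm_mod.focal_complex_force(
                    fc, st.cell.ci.x[fc.ci_node], fc.anchor(st.net),
                    st.params.adhesion)
                tr += fci
        # intracellular: adhesion + ratchet force through tip-cap CC
        intra = np.zeros(3)
        cap = set(tip_idx.tolist())
        for f in st.filaments.values():
            if f.adhesion is not None and f.adhesion in cap:
                d = st.cell.cc.x[f.adhesion] - f.barbed
                intra += st.params.actin.kappa_adhesion * d
        adhered = sum(1 for f in st.filaments.values()
                      if f.state == act.ADHESION)
        rows.append(dict(
            t=st.t, tip_x=tip[0], tip_y=tip[1], tip_z=tip[2],
            nuc_x=nuc[0], nuc_y=nuc[1], nuc_z=nuc[2],
            traction_nN=float(np.linalg.norm(tr)) / 1000.0,
            intracellular_nN=float(np.linalg.norm(intra)) / 1000.0,
            n_adhered=adhered, n_filaments=len(st.filaments),
            phase=st.schedule.phase))

    engine.run(state, config.total_time, config.sample_interval, sample)
    rec = TrajectoryRecord(pd.DataFrame(rows))
    rec.state = state
    return rec


# ------------------------------------------------------------ analysis

def tip_position(ci_x: np.ndarray, polarity) -> int:
    """Index of the membrane node with maximal projection on the
    polarity axis (ties broken by the lowest index)."""
    proj = np.asarray(ci_x) @ np.asarray(polarity, dtype=float)
    return int(np.argmax(proj))


def average_speed(times: np.ndarray, positions: np.ndarray,
                  window: float = 180.0) -> float:
    """Mean of |dx|/dt over consecutive windows of the given width.

    Mirrors a timelapse protocol: the path is resampled at the window
    interval and speeds are averaged over the hops.
    """
    times = np.asarray(times, dtype=float)
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.ndim == 1 or positions.shape[0] != len(times):
        raise ValueError("times and positions must align")
    if len(times) < 2:
        raise ValueError("need at least two samples")
    t0, t1 = times[0], times[-1]
    n_win = max(1, int((t1 - t0) // window))
    grid = t0 + np.arange(n_win + 1) * window
    grid = grid[grid <= t1 + 1e-9]
    if len(grid) < 2:
        grid = np.array([t0, t1])
    interp = np.stack([np.interp(grid, times, positions[:, k])
                       for k in range(positions.shape[1])], axis=1)
    hops = np.linalg.norm(np.diff(interp, axis=0), axis=1)
    dts = np.diff(grid)
    return float(np.mean(hops / dts))


def linear_fit_r2(x, y):
    """OLS fit; returns (slope, intercept, r^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least three points")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    if np.var(y) == 0:
        res = y - y.mean()
        if np.allclose(res, 0):
            return 0.0, float(y.mean()), 1.0
        raise ValueError("degenerate y")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
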