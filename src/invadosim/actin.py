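"""Branched actin filaments: mechanics, growth, lifecycle.

A filament is a polyline from pointed end (node 0) to barbed end (node
-1).  Segment rest lengths grow at the barbed end (Brownian-ratchet
polymerization, load-dependent against the cortex) and shrink at the
pointed end.  Each filament carries a discrete state:

===  ==========  ====================================================
S    name        meaning
===  ==========  ====================================================
1    nucleated   daughter just branched off an Arp2/3 site
2    growth      free elongation toward the cortex
3    adhesion    barbed end bound to the actin cortex layer (gap < 100 nm)
4    detach      adhesion ruptured (tension > 20 pN)
5    ratchet     pushing the cortex through the thermal ratchet
6    capped      capping protein blocks the barbed end
7    uncapped    released at the start of a new protrusive phase
===  ==========  ====================================================

Elastic forces (stretch, bend, Arp2/3 link, branch angle, branch
dihedral) are analytic gradients of the corresponding energies; the test
suite checks each against central finite differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import ActinParams

# filament states
NUCLEATED, GROWTH, ADHESION, DETACH, RATCHET, CAPPED, UNCAPPED = range(1, 8)

_EPS = 1e-12
_SIN_MIN = 0.05   # ~3 degrees: dihedral undefined below this


def _cross(a, b):
    """3-vector cross product without numpy's moveaxis overhead."""
    out = np.empty(np.broadcast(a, b).shape)
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out



@dataclass
class ActinFilament:
    fid: int
    x: np.ndarray                       # (n, 3) nm, pointed -> barbed
    L0: np.ndarray                      # (n-1,) segment rest lengths
    state: int = GROWTH
    capped: bool = False
    mother: tuple | None = None         # (mother fid, mother node index)
    adhesion: int | None = None         # CC node index when S = 3
    pattern: str = "leading-edge"       # or "perinuclear"

    @property
    def n_nodes(self) -> int:
        return len(self.x)

    @property
    def barbed(self) -> np.ndarray:
        return self.x[-1]

    @property
    def pointed(self) -> np.ndarray:
        return self.x[0]

    def contour_rest(self) -> float:
        return float(np.sum(self.L0))

    def end_to_end(self) -> float:
        return float(np.linalg.norm(self.x[-1] - self.x[0]))

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.x, axis=0), axis=1)

    def direction(self) -> np.ndarray:
        d = self.x[-1] - self.x[0]
        n = np.linalg.norm(d)
        return d / n if n > 0 else np.array([0.0, 0.0, 1.0])


# ----------------------------------------------------------- simple laws

def effective_segment_stiffness(L0: float,
                                params: ActinParams | None = None) -> float:
    """A_A * E_A / L0 in pN/nm (0.46 N/m at the 150-nm initial length)."""
    params = params or ActinParams()
    if L0 <= 0:
        raise ValueError("rest length must be positive")
    return params.area * params.youngs / L0


def load_dependent_growth_rate(f_cortex: float, n_f: int,
                               params: ActinParams | None = None) -> float:
    """Exponential (concave-up) force-velocity law of polymerization.

    v_g = v0 exp(-f_cortex / (n_F f0)), with the cortex tension shared
    by the ``n_f`` filaments touching the cortex node.
    """
    params = params or ActinParams()
    if n_f < 1:
        raise ValueError("not in contact (n_f = 0): use the constant rate")
    if f_cortex < 0:
        raise ValueError("cortex tension must be non-negative")
    return params.v0 * math.exp(-f_cortex / (n_f * params.f0))


def capping_probability(k_cap: float, dt: float) -> float:
    """Per-step Poisson capping probability 1 - exp(-k dt)."""
    return -math.expm1(-k_cap * dt)


def ratchet_force(n_hat: np.ndarray, v_barbed: np.ndarray,
                  v_cortex: np.ndarray, protrusive: bool,
                  params: ActinParams | None = None) -> np.ndarray:
    """Brownian-ratchet polymerization force on the cortex node.

    F = F_p log(v0 / |n . (v_b - v_a)|) along the membrane normal,
    clamped to [0, F_max] (the law diverges at zero relative speed and
    turns negative above v0); identically zero outside the protrusive
    phase, when capping protein blocks monomer insertion.
    """
    params = params or ActinParams()
    if not protrusive:
        return np.zeros(3)
    s = abs(float(np.dot(n_hat, v_barbed - v_cortex)))
    if s < _EPS:
        mag = params.f_ratchet_max
    else:
        mag = params.f_ratchet * math.log(params.v0 / s)
        mag = min(max(mag, 0.0), params.f_ratchet_max)
    return mag * np.asarray(n_hat, dtype=float)


# ----------------------------------------------------- elastic mechanics

def filament_energy(x: np.ndarray, L0: np.ndarray,
                    params: ActinParams | None = None) -> float:
    """Stretch plus bend energy of one polyline, pN nm."""
    params = params or ActinParams()
    seg = np.diff(x, axis=0)
    L = np.linalg.norm(seg, axis=1)
    kappa = params.area * params.youngs / np.maximum(
        L0, params.seg_kappa_floor)
    h = 0.5 * float(np.sum(kappa * (L - L0) ** 2))
    if len(x) > 2:
        t = seg / L[:, None]
        c = np.clip(np.einsum("ij,ij->i", t[:-1], t[1:]),
                    -1 + _EPS, 1 - _EPS)
        theta = np.arccos(c)
        h += 0.5 * params.bend_modulus * float(np.sum(theta**2 / L0[:-1]))
    return h


def filament_elastic_forces(x: np.ndarray, L0: np.ndarray,
                            params: ActinParams | None = None) -> np.ndarray:
    """-dH/dx for every node of one filament (stretch + bend)."""
    params = params or ActinParams()
    n = len(x)
    f = np.zeros_like(x)
    seg = np.diff(x, axis=0)
    L = np.linalg.norm(seg, axis=1)
    L = np.maximum(L, _EPS)
    unit = seg / L[:, None]
    kappa = params.area * params.youngs / np.maximum(
        L0, params.seg_kappa_floor)
    t = (kappa * (L - L0))[:, None] * unit
    f[:-1] += t
    f[1:] -= t
    if n > 2:
        c = np.einsum("ij,ij->i", unit[:-1], unit[1:])
        c_cl = np.clip(c, -1 + _EPS, 1 - _EPS)
        theta = np.arccos(c_cl)
        # coefficient of -dc/dx in the force: kb * theta / (L0 sin)
        coef = (params.bend_modulus * theta
                / (L0[:-1] * np.sqrt(1.0 - c_cl**2)))
        u_hat, v_hat = unit[:-1], unit[1:]
        lu, lv = L[:-1, None], L[1:, None]
        dca = -(v_hat - c_cl[:, None] * u_hat) / lu
        dcc = (u_hat - c_cl[:, None] * v_hat) / lv
        dcb = -dca - dcc
        ga = coef[:, None] * dca
        gb = coef[:, None] * dcb
        gc = coef[:, None] * dcc
        idx = np.arange(n - 2)
        np.add.at(f, idx, ga)
        np.add.at(f, idx + 1, gb)
        np.add.at(f, idx + 2, gc)
    return f


def filament_elastic_force(fil: ActinFilament, j: int,
                           params: ActinParams | None = None) -> np.ndarray:
    if not 0 <= j < fil.n_nodes:
        raise IndexError("node out of range")
    return filament_elastic_forces(fil.x, fil.L0, params)[j]


# -------------------------------------------------------- branch forces

def _unit(v):
    n = np.linalg.norm(v)
    return v / n, n


def branch_energy(p1, p2, q1, q2, params: ActinParams | None = None,
                  lam0: float | None = None) -> float:
    """Arp2/3 spring + branch-angle + dihedral energy of one branch.

    ``p1``/``p2``: the mother node carrying the Arp2/3 complex and its
    barbed-side neighbour; ``q1``/``q2``: the daughter's first two nodes.
    """
    params = params or ActinParams()
    lam0 = params.lambda_arp if lam0 is None else lam0
    w = np.asarray(p1, float) - np.asarray(q1, float)
    larp = np.linalg.norm(w)
    h = 0.5 * params.kappa_arp * (larp - params.lambda_arp) ** 2
    u_hat, _ = _unit(np.asarray(p2, float) - p1)
    v_hat, _ = _unit(np.asarray(q2, float) - q1)
    c = np.clip(np.dot(u_hat, v_hat), -1 + _EPS, 1 - _EPS)
    phi = math.acos(c)
    h += 0.5 * params.kappa_br_ang * (phi - params.branch_angle0)**2 / lam0
    m1 = _cross(w, u_hat)
    m2 = _cross(w, v_hat)
    n1, n2 = np.linalg.norm(m1), np.linalg.norm(m2)
    if n1 > _SIN_MIN * larp and n2 > _SIN_MIN * larp:
        cd = np.clip(np.dot(m1 / n1, m2 / n2), -1 + _EPS, 1 - _EPS)
        psi = math.acos(cd)
        h += 0.5 * params.kappa_br_dihed * psi**2 / lam0
    return float(h)


def branch_forces(p1, p2, q1, q2, params: ActinParams | None = None):
    """Analytic -dH/dx of :func:`branch_energy` at the four nodes.

    Returns ``(f_p1, f_p2, f_q1, f_q2, degenerate)`` where ``degenerate``
    flags a collinear geometry whose dihedral term was skipped this step.
    """
    params = params or ActinParams()
    p1 = np.asarray(p1, float); p2 = np.asarray(p2, float)
    q1 = np.asarray(q1, float); q2 = np.asarray(q2, float)
    lam0 = params.lambda_arp
    f = [np.zeros(3) for _ in range(4)]

    # Arp2/3 spring between p1 and q1
    w = p1 - q1
    larp = np.linalg.norm(w)
    if larp > _EPS:
        g = params.kappa_arp * (larp - params.lambda_arp) * w / larp
        f[0] -= g
        f[2] += g

    u = p2 - p1
    v = q2 - q1
    u_hat, lu = _unit(u)
    v_hat, lv = _unit(v)

    # branch angle phi -> 70 degrees
    c = np.dot(u_hat, v_hat)
    c_cl = np.clip(c, -1 + _EPS, 1 - _EPS)
    phi = math.acos(c_cl)
    coef = (params.kappa_br_ang * (phi - params.branch_angle0)
            / (lam0 * math.sqrt(1.0 - c_cl**2)))
    dc_p2 = (v_hat - c_cl * u_hat) / lu
    dc_q2 = (u_hat - c_cl * v_hat) / lv
    f[0] += coef * (-dc_p2)        # = -coef * dc/dp1, dc/dp1 = -dc/dp2
    f[1] += coef * dc_p2
    f[2] += coef * (-dc_q2)
    f[3] += coef * dc_q2

    # Dihedral psi -> 0 between planes (p2,p1,q1) and (p1,q1,q2).  The
    # angle depends only on directions, so work with the raw normals
    # m1 = w x u, m2 = w x v; for m = a x b the differentials are
    # dm = da x b + a x db, i.e. skew matrices whose transposes turn
    # (dc/dm) into plain cross products below.
    degenerate = False
    m1 = _cross(w, u)
    m2 = _cross(w, v)
    n1, n2 = np.linalg.norm(m1), np.linalg.norm(m2)
    # the torque arm vanishes (and the gradient diverges) as either
    # plane collapses; skip the dihedral within a few degrees of
    # collinearity, matching the energy-side guard
    if n1 < _SIN_MIN * larp * lu or n2 < _SIN_MIN * larp * lv:
        degenerate = True
    else:
        m1h, m2h = m1 / n1, m2 / n2
        cd_cl = np.clip(np.dot(m1h, m2h), -1 + _EPS, 1 - _EPS)
        psi = math.acos(cd_cl)
        coefd = (params.kappa_br_dihed * psi
                 / (lam0 * math.sqrt(1.0 - cd_cl**2)))
        g1 = (m2h - cd_cl * m1h) / n1        # dc/dm1
        g2 = (m1h - cd_cl * m2h) / n2        # dc/dm2
        dc_dp1 = _cross(u + w, g1) + _cross(v, g2)
        dc_dp2 = -_cross(w, g1)
        dc_dq2 = -_cross(w, g2)
        dc_dq1 = -(dc_dp1 + dc_dp2 + dc_dq2)  # translation invariance
        # F = -k psi/lam dpsi/dx and dpsi/dx = -dc/(sin psi) -> +coefd*dc
        f[0] += coefd * dc_dp1
        f[1] += coefd * dc_dp2
        f[2] += coefd * dc_dq1
        f[3] += coefd * dc_dq2
    return f[0], f[1], f[2], f[3], degenerate


# ------------------------------------------------------ growth & turnover

def update_rest_lengths(fil: ActinFilament, protrusive: bool, dt: float,
                        v_g: float | None = None,
                        params: ActinParams | None = None) -> bool:
    """Advance polymerization/depolymerization by ``dt``.

    The barbed segment rest length grows at ``v_g`` (default: the free
    20 nm/s) during the protrusive phase while uncapped; the pointed
    segment shrinks at v_s in every phase.  Segments are subdivided at
    the 300-nm split threshold and absorbed below the merge threshold.
    Returns False when the filament has shrunk away (caller deletes it).
    """
    params = params or ActinParams()
    if dt <= 0:
        raise ValueError("dt must be positive")
    if protrusive and not fil.capped and fil.state != CAPPED:
        rate = params.v_growth if v_g is None else v_g
        fil.L0[-1] += rate * dt
        if fil.L0[-1] > params.seg_split:
            _split_barbed(fil)
    fil.L0[0] -= params.v_shrink * dt
    while fil.L0[0] <= 0:
        if fil.n_nodes <= 2:
            return False
        carry = fil.L0[0]
        fil.x = fil.x[1:]
        fil.L0 = fil.L0[1:]
        fil.L0[0] += carry
    if fil.n_nodes > 2 and fil.L0[0] < params.seg_merge:
        fil.L0 = np.concatenate([[fil.L0[0] + fil.L0[1]], fil.L0[2:]])
        fil.x = np.vstack([fil.x[:1], fil.x[2:]])
    return True


def _split_barbed(fil: ActinFilament) -> None:
    mid = 0.5 * (fil.x[-2] + fil.x[-1])
    half = fil.L0[-1] / 2.0
    fil.x = np.vstack([fil.x[:-1], mid, fil.x[-1]])
    fil.L0 = np.concatenate([fil.L0[:-1], [half, half]])


def is_buckled(fil: ActinFilament,
               params: ActinParams | None = None) -> bool:
    """Buckling criterion for severing: end-to-end < 0.9 x contour."""
    params = params or ActinParams()
    contour = float(np.sum(fil.segment_lengths()))
    if contour <= 0:
        return False
    return fil.end_to_end() < params.buckle_ratio * contour


def sever_filament(fil: ActinFilament, piece_length: float = 300.0):
    """Partition a filament into pieces of at most ``piece_length`` nm of
    rest contour (cofilin/gelsolin fragmentation); contour is conserved
    at the severing instant.  A filament already short enough is
    returned unchanged as a single piece.
    """
    total = fil.contour_rest()
    if total <= piece_length:
        return [fil]
    n_pieces = int(math.ceil(total / piece_length - 1e-9))
    cuts = [piece_length * k for k in range(1, n_pieces)]
    cum = np.concatenate([[0.0], np.cumsum(fil.L0)])
    pieces = []
    start_s = 0.0
    start_pt = fil.x[0].copy()
    start_seg = 0
    for cut in cuts + [total]:
        nodes = [start_pt]
        rests = []
        k = start_seg
        s = start_s
        while cum[k + 1] < cut - 1e-9:
            rests.append(cum[k + 1] - s)
            nodes.append(fil.x[k + 1].copy())
            s = cum[k + 1]
            k += 1
        # interpolated cut point inside segment k
        frac = (cut - cum[k]) / fil.L0[k]
        cut_pt = fil.x[k] + frac * (fil.x[k + 1] - fil.x[k])
        rests.append(cut - s)
        nodes.append(cut_pt if cut < total - 1e-9 else fil.x[-1].copy())
        pieces.append(ActinFilament(
            fid=-1, x=np.asarray(nodes), L0=np.asarray(rests),
            state=GROWTH, capped=fil.capped, mother=None,
            adhesion=None, pattern=fil.pattern))
        start_s = cut
        start_pt = cut_pt
        start_seg = k
    # the piece containing the original pointed end keeps the lineage
    pieces[0].mother = fil.mother
    pieces[-1].adhesion = fil.adhesion
    pieces[-1].state = fil.state if fil.state in (ADHESION, CAPPED) \
        else GROWTH
    return pieces
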