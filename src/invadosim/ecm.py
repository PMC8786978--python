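"""Discrete collagen fiber network, integrin adhesions, degradation.

The matrix is a random assembly of straight collagen type-1 fibers
(diameter 41 nm) clipped to a box, discretized into ~0.5-um line
elements and welded into junctions where fibers pass close to one
another.  Fiber elements carry stretch and bend elasticity (same
functional form as the actin filaments, with collagen parameters);
degraded elements exert no force and accept no bonds.  Integrin
clusters on the invadopodial membrane form focal complexes with nearby
fiber nodes whose bond number follows Bell slip-bond kinetics.

A simulated volumetric stretch test measures the network's bulk
modulus; with the default pore size (3.0 um) and the calibrated
collagen modulus it reports ~2.6 kPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.special import erf

from .params import EcmParams, AdhesionParams, KBT

__all__ = [
    "EcmFiberNetwork", "FocalComplex", "generate_network", "fiber_forces",
    "fiber_energy", "bond_on_rate", "bond_off_rate", "bond_kinetics_step",
    "focal_complex_force", "volume_exclusion_forces", "degrade_segments",
    "bulk_modulus_stretch_test", "measure_pore_size",
]


@dataclass
class EcmFiberNetwork:
    nodes: np.ndarray            # (N, 3) nm
    segments: np.ndarray         # (S, 2) node indices
    rest_length: np.ndarray      # (S,)
    fiber_id: np.ndarray         # (S,)
    intact: np.ndarray           # (S,) bool
    triples: np.ndarray          # (B, 3) consecutive nodes within a fiber
    triple_seg: np.ndarray       # (B, 2) the two segment rows of a triple
    box: np.ndarray              # (3,) nm
    params: EcmParams
    pore_size: float = 0.0       # measured, nm
    stiffness_scale: np.ndarray | None = None   # (S,) modulus factor
    rest_angle: np.ndarray | None = None        # (B,) as-built angles

    def __post_init__(self):
        if self.stiffness_scale is None:
            self.stiffness_scale = np.ones(len(self.segments))
        if self.rest_angle is None:
            self.rest_angle = np.zeros(len(self.triples))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def segment_midpoints(self) -> np.ndarray:
        return 0.5 * (self.nodes[self.segments[:, 0]]
                      + self.nodes[self.segments[:, 1]])

    def boundary_mask(self, margin: float = 500.0) -> np.ndarray:
        x = self.nodes
        lo = np.any(x < margin, axis=1)
        hi = np.any(x > self.box[None, :] - margin, axis=1)
        return lo | hi


@dataclass
class FocalComplex:
    """Integrin cluster bonding one CI node to a point on a fiber.

    The anchor is the closest point of the fiber segment at formation
    time, stored as (segment row, fractional position); reactions are
    lever-distributed onto the segment's two nodes.
    """

    ci_node: int
    seg: int
    frac: float = 0.0
    n_b: float = 0.0
    n_tot: int = 50

    def anchor(self, net: "EcmFiberNetwork") -> np.ndarray:
        i, j = net.segments[self.seg]
        return (1.0 - self.frac) * net.nodes[i] + self.frac * net.nodes[j]


# ------------------------------------------------------------- generator

def _sample_fiber(rng, box):
    """A random chord through the box: point + isotropic direction."""
    p = rng.random(3) * box
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    # clip the infinite line p + t v to the box
    t_lo, t_hi = -np.inf, np.inf
    for k in range(3):
        if abs(v[k]) < 1e-12:
            continue
        a, b = (0.0 - p[k]) / v[k], (box[k] - p[k]) / v[k]
        t_lo = max(t_lo, min(a, b))
        t_hi = min(t_hi, max(a, b))
    return p + t_lo * v, p + t_hi * v


def measure_pore_size(points: np.ndarray, box, grid_step: float = 1000.0,
                      fiber_radius: float = 20.5) -> float:
    """Mean nearest-void diameter: twice the mean distance from a regular
    grid of sample points to the nearest fiber surface."""
    tree = cKDTree(points)
    axes = [np.arange(grid_step / 2, box[k], grid_step) for k in range(3)]
    gx = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d, _ = tree.query(gx, workers=1)
    return 2.0 * float(np.mean(np.maximum(d - fiber_radius, 0.0)))


def generate_network(box, pore_size: float, fiber_diameter: float,
                     seed: int, params: EcmParams | None = None,
                     max_iter: int = 12) -> EcmFiberNetwork:
    """Random straight-fiber network matched to a target pore size.

    Fibers are random chords of the box discretized at ~0.5 um; the
    fiber count is iterated until the measured mean pore size is within
    2.5 % of the target (for Poisson lines the pore size scales as
    1/sqrt(length density), which makes the iteration a one-dimensional
    fixed point).  Nodes of different fibers closer than the weld radius
    are merged into crosslink junctions.  Deterministic under ``seed``.
    """
    params = params or EcmParams()
    box = np.asarray(box, dtype=float)
    if pore_size <= 0 or np.any(box <= 0):
        raise ValueError("pore size and box must be positive")
    if pore_size > 0.5 * box.min():
        raise ValueError("pore size must be well below the box dimensions")
    rng = np.random.default_rng(seed)
    vol = float(np.prod(box))
    mean_chord = float(np.mean(box))          # crude initial guess
    rho = 1.0 / pore_size**2                  # length density, nm^-2
    n_fib = max(4, int(round(rho * vol / mean_chord)))

    chords, measured = None, None
    best = None        # (error, chords, measured)
    for _ in range(max_iter):
        chords = [_sample_fiber(rng, box) for _ in range(n_fib)]
        pts = []
        for a, b in chords:
            L = np.linalg.norm(b - a)
            m = max(2, int(L // 250.0))
            s = np.linspace(0.0, 1.0, m)[:, None]
            pts.append(a + s * (b - a))
        measured = measure_pore_size(np.vstack(pts), box,
                                     fiber_radius=fiber_diameter / 2)
        err = abs(measured - pore_size)
        if best is None or err < best[0]:
            best = (err, chords, measured)
        if err <= 0.025 * pore_size:
            break
        scale = (measured / pore_size) ** 2
        n_new = int(round(n_fib * scale))
        n_fib = max(4, min(n_new, n_fib * 4))
    else:
        # one-fiber granularity can exceed the tight tolerance; keep
        # the closest draw when it is still comfortably within spec
        err, chords, measured = best
        if err > 0.05 * pore_size:
            raise RuntimeError(
                f"pore-size target {pore_size} nm unreachable: best "
                f"measured {measured:.0f} nm")

    # discretize into ~seg_length elements
    node_list, seg_list, fid_list, chain_list = [], [], [], []
    for fid, (a, b) in enumerate(chords):
        L = float(np.linalg.norm(b - a))
        m = max(1, int(round(L / params.seg_length)))
        s = np.linspace(0.0, 1.0, m + 1)[:, None]
        xs = a + s * (b - a)
        base = len(node_list)
        node_list.extend(xs)
        chain_list.append(list(range(base, base + m + 1)))
        for k in range(m):
            seg_list.append((base + k, base + k + 1))
            fid_list.append(fid)
    nodes = np.asarray(node_list)

    # weld nearby nodes of different fibers into shared junctions
    owner = np.concatenate([[i] * len(ch) for i, ch in
                            enumerate(chain_list)])
    tree = cKDTree(nodes)
    pairs = tree.query_pairs(params.weld_radius, output_type="ndarray")
    pairs = pairs[owner[pairs[:, 0]] != owner[pairs[:, 1]]]
    parent = np.arange(len(nodes))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    root = np.array([find(i) for i in range(len(nodes))])
    uniq, new_idx = np.unique(root, return_inverse=True)
    merged = np.zeros((len(uniq), 3))
    np.add.at(merged, new_idx, nodes)
    cnt = np.bincount(new_idx).astype(float)
    merged /= cnt[:, None]

    segs, fids = [], []
    for (i, j), fid in zip(seg_list, fid_list):
        a, b = new_idx[i], new_idx[j]
        if a != b:
            segs.append((a, b))
            fids.append(fid)
    # bridge remaining components with short crosslink fibers at their
    # closest approach (collagen gels are fully percolated; a line model
    # welded at finite resolution is not, so the residual links are made
    # explicit elements with the same fiber mechanics)
    n_all = len(merged)
    while True:
        adj = coo_matrix((np.ones(len(segs)),
                          (np.array(segs)[:, 0], np.array(segs)[:, 1])),
                         shape=(n_all, n_all))
        n_comp, labels = connected_components(adj, directed=False)
        if n_comp <= 1:
            break
        sizes = np.bincount(labels)
        main = int(np.argmax(sizes))
        main_idx = np.where(labels == main)[0]
        other_idx = np.where(labels != main)[0]
        tree_main = cKDTree(merged[main_idx])
        d, nn = tree_main.query(merged[other_idx], workers=1)
        k = int(np.argmin(d))
        a = int(other_idx[k])
        b = int(main_idx[nn[k]])
        segs.append((a, b))
        fids.append(n_fib + n_comp)
    segments = np.asarray(segs)
    fiber_id = np.asarray(fids)
    rest = np.linalg.norm(merged[segments[:, 1]]
                          - merged[segments[:, 0]], axis=1)

    # bending triples: consecutive segments of the same fiber
    triples, tsegs = [], []
    for fid in range(n_fib):
        rows = np.where(fiber_id == fid)[0]
        for r1, r2 in zip(rows[:-1], rows[1:]):
            if segments[r1, 1] == segments[r2, 0]:
                triples.append((segments[r1, 0], segments[r1, 1],
                                segments[r2, 1]))
                tsegs.append((r1, r2))
    net = EcmFiberNetwork(
        nodes=merged, segments=segments, rest_length=rest,
        fiber_id=fiber_id, intact=np.ones(len(segments), dtype=bool),
        triples=np.asarray(triples if triples else
                           np.empty((0, 3), dtype=int)),
        triple_seg=np.asarray(tsegs if tsegs else
                              np.empty((0, 2), dtype=int)),
        box=box, params=params, pore_size=measured)
    # welding kinks the chains: the as-built angles are stress-free
    if len(net.triples):
        a, b, c = (merged[net.triples[:, k]] for k in range(3))
        u = b - a
        v = c - b
        cth = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        net.rest_angle = np.arccos(np.clip(cth, -1 + 1e-12, 1 - 1e-12))

    n_comp, labels = connected_components(coo_matrix(
        (np.ones(len(segments)), (segments[:, 0], segments[:, 1])),
        shape=(len(merged), len(merged))), directed=False)
    giant = np.bincount(labels).max() / len(merged)
    if giant < 0.9:
        raise RuntimeError(
            f"generated network not connected (giant component "
            f"{giant:.0%}); increase the weld radius or fiber density")
    return net


def carve_cavity(net: EcmFiberNetwork, center, radius: float,
                 margin: float = 50.0) -> int:
    """Carve the initial cell volume out of the fiber network.

    Segments fully inside ``radius + margin`` of ``center`` are
    deleted; segments crossing the surface are clipped by projecting
    their inside node radially onto the sphere, so fiber ends rest
    directly against the membrane (the cell is embedded in the gel,
    not floating in a moat).  Clipped elements are re-zeroed (rest
    length/angle from the clipped geometry).  Returns the number of
    segments removed.
    """
    center = np.asarray(center, dtype=float)
    rcut = radius + margin
    d0 = np.linalg.norm(net.nodes[net.segments[:, 0]] - center, axis=1)
    d1 = np.linalg.norm(net.nodes[net.segments[:, 1]] - center, axis=1)
    keep = np.maximum(d0, d1) > rcut      # at least one node outside
    # project inside nodes of kept (crossing) segments onto the sphere
    inside_nodes = np.unique(np.concatenate([
        net.segments[keep & (d0 <= rcut), 0],
        net.segments[keep & (d1 <= rcut), 1]]))
    for n in inside_nodes:
        rel = net.nodes[n] - center
        r = np.linalg.norm(rel)
        if r < 1e-9:
            rel, r = np.array([0.0, 0.0, 1.0]), 1.0
        net.nodes[n] = center + rel / r * rcut
    if len(inside_nodes):
        moved = np.isin(net.segments[:, 0], inside_nodes) | \
            np.isin(net.segments[:, 1], inside_nodes)
        L = np.linalg.norm(net.nodes[net.segments[:, 1]]
                           - net.nodes[net.segments[:, 0]], axis=1)
        net.rest_length = np.where(moved, np.maximum(L, 1.0),
                                   net.rest_length)
        if len(net.triples):
            a, b, c = (net.nodes[net.triples[:, k]] for k in range(3))
            u, v = b - a, c - b
            cth = np.einsum("ij,ij->i", u, v) / np.maximum(
                np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1),
                1e-12)
            th = np.arccos(np.clip(cth, -1 + 1e-12, 1 - 1e-12))
            tmoved = np.isin(net.triples, inside_nodes).any(axis=1)
            net.rest_angle = np.where(tmoved, th, net.rest_angle)
    removed = int(np.count_nonzero(~keep))
    if removed == 0:
        return 0
    old_rows = np.where(keep)[0]
    row_map = {int(r): i for i, r in enumerate(old_rows)}
    net.segments = net.segments[keep]
    net.rest_length = net.rest_length[keep]
    net.fiber_id = net.fiber_id[keep]
    net.intact = net.intact[keep]
    net.stiffness_scale = net.stiffness_scale[keep]
    if len(net.triples):
        tkeep = np.array([a in row_map and b in row_map
                          for a, b in net.triple_seg])
        net.triples = net.triples[tkeep]
        net.rest_angle = net.rest_angle[tkeep]
        net.triple_seg = np.array(
            [[row_map[int(a)], row_map[int(b)]]
             for a, b in net.triple_seg[tkeep]], dtype=int) \
            if np.any(tkeep) else np.empty((0, 2), dtype=int)
    return removed


# ------------------------------------------------------------- mechanics

def fiber_energy(net: EcmFiberNetwork,
                 nodes: np.ndarray | None = None) -> float:
    """Stretch + bend elastic energy of the intact fibers, pN nm."""
    x = net.nodes if nodes is None else nodes
    p = net.params
    i, j = net.segments[:, 0], net.segments[:, 1]
    L = np.linalg.norm(x[j] - x[i], axis=1)
    kap = net.stiffness_scale * p.area * p.youngs / net.rest_length
    h = 0.5 * float(np.sum(np.where(net.intact,
                                    kap * (L - net.rest_length)**2, 0.0)))
    if len(net.triples):
        ok = net.intact[net.triple_seg[:, 0]] & \
            net.intact[net.triple_seg[:, 1]]
        a, b, c = (x[net.triples[:, k]] for k in range(3))
        u = b - a
        v = c - b
        lu = np.linalg.norm(u, axis=1)
        lv = np.linalg.norm(v, axis=1)
        cth = np.clip(np.einsum("ij,ij->i", u, v) / (lu * lv),
                      -1 + 1e-12, 1 - 1e-12)
        th = np.arccos(cth) - net.rest_angle
        L0b = net.rest_length[net.triple_seg[:, 0]]
        sc = net.stiffness_scale[net.triple_seg[:, 0]]
        h += 0.5 * p.bend_modulus * float(
            np.sum(np.where(ok, sc * th**2 / L0b, 0.0)))
    return h


def fiber_forces(net: EcmFiberNetwork,
                 nodes: np.ndarray | None = None) -> np.ndarray:
    """-dH/dx on every fiber node; degraded segments exert nothing."""
    x = net.nodes if nodes is None else nodes
    p = net.params
    f = np.zeros_like(x)
    i, j = net.segments[:, 0], net.segments[:, 1]
    d = x[j] - x[i]
    L = np.maximum(np.linalg.norm(d, axis=1), 1e-12)
    unit = d / L[:, None]
    kap = net.stiffness_scale * p.area * p.youngs / net.rest_length
    t = np.where(net.intact, kap * (L - net.rest_length), 0.0)[:, None] \
        * unit
    np.add.at(f, i, t)
    np.add.at(f, j, -t)
    if len(net.triples):
        ok = net.intact[net.triple_seg[:, 0]] & \
            net.intact[net.triple_seg[:, 1]]
        ia, ib, ic = (net.triples[:, k] for k in range(3))
        a, b, c = x[ia], x[ib], x[ic]
        u = b - a
        v = c - b
        lu = np.maximum(np.linalg.norm(u, axis=1), 1e-12)
        lv = np.maximum(np.linalg.norm(v, axis=1), 1e-12)
        uh = u / lu[:, None]
        vh = v / lv[:, None]
        cth = np.einsum("ij,ij->i", uh, vh)
        ccl = np.clip(cth, -1 + 1e-12, 1 - 1e-12)
        th = np.arccos(ccl) - net.rest_angle
        L0b = net.rest_length[net.triple_seg[:, 0]]
        sc = net.stiffness_scale[net.triple_seg[:, 0]]
        coef = np.where(ok, sc * p.bend_modulus * th
                        / (L0b * np.sqrt(1 - ccl**2)), 0.0)
        dca = -(vh - ccl[:, None] * uh) / lu[:, None]
        dcc = (uh - ccl[:, None] * vh) / lv[:, None]
        np.add.at(f, ia, coef[:, None] * dca)
        np.add.at(f, ib, coef[:, None] * (-dca - dcc))
        np.add.at(f, ic, coef[:, None] * dcc)
    return f


# -------------------------------------------------------- adhesion bonds

def bond_on_rate(L_b: float, params: AdhesionParams | None = None) -> float:
    """Gaussian-in-extension association rate with the confinement
    partition function Z0."""
    p = params or AdhesionParams()
    if L_b < 0:
        raise ValueError("bond length must be non-negative")
    ext = L_b - p.lam
    z0 = math.sqrt(math.pi * KBT / (2 * p.kappa_lr)) * (
        erf(ext * math.sqrt(p.kappa_lr / (2 * KBT)))
        + erf(p.lam * math.sqrt(p.kappa_lr / (2 * KBT))))
    z0 = max(z0, 1e-9)
    return p.k_on0 * (p.l_bind / z0) * math.exp(
        -p.kappa_lr * ext**2 / (2 * KBT))


def bond_off_rate(L_b: float, params: AdhesionParams | None = None) -> float:
    """Bell slip-bond dissociation, exponential in the bond force."""
    p = params or AdhesionParams()
    if L_b < 0:
        raise ValueError("bond length must be non-negative")
    return p.k_off0 * math.exp(p.kappa_lr * (L_b - p.lam) * p.x_b / KBT)


def bond_kinetics_step(fc: FocalComplex, L_b: float, dt: float,
                       params: AdhesionParams | None = None) -> float:
    """Advance dn/dt = k_on (n_tot - n) - k_off n by ``dt`` with the
    rates frozen at the current extension (exact exponential update, so
    the fixed-extension equilibrium n_tot k_on/(k_on+k_off) is the exact
    long-time limit)."""
    k_on = bond_on_rate(L_b, params)
    k_off = bond_off_rate(L_b, params)
    ktot = k_on + k_off
    n_eq = fc.n_tot * k_on / ktot if ktot > 0 else fc.n_b
    fc.n_b = n_eq + (fc.n_b - n_eq) * math.exp(-ktot * dt)
    fc.n_b = min(max(fc.n_b, 0.0), float(fc.n_tot))
    return fc.n_b


def focal_complex_force(fc: FocalComplex, ci_x: np.ndarray,
                        anchor_x: np.ndarray,
                        params: AdhesionParams | None = None):
    """F = n_b kappa_LR (L_b - lambda) toward the fiber anchor on the
    CI node; the exact opposite on the fiber (this reaction is what
    remodels and densifies the matrix)."""
    p = params or AdhesionParams()
    d = np.asarray(anchor_x) - np.asarray(ci_x)
    L = float(np.linalg.norm(d))
    if L < 1e-12:
        return np.zeros(3), np.zeros(3), L
    f = fc.n_b * p.kappa_lr * (L - p.lam) * d / L
    return f, -f, L


def point_segment_closest(p: np.ndarray, a: np.ndarray,
                          b: np.ndarray) -> tuple:
    """(fraction, distance) of the closest point on segment a-b to p."""
    d = b - a
    L2 = float(np.dot(d, d))
    t = 0.0 if L2 < 1e-18 else float(np.clip(np.dot(p - a, d) / L2, 0, 1))
    return t, float(np.linalg.norm(a + t * d - p))


# ---------------------------------------------------- exclusion & decay

def volume_exclusion_forces(surface_x: np.ndarray,
                            normals: np.ndarray,
                            points: np.ndarray,
                            kappa: float,
                            keep_outside: bool = True,
                            tree: cKDTree | None = None):
    """Penalty forces keeping ``points`` on one side of a closed surface.

    Each point is tested against its nearest surface node's outward
    normal: signed depth d = (point - node) . n.  With
    ``keep_outside=True`` points at d < 0 (inside) are pushed out along
    +n; with False, points at d > 0 are pushed back in.  Reactions act
    on the surface nodes; pairs are exactly equal and opposite.

    Returns ``(f_points, f_surface, contact_count)``.
    """
    f_pts = np.zeros_like(points)
    f_surf = np.zeros_like(surface_x)
    if len(points) == 0:
        return f_pts, f_surf, 0
    if tree is None:
        tree = cKDTree(surface_x)
    _, idx = tree.query(points, workers=1)
    n = normals[idx]
    depth = np.einsum("ij,ij->i", points - surface_x[idx], n)
    if keep_outside:
        mask = depth < 0.0
        mag = -depth
    else:
        mask = depth > 0.0
        mag = depth
    sign = 1.0 if keep_outside else -1.0
    f = sign * kappa * np.where(mask, mag, 0.0)[:, None] * n
    f_pts += f
    np.add.at(f_surf, idx, -f)
    return f_pts, f_surf, int(np.count_nonzero(mask))


def degrade_segments(net: EcmFiberNetwork, phi6_at, threshold: float,
                     phi6_init=1.0,
                     positions: np.ndarray | None = None) -> int:
    """Irreversibly degrade segments whose local ECM concentration has
    fallen below ``threshold`` x its initial value.

    ``phi6_at`` maps an (M, 3) array of positions to phi6 values;
    ``phi6_init`` is a scalar or per-segment baseline (segments whose
    baseline is already ~0 sit outside the initialized collagen field
    and are never degraded by it).  ``positions`` overrides the probe
    points — the chemical state belongs to the material, so callers
    probe at the segments' original midpoints rather than wherever
    mechanics has since pushed them.
    Returns the number of segments newly degraded.
    """
    live = np.where(net.intact)[0]
    if len(live) == 0:
        return 0
    pts = (net.segment_midpoints() if positions is None
           else np.asarray(positions))
    phi6 = np.asarray(phi6_at(pts[live]))
    base = np.broadcast_to(np.asarray(phi6_init, dtype=float),
                           net.intact.shape)[live]
    gone = live[(base > 0.05) & (phi6 < threshold * base)]
    net.intact[gone] = False
    return len(gone)


# ------------------------------------------------------- stretch test

def _relax(net: EcmFiberNetwork, x0: np.ndarray, free: np.ndarray,
           tol: float = 1e-3, maxiter: int = 2000) -> np.ndarray:
    """Minimize elastic energy over the free nodes (L-BFGS)."""
    x = x0.copy()
    fidx = np.where(free)[0]
    if len(fidx) == 0:
        return x

    def fun(z):
        x[fidx] = z.reshape(-1, 3)
        e = fiber_energy(net, x)
        g = -fiber_forces(net, x)[fidx]
        return e, g.ravel()

    res = optimize.minimize(fun, x[fidx].ravel(), jac=True,
                            method="L-BFGS-B",
                            options={"maxiter": maxiter, "gtol": tol})
    x[fidx] = res.x.reshape(-1, 3)
    return x


def bulk_modulus_stretch_test(net: EcmFiberNetwork,
                              strains=(0.01, 0.02, 0.03),
                              margin: float = 500.0) -> dict:
    """Simulated volumetric stretch test.

    Boundary nodes are displaced affinely to volumetric strains
    eps_v = dV/V, interior nodes relax to elastic equilibrium, and the
    pressure p = dU/dV is read off from the relaxed energies by central
    differences; the bulk modulus is the slope of the linear fit of p
    against eps_v.  Returns the modulus in Pa together with the
    stress-strain record.
    """
    strains = np.asarray(strains, dtype=float)
    if np.any(strains <= 0):
        raise ValueError("strains must be positive")
    eps = np.concatenate([[0.0], strains])
    boundary = net.boundary_mask(margin)
    free = ~boundary
    center = net.box / 2.0
    v0 = float(np.prod(net.box))
    energies = []
    x = net.nodes.copy()
    for e in eps:
        lam = (1.0 + e) ** (1.0 / 3.0)
        xa = center + (net.nodes - center) * lam
        x[boundary] = xa[boundary]
        x = _relax(net, x, free)
        energies.append(fiber_energy(net, x))
    energies = np.asarray(energies)
    # pressure at midpoints (pN/nm^2), then K = dp/deps_v
    p_mid = np.diff(energies) / (np.diff(eps) * v0)
    e_mid = 0.5 * (eps[:-1] + eps[1:])
    slope = np.polyfit(e_mid, p_mid, 1)[0] if len(e_mid) > 1 else \
        p_mid[0] / e_mid[0]
    return {
        "bulk_modulus_pa": float(slope) * 1e6,     # pN/nm^2 -> Pa
        "strain": e_mid, "stress_pa": p_mid * 1e6,
        "energies": energies,
    }
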