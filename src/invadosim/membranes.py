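"""Five coupled viscoelastic cell surfaces.

The cell is bounded by three concentric triangulated spheres — the
invadopodial membrane (CI), the force-transduction layer (CT) 50 nm below
it, and the actin cortex layer (CC) another 50 nm below — and the nucleus
by two more (perinuclear actin layer PAL and nuclear membrane surface
NMS).  All five share one icosphere topology; paired layers are coupled
node-by-node with vertical springs.  Elastic forces are exact gradients of
line-stretch and area-strain energies, so every force routine here has a
finite-difference oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .params import MembraneParams, ActinParams

__all__ = [
    "SurfaceMesh", "LayeredCellMesh", "build_spherical_cell",
    "elastic_forces", "membrane_elastic_force", "elastic_energy",
    "transduce_and_cortex_forces", "nuclear_link_force", "node_normals",
]

_EPS_AREA = 1e-9  # nm^2; below this a triangle is degenerate


def _cross(a, b):
    """Row-wise cross product without numpy's moveaxis overhead."""
    out = np.empty(np.broadcast(a, b).shape)
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out



@dataclass
class SurfaceMesh:
    """One closed triangulated surface with line and area elasticity."""

    layer: str
    x: np.ndarray                 # (N, 3) nm
    triangles: np.ndarray         # (T, 3) int
    edges: np.ndarray             # (E, 2) int, i < j
    rest_length: np.ndarray       # (E,) nm
    rest_area: np.ndarray         # (T,) nm^2
    kappa_edge: np.ndarray        # (E,) pN/nm
    kappa_area: float             # pN/nm^2 (0 disables the area term)
    c_pair: float = 0.5           # pN s/nm, edge dashpot
    c_ground: float = 1.0         # pN s/nm, ground drag

    @property
    def n_nodes(self) -> int:
        return len(self.x)

    def edge_lengths(self) -> np.ndarray:
        d = self.x[self.edges[:, 1]] - self.x[self.edges[:, 0]]
        return np.linalg.norm(d, axis=1)

    def triangle_areas(self) -> np.ndarray:
        a, b, c = (self.x[self.triangles[:, k]] for k in range(3))
        n = _cross(b - a, c - a)
        return 0.5 * np.linalg.norm(n, axis=1)

    def validate(self) -> None:
        if np.any(self.rest_length <= 0) or np.any(self.rest_area <= 0):
            raise ValueError("rest lengths and areas must be positive")


def _edges_of(triangles: np.ndarray) -> np.ndarray:
    e = np.vstack([triangles[:, [0, 1]], triangles[:, [1, 2]],
                   triangles[:, [2, 0]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


def _make_surface(layer: str, verts: np.ndarray, tris: np.ndarray,
                  kappa_line, kappa_area: float, c_pair: float,
                  c_ground: float) -> SurfaceMesh:
    edges = _edges_of(tris)
    d = verts[edges[:, 1]] - verts[edges[:, 0]]
    rest_length = np.linalg.norm(d, axis=1)
    a, b, c = (verts[tris[:, k]] for k in range(3))
    rest_area = 0.5 * np.linalg.norm(_cross(b - a, c - a), axis=1)
    if np.isscalar(kappa_line):
        kappa_edge = np.full(len(edges), float(kappa_line))
    else:
        kappa_edge = np.asarray(kappa_line, dtype=float)
    return SurfaceMesh(layer, verts.astype(float).copy(), tris.copy(),
                       edges, rest_length, rest_area, kappa_edge,
                       kappa_area, c_pair, c_ground)


@dataclass
class LayeredCellMesh:
    """The five surfaces plus their vertical inter-layer couplings."""

    ci: SurfaceMesh
    ct: SurfaceMesh
    cc: SurfaceMesh
    pal: SurfaceMesh
    nms: SurfaceMesh
    kappa_t: float               # CI<->CT, pN/nm
    kappa_c: float               # CT<->CC, pN/nm
    kappa_nuc: float             # PAL<->NMS (reuses kappa_c by default)
    link_rest: float             # nm
    c_link: float = 0.5

    def layers(self):
        return {"CI": self.ci, "CT": self.ct, "CC": self.cc,
                "PAL": self.pal, "NMS": self.nms}


def build_spherical_cell(radius_cell: float, radius_nucleus: float,
                         subdivision_level: int,
                         params: MembraneParams | None = None,
                         actin: ActinParams | None = None,
                         center=(0.0, 0.0, 0.0)) -> LayeredCellMesh:
    """Five concentric icosphere layers at rest (zero elastic force).

    ``radius_cell``/``radius_nucleus`` in nm.  CI sits at the cell radius
    with CT and CC offset inward by the 50-nm inter-layer rest length;
    PAL wraps the nucleus 50 nm above NMS.  Raises for a subdivision too
    coarse to resolve the layer offsets or for radii that make the
    cortex and the perinuclear layer overlap.
    """
    params = params or MembraneParams()
    actin = actin or ActinParams()
    if radius_cell <= 0 or radius_nucleus <= 0:
        raise ValueError("radii must be positive")
    if subdivision_level < 1:
        raise ValueError("subdivision level < 1 is too coarse to offset "
                         "the layered surfaces without self-intersection")
    g = params.link_rest
    if radius_cell - 2 * g <= radius_nucleus + g:
        raise ValueError("nucleus too large: cortex would intersect the "
                         "perinuclear layer")

    ico = trimesh.creation.icosphere(subdivisions=subdivision_level,
                                     radius=1.0)
    unit = np.asarray(ico.vertices)
    tris = np.asarray(ico.faces)
    center = np.asarray(center, dtype=float)

    def at(r):
        return unit * r + center

    ci = _make_surface("CI", at(radius_cell), tris, params.kappa_line_ci,
                       params.kappa_area_ci, params.c_pair, params.c_ground)
    ct = _make_surface("CT", at(radius_cell - g), tris,
                       params.kappa_line_ct, 0.0, params.c_pair,
                       params.c_ground)
    # cortex line stiffness per edge: A_A E_A / L0
    cc_verts = at(radius_cell - 2 * g)
    cc_edges = _edges_of(tris)
    cc_L0 = np.linalg.norm(cc_verts[cc_edges[:, 1]]
                           - cc_verts[cc_edges[:, 0]], axis=1)
    cc = _make_surface("CC", cc_verts, tris,
                       actin.area * actin.youngs / cc_L0, 0.0,
                       params.c_pair, params.c_ground)
    pal = _make_surface("PAL", at(radius_nucleus + g), tris,
                        params.kappa_line_nuc, params.kappa_area_nuc,
                        params.c_pair, params.c_ground)
    nms = _make_surface("NMS", at(radius_nucleus), tris,
                        params.kappa_line_nuc, params.kappa_area_nuc,
                        params.c_pair, params.c_ground)
    return LayeredCellMesh(ci, ct, cc, pal, nms, params.kappa_t,
                           params.kappa_c, params.kappa_c, g,
                           params.c_link)


# ---------------------------------------------------------------- energies

def elastic_energy(mesh: SurfaceMesh) -> float:
    """H_L + H_A: line stretch plus area strain energy, pN nm."""
    dL = mesh.edge_lengths() - mesh.rest_length
    h = 0.5 * float(np.sum(mesh.kappa_edge * dL * dL))
    if mesh.kappa_area:
        dA = mesh.triangle_areas() - mesh.rest_area
        h += 0.5 * mesh.kappa_area * float(np.sum(dA * dA / mesh.rest_area))
    return h


def elastic_forces(mesh: SurfaceMesh) -> np.ndarray:
    """-dH/dx at every node: stretched edges pull, compressed push."""
    f = np.zeros_like(mesh.x)
    i, j = mesh.edges[:, 0], mesh.edges[:, 1]
    d = mesh.x[j] - mesh.x[i]
    L = np.linalg.norm(d, axis=1)
    if np.any(L <= 0):
        raise ValueError("zero-length edge")
    unit = d / L[:, None]
    t = (mesh.kappa_edge * (L - mesh.rest_length))[:, None] * unit
    np.add.at(f, i, t)
    np.add.at(f, j, -t)
    if mesh.kappa_area:
        ia, ib, ic = (mesh.triangles[:, k] for k in range(3))
        a, b, c = mesh.x[ia], mesh.x[ib], mesh.x[ic]
        n = _cross(b - a, c - a)
        nn = np.linalg.norm(n, axis=1)
        if np.any(nn < _EPS_AREA):
            raise ValueError("degenerate (zero-area) triangle")
        nhat = n / nn[:, None]
        area = 0.5 * nn
        g = (mesh.kappa_area * (area - mesh.rest_area) / mesh.rest_area)
        np.add.at(f, ia, -g[:, None] * 0.5 * _cross(nhat, c - b))
        np.add.at(f, ib, -g[:, None] * 0.5 * _cross(nhat, a - c))
        np.add.at(f, ic, -g[:, None] * 0.5 * _cross(nhat, b - a))
    return f


def membrane_elastic_force(mesh: SurfaceMesh, node: int) -> np.ndarray:
    """Elastic force vector (pN) at one node."""
    if not 0 <= node < mesh.n_nodes:
        raise IndexError("node out of range")
    return elastic_forces(mesh)[node]


# ------------------------------------------------------- layer couplings

def _pair_spring(xa: np.ndarray, xb: np.ndarray, kappa: float,
                 rest: float):
    """Vertical node-pair springs; returns (force on a, force on b)."""
    d = xb - xa
    L = np.linalg.norm(d, axis=1)
    unit = d / np.maximum(L, 1e-12)[:, None]
    fa = (kappa * (L - rest))[:, None] * unit
    return fa, -fa


def transduce_and_cortex_forces(cell: LayeredCellMesh):
    """Inter-layer transduction and cortex coupling forces.

    Returns ``(f_ci, f_ct, f_cc)``: the CI<->CT spring force (kappa_T,
    rest 50 nm) acting equal-and-opposite on paired nodes, and the
    CT<->CC spring (kappa_C) likewise; each array is the coupling force
    only (in-plane layer elasticity comes from :func:`elastic_forces`).
    """
    f_it, f_ti = _pair_spring(cell.ci.x, cell.ct.x, cell.kappa_t,
                              cell.link_rest)
    f_tc, f_ct_ = _pair_spring(cell.ct.x, cell.cc.x, cell.kappa_c,
                               cell.link_rest)
    return f_it, f_ti + f_tc, f_ct_


def nuclear_membrane_link_forces(cell: LayeredCellMesh):
    """PAL<->NMS vertical springs (form identical to CI<->CT)."""
    return _pair_spring(cell.pal.x, cell.nms.x, cell.kappa_nuc,
                        cell.link_rest)


def nuclear_link_force(mesh: SurfaceMesh, node: int,
                       attach_point: np.ndarray, kappa: float,
                       rest: float) -> np.ndarray:
    """Crosslinker (filamin / alpha-actinin) spring pulling a nuclear
    node toward its actin-side attachment; the energy gradient of
    1/2 kappa (L - L0)^2."""
    d = np.asarray(attach_point, dtype=float) - mesh.x[node]
    L = float(np.linalg.norm(d))
    if L < 1e-12:
        return np.zeros(3)
    return kappa * (L - rest) * d / L


def node_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Outward unit normals (area-weighted average of face normals)."""
    ia, ib, ic = (mesh.triangles[:, k] for k in range(3))
    n = _cross(mesh.x[ib] - mesh.x[ia], mesh.x[ic] - mesh.x[ia])
    acc = np.zeros_like(mesh.x)
    for idx in (ia, ib, ic):
        np.add.at(acc, idx, n)
    norm = np.linalg.norm(acc, axis=1)
    return acc / np.maximum(norm, 1e-12)[:, None]
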