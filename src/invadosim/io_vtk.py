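"""Plain-text snapshot writers: legacy ASCII VTK and CSV.

Surfaces go out as VTK polydata (points, triangles, per-node force
magnitude), filaments and fibers as VTK polyline sets, RD fields as VTK
structured points; tabular snapshots (filament nodes, linker
populations, events) as CSV.
"""

from __future__ import annotations

import csv

import numpy as np


def _header(fh, title):
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\n")


def write_surface_vtk(path, mesh, scalars=None,
                      scalar_name="force_magnitude") -> None:
    """Triangulated surface as legacy VTK polydata."""
    with open(path, "w") as fh:
        _header(fh, f"invadosim surface {mesh.layer}")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(mesh.x)} float\n")
        for p in mesh.x:
            fh.write(f"{p[0]:.3f} {p[1]:.3f} {p[2]:.3f}\n")
        t = mesh.triangles
        fh.write(f"POLYGONS {len(t)} {4 * len(t)}\n")
        for a, b, c in t:
            fh.write(f"3 {a} {b} {c}\n")
        if scalars is not None:
            fh.write(f"POINT_DATA {len(mesh.x)}\n")
            fh.write(f"SCALARS {scalar_name} float 1\n")
            fh.write("LOOKUP_TABLE default\n")
            for s in scalars:
                fh.write(f"{s:.5f}\n")


def write_polylines_vtk(path, polylines, title="invadosim lines") -> None:
    """A set of polylines (list of (n_i, 3) arrays) as VTK polydata."""
    pts = np.vstack(polylines) if polylines else np.empty((0, 3))
    with open(path, "w") as fh:
        _header(fh, title)
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        for p in pts:
            fh.write(f"{p[0]:.3f} {p[1]:.3f} {p[2]:.3f}\n")
        size = sum(len(pl) + 1 for pl in polylines)
        fh.write(f"LINES {len(polylines)} {size}\n")
        base = 0
        for pl in polylines:
            idx = " ".join(str(base + k) for k in range(len(pl)))
            fh.write(f"{len(pl)} {idx}\n")
            base += len(pl)


def write_field_vtk(path, field, species="phi1") -> None:
    """One RD species as VTK structured points."""
    from .rd import SPECIES
    c = field.conc[SPECIES.index(species)]
    nx, ny, nz = c.shape
    with open(path, "w") as fh:
        _header(fh, f"invadosim field {species}")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        o = field.origin
        fh.write(f"ORIGIN {o[0]:.1f} {o[1]:.1f} {o[2]:.1f}\n")
        h = field.h
        fh.write(f"SPACING {h:.1f} {h:.1f} {h:.1f}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write(f"SCALARS {species} float 1\n")
        fh.write("LOOKUP_TABLE default\n")
        for v in c.transpose(2, 1, 0).ravel():
            fh.write(f"{v:.6g}\n")


def write_filaments_csv(path, filaments) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filament", "node", "x", "y", "z", "state"])
        for fid, f in sorted(filaments.items()):
            for j, p in enumerate(f.x):
                w.writerow([fid, j, f"{p[0]:.3f}", f"{p[1]:.3f}",
                            f"{p[2]:.3f}", f.state])


def write_linkers_csv(path, links) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["kind", "fid_a", "seg_a", "alpha", "fid_b", "seg_b",
                    "beta", "tension_pN"])
        for lk_ in links:
            w.writerow([lk_.kind, lk_.a.fid, lk_.a.seg,
                        f"{lk_.a.frac:.4f}", lk_.b.fid, lk_.b.seg,
                        f"{lk_.b.frac:.4f}", f"{lk_.tension:.4f}"])


def write_fibers_csv(path, net) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["segment", "fiber", "n0", "n1", "x0", "y0", "z0",
                    "x1", "y1", "z1", "intact"])
        for s, (i, j) in enumerate(net.segments):
            a, b = net.nodes[i], net.nodes[j]
            w.writerow([s, int(net.fiber_id[s]), i, j,
                        f"{a[0]:.1f}", f"{a[1]:.1f}", f"{a[2]:.1f}",
                        f"{b[0]:.1f}", f"{b[1]:.1f}", f"{b[2]:.1f}",
                        int(net.intact[s])])


def write_events_csv(path, events) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t", "event", "detail"])
        for t, name, detail in events:
            w.writerow([f"{t:.4f}", name, detail])
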