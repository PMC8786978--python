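"""Six-species MMP reaction-diffusion field on a regular 3D grid.

Species (dimensionless normalized concentrations):

* phi1 — MMP-2, diffusible, activated from the ternary complex
* phi2 — TIMP-2, diffusible, secreted at invadopodium tips
* phi3 — MT1-MMP, membrane-bound (no diffusion), secreted at tips
* phi4 — ternary complex MT1-MMP:TIMP-2:proMMP-2 (no diffusion)
* phi5 — ligand / free collagen molecules, diffusible, released by
  degradation
* phi6 — intact ECM, consumed by MMP-2 (monotone non-increasing)

Explicit FTCS stepping with 7-point-stencil diffusion, zero-flux box
boundaries, and mass-action reactions exactly as the model's rate table
writes them.  Secretion is confined to tip-source grid nodes and to the
protrusive phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import RdParams

SPECIES = ("phi1", "phi2", "phi3", "phi4", "phi5", "phi6")


@dataclass
class RdField:
    origin: np.ndarray               # (3,) nm
    shape: tuple                     # (nx, ny, nz)
    params: RdParams
    conc: np.ndarray = None          # (6, nx, ny, nz)

    def __post_init__(self):
        if self.conc is None:
            self.conc = np.zeros((6,) + tuple(self.shape))

    @property
    def h(self) -> float:
        return self.params.h

    def species(self, name: str) -> np.ndarray:
        return self.conc[SPECIES.index(name)]

    def total_mass(self, name: str) -> float:
        return float(self.species(name).sum())

    def stability_limit(self) -> float:
        dmax = max(self.params.d_phi1, self.params.d_phi2,
                   self.params.d_phi5)
        if dmax <= 0:
            return np.inf
        return self.h**2 / (6.0 * dmax)


def make_field(box, params: RdParams | None = None,
               origin=(0.0, 0.0, 0.0)) -> RdField:
    params = params or RdParams()
    box = np.asarray(box, dtype=float)
    shape = tuple(max(2, int(round(b / params.h))) for b in box)
    return RdField(np.asarray(origin, dtype=float), shape, params)


def _laplacian(c: np.ndarray, h: float) -> np.ndarray:
    """7-point Laplacian with zero-flux (mirror) boundaries."""
    out = np.zeros_like(c)
    for ax in range(3):
        plus = np.concatenate([np.take(c, range(1, c.shape[ax]), axis=ax),
                               np.take(c, [-1], axis=ax)], axis=ax)
        minus = np.concatenate([np.take(c, [0], axis=ax),
                                np.take(c, range(0, c.shape[ax] - 1),
                                        axis=ax)], axis=ax)
        out += plus + minus - 2.0 * c
    return out / h**2


def rd_step(field: RdField, dt: float, phase: str,
            tip_nodes: np.ndarray | None,
            mt1mmp_on: bool = True) -> None:
    """One explicit step of all six equations.

    Secretion (alpha_phi2, alpha_phi3) acts only on the tip-source
    nodes and only while ``phase == 'protrusive'`` (and not knocked
    out); with ligand feedback enabled the secretion rate scales with
    the local ligand concentration phi5.  Faults if ``dt`` exceeds the
    diffusive stability bound h^2 / (6 max D).
    """
    p = field.params
    if dt > field.stability_limit() + 1e-15:
        raise ValueError(
            f"dt = {dt} exceeds the stability limit "
            f"{field.stability_limit():.3e} s")
    c1, c2, c3, c4, c5, c6 = field.conc
    r12 = p.k_on_12 * c1 * c2
    r23 = p.k_on_23 * c2 * c3
    r34 = p.k_on_34 * c3 * c4
    r4 = p.k_off_4 * c4
    deg = p.k_deg_6 * c1 * c6

    d1 = p.d_phi1 * _laplacian(c1, p.h) - r12 + r34 - p.k_decay_1 * c1
    d2 = p.d_phi2 * _laplacian(c2, p.h) - r12 - r23 + r4
    d3 = -r23 + r4 - p.k_decay_3 * c3
    d4 = r23 + r34 - r4
    d5 = p.d_phi5 * _laplacian(c5, p.h) - p.k_decay_5 * c5 + deg
    d6 = -deg

    if (phase == "protrusive" and mt1mmp_on and tip_nodes is not None
            and len(tip_nodes)):
        ijk = tuple(tip_nodes.T)
        gain2 = p.alpha_phi2
        gain3 = p.alpha_phi3
        if p.ligand_feedback:
            lig = c5[ijk]
            d2[ijk] += gain2 * lig
            d3[ijk] += gain3 * lig
        else:
            d2[ijk] += gain2
            d3[ijk] += gain3

    field.conc[0] = np.maximum(c1 + dt * d1, 0.0)
    field.conc[1] = np.maximum(c2 + dt * d2, 0.0)
    field.conc[2] = np.maximum(c3 + dt * d3, 0.0)
    field.conc[3] = np.maximum(c4 + dt * d4, 0.0)
    field.conc[4] = np.maximum(c5 + dt * d5, 0.0)
    field.conc[5] = np.minimum(c6, np.maximum(c6 + dt * d6, 0.0))


def tip_source_nodes(field: RdField, ci_x: np.ndarray,
                     polarity: np.ndarray,
                     cap_fraction: float | None = None) -> np.ndarray:
    """Grid nodes within one spacing of the CI tip cap.

    The cap is the ``cap_fraction`` of membrane nodes with the largest
    projection on the polarity axis (MT1-MMP accumulates at the tips of
    invadopodia).  Returns an (M, 3) integer index array.
    """
    p = field.params
    if cap_fraction is None:
        cap_fraction = p.tip_cap_fraction
    if cap_fraction <= 0 or len(ci_x) == 0:
        return np.empty((0, 3), dtype=int)
    proj = ci_x @ np.asarray(polarity, dtype=float)
    n_cap = max(1, int(round(cap_fraction * len(ci_x))))
    cap = ci_x[np.argsort(proj)[-n_cap:]]
    idx = np.round((cap - field.origin) / p.h - 0.5).astype(int)
    out = set()
    rng3 = (-1, 0, 1)
    shape = field.shape
    for i, j, k in idx:
        for di in rng3:
            for dj in rng3:
                for dk in rng3:
                    a, b, c = i + di, j + dj, k + dk
                    if 0 <= a < shape[0] and 0 <= b < shape[1] \
                            and 0 <= c < shape[2]:
                        out.add((a, b, c))
    return np.asarray(sorted(out), dtype=int) if out else \
        np.empty((0, 3), dtype=int)


def sample_field(field: RdField, positions: np.ndarray,
                 species: str | None = None) -> np.ndarray:
    """Trilinear interpolation at arbitrary positions (nm).

    Out-of-box positions clamp to the boundary value.  Returns an
    (M, 6) array, or (M,) when a single species is requested.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    p = field.params
    g = (pos - field.origin) / p.h - 0.5     # cell-centered grid coords
    shape = np.asarray(field.shape)
    g = np.clip(g, 0.0, shape - 1.000001)
    i0 = np.floor(g).astype(int)
    f = g - i0
    i1 = np.minimum(i0 + 1, shape - 1)
    which = [SPECIES.index(species)] if species else range(6)
    out = np.zeros((len(pos), len(which)))
    for m, s in enumerate(which):
        c = field.conc[s]
        acc = np.zeros(len(pos))
        for dx in (0, 1):
            wx = (1 - f[:, 0]) if dx == 0 else f[:, 0]
            ix = i0[:, 0] if dx == 0 else i1[:, 0]
            for dy in (0, 1):
                wy = (1 - f[:, 1]) if dy == 0 else f[:, 1]
                iy = i0[:, 1] if dy == 0 else i1[:, 1]
                for dz in (0, 1):
                    wz = (1 - f[:, 2]) if dz == 0 else f[:, 2]
                    iz = i0[:, 2] if dz == 0 else i1[:, 2]
                    acc += wx * wy * wz * c[ix, iy, iz]
        out[:, m] = acc
    return out[:, 0] if species else out


def init_collagen(field: RdField, fiber_points: np.ndarray,
                  value: float = 1.0, ligand_too: bool = False) -> None:
    """Set phi6 (and optionally phi5) to ``value`` in every grid cell
    containing fiber material, zero elsewhere."""
    p = field.params
    idx = np.round((fiber_points - field.origin) / p.h - 0.5).astype(int)
    shape = np.asarray(field.shape)
    idx = np.clip(idx, 0, shape - 1)
    phi6 = np.zeros(field.shape)
    phi6[tuple(idx.T)] = value
    field.conc[5] = phi6
    if ligand_too:
        field.conc[4] = phi6.copy()
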