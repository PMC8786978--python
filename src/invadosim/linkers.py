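"""Actin crosslinkers and bipolar myosin minifilaments.

Fascin bundles near-parallel filaments in the invadopodium core, filamin
joins parallel-or-orthogonal filaments in the leading-edge cone (and can
tether filaments to the perinuclear actin layer), and alpha-actinin plus
bipolar myosin act on near-parallel perinuclear filaments during the
retractile phase only.  Every element is a linear spring attached at
fractional positions (alpha, beta) along two filament segments; myosin
endpoints additionally slide toward the barbed ends with the Hill
force-velocity law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import LinkerParams

KINDS = ("fascin", "filamin", "alpha_actinin", "myosin")


@dataclass
class Endpoint:
    fid: int                 # filament id, or -1 when bound to the PAL
    seg: int                 # segment index j (node j -> j+1)
    frac: float              # alpha in [0, 1]
    pal_node: int = -1       # PAL node index when fid == -1


@dataclass
class LinkerOrMotor:
    kind: str
    a: Endpoint
    b: Endpoint
    rest: float
    kappa: float
    birth: float = 0.0
    turnover: float = 60.0
    tension: float = 0.0     # |kappa (L - L0)| of the previous step
    stale: bool = False

    def active(self, phase: str) -> bool:
        """alpha-actinin and myosin engage only while retracting."""
        if self.stale:
            return False
        if self.kind in ("alpha_actinin", "myosin"):
            return phase == "retractile"
        return True


def binding_position(filaments: dict, ep: Endpoint,
                     pal_x: np.ndarray | None = None) -> np.ndarray:
    """Convex combination (1-a) x_j + a x_{j+1} on the host segment."""
    if ep.fid == -1:
        return pal_x[ep.pal_node]
    fil = filaments[ep.fid]
    j = ep.seg
    return (1.0 - ep.frac) * fil.x[j] + ep.frac * fil.x[j + 1]


def endpoint_alive(filaments: dict, ep: Endpoint,
                   n_pal: int | None = None) -> bool:
    if ep.fid == -1:
        return n_pal is None or 0 <= ep.pal_node < n_pal
    fil = filaments.get(ep.fid)
    return fil is not None and 0 <= ep.seg < fil.n_nodes - 1


def linker_force(link: LinkerOrMotor, filaments: dict,
                 pal_x: np.ndarray | None = None):
    """Spring force of one crosslinker/motor, lever-distributed.

    Returns ``(contributions, tension)`` where contributions is a list of
    ``(fid_or_-1, node_index, force_vector)``; the connector force is
    split onto the supporting segment nodes with weights (1-frac, frac),
    which is exactly the gradient of the spring energy with the
    fractional positions held fixed.  Action equals reaction across the
    two attachment structures.
    """
    xa = binding_position(filaments, link.a, pal_x)
    xb = binding_position(filaments, link.b, pal_x)
    d = xb - xa
    L = float(np.linalg.norm(d))
    if L < 1e-12:
        return [], 0.0
    unit = d / L
    fmag = link.kappa * (L - link.rest)
    f_on_a = fmag * unit             # pulls a toward b when stretched
    out = []
    for ep, fvec in ((link.a, f_on_a), (link.b, -f_on_a)):
        if ep.fid == -1:
            out.append((-1, ep.pal_node, fvec))
        else:
            out.append((ep.fid, ep.seg, (1.0 - ep.frac) * fvec))
            out.append((ep.fid, ep.seg + 1, ep.frac * fvec))
    return out, abs(fmag)


def linker_energy(link: LinkerOrMotor, filaments: dict,
                  pal_x: np.ndarray | None = None) -> float:
    xa = binding_position(filaments, link.a, pal_x)
    xb = binding_position(filaments, link.b, pal_x)
    L = float(np.linalg.norm(xb - xa))
    return 0.5 * link.kappa * (L - link.rest) ** 2


def hill_sliding_velocity(f_ext: float,
                          params: LinkerParams | None = None) -> float:
    """Hill force-velocity law of non-muscle myosin II.

    v = v0 (F_stall - F) / (F_stall + c_m F); 160 nm/s unloaded, zero at
    and above stall (the raw law turns negative there).
    """
    params = params or LinkerParams()
    if f_ext < 0:
        raise ValueError("load must be non-negative")
    if f_ext >= params.f_stall:
        return 0.0
    return (params.v_sliding0 * (params.f_stall - f_ext)
            / (params.f_stall + params.c_m * f_ext))


def advance_endpoint(ep: Endpoint, filaments: dict, v: float,
                     dt: float) -> None:
    """Slide one endpoint toward its filament's barbed end.

    alpha* = alpha + v dt / |segment|; walking past a segment's barbed
    node hops onto the next segment, clamping at the terminal barbed
    end.
    """
    if ep.fid == -1 or v <= 0:
        return
    fil = filaments[ep.fid]
    travel = v * dt
    while travel > 0:
        seg_len = float(np.linalg.norm(fil.x[ep.seg + 1] - fil.x[ep.seg]))
        if seg_len < 1e-12:
            break
        da = travel / seg_len
        if ep.frac + da <= 1.0:
            ep.frac += da
            return
        travel -= (1.0 - ep.frac) * seg_len
        if ep.seg + 1 >= fil.n_nodes - 1:
            ep.frac = 1.0          # clamped at the barbed end
            return
        ep.seg += 1
        ep.frac = 0.0


def advance_sliding(motor: LinkerOrMotor, filaments: dict,
                    dt: float, params: LinkerParams | None = None) -> float:
    """Hill-rate sliding of both myosin endpoints (simultaneous).

    The load is the motor tension sensed at the previous step.  Returns
    the velocity used.
    """
    params = params or LinkerParams()
    v = hill_sliding_velocity(motor.tension, params)
    advance_endpoint(motor.a, filaments, v, dt)
    advance_endpoint(motor.b, filaments, v, dt)
    return v


# -------------------------------------------------------------- placement

def _closest_frac(fil, seg: int, target: np.ndarray, rng,
                  jitter: float = 0.1) -> float:
    """Fraction along a segment closest to ``target``, jittered."""
    a, b = fil.x[seg], fil.x[seg + 1]
    d = b - a
    L2 = float(np.dot(d, d))
    t = 0.5 if L2 < 1e-18 else float(np.clip(
        np.dot(target - a, d) / L2, 0.0, 1.0))
    return float(np.clip(t + rng.uniform(-jitter, jitter), 0.0, 1.0))


def _mutual_angle_deg(d1: np.ndarray, d2: np.ndarray) -> float:
    c = abs(float(np.dot(d1, d2)))
    return math.degrees(math.acos(min(c, 1.0)))


def _pair_eligible(kind: str, f1, f2, params: LinkerParams) -> bool:
    ang = _mutual_angle_deg(f1.direction(), f2.direction())
    if kind in ("fascin", "alpha_actinin", "myosin"):
        return ang < params.parallel_max_deg
    lo, hi = params.ortho_band_deg
    return ang < params.parallel_max_deg or lo <= ang <= hi


def in_leading_edge(pos: np.ndarray, center: np.ndarray,
                    polarity: np.ndarray, cone_deg: float) -> bool:
    r = pos - center
    n = np.linalg.norm(r)
    if n < 1e-9:
        return True
    c = float(np.dot(r / n, polarity))
    return c > math.cos(math.radians(cone_deg))


def place_and_turnover(filaments: dict, links: list, phase: str, t: float,
                       dt: float, rng, center: np.ndarray,
                       polarity: np.ndarray,
                       params: LinkerParams | None = None,
                       pal_x: np.ndarray | None = None,
                       ko: set | None = None,
                       max_per_kind: int = 200) -> list:
    """One binding/turnover control step (nominally every second).

    Eligible pairs bind with probability p_bind; links older than their
    turnover time are removed (rebinding happens on later calls).
    Knockout flags in ``ko`` suppress the corresponding species entirely.
    Returns the updated link list.
    """
    params = params or LinkerParams()
    ko = ko or set()
    links = [lk for lk in links
             if not lk.stale and (t - lk.birth) <= lk.turnover
             and endpoint_alive(filaments, lk.a,
                                None if pal_x is None else len(pal_x))
             and endpoint_alive(filaments, lk.b,
                                None if pal_x is None else len(pal_x))]
    fils = list(filaments.values())
    counts = {k: sum(1 for lk in links if lk.kind == k) for k in KINDS}
    mids = {f.fid: 0.5 * (f.x[0] + f.x[-1]) for f in fils}
    p = params.p_bind * dt
    for i in range(len(fils)):
        for j in range(i + 1, len(fils)):
            f1, f2 = fils[i], fils[j]
            # closest approach between the two polylines (node-to-node)
            d2 = np.sum((f1.x[:, None, :] - f2.x[None, :, :])**2, axis=2)
            j1, j2 = np.unravel_index(int(np.argmin(d2)), d2.shape)
            gap = math.sqrt(float(d2[j1, j2]))
            for kind in KINDS:
                if kind in ko or counts[kind] >= max_per_kind:
                    continue
                if kind in ("alpha_actinin", "myosin"):
                    if phase != "retractile":
                        continue
                    if not (f1.pattern == "perinuclear"
                            or f2.pattern == "perinuclear"):
                        continue
                else:
                    le = in_leading_edge(mids[f1.fid], center, polarity,
                                         params.cone_deg) and \
                         in_leading_edge(mids[f2.fid], center, polarity,
                                         params.cone_deg)
                    if not le:
                        continue
                rest = params.rest[kind]
                if gap > rest * (1.0 + params.distance_slack):
                    continue
                if not _pair_eligible(kind, f1, f2, params):
                    continue
                if rng.random() >= p:
                    continue
                # bind at the closest approach (the protein's reach),
                # with a little positional jitter along each segment
                s1 = min(j1, f1.n_nodes - 2)
                s2 = min(j2, f2.n_nodes - 2)
                a1 = _closest_frac(f1, s1, f2.x[j2], rng)
                a2 = _closest_frac(f2, s2, f1.x[j1], rng)
                links.append(LinkerOrMotor(
                    kind=kind,
                    a=Endpoint(f1.fid, s1, a1),
                    b=Endpoint(f2.fid, s2, a2),
                    rest=rest, kappa=params.kappa, birth=t,
                    turnover=params.turnover))
                counts[kind] += 1
    # alpha-actinin tether: perinuclear filament <-> nearest PAL node
    # (the nuclear crosslinking force acts through filamin or
    # alpha-actinin; this is how retractile contraction reaches the
    # nucleus)
    if pal_x is not None and "alpha_actinin" not in ko \
            and phase == "retractile":
        for f in fils:
            if f.pattern != "perinuclear":
                continue
            if counts["alpha_actinin"] >= max_per_kind:
                break
            rest = params.rest["alpha_actinin"]
            d = np.linalg.norm(pal_x - 0.5 * (f.x[0] + f.x[-1]), axis=1)
            k = int(np.argmin(d))
            if d[k] < rest * (1 + params.distance_slack) * 3 \
                    and rng.random() < p:
                seg = min(f.n_nodes // 2, f.n_nodes - 2)
                links.append(LinkerOrMotor(
                    "alpha_actinin",
                    Endpoint(f.fid, seg,
                             _closest_frac(f, seg, pal_x[k], rng)),
                    Endpoint(-1, 0, 0.0, pal_node=k),
                    rest=rest, kappa=params.kappa, birth=t,
                    turnover=params.turnover))
                counts["alpha_actinin"] += 1

    # filamin tether: leading-edge filament <-> nearest PAL node
    if pal_x is not None and "filamin" not in ko:
        for f in fils:
            if counts["filamin"] >= max_per_kind:
                break
            if not in_leading_edge(mids[f.fid], center, polarity,
                                   params.cone_deg):
                continue
            d = np.linalg.norm(pal_x - f.x[0], axis=1)
            k = int(np.argmin(d))
            rest = params.rest["filamin"]
            if d[k] < rest * (1 + params.distance_slack) \
                    and rng.random() < p:
                links.append(LinkerOrMotor(
                    "filamin", Endpoint(f.fid, 0, 0.0),
                    Endpoint(-1, 0, 0.0, pal_node=k),
                    rest=rest, kappa=params.kappa, birth=t,
                    turnover=params.turnover))
                counts["filamin"] += 1
    return links
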